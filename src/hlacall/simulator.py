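"""Synthetic barcoded-amplicon read simulator with a known truth table.

Emulates the data regime of multiplexed class I HLA amplicon sequencing:
per sample, six amplicons (exons 2 and 3 of three loci), reads of ~350 bp
drawn from one of the two chromosomes, ~1% substitution error, coverage of
tens to ~150 reads per exon, with optional allelic coverage imbalance
(the dominant real-world failure mode, producing false homozygotes) and
cross-sample contamination (which leaves more than two haplotypes visible
at a locus).  Homopolymer-specific indel errors of pyrosequencing are not
simulated; the model is substitution-only throughout.

The toy allele dictionary contains, by construction, one pair of alleles
identical over the sequenced exons (the nomenclature-ambiguity case, which
only a frequency prior can separate) and one pair differing at a single
diagnostic column.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pysam

from .allele_db import (
    AlleleDictionary,
    AlleleName,
    AlleleSequence,
    FrequencyTable,
)
from .demux import BarcodeManifest, PrimerManifest, RawRead, write_fastq
from .seqcodes import N_BASES, decode, encode, revcomp

DEFAULT_POPULATION = "sim_pop"


@dataclass
class ToyDictionarySpec:
    """Shape of the generated allele dictionary.

    Defaults emulate the sequenced class I exons: three loci, exons 2 and 3
    of roughly 270 bp, a polymorphic-column density in the range seen at
    HLA class I, and 20 alleles per locus.  The exon-identical "twin"
    allele receives a small fixed frequency (real exon-2/3-identical
    alleles are rare variants of a common allele); all other frequencies
    are a symmetric Dirichlet draw.
    """

    loci: tuple[str, ...] = ("A", "B", "C")
    n_alleles: int = 20
    exon_lengths: dict[str, int] = field(
        default_factory=lambda: {"exon2": 270, "exon3": 276}
    )
    polymorphic_density: float = 0.08
    alt_prob: float = 0.3
    #: fraction of polymorphic columns carrying a second alternative base
    #: (class I alignments are not purely biallelic)
    triallelic_fraction: float = 0.25
    ambiguous_pair: bool = True
    ambiguous_freq: float = 1e-3
    single_diff_pair: bool = True
    frequency_alpha: float = 0.5


def make_toy_dictionary(
    spec: ToyDictionarySpec | None = None,
    seed: int = 0,
    population: str = DEFAULT_POPULATION,
) -> tuple[AlleleDictionary, FrequencyTable]:
    """Generate a random toy allele dictionary plus matching frequencies.

    Per locus: a random base sequence per exon, polymorphic columns at the
    configured density with one alternative base each, and allele variant
    patterns drawn independently per column.  Allele names follow HLA
    nomenclature; the constructed ambiguous twin and single-column pairs
    share the 2-digit group of their partner allele, as their real
    counterparts do.  Frequencies are normalized to sum to 1 per locus.
    """
    spec = spec or ToyDictionarySpec()
    if spec.n_alleles < 2:
        raise ValueError("need at least 2 alleles per locus")
    rng = np.random.default_rng(seed)
    total_len = sum(spec.exon_lengths.values())
    n_poly_total = int(round(spec.polymorphic_density * total_len))
    if n_poly_total > total_len:
        raise ValueError("polymorphic density implies more columns than exist")

    n_special = int(spec.ambiguous_pair) + int(spec.single_diff_pair)
    n_core = spec.n_alleles - n_special
    if n_core < 2:
        raise ValueError("spec leaves fewer than 2 non-constructed alleles")

    alleles_by_locus: dict[str, list[AlleleSequence]] = {}
    entries: dict[tuple[str, str], float] = {}
    for locus in spec.loci:
        exon_ids = sorted(spec.exon_lengths)
        base = {
            e: rng.integers(0, N_BASES, size=spec.exon_lengths[e]).astype(np.uint8)
            for e in exon_ids
        }
        bounds = {}
        off = 0
        for e in exon_ids:
            bounds[e] = (off, off + spec.exon_lengths[e])
            off += spec.exon_lengths[e]
        ref = np.concatenate([base[e] for e in exon_ids])
        poly_cols = np.sort(
            rng.choice(total_len, size=n_poly_total, replace=False)
        )
        shift1 = rng.integers(1, N_BASES, size=n_poly_total)
        alt1 = (ref[poly_cols] + shift1) % N_BASES
        # second alternative at a subset of columns, distinct from ref and alt1
        shift2 = ((shift1 - 1 + rng.integers(1, 3, size=n_poly_total)) % 3) + 1
        alt2 = (ref[poly_cols] + shift2) % N_BASES
        has_alt2 = rng.random(n_poly_total) < spec.triallelic_fraction
        alt2[~has_alt2] = alt1[~has_alt2]
        alts = np.stack([ref[poly_cols], alt1, alt2])  # state -> base per column

        # distinct variant patterns (state 0=ref, 1=alt1, 2=alt2) for core alleles
        if n_core > 2 ** max(n_poly_total, 0):
            raise ValueError(
                f"cannot build {n_core} distinct alleles from "
                f"{n_poly_total} polymorphic columns"
            )
        patterns: list[np.ndarray] = []
        seen: set[bytes] = set()
        while len(patterns) < n_core:
            is_alt = rng.random(n_poly_total) < spec.alt_prob
            which = 1 + (has_alt2 & (rng.random(n_poly_total) < 0.5)).astype(np.uint8)
            pat = np.where(is_alt, which, 0).astype(np.uint8)
            key = pat.tobytes()
            if key in seen:
                continue
            seen.add(key)
            patterns.append(pat)

        names = [AlleleName(locus, f"{i + 1:02d}", "01") for i in range(n_core)]
        if spec.single_diff_pair:
            # partner of core allele 0, differing at exactly one column
            for flip in rng.permutation(n_poly_total):
                pat = patterns[0].copy()
                pat[flip] = 0 if pat[flip] != 0 else 1
                if pat.tobytes() not in seen:
                    break
            seen.add(pat.tobytes())
            patterns.append(pat)
            names.append(AlleleName(locus, names[0].field1, "02"))
        if spec.ambiguous_pair:
            # exon-identical twin of core allele 1
            patterns.append(patterns[1].copy())
            names.append(AlleleName(locus, names[1].field1, "02"))

        seqs = []
        for name, pat in zip(names, patterns):
            codes = ref.copy()
            codes[poly_cols] = alts[pat, np.arange(n_poly_total)]
            seqs.append(
                AlleleSequence(
                    name,
                    {e: decode(codes[bounds[e][0]:bounds[e][1]]) for e in exon_ids},
                )
            )
        alleles_by_locus[locus] = seqs

        freqs = rng.gamma(spec.frequency_alpha, size=len(names))
        freqs /= freqs.sum()
        if spec.ambiguous_pair:
            twin = len(names) - 1
            freqs[twin] = 0.0
            freqs *= (1.0 - spec.ambiguous_freq) / freqs.sum()
            freqs[twin] = spec.ambiguous_freq
        for name, f in zip(names, freqs):
            entries[(population, name.render())] = float(f)

    return AlleleDictionary(alleles_by_locus), FrequencyTable(entries)


@dataclass
class SimConfig:
    """Study conditions for one simulated sequencing pool.

    ``mean_coverage`` is the Poisson mean number of reads per sample per
    exon.  ``imbalance`` r biases haplotype sampling to r/(1+r) for the
    first allele of the pair (r=1 is balanced).  ``contamination`` replaces
    that fraction of a sample's reads with reads from another sample's
    chromosomes (keeping the recipient's barcode).  Base qualities are the
    Phred equivalent of ``error_rate``; ``quality_jitter`` > 0 switches to
    per-base qualities jittered around that value, with errors applied at
    each base's own quality.
    """

    n_samples: int = 95
    mean_coverage: float = 50.0
    error_rate: float = 0.01
    read_length_mean: float = 364.0
    read_length_sd: float = 124.0
    min_read_length: int = 40
    imbalance: float = 1.0
    contamination: float = 0.0
    reverse_fraction: float = 0.0
    quality_jitter: float = 0.0
    barcode_length: int = 8
    primer_length: int = 20
    seed: int = 0


@dataclass
class SimulatedDataset:
    """Reads plus full ground truth for one simulated pool."""

    reads: list[RawRead]
    truth_pairs: pd.DataFrame  # sample, locus, allele1, allele2, major_allele
    read_truth: pd.DataFrame
    barcodes: BarcodeManifest
    primers: PrimerManifest
    dictionary: AlleleDictionary
    frequencies: FrequencyTable
    population: str
    config: SimConfig

    @property
    def samples(self) -> list[str]:
        return sorted(self.barcodes.barcodes)

    def write_outputs(self, outdir: str | Path, sam: bool = False) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.dictionary.save(outdir / "dictionary")
        self.frequencies.to_tsv(outdir / "frequencies.tsv")
        self.barcodes.to_tsv(outdir / "barcodes.tsv")
        self.primers.to_tsv(outdir / "primers.tsv")
        write_fastq(self.reads, outdir / "reads.fastq")
        self.truth_pairs.to_csv(outdir / "truth_pairs.tsv", sep="\t", index=False)
        self.read_truth.to_csv(outdir / "read_truth.tsv", sep="\t", index=False)
        if sam:
            write_truth_sam(self, outdir / "reads.sam")


def _random_kmers(rng: np.random.Generator, n: int, k: int) -> list[str]:
    if n > 4 ** k:
        raise ValueError(f"cannot draw {n} distinct {k}-mers")
    ints = rng.choice(4 ** k, size=n, replace=False)
    out = []
    for v in ints:
        chars = []
        for _ in range(k):
            chars.append("ACGT"[v % 4])
            v //= 4
        out.append("".join(chars))
    return out


def _make_primers(
    rng: np.random.Generator, dictionary: AlleleDictionary, length: int
) -> PrimerManifest:
    targets = [
        (locus, exon)
        for locus in dictionary.loci
        for exon in sorted(dictionary.exon_bounds(locus))
    ]
    while True:
        seqs = _random_kmers(rng, 2 * len(targets), length)
        # primers must stay distinguishable under the demux mismatch tolerance
        ok = all(
            sum(a != b for a, b in zip(seqs[i], seqs[j])) > 4
            for i in range(len(seqs))
            for j in range(i + 1, len(seqs))
        )
        if ok:
            break
    primers = {}
    for idx, (locus, exon) in enumerate(targets):
        primers[(locus, exon, "F")] = seqs[2 * idx]
        primers[(locus, exon, "R")] = seqs[2 * idx + 1]
    return PrimerManifest(primers)


def _phred(error_rate: float) -> int:
    if error_rate <= 0:
        return 40
    return int(np.clip(round(-10.0 * math.log10(error_rate)), 2, 40))


def simulate_reads(
    dictionary: AlleleDictionary,
    frequencies: FrequencyTable,
    config: SimConfig | None = None,
    truth_pairs: pd.DataFrame | None = None,
    population: str = DEFAULT_POPULATION,
) -> SimulatedDataset:
    """Generate a barcoded amplicon pool with per-read ground truth.

    True allele pairs are drawn i.i.d. from the frequency table unless an
    explicit ``truth_pairs`` frame (sample, locus, allele1, allele2) is
    supplied.  The same seed yields byte-identical FASTQ and truth tables.
    """
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed)
    samples = [f"S{i + 1:03d}" for i in range(config.n_samples)]
    barcodes = BarcodeManifest(
        dict(zip(samples, _random_kmers(rng, config.n_samples, config.barcode_length)))
    )
    primers = _make_primers(rng, dictionary, config.primer_length)

    # true pairs per sample/locus
    pair_of: dict[tuple[str, str], tuple[str, str]] = {}
    if truth_pairs is not None:
        for r in truth_pairs.itertuples():
            pair_of[(r.sample, r.locus)] = (r.allele1, r.allele2)
    freq_by_locus: dict[str, tuple[list[str], np.ndarray]] = {}
    for locus in dictionary.loci:
        names = [a.render() for a in dictionary.alleles(locus)]
        p = np.array([frequencies.get(population, n, 0.0) for n in names])
        if p.sum() <= 0:
            p = np.ones(len(names))
        freq_by_locus[locus] = (names, p / p.sum())
    truth_rows = []
    for sample in samples:
        for locus in dictionary.loci:
            if (sample, locus) not in pair_of:
                names, p = freq_by_locus[locus]
                picks = rng.choice(len(names), size=2, p=p)
                pair_of[(sample, locus)] = (names[picks[0]], names[picks[1]])
            a1, a2 = pair_of[(sample, locus)]
            truth_rows.append(
                {"sample": sample, "locus": locus, "allele1": a1, "allele2": a2,
                 "major_allele": a1}
            )

    # haplotype sequences per sample/locus/exon (ungapped in the toy regime)
    def hap_codes(locus: str, allele: str, exon: str) -> np.ndarray:
        s, t = dictionary.exon_bounds(locus)[exon]
        codes = dictionary.allele_codes(locus, allele)[s:t]
        if (codes >= N_BASES).any():
            raise ValueError(
                f"allele {allele} has gaps/unknowns in {exon}; "
                "the simulator is substitution-only"
            )
        return codes

    # one contaminating individual per sample, as in a pipetting cross-over
    donor_of: dict[str, str] = {}
    if config.contamination > 0 and len(samples) > 1:
        for sample in samples:
            others = [s for s in samples if s != sample]
            donor_of[sample] = others[int(rng.integers(len(others)))]

    p_major = config.imbalance / (1.0 + config.imbalance)
    q_base = _phred(config.error_rate)
    reads: list[RawRead] = []
    read_rows = []
    for sample in samples:
        bc_codes = encode(barcodes.barcodes[sample])
        for locus in dictionary.loci:
            for exon in sorted(dictionary.exon_bounds(locus)):
                exon_len = (
                    dictionary.exon_bounds(locus)[exon][1]
                    - dictionary.exon_bounds(locus)[exon][0]
                )
                n_reads = rng.poisson(config.mean_coverage)
                primer_f = encode(primers.primers[(locus, exon, "F")])
                primer_r = encode(primers.primers[(locus, exon, "R")])
                for serial in range(n_reads):
                    source = sample
                    if sample in donor_of and rng.random() < config.contamination:
                        source = donor_of[sample]
                        hap_idx = int(rng.random() < 0.5)
                    else:
                        hap_idx = 0 if rng.random() < p_major else 1
                    allele = pair_of[(source, locus)][hap_idx]
                    hap = hap_codes(locus, allele, exon)

                    length = int(
                        np.clip(
                            round(rng.normal(config.read_length_mean,
                                             config.read_length_sd)),
                            config.min_read_length,
                            exon_len,
                        )
                    )
                    start = int(rng.integers(0, exon_len - length + 1))
                    insert = hap[start:start + length].copy()
                    reverse = (
                        config.reverse_fraction > 0
                        and rng.random() < config.reverse_fraction
                    )
                    if reverse:
                        insert = encode(revcomp(decode(insert)))
                        primer = primer_r
                    else:
                        primer = primer_f
                    codes = np.concatenate([bc_codes, primer, insert])

                    if config.quality_jitter > 0:
                        quals = np.clip(
                            np.round(
                                rng.normal(q_base, config.quality_jitter,
                                           size=len(codes))
                            ),
                            2, 40,
                        ).astype(np.int16)
                        e_per_base = 10.0 ** (-quals / 10.0)
                        err = rng.random(len(codes)) < e_per_base
                    else:
                        quals = np.full(len(codes), q_base, dtype=np.int16)
                        err = (
                            rng.random(len(codes)) < config.error_rate
                            if config.error_rate > 0
                            else np.zeros(len(codes), dtype=bool)
                        )
                    if err.any():
                        shift = rng.integers(1, N_BASES, size=int(err.sum()))
                        codes[err] = (codes[err] + shift) % N_BASES

                    read_id = f"{sample}:{locus}:{exon}:{serial:06d}"
                    reads.append(RawRead(read_id, decode(codes), quals))
                    read_rows.append(
                        {
                            "read_id": read_id,
                            "sample": sample,
                            "locus": locus,
                            "exon": exon,
                            "source_sample": source,
                            "haplotype": hap_idx,
                            "allele": allele,
                            "start": start,
                            "length": length,
                            "strand": "-" if reverse else "+",
                            "contaminated": source != sample,
                            "prefix_length": len(bc_codes) + len(primer),
                        }
                    )

    truth_pairs_df = pd.DataFrame(
        truth_rows, columns=["sample", "locus", "allele1", "allele2", "major_allele"]
    )
    read_truth = pd.DataFrame(
        read_rows,
        columns=[
            "read_id", "sample", "locus", "exon", "source_sample", "haplotype",
            "allele", "start", "length", "strand", "contaminated", "prefix_length",
        ],
    )
    return SimulatedDataset(
        reads=reads,
        truth_pairs=truth_pairs_df,
        read_truth=read_truth,
        barcodes=barcodes,
        primers=primers,
        dictionary=dictionary,
        frequencies=frequencies,
        population=population,
        config=config,
    )


def write_truth_sam(dataset: SimulatedDataset, path: str | Path) -> None:
    """Write the simulated reads at their true placements as SAM records.

    Only the biological insert is written (barcode and primer trimmed);
    reference names are ``LOCUS|EXON`` matching the dictionary export, so
    the file round-trips through alignment ingest.
    """
    d = dataset.dictionary
    sq = []
    ref_id = {}
    for locus in d.loci:
        for exon, (s, t) in sorted(d.exon_bounds(locus).items()):
            ref_id[(locus, exon)] = len(sq)
            sq.append({"SN": f"{locus}|{exon}", "LN": t - s})
    header = {"HD": {"VN": "1.6", "SO": "unknown"}, "SQ": sq}
    reads_by_id = {r.id: r for r in dataset.reads}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for row in dataset.read_truth.itertuples():
            raw = reads_by_id[row.read_id]
            insert = raw.bases[row.prefix_length:]
            quals = raw.qualities[row.prefix_length:]
            if row.strand == "-":
                insert = revcomp(insert)
                quals = quals[::-1]
            rec = pysam.AlignedSegment()
            rec.query_name = row.read_id
            rec.query_sequence = insert
            rec.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(q + 33) for q in quals)
            )
            rec.reference_id = ref_id[(row.locus, row.exon)]
            rec.reference_start = int(row.start)
            rec.cigarstring = f"{len(insert)}M"
            rec.mapping_quality = 60
            rec.flag = 16 if row.strand == "-" else 0
            out.write(rec)
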