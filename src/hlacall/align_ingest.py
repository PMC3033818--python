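"""Per-locus aligned reads: SAM ingest, plumbing aligner, filters, coverage.

Reads enter the caller in master-alignment column space, either by ingesting
an external SAM/BAM alignment (reference names ``LOCUS|EXON`` as exported by
:meth:`AlleleDictionary.reference_fasta`) or through the built-in gapless
local aligner used as test plumbing.  A homology filter then removes reads
that disagree with every known allele at most of the polymorphic columns
they cover — the signature of a mislocalized read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
import pysam

from .allele_db import AlleleDictionary
from .demux import RawRead
from .seqcodes import N_BASES, encode, revcomp

#: bases below this Phred quality are treated as unknown everywhere
DEFAULT_QUALITY_FLOOR = 5

#: fraction of read positions that must match the consensus to accept an
#: alignment, and minimum per-read SNP homology to the closest allele
ALIGN_SCORE_FRACTION = 0.75
HOMOLOGY_THRESHOLD = 0.75


@dataclass
class AssignedRead:
    """A read placed in a locus's master-alignment column space."""

    sample: str
    locus: str
    exon: str
    start: int  # 0-based global column of the first aligned base
    bases: str
    qualities: np.ndarray
    strand: str = "+"
    id: str = ""
    _codes: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.qualities = np.asarray(self.qualities, dtype=np.int16)
        if len(self.bases) != len(self.qualities):
            raise ValueError("bases/qualities length mismatch")

    @property
    def codes(self) -> np.ndarray:
        if self._codes is None:
            self._codes = encode(self.bases)
        return self._codes

    @property
    def end(self) -> int:
        """Exclusive end column."""
        return self.start + len(self.bases)

    def known_mask(self, quality_floor: int = DEFAULT_QUALITY_FLOOR) -> np.ndarray:
        """True where the base is callable: A/C/G/T and quality >= floor."""
        return (self.codes < N_BASES) & (self.qualities >= quality_floor)


@dataclass
class IngestStats:
    mapped: int = 0
    skipped_unmapped: int = 0
    skipped_secondary: int = 0
    skipped_indel: int = 0


def ingest_alignments(
    path: str | Path,
    dictionary: AlleleDictionary,
    sample_of: Callable[[pysam.AlignedSegment], str] | None = None,
) -> tuple[list[AssignedRead], IngestStats]:
    """Ingest a SAM/BAM file into master-alignment space.

    Reference names must be ``LOCUS|EXON``.  Soft-clipped ends are removed;
    unmapped and secondary/supplementary records are skipped and counted, as
    are records whose CIGAR contains indels (the model is substitution-only).
    By default the sample id is the read-name prefix before the first ``:``;
    pass ``sample_of`` to override (e.g. to use read groups).
    """
    if sample_of is None:
        sample_of = lambda rec: rec.query_name.split(":", 1)[0]
    reads: list[AssignedRead] = []
    stats = IngestStats()
    with pysam.AlignmentFile(str(path), check_sq=False) as af:
        for rec in af:
            if rec.is_unmapped:
                stats.skipped_unmapped += 1
                continue
            if rec.is_secondary or rec.is_supplementary:
                stats.skipped_secondary += 1
                continue
            ref = rec.reference_name
            locus, _, exon = ref.partition("|")
            try:
                bounds = dictionary.exon_bounds(locus)
            except KeyError:
                raise ValueError(f"unknown reference name {ref!r} in {path}") from None
            if not exon or exon not in bounds:
                raise ValueError(f"unknown reference name {ref!r} in {path}")
            ops = {op for op, _ in rec.cigartuples or ()}
            if ops & {1, 2, 3}:  # I, D, N
                stats.skipped_indel += 1
                continue
            seq = rec.query_alignment_sequence  # soft clips removed
            quals = rec.query_alignment_qualities
            if seq is None or quals is None:
                stats.skipped_unmapped += 1
                continue
            offset = bounds[exon][0]
            reads.append(
                AssignedRead(
                    sample=sample_of(rec),
                    locus=locus,
                    exon=exon,
                    start=offset + rec.reference_start,
                    bases=seq.upper(),
                    qualities=np.asarray(quals, dtype=np.int16),
                    strand="-" if rec.is_reverse else "+",
                    id=rec.query_name,
                )
            )
            stats.mapped += 1
    return reads, stats


def plumbing_align(
    read: RawRead,
    locus: str,
    dictionary: AlleleDictionary,
    sample: str = "",
    exon: str | None = None,
    strand: str = "+",
    score_fraction: float = ALIGN_SCORE_FRACTION,
) -> AssignedRead | None:
    """Gapless local placement of a read against the locus consensus.

    Scores every offset with match +1 / mismatch -1 and keeps the best;
    returns None when the best score is below ``score_fraction`` of the
    read length.  Reverse-strand reads are reverse-complemented first so
    stored bases are always in alignment orientation.  This is deliberately
    minimal plumbing standing in for an external aligner.
    """
    bases = revcomp(read.bases) if strand == "-" else read.bases
    quals = read.qualities[::-1] if strand == "-" else read.qualities
    try:
        codes = encode(bases)
    except Exception:
        return None
    n = len(codes)
    if n == 0:
        return None
    exons = [exon] if exon is not None else sorted(dictionary.exon_bounds(locus))
    consensus = dictionary.consensus(locus)
    best_score = -n - 1
    best_place: tuple[str, int] | None = None
    for ex in exons:
        s, t = dictionary.exon_bounds(locus)[ex]
        ref = consensus[s:t]
        if n > len(ref):
            continue
        windows = np.lib.stride_tricks.sliding_window_view(ref, n)
        matches = (windows == codes).sum(axis=1)
        scores = 2 * matches - n
        k = int(scores.argmax())
        if scores[k] > best_score:
            best_score = int(scores[k])
            best_place = (ex, s + k)
    if best_place is None or best_score < score_fraction * n:
        return None
    ex, start = best_place
    return AssignedRead(
        sample=sample, locus=locus, exon=ex, start=start,
        bases=bases, qualities=quals, strand=strand, id=read.id,
    )


def misalignment_filter(
    reads: Sequence[AssignedRead],
    dictionary: AlleleDictionary,
    threshold: float = HOMOLOGY_THRESHOLD,
    quality_floor: int = DEFAULT_QUALITY_FLOOR,
) -> tuple[list[AssignedRead], int]:
    """Remove reads with < ``threshold`` SNP homology to the closest allele.

    For each read, over the polymorphic columns it covers with a callable
    base, SNP homology is the maximum over dictionary alleles of the
    fraction of those columns where the read matches the allele.  Reads
    covering fewer than two such columns cannot meaningfully fail a 75%
    test and are always kept.
    """
    kept: list[AssignedRead] = []
    removed = 0
    poly_cache: dict[str, np.ndarray] = {}
    for read in reads:
        poly = poly_cache.get(read.locus)
        if poly is None:
            poly = dictionary.polymorphic_columns(read.locus)
            poly_cache[read.locus] = poly
        if snp_homology(read, dictionary, poly, quality_floor) >= threshold:
            kept.append(read)
        else:
            removed += 1
    return kept, removed


def snp_homology(
    read: AssignedRead,
    dictionary: AlleleDictionary,
    poly: np.ndarray | None = None,
    quality_floor: int = DEFAULT_QUALITY_FLOOR,
) -> float:
    """Best agreement fraction with any allele over covered polymorphic columns.

    Returns 1.0 when the read covers fewer than two callable polymorphic
    columns (vacuously homologous).
    """
    if poly is None:
        poly = dictionary.polymorphic_columns(read.locus)
    cols = poly[(poly >= read.start) & (poly < read.end)]
    if cols.size == 0:
        return 1.0
    rel = cols - read.start
    known = read.known_mask(quality_floor)[rel]
    cols = cols[known]
    if cols.size < 2:
        return 1.0
    read_bases = read.codes[cols - read.start]
    allele_bases = dictionary.codes(read.locus)[:, cols]
    agree = (allele_bases == read_bases[None, :]).mean(axis=1)
    return float(agree.max())


@dataclass
class CoverageSummary:
    """Per (sample, locus) column-depth vectors and per-exon mean depths."""

    vectors: dict[tuple[str, str], np.ndarray]
    exon_means: dict[tuple[str, str, str], float]

    def mean(self, sample: str, locus: str, exon: str) -> float:
        return self.exon_means.get((sample, locus, exon), 0.0)

    def vector(self, sample: str, locus: str) -> np.ndarray:
        return self.vectors[(sample, locus)]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"sample": s, "locus": l, "exon": e, "mean_depth": d,
             "covered": d > 0}
            for (s, l, e), d in sorted(self.exon_means.items())
        ]
        return pd.DataFrame(
            rows, columns=["sample", "locus", "exon", "mean_depth", "covered"]
        )


def depth_of_coverage(
    reads: Iterable[AssignedRead],
    dictionary: AlleleDictionary,
    samples: Iterable[str] | None = None,
) -> CoverageSummary:
    """Column depth per (sample, locus) and mean depth per exon.

    ``samples`` optionally forces rows (with zero depth) for sample/locus
    combinations that received no reads, so uncovered exons are reported.
    """
    vectors: dict[tuple[str, str], np.ndarray] = {}
    if samples is not None:
        for s in samples:
            for locus in dictionary.loci:
                vectors[(s, locus)] = np.zeros(
                    dictionary.locus_length(locus), dtype=np.int64
                )
    for read in reads:
        key = (read.sample, read.locus)
        vec = vectors.get(key)
        if vec is None:
            vec = np.zeros(dictionary.locus_length(read.locus), dtype=np.int64)
            vectors[key] = vec
        vec[read.start:read.end] += 1
    exon_means: dict[tuple[str, str, str], float] = {}
    for (sample, locus), vec in vectors.items():
        for exon, (s, t) in dictionary.exon_bounds(locus).items():
            exon_means[(sample, locus, exon)] = float(vec[s:t].mean())
    return CoverageSummary(vectors, exon_means)
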