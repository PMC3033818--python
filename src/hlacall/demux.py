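"""Barcode demultiplexing and primer-based locus assignment.

Pooled amplicon reads carry a sample-identifying molecular barcode (6-9 bp)
at the 5' end followed by a locus/exon-specific PCR primer (18-21 bp, IUPAC
degenerate codes allowed).  Demultiplexing matches the barcode exactly at
the read start (optionally tolerating one mismatch); locus assignment then
matches the remaining prefix against the primer panel.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

from .seqcodes import IUPAC, iupac_mismatches

BARCODE_LEN_RANGE = (6, 9)
PRIMER_LEN_RANGE = (18, 21)


class ManifestError(ValueError):
    """A barcode or primer manifest violates a structural constraint."""


@dataclass
class RawRead:
    """An unparsed read: id, bases and Phred-scale base qualities."""

    id: str
    bases: str
    qualities: np.ndarray

    def __post_init__(self) -> None:
        self.qualities = np.asarray(self.qualities, dtype=np.int16)
        if len(self.bases) != len(self.qualities):
            raise ValueError(
                f"read {self.id}: {len(self.bases)} bases vs "
                f"{len(self.qualities)} qualities"
            )

    def trimmed(self, n: int) -> "RawRead":
        return RawRead(self.id, self.bases[n:], self.qualities[n:])


class BarcodeManifest:
    """sample id -> barcode.  Barcodes must be unique and prefix-free.

    A barcode that is a prefix of another would make assignment at the read
    start ambiguous, so manifests containing one are rejected at load time.
    """

    def __init__(self, barcodes: Mapping[str, str]) -> None:
        self.barcodes = {s: b.upper() for s, b in barcodes.items()}
        seen: dict[str, str] = {}
        for sample, bc in self.barcodes.items():
            lo, hi = BARCODE_LEN_RANGE
            if not lo <= len(bc) <= hi:
                raise ManifestError(
                    f"barcode for {sample} has length {len(bc)}, expected {lo}-{hi}"
                )
            if set(bc) - set("ACGT"):
                raise ManifestError(f"barcode for {sample} has non-ACGT characters")
            if bc in seen:
                raise ManifestError(f"barcode {bc} shared by {seen[bc]} and {sample}")
            seen[bc] = sample
        codes = sorted(seen)
        for a, b in zip(codes[:-1], codes[1:]):
            if b.startswith(a):
                raise ManifestError(
                    f"barcode {a} ({seen[a]}) is a prefix of {b} ({seen[b]})"
                )
        self._by_length: dict[int, dict[str, str]] = {}
        for sample, bc in self.barcodes.items():
            self._by_length.setdefault(len(bc), {})[bc] = sample

    def match(self, bases: str, max_mismatch: int = 0) -> tuple[str, int] | None:
        """Match the read prefix; returns (sample, barcode length) or None."""
        for length in sorted(self._by_length):
            prefix = bases[:length].upper()
            sample = self._by_length[length].get(prefix)
            if sample is not None:
                return sample, length
        if max_mismatch > 0:
            best: tuple[str, int] | None = None
            n_best = 0
            for length, table in self._by_length.items():
                prefix = bases[:length].upper()
                for bc, sample in table.items():
                    d = sum(1 for x, y in zip(prefix, bc) if x != y) + max(
                        0, length - len(prefix)
                    )
                    if d <= max_mismatch:
                        best = (sample, length)
                        n_best += 1
            if n_best == 1:
                return best
        return None

    @classmethod
    def from_tsv(cls, path: str | Path) -> "BarcodeManifest":
        df = pd.read_csv(path, sep="\t", dtype=str)
        return cls(dict(zip(df["sample"], df["barcode"])))

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            sorted(self.barcodes.items()), columns=["sample", "barcode"]
        ).to_csv(path, sep="\t", index=False)


class PrimerManifest:
    """(locus, exon, orientation) -> primer sequence.

    Orientation is ``F`` (forward) or ``R`` (reverse); every (locus, exon)
    must provide both.  Primers may contain IUPAC degenerate codes.
    """

    def __init__(self, primers: Mapping[tuple[str, str, str], str]) -> None:
        self.primers = {k: v.upper() for k, v in primers.items()}
        pairs = {(loc, ex) for loc, ex, _ in self.primers}
        lo, hi = PRIMER_LEN_RANGE
        for (locus, exon, orient), seq in self.primers.items():
            if orient not in ("F", "R"):
                raise ManifestError(f"orientation must be F or R, got {orient!r}")
            if not lo <= len(seq) <= hi:
                raise ManifestError(
                    f"primer {locus}/{exon}/{orient} has length {len(seq)}, "
                    f"expected {lo}-{hi}"
                )
            if set(seq) - set(IUPAC):
                raise ManifestError(
                    f"primer {locus}/{exon}/{orient} has non-IUPAC characters"
                )
        for locus, exon in pairs:
            for orient in ("F", "R"):
                if (locus, exon, orient) not in self.primers:
                    raise ManifestError(f"missing {orient} primer for {locus}/{exon}")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PrimerManifest":
        df = pd.read_csv(path, sep="\t", dtype=str)
        return cls(
            {
                (r.locus, r.exon, r.orientation): r.primer
                for r in df.itertuples()
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            {"locus": loc, "exon": ex, "orientation": o, "primer": seq}
            for (loc, ex, o), seq in sorted(self.primers.items())
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


@dataclass
class DemuxReport:
    """Accounting of a demultiplexing pass; parsed + unassigned == total."""

    total: int = 0
    parsed: int = 0
    unassigned: int = 0
    per_sample: Counter = field(default_factory=Counter)

    @property
    def parse_rate(self) -> float:
        return self.parsed / self.total if self.total else 0.0

    def to_dict(self) -> dict:
        return {
            "total": self.total,
            "parsed": self.parsed,
            "unassigned": self.unassigned,
            "parse_rate": self.parse_rate,
            "per_sample": dict(sorted(self.per_sample.items())),
        }


def demultiplex(
    reads: Iterable[RawRead],
    barcodes: BarcodeManifest,
    max_mismatch: int = 0,
) -> tuple[dict[str, list[RawRead]], DemuxReport]:
    """Split pooled reads by molecular barcode.

    Each read is assigned to at most one sample; assigned reads have the
    barcode trimmed.  Reads shorter than any barcode, or whose prefix
    matches no barcode, go to the unassigned bin.
    """
    out: dict[str, list[RawRead]] = {s: [] for s in barcodes.barcodes}
    report = DemuxReport()
    for read in reads:
        report.total += 1
        hit = barcodes.match(read.bases, max_mismatch=max_mismatch)
        if hit is None:
            report.unassigned += 1
            continue
        sample, bc_len = hit
        out[sample].append(read.trimmed(bc_len))
        report.parsed += 1
        report.per_sample[sample] += 1
    return out, report


@dataclass
class LocusAssignment:
    locus: str
    exon: str
    strand: str  # '+' read begins with forward primer, '-' with reverse
    read: RawRead  # primer-trimmed


def assign_locus(
    read: RawRead,
    primers: PrimerManifest,
    max_mismatch: int = 1,
) -> LocusAssignment | None:
    """Assign a barcode-trimmed read to (locus, exon, strand) by its primer.

    The read prefix is compared against every primer allowing IUPAC
    degeneracy and up to ``max_mismatch`` mismatches.  A read starting with
    a reverse primer is the reverse-complement strand of the amplicon and is
    reported with strand '-'.  Ties between two distinct (locus, exon)
    targets at the best mismatch count are left unassigned.
    """
    best: list[tuple[str, str, str]] = []
    best_d = max_mismatch + 1
    for (locus, exon, orient), primer in primers.primers.items():
        if len(read.bases) < len(primer):
            continue
        d = iupac_mismatches(primer, read.bases, limit=min(max_mismatch, best_d))
        if d < best_d:
            best_d = d
            best = [(locus, exon, orient)]
        elif d == best_d and d <= max_mismatch:
            best.append((locus, exon, orient))
    if best_d > max_mismatch:
        return None
    targets = {(loc, ex) for loc, ex, _ in best}
    if len(targets) > 1:
        return None  # ambiguous between loci/exons
    locus, exon, orient = best[0]
    primer_len = len(primers.primers[(locus, exon, orient)])
    strand = "+" if orient == "F" else "-"
    return LocusAssignment(locus, exon, strand, read.trimmed(primer_len))


# ---------------------------------------------------------------------------
# FASTQ plumbing
# ---------------------------------------------------------------------------

def read_fastq(path: str | Path) -> list[RawRead]:
    """Read a FASTQ file (Sanger quality encoding) into RawReads."""
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        out.append(
            RawRead(
                rec.id,
                str(rec.seq).upper(),
                np.asarray(rec.letter_annotations["phred_quality"], dtype=np.int16),
            )
        )
    return out


def write_fastq(reads: Iterable[RawRead], path: str | Path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    recs = []
    for r in reads:
        rec = SeqRecord(Seq(r.bases), id=r.id, description="")
        rec.letter_annotations["phred_quality"] = [int(q) for q in r.qualities]
        recs.append(rec)
    handle = path if hasattr(path, "write") else str(path)
    SeqIO.write(recs, handle, "fastq")
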