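"""Allele dictionary and population allele-frequency tables.

The allele dictionary holds, per locus, a multiple alignment of all known
allele sequences over the amplified exons (IMGT/HLA-style), indexed by the
columns at which alleles actually differ (the polymorphic columns).  The
frequency table maps (population, allele) to a population allele frequency
and is used downstream as a prior over allele pairs.

Coordinates: alignment columns are 0-based internally.  Exons of one locus
are concatenated into a single per-locus column space (exon order is the
sorted exon id); externally reported positions use the dictionary's 1-based
reference labels when a label sidecar is provided.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .seqcodes import GAP, N_BASES, SequenceAlphabetError, decode, encode


class DictionaryError(ValueError):
    """The allele dictionary violates a structural invariant."""


class NoFrequencyData(LookupError):
    """No frequency source is available for the requested allele."""


_NAME_RE = re.compile(r"^(?P<locus>[^*]+)\*(?P<f1>\d{2,3})(?::(?P<f2>\d{2,3}))?$")


@dataclass(frozen=True, order=True)
class AlleleName:
    """A 4-digit (protein-level) or 2-digit (group-level) HLA allele name.

    Rendered as ``LOCUS*F1:F2`` (e.g. ``A*02:07``) or ``LOCUS*F1`` for a
    2-digit group.
    """

    locus: str
    field1: str
    field2: str | None = None

    @classmethod
    def parse(cls, text: str) -> "AlleleName":
        m = _NAME_RE.match(text.strip())
        if not m:
            raise ValueError(f"not a valid allele name: {text!r}")
        return cls(m["locus"], m["f1"], m["f2"])

    def render(self) -> str:
        if self.field2 is None:
            return f"{self.locus}*{self.field1}"
        return f"{self.locus}*{self.field1}:{self.field2}"

    def truncate(self) -> "AlleleName":
        """Drop field2, yielding the 2-digit allele group."""
        return AlleleName(self.locus, self.field1)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()


def truncate_to_2digit(name: AlleleName | str) -> AlleleName:
    """2-digit (allele group) truncation: ``A*02:07`` -> ``A*02``."""
    if isinstance(name, str):
        name = AlleleName.parse(name)
    return name.truncate()


@dataclass
class AlleleSequence:
    """One allele's gapped sequence per exon, over the locus master alignment."""

    name: AlleleName
    exon_sequences: dict[str, str]


class AlleleDictionary:
    """Validated, indexed per-locus allele alignments.

    Parameters
    ----------
    alleles_by_locus:
        locus -> list of :class:`AlleleSequence`.  All alleles of one locus
        must provide the same exon ids with identical gapped lengths.
    position_labels:
        optional locus -> {global column -> reference position label}; labels
        are carried as opaque strings (e.g. genomic coordinates of the
        source build) and never interpreted.
    """

    def __init__(
        self,
        alleles_by_locus: Mapping[str, Sequence[AlleleSequence]],
        position_labels: Mapping[str, Mapping[int, str]] | None = None,
    ) -> None:
        self._alleles: dict[str, list[AlleleSequence]] = {}
        self._codes: dict[str, np.ndarray] = {}
        self._index: dict[str, dict[str, int]] = {}
        self._exon_bounds: dict[str, dict[str, tuple[int, int]]] = {}
        self._poly: dict[str, np.ndarray] = {}
        self.position_labels: dict[str, dict[int, str]] = {
            loc: dict(m) for loc, m in (position_labels or {}).items()
        }

        for locus, alleles in alleles_by_locus.items():
            alleles = list(alleles)
            if not alleles:
                raise DictionaryError(f"locus {locus}: no alleles")
            exon_ids = sorted(alleles[0].exon_sequences)
            lengths = {e: len(alleles[0].exon_sequences[e]) for e in exon_ids}
            index: dict[str, int] = {}
            rows = []
            for a in alleles:
                nm = a.name.render()
                if nm in index:
                    raise DictionaryError(f"duplicate allele name {nm}")
                if sorted(a.exon_sequences) != exon_ids:
                    raise DictionaryError(f"{nm}: exon set differs from locus {locus}")
                parts = []
                for e in exon_ids:
                    seq = a.exon_sequences[e]
                    if len(seq) != lengths[e]:
                        raise DictionaryError(
                            f"{nm}: {e} gapped length {len(seq)} != {lengths[e]}"
                        )
                    try:
                        parts.append(encode(seq))
                    except SequenceAlphabetError as exc:
                        raise DictionaryError(f"{nm} {e}: {exc}") from None
                index[nm] = len(rows)
                rows.append(np.concatenate(parts) if parts else np.empty(0, np.uint8))
            bounds: dict[str, tuple[int, int]] = {}
            off = 0
            for e in exon_ids:
                bounds[e] = (off, off + lengths[e])
                off += lengths[e]
            codes = np.vstack(rows)
            self._alleles[locus] = alleles
            self._codes[locus] = codes
            self._index[locus] = index
            self._exon_bounds[locus] = bounds
            self._poly[locus] = _polymorphic_columns(codes)

    # -- structure ---------------------------------------------------------
    @property
    def loci(self) -> list[str]:
        return sorted(self._alleles)

    def alleles(self, locus: str) -> list[AlleleName]:
        return [a.name for a in self._alleles[locus]]

    def allele_sequences(self, locus: str) -> list[AlleleSequence]:
        return list(self._alleles[locus])

    def allele_index(self, locus: str, name: AlleleName | str) -> int:
        key = name.render() if isinstance(name, AlleleName) else name
        try:
            return self._index[locus][key]
        except KeyError:
            raise KeyError(f"allele {key} not in dictionary at locus {locus}") from None

    def codes(self, locus: str) -> np.ndarray:
        """(n_alleles, n_columns) uint8 code matrix for one locus."""
        return self._codes[locus]

    def allele_codes(self, locus: str, name: AlleleName | str) -> np.ndarray:
        return self._codes[locus][self.allele_index(locus, name)]

    def locus_length(self, locus: str) -> int:
        return self._codes[locus].shape[1]

    def exon_bounds(self, locus: str) -> dict[str, tuple[int, int]]:
        """exon id -> (start, end) half-open range in the locus column space."""
        return dict(self._exon_bounds[locus])

    def exon_of_column(self, locus: str, col: int) -> str:
        for e, (s, t) in self._exon_bounds[locus].items():
            if s <= col < t:
                return e
        raise IndexError(f"column {col} outside locus {locus}")

    def position_label(self, locus: str, col: int) -> str:
        """Reference label for a column (1-based fallback when no sidecar)."""
        return self.position_labels.get(locus, {}).get(col, str(col + 1))

    # -- variation ---------------------------------------------------------
    def polymorphic_columns(self, locus: str) -> np.ndarray:
        """Sorted columns where >= 2 distinct callable bases occur among alleles."""
        return self._poly[locus]

    def adjacent_polymorphic_pairs(self, locus: str) -> list[tuple[int, int]]:
        """Consecutive polymorphic-column pairs restricted to a single exon.

        No read spans two amplicons, so cross-exon pairs can never collect
        spanning-read evidence and are omitted.
        """
        cols = self._poly[locus]
        pairs = []
        for i, j in zip(cols[:-1], cols[1:]):
            if self.exon_of_column(locus, int(i)) == self.exon_of_column(locus, int(j)):
                pairs.append((int(i), int(j)))
        return pairs

    def consensus(self, locus: str) -> np.ndarray:
        """Majority base per column (ties to the smallest code; all-gap -> N)."""
        codes = self._codes[locus]
        n_cols = codes.shape[1]
        out = np.full(n_cols, 5, dtype=np.uint8)  # UNKNOWN
        counts = np.zeros((N_BASES, n_cols), dtype=np.int64)
        for b in range(N_BASES):
            counts[b] = (codes == b).sum(axis=0)
        any_base = counts.sum(axis=0) > 0
        out[any_base] = counts[:, any_base].argmax(axis=0).astype(np.uint8)
        return out

    def consensus_exon(self, locus: str, exon: str) -> np.ndarray:
        s, t = self._exon_bounds[locus][exon]
        return self.consensus(locus)[s:t]

    # -- persistence -------------------------------------------------------
    def save(self, outdir: str | Path) -> None:
        """Write one aligned multi-FASTA per locus/exon plus label sidecars."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for locus in self.loci:
            for exon, (s, t) in self._exon_bounds[locus].items():
                recs = [
                    SeqRecord(
                        Seq(decode(self._codes[locus][i, s:t])),
                        id=a.name.render(),
                        description="",
                    )
                    for i, a in enumerate(self._alleles[locus])
                ]
                SeqIO.write(recs, outdir / f"{locus}.{exon}.fasta", "fasta")
                labels = {
                    c - s: lab
                    for c, lab in self.position_labels.get(locus, {}).items()
                    if s <= c < t
                }
                if labels:
                    pd.DataFrame(
                        {"column": [c + 1 for c in sorted(labels)],
                         "label": [labels[c] for c in sorted(labels)]}
                    ).to_csv(outdir / f"{locus}.{exon}.positions.tsv",
                             sep="\t", index=False)

    def reference_fasta(self, path: str | Path) -> None:
        """Export per-locus/exon consensus references for an external aligner."""
        recs = []
        for locus in self.loci:
            for exon, (s, t) in self._exon_bounds[locus].items():
                recs.append(
                    SeqRecord(Seq(decode(self.consensus(locus)[s:t])),
                              id=f"{locus}|{exon}", description="")
                )
        SeqIO.write(recs, str(path), "fasta")


def _polymorphic_columns(codes: np.ndarray) -> np.ndarray:
    """Columns with >= 2 distinct callable (A/C/G/T) symbols among alleles."""
    present = np.zeros(codes.shape[1], dtype=np.int64)
    for b in range(N_BASES):
        present += (codes == b).any(axis=0)
    return np.nonzero(present >= 2)[0]


def load_dictionary(path: str | Path) -> AlleleDictionary:
    """Load an allele dictionary from a directory of ``LOCUS.EXON.fasta`` files.

    Each FASTA holds the gapped per-exon alignment for one locus, one record
    per allele, header = full allele name.  An optional sidecar
    ``LOCUS.EXON.positions.tsv`` (columns ``column`` 1-based, ``label``)
    attaches reference position labels.
    """
    path = Path(path)
    fastas = sorted(path.glob("*.fasta"))
    if not fastas:
        raise DictionaryError(f"no .fasta files under {path}")
    per_locus: dict[str, dict[str, dict[str, str]]] = {}
    labels: dict[str, dict[int, str]] = {}
    for fa in fastas:
        stem = fa.name[: -len(".fasta")]
        locus, _, exon = stem.rpartition(".")
        if not locus:
            raise DictionaryError(f"cannot parse locus/exon from {fa.name}")
        for rec in SeqIO.parse(str(fa), "fasta"):
            seqs = per_locus.setdefault(locus, {}).setdefault(rec.id, {})
            if exon in seqs:
                raise DictionaryError(f"duplicate allele name {rec.id} in {fa.name}")
            seqs[exon] = str(rec.seq).upper()
    # sidecar labels need exon offsets; build alleles first
    alleles_by_locus = {
        locus: [
            AlleleSequence(AlleleName.parse(nm), exons)
            for nm, exons in sorted(allele_map.items())
        ]
        for locus, allele_map in per_locus.items()
    }
    dictionary = AlleleDictionary(alleles_by_locus)
    for fa in fastas:
        stem = fa.name[: -len(".fasta")]
        locus, _, exon = stem.rpartition(".")
        sidecar = fa.with_name(f"{stem}.positions.tsv")
        if sidecar.exists():
            off = dictionary.exon_bounds(locus)[exon][0]
            df = pd.read_csv(sidecar, sep="\t", dtype={"label": str})
            labels.setdefault(locus, {}).update(
                {off + int(c) - 1: lab for c, lab in zip(df["column"], df["label"])}
            )
    dictionary.position_labels = labels
    return dictionary


# ---------------------------------------------------------------------------
# Allele frequencies
# ---------------------------------------------------------------------------

def weighted_frequency(sources: Iterable[tuple[float, float]]) -> float:
    """Sample-size weighted mean of allele frequencies from several sources.

    ``sources`` is a list of ``(frequency, sample_size)``; returns
    sum(f_i * n_i) / sum(n_i).  Raises :class:`NoFrequencyData` on an empty
    list (the caller substitutes its configured floor).
    """
    total_w = 0.0
    total = 0.0
    for f, n in sources:
        if n <= 0:
            raise ValueError(f"sample size must be > 0, got {n}")
        total += f * n
        total_w += n
    if total_w == 0:
        raise NoFrequencyData("no frequency sources")
    return total / total_w


class FrequencyTable:
    """(population, allele) -> frequency, with a floor for missing alleles.

    Partial tables are allowed: per (population, locus) the frequencies must
    sum to at most 1 (+ tolerance) but may sum to less.
    """

    SUM_TOL = 1e-6

    def __init__(self, entries: Mapping[tuple[str, str], float]) -> None:
        self.entries: dict[tuple[str, str], float] = {}
        sums: dict[tuple[str, str], float] = {}
        for (pop, allele), f in entries.items():
            if f < 0:
                raise ValueError(f"negative frequency for {pop}/{allele}")
            name = AlleleName.parse(allele) if isinstance(allele, str) else allele
            key = (pop, name.render())
            self.entries[key] = float(f)
            locus_key = (pop, name.locus)
            sums[locus_key] = sums.get(locus_key, 0.0) + float(f)
        for (pop, locus), s in sums.items():
            if s > 1.0 + self.SUM_TOL:
                raise ValueError(
                    f"frequencies for population {pop}, locus {locus} sum to {s:.6f} > 1"
                )
        self.populations = {pop for pop, _ in self.entries}

    def get(self, population: str, allele: AlleleName | str,
            floor: float = 1e-5) -> float:
        """Frequency of ``allele`` in ``population``; ``floor`` when absent.

        The floor keeps rare alleles assignable: frequencies act as priors,
        never as exclusion.
        """
        key = allele.render() if isinstance(allele, AlleleName) else allele
        f = self.entries.get((population, key))
        if f is None or f <= 0.0:
            return floor
        return f

    # -- persistence -------------------------------------------------------
    @classmethod
    def from_tsv(cls, path: str | Path) -> "FrequencyTable":
        """Load a TSV with columns population, allele, frequency, sample_size.

        Multiple rows for one (population, allele) — multiple literature
        sources — are combined by :func:`weighted_frequency`.
        """
        df = pd.read_csv(path, sep="\t")
        required = {"population", "allele", "frequency", "sample_size"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"frequency table missing columns: {sorted(missing)}")
        entries: dict[tuple[str, str], float] = {}
        for (pop, allele), grp in df.groupby(["population", "allele"], sort=True):
            entries[(pop, allele)] = weighted_frequency(
                list(zip(grp["frequency"], grp["sample_size"]))
            )
        return cls(entries)

    def to_tsv(self, path: str | Path, sample_size: int = 1) -> None:
        rows = [
            {"population": pop, "allele": allele, "frequency": f,
             "sample_size": sample_size}
            for (pop, allele), f in sorted(self.entries.items())
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
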