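"""Phase consistency of an allele pair with reads spanning adjacent sites.

A read that covers two polymorphic columns reports which variant bases
co-occur on one chromosome.  For a candidate allele pair, each adjacent
pair of polymorphic columns (within one exon) defines at most two expected
two-site haplotypes; with n spanning reads of which k match an expected
haplotype, the evidence contributes Binomial(k; n, 1 - p_err) where p_err
is the sequencing error rate (default 1%).  Contributions multiply across
site pairs (sum in log space); a site pair with no spanning reads is
uninformative and contributes probability 1.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import binom

from .align_ingest import DEFAULT_QUALITY_FLOOR, AssignedRead
from .allele_db import AlleleDictionary, AlleleName
from .seqcodes import N_BASES

DEFAULT_P_ERR = 0.01


@dataclass
class SitePairEvidence:
    """Spanning-read haplotype counts at one adjacent polymorphic column pair."""

    col_i: int
    col_j: int
    counts: dict[tuple[int, int], int]  # (base code at i, base code at j) -> n

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class PhaseScore:
    pair: tuple[AlleleName, AlleleName]
    log_p_phase: float
    informative_pairs: int


def collect_site_pairs(
    reads: Sequence[AssignedRead],
    dictionary: AlleleDictionary,
    locus: str,
    quality_floor: int = DEFAULT_QUALITY_FLOOR,
) -> list[SitePairEvidence]:
    """Count two-site haplotypes of reads spanning adjacent polymorphic columns.

    Only reads covering both columns with callable bases are counted; one
    evidence record is returned per adjacent pair with at least one
    spanning read.
    """
    pairs = dictionary.adjacent_polymorphic_pairs(locus)
    if not pairs or not reads:
        return []
    starts = np.array([r.start for r in reads])
    ends = np.array([r.end for r in reads])
    out: list[SitePairEvidence] = []
    for i, j in pairs:
        idx = np.nonzero((starts <= i) & (ends > j))[0]
        counts: Counter = Counter()
        for k in idx:
            r = reads[k]
            bi, bj = int(r.codes[i - r.start]), int(r.codes[j - r.start])
            if bi >= N_BASES or bj >= N_BASES:
                continue
            if (r.qualities[i - r.start] < quality_floor
                    or r.qualities[j - r.start] < quality_floor):
                continue
            counts[(bi, bj)] += 1
        if counts:
            out.append(SitePairEvidence(i, j, dict(counts)))
    return out


def p_phase(
    pair: tuple[AlleleName | str, AlleleName | str],
    evidence: Sequence[SitePairEvidence],
    dictionary: AlleleDictionary,
    locus: str,
    p_err: float = DEFAULT_P_ERR,
) -> PhaseScore:
    """Log P_phase of a candidate allele pair given spanning-read evidence.

    At each site pair, k counts spanning reads matching either of the
    candidate's expected two-site haplotypes (reads matching neither count
    in n only — they are evidence against the candidate); if both alleles
    are identical at both sites the single expected haplotype is used.
    Site pairs where either allele has a gap/unknown base are skipped.
    """
    if not 0.0 < p_err < 1.0:
        raise ValueError(f"p_err must be in (0, 1), got {p_err}")
    names = [n if isinstance(n, AlleleName) else AlleleName.parse(n) for n in pair]
    c1 = dictionary.allele_codes(locus, names[0])
    c2 = dictionary.allele_codes(locus, names[1])
    ks, ns = _phase_counts(c1, c2, evidence)
    total = float(binom.logpmf(ks, ns, 1.0 - p_err).sum()) if ks.size else 0.0
    return PhaseScore((names[0], names[1]), total, int(ks.size))


def _phase_counts(
    codes1: np.ndarray,
    codes2: np.ndarray,
    evidence: Sequence[SitePairEvidence],
) -> tuple[np.ndarray, np.ndarray]:
    """(k, n) arrays over the informative site pairs for one candidate pair."""
    ks: list[int] = []
    ns: list[int] = []
    for ev in evidence:
        i, j = ev.col_i, ev.col_j
        h1 = (int(codes1[i]), int(codes1[j]))
        h2 = (int(codes2[i]), int(codes2[j]))
        if max(h1) >= N_BASES or max(h2) >= N_BASES:
            continue
        n = ev.total
        if n == 0:
            continue
        k = ev.counts.get(h1, 0)
        if h2 != h1:
            k += ev.counts.get(h2, 0)
        ks.append(k)
        ns.append(n)
    return np.asarray(ks, dtype=np.int64), np.asarray(ns, dtype=np.int64)


def phase_matrix(
    codes: np.ndarray,
    pair_indices: Sequence[tuple[int, int]],
    evidence: Sequence[SitePairEvidence],
    p_err: float = DEFAULT_P_ERR,
) -> tuple[np.ndarray, np.ndarray]:
    """Log P_phase for many candidate pairs at once.

    ``codes`` is the (n_alleles, n_cols) dictionary code matrix and
    ``pair_indices`` the allele-row pairs to score.  Returns
    ``(log_p_phase, informative_counts)`` aligned with ``pair_indices``;
    equivalent to calling :func:`p_phase` per pair but with one vectorized
    binomial evaluation.
    """
    n_pairs = len(pair_indices)
    total = np.zeros(n_pairs)
    ninf = np.zeros(n_pairs, dtype=np.int64)
    ks: list[int] = []
    ns: list[int] = []
    which: list[int] = []
    for ev in evidence:
        i, j = ev.col_i, ev.col_j
        n = ev.total
        if n == 0:
            continue
        for p, (a, b) in enumerate(pair_indices):
            h1 = (int(codes[a, i]), int(codes[a, j]))
            h2 = (int(codes[b, i]), int(codes[b, j]))
            if max(h1) >= N_BASES or max(h2) >= N_BASES:
                continue
            k = ev.counts.get(h1, 0)
            if h2 != h1:
                k += ev.counts.get(h2, 0)
            ks.append(k)
            ns.append(n)
            which.append(p)
    if ks:
        contrib = binom.logpmf(np.asarray(ks), np.asarray(ns), 1.0 - p_err)
        np.add.at(total, which, contrib)
        np.add.at(ninf, which, 1)
    return total, ninf
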