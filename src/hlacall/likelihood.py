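"""Diploid genotype likelihoods per alignment column and P_genotype.

Model: reads are independent; a base call ``b`` with Phred quality Q has
error probability e = 10^(-Q/10), is correct with probability 1 - e and is
any specific wrong base with probability e/3.  For a diploid genotype
{x, y} the read is drawn from either haplotype with probability 1/2, so

    P(b | {x, y}) = 1/2 * P(b | x, e) + 1/2 * P(b | y, e).

Per-column log-likelihoods over the 10 unordered diploid genotypes are
normalized into genotype posteriors under a uniform genotype prior; the
genotype-concordance score of an allele pair, P_genotype, is the product of
the posteriors of the pair's implied genotype across columns (a sum in log
space).  Columns where either allele carries a gap or unknown symbol are
skipped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .align_ingest import DEFAULT_QUALITY_FLOOR, AssignedRead
from .allele_db import AlleleDictionary, AlleleName
from .seqcodes import N_BASES, encode

#: canonical order of the 10 unordered diploid genotypes (base-code pairs)
GENOTYPES: tuple[tuple[int, int], ...] = tuple(
    (x, y) for x in range(N_BASES) for y in range(x, N_BASES)
)

#: (4, 4) -> genotype index, symmetric
GENOTYPE_INDEX = np.zeros((N_BASES, N_BASES), dtype=np.int64)
for _g, (_x, _y) in enumerate(GENOTYPES):
    GENOTYPE_INDEX[_x, _y] = _g
    GENOTYPE_INDEX[_y, _x] = _g


@dataclass
class SitePileup:
    """Base/quality observations from kept reads at one alignment column."""

    column: int
    bases: str
    qualities: np.ndarray

    def __post_init__(self) -> None:
        self.qualities = np.asarray(self.qualities, dtype=np.int16)
        if len(self.bases) != len(self.qualities):
            raise ValueError("bases/qualities length mismatch")


@dataclass
class GenotypeLikelihoods:
    """Log-likelihood of the observations for each of the 10 genotypes."""

    column: int
    loglik: np.ndarray  # shape (10,), order of GENOTYPES

    def normalized(self) -> np.ndarray:
        """Log genotype posteriors under a uniform genotype prior."""
        return self.loglik - logsumexp(self.loglik)


def _base_given_allele(e: float) -> np.ndarray:
    """(observed base, true base) -> probability; 1-e on the diagonal, e/3 off."""
    p = np.full((N_BASES, N_BASES), e / 3.0)
    np.fill_diagonal(p, 1.0 - e)
    return p


def _contribution_matrix(q: int) -> np.ndarray:
    """(observed base, genotype) -> log P(b | {x, y}) at quality q."""
    e = 10.0 ** (-q / 10.0)
    p = _base_given_allele(e)
    out = np.empty((N_BASES, len(GENOTYPES)))
    for g, (x, y) in enumerate(GENOTYPES):
        out[:, g] = np.log(0.5 * p[:, x] + 0.5 * p[:, y])
    return out


def site_likelihoods(
    pileup: SitePileup, quality_floor: int = DEFAULT_QUALITY_FLOOR
) -> GenotypeLikelihoods:
    """Genotype log-likelihoods at one column.

    An empty pileup (or one with no callable base) yields log-likelihood 0
    for all 10 genotypes — completely uninformative.
    """
    ll = np.zeros(len(GENOTYPES))
    codes = encode(pileup.bases)
    for b, q in zip(codes, pileup.qualities):
        if b >= N_BASES or q < quality_floor:
            continue
        ll += _contribution_matrix(int(q))[b]
    return GenotypeLikelihoods(pileup.column, ll)


def pileup_matrices(
    reads: Sequence[AssignedRead],
    n_columns: int,
    quality_floor: int = DEFAULT_QUALITY_FLOOR,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-column genotype log-likelihoods for a set of reads.

    Returns ``(loglik, base_counts)`` where ``loglik`` is (n_columns, 10)
    and ``base_counts`` is (n_columns, 4) counts of callable observations.
    Agrees with :func:`site_likelihoods` column by column.
    """
    ll = np.zeros((n_columns, len(GENOTYPES)))
    counts = np.zeros((n_columns, N_BASES), dtype=np.int64)
    if not reads:
        return ll, counts
    cols = np.concatenate([np.arange(r.start, r.end) for r in reads])
    codes = np.concatenate([r.codes for r in reads])
    quals = np.concatenate([r.qualities for r in reads])
    keep = (codes < N_BASES) & (quals >= quality_floor)
    cols, codes, quals = cols[keep], codes[keep], quals[keep]
    for q in np.unique(quals):
        sel = quals == q
        c = np.zeros((n_columns, N_BASES), dtype=np.int64)
        np.add.at(c, (cols[sel], codes[sel]), 1)
        counts += c
        ll += c @ _contribution_matrix(int(q))
    return ll, counts


def normalize_columns(loglik: np.ndarray) -> np.ndarray:
    """Row-normalize per-column genotype log-likelihoods into log posteriors."""
    return loglik - logsumexp(loglik, axis=1, keepdims=True)


def p_genotype(
    pair: tuple[AlleleName | str, AlleleName | str],
    normalized_loglik: np.ndarray,
    dictionary: AlleleDictionary,
    locus: str,
) -> float:
    """Log P_genotype for an allele pair.

    Sums the per-column normalized log posterior of the genotype implied by
    the pair over every column where both alleles carry a callable base.
    Symmetric in the pair.  Raises KeyError naming an allele absent from
    the dictionary.
    """
    c1 = dictionary.allele_codes(locus, _render(pair[0]))
    c2 = dictionary.allele_codes(locus, _render(pair[1]))
    return float(pair_loglik(c1[None, :], c2[None, :], normalized_loglik)[0])


def pair_loglik(
    codes1: np.ndarray, codes2: np.ndarray, normalized_loglik: np.ndarray
) -> np.ndarray:
    """Batched log P_genotype: (n_pairs, n_cols) allele code rows -> (n_pairs,)."""
    valid = (codes1 < N_BASES) & (codes2 < N_BASES)
    g = GENOTYPE_INDEX[
        np.minimum(codes1, N_BASES - 1), np.minimum(codes2, N_BASES - 1)
    ]
    n_cols = normalized_loglik.shape[0]
    vals = normalized_loglik[np.arange(n_cols)[None, :], g]
    return np.where(valid, vals, 0.0).sum(axis=1)


def _render(name: AlleleName | str) -> str:
    return name.render() if isinstance(name, AlleleName) else name
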