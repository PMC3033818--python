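"""Allele-pair enumeration, posterior combination and HLA call emission.

For each sample and locus the caller scores every unordered pair of
dictionary alleles with three log-components — genotype concordance
(P_genotype), phase consistency (P_phase) and the population prior
(P_frequency, the plain product of the two allele frequencies) — sums them
into P_combined and normalizes over all pairs so the posteriors at the
locus sum to 1.  The matching set is every pair attaining the maximal
P_genotype * P_phase; the best guess is the member of the matching set with
the highest P_combined, ties broken by allele-name order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .align_ingest import (
    DEFAULT_QUALITY_FLOOR,
    AssignedRead,
    depth_of_coverage,
)
from .allele_db import AlleleDictionary, AlleleName, FrequencyTable, truncate_to_2digit
from .likelihood import normalize_columns, pair_loglik, pileup_matrices
from .phasing import DEFAULT_P_ERR, collect_site_pairs, phase_matrix

#: mean exon depth below which a call is flagged
LOW_COVERAGE_DEPTH = 20

#: matching-set tolerance on log(P_genotype * P_phase)
MATCHING_SET_TOL = 1e-9

DEFAULT_FREQUENCY_FLOOR = 1e-5

#: contamination signature: >= this many columns showing >= 3 bases each
#: carried by >= 10% of the column's reads (a diploid explains at most 2)
CONTAMINATION_MIN_COLUMNS = 2
CONTAMINATION_MIN_BASES = 3
CONTAMINATION_BASE_FRACTION = 0.10


@dataclass
class PairScore:
    """All score components for one candidate allele pair."""

    pair: tuple[AlleleName, AlleleName]
    log_p_genotype: float
    log_p_phase: float
    log_p_frequency: float
    log_p_combined: float
    posterior: float


@dataclass
class HLACall:
    """The typing result at one locus for one sample."""

    sample: str
    locus: str
    status: str  # "ok" or "no_call"
    best_pair: tuple[AlleleName, AlleleName] | None = None
    posterior: float = 0.0
    matching_set: list[tuple[AlleleName, AlleleName]] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)

    @property
    def best_pair_2digit(self) -> tuple[AlleleName, AlleleName] | None:
        if self.best_pair is None:
            return None
        return tuple(truncate_to_2digit(a) for a in self.best_pair)


def p_frequency(
    pair: tuple[AlleleName | str, AlleleName | str],
    table: FrequencyTable | None,
    population: str | None,
    floor: float = DEFAULT_FREQUENCY_FLOOR,
    n_alleles: int | None = None,
    hwe: bool = False,
) -> float:
    """Log prior of an allele pair: log(f_i * f_j) in the given population.

    Alleles missing from the table receive the configured floor so rare
    alleles are never excluded outright.  With an unspecified population
    (or no table) the prior is uniform over dictionary alleles — a constant
    that cancels under normalization.  ``hwe`` adds the Hardy-Weinberg
    heterozygote factor of 2 (off by default: the prior is the plain
    product of frequencies).
    """
    a, b = (_as_name(pair[0]), _as_name(pair[1]))
    if table is None or population is None or population == "uniform":
        f = 1.0 / n_alleles if n_alleles else 1.0
        fa = fb = f
    else:
        fa = table.get(population, a, floor)
        fb = table.get(population, b, floor)
    lp = math.log(fa) + math.log(fb)
    if hwe and a != b:
        lp += math.log(2.0)
    return lp


def call_locus(
    reads: Sequence[AssignedRead],
    dictionary: AlleleDictionary,
    locus: str,
    frequencies: FrequencyTable | None = None,
    population: str | None = None,
    sample: str = "",
    p_err: float = DEFAULT_P_ERR,
    frequency_floor: float = DEFAULT_FREQUENCY_FLOOR,
    quality_floor: int = DEFAULT_QUALITY_FLOOR,
    hwe: bool = False,
) -> tuple[HLACall, list[PairScore]]:
    """Score all allele pairs at one locus and emit the call.

    ``reads`` are the sample's kept reads at this locus (all exons).  With
    zero reads a "no_call" status is returned rather than an exception.
    """
    reads = [r for r in reads if r.locus == locus]
    if not reads:
        return HLACall(sample=sample, locus=locus, status="no_call"), []

    n_cols = dictionary.locus_length(locus)
    loglik, base_counts = pileup_matrices(reads, n_cols, quality_floor)
    norm_ll = normalize_columns(loglik)
    codes = dictionary.codes(locus)
    names = dictionary.alleles(locus)
    n = len(names)
    pairs = [(i, j) for i in range(n) for j in range(i, n)]
    ai = np.array([p[0] for p in pairs])
    aj = np.array([p[1] for p in pairs])

    lgen = pair_loglik(codes[ai], codes[aj], norm_ll)
    evidence = collect_site_pairs(reads, dictionary, locus, quality_floor)
    lpha, _ = phase_matrix(codes, pairs, evidence, p_err)
    lfrq = np.array(
        [
            p_frequency(
                (names[i], names[j]), frequencies, population,
                floor=frequency_floor, n_alleles=n, hwe=hwe,
            )
            for i, j in pairs
        ]
    )
    lcomb = lgen + lpha + lfrq
    log_post = lcomb - logsumexp(lcomb)
    posterior = np.exp(log_post)

    evid = lgen + lpha
    in_set = evid >= evid.max() - MATCHING_SET_TOL
    set_idx = np.nonzero(in_set)[0]
    # best guess: max P_combined within the matching set, name-order ties
    best = min(
        set_idx,
        key=lambda k: (-lcomb[k], names[pairs[k][0]], names[pairs[k][1]]),
    )

    flags = _qc_flags(reads, dictionary, locus, base_counts, sample)
    call = HLACall(
        sample=sample,
        locus=locus,
        status="ok",
        best_pair=(names[pairs[best][0]], names[pairs[best][1]]),
        posterior=float(posterior[best]),
        matching_set=[(names[pairs[k][0]], names[pairs[k][1]]) for k in set_idx],
        flags=flags,
    )
    scores = [
        PairScore(
            pair=(names[i], names[j]),
            log_p_genotype=float(lgen[k]),
            log_p_phase=float(lpha[k]),
            log_p_frequency=float(lfrq[k]),
            log_p_combined=float(lcomb[k]),
            posterior=float(posterior[k]),
        )
        for k, (i, j) in enumerate(pairs)
    ]
    return call, scores


def _qc_flags(
    reads: Sequence[AssignedRead],
    dictionary: AlleleDictionary,
    locus: str,
    base_counts: np.ndarray,
    sample: str,
) -> list[str]:
    flags = []
    coverage = depth_of_coverage(reads, dictionary)
    means = [
        coverage.mean(sample if sample else reads[0].sample, locus, exon)
        for exon in dictionary.exon_bounds(locus)
    ]
    if min(means, default=0.0) < LOW_COVERAGE_DEPTH:
        flags.append("low_coverage")
    depth = base_counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = base_counts / np.maximum(depth, 1)[:, None]
    n_major = ((frac >= CONTAMINATION_BASE_FRACTION) & (base_counts >= 1)).sum(axis=1)
    if (n_major >= CONTAMINATION_MIN_BASES).sum() >= CONTAMINATION_MIN_COLUMNS:
        flags.append("possible_contamination")
    return flags


def call_samples(
    reads: Iterable[AssignedRead],
    dictionary: AlleleDictionary,
    frequencies: FrequencyTable | None = None,
    population: str | None = None,
    samples: Iterable[str] | None = None,
    **kwargs,
) -> tuple[list[HLACall], pd.DataFrame]:
    """Call every (sample, locus) present in ``reads``.

    ``samples`` optionally forces no_call rows for samples without reads.
    Returns calls sorted by (sample, locus) plus the full per-pair score
    table as a DataFrame.
    """
    grouped: dict[tuple[str, str], list[AssignedRead]] = {}
    for r in reads:
        grouped.setdefault((r.sample, r.locus), []).append(r)
    if samples is not None:
        for s in samples:
            for locus in dictionary.loci:
                grouped.setdefault((s, locus), [])
    calls: list[HLACall] = []
    rows = []
    for (sample, locus) in sorted(grouped):
        call, scores = call_locus(
            grouped[(sample, locus)], dictionary, locus,
            frequencies=frequencies, population=population, sample=sample,
            **kwargs,
        )
        calls.append(call)
        for sc in scores:
            rows.append(
                {
                    "sample": sample,
                    "locus": locus,
                    "allele1": sc.pair[0].render(),
                    "allele2": sc.pair[1].render(),
                    "log_p_genotype": sc.log_p_genotype,
                    "log_p_phase": sc.log_p_phase,
                    "log_p_frequency": sc.log_p_frequency,
                    "log_p_combined": sc.log_p_combined,
                    "posterior": sc.posterior,
                }
            )
    columns = [
        "sample", "locus", "allele1", "allele2", "log_p_genotype",
        "log_p_phase", "log_p_frequency", "log_p_combined", "posterior",
    ]
    return calls, pd.DataFrame(rows, columns=columns)


def calls_to_frame(calls: Sequence[HLACall]) -> pd.DataFrame:
    """Flatten calls into a deterministic, TSV-ready table."""
    rows = []
    for c in sorted(calls, key=lambda c: (c.sample, c.locus)):
        bp = c.best_pair
        rows.append(
            {
                "sample": c.sample,
                "locus": c.locus,
                "status": c.status,
                "allele1": bp[0].render() if bp else "",
                "allele2": bp[1].render() if bp else "",
                "allele1_2digit": truncate_to_2digit(bp[0]).render() if bp else "",
                "allele2_2digit": truncate_to_2digit(bp[1]).render() if bp else "",
                "posterior": round(c.posterior, 12),
                "matching_set": ";".join(
                    f"{a.render()}/{b.render()}" for a, b in c.matching_set
                ),
                "flags": ",".join(c.flags),
            }
        )
    columns = [
        "sample", "locus", "status", "allele1", "allele2",
        "allele1_2digit", "allele2_2digit", "posterior", "matching_set", "flags",
    ]
    return pd.DataFrame(rows, columns=columns)


# ---------------------------------------------------------------------------
# Concordance against gold-standard types
# ---------------------------------------------------------------------------

@dataclass
class ConcordanceResult:
    """Typing accuracy against a truth table at 4- and 2-digit resolution."""

    concordant_4digit: int
    concordant_2digit: int
    total_alleles: int
    missing_truth: int
    details: pd.DataFrame

    @property
    def accuracy_4digit(self) -> float:
        return self.concordant_4digit / self.total_alleles if self.total_alleles else 0.0

    @property
    def accuracy_2digit(self) -> float:
        return self.concordant_2digit / self.total_alleles if self.total_alleles else 0.0


def _pair_concordance(
    called: tuple[AlleleName, AlleleName], truth: tuple[AlleleName, AlleleName]
) -> int:
    """Concordant alleles under the best matching of two unordered pairs."""
    c1, c2 = called
    t1, t2 = truth
    direct = (c1 == t1) + (c2 == t2)
    crossed = (c1 == t2) + (c2 == t1)
    return max(direct, crossed)


def evaluate_concordance(
    calls: Sequence[HLACall],
    truth: pd.DataFrame | Mapping[tuple[str, str], tuple[str, str]],
) -> ConcordanceResult:
    """Per-allele concordance of calls with gold-standard types.

    ``truth`` is a DataFrame with columns sample, locus, allele1, allele2
    (or an equivalent mapping).  Each called pair is matched to the truth
    pair in the orientation maximizing agreement; accuracy is concordant
    alleles over total truth alleles.  Sample/locus entries without truth
    are skipped and counted.
    """
    if isinstance(truth, pd.DataFrame):
        table = {
            (r.sample, r.locus): (r.allele1, r.allele2) for r in truth.itertuples()
        }
    else:
        table = dict(truth)
    conc4 = conc2 = total = missing = 0
    rows = []
    for call in calls:
        t = table.get((call.sample, call.locus))
        if t is None:
            missing += 1
            continue
        truth_pair = (AlleleName.parse(t[0]), AlleleName.parse(t[1]))
        total += 2
        if call.status != "ok" or call.best_pair is None:
            n4 = n2 = 0
        else:
            n4 = _pair_concordance(call.best_pair, truth_pair)
            n2 = _pair_concordance(
                tuple(a.truncate() for a in call.best_pair),
                tuple(a.truncate() for a in truth_pair),
            )
        conc4 += n4
        conc2 += n2
        rows.append(
            {
                "sample": call.sample,
                "locus": call.locus,
                "called1": call.best_pair[0].render() if call.best_pair else "",
                "called2": call.best_pair[1].render() if call.best_pair else "",
                "truth1": truth_pair[0].render(),
                "truth2": truth_pair[1].render(),
                "concordant_4digit": n4,
                "concordant_2digit": n2,
            }
        )
    details = pd.DataFrame(
        rows,
        columns=[
            "sample", "locus", "called1", "called2", "truth1", "truth2",
            "concordant_4digit", "concordant_2digit",
        ],
    )
    return ConcordanceResult(conc4, conc2, total, missing, details)


def _as_name(name: AlleleName | str) -> AlleleName:
    return name if isinstance(name, AlleleName) else AlleleName.parse(name)
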