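"""Shared test utilities: tiny dictionary builders and an independent
brute-force posterior oracle.

The oracle enumerates every allele pair with plain (non-log) probability
arithmetic and pure-Python loops, deliberately sharing no code with the
implementation it checks.
"""

from __future__ import annotations

from math import comb

import numpy as np

from hlacall.allele_db import AlleleDictionary, AlleleName, AlleleSequence
from hlacall.align_ingest import AssignedRead


def make_dictionary(spec: dict, labels=None) -> AlleleDictionary:
    """Build a dictionary from {locus: {allele: {exon: seq}}}."""
    alleles = {
        locus: [
            AlleleSequence(AlleleName.parse(name), dict(exons))
            for name, exons in allele_map.items()
        ]
        for locus, allele_map in spec.items()
    }
    return AlleleDictionary(alleles, position_labels=labels)


def make_read(sample, locus, exon, start, bases, q=30, dictionary=None, strand="+"):
    """AssignedRead with uniform quality; start is the global column."""
    return AssignedRead(
        sample=sample, locus=locus, exon=exon, start=start,
        bases=bases, qualities=np.full(len(bases), q, dtype=np.int16),
        strand=strand,
    )


# ---------------------------------------------------------------------------
# Brute-force oracle (direct probability arithmetic, no log-space tricks)
# ---------------------------------------------------------------------------

_BASES = "ACGT"


def _error_prob(q):
    return 10.0 ** (-q / 10.0)


def _p_base_given_allele(b, a, e):
    return 1.0 - e if b == a else e / 3.0


def brute_force_polymorphic(seq_by_allele):
    """Columns (indices into the concatenated strings) with >= 2 distinct bases."""
    seqs = list(seq_by_allele.values())
    n = len(seqs[0])
    poly = []
    for c in range(n):
        distinct = {s[c] for s in seqs if s[c] in _BASES}
        if len(distinct) >= 2:
            poly.append(c)
    return poly


def brute_force_posteriors(
    reads,
    dictionary,
    locus,
    frequencies=None,
    population=None,
    p_err=0.01,
    floor=1e-5,
    q_floor=5,
):
    """Posterior over all unordered allele pairs, by direct enumeration.

    Returns {(name1, name2): (p_genotype, p_phase, p_frequency, posterior)}
    with names in dictionary order.  p_genotype here is the plain product of
    per-column genotype posteriors, matching the implementation's definition
    on the probability scale.
    """
    names = [a.render() for a in dictionary.alleles(locus)]
    seq = {
        n: "".join(
            "ACGT-N"[c] for c in dictionary.allele_codes(locus, n)
        )
        for n in names
    }
    n_cols = dictionary.locus_length(locus)

    # per-column observations (base, error prob)
    obs = [[] for _ in range(n_cols)]
    for r in reads:
        if r.locus != locus:
            continue
        for off, (b, q) in enumerate(zip(r.bases, r.qualities)):
            if b in _BASES and q >= q_floor:
                obs[r.start + off].append((b, _error_prob(int(q))))

    # per-column genotype posteriors over the 10 unordered genotypes
    genotypes = [(x, y) for i, x in enumerate(_BASES) for y in _BASES[i:]]
    col_post = []
    for c in range(n_cols):
        liks = []
        for x, y in genotypes:
            L = 1.0
            for b, e in obs[c]:
                L *= 0.5 * _p_base_given_allele(b, x, e) + 0.5 * _p_base_given_allele(b, y, e)
            liks.append(L)
        total = sum(liks)
        col_post.append({g: l / total for g, l in zip(genotypes, liks)})

    # adjacent polymorphic pairs within one exon, recomputed independently
    poly = brute_force_polymorphic(seq)
    bounds = dictionary.exon_bounds(locus)

    def exon_of(c):
        return next(e for e, (s, t) in bounds.items() if s <= c < t)

    adj = [
        (i, j)
        for i, j in zip(poly[:-1], poly[1:])
        if exon_of(i) == exon_of(j)
    ]

    # spanning-read haplotype counts per adjacent pair
    span = []
    for i, j in adj:
        counts = {}
        for r in reads:
            if r.locus != locus or not (r.start <= i and r.start + len(r.bases) > j):
                continue
            bi, bj = r.bases[i - r.start], r.bases[j - r.start]
            qi, qj = r.qualities[i - r.start], r.qualities[j - r.start]
            if bi in _BASES and bj in _BASES and qi >= q_floor and qj >= q_floor:
                counts[(bi, bj)] = counts.get((bi, bj), 0) + 1
        span.append(((i, j), counts))

    out = {}
    raw = {}
    for ia, a in enumerate(names):
        for b in names[ia:]:
            # genotype component
            pg = 1.0
            for c in range(n_cols):
                xa, xb = seq[a][c], seq[b][c]
                if xa not in _BASES or xb not in _BASES:
                    continue
                g = (xa, xb) if (xa, xb) in col_post[c] else (xb, xa)
                pg *= col_post[c][g]
            # phase component
            pp = 1.0
            for (i, j), counts in span:
                ha = (seq[a][i], seq[a][j])
                hb = (seq[b][i], seq[b][j])
                if any(x not in _BASES for x in ha + hb):
                    continue
                n = sum(counts.values())
                if n == 0:
                    continue
                k = counts.get(ha, 0)
                if hb != ha:
                    k += counts.get(hb, 0)
                pp *= comb(n, k) * (1.0 - p_err) ** k * p_err ** (n - k)
            # frequency component
            if frequencies is None or population is None:
                pf = (1.0 / len(names)) ** 2
            else:
                fa = frequencies.get(population, a, floor)
                fb = frequencies.get(population, b, floor)
                pf = fa * fb
            raw[(a, b)] = (pg, pp, pf, pg * pp * pf)
    total = sum(v[3] for v in raw.values())
    for k, (pg, pp, pf, pc) in raw.items():
        out[k] = (pg, pp, pf, pc / total)
    return out
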