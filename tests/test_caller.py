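"""Pair enumeration, posterior combination, calls and concordance."""

import math

import numpy as np
import pandas as pd
import pytest

from hlacall.allele_db import AlleleName, FrequencyTable
from hlacall.caller import (
    HLACall,
    call_locus,
    evaluate_concordance,
    p_frequency,
)

from helpers import brute_force_posteriors, make_dictionary, make_read


class TestPFrequency:
    TABLE = FrequencyTable({("eur", "A*02:01"): 0.10, ("eur", "A*02:07"): 0.05})

    def test_heterozygote_plain_product(self):
        lp = p_frequency(("A*02:01", "A*02:07"), self.TABLE, "eur")
        assert math.exp(lp) == pytest.approx(0.005)

    def test_homozygote_squared(self):
        lp = p_frequency(("A*02:01", "A*02:01"), self.TABLE, "eur")
        assert math.exp(lp) == pytest.approx(0.01)

    def test_missing_allele_uses_floor(self):
        lp = p_frequency(("A*02:01", "A*99:01"), self.TABLE, "eur", floor=1e-5)
        assert math.exp(lp) == pytest.approx(1e-6)

    def test_unspecified_population_is_uniform(self):
        lp = p_frequency(("A*02:01", "A*02:07"), self.TABLE, None, n_alleles=4)
        assert math.exp(lp) == pytest.approx(1 / 16)

    def test_hwe_flag_doubles_heterozygotes(self):
        base = p_frequency(("A*02:01", "A*02:07"), self.TABLE, "eur")
        hwe = p_frequency(("A*02:01", "A*02:07"), self.TABLE, "eur", hwe=True)
        assert hwe - base == pytest.approx(math.log(2))
        hom = p_frequency(("A*02:01", "A*02:01"), self.TABLE, "eur", hwe=True)
        assert math.exp(hom) == pytest.approx(0.01)


def simulate_pair_reads(dictionary, locus, pair, n_reads, seed, q=30,
                        sample="S1"):
    """Reads drawn alternately from the two alleles of a pair, no errors."""
    rng = np.random.default_rng(seed)
    n_cols = dictionary.locus_length(locus)
    reads = []
    for i in range(n_reads):
        seq = "".join(
            "ACGT-N"[c] for c in dictionary.allele_codes(locus, pair[i % 2])
        )
        start = int(rng.integers(0, max(1, n_cols - 10)))
        length = int(rng.integers(8, n_cols - start + 1))
        reads.append(make_read(sample, locus, "exon2", start,
                               seq[start:start + length], q=q))
    return reads


class TestCallLocus:
    def test_ambiguous_twin_resolved_by_frequency(self):
        # P and Q identical over the sequenced exon; R distinct
        d = make_dictionary(
            {"A": {"A*01:01": {"exon2": "ACGTACGTACGTACGTACGT"},
                   "A*01:02": {"exon2": "ACGTACGTACGTACGTACGT"},
                   "A*02:01": {"exon2": "ACCTACGAACGTACTTACGT"}}}
        )
        freqs = FrequencyTable(
            {("p", "A*01:01"): 0.2, ("p", "A*01:02"): 0.01, ("p", "A*02:01"): 0.3}
        )
        reads = simulate_pair_reads(d, "A", ("A*01:01", "A*01:01"), 20, seed=3)
        call, scores = call_locus(reads, d, "A", freqs, "p", sample="S1")
        matching = {tuple(a.render() for a in pair) for pair in call.matching_set}
        assert matching == {
            ("A*01:01", "A*01:01"),
            ("A*01:01", "A*01:02"),
            ("A*01:02", "A*01:02"),
        }
        assert tuple(a.render() for a in call.best_pair) == ("A*01:01", "A*01:01")

    def test_single_diagnostic_column_discriminates(self):
        # two alleles separated by one T>C substitution
        d = make_dictionary(
            {"C": {"C*02:02": {"exon2": "ACGTACCTACGTACGTACGT"},
                   "C*02:10": {"exon2": "ACGTACTTACGTACGTACGT"}}}
        )
        reads = simulate_pair_reads(d, "C", ("C*02:10", "C*02:10"), 20, seed=4)
        call, _ = call_locus(reads, d, "C")
        assert tuple(a.render() for a in call.best_pair) == ("C*02:10", "C*02:10")

    def test_no_reads_is_no_call_not_exception(self, tiny_dict):
        call, scores = call_locus([], tiny_dict, "A", sample="S9")
        assert call.status == "no_call"
        assert call.best_pair is None
        assert scores == []

    def test_posteriors_sum_to_one(self, tiny_dict):
        reads = simulate_pair_reads(tiny_dict, "A", ("A*01:01", "A*02:01"),
                                    15, seed=5)
        _, scores = call_locus(reads, tiny_dict, "A")
        assert sum(s.posterior for s in scores) == pytest.approx(1.0, abs=1e-9)

    def test_component_scaling_leaves_posterior_unchanged(self, tiny_dict):
        """Frequency rescaling by a constant cancels under normalization."""
        reads = simulate_pair_reads(tiny_dict, "A", ("A*01:01", "A*02:01"),
                                    15, seed=6)
        f1 = FrequencyTable({("p", "A*01:01"): 0.2, ("p", "A*02:01"): 0.2,
                             ("p", "A*03:01"): 0.2})
        f2 = FrequencyTable({("p", "A*01:01"): 0.1, ("p", "A*02:01"): 0.1,
                             ("p", "A*03:01"): 0.1})
        _, s1 = call_locus(reads, tiny_dict, "A", f1, "p", frequency_floor=0.2)
        _, s2 = call_locus(reads, tiny_dict, "A", f2, "p", frequency_floor=0.1)
        for a, b in zip(s1, s2):
            assert a.posterior == pytest.approx(b.posterior, abs=1e-12)

    def test_uniform_frequencies_reduce_to_evidence_argmax(self, tiny_dict):
        reads = simulate_pair_reads(tiny_dict, "A", ("A*01:01", "A*03:01"),
                                    15, seed=7)
        call_u, scores_u = call_locus(reads, tiny_dict, "A")
        best_evidence = max(
            scores_u, key=lambda s: s.log_p_genotype + s.log_p_phase
        )
        assert call_u.best_pair == best_evidence.pair

    def test_best_guess_always_in_matching_set(self, tiny_dict):
        for seed in range(5):
            reads = simulate_pair_reads(tiny_dict, "A", ("A*01:01", "A*02:01"),
                                        12, seed=seed)
            call, _ = call_locus(reads, tiny_dict, "A")
            assert call.best_pair in call.matching_set

    def test_low_coverage_flag(self, tiny_dict):
        reads = simulate_pair_reads(tiny_dict, "A", ("A*01:01", "A*01:01"),
                                    3, seed=8)
        call, _ = call_locus(reads, tiny_dict, "A")
        assert "low_coverage" in call.flags

    def test_full_posterior_matches_bruteforce(self):
        """4-allele dictionary, 30 fixed reads, every pair to 1e-9."""
        d = make_dictionary(
            {"A": {"A*01:01": {"exon2": "ACGTACGTACGTACGTACGT"},
                   "A*01:02": {"exon2": "ACGTACCTACGTACGTACGT"},
                   "A*02:01": {"exon2": "ACCTACGTACGAACGTACTT"},
                   "A*03:01": {"exon2": "TCGTACGTACTTACGTACGA"}}}
        )
        freqs = FrequencyTable(
            {("p", "A*01:01"): 0.4, ("p", "A*01:02"): 0.05,
             ("p", "A*02:01"): 0.3, ("p", "A*03:01"): 0.2}
        )
        reads = simulate_pair_reads(d, "A", ("A*01:02", "A*02:01"), 30, seed=9)
        _, scores = call_locus(reads, d, "A", freqs, "p")
        oracle = brute_force_posteriors(reads, d, "A", freqs, "p")
        assert len(scores) == 10
        for s in scores:
            key = (s.pair[0].render(), s.pair[1].render())
            assert s.posterior == pytest.approx(oracle[key][3], abs=1e-9)


class TestEvaluateConcordance:
    def _call(self, sample, locus, a, b):
        return HLACall(
            sample=sample, locus=locus, status="ok",
            best_pair=(AlleleName.parse(a), AlleleName.parse(b)),
            matching_set=[(AlleleName.parse(a), AlleleName.parse(b))],
        )

    def test_exact_match(self):
        calls = [self._call("S1", "A", "A*02:01", "A*02:07")]
        truth = pd.DataFrame(
            [{"sample": "S1", "locus": "A",
              "allele1": "A*02:01", "allele2": "A*02:07"}]
        )
        res = evaluate_concordance(calls, truth)
        assert res.concordant_4digit == 2
        assert res.accuracy_4digit == 1.0

    def test_false_homozygote_scores_half_at_4digit(self):
        calls = [self._call("S1", "A", "A*02:01", "A*02:01")]
        truth = pd.DataFrame(
            [{"sample": "S1", "locus": "A",
              "allele1": "A*02:01", "allele2": "A*02:07"}]
        )
        res = evaluate_concordance(calls, truth)
        assert res.concordant_4digit == 1
        assert res.concordant_2digit == 2  # same A*02 group

    def test_unordered_pair_orientation(self):
        calls = [self._call("S1", "B", "B*39:24", "B*07:02")]
        truth = pd.DataFrame(
            [{"sample": "S1", "locus": "B",
              "allele1": "B*07:02", "allele2": "B*39:24"}]
        )
        assert evaluate_concordance(calls, truth).concordant_4digit == 2

    def test_missing_truth_skipped_and_counted(self):
        calls = [self._call("S1", "A", "A*01:01", "A*01:01"),
                 self._call("S2", "A", "A*01:01", "A*01:01")]
        truth = pd.DataFrame(
            [{"sample": "S1", "locus": "A",
              "allele1": "A*01:01", "allele2": "A*01:01"}]
        )
        res = evaluate_concordance(calls, truth)
        assert res.missing_truth == 1
        assert res.total_alleles == 2

    def test_agrees_with_simulator_bookkeeping(self, small_dataset):
        """Tallying concordance two independent ways gives the same answer."""
        from hlacall.pipeline import type_simulated

        res = type_simulated(small_dataset)
        conc = evaluate_concordance(res.calls, small_dataset.truth_pairs)
        # independent tally straight off the truth frame
        by_key = {(c.sample, c.locus): c for c in res.calls}
        n_match = 0
        for row in small_dataset.truth_pairs.itertuples():
            call = by_key[(row.sample, row.locus)]
            called = sorted(a.render() for a in call.best_pair)
            want = sorted([row.allele1, row.allele2])
            if called == want:
                n_match += 2
            elif called[0] in want or called[1] in want:
                n_match += 1
        assert conc.concordant_4digit == n_match
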