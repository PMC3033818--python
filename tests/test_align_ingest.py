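"""Alignment ingest, plumbing aligner, misalignment filter, coverage."""

import numpy as np
import pytest

from hlacall.align_ingest import (
    depth_of_coverage,
    ingest_alignments,
    misalignment_filter,
    plumbing_align,
    snp_homology,
)
from hlacall.demux import RawRead
from hlacall.seqcodes import decode, revcomp
from hlacall.simulator import write_truth_sam

from helpers import make_dictionary, make_read


@pytest.fixture(scope="module")
def filter_dict():
    """Two alleles differing at 4 evenly spaced columns."""
    ref = list("ACGTACGTACGTACGTACGT")
    alt = ref.copy()
    for c in (2, 7, 12, 17):
        alt[c] = "A" if ref[c] != "A" else "C"
    return make_dictionary(
        {"A": {"A*01:01": {"exon2": "".join(ref)},
               "A*02:01": {"exon2": "".join(alt)}}}
    )


class TestPlumbingAlign:
    def test_exact_substring_placed_at_true_offset(self, toy_dictionary):
        d, _ = toy_dictionary
        cons = d.consensus("A")
        s, t = d.exon_bounds("A")["exon2"]
        frag = decode(cons[s + 30:s + 130])
        read = RawRead("r", frag, np.full(100, 30, dtype=np.int16))
        placed = plumbing_align(read, "A", d, exon="exon2")
        assert placed is not None and placed.start == s + 30

    def test_random_bases_unaligned(self, toy_dictionary):
        d, _ = toy_dictionary
        rng = np.random.default_rng(5)
        for _ in range(20):
            bases = "".join(rng.choice(list("ACGT"), size=120))
            read = RawRead("r", bases, np.full(120, 30, dtype=np.int16))
            assert plumbing_align(read, "A", d) is None

    def test_noisy_reads_recover_truth_placement(self, small_dataset):
        d = small_dataset.dictionary
        truth = small_dataset.read_truth.set_index("read_id")
        checked = 0
        for raw in small_dataset.reads[:300]:
            row = truth.loc[raw.id]
            insert = raw.bases[row.prefix_length:]
            quals = raw.qualities[row.prefix_length:]
            read = RawRead(raw.id, insert, quals)
            placed = plumbing_align(read, row.locus, d, exon=row.exon)
            assert placed is not None
            s = d.exon_bounds(row.locus)[row.exon][0]
            assert placed.start == s + row.start
            checked += 1
        assert checked == 300

    def test_reverse_strand_read_is_flipped_back(self, toy_dictionary):
        d, _ = toy_dictionary
        cons = d.consensus("A")
        s, _ = d.exon_bounds("A")["exon2"]
        frag = decode(cons[s + 10:s + 90])
        read = RawRead("r", revcomp(frag), np.full(80, 30, dtype=np.int16))
        placed = plumbing_align(read, "A", d, exon="exon2", strand="-")
        assert placed is not None
        assert placed.start == s + 10
        assert placed.bases == frag


class TestSamIngest:
    def test_truth_sam_roundtrip(self, small_dataset, tmp_path):
        path = tmp_path / "reads.sam"
        write_truth_sam(small_dataset, path)
        reads, stats = ingest_alignments(path, small_dataset.dictionary)
        assert stats.mapped == len(small_dataset.reads)
        truth = small_dataset.read_truth.set_index("read_id")
        d = small_dataset.dictionary
        for r in reads[:200]:
            row = truth.loc[r.id]
            assert r.sample == row["sample"]
            s = d.exon_bounds(row.locus)[row.exon][0]
            assert (r.locus, r.exon, r.start) == (row.locus, row.exon, s + row.start)

    def test_secondary_and_indel_records_skipped(self, tiny_dict, tmp_path):
        sam = tmp_path / "x.sam"
        sam.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:A|exon2\tLN:20\n"
            "S1:a\t0\tA|exon2\t1\t60\t8M\t*\t0\t0\tACGTACGT\tIIIIIIII\n"
            "S1:b\t256\tA|exon2\t1\t60\t8M\t*\t0\t0\tACGTACGT\tIIIIIIII\n"
            "S1:c\t0\tA|exon2\t1\t60\t4M1I3M\t*\t0\t0\tACGTAACG\tIIIIIIII\n"
            "S1:d\t4\t*\t0\t0\t*\t*\t0\t0\tACGT\tIIII\n"
        )
        reads, stats = ingest_alignments(sam, tiny_dict)
        assert [r.id for r in reads] == ["S1:a"]
        assert stats.skipped_secondary == 1
        assert stats.skipped_indel == 1
        assert stats.skipped_unmapped == 1

    def test_unknown_reference_is_fatal(self, tiny_dict, tmp_path):
        sam = tmp_path / "x.sam"
        sam.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:Z|exon9\tLN:20\n"
            "S1:a\t0\tZ|exon9\t1\t60\t4M\t*\t0\t0\tACGT\tIIII\n"
        )
        with pytest.raises(ValueError, match="Z\\|exon9"):
            ingest_alignments(sam, tiny_dict)

    def test_soft_clips_removed(self, tiny_dict, tmp_path):
        sam = tmp_path / "x.sam"
        sam.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:A|exon2\tLN:20\n"
            "S1:a\t0\tA|exon2\t3\t60\t2S4M2S\t*\t0\t0\tTTACGTGG\tIIIIIIII\n"
        )
        reads, _ = ingest_alignments(sam, tiny_dict)
        assert reads[0].bases == "ACGT"
        assert reads[0].start == 2


class TestMisalignmentFilter:
    def _read_matching(self, filter_dict, agree):
        """Read covering all 4 polymorphic columns, agreeing with allele 1
        (the alt allele) at ``agree`` of them and with neither elsewhere."""
        alt = decode(filter_dict.allele_codes("A", "A*02:01"))
        bases = list(alt)
        poly = list(filter_dict.polymorphic_columns("A"))
        for c in poly[agree:]:
            current = bases[c]
            ref = decode(filter_dict.allele_codes("A", "A*01:01"))[c]
            bases[c] = next(b for b in "ACGT" if b not in (current, ref))
        return make_read("S1", "A", "exon2", 0, "".join(bases))

    def test_perfect_agreement_kept(self, filter_dict):
        read = self._read_matching(filter_dict, 4)
        kept, removed = misalignment_filter([read], filter_dict)
        assert removed == 0 and len(kept) == 1

    def test_half_agreement_removed(self, filter_dict):
        read = self._read_matching(filter_dict, 2)
        assert snp_homology(read, filter_dict) == pytest.approx(0.5)
        kept, removed = misalignment_filter([read], filter_dict)
        assert removed == 1 and not kept

    def test_three_quarters_is_kept(self, filter_dict):
        # 3/4 = 0.75 attains the threshold; removal requires strictly below
        read = self._read_matching(filter_dict, 3)
        kept, removed = misalignment_filter([read], filter_dict)
        assert removed == 0 and len(kept) == 1

    def test_read_covering_no_polymorphic_column_kept(self, filter_dict):
        read = make_read("S1", "A", "exon2", 3, "TACG")  # columns 3-6
        kept, removed = misalignment_filter([read], filter_dict)
        assert removed == 0 and len(kept) == 1

    def test_idempotent(self, filter_dict):
        reads = [self._read_matching(filter_dict, k) for k in (4, 3, 2, 1)]
        kept, _ = misalignment_filter(reads, filter_dict)
        kept2, removed2 = misalignment_filter(kept, filter_dict)
        assert removed2 == 0
        assert [r.bases for r in kept2] == [r.bases for r in kept]

    def test_threshold_monotonicity(self, filter_dict):
        reads = [self._read_matching(filter_dict, k) for k in (4, 3, 2, 1)] * 3
        n_kept = [
            len(misalignment_filter(reads, filter_dict, threshold=t)[0])
            for t in (0.0, 0.25, 0.5, 0.75, 1.0)
        ]
        assert n_kept == sorted(n_kept, reverse=True)

    def test_on_target_reads_survive_decoy_reads_removed(self, toy_dictionary):
        # reads from locus A kept; reads force-placed at locus B removed
        d, f = toy_dictionary
        from hlacall import SimConfig, simulate_reads

        ds = simulate_reads(d, f, SimConfig(n_samples=4, mean_coverage=30,
                                            error_rate=0.05, seed=55))
        truth = ds.read_truth.set_index("read_id")
        on_target, decoys = [], []
        for raw in ds.reads:
            row = truth.loc[raw.id]
            if row.locus != "A":
                continue
            insert = raw.bases[row.prefix_length:]
            quals = raw.qualities[row.prefix_length:]
            s = d.exon_bounds("A")[row.exon][0]
            on_target.append(make_read(row.sample, "A", row.exon,
                                       s + row.start, insert))
            decoys.append(make_read(row.sample, "B", row.exon,
                                    s + row.start, insert))
        kept_on, _ = misalignment_filter(on_target, d)
        kept_decoy, _ = misalignment_filter(decoys, d)
        assert len(kept_on) >= 0.99 * len(on_target)
        assert len(kept_decoy) <= 0.05 * len(decoys)


class TestDepthOfCoverage:
    def test_uniform_cover(self, tiny_dict):
        reads = [make_read("S1", "A", "exon2", 0, "ACGTACGTACGTACGTACGT")
                 for _ in range(10)]
        cov = depth_of_coverage(reads, tiny_dict)
        assert cov.mean("S1", "A", "exon2") == 10
        assert (cov.vector("S1", "A") == 10).all()

    def test_zero_reads_flagged_uncovered(self, tiny_dict):
        cov = depth_of_coverage([], tiny_dict, samples=["S1"])
        assert cov.mean("S1", "A", "exon2") == 0.0
        frame = cov.to_frame()
        assert not frame["covered"].any()

    def test_staggered_half_cover(self, tiny_dict):
        # 8 reads over the first half; second half uncovered -> mean 4
        reads = [make_read("S1", "A", "exon2", 0, "ACGTACGTAC")
                 for _ in range(8)]
        cov = depth_of_coverage(reads, tiny_dict)
        assert cov.mean("S1", "A", "exon2") == pytest.approx(4.0)
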