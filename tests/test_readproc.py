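"""Read clipping, alignment filtering, RT-stop inference and count accumulation."""

from collections import Counter

import numpy as np
import pytest

from tstructseq import readproc
from tstructseq.readproc import (
    AlignedRead,
    PrimerEntry,
    PrimerPanel,
    TranscriptRef,
    accumulate_counts,
    assign_primers,
    clip_reads,
    filter_alignments,
    infer_termination,
)


def _read(start, end, mm=0, w=1.0, rid="r", primer=None):
    return AlignedRead(read_id=rid, transcript="tx", start=start, end=end,
                       aligned_length=end - start + 1, mismatches=mm, weight=w,
                       primer=primer)


class TestClipReads:
    def test_removes_fixed_prefix(self):
        clipped, skipped = clip_reads([("r1", "NNNACGT", "IIIIIII")])
        assert clipped == [("r1", "ACGT", "IIII")]
        assert skipped == 0

    def test_short_read_skipped_with_counter(self):
        clipped, skipped = clip_reads([("r1", "NNN", "III")])
        assert clipped == []
        assert skipped == 1

    def test_empty_input(self):
        assert clip_reads([]) == ([], 0)

    def test_seqrecord_qualities_clipped_in_lockstep(self):
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord

        rec = SeqRecord(Seq("NNNACGT"), id="r1",
                        letter_annotations={"phred_quality": [1, 2, 3, 30, 31, 32, 33]})
        clipped, _ = clip_reads([rec])
        assert str(clipped[0].seq) == "ACGT"
        assert clipped[0].letter_annotations["phred_quality"] == [30, 31, 32, 33]

    def test_order_preserved(self):
        recs = [("a", "NNNAAAA", None), ("b", "NNNCCCC", None)]
        clipped, _ = clip_reads(recs)
        assert [c[0] for c in clipped] == ["a", "b"]


class TestFilterAlignments:
    @pytest.mark.parametrize("length,mm,kept", [
        (59, 0, False),   # below minimum aligned length
        (60, 2, True),    # both boundaries inclusive
        (60, 0, True),
        (75, 3, False),   # too many mismatches
    ])
    def test_boundaries(self, length, mm, kept):
        reads = [_read(1, length, mm=mm)]
        assert bool(filter_alignments(reads)) is kept

    def test_missing_mismatch_field_discarded_with_own_tally(self):
        tally = Counter()
        out = filter_alignments([_read(1, 80, mm=None)], tally=tally)
        assert out == []
        assert tally == {"missing_mismatch_field": 1}

    def test_idempotent(self, rng):
        reads = [_read(1, int(rng.integers(40, 120)), mm=int(rng.integers(0, 5)))
                 for _ in range(200)]
        once = filter_alignments(reads)
        assert filter_alignments(once) == once


class TestInferTermination:
    def test_stop_one_before_alignment_start(self):
        assert infer_termination(_read(101, 180)) == 100

    def test_runoff_read_has_no_termination(self):
        assert infer_termination(_read(1, 80)) == 0

    def test_multimapped_weights_split_terminations(self):
        sites = [_read(101, 180, w=0.5), _read(501, 580, w=0.5)]
        primer = PrimerEntry("P", 610, 630)
        tc = accumulate_counts(sites, primer, "treated", 700)
        assert tc.n[100] == pytest.approx(0.5)
        assert tc.n[500] == pytest.approx(0.5)
        # weight conservation across alignment sites
        assert tc.n.sum() == pytest.approx(1.0)


class TestAccumulateCounts:
    def test_coverage_and_primer_exclusion(self):
        primer = PrimerEntry("P", 181, 205)
        tc = accumulate_counts([_read(101, 180)], primer, "treated", 300)
        assert tc.n[100] == 1
        assert np.all(tc.r[101:156] == 1)          # > 25 nt from the annealing site
        assert np.all(tc.r[156:181] == 0)          # within 25 nt: excluded
        assert tc.excluded[156] and not tc.excluded[155]

    def test_no_reads_gives_all_zero(self):
        tc = accumulate_counts([], PrimerEntry("P", 181, 205), "treated", 300)
        assert tc.n.sum() == 0 and tc.r.sum() == 0

    def test_additivity_over_read_lists(self, rng):
        primer = PrimerEntry("P", 281, 300)
        reads = [_read(int(a), int(a) + 60, rid=f"r{k}")
                 for k, a in enumerate(rng.integers(2, 200, size=50))]
        whole = accumulate_counts(reads, primer, "t", 400)
        part1 = accumulate_counts(reads[:20], primer, "t", 400)
        part2 = accumulate_counts(reads[20:], primer, "t", 400)
        combined = part1 + part2
        np.testing.assert_allclose(whole.n, combined.n)
        np.testing.assert_allclose(whole.r, combined.r)

    def test_two_identical_reads_double_the_count(self):
        primer = PrimerEntry("P", 281, 300)
        tc = accumulate_counts([_read(101, 180), _read(101, 180)], primer, "t", 400)
        assert tc.n[100] == 2

    def test_no_readthrough_at_own_termination_position(self, rng):
        primer = PrimerEntry("P", 281, 300)
        for a in rng.integers(30, 250, size=20):
            tc = accumulate_counts([_read(int(a), int(a) + 30)], primer, "t", 400)
            assert tc.r[int(a) - 1] == 0 or tc.excluded[int(a) - 1]

    def test_out_of_bounds_read_discarded(self):
        primer = PrimerEntry("P", 181, 205)
        tc = accumulate_counts([_read(250, 320)], primer, "t", 300)
        assert tc.n.sum() == 0 and tc.r.sum() == 0

    def test_totals_conserved(self):
        primer = PrimerEntry("P", 281, 300)
        reads = [_read(101, 180), _read(50, 180), _read(1, 180)]  # last is run-off
        tc = accumulate_counts(reads, primer, "t", 400)
        assert tc.n.sum() <= tc.total_weight


class TestPrimerAssignment:
    def test_assignment_by_proximity_to_annealing_site(self):
        panel = PrimerPanel([PrimerEntry("P1", 200, 219), PrimerEntry("P2", 400, 419)],
                            min_pool_spacing=0)
        assigned, dropped = assign_primers([_read(100, 199), _read(250, 399)], panel)
        assert [r.primer for r in assigned] == ["P1", "P2"]
        assert dropped == 0

    def test_off_target_read_dropped(self):
        panel = PrimerPanel([PrimerEntry("P1", 400, 419)], min_pool_spacing=0)
        assigned, dropped = assign_primers([_read(10, 80)], panel)
        assert assigned == [] and dropped == 1

    def test_slack_window(self):
        panel = PrimerPanel([PrimerEntry("P1", 200, 219)], min_pool_spacing=0)
        ok, _ = assign_primers([_read(100, 194)], panel, slack=5)
        assert ok and ok[0].primer == "P1"
        none, dropped = assign_primers([_read(100, 193)], panel, slack=5)
        assert dropped == 1


class TestPanelAndTranscript:
    def test_transcript_converts_t_and_validates(self):
        tx = TranscriptRef(name="x", sequence="ACGT")
        assert tx.sequence == "ACGU" and tx.length == 4 and tx.base(4) == "U"
        with pytest.raises(ValueError):
            TranscriptRef(name="x", sequence="ACGX")

    def test_close_primers_in_pool_warn(self):
        with pytest.warns(UserWarning, match="apart"):
            PrimerPanel([PrimerEntry("a", 100, 119, pool="1"),
                         PrimerEntry("b", 300, 319, pool="1")])

    def test_primer_beyond_transcript_is_error(self):
        with pytest.raises(ValueError, match="exceeds"):
            PrimerPanel([PrimerEntry("a", 100, 119)], transcript_length=110)


class TestSamRoundTrip:
    def test_simulated_sam_reingests_identically(self, tmp_path, sim_experiment):
        from tstructseq import simdata

        _, truth, treated, _ = sim_experiment
        sam = tmp_path / "t.sam"
        subset = treated[:500]
        simdata.reads_to_sam(subset, truth, sam)
        back = readproc.read_sam(sam, transcript=truth.transcript.name)
        assert len(back) == len(subset)
        for orig, new in zip(sorted(subset, key=lambda r: r.read_id),
                             sorted(back, key=lambda r: r.read_id)):
            assert (orig.start, orig.end, orig.aligned_length) == \
                   (new.start, new.end, new.aligned_length)

    def test_multimapped_nh_tag_weights(self, tmp_path):
        sam = tmp_path / "m.sam"
        sam.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:tx\tLN:700\n"
            "r1\t0\ttx\t101\t42\t80M\t*\t0\t0\t" + "A" * 80 + "\t*\tNM:i:0\tNH:i:2\n"
            "r1\t256\ttx\t501\t42\t80M\t*\t0\t0\t" + "A" * 80 + "\t*\tNM:i:0\tNH:i:2\n")
        reads = readproc.read_sam(sam)
        assert len(reads) == 2
        assert sum(r.weight for r in reads) == pytest.approx(1.0)

    def test_fastq_clip_path(self, tmp_path, sim_experiment):
        from tstructseq import simdata

        _, truth, treated, _ = sim_experiment
        fq = tmp_path / "raw.fastq"
        simdata.reads_to_fastq(treated[:20], truth, fq)
        out = tmp_path / "clipped.fastq"
        skipped = readproc.clip_fastq(fq, out)
        assert skipped == 0
        from Bio import SeqIO

        recs = list(SeqIO.parse(str(out), "fastq"))
        assert len(recs) == 20
        assert all(not str(r.seq).startswith("NNN") for r in recs)
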