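import numpy as np
import pytest
from Bio.Seq import Seq

from trbdisorder.synthetic_data import (CohortConfig, backtranslate,
                                        simulate_cohort)
from trbdisorder.vdj_mining import (REASON_FRAMESHIFT, REASON_STOP_CODON,
                                    Rejection, RecombinationRead,
                                    SequencingRead, extract_cdr3,
                                    match_segment, mine_reads)


def make_read(seq: str, read_id: str = "r1", case_id: str = "caseA") -> SequencingRead:
    return SequencingRead(read_id=read_id, case_id=case_id, seq=seq)


def planted_read(v, j, middle_aa: str, v_extra: int = 3, j_tail: int = 3,
                 mid_nt: str | None = None) -> str:
    """Germline V window + v_extra codons + junction middle + J from j_tail
    residues before the doublet — the layout the generator plants."""
    cys_end = 3 * v.cys_index + 3
    v_part = v.nt_seq[: cys_end + 3 * v_extra]
    if mid_nt is None:
        mid_nt = backtranslate(middle_aa)
    j_part = j.nt_seq[3 * (j.fg_index - j_tail):]
    return v_part + mid_nt + j_part


class TestMatchSegment:
    def test_planted_v_terminus_found_at_correct_offset(self, toy_reference):
        v = toy_reference.v("TRBV02")
        window = v.anchor_window_nt
        planted = window[-30:]
        seq = "A" * 17 + planted + "G" * 40
        match = match_segment(seq, v, min_match=15)
        assert match is not None
        assert match.length >= 30
        assert match.read_start + match.length == 17 + 30

    def test_match_below_threshold_is_none(self, toy_reference):
        v = toy_reference.v("TRBV02")
        planted = v.anchor_window_nt[-14:]
        seq = "A" * 20 + planted + "G" * 40
        assert match_segment(seq, v, min_match=15) is None

    def test_random_reads_never_match_at_default_threshold(self, toy_reference):
        # chance of a 20-nt exact match per offset is 4^-20; expect 0 over 1,000 reads
        rng = np.random.default_rng(7)
        nt = np.array(list("ACGT"))
        segments = list(toy_reference.v_segments.values())
        hits = 0
        for _ in range(1000):
            seq = "".join(nt[rng.integers(0, 4, size=100)])
            hits += sum(
                match_segment(seq, seg, min_match=20) is not None
                for seg in segments
            )
        assert hits == 0

    def test_min_match_must_be_positive(self, toy_reference):
        with pytest.raises(ValueError):
            match_segment("ACGT", toy_reference.v("TRBV01"), min_match=0)


class TestExtractCdr3:
    """The worked junction: V 'MGIRLLCASS' + middle 'LGE' + J tail 'TQY'F
    reads out as CDR3 'CASSLGETQYF'."""

    def test_planted_junction_recovers_ground_truth_cdr3(self, toy_reference):
        v, j = toy_reference.v("TRBV01"), toy_reference.j("TRBJ01")
        read = make_read(planted_read(v, j, "LGE"))
        result = mine_reads([read], toy_reference)
        assert len(result.accepted) == 1
        rec = result.accepted[0]
        assert (rec.v_id, rec.j_id, rec.cdr3_aa) == ("TRBV01", "TRBJ01", "CASSLGETQYF")
        assert len(rec.cdr3_nt) == 3 * len(rec.cdr3_aa)

    def test_single_deleted_nucleotide_is_a_frameshift(self, toy_reference):
        v, j = toy_reference.v("TRBV01"), toy_reference.j("TRBJ01")
        mid = backtranslate("LGE")
        read = make_read(planted_read(v, j, "LGE", mid_nt=mid[:-1]))
        result = mine_reads([read], toy_reference)
        assert not result.accepted
        assert result.rejected[0].reason == REASON_FRAMESHIFT

    def test_in_frame_stop_codon_rejected(self, toy_reference):
        v, j = toy_reference.v("TRBV01"), toy_reference.j("TRBJ01")
        read = make_read(planted_read(v, j, "LGE", mid_nt="TAA" + backtranslate("GE")))
        result = mine_reads([read], toy_reference)
        assert not result.accepted
        assert result.rejected[0].reason == REASON_STOP_CODON

    def test_unknown_segment_id_is_an_error(self, toy_reference):
        v, j = toy_reference.v("TRBV01"), toy_reference.j("TRBJ01")
        read = make_read(planted_read(v, j, "LGE"))
        v_match = match_segment(read.seq, v, 20)
        j_match = match_segment(read.seq, j, 15)
        bad = type(v_match)(segment_id="TRBV99", read_start=v_match.read_start,
                            length=v_match.length)
        with pytest.raises(KeyError, match="TRBV99"):
            extract_cdr3(read, bad, j_match, toy_reference)


class TestMineReads:
    def test_planted_cohort_mined_with_full_recall_and_precision(self):
        config = CohortConfig(n_cases=1, n_recomb_per_case=10,
                              n_background_per_case=990, seed=5)
        cohort = simulate_cohort(config)
        result = mine_reads(cohort.reads, cohort.reference)
        truth = {(p.case_id, p.read_id): (p.v_id, p.j_id, p.cdr3_aa)
                 for p in cohort.truth.plants if p.productive}
        mined = {(r.case_id, r.read_id): (r.v_id, r.j_id, r.cdr3_aa)
                 for r in result.accepted}
        assert mined == truth  # recall 1.0 and precision 1.0, calls exact

    def test_empty_read_set_yields_empty_output(self, toy_reference):
        result = mine_reads([], toy_reference)
        assert result.accepted == [] and result.rejected == []

    def test_every_read_accounted_for_exactly_once(self, small_cohort):
        result = mine_reads(small_cohort.reads, small_cohort.reference)
        assert len(result.accepted) + len(result.rejected) == len(small_cohort.reads)
        seen = {(r.case_id, r.read_id) for r in result.accepted}
        seen |= {(r.case_id, r.read_id) for r in result.rejected}
        assert len(seen) == len(small_cohort.reads)

    def test_mining_is_strand_symmetric(self, small_cohort):
        reference = small_cohort.reference
        reads = small_cohort.reads[:120]
        flipped = [SequencingRead(r.read_id, r.case_id,
                                  str(Seq(r.seq).reverse_complement()))
                   for r in reads]
        calls = lambda res: sorted((r.v_id, r.j_id, r.cdr3_aa) for r in res.accepted)
        assert calls(mine_reads(reads, reference)) == calls(mine_reads(flipped, reference))

    def test_nonproductive_plants_rejected_with_their_defect(self):
        config = CohortConfig(n_cases=2, n_recomb_per_case=8,
                              n_background_per_case=0,
                              nonproductive_fraction=1.0, seed=9)
        cohort = simulate_cohort(config)
        result = mine_reads(cohort.reads, cohort.reference)
        assert not result.accepted
        reasons = {(r.case_id, r.read_id): r.reason for r in result.rejected}
        for plant in cohort.truth.plants:
            assert reasons[(plant.case_id, plant.read_id)] == plant.defect
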