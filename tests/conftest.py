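import pytest

from trbdisorder.reference_io import JGeneSegment, Reference, VGeneSegment
from trbdisorder.synthetic_data import CohortConfig, backtranslate, simulate_cohort


def v_segment(seg_id: str, aa: str, cys_index: int) -> VGeneSegment:
    return VGeneSegment.from_nt(seg_id, backtranslate(aa), cys_index=cys_index)


def j_segment(seg_id: str, aa: str, fg_index: int) -> JGeneSegment:
    return JGeneSegment.from_nt(seg_id, backtranslate(aa), fg_index=fg_index)


@pytest.fixture(scope="session")
def toy_reference() -> Reference:
    """Three V and two J segments with hand-placed anchors.

    TRBV01 ends ...LLCASS with the conserved Cys at index 6; TRBJ01 carries
    its FG doublet after the CDR3-tail context 'TQY', TRBJ02 after 'EAF'.
    """
    ref = Reference()
    ref.add(v_segment("TRBV01", "MGIRLLCASS", 6))
    ref.add(v_segment("TRBV02", "MKWTLDPEGALYLCASS", 13))
    ref.add(v_segment("TRBV03", "MNHEYQAVKDTICVVG", 12))
    ref.add(j_segment("TRBJ01", "NSTQYFGPGTRLTVT", 5))
    ref.add(j_segment("TRBJ02", "NTEAFFGQGTRLTVV", 5))
    return ref


@pytest.fixture(scope="session")
def small_cohort():
    """A small synthetic cohort shared by read-level tests."""
    config = CohortConfig(n_cases=12, n_recomb_per_case=10,
                          n_background_per_case=20, seed=42)
    return simulate_cohort(config)
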