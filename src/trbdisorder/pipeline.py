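"""End-to-end convenience: reads -> mining -> assembly -> scoring -> survival."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .reference_io import ClinicalRecord, Reference
from .region_assembly import AssemblyResult, assemble_all
from .scoring import CaseScore, ScoreTrack, case_average, score_regions
from .survival import StratificationReport, stratify_and_test
from .vdj_mining import (DEFAULT_MIN_MATCH_J, DEFAULT_MIN_MATCH_V,
                         MiningResult, SequencingRead, mine_reads)


@dataclass
class PipelineResult:
    mining: MiningResult
    assembly: AssemblyResult
    case_scores: list[CaseScore]
    report: StratificationReport


def run_pipeline(reads: Iterable[SequencingRead],
                 reference: Reference,
                 clinical: Iterable[ClinicalRecord],
                 tracks: Mapping[str, ScoreTrack] | None = None,
                 parameter: str = "track:disorder",
                 track_channels: Sequence[str] = ("disorder",),
                 min_match_v: int = DEFAULT_MIN_MATCH_V,
                 min_match_j: int = DEFAULT_MIN_MATCH_J) -> PipelineResult:
    """Run the whole analysis for one cohort and one stratification parameter.

    ``parameter`` may be a residue-set fraction (e.g. ``disorder_fraction``)
    or a track mean (``track:<channel>``, requiring ``tracks`` keyed by
    ``case_id|read_id``).
    """
    mining = mine_reads(reads, reference, min_match_v=min_match_v,
                        min_match_j=min_match_j)
    assembly = assemble_all(mining.accepted, reference)
    seq_scores = score_regions(
        assembly.regions,
        tracks=tracks if parameter.startswith("track:") else None,
        track_channels=track_channels,
    )
    case_scores = case_average(seq_scores)
    report = stratify_and_test(case_scores, clinical, parameter)
    return PipelineResult(mining=mining, assembly=assembly,
                          case_scores=case_scores, report=report)
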