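"""Synthetic cohorts with known ground truth for end-to-end testing.

Generates everything the pipeline consumes: a toy V/J gene-segment reference,
per-case read sets in which recombined V-CDR3-J junctions are planted inside
uniform-random genomic background, stand-in per-residue disorder tracks, and
survival times whose hazard depends on each case's mean disorder.

A planted read is built from germline nucleotides so the miner can recover it
exactly: a suffix of the V ending at the conserved-Cys codon plus a few
germline residues beyond it, a back-translated junction middle whose
composition follows the case's disorder propensity, and the J from a few
residues before the FG doublet through its 3' end.  Back-translation uses a
fixed codon table (lexicographically first codon per amino acid) for
determinism.

The stand-in disorder track scores each residue ``base + effect *
1[residue is disorder-promoting] + noise``, clipped to [0, 1] — a monotone
stand-in whose case means the survival simulator converts into exponential
event times with a configurable hazard ratio between the upper and lower
disorder halves, under independent uniform censoring.  By default low
disorder implies longer survival.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq
from scipy.optimize import brentq

from .reference_io import (ClinicalRecord, JGeneSegment, Reference,
                           VGeneSegment, write_clinical, write_reference)
from .region_assembly import VariableRegion, assemble
from .scoring import DISORDER_PROMOTING, AA_ALPHABET, ScoreTrack, write_track
from .vdj_mining import RecombinationRead, SequencingRead

logger = logging.getLogger(__name__)

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
NT_ORDER = np.array(list("ACGT"))

#: fixed back-translation: lexicographically first codon per amino acid
BACKTRANSLATION: dict[str, str] = {}
for codon, aa in sorted(standard_dna_table.forward_table.items()):
    BACKTRANSLATION.setdefault(aa, codon)

ORDER_POOL = sorted(set(AA_ALPHABET) - DISORDER_PROMOTING - {"C"})
DISORDER_POOL = sorted(DISORDER_PROMOTING)

LOW_DISORDER_BETTER = "low_disorder_better"
HIGH_DISORDER_BETTER = "high_disorder_better"


def backtranslate(aa_seq: str) -> str:
    return "".join(BACKTRANSLATION[aa] for aa in aa_seq)


def _random_aa(rng: np.random.Generator, n: int, pool: str | list[str] = AA_ORDER) -> str:
    pool = list(pool)
    return "".join(pool[i] for i in rng.integers(0, len(pool), size=n))


def _random_nt(rng: np.random.Generator, n: int) -> str:
    return "".join(NT_ORDER[rng.integers(0, 4, size=n)])


@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort."""

    n_cases: int = 64
    n_recomb_per_case: int = 20
    n_background_per_case: int = 80
    mid_len_range: tuple[int, int] = (2, 6)   # junction middle, amino acids
    v_overlap_residues: int = 3               # germline residues after the Cys
    j_tail_residues: int = 4                  # germline residues before the doublet F
    v_plant_nt: int = 30                      # V nucleotides planted before the Cys codon end
    read_length: int = 150
    nonproductive_fraction: float = 0.0
    hazard_ratio: float = 4.0
    censoring_fraction: float = 0.2
    baseline_mean_months: float = 60.0
    direction: str = LOW_DISORDER_BETTER
    disorder_base: float = 0.25
    disorder_effect: float = 0.5
    track_noise_sd: float = 0.05
    rho_range: tuple[float, float] = (0.25, 0.85)  # per-case disorder propensity
    n_v: int = 3
    n_j: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hazard_ratio <= 0:
            raise ValueError("hazard_ratio must be > 0")
        if not (0 <= self.censoring_fraction < 1):
            raise ValueError("censoring_fraction must be in [0, 1)")
        if min(self.n_cases, self.n_recomb_per_case, self.n_background_per_case) < 0:
            raise ValueError("counts must be >= 0")
        if self.direction not in (LOW_DISORDER_BETTER, HIGH_DISORDER_BETTER):
            raise ValueError(f"unknown direction {self.direction!r}")


@dataclass(frozen=True)
class PlantTruth:
    """Ground truth for one planted recombination read."""

    read_id: str
    case_id: str
    v_id: str
    j_id: str
    cdr3_aa: Optional[str]     # None for non-productive plants
    cdr3_nt: Optional[str]
    productive: bool
    defect: Optional[str]      # 'frameshift' | 'stop_codon' | None
    strand: str


@dataclass
class CaseTruth:
    case_id: str
    rho: float
    mean_disorder: Optional[float]
    group: Optional[str]               # 'lower' | 'upper' (by true disorder mean)
    event_time_months: float
    os_months: float
    event: int


@dataclass
class GroundTruth:
    plants: list[PlantTruth]
    cases: dict[str, CaseTruth]


@dataclass
class SyntheticCohort:
    config: CohortConfig
    reference: Reference
    reads: list[SequencingRead]
    regions: dict[str, VariableRegion]   # truth regions, keyed by case_id|read_id
    tracks: dict[str, ScoreTrack]
    clinical: list[ClinicalRecord]
    truth: GroundTruth


def make_reference(n_v: int = 3, n_j: int = 2, seed: int = 0) -> Reference:
    """A toy V/J reference with valid anchors, deterministic given the seed.

    V segments are ~30 amino acids with the conserved Cys three residues from
    the 3' end; J segments place the FG doublet after a short 5' region, with
    a CDR3-tail context before it and a framework tail after it.
    """
    if n_v < 1 or n_j < 1:
        raise ValueError("need at least one V and one J segment")
    rng = np.random.default_rng(seed)
    reference = Reference()
    for i in range(1, n_v + 1):
        prefix = _random_aa(rng, 26, pool=sorted(set(AA_ORDER) - {"C"}))
        tail = _random_aa(rng, 3, pool=sorted(set(AA_ORDER) - {"C"}))
        aa = prefix + "C" + tail
        reference.add(VGeneSegment.from_nt(f"TRBV{i}", backtranslate(aa), cys_index=26))
    for i in range(1, n_j + 1):
        while True:
            prefix = _random_aa(rng, 5)
            tail = _random_aa(rng, 8)
            aa = prefix + "FG" + tail
            if aa.find("FG") == 5:
                break
        reference.add(JGeneSegment.from_nt(f"TRBJ{i}", backtranslate(aa), fg_index=5))
    return reference


def _build_plant(rng: np.random.Generator, config: CohortConfig,
                 v: VGeneSegment, j: JGeneSegment, rho: float,
                 defect: Optional[str]) -> tuple[str, Optional[str], Optional[str]]:
    """Plant nucleotides and (cdr3_aa, cdr3_nt) ground truth (None if defective)."""
    u = min(config.v_overlap_residues, len(v.aa_seq) - v.cys_index - 1)
    t = min(config.j_tail_residues, j.fg_index)
    mid_len = int(rng.integers(config.mid_len_range[0], config.mid_len_range[1] + 1))
    middle = ""
    for _ in range(mid_len):
        pool = DISORDER_POOL if rng.random() < rho else ORDER_POOL
        middle += pool[int(rng.integers(0, len(pool)))]

    cys_end = 3 * v.cys_index + 3
    v_part = v.nt_seq[cys_end - config.v_plant_nt : cys_end + 3 * u]
    mid_nt = backtranslate(middle)
    j_part = j.nt_seq[3 * (j.fg_index - t) :]

    if defect == "frameshift":
        pos = int(rng.integers(0, len(mid_nt) + 1))
        mid_nt = mid_nt[:pos] + NT_ORDER[int(rng.integers(0, 4))] + mid_nt[pos:]
        return v_part + mid_nt + j_part, None, None
    if defect == "stop_codon":
        mid_nt = "TAA" + mid_nt[3:]
        return v_part + mid_nt + j_part, None, None

    cdr3_aa = ("C" + v.aa_seq[v.cys_index + 1 : v.cys_index + 1 + u]
               + middle + j.aa_seq[j.fg_index - t : j.fg_index] + "F")
    cdr3_nt = (v.nt_seq[3 * v.cys_index : cys_end + 3 * u] + mid_nt
               + j.nt_seq[3 * (j.fg_index - t) : 3 * j.fg_index + 3])
    return v_part + mid_nt + j_part, cdr3_aa, cdr3_nt


def _embed(rng: np.random.Generator, plant_nt: str, read_length: int) -> tuple[str, str]:
    """Embed the plant in random background at a random offset, random strand."""
    if len(plant_nt) >= read_length:
        seq = plant_nt
    else:
        pad = read_length - len(plant_nt)
        offset = int(rng.integers(0, pad + 1))
        bg = _random_nt(rng, pad)
        seq = bg[:offset] + plant_nt + bg[offset:]
    if rng.random() < 0.5:
        return str(Seq(seq).reverse_complement()), "reverse-complement"
    return seq, "forward"


def simulate_reads(config: CohortConfig, reference: Reference,
                   rng: np.random.Generator) -> tuple[list[SequencingRead], list[PlantTruth], dict[str, float]]:
    """Per-case read sets with planted recombination reads; returns the reads,
    the plant-level ground truth, and each case's disorder propensity rho."""
    v_list = sorted(reference.v_segments.values(), key=lambda s: s.id)
    j_list = sorted(reference.j_segments.values(), key=lambda s: s.id)
    reads: list[SequencingRead] = []
    plants: list[PlantTruth] = []
    rhos: dict[str, float] = {}
    for c in range(1, config.n_cases + 1):
        case_id = f"case{c:03d}"
        rho = float(rng.uniform(*config.rho_range))
        rhos[case_id] = rho
        for r in range(config.n_recomb_per_case):
            read_id = f"{case_id}_recomb{r:04d}"
            v = v_list[int(rng.integers(0, len(v_list)))]
            j = j_list[int(rng.integers(0, len(j_list)))]
            defect = None
            if rng.random() < config.nonproductive_fraction:
                defect = "frameshift" if rng.random() < 0.5 else "stop_codon"
            plant_nt, cdr3_aa, cdr3_nt = _build_plant(rng, config, v, j, rho, defect)
            seq, strand = _embed(rng, plant_nt, config.read_length)
            reads.append(SequencingRead(read_id=read_id, case_id=case_id, seq=seq))
            plants.append(PlantTruth(
                read_id=read_id, case_id=case_id, v_id=v.id, j_id=j.id,
                cdr3_aa=cdr3_aa, cdr3_nt=cdr3_nt,
                productive=defect is None, defect=defect, strand=strand,
            ))
        for b in range(config.n_background_per_case):
            reads.append(SequencingRead(
                read_id=f"{case_id}_bg{b:04d}", case_id=case_id,
                seq=_random_nt(rng, config.read_length),
            ))
    return reads, plants, rhos


def standin_disorder_track(aa_seq: str, rng: np.random.Generator,
                           seq_id: str = "seq",
                           base: float = 0.25, effect: float = 0.5,
                           noise_sd: float = 0.05) -> ScoreTrack:
    """Stand-in per-residue disorder scorer, monotone in the disorder-promoting
    fraction: ``base + effect * indicator + Normal(0, noise_sd)``, clipped."""
    indicator = np.array([aa in DISORDER_PROMOTING for aa in aa_seq], dtype=float)
    values = base + effect * indicator
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=len(aa_seq))
    values = np.clip(values, 0.0, 1.0)
    return ScoreTrack(seq_id=seq_id, residues=aa_seq, channels={"disorder": values})


def simulate_survival(case_means: Mapping[str, Optional[float]],
                      config: CohortConfig,
                      rng: np.random.Generator) -> tuple[list[ClinicalRecord], dict[str, CaseTruth]]:
    """Exponential survival with a hazard-ratio step at the cohort's median
    true disorder, under independent Uniform(0, m) censoring with m solved so
    the expected censored fraction matches the configuration.

    Cases with no disorder mean (no productive reads) keep the baseline
    hazard and no group label.
    """
    scored = sorted((v, k) for k, v in case_means.items() if v is not None)
    n_lower = math.ceil(len(scored) / 2)
    groups: dict[str, str] = {}
    for i, (_, case_id) in enumerate(scored):
        groups[case_id] = "lower" if i < n_lower else "upper"

    lam0 = 1.0 / config.baseline_mean_months
    hazards: dict[str, float] = {}
    for case_id in sorted(case_means):
        group = groups.get(case_id)
        boosted = (group == "upper") if config.direction == LOW_DISORDER_BETTER \
            else (group == "lower")
        hazards[case_id] = lam0 * config.hazard_ratio if boosted else lam0

    lams = np.array([hazards[c] for c in sorted(hazards)])

    def expected_censored(m: float) -> float:
        return float(np.mean((1.0 - np.exp(-lams * m)) / (lams * m)))

    if config.censoring_fraction > 0:
        m = brentq(lambda x: expected_censored(x) - config.censoring_fraction,
                   1e-9, 1e9)
    else:
        m = None

    clinical: list[ClinicalRecord] = []
    truth: dict[str, CaseTruth] = {}
    for case_id in sorted(case_means):
        t_event = float(rng.exponential(1.0 / hazards[case_id]))
        if m is None:
            os_months, event = t_event, 1
        else:
            c_time = float(rng.uniform(0.0, m))
            os_months, event = min(t_event, c_time), int(t_event <= c_time)
        clinical.append(ClinicalRecord(case_id=case_id, os_months=os_months, event=event))
        truth[case_id] = CaseTruth(
            case_id=case_id, rho=float("nan"),
            mean_disorder=case_means[case_id], group=groups.get(case_id),
            event_time_months=t_event, os_months=os_months, event=event,
        )
    return clinical, truth


def simulate_cohort(config: CohortConfig | None = None,
                    out_dir: str | Path | None = None) -> SyntheticCohort:
    """Generate a full cohort; optionally write it to disk.

    Files written: ``ref.fa``, ``anchors.tsv``, ``reads/<case>.fastq``,
    ``manifest.tsv``, ``tracks/<seq_id>.tsv`` (``|`` encoded as ``__``),
    ``clinical.tsv``, ``truth.json``.  Byte-identical under a fixed seed.
    """
    config = config or CohortConfig()
    rng = np.random.default_rng(config.seed)
    reference = make_reference(config.n_v, config.n_j, seed=config.seed)
    reads, plants, rhos = simulate_reads(config, reference, rng)

    regions: dict[str, VariableRegion] = {}
    tracks: dict[str, ScoreTrack] = {}
    case_region_means: dict[str, list[float]] = {c: [] for c in rhos}
    for plant in plants:
        if not plant.productive:
            continue
        rec = RecombinationRead(
            read_id=plant.read_id, case_id=plant.case_id,
            v_id=plant.v_id, j_id=plant.j_id,
            cdr3_aa=plant.cdr3_aa, cdr3_nt=plant.cdr3_nt, strand=plant.strand,
        )
        region = assemble(rec, reference)
        if isinstance(region, VariableRegion):
            regions[region.seq_id] = region
            track = standin_disorder_track(
                region.aa_seq, rng, seq_id=region.seq_id,
                base=config.disorder_base, effect=config.disorder_effect,
                noise_sd=config.track_noise_sd,
            )
            tracks[region.seq_id] = track
            case_region_means[plant.case_id].append(
                float(np.mean(track.channels["disorder"]))
            )

    case_means: dict[str, Optional[float]] = {
        c: (float(np.mean(v)) if v else None) for c, v in case_region_means.items()
    }
    clinical, case_truth = simulate_survival(case_means, config, rng)
    for case_id, rho in rhos.items():
        case_truth[case_id].rho = rho

    cohort = SyntheticCohort(
        config=config, reference=reference, reads=reads, regions=regions,
        tracks=tracks, clinical=clinical,
        truth=GroundTruth(plants=plants, cases=case_truth),
    )
    if out_dir is not None:
        write_cohort(cohort, out_dir)
    return cohort


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    (out_dir / "reads").mkdir(parents=True, exist_ok=True)
    (out_dir / "tracks").mkdir(exist_ok=True)
    write_reference(cohort.reference, out_dir / "ref.fa", out_dir / "anchors.tsv")

    by_case: dict[str, list[SequencingRead]] = {}
    for read in cohort.reads:
        by_case.setdefault(read.case_id, []).append(read)
    with open(out_dir / "manifest.tsv", "w") as manifest:
        manifest.write("case_id\tpath\n")
        for case_id in sorted(by_case):
            rel = f"reads/{case_id}.fastq"
            manifest.write(f"{case_id}\t{rel}\n")
            with open(out_dir / rel, "w") as fq:
                for read in by_case[case_id]:
                    fq.write(f"@{read.read_id}\n{read.seq}\n+\n{'I' * len(read.seq)}\n")

    for seq_id in sorted(cohort.tracks):
        safe = seq_id.replace("|", "__")
        write_track(cohort.tracks[seq_id], out_dir / "tracks" / f"{safe}.tsv")

    write_clinical(cohort.clinical, out_dir / "clinical.tsv")

    truth = {
        "plants": [asdict(p) for p in cohort.truth.plants],
        "cases": {c: asdict(t) for c, t in sorted(cohort.truth.cases.items())},
    }
    with open(out_dir / "truth.json", "w") as handle:
        json.dump(truth, handle, indent=1, sort_keys=True)
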