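"""Stitch mined CDR3s with germline V and J amino-acid sequences.

The full variable-region peptide is built in two concatenations.  First the
CDR3 is merged into the V: the longest common substring (LCS) between the
CDR3 and the V amino-acid sequence is computed under the anchoring constraint
that it start at the V's conserved cysteine and at CDR3 position 0 — with
both start positions fixed, the anchored LCS is simply the longest common
prefix of the CDR3 and the V suffix from the cysteine, and is unique by
construction.  The LCS and everything after it are dropped from the V and the
full CDR3 is appended.  Sequences whose anchored LCS is the bare single
cysteine are excluded (a known failure mode of junction calling).  Second,
the J is trimmed to start at its phenylalanine-glycine doublet and appended;
because the CDR3 already ends at the doublet phenylalanine, the J suffix is
joined from the glycine so the junction reads ``...F·G...`` without a doubled
phenylalanine.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd

from .reference_io import JGeneSegment, Reference, VGeneSegment
from .vdj_mining import RecombinationRead

logger = logging.getLogger(__name__)

REASON_SINGLE_C = "single_C"
REASON_NO_OVERLAP = "no_overlap"


@dataclass(frozen=True)
class VariableRegion:
    """A stitched V-CDR3-J amino-acid sequence with provenance.

    ``cdr3_span`` is the half-open interval of the CDR3 within ``aa_seq``;
    ``lcs`` is the anchored V/CDR3 overlap.
    """

    case_id: str
    read_id: str
    v_id: str
    j_id: str
    aa_seq: str
    lcs: str
    cdr3_start: int
    cdr3_end: int

    def __post_init__(self) -> None:
        if not self.lcs.startswith("C") or len(self.lcs) < 1:
            raise ValueError(f"{self.read_id}: invalid LCS {self.lcs!r}")
        if self.aa_seq[self.cdr3_start] != "C":
            raise ValueError(f"{self.read_id}: CDR3 span does not start at Cys")
        if "*" in self.aa_seq:
            raise ValueError(f"{self.read_id}: stop symbol in assembled region")

    @property
    def cdr3_aa(self) -> str:
        return self.aa_seq[self.cdr3_start : self.cdr3_end]

    @property
    def seq_id(self) -> str:
        return f"{self.case_id}|{self.read_id}"


@dataclass(frozen=True)
class AssemblyRejection:
    case_id: str
    read_id: str
    reason: str


def v_cdr3_lcs(cdr3_aa: str, v_aa: str, cys_index: int) -> str:
    """Anchored longest common substring of the CDR3 and the V sequence.

    Both start positions are fixed (the V's conserved cysteine; CDR3 position
    0), so the result is the longest common prefix of ``cdr3_aa`` and
    ``v_aa[cys_index:]`` — empty when even the cysteine does not match.
    """
    if not cdr3_aa.startswith("C"):
        raise ValueError(f"CDR3 {cdr3_aa!r} must start with 'C'")
    v_tail = v_aa[cys_index:]
    n = 0
    for a, b in zip(cdr3_aa, v_tail):
        if a != b:
            break
        n += 1
    return cdr3_aa[:n]


def stitch_v_cdr3(v: VGeneSegment, cdr3_aa: str) -> str:
    """Merge the CDR3 into the V; returns the V-CDR3 string or a rejection reason.

    The anchored LCS and all following V residues are removed from the V and
    the full CDR3 (including the LCS) is concatenated.  A single-residue 'C'
    LCS is rejected (``single_C``); no anchored overlap at all is
    ``no_overlap``.
    """
    lcs = v_cdr3_lcs(cdr3_aa, v.aa_seq, v.cys_index)
    if len(lcs) == 0:
        return REASON_NO_OVERLAP
    if len(lcs) == 1:
        return REASON_SINGLE_C
    return v.aa_seq[: v.cys_index] + cdr3_aa


def trim_j(j: JGeneSegment) -> str:
    """J amino acids from the FG doublet onward (residues before it removed)."""
    suffix = j.aa_seq[j.fg_index :]
    assert suffix.startswith("FG")
    return suffix


def assemble(read: RecombinationRead, reference: Reference) -> VariableRegion | AssemblyRejection:
    """Assemble one mined read into a full V-CDR3-J variable region."""
    v = reference.v(read.v_id)
    j = reference.j(read.j_id)
    lcs = v_cdr3_lcs(read.cdr3_aa, v.aa_seq, v.cys_index)
    v_cdr3 = stitch_v_cdr3(v, read.cdr3_aa)
    if v_cdr3 in (REASON_NO_OVERLAP, REASON_SINGLE_C):
        return AssemblyRejection(read.case_id, read.read_id, v_cdr3)
    j_suffix = trim_j(j)
    # the CDR3 ends at the doublet Phe, so join the J from its Gly
    aa_seq = v_cdr3 + j_suffix[1:]
    return VariableRegion(
        case_id=read.case_id, read_id=read.read_id,
        v_id=read.v_id, j_id=read.j_id,
        aa_seq=aa_seq, lcs=lcs,
        cdr3_start=v.cys_index,
        cdr3_end=v.cys_index + len(read.cdr3_aa),
    )


@dataclass
class AssemblyResult:
    regions: list[VariableRegion]
    rejected: list[AssemblyRejection]


def assemble_all(reads: Iterable[RecombinationRead], reference: Reference) -> AssemblyResult:
    """Assemble a batch; every read is emitted or logged with a reason."""
    regions: list[VariableRegion] = []
    rejected: list[AssemblyRejection] = []
    n = 0
    for read in reads:
        n += 1
        outcome = assemble(read, reference)
        if isinstance(outcome, VariableRegion):
            regions.append(outcome)
        else:
            rejected.append(outcome)
    assert len(regions) + len(rejected) == n
    if rejected:
        logger.info("assembly excluded %d of %d reads (%s)", len(rejected), n,
                    ", ".join(sorted({r.reason for r in rejected})))
    return AssemblyResult(regions=regions, rejected=rejected)


def regions_frame(result: AssemblyResult) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.case_id, r.read_id, r.v_id, r.j_id, r.aa_seq, r.cdr3_start, r.cdr3_end, r.lcs)
         for r in result.regions],
        columns=["case_id", "read_id", "v_id", "j_id", "aa_seq",
                 "cdr3_start", "cdr3_end", "lcs"],
    )


def write_regions_fasta(result: AssemblyResult, path: str | Path) -> None:
    """Peptide FASTA (id = case_id|read_id) for external disorder predictors."""
    with open(path, "w") as handle:
        for r in result.regions:
            handle.write(f">{r.seq_id}\n{r.aa_seq}\n")
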