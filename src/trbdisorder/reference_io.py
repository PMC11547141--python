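"""Read and validate V/J gene-segment references and clinical tables.

A reference is a nucleotide FASTA whose headers carry the segment role and
anchor position (``id|role|anchor_index``), optionally overridden by a sidecar
TSV (columns ``id``, ``role``, ``anchor_index``).  Amino-acid sequences are
derived by in-frame translation of the nucleotide record, so a reference
round-trips exactly through :func:`write_reference` / :func:`load_reference`.

Anchors are the two conserved residues framing the CDR3: the V segment's
CDR3-starting cysteine and the first residue of the J segment's
phenylalanine-glycine (FGXG) doublet.  All indices are 0-based; intervals are
half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")


class ReferenceValidationError(ValueError):
    """A reference record violates a structural invariant."""


class ClinicalValidationError(ValueError):
    """A clinical table row violates a structural invariant."""


def translate_nt(nt_seq: str) -> str:
    """Translate complete codons of ``nt_seq`` in frame 0 ('*' marks stops)."""
    usable = len(nt_seq) - len(nt_seq) % 3
    return str(Seq(nt_seq[:usable]).translate())


@dataclass(frozen=True)
class VGeneSegment:
    """A V gene segment: nucleotides through just past the CDR3 start.

    ``cys_index`` locates the conserved CDR3-starting cysteine in ``aa_seq``.
    """

    id: str
    nt_seq: str
    aa_seq: str
    cys_index: int

    def __post_init__(self) -> None:
        if not (0 <= self.cys_index < len(self.aa_seq)):
            raise ReferenceValidationError(
                f"{self.id}: cys_index {self.cys_index} outside amino-acid "
                f"sequence of length {len(self.aa_seq)}"
            )
        if self.aa_seq[self.cys_index] != "C":
            raise ReferenceValidationError(
                f"{self.id}: residue at cys_index {self.cys_index} is "
                f"{self.aa_seq[self.cys_index]!r}, expected 'C'"
            )
        if translate_nt(self.nt_seq) != self.aa_seq:
            raise ReferenceValidationError(
                f"{self.id}: nucleotide sequence does not translate to the "
                "declared amino-acid sequence in frame 0"
            )

    @classmethod
    def from_nt(cls, id: str, nt_seq: str, cys_index: int) -> "VGeneSegment":
        return cls(id=id, nt_seq=nt_seq, aa_seq=translate_nt(nt_seq), cys_index=cys_index)

    @property
    def anchor_window_nt(self) -> str:
        """Nucleotides from the 5' end through the end of the Cys codon."""
        return self.nt_seq[: 3 * self.cys_index + 3]


@dataclass(frozen=True)
class JGeneSegment:
    """A J gene segment; ``fg_index`` locates the F of the FG doublet."""

    id: str
    nt_seq: str
    aa_seq: str
    fg_index: int

    def __post_init__(self) -> None:
        if not (0 <= self.fg_index < len(self.aa_seq) - 1):
            raise ReferenceValidationError(
                f"{self.id}: fg_index {self.fg_index} leaves no room for the "
                "FG doublet"
            )
        doublet = self.aa_seq[self.fg_index : self.fg_index + 2]
        if doublet != "FG":
            raise ReferenceValidationError(
                f"{self.id}: residues at fg_index {self.fg_index} are "
                f"{doublet!r}, expected 'FG'"
            )
        if translate_nt(self.nt_seq) != self.aa_seq:
            raise ReferenceValidationError(
                f"{self.id}: nucleotide sequence does not translate to the "
                "declared amino-acid sequence in frame 0"
            )

    @classmethod
    def from_nt(cls, id: str, nt_seq: str, fg_index: int) -> "JGeneSegment":
        return cls(id=id, nt_seq=nt_seq, aa_seq=translate_nt(nt_seq), fg_index=fg_index)

    @property
    def anchor_window_nt(self) -> str:
        """Nucleotides from the 5' end through the end of the Gly codon."""
        return self.nt_seq[: 3 * self.fg_index + 6]


@dataclass
class Reference:
    """An indexed V/J gene-segment reference."""

    v_segments: dict[str, VGeneSegment] = field(default_factory=dict)
    j_segments: dict[str, JGeneSegment] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.v_segments) + len(self.j_segments)

    def v(self, v_id: str) -> VGeneSegment:
        try:
            return self.v_segments[v_id]
        except KeyError:
            raise KeyError(f"unknown V segment id {v_id!r}") from None

    def j(self, j_id: str) -> JGeneSegment:
        try:
            return self.j_segments[j_id]
        except KeyError:
            raise KeyError(f"unknown J segment id {j_id!r}") from None

    def add(self, segment: VGeneSegment | JGeneSegment) -> None:
        pool = self.v_segments if isinstance(segment, VGeneSegment) else self.j_segments
        if segment.id in self.v_segments or segment.id in self.j_segments:
            raise ReferenceValidationError(f"duplicate segment id {segment.id!r}")
        pool[segment.id] = segment


def load_reference(fasta_path: str | Path, anchors_path: str | Path | None = None) -> Reference:
    """Load a V/J reference from FASTA (+ optional anchor sidecar TSV).

    FASTA headers are ``id|role|anchor_index`` with role ``V`` or ``J`` and the
    anchor a 0-based amino-acid index (Cys for V, doublet-F for J).  A sidecar
    TSV with columns ``id``, ``role``, ``anchor_index`` takes precedence for
    the ids it lists, covering exports whose headers carry no anchors.
    """
    fasta_path = Path(fasta_path)
    sidecar: dict[str, tuple[str, int]] = {}
    if anchors_path is not None:
        anc = pd.read_csv(anchors_path, sep="\t", dtype={"id": str, "role": str})
        for row in anc.itertuples(index=False):
            sidecar[str(row.id)] = (str(row.role), int(row.anchor_index))

    reference = Reference()
    for record in SeqIO.parse(str(fasta_path), "fasta"):
        parts = record.description.split("|")
        seg_id = parts[0]
        if seg_id in sidecar:
            role, anchor = sidecar[seg_id]
        elif len(parts) >= 3:
            role, anchor = parts[1], int(parts[2])
        else:
            raise ReferenceValidationError(
                f"{seg_id}: no role/anchor in header and no sidecar entry"
            )
        role = role.upper()
        nt_seq = str(record.seq).upper()
        if role == "V":
            reference.add(VGeneSegment.from_nt(seg_id, nt_seq, anchor))
        elif role == "J":
            reference.add(JGeneSegment.from_nt(seg_id, nt_seq, anchor))
        else:
            raise ReferenceValidationError(f"{seg_id}: unknown role {role!r}")
    logger.info(
        "loaded reference %s: %d V, %d J segments",
        fasta_path.name, len(reference.v_segments), len(reference.j_segments),
    )
    return reference


def write_reference(reference: Reference, fasta_path: str | Path,
                    anchors_path: str | Path | None = None) -> None:
    """Write a reference as FASTA with structured headers (+ optional sidecar)."""
    records = []
    rows = []
    for seg in reference.v_segments.values():
        records.append(SeqRecord(Seq(seg.nt_seq), id=f"{seg.id}|V|{seg.cys_index}", description=""))
        rows.append({"id": seg.id, "role": "V", "anchor_index": seg.cys_index})
    for seg in reference.j_segments.values():
        records.append(SeqRecord(Seq(seg.nt_seq), id=f"{seg.id}|J|{seg.fg_index}", description=""))
        rows.append({"id": seg.id, "role": "J", "anchor_index": seg.fg_index})
    SeqIO.write(records, str(fasta_path), "fasta")
    if anchors_path is not None:
        pd.DataFrame(rows).to_csv(anchors_path, sep="\t", index=False)


@dataclass(frozen=True)
class ClinicalRecord:
    """One case: overall-survival time, event flag, and covariates."""

    case_id: str
    os_months: float
    event: int
    covariates: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.os_months < 0:
            raise ClinicalValidationError(
                f"{self.case_id}: negative survival time {self.os_months}"
            )
        if self.event not in (0, 1):
            raise ClinicalValidationError(
                f"{self.case_id}: event flag {self.event!r} not in {{0, 1}}"
            )


REQUIRED_CLINICAL_COLUMNS = ("case_id", "os_months", "event")


def load_clinical(path: str | Path, query: str | None = None) -> list[ClinicalRecord]:
    """Load a clinical TSV; extra columns become covariates.

    ``query`` is an optional pandas filter expression applied before
    validation (e.g. ``"mycn_amplified == 1"``); filtering is idempotent.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in REQUIRED_CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ClinicalValidationError(f"clinical table missing columns {missing}")
    if query is not None:
        df = df.query(query)
    if df["case_id"].duplicated().any():
        dupes = df.loc[df["case_id"].duplicated(), "case_id"].tolist()
        raise ClinicalValidationError(f"duplicate case_id values {dupes}")
    covariate_cols = [c for c in df.columns if c not in REQUIRED_CLINICAL_COLUMNS]
    records = []
    for row in df.itertuples(index=False):
        rec = row._asdict()
        records.append(
            ClinicalRecord(
                case_id=str(rec["case_id"]),
                os_months=float(rec["os_months"]),
                event=int(rec["event"]),
                covariates={c: rec[c] for c in covariate_cols},
            )
        )
    return records


def clinical_frame(records: Iterable[ClinicalRecord]) -> pd.DataFrame:
    """Tabulate clinical records (case_id, os_months, event, covariates...)."""
    rows = []
    for r in records:
        row = {"case_id": r.case_id, "os_months": r.os_months, "event": r.event}
        row.update(r.covariates)
        rows.append(row)
    return pd.DataFrame(rows)


def write_clinical(records: Iterable[ClinicalRecord], path: str | Path) -> None:
    clinical_frame(records).to_csv(path, sep="\t", index=False)
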