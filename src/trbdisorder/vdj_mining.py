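"""Recover TRB V(D)J recombination reads from nucleotide reads.

A recombination read carries, on one strand, an exact anchored match to a V
gene segment and, downstream, an exact anchored match to a J gene segment,
with a productive CDR3 in between.  Anchored means the match pins the CDR3
frame: the V match is the longest suffix of the V nucleotide window ending at
the end of the conserved-cysteine codon that occurs in the read; the J match
is the longest suffix of the J 5' window ending at the end of the doublet
glycine codon.  The CDR3 is then translated from the cysteine codon through
the doublet-phenylalanine codon and accepted iff the span is a multiple of
three and stop-free.

Matching is exact (no mismatches or indels); defaults are 20 nt for V and
15 nt for J.  Both strands are searched; every input read is accounted for
exactly once, as accepted, rejected (with reason), or unmatched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from .reference_io import JGeneSegment, Reference, VGeneSegment, translate_nt

logger = logging.getLogger(__name__)

DEFAULT_MIN_MATCH_V = 20
DEFAULT_MIN_MATCH_J = 15

FORWARD = "forward"
REVCOMP = "reverse-complement"

#: rejection reasons, in the order they are checked
REASON_UNMATCHED = "unmatched"
REASON_ANCHORS_OUT_OF_ORDER = "anchors_out_of_order"
REASON_ANCHOR_OUTSIDE_READ = "anchor_outside_read"
REASON_FRAMESHIFT = "frameshift"
REASON_STOP_CODON = "stop_codon"

NT_ALPHABET = set("ACGTN")


@dataclass(frozen=True)
class SequencingRead:
    """A nucleotide read attributed to a case."""

    read_id: str
    case_id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"{self.read_id}: empty sequence")
        bad = set(self.seq) - NT_ALPHABET
        if bad:
            raise ValueError(f"{self.read_id}: non-ACGTN symbols {sorted(bad)}")


@dataclass(frozen=True)
class SegmentMatch:
    """An anchored exact match of a gene segment within a read.

    ``read_start`` is the 0-based read offset of the match; the matched
    nucleotides are the final ``length`` bases of the segment's anchor window
    (V: ending at the Cys codon end; J: ending at the Gly codon end).
    """

    segment_id: str
    read_start: int
    length: int


@dataclass(frozen=True)
class RecombinationRead:
    """A read with validated V and J matches and a productive CDR3."""

    read_id: str
    case_id: str
    v_id: str
    j_id: str
    cdr3_aa: str
    cdr3_nt: str
    strand: str

    def __post_init__(self) -> None:
        if not self.cdr3_aa.startswith("C"):
            raise ValueError(f"{self.read_id}: CDR3 {self.cdr3_aa!r} lacks leading Cys")
        if "*" in self.cdr3_aa:
            raise ValueError(f"{self.read_id}: CDR3 {self.cdr3_aa!r} contains stop")
        if len(self.cdr3_nt) != 3 * len(self.cdr3_aa):
            raise ValueError(f"{self.read_id}: CDR3 nt/aa length mismatch")
        if not self.cdr3_aa.endswith("F"):
            raise ValueError(f"{self.read_id}: CDR3 {self.cdr3_aa!r} lacks doublet Phe")


@dataclass(frozen=True)
class Rejection:
    read_id: str
    case_id: str
    reason: str


@dataclass
class MiningResult:
    accepted: list[RecombinationRead]
    rejected: list[Rejection]

    @property
    def n_unmatched(self) -> int:
        return sum(1 for r in self.rejected if r.reason == REASON_UNMATCHED)


def _longest_anchored_suffix(window: str, read_seq: str, min_match: int) -> Optional[tuple[int, int]]:
    """Longest suffix of ``window`` occurring in ``read_seq`` (length >= min_match).

    Returns (read_start, length) at the lowest read position, or None.
    Occurrence of the length-L suffix implies occurrence of every shorter
    suffix, so the search is a binary search on L.
    """
    hi = len(window)
    lo = min_match
    if lo > hi or read_seq.find(window[-lo:]) < 0:
        return None
    # invariant: suffix of length lo occurs, suffix of length hi+1 does not
    while lo < hi:
        mid = (lo + hi + 1) // 2
        if read_seq.find(window[-mid:]) >= 0:
            lo = mid
        else:
            hi = mid - 1
    return read_seq.find(window[-lo:]), lo


def match_segment(read_seq: str, segment: VGeneSegment | JGeneSegment,
                  min_match: int) -> Optional[SegmentMatch]:
    """Best anchored exact match of ``segment`` in ``read_seq``, or None.

    Deterministic: the longest match wins; its position is the lowest read
    offset at which the matched suffix occurs.
    """
    if min_match < 1:
        raise ValueError("min_match must be >= 1")
    hit = _longest_anchored_suffix(segment.anchor_window_nt, read_seq, min_match)
    if hit is None:
        return None
    pos, length = hit
    return SegmentMatch(segment_id=segment.id, read_start=pos, length=length)


def _best_match(read_seq: str, segments: Sequence[VGeneSegment | JGeneSegment],
                min_match: int) -> Optional[SegmentMatch]:
    """Best match over segments: longest, then lowest read position, then
    lexicographically smallest segment id (ambiguity logged)."""
    best: Optional[SegmentMatch] = None
    ambiguous = False
    for seg in sorted(segments, key=lambda s: s.id):
        m = match_segment(read_seq, seg, min_match)
        if m is None:
            continue
        if best is None:
            best = m
            continue
        key, best_key = (-m.length, m.read_start), (-best.length, best.read_start)
        if key < best_key:
            best, ambiguous = m, False
        elif key == best_key:
            ambiguous = True  # equal match: keep lexicographically smaller id
    if ambiguous and best is not None:
        logger.debug("ambiguous segment match resolved to %s", best.segment_id)
    return best


def extract_cdr3(read: SequencingRead, v_match: SegmentMatch, j_match: SegmentMatch,
                 reference: Reference, strand: str = FORWARD,
                 read_seq: str | None = None) -> RecombinationRead | Rejection:
    """Translate the CDR3 between anchored V and J matches.

    The span runs from the V cysteine codon (the final codon of the V match)
    through the J doublet-phenylalanine codon (the codon before the G codon
    ending the J match).  Accepted iff the span is in frame and stop-free.
    ``read_seq`` supplies the strand-oriented sequence when it differs from
    ``read.seq`` (reverse-complement search).
    """
    reference.v(v_match.segment_id)  # raise on unknown ids
    reference.j(j_match.segment_id)
    seq = read.seq if read_seq is None else read_seq

    cys_start = v_match.read_start + v_match.length - 3
    f_start = j_match.read_start + j_match.length - 6
    f_end = f_start + 3
    if cys_start < 0 or f_end > len(seq) or v_match.length < 3 or j_match.length < 6:
        return Rejection(read.read_id, read.case_id, REASON_ANCHOR_OUTSIDE_READ)
    if cys_start >= f_start:
        return Rejection(read.read_id, read.case_id, REASON_ANCHORS_OUT_OF_ORDER)
    cdr3_nt = seq[cys_start:f_end]
    if len(cdr3_nt) % 3 != 0:
        return Rejection(read.read_id, read.case_id, REASON_FRAMESHIFT)
    cdr3_aa = translate_nt(cdr3_nt)
    if "*" in cdr3_aa:
        return Rejection(read.read_id, read.case_id, REASON_STOP_CODON)
    return RecombinationRead(
        read_id=read.read_id, case_id=read.case_id,
        v_id=v_match.segment_id, j_id=j_match.segment_id,
        cdr3_aa=cdr3_aa, cdr3_nt=cdr3_nt, strand=strand,
    )


def _mine_one(read: SequencingRead, reference: Reference,
              min_match_v: int, min_match_j: int) -> RecombinationRead | Rejection:
    v_pool = list(reference.v_segments.values())
    j_pool = list(reference.j_segments.values())
    first_rejection: Optional[Rejection] = None
    for strand, seq in ((FORWARD, read.seq),
                        (REVCOMP, str(Seq(read.seq).reverse_complement()))):
        v_match = _best_match(seq, v_pool, min_match_v)
        j_match = _best_match(seq, j_pool, min_match_j)
        if v_match is None or j_match is None:
            continue
        outcome = extract_cdr3(read, v_match, j_match, reference,
                               strand=strand, read_seq=seq)
        if isinstance(outcome, RecombinationRead):
            return outcome
        if first_rejection is None:
            first_rejection = outcome
    if first_rejection is not None:
        return first_rejection
    return Rejection(read.read_id, read.case_id, REASON_UNMATCHED)


def mine_reads(reads: Iterable[SequencingRead], reference: Reference,
               min_match_v: int = DEFAULT_MIN_MATCH_V,
               min_match_j: int = DEFAULT_MIN_MATCH_J) -> MiningResult:
    """Mine recombination reads; every input read is accepted or logged.

    Output is sorted by (case_id, read_id) for determinism.
    """
    accepted: list[RecombinationRead] = []
    rejected: list[Rejection] = []
    n = 0
    for read in reads:
        n += 1
        outcome = _mine_one(read, reference, min_match_v, min_match_j)
        if isinstance(outcome, RecombinationRead):
            accepted.append(outcome)
        else:
            rejected.append(outcome)
    accepted.sort(key=lambda r: (r.case_id, r.read_id))
    rejected.sort(key=lambda r: (r.case_id, r.read_id))
    assert len(accepted) + len(rejected) == n
    logger.info("mined %d reads: %d accepted, %d rejected/unmatched",
                n, len(accepted), len(rejected))
    return MiningResult(accepted=accepted, rejected=rejected)


# ---------------------------------------------------------------------------
# I/O

def read_sequences(path: str | Path, case_id: str) -> Iterator[SequencingRead]:
    """Stream reads from FASTQ or FASTA (qualities ignored)."""
    path = Path(path)
    fmt = "fastq" if path.suffix.lower() in {".fastq", ".fq"} else "fasta"
    for record in SeqIO.parse(str(path), fmt):
        yield SequencingRead(read_id=record.id, case_id=case_id, seq=str(record.seq).upper())


def read_manifest(manifest_path: str | Path) -> Iterator[SequencingRead]:
    """Stream reads for all cases listed in a manifest TSV (case_id, path).

    Relative paths are resolved against the manifest's directory.
    """
    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path, sep="\t", dtype=str)
    for row in manifest.itertuples(index=False):
        path = Path(row.path)
        if not path.is_absolute():
            path = manifest_path.parent / path
        yield from read_sequences(path, case_id=str(row.case_id))


def reads_frame(result: MiningResult) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.case_id, r.read_id, r.v_id, r.j_id, r.cdr3_aa, r.cdr3_nt, r.strand)
         for r in result.accepted],
        columns=["case_id", "read_id", "v_id", "j_id", "cdr3_aa", "cdr3_nt", "strand"],
    )


def rejections_frame(result: MiningResult) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.case_id, r.read_id, r.reason) for r in result.rejected],
        columns=["case_id", "read_id", "reason"],
    )
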