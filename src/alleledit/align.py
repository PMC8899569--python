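"""Fitting (glocal) alignment of amplicon reads to the mutant reference.

Reads are aligned end-to-end against the amplicon with affine gap penalties;
the reference flanks outside the read are free (end gaps on the reference cost
nothing).  This is the standard fitting alignment used by amplicon-editing
pipelines: the read is a sequenced fragment of the amplicon, so it must be
consumed entirely while the reference may extend past it on either side.

The engine is Biopython's :class:`Bio.Align.PairwiseAligner` (optimal Gotoh
DP in C).  Two exact-match fast paths bypass it: a read that is a perfect
substring of the mutant sequence (all matches), or of the derived wild-type
sequence (all matches except the annotated allele sites) — together these
cover the bulk of error-free reads.  Indels in the traceback are
left-normalized so gap placement is deterministic (leftmost) regardless of
the engine's internal tie-breaking.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

from Bio import Align

from .reference import AmpliconReference, derive_wt_sequence


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring for read-to-amplicon alignment.

    Penalties are stored as nonnegative magnitudes.  A gap of length k costs
    ``gap_open + (k - 1) * gap_extend``.  Reads whose alignment identity falls
    below ``min_identity`` are discarded downstream.
    """

    match_score: float = 2.0
    mismatch_penalty: float = 3.0
    gap_open: float = 6.0
    gap_extend: float = 1.0
    min_identity: float = 0.75

    def __post_init__(self) -> None:
        if not (self.gap_open >= self.gap_extend >= 0):
            raise ValueError("require gap_open >= gap_extend >= 0")
        if not (0.0 <= self.min_identity <= 1.0):
            raise ValueError("min_identity must lie in [0, 1]")


class AlignmentOp(NamedTuple):
    """One alignment operation against the reference.

    ``op`` is one of ``M`` (match), ``X`` (mismatch), ``I`` (insertion) or
    ``D`` (deletion).  ``ref_offset`` is 1-based: for M/X/D the first reference
    base of the run; for I the base 5' of the insertion point (between-base
    convention shared with guide cut sites).  ``read_seq`` carries the read
    bases for X and I operations (empty for M and D).
    """

    op: str
    ref_offset: int
    length: int
    read_seq: str = ""


@dataclass
class AlignedRead:
    """Per-read alignment evidence.

    ``ops`` tile the read exactly, with nondecreasing reference offsets.
    ``marker_call`` and ``indels_in_window`` are filled in by the
    quantification step.
    """

    read_id: str
    ops: tuple[AlignmentOp, ...]
    ref_start: int            # first reference base covered (1-based)
    ref_end: int              # last reference base covered (inclusive)
    score: float
    identity: float
    discarded: bool = False
    marker_call: str | None = None
    indels_in_window: list | None = None

    def covers(self, offset: int) -> bool:
        return self.ref_start <= offset <= self.ref_end


def _make_aligner(params: AlignmentParams) -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = params.match_score
    a.mismatch_score = -params.mismatch_penalty
    # internal gaps: affine, both insertions (read bases absent from the
    # reference) and deletions (reference bases absent from the read)
    a.open_internal_insertion_score = -params.gap_open
    a.extend_internal_insertion_score = -params.gap_extend
    a.open_internal_deletion_score = -params.gap_open
    a.extend_internal_deletion_score = -params.gap_extend
    # reference flanks outside the read are free; unaligned read ends are not
    a.open_end_deletion_score = 0.0
    a.extend_end_deletion_score = 0.0
    a.open_end_insertion_score = -params.gap_open
    a.extend_end_insertion_score = -params.gap_extend
    return a


def _ops_from_blocks(ref: str, read: str, tblocks, qblocks) -> list[AlignmentOp]:
    """Convert Biopython aligned blocks into M/X/I/D runs (1-based offsets)."""
    ops: list[AlignmentOp] = []
    prev_t = prev_q = None
    for (t0, t1), (q0, q1) in zip(tblocks, qblocks):
        if prev_t is not None:
            if t0 > prev_t:   # reference consumed without read: deletion
                ops.append(AlignmentOp("D", prev_t + 1, t0 - prev_t))
            if q0 > prev_q:   # read consumed without reference: insertion
                ops.append(AlignmentOp("I", t0, q0 - prev_q, read[prev_q:q0]))
        # aligned block: split into M/X runs
        run_start = 0
        rel = None
        for k in range(t1 - t0 + 1):
            state = (ref[t0 + k] == read[q0 + k]) if k < t1 - t0 else None
            if state != rel:
                if rel is not None:
                    op = "M" if rel else "X"
                    ops.append(AlignmentOp(
                        op, t0 + run_start + 1, k - run_start,
                        "" if rel else read[q0 + run_start:q0 + k]))
                rel = state
                run_start = k
        prev_t, prev_q = t1, q1
    return ops


def _left_normalize(ref: str, ops: list[AlignmentOp]) -> list[AlignmentOp]:
    """Shift each indel as far left as sequence identity allows.

    A deletion of ref[s..e] may move one base left whenever ref[s-1] == ref[e];
    an insertion after ref position p may move left whenever ref[p] equals the
    insertion's last base (which then rotates to its front).  Flanking match
    runs are adjusted accordingly.  Shifts stop at the preceding operation
    boundary, so the op list stays consistent.
    """
    out = list(ops)
    for i, op in enumerate(out):
        if op.op not in ("I", "D"):
            continue
        if i == 0 or out[i - 1].op != "M":
            continue
        room = out[i - 1].length
        shift = 0
        if op.op == "D":
            s = op.ref_offset           # 1-based first deleted base
            e = op.ref_offset + op.length - 1
            while shift < room and s - shift - 1 >= 1 \
                    and ref[s - shift - 2] == ref[e - shift]:
                shift += 1
            if shift:
                out[i] = AlignmentOp("D", s - shift, op.length)
        else:
            p = op.ref_offset           # base 5' of the insertion point
            ins = op.read_seq
            while shift < room and p - shift >= 1 \
                    and ref[p - shift - 1] == ins[-1]:
                ins = ins[-1] + ins[:-1]
                shift += 1
            if shift:
                out[i] = AlignmentOp("I", p - shift, op.length, ins)
        if shift:
            out[i - 1] = out[i - 1]._replace(length=room - shift)
            # re-open a match run to the right of the shifted indel
            fill_start = (out[i].ref_offset + out[i].length if op.op == "D"
                          else out[i].ref_offset + 1)
            fill = AlignmentOp("M", fill_start, shift)
            out.insert(i + 1, fill)
    merged: list[AlignmentOp] = []
    for op in out:
        if op.length == 0:
            continue
        if merged and merged[-1].op == op.op == "M" \
                and merged[-1].ref_offset + merged[-1].length == op.ref_offset:
            merged[-1] = merged[-1]._replace(length=merged[-1].length + op.length)
        else:
            merged.append(op)
    return merged


def _identity(ops: list[AlignmentOp]) -> float:
    matches = sum(o.length for o in ops if o.op == "M")
    columns = sum(o.length for o in ops)
    return matches / columns if columns else 0.0


def _finalize(read_id: str, ops: list[AlignmentOp], score: float,
              params: AlignmentParams) -> AlignedRead:
    ref_positions = [o.ref_offset for o in ops if o.op != "I"]
    ref_ends = [o.ref_offset + o.length - 1 for o in ops if o.op != "I"]
    ident = _identity(ops)
    return AlignedRead(
        read_id=read_id, ops=tuple(ops),
        ref_start=min(ref_positions) if ref_positions else 0,
        ref_end=max(ref_ends) if ref_ends else 0,
        score=score, identity=ident,
        discarded=ident < params.min_identity,
    )


def align_read(read_seq: str, ref: AmpliconReference,
               params: AlignmentParams | None = None,
               read_id: str = "read") -> AlignedRead:
    """Optimal fitting alignment of one read to the mutant amplicon.

    Allele identity is *not* decided here — reads from either allele align to
    the mutant reference, and the marker column is read out downstream.
    """
    if params is None:
        params = AlignmentParams()
    read = read_seq.upper()
    if not read:
        raise ValueError("empty read")
    mut = ref.sequence

    # fast path 1: exact substring of the mutant allele
    pos = mut.find(read)
    if pos >= 0:
        ops = [AlignmentOp("M", pos + 1, len(read))]
        return _finalize(read_id, ops, params.match_score * len(read), params)

    # fast path 2: exact substring of the derived wild-type allele; against
    # the mutant reference this is all matches except covered allele sites
    if ref.sites:
        wt = derive_wt_sequence(ref)
        pos = wt.find(read)
        if pos >= 0:
            covered = sorted(s.offset for s in ref.sites
                             if pos + 1 <= s.offset <= pos + len(read))
            ops = []
            cursor = pos + 1
            for off in covered:
                if off > cursor:
                    ops.append(AlignmentOp("M", cursor, off - cursor))
                ops.append(AlignmentOp("X", off, 1, wt[off - 1]))
                cursor = off + 1
            if pos + len(read) >= cursor:
                ops.append(AlignmentOp("M", cursor, pos + len(read) - cursor + 1))
            score = (params.match_score * (len(read) - len(covered))
                     - params.mismatch_penalty * len(covered))
            return _finalize(read_id, ops, score, params)

    aligner = _make_aligner(params)
    aln = aligner.align(mut, read)[0]
    tblocks = [(int(a), int(b)) for a, b in aln.aligned[0]]
    qblocks = [(int(a), int(b)) for a, b in aln.aligned[1]]
    ops = _ops_from_blocks(mut, read, tblocks, qblocks)
    ops = _left_normalize(mut, ops)
    return _finalize(read_id, ops, float(aln.score), params)
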