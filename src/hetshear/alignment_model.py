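"""Alignment records and the local (Smith-Waterman) realigner.

Coordinate conventions, used everywhere in this package:

* Reference positions are 1-based and inclusive, as in SAM.
* A *breakpoint* is the last reference base before a structural-variant
  junction.  A right soft-clip whose last aligned base is ``p`` sits at
  junction coordinate ``p``; a left soft-clip whose first aligned base is
  ``p`` sits at junction coordinate ``p - 1``.

The local aligner plays the role of BWA-SW in the refinement loop: it finds
the optimal local alignment of a read inside a breakpoint-neighbourhood
window, with affine gap penalties, and turns the unaligned read ends into
soft-clips instead of forcing an end-to-end placement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pysam
from numba import njit

logger = logging.getLogger("hetshear")

SPANNING = "spanning"
SOFT_CLIPPED = "soft_clipped"
NEITHER = "neither"

_CIGAR_OPS = "MIDS"


class AlignmentError(ValueError):
    """Malformed alignment input."""


@dataclass(frozen=True)
class Scoring:
    """Affine-gap local alignment scores (BWA-SW-like defaults).

    A gap of length ``k`` costs ``gap_open + k * gap_extend``.
    """

    match: int = 1
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -2


DEFAULT_SCORING = Scoring()


@dataclass(slots=True)
class AlignedRead:
    """One read's placement on the reference.

    ``seq`` is stored in reference-forward orientation (SAM convention);
    ``is_reverse`` records the sequencing strand.  ``cigar`` is a list of
    ``(op, length)`` with op in ``M I D S``; soft-clips only at the ends.
    """

    name: str
    chrom: str | None
    pos: int  # 1-based leftmost aligned reference position (0 if unmapped)
    cigar: list[tuple[str, int]]
    seq: str
    mapped: bool = True
    is_reverse: bool = False
    is_read1: bool = True
    mate_chrom: str | None = None
    mate_pos: int = 0
    mate_mapped: bool = False

    # ------------------------------------------------------------------ geometry
    @property
    def uid(self) -> tuple[str, bool]:
        return (self.name, self.is_read1)

    @property
    def read_length(self) -> int:
        return len(self.seq)

    @property
    def left_clip(self) -> int:
        if self.cigar and self.cigar[0][0] == "S":
            return self.cigar[0][1]
        return 0

    @property
    def right_clip(self) -> int:
        if self.cigar and self.cigar[-1][0] == "S":
            return self.cigar[-1][1]
        return 0

    @property
    def clipped_prefix(self) -> str:
        return self.seq[: self.left_clip]

    @property
    def clipped_suffix(self) -> str:
        n = self.right_clip
        return self.seq[len(self.seq) - n :] if n else ""

    @property
    def ref_end(self) -> int:
        """1-based inclusive rightmost aligned reference position."""
        end = self.pos - 1
        for op, ln in self.cigar:
            if op in ("M", "D"):
                end += ln
        return end

    def match_blocks(self) -> list[tuple[int, int]]:
        """Contiguous match segments on the reference, broken by I/D."""
        blocks: list[tuple[int, int]] = []
        ref = self.pos
        for op, ln in self.cigar:
            if op == "M":
                blocks.append((ref, ref + ln - 1))
                ref += ln
            elif op == "D":
                ref += ln
        return blocks

    def validate(self) -> None:
        if not self.cigar:
            raise AlignmentError(f"{self.name}: empty CIGAR")
        consumed = sum(ln for op, ln in self.cigar if op in ("M", "I", "S"))
        if consumed != len(self.seq):
            raise AlignmentError(
                f"{self.name}: CIGAR consumes {consumed} bases, sequence has {len(self.seq)}"
            )
        for k, (op, _ln) in enumerate(self.cigar):
            if op not in _CIGAR_OPS:
                raise AlignmentError(f"{self.name}: unsupported CIGAR op {op!r}")
            if op == "S" and k not in (0, len(self.cigar) - 1):
                raise AlignmentError(f"{self.name}: internal soft-clip")


# --------------------------------------------------------------------------- SAM I/O
def _from_pysam(rec: pysam.AlignedSegment) -> AlignedRead:
    if rec.is_unmapped:
        return AlignedRead(
            name=rec.query_name or "",
            chrom=None,
            pos=0,
            cigar=[("S", len(rec.query_sequence or ""))],
            seq=rec.query_sequence or "",
            mapped=False,
            is_reverse=rec.is_reverse,
            is_read1=not rec.is_read2,
            mate_chrom=rec.next_reference_name if rec.mate_is_mapped else None,
            mate_pos=(rec.next_reference_start or 0) + 1 if rec.mate_is_mapped else 0,
            mate_mapped=bool(rec.is_paired and rec.mate_is_mapped),
        )
    cigar: list[tuple[str, int]] = []
    for code, ln in rec.cigartuples or []:
        # 0=M 1=I 2=D 4=S 5=H (7/8 = =/X folded into M)
        if code in (0, 7, 8):
            op = "M"
        elif code == 1:
            op = "I"
        elif code == 2:
            op = "D"
        elif code == 4:
            op = "S"
        elif code == 5:
            # hard clips carry no sequence; count them as zero-length markers
            continue
        else:
            raise AlignmentError(f"{rec.query_name}: unsupported CIGAR code {code}")
        if cigar and cigar[-1][0] == op:
            cigar[-1] = (op, cigar[-1][1] + ln)
        else:
            cigar.append((op, ln))
    read = AlignedRead(
        name=rec.query_name or "",
        chrom=rec.reference_name,
        pos=rec.reference_start + 1,
        cigar=cigar,
        seq=rec.query_sequence or "",
        mapped=True,
        is_reverse=rec.is_reverse,
        is_read1=not rec.is_read2,
        mate_chrom=rec.next_reference_name if (rec.is_paired and rec.mate_is_mapped) else None,
        mate_pos=(rec.next_reference_start or 0) + 1 if (rec.is_paired and rec.mate_is_mapped) else 0,
        mate_mapped=bool(rec.is_paired and rec.mate_is_mapped),
    )
    read.validate()
    return read


def read_alignment_file(
    path: str | Path,
    region: tuple[str, int, int] | None = None,
    include_unmapped: bool = True,
) -> Iterator[AlignedRead]:
    """Stream :class:`AlignedRead` records from a SAM/BAM file.

    ``region`` is ``(chrom, start, end)``, 1-based inclusive; mapped records
    whose span does not intersect it are skipped (unmapped records are kept
    iff ``include_unmapped``).
    """
    path = str(path)
    mode = "rb" if path.endswith(".bam") else "r"
    try:
        fh = pysam.AlignmentFile(path, mode, check_sq=True)
    except (OSError, ValueError) as exc:
        raise AlignmentError(f"cannot read alignment file {path}: {exc}") from exc
    with fh:
        if not fh.header.references:
            raise AlignmentError(f"{path}: missing @SQ header lines")
        records = enumerate(fh)
        i = 0
        while True:
            try:
                i, rec = next(records)
            except StopIteration:
                break
            except (OSError, ValueError) as exc:  # truncated/malformed record
                raise AlignmentError(f"{path}, record {i + 1}: {exc}") from exc
            if rec.is_secondary or rec.is_supplementary:
                continue
            try:
                read = _from_pysam(rec)
            except AlignmentError as exc:
                raise AlignmentError(f"{path}, record {i + 1}: {exc}") from exc
            if not read.mapped:
                if include_unmapped:
                    yield read
                continue
            if region is not None:
                chrom, start, end = region
                if read.chrom != chrom or read.ref_end < start or read.pos > end:
                    continue
            yield read


def write_alignment_file(
    path: str | Path,
    reads: Iterable[AlignedRead],
    reference_lengths: dict[str, int],
    qual_char: str = "I",
) -> None:
    """Write records as SAM (or BAM when the path ends in .bam)."""
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": name, "LN": ln} for name, ln in reference_lengths.items()],
    }
    path = str(path)
    mode = "wb" if path.endswith(".bam") else "wh"
    code = {"M": 0, "I": 1, "D": 2, "S": 4}
    with pysam.AlignmentFile(path, mode, header=header) as out:
        for read in reads:
            rec = pysam.AlignedSegment(out.header)
            rec.query_name = read.name
            rec.query_sequence = read.seq
            rec.query_qualities = pysam.qualitystring_to_array(qual_char * len(read.seq))
            flag = 0x1
            flag |= 0x40 if read.is_read1 else 0x80
            if read.mapped:
                rec.reference_name = read.chrom
                rec.reference_start = read.pos - 1
                rec.cigartuples = [(code[op], ln) for op, ln in read.cigar]
                if read.is_reverse:
                    flag |= 0x10
            else:
                flag |= 0x4
            if read.mate_mapped and read.mate_chrom is not None:
                rec.next_reference_name = read.mate_chrom
                rec.next_reference_start = read.mate_pos - 1
            else:
                flag |= 0x8
            rec.flag = flag
            rec.mapping_quality = 60 if read.mapped else 0
            out.write(rec)


def drop_duplicate_fragments(reads: Iterable[AlignedRead]) -> list[AlignedRead]:
    """Optional PCR-duplicate filter: keep one fragment per identical outer
    coordinate pair (leftmost read position, mate position, orientation).

    Duplicate marking is normally done upstream; this trivial filter covers
    inputs where it was not.  Unmapped reads and reads whose mate is
    unmapped are kept as-is.
    """
    kept: list[AlignedRead] = []
    seen: set[tuple] = set()
    drop_names: set[str] = set()
    by_name: dict[str, list[AlignedRead]] = {}
    for read in reads:
        by_name.setdefault(read.name, []).append(read)
    for name in sorted(by_name):
        mates = by_name[name]
        first = next((r for r in mates if r.is_read1), mates[0])
        if first.mapped and first.mate_mapped:
            key = (
                min(first.pos, first.mate_pos),
                max(first.pos, first.mate_pos),
                first.chrom,
                first.mate_chrom,
                first.is_reverse,
            )
            if key in seen:
                drop_names.add(name)
                continue
            seen.add(key)
        kept.extend(mates)
    if drop_names:
        logger.info("duplicate filter removed %d fragments", len(drop_names))
    return kept


# --------------------------------------------------------------------------- local aligner
@dataclass(frozen=True)
class LocalAlignmentResult:
    """Optimal local alignment of a read inside a reference window.

    Spans are 1-based inclusive; ``ref_*`` are window coordinates.  The
    unaligned read ends are the implied soft-clips:
    ``read_start - 1`` bases on the left, ``read_length - read_end`` on the
    right.
    """

    score: int
    ref_start: int
    ref_end: int
    read_start: int
    read_end: int
    n_matches: int
    read_length: int
    path: tuple[tuple[str, int], ...] = field(default=())
    aligned: bool = True

    @property
    def left_clip(self) -> int:
        return self.read_start - 1

    @property
    def right_clip(self) -> int:
        return self.read_length - self.read_end

    def cigar(self) -> list[tuple[str, int]]:
        out: list[tuple[str, int]] = []
        if self.left_clip:
            out.append(("S", self.left_clip))
        out.extend(self.path)
        if self.right_clip:
            out.append(("S", self.right_clip))
        return out


_UNALIGNED = LocalAlignmentResult(0, 0, 0, 0, 0, 0, 0, (), aligned=False)

_NEG = np.int32(-(10**7))


@njit(cache=True)
def _sw_fill(x, y, ms, mms, go, ge):  # pragma: no cover - exercised via local_align
    n = x.shape[0]
    m = y.shape[0]
    H = np.zeros((n + 1, m + 1), np.int32)
    E = np.full((n + 1, m + 1), _NEG, np.int32)
    F = np.full((n + 1, m + 1), _NEG, np.int32)
    for i in range(1, n + 1):
        xi = x[i - 1]
        for j in range(1, m + 1):
            e = H[i, j - 1] + go + ge
            t = E[i, j - 1] + ge
            if t > e:
                e = t
            f = H[i - 1, j] + go + ge
            t = F[i - 1, j] + ge
            if t > f:
                f = t
            s = ms if xi == y[j - 1] else mms
            h = H[i - 1, j - 1] + s
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            H[i, j] = h
            E[i, j] = e
            F[i, j] = f
    return H, E, F


@njit(cache=True)
def _sw_traceback(x, y, H, E, F, ms, mms, go, ge, i0, j0):  # pragma: no cover
    """Trace one optimal path ending at (i0, j0); diagonal-preferring.

    Returns (read_start0, ref_start0, n_matches, ops) with 0-based starts and
    ops codes 0=M (diagonal), 1=I (read insertion), 2=D (reference gap),
    emitted in reverse order.
    """
    i = i0
    j = j0
    ops = np.empty(i0 + j0, np.uint8)
    k = 0
    nm = 0
    state = 0
    while i > 0 and j > 0:
        if state == 0:
            h = H[i, j]
            if h == 0:
                break
            s = ms if x[i - 1] == y[j - 1] else mms
            if h == H[i - 1, j - 1] + s:
                ops[k] = 0
                k += 1
                if x[i - 1] == y[j - 1]:
                    nm += 1
                i -= 1
                j -= 1
            elif h == E[i, j]:
                state = 1
            else:
                state = 2
        elif state == 1:
            ops[k] = 2
            k += 1
            if E[i, j] == H[i, j - 1] + go + ge:
                state = 0
            j -= 1
        else:
            ops[k] = 1
            k += 1
            if F[i, j] == H[i - 1, j] + go + ge:
                state = 0
            i -= 1
    return i, j, nm, ops[:k]


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


def _ops_to_path(ops: np.ndarray) -> tuple[tuple[str, int], ...]:
    names = ("M", "I", "D")
    path: list[tuple[str, int]] = []
    for code in ops[::-1]:
        op = names[code]
        if path and path[-1][0] == op:
            path[-1] = (op, path[-1][1] + 1)
        else:
            path.append((op, 1))
    return tuple(path)


_MAX_TIE_TRACEBACKS = 64


def local_align(
    read_seq: str, window_seq: str, scoring: Scoring = DEFAULT_SCORING
) -> LocalAlignmentResult:
    """Optimal Smith-Waterman local alignment of ``read_seq`` in ``window_seq``.

    Deterministic tie-break among equal-score optima: lowest ``ref_start``,
    then longest aligned reference span, then lowest ``read_start``.  Returns
    an ``aligned=False`` result when no positive-scoring alignment exists.
    """
    if not read_seq or not window_seq:
        raise AlignmentError("local_align requires non-empty read and window sequences")
    x = _encode(read_seq)
    y = _encode(window_seq)
    ms, mms = scoring.match, scoring.mismatch
    go, ge = scoring.gap_open, scoring.gap_extend
    H, E, F = _sw_fill(x, y, ms, mms, go, ge)
    best = int(H.max())
    if best <= 0:
        return replace(_UNALIGNED, read_length=len(read_seq))
    cells = np.argwhere(H == best)
    # stable candidate order by (ref_end, read_end); cap tracebacks in
    # degenerate low-complexity windows
    order = np.lexsort((cells[:, 0], cells[:, 1]))
    cells = cells[order][:_MAX_TIE_TRACEBACKS]
    chosen: tuple | None = None
    for i0, j0 in cells:
        ri, rj, nm, ops = _sw_traceback(x, y, H, E, F, ms, mms, go, ge, int(i0), int(j0))
        cand = (rj + 1, -(int(j0) - rj), ri + 1, int(i0), int(j0), nm, ops)
        if chosen is None or cand[:3] < chosen[:3]:
            chosen = cand
    assert chosen is not None
    ref_start, negspan, read_start, read_end, ref_end, nm, ops = chosen
    return LocalAlignmentResult(
        score=best,
        ref_start=ref_start,
        ref_end=ref_end,
        read_start=read_start,
        read_end=read_end,
        n_matches=int(nm),
        read_length=len(read_seq),
        path=_ops_to_path(ops),
    )


# --------------------------------------------------------------------------- classification
def classify_read_at_breakpoint(
    read: AlignedRead,
    chrom: str,
    pos: int,
    side: str = "both",
    anchor: int = 5,
    clip_tolerance: int = 2,
) -> str:
    """Classify a read at a breakpoint junction as spanning / soft_clipped / neither.

    ``pos`` is the last reference base before the junction; ``side`` is the
    side on which variant-supporting reads are clipped (``"left"``,
    ``"right"`` or ``"both"``).  A read *spans* when a single match segment
    covers ``[pos - anchor + 1, pos + anchor]`` and no clip boundary lies
    within ``clip_tolerance`` of ``pos``; it is *soft_clipped* when a clip
    boundary on the given side lies within ``clip_tolerance`` of ``pos``.
    The categories are mutually exclusive.
    """
    if side not in ("left", "right", "both"):
        raise ValueError(f"invalid side {side!r}")
    if not read.mapped or read.chrom != chrom:
        return NEITHER
    clip_near = False
    if side in ("right", "both") and read.right_clip > 0:
        if abs(read.ref_end - pos) <= clip_tolerance:
            clip_near = True
    if side in ("left", "both") and read.left_clip > 0:
        if abs((read.pos - 1) - pos) <= clip_tolerance:
            clip_near = True
    if clip_near:
        return SOFT_CLIPPED
    # any clip boundary (either side) close to pos disqualifies spanning
    boundary_near = (read.right_clip > 0 and abs(read.ref_end - pos) <= clip_tolerance) or (
        read.left_clip > 0 and abs((read.pos - 1) - pos) <= clip_tolerance
    )
    if not boundary_near:
        for a, b in read.match_blocks():
            if a <= pos - anchor + 1 and b >= pos + anchor:
                return SPANNING
    return NEITHER
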