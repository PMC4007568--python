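"""Iterative soft-clip refinement around candidate SV breakpoints.

Global end-to-end aligners mis-handle reads that cross an SV junction: a
read overhanging the junction by only a few bases is forced into a
mismatched end-to-end placement, and a read split near its middle may be
left unmapped.  Both failure modes suppress the soft-clip evidence that
split-read SV callers and the heterogeneity estimator depend on.

The loop implemented here: detect SVs, extract the reads near their
breakpoints plus all unmapped reads from the *original* alignment, realign
those reads individually with the local aligner (breakpoint reads inside
their SV neighbourhoods, unmapped reads against the whole reference via
exact-seed windows), re-detect, and repeat until the SV set is stable.
Concordant reads far from any breakpoint are never touched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from .alignment_model import AlignedRead, DEFAULT_SCORING, Scoring, local_align
from .simulate import StructuralVariant, revcomp
from .sv_detect import detect_svs, filter_derivative_svs

logger = logging.getLogger("hetshear")


@dataclass
class RefinementState:
    """Snapshot of one detect-extract-realign iteration."""

    iteration: int
    svs: list[StructuralVariant]
    extracted_read_ids: set
    converged: bool = False

    @property
    def sv_keys(self) -> frozenset:
        return frozenset(sv.key for sv in self.svs)


# --------------------------------------------------------------------------- extraction
def extract_candidates(
    reads: Sequence[AlignedRead],
    svs: Sequence[StructuralVariant],
    neighborhood: int = 650,
) -> tuple[dict[tuple, list[AlignedRead]], list[AlignedRead]]:
    """Breakpoint-neighbourhood reads per SV plus all unmapped reads.

    A mapped read belongs to an SV when its aligned span overlaps
    ``[bp - neighborhood, bp + neighborhood]`` for either breakpoint.
    """
    per_sv: dict[tuple, list[AlignedRead]] = {sv.key: [] for sv in svs}
    windows = []
    for sv in svs:
        for chrom, bp in ((sv.chrom1, sv.bp1), (sv.chrom2, sv.bp2)):
            windows.append((sv.key, chrom, bp - neighborhood, bp + neighborhood))
    unmapped: list[AlignedRead] = []
    for read in reads:
        if not read.mapped:
            unmapped.append(read)
            continue
        if not windows:
            continue
        start, end = read.pos, read.ref_end
        hit_keys = set()
        for key, chrom, lo, hi in windows:
            if read.chrom == chrom and end >= lo and start <= hi and key not in hit_keys:
                per_sv[key].append(read)
                hit_keys.add(key)
    return per_sv, unmapped


# --------------------------------------------------------------------------- realignment
def _build_seed_index(reference: str, seed_len: int, max_hits: int = 50) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i in range(len(reference) - seed_len + 1):
        kmer = reference[i : i + seed_len]
        hits = index.setdefault(kmer, [])
        if len(hits) < max_hits:
            hits.append(i + 1)  # 1-based
    return index


def _best_window_placement(
    seq: str,
    windows: Sequence[tuple[int, int]],
    reference: str,
    scoring: Scoring,
) -> tuple[int, int, tuple[tuple[str, int], ...]] | None:
    """Highest-scoring local placement of ``seq`` over candidate windows.

    Returns (score, ref_pos_of_first_aligned_base, cigar) or None.
    Deterministic: windows are scanned in order; a strictly higher score is
    required to displace an earlier placement.
    """
    best: tuple[int, int, tuple[tuple[str, int], ...]] | None = None
    for lo, hi in windows:
        lo = max(1, lo)
        hi = min(len(reference), hi)
        if hi <= lo:
            continue
        res = local_align(seq, reference[lo - 1 : hi], scoring)
        if not res.aligned:
            continue
        pos = lo - 1 + res.ref_start
        if best is None or res.score > best[0]:
            best = (res.score, pos, tuple(res.cigar()))
    return best


def realign_candidates(
    per_sv: dict[tuple, list[AlignedRead]],
    unmapped: Sequence[AlignedRead],
    reference: str,
    svs: Sequence[StructuralVariant],
    neighborhood: int = 650,
    scoring: Scoring = DEFAULT_SCORING,
    min_score: int = 20,
    seed_len: int = 20,
    chrom: str = "ref",
) -> dict[tuple, AlignedRead]:
    """Realign extracted reads individually; returns replacement records by uid.

    Breakpoint reads are aligned inside their SV's breakpoint windows
    (padded by the read length so a read overlapping the extraction
    neighbourhood always fits entirely); unmapped reads are aligned against
    the whole reference by exact-seed-and-extend in both orientations.
    Reads that reach ``min_score`` nowhere stay unmapped.
    """
    sv_by_key = {sv.key: sv for sv in svs}
    read_windows: dict[tuple, list[tuple[int, int]]] = {}
    read_obj: dict[tuple, AlignedRead] = {}
    for key, members in per_sv.items():
        sv = sv_by_key[key]
        pad = neighborhood + max((m.read_length for m in members), default=100) + 10
        wins = [(sv.bp1 - pad, sv.bp1 + pad), (sv.bp2 - pad, sv.bp2 + pad)]
        for m in members:
            read_obj[m.uid] = m
            read_windows.setdefault(m.uid, []).extend(wins)
    replacements: dict[tuple, AlignedRead] = {}
    for uid, wins in read_windows.items():
        read = read_obj[uid]
        best = _best_window_placement(read.seq, wins, reference, scoring)
        if best is not None and best[0] >= min_score:
            _, pos, cigar = best
            replacements[uid] = AlignedRead(
                name=read.name,
                chrom=chrom,
                pos=pos,
                cigar=list(cigar),
                seq=read.seq,
                mapped=True,
                is_reverse=read.is_reverse,
                is_read1=read.is_read1,
                mate_chrom=read.mate_chrom,
                mate_pos=read.mate_pos,
                mate_mapped=read.mate_mapped,
            )
        else:
            replacements[uid] = AlignedRead(
                name=read.name,
                chrom=None,
                pos=0,
                cigar=[("S", len(read.seq))],
                seq=read.seq,
                mapped=False,
                is_reverse=False,
                is_read1=read.is_read1,
                mate_chrom=read.mate_chrom,
                mate_pos=read.mate_pos,
                mate_mapped=read.mate_mapped,
            )
    if unmapped:
        index = _build_seed_index(reference, seed_len)
        for read in unmapped:
            placed = None
            for rc in (False, True):
                seq = revcomp(read.seq) if rc else read.seq
                wins: list[tuple[int, int]] = []
                for off in range(0, max(1, len(seq) - seed_len + 1), max(1, seed_len // 2)):
                    for hit in index.get(seq[off : off + seed_len], ()):
                        wins.append((hit - off - len(seq) - 10, hit - off + 2 * len(seq) + 10))
                if not wins:
                    continue
                # merge overlapping candidate windows, keep deterministic order
                wins = sorted(set(wins))
                merged = [wins[0]]
                for lo, hi in wins[1:]:
                    if lo <= merged[-1][1]:
                        merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
                    else:
                        merged.append((lo, hi))
                best = _best_window_placement(seq, merged, reference, scoring)
                if best is not None and (placed is None or best[0] > placed[0][0]):
                    placed = (best, rc)
            if placed is not None and placed[0][0] >= min_score:
                (score, pos, cigar), rc = placed
                replacements[read.uid] = AlignedRead(
                    name=read.name,
                    chrom=chrom,
                    pos=pos,
                    cigar=list(cigar),
                    seq=revcomp(read.seq) if rc else read.seq,
                    mapped=True,
                    is_reverse=rc,
                    is_read1=read.is_read1,
                    mate_chrom=read.mate_chrom,
                    mate_pos=read.mate_pos,
                    mate_mapped=read.mate_mapped,
                )
            else:
                replacements[read.uid] = read
    return replacements


def _placement_key(read: AlignedRead) -> tuple:
    return (read.mapped, read.chrom, read.pos, tuple(read.cigar))


def _sorted_alignment(reads: Sequence[AlignedRead]) -> list[AlignedRead]:
    mapped = sorted(
        (r for r in reads if r.mapped), key=lambda r: (r.chrom, r.pos, r.name, not r.is_read1)
    )
    unmapped = sorted((r for r in reads if not r.mapped), key=lambda r: (r.name, not r.is_read1))
    return mapped + unmapped


# --------------------------------------------------------------------------- the loop
def run_refinement(
    reads: Sequence[AlignedRead],
    reference: str,
    max_iterations: int = 5,
    neighborhood: int = 650,
    scoring: Scoring = DEFAULT_SCORING,
    min_score: int = 20,
    seed_len: int = 20,
    min_clip_len: int = 8,
    merge_window: int = 2,
    min_cluster_support: int = 3,
    search_radius: int = 100_000,
    min_identity: float = 0.9,
    clip_tolerance: int = 2,
    main_window: int = 10,
    support_ratio: float = 0.1,
    chrom: str = "ref",
) -> tuple[list[StructuralVariant], list[AlignedRead], list[RefinementState]]:
    """Detect -> extract -> realign until the SV set is stable.

    Extraction always re-reads the original alignment, so each iteration's
    alignment is a pure function of the current SV set and the loop cannot
    oscillate.  Convergence: the SV set (type + both breakpoints) repeats,
    or realignment leaves every extracted placement unchanged.  Hitting
    ``max_iterations`` without convergence logs a warning and returns the
    last state flagged ``converged=False``.  The derivative-SV filter is
    applied once, after the loop.
    """
    original = _sorted_alignment(reads)
    original_by_uid = {r.uid: r for r in original}
    current = original
    history: list[RefinementState] = []
    prev_keys: frozenset | None = None
    converged = False
    svs: list[StructuralVariant] = []
    for iteration in range(1, max_iterations + 1):
        svs = detect_svs(
            current,
            reference,
            min_clip_len=min_clip_len,
            merge_window=merge_window,
            min_cluster_support=min_cluster_support,
            scoring=scoring,
            search_radius=search_radius,
            min_identity=min_identity,
            clip_tolerance=clip_tolerance,
        )
        state = RefinementState(iteration=iteration, svs=svs, extracted_read_ids=set())
        history.append(state)
        keys = state.sv_keys
        if prev_keys is not None and keys == prev_keys:
            state.converged = True
            converged = True
            logger.info("iteration %d: SV set unchanged (%d SVs); converged", iteration, len(svs))
            break
        prev_keys = keys
        per_sv, unmapped = extract_candidates(original, svs, neighborhood)
        extracted_ids = {r.uid for members in per_sv.values() for r in members}
        extracted_ids |= {r.uid for r in unmapped}
        state.extracted_read_ids = extracted_ids
        replacements = realign_candidates(
            per_sv,
            unmapped,
            reference,
            svs,
            neighborhood=neighborhood,
            scoring=scoring,
            min_score=min_score,
            seed_len=seed_len,
            chrom=chrom,
        )
        n_moved = sum(
            1
            for uid, rec in replacements.items()
            if _placement_key(rec) != _placement_key(original_by_uid[uid])
        )
        logger.info(
            "iteration %d: %d SVs, extracted %d reads (%d unmapped), %d placements changed",
            iteration,
            len(svs),
            len(extracted_ids),
            len(unmapped),
            n_moved,
        )
        if n_moved == 0:
            # detection is deterministic, so the next pass would repeat exactly
            state.converged = True
            converged = True
            break
        current = _sorted_alignment(
            [r for r in original if r.uid not in replacements] + list(replacements.values())
        )
    if not converged:
        logger.warning(
            "refinement did not converge within %d iterations; returning last state", max_iterations
        )
    final_svs = filter_derivative_svs(
        svs, main_window=main_window, support_ratio=support_ratio, clip_tolerance=clip_tolerance
    )
    return final_svs, current, history
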