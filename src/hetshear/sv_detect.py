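"""Base-pair-resolution split-read SV caller.

Reads crossing an SV junction align only partially to the reference; the
clipped remainder points at the partner locus.  Detection proceeds in three
steps: (1) cluster soft-clip boundaries that fall at (nearly) the same
junction coordinate, (2) match partner clusters by locally aligning each
cluster's consensus clipped sequence near the other cluster and requiring a
reciprocal hit, (3) type the event from the clip sides, strand and relative
order of the matched pair:

* right-clip at ``p1`` whose clip continues on the forward strand after
  ``p2 > p1``  -> deletion of ``p1+1 .. p2``;
* right-clip at ``p2`` whose clip jumps back to the forward strand at
  ``p1+1 < p2`` -> tandem duplication of ``p1+1 .. p2``;
* same-side clusters whose clips match across the pair on the reverse
  complement -> inversion;
* reciprocal cross-chromosome match -> translocation (reported only).

Cluster junction coordinates use the package convention (the last reference
base before the junction), so a matched pair's coordinates are directly the
SV breakpoints.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from .alignment_model import AlignedRead, AlignmentError, DEFAULT_SCORING, Scoring, local_align
from .simulate import DEL, DUP, INV, TRA, StructuralVariant, revcomp

logger = logging.getLogger("hetshear")

__all__ = [
    "SoftClipCluster",
    "StructuralVariant",
    "build_clusters",
    "match_partners",
    "filter_derivative_svs",
    "detect_svs",
    "write_sv_report",
]


@dataclass(frozen=True)
class SoftClipCluster:
    """A pileup of reads sharing a soft-clip junction coordinate.

    ``pos`` is the junction coordinate (last reference base before the
    junction); ``side`` says whether members are clipped on their right
    (clip extends past ``pos``) or left (clip precedes ``pos + 1``).
    ``consensus_clip`` reads away from the junction for ``side == 'right'``
    and toward it (i.e. its last base abuts the junction) for ``'left'``.
    """

    chrom: str
    pos: int
    side: str  # "left" | "right"
    support: int
    consensus_clip: str


def _consensus(clips: Sequence[str], side: str) -> str:
    """Per-column majority over member clips anchored at the junction.

    Right clips are anchored at their start, left clips at their end.
    Column ties break toward the lexicographically smallest base.
    """
    if side == "left":
        clips = [c[::-1] for c in clips]
    width = max(len(c) for c in clips)
    out = []
    for col in range(width):
        counts = Counter(c[col] for c in clips if len(c) > col)
        top = max(counts.values())
        base = min(b for b, n in counts.items() if n == top)
        out.append(base)
    cons = "".join(out)
    return cons[::-1] if side == "left" else cons


def build_clusters(
    reads: Iterable[AlignedRead],
    min_clip_len: int = 8,
    merge_window: int = 2,
    min_cluster_support: int = 3,
) -> list[SoftClipCluster]:
    """Cluster soft-clip boundaries from a coordinate-sorted read stream.

    Boundaries within ``merge_window`` of each other merge into one cluster
    whose position is the modal boundary; clusters with fewer than
    ``min_cluster_support`` members are dropped.  Hard-clipped records (no
    clip sequence available) contribute to support but not to the consensus.
    """
    events: dict[tuple[str, str], list[tuple[int, str]]] = defaultdict(list)
    last: tuple[str, int] | None = None
    for read in reads:
        if not read.mapped:
            continue
        key = (read.chrom, read.pos)
        if last is not None and read.chrom == last[0] and read.pos < last[1]:
            raise AlignmentError(
                "input is not coordinate-sorted; sort the alignment before clustering"
            )
        last = key
        if read.right_clip >= min_clip_len:
            events[(read.chrom, "right")].append((read.ref_end, read.clipped_suffix))
        if read.left_clip >= min_clip_len:
            events[(read.chrom, "left")].append((read.pos - 1, read.clipped_prefix))
    clusters: list[SoftClipCluster] = []
    for (chrom, side), boundary_list in events.items():
        boundary_list.sort(key=lambda t: t[0])
        group: list[tuple[int, str]] = []
        prev = None
        for pos, clip in boundary_list + [(None, "")]:  # sentinel flush
            if prev is not None and (pos is None or pos - prev > merge_window):
                counts = Counter(p for p, _ in group)
                top = max(counts.values())
                modal = min(p for p, n in counts.items() if n == top)
                if len(group) >= min_cluster_support:
                    clips = [c for _, c in group if c]
                    clusters.append(
                        SoftClipCluster(
                            chrom=chrom,
                            pos=modal,
                            side=side,
                            support=len(group),
                            consensus_clip=_consensus(clips, side) if clips else "",
                        )
                    )
                group = []
            if pos is None:
                break
            group.append((pos, clip))
            prev = pos
    clusters.sort(key=lambda c: (c.chrom, c.pos, c.side))
    return clusters


# --------------------------------------------------------------------------- partner matching
def _directed_hit(
    clip: str,
    reference: str,
    target: int,
    expect: str,  # "start_after" | "end_at"
    rc: bool,
    scoring: Scoring,
    min_identity: float,
    clip_tolerance: int,
) -> int | None:
    """Align a consensus clip near an implied junction on one strand.

    ``expect == "start_after"``: the clip's first base should land at
    ``target + 1``; ``"end_at"``: its last base should land at ``target``.
    Returns the implied junction coordinate on success, else None.
    """
    if not clip:
        return None
    seq = revcomp(clip) if rc else clip
    pad = clip_tolerance + 5
    lo = max(1, target - len(seq) - pad)
    hi = min(len(reference), target + len(seq) + pad)
    if hi <= lo:
        return None
    window = reference[lo - 1 : hi]
    res = local_align(seq, window, scoring)
    if not res.aligned or res.n_matches < min_identity * len(seq):
        return None
    if expect == "start_after":
        implied = (lo - 1 + res.ref_start) - res.read_start  # junction before clip base 1
    else:
        implied = (lo - 1 + res.ref_end) + (len(seq) - res.read_end)
    if abs(implied - target) > clip_tolerance:
        return None
    return implied


def _pair_to_sv(
    a: SoftClipCluster,
    b: SoftClipCluster,
    reference: dict[str, str],
    scoring: Scoring,
    min_identity: float,
    clip_tolerance: int,
) -> StructuralVariant | None:
    """Try to explain an (ordered, a.pos < b.pos) same-chromosome cluster
    pair as one SV; both directions must reach ``min_identity``."""
    ref = reference[a.chrom]
    if a.side == "right" and b.side == "left":
        # deletion: a's clip resumes after b, b's clip ends at a
        ja = _directed_hit(a.consensus_clip, ref, b.pos, "start_after", False, scoring, min_identity, clip_tolerance)
        jb = _directed_hit(b.consensus_clip, ref, a.pos, "end_at", False, scoring, min_identity, clip_tolerance)
        if ja is None or jb is None:
            return None
        bp1, bp2 = jb, ja
        if bp1 >= bp2:
            return None
        return StructuralVariant(DEL, a.chrom, bp1, a.chrom, bp2, a.support, b.support)
    if a.side == "left" and b.side == "right":
        # tandem duplication: b's clip jumps back to start after a, a's clip
        # is the segment end at b
        jb = _directed_hit(b.consensus_clip, ref, a.pos, "start_after", False, scoring, min_identity, clip_tolerance)
        ja = _directed_hit(a.consensus_clip, ref, b.pos, "end_at", False, scoring, min_identity, clip_tolerance)
        if ja is None or jb is None:
            return None
        bp1, bp2 = jb, ja
        if bp1 >= bp2:
            return None
        return StructuralVariant(DUP, a.chrom, bp1, a.chrom, bp2, a.support, b.support)
    if a.side == b.side:
        # inversion: clips match the reverse complement across the pair
        if a.side == "right":
            ja = _directed_hit(a.consensus_clip, ref, b.pos, "end_at", True, scoring, min_identity, clip_tolerance)
            jb = _directed_hit(b.consensus_clip, ref, a.pos, "end_at", True, scoring, min_identity, clip_tolerance)
            if ja is None or jb is None:
                return None
            bp1, bp2 = jb, ja
        else:
            ja = _directed_hit(a.consensus_clip, ref, b.pos, "start_after", True, scoring, min_identity, clip_tolerance)
            jb = _directed_hit(b.consensus_clip, ref, a.pos, "start_after", True, scoring, min_identity, clip_tolerance)
            if ja is None or jb is None:
                return None
            bp1, bp2 = jb, ja
        if bp1 >= bp2:
            return None
        return StructuralVariant(INV, a.chrom, bp1, a.chrom, bp2, a.support, b.support)
    return None


def _tra_pair(
    a: SoftClipCluster,
    b: SoftClipCluster,
    reference: dict[str, str],
    scoring: Scoring,
    min_identity: float,
    clip_tolerance: int,
) -> StructuralVariant | None:
    """Cross-chromosome reciprocal forward match (reported only)."""
    if a.side == "right" and b.side == "left":
        ja = _directed_hit(a.consensus_clip, reference[b.chrom], b.pos, "start_after", False, scoring, min_identity, clip_tolerance)
        jb = _directed_hit(b.consensus_clip, reference[a.chrom], a.pos, "end_at", False, scoring, min_identity, clip_tolerance)
        if ja is None or jb is None:
            return None
        c1, p1, s1 = a.chrom, jb, a.support
        c2, p2, s2 = b.chrom, ja, b.support
        if (c2, p2) < (c1, p1):
            c1, p1, s1, c2, p2, s2 = c2, p2, s2, c1, p1, s1
        return StructuralVariant(TRA, c1, p1, c2, p2, s1, s2)
    return None


def match_partners(
    clusters: Sequence[SoftClipCluster],
    reference: dict[str, str] | str,
    scoring: Scoring = DEFAULT_SCORING,
    search_radius: int = 100_000,
    min_identity: float = 0.9,
    clip_tolerance: int = 2,
) -> list[StructuralVariant]:
    """Emit candidate SVs from reciprocally matching cluster pairs.

    Every unordered cluster pair within ``search_radius`` (same chromosome)
    or across chromosomes is tested against the type templates above; both
    clip-to-partner alignments must reach ``min_identity`` over the
    consensus clip.  Duplicate events found through independent cluster
    pairs (an inversion surfaces once per clip side) are merged, summing
    support per breakpoint.  Unmatched clusters are left for diagnostics.
    """
    if isinstance(reference, str):
        reference = {clusters[0].chrom if clusters else "ref": reference}
    merged: dict[tuple, StructuralVariant] = {}
    matched: set[int] = set()
    for i in range(len(clusters)):
        for j in range(i + 1, len(clusters)):
            a, b = clusters[i], clusters[j]
            if a.chrom == b.chrom:
                if abs(a.pos - b.pos) > search_radius:
                    continue
                if (b.pos, b.side) < (a.pos, a.side):
                    a, b = b, a
                sv = _pair_to_sv(a, b, reference, scoring, min_identity, clip_tolerance)
            else:
                sv = _tra_pair(a, b, reference, scoring, min_identity, clip_tolerance) or _tra_pair(
                    b, a, reference, scoring, min_identity, clip_tolerance
                )
            if sv is None:
                continue
            matched.update((i, j))
            if sv.key in merged:
                old = merged[sv.key]
                merged[sv.key] = replace(
                    old,
                    support_bp1=old.support_bp1 + sv.support_bp1,
                    support_bp2=old.support_bp2 + sv.support_bp2,
                )
            else:
                merged[sv.key] = sv
    unmatched = len(clusters) - len(matched)
    if unmatched:
        logger.debug("match_partners: %d unmatched soft-clip clusters retained", unmatched)
    return sorted(merged.values(), key=lambda s: s.key)


# --------------------------------------------------------------------------- derivative filter
def filter_derivative_svs(
    svs: Sequence[StructuralVariant],
    main_window: int = 10,
    support_ratio: float = 0.1,
    clip_tolerance: int = 2,
) -> list[StructuralVariant]:
    """Demote low-support calls that differ from a stronger call by a few
    bases on one breakpoint (sequencing-error artifacts).

    A candidate is marked ``filtered`` when a same-type SV shares one
    breakpoint (within ``clip_tolerance``), has its other breakpoint within
    ``main_window``, and the candidate's total support is below
    ``support_ratio`` times the main SV's.  Survivors become ``confirmed``.
    """

    def total(sv: StructuralVariant) -> int:
        return sv.support_bp1 + sv.support_bp2

    out: list[StructuralVariant] = []
    for sv in svs:
        doomed = False
        for other in svs:
            if other is sv or other.sv_type != sv.sv_type:
                continue
            if other.chrom1 != sv.chrom1 or other.chrom2 != sv.chrom2:
                continue
            d1 = abs(other.bp1 - sv.bp1)
            d2 = abs(other.bp2 - sv.bp2)
            shares = (d1 <= clip_tolerance and d2 <= main_window) or (
                d2 <= clip_tolerance and d1 <= main_window
            )
            if shares and total(sv) < support_ratio * total(other):
                doomed = True
                break
        out.append(replace(sv, status="filtered" if doomed else "confirmed"))
    return out


def detect_svs(
    reads: Iterable[AlignedRead],
    reference: dict[str, str] | str,
    min_clip_len: int = 8,
    merge_window: int = 2,
    min_cluster_support: int = 3,
    scoring: Scoring = DEFAULT_SCORING,
    search_radius: int = 100_000,
    min_identity: float = 0.9,
    clip_tolerance: int = 2,
) -> list[StructuralVariant]:
    """Cluster + match in one call (reads must be coordinate-sorted)."""
    clusters = build_clusters(reads, min_clip_len, merge_window, min_cluster_support)
    return match_partners(clusters, reference, scoring, search_radius, min_identity, clip_tolerance)


SV_REPORT_COLUMNS = [
    "sv_id",
    "type",
    "chrom1",
    "bp1",
    "chrom2",
    "bp2",
    "support_bp1",
    "support_bp2",
    "status",
]


def write_sv_report(svs: Sequence[StructuralVariant], path, extra: dict | None = None) -> None:
    """Fixed-column TSV report; ``extra`` maps sv_id -> dict of added columns."""
    extra_cols: list[str] = []
    if extra:
        seen = set()
        for row in extra.values():
            for k in row:
                if k not in seen:
                    seen.add(k)
                    extra_cols.append(k)
    with open(path, "w") as fh:
        fh.write("\t".join(SV_REPORT_COLUMNS + extra_cols) + "\n")
        for idx, sv in enumerate(svs, start=1):
            sv_id = f"SV{idx}"
            row = [
                sv_id,
                sv.sv_type,
                sv.chrom1,
                str(sv.bp1),
                sv.chrom2,
                str(sv.bp2),
                str(sv.support_bp1),
                str(sv.support_bp2),
                sv.status,
            ]
            if extra_cols:
                vals = (extra or {}).get(sv_id, {})
                row += [str(vals.get(c, "-")) for c in extra_cols]
            fh.write("\t".join(row) + "\n")
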