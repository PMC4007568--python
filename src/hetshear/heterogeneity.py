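"""Heterogeneity estimation from spanning vs soft-clipped breakpoint reads.

For each SV, let ``A`` be the total number of aligned reads that span either
breakpoint and ``B`` the total number of reads soft-clipped at either
breakpoint.  The estimated variant depth ``V`` and reference depth ``R``
depend on the SV type, and the heterogeneity fraction is ``H = V / (V + R)``:

* deletion:            ``V = B``, ``R = A/2``            -> ``H = B / (B + A/2)``
  (the variant allele has a single junction whose reads split between the
  two reference breakpoints, while reference-allele reads span both, so the
  spanning count is averaged over the two loci);
* tandem duplication:  ``V = B``, ``R = A/2 - B``        -> ``H = B / (A/2)``
  (reads spanning the outer edges of the duplicated segment come from both
  alleles, so the variant depth is subtracted back out; sampling noise can
  push ``R`` below zero, in which case the estimate is clamped to 1 and
  flagged);
* inversion:           no copy-number change             -> ``H = B / (A + B)``.

Translocations are reported with the inversion formula (no copy-number
adjustment is derivable for them); the output flags that assumption.

All estimates assume intra-cellular homozygosity: ``H = 50%`` could equally
mean half the cells homozygous or all cells heterozygous for the variant.
"""

from __future__ import annotations

import logging
from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

from .alignment_model import AlignedRead, SOFT_CLIPPED, SPANNING, classify_read_at_breakpoint
from .simulate import DEL, DUP, INV, TRA, StructuralVariant

logger = logging.getLogger("hetshear")

_FORMULA = {DEL: "deletion", DUP: "duplication", INV: "inversion", TRA: "inversion"}


@dataclass(frozen=True)
class HetEstimate:
    """Per-SV heterogeneity estimate.

    ``H`` is a fraction in [0, 1]; ``het_percent`` renders it the way
    reports print it (two decimals).  ``defined`` is False when A = B = 0
    (no breakpoint evidence at all); ``clamped`` marks a duplication whose
    soft-clip count exceeded half the spanning count.
    """

    sv_type: str
    A: int
    B: int
    V: float
    R: float
    H: float | None
    formula: str
    defined: bool = True
    clamped: bool = False
    assumed_formula: bool = False

    @property
    def het_percent(self) -> str:
        return "-" if self.H is None else f"{self.H * 100:.2f}"


def estimate_het(sv_type: str, A: int, B: int) -> HetEstimate:
    """Apply the type-specific heterogeneity formula to counts (A, B).

    Exact rational arithmetic; the result is converted to float at the end.
    ``A = B = 0`` yields an undefined estimate (``H is None``) with a
    warning - never a silent 0 or 1.
    """
    if A < 0 or B < 0:
        raise ValueError(f"negative read counts: A={A}, B={B}")
    formula = _FORMULA[sv_type]
    assumed = sv_type == TRA
    if A == 0 and B == 0:
        logger.warning("heterogeneity undefined for %s: no spanning or soft-clipped reads", sv_type)
        return HetEstimate(sv_type, A, B, 0.0, 0.0, None, formula, defined=False, assumed_formula=assumed)
    if formula == "deletion":
        V = Fraction(B)
        R = Fraction(A, 2)
        H = V / (V + R)
        return HetEstimate(sv_type, A, B, float(V), float(R), float(H), formula)
    if formula == "duplication":
        V = Fraction(B)
        R = Fraction(A, 2) - V
        clamped = R < 0
        if clamped:
            R = Fraction(0)
        H = V / (V + R) if (V + R) > 0 else Fraction(1)
        return HetEstimate(sv_type, A, B, float(V), float(max(R, 0)), float(min(H, 1)), formula, clamped=clamped)
    # inversion (and translocation, by assumption)
    H = Fraction(B, A + B)
    return HetEstimate(sv_type, A, B, float(B), float(A), float(H), formula, assumed_formula=assumed)


# --------------------------------------------------------------------------- counting
class _ReadIndex:
    """Sorted-by-start index over mapped reads for window queries."""

    def __init__(self, reads: Sequence[AlignedRead], max_read_span: int = 1000):
        self.reads = sorted((r for r in reads if r.mapped), key=lambda r: (r.chrom, r.pos))
        self.starts = [(r.chrom, r.pos) for r in self.reads]
        self.max_span = max(
            (r.ref_end - r.pos + 1 for r in self.reads), default=0
        )

    def overlapping(self, chrom: str, lo: int, hi: int) -> list[AlignedRead]:
        i = bisect_left(self.starts, (chrom, lo - self.max_span))
        j = bisect_right(self.starts, (chrom, hi))
        return [r for r in self.reads[i:j] if r.ref_end >= lo]


def count_breakpoint_reads(
    reads: Sequence[AlignedRead] | _ReadIndex,
    sv: StructuralVariant,
    anchor: int = 5,
    clip_tolerance: int = 2,
    reference_lengths: dict[str, int] | None = None,
) -> tuple[int, int]:
    """Count (A, B) for one SV on a (post-refinement) alignment.

    ``A`` sums spanning classifications over both breakpoints; ``B`` counts
    each read once even if it is clipped at both junction positions of the
    SV (short variant-allele fragments).
    """
    if reference_lengths is not None:
        for chrom, bp in ((sv.chrom1, sv.bp1), (sv.chrom2, sv.bp2)):
            if chrom in reference_lengths and not (1 <= bp < reference_lengths[chrom]):
                raise ValueError(f"breakpoint {chrom}:{bp} outside reference bounds")
    index = reads if isinstance(reads, _ReadIndex) else _ReadIndex(reads)
    side1, side2 = sv.clip_sides()
    A = 0
    clipped_uids: set = set()
    pad = anchor + clip_tolerance + 1
    for chrom, bp, side in ((sv.chrom1, sv.bp1, side1), (sv.chrom2, sv.bp2, side2)):
        for read in index.overlapping(chrom, bp - pad, bp + pad):
            cls = classify_read_at_breakpoint(read, chrom, bp, side, anchor, clip_tolerance)
            if cls == SPANNING:
                A += 1
            elif cls == SOFT_CLIPPED:
                clipped_uids.add(read.uid)
    return A, len(clipped_uids)


def estimate_all(
    reads: Sequence[AlignedRead],
    svs: Sequence[StructuralVariant],
    anchor: int = 5,
    clip_tolerance: int = 2,
) -> list[HetEstimate]:
    """Count and estimate for every SV against one shared read index."""
    index = _ReadIndex(reads)
    out = []
    for sv in svs:
        A, B = count_breakpoint_reads(index, sv, anchor, clip_tolerance)
        out.append(estimate_het(sv.sv_type, A, B))
    return out
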