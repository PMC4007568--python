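"""Personal genomic sequence construction.

Applies a selected set of structural variants to the reference to produce
the individual sample's sequence, plus a reference -> personal coordinate
map.  Breakpoint-to-interval convention (see ``alignment_model``): with
``bp1``/``bp2`` both "last base before the junction" coordinates, an edit
acts on reference positions ``bp1+1 .. bp2``::

    reference   ... x [ bp1 ] | s s s [ bp2 ] | y ...
    DEL         ... x [ bp1 ] | y ...                         (segment removed)
    DUP         ... x [ bp1 ] | s s s [ bp2 ] | s s s [ bp2 ] | y ...
    INV         ... x [ bp1 ] | revcomp(s s s) | y ...

Edits are applied right-to-left so earlier coordinates stay valid.  The
coordinate map is positional: deleted reference bases map to "-", bases
inside an inverted segment keep their (length-preserving) position even
though their base identity is reverse-complemented, and the map is monotone
over all non-deleted positions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .heterogeneity import HetEstimate
from .simulate import DEL, DUP, INV, StructuralVariant, revcomp

logger = logging.getLogger("hetshear")

_APPLYABLE = (DEL, DUP, INV)


class EditError(ValueError):
    """Invalid edit selection or application."""


@dataclass(frozen=True)
class EditPlan:
    """Ordered, validated set of SV edits (sorted by bp1 descending)."""

    edits: tuple[StructuralVariant, ...]
    inclusion_rule: str  # e.g. "threshold h_min=0.5" or "explicit"


def _check_disjoint(svs: Sequence[StructuralVariant]) -> None:
    ordered = sorted(svs, key=lambda s: s.bp1)
    for a, b in zip(ordered, ordered[1:]):
        if b.bp1 < a.bp2:
            raise EditError(
                f"overlapping SVs selected: {a.sv_type}@{a.bp1}-{a.bp2} and {b.sv_type}@{b.bp1}-{b.bp2}"
            )


def select_svs(
    svs: Sequence[StructuralVariant],
    estimates: Sequence[HetEstimate] | None = None,
    h_min: float | None = None,
    ids: Sequence[str] | None = None,
    sv_ids: Sequence[str] | None = None,
) -> EditPlan:
    """Choose which SVs to apply.

    Threshold mode (``h_min``): keep confirmed SVs whose estimated
    heterogeneity fraction is at least ``h_min`` (requires ``estimates``,
    aligned 1:1 with ``svs``).  Explicit mode (``ids``): keep exactly the
    listed ``SV<n>`` ids (1-based order in ``svs``).  Overlapping or
    inapplicable (translocation) selections are rejected.
    """
    ids = ids if ids is not None else sv_ids
    if (h_min is None) == (ids is None):
        raise EditError("choose exactly one of h_min= (threshold mode) or ids= (explicit mode)")
    chosen: list[StructuralVariant] = []
    if h_min is not None:
        if estimates is None or len(estimates) != len(svs):
            raise EditError("threshold mode requires one HetEstimate per SV")
        rule = f"threshold h_min={h_min:g}"
        for sv, est in zip(svs, estimates):
            if sv.status == "filtered" or sv.sv_type not in _APPLYABLE:
                continue
            if est.defined and est.H is not None and est.H >= h_min:
                chosen.append(sv)
    else:
        rule = "explicit"
        by_id = {f"SV{i}": sv for i, sv in enumerate(svs, start=1)}
        for sv_id in ids or ():
            if sv_id not in by_id:
                raise EditError(f"unknown SV id {sv_id!r}; have {sorted(by_id)}")
            sv = by_id[sv_id]
            if sv.sv_type not in _APPLYABLE:
                raise EditError(f"{sv_id} is a {sv.sv_type}; only DEL/DUP/INV can be applied")
            chosen.append(sv)
    _check_disjoint(chosen)
    return EditPlan(tuple(sorted(chosen, key=lambda s: -s.bp1)), rule)


def apply_edits(reference: str, plan: EditPlan) -> tuple[str, np.ndarray]:
    """Apply the plan; returns (personal sequence, coordinate map).

    The map has one entry per reference position (1-based index i at
    ``map[i-1]``): the personal-genome position, or -1 for deleted bases.
    """
    L = len(reference)
    for sv in plan.edits:
        if not (1 <= sv.bp1 < sv.bp2 <= L):
            raise EditError(f"edit {sv.sv_type}@{sv.bp1}-{sv.bp2} outside sequence bounds (1..{L})")
    _check_disjoint(plan.edits)
    seq = reference
    for sv in plan.edits:  # bp1 descending: later edits don't shift earlier coords
        a, b = sv.bp1, sv.bp2  # segment = seq[a:b] in 0-based slicing
        if sv.sv_type == DEL:
            seq = seq[:a] + seq[b:]
        elif sv.sv_type == DUP:
            seq = seq[:b] + seq[a:b] + seq[b:]
        elif sv.sv_type == INV:
            seq = seq[:a] + revcomp(seq[a:b]) + seq[b:]
    coord = np.arange(1, L + 1, dtype=np.int64)
    shift = np.zeros(L, dtype=np.int64)
    deleted = np.zeros(L, dtype=bool)
    for sv in plan.edits:
        a, b = sv.bp1, sv.bp2
        if sv.sv_type == DEL:
            deleted[a:b] = True
            if b < L:
                shift[b:] -= b - a
        elif sv.sv_type == DUP:
            if b < L:
                shift[b:] += b - a
        # INV is length-preserving and positional: no shift
    coord = coord + shift
    coord[deleted] = -1
    return seq, coord


def write_personal_fasta(
    path: str | Path,
    seq: str,
    chrom: str,
    applied_ids: Sequence[str],
    width: int = 70,
    tool_version: str = "hetshear/0.1.0",
) -> None:
    with open(path, "w") as fh:
        applied = ",".join(applied_ids) if applied_ids else "none"
        fh.write(f">{chrom} personal applied={applied} {tool_version}\n")
        for i in range(0, len(seq), width):
            fh.write(seq[i : i + width] + "\n")


def write_coordinate_map(path: str | Path, coord: np.ndarray) -> None:
    with open(path, "w") as fh:
        fh.write("ref_pos\tpersonal_pos\n")
        for i, p in enumerate(coord, start=1):
            fh.write(f"{i}\t{'-' if p < 0 else int(p)}\n")
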