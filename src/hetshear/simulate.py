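"""Heterogeneous paired-end read simulator and truth emitters.

Emulates the evaluation protocol for a two-population sequencing sample: a
reference haplotype and a variant haplotype carrying non-overlapping
deletions, tandem duplications and inversions.  Fragments are drawn with a
configurable mixture fraction from the two haplotypes, with 75 bp paired-end
reads, fragment sizes from a truncated normal (mean 250, sd 20, inclusive
bounds [175, 325]), error-free bases and uniform phred-40 qualities.

Two truth-alignment dialects let every downstream stage be tested without an
external aligner:

* ``oracle`` - each read is placed at its true reference position with
  correct soft-clipping at true SV junctions (what a perfect local aligner
  would produce);
* ``naive`` - reads crossing a junction by at most ``naive_margin`` bases
  are forced into an end-to-end placement with mismatches (the failure mode
  of a global aligner), and reads crossing by more are left unmapped.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .alignment_model import AlignedRead

DEL, DUP, INV, TRA = "DEL", "DUP", "INV", "TRA"
_SV_TYPES = (DEL, DUP, INV)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class SimulationError(ValueError):
    """Invalid simulation configuration or SV specification."""


# --------------------------------------------------------------------------- SVs
@dataclass(frozen=True)
class StructuralVariant:
    """A structural variant on reference coordinates.

    ``bp1``/``bp2`` follow the package-wide convention: ``bp1`` is the last
    reference base before the affected segment and ``bp2`` the last base of
    the affected segment, so the segment is ``bp1+1 .. bp2`` (1-based,
    inclusive).  A DEL removes it, a DUP repeats it in tandem, an INV
    reverse-complements it in place.
    """

    sv_type: str
    chrom1: str
    bp1: int
    chrom2: str
    bp2: int
    support_bp1: int = 0
    support_bp2: int = 0
    status: str = "candidate"

    def __post_init__(self):
        if self.sv_type in _SV_TYPES:
            if self.chrom1 != self.chrom2:
                raise SimulationError(f"{self.sv_type} breakpoints on different chromosomes")
            if not self.bp1 < self.bp2:
                raise SimulationError(
                    f"{self.sv_type} requires bp1 < bp2, got {self.bp1} >= {self.bp2}"
                )
        elif self.sv_type == TRA:
            if self.chrom1 == self.chrom2:
                raise SimulationError("TRA requires distinct chromosomes")
        else:
            raise SimulationError(f"unknown SV type {self.sv_type!r}")

    @property
    def key(self) -> tuple:
        return (self.sv_type, self.chrom1, self.bp1, self.chrom2, self.bp2)

    @property
    def length(self) -> int:
        return self.bp2 - self.bp1

    def clip_sides(self) -> tuple[str, str]:
        """Side on which variant-supporting reads are soft-clipped, per breakpoint."""
        return {
            DEL: ("right", "left"),
            DUP: ("left", "right"),
            INV: ("both", "both"),
            TRA: ("both", "both"),
        }[self.sv_type]


@dataclass(frozen=True)
class SimulationConfig:
    reference_length: int = 70_000
    sv_spec: tuple[tuple[str, int, int], ...] = ()  # (type, length, anchor)
    variant_fraction: float = 0.2
    coverage: float = 20.0
    read_length: int = 75
    fragment_mean: float = 250.0
    fragment_sd: float = 20.0
    fragment_min: int = 175
    fragment_max: int = 325
    seed: int = 0
    chrom: str = "ref"

    def __post_init__(self):
        if not (self.fragment_min <= self.fragment_mean <= self.fragment_max):
            raise SimulationError("require fragment_min <= fragment_mean <= fragment_max")
        if not (0.0 <= self.variant_fraction <= 1.0):
            raise SimulationError(f"variant_fraction {self.variant_fraction} outside [0, 1]")
        if self.read_length > self.fragment_min:
            raise SimulationError("read_length exceeds fragment_min; mates would overlap source bounds")
        if self.reference_length < self.fragment_max:
            raise SimulationError("reference shorter than fragment_max")
        if self.coverage <= 0:
            raise SimulationError("coverage must be positive")

    @property
    def n_fragments(self) -> int:
        return int(self.coverage * self.reference_length // (2 * self.read_length))


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one simulated fragment."""

    fragment_id: int
    haplotype: str  # "reference" | "variant"
    origin_start: int  # 1-based on the source haplotype
    fragment_length: int
    variant_fraction: float


@dataclass(frozen=True)
class ReadPair:
    name: str
    seq1: str  # mate 1, sequencing orientation (source forward strand)
    seq2: str  # mate 2, sequencing orientation (reverse strand of source)


# --------------------------------------------------------------------------- reference & SV sets
def random_reference(length: int, seed: int) -> str:
    """Uniform-random (hence effectively non-repetitive) DNA sequence."""
    rng = np.random.default_rng(seed)
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def _extension_never_positive(
    a: str, b: str, match: int = 1, mismatch: int = -3, max_len: int = 80
) -> bool:
    """True when aligning ``a`` against ``b`` base-by-base never accumulates
    a positive score prefix (so a local aligner gains nothing by extending a
    match across the junction into this comparison)."""
    score = 0
    for x, y in zip(a[:max_len], b[:max_len]):
        score += match if x == y else mismatch
        if score > 0:
            return False
    return True


def _junction_clean(reference: str, sv: StructuralVariant) -> bool:
    """True when no microhomology blurs either junction of the SV.

    A junction is *clean* when a local aligner scoring matches +1 and
    mismatches -3 can never profit from extending an alignment across it in
    either direction, so the soft-clip boundary of every junction-crossing
    read is uniquely the true breakpoint and exact-recall checks are
    well-posed (mirrors evaluating in a deliberately non-repetitive region).
    """
    r = reference
    b1, b2 = sv.bp1, sv.bp2  # 0-based indices of ref bases bp1+1 and bp2+1
    if sv.sv_type in (DEL, DUP):
        # crossing reads continue with ref[bp2+1:] where the reference has
        # ref[bp1+1:] (forward) and with reversed ref[..bp1] vs ref[..bp2]
        # (backward); the comparisons are the same for DEL and DUP fusions
        fwd = _extension_never_positive(r[b1:], r[b2:])
        bwd = _extension_never_positive(r[:b1][::-1], r[:b2][::-1])
        return fwd and bwd
    if sv.sv_type == INV:
        # inner: comp(ref[bp2-k]) vs ref[bp1+1+k]; outer: comp(ref[bp1-k])
        # vs ref[bp2+1+k] (each covers both read orientations by symmetry)
        inner = _extension_never_positive(revcomp(r[max(0, b2 - 80) : b2]), r[b1:])
        outer = _extension_never_positive(revcomp(r[max(0, b1 - 80) : b1]), r[b2:])
        return inner and outer
    return True


def validate_sv_spec(
    reference_length: int, sv_spec: Sequence[tuple[str, int, int]], chrom: str = "ref"
) -> list[StructuralVariant]:
    """Turn (type, length, anchor) triples into validated, sorted SVs.

    ``anchor`` is the 1-based first base of the affected segment, so
    ``bp1 = anchor - 1`` and ``bp2 = anchor + length - 1``.
    """
    svs = []
    for spec in sv_spec:
        sv_type, length, anchor = spec
        if sv_type not in _SV_TYPES:
            raise SimulationError(f"unsupported SV type in spec: {spec!r}")
        if length < 1:
            raise SimulationError(f"non-positive SV length: {spec!r}")
        if anchor < 2 or anchor + length - 1 > reference_length - 1:
            raise SimulationError(
                f"SV {spec!r} outside usable reference range [2, {reference_length - 1}]"
            )
        svs.append(StructuralVariant(sv_type, chrom, anchor - 1, chrom, anchor + length - 1))
    svs.sort(key=lambda s: s.bp1)
    for a, b in zip(svs, svs[1:]):
        if b.bp1 < a.bp2:
            raise SimulationError(
                f"overlapping SVs: {a.sv_type}@{a.bp1 + 1}-{a.bp2} and {b.sv_type}@{b.bp1 + 1}-{b.bp2}"
            )
    return svs


def make_sv_set(
    reference: str,
    sv_type: str,
    sizes: Sequence[int] = (150, 1000, 30000),
    seed: int = 0,
    edge_margin: int = 1000,
    min_gap: int = 1500,
    max_tries: int = 500,
) -> list[tuple[str, int, int]]:
    """Place non-overlapping SVs of the given sizes at random clean anchors.

    Layouts are resampled until every junction is microhomology-free (see
    :func:`_junction_clean`).  Returns ``(type, length, anchor)`` triples.
    """
    L = len(reference)
    sizes = list(sizes)
    need = sum(sizes) + 2 * edge_margin + (len(sizes) - 1) * min_gap
    if need > L:
        raise SimulationError(f"reference of {L} bp too short for SV sizes {sizes}")
    rng = np.random.default_rng(seed)
    for _ in range(max_tries):
        order = rng.permutation(len(sizes))
        slack = L - need
        cuts = np.sort(rng.integers(0, slack + 1, size=len(sizes)))
        spec = []
        pos = edge_margin + 1
        prev_cut = 0
        ok = True
        for k, idx in enumerate(order):
            pos += int(cuts[k] - prev_cut)
            prev_cut = int(cuts[k])
            length = sizes[idx]
            triple = (sv_type, length, pos)
            sv = StructuralVariant(sv_type, "ref", pos - 1, "ref", pos + length - 1)
            if not _junction_clean(reference, sv):
                ok = False
                break
            spec.append(triple)
            pos += length + min_gap
        if ok:
            return sorted(spec, key=lambda t: t[2])
    raise SimulationError("could not place microhomology-free SV set; sequence too repetitive")


# --------------------------------------------------------------------------- variant genome
@dataclass(frozen=True)
class Segment:
    """Mapping of one variant-genome interval onto the reference.

    1-based inclusive on both axes; ``strand == '-'`` means the variant
    interval is the reverse complement of the reference interval.
    """

    var_start: int
    var_end: int
    ref_start: int
    ref_end: int
    strand: str  # '+' | '-'


def build_variant_genome(
    reference: str, sv_spec: Sequence[tuple[str, int, int]], chrom: str = "ref"
) -> tuple[str, list[StructuralVariant]]:
    """Apply an SV spec to the reference; returns the variant sequence and
    the truth SVs with exact reference-coordinate breakpoints."""
    svs = validate_sv_spec(len(reference), sv_spec, chrom)
    parts: list[str] = []
    cur = 0  # 0-based consumed prefix of the reference
    for sv in svs:
        a, b = sv.bp1, sv.bp2  # segment = reference[a:b] 0-based
        parts.append(reference[cur:a])
        if sv.sv_type == DEL:
            pass
        elif sv.sv_type == DUP:
            parts.append(reference[a:b])
            parts.append(reference[a:b])
        elif sv.sv_type == INV:
            parts.append(revcomp(reference[a:b]))
        cur = b
    parts.append(reference[cur:])
    return "".join(parts), svs


def variant_segment_map(reference_length: int, svs: Sequence[StructuralVariant]) -> list[Segment]:
    """Piecewise variant->reference coordinate map implied by a sorted SV list."""
    segs: list[Segment] = []
    vpos = 1
    cur = 1  # next unconsumed reference base

    def emit(rs: int, re_: int, strand: str) -> None:
        nonlocal vpos
        ln = re_ - rs + 1
        if ln > 0:
            segs.append(Segment(vpos, vpos + ln - 1, rs, re_, strand))
            vpos += ln

    for sv in sorted(svs, key=lambda s: s.bp1):
        emit(cur, sv.bp1, "+")
        a, b = sv.bp1 + 1, sv.bp2
        if sv.sv_type == DEL:
            pass
        elif sv.sv_type == DUP:
            emit(a, b, "+")
            emit(a, b, "+")
        elif sv.sv_type == INV:
            emit(a, b, "-")
        cur = sv.bp2 + 1
    emit(cur, reference_length, "+")
    # merge adjacent reference-collinear pieces (e.g. the flank preceding a
    # tandem duplication and the duplication's first copy): a read crossing
    # such a boundary is an ordinary contiguous placement, not a junction
    merged: list[Segment] = []
    for seg in segs:
        if (
            merged
            and merged[-1].strand == "+"
            and seg.strand == "+"
            and merged[-1].var_end + 1 == seg.var_start
            and merged[-1].ref_end + 1 == seg.ref_start
        ):
            prev = merged.pop()
            merged.append(Segment(prev.var_start, seg.var_end, prev.ref_start, seg.ref_end, "+"))
        else:
            merged.append(seg)
    return merged


# --------------------------------------------------------------------------- read sampling
def _sample_fragment_lengths(rng: np.random.Generator, n: int, cfg: SimulationConfig) -> np.ndarray:
    """Rejection-sample rounded N(mean, sd) lengths inside the inclusive bounds."""
    out = np.empty(n, dtype=np.int64)
    filled = 0
    while filled < n:
        draw = np.rint(rng.normal(cfg.fragment_mean, cfg.fragment_sd, size=(n - filled) * 2 + 16))
        keep = draw[(draw >= cfg.fragment_min) & (draw <= cfg.fragment_max)].astype(np.int64)
        take = min(len(keep), n - filled)
        out[filled : filled + take] = keep[:take]
        filled += take
    return out


def sample_reads(
    config: SimulationConfig, reference: str, variant: str
) -> tuple[list[ReadPair], list[TruthRecord]]:
    """Draw error-free paired-end fragments from the two-haplotype mixture.

    The fragment count is ``floor(coverage * reference_length / (2 * read_length))``
    (coverage is defined over the reference haplotype's length); each
    fragment's haplotype is Bernoulli(``variant_fraction``) and its start is
    uniform over its source haplotype.  Deterministic under a fixed seed.
    """
    if len(reference) != config.reference_length:
        raise SimulationError("reference length does not match the configuration")
    rng = np.random.default_rng(config.seed)
    n = config.n_fragments
    r = config.read_length
    haps = rng.random(n) < config.variant_fraction
    lengths = _sample_fragment_lengths(rng, n, config)
    sources = (reference, variant)
    if len(variant) < config.fragment_max:
        raise SimulationError("variant haplotype shorter than fragment_max")
    starts = np.empty(n, dtype=np.int64)
    for hap_flag, source in ((False, reference), (True, variant)):
        idx = np.nonzero(haps == hap_flag)[0]
        span = len(source) - lengths[idx] + 1  # valid 1-based start count
        starts[idx] = 1 + np.floor(rng.random(len(idx)) * span).astype(np.int64)
    pairs: list[ReadPair] = []
    truth: list[TruthRecord] = []
    for i in range(n):
        source = sources[1] if haps[i] else sources[0]
        s = int(starts[i])
        f = int(lengths[i])
        frag = source[s - 1 : s - 1 + f]
        hap = "variant" if haps[i] else "reference"
        name = f"frag{i:06d}.{'var' if haps[i] else 'ref'}"
        pairs.append(ReadPair(name, frag[:r], revcomp(frag[f - r :])))
        truth.append(TruthRecord(i, hap, s, f, config.variant_fraction))
    return pairs, truth


# --------------------------------------------------------------------------- truth alignment
@dataclass(frozen=True)
class _Placement:
    pos: int
    cigar: tuple[tuple[str, int], ...]
    seq: str
    mapped: bool
    is_reverse: bool


def _place_mate(
    source_start: int,
    source_end: int,
    source_strand: str,
    source_seq: str,
    segments: Sequence[Segment],
    reference_length: int,
    mode: str,
    naive_margin: int,
) -> _Placement:
    """Place one mate (a source-haplotype interval) on the reference."""
    s, e = source_start, source_end
    pieces = [
        (max(s, seg.var_start), min(e, seg.var_end), seg)
        for seg in segments
        if seg.var_end >= s and seg.var_start <= e
    ]
    ps, pe, seg = max(pieces, key=lambda p: (p[1] - p[0], -p[0]))
    plen = pe - ps + 1
    if seg.strand == "+":
        rs = seg.ref_start + (ps - seg.var_start)
        re_ = rs + plen - 1
        left_clip, right_clip = ps - s, e - pe
        sam_seq = source_seq[s - 1 : e]
    else:
        re_ = seg.ref_end - (ps - seg.var_start)
        rs = re_ - plen + 1
        left_clip, right_clip = e - pe, ps - s
        sam_seq = revcomp(source_seq[s - 1 : e])
    is_reverse = (source_strand == "-") != (seg.strand == "-")
    if mode == "oracle" or (left_clip == 0 and right_clip == 0):
        cigar: list[tuple[str, int]] = []
        if left_clip:
            cigar.append(("S", left_clip))
        cigar.append(("M", plen))
        if right_clip:
            cigar.append(("S", right_clip))
        return _Placement(rs, tuple(cigar), sam_seq, True, is_reverse)
    if mode != "naive":
        raise SimulationError(f"unknown truth-alignment mode {mode!r}")
    overhang = left_clip + right_clip
    if overhang > naive_margin:
        return _Placement(0, (("S", e - s + 1),), source_seq[s - 1 : e], False, False)
    pos0 = rs - left_clip
    end0 = re_ + right_clip
    if pos0 < 1 or end0 > reference_length:
        return _Placement(0, (("S", e - s + 1),), source_seq[s - 1 : e], False, False)
    return _Placement(pos0, (("M", e - s + 1),), sam_seq, True, is_reverse)


def emit_truth_alignment(
    pairs: Sequence[ReadPair],
    truth: Sequence[TruthRecord],
    reference: str,
    svs: Sequence[StructuralVariant],
    mode: str = "oracle",
    naive_margin: int = 5,
    chrom: str = "ref",
) -> list[AlignedRead]:
    """Place every simulated read on the reference; see the module docstring
    for the two dialects.  Output records satisfy SAM invariants."""
    L = len(reference)
    identity = [Segment(1, L, 1, L, "+")]
    var_segs = variant_segment_map(L, svs)
    reads: list[AlignedRead] = []
    # reconstruct the variant haplotype lazily for sequence slicing
    variant_seq: str | None = None
    for pair, rec in zip(pairs, truth):
        if rec.haplotype == "variant":
            segs = var_segs
            if variant_seq is None:
                variant_seq = _sequence_from_segments(reference, var_segs)
            source = variant_seq
        else:
            segs = identity
            source = reference
        s, f, r = rec.origin_start, rec.fragment_length, len(pair.seq1)
        p1 = _place_mate(s, s + r - 1, "+", source, segs, L, mode, naive_margin)
        p2 = _place_mate(s + f - r, s + f - 1, "-", source, segs, L, mode, naive_margin)
        for placement, other, first in ((p1, p2, True), (p2, p1, False)):
            reads.append(
                AlignedRead(
                    name=pair.name,
                    chrom=chrom if placement.mapped else None,
                    pos=placement.pos,
                    cigar=list(placement.cigar),
                    seq=placement.seq,
                    mapped=placement.mapped,
                    is_reverse=placement.is_reverse,
                    is_read1=first,
                    mate_chrom=chrom if other.mapped else None,
                    mate_pos=other.pos,
                    mate_mapped=other.mapped,
                )
            )
    return reads


def _sequence_from_segments(reference: str, segments: Sequence[Segment]) -> str:
    parts = []
    for seg in segments:
        chunk = reference[seg.ref_start - 1 : seg.ref_end]
        parts.append(chunk if seg.strand == "+" else revcomp(chunk))
    return "".join(parts)


# --------------------------------------------------------------------------- file outputs
def write_fastq(pairs: Iterable[ReadPair], prefix: str | Path, qual_char: str = "I") -> None:
    """Paired FASTQ with /1 and /2 name suffixes and uniform phred-40 quality."""
    prefix = str(prefix)
    with open(prefix + "_1.fastq", "w") as f1, open(prefix + "_2.fastq", "w") as f2:
        for p in pairs:
            f1.write(f"@{p.name}/1\n{p.seq1}\n+\n{qual_char * len(p.seq1)}\n")
            f2.write(f"@{p.name}/2\n{p.seq2}\n+\n{qual_char * len(p.seq2)}\n")


def write_truth_tables(
    truth: Iterable[TruthRecord],
    svs: Iterable[StructuralVariant],
    prefix: str | Path,
    variant_fraction: float | None = None,
) -> None:
    prefix = str(prefix)
    with open(prefix + ".truth_fragments.tsv", "w") as fh:
        fh.write("fragment_id\thaplotype\torigin_start\tfragment_length\n")
        for t in truth:
            if variant_fraction is None:
                variant_fraction = t.variant_fraction
            fh.write(f"{t.fragment_id}\t{t.haplotype}\t{t.origin_start}\t{t.fragment_length}\n")
    vf = "-" if variant_fraction is None else f"{variant_fraction:g}"
    with open(prefix + ".truth_svs.tsv", "w") as fh:
        fh.write("type\tchrom\tbp1\tbp2\tvariant_fraction\n")
        for sv in svs:
            fh.write(f"{sv.sv_type}\t{sv.chrom1}\t{sv.bp1}\t{sv.bp2}\t{vf}\n")


def simulate_dataset(
    config: SimulationConfig, reference: str | None = None, mode: str = "oracle"
) -> dict:
    """One-stop simulation: reference, variant genome, reads, truth alignment.

    Returns a dict with keys ``reference``, ``variant``, ``svs``, ``pairs``,
    ``truth``, ``reads`` (the truth alignment in the requested mode).
    """
    if reference is None:
        reference = random_reference(config.reference_length, config.seed + 10_007)
    variant, svs = build_variant_genome(reference, config.sv_spec, config.chrom)
    pairs, truth = sample_reads(config, reference, variant)
    reads = emit_truth_alignment(pairs, truth, reference, svs, mode=mode, chrom=config.chrom)
    return {
        "reference": reference,
        "variant": variant,
        "svs": svs,
        "pairs": pairs,
        "truth": truth,
        "reads": reads,
    }
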