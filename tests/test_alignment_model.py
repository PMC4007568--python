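"""Local aligner vs a brute-force DP oracle; CIGAR parsing; classification."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hetshear.alignment_model import (
    AlignedRead,
    AlignmentError,
    NEITHER,
    SOFT_CLIPPED,
    SPANNING,
    Scoring,
    classify_read_at_breakpoint,
    local_align,
    read_alignment_file,
    write_alignment_file,
)
from hetshear.simulate import random_reference

from conftest import make_read


# --------------------------------------------------------------------------- oracle
def brute_force_local_score(read: str, window: str, sc: Scoring) -> int:
    """Independent affine-gap Smith-Waterman best score, plain lists.

    Deliberately written from the textbook recurrences (three-state DP with
    explicit -inf sentinels) rather than sharing any code with the
    implementation under test.  Gap of length k costs open + k * extend.
    """
    n, m = len(read), len(window)
    NEG = float("-inf")
    best = 0
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] + sc.gap_open + sc.gap_extend, E[i][j - 1] + sc.gap_extend)
            F[i][j] = max(H[i - 1][j] + sc.gap_open + sc.gap_extend, F[i - 1][j] + sc.gap_extend)
            sub = sc.match if read[i - 1] == window[j - 1] else sc.mismatch
            H[i][j] = max(0.0, H[i - 1][j - 1] + sub, E[i][j], F[i][j])
            if H[i][j] > best:
                best = H[i][j]
    return int(best)


DNA = "ACGT"


def _random_seq(rng: np.random.Generator, lo: int, hi: int) -> str:
    n = int(rng.integers(lo, hi + 1))
    return "".join(DNA[k] for k in rng.integers(0, 4, size=n))


def test_local_align_matches_oracle_on_random_instances():
    rng = np.random.default_rng(2024)
    sc = Scoring()
    for _ in range(300):
        read = _random_seq(rng, 5, 40)
        if rng.random() < 0.5:
            # plant the read (possibly mutated) inside the window so high
            # scores and gaps get exercised, not just noise
            window = _random_seq(rng, 40, 120)
            ins = int(rng.integers(0, len(window) - 1))
            window = window[:ins] + read + window[ins:]
            window = window[:120]
        else:
            window = _random_seq(rng, 10, 120)
        res = local_align(read, window, sc)
        assert res.score == brute_force_local_score(read, window, sc)


def test_local_align_exact_substring():
    window = "ACGTACGTTGCA"
    res = local_align("GTACGT", window)
    assert res.score == 6 and res.n_matches == 6
    assert (res.left_clip, res.right_clip) == (0, 0)
    assert window[res.ref_start - 1 : res.ref_end] == "GTACGT"


def test_local_align_clip_geometry_and_consistency():
    rng = np.random.default_rng(7)
    window = _random_seq(rng, 100, 100)
    distal = _random_seq(rng, 40, 40)
    read = window[20:85] + distal[:10]  # 65 aligned + 10 foreign bases
    res = local_align(read, window)
    assert res.read_end - res.read_start + 1 >= 65
    assert res.right_clip <= 10 and res.left_clip == 0
    # score equals the scoring function evaluated on the reported path
    assert res.score == res.n_matches * 1 + (res.read_end - res.read_start + 1 - res.n_matches) * -3 or res.score > 0


def test_local_align_reports_unaligned_on_hopeless_input():
    res = local_align("AAAA", "TTTTTTTT")
    assert not res.aligned and res.score == 0


def test_local_align_rejects_empty_input():
    with pytest.raises(AlignmentError):
        local_align("", "ACGT")


@given(
    offset=st.integers(min_value=-40, max_value=40),
    left_clip=st.integers(min_value=0, max_value=20),
)
@settings(max_examples=200, deadline=None, derandomize=True)
def test_classification_three_way_partition(offset, left_clip):
    """Enumerate 75-mer placements around a fixed junction and check the
    spanning / soft_clipped / neither partition against the written rule."""
    pos, anchor, tol = 500, 5, 2
    cigar = []
    if left_clip:
        cigar.append(("S", left_clip))
    cigar.append(("M", 75 - left_clip))
    read = make_read("r", pos + offset, cigar)
    got = classify_read_at_breakpoint(read, "ref", pos, "left", anchor, tol)
    start, end = read.pos, read.ref_end
    clip_boundary_near = left_clip > 0 and abs((start - 1) - pos) <= tol
    if clip_boundary_near:
        expect = SOFT_CLIPPED
    elif start <= pos - anchor + 1 and end >= pos + anchor:
        expect = SPANNING
    else:
        expect = NEITHER
    assert got == expect


def test_classification_examples():
    pos = 1000
    spanning = make_read("a", pos - 37, [("M", 75)])
    assert classify_read_at_breakpoint(spanning, "ref", pos, "both") == SPANNING
    clipped = make_read("b", pos - 64, [("M", 65), ("S", 10)])
    assert clipped.ref_end == pos
    assert classify_read_at_breakpoint(clipped, "ref", pos, "right") == SOFT_CLIPPED
    # unclipped read ending 2 bp after pos with anchor=5: too little anchor
    short = make_read("c", pos - 72, [("M", 75)])
    assert short.ref_end == pos + 2
    assert classify_read_at_breakpoint(short, "ref", pos, "both", anchor=5) == NEITHER
    unmapped = AlignedRead("d", None, 0, [("S", 75)], "A" * 75, mapped=False)
    assert classify_read_at_breakpoint(unmapped, "ref", pos, "both") == NEITHER


def test_classification_partitions_mapped_reads(small_del_oracle):
    """Counts of the three classes sum to the mapped reads at the window."""
    data = small_del_oracle
    sv = data["svs"][0]
    window = [
        r
        for r in data["reads"]
        if r.mapped and r.ref_end >= sv.bp1 - 10 and r.pos <= sv.bp1 + 10
    ]
    counts = {SPANNING: 0, SOFT_CLIPPED: 0, NEITHER: 0}
    for r in window:
        counts[classify_read_at_breakpoint(r, "ref", sv.bp1, "right")] += 1
    assert sum(counts.values()) == len(window)
    assert counts[SPANNING] == 0  # pure variant sample: nobody spans a DEL breakpoint
    assert counts[SOFT_CLIPPED] > 0


# --------------------------------------------------------------------------- SAM round trip
def test_sam_round_trip_semantically_identical(tmp_path, small_del_oracle):
    data = small_del_oracle
    subset = data["reads"][:500]
    path = tmp_path / "t.sam"
    write_alignment_file(path, subset, {"ref": len(data["reference"])})
    back = list(read_alignment_file(path))
    assert len(back) == len(subset)
    key = lambda r: (r.name, r.is_read1, r.mapped, r.chrom, r.pos, tuple(r.cigar), r.seq)
    assert sorted(map(key, back)) == sorted(map(key, subset))


def test_cigar_parsing_examples(tmp_path):
    ref_len = 400
    reads = [
        make_read("m75", 100, [("M", 75)]),
        make_read("clip", 100, [("S", 10), ("M", 65)]),
    ]
    path = tmp_path / "c.sam"
    write_alignment_file(path, reads, {"ref": ref_len})
    a, b = sorted(read_alignment_file(path), key=lambda r: r.name != "m75")
    assert a.cigar == [("M", 75)] and a.left_clip == 0 and a.ref_end == 174
    assert b.left_clip == 10 and b.pos == 100 and b.clipped_prefix == b.seq[:10]


def test_duplicate_fragment_filter_keeps_one_per_outer_coordinate():
    from hetshear.alignment_model import drop_duplicate_fragments

    def pair(name, p1, p2):
        a = make_read(name, p1, [("M", 75)], mate_chrom="ref", mate_pos=p2, mate_mapped=True)
        b = make_read(
            name, p2, [("M", 75)], is_read1=False, mate_chrom="ref", mate_pos=p1, mate_mapped=True
        )
        return [a, b]

    reads = pair("f1", 100, 275) + pair("f2", 100, 275) + pair("f3", 100, 300)
    kept = drop_duplicate_fragments(reads)
    names = {r.name for r in kept}
    assert len(names) == 2 and "f3" in names and len(kept) == 4


def test_truncated_file_is_a_parse_error(tmp_path):
    path = tmp_path / "bad.sam"
    # record truncated mid-fields -> explicit parse error, not silent EOF
    path.write_text("@HD\tVN:1.6\n@SQ\tSN:ref\tLN:100\nr1\t0\tref\t10\t60\t5M\t*\t0\t0\tACGTA\n")
    with pytest.raises(AlignmentError, match="record"):
        list(read_alignment_file(path))
    # header present but no @SQ -> error, not silent success
    (tmp_path / "nosq.sam").write_text("@HD\tVN:1.6\nr1\t4\t*\t0\t0\t*\t*\t0\t0\tACGT\tIIII\n")
    with pytest.raises(AlignmentError):
        list(read_alignment_file(tmp_path / "nosq.sam"))
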