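"""Simulator: variant-genome construction, read sampling, truth alignments."""

from __future__ import annotations

import math

import numpy as np
import pytest

from hetshear.simulate import (
    SimulationConfig,
    SimulationError,
    build_variant_genome,
    emit_truth_alignment,
    make_sv_set,
    random_reference,
    revcomp,
    sample_reads,
    simulate_dataset,
    write_fastq,
)

REF12 = "AAACCCGGGTTT"


@pytest.mark.parametrize(
    "spec,expected",
    [
        ([("DEL", 3, 4)], "AAAGGGTTT"),  # excise CCC
        ([("DUP", 3, 4)], "AAACCCCCCGGGTTT"),  # tandem-double CCC
        ([("INV", 3, 7)], "AAACCCCCCTTT"),  # GGG -> reverse complement CCC
    ],
)
def test_build_variant_genome_single_edits(spec, expected):
    variant, svs = build_variant_genome(REF12, spec)
    assert variant == expected
    (sv,) = svs
    assert (sv.bp1, sv.bp2) == (spec[0][2] - 1, spec[0][2] + spec[0][1] - 1)
    assert len(variant) - len(REF12) == {"DEL": -3, "DUP": 3, "INV": 0}[sv.sv_type]


def test_build_variant_genome_rejects_overlap_and_bounds():
    with pytest.raises(SimulationError, match="overlap"):
        build_variant_genome(REF12, [("DEL", 4, 3), ("DUP", 4, 5)])
    with pytest.raises(SimulationError, match="range"):
        build_variant_genome(REF12, [("DEL", 100, 3)])
    with pytest.raises(SimulationError, match="range"):
        build_variant_genome(REF12, [("DEL", 3, 1)])  # needs a left flank


def test_fragment_count_follows_coverage_definition():
    cfg = SimulationConfig(reference_length=70_000, coverage=20.0)
    assert cfg.n_fragments == math.floor(20 * 70_000 / 150) == 9333


def test_sample_reads_mixture_and_fragment_invariants():
    ref = random_reference(20_000, 5)
    variant, svs = build_variant_genome(ref, [("DEL", 300, 9000)])
    cfg = SimulationConfig(
        reference_length=20_000, sv_spec=(("DEL", 300, 9000),), variant_fraction=0.2,
        coverage=75.0, seed=42,
    )
    pairs, truth = sample_reads(cfg, ref, variant)
    n = len(truth)
    assert n == cfg.n_fragments == 10_000
    n_var = sum(t.haplotype == "variant" for t in truth)
    sigma = math.sqrt(n * 0.2 * 0.8)
    assert abs(n_var - 0.2 * n) <= 3 * sigma
    lengths = np.array([t.fragment_length for t in truth])
    assert lengths.min() >= 175 and lengths.max() <= 325
    assert abs(lengths.mean() - 250) <= 3 * 20 / math.sqrt(n)
    # error-free copies: read 1 is the fragment prefix of the source haplotype
    t0, p0 = truth[0], pairs[0]
    source = variant if t0.haplotype == "variant" else ref
    frag = source[t0.origin_start - 1 : t0.origin_start - 1 + t0.fragment_length]
    assert p0.seq1 == frag[:75]
    assert p0.seq2 == revcomp(frag[-75:])


def test_variant_fraction_zero_yields_only_reference_haplotype():
    ref = random_reference(2000, 1)
    variant, _ = build_variant_genome(ref, [("DEL", 100, 500)])
    cfg = SimulationConfig(
        reference_length=2000, sv_spec=(("DEL", 100, 500),), variant_fraction=0.0,
        coverage=10.0, seed=7,
    )
    _, truth = sample_reads(cfg, ref, variant)
    assert truth and all(t.haplotype == "reference" for t in truth)


def test_determinism_byte_identical_outputs(tmp_path):
    cfg = SimulationConfig(
        reference_length=3000, sv_spec=(("DEL", 150, 1200),), variant_fraction=0.5,
        coverage=20.0, seed=99,
    )
    outs = []
    for run in ("a", "b"):
        data = simulate_dataset(cfg)
        prefix = tmp_path / run
        write_fastq(data["pairs"], prefix)
        outs.append(
            (prefix.with_name(run + "_1.fastq").read_bytes(), prefix.with_name(run + "_2.fastq").read_bytes())
        )
    assert outs[0] == outs[1]


def test_coverage_conservation_on_reference_haplotype():
    """Mean truth-placement depth tracks configured coverage within 5%."""
    L, cov = 20_000, 30.0
    ref = random_reference(L, 3)
    cfg = SimulationConfig(reference_length=L, variant_fraction=0.0, coverage=cov, seed=3)
    pairs, truth = sample_reads(cfg, ref, ref)
    reads = emit_truth_alignment(pairs, truth, ref, [], mode="oracle")
    depth = np.zeros(L)
    for r in reads:
        depth[r.pos - 1 : r.ref_end] += 1
    assert abs(depth.mean() - cov) / cov < 0.05


def test_oracle_vs_naive_placement_at_deletion_junction():
    """A variant read overhanging a DEL junction by 10 bases: oracle clips it
    (65M10S), naive forces a 75M end-to-end placement with mismatches."""
    L = 4000
    ref = random_reference(L, 8)
    spec = make_sv_set(ref, "DEL", sizes=(400,), seed=8, edge_margin=800, min_gap=1)
    variant, svs = build_variant_genome(ref, spec)
    (sv,) = svs
    from hetshear.simulate import ReadPair, TruthRecord

    # fragment starting 65 bases before the variant-side junction
    var_junction = sv.bp1  # variant coordinate == reference coordinate left of the DEL
    start = var_junction - 65 + 1
    frag = variant[start - 1 : start - 1 + 250]
    pair = ReadPair("x", frag[:75], revcomp(frag[-75:]))
    rec = TruthRecord(0, "variant", start, 250, 1.0)
    oracle = emit_truth_alignment([pair], [rec], ref, svs, mode="oracle")
    naive = emit_truth_alignment([pair], [rec], ref, svs, mode="naive", naive_margin=15)
    o1 = next(r for r in oracle if r.is_read1)
    n1 = next(r for r in naive if r.is_read1)
    assert o1.cigar == [("M", 65), ("S", 10)]
    assert o1.ref_end == sv.bp1  # clip boundary at the true junction
    assert n1.cigar == [("M", 75)] and n1.pos == o1.pos
    # mismatches present in the forced global placement
    tail = ref[n1.pos - 1 + 65 : n1.pos - 1 + 75]
    assert tail != n1.seq[65:]
    # beyond the margin the read is left unmapped
    strict = emit_truth_alignment([pair], [rec], ref, svs, mode="naive", naive_margin=5)
    assert not next(r for r in strict if r.is_read1).mapped


def test_reference_reads_identical_in_both_modes(small_del_oracle):
    data = small_del_oracle
    naive = emit_truth_alignment(
        data["pairs"], data["truth"], data["reference"], data["svs"], mode="naive"
    )
    for o, n in zip(data["reads"], naive):
        if o.mapped and len(o.cigar) == 1:  # fully inside one segment
            assert (n.pos, n.cigar) == (o.pos, o.cigar)


def test_make_sv_set_is_valid_and_deterministic():
    ref = random_reference(70_000, 0)
    a = make_sv_set(ref, "DUP", seed=4)
    b = make_sv_set(ref, "DUP", seed=4)
    assert a == b
    assert sorted(ln for _, ln, _ in a) == [150, 1000, 30000]
    build_variant_genome(ref, a)  # validates non-overlap and bounds


def test_config_validation_errors():
    with pytest.raises(SimulationError):
        SimulationConfig(variant_fraction=1.5)
    with pytest.raises(SimulationError):
        SimulationConfig(fragment_min=300, fragment_mean=250)
    with pytest.raises(SimulationError):
        SimulationConfig(reference_length=100)
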