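"""Shared fixtures: tiny deterministic scenarios built at test time."""

from __future__ import annotations

import pytest

from hetshear.alignment_model import AlignedRead
from hetshear.cli_io import simulate_scenario


@pytest.fixture(scope="session")
def small_del_oracle():
    """8 kb reference, two deletions (150/1000 bp), pure variant sample, oracle clips."""
    return simulate_scenario("DEL", 50, 1.0, seed=11, sizes=(150, 1000), reference_length=8000)


@pytest.fixture(scope="session")
def small_mixed_naive():
    """8 kb reference, two deletions, 60% variant mixture, naive-aligner dialect."""
    return simulate_scenario(
        "DEL", 60, 0.6, seed=12, sizes=(150, 1000), reference_length=8000, mode="naive"
    )


def make_read(
    name: str,
    pos: int,
    cigar: list[tuple[str, int]],
    seq: str | None = None,
    chrom: str = "ref",
    **kw,
) -> AlignedRead:
    """Hand-built mapped read; sequence defaults to 'A' * consumed length."""
    if seq is None:
        seq = "A" * sum(ln for op, ln in cigar if op in ("M", "I", "S"))
    return AlignedRead(name=name, chrom=chrom, pos=pos, cigar=cigar, seq=seq, **kw)
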