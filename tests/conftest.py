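"""Shared fixtures: toy genomes and small hand-built profiles."""

from __future__ import annotations

import pytest

from ibcscars import GenomeBuild, Chromosome, Segment, make_toy_build, profile_from_segments


@pytest.fixture(scope="session")
def toy_build() -> GenomeBuild:
    """3 x 100 Mb chromosomes, 2 Mb centered centromeres."""
    return make_toy_build()


@pytest.fixture(scope="session")
def big_build() -> GenomeBuild:
    """8 x 100 Mb chromosomes: enough ends/arms for multi-event planting."""
    return make_toy_build(n_chrom=8)


@pytest.fixture
def quiet_profile(toy_build):
    """Fully covered diploid heterozygous genome."""
    segs = [
        Segment(c.name, 0, c.length, 2.0, 1.0) for c in toy_build.chromosomes
    ]
    return profile_from_segments("QUIET", segs)


def mb(x: float) -> int:
    return int(x * 1_000_000)
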