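import numpy as np
import pytest

from dhslink import synthetic
from dhslink.types import GeneModel, GenomeAnnotation, Hotspot, HotspotSet


@pytest.fixture(scope="session")
def fixture0():
    """One full default-scale fixture shared across the session."""
    return synthetic.generate_fixture(seed=11)


@pytest.fixture(scope="session")
def small_config():
    """A miniature configuration for fast write/round-trip tests."""
    cfg = synthetic.FixtureConfig(
        n_chroms=1,
        chrom_length=300_000,
        n_genes=8,
        total_reads=200_000,
        truth=synthetic.TruthSpec(
            n_shared=20,
            n_unique={"B34": 3, "B39d1": 3, "OIMd1": 4},
            n_planted_enhancers=3,
        ),
    )
    return cfg


def make_set(intervals, condition="A", sample_id=None, total_reads=10_000_000,
             raws=None):
    """HotspotSet from bare (chrom, start, end) triples."""
    sites = []
    for i, (chrom, start, end) in enumerate(intervals):
        raw = raws[i] if raws else 10
        sites.append(
            Hotspot(
                chrom=chrom, start=start, end=end, raw_maxd=raw,
                norm_maxd=raw * 1e7 / total_reads,
                site_id=f"{condition}_{i}",
            )
        )
    return HotspotSet(
        sample_id=sample_id or f"{condition}_rep",
        condition=condition,
        total_reads=total_reads,
        sites=sites,
    )


def random_intervals(rng, n, chroms=("chr1", "chr2"), span=100_000, width=400):
    out = []
    for _ in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, span))
        out.append((chrom, start, start + int(rng.integers(50, width))))
    return out


@pytest.fixture
def simple_genes():
    """Two genes on chr1 (one per strand) plus one on chr2."""
    return [
        GeneModel("GA", "chr1", "+", 100_000, 110_000,
                  ((100_000, 101_000), (105_000, 110_000))),
        GeneModel("GB", "chr1", "-", 200_000, 212_000,
                  ((200_000, 204_000), (208_000, 212_000))),
        GeneModel("GC", "chr2", "+", 50_000, 60_000,
                  ((50_000, 52_000), (55_000, 60_000))),
    ]


@pytest.fixture
def simple_genome(simple_genes):
    return GenomeAnnotation(
        chroms={"chr1": 500_000, "chr2": 300_000}, genes=simple_genes
    )
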