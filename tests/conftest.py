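"""Shared fixtures: small in-memory datasets and scaled-down simulations."""

import pytest

from chemoevo.catalog import CloneGenotype, MutationId, Segment, SnpRecord
from chemoevo.simulate import SimConfig, SimSegment


@pytest.fixture
def toy_records() -> list[SnpRecord]:
    """Three vessels sharing one mutation, plus vessel-private alleles."""
    shared = MutationId(2_238_647, "C", "A")
    return [
        SnpRecord("1", shared, "upstream mglB", "noncoding",
                  {50: 0.02, 100: 0.40, 150: 0.95, 200: 0.99}),
        SnpRecord("2", shared, "upstream mglB", "noncoding",
                  {50: 0.05, 100: 0.10, 150: 0.30, 200: 0.60}),
        SnpRecord("3", shared, "upstream mglB", "noncoding",
                  {50: 0.01, 100: 0.02, 150: 0.08, 200: 0.02}),
        SnpRecord("1", MutationId(100, "G", "T"), "galS", "missense",
                  {50: 0.02, 100: 0.10, 150: 0.04, 200: 0.00}),
        SnpRecord("2", MutationId(100, "G", "T"), "galS", "missense",
                  {50: 0.00, 100: 0.03, 150: 0.06, 200: 0.01}),
        SnpRecord("1", MutationId(200, "C", "A"), "hfq", "nonsense",
                  {50: 0.00, 100: 0.00, 150: 0.20, 200: 0.55}),
        SnpRecord("3", MutationId(300, "A", "G"), "pgi", "synonymous",
                  {50: 0.00, 100: 0.005, 150: 0.00, 200: 0.00}),
    ]


@pytest.fixture
def toy_segments() -> list[Segment]:
    return [
        Segment("upstream mglB", 120, "intergenic"),
        Segment("galS", 1041, "gene"),
        Segment("hfq", 309, "gene"),
        Segment("pgi", 1650, "gene"),
    ]


@pytest.fixture
def toy_clones() -> list[CloneGenotype]:
    a = MutationId(10, "C", "A")
    b = MutationId(20, "G", "T")
    c = MutationId(30, "C", "A")
    return [
        CloneGenotype("c1", "1", frozenset({a})),
        CloneGenotype("c2", "1", frozenset({a, b})),
        CloneGenotype("c3", "1", frozenset({a, b, c})),
        CloneGenotype("c4", "1", frozenset()),
    ]


def small_sim_config(seed: int, **overrides) -> SimConfig:
    """A fast test-scale configuration: 20 kb genome, 2 kGen-equivalent run.

    Kept deliberately small so property tests over many replicates stay
    quick; the full-scale default config is exercised where a single run
    suffices.
    """
    segments = []
    for i in range(8):
        hot = i in (2, 5)
        segments.append(SimSegment(f"gene{i + 1:03d}", 1800, "gene", hotspot=hot))
        segments.append(SimSegment(f"ig{i + 1:03d}", 400, "intergenic"))
    total = sum(s.length_bp for s in segments)
    defaults = dict(
        pop_size=2_000,
        n_generations=150,
        sample_interval=25,
        genome_length=total,
        segments=segments,
        mu=0.02,
        seed=seed,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


@pytest.fixture
def sim_config() -> SimConfig:
    return small_sim_config(seed=7)
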