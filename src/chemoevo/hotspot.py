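"""Poisson excess-mutation test over genomic segments.

Under a uniform per-bp mutation process, the number of mutations landing in a
segment of length *l* is Poisson with mean lambda = rho * l, where
rho = M / L is the genome-wide mutation density (M mutations over a genome of
L bp).  A segment with n observed mutations is scored by the upper tail

    p = sum_{i=n}^{cap} lambda^i e^(-lambda) / i!

with the summation index capped (default 50); beyond the cap the terms no
longer affect the value at the magnitudes of interest.  Segments are ranked by
ascending p and corrected for multiple testing with the rank-adjusted
estimator fdr_i = N * p_i / i (N tested segments), with step-up monotonicity
enforced and values capped at 1 — the Benjamini-Hochberg adjusted p-value.  A
literal Bonferroni variant (N * p) is available via ``method="bonferroni"``.

Evaluation is in log-space throughout: tail probabilities down to ~1e-53 arise
for the most heavily hit genes and naive factorial arithmetic overflows long
before n = 50.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp
from scipy.stats import poisson

from .catalog import Segment, SnpRecord

__all__ = [
    "MutationDensity",
    "SegmentTestResult",
    "mutation_density",
    "expected_mutations",
    "poisson_upper_tail",
    "adjust_fdr",
    "test_all_segments",
    "results_to_frame",
]


@dataclass(frozen=True)
class MutationDensity:
    """Genome-wide mutation density rho = M / L (mutations per bp)."""

    M: int
    L: int

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ValueError(f"genome length L must be >= 1, got {self.L}")
        if self.M < 0:
            raise ValueError(f"mutation count M must be >= 0, got {self.M}")

    @property
    def rho(self) -> float:
        return self.M / self.L


@dataclass
class SegmentTestResult:
    """Per-segment observed/expected counts and corrected significance."""

    segment: Segment
    n_obs: int
    n_unique: int
    lam: float
    p_uncorrected: float
    rank: int = 0
    fdr: float = float("nan")
    n_segments: int = 0


def mutation_density(M: int, L: int) -> MutationDensity:
    """Overall density of mutations: M observed over a genome of L bp."""
    return MutationDensity(M, L)


def expected_mutations(density: MutationDensity, segment: Segment) -> float:
    """Expected mutation count lambda = rho * l for a segment of length l."""
    return density.rho * segment.length_bp


def poisson_upper_tail(n: int, lam: float, cap: int | None = 50) -> float:
    """P(n or more mutations) under Poisson(lambda), summed up to ``cap``.

    ``cap=None`` gives the exact survival function P(X >= n).  With the
    default cap of 50 the truncation is negligible for the regimes of
    interest (lambda of order 1, n up to a few tens).  If ``cap < n`` the
    summation range is empty and 0 is returned.
    """
    if n < 0 or lam < 0:
        raise ValueError(f"n and lam must be non-negative, got n={n}, lam={lam}")
    if cap is None:
        return float(poisson.sf(n - 1, lam))
    if cap < n:
        return 0.0
    if lam == 0.0:
        return 1.0 if n == 0 else 0.0
    i = np.arange(n, cap + 1)
    log_terms = i * math.log(lam) - lam - gammaln(i + 1)
    return float(min(1.0, math.exp(logsumexp(log_terms))))


def adjust_fdr(
    results: Sequence[SegmentTestResult],
    n_segments: int,
    method: Literal["rank", "bonferroni"] = "rank",
) -> list[SegmentTestResult]:
    """Sort by ascending p, assign 1-based ranks, and populate ``fdr``.

    ``rank``: fdr_i = N * p_i / rank_i with step-up monotonicity (each value
    is at most the smallest value at any worse rank) and capping at 1 — the
    Benjamini-Hochberg adjusted p-value.  ``bonferroni``: fdr = N * p, capped.
    ``n_segments`` is N, the number of tested segments; it may exceed the
    number of scored results (segments with no conceivable hit need not be
    materialised) but not fall short of it.
    """
    if n_segments < 1:
        raise ValueError("n_segments must be >= 1")
    if n_segments < len(results):
        raise ValueError(
            f"n_segments ({n_segments}) smaller than number of results ({len(results)})"
        )
    ordered = sorted(results, key=lambda r: (r.p_uncorrected, r.segment.name))
    raw = []
    for rank, res in enumerate(ordered, start=1):
        res.rank = rank
        res.n_segments = n_segments
        if method == "bonferroni":
            raw.append(n_segments * res.p_uncorrected)
        else:
            raw.append(n_segments * res.p_uncorrected / rank)
    if method == "rank":
        # step-up: enforce monotone non-decreasing fdr along increasing rank
        running = 1.0
        for i in range(len(raw) - 1, -1, -1):
            running = min(running, raw[i])
            raw[i] = running
    for res, f in zip(ordered, raw):
        res.fdr = min(1.0, f)
    return ordered


def test_all_segments(
    records: Iterable[SnpRecord],
    segments: Sequence[Segment],
    genome_length: int,
    dedup: bool = False,
    cap: int | None = 50,
    fdr_method: Literal["rank", "bonferroni"] = "rank",
) -> list[SegmentTestResult]:
    """Score every annotated segment for an excess of mutations.

    Counts are aggregated across vessels and timepoints.  By default each
    record (one mutation event in one vessel) counts once, so an identical
    allele recurring in two vessels contributes two observations; ``dedup``
    switches the tested count to distinct alleles.  M for the density is the
    total count under the same mode.  Records whose segment label is missing
    from the annotation are a hard error listing the offenders.
    """
    records = list(records)
    by_name = {s.name: s for s in segments}
    unknown = sorted({r.segment for r in records} - by_name.keys())
    if unknown:
        raise ValueError(f"records reference unannotated segment(s): {unknown}")

    events: dict[str, int] = {s.name: 0 for s in segments}
    alleles: dict[str, set] = {s.name: set() for s in segments}
    for r in records:
        events[r.segment] += 1
        alleles[r.segment].add(r.mutation)

    if dedup:
        M = len({r.mutation for r in records})
        count = {name: len(a) for name, a in alleles.items()}
    else:
        M = len(records)
        count = events
    density = mutation_density(M, genome_length)

    results = []
    for seg in segments:
        lam = expected_mutations(density, seg)
        n = count[seg.name]
        results.append(
            SegmentTestResult(
                segment=seg,
                n_obs=events[seg.name],
                n_unique=len(alleles[seg.name]),
                lam=lam,
                p_uncorrected=poisson_upper_tail(n, lam, cap),
            )
        )
    return adjust_fdr(results, n_segments=len(segments), method=fdr_method)


def results_to_frame(results: Sequence[SegmentTestResult]):
    """Table-style DataFrame (segment, counts, lambda, p, rank, fdr)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "rank": [r.rank for r in results],
            "segment": [r.segment.name for r in results],
            "length_bp": [r.segment.length_bp for r in results],
            "n_obs": [r.n_obs for r in results],
            "n_unique": [r.n_unique for r in results],
            "lambda": [r.lam for r in results],
            "p_uncorrected": [r.p_uncorrected for r in results],
            "fdr": [r.fdr for r in results],
        }
    )
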