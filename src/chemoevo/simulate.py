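"""Wright-Fisher chemostat simulator for a mutator/suppressor *E. coli* population.

The generator emulates the study conditions of a glucose-limited chemostat
evolution experiment seeded with a MutY-deficient, nonsense-suppressed
mutator: constant population size under resource limitation (non-overlapping
Wright-Fisher generations stand in for continuous dilution), a de novo SNP
input dominated by GC→TA transversions (default bias 0.975), coding-class
proportions 69.2 % missense / 23.4 % synonymous / 7.4 % nonsense, beneficial
mutations confined to a small set of hotspot segments (driving clonal
interference among competing lineages), whole-population sequencing every 50
generations with a 1 % detection floor, and a 96-clone sample drawn at one
timepoint.  The population size is scaled down (default 1e5 vs the
experiment's >1e10 cells) while the detection threshold is kept at 1 % so
censoring behaves comparably; consequences of the scaling are discussed in
the methods note.

Fitness is additive across mutations (1 + sum of selection coefficients) and
selection coefficients are drawn from a configurable DFE only for
non-synonymous hits in hotspot segments; everything else is neutral.  All
randomness flows from one root seed; vessels get deterministic sub-streams.
The full genealogy (parent links, per-edge origin events, per-generation
genotype counts) is retained as ground truth so downstream inference can be
scored against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np

from .catalog import CloneGenotype, MutationId, Segment, SnpRecord

__all__ = [
    "SimSegment",
    "SimConfig",
    "OriginEvent",
    "SimTruth",
    "default_segments",
    "default_config",
    "simulate",
    "export_population_table",
    "sample_clones",
    "null_scatter",
    "scatter_records",
    "simulate_sweep",
    "fit_selection_coefficient",
    "export_vcf_series",
]

_COMPLEMENTARY_GC_TA = {("C", "A"), ("G", "T")}
_BASES = "ACGT"


@dataclass(frozen=True)
class SimSegment(Segment):
    """Segment with simulation attributes: hotspot flag and a per-bp mutation
    rate multiplier (1 = genome-average)."""

    hotspot: bool = False
    rate_multiplier: float = 1.0


@dataclass
class SimConfig:
    """Parameters of one simulated evolution experiment (all vessels)."""

    pop_size: int = 100_000
    n_generations: int = 500
    sample_interval: int = 50
    n_vessels: int = 3
    genome_length: int = 200_000
    segments: list[SimSegment] = field(default_factory=lambda: default_segments())
    mu: float = 0.01  # per genome per generation (scaled-down mutator rate)
    gc_ta_bias: float = 0.975
    class_probs: tuple[float, float, float] = (0.692, 0.234, 0.074)
    dfe: tuple[str, float] = ("exponential", 0.05)  # ("exponential", mean) | ("point", s)
    detection_threshold: float = 0.01
    fixation_threshold: float = 0.98
    clone_sample_size: int = 96
    seed: int = 0
    allow_recurrence: bool = True
    max_mutations_per_generation: int = 50_000

    def __post_init__(self) -> None:
        if self.pop_size < 10:
            raise ValueError("pop_size must be >= 10")
        if not 0 <= self.gc_ta_bias <= 1:
            raise ValueError("gc_ta_bias must lie in [0,1]")
        if abs(sum(self.class_probs) - 1.0) > 1e-9:
            raise ValueError("class_probs must sum to 1")
        total = sum(s.length_bp for s in self.segments)
        if total != self.genome_length:
            raise ValueError(
                f"segments must tile the genome: sum {total} != {self.genome_length}"
            )
        if self.pop_size * self.mu > self.max_mutations_per_generation:
            raise ValueError(
                "pop_size * mu exceeds the per-generation mutation guard "
                f"({self.pop_size * self.mu:.0f} > {self.max_mutations_per_generation}); "
                "scale pop_size or mu down"
            )

    @property
    def sampled_generations(self) -> list[int]:
        return list(range(self.sample_interval, self.n_generations + 1, self.sample_interval))


def default_segments(
    genome_length: int = 200_000,
    n_genes: int = 60,
    n_hotspots: int = 6,
) -> list[SimSegment]:
    """A deterministic gene/intergenic tiling of the scaled-down genome.

    Gene lengths cycle through a realistic spread around the ~1 kb bacterial
    mean (here 0.9-2.4 kb); a short intergenic spacer follows each gene and a
    final intergenic block pads to ``genome_length``.  Every ``n_genes /
    n_hotspots``-th gene is flagged as a beneficial-mutation hotspot.
    """
    pattern = [900, 1200, 1500, 1800, 2100, 2400]
    spacer = 400
    segments: list[SimSegment] = []
    used = 0
    hotspot_every = max(1, n_genes // max(1, n_hotspots))
    n_marked = 0
    for i in range(n_genes):
        glen = pattern[i % len(pattern)]
        hot = n_marked < n_hotspots and i % hotspot_every == hotspot_every // 2
        if hot:
            n_marked += 1
        segments.append(SimSegment(f"gene{i + 1:03d}", glen, "gene", hotspot=hot))
        segments.append(SimSegment(f"upstream gene{i + 2:03d}", spacer, "intergenic"))
        used += glen + spacer
    if used > genome_length:
        raise ValueError("gene tiling exceeds genome_length")
    if used < genome_length:
        segments.append(SimSegment("intergenic_backbone", genome_length - used, "intergenic"))
    return segments


def default_config(**overrides) -> SimConfig:
    return SimConfig(**overrides)


@dataclass(frozen=True)
class OriginEvent:
    """One de novo mutation event: where, what, when, and its fitness effect."""

    origin_id: int
    mutation: MutationId
    segment: str
    functional_class: str
    s: float
    generation: int
    genotype_id: int  # the new genotype created by this event


@dataclass
class SimTruth:
    """Ground truth of one vessel: genealogy, origins, per-generation counts."""

    config: SimConfig
    vessel: str
    parent: dict[int, int]  # genotype -> parent genotype (0 = ancestor)
    edge_origins: dict[int, list[int]]  # genotype -> origin ids gained on its edge
    origins: dict[int, OriginEvent]
    counts_by_generation: list[dict[int, int]]  # index = generation (0-based incl. gen 0)
    _genotype_cache: dict[int, frozenset[int]] = field(default_factory=dict, repr=False)

    def genotype_origins(self, genotype_id: int) -> frozenset[int]:
        """All origin ids carried by a genotype (union along its root path)."""
        if genotype_id in self._genotype_cache:
            return self._genotype_cache[genotype_id]
        path = []
        g = genotype_id
        while g not in self._genotype_cache and g != 0:
            path.append(g)
            g = self.parent[g]
        acc = self._genotype_cache.get(g, frozenset())
        for gid in reversed(path):
            acc = acc | frozenset(self.edge_origins[gid])
            self._genotype_cache[gid] = acc
        return self._genotype_cache.get(genotype_id, acc)

    def genotype_mutations(self, genotype_id: int) -> frozenset[MutationId]:
        return frozenset(
            self.origins[o].mutation for o in self.genotype_origins(genotype_id)
        )

    def frequency_matrix(self, generations: Sequence[int] | None = None):
        """(genotype ids, generations, frequency array) for the asked columns."""
        if generations is None:
            generations = range(len(self.counts_by_generation))
        gids = sorted(self.parent)
        idx = {g: i for i, g in enumerate(gids)}
        mat = np.zeros((len(gids), len(list(generations))))
        gens = list(generations)
        for j, gen in enumerate(gens):
            for g, c in self.counts_by_generation[gen].items():
                mat[idx[g], j] = c / self.config.pop_size
        return gids, gens, mat

    def mutation_frequency(self, mutation: MutationId, generation: int) -> float:
        """True frequency of a (position, ref, alt) triple, merging all of its
        independent origins, at one generation."""
        total = 0
        for g, c in self.counts_by_generation[generation].items():
            if mutation in self.genotype_mutations(g):
                total += c
        return total / self.config.pop_size


def _dfe_draw(dfe: tuple[str, float], rng: np.random.Generator) -> float:
    kind, value = dfe
    if kind == "exponential":
        return float(rng.exponential(value))
    if kind == "point":
        return float(value)
    raise ValueError(f"unknown dfe kind {kind!r}")


def _segment_starts(segments: Sequence[SimSegment]) -> np.ndarray:
    return np.cumsum([0] + [s.length_bp for s in segments])[:-1]


def _draw_mutation_identity(
    position: int,
    segment: SimSegment,
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[MutationId, str]:
    """Assign ref/alt alleles and a functional class to a new SNP."""
    if rng.random() < config.gc_ta_bias:
        ref, alt = ("C", "A") if rng.random() < 0.5 else ("G", "T")
    else:
        ref = _BASES[rng.integers(4)]
        alt = _BASES[rng.integers(4)]
        while alt == ref or (ref, alt) in _COMPLEMENTARY_GC_TA:
            alt = _BASES[rng.integers(4)]
    if segment.kind == "gene":
        fclass = ("missense", "synonymous", "nonsense")[
            rng.choice(3, p=np.asarray(config.class_probs))
        ]
    else:
        fclass = "noncoding"
    return MutationId(position, ref, alt), fclass


def simulate(config: SimConfig, vessel: str = "1") -> SimTruth:
    """Run one vessel's Wright-Fisher dynamics and return full ground truth.

    Per generation: genotype counts are multinomially resampled with weights
    proportional to count x (1 + s_genotype), where s_genotype sums its
    mutations' coefficients; then Poisson-many new mutations land uniformly
    per bp (per-segment rate multipliers applied), each founding a new
    genotype.  Identical (position, ref, alt) triples may recur and are
    recorded as separate origin events unless ``allow_recurrence`` is off, in
    which case positions are drawn without replacement.
    """
    rng = np.random.default_rng((config.seed, int(vessel) if vessel.isdigit() else hash(vessel) % 2**16))
    N = config.pop_size
    segments = config.segments
    starts = _segment_starts(segments)
    seg_weight = np.array([s.length_bp * s.rate_multiplier for s in segments], float)
    mu_eff = config.mu * seg_weight.sum() / config.genome_length
    seg_p = seg_weight / seg_weight.sum()

    parent: dict[int, int] = {0: 0}
    edge_origins: dict[int, list[int]] = {0: []}
    origins: dict[int, OriginEvent] = {}
    fitness: dict[int, float] = {0: 1.0}
    counts: dict[int, int] = {0: N}
    counts_by_generation = [dict(counts)]
    used_positions: set[int] = set()
    next_gid, next_oid = 1, 1

    for gen in range(1, config.n_generations + 1):
        gids = list(counts)
        n = np.array([counts[g] for g in gids], float)
        w = n * np.array([fitness[g] for g in gids])
        offspring = rng.multinomial(N, w / w.sum())
        counts = {g: int(c) for g, c in zip(gids, offspring) if c}

        n_new = rng.poisson(N * mu_eff)
        if n_new:
            gids = list(counts)
            weights = np.array([counts[g] for g in gids], float)
            hosts = rng.choice(len(gids), size=n_new, p=weights / weights.sum())
            seg_idx = rng.choice(len(segments), size=n_new, p=seg_p)
            for host_i, si in zip(hosts, seg_idx):
                host = gids[host_i]
                if counts.get(host, 0) < 1:
                    continue
                seg = segments[si]
                position = int(starts[si] + rng.integers(seg.length_bp) + 1)
                if not config.allow_recurrence:
                    tries = 0
                    while position in used_positions and tries < 100:
                        position = int(starts[si] + rng.integers(seg.length_bp) + 1)
                        tries += 1
                    if position in used_positions:
                        continue
                    used_positions.add(position)
                mut, fclass = _draw_mutation_identity(position, seg, config, rng)
                s = (
                    _dfe_draw(config.dfe, rng)
                    if seg.hotspot and fclass != "synonymous"
                    else 0.0
                )
                gid, oid = next_gid, next_oid
                next_gid, next_oid = next_gid + 1, next_oid + 1
                parent[gid] = host
                edge_origins[gid] = [oid]
                origins[oid] = OriginEvent(oid, mut, seg.name, fclass, s, gen, gid)
                fitness[gid] = fitness[host] + s
                counts[host] -= 1
                if counts[host] == 0:
                    del counts[host]
                counts[gid] = 1
        counts_by_generation.append(dict(counts))

    return SimTruth(config, vessel, parent, edge_origins, origins, counts_by_generation)


def export_population_table(truth: SimTruth) -> list[SnpRecord]:
    """What a population-sequencing caller would report: per-triple frequency
    trajectories at the sampled generations, censored at the detection floor.

    Frequencies of all origins of the same (position, ref, alt) triple are
    merged (a caller cannot tell recurrent origins apart); triples never
    reaching ``detection_threshold`` at any sampled generation are dropped.
    """
    config = truth.config
    gens = config.sampled_generations
    freq: dict[MutationId, dict[int, float]] = {}
    meta: dict[MutationId, tuple[str, str]] = {}
    for gen in gens:
        totals: dict[MutationId, int] = {}
        for g, c in truth.counts_by_generation[gen].items():
            # a genotype may carry two independent origins of one triple;
            # the triple's frequency counts such a genotype once
            for mut in truth.genotype_mutations(g):
                totals[mut] = totals.get(mut, 0) + c
        for mut, c in totals.items():
            freq.setdefault(mut, {})[gen] = c / config.pop_size
    for oid in sorted(truth.origins):
        ev = truth.origins[oid]
        meta.setdefault(ev.mutation, (ev.segment, ev.functional_class))
    records = []
    for mut in sorted(freq):
        traj = {g: freq[mut].get(g, 0.0) for g in gens}
        if max(traj.values()) < config.detection_threshold:
            continue
        segment, fclass = meta[mut]
        records.append(SnpRecord(truth.vessel, mut, segment, fclass, traj))
    return records


def sample_clones(
    truth: SimTruth,
    generation: int,
    n: int | None = None,
    seed: int | None = None,
) -> list[CloneGenotype]:
    """Draw ``n`` clones multinomially by true genotype frequencies.

    Clone genotypes carry the full mutation set (clone sequencing has no 1 %
    detection floor).  Deterministic given the seed (defaults to the
    config seed).
    """
    config = truth.config
    if not 0 <= generation < len(truth.counts_by_generation):
        raise ValueError(f"generation {generation} outside simulated range")
    n = n if n is not None else config.clone_sample_size
    rng = np.random.default_rng(
        (config.seed if seed is None else seed, 101, generation)
    )
    counts = truth.counts_by_generation[generation]
    gids = sorted(counts)
    p = np.array([counts[g] for g in gids], float)
    draws = rng.multinomial(n, p / p.sum())
    clones = []
    i = 0
    for gid, k in zip(gids, draws):
        for _ in range(int(k)):
            i += 1
            clones.append(
                CloneGenotype(
                    f"v{truth.vessel}_g{generation}_c{i:03d}",
                    truth.vessel,
                    truth.genotype_mutations(gid),
                )
            )
    return clones


def scatter_records(
    config: SimConfig,
    n_mutations: int | None = None,
    vessel: str = "1",
    seed: int | None = None,
) -> list[SnpRecord]:
    """Neutral uniform scatter of SNPs over the segment tiling (no dynamics).

    Placement is uniform per bp, modulated by each segment's
    ``rate_multiplier`` — set multipliers above 1 to plant enriched segments.
    The expected total count is ``pop_size * mu * n_generations`` unless
    given explicitly.  Each SNP gets a minimal supra-threshold trajectory;
    the output exists to calibrate the hotspot statistic, where only the
    per-segment counts matter.
    """
    rng = np.random.default_rng((config.seed if seed is None else seed, 777))
    if n_mutations is None:
        n_mutations = int(rng.poisson(config.pop_size * config.mu * config.n_generations))
    segments = config.segments
    starts = _segment_starts(segments)
    weight = np.array([s.length_bp * s.rate_multiplier for s in segments], float)
    seg_idx = rng.choice(len(segments), size=n_mutations, p=weight / weight.sum())
    g0 = config.sample_interval
    records = []
    seen: set[tuple[str, MutationId]] = set()
    for si in seg_idx:
        seg = segments[si]
        position = int(starts[si] + rng.integers(seg.length_bp) + 1)
        mut, fclass = _draw_mutation_identity(position, seg, config, rng)
        key = (vessel, mut)
        if key in seen:  # caller would merge identical triples in one vessel
            continue
        seen.add(key)
        freq = float(rng.uniform(config.detection_threshold, 0.1))
        records.append(SnpRecord(vessel, mut, seg.name, fclass, {g0: freq}))
    return records


def null_scatter(
    config: SimConfig,
    n_mutations: int | None = None,
    vessel: str = "1",
    seed: int | None = None,
) -> list[SnpRecord]:
    """Uniform neutral scatter with all hotspot flags and multipliers cleared:
    per-segment counts follow the length-proportional Poisson null."""
    flat = replace(
        config,
        segments=[
            replace(s, hotspot=False, rate_multiplier=1.0) for s in config.segments
        ],
    )
    return scatter_records(flat, n_mutations=n_mutations, vessel=vessel, seed=seed)


def simulate_sweep(
    pop_size: int,
    s: float,
    f0: float,
    n_generations: int,
    seed: int = 0,
) -> np.ndarray:
    """Trajectory of a single beneficial mutation under selection + drift.

    Two competing genotypes, no further mutation: each generation the mutant
    count is binomially resampled with success probability
    f(1+s) / (1 + f s).  Returns frequencies at generations 0..n.
    """
    rng = np.random.default_rng((seed, 909))
    k = max(1, int(round(f0 * pop_size)))
    out = [k / pop_size]
    for _ in range(n_generations):
        f = k / pop_size
        p = f * (1 + s) / (1 + f * s)
        k = int(rng.binomial(pop_size, p))
        out.append(k / pop_size)
        if k in (0, pop_size):
            out.extend([k / pop_size] * (n_generations - len(out) + 1))
            break
    return np.array(out)


def fit_selection_coefficient(
    frequencies: np.ndarray,
    generations: np.ndarray | None = None,
) -> float:
    """Estimate s from a sweep trajectory by logistic (logit-linear) fit.

    For a haploid sweep, logit f(t) is linear in t with slope log(1 + s);
    endpoints at 0 or 1 are excluded (logit undefined).
    """
    f = np.asarray(frequencies, float)
    t = np.arange(len(f)) if generations is None else np.asarray(generations, float)
    keep = (f > 0) & (f < 1)
    f, t = f[keep], t[keep]
    if len(f) < 2:
        raise ValueError("need at least 2 interior frequencies to fit")
    slope = np.polyfit(t, np.log(f / (1 - f)), 1)[0]
    return float(np.exp(slope) - 1.0)


def export_vcf_series(
    records: Sequence[SnpRecord],
    directory,
    prefix: str = "pop",
    contig: str = "chr",
    genome_length: int | None = None,
) -> list[tuple[int, str]]:
    """Write one minimal VCF 4.2 file per sampled generation (AF in INFO).

    Only sites with non-zero frequency at a generation appear in that file,
    mirroring a caller's per-timepoint output.  Returns (generation, path)
    pairs in generation order.
    """
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    generations = sorted({g for r in records for g in r.trajectory})
    out = []
    for gen in generations:
        lines = [
            "##fileformat=VCFv4.2",
            '##INFO=<ID=AF,Number=A,Type=Float,Description="Allele Frequency">',
        ]
        if genome_length:
            lines.append(f"##contig=<ID={contig},length={genome_length}>")
        lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
        for r in sorted(records, key=lambda r: r.mutation):
            f = r.frequency_at(gen)
            if f <= 0:
                continue
            m = r.mutation
            lines.append(
                f"{contig}\t{m.position}\t.\t{m.ref}\t{m.alt}\t.\tPASS\tAF={f:.6g}"
            )
        path = directory / f"{prefix}_g{gen}.vcf"
        path.write_text("\n".join(lines) + "\n")
        out.append((gen, str(path)))
    return out
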