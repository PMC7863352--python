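"""Lineage nesting and Muller diagrams from clone + population sequencing.

A *lineage* is a cohort of mutations gained together on one edge of the clone
genealogy.  Clone genotypes, being cumulative under irreversible mutation,
nest by set containment: genotype A is ancestral to genotype B iff A's
mutation set is a proper subset of B's.  The containment tree over distinct
sampled genotypes, with the empty-set ancestor as root, is the lineage tree;
each edge carries the mutations gained on it.  Population allele-frequency
trajectories are then combined with this nesting to draw Muller diagrams:
stacked bands over time in which every child lineage is rendered inside its
parent, band widths are inclusive lineage frequencies, and the full plot
height is the whole population.

The lineage file format (versioned header ``#muller-lineages v1``) stores the
nesting only; frequencies always come from the mutation table, so the same
lineage file can be replayed against updated calls.
"""

from __future__ import annotations

import colorsys
import hashlib
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .catalog import CloneGenotype, MutationId, SnpRecord

__all__ = [
    "Lineage",
    "LineageTree",
    "LineageError",
    "infer_lineages",
    "read_lineage_file",
    "write_lineage_file",
    "lineage_trajectories",
    "LineageSeries",
    "muller_frames",
    "MullerLayout",
    "render_muller",
    "clone_vs_population_concordance",
    "ConcordanceResult",
]

ROOT = "root"
LINEAGE_FILE_HEADER = "#muller-lineages v1"


class LineageError(ValueError):
    """Raised for invalid lineage trees or malformed lineage files."""


@dataclass
class Lineage:
    """One lineage: the cohort of mutations gained on its edge from parent."""

    lineage_id: str
    parent_id: str
    defining_mutations: frozenset[MutationId]
    label: str = ""

    def __post_init__(self) -> None:
        self.defining_mutations = frozenset(self.defining_mutations)
        if not self.label:
            self.label = self.lineage_id


class LineageTree:
    """Rooted tree of lineages; the root is the (mutation-free) ancestor."""

    def __init__(self, lineages: Iterable[Lineage]):
        self.lineages: dict[str, Lineage] = {}
        for lin in lineages:
            if lin.lineage_id in self.lineages or lin.lineage_id == ROOT:
                raise LineageError(f"duplicate lineage_id {lin.lineage_id!r}")
            self.lineages[lin.lineage_id] = lin
        self._children: dict[str, list[str]] = {ROOT: []}
        for lin in self.lineages.values():
            self._children.setdefault(lin.lineage_id, [])
        for lin in self.lineages.values():
            if lin.parent_id != ROOT and lin.parent_id not in self.lineages:
                raise LineageError(
                    f"lineage {lin.lineage_id!r} references unknown parent "
                    f"{lin.parent_id!r}"
                )
            self._children[lin.parent_id].append(lin.lineage_id)
        self._check_acyclic_and_disjoint()

    def _check_acyclic_and_disjoint(self) -> None:
        seen: set[str] = set()
        claimed: dict[MutationId, str] = {}

        def descend(node: str, path_muts: frozenset[MutationId]) -> None:
            seen.add(node)
            for cid in self._children[node]:
                lin = self.lineages[cid]
                overlap = lin.defining_mutations & path_muts
                if overlap:
                    raise LineageError(
                        f"lineage {cid!r} re-claims ancestral mutation(s) "
                        f"{sorted(m.token() for m in overlap)}"
                    )
                for m in lin.defining_mutations:
                    if m in claimed and not self._is_ancestor_or_self(claimed[m], cid):
                        # same triple on two independent edges = recurrent
                        # origin; legal, disambiguated by lineage context
                        pass
                    claimed.setdefault(m, cid)
                descend(cid, path_muts | lin.defining_mutations)

        descend(ROOT, frozenset())
        orphaned = set(self.lineages) - seen
        if orphaned:
            raise LineageError(f"unreachable lineage(s) (cycle?): {sorted(orphaned)}")

    def _is_ancestor_or_self(self, a: str, b: str) -> bool:
        node = b
        while node != ROOT:
            if node == a:
                return True
            node = self.lineages[node].parent_id
        return a == ROOT

    def children(self, lineage_id: str) -> list[str]:
        return list(self._children[lineage_id])

    def genotype(self, lineage_id: str) -> frozenset[MutationId]:
        """Full genotype: union of defining cohorts on the root path."""
        muts: set[MutationId] = set()
        node = lineage_id
        while node != ROOT:
            lin = self.lineages[node]
            muts |= lin.defining_mutations
            node = lin.parent_id
        return frozenset(muts)

    def depth(self, lineage_id: str) -> int:
        d, node = 0, lineage_id
        while node != ROOT:
            node = self.lineages[node].parent_id
            d += 1
        return d

    def __len__(self) -> int:
        return len(self.lineages)

    def __iter__(self):
        return iter(self.lineages.values())


def _trajectory_vector(record: SnpRecord, generations: Sequence[int]) -> np.ndarray:
    return np.array([record.frequency_at(g) for g in generations])


def infer_lineages(
    clones: Sequence[CloneGenotype],
    trajectories: Sequence[SnpRecord] = (),
    cotrend_threshold: float = 0.8,
) -> LineageTree:
    """Arrange distinct clone genotypes into a lineage tree by containment.

    Each distinct non-empty genotype becomes a lineage whose parent is the
    largest sampled genotype strictly contained in it (ties break on the
    lexicographically smallest genotype); incomparable genotypes end up as
    siblings.  Mutations seen only in the population data become leaf
    lineages attached under the deepest lineage whose genotype is contained
    in the set of mutations they co-trend with (Pearson correlation of
    trajectories >= ``cotrend_threshold``), or under the root if none.
    """
    genotypes = sorted(
        {c.mutations for c in clones if c.mutations},
        key=lambda g: (len(g), sorted(m.token() for m in g)),
    )
    ids = {g: f"L{i + 1}" for i, g in enumerate(genotypes)}
    lineages: list[Lineage] = []
    for g in genotypes:
        parents = [h for h in genotypes if h < g]
        if parents:
            parent = max(parents, key=lambda h: (len(h), [m.token() for m in sorted(h)]))
            pid, pmuts = ids[parent], parent
        else:
            pid, pmuts = ROOT, frozenset()
        lineages.append(Lineage(ids[g], pid, g - pmuts))

    tree = LineageTree(lineages)
    orphan = [
        r for r in trajectories if not any(r.mutation in g for g in genotypes)
    ]
    if orphan:
        tree = _attach_population_only(tree, orphan, list(trajectories), cotrend_threshold)
    return tree


def _attach_population_only(
    tree: LineageTree,
    orphans: Sequence[SnpRecord],
    trajectories: Sequence[SnpRecord],
    threshold: float,
) -> LineageTree:
    generations = sorted({g for r in trajectories for g in r.trajectory})
    vectors = {r.mutation: _trajectory_vector(r, generations) for r in trajectories}
    lineages = list(tree)
    next_idx = len(lineages) + 1
    for rec in sorted(orphans, key=lambda r: r.mutation):
        v = vectors[rec.mutation]
        cotrending: set[MutationId] = set()
        for other, w in vectors.items():
            if other == rec.mutation:
                continue
            if v.std() == 0 or w.std() == 0:
                continue
            if float(np.corrcoef(v, w)[0, 1]) >= threshold:
                cotrending.add(other)
        candidates = [
            lin.lineage_id
            for lin in tree  # clone-supported lineages only host orphans
            if tree.genotype(lin.lineage_id) <= cotrending
        ]
        host = max(candidates, key=lambda L: (tree.depth(L), L), default=ROOT)
        lineages.append(
            Lineage(f"L{next_idx}", host, frozenset({rec.mutation}))
        )
        next_idx += 1
    return LineageTree(lineages)


# ---------------------------------------------------------------------------
# lineage file format
# ---------------------------------------------------------------------------


def write_lineage_file(tree: LineageTree, path: str | Path) -> None:
    lines = [LINEAGE_FILE_HEADER, "lineage_id\tparent_id\tdefining_mutations\tlabel"]
    for lin in sorted(tree, key=lambda l: l.lineage_id):
        muts = ",".join(m.token() for m in sorted(lin.defining_mutations)) or "."
        lines.append(f"{lin.lineage_id}\t{lin.parent_id}\t{muts}\t{lin.label}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_lineage_file(path: str | Path) -> LineageTree:
    """Parse and validate a ``#muller-lineages v1`` file; errors name lines."""
    text = Path(path).read_text().splitlines()
    if not text or not text[0].startswith(LINEAGE_FILE_HEADER):
        raise LineageError(f"{path}: missing '{LINEAGE_FILE_HEADER}' header")
    lineages = []
    for lineno, line in enumerate(text[1:], start=2):
        if not line.strip() or line.startswith("#") or line.startswith("lineage_id\t"):
            continue
        parts = line.split("\t")
        if len(parts) != 4:
            raise LineageError(f"{path}:{lineno}: expected 4 columns, got {len(parts)}")
        lid, pid, muts, label = parts
        tokens = [t for t in muts.split(",") if t and t != "."]
        try:
            cohort = frozenset(MutationId.from_token(t) for t in tokens)
        except ValueError as exc:
            raise LineageError(f"{path}:{lineno}: {exc}") from exc
        lineages.append(Lineage(lid, pid, cohort, label))
    try:
        return LineageTree(lineages)
    except LineageError as exc:
        raise LineageError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# lineage frequencies and the Muller layout
# ---------------------------------------------------------------------------


@dataclass
class LineageSeries:
    """Per-lineage inclusive and exclusive frequency series on a common grid."""

    generations: list[int]
    inclusive: dict[str, np.ndarray]  # lineage_id -> series (ROOT included, = 1)
    exclusive: dict[str, np.ndarray]
    tree: LineageTree


def lineage_trajectories(
    tree: LineageTree,
    trajectories: Sequence[SnpRecord],
    estimator: str = "cohort-mean",
) -> LineageSeries:
    """Combine lineage nesting with population allele frequencies.

    A lineage's *inclusive* frequency is the estimator (mean or max) over its
    defining cohort's allele frequencies — cohort members travel together on
    one genetic background, so their trajectories agree up to noise.  The
    *exclusive* frequency (the band width actually plotted) subtracts the
    children; when measurement noise makes children sum above their parent,
    the children are rescaled proportionally to fit and the parent's
    exclusive width floors at zero, preserving conservation.
    """
    if estimator not in ("cohort-mean", "cohort-max"):
        raise ValueError(f"unknown estimator {estimator!r}")
    generations = sorted({g for r in trajectories for g in r.trajectory})
    if not generations:
        raise ValueError("no sampled generations in trajectories")
    lookup: dict[MutationId, np.ndarray] = {}
    for r in trajectories:
        lookup[r.mutation] = _trajectory_vector(r, generations)

    inclusive: dict[str, np.ndarray] = {ROOT: np.ones(len(generations))}
    for lin in tree:
        vecs = []
        for m in lin.defining_mutations:
            if m in lookup:
                vecs.append(lookup[m])
            else:
                warnings.warn(
                    f"lineage {lin.lineage_id}: no trajectory for {m.token()}; "
                    "treated as frequency 0"
                )
                vecs.append(np.zeros(len(generations)))
        if not vecs:
            vecs = [np.zeros(len(generations))]
        stack = np.vstack(vecs)
        inclusive[lin.lineage_id] = (
            stack.mean(axis=0) if estimator == "cohort-mean" else stack.max(axis=0)
        )

    # top-down rescaling: children must fit inside the parent at every time
    exclusive: dict[str, np.ndarray] = {}

    def descend(node: str) -> None:
        parent = inclusive[node]
        kids = tree.children(node)
        child_sum = np.zeros_like(parent)
        for k in kids:
            child_sum += inclusive[k]
        with np.errstate(divide="ignore", invalid="ignore"):
            scale = np.where(child_sum > parent, np.where(child_sum > 0, parent / np.maximum(child_sum, 1e-300), 1.0), 1.0)
        for k in kids:
            inclusive[k] = inclusive[k] * scale
        exclusive[node] = np.maximum(parent - sum((inclusive[k] for k in kids), np.zeros_like(parent)), 0.0)
        for k in kids:
            descend(k)

    descend(ROOT)
    return LineageSeries(generations, inclusive, exclusive, tree)


@dataclass
class MullerLayout:
    """Stacked-band layout: per output time, each lineage's [lower, upper]."""

    times: np.ndarray
    bands: dict[str, np.ndarray]  # lineage_id -> (n_times, 2) inclusive band
    order: list[str]  # fixed drawing order (pre-order of the lineage tree)
    tree: LineageTree

    def frame(self, i: int) -> list[tuple[str, float, float]]:
        return [(lid, *self.bands[lid][i]) for lid in self.order]


def _sibling_order(tree: LineageTree, series: LineageSeries, node: str) -> list[str]:
    def first_detection(lid: str) -> int:
        inc = series.inclusive[lid]
        hits = np.nonzero(inc > 0)[0]
        return series.generations[hits[0]] if len(hits) else 10**9

    return sorted(tree.children(node), key=lambda k: (first_detection(k), k))


def muller_frames(
    tree: LineageTree,
    series: LineageSeries,
    interpolation: int = 10,
) -> MullerLayout:
    """Recursive band layout with exact conservation.

    Each parent splits its band into half of its exclusive width, the nested
    children (in fixed first-detection order), then the other half, so
    children sit visually inside their parents.  Frequencies are linearly
    interpolated with ``interpolation`` steps between sampled generations;
    zero-frequency lineages keep zero-width bands, so emergence and
    extinction render as pinches rather than appearing/vanishing polygons.
    """
    gens = np.array(series.generations, dtype=float)
    if len(gens) == 1:
        times = gens
    else:
        pieces = [
            np.linspace(gens[i], gens[i + 1], interpolation + 1)[:-1]
            for i in range(len(gens) - 1)
        ]
        times = np.concatenate(pieces + [gens[-1:]])

    def interp(v: np.ndarray) -> np.ndarray:
        return np.interp(times, gens, v)

    inclusive = {lid: interp(v) for lid, v in series.inclusive.items()}
    exclusive = {lid: interp(v) for lid, v in series.exclusive.items()}

    bands: dict[str, np.ndarray] = {}
    nt = len(times)
    order: list[str] = []

    def layout(node: str, lower: np.ndarray) -> None:
        width = inclusive[node]
        bands[node] = np.stack([lower, lower + width], axis=1)
        order.append(node)
        cursor = lower + exclusive[node] / 2.0
        for kid in _sibling_order(tree, series, node):
            layout(kid, cursor.copy())
            cursor = cursor + inclusive[kid]

    # renormalise interpolation drift: interpolated exclusive widths sum to
    # interpolated inclusive parent exactly because interpolation is linear
    layout(ROOT, np.zeros(nt))
    top = bands[ROOT][:, 1]
    if not np.allclose(top, 1.0, atol=1e-9):
        raise AssertionError("root band does not span [0,1]; upstream rescaling bug")
    for lid, band in bands.items():
        if band.min() < -1e-9 or band.max() > 1 + 1e-9:
            raise ValueError(f"lineage {lid}: band outside [0,1] (upstream bug)")
    return MullerLayout(times, bands, order, tree)


def _lineage_color(lineage_id: str, palette: Mapping[str, str] | None) -> str:
    if palette and lineage_id in palette:
        return palette[lineage_id]
    if lineage_id == ROOT:
        return "#d9d9d9"
    digest = hashlib.md5(lineage_id.encode()).digest()
    hue = digest[0] / 255.0
    sat = 0.45 + 0.4 * (digest[1] / 255.0)
    val = 0.65 + 0.3 * (digest[2] / 255.0)
    r, g, b = colorsys.hsv_to_rgb(hue, sat, val)
    return f"#{int(r * 255):02x}{int(g * 255):02x}{int(b * 255):02x}"


def render_muller(
    layout: MullerLayout,
    path: str | Path | None = None,
    palette: Mapping[str, str] | None = None,
    width: int = 900,
    height: int = 420,
    margin: int = 40,
) -> str:
    """Render the layout as an SVG document (one path per lineage).

    Each lineage is drawn as the region between its band's lower and upper
    boundary minus the nested children block — concretely, an upper and a
    lower strip emitted as two subpaths of a single ``<path>`` element, so
    polygon interiors are pairwise disjoint.  Output is deterministic:
    re-rendering the same layout and palette is byte-identical.
    """
    t = layout.times
    t0, t1 = float(t[0]), float(t[-1])
    span = (t1 - t0) or 1.0

    def sx(x: float) -> float:
        return margin + (x - t0) / span * (width - 2 * margin)

    def sy(y: float) -> float:
        return height - margin - y * (height - 2 * margin)

    def fmt(v: float) -> str:
        return f"{v:.3f}"

    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" height="{height}" '
        f'viewBox="0 0 {width} {height}">',
        f'<rect x="0" y="0" width="{width}" height="{height}" fill="white"/>',
    ]
    for lid in layout.order:
        band = layout.bands[lid]
        kids = _children_in_order(layout, lid)
        if kids:
            kid_lower = np.min([layout.bands[k][:, 0] for k in kids], axis=0)
            kid_upper = np.max([layout.bands[k][:, 1] for k in kids], axis=0)
        else:
            mid = band.mean(axis=1)
            kid_lower = kid_upper = mid
        subpaths = []
        for lo, hi in ((band[:, 0], kid_lower), (kid_upper, band[:, 1])):
            pts = [(sx(x), sy(y)) for x, y in zip(t, lo)]
            pts += [(sx(x), sy(y)) for x, y in zip(t[::-1], hi[::-1])]
            d = "M" + " L".join(f"{fmt(x)},{fmt(y)}" for x, y in pts) + " Z"
            subpaths.append(d)
        color = _lineage_color(lid, palette)
        parts.append(
            f'<path d="{" ".join(subpaths)}" fill="{color}" stroke="none">'
            f"<title>{lid}</title></path>"
        )
    parts.append("</svg>")
    doc = "\n".join(parts) + "\n"
    if path is not None:
        Path(path).write_text(doc)
    return doc


def _children_in_order(layout: MullerLayout, lineage_id: str) -> list[str]:
    kids = set(layout.tree.children(lineage_id))
    return [lid for lid in layout.order if lid in kids]


# ---------------------------------------------------------------------------
# clone vs population concordance
# ---------------------------------------------------------------------------


@dataclass
class ConcordanceResult:
    """Paired clone-based vs population frequencies with Pearson r."""

    table: "object"  # pandas DataFrame: mutation, clone_freq, pop_freq, clone_se
    r: float  # NaN when undefined (fewer than 2 distinct points)
    n_clones: int


def clone_vs_population_concordance(
    clones: Sequence[CloneGenotype],
    trajectories: Sequence[SnpRecord],
    generation: int,
) -> ConcordanceResult:
    """Compare clone-sample allele frequencies to population calls.

    For each mutation seen in either dataset, the clone-based estimate is
    carriers / n_clones (with binomial standard error); the population value
    is the allele frequency at the matched generation.  Pearson's r over the
    pairs quantifies how representative the isolated clones are.
    """
    import pandas as pd
    from scipy.stats import pearsonr

    if len(clones) < 2:
        raise ValueError("need at least 2 clones")
    n = len(clones)
    pop = {r.mutation: r.frequency_at(generation) for r in trajectories}
    muts = sorted(set(pop) | set().union(*(c.mutations for c in clones)))
    rows = []
    for m in muts:
        carriers = sum(m in c.mutations for c in clones)
        cf = carriers / n
        rows.append(
            {
                "mutation": m.token(),
                "clone_freq": cf,
                "pop_freq": pop.get(m, 0.0),
                "clone_se": math.sqrt(cf * (1 - cf) / n),
            }
        )
    table = pd.DataFrame(rows)
    x, y = table["clone_freq"].to_numpy(), table["pop_freq"].to_numpy()
    if len(table) < 2 or x.std() == 0 or y.std() == 0:
        r = float("nan")
    else:
        r = float(pearsonr(x, y).statistic)
    return ConcordanceResult(table, r, n)
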