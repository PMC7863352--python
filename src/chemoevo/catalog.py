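"""Data model and I/O for evolve-and-resequence mutation tables.

The central objects are :class:`SnpRecord` — one SNP observed in one chemostat
vessel, with its allele-frequency trajectory over sampled generations — and
:class:`CloneGenotype` — the mutation set of a single sequenced clone.  Around
them sit loaders for the canonical tab-separated tables (mutation table, clone
genotype table, segment annotation) and the trajectory summary statistics used
to characterise clonal interference: maximum vs final frequency, near-fixation
(> 98 %) calls, cross-vessel recurrence, per-gene cumulative frequencies, and
the mutation spectrum.

Conventions: coordinates are 1-based on the forward reference strand; a
mutation's identity is the ``(position, ref, alt)`` triple, so the same triple
seen in two vessels is "the same mutation" (independently arisen or not);
frequencies are proportions in [0, 1]; a mutation absent from a timepoint's
call set has frequency 0 there, not missing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "MutationId",
    "SnpRecord",
    "Segment",
    "CloneGenotype",
    "SnpTableError",
    "load_snp_table",
    "write_snp_table",
    "load_vcf_series",
    "load_clone_table",
    "write_clone_table",
    "load_segment_table",
    "write_segment_table",
    "max_and_final_frequency",
    "classify_fixed",
    "fixed_allele_count",
    "cross_vessel_recurrence",
    "RecurrenceSummary",
    "gene_cumulative_frequency",
    "pick_clone_timepoint",
    "spectrum_summary",
    "SpectrumSummary",
]

NUCLEOTIDES = frozenset("ACGT")

#: functional classes a SNP can take; ``noncoding`` is reserved for intergenic
#: / regulatory segments.
FUNCTIONAL_CLASSES = ("missense", "synonymous", "nonsense", "noncoding")

#: the GC→TA transversions on the forward reference strand
GC_TA = frozenset({("C", "A"), ("G", "T")})


class SnpTableError(ValueError):
    """Raised for malformed mutation / clone / segment tables."""


@dataclass(frozen=True, order=True)
class MutationId:
    """Identity of a point mutation: 1-based position plus ref/alt alleles."""

    position: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.ref not in NUCLEOTIDES or self.alt not in NUCLEOTIDES:
            raise ValueError(f"ref/alt must be nucleotides, got {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at position {self.position}")

    @property
    def is_gc_ta(self) -> bool:
        """True for the GC→TA transversions (C→A or G→T on the reference)."""
        return (self.ref, self.alt) in GC_TA

    def token(self) -> str:
        return f"{self.position}:{self.ref}>{self.alt}"

    @classmethod
    def from_token(cls, token: str) -> "MutationId":
        pos, _, alleles = token.partition(":")
        ref, _, alt = alleles.partition(">")
        try:
            return cls(int(pos), ref, alt)
        except ValueError as exc:
            raise SnpTableError(f"bad mutation token {token!r}: {exc}") from exc


@dataclass
class SnpRecord:
    """One SNP in one vessel with its allele-frequency trajectory.

    ``trajectory`` maps sampled generation (int, typically multiples of 50) to
    allele frequency in [0, 1]; keys are kept in increasing generation order.
    """

    vessel: str
    mutation: MutationId
    segment: str
    functional_class: str
    trajectory: dict[int, float]

    def __post_init__(self) -> None:
        if self.functional_class not in FUNCTIONAL_CLASSES:
            raise ValueError(
                f"functional_class must be one of {FUNCTIONAL_CLASSES}, "
                f"got {self.functional_class!r}"
            )
        gens = list(self.trajectory)
        if gens != sorted(gens):
            self.trajectory = dict(sorted(self.trajectory.items()))
        for g, f in self.trajectory.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(
                    f"frequency {f} at generation {g} outside [0,1] "
                    f"({self.vessel} {self.mutation.token()})"
                )

    @property
    def generations(self) -> list[int]:
        return list(self.trajectory)

    def frequency_at(self, generation: int) -> float:
        """Frequency at ``generation``; absent timepoints count as 0."""
        return self.trajectory.get(generation, 0.0)

    @property
    def max_frequency(self) -> float:
        return max(self.trajectory.values())

    @property
    def final_frequency(self) -> float:
        return self.trajectory[max(self.trajectory)]


@dataclass(frozen=True)
class Segment:
    """A genomic segment (gene or intergenic region) of known length."""

    name: str
    length_bp: int
    kind: str = "gene"

    def __post_init__(self) -> None:
        if self.length_bp < 1:
            raise ValueError(f"segment {self.name}: length_bp must be >= 1")
        if self.kind not in ("gene", "intergenic"):
            raise ValueError(f"segment {self.name}: kind must be gene|intergenic")


@dataclass
class CloneGenotype:
    """The derived-mutation set carried by a single sequenced clone.

    The ancestor is represented by an empty mutation set.
    """

    clone_id: str
    vessel: str
    mutations: frozenset[MutationId] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.mutations = frozenset(self.mutations)


# ---------------------------------------------------------------------------
# table I/O
# ---------------------------------------------------------------------------

#: canonical column map for the mutation table; override entries to adapt to
#: other dialects (e.g. a supplementary spreadsheet export).
DEFAULT_DIALECT: dict[str, str] = {
    "vessel": "vessel",
    "position": "position",
    "ref": "ref",
    "alt": "alt",
    "segment": "segment",
    "functional_class": "class",
}

_GEN_PREFIX = "g"


def _parse_frequency(raw, column: str, row: int) -> float:
    if raw is None or (isinstance(raw, float) and pd.isna(raw)) or raw == ".":
        return 0.0
    try:
        f = float(raw)
    except (TypeError, ValueError) as exc:
        raise SnpTableError(f"row {row}: non-numeric frequency {raw!r} in {column}") from exc
    if not 0.0 <= f <= 1.0:
        raise SnpTableError(f"row {row}: frequency {f} in {column} outside [0,1]")
    return f


def load_snp_table(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
) -> list[SnpRecord]:
    """Read the canonical mutation-table TSV into :class:`SnpRecord` objects.

    The table has one row per (vessel, mutation) and one frequency column per
    sampled generation, named ``g<N>``.  ``.`` (or an empty cell) means the
    allele was not called at that timepoint and is read as frequency 0.

    Raises :class:`SnpTableError` naming the offending column or 1-based data
    row for missing columns or out-of-range frequencies.
    """
    colmap = dict(DEFAULT_DIALECT)
    if dialect:
        colmap.update(dialect)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, na_values=[""])
    missing = [c for c in colmap.values() if c not in df.columns]
    if missing:
        raise SnpTableError(f"{path}: missing required column(s) {missing}")
    gen_cols: list[tuple[int, str]] = []
    for col in df.columns:
        if col.startswith(_GEN_PREFIX) and col[len(_GEN_PREFIX):].isdigit():
            gen_cols.append((int(col[len(_GEN_PREFIX):]), col))
    gen_cols.sort()
    if not gen_cols and len(df):
        raise SnpTableError(f"{path}: no generation columns (g<N>) found in header")

    records: list[SnpRecord] = []
    for idx, row in enumerate(df.itertuples(index=False), start=1):
        row_d = dict(zip(df.columns, row))
        try:
            mut = MutationId(
                int(row_d[colmap["position"]]),
                str(row_d[colmap["ref"]]).strip().upper(),
                str(row_d[colmap["alt"]]).strip().upper(),
            )
        except (TypeError, ValueError) as exc:
            raise SnpTableError(f"row {idx}: bad mutation fields: {exc}") from exc
        trajectory = {
            gen: _parse_frequency(row_d[col], col, idx) for gen, col in gen_cols
        }
        try:
            records.append(
                SnpRecord(
                    vessel=str(row_d[colmap["vessel"]]),
                    mutation=mut,
                    segment=str(row_d[colmap["segment"]]),
                    functional_class=str(row_d[colmap["functional_class"]]),
                    trajectory=trajectory,
                )
            )
        except ValueError as exc:
            raise SnpTableError(f"row {idx}: {exc}") from exc
    return records


def write_snp_table(records: Sequence[SnpRecord], path: str | Path) -> None:
    """Write records to the canonical TSV (inverse of :func:`load_snp_table`)."""
    generations = sorted({g for r in records for g in r.trajectory})
    header = ["vessel", "position", "ref", "alt", "segment", "class"] + [
        f"{_GEN_PREFIX}{g}" for g in generations
    ]
    lines = ["\t".join(header)]
    for r in records:
        row = [
            r.vessel,
            str(r.mutation.position),
            r.mutation.ref,
            r.mutation.alt,
            r.segment,
            r.functional_class,
        ] + [repr(r.frequency_at(g)) for g in generations]
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


def load_vcf_series(
    paths: Sequence[str | Path],
    generations: Sequence[int],
    vessel: str,
    freq_key: str = "AF",
    segment_lookup: Mapping[int, str] | None = None,
    class_lookup: Mapping[MutationId, str] | None = None,
) -> list[SnpRecord]:
    """Assemble trajectories from per-timepoint VCF files.

    ``paths`` and ``generations`` run in parallel, ordered by generation.  The
    per-site allele frequency is read from INFO key ``freq_key``.  A site
    absent from a file gets frequency 0 at that generation.  Positions within
    a file must be sorted and unique, or a :class:`SnpTableError` is raised.

    Segment / functional-class annotations are not part of VCF; they are taken
    from the optional lookups and default to ``"unknown"`` / ``"noncoding"``.
    """
    from cyvcf2 import VCF  # optional dependency, imported lazily

    if len(paths) != len(generations):
        raise ValueError("paths and generations must have equal length")
    if list(generations) != sorted(generations):
        raise SnpTableError("VCF files must be ordered by increasing generation")

    freqs: dict[MutationId, dict[int, float]] = {}
    for path, gen in zip(paths, generations):
        last_pos = -1
        seen: set[int] = set()
        for variant in VCF(str(path)):
            pos = variant.POS
            if pos < last_pos:
                raise SnpTableError(f"{path}: unsorted position {pos}")
            if pos in seen:
                raise SnpTableError(f"{path}: duplicated position {pos}")
            seen.add(pos)
            last_pos = pos
            af = variant.INFO.get(freq_key)
            if af is None:
                raise SnpTableError(f"{path}: site {pos} lacks INFO/{freq_key}")
            for alt, f in zip(variant.ALT, af if isinstance(af, tuple) else (af,)):
                mut = MutationId(pos, variant.REF, alt)
                freqs.setdefault(mut, {})[gen] = float(f)

    records = []
    for mut, traj in sorted(freqs.items()):
        full = {g: traj.get(g, 0.0) for g in generations}
        segment = (segment_lookup or {}).get(mut.position, "unknown")
        fclass = (class_lookup or {}).get(mut, "noncoding")
        records.append(SnpRecord(vessel, mut, segment, fclass, full))
    return records


def load_clone_table(path: str | Path) -> list[CloneGenotype]:
    """Read the clone genotype TSV: clone_id, vessel, ``;``-joined mutation tokens."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("clone_id", "vessel", "mutations"):
        if col not in df.columns:
            raise SnpTableError(f"{path}: missing required column {col!r}")
    clones = []
    for idx, row in df.iterrows():
        tokens = [t for t in str(row["mutations"]).split(";") if t and t != "."]
        muts = frozenset(MutationId.from_token(t) for t in tokens)
        clones.append(CloneGenotype(str(row["clone_id"]), str(row["vessel"]), muts))
    return clones


def write_clone_table(clones: Sequence[CloneGenotype], path: str | Path) -> None:
    lines = ["clone_id\tvessel\tmutations"]
    for c in clones:
        tokens = ";".join(m.token() for m in sorted(c.mutations)) or "."
        lines.append(f"{c.clone_id}\t{c.vessel}\t{tokens}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_segment_table(path: str | Path) -> list[Segment]:
    """Read the segment annotation TSV: name, length_bp, kind."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("name", "length_bp", "kind"):
        if col not in df.columns:
            raise SnpTableError(f"{path}: missing required column {col!r}")
    segs = [
        Segment(str(r["name"]), int(r["length_bp"]), str(r["kind"]))
        for _, r in df.iterrows()
    ]
    names = [s.name for s in segs]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise SnpTableError(f"{path}: duplicate segment name(s) {dupes}")
    return segs


def write_segment_table(segments: Sequence[Segment], path: str | Path) -> None:
    lines = ["name\tlength_bp\tkind"]
    lines += [f"{s.name}\t{s.length_bp}\t{s.kind}" for s in segments]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# trajectory summary statistics
# ---------------------------------------------------------------------------


def max_and_final_frequency(record: SnpRecord) -> tuple[float, float]:
    """Return (maximum, final) allele frequency over the sampled trajectory.

    An allele whose final frequency is below its maximum has been pushed back
    by competing lineages — the signature of clonal interference.
    """
    if not record.trajectory:
        raise ValueError(f"{record.mutation.token()}: empty trajectory")
    return record.max_frequency, record.final_frequency


def classify_fixed(
    records: Iterable[SnpRecord],
    threshold: float = 0.98,
    window: tuple[int, int] = (50, 500),
) -> list[SnpRecord]:
    """Records whose frequency strictly exceeds ``threshold`` at any sampled
    generation inside ``window`` (inclusive) — the operational near-fixation
    call.  Exact equality with the threshold does not qualify.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    lo, hi = window
    out = []
    for r in records:
        if any(lo <= g <= hi and f > threshold for g, f in r.trajectory.items()):
            out.append(r)
    return out


def fixed_allele_count(
    records: Iterable[SnpRecord],
    threshold: float = 0.98,
    window: tuple[int, int] = (50, 500),
) -> int:
    """Number of distinct alleles (deduplicated across vessels) ever fixing."""
    return len({r.mutation for r in classify_fixed(records, threshold, window)})


@dataclass
class RecurrenceSummary:
    """Cross-vessel recurrence of identical (position, ref, alt) mutations."""

    in_three: list[MutationId]
    in_two: list[MutationId]
    n_vessels: int

    @property
    def counts(self) -> tuple[int, int]:
        return len(self.in_three), len(self.in_two)


def cross_vessel_recurrence(
    records: Iterable[SnpRecord], min_freq: float = 0.01
) -> RecurrenceSummary:
    """Count mutations recurring in all three vs exactly two vessels.

    A mutation "occurs" in a vessel iff its trajectory there reaches at least
    ``min_freq``; grouping is by the (position, ref, alt) triple, so identical
    mutations in different vessels are independent parallel origins.
    """
    by_mut: dict[MutationId, set[str]] = {}
    vessels: set[str] = set()
    for r in records:
        vessels.add(r.vessel)
        if r.trajectory and r.max_frequency >= min_freq:
            by_mut.setdefault(r.mutation, set()).add(r.vessel)
    in_three = sorted(m for m, v in by_mut.items() if len(v) >= 3)
    in_two = sorted(m for m, v in by_mut.items() if len(v) == 2)
    return RecurrenceSummary(in_three, in_two, len(vessels))


def gene_cumulative_frequency(
    records: Iterable[SnpRecord], segment: str, vessel: str
) -> dict[int, float]:
    """Per-generation sum of allele frequencies over a segment in one vessel.

    The sum may exceed 1 when alleles of the segment co-occur in single clones
    (each contributes its own frequency); such generations are reported as-is
    with a warning, not clipped.
    """
    hits = [r for r in records if r.vessel == vessel and r.segment == segment]
    if not hits:
        warnings.warn(f"no records for segment {segment!r} in vessel {vessel!r}")
        generations = sorted({g for r in records for g in r.trajectory})
        return {g: 0.0 for g in generations}
    generations = sorted({g for r in hits for g in r.trajectory})
    cumulative = {g: sum(r.frequency_at(g) for r in hits) for g in generations}
    over = [g for g, f in cumulative.items() if f > 1.0]
    if over:
        warnings.warn(
            f"cumulative frequency of {segment!r} in vessel {vessel!r} exceeds 1 "
            f"at generation(s) {over} (co-occurring alleles double-count)"
        )
    return cumulative


def pick_clone_timepoint(
    records: Iterable[SnpRecord], vessel: str, min_freq: float = 0.05
) -> int:
    """Generation with the largest number of distinct alleles at >= ``min_freq``.

    This is the timepoint chosen for isolating clones: maximal standing allelic
    diversity gives the best chance of phasing high-frequency alleles.  Ties go
    to the earliest generation.
    """
    counts: dict[int, int] = {}
    for r in records:
        if r.vessel != vessel:
            continue
        for g, f in r.trajectory.items():
            counts.setdefault(g, 0)
            if f >= min_freq:
                counts[g] += 1
    if not counts:
        raise ValueError(f"no sampled generations for vessel {vessel!r}")
    return min(sorted(counts), key=lambda g: (-counts[g], g))


@dataclass
class SpectrumSummary:
    """Mutation-spectrum fractions over a set of SNP records."""

    gc_ta_fraction: float
    n_snps: int
    missense_fraction: float
    synonymous_fraction: float
    nonsense_fraction: float
    n_coding: int


def spectrum_summary(records: Sequence[SnpRecord]) -> SpectrumSummary:
    """GC→TA fraction among all SNPs and class fractions among coding SNPs.

    A MutY-deficient mutator yields an extreme GC→TA transversion bias; the
    coding-class split (missense / synonymous / nonsense) sums to 1 over
    coding records.  Fractions are 0 when the respective denominator is empty.
    """
    n = len(records)
    gc_ta = sum(r.mutation.is_gc_ta for r in records)
    coding = [r for r in records if r.functional_class != "noncoding"]
    nc = len(coding)

    def frac(k: int, d: int) -> float:
        return k / d if d else 0.0

    return SpectrumSummary(
        gc_ta_fraction=frac(gc_ta, n),
        n_snps=n,
        missense_fraction=frac(sum(r.functional_class == "missense" for r in coding), nc),
        synonymous_fraction=frac(sum(r.functional_class == "synonymous" for r in coding), nc),
        nonsense_fraction=frac(sum(r.functional_class == "nonsense" for r in coding), nc),
        n_coding=nc,
    )
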