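# Methods

This note records the models behind each stage of the pipeline, the defaults
and why they were chosen, the numerical conventions, and what the synthetic
data generator does and does not capture.

## Data model

A point mutation is identified by its `(position, ref, alt)` triple on the
forward reference strand (1-based, fully closed coordinates); the same triple
observed in two vessels is treated as the same allele arising independently.
Strand is not modelled.  A population-sequencing record couples one such
triple, in one vessel, to an allele-frequency trajectory over the sampled
generations (every 50 generations by default).  A mutation absent from a
timepoint's call set is assigned frequency 0 rather than missing — lineage
frequencies and Muller bands need continuous trajectories, and in an
evolve-and-resequence design "not called" at a 1 % floor is operationally
"(near) absent".  Clone genotypes are sets of triples; the ancestor is the
empty set, so only derived alleles are represented.

Trajectory summaries follow the operational definitions used in chemostat
evolution studies: *near-fixation* is frequency strictly above 98 % at any
sampled generation between 50 and 500 (exact equality does not qualify);
*recurrence* groups records by triple and asks in how many vessels the
trajectory ever reaches 1 %; the clone-sampling timepoint is the generation
maximising the number of distinct alleles at ≥ 5 % frequency (ties go to the
earliest generation — deterministic, and favouring less-diverged clones).
Per-gene cumulative frequencies simply sum allele frequencies per segment and
can legitimately exceed 1 when alleles co-occur in one genome; such values
are flagged, not clipped.

## Excess-mutation (hotspot) statistic

Under a uniform per-bp mutation process the count in a segment of length *l*
is Poisson with mean λ = ρ·l, ρ = M/L the genome-wide density.  A segment
with *n* observed mutations is scored by the capped upper tail

p = Σ_{i=n}^{50} λ^i e^{−λ} / i!

evaluated in log-space (`logsumexp` over `i·log λ − λ − log i!`); tails down
to ~1e−53 occur for the most heavily hit genes and naive factorial
arithmetic overflows long before i = 50.  The cap of 50 is a configurable
convention; the truncation error is far below any tolerance of interest for
λ ≲ 10 (the uncapped survival function is available with `cap=None`, and is
what the analysis driver uses for very long segments where n can exceed the
cap — the capped convention returns 0 there, which would rank a *depleted*
segment first).

Multiple testing uses the rank-adjusted estimator fdr_i = N·p_i / rank_i over
N tested segments, with step-up monotonicity (each value capped by the
minimum at any worse rank) and capping at 1 — the Benjamini–Hochberg adjusted
p-value.  A literal Bonferroni variant (N·p) is provided.  The published
benchmark table this statistic is validated against (see
`chemoevo.benchmarks`) is arithmetically consistent only with the
rank-adjusted form: fdr·rank/p is constant across its rows (≈ 9.71·10⁴
clonal, ≈ 6.75·10⁴ population, spread < 1–2 %), which also back-derives N,
since the number of tested segments was never printed.  That N is far larger
than the number of annotated genes implies the original tests were run over
sub-gene segment tilings; segment tilings are therefore always user-supplied
here, never inferred.  By default the tested count per segment is total
mutation events aggregated over vessels (recurrent identical alleles count
once per vessel of origin); a `dedup` mode counts distinct alleles instead.

Reproduction tolerance: printed λ values carry 4 (clonal) or 2 (population)
decimals and are the only recoverable input, which bounds agreement of
recomputed p-values at roughly 2 % relative for the clonal rows; the
population rows are reproducible only to ~10–20 % and are used for the
FDR-structure check, not for p-value regression.

## Camin-Sokal clone phylogenies

Clone genotypes are recoded as binary presence/absence characters with the
ancestor as an all-zero outgroup.  Under the Camin-Sokal criterion characters
may be gained (0→1) repeatedly but never lost — appropriate when an extreme
GC→TA transversion bias makes exact reversion negligible.  For a fixed
rooted topology the optimal gain placement for a character with carrier set
S is the set of maximal clades wholly contained in S (placing a gain above a
clade already inside S can never help, and overlapping gains on one path are
forbidden); the tree score is the total number of gains, and a character with
≥ 2 gains is a within-vessel parallel origin.

Search proceeds in three tiers: (1) if all character pairs are compatible
(carrier sets pairwise nested or disjoint) the perfect phylogeny is built
directly from the laminar carrier family — provably optimal at one gain per
character; (2) otherwise, after collapsing identical genotypes into single
taxa, up to 8 collapsed taxa are solved exactly by enumerating all rooted
binary topologies; (3) beyond that, greedy stepwise addition (taxa in
decreasing mutation count) followed by nearest-neighbour-interchange hill
climbing, which never worsens the score.  Ties among co-optimal topologies
break on a canonical order-invariant form, so results are deterministic
without a seed; the exact tier also reports how many co-optimal topologies
existed.  Zero-gain internal edges are collapsed before output, so
unresolved structure appears as polytomies rather than arbitrary
bifurcations, and collapsed identical-genotype groups re-expand as
polytomies of named leaves.  Every output tree is structurally validated:
each taxon's genotype must equal the union of gains on its root path and no
character may repeat along a path.

Newick export writes integer branch lengths equal to the gain count and can
annotate gains in bracketed comments; labels containing underscores are
quoted (standard readers otherwise convert them to spaces).

## Lineage nesting and Muller diagrams

Because mutation is irreversible here, clone genotypes are cumulative, and
distinct sampled genotypes nest by set containment: the parent of a genotype
is the largest sampled genotype strictly contained in it (ties cannot occur
among genotypes produced by a single genealogy; for arbitrary input the tie
breaks lexicographically).  Mutations gained on one edge form that lineage's
defining cohort.  Mutations detected in the population but absent from every
clone become leaf lineages attached under the deepest lineage whose genotype
is contained in the set of mutations they co-trend with (Pearson correlation
of trajectories ≥ 0.8 by default), or under the root when none qualifies.
Divergent cohorts are not auto-split; members lacking trajectories are
flagged with warnings and treated as frequency 0.

A lineage's inclusive frequency is by default the *mean* of its defining
cohort's allele frequencies (cohort members ride the same background, so
their trajectories agree up to measurement noise; the mean is the natural
pooled estimate).  A `cohort-max` estimator is available for sparse data.
When children sum above their parent at a timepoint — measurement noise, or
cohort members censored at different floors — the children are rescaled
proportionally to fit and the parent's exclusive width floors at 0; this is
the minimal correction that preserves conservation.  The root (ancestor)
always has inclusive frequency 1.

The layout is recursive: each parent's band is split into half of its
exclusive width, its children in a fixed sibling order (ascending
first-detection generation), and the other half, so children are drawn
inside their parents.  Frequencies are linearly interpolated between sampled
generations; since the parent = exclusive + Σ children identity is linear it
survives interpolation exactly, and every frame tiles [0, 1] to floating
point accuracy.  Lineages at zero frequency keep zero-width bands, so
emergence and extinction render as pinches.  SVG output draws one path per
lineage (its band minus the nested child block, as upper and lower strips),
giving pairwise disjoint interiors; colours are derived from an MD5 hash of
the lineage id, so re-rendering is byte-identical.

The lineage file format (`#muller-lineages v1`) stores ids, parent links,
comma-joined defining cohorts, and labels — never frequencies, which always
come from the mutation table.  Reading validates the tree: unknown parents,
duplicate ids, and re-claimed ancestral mutations are hard errors naming the
offending line.  Recurrent origins of one triple are legal as entries on
different, non-nested edges (the format keys edges, not mutations).

## Chemostat simulator

Non-overlapping Wright-Fisher generations at constant population size stand
in for chemostat growth: continuous dilution holds N and the limiting
resource constant, and the mechanistic physiology (dilution rate, residual
substrate) is deliberately not modelled.  Each generation, genotype counts
are multinomially resampled with weights proportional to count × (1 + s),
where s sums the genotype's selection coefficients (additive fitness, no
epistasis; a pairwise-interaction hook was considered and left out — no
quantitative epistasis model is available to parameterise it).  New
mutations arrive Poisson(N·μ_eff) per generation, land uniformly per bp
(modulated by optional per-segment rate multipliers), and found new
genotypes; each origin event is recorded with its generation, fitness
effect, and host genotype, so the full genealogy and per-generation count
vectors are retained as ground truth.

Defaults and rationale:

- `pop_size = 1e5` — scaled down from > 10¹⁰ cells; large enough that a 1 %
  detection floor (1000 copies) is far above single-copy noise, small enough
  for seconds-per-vessel runtimes.
- `n_generations = 500`, `sample_interval = 50`, `n_vessels = 3`,
  `clone_sample_size = 96` — the study design being emulated.
- `genome_length = 2·10⁵` bp with a deterministic tiling of 60 genes
  (0.9–2.4 kb), short intergenic spacers, and a long intergenic backbone;
  6 genes are beneficial-mutation hotspots, mirroring the handful of
  repeatedly hit regulatory loci in real glucose-limited evolutions.
- `mu = 0.01` per genome per generation.  The emulated ancestor is a ~30-fold
  mutator (per-genome input of order 3·10⁻² on a 4.6 Mb genome); on the
  23-fold-reduced genome a rate of 10⁻² keeps the *per-genome* input within
  a factor of a few of the real strain while keeping half a million origin
  events per vessel tractable.  It yields roughly 100–150 detected (≥ 1 %)
  SNPs per vessel — the right order relative to the ~1100 per vessel at full
  scale — with near-linear accumulation over time.
- `gc_ta_bias = 0.975` and `class_probs = (0.692, 0.234, 0.074)` — the
  mutator's observed spectrum.  Both are properties of the *input* process;
  the detected subset is mildly enriched for missense changes because
  beneficial mutations are drawn only from non-synonymous hits, which is
  itself realistic.
- `dfe = ("exponential", 0.05)` at hotspot segments, non-synonymous hits
  only; everything else neutral.  No quantitative selection coefficients
  were available to fit, so an exponential DFE with mean 5 % — a standard
  choice for beneficial effects strong enough to sweep within hundreds of
  generations — was fixed once.  It produces pervasive clonal interference:
  most detected alleles peak below 10 % and end below their maxima.
- `detection_threshold = 0.01` kept at the experimental 1 % so censoring
  behaves comparably despite the scaled-down N.

Randomness: one root seed; vessels, clone draws, and scatter fixtures use
deterministically derived sub-streams, so a configuration and seed fully
determine every output.  A guard rejects configurations whose per-generation
mutation count would exceed 5·10⁴ (runaway memory), advising rescaling.

Exports: the population table merges all origins of a triple (a caller
cannot distinguish recurrent origins), reports frequencies at sampled
generations only, and censors triples never reaching the detection floor.
Clone samples are multinomial draws from the true genotype frequencies and
are *not* censored, matching clone sequencing's per-genome calling.  A
minimal per-timepoint VCF 4.2 series (AF in INFO) can be written and read
back.  `null_scatter` bypasses the dynamics entirely: counts per segment are
length-proportional Poisson draws, the exact null of the hotspot statistic,
with rate multipliers available to plant enrichment for power checks
(placement-rate enrichment is the direct formalisation of "k-fold enriched"
for a count statistic, and avoids confounding enrichment with hitchhiking).

What the generator does *not* emulate: sequencing-read noise (frequencies
are emitted exactly; binomial read-depth noise would sit on top), indels and
structural variants, contamination, epistasis, ecological interactions such
as cross-feeding, within-gene positional hotspots (enrichment is uniform
within a segment, so identical-triple parallelism is much rarer than in the
real data unless recurrence is explicitly planted), and linkage to a real
reference sequence (ref/alt bases are assigned consistently with the
spectrum draw, not read from sequence).  Passing tests on this generator
therefore demonstrate correctness of the *inference machinery* under the
stated model, not robustness to noise sources the model omits.

## Scales used by the test suite

Replicate-heavy checks (perfect-phylogeny recovery, Muller conservation,
calibration) run on a reduced configuration — 2·10³ cells, 20 kb genome,
150 generations sampled every 25, μ = 0.02 — chosen so that twenty seeded
replicates finish in seconds while still producing dozens of detected
mutations and multi-level lineage trees.  Single-run fidelity checks (GC→TA
fraction, accumulation linearity, interference signature) use the full
default configuration.  The exhaustive parsimony oracle suite covers the
complete 3-taxa × 2-character space plus seeded draws up to 6 × 5, the
largest sizes at which the independent topology-enumeration oracle stays
fast.

## Known limitations

- The heuristic parsimony tier (stepwise addition + NNI) guarantees only a
  local optimum; exactness is proven up to 8 collapsed taxa and for all
  compatible matrices of any size.
- Lineage inference assumes the sampled clones contain the backbone
  genotypes; a mutation whose true background was never sampled attaches by
  trajectory correlation, which can misplace alleles with similar dynamics.
- The cap-at-50 tail convention returns p = 0 when n exceeds the cap; use
  the uncapped survival function for segments long enough to make that
  regime reachable.
- Population benchmark p-values are reproducible only to the ~2-decimal
  precision of their printed λ inputs.
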