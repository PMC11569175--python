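# Methods

This note records the models, conventions and numerical choices behind
`scmregions`, and what the synthetic cohorts do and do not establish.

## Preprocessing

Genes present in fewer than 5 spots and spots with fewer than 500 total
UMIs are discarded (strict `<` on both boundaries). The two filters are
iterated to a fixed point, gene filter first: a spot removal can push a gene
below the spot floor, and iterating makes the filter idempotent and leaves
the retained matrix jointly consistent (every kept gene is nonzero in ≥ 5
kept spots, every kept spot has ≥ 500 UMIs over kept genes). In practice the
fixed point is reached after the first pass on realistic data.

Normalization is median-library scaling followed by log1p: each spot's
counts are scaled so its total equals the sample's median spot total. This
is a deliberate simplification of pooling-based size-factor estimation: every
downstream test is rank-based (Wilcoxon, Kruskal–Wallis, Spearman) or
bin-matched (module scores), hence insensitive to monotone per-spot scaling.
The target total is a parameter of `normalize_log`, so a different scheme
can be slotted in.

Mitochondrial/ribosomal genes are recognised by the symbol prefixes `MT-`,
`RPL`, `RPS` (configurable regex); there is no universal convention, and this
is the common human-symbol one.

## Region calling

NMF (scikit-learn, Frobenius objective, coordinate descent, `nndsvd`
initialisation, `max_iter = 2000`, `tol = 1e-6`) is fitted to the pooled
spots × cell-states abundance matrix for every k in [5, 12]. Abundances
enter unnormalised — they are inferred cell counts and the argmax labeling
is invariant to positive per-spot scaling anyway; a per-spot
sum-normalisation switch exists but is off by default. The deterministic
SVD-based initialisation makes the whole scan reproducible without
restarts.

For each k, component j's *top state* is `argmax H[j]`; k is admissible when
all top states are distinct, and the chosen model is the largest admissible
k. If no k qualifies the selection raises an error listing the duplicated
states per k — silent fallback would hide a structurally inadequate
abundance matrix. Exact argmax ties (measure-zero, but possible on
constructed data) break to the lowest index, making tie behaviour
deterministic; all-zero W rows get a reserved "unassigned" label (0) and a
warning.

Per-sample region fractions are computed over assigned spots and compared
across sample categories with a Kruskal–Wallis test plus all pairwise
two-sided rank-sum tests. The rank-sum implementation enumerates all
C(n, n₁) group arrangements exactly (midranks, so ties are handled) whenever
that count is ≤ 20 000, and otherwise uses the tie-corrected normal
approximation with continuity correction. Degenerate inputs (all values
identical) give p = 1.

## Region markers

Within each sample, each region with ≥ 10 spots is tested one-vs-rest per
gene with the two-sided rank-sum test; BH runs across genes within each
(sample, region); DE requires log2FC ≥ 1 and p_adj < 0.05. Fold change is
computed on the linear scale: log2((mean expm1(norm) + ε)/(… + ε)),
ε = 10⁻⁹ — the convention under which the printed threshold of 1 is
meaningful.

The meta-analysis treats each tested (sample, region) pair as an *instance*.
For gene g and region r, a 2×2 table counts instances of r with/without a DE
call for g against the same over all other regions; the one-sided (greater)
Fisher p is the upper hypergeometric tail, computed through
`hypergeom.sf` so vanishingly small p-values keep log accuracy. BH is
applied across genes within each region — matching the per-region marker
lists the analysis reports. Instances dropped by the 10-spot floor are
*untested*: they appear in neither margin. A gene never tested in a region
is excluded from that region's family rather than entered at p = 1.

Category-wise (group) DE pools a region's spots across samples within each
category on the shared gene space and tests category pairs with ≥ 10 spots
each; flags require |log2FC| ≥ 1 and p_adj < 0.05 per pair. Gene-set
overrepresentation among markers is a one-sided Fisher test per (region,
set) over the universe of genes tested at least once, BH across sets within
region.

## Spatial structure

Valid Visium array coordinates have even row+col parity; the axial transform
q = (col − row)/2, r = row turns the staggered grid into standard hex
coordinates with distance (|dq| + |dr| + |dq + dr|)/2. Ring adjacencies up
to 3 rings (≈ 300 µm at 100 µm pitch) are precomputed pairwise; parity
violations are reported with the offending spot.

Neighborhood enrichment counts spot pairs within 3 rings joining each
region pair (unweighted — every edge with d ≤ 3 counts equally) and
standardises against label permutations: z = (obs − mean)/sd over the
permutation null, with z = 0 wherever the null is degenerate (sd = 0, e.g.
single-label samples). Missing regions are zeroed per sample before the
cohort mean.

Proximity annotation: a focal spot is *anchored* when at least one ring-1
neighbor shares its region (lone spots are *sporadic* and create no
proximal band). A non-focal spot is *proximal* when it lies within 3 rings
of **two anchored focal spots that are adjacent to each other** — the
pair-adjacency reading of "two or more adjacent focal spots"; the stated
purpose of the clause is to exclude sporadic single spots, which a lone spot
could never satisfy. The alternative reading (any two anchored focal spots
within 3 rings, not necessarily adjacent) is available behind
`rule="any-two"`. All remaining non-focal spots are *distant*, so
proximal/distant exactly partition them. Samples with fewer than 10 focal
spots are excluded outright.

Interfaces: a spot of region F *interacts* with region G when it is
anchored in F and has ≥ 2 region-G spots within 3 rings (symmetrically for
G); the (sample, F–G) interface exists when both interacting sets have ≥ 10
spots.

## Signature scoring

Genes are ranked by mean normalized expression (ties broken by gene name)
and cut into 25 equal-frequency bins; each set gene contributes 50 control
genes from its own bin — the whole bin when it holds ≤ 50 genes (exhausting
it deterministically), otherwise a seeded draw without replacement. The
score is the mean over set genes minus the mean over the pooled control
draw. No gene is excluded from the control pool, so set genes may serve as
their own controls; consequently a set that concentrates in few bins partly
controls against itself and its score is conservatively shrunk — the
synthetic generator therefore spreads planted sets across bins (below).
Set genes are iterated in name order so the draw is invariant to gene/spot
ordering in the input.

Effect sizes between a focal and another spot group use Welch's t-test plus
the percentile star rule: ★★★/★★/★ when the other group's 90th/80th/70th
percentile lies below the focal mean (highest satisfied tier, p < 0.05
required; the tiers nest by monotonicity of percentiles).

The fraction–score correlation pools every sample's non-focal raw counts,
drops genes expressed in fewer than 10 samples, renormalises the pool as one
pseudo-sample, scores it, and correlates each sample's mean non-focal score
with its focal-region fraction (Spearman). At least 4 samples are required;
constant inputs return ρ = 0 with a warning.

## Ligand–receptor testing

Pairs with fewer than 3 literature references are dropped. A directed pair
is tested at a (sample, interface) only when the ligand is detected
(count > 0) in more than 1% of the F-side interacting spots and the
receptor likewise on the G side; gated-out pairs are *untested*, never
p = 1 — folding them in as non-significant would bias the downstream
enrichment denominators. The statistic is the mean of the two side means of
normalized expression; the null permutes the side assignment over the union
of interacting spots, with one shared permutation stream per (sample,
interface) so all pairs see the same nulls. The two sides are ordered
canonically before permuting, which makes the p exactly invariant to
swapping which region is called F (with ligand and receptor swapped
accordingly). The add-one estimator p = (1 + #{null ≥ obs})/(1 + n_perms)
never returns 0; the smallest attainable value is 1/(n_perms + 1). BH runs
within (sample, interface, direction); active = p_adj < 0.05.

Interface specificity: for each pair and interface type (partner region ×
direction, seen from the focal region), a one-sided Fisher test compares
active counts at that type against all other types over (sample, interface)
instances, BH across pairs within type. Pairs tested at a single type are
flagged (`single_type`) since their 2×2 has a degenerate margin.
Multi-subunit complexes are not modelled: a complex row in an input table
should be expanded to subunit pairs upstream.

## The synthetic cohort generator

The generator is first-class, tested code; its defaults are the study
conditions every guarantee is stated under: 12 samples (3 × BPH/TRNA/NEADT/
CRPC-like), a 30 × 30 hex lattice (900 spots), 8 latent regions over 26
cell states, 1000 genes, 10 markers per region at log2FC = 2, NB dispersion
10 (variance μ + μ²/10), log-normal library sizes around 3000 UMIs (σ = 0.3
on the log scale), ~20 cells per spot, signature shift 0.5 (natural-log
scale), AR-like downshift of 1 log2 unit in NEADT/CRPC samples,
fraction–score coupling 2.0, and 5 added counts per spot of planted
ligand–receptor effect.

Model choices worth recording:

* **Regions** grow from k seed spots by randomized BFS, giving compact
  connected patches (≥ 60% of ring-1 neighbors share a spot's label at
  defaults). Regions 1 and 2 are seeded on adjacent spots so the planted
  ligand–receptor interface exists in every sample.
* **Abundance** is deliberately low-rank: each region has a fixed
  composition profile (0.7 on its dominant state, 0.3 background
  concentrated 95% on the states that dominate somewhere), shared across
  samples, with per-spot log-normal jitter. Deconvolution output of a
  curated reference behaves this way — states that dominate nowhere are
  rare everywhere — and it is the regime in which the component-uniqueness
  stopping rule has a well-defined answer: with full-rank i.i.d. per-spot
  noise, extra NMF components latch onto unused states with unique argmaxes
  and the rule never stops.
* **Signature shifts** are planted in log1p space: the per-gene count
  multiplier solves log1p(mμ) − log1p(μ) = shift at the typical library
  size, so bin-matched scores recover the shift directly. Planted set genes
  are spread across the upper expression range with a fixed stride; packed
  into consecutive ranks they would dominate their own control bins and the
  score would shrink toward zero by construction.
* **Ligand–receptor planting** inflates the ligand only in source-region
  spots within 3 rings of the target and the receptor only in target-region
  spots within 3 rings of the source. Inflating the ligand across the whole
  source region would make the pair active at *every* interface of that
  region (the permutation statistic detects any side asymmetry), destroying
  interface specificity.
* **Determinism**: one master seed; per-sample substreams keyed by
  (category, index within category), so adding a sample never changes
  existing ones; cohort-level gene assignments and region profiles use fixed
  substream offsets.

What the generator does **not** emulate: spot swapping/bleed-over, doublets,
segmentation error in the upstream deconvolution, batch effects, gene–gene
correlation beyond the planted structure, and any real marker identity.
Passing tests therefore establish that the implementation computes the
stated procedures correctly and recovers known planted structure at
realistic noise — not that the biological conclusions transfer to any real
cohort.

## Problem sizes and tolerances

The test and acceptance workloads use the default cohort for region
recovery (12 × 900 spots), 12 × 12 lattices with 200 genes for the 100-cohort
marker-calibration runs, 100–200 replicate samples for permutation-null
calibration (500 permutations each), and 300–500 pair tests for
ligand–receptor null uniformity — sizes chosen so each property is measured
with comfortable statistical margin on a single CPU. Numerical tolerances:
NMF `tol = 1e-6`; exact-test assertions compare to closed forms at float
precision; calibration checks use the bands stated in the tests (null z
mean within ±0.1, SD within [0.8, 1.2]; shift recovery within 10%;
one-sided KS at α ≈ 0.01 for p-value uniformity).

## Known limitations

* The rank-sum exact path enumerates arrangements only up to 20 000; between
  that and the asymptotic regime, small-sample p-values are approximate.
* Scoring densifies the expression matrix per sample; samples far larger
  than Visium capture areas (~5k spots) would warrant a sparse path.
* `fraction_score_correlation` pools all non-focal spots in memory.
* Multi-subunit ligand/receptor complexes are out of scope (see above).
* The uniqueness stopping rule inherits NMF's non-identifiability at
  component counts beyond the data's effective rank; on such data the
  selection trace, not just the chosen k, should be inspected.
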