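# Methods

This note documents the models and procedures implemented in `quantkit`,
the parameter choices that matter, what the synthetic-data generators do and
do not emulate, and the numerical conventions.

## Ommatidial disorderliness scoring

**Model.** The compound eye is treated as a noisy hexagonal point lattice:
each ommatidium contributes one bright, roughly isotropic intensity peak.
Scoring proceeds in three stages.

*Detection.* The image is Gaussian-smoothed (`smooth_sigma`, default 2 px),
thresholded (Otsu by default, or an absolute intensity), and local maxima
are taken in decreasing intensity order subject to a minimum Euclidean
separation (`min_separation`, default 6 px). Each peak is refined to
sub-pixel position by the intensity-weighted centroid of the
above-threshold smoothed signal in a window of half-width
`round(min_separation)`; without this refinement the length
coefficient-of-variation inherits a grid-quantization floor. Detection is
fully deterministic; a constant image yields an empty set.

*Fans.* For each center, the six nearest other centers (Euclidean distance,
ties broken by smaller index under lexicographic center ordering, so results
are reproducible and match exhaustive search) define six vectors with
lengths and angles. A center is *interior* when (a) its 6th neighbor lies
within 1.8× the median nearest-neighbor distance and (b) its neighbors
surround it — the largest gap between sorted neighbor directions is at most
100°. Condition (b) is what makes the score exact in the ideal limit: on a
perfect lattice the distance rule alone admits lattice-edge sites whose 6th
neighbor sits at √3 × spacing ≈ 1.73 × spacing, and those fans are
geometrically distorted even in a perfect eye (largest direction gap ≥
120°). A site adjacent to a single missing ommatidium has a largest gap of
90° and is retained, so lattice damage is still counted.

*Scores.* Per interior center, length disorderliness is the population
(n-divisor) SD of the six lengths over their mean — population form so that
hand-worked examples are exact at the fixed fan size — and angle
disorderliness is the mean over the six wraparound-consecutive angular gaps
of |gap − 60°|/60°. `distance_od` and `angle_od` are 100× the respective
means over interior centers; the composite phenotypic score is their sum,
with the detected count reported separately rather than folded into the
score, keeping each subscore interpretable. Both subscores are invariant
under translation, rotation, and uniform scaling of the center set; a
perfect hexagonal lattice scores (0, 0, 0) to floating tolerance.

*Necrosis and cell counting.* Necrotic-patch area is the total size of
8-connected components of pixels strictly below a dark threshold, ignoring
components of at most 10 px (speckle). Cell counting offers two strategies
mirroring common ImageJ practice: above-threshold connected components
(AnalyzeParticles-style) and smoothed local maxima with minimum separation
(nuclei-counter-style); on well-separated synthetic blobs they agree
exactly, and across varying true counts they correlate strongly (r > 0.9).

## Weighted-network connectivity

**Model.** An undirected gene network with positive confidence weights.
Edge retention follows either a strict minimum weight (default > 2.0) or the
top fraction of edges by weight (default 0.5%, keeping ⌈fE⌉ edges with ties
at the realized cutoff all retained); duplicate pairs collapse to their
maximum weight and isolated nodes are dropped. Distances run over the edge
length transform 1/w — the simplest strictly decreasing transform, kept as a
configuration point (e.g. −log(w/w_max) can be swapped in). Distance is the
Dijkstra shortest-path length; genes absent from the network and unreachable
partners are reported and excluded from means rather than assigned penalty
distances, which would need an arbitrary constant.

**Null.** 500 anchor genes drawn without replacement from the node set;
for each anchor, 100 replicates of 20 random partners; each replicate
contributes the anchor's mean shortest distance to the reachable partners
(empty-reach replicates are flagged and excluded). Anchors are drawn from
network nodes, not an external genome list, since distances are only
defined for nodes. The 20-partner choice mirrors testing a ~21-gene locus:
each anchor plays the role of one gene of a random 21-gene set.

**Tests.** Set-level: one-tailed Mann-Whitney (alternative: distances
stochastically smaller, i.e. the set is more connected) of the set's
per-gene mean distances against the null replicate means. Gene-level: the
gene's mean distance is ranked within the null replicate means — the exact
single-observation Mann-Whitney test, equivalent to an empirical
percentile, with smallest attainable p equal to 1/(#null + 1). The
gene-level statistic deliberately uses the mean rather than the gene's raw
pairwise distances: the raw distances all share the query gene and are
strongly correlated, so a many-sample rank test against the null is heavily
overdispersed and flags ordinary degree heterogeneity (simulation on
module-free networks shows per-seed false-flag rates of tens of percent for
the raw-distance variant, versus calibrated behavior for the mean-rank
test). BH correction is applied across all tests emitted in one report, and
a gene or set is flagged at q < 0.05. Simulations with a 15-gene module
planted at 5× weights in a 500-gene background recover all module genes in
every seed while flagging ~2% of random probe genes.

## Overlap enrichment

Observed overlap is the number of candidate genes present in the universe
and annotated; candidates absent from the universe are counted separately,
never silently dropped. Symbols are normalized by uppercasing and stripping
whitespace only — alias resolution is a data-curation problem outside this
package. The null draws `n_sim` (default 100,000) uniform same-size gene
sets without replacement (vectorized as the k smallest of N iid uniform
keys, chunked to bound memory) and records annotated counts; the summary
reports min/mean/max and percentiles. The empirical p-value is the
inclusive upper tail #{sim ≥ observed}/n_sim, with no pseudo-count; a zero
tail is reported as the bound p < 1/n_sim rather than a literal zero.
Inclusive ≥ is a documented convention, not an inference about any
particular prior analysis. The simulated tail converges to the
hypergeometric survival function, and with null-drawn candidates the
p-values are super-uniform (measured type-I error at α = 0.05 ≈ 0.035-0.045
at n_sim = 2,000; the shortfall from 0.05 is the expected discreteness of
the count support). Fisher's exact test on 2×2 tables (two-sided by
summing hypergeometric probabilities at most that of the observed table;
odds ratio ad/bc with 0/∞ conventions) supports contingency-style
companions to the Monte-Carlo test.

## Statistical primitives

Mann-Whitney U uses midranks; p-values come from full enumeration of rank
splits when both samples have ≤ 10 observations and no ties are present
(≤ 184,756 arrangements — instant, and bit-exact against a brute-force
oracle), from direct enumeration of the singleton's insertion position when
one sample has a single observation (the normal approximation's smallest
attainable p at n = 1 is ~0.04 regardless of the other sample's size), and
otherwise from a normal approximation with tie correction and continuity
correction. One-tailed directions follow the stochastic-ordering
convention. BH adjustment is the standard step-up q(i) = min over j ≥ i of
m·p(j)/j, capped at 1; note that a second application is only a no-op on
flat (fully-adjusted) families. ΔΔCt relative expression is 2^(−ΔΔCt) with
ΔΔCt = (Ct_target,test − Ct_ref,test) − (Ct_target,control −
Ct_ref,control), invariant to a constant shift of all four cycle values.

## Synthetic-data generators

All generators are pure functions of their spec (seed included): identical
inputs give bit-identical outputs.

*Eye images.* Hexagonal lattice as offset rows (row pitch spacing·√3/2,
alternate rows shifted spacing/2), so interior six-neighbor geometry is
exact. Defaults: 10×10 sites, spacing 20 px, blob σ 2.5 px (spacing must
exceed 4σ for blobs to be resolvable), additive Gaussian blobs at 75% of
full scale over an 8% background pedestal, sensor noise σ 2 intensity
units, 8-bit output. Dropout removes a deterministic round(f·n) of
uniformly chosen sites so exact-count assertions hold. Necrotic disks are
burned in last at intensity 0; the nonzero background pedestal is what
makes their thresholded area analytically recoverable. The Gaussian-blob
profile is a stand-in, not a claim about imaging physics: no lens
vignetting, bristle/cone substructure, specular highlights, or z-stack
artifacts are modeled, so passing tests demonstrate correctness of the
geometry and scoring pipeline, not robustness to every real-microscopy
nuisance.

*Networks.* Erdős–Rényi background (default 500 genes, edge probability
0.05 — dense enough that a 500-anchor null is connected, sparse enough that
module structure matters) with weights 10⁻³ + Exponential(mean 1); the
heavy-ish tail makes top-fraction thresholding meaningful. The planted
module is an intra-module clique whose weights are background draws × the
multiplier: presence of all internal edges is what makes the module a
recoverable ground truth, the weight law is unchanged (multiplier 1 is
statistically indistinguishable from background), and edges outside the
module are never altered. Real interaction networks have heavy-tailed
degree distributions and correlated edge confidences that this generator
does not emulate.

*Universes.* Independent per-gene annotation at a base rate (default
18,000 genes, 10% annotated — a genome-scale universe with an
apoptosis-sized annotation class), with a candidate set (default 756 genes)
drawn without replacement whose annotation rate is multiplied by an
enrichment factor (default 1.5). Real annotation sets are correlated
through pathway structure; the independence assumption is what makes the
hypergeometric reference exact.

## Pipeline

Stages are configured in TOML and run in dependency order (generation
before analysis) after validating the schema and every referenced input
path. Per-stage sub-seeds are SHA-256 hashes of (global seed, stage name),
so adding or reordering stages never perturbs another stage's randomness.
Each run writes a manifest with parameters, sub-seeds, package version, and
SHA-256 checksums of every output; identical config + seed reproduces
byte-identical outputs.

## Problem sizes used in the checks

The test suite and `scripts/acceptance.py` run at desk scale: 10×10-site
eye images with 20 seeds per condition; 500-gene networks (600 for the
null-size contract) with nulls of 300 anchors × 50 replicates in the
repeated recovery simulations and the full 500 × 100 default where the
contract itself is asserted; overlap calibration with a 2,000-gene universe,
1,000 repeats at n_sim = 2,000, and genome-scale single runs at 18,000
genes with n_sim = 100,000. Exact-oracle checks enumerate graphs of ≤ 8
nodes, rank splits with both samples ≤ 8, and 2×2 tables with totals ≤ 30.

## Known limitations

- Absolute composite-score magnitudes are not comparable to any external
  scoring tool: the combination rule here (distance OD + angle OD, counts
  reported separately) is this package's own fixed convention, and only
  orderings, zero limits, and monotonicity are meaningful.
- The reciprocal weight→length transform is a convention; analyses on real
  networks should check sensitivity to the transform choice.
- Gene-level connectivity flags are conditional on the supplied network;
  degree heterogeneity in real networks means "more connected than random
  genes" is a property of the gene's neighborhood, not evidence of a
  specific pathway.
- The overlap module treats the universe as an explicit input and performs
  no alias resolution or annotation harvesting.
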