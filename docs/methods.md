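# Methods

This note documents the models implemented in `cphylo`, the defaults
they ship with, what the synthetic-data generators do and do not
emulate, and the numerical choices a user may want to audit.

## Grids, records, and conventions

Climate layers are ESRI ASCII grids on a regular WGS84 lon/lat raster
(the study system works at 0.5°; no projections are supported).  Pixel
assignment is half-open — a point belongs to column
`floor((x − x_origin)/cell)` and row `floor((y_top − y)/cell)` — so
points on the east/south outer edge are out of bounds; this makes
one-record-per-pixel thinning unambiguous and idempotent.  Thinning
keeps the first record per cell in input order (the original study does
not state which record was kept; this is our convention).  All
stochastic stages draw their generator from a stage-named sub-seed of
the run seed.

## Ensemble distribution modeling

The ensemble logic, not any individual learner, is the object of
interest.  Three reference learners satisfy the learner contract
(climate vector → suitability in [0, 1]):

* **envelope** — per-variable [5, 95] percentile box; suitability 1
  inside, decaying linearly to 0 over one inter-percentile width
  outside (the decay width is a documented constant).  Deliberately
  coarse; its flat interior caps its AUC on correlated predictors.
* **mahalanobis** — distance to the presence centroid under the
  presence covariance, mapped to suitability by exp(−d²/2) (1 at the
  centroid).
* **logistic** — weighted binomial GLM on linear terms, fitted by
  iteratively reweighted least squares, with background records
  down-weighted by n_presence/n_background so both classes carry equal
  total weight.

Learners are gated by mean verification AUC (rank-based with midranks)
over ten seeded 70/30 splits stratified by class; the 0.7 cutoff and
final refit on 100% of records follow standard ensemble practice.
Binary maps come from two threshold rules — the lowest cutoff with
|sensitivity − specificity| minimal, and the mean background
probability — so each retained learner casts 2 votes per
circulation-model replicate per time slice; vote counts are
data-driven, not hard-coded.  A refugium is a pixel whose vote
percentage clears the stability level (50 or 75%) in *all four* time
slices and that is not under the glacial ice mask.  Predictor pruning
is greedy by descending importance with a Spearman |ρ| ≤ 0.7 rule
against everything already kept; the importance score is pluggable.

## DEC range evolution

Ranges are nonempty subsets of six candidate refugia (Beringia,
Olympics, North/South Cascades, Central/Southern Rockies) with at most
two areas (21 living states plus an absorbing extinct state; state 0 is
the empty range, living states follow in (size, lexicographic) order).
Anagenesis: area `a` is gained at rate `d · Σ_{b∈R} M[b,a]` and each
occupied area lost at rate `e`.  Cladogenesis enumerates, for a
widespread range, vicariance and subset-sympatry ordered daughter
pairs with uniform weights — 6 scenarios at 1/6 for |R| = 2 (the
convention is fixed here because published descriptions are ambiguous
about ordered-pair counting).

**Time units.** Everything in the module is kiloyears before present;
rates are per KY.  Published DEC rates for this clade (≈ 0.005) are
only dimensionally consistent with a kiloyear-scaled tree even where
they are labeled per year, so the package standardizes on KY and
provides a `time_scale` argument for year-scaled trees.

**Epochs.** The default table marks 0–14 KYA as present-connectivity
interglacial, 115–130, 190–245, 320–340 and 405–425 KYA as
last-interglacial-connectivity interglacials, everything else
(extended to the root age) as glacial.  Glacial epochs disconnect the
northern refugium from everything south of the ice; older interglacials
disconnect the coastal ranges from the Rockies.  Both the boundaries
and the connectivity edits are documented package defaults, not data.
The refugium adjacency list ships as an editable CSV.

**Likelihood.** Per-branch transition matrices are products of
`expm(Q_epoch · Δt)` over the epoch segments spanned by the branch,
oldest first (scaling-and-squaring `expm`; verified against a
Runge–Kutta integration of the forward equation to < 10⁻⁸).  Tip
indicator vectors are combined postorder through the cladogenesis
table; the root likelihood averages over living states with uniform
weights.  Full-epoch exponentials are cached across branches, which is
what makes ML fitting (bounded Powell on log rates in [10⁻¹⁰, 10],
two starts, tolerance 10⁻⁸ by default) run in seconds on 50-tip trees.
Root-range profiles report per-state −ln L within 2 units of the best.

**Forward simulation and its bias.** The generator evolves ranges by
Gillespie simulation with the epoch in force at each moment and
restarts the whole tree when any lineage goes extinct, reporting the
restart count.  Because the DEC likelihood does not condition on
survival, this rejection step biases simulated datasets toward fewer
extinctions.  At the recovery-study conditions (d = 0.005, e = 0.001
per KY, 50-tip Yule trees with ≈ 1030 KY roots matching the study
clade's branch scale) only ~1 simulation in 150 survives, and the
profile likelihood in e is flat to within ~2 units from 10⁻⁸ to
3×10⁻⁴: dispersal is recovered well (median d̂ ≈ 0.9× truth over 20
replicates) but extinction collapses toward zero (median ê ≈ 3×10⁻⁵).
This is the well-documented weak identifiability of DEC extinction
compounded by survival conditioning; we report it rather than
adjusting the study conditions, and the corresponding recovery check
fails honestly on the extinction rate.  Hypothesis *ranking* is robust:
data simulated under northward-only dispersal rank the northward
scenario first in 20/20 replicates.

## Niche overlap

Background climate is standardized and decomposed by PCA (deterministic
sign convention: the largest-magnitude loading of each axis is
positive).  Occurrence and background densities are separable Gaussian
KDEs on a 100×100 grid spanning the background's PC1/PC2 extent, with
per-axis Silverman bandwidths estimated from the background and shared
by both densities (an explicit bandwidth override exists; note literal
e-scale invariance of z = o/e only holds at fixed bandwidth, because
Silverman's rule depends on n).  Occupancy is z = o/e where background
density exceeds 10⁻⁶ of its peak, renormalized to sum 1; overlap is
Schoener's D.  Equivalency re-splits the pooled occurrences without
replacement; similarity redraws one species' points with replacement
from its background availability (grid-translation nulls are not
implemented; availability resampling is our documented choice).  Both
use two-sided add-one p-values `min(1, 2(1 + k)/(1 + reps))`, whose
attainable floor at 100 repetitions is 2/101 = 0.0198 and whose values
form an even-multiples-of-1/101 lattice.

## Sequence statistics

Sites containing any gap or N are removed listwise before anything is
computed, so n, S, h, θ_S = S/(a₁L) and π share one site set.
Tajima's D uses the 1989 constants; Fu & Li's D* and F* use the
no-outgroup star constants with singletons defined as minor-allele
count 1.  The constants were validated by simulation: the null means of
all three statistics sit near zero (D in [−0.3, 0.1], its known slight
negative bias).  Significance comes from Kingman-coalescent samples of
the same n conditioned on the observed S (fixed-S mode; a θ-mode
exists but is not the default since the empirical statistics condition
on S), with two-tailed add-one p-values.  The calibration check uses
199 null repetitions per dataset, which makes the discrete test
essentially exact at α = 0.05.

## Chronograms and rates

Ages are `height/μ × generation_time` with μ in
substitutions/site/generation; defaults cover the plant autosomal rate
7.1×10⁻⁹ ± 0.7 and the noncoding rate 1.5×10⁻⁸ ± 0.5, generation time
2 years.  Rate error brackets an age as `age·μ/(μ+σ)` to
`age·μ/(μ−σ)`; reported kiloyears round half-up (sources mix rounding
conventions for half values, e.g. 461 vs 462 for 461.5; we use
half-up consistently).  The packaged chronogram fixture encodes the
published crown ages (1030, 560, 510, 386, 240 KY); the two internal
nodes joining the three subclades are unpublished and set to 770 KY as
a labeled assumption, as is the taxon × refugium range matrix.

## Morphometrics

The classification tree splits on categorical subset membership,
greedily maximizing Gini decrease, with ties broken by column order
then lexicographically smallest subset; stopping defaults (min leaf 5,
min split 10, minimum gain 1% of root Gini) mirror common tree-package
defaults.  Unseen levels at prediction time route to the complement
branch.  LDA is classical Fisher discriminant analysis: generalized
eigenvectors of the between/within scatter, coefficients normalized to
unit pooled within-class variance with the largest coefficient
positive, proportion of trace = eigenvalue share (cross-checked
against scikit-learn's eigen solver); a singular within-scatter gets a
10⁻⁸-scale ridge and a warning.  Log₁₀ transforms apply to the six
skewed length characters; non-positive draws in a log column are
clipped to the column's smallest positive value with a warning (an
artifact of sampling unbounded normals for strictly positive lengths).

## What the generators emulate — and what they don't

Synthetic climate is a shared latitudinal gradient plus low-pass
Gaussian noise mixed to a requested correlation; real climate has
anisotropic topographic structure the generator does not attempt.
Occurrences are drawn proportional to a logistic suitability with no
sampling bias, so tests of model recovery say nothing about spatially
biased herbarium collections.  Morphology draws characters
independently (the source gives only per-taxon means/SDs, no
correlations), so discriminant coefficients are comparable only in
aggregate (share of trace), not entry-by-entry.  The coalescent is
neutral, panmictic and recombination-free.  Note the categorical
morphology source table has a misaligned lower block; the shipped
reconstruction (including an invented seed row for *C. scouleri*) is
clearly labeled and documented in `cphylo.datasets`.

## Problem sizes

Default test and reproduction runs use 40×50-cell climate grids,
100–150 occurrence records per species, 100 randomization repetitions,
1000-replicate neutrality nulls (199 inside the calibration loop),
and 20-replicate simulation studies on 20–50-tip trees — sizes at
which every stage completes in seconds to a few minutes on one core
while keeping Monte-Carlo error well inside the asserted tolerances.
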