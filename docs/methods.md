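# Methods

This note documents the statistical procedures, defaults and design
choices behind each stage, and what the synthetic cohort generator does
and does not emulate.

## Data model and preprocessing

A `FeatureTable` is a nonnegative abundance matrix (features × samples)
tagged with a modality (metabolite or lipid) and a normalization state.
`SampleMeta` carries age (years), sex (F/M) and an ordered life-stage
group. Default group boundaries, configurable: newborn = age exactly 0
(cord blood), early childhood (0, 6), middle childhood [6, 12),
adolescence [12, 19), early adulthood [19, 40), middle adulthood
[40, 65), late adulthood ≥ 65. The 65/40 cut-offs are reused by the
elderly-vs-young classification task.

**Normalization.** Total-sum normalization divides each sample column by
its total so columns sum to 1; it is idempotent and the primary method.
Median-ratio normalization divides each column by its median over *all*
values, zeros included; when that median is 0 (heavily zero-inflated
samples) the median of the nonzero values is used instead — the all-value
median is the natural statistic but is fragile under zero inflation, so
the fallback keeps the operation total. Zeros pass through normalization
unchanged: no pseudo-count is added, which keeps normalization linear; log
transforms downstream add an offset instead.

**Log transforms.** Statistical stages work on `log10(x + offset)` (log2
for PCA/PVCA, matching common display conventions). The default offset is
half the smallest positive value in the table — small relative to real
intensities, so it only regularizes exact zeros. On fixtures without
zeros the offset can be set to 0 explicitly; a non-negligible offset
compresses the low end of the scale and attenuates negative slopes.

**Filtering.** The nonzero filter keeps features whose nonzero fraction
*strictly exceeds* the threshold (default 0.5) in at least one group; a
feature nonzero in exactly half of every group is dropped. The QC filter
keeps features with QC coefficient of variation strictly below 0.3
(sd/mean over pooled-QC replicate columns, ddof = 1; zero-mean features
are flagged undefined and dropped). Both filters emit drop reports and
commute with each other. A no-op batch-correction hook preserves the
signature through which an externally corrected table (e.g. QC-anchored
support-vector regression) can be injected.

## Differential profiling

Two-group comparisons use a two-sided t test on the log10 scale. The
Welch (unequal-variance) form is the default: variances across life-stage
groups are plainly unequal, and Welch is the safer test under that
heterogeneity; a pooled-variance switch is available for strict
textbook-t behaviour. P-values are Benjamini–Hochberg adjusted across all
features *within one comparison* (not across comparisons), and features
are called up/down at q < 0.05. Zero-variance features with equal means
have an undefined statistic and are flagged non-significant rather than
crashing.

Newborn contrasts run newborn-vs-each-other-group and report upset-style
intersection counts of the significant sets. Group markers use a
pooled-rest comparison — feature significantly up in group g versus all
remaining samples pooled — plus the requirement that g holds the feature's
maximal group mean; pooled-rest is more stable than requiring all pairwise
wins, and the maximal-mean condition enforces specificity.

The class-level change score is defined here as
(n_up − n_down) / n_class over a feature → class map, bounded in [−1, 1]
and reported with the class size. This formula is this package's own
operationalization of a directional class summary; the literature uses
several variants and none is canonical.

Pathway over-representation is the one-sided hypergeometric tail
P[overlap ≥ observed] over a local GMT collection, with pathways smaller
than 2 members (after restriction to the analysis universe) untested and
BH adjustment across tested pathways. Members outside the universe are
dropped with a warning.

**Compositional caveat.** Total-sum normalization couples features: a
block of strongly elevated features in one group deflates every other
feature in that group's samples, which can make null features appear
significant in extreme fixtures where markers dominate the column totals.
With realistic marker fractions (a few percent of features) the effect is
negligible, but tests of marker stability across normalizations are
restricted to the engineered markers for this reason.

## Age-trajectory modelling

**Linear.** Per feature, ordinary least squares of log10 abundance on age
with a binary sex covariate and no interaction. The age term is tested
with a Type-II F test; in this additive two-covariate model that is
exactly the squared t of the age coefficient, which is what the
vectorized implementation computes. BH adjustment runs across the
non-degenerate features; zero-variance features are excluded from the
family.

**LOESS.** Locally weighted polynomial regression, degree 2, tricube
weights over the nearest `ceil(span·n)` neighbours, span 0.75 by default,
evaluated on a 50-point age grid inside the observed range. Because the
fitted value at a grid point is linear in the responses, the smoother
matrix is built once from the ages and applied to all features as one
matrix product. Curves are z-scored over the grid before clustering;
flat curves are excluded and reported. Span, degree and the
standardization rule are package choices.

**Trajectory clustering.** Agglomerative clustering (Euclidean distance,
complete linkage by default; ward/average available) of the standardized
curves, cut at k = 8 clusters by default. Identical curves collapse the
tree; the cut refuses to fabricate k clusters in that case and raises.
Cluster means over members give the archetype curves.

**DE-SWAN.** For each center age c, the young stratum is ages in
[c − w/2, c) and the old stratum (c, c + w/2]; samples at exactly c
belong to neither (the half-open convention is asserted by test). Each
feature is fit by OLS of log10 abundance on the stratum indicator plus
sex; the stratum term's p-values are BH-adjusted within the center and
`n_sig` counts q < 0.05. Centers default to 1-year steps across the
observed range; centers with fewer than 3 samples on either side are
skipped and recorded. The headline window is 20 years (±10); a 5-year
(±2.5) variant is a config knob — both readings of "5-year intervals
across a 20-year window" are exposed rather than silently reconciled.
Peak calling is deterministic: a center is a peak iff its count is
maximal within ±5 years (plateaus collapse to their first center) and
exceeds the curve's median by at least twice the median absolute
deviation.

## Lipid structure

The parser accepts `CLASS(C1:D1/.../Cn:Dn)` with optional whitespace and
an optional sphingoid `d`/`t` prefix, which is recorded but does not
change carbon counting. Saturation is a total function of the double-bond
count: S at 0, MU at exactly 1, PU at ≥ 2.

The chain-length × saturation matrix defaults to *per-chain* attribution:
a species contributes its group-summed intensity once per distinct chain
length it contains, classified by that chain's own double bonds —
matching chain-resolved displays. A per-species mode (one contribution at
total carbons, classified by total double bonds) is available; under it
the matrix total equals the class total intensity.

PU:S ratios are computed per sample (sum of PU intensities over sum of S
intensities, species-level classification) and then averaged within each
life-stage group with SEM — the per-sample form matches replicate-level
reporting and is invariant to per-sample rescaling, unlike pooled sums
under unequal group sizes. Samples with zero saturated total are flagged
infinite and excluded from the group mean with a count.

## Variance decomposition and networks

PCA runs on log2, feature-centered data via SVD; constant features are
dropped with a warning.

PVCA retains PCs up to 60% cumulative explained variance (configurable),
treats age as the categorical life-stage group (a continuous covariate
cannot enter a classical variance-component decomposition), and fits, per
retained PC, a mixed model with random intercepts for age, sex and
age×sex under REML with non-negativity. Convergence is policed strictly —
any optimizer convergence warning rejects the fit, because boundary
estimates for a two-level factor (sex) can otherwise pass through
arbitrarily inflated. On rejection a method-of-moments fallback is used
and logged: the classical one-way ANOVA component (MSB − MSW)/n₀, clipped
at zero, per main factor; the combined-factor component net of the main
effects for the interaction; the within-cell mean square as residual.
Per-PC fractions are normalized, averaged with eigenvalue weights, and
re-normalized to sum to 1.

The metabolite–lipid network takes the top 50 features per side with the
largest |age slope| among those with q_age < 0.05, scores all cross-pairs
with Spearman's rank correlation (average ranks for ties) on shared
samples, and keeps edges with |rho| > 0.5 and p < 0.05, annotated with
both endpoints' slopes. Output is an edge list and GraphML.

## Aging clocks and biomarker panel

**Full clock.** Features (metabolite, lipid, or both tables concatenated
on shared samples with a modality tag) are log10-transformed. For every
(α, training fraction) pair — defaults α ∈ {0.1, 0.3, 0.5, 0.7, 0.9},
fractions {0.5, 0.6, 0.7, 0.8} — the cohort is split train/test
stratified by life-stage group, λ is selected by 10-fold CV on the
training split over a 20-point log-spaced grid from λ_max (the smallest
λ zeroing all coefficients) down three decades, and MAE is measured on
the held-out test split; the smallest test MAE wins. Features are
standardized to zero mean/unit variance inside every fit, so predictions
are invariant to per-feature affine rescaling of the log design. All
randomness derives from one seed; identical inputs and seed give
identical coefficients.

A note on the mixing grid: with many more features than samples, heavily
ridge-weighted mixes (small α) spread weight across noise features and
can bury even a perfect predictor, while sparse mixes isolate it — which
is why model selection over the full α range matters and why the sparse
end of the grid typically wins on cohorts with few informative features.

**Reduced clock.** Features with nonzero coefficients are ranked by
absolute standardized coefficient — the fitted model's own measure of
contribution (ranking by univariate age correlation is a config switch).
Clocks are refit on the top 2, 3, … features at an 80% training fraction,
recording test-split Pearson r by default (MAE optional). A two-segment
continuous broken-stick regression (grid search over the knot, least
squares per candidate) locates the point of diminishing returns; the
breakpoint is the knot rounded to the nearest size, and the final model
is refit there. Fits where the two-segment model barely improves on a
single line are flagged low-confidence.

**Panel.** Three selection criteria are intersected: (1) significantly up
in the elderly, computed as the ≥ 65 vs < 40 years contrast to mirror the
classifier's classes; (2) q_age < 0.05 with positive age slope; (3)
nonzero clock coefficient. The intersection feeds an L2-penalized
logistic classifier of elderly vs young (middle-aged samples excluded),
evaluated by stratified 10-fold cross-validated ROC with per-fold
standardization; the fold count drops with a warning when the smaller
class is small.

## Pipeline

`run_pipeline` executes simulate → normalize → de → trajectories →
deswan → lipids → pvca → network → clock → panel in dependency order,
refusing a stage whose upstream dependency is toggled off. One global
seed derives per-stage seeds via SHA-256 of "seed:stage", so toggling one
stage never shifts another's randomness. All tables are written with
fixed column order and 12-significant-digit formatting; identical config
and seed give byte-identical output trees. The manifest records stage
outputs with SHA-256 digests, the seed and package version.

## Synthetic cohort: what it emulates and what it does not

The generator draws 136 subjects by default — 16 cord-blood newborns at
age exactly 0 and 20 subjects per post-natal group, ages uniform within
the group boundaries — with Bernoulli(0.5) sex. Feature abundance is
`base_level · exp(trajectory(age) + sex_delta·[male] + N(0, σ))` with
σ = 0.2 by default (a mid-range biological coefficient of variation for
plasma features) and 2% missing-at-random zeros. Trajectory kinds: null;
linear (log-slope β per year, defaults ±0.005 to ±0.02 — 0.5–2% yearly
change, the magnitude a cohort of this size resolves); Gaussian peaks in
log space (the minimal generator of crest-shaped LOESS archetypes);
steps; and group markers. The default mixture is 200 null, 60 linear, 30
peak, 30 step and 3 markers per group. The lipid panel names its features
in parseable shorthand across 27 classes; saturated SPH species carry a
newborn marker (emulating elevated saturated sphingoid bases in cord
blood), and polyunsaturated TG/PE (up) and PC/PI (down) species carry
balanced ±0.01 linear trends so that individual lipids age-trend — giving
the lipid age models and the cross-modality network real endpoints —
while the aggregate PU:S ratio stays near-level across groups once SPH is
excluded.

One global seed spawns an independent substream per feature and one for
the subjects, so adding feature blocks never perturbs existing data.

Deliberately *not* emulated: instrument drift and batch structure,
realistic metabolite correlation blocks beyond what shared trajectories
induce, heavy-tailed intensity distributions, informative missingness,
and cord-blood vs venous-blood matrix effects. Passing tests therefore
demonstrate the statistical machinery's correctness and calibration under
a clean generative model, not robustness to those real-data phenomena.
Statistical-calibration fixtures (type-I error of the linear model and
DE-SWAN) set zero inflation to 0, since point masses at zero violate the
normality the t-based calibration check presumes.

## Numerical choices and degenerate inputs

- BH adjustment: standard step-up, order-preserving, capped at 1.
- t tests with zero variance in both groups: statistic undefined, flagged
  degenerate, excluded from the BH family.
- LOESS with duplicate ages (all newborns at 0): the bandwidth guard
  replaces a zero kth-distance with a tiny positive value; rank-deficient
  local fits fall back to least-squares pseudo-inverse behaviour.
- Broken-stick fits need ≥ 4 points; flat curves are flagged rather than
  assigned a meaningful knot.
- PVCA with a single-level factor: that factor's fraction is 0 with a
  warning; an all-zero decomposition falls back to residual = 1.
- Elastic-net λ grids are computed from the standardized training design;
  the grid floor λ_max·10⁻³ bounds run time without touching the CV
  optimum in practice.

## Problem sizes in tests and the acceptance script

Test fixtures use the cohort at its study scale (136 subjects) with
feature counts of 100–1000 per check, and the clock-recovery check uses
150 subjects × 500 features with 30 informative; the end-to-end
determinism check runs the full pipeline at a reduced feature count
(~60 metabolites) with a trimmed clock grid. The acceptance script runs
the complete default-scale pipeline (339 metabolites and 194 lipids
after filtering, 136 subjects). These sizes were chosen so the entire
suite and script run comfortably on a single CPU while keeping every
statistical check at the sample size that makes it meaningful.

## Known limitations

- The change-score formula is a package definition, not a community
  standard; compare across datasets only within this package.
- PVCA's age binning inherits the life-stage groups; finer binning would
  shift fractions.
- The reduced clock's accuracy curve is computed on a single fixed test
  split; very small cohorts give noisy curves and low-confidence knots.
- DE-SWAN centers near the age range's ends lose one stratum and are
  skipped; peaks within half a window of the boundary are therefore not
  observable.
- The elderly-up contrast for panel selection fixes the comparator at
  < 40 years; other comparators (e.g. all non-elderly) would change set 1.
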