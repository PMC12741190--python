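# lifespanomics

Analysis toolkit for untargeted plasma metabolomics and lipidomics across
the human lifespan: from a features × samples abundance table and per-sample
age/sex annotations, it quantifies how the plasma metabolome and lipidome
reorganize from birth to late adulthood and distils that signal into an
elastic-net "aging clock" and a compact biomarker panel.

It is aimed at computational biologists working with cross-sectional omics
cohorts — the kind of study that profiles ~10²–10³ subjects binned into
life-stage groups (newborn, early/middle childhood, adolescence,
early/middle/late adulthood) — and covers the full downstream path:

- **Tables & preprocessing** — total-sum and median-ratio normalization,
  group-wise nonzero filtering, QC coefficient-of-variation filtering
  (`core_tables`).
- **Differential profiling** — Welch t tests between life-stage groups with
  Benjamini–Hochberg FDR control, newborn-versus-all contrasts with
  upset-style intersection counts, per-group marker discovery, class-level
  change scores, and GMT-based hypergeometric pathway over-representation
  (`differential`).
- **Age trajectories** — per-feature linear models
  `log10 x ~ α + β₁·age + β₂·sex` with an F test on the age term; LOESS
  curves hierarchically clustered into trajectory archetypes; and DE-SWAN
  (differential-expression sliding-window analysis), which counts
  significant features in age windows sliding across the lifespan and
  calls the peak ages of metabolic change (`trajectory`).
- **Lipid structure** — a parser for shorthand such as `TG(16:0/18:1/18:2)`
  or `SPH(d18:0)`, chain-length × saturation summaries, and
  polyunsaturated : saturated (PU:S) intensity ratios per life-stage group
  (`lipids`).
- **Variance & networks** — PCA, principal variance component analysis
  (PVCA) attributing variance to age, sex, age×sex and residual, and
  Spearman correlation networks linking the top age-associated metabolites
  and lipids (`variance`).
- **Aging clocks** — elastic-net chronological-age prediction with model
  selection over the L1/L2 mixing parameter, training fraction and
  cross-validated penalty; broken-stick model reduction down to a handful
  of features; and a triple-intersection biomarker panel scored by
  cross-validated ROC for separating the elderly (≥ 65 y) from the young
  (< 40 y) (`clock`).
- **Synthetic cohorts** — a generator producing age/sex-annotated tables
  with known ground truth (null, linear, peaked, step-change and
  group-marker trajectories under log-normal noise and zero inflation), so
  every stage is testable end to end without external data (`synthetic`).

## The clock in brief

Given log-transformed abundances X (samples × features, standardized) and
chronological ages y, the clock solves

    min_β  1/(2n) ‖y − Xβ‖² + λ (α‖β‖₁ + (1−α)/2 ‖β‖²)

for a grid of mixing parameters α ∈ [0.1, 0.9] and training fractions
≥ 0.5; λ is picked by 10-fold cross-validation on the training split and
the (α, fraction, λ) triple with the smallest held-out mean absolute error
(MAE, in years) is kept. The reduced clock ranks the selected features by
|β| (standardized), refits on the top 2, 3, 4, … features, and fits a
two-segment broken-stick regression to the accuracy-versus-size curve; the
knot is the reduced model size.

## Worked example

```python
from lifespanomics import total_sum_normalize
from lifespanomics.synthetic import (CohortConfig, default_specs,
                                     simulate_cohort, simulate_lipid_panel)
from lifespanomics.trajectory import deswan
from lifespanomics.clock import fit_clock

cfg = CohortConfig(seed=1)                       # 136 subjects, ages 0-84
metab, meta, truth = simulate_cohort(cfg, default_specs())
lipid, _, _ = simulate_lipid_panel(cfg)
metab_n, lipid_n = total_sum_normalize(metab), total_sum_normalize(lipid)

curve = deswan(metab_n, meta, window=20)
print("DE-SWAN peaks (metabolome):", curve.peaks)

clock = fit_clock([metab_n, lipid_n], meta, alpha_grid=(0.1, 0.5, 0.9),
                  train_fractions=(0.7,), seed=1)
print(clock.summary())
```

prints

```
DE-SWAN peaks (metabolome): [12.0, 67.0]
Aging clock (elastic net)
  features in design    : 533
  nonzero coefficients  : 335
  alpha (L1 mixing)     : 0.1
  lambda (penalty)      : 0.485872
  train fraction        : 0.7
  test MAE (years)      : 3.724
  test Pearson r        : 0.984
  top coefficients (standardized):
    linear_0057                              -0.8473
    TG(16:0/18:1/18:2)                       +0.8056
    ...
```

The DE-SWAN peaks at ages 12 and 67 are the centers where the most
features differ between the younger and older halves of a 20-year window —
here driven by the generator's step/peak trajectories around ages 10 and
65. The clock predicts chronological age on the held-out test split to
within 3.7 years on average (Pearson r = 0.98), mixing metabolite and lipid
features; coefficients are on the standardized scale, so their magnitudes
are comparable across features.

The same analysis runs end to end from the shell:

```bash
lifespanomics run-all --seed 1 --outdir results_run
```

writing every stage's tables, the clock JSON, and a manifest with SHA-256
digests; identical seeds give byte-identical outputs.

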