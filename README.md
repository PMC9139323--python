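# assayval

Statistics for the analytical validation of quantitative clinical assays:
detection capability (LoB/LoD/LoQ), linearity, nested precision,
Passing-Bablok trueness, storage stability, and two-stage interference
evaluation — as a tested Python library with a thin CLI, plus synthetic
study generators that reproduce the standard experimental designs so every
stage can be exercised end to end without external data.

It is written for laboratory statisticians and assay developers running
CLSI-style validation programs, with the metabolite-panel/GFR-score setting
(serum creatinine, valine, myo-inositol in µmol/L; scores in
mL/min/1.73 m²) as the motivating use case.

## What it computes

**Detection capability.** From pooled blank-pool results,
LoB = x̄_B + z₀.₉₅·s_B (parametric) or the interpolated order statistic at
rank 0.5 + B·0.95 (nonparametric, auto-selected by a Shapiro-Wilk gate).
Low-level pool variances are checked for homogeneity with Cochran's C
(C = s²_max / Σs²ᵢ against the F-based critical value); if homogeneous,
LoD = LoB + c_p·SD_pooled with c_p = z₀.₉₅/(1 − 1/(4f)); otherwise the
nonparametric variant takes the lowest pool mean with ≥ 95% of results
above LoB. LoQ is, per reagent lot, the minimum pool mean whose
within-laboratory CV is below 20%, and overall the maximum over lots.

**Linearity.** OLS polynomial hierarchy y = b₀+b₁x, +b₂x², +b₃x³ on all
replicate points of an 11-level intermixture series, t-tests on b₂/b₃, and
— when a nonlinear term is significant — the degree of nonlinearity
max|ŷ_nonlin − ŷ_lin|/|ŷ_lin|·100 evaluated at the assigned levels. The
composite verdict requires r ≥ 0.95, per-level repeatability CV < 15%,
≤ 15% missing per level, ≥ 5 consecutive passing levels, and either no
significant nonlinear term or a degree < 10%; the top of the longest
passing stretch is the upper limit of the linear range (LoL).

**Precision.** Method-of-moments nested ANOVA. Single site
(day > run > replicate): σ²_rep = MS_error, σ²_run = (MS_run − MS_error)/n_rep,
σ²_day = (MS_day − MS_run)/(n_rep·n_run), negative estimates truncated to 0,
all expressed as CV% of the pool mean; within-laboratory
CV = √(CV²_rep + CV²_run + CV²_day). Multi site (site > day > replicate,
one run/day) analogously, with reproducibility = √(CV²_within-lab + CV²_site).

**Trueness.** Passing-Bablok regression (shifted median of pairwise slopes
with the classical −1-exclusion and K-offset conventions, rank-based CIs)
plus per-analyte acceptance (|slope − 1| ≤ 0.15 for creatinine and
myo-inositol, ≤ 0.075 for valine; r ≥ 0.90), and spike-recovery analysis
for analytes without a reference method.

**Stability.** Per-donor OLS of the measurand on storage time; duration =
earliest crossing of the one-sided 95% pointwise confidence band with the
±10% drift limits anchored at the baseline mean, or the study horizon when
the slope is not significant or no crossing occurs.

**Interference.** Worst-case screen (10 spiked vs 10 control aliquots per
serum pool): flagged when |mean relative bias| > 10% or more than 10% of
test results are lost; flagged substances go to a 5-level dose-response
(0/25/50/75/100% spikes) that confirms interference and localizes the
lowest tripping concentration.

## Worked example

Simulate and evaluate the standard single-site precision design
(4 serum pools × 20 days × 2 runs/day × 3 replicates = 480 measurements)
with known generating components:

```bash
assayval precision --config precision.yaml
```

with `precision.yaml`:

```yaml
study_kind: precision_single
seed: 7
simulate:
  pools:
    - {pool_id: P1, true_mean: 53.5, cv_repeatability: 2.8, cv_between_run: 1.3, cv_between_day: 2.4}
    - {pool_id: P2, true_mean: 55.4, cv_repeatability: 2.9, cv_between_run: 1.8, cv_between_day: 0.0}
    - {pool_id: P3, true_mean: 78.1, cv_repeatability: 3.7, cv_between_run: 0.0, cv_between_day: 1.2}
    - {pool_id: P4, true_mean: 82.4, cv_repeatability: 3.6, cv_between_run: 2.3, cv_between_day: 1.0}
acceptance:
  max_repeatability_cv: 10.0
```

prints

```
Pool	Mean	Repeatability [CV%]	Between-Run [CV%]	Between-Day [CV%]	Within-Laboratory [CV%]	Reproducibility [CV%]
P1	53.6	2.7	1.5	2.3	3.9	n.a.
P2	55.8	2.8	2.8	0.0	4.0	n.a.
P3	78.2	4.3	0.0	1.6	4.6	n.a.
P4	82.5	3.7	2.1	1.7	4.6	n.a.

Verdicts:
  [PASS] design_completeness: design complete
  [PASS] repeatability_cv: max repeatability CV 4.26% vs allowance 10.0%
```

Each row is one serum pool: the estimated grand mean, the three nested
variance components as CV% (a 0.0 means the component's mean square fell
below the stratum beneath it and was truncated), and their root sum of
squares as the within-laboratory CV. The estimates scatter around the
generating components with the sampling error a 120-measurement pool
implies; the verdicts apply the design-completeness (≤ 10% missing per
pool) and repeatability-allowance rules. Exit status is 0 when all
verdicts pass, 2 otherwise.

The same pattern (`assayval detection|linearity|trueness|stability|interference
--config …`) drives every other stage; `assayval simulate <study_kind>`
writes the synthetic measurement tables themselves.

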