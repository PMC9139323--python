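# Methods

This note documents the statistical procedures assayval implements, the
choices made where the conventions leave room, and what the synthetic
generators do and do not emulate.

## Data model and missing-data accounting

All stages consume one long-format table: one row per individual
measurement, tagged with the design factors that stage needs (pool, site,
day, run, replicate, storage time point, dilution level, interference arm,
reagent lot). A row either carries a value (`status = ok`) or records that
the assay produced nothing (`status = no_result`). "Missing" always counts
both rows absent relative to the declared factor grid and retained
`no_result` rows; the default per-pool allowance is 10%. CSVs are UTF-8,
comma-separated, header mandatory, decimal point, empty string for absent
fields — chosen for unambiguous cross-language interchange, and the reader
uses round-trip float parsing so write/read is bit-exact.

Day numbering is 1-based for precision study days and 0-based for
stability time (t₀ = day 0 is the baseline), matching how the two designs
are naturally described. Extra replicates beyond the declared design are
used, not discarded; the design check reports the deviation.

## Detection capability

* **LoB.** Pooled across blank pools (a compilation of several dialyzed
  pools rather than one sample). Parametric: mean + z₀.₉₅·sd. Nonparametric:
  linear interpolation between adjacent order statistics at rank position
  0.5 + B·(1−α) (1-based). The auto mode uses Shapiro-Wilk at 0.05 on the
  pooled blanks as the normality gate — the guideline leaves the
  distribution check open, so the gate is stated explicitly here. At least
  20 blanks are required.
* **Cochran's C.** C = max s²ᵢ / Σ s²ᵢ, critical value
  1/(1 + (k−1)/F) with F = F⁻¹(1 − α/k; ν, (k−1)ν) — the union-bound
  closed form, verified in the tests against a 100,000-draw simulated null
  quantile. All-zero variances raise a degenerate-input error; in the LoD
  chain, perfectly constant pools short-circuit to the trivially
  homogeneous classical path with SD_pooled = 0.
* **LoD.** Classical path: LoB + c_p·SD_pooled with
  c_p = z₀.₉₅/(1 − 1/(4f)). The df convention is f = N_low − (number of
  pools) (pooled within-pool df). Variant path when Cochran rejects: scan
  pools lowest-mean-first for the first with ≥ 95% of results above LoB
  (the 95% exceedance aligns with β = 0.05); no qualifying pool is an
  error, not a silent extrapolation.
* **LoQ.** Per lot, minimum pool mean whose within-laboratory CV
  (repeatability + between-day from the pool's day-nested results, via the
  precision module) is < 20%; overall LoQ = max over lots, so adding a lot
  can only raise it. The LoB ≤ LoD ≤ LoQ ordering is asserted after
  estimation; a violation is flagged, never reordered.

## Linearity

Fits of order 1–3 on all replicate points (not level means — uses all the
data; documented because the two conventions give different r). Orders
with fewer than order + 2 distinct levels are skipped with a reason.
Nonlinear terms are tested two-sided at 0.05; when any is significant the
best nonlinear model is the one with the smaller standard error of
regression, ties toward the lower order, and the degree of nonlinearity is
evaluated at the assigned level concentrations (not continuously). The
per-level repeatability CV uses the level's replicate mean as denominator.
LoL is the highest assigned concentration in the longest consecutive
passing stretch; ties between equally long stretches go to the
higher-concentration one, since LoL is an upper limit. The verdict is
invariant under rescaling the concentration axis (coefficients transform
accordingly).

## Precision

Method-of-moments nested ANOVA rather than REML: it is the canonical
precision-evaluation estimator, and it makes the truncation of negative
component estimates explicit (truncation at the variance scale, before CV
conversion — a reported 0.0 CV is a truncation event). The implementation
is generic over a nesting order (day > run, site > day, or day alone for
the LoQ rule) using average subgroup counts in the expected-mean-square
coefficients, which is exact on balanced data; all standard designs here
are balanced. The multi-site model has no run factor (one run per day by
design). The grand mean is the unweighted mean of all ok results in the
pool. Within-laboratory and reproducibility CVs are root sums of squares
of *unrounded* components; rounding (1 decimal, half away from zero)
happens only at render time, which is why a rendered total can differ by
0.1 from recombining the rendered components.

## Passing-Bablok trueness

Slope = shifted median of pairwise slopes S_ij: pairs with identical
points contribute nothing, vertical pairs contribute ±∞ with the sign of
Δy, S_ij = −1 exactly is excluded, and the median position is offset by
K = #{S_ij < −1}, with the even-count median the mean of the two central
order statistics after the shift. These are the classical conventions and
give the estimator its exchange symmetry (slope(x,y) = 1/slope(y,x) on
tie-free data, asserted to 1e-9 in tests). CIs use the rank-based normal
approximation with z = 1.96 and are informational; the acceptance rule
uses only the slope tolerance (1 ± 0.15, or 1 ± 0.075 for valine) and
Pearson r ≥ 0.90 computed on the same pairs as given (no prior averaging
of site replicates — documented, since the alternative convention exists).
Spike recovery reports (spiked − mock)/added per pair and a Passing-Bablok
fit of observed vs expected (mock + added); a single spike level has a
degenerate abscissa and returns the recovery table without a regression.

## Stability

Per donor and condition, OLS of value on time over all replicates, with
the baseline mean taken from the t₀ replicates only (drift limits anchor
to the measured baseline, not the regression intercept). The confidence
band is the *pointwise* one-sided 95% bound of the regression mean —
pointwise matches standard stability-study practice and keeps the
noiseless case exact. Crossing search: 512-point bracket grid on
[0, horizon] then bisection to 1e-3 days; an independent fine-grid scan
oracle backs this in the tests. Degenerate zero-residual fits are handled
explicitly: zero slope → p = 1 (non-significant, duration = horizon);
nonzero slope with zero residual → p = 0 and the band collapses onto the
line, so the duration is the exact line/limit intersection. The duration
can never exceed the horizon, and each result records which branch fired
(non-significant slope, no crossing, or band crossing) so horizon-valued
durations are auditable.

## Interference

The screen flag is two-sided (|bias| > 10%): positive biases interfere
too. Result loss is its own interference mechanism: a test arm or dose
level with more than the 10% missing-data allowance lost — including
total loss, where the bias is undefined — is flagged/tripped. The
dose-response threshold is the lowest tested fraction that trips; the
machine-readable field stores the fraction (and fraction × the worst-case
spike concentration when configured), while the prose helper renders
"> previous level's concentration", matching how such thresholds are
customarily reported. Both are emitted to avoid ambiguity. Dose-response
is expected to run on serum pools independent of the screen's.

## Synthetic-data generators

Noise is multiplicative Gaussian on the CV scale: value =
truth × (1 + Σ effects), each hierarchical effect zero-mean Gaussian with
sd = CV/100, shared within its stratum (day ⊃ run ⊃ replicate;
site ⊃ day ⊃ replicate). This maps generator parameters one-to-one onto
the CV% components the estimators report. Values are truncated at zero
after noise (concentrations are nonnegative) with a warning per event;
at the CV levels used (≤ ~10%) truncation is effectively never hit.
"No result" events are Bernoulli per measurement with no attributed
cause. A single global seed feeds a labelled stream splitter so each
study is independently reproducible bit-for-bit.

Default designs are the standard ones: 20 days × 2 runs × 3 replicates
single-site precision; 3 sites × 5 days × 6 replicates multi-site; 11
equidistant intermixture levels with 3 replicates; 4 blank + 4 low pools
× 45 replicates over 3 lots and 3 days; serum stability at days 0–8
(5 baseline replicates, 3 per later day) and on-board at days 0, 1, 4, 7,
9, 10; interference screens with 10 aliquots per arm and 5-replicate
dose-response levels.

What the generators do *not* emulate: spectral acquisition and peak
fitting, matrix effects, non-Gaussian heavy tails, drift nonlinearity,
correlated loss of results, or between-lot biases in low-level panels.
Passing tests therefore demonstrate the *statistical machinery* —
estimator correctness, decision-rule operating characteristics, design
bookkeeping — not the analytical behaviour of any real instrument.

The GFR score surrogate is a documented power-law stand-in
(score = scale·∏(marker/ref)^βᵢ·(age/40)^γ·sex factor, with negative
exponents for creatinine, myo-inositol, valine and cystatin C), present so
the pipeline can be exercised at the score level; it is not the marketed
equation, whose coefficients are proprietary and out of scope.

## Problem sizes and numerics

Monte-Carlo suites use 500 simulated studies for variance-component
recovery, 500–1,000 series for linearity error rates, 1,000 courses for
stability rates, 2,000 screens per arm of the interference operating
characteristics, and 10,000 fresh draws for the LoB exceedance rate —
sizes at which binomial/sampling error is comfortably inside the asserted
bands while the whole suite stays interactive. OLS uses `lstsq` with a
relative residual floor (1e-12 of total variance) so exact fits are
recognized as zero-residual instead of amplifying cancellation noise.
Bisection tolerance for stability crossings is 1e-3 days.

## Known limitations

* The nested-ANOVA expected-mean-square coefficients use average subgroup
  counts; strongly unbalanced data would need Satterthwaite-style
  weighting, which is not implemented.
* No confidence intervals on variance components.
* Passing-Bablok assumes a positive association convention; data with a
  truly negative slope are outside its intended use here.
* The linearity false-rejection rate is the t-tests' nominal level only
  under the Gaussian noise model; heavy-tailed noise will inflate it.
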