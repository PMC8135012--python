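# Methods

`ooclock` implements the statistical core of a comparative epigenetic-aging
study of bovine oocytes and blood: sparse linear "epigenetic clocks" that
predict age from CpG methylation, and a per-CpG aging EWAS with cross-tissue
meta-analysis. Because the consortium array data the design is modelled on
are not bundled here, the package ships a synthetic-data generator that
reproduces the statistical structure those analyses rely on, with per-probe
ground truth, so every stage is testable end to end.

## Data model

Methylation is represented as beta values — the methylated fraction at a CpG,
in [0, 1] — in a probe-by-sample matrix. Samples carry species (cattle,
human), tissue (blood, oocyte, skin), age in years, the species' maximum
lifespan, and an optional donor id linking isogenic samples. The CpG
annotation manifest records chromosome, 1-based position, nearest gene,
signed distance to its transcription start site (negative = upstream),
a region class and CpG-island status. A probe is a *promoter* probe exactly
when its TSS distance lies in [−10 kb, +1 kb]; the annotation reader flags
(but does not reject) rows violating this, since external manifests may use
other conventions. The pipeline requires complete matrices: missing betas
are a hard error rather than silently imputed, a deliberate choice because
imputation policy materially affects penalized fits and should be explicit
upstream.

## Age transforms

Clocks regress a transform of age, not raw age, on methylation:

* **identity** — age in years; used for within-species clocks.
* **relative age** — age divided by the species' maximum lifespan (38 y for
  cattle, 122.5 y for humans), giving values in (0, 1]. One prediction
  equation in relative age is meaningful for species with very different
  lifespans; predictions are mapped back to years by multiplying by the
  lifespan of the sample's species.
* **log-linear** — log(age + offset) below a maturity knot, continued
  linearly with matched value and slope above it. This is provided as an
  option for juvenile-heavy designs but is off by default: its exact
  parameterization (offset, knot) is a free design choice here, so nothing
  downstream depends on it.

All transforms are strictly increasing and invert to 1e−10.

## Clocks

A clock is an elastic-net linear model of transformed age on probe betas.
Predictors are standardized internally (penalty fairness across probes);
coefficients are reported back on the original beta scale. The L1/L2 mixing
parameter defaults to 0.5 — the convention in the clock literature, since
pure lasso is unstable among correlated CpGs — and penalty strength is
selected by internal 10-fold cross-validation at the minimum mean squared
error rather than the 1-SE rule, favouring accuracy over sparsity. The
numerical path uses a 25-point alpha grid with coordinate-descent tolerance
1e−3 (max 2,000 iterations); a tighter tolerance changes held-out
predictions by less than the simulation noise floor while costing an order
of magnitude more time.

Out-of-sample DNAm age comes from leave-one-sample-out or k-fold schemes in
which the full procedure — including penalty selection — is rerun without
the held-out samples; nothing from a held-out sample ever reaches its own
model. k-fold folds are stratified by species × tissue (dealt round-robin so
global fold sizes differ by at most one) and can be grouped by donor so
isogenic samples never straddle a fold. Training internally canonicalizes
sample order, making estimates invariant to input column order.
Back-transformed predictions are *not* clipped to (0, max lifespan]:
out-of-range predictions are reported as-is with a warning, because clipping
would mask calibration failure.

One behaviour worth knowing: under a null (e.g. permuted ages), the elastic
net collapses toward the intercept-only model, and the leave-one-out
estimate of sample *i* is then the training mean without *i* — which is
perfectly anti-correlated with the held-out age. This is an artifact of LOO
with near-constant predictions, not information leakage; with any prediction
noise present the null LOO correlation is small, as the permutation test in
the suite checks.

**Age acceleration** is the residual of cross-validated DNAm age regressed
(OLS) on chronological age *within a tissue*. Using residuals rather than
DNAmAge − Age removes each tissue's calibration slope and intercept, which
is what makes accelerations comparable between blood and oocytes of the
same donors. The cross-tissue acceleration comparison pairs donors and
reports the Pearson correlation with its two-sided p-value plus per-tissue
median/IQR summaries.

## EWAS

Within one tissue each probe is screened by the Pearson correlation r of its
betas with age in years (the screening convention for a numeric trait), with

    t = r·sqrt(n−2)/sqrt(1−r²),  p two-sided from Student t(n−2),
    Z = sign(r)·Φ⁻¹(1 − p/2).

p is floored at 1e−300 so Z stays finite (cap ≈ 37.0); constant probes get
undefined statistics, are excluded from selection, and are counted in the
log. Tissues are combined with Stouffer's method, z_meta = (w₁z₁ + w₂z₂) /
sqrt(w₁² + w₂²), with unit weights by default ((z₁+z₂)/√2); √n weighting is
available by flag since the weighting convention is not fixed by the method
itself. Age is screened untransformed (years) within a tissue.

Top CpGs are those with p < 1e−4, split by direction of change, keeping at
most 500 per direction ranked by |Z| with ties broken by probe id. No
multiple-testing correction beyond this fixed threshold is applied to the
selection (a BH-FDR column can be computed but is deliberately not used for
it). Cross-tissue divergence classes: a probe significant in both tissues
with opposite signs is `divergent_both`, with equal signs `concordant_both`,
otherwise `blood_only` / `oocyte_only` / `neither`.

Feature enrichment (e.g. promoter status among blood-hypermethylated CpGs)
uses the 2×2 odds ratio ad/bc and the exact upper-tail hypergeometric
p-value P(X ≥ a) — no normal approximation at any background size used here.
The background is all probes with defined statistics in the tissue, a choice
that is configurable because published analyses rarely state it. Island
effects are summarized two ways: a Welch t test of Z by island status, and
mean beta per tissue × island stratum.

## The synthetic-data generator

The generator emulates the features the analyses depend on — it is a
study-design model, not a biology model:

* beta(probe, sample) = baseline(tissue) + slope(tissue) × age + ε, with
  ε ~ N(0, σ) i.i.d. on the beta scale and clipping to [0, 1]. Additive
  Gaussian noise (rather than logit-scale noise) keeps every moment directly
  checkable against ground truth; the clipped fraction is recorded and stays
  well under 1% at the defaults.
* probe classes: blood-up/down and oocyte-up/down (disjoint tissue-specific
  aging sets), small `shared` (same-sign) and `divergent` (opposite-sign)
  classes to exercise the cross-tissue classifier, remainder null. Defaults:
  60/60/40/40/20/20 of 2,000 probes.
* slopes are drawn from 0.005–0.02 beta per cattle year — a realistic drift
  range for age-related CpGs that also keeps the signal feasible inside
  [0, 1] across the human age range. The dual-species link is equal drift
  per *relative-age* unit: a species with lifespan M gets per-year slope
  scaled by 38/M, so the same probes carry the shared signal in both
  species while remaining linear in years within each. The truth table
  records cattle per-year slopes.
* baselines: island probes are low-methylated in both tissues (0.05–0.25);
  non-island baselines are drawn from 0.55–0.85 in blood and 0.35–0.65 in
  oocytes, encoding the lower oocyte baseline outside islands. Baselines of
  sloped probes are shifted where needed so the noise-free trajectory stays
  in [0.02, 0.98] over the widest sampled age span.
* annotation: a toy 29-chromosome layout with probes every 10 kb, gene
  symbols shared by neighbouring probe blocks, TSS distances drawn
  consistently with region class, half of blood-up probes placed in
  promoters (background 10%) and 60% on islands (background 30%) so the
  enrichment and island analyses have signal to find.
* design sizes: 60 cattle blood + 40 cattle oocyte + 60 human blood samples,
  cattle ages uniform on 0.5–13.3 y, human on 1–100 y. These are desk-scale
  counts mirroring the relative composition of a realistic two-tissue cohort
  with a human panel; effect-size distributions are chosen for testability,
  not estimated from any dataset.
* isogenic mode: each donor contributes one blood and one oocyte sample at
  the same age; a per-donor latent acceleration offset (years, default sd
  1.5 — the scale of residual epigenetic-age scatter) enters the methylation
  signal with configurable cross-tissue correlation ρ (default 0), making
  the acceleration-correlation analysis testable under both the null and a
  coupled alternative.

What the generator does *not* emulate: probe-wise heteroskedasticity and
beta-distributed noise, cell-composition effects, batch structure, spatial
correlation along the genome, and non-linear (e.g. logarithmic juvenile)
aging trajectories. Passing tests therefore demonstrate the correctness and
calibration of the statistical machinery under its stated model, not
performance on real arrays.

## Problem sizes and reproducibility

Cross-validated clock runs in the test-suite and the acceptance script use
the default 2,000-probe design, LOO for the 100-sample cattle clocks and
10-fold CV for the 160-sample dual-species clocks; the acceleration
Monte-Carlo uses 300-probe, 40-donor replicates (200 null, 25 coupled),
sizes chosen to give stable Monte-Carlo estimates at desk scale. Every
stochastic stage takes an explicit seed; fixed seeds give bit-identical
simulations, clock files and reports. The tissue-transfer correlation is
evaluated on a 200-sample oocyte panel because the quantity being measured
is pure prediction noise (sd ≈ 1/√n), and the larger panel tightens the
Monte-Carlo error of the estimate without changing the property itself.

## Known limitations

* The elastic-net clocks assume a linear signal in transformed age; real
  clocks often need non-linear juvenile transforms (the log-linear option
  exists but its parameters are not calibrated to any dataset).
* The EWAS screen is a marginal Pearson correlation per CpG; no covariates
  (sex, batch, cell composition) are supported.
* The enrichment background and the divergence thresholds are configurable
  precisely because published choices vary; results depend on them.
* Synthetic-data defaults are a modelling choice, labelled as such; none of
  the generator's parameters were estimated from real methylation data.
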