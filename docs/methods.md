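# Methods

## The asymmetry index

`cortasym` quantifies structural brain asymmetry from regional cortical
thickness. For one scan, each hemisphere contributes 34 Desikan–Killiany
regional mean thicknesses (mm). These are treated as a sample from that
hemisphere's thickness distribution; the cortical asymmetry index (CAI) is
the Jensen–Shannon *distance* between the two estimated distributions,

    CAI = sqrt( H(m) − (H(p) + H(q)) / 2 ),    m = (p + q) / 2,

with `p`, `q` the left/right distributions, `H` the Shannon entropy in base-2
logarithms, and `m` their pointwise mixture. With base-2 logs the divergence
is bounded by 1, so CAI ∈ [0, 1]: 0 for identical hemispheric distributions,
1 for distributions with disjoint support. The square root (distance, not
divergence) is used because it is a true metric — it satisfies the triangle
inequality — and keeps the index on an interpretable [0, 1] scale.

Design choices that the definition leaves open, and what this package does:

- **Density estimator.** Default: equal-width histogram with 16 bins, with a
  small mass `epsilon = 1e-6` added to every bin before renormalization so
  that empty bins never produce infinities. A Gaussian KDE evaluated on the
  same grid is available (`estimator="gaussian_kde"`) for sensitivity
  analyses. The histogram default is deterministic, auditable, and cheap;
  `CAIConfig` exposes every knob so an alternative binning rule can be
  matched later without API changes.
- **Support.** Default per participant: the pooled min–max of both
  hemispheres' 68 values, padded by half a bin width so boundary observations
  are strictly interior (`pooled_min_max`). This makes CAI a purely
  within-individual measure, insensitive to cohort-level scaling. A
  `fixed_range` policy is available for cross-cohort standardization. A
  degenerate pooled range (all 68 values equal) is widened to ±0.5 mm; the
  index is 0 there regardless.
- **Regions are unweighted** (no surface-area weighting) and region identity
  is ignored: the index compares distributions, not matched regions, so it is
  exactly invariant to a common relabelling and responds to distributional
  shifts such as lateralized thinning.

## Cohort semantics

Participants are classified as CTR (mutation-negative, CDR 0), AMC
(asymptomatic carriers, CDR 0), or SMC (symptomatic carriers, CDR ≥ 0.5);
SMC subdivides into SMC-MCI (CDR = 0.5) and SMC-AD (CDR ≥ 1). The disease
clock is EYO — estimated years from symptom onset — the participant's age
minus the affected parent's symptom-onset age, negative before expected
onset. These derivations are enforced as validation invariants at ingest:
a CTR row with CDR 0.5, or an SMC subgroup inconsistent with CDR, is a
hard error. Missing biomarkers (MMSE, CSF/plasma NfL, hippocampal volume)
propagate as missing and are excluded pairwise downstream. Sex is a
two-level factor with female as the reference level, fixed so covariate
coefficients are reproducible.

## Synthetic cohort generator

The generator (`cortasym.simulate`) emulates the statistical structure of two
ADAD observational cohorts so the full pipeline is testable without
participant data:

- `dian_like` — 215 CTR / 234 AMC / 73 SMC-MCI / 42 SMC-AD; group EYO means
  (SD) of −10.4 (11.8), −14.1 (8.6), −1.0 (7.0), +3.1 (7.0) years; up to
  seven visits (baseline plus six follow-ups); 58% women.
- `barcelona_like` — 19 CTR / 22 AMC / 19 SMC; AMC closer to onset
  (−9.4 ± 10.7); baseline only; 68% women.

A latent **disease burden** b(EYO) = logistic((EYO − m)/s) with midpoint
m = −2 years and scale s = 4 years drives all disease effects in carriers
(CTR have b = 0). Per participant, a regional thickness pattern is drawn once
(Normal(2.5, 0.25) mm per region, shared across hemispheres); both
hemispheres thin by `b · max_thinning` (0.35 mm at full burden), and the left
thins by an additional factor `(1 + δ·b)`, so asymmetry accelerates with
stage. i.i.d. measurement noise (SD 0.05 mm) is added per region and
hemisphere at every visit. NfL follows a multiplicative lognormal link
(baseline 250 pg/ml CSF / 6 pg/ml plasma, fold increases 8 and 4 per unit
burden, log-noise SD 0.35 — NfL is strictly positive and right-skewed, which
the lognormal respects); MMSE loses 11 points per unit burden (noise SD 1.2,
clipped to [0, 30]); hippocampal volume loses 800 mm³ per unit burden from a
4200 ± 350 mm³ baseline. Follow-up counts are truncated uniformly at random
up to the visit cap; each visit advances age and EYO by exactly the visit
interval (default 1 year). Group labels are the baseline classification and
do not convert between visits.

The lateralization dial δ (`left_thinning_excess`) defaults to **0.36**,
calibrated once by simulation so that the baseline SMC − CTR mean CAI gap in
the `dian_like` template is ≈ 0.5 pooled standard deviations (measured
0.48–0.52 across 30 replicate cohorts). APOE genotypes are drawn from
population-like frequencies and are asymmetry-neutral by default: no
mechanistic link from genotype to asymmetry is imposed, and any APOE effect
a user wants to study must be injected explicitly.

What the generator does *not* emulate: site/scanner effects, informative
dropout, within-family correlation, regional (topographic) specificity of
atrophy, and measurement error that scales with disease severity. Passing
tests therefore demonstrate that the pipeline recovers effects of the
assumed form at realistic sizes and noise levels — not that real cohorts
satisfy those assumptions.

## Cross-sectional inference

**Covariate-adjusted permutation test.** The group test adjusts for age, sex,
and EYO (plus CDR where noted) inside the permutation scheme using
Freedman–Lane residual permutation: fit the covariate-only model, permute its
residuals, add them back to its fitted values, refit the full
(group + covariates) model on each pseudo-response, and recompute the
group-factor F. The p-value is `(1 + #{F* ≥ F_obs}) / (B + 1)` with B = 9999
permutations by default (resolution below 0.001) and the seed recorded in
every result. Freedman–Lane was chosen because it is the standard
residual-permutation scheme with good type-I control when nuisance covariates
are correlated with the factor of interest; the statistic is the two-sided F
for the group factor. Projections use rank-robust orthonormal bases, so
constant or collinear covariate columns collapse harmlessly.

Note one structural constraint: CDR *defines* the AMC/SMC split (AMC ⇒ CDR 0),
so for AMC-vs-SMC contrasts CDR would alias the group factor and is omitted
from their covariates; it is retained for the APOE-genotype omnibus test,
where it varies within the tested factor's levels.

**ANCOVA.** OLS of CAI on group + covariates; F-test for the group factor;
pairwise contrasts are the model's estimated marginal group differences,
tested with the model t distribution and Benjamini–Hochberg-adjusted as one
family per analysis question (the three pairwise contrasts form one family).
Rank-deficient designs fail with the aliased column named.

**ROC.** AUC by the Mann–Whitney identity (concordant pairs, ties counted
half). All markers are oriented "higher = more disease-like" before
comparison; hippocampal volume is negated. Point AUCs only — no DeLong
intervals.

**Demographics.** Continuous variables are summarized mean (SD) and tested
with Kruskal–Wallis (small cohorts) or one-way ANOVA (large cohorts);
discrete variables with Fisher's exact test. The r×c exact test enumerates
all tables with the observed margins and sums multivariate hypergeometric
probabilities of tables no more probable than the observed one (the same
two-sided convention R's `fisher.test` uses), with a relative tolerance of
1e-7 on probability ties; beyond ~2×10⁶ candidate tables it switches to a
seeded Monte-Carlo version that permutes one margin's labels.

**Correlations.** Spearman (rank-then-Pearson with average ranks, t
approximation on n − 2 df) for small cohorts, Pearson for large ones, on
baseline visits only, with pairwise-complete n recorded per result. Constant
inputs yield a flagged result, not an exception; subgroups with n < 3 are
flagged insufficient. Correlation p-values are reported unadjusted to match
the presentation conventions of the field; an opt-in battery-wide BH switch
exists. Age is kept in the battery even though no age association is
expected — null results are part of the validation surface.

## Longitudinal trajectories

The trajectory model regresses CAI on EYO across all visits:

    CAI ~ s(EYO) + group + group:EYO + age + sex

with one common penalized cubic B-spline smooth of EYO (10 basis functions,
curvature penalty), parametric group offsets, and *linear* group×EYO
interactions. Keeping the interaction linear means each non-reference group's
divergence from the reference trajectory is summarized by a single
coefficient with one t statistic — the headline number reported per group —
which a per-group free smooth would not provide. The smoothing parameter is
chosen by generalized cross-validation, GCV(α) = n·RSS/(n − edf)², over a
fixed log-spaced grid (10⁻⁴…10⁶); `edf` is the effective degrees of freedom
of the penalized fit. The penalty is the integrated squared second
derivative of the smooth, which (like a second-order difference penalty)
leaves linear trends unpenalized, so on noiseless linear data the fit is
exact and the interaction coefficient is recovered to machine precision.
A `smooth=False` switch collapses s(EYO) to a plain linear EYO term (OLS),
since it is ambiguous whether such an analysis needs a smooth at all; the
smooth is the default.

Grouping variants: CTR vs all carriers; CTR/AMC/SMC; CTR/AMC/SMC-MCI/SMC-AD.
CTR is always the reference.

Predictions are evaluated at reference covariates (mean age, balanced sex)
with pointwise standard errors from the penalized coefficient covariance.
The prediction grid must lie inside the fitted EYO range; with an explicit
`allow_extrapolation` flag the smooth's contribution is frozen at the
boundary and only the parametric group:EYO part continues linearly.

**Known limitation (prominent):** repeated measures are treated as
independent — there are no within-participant random effects. Interaction
standard errors are therefore anti-conservative on strongly clustered data.
The synthetic generator draws visit-level noise independently, so the
calibration checks in the test suite are valid under that model, but real
longitudinal cohorts violate it.

## Numerical conventions

- Entropies use 0·log 0 = 0; JS divergences are clipped at [0, 1] before the
  square root to absorb rounding at the 1e-16 level.
- Histogram masses are epsilon-smoothed then renormalized to sum to 1 within
  1e-12 (enforced by the `DiscreteDistribution` invariant).
- Permutation p-values are never 0 by construction (the +1 convention) and
  respect `p ≥ 1/(B+1)`.
- BH adjustment is the step-up rule `min_j≥i (p_(j)·m/j)` capped at 1,
  monotone in raw rank.
- All CSV output uses a fixed float format (`%.10g`) so reruns with the same
  config and seeds are byte-identical.
- One noted convention: a CSF-NfL correlation threshold that appears in the
  literature as "P < 0.5" is treated as the conventional "P < 0.05"
  throughout.

## Problem sizes used in validation

The validation suite sizes its simulations to exercise the claimed
properties at full strength while remaining routine to run: 1000 random
distribution pairs for the metric oracle; 100 participants per thinning
offset for the dose-response check; 500 null datasets (n = 60, 999
permutations) for permutation calibration; 100 full-size `dian_like`
baseline replicates for power, sign-recovery, and AUC checks; 100 stochastic
and 100 null trajectory fits (30 participants per group, 4 visits, noise SD
0.08 — the CAI residual scale the generator produces) for interaction power
and calibration; smaller cohorts (e.g. 25/25/12/12 × 3 visits) for
end-to-end determinism. `scripts/acceptance.py` replays all of these from a
single command-line seed.
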