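# cortasym

Cortical thickness asymmetry analysis for autosomal-dominant Alzheimer's
disease (ADAD) cohorts.

Alzheimer's disease thins the cortex asymmetrically — more in the left
hemisphere — and that asymmetry grows along the disease continuum, making it
a candidate progression biomarker in ADAD mutation carriers, who can be
staged years before symptoms by their estimated years to onset (EYO).
`cortasym` is for neuroimaging and biomarker researchers who have
FreeSurfer-style regional thickness tables and want to (a) compute a
per-scan **cortical asymmetry index (CAI)** and (b) run the complete
statistical pipeline around it: covariate-adjusted group inference, biomarker
ROC comparison, NfL/MMSE/EYO correlation batteries, and longitudinal
trajectory modelling.

## The index

Each hemisphere's 34 Desikan–Killiany regional mean thicknesses are treated
as a sample from that hemisphere's thickness distribution. With p and q the
left/right distributions estimated on a shared support, and H(·) the Shannon
entropy in bits,

```
CAI = sqrt( H((p+q)/2) − (H(p) + H(q))/2 )        CAI ∈ [0, 1]
```

— the Jensen–Shannon distance. 0 means distributionally identical
hemispheres; 1 means disjoint thickness distributions; higher values mean a
more asymmetric brain. Defaults: 16-bin histogram on the participant's
pooled thickness range (half-bin padding, epsilon smoothing); a Gaussian-KDE
estimator is available. See `docs/methods.md` for every convention.

The package also ships a synthetic ADAD cohort generator (two templates
modelled on a small uni-centric cohort and a large multi-centric longitudinal
one) whose latent disease burden is logistic in EYO and drives lateralized
thinning, NfL elevation, and MMSE decline — so the whole pipeline is testable
end-to-end without participant data.

## Worked example

```python
from cortasym import (default_config, generate_cohort, compute_cai_table,
                      fit_trajectory_model)
from cortasym.io import build_analysis_table
from cortasym.inference import adjusted_permutation_test, roc_auc

cohort = generate_cohort(default_config("dian_like", seed=42))
table = build_analysis_table(cohort, compute_cai_table(cohort))
baseline = table[table.visit == 0]
print(baseline.groupby("group")["cai"].agg(["mean", "std", "count"]).round(3))

sub = baseline[baseline.group.isin(["SMC", "CTR"])].reset_index(drop=True)
res = adjusted_permutation_test(sub["cai"], sub["group"],
                                sub[["age_years", "sex", "eyo_years"]],
                                n_permutations=9999, seed=0)
print(f"SMC vs CTR (age/sex/EYO adjusted): F = {res.statistic_observed:.2f}, "
      f"p = {res.p_value:.4f}")
print(f"AUC (CAI, SMC vs CTR): {roc_auc(sub['cai'], sub['group'] == 'SMC').auc:.3f}")

fit = fit_trajectory_model(table, grouping="three_group")
t = fit.interaction_tests["SMC"]
print(f"SMC x EYO interaction: t = {t['t']:.2f}, P = {t['p']:.2g}")
```

prints

```
        mean    std  count
group
AMC    0.359  0.068    234
CTR    0.352  0.075    215
SMC    0.392  0.081    115
SMC vs CTR (age/sex/EYO adjusted): F = 8.75, p = 0.0040
AUC (CAI, SMC vs CTR): 0.642
SMC x EYO interaction: t = 6.50, P = 8.1e-11
```

Read: symptomatic carriers are measurably more asymmetric than controls at
baseline (a Freedman–Lane permutation test adjusting for age, sex, and EYO
rejects at p = 0.004), CAI alone separates SMC from CTR with AUC 0.64, and
longitudinally the SMC group's asymmetry grows faster with EYO than
controls' (linear group×EYO interaction t = 6.5 in a penalized-spline model
that also adjusts for age and sex).

## Command line

```
cai simulate --template dian_like --seed 0 --out-dir cohort/
cai compute  --thickness cohort/thickness_wide.tsv --metadata cohort/metadata.csv --out table.csv
cai analyze cross-sectional --table table.csv --out xs/
cai analyze associations    --table table.csv --out correlations.csv
cai analyze longitudinal    --table table.csv --grouping four_group --out gam/
cai run --config run.yaml        # full reproducible pipeline -> manifest + tables
```

Thickness input is either the tab-separated wide layout `aparcstats2table`
emits (`lh_<region>_thickness` / `rh_<region>_thickness` columns) or a tidy
long CSV; metadata is a CSV with group/CDR/EYO/biomarker columns. `cai run`
writes a results bundle (analysis table, demographics, group tests, ROC,
correlations, trajectory grids) plus a manifest recording the package
version, config hash, and every seed — reruns are byte-identical.

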