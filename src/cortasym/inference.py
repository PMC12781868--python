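"""Cross-sectional group inference on the asymmetry index.

Covers the baseline comparisons an ADAD asymmetry study needs:

* covariate-adjusted permutation tests (Freedman-Lane residual permutation,
  F statistic for the group factor);
* ANCOVA (OLS) with pairwise estimated-marginal-difference contrasts;
* Benjamini-Hochberg step-up adjustment;
* ROC/AUC comparison of biomarkers (Mann-Whitney pair-counting identity);
* a demographics table with Kruskal-Wallis / ANOVA for continuous variables
  and Fisher's exact test (r x c, full enumeration with a seeded Monte-Carlo
  fallback) for discrete ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .cohort import ValidationError


# --------------------------------------------------------------------------
# design-matrix plumbing

def _encode_covariates(covariates: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Numeric design columns for a covariate table.

    Non-numeric columns are dummy-encoded dropping the first level in sorted
    order (so sex={female,male} becomes an is-male indicator: female is the
    reference).
    """
    cols: list[np.ndarray] = []
    names: list[str] = []
    for name in covariates.columns:
        col = covariates[name]
        if pd.api.types.is_numeric_dtype(col) and not pd.api.types.is_bool_dtype(col):
            cols.append(col.to_numpy(dtype=float))
            names.append(name)
        else:
            levels = sorted(pd.unique(col.astype(str)))
            for lev in levels[1:]:
                cols.append((col.astype(str) == lev).to_numpy(dtype=float))
                names.append(f"{name}[{lev}]")
    X = np.column_stack(cols) if cols else np.empty((len(covariates), 0))
    return X, names


def _group_dummies(group: np.ndarray) -> tuple[np.ndarray, list[str]]:
    levels = sorted(pd.unique(pd.Series(group).astype(str)))
    dummies = np.column_stack([(group == lev).astype(float) for lev in levels[1:]])
    return dummies, levels


# --------------------------------------------------------------------------
# Freedman-Lane permutation test

@dataclass(frozen=True)
class PermutationResult:
    statistic_observed: float
    p_value: float
    n_permutations: int
    seed: int
    covariates: tuple[str, ...]
    df_num: int
    df_den: int

    def __post_init__(self) -> None:
        assert self.p_value >= 1.0 / (self.n_permutations + 1) - 1e-15


def adjusted_permutation_test(
    y: Sequence[float],
    group: Sequence,
    covariates: Optional[pd.DataFrame] = None,
    n_permutations: int = 9999,
    seed: int = 0,
) -> PermutationResult:
    """Permutation F-test for a group factor, adjusting for nuisance covariates.

    Freedman-Lane scheme: the covariate-only (reduced) model is fitted once;
    its residuals are permuted and added back to its fitted values to form
    pseudo-responses, the full model (group + covariates) is refitted on each,
    and the group-factor F statistic is recomputed. The p-value is
    ``(1 + #{F* >= F_obs}) / (n_permutations + 1)``.
    """
    if n_permutations < 99:
        raise ValueError("n_permutations must be at least 99")
    y = np.asarray(y, dtype=float)
    group = np.asarray(pd.Series(group).astype(str))
    n = y.size
    if group.size != n:
        raise ValueError("y and group must have equal length")
    if covariates is None:
        covariates = pd.DataFrame(index=range(n))
    if len(covariates) != n:
        raise ValueError("covariates must have one row per observation")
    if not np.all(np.isfinite(y)):
        raise ValueError("y contains missing/non-finite values; apply pairwise deletion first")

    levels, counts = np.unique(group, return_counts=True)
    if levels.size < 2:
        raise ValueError("group factor is constant; need at least 2 levels")
    if counts.min() < 2:
        raise ValueError("every group level needs at least 2 observations")

    from scipy.linalg import orth

    Z, cov_names = _encode_covariates(covariates)
    G, _ = _group_dummies(group)
    X_red = np.column_stack([np.ones(n), Z])
    X_full = np.column_stack([X_red, G])
    # rank-robust orthonormal bases (constant or collinear covariates collapse)
    Q_red = orth(X_red)
    Q_full = orth(X_full)
    df_num = Q_full.shape[1] - Q_red.shape[1]
    df_den = n - Q_full.shape[1]
    if df_num < 1:
        raise ValueError("group factor is aliased with the covariates")
    if df_den < 1:
        raise ValueError("not enough observations for the full model")

    def f_stat_cols(Y: np.ndarray) -> np.ndarray:
        tot = np.einsum("ij,ij->j", Y, Y)
        fit_r = Q_red.T @ Y
        fit_f = Q_full.T @ Y
        rss_r = tot - np.einsum("ij,ij->j", fit_r, fit_r)
        rss_f = tot - np.einsum("ij,ij->j", fit_f, fit_f)
        rss_f = np.maximum(rss_f, 1e-300)
        return ((rss_r - rss_f) / df_num) / (rss_f / df_den)

    f_obs = float(f_stat_cols(y[:, None])[0])

    rng = np.random.default_rng(seed)
    fitted_red = Q_red @ (Q_red.T @ y)
    resid_red = y - fitted_red
    perm_idx = np.argsort(rng.random((n, n_permutations)), axis=0)
    Y_star = fitted_red[:, None] + resid_red[perm_idx]
    f_perm = f_stat_cols(Y_star)

    p = (1.0 + np.sum(f_perm >= f_obs - 1e-12)) / (n_permutations + 1.0)
    return PermutationResult(
        statistic_observed=f_obs,
        p_value=float(p),
        n_permutations=n_permutations,
        seed=seed,
        covariates=tuple(cov_names),
        df_num=df_num,
        df_den=df_den,
    )


# --------------------------------------------------------------------------
# BH adjustment

def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


# --------------------------------------------------------------------------
# group comparison reports

@dataclass(frozen=True)
class GroupComparisonReport:
    method: str  # "permutation" | "ancova_pairwise"
    contrasts: tuple[dict, ...]  # {group_a, group_b, statistic, p_raw, p_adjusted}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(list(self.contrasts))


def pairwise_permutation_report(
    y: Sequence[float],
    group: Sequence,
    covariates: Optional[pd.DataFrame] = None,
    n_permutations: int = 9999,
    seed: int = 0,
) -> GroupComparisonReport:
    """All pairwise group contrasts by Freedman-Lane tests, BH-corrected as one family."""
    y = np.asarray(y, dtype=float)
    group = np.asarray(pd.Series(group).astype(str))
    levels = sorted(np.unique(group))
    rows = []
    for i, (a, b) in enumerate(combinations(levels, 2)):
        mask = np.isin(group, [a, b])
        cov_ab = covariates.loc[mask].reset_index(drop=True) if covariates is not None else None
        res = adjusted_permutation_test(
            y[mask], group[mask], cov_ab, n_permutations=n_permutations, seed=seed + i
        )
        rows.append({"group_a": a, "group_b": b,
                     "statistic": res.statistic_observed, "p_raw": res.p_value})
    adj = bh_adjust([r["p_raw"] for r in rows])
    for r, a_ in zip(rows, adj):
        r["p_adjusted"] = float(a_)
    return GroupComparisonReport(method="permutation", contrasts=tuple(rows))


def ancova_group_test(
    y: Sequence[float],
    group: Sequence,
    covariates: Optional[pd.DataFrame] = None,
) -> dict:
    """ANCOVA: OLS of y on group + covariates; F for group; BH-adjusted pairwise contrasts.

    Pairwise contrasts are the model's estimated marginal group differences
    (differences of group coefficients at fixed covariates), tested with the
    model's t distribution.
    """
    import statsmodels.api as sm

    y = np.asarray(y, dtype=float)
    group = np.asarray(pd.Series(group).astype(str))
    n = y.size
    if covariates is None:
        covariates = pd.DataFrame(index=range(n))
    Z, cov_names = _encode_covariates(covariates)
    G, levels = _group_dummies(group)
    if len(levels) < 2:
        raise ValueError("group factor is constant; need at least 2 levels")
    X = np.column_stack([np.ones(n), G, Z])
    names = ["const"] + [f"group[{lev}]" for lev in levels[1:]] + cov_names
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the aliased column: the first whose removal leaves rank unchanged
        for j in range(X.shape[1]):
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank:
                raise ValueError(f"design matrix is rank-deficient; column {names[j]!r} is aliased")
        raise ValueError("design matrix is rank-deficient")

    k_groups = len(levels) - 1
    if np.ptp(y) == 0:
        # degenerate response: no variance to explain, F = 0 by convention
        rows = [{"group_a": a, "group_b": b, "estimate": 0.0, "statistic": 0.0,
                 "p_raw": 1.0, "p_adjusted": 1.0} for a, b in combinations(levels, 2)]
        report = GroupComparisonReport(method="ancova_pairwise", contrasts=tuple(rows))
        return {"F": 0.0, "p": 1.0, "df_num": k_groups, "df_den": n - X.shape[1],
                "pairwise": report, "ols_result": None}

    model = sm.OLS(y, pd.DataFrame(X, columns=names))
    res = model.fit()
    # F-test that all group coefficients vanish
    R = np.zeros((k_groups, X.shape[1]))
    for i in range(k_groups):
        R[i, 1 + i] = 1.0
    ftest = res.f_test(R)
    F = float(np.squeeze(ftest.fvalue))
    p = float(ftest.pvalue)

    # pairwise estimated marginal differences
    coef_of = {lev: np.zeros(X.shape[1]) for lev in levels}
    for i, lev in enumerate(levels[1:]):
        coef_of[lev][1 + i] = 1.0
    rows = []
    for a, b in combinations(levels, 2):
        c = coef_of[b] - coef_of[a]
        tt = res.t_test(c)
        rows.append({
            "group_a": a, "group_b": b,
            "estimate": float(np.squeeze(tt.effect)),
            "statistic": float(np.squeeze(tt.tvalue)),
            "p_raw": float(np.squeeze(tt.pvalue)),
        })
    adj = bh_adjust([r["p_raw"] for r in rows])
    for r, a_ in zip(rows, adj):
        r["p_adjusted"] = float(a_)
    report = GroupComparisonReport(method="ancova_pairwise", contrasts=tuple(rows))
    return {"F": F, "p": p, "df_num": k_groups, "df_den": int(res.df_resid),
            "pairwise": report, "ols_result": res}


# --------------------------------------------------------------------------
# ROC / AUC

@dataclass(frozen=True)
class ROCResult:
    auc: float
    positive_label: str
    marker: str
    n_pos: int
    n_neg: int


def roc_auc(
    score: Sequence[float],
    is_positive: Sequence[bool],
    marker: str = "cai",
    positive_label: str = "positive",
) -> ROCResult:
    """AUC by the Mann-Whitney identity: P(score_pos > score_neg) + 0.5 P(tie)."""
    score = np.asarray(score, dtype=float)
    pos = np.asarray(is_positive, dtype=bool)
    if score.size != pos.size:
        raise ValueError("score and is_positive must have equal length")
    n_pos = int(pos.sum())
    n_neg = int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute an AUC")
    ranks = stats.rankdata(score)  # average ranks handle ties as 0.5
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return ROCResult(
        auc=float(u / (n_pos * n_neg)),
        positive_label=positive_label,
        marker=marker,
        n_pos=n_pos,
        n_neg=n_neg,
    )


# markers whose raw scale points the "wrong way" (lower = more disease-like)
MARKER_SIGN = {"cai": 1.0, "nfl_csf": 1.0, "nfl_plasma": 1.0, "hippocampal_volume": -1.0}

MARKER_COLUMN = {
    "cai": "cai",
    "nfl_csf": "csf_nfl_pg_ml",
    "nfl_plasma": "plasma_nfl_pg_ml",
    "hippocampal_volume": "hippocampal_volume_mm3",
}


def roc_battery(
    table: pd.DataFrame,
    positive_group: str,
    negative_group: str,
    markers: Sequence[str] = ("cai", "hippocampal_volume", "nfl_csf", "nfl_plasma"),
    group_column: str = "group",
) -> list[ROCResult]:
    """AUC of each marker for one group contrast, with disease-direction sign conventions."""
    out = []
    sub = table[table[group_column].isin([positive_group, negative_group])]
    for marker in markers:
        col = MARKER_COLUMN[marker]
        if col not in sub.columns:
            continue
        rows = sub.dropna(subset=[col])
        score = rows[col].to_numpy(dtype=float) * MARKER_SIGN[marker]
        out.append(roc_auc(score, rows[group_column] == positive_group,
                           marker=marker, positive_label=positive_group))
    return out


# --------------------------------------------------------------------------
# Fisher's exact test for r x c tables

def _log_table_prob(table: np.ndarray, logfact_margins: float, log_n_fact: float) -> float:
    return logfact_margins - log_n_fact - gammaln(table + 1.0).sum()


def fisher_exact_rxc(
    table: Sequence[Sequence[int]],
    max_tables: int = 2_000_000,
    n_monte_carlo: int = 99_999,
    seed: int = 0,
) -> float:
    """Two-sided Fisher exact p for an r x c contingency table.

    Full enumeration over all tables with the observed margins, summing the
    multivariate hypergeometric probabilities of tables no more probable than
    the observed one (the convention R's ``fisher.test`` uses). If the
    enumeration would exceed ``max_tables`` candidate tables, a seeded
    Monte-Carlo version (sampling tables by permuting one margin's labels)
    is used instead.
    """
    obs = np.asarray(table, dtype=int)
    if obs.ndim != 2 or np.any(obs < 0):
        raise ValueError("table must be a non-negative 2-D array of counts")
    obs = obs[obs.sum(axis=1) > 0][:, obs.sum(axis=0) > 0]
    if obs.shape[0] < 2 or obs.shape[1] < 2:
        return 1.0
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    n = int(obs.sum())
    logfact_margins = gammaln(row + 1.0).sum() + gammaln(col + 1.0).sum()
    log_n_fact = float(gammaln(n + 1.0))
    log_p_obs = _log_table_prob(obs, logfact_margins, log_n_fact)

    # rough enumeration-size estimate: product of free-cell ranges
    est = 1.0
    for i in range(obs.shape[0] - 1):
        for j in range(obs.shape[1] - 1):
            est *= min(row[i], col[j]) + 1
    if est > max_tables:
        return _fisher_monte_carlo(obs, row, col, log_p_obs, logfact_margins,
                                   log_n_fact, n_monte_carlo, seed)

    r, c = obs.shape
    tol = 1e-7
    total = 0.0

    def recurse(i: int, rem_row: np.ndarray, rem_col: np.ndarray, log_acc: float) -> None:
        nonlocal total
        if i == r - 1:
            # last row forced by column margins
            cells = rem_col
            if np.any(cells < 0):
                return
            lp = log_acc - gammaln(cells + 1.0).sum()
            if lp <= log_p_obs + tol * abs(log_p_obs):
                total += math.exp(lp)
            return
        # enumerate row i over free cells 0..c-2, last cell forced
        def fill(j: int, rem_in_row: int, rem_col_now: np.ndarray, log_now: float) -> None:
            if j == c - 1:
                x = rem_in_row
                if x < 0 or x > rem_col_now[j]:
                    return
                nxt = rem_col_now.copy()
                nxt[j] -= x
                recurse(i + 1, rem_row, nxt, log_now - float(gammaln(x + 1.0)))
                return
            hi = min(rem_in_row, int(rem_col_now[j]))
            for x in range(hi + 1):
                nxt = rem_col_now.copy()
                nxt[j] -= x
                fill(j + 1, rem_in_row - x, nxt, log_now - float(gammaln(x + 1.0)))

        fill(0, int(rem_row[i]), rem_col, log_acc)

    base = logfact_margins - log_n_fact
    recurse(0, row, col.copy(), base)
    return float(min(total, 1.0))


def _fisher_monte_carlo(obs, row, col, log_p_obs, logfact_margins, log_n_fact,
                        n_monte_carlo: int, seed: int) -> float:
    rng = np.random.default_rng(seed)
    labels = np.repeat(np.arange(obs.shape[1]), col)
    row_idx = np.repeat(np.arange(obs.shape[0]), row)
    tol = 1e-7
    hits = 0
    for _ in range(n_monte_carlo):
        perm = rng.permutation(labels)
        t = np.zeros(obs.shape, dtype=int)
        np.add.at(t, (row_idx, perm), 1)
        lp = _log_table_prob(t, logfact_margins, log_n_fact)
        if lp <= log_p_obs + tol * abs(log_p_obs):
            hits += 1
    return (hits + 1.0) / (n_monte_carlo + 1.0)


# --------------------------------------------------------------------------
# demographics table

DEMOGRAPHIC_CONTINUOUS = ("age_years", "eyo_years", "mmse", "csf_nfl_pg_ml", "plasma_nfl_pg_ml")
DEMOGRAPHIC_DISCRETE = ("sex", "apoe_e4_carrier")


def demographics_table(
    table: pd.DataFrame,
    group_column: str = "group",
    continuous_test: str = "kruskal_wallis",
    discrete_test: str = "fisher_exact",
    continuous: Sequence[str] = DEMOGRAPHIC_CONTINUOUS,
    discrete: Sequence[str] = DEMOGRAPHIC_DISCRETE,
    seed: int = 0,
) -> pd.DataFrame:
    """Group-by-variable demographics with per-variable test p-values.

    Continuous variables are summarized "mean (SD)" per group and tested with
    Kruskal-Wallis or one-way ANOVA; discrete variables are cross-tabulated
    and tested with Fisher's exact test.
    """
    import warnings

    if continuous_test not in ("kruskal_wallis", "anova"):
        raise ValueError(f"unknown continuous_test {continuous_test!r}")
    if discrete_test != "fisher_exact":
        raise ValueError(f"unknown discrete_test {discrete_test!r}")
    groups = sorted(table[group_column].dropna().unique())
    if len(groups) < 2:
        raise ValueError("need at least 2 groups for a demographics table")
    rows = []
    for var in continuous:
        if var not in table.columns:
            continue
        samples = [table.loc[table[group_column] == g, var].dropna().to_numpy(dtype=float)
                   for g in groups]
        summary = {g: f"{s.mean():.1f} ({s.std(ddof=1):.1f})" if s.size > 1 else "n/a"
                   for g, s in zip(groups, samples)}
        pooled = np.concatenate([s for s in samples if s.size])
        if pooled.size == 0 or np.unique(pooled).size < 2:
            warnings.warn(f"variable {var!r} has a single distinct value; p reported as missing")
            p = np.nan
        elif continuous_test == "kruskal_wallis":
            p = float(stats.kruskal(*[s for s in samples if s.size]).pvalue)
        else:
            p = float(stats.f_oneway(*[s for s in samples if s.size]).pvalue)
        rows.append({"variable": var, **summary, "test": continuous_test, "p": p})
    for var in discrete:
        if var not in table.columns:
            continue
        sub = table.dropna(subset=[var])
        ct = pd.crosstab(sub[var], sub[group_column])
        summary = {g: "/".join(str(int(v)) for v in ct[g]) if g in ct else "0"
                   for g in groups}
        if ct.shape[0] < 2 or ct.shape[1] < 2:
            warnings.warn(f"variable {var!r} has a single distinct value; p reported as missing")
            p = np.nan
        else:
            p = fisher_exact_rxc(ct.to_numpy(), seed=seed)
        rows.append({"variable": var, **summary, "test": "fisher_exact", "p": p})
    return pd.DataFrame(rows)
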