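"""Correlation of the asymmetry index with clinical and biomarker variables.

Spearman's rank correlation is the default for small cohorts (robust at
n ~ 20-60), Pearson's for large ones; the association battery runs CAI
against age, EYO, MMSE, and NfL (CSF and plasma) within the subgroups where
those associations are scientifically meaningful (all mutation carriers,
SMC, and for large cohorts also AMC, SMC-MCI and SMC-AD), on baseline
visits only, with pairwise deletion of missing values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class CorrelationResult:
    method: str  # "spearman" | "pearson"
    variable: str
    subgroup: str
    r: float  # NaN when undefined (constant input) or insufficient n
    p: float
    n: int
    flag: str = "ok"  # "ok" | "constant_input" | "insufficient_n"

    @property
    def valid(self) -> bool:
        return self.flag == "ok"


def correlate(
    x: Sequence[float],
    y: Sequence[float],
    method: str = "spearman",
    variable: str = "",
    subgroup: str = "",
) -> CorrelationResult:
    """Correlate two vectors after pairwise deletion of missing values.

    A constant vector yields a flagged result with r = NaN rather than an
    exception; n < 3 after deletion yields an ``insufficient_n`` flag.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError(f"unknown method {method!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    n = int(x.size)
    if n < 3:
        return CorrelationResult(method, variable, subgroup, np.nan, np.nan, n,
                                 flag="insufficient_n")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(method, variable, subgroup, np.nan, np.nan, n,
                                 flag="constant_input")
    if method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        r, p = stats.pearsonr(x, y)
    return CorrelationResult(method, variable, subgroup, float(r), float(p), n)


BATTERY_VARIABLES = {
    "age": "age_years",
    "eyo": "eyo_years",
    "mmse": "mmse",
    "csf_nfl": "csf_nfl_pg_ml",
    "plasma_nfl": "plasma_nfl_pg_ml",
}

_SUBGROUP_MASKS = {
    "mutation_carriers": lambda t: t["group"].isin(["AMC", "SMC"]),
    "AMC": lambda t: t["group"] == "AMC",
    "SMC": lambda t: t["group"] == "SMC",
    "SMC_MCI": lambda t: t["smc_subgroup"] == "SMC_MCI",
    "SMC_AD": lambda t: t["smc_subgroup"] == "SMC_AD",
}


def default_subgroups(cohort_template: str) -> tuple[str, ...]:
    if cohort_template == "dian_like":
        return ("mutation_carriers", "AMC", "SMC", "SMC_MCI", "SMC_AD")
    return ("mutation_carriers", "SMC")


def default_method(cohort_template: str) -> str:
    # rank correlation for the small cohort, Pearson for the large one
    return "spearman" if cohort_template == "barcelona_like" else "pearson"


def association_battery(
    table: pd.DataFrame,
    subgroups: Optional[Sequence[str]] = None,
    variables: Sequence[str] = tuple(BATTERY_VARIABLES),
    method: Optional[str] = None,
    bh_across_battery: bool = False,
) -> list[CorrelationResult]:
    """One CAI correlation per (subgroup, variable), baseline visits only."""
    baseline = table[table["visit"] == 0]
    template = baseline["cohort"].iloc[0] if "cohort" in baseline.columns and len(baseline) else "dian_like"
    method = method or default_method(template)
    subgroups = tuple(subgroups) if subgroups is not None else default_subgroups(template)
    results: list[CorrelationResult] = []
    for sub in subgroups:
        if sub not in _SUBGROUP_MASKS:
            raise ValueError(f"unknown subgroup {sub!r}")
        rows = baseline[_SUBGROUP_MASKS[sub](baseline)]
        for var in variables:
            col = BATTERY_VARIABLES[var]
            if col not in rows.columns:
                continue
            results.append(
                correlate(rows["cai"], pd.to_numeric(rows[col], errors="coerce"),
                          method=method, variable=var, subgroup=sub)
            )
    if bh_across_battery:
        from .inference import bh_adjust

        valid = [r for r in results if r.valid]
        adj = bh_adjust([r.p for r in valid])
        adj_map = {id(r): a for r, a in zip(valid, adj)}
        results = [
            CorrelationResult(r.method, r.variable, r.subgroup, r.r,
                              float(adj_map[id(r)]) if r.valid else r.p, r.n, r.flag)
            for r in results
        ]
    return results


def results_to_frame(results: Sequence[CorrelationResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])
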