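"""Longitudinal asymmetry trajectories over the EYO disease clock.

The trajectory model regresses CAI on estimated years to onset (EYO) across
all visits, semi-parametrically:

    CAI ~ s(EYO) + group + group:EYO + age + sex

with one common penalized cubic B-spline smooth of EYO shared by all groups,
parametric group offsets, *linear* group-by-EYO interactions (so that each
non-reference group's divergence from the reference trajectory is summarized
by a single t statistic), and age and sex as parametric nuisance terms. The
smoothing parameter is chosen by generalized cross-validation over a fixed
alpha grid. Setting ``smooth=False`` collapses the smooth to a plain linear
EYO term (ordinary least squares).

Repeated measures are treated as independent observations — there are no
within-participant random effects — which anti-conservatively narrows the
interaction standard errors; see docs/methods.md.

The module is organized statsmodels-style: build a :class:`TrajectoryModel`
from an analysis table, call :meth:`~TrajectoryModel.fit`, and read
estimates, interaction tests and predictions off the returned
:class:`TrajectoryResults`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

GROUPINGS = ("carriers_vs_ctr", "three_group", "four_group")


@dataclass(frozen=True)
class SmoothBasisConfig:
    """Penalized B-spline settings for the common EYO smooth."""

    n_basis: int = 10  # degrees of freedom of the B-spline basis
    degree: int = 3  # cubic
    alpha_grid: tuple[float, ...] = tuple(float(a) for a in np.logspace(-4, 6, 11))


def _grouping_labels(table: pd.DataFrame, grouping: str) -> pd.Series:
    if grouping == "carriers_vs_ctr":
        return table["group"].map(lambda g: "CTR" if g == "CTR" else "carrier")
    if grouping == "three_group":
        return table["group"].copy()
    if grouping == "four_group":
        return np.where(table["group"] == "SMC", table["smc_subgroup"], table["group"])
    raise ValueError(f"unknown grouping {grouping!r} (expected one of {GROUPINGS})")


class TrajectoryModel:
    """Semi-parametric model of CAI against EYO with group-specific slopes.

    Parameters
    ----------
    table
        Analysis table (all visits) with columns ``cai, eyo_years, age_years,
        sex, group, smc_subgroup``.
    grouping
        ``carriers_vs_ctr`` (CTR vs all carriers), ``three_group``
        (CTR/AMC/SMC) or ``four_group`` (CTR/AMC/SMC-MCI/SMC-AD). CTR is
        always the reference level.
    smooth
        Include the penalized spline smooth of EYO. With ``False`` the model
        is a purely parametric OLS with a linear EYO main effect.
    """

    def __init__(
        self,
        table: pd.DataFrame,
        grouping: str = "three_group",
        basis: Optional[SmoothBasisConfig] = None,
        smooth: bool = True,
    ) -> None:
        required = {"cai", "eyo_years", "age_years", "sex"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"analysis table is missing column(s) {sorted(missing)}")
        table = table.dropna(subset=["cai", "eyo_years", "age_years", "sex"])
        table = table.sort_values(
            ["participant_id", "visit"] if "participant_id" in table.columns else ["eyo_years"]
        ).reset_index(drop=True)
        self.table = table
        self.grouping = grouping
        self.basis = basis or SmoothBasisConfig()
        self.smooth = smooth

        labels = pd.Series(_grouping_labels(table, grouping), index=table.index).astype(str)
        self.levels = ["CTR"] + sorted(set(labels) - {"CTR"}) if "CTR" in set(labels) \
            else sorted(set(labels))
        if len(self.levels) < 2:
            raise ValueError("need at least 2 groups present")
        self.group_labels = labels
        self.eyo = table["eyo_years"].to_numpy(dtype=float)
        for lev in self.levels:
            if np.unique(self.eyo[labels == lev]).size < 3:
                raise ValueError(
                    f"group {lev!r} has fewer than 3 distinct EYO values; "
                    "no longitudinal spread to fit a trajectory"
                )
        self.y = table["cai"].to_numpy(dtype=float)
        self.age = table["age_years"].to_numpy(dtype=float)
        self.is_male = (table["sex"].astype(str) == "male").to_numpy(dtype=float)
        self._build_design()

    def _build_design(self) -> None:
        n = self.y.size
        cols = [np.ones(n)]
        names = ["const"]
        for lev in self.levels[1:]:
            cols.append((self.group_labels == lev).to_numpy(dtype=float))
            names.append(f"group[{lev}]")
        for lev in self.levels[1:]:
            cols.append((self.group_labels == lev).to_numpy(dtype=float) * self.eyo)
            names.append(f"group[{lev}]:eyo")
        if not self.smooth:
            cols.append(self.eyo)
            names.append("eyo")
        cols.append(self.age)
        names.append("age")
        cols.append(self.is_male)
        names.append("sex[male]")
        self.exog = np.column_stack(cols)
        self.exog_names = names
        self.interaction_index = {
            lev: names.index(f"group[{lev}]:eyo") for lev in self.levels[1:]
        }

    def fit(self, alpha: Optional[float] = None) -> "TrajectoryResults":
        """Fit by (penalized) least squares; alpha by GCV when not given."""
        if not self.smooth:
            import statsmodels.api as sm

            res = sm.OLS(self.y, self.exog).fit()
            rss = float(np.sum(res.resid ** 2))
            edf = float(self.exog.shape[1])
            n = self.y.size
            gcv = n * rss / (n - edf) ** 2
            return TrajectoryResults(self, res, alpha=0.0, gcv=gcv, edf=edf)

        from statsmodels.gam.api import BSplines, GLMGam

        smoother = BSplines(
            self.eyo, df=[self.basis.n_basis], degree=[self.basis.degree],
            include_intercept=False,
        )
        self._smoother = smoother

        def fit_at(a: float):
            from statsmodels.tools.sm_exceptions import PerfectSeparationError

            gam = GLMGam(self.y, exog=self.exog, smoother=smoother, alpha=[a])
            try:
                return gam.fit()
            except PerfectSeparationError:
                # noiseless data fit the model exactly; the penalized IRLS loop
                # refuses a zero-residual solution, so fall back to plain OLS on
                # the combined [parametric | basis] design (the penalty is
                # irrelevant at an exact interpolant)
                import statsmodels.api as sm

                res = sm.OLS(self.y, np.column_stack([self.exog, smoother.basis])).fit()
                res.edf = np.ones(res.params.size)
                return res

        if alpha is None:
            best = (np.inf, None, None)
            n = self.y.size
            for a in self.basis.alpha_grid:
                res = fit_at(a)
                rss = float(np.sum((self.y - res.fittedvalues) ** 2))
                edf = float(np.sum(res.edf))
                gcv = n * rss / max(n - edf, 1e-9) ** 2
                if gcv < best[0]:
                    best = (gcv, a, res)
            gcv, alpha, res = best
        else:
            res = fit_at(alpha)
            rss = float(np.sum((self.y - res.fittedvalues) ** 2))
            edf = float(np.sum(res.edf))
            gcv = self.y.size * rss / max(self.y.size - edf, 1e-9) ** 2
        return TrajectoryResults(self, res, alpha=float(alpha), gcv=float(gcv),
                                 edf=float(np.sum(res.edf)))


@dataclass
class TrajectoryResults:
    """Fitted trajectory model: estimates, interaction tests, predictions."""

    model: TrajectoryModel
    _res: object
    alpha: float
    gcv: float
    edf: float

    def __post_init__(self) -> None:
        names = self.model.exog_names
        params = np.asarray(self._res.params, dtype=float)
        bse = np.asarray(self._res.bse, dtype=float)
        tvals = np.asarray(self._res.tvalues, dtype=float)
        pvals = np.asarray(self._res.pvalues, dtype=float)
        self.params = pd.Series(params[: len(names)], index=names)
        self.bse = pd.Series(bse[: len(names)], index=names)
        self.interaction_tests = {
            lev: {
                "coefficient": float(params[i]),
                "se": float(bse[i]),
                "t": float(tvals[i]),
                "p": float(pvals[i]),
            }
            for lev, i in self.model.interaction_index.items()
        }
        self.n_observations = int(self.model.y.size)
        self.n_participants = (
            int(self.model.table["participant_id"].nunique())
            if "participant_id" in self.model.table.columns
            else self.n_observations
        )
        self.eyo_range = (float(self.model.eyo.min()), float(self.model.eyo.max()))

    @property
    def fittedvalues(self) -> np.ndarray:
        return np.asarray(self._res.fittedvalues, dtype=float)

    @property
    def resid(self) -> np.ndarray:
        return self.model.y - self.fittedvalues

    def _design_for(self, group_level: str, eyo_grid: np.ndarray,
                    eyo_param: Optional[np.ndarray] = None) -> np.ndarray:
        m = eyo_grid.size
        eyo_param = eyo_grid if eyo_param is None else eyo_param
        cols = [np.ones(m)]
        for lev in self.model.levels[1:]:
            cols.append(np.full(m, float(lev == group_level)))
        for lev in self.model.levels[1:]:
            cols.append(eyo_param * float(lev == group_level))
        if not self.model.smooth:
            cols.append(eyo_param)
        cols.append(np.full(m, self.model.age.mean()))  # reference covariates:
        cols.append(np.full(m, 0.5))  # mean age, balanced sex
        X = np.column_stack(cols)
        if self.model.smooth:
            B = self.model._smoother.transform(eyo_grid.reshape(-1, 1))
            X = np.column_stack([X, B])
        return X

    def predict_trajectories(
        self,
        eyo_grid: Sequence[float],
        allow_extrapolation: bool = False,
    ) -> pd.DataFrame:
        """Per-group CAI predictions (and pointwise SEs) at reference covariates.

        The grid must lie within the fitted EYO range unless
        ``allow_extrapolation`` is set, in which case the smooth's contribution
        is frozen at the nearest boundary and only the parametric part (the
        group-specific linear EYO terms) continues linearly.
        """
        grid = np.asarray(eyo_grid, dtype=float)
        lo, hi = self.eyo_range
        outside = (grid < lo) | (grid > hi)
        if outside.any() and not allow_extrapolation:
            raise ValueError(
                f"eyo_grid extends outside the fitted range [{lo:.2f}, {hi:.2f}]; "
                "pass allow_extrapolation=True to continue the parametric part linearly"
            )
        grid_clamped = np.clip(grid, lo, hi)
        cov = np.asarray(self._res.cov_params())
        params = np.asarray(self._res.params, dtype=float)
        frames = []
        for lev in self.model.levels:
            X = self._design_for(lev, grid_clamped, eyo_param=grid)
            pred = X @ params
            se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", X, cov, X), 0.0))
            frames.append(pd.DataFrame({
                "group": lev, "eyo_years": grid, "cai_pred": pred, "se": se,
                "extrapolated": outside,
            }))
        return pd.concat(frames, ignore_index=True)

    def summary(self) -> str:
        lines = [
            "Trajectory model: CAI ~ "
            + ("s(EYO)" if self.model.smooth else "EYO")
            + " + group + group:EYO + age + sex",
            f"grouping: {self.model.grouping}   groups: {', '.join(self.model.levels)}"
            f"   reference: {self.model.levels[0]}",
            f"n_observations: {self.n_observations}   n_participants: {self.n_participants}",
            f"alpha (GCV): {self.alpha:.4g}   edf: {self.edf:.2f}   GCV: {self.gcv:.4g}",
            "",
            f"{'term':<22}{'coef':>12}{'se':>12}{'t':>9}{'p':>10}",
        ]
        tvals = np.asarray(self._res.tvalues, dtype=float)
        pvals = np.asarray(self._res.pvalues, dtype=float)
        for i, name in enumerate(self.model.exog_names):
            lines.append(
                f"{name:<22}{self.params.iloc[i]:>12.5f}{self.bse.iloc[i]:>12.5f}"
                f"{tvals[i]:>9.2f}{pvals[i]:>10.4f}"
            )
        lines.append("")
        for lev, t in self.interaction_tests.items():
            lines.append(
                f"{lev} x EYO interaction: t = {t['t']:.2f}, P = {t['p']:.4g}"
            )
        return "\n".join(lines)


def fit_trajectory_model(
    table: pd.DataFrame,
    grouping: str = "three_group",
    basis: Optional[SmoothBasisConfig] = None,
    smooth: bool = True,
    alpha: Optional[float] = None,
) -> TrajectoryResults:
    """Convenience wrapper: build a :class:`TrajectoryModel` and fit it."""
    return TrajectoryModel(table, grouping=grouping, basis=basis, smooth=smooth).fit(alpha=alpha)
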