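"""Discrete-time survival estimation and effect measures.

The monthly grid makes survival analysis elementary: the discrete hazard at
month ``m`` is the probability of death during interval ``m`` given survival
to its start, and survival is the product-limit ``S_m = prod(1 - h_j)``.
Person-time rows with index ``k`` carry deaths "by the end of interval k+1",
so row ``k`` informs the hazard of month ``m = k + 1``.

Two estimators are provided: the (optionally weighted) life-table /
Kaplan-Meier estimator, and a pooled logistic regression for the hazard
whose baseline-time flexibility is declarative (quadratic by default,
saturated or spline optional).  Effect measures follow the trial-analysis
conventions: the discrete hazard ratio dHR (exponentiated arm coefficient),
the cumulative hazard ratio cHR at the horizon, and the risk ratio RR at the
horizon.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .core_data import DesignBuilder, TermSpec

__all__ = [
    "SurvivalCurve",
    "PooledLogisticFit",
    "EffectEstimates",
    "FitFailure",
    "km_curve",
    "fit_pooled_logistic",
    "curve_from_fit",
    "standardized_curve",
    "effect_estimates",
    "quadratic_time_terms",
]


class FitFailure(RuntimeError):
    """A model fit failed (non-convergence, separation, empty data).

    The bootstrap catches this and counts a replicate failure.
    """


@dataclass
class SurvivalCurve:
    """Hazard / survival / risk on the monthly grid 1..K.

    ``months[i]`` is the end of month ``i+1``; ``hazard[i]`` the discrete
    hazard of that month, ``survival[i]`` the product-limit survival and
    ``risk[i] = 1 - survival[i]``.  ``n_at_risk`` is the (possibly weighted)
    at-risk mass entering each month.  ``truncated_at`` marks the first
    month with zero at-risk mass, beyond which the curve is carried flat and
    undefined hazards are NaN.
    """

    months: np.ndarray
    hazard: np.ndarray
    survival: np.ndarray
    risk: np.ndarray
    n_at_risk: np.ndarray
    weighted: bool = False
    truncated_at: Optional[int] = None

    @classmethod
    def from_hazard(
        cls,
        hazard: np.ndarray,
        n_at_risk: Optional[np.ndarray] = None,
        weighted: bool = False,
        truncated_at: Optional[int] = None,
    ) -> "SurvivalCurve":
        hazard = np.asarray(hazard, dtype=float)
        surv = np.cumprod(1.0 - np.nan_to_num(hazard, nan=0.0))
        months = np.arange(1, len(hazard) + 1)
        if n_at_risk is None:
            n_at_risk = np.full(len(hazard), np.nan)
        return cls(
            months=months,
            hazard=hazard,
            survival=surv,
            risk=1.0 - surv,
            n_at_risk=np.asarray(n_at_risk, dtype=float),
            weighted=weighted,
            truncated_at=truncated_at,
        )

    @classmethod
    def from_risk(cls, risk: np.ndarray, weighted: bool = False) -> "SurvivalCurve":
        """Build a curve from a cumulative-risk sequence (e.g. a simulation)."""
        risk = np.asarray(risk, dtype=float)
        surv = 1.0 - risk
        prev = np.concatenate([[1.0], surv[:-1]])
        with np.errstate(divide="ignore", invalid="ignore"):
            hazard = np.where(prev > 0, 1.0 - surv / prev, np.nan)
        return cls(
            months=np.arange(1, len(risk) + 1),
            hazard=hazard,
            survival=surv,
            risk=risk,
            n_at_risk=np.full(len(risk), np.nan),
            weighted=weighted,
        )

    def risk_at(self, month: int) -> float:
        if month < 1 or month > len(self.months):
            raise ValueError(f"month {month} outside curve grid 1..{len(self.months)}")
        return float(self.risk[month - 1])

    def survival_at(self, month: int) -> float:
        return 1.0 - self.risk_at(month)

    def greenwood_se(self, month: int) -> float:
        """Greenwood standard error of the risk (= SE of survival) at a month.

        Requires at-risk counts; for weighted curves this treats the weighted
        masses as effective counts (an approximation).
        """
        h = np.nan_to_num(self.hazard[:month], nan=0.0)
        n = self.n_at_risk[:month]
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where((n > 0) & (h < 1), h / (n * (1.0 - h)), 0.0)
        s = self.survival[month - 1]
        return float(s * np.sqrt(terms.sum()))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "month": self.months,
                "hazard": self.hazard,
                "survival": self.survival,
                "risk": self.risk,
                "n_at_risk": self.n_at_risk,
            }
        )


@dataclass
class PooledLogisticFit:
    """A fitted pooled (over person-time) logistic hazard model."""

    labels: list[str]
    params: np.ndarray
    cov_params: np.ndarray
    converged: bool
    n_obs: int
    builder: DesignBuilder
    llf: float = np.nan
    failure_reason: Optional[str] = None

    def coef(self, label: str) -> float:
        return float(self.params[self.labels.index(label)])

    def se(self, label: str) -> float:
        i = self.labels.index(label)
        return float(np.sqrt(self.cov_params[i, i]))

    def predict(self, df: pd.DataFrame) -> np.ndarray:
        X, _ = self.builder.transform(df)
        eta = X @ self.params
        return 1.0 / (1.0 + np.exp(-eta))

    @property
    def aic(self) -> float:
        return -2.0 * self.llf + 2.0 * len(self.params)


@dataclass
class EffectEstimates:
    """dHR, cHR and RR comparing experimental to control at a horizon."""

    horizon: int
    estimator: str
    rr: float = np.nan
    chr: float = np.nan
    dhr: float = np.nan
    chr_method: str = "log_survival"
    rr_ci: Optional[tuple] = None
    chr_ci: Optional[tuple] = None
    dhr_ci: Optional[tuple] = None
    flags: list = field(default_factory=list)

    def to_frame(self, approach: str = "") -> pd.DataFrame:
        rows = []
        for measure, est, ci in (
            ("dHR", self.dhr, self.dhr_ci),
            ("cHR", self.chr, self.chr_ci),
            ("RR", self.rr, self.rr_ci),
        ):
            rows.append(
                {
                    "approach": approach,
                    "estimator": self.estimator,
                    "measure": measure,
                    "estimate": est,
                    "ci_low": ci[0] if ci else np.nan,
                    "ci_high": ci[1] if ci else np.nan,
                }
            )
        return pd.DataFrame(rows)


def km_curve(
    table: pd.DataFrame,
    weights: Optional[pd.Series] = None,
    horizon: Optional[int] = None,
) -> SurvivalCurve:
    """(Weighted) life-table estimator on the person-time table.

    ``weights`` is a per-row series aligned with ``table``'s index; the
    unweighted case is the Kaplan-Meier estimator on the discretized data.
    Subjects censored in month k count as at risk during month k (standard
    life-table convention); deaths leave the risk set after their month.
    """
    if weights is None:
        w = np.ones(len(table))
        weighted = False
    else:
        w = np.asarray(weights.reindex(table.index), dtype=float)
        if np.any(~np.isfinite(w)):
            raise ValueError("non-finite weights passed to km_curve")
        weighted = True
    k = table["k"].to_numpy()
    y = table["outcome"].to_numpy()
    K = int(k.max()) + 1 if len(k) else 0
    if horizon is not None:
        K = max(K, horizon)
    at_risk = np.bincount(k, weights=w, minlength=K)
    deaths = np.bincount(k, weights=w * y, minlength=K)
    hazard = np.full(K, np.nan)
    truncated_at = None
    for m in range(K):
        if at_risk[m] > 0:
            hazard[m] = deaths[m] / at_risk[m]
        else:
            truncated_at = m + 1
            break
    return SurvivalCurve.from_hazard(
        hazard, n_at_risk=at_risk, weighted=weighted, truncated_at=truncated_at
    )


def quadratic_time_terms() -> list[TermSpec]:
    """The default baseline-hazard flexibility: time as a quadratic polynomial."""
    return [TermSpec("k", role="time_varying", transform="quadratic")]


def fit_pooled_logistic(
    table: pd.DataFrame,
    terms: Sequence[TermSpec],
    outcome_col: str = "outcome",
    weights: Optional[pd.Series] = None,
    builder: Optional[DesignBuilder] = None,
) -> PooledLogisticFit:
    """Maximum-likelihood logistic fit of a discrete hazard.

    Rows must already be restricted to the at-risk set.  ``weights`` makes
    this a weighted (pseudo-likelihood) fit for IPCW outcome models.  An
    all-zero or all-one outcome, separation, or non-convergence yields a fit
    flagged ``converged = False`` — callers (and the bootstrap) must check.
    """
    if len(table) == 0:
        raise FitFailure("empty fitting table")
    y = np.asarray(table[outcome_col], dtype=float)
    if builder is None:
        builder = DesignBuilder(terms, add_intercept=True)
        builder.fit(table)
    X, labels = builder.transform(table)
    w = None if weights is None else np.asarray(weights.reindex(table.index), float)
    n_events = y.sum() if w is None else float((y * w).sum())
    if n_events == 0 or n_events == (len(y) if w is None else float(np.sum(w))):
        return PooledLogisticFit(
            labels=labels,
            params=np.full(X.shape[1], np.nan),
            cov_params=np.full((X.shape[1], X.shape[1]), np.nan),
            converged=False,
            n_obs=len(y),
            builder=builder,
            failure_reason="degenerate outcome (no variation)",
        )
    model = sm.GLM(y, X, family=sm.families.Binomial(), var_weights=w)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(maxiter=100)
        converged = bool(res.converged) and np.all(np.isfinite(res.params))
        # huge coefficients signal quasi-separation even when IRLS "converges"
        if converged and np.max(np.abs(res.params)) > 50:
            converged = False
        return PooledLogisticFit(
            labels=labels,
            params=np.asarray(res.params),
            cov_params=np.asarray(res.cov_params()),
            converged=converged,
            n_obs=len(y),
            builder=builder,
            llf=float(res.llf),
            failure_reason=None if converged else "non-convergence or separation",
        )
    except Exception as exc:  # separation / singular matrix
        return PooledLogisticFit(
            labels=labels,
            params=np.full(X.shape[1], np.nan),
            cov_params=np.full((X.shape[1], X.shape[1]), np.nan),
            converged=False,
            n_obs=len(y),
            builder=builder,
            failure_reason=str(exc),
        )


def curve_from_fit(
    fit: PooledLogisticFit, profile: pd.DataFrame, horizon: int
) -> SurvivalCurve:
    """Model-implied survival curve for one covariate profile.

    ``profile`` is a single-row frame of covariate values; time (``k``) is
    swept over 0..horizon-1 with all other columns held fixed.
    """
    if not fit.converged:
        raise FitFailure(f"cannot predict from failed fit: {fit.failure_reason}")
    if len(profile) != 1:
        raise ValueError("profile must be a single row; see standardized_curve")
    grid = profile.loc[profile.index.repeat(horizon)].reset_index(drop=True)
    grid["k"] = np.arange(horizon)
    hazard = fit.predict(grid)
    return SurvivalCurve.from_hazard(hazard)


def standardized_curve(
    fit: PooledLogisticFit,
    baseline_table: pd.DataFrame,
    horizon: int,
    set_columns: Optional[dict] = None,
) -> SurvivalCurve:
    """Marginal curve standardized over a baseline-covariate table.

    Implements the cloned-dataset procedure: every subject in
    ``baseline_table`` (one row each) is copied across months 0..horizon-1,
    ``set_columns`` forces intervention columns (e.g. ``{"arm": 1}``),
    per-subject hazards are cumulated into per-subject risks, and the
    marginal risk at each month is the *mean of risks* (never a mean of
    hazards).
    """
    if not fit.converged:
        raise FitFailure(f"cannot predict from failed fit: {fit.failure_reason}")
    n = len(baseline_table)
    grid = baseline_table.loc[baseline_table.index.repeat(horizon)].reset_index(
        drop=True
    )
    grid["k"] = np.tile(np.arange(horizon), n)
    if set_columns:
        for col, value in set_columns.items():
            grid[col] = value
    hazards = fit.predict(grid).reshape(n, horizon)
    surv = np.cumprod(1.0 - hazards, axis=1)
    marginal_risk = 1.0 - surv.mean(axis=0)
    return SurvivalCurve.from_risk(marginal_risk)


def effect_estimates(
    curve_control: SurvivalCurve,
    curve_experimental: SurvivalCurve,
    fit: Optional[PooledLogisticFit] = None,
    horizon: int = 48,
    arm_label: str = "arm",
    chr_method: str = "log_survival",
) -> EffectEstimates:
    """RR, cHR (and dHR when an outcome fit with an arm term is supplied).

    ``chr_method='log_survival'`` uses the cumulative hazard ``-ln S(t)``;
    ``'sum_hazard'`` uses the discrete sum of hazards.  Both coincide for
    small hazards; the choice is recorded on the result.
    """
    flags = []
    risk_c = curve_control.risk_at(horizon)
    risk_e = curve_experimental.risk_at(horizon)
    if risk_c <= 0:
        flags.append("zero risk in control arm: RR undefined")
        rr = np.nan
    else:
        rr = risk_e / risk_c
    if chr_method == "log_survival":
        s_c, s_e = 1.0 - risk_c, 1.0 - risk_e
        if s_c >= 1.0 or s_c <= 0.0 or s_e <= 0.0:
            flags.append("survival at 1 or 0: cHR undefined")
            chr_val = np.nan
        else:
            chr_val = np.log(s_e) / np.log(s_c)
    elif chr_method == "sum_hazard":
        h_c = np.nansum(curve_control.hazard[:horizon])
        h_e = np.nansum(curve_experimental.hazard[:horizon])
        chr_val = h_e / h_c if h_c > 0 else np.nan
        if h_c <= 0:
            flags.append("zero cumulative hazard in control arm: cHR undefined")
    else:
        raise ValueError(f"unknown chr_method {chr_method!r}")
    dhr = np.nan
    if fit is not None and fit.converged and arm_label in fit.labels:
        dhr = float(np.exp(fit.coef(arm_label)))
    return EffectEstimates(
        horizon=horizon,
        estimator="km" if fit is None else "pooled_logistic",
        rr=rr,
        chr=chr_val,
        dhr=dhr,
        chr_method=chr_method,
        flags=flags,
    )
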