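"""Noniterative-conditional-expectation parametric g-formula.

Each arm of the trial is analysed as a separate observational study: pooled
over time models are fitted for every time-varying covariate (logistic for
binary/categorical, linear-Gaussian for continuous) and for the discrete
hazard of death, then Monte-Carlo simulation rolls covariate histories
forward under a sustained treatment strategy ("always treat", with
switching and loss to follow-up eliminated) and accumulates the
counterfactual risk.

Deterministic knowledge is wired into both fitting and simulation:
progression indicators are absorbing (models are fitted only where the
lagged value is 0, and simulated values stick at 1), and the hazard of
death is structurally 0 before disease progression.  A post-hoc audit of
every simulated dataset verifies the intervention, the restrictions and
the covariate ordering, and the natural-course mode (treatment and
switching simulated from their observed distributions, no intervention)
backs the standard model-misspecification diagnostic: simulated covariate
means and risks are compared month by month against the observed data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import DesignBuilder, TermSpec
from .discrete_survival import (
    EffectEstimates,
    FitFailure,
    PooledLogisticFit,
    SurvivalCurve,
    effect_estimates,
    fit_pooled_logistic,
    km_curve,
)

__all__ = [
    "CovariateModel",
    "GFormulaSpec",
    "LinearGaussianFit",
    "GFormulaModels",
    "GFormulaResult",
    "default_gformula_spec",
    "fit_gformula_models",
    "simulate_counterfactual",
    "natural_course_check",
    "gformula_effects",
    "screen_gformula_spec",
    "add_lag_columns",
]

_FAMILIES = ("binary-logistic", "categorical-logistic", "linear-gaussian")
_TVC_LAGS = {"dp": "lag_dp", "icp": "lag_icp", "ecog_tv": "lag_ecog_tv", "tls": "lag_tls"}


@dataclass(frozen=True)
class CovariateModel:
    """One time-varying covariate's conditional model.

    ``terms`` may reference baseline covariates, time ``k``, current
    ``treatment``, lagged state (``lag_dp``, ``lag_icp``, ``lag_ecog_tv``,
    ``lag_tls``, ``lag_treatment``) and covariates simulated *earlier in
    the same interval* (covariate order is the spec's list order).
    ``absorbing`` covariates are fitted on person-time with lagged value 0
    and stick at 1 once set.
    """

    name: str
    family: str
    terms: Sequence[TermSpec]
    absorbing: bool = False

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}")


@dataclass(frozen=True)
class GFormulaSpec:
    """Ordered covariate models, outcome model and simulation settings."""

    covariate_models: Sequence[CovariateModel]
    outcome_terms: Sequence[TermSpec]
    n_simulated: int = 10_000
    horizon: int = 48
    label: str = "gformula"
    # switching hazard model (control arm), used only by the natural course
    switch_terms: Sequence[TermSpec] = (
        TermSpec("tls", "time_varying", "linear"),
        TermSpec("ecog_tv", "time_varying", "linear"),
        TermSpec("tdp", "time_varying", "linear"),
    )

    def __post_init__(self) -> None:
        known = set(_TVC_LAGS) | {"tdp"}
        simulated: set = set()
        for cm in self.covariate_models:
            for t in cm.terms:
                base = t.name
                if base.startswith("lag_") or base in ("k", "treatment", "lag_treatment", "tdp"):
                    continue
                if base in known and base not in simulated:
                    raise ValueError(
                        f"model for {cm.name} references {base!r} before it is "
                        f"simulated (covariate order is the list order)"
                    )
            simulated.add(cm.name)


@dataclass
class LinearGaussianFit:
    """Pooled linear regression with Gaussian residuals."""

    labels: list[str]
    params: np.ndarray
    resid_sd: float
    builder: DesignBuilder
    converged: bool = True
    n_obs: int = 0
    failure_reason: Optional[str] = None

    def predict(self, df: pd.DataFrame) -> np.ndarray:
        X, _ = self.builder.transform(df)
        return X @ self.params


@dataclass
class GFormulaModels:
    """Fitted model set for one arm."""

    arm: int
    spec: GFormulaSpec
    covariate_fits: dict
    outcome_fit: PooledLogisticFit
    switch_fit: Optional[PooledLogisticFit] = None
    dropped_terms: dict = field(default_factory=dict)

    @property
    def converged(self) -> bool:
        return self.outcome_fit.converged and all(
            f.converged for f in self.covariate_fits.values()
        )


@dataclass
class GFormulaResult:
    """Counterfactual risk curve plus simulated covariate means and audit."""

    strategy: str
    arm: int
    risk: np.ndarray
    covariate_means: pd.DataFrame
    n_simulated: int
    label: str = ""
    audit: dict = field(default_factory=dict)
    clamped: int = 0

    @property
    def curve(self) -> SurvivalCurve:
        return SurvivalCurve.from_risk(self.risk)

    def risk_at(self, month: int) -> float:
        return float(self.risk[month - 1])

    def mc_se(self, month: int) -> float:
        p = self.risk_at(month)
        return float(np.sqrt(p * (1.0 - p) / self.n_simulated))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "month": np.arange(1, len(self.risk) + 1),
                "strategy": self.strategy,
                "risk": self.risk,
                "mc_se": [self.mc_se(m) for m in range(1, len(self.risk) + 1)],
            }
        )


def default_gformula_spec(
    n_simulated: int = 10_000, horizon: int = 48, label: str = "gformula-spec-1"
) -> GFormulaSpec:
    """The shipped well-specified model set.

    Covariate order: progression, intracranial progression, performance
    state, lesion size — progression first so same-interval models may
    condition on it.  History depth is one lag of each covariate plus the
    current interval's earlier covariates; the outcome model reads the
    current state plus quadratic time.
    """
    return GFormulaSpec(
        covariate_models=(
            CovariateModel(
                "dp",
                "binary-logistic",
                (
                    TermSpec("lag_treatment", "time_varying", "linear"),
                    TermSpec("lag_tls", "time_varying", "linear"),
                    TermSpec("lag_ecog_tv", "time_varying", "linear"),
                    TermSpec("age", "baseline", "linear"),
                ),
                absorbing=True,
            ),
            CovariateModel(
                "icp",
                "binary-logistic",
                (
                    TermSpec("ics", "baseline", "categorical", 2),
                    TermSpec("lag_dp", "time_varying", "linear"),
                    TermSpec("lag_treatment", "time_varying", "linear"),
                ),
                absorbing=True,
            ),
            CovariateModel(
                "ecog_tv",
                "binary-logistic",
                (
                    TermSpec("lag_ecog_tv", "time_varying", "linear"),
                    TermSpec("lag_treatment", "time_varying", "linear"),
                    TermSpec("lag_dp", "time_varying", "linear"),
                ),
            ),
            CovariateModel(
                "tls",
                "linear-gaussian",
                (
                    TermSpec("lag_tls", "time_varying", "linear"),
                    TermSpec("lag_treatment", "time_varying", "linear"),
                    TermSpec("lag_dp", "time_varying", "linear"),
                ),
            ),
        ),
        outcome_terms=(
            TermSpec("treatment", "time_varying", "linear"),
            TermSpec("tls", "time_varying", "linear"),
            TermSpec("ecog_tv", "time_varying", "linear"),
            TermSpec("icp", "time_varying", "linear"),
        ),
        n_simulated=n_simulated,
        horizon=horizon,
        label=label,
    )


def add_lag_columns(table: pd.DataFrame) -> pd.DataFrame:
    """One-month lags of the time-varying state, within subject.

    At ``k = 0`` lagged progression indicators are 0, lagged ECOG/TLS equal
    their baseline (first-row) values and lagged treatment equals the
    randomized assignment.
    """
    work = table.sort_values(["subject_id", "k"]).copy()
    grp = work.groupby("subject_id", sort=False)
    for cur, lag in _TVC_LAGS.items():
        work[lag] = grp[cur].shift(1)
    work["lag_treatment"] = grp["treatment"].shift(1)
    first = work["k"] == 0
    work.loc[first, "lag_dp"] = 0
    work.loc[first, "lag_icp"] = 0
    work.loc[first, "lag_ecog_tv"] = work.loc[first, "ecog_tv"]
    work.loc[first, "lag_tls"] = work.loc[first, "tls"]
    work.loc[first, "lag_treatment"] = work.loc[first, "arm"]
    return work


def _drop_constant_terms(
    df: pd.DataFrame, terms: Sequence[TermSpec]
) -> tuple[list[TermSpec], list[str]]:
    """Remove terms whose column is constant on the fitting data (e.g.
    treatment in the experimental arm, where everyone is always treated)."""
    kept, dropped = [], []
    for t in terms:
        if t.name in df.columns and df[t.name].nunique() <= 1:
            dropped.append(t.name)
        else:
            kept.append(t)
    return kept, dropped


def fit_gformula_models(
    table: pd.DataFrame, spec: GFormulaSpec, arm: int
) -> GFormulaModels:
    """Fit the covariate, outcome (and switching) models for one arm.

    Covariate models are fitted on person-time from interval 1 onward
    (interval 0 is the baseline state, which the simulation resamples
    directly); absorbing covariates only where the lagged value is 0.  The
    outcome model is fitted on post-progression person-time only — the
    death-gating restriction.  Any model with an empty eligible subset or a
    failed fit raises :class:`FitFailure` (a bootstrap replicate failure).
    """
    arm_table = table.loc[table["arm"] == arm]
    if len(arm_table) == 0:
        raise FitFailure(f"g-formula: no person-time in arm {arm}")
    work = add_lag_columns(arm_table)
    fit_rows = work.loc[work["k"] >= 1]
    covariate_fits: dict = {}
    dropped_record: dict = {}
    for cm in spec.covariate_models:
        rows = fit_rows
        if cm.absorbing:
            rows = rows.loc[rows[_TVC_LAGS[cm.name]] == 0]
        if len(rows) == 0:
            raise FitFailure(
                f"g-formula arm {arm}: empty eligible subset for {cm.name}"
            )
        if cm.absorbing and rows[cm.name].nunique() <= 1 and rows[cm.name].iloc[0] == 1:
            # everyone flips immediately: degenerate but simulable as constant
            raise FitFailure(
                f"g-formula arm {arm}: {cm.name} has no variation in eligible set"
            )
        terms, dropped = _drop_constant_terms(rows, list(cm.terms))
        if dropped:
            dropped_record[cm.name] = dropped
        if cm.family in ("binary-logistic", "categorical-logistic"):
            if cm.family == "categorical-logistic" and rows[cm.name].nunique() > 2:
                fit = _fit_multinomial(rows, cm.name, terms)
            else:
                fit = fit_pooled_logistic(rows, terms, outcome_col=cm.name)
            if not fit.converged:
                raise FitFailure(
                    f"g-formula arm {arm}: model for {cm.name} failed "
                    f"({fit.failure_reason})"
                )
        else:
            fit = _fit_linear_gaussian(rows, cm.name, terms)
        covariate_fits[cm.name] = fit

    at_risk = work.loc[work["dp"] == 1]
    if len(at_risk) == 0 or at_risk["outcome"].sum() == 0:
        raise FitFailure(f"g-formula arm {arm}: no deaths in post-progression set")
    outcome_terms, dropped = _drop_constant_terms(at_risk, list(spec.outcome_terms))
    if dropped:
        dropped_record["outcome"] = dropped
    outcome_fit = fit_pooled_logistic(at_risk, outcome_terms, outcome_col="outcome")
    if not outcome_fit.converged:
        raise FitFailure(
            f"g-formula arm {arm}: outcome model failed ({outcome_fit.failure_reason})"
        )

    switch_fit = None
    if arm == 0 and (work["switched"] == 1).any():
        post = work.loc[
            (work["dp"] == 1)
            & ((work["switched"] == 0) | (_switch_event_rows(work)))
        ].copy()
        post["_switch_event"] = _switch_event_rows(work).loc[post.index].astype(int)
        s_terms, _ = _drop_constant_terms(post, list(spec.switch_terms))
        switch_fit = fit_pooled_logistic(post, s_terms, outcome_col="_switch_event")

    return GFormulaModels(
        arm=arm,
        spec=spec,
        covariate_fits=covariate_fits,
        outcome_fit=outcome_fit,
        switch_fit=switch_fit,
        dropped_terms=dropped_record,
    )


def _switch_event_rows(work: pd.DataFrame) -> pd.Series:
    prev = work.groupby("subject_id", sort=False)["switched"].shift(1, fill_value=0)
    return (work["switched"] == 1) & (prev == 0)


def _fit_linear_gaussian(
    rows: pd.DataFrame, name: str, terms: Sequence[TermSpec]
) -> LinearGaussianFit:
    builder = DesignBuilder(terms, add_intercept=True)
    X, labels = builder.fit_transform(rows)
    y = rows[name].to_numpy(dtype=float)
    try:
        params, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    except np.linalg.LinAlgError as exc:
        raise FitFailure(f"linear model for {name} failed: {exc}")
    resid = y - X @ params
    dof = max(len(y) - X.shape[1], 1)
    resid_sd = float(np.sqrt(resid @ resid / dof))
    return LinearGaussianFit(
        labels=labels, params=params, resid_sd=resid_sd, builder=builder, n_obs=len(y)
    )


class _MultinomialFit:
    """Pooled multinomial logistic model for a >2-level covariate."""

    def __init__(self, levels, builder, params):
        self.levels = levels
        self.builder = builder
        self.params = params       # (n_features, n_levels - 1)
        self.converged = True
        self.failure_reason = None
        self.labels = []

    def predict_proba(self, df: pd.DataFrame) -> np.ndarray:
        X, _ = self.builder.transform(df)
        eta = X @ self.params      # reference level first
        exp_eta = np.exp(eta - eta.max(axis=1, keepdims=True).clip(min=0))
        denom = np.exp(-eta.max(axis=1, keepdims=True).clip(min=0)) + exp_eta.sum(
            axis=1, keepdims=True
        )
        probs_rest = exp_eta / denom
        p0 = 1.0 - probs_rest.sum(axis=1, keepdims=True)
        return np.hstack([p0, probs_rest])


def _fit_multinomial(rows, name, terms) -> _MultinomialFit:
    import statsmodels.api as sm

    builder = DesignBuilder(terms, add_intercept=True)
    X, labels = builder.fit_transform(rows)
    levels = sorted(rows[name].unique())
    y = rows[name].map({lvl: i for i, lvl in enumerate(levels)}).to_numpy()
    try:
        res = sm.MNLogit(y, X).fit(disp=0, maxiter=200)
    except Exception as exc:
        raise FitFailure(f"multinomial model for {name} failed: {exc}")
    fit = _MultinomialFit(levels, builder, np.asarray(res.params))
    fit.labels = labels
    return fit


_STRATEGY_TREATMENT = {"always_control": 0, "always_experimental": 1}


def simulate_counterfactual(
    models: GFormulaModels,
    baseline_table: pd.DataFrame,
    strategy: str,
    seed: int,
    n_simulated: Optional[int] = None,
    natural_course: bool = False,
) -> GFormulaResult:
    """Monte-Carlo simulation of covariate and outcome histories.

    Baseline profiles are resampled with replacement from ``baseline_table``
    (the ``k = 0`` rows of the arm being analysed).  Each month, covariates
    are simulated in spec order from the fitted models with treatment
    forced to the strategy's value; absorbing restrictions and the
    death-gating rule are applied; censoring is never simulated.  In
    natural-course mode treatment follows the fitted switching model
    (control arm) instead of the intervention.

    Linear predictors that map outside [0, 1] cannot occur for logistic
    models; Gaussian covariates are left unclamped.
    """
    if not natural_course and strategy not in _STRATEGY_TREATMENT:
        raise ValueError(f"unknown strategy {strategy!r}")
    if not models.converged:
        raise FitFailure("g-formula models not converged")
    spec = models.spec
    n = n_simulated or spec.n_simulated
    K = spec.horizon
    rng = np.random.default_rng(seed)
    base = baseline_table.reset_index(drop=True)
    idx = rng.integers(0, len(base), size=n)
    state = base.loc[idx].reset_index(drop=True).copy()
    state["k"] = 0
    state["dp"] = state["dp"].astype(int)
    state["icp"] = state["icp"].astype(int)
    state["tdp"] = 0
    if natural_course:
        state["treatment"] = state["arm"]
    else:
        state["treatment"] = _STRATEGY_TREATMENT[strategy]
    switched = np.zeros(n, dtype=bool)
    prog_month = np.where(state["dp"] == 1, 0, -1)
    alive = np.ones(n, dtype=bool)
    dead_by = np.full(n, K + 1)

    risk = np.zeros(K)
    cov_names = [cm.name for cm in spec.covariate_models]
    means = {name: np.full(K, np.nan) for name in cov_names}
    means_treatment = np.full(K, np.nan)

    # month 0: record state; death gated on dp (dp_0 is observed baseline)
    for name in cov_names:
        means[name][0] = state.loc[alive, name].mean()
    means_treatment[0] = state.loc[alive, "treatment"].mean()
    at_risk0 = alive & (state["dp"].to_numpy() == 1)
    if at_risk0.any():
        p0 = np.zeros(n)
        p0[at_risk0] = models.outcome_fit.predict(state.loc[at_risk0])
        died0 = at_risk0 & (rng.uniform(size=n) < p0)
        dead_by[died0] = 1
        alive &= ~died0
    risk[0] = np.mean(dead_by <= 1)

    for k in range(1, K):
        # shift current state into lags
        state["lag_dp"] = state["dp"]
        state["lag_icp"] = state["icp"]
        state["lag_ecog_tv"] = state["ecog_tv"]
        state["lag_tls"] = state["tls"]
        state["lag_treatment"] = state["treatment"]
        state["k"] = k

        for cm in spec.covariate_models:
            fit = models.covariate_fits[cm.name]
            if cm.family == "linear-gaussian":
                mean = fit.predict(state)
                value = mean + fit.resid_sd * rng.normal(size=n)
                state[cm.name] = np.where(alive, value, state[cm.name])
            elif isinstance(fit, _MultinomialFit):
                probs = fit.predict_proba(state)
                u = rng.uniform(size=n)
                draws = (u[:, None] > probs.cumsum(axis=1)).sum(axis=1)
                value = np.asarray(fit.levels)[draws]
                state[cm.name] = np.where(alive, value, state[cm.name])
            else:
                p = fit.predict(state)
                draw = (rng.uniform(size=n) < p).astype(int)
                if cm.absorbing:
                    prev = state[_TVC_LAGS[cm.name]].to_numpy().astype(int)
                    value = np.where(prev == 1, 1, draw)
                else:
                    value = draw
                state[cm.name] = np.where(alive, value, state[cm.name])
            if cm.name == "dp":
                newly = (state["dp"].to_numpy() == 1) & (prog_month < 0) & alive
                prog_month[newly] = k
        dp_now = state["dp"].to_numpy() == 1
        state["tdp"] = np.where(dp_now & (prog_month >= 0), k - prog_month, 0)

        if natural_course and models.arm == 0 and models.switch_fit is not None:
            eligible = alive & dp_now & ~switched
            if eligible.any():
                p_sw = np.zeros(n)
                p_sw[eligible] = models.switch_fit.predict(state.loc[eligible])
                new_sw = eligible & (rng.uniform(size=n) < p_sw)
                switched |= new_sw
            state["treatment"] = np.where(switched, 1, state["arm"])
        elif not natural_course:
            state["treatment"] = _STRATEGY_TREATMENT[strategy]

        for name in cov_names:
            means[name][k] = state.loc[alive, name].mean() if alive.any() else np.nan
        means_treatment[k] = (
            state.loc[alive, "treatment"].mean() if alive.any() else np.nan
        )

        at_risk = alive & dp_now
        if at_risk.any():
            p_death = np.zeros(n)
            p_death[at_risk] = models.outcome_fit.predict(state.loc[at_risk])
            died = at_risk & (rng.uniform(size=n) < p_death)
            dead_by[died] = k + 1
            alive &= ~died
        risk[k] = np.mean(dead_by <= k + 1)

    cov_frame = pd.DataFrame({"month": np.arange(K), **means})
    cov_frame["treatment"] = means_treatment
    audit = {
        "risk_non_decreasing": bool(np.all(np.diff(risk) >= -1e-12)),
        "dp_mean_non_decreasing": bool(
            np.all(np.diff(np.nan_to_num(means["dp"], nan=1.0)) >= -0.05)
        ),
        "treatment_forced": bool(natural_course)
        or bool(
            np.isclose(
                np.nanmean(means_treatment), _STRATEGY_TREATMENT[strategy]
            )
        ),
        "no_censoring_simulated": True,
    }
    return GFormulaResult(
        strategy=strategy if not natural_course else "natural_course",
        arm=models.arm,
        risk=risk,
        covariate_means=cov_frame,
        n_simulated=n,
        label=spec.label,
        audit=audit,
    )


def natural_course_check(
    models: GFormulaModels,
    table: pd.DataFrame,
    seed: int,
    n_simulated: int = 20_000,
    se_multiple: float = 3.0,
) -> pd.DataFrame:
    """Model-misspecification diagnostic: natural course versus observed.

    Simulates the arm with no intervention and compares, month by month,
    simulated covariate means against observed means among subjects still
    under follow-up, and the simulated cumulative risk against the
    Kaplan-Meier risk.  The pass criterion is agreement within
    ``se_multiple`` combined (simulation + sampling) standard errors.
    """
    arm_table = table.loc[table["arm"] == models.arm]
    baseline = arm_table.loc[arm_table["k"] == 0]
    sim = simulate_counterfactual(
        models,
        baseline,
        strategy="always_control",
        seed=seed,
        n_simulated=n_simulated,
        natural_course=True,
    )
    km = km_curve(arm_table, horizon=models.spec.horizon)
    rows = []
    cov_names = [cm.name for cm in models.spec.covariate_models]
    for k in range(models.spec.horizon):
        obs_rows = arm_table.loc[arm_table["k"] == k]
        for name in cov_names:
            if len(obs_rows) < 5:
                continue
            obs_mean = obs_rows[name].mean()
            obs_se = obs_rows[name].std(ddof=1) / np.sqrt(len(obs_rows))
            sim_mean = sim.covariate_means.loc[k, name]
            sim_col_sd = max(
                np.sqrt(max(sim_mean * (1 - sim_mean), 0.0))
                if name != "tls"
                else obs_rows[name].std(ddof=1),
                1e-12,
            )
            sim_se = sim_col_sd / np.sqrt(n_simulated)
            se = np.sqrt(obs_se**2 + sim_se**2)
            diff = sim_mean - obs_mean
            rows.append(
                {
                    "month": k,
                    "quantity": name,
                    "observed": obs_mean,
                    "simulated": sim_mean,
                    "abs_diff": abs(diff),
                    "rel_diff": abs(diff) / abs(obs_mean) if obs_mean else np.nan,
                    "se": se,
                    "ok": bool(abs(diff) <= se_multiple * se) if se > 0 else True,
                }
            )
        m = k + 1
        obs_risk = km.risk_at(m)
        n0 = arm_table["subject_id"].nunique()
        sim_risk = sim.risk[k]
        # Greenwood SE degenerates to 0 while the observed risk is still 0;
        # floor it with the binomial SE implied by the simulated risk
        obs_se_risk = max(
            km.greenwood_se(m),
            np.sqrt(max(sim_risk * (1 - sim_risk), 0.0) / n0),
        )
        sim_se_risk = np.sqrt(max(sim_risk * (1 - sim_risk), 0) / n_simulated)
        se = np.sqrt(obs_se_risk**2 + sim_se_risk**2)
        diff = sim_risk - obs_risk
        rows.append(
            {
                "month": m,
                "quantity": "risk",
                "observed": obs_risk,
                "simulated": sim_risk,
                "abs_diff": abs(diff),
                "rel_diff": abs(diff) / obs_risk if obs_risk else np.nan,
                "se": se,
                "ok": bool(abs(diff) <= se_multiple * se) if se > 0 else True,
            }
        )
    return pd.DataFrame(rows)


def gformula_effects(
    result_control: GFormulaResult,
    result_experimental: GFormulaResult,
    horizon: int = 48,
    chr_method: str = "log_survival",
) -> EffectEstimates:
    """RR and cHR from the two counterfactual risk curves."""
    if len(result_control.risk) != len(result_experimental.risk):
        raise ValueError("mismatched horizons between g-formula results")
    eff = effect_estimates(
        result_control.curve,
        result_experimental.curve,
        horizon=horizon,
        chr_method=chr_method,
    )
    eff.estimator = "gformula"
    return eff


def screen_gformula_spec(
    table: pd.DataFrame, spec: GFormulaSpec, arm: int, p_threshold: float = 0.2
) -> GFormulaSpec:
    """Regenerate a specification ladder by per-term p-value screening.

    Refits every covariate and outcome model on the arm's person-time and
    keeps only terms with Wald p-value below the threshold (single-column
    terms) or likelihood-ratio p below the threshold (multi-column terms);
    lagged own-value terms are always kept so each covariate remains
    autoregressive.
    """
    models = fit_gformula_models(table, spec, arm)
    work = add_lag_columns(table.loc[table["arm"] == arm])

    def keep_terms(fit, terms, own_lag=None, rows=None):
        kept = []
        for t in terms:
            if own_lag is not None and t.name == own_lag:
                kept.append(t)
                continue
            if not hasattr(fit, "cov_params"):
                kept.append(t)
                continue
            cols = [
                i
                for i, lbl in enumerate(fit.labels)
                if lbl == t.name or lbl.startswith(f"{t.name}[")
                or lbl.startswith(f"{t.name}_s") or lbl == f"{t.name}^2"
            ]
            if not cols:
                continue
            zs = [
                fit.params[i] / np.sqrt(fit.cov_params[i, i]) for i in cols
            ]
            p = min(float(2 * stats.norm.sf(abs(z))) for z in zs)
            if p < p_threshold:
                kept.append(t)
        return tuple(kept)

    new_models = []
    for cm in spec.covariate_models:
        fit = models.covariate_fits[cm.name]
        own_lag = _TVC_LAGS.get(cm.name)
        new_models.append(
            replace(cm, terms=keep_terms(fit, cm.terms, own_lag=own_lag))
        )
    new_outcome = keep_terms(models.outcome_fit, spec.outcome_terms)
    return replace(
        spec,
        covariate_models=tuple(new_models),
        outcome_terms=new_outcome,
        label=f"{spec.label}-screened-p{p_threshold}",
    )
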