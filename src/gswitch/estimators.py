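"""The analysis battery: ITT variants, naive per-protocol, and IPCW.

Every approach consumes the long person-time table and returns survival
curves per arm plus dHR / cHR / RR at the horizon.  The ITT analyses target
the effect of *assignment*; the per-protocol analyses target the sustained
strategies "always treat with the experimental drug" versus "always treat
with the control drug".  The naive per-protocol modes (excluding switchers,
censoring at switching) are deliberately biased comparators under
treatment-confounder feedback; the IPCW mode censors at the minimum of
switching and LTFU/AC and re-weights by the product of the two inverse
probability weights, then fits an outcome model that — by construction —
contains only the randomized arm and time terms, never the confounders.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .core_data import TermSpec
from .discrete_survival import (
    EffectEstimates,
    FitFailure,
    PooledLogisticFit,
    curve_from_fit,
    effect_estimates,
    fit_pooled_logistic,
    km_curve,
    quadratic_time_terms,
    standardized_curve,
)
from .weighting import (
    WeightSeries,
    WeightSpec,
    combine_weights,
    compute_weights,
    fit_weight_models,
    truncate_weights,
    weight_diagnostics,
)

__all__ = [
    "AnalysisRequest",
    "AnalysisResult",
    "itt_analysis",
    "naive_pp",
    "ipcw_pp_analysis",
    "IPCW_OUTCOME_TERMS",
]

_ITT_APPROACHES = ("itt_unadjusted", "itt_strata", "itt_baseline", "itt_marginal")
_APPROACHES = _ITT_APPROACHES + (
    "pp_exclude_switchers",
    "pp_censor_at_switch",
    "pp_ipcw",
)

# the IPCW outcome model: randomized arm + linear and quadratic time, and
# nothing else — confounders live in the weights, never in this model
IPCW_OUTCOME_TERMS = (
    TermSpec("arm", "baseline", "linear"),
    TermSpec("k", "time_varying", "quadratic"),
)

BASELINE_ADJUSTMENT_TERMS = (
    TermSpec("age", "baseline", "linear"),
    TermSpec("ecog", "baseline", "categorical", 3),
    TermSpec("ics", "baseline", "categorical", 2),
    TermSpec("race", "baseline", "categorical", 2),
    TermSpec("sex", "baseline", "categorical", 2),
    TermSpec("smoking", "baseline", "categorical", 3),
    TermSpec("strata", "baseline", "categorical", 4),
    TermSpec("diagnosis_stage", "baseline", "categorical", 4),
    TermSpec("lung_involvement", "baseline", "categorical", 4),
    TermSpec("prior_radiation", "baseline", "categorical", 2),
)

STRATA_ADJUSTMENT_TERMS = (TermSpec("strata", "baseline", "categorical", 4),)


@dataclass(frozen=True)
class AnalysisRequest:
    """One requested analysis (Table-1-style approach taxonomy)."""

    approach: str
    adjustment_terms: Sequence[TermSpec] = ()
    switch_spec: Optional[WeightSpec] = None
    ltfu_spec: Optional[WeightSpec] = None
    truncation: Optional[tuple] = None
    horizon: int = 48
    estimators: tuple = ("pooled_logistic", "km")
    chr_method: str = "log_survival"
    # weight variant applied to the outcome model and weighted KM.  The
    # unstabilized default keeps the weighted risk set proportional to
    # 1 / P(remaining unswitched and uncensored): switching-weight accrual
    # starts at the subject's progression time, so the stabilizing time-only
    # numerator is not a common factor within an analysis month and can
    # re-rank subjects by progression time — a covariate the arm+time
    # outcome model cannot absorb.  Stabilized weights remain the basis of
    # all weight diagnostics.
    weight_type: str = "unstabilized"

    def __post_init__(self) -> None:
        if self.approach not in _APPROACHES:
            raise ValueError(f"unknown approach {self.approach!r}")
        if self.approach == "pp_ipcw":
            if self.switch_spec is None or self.ltfu_spec is None:
                raise ValueError("pp_ipcw requires switch_spec and ltfu_spec")
        elif self.switch_spec is not None or (
            self.ltfu_spec is not None and self.approach not in _ITT_APPROACHES
        ):
            raise ValueError("weight specs only valid for pp_ipcw (or LTFU in ITT)")
        if self.approach == "itt_unadjusted" and self.adjustment_terms:
            raise ValueError("itt_unadjusted takes no adjustment terms")


@dataclass
class AnalysisResult:
    approach: str
    curves: dict                        # estimator -> {0: curve, 1: curve}
    effects: dict                       # estimator -> EffectEstimates
    fit: Optional[PooledLogisticFit] = None
    weights: Optional[WeightSeries] = None
    weight_diagnostics: Optional[object] = None
    flags: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        frames = [
            eff.to_frame(approach=self.approach) for eff in self.effects.values()
        ]
        return pd.concat(frames, ignore_index=True)


def _outcome_terms(adjustment: Sequence[TermSpec]) -> list[TermSpec]:
    return [TermSpec("arm", "baseline", "linear")] + quadratic_time_terms() + list(
        adjustment
    )


def _baseline_rows(table: pd.DataFrame) -> pd.DataFrame:
    return table.loc[table["k"] == 0].copy()


def _run_battery(
    table: pd.DataFrame,
    adjustment: Sequence[TermSpec],
    horizon: int,
    approach: str,
    estimators: tuple,
    chr_method: str,
    weights: Optional[pd.Series] = None,
    weight_series: Optional[WeightSeries] = None,
    marginal: bool = False,
) -> AnalysisResult:
    """Shared engine: pooled logistic + KM per arm, with optional weights."""
    curves: dict = {}
    effects: dict = {}
    flags: list[str] = []
    terms = _outcome_terms(adjustment)
    fit = fit_pooled_logistic(table, terms, weights=weights)
    if not fit.converged:
        raise FitFailure(f"{approach}: outcome model failed ({fit.failure_reason})")
    if "pooled_logistic" in estimators:
        if adjustment or marginal:
            baseline = _baseline_rows(table)
            pl_curves = {
                z: standardized_curve(fit, baseline, horizon, set_columns={"arm": z})
                for z in (0, 1)
            }
        else:
            pl_curves = {
                z: curve_from_fit(fit, pd.DataFrame({"arm": [z]}), horizon)
                for z in (0, 1)
            }
        curves["pooled_logistic"] = pl_curves
        effects["pooled_logistic"] = effect_estimates(
            pl_curves[0], pl_curves[1], fit=fit, horizon=horizon, chr_method=chr_method
        )
    if "km" in estimators:
        km_curves = {}
        for z in (0, 1):
            sub = table.loc[table["arm"] == z]
            w = None if weights is None else weights.loc[sub.index]
            km_curves[z] = km_curve(sub, weights=w, horizon=horizon)
        curves["km"] = km_curves
        effects["km"] = effect_estimates(
            km_curves[0], km_curves[1], horizon=horizon, chr_method=chr_method
        )
    return AnalysisResult(
        approach=approach,
        curves=curves,
        effects=effects,
        fit=fit,
        weights=weight_series,
        flags=flags,
    )


def itt_analysis(table: pd.DataFrame, request: AnalysisRequest) -> AnalysisResult:
    """Effect of treatment *assignment* on survival.

    Variants: unadjusted (arm + quadratic time); adjusted for randomization
    strata or the full baseline covariate set (conditional dHR, curves
    standardized over the observed baseline distribution); and the marginal
    variant, which standardizes the unadjusted-covariate model over two
    cloned copies of the baseline cohort, one per assigned arm.  Supplying
    ``request.ltfu_spec`` weights the analysis by LTFU/AC inverse
    probability weights, relaxing non-informative censoring.
    """
    if request.approach not in _ITT_APPROACHES:
        raise ValueError(f"itt_analysis got {request.approach!r}")
    adjustment = {
        "itt_unadjusted": (),
        "itt_strata": request.adjustment_terms or STRATA_ADJUSTMENT_TERMS,
        "itt_baseline": request.adjustment_terms or BASELINE_ADJUSTMENT_TERMS,
        "itt_marginal": request.adjustment_terms or BASELINE_ADJUSTMENT_TERMS,
    }[request.approach]
    weights = None
    weight_series = None
    work = table
    if request.ltfu_spec is not None:
        models = fit_weight_models(table, request.ltfu_spec)
        weight_series = compute_weights(models, table)
        work = table.loc[table["censored"] == 0]
        weights = weight_series.aligned_to(work)
    result = _run_battery(
        work,
        adjustment,
        request.horizon,
        request.approach,
        request.estimators,
        request.chr_method,
        weights=weights,
        weight_series=weight_series,
        marginal=request.approach == "itt_marginal",
    )
    if weight_series is not None:
        result.weight_diagnostics = weight_diagnostics(weight_series)
    return result


def naive_pp(
    table: pd.DataFrame,
    mode: str,
    adjustment_terms: Sequence[TermSpec] = (),
    horizon: int = 48,
    estimators: tuple = ("pooled_logistic", "km"),
    chr_method: str = "log_survival",
) -> AnalysisResult:
    """Naive per-protocol analyses.

    ``mode='exclude'`` drops all person-time of subjects who ever switch;
    ``mode='censor'`` truncates switchers at the switch interval (the switch
    row itself is removed and no event is recorded).  Both then compare the
    arms as randomized.  These comparators are biased when switching is
    driven by prognostic time-varying covariates.
    """
    if mode not in ("exclude", "censor"):
        raise ValueError(f"naive_pp mode must be 'exclude' or 'censor', got {mode!r}")
    if mode == "exclude":
        ever = table.groupby("subject_id")["switched"].transform("max")
        work = table.loc[ever == 0]
        approach = "pp_exclude_switchers"
    else:
        work = table.loc[table["switched"] == 0]
        approach = "pp_censor_at_switch"
    if not (work["arm"] == 0).any():
        raise FitFailure(f"{approach}: control arm empty after filtering")
    return _run_battery(
        work, adjustment_terms, horizon, approach, estimators, chr_method
    )


def ipcw_pp_analysis(table: pd.DataFrame, request: AnalysisRequest) -> AnalysisResult:
    """Per-protocol effect via inverse-probability-of-censoring weighting.

    Builds switching and LTFU/AC weights, multiplies them, optionally
    truncates, censors person-time at the minimum of the two events, and
    fits the weighted outcome model (arm + time + time^2 — never the
    confounders) and the weighted KM.  Positivity alarms from the weight
    models propagate into ``flags``.
    """
    if request.approach != "pp_ipcw":
        raise ValueError(f"ipcw_pp_analysis got {request.approach!r}")
    switch_models = fit_weight_models(table, request.switch_spec)
    ltfu_models = fit_weight_models(table, request.ltfu_spec)
    w_switch = compute_weights(switch_models, table)
    w_ltfu = compute_weights(ltfu_models, table)
    combined = combine_weights(w_switch, w_ltfu)
    if request.truncation is not None:
        combined = truncate_weights(combined, *request.truncation)
    work = table.loc[(table["switched"] == 0) & (table["censored"] == 0)]
    weights = combined.aligned_to(work, column=request.weight_type)
    if weights.isna().any():
        raise FitFailure("weight/person-time misalignment in IPCW analysis")
    result = _run_battery(
        work,
        (),
        request.horizon,
        "pp_ipcw",
        request.estimators,
        request.chr_method,
        weights=weights,
        weight_series=combined,
    )
    # structural check: the outcome model must contain arm and time only
    assert [t.name for t in _outcome_terms(())] == ["arm", "k"]
    result.weight_diagnostics = weight_diagnostics(combined)
    result.flags.extend(switch_models.positivity_flags)
    result.flags.extend(ltfu_models.positivity_flags)
    return result
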