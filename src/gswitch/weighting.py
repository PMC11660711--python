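"""Inverse-probability-of-censoring weights for switching and LTFU/AC.

Both crossover to the experimental drug and loss to follow-up are treated
as censoring events: person-time at and after the event is removed, and the
remaining comparable person-time is up-weighted so that, under correct
specification, the weighted risk set reproduces the population in which the
event never happens.

Weights are built per arm from paired pooled logistic models: the
*denominator* model conditions on baseline and time-varying covariates, the
*numerator* model on functions of time alone (stabilization).  The
stabilized weight at interval ``k`` is the cumulative ratio of
numerator-to-denominator event-free probabilities through ``k`` inclusive;
the unstabilized weight inverts the denominator alone.  Deterministic
knowledge is wired in: experimental-arm subjects, and control subjects
before disease progression, cannot switch and carry a switching weight of
exactly 1 at every interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import TermSpec
from .discrete_survival import FitFailure, fit_pooled_logistic

__all__ = [
    "WeightSpec",
    "WeightSeries",
    "WeightModelSet",
    "WeightDiagnostics",
    "fit_weight_models",
    "compute_weights",
    "combine_weights",
    "truncate_weights",
    "weight_diagnostics",
    "screen_covariates",
    "switching_spec_full",
    "switching_spec_dropped_tdp",
    "ltfu_spec_default",
]


def _first_event_rows(table: pd.DataFrame, indicator: str) -> pd.Series:
    """Boolean mask of the first row (per subject) where an absorbing
    indicator turns 1 — the event interval."""
    grp = table.groupby("subject_id", sort=False)[indicator]
    prev = grp.shift(1, fill_value=0)
    return (table[indicator] == 1) & (prev == 0)


@dataclass(frozen=True)
class WeightSpec:
    """Declarative description of one weighting model.

    ``denominator_terms`` may be a single term list (used for every fitted
    arm) or a mapping ``{arm: terms}`` for arm-specific covariate sets.
    Numerator terms must be functions of time only.  Switching weights are
    fitted on control-arm post-progression person-time only
    (``restrict_to_post_progression``); LTFU/AC weights are fitted
    separately in each arm.
    """

    target: Literal["switching", "ltfu_ac"]
    denominator_terms: Union[Sequence[TermSpec], dict]
    numerator_terms: Sequence[TermSpec] = field(
        default_factory=lambda: (TermSpec("k", "time_varying", "linear"),)
    )
    restrict_to_post_progression: bool = True
    label: str = ""

    def __post_init__(self) -> None:
        if self.target not in ("switching", "ltfu_ac"):
            raise ValueError(f"unknown weight target {self.target!r}")
        if self.target == "switching" and not self.restrict_to_post_progression:
            raise ValueError(
                "switching weights must be restricted to post-progression "
                "person-time (crossover is impossible before progression)"
            )
        for term in self.numerator_terms:
            if term.name != "k":
                raise ValueError(
                    f"numerator terms must involve time only, got {term.name!r}"
                )

    def terms_for_arm(self, arm: int) -> list[TermSpec]:
        if isinstance(self.denominator_terms, dict):
            return list(self.denominator_terms[arm])
        return list(self.denominator_terms)

    @property
    def fitted_arms(self) -> tuple:
        return (0,) if self.target == "switching" else (0, 1)


@dataclass
class WeightModelSet:
    """Paired numerator/denominator fits per arm, plus positivity flags."""

    spec: WeightSpec
    numerator: dict
    denominator: dict
    positivity_flags: list = field(default_factory=list)

    @property
    def converged(self) -> bool:
        return all(f.converged for f in self.numerator.values()) and all(
            f.converged for f in self.denominator.values()
        )


@dataclass
class WeightDiagnostics:
    mean: float
    sd: float
    min: float
    max: float
    n: int
    flags: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "mean": self.mean,
                    "sd": self.sd,
                    "min": self.min,
                    "max": self.max,
                    "n_person_intervals": self.n,
                    "flags": "; ".join(self.flags),
                }
            ]
        )


@dataclass
class WeightSeries:
    """Per (subject, interval) stabilized and unstabilized IPC weights.

    ``frame`` has columns ``subject_id, k, stabilized, unstabilized`` and
    covers exactly the person-time retained after censoring at the target
    event.  Weights are non-anticipating: the weight at ``k`` depends only
    on data through ``k``.
    """

    frame: pd.DataFrame
    target: str = ""
    label: str = ""

    def __post_init__(self) -> None:
        required = {"subject_id", "k", "stabilized", "unstabilized"}
        if not required <= set(self.frame.columns):
            raise ValueError(f"WeightSeries frame missing {required - set(self.frame.columns)}")
        if np.any(~np.isfinite(self.frame["stabilized"])) or np.any(
            self.frame["stabilized"] <= 0
        ):
            raise ValueError("stabilized weights must be positive and finite")

    def aligned_to(self, table: pd.DataFrame, column: str = "stabilized") -> pd.Series:
        """Weights as a series indexed like ``table`` (inner person-time)."""
        merged = table[["subject_id", "k"]].merge(
            self.frame[["subject_id", "k", column]], on=["subject_id", "k"], how="left"
        )
        out = pd.Series(merged[column].to_numpy(), index=table.index)
        return out

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def fit_weight_models(table: pd.DataFrame, spec: WeightSpec) -> WeightModelSet:
    """Fit numerator/denominator pooled logistic models for one weight target.

    For switching: the event indicator is the first interval with
    ``switched = 1``; eligible person-time is control-arm post-progression
    person-time up to and including the event interval.  For LTFU/AC: the
    event is the ``censored`` flag; eligible person-time is the whole arm.
    A positivity red flag is raised when any predicted event probability
    exceeds 0.99.
    """
    numerator: dict = {}
    denominator: dict = {}
    flags: list[str] = []
    if spec.target == "switching":
        event = _first_event_rows(table, "switched").astype(int)
    else:
        event = table["censored"].astype(int)
    for arm in spec.fitted_arms:
        mask = table["arm"] == arm
        if spec.target == "switching":
            # post-progression person-time, censored at (and including) the
            # switch event interval
            mask = mask & (table["dp"] == 1) & (
                (table["switched"] == 0) | (event == 1)
            )
        eligible = table.loc[mask]
        if len(eligible) == 0:
            raise FitFailure(
                f"{spec.target} weights, arm {arm}: empty eligible person-time"
            )
        ev = event.loc[eligible.index]
        if ev.sum() == 0:
            raise FitFailure(
                f"{spec.target} weights, arm {arm}: no events in eligible set"
            )
        work = eligible.copy()
        work["_event"] = ev
        den = fit_pooled_logistic(work, spec.terms_for_arm(arm), outcome_col="_event")
        num = fit_pooled_logistic(work, spec.numerator_terms, outcome_col="_event")
        if den.converged:
            p_hat = den.predict(work)
            if np.any(p_hat > 0.99):
                flags.append(
                    f"positivity red flag: arm {arm} predicted {spec.target} "
                    f"probability > 0.99"
                )
        numerator[arm] = num
        denominator[arm] = den
    return WeightModelSet(
        spec=spec, numerator=numerator, denominator=denominator, positivity_flags=flags
    )


def compute_weights(
    models: WeightModelSet, table: pd.DataFrame, spec: Optional[WeightSpec] = None
) -> WeightSeries:
    """Cumulative stabilized and unstabilized weights on retained person-time.

    Retained person-time excludes the event interval and everything after
    it.  For subjects under a deterministic rule (experimental arm, or
    control pre-progression for switching) the stabilized weight is exactly
    1.  A predicted event-free probability of 0 raises :class:`FitFailure`
    naming the subject and interval.
    """
    spec = spec or models.spec
    if not models.converged:
        raise FitFailure(f"{spec.target} weight models did not converge")
    work = table.sort_values(["subject_id", "k"]).copy()
    if spec.target == "switching":
        event_rows = _first_event_rows(work, "switched").astype(bool)
        retained = work["switched"] == 0
    else:
        event_rows = work["censored"].astype(bool)
        retained = work["censored"] == 0

    log_stab = np.zeros(len(work))
    log_unstab = np.zeros(len(work))
    contributes = np.zeros(len(work), dtype=bool)
    for arm in spec.fitted_arms:
        mask = (work["arm"] == arm).to_numpy()
        if spec.target == "switching":
            mask &= (work["dp"] == 1).to_numpy() & retained.to_numpy()
        else:
            mask &= retained.to_numpy()
        if not mask.any():
            continue
        sub = work.loc[mask]
        p_den = models.denominator[arm].predict(sub)
        p_num = models.numerator[arm].predict(sub)
        bad = p_den >= 1.0
        if np.any(bad):
            first = sub.loc[bad].iloc[0]
            raise FitFailure(
                f"infinite weight: event-free probability 0 for subject "
                f"{first['subject_id']} at interval {int(first['k'])}"
            )
        log_stab[mask] = np.log1p(-p_num) - np.log1p(-p_den)
        log_unstab[mask] = -np.log1p(-p_den)
        contributes[mask] = True

    work["_log_stab"] = log_stab
    work["_log_unstab"] = log_unstab
    grp = work.groupby("subject_id", sort=False)
    stabilized = np.exp(grp["_log_stab"].cumsum())
    unstabilized_raw = np.exp(grp["_log_unstab"].cumsum())
    # the unstabilized weight is 1 (not 1/prod) wherever no factor has
    # accrued yet; the cumulative sums already guarantee that
    frame = pd.DataFrame(
        {
            "subject_id": work["subject_id"],
            "k": work["k"],
            "stabilized": stabilized,
            "unstabilized": unstabilized_raw,
        }
    ).loc[retained.to_numpy()]
    return WeightSeries(
        frame=frame.reset_index(drop=True), target=spec.target, label=spec.label
    )


def combine_weights(a: WeightSeries, b: WeightSeries) -> WeightSeries:
    """Elementwise product on the intersection of retained person-time.

    The intersection implements censoring at the minimum of the two events
    (e.g. switching and LTFU/AC).
    """
    merged = a.frame.merge(
        b.frame, on=["subject_id", "k"], how="inner", suffixes=("_a", "_b")
    )
    frame = pd.DataFrame(
        {
            "subject_id": merged["subject_id"],
            "k": merged["k"],
            "stabilized": merged["stabilized_a"] * merged["stabilized_b"],
            "unstabilized": merged["unstabilized_a"] * merged["unstabilized_b"],
        }
    )
    return WeightSeries(frame=frame, target=f"{a.target}*{b.target}", label=a.label)


def truncate_weights(
    ws: WeightSeries, lower_pct: float, upper_pct: float
) -> WeightSeries:
    """Clip weights to empirical percentiles of the pooled distribution.

    Percentiles are computed over pooled person-time rows (stabilized and
    unstabilized each against their own distribution).  ``(0, 100)`` leaves
    weights unchanged; ``(50, 50)`` maps every weight to the median, i.e. a
    constant — downstream, that reproduces the unadjusted analysis.
    """
    if not (0 <= lower_pct <= upper_pct <= 100):
        raise ValueError("percentiles must satisfy 0 <= lower <= upper <= 100")
    frame = ws.frame.copy()
    for col in ("stabilized", "unstabilized"):
        lo, hi = np.percentile(frame[col], [lower_pct, upper_pct])
        frame[col] = np.clip(frame[col], lo, hi)
    return WeightSeries(frame=frame, target=ws.target, label=f"{ws.label} truncated ({lower_pct},{upper_pct})")


def weight_diagnostics(
    ws: WeightSeries,
    column: str = "stabilized",
    mean_tolerance: float = 0.1,
    max_multiple: float = 20.0,
) -> WeightDiagnostics:
    """Mean/SD/min/max over person-time, with extreme-weight alarms.

    Flags fire when the mean drifts from 1 by more than ``mean_tolerance``
    or the maximum exceeds ``max_multiple`` times the mean — the signature
    of an unstable weighting model.
    """
    w = ws.frame[column].to_numpy()
    if len(w) == 0:
        raise ValueError("empty weight series")
    mean, sd = float(np.mean(w)), float(np.std(w, ddof=1)) if len(w) > 1 else 0.0
    flags = []
    if abs(mean - 1.0) > mean_tolerance:
        flags.append(f"mean weight {mean:.3f} deviates from 1 by > {mean_tolerance}")
    if np.max(w) > max_multiple * mean:
        flags.append(
            f"max weight {np.max(w):.2f} exceeds {max_multiple:.0f}x the mean"
        )
    return WeightDiagnostics(
        mean=mean,
        sd=sd,
        min=float(np.min(w)),
        max=float(np.max(w)),
        n=len(w),
        flags=flags,
    )


def screen_covariates(
    table: pd.DataFrame,
    candidates: Sequence[TermSpec],
    event_col: str,
    p_threshold: float = 0.20,
    or_bounds: tuple = (0.75, 1.33),
) -> tuple[list[TermSpec], pd.DataFrame]:
    """Univariate pooled-logistic covariate screen.

    A candidate is retained when its p-value is at or below ``p_threshold``
    or its odds ratio falls outside ``or_bounds`` (for multi-column terms:
    a likelihood-ratio p-value and the most extreme column-wise OR).  AIC
    against the intercept-only model is reported alongside.  Candidates
    with constant columns are skipped with a note.  Output order follows
    input order.
    """
    null_fit = fit_pooled_logistic(
        table, [], outcome_col=event_col
    )
    rows = []
    selected: list[TermSpec] = []
    for term in candidates:
        values = table[term.name]
        if values.nunique() <= 1:
            rows.append(
                {
                    "term": term.name,
                    "or": np.nan,
                    "p_value": np.nan,
                    "aic": np.nan,
                    "selected": False,
                    "note": "constant column; skipped",
                }
            )
            continue
        fit = fit_pooled_logistic(table, [term], outcome_col=event_col)
        if not fit.converged:
            rows.append(
                {
                    "term": term.name,
                    "or": np.nan,
                    "p_value": np.nan,
                    "aic": np.nan,
                    "selected": False,
                    "note": f"fit failed: {fit.failure_reason}",
                }
            )
            continue
        free = [lbl for lbl in fit.labels if lbl != "const"]
        ors = np.exp([fit.coef(lbl) for lbl in free])
        # most extreme OR on the log scale
        or_star = float(ors[np.argmax(np.abs(np.log(ors)))])
        if len(free) == 1:
            z = fit.coef(free[0]) / fit.se(free[0])
            p_value = float(2 * stats.norm.sf(abs(z)))
        else:
            lr = 2 * (fit.llf - null_fit.llf)
            p_value = float(stats.chi2.sf(max(lr, 0.0), df=len(free)))
        keep = p_value <= p_threshold or not (
            or_bounds[0] <= or_star <= or_bounds[1]
        )
        rows.append(
            {
                "term": term.name,
                "or": or_star,
                "p_value": p_value,
                "aic": fit.aic,
                "selected": keep,
                "note": "",
            }
        )
        if keep:
            selected.append(term)
    report = pd.DataFrame(rows)
    report.attrs["null_aic"] = null_fit.aic if null_fit.converged else np.nan
    return selected, report


# --- shipped weighting-model specification ladders -------------------------

_SWITCH_FULL_TERMS = (
    TermSpec("age", "baseline", "linear"),
    TermSpec("diagnosis_stage", "baseline", "categorical", 4),
    TermSpec("ics", "baseline", "categorical", 2),
    TermSpec("lung_involvement", "baseline", "categorical", 4),
    TermSpec("strata", "baseline", "categorical", 4),
    TermSpec("smoking", "baseline", "categorical", 3),
    TermSpec("k", "time_varying", "linear"),
    TermSpec("ecog_tv", "time_varying", "categorical", 2),
    TermSpec("tls", "time_varying", "linear"),
    TermSpec("tdp", "time_varying", "quadratic"),
)


def switching_spec_full(label: str = "switch-spec-1") -> WeightSpec:
    """Full switching weight model: prognostic baseline covariates plus
    follow-up time, performance state, lesion size, and linear + quadratic
    time since progression."""
    return WeightSpec(
        target="switching",
        denominator_terms=_SWITCH_FULL_TERMS,
        numerator_terms=(TermSpec("k", "time_varying", "linear"),),
        restrict_to_post_progression=True,
        label=label,
    )


def switching_spec_dropped_tdp(label: str = "switch-spec-7") -> WeightSpec:
    """Full model with time-since-progression removed — the destabilizing
    misspecification explored in the sensitivity ladder."""
    terms = tuple(t for t in _SWITCH_FULL_TERMS if t.name != "tdp")
    return WeightSpec(
        target="switching",
        denominator_terms=terms,
        numerator_terms=(TermSpec("k", "time_varying", "linear"),),
        restrict_to_post_progression=True,
        label=label,
    )


def ltfu_spec_default(label: str = "ltfu-spec-1") -> WeightSpec:
    """LTFU/AC weight model: time plus current disease state per arm."""
    terms = (
        TermSpec("k", "time_varying", "linear"),
        TermSpec("dp", "time_varying", "categorical", 2),
        TermSpec("tls", "time_varying", "linear"),
    )
    return WeightSpec(
        target="ltfu_ac",
        denominator_terms=terms,
        numerator_terms=(TermSpec("k", "time_varying", "linear"),),
        restrict_to_post_progression=False,
        label=label,
    )
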