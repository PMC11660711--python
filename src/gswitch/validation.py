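"""Bootstrap-ready estimation procedures over subject collections.

The bootstrap resamples *subjects*; every procedure here is a pure function
from a subject collection to a scalar estimate, re-running the complete
pipeline (person-time expansion, weight fitting, outcome fitting or
g-formula fitting plus simulation) on each call.  These are the procedures
used for interval estimation and for validating the estimators against the
generator's counterfactual truth.
"""

from __future__ import annotations

from typing import Sequence

from .core_data import SubjectRecord, expand_to_person_time
from .estimators import AnalysisRequest, ipcw_pp_analysis, itt_analysis, naive_pp
from .gformula import GFormulaSpec, fit_gformula_models, simulate_counterfactual

__all__ = [
    "itt_rr",
    "naive_rr",
    "naive_control_risk",
    "ipcw_rr",
    "ipcw_control_risk",
    "gformula_rr",
    "gformula_risk",
]


def _table(subjects: Sequence[SubjectRecord], horizon: int):
    return expand_to_person_time(subjects, horizon)


def itt_rr(request: AnalysisRequest, estimator: str = "pooled_logistic"):
    """RR at the horizon from an ITT analysis."""

    def procedure(subjects):
        table = _table(subjects, request.horizon)
        return itt_analysis(table, request).effects[estimator].rr

    return procedure


def naive_rr(mode: str, horizon: int = 48, estimator: str = "pooled_logistic"):
    def procedure(subjects):
        table = _table(subjects, horizon)
        return naive_pp(table, mode, horizon=horizon).effects[estimator].rr

    return procedure


def naive_control_risk(horizon: int = 48):
    """Censor-at-switch Kaplan-Meier risk at the horizon, control arm."""

    def procedure(subjects):
        table = _table(subjects, horizon)
        res = naive_pp(table, "censor", horizon=horizon)
        return res.curves["km"][0].risk_at(horizon)

    return procedure


def ipcw_rr(request: AnalysisRequest, estimator: str = "pooled_logistic"):
    def procedure(subjects):
        table = _table(subjects, request.horizon)
        return ipcw_pp_analysis(table, request).effects[estimator].rr

    return procedure


def ipcw_control_risk(request: AnalysisRequest, estimator: str = "km"):
    """IPC-weighted risk at the horizon in the control arm — the estimate of
    the "never switch, never lost" counterfactual risk."""

    def procedure(subjects):
        table = _table(subjects, request.horizon)
        res = ipcw_pp_analysis(table, request)
        return res.curves[estimator][0].risk_at(request.horizon)

    return procedure


def gformula_risk(spec: GFormulaSpec, arm: int, strategy: str, sim_seed: int = 1000):
    """G-formula counterfactual risk at the horizon for one arm/strategy.

    The Monte-Carlo seed is fixed so the procedure is a deterministic
    function of the subject sample; bootstrap variation then reflects the
    data, with the (small) simulation noise folded in.
    """

    def procedure(subjects):
        table = _table(subjects, spec.horizon)
        models = fit_gformula_models(table, spec, arm)
        baseline = table.loc[(table["arm"] == arm) & (table["k"] == 0)]
        result = simulate_counterfactual(models, baseline, strategy, seed=sim_seed)
        return result.risk_at(spec.horizon)

    return procedure


def gformula_rr(spec: GFormulaSpec, sim_seed: int = 1000):
    """G-formula RR: experimental strategy risk over control strategy risk."""

    def procedure(subjects):
        table = _table(subjects, spec.horizon)
        risks = {}
        for arm, strategy in ((0, "always_control"), (1, "always_experimental")):
            models = fit_gformula_models(table, spec, arm)
            baseline = table.loc[(table["arm"] == arm) & (table["k"] == 0)]
            risks[arm] = simulate_counterfactual(
                models, baseline, strategy, seed=sim_seed + arm
            ).risk_at(spec.horizon)
        return risks[1] / risks[0]

    return procedure
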