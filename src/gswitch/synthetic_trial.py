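"""Synthetic two-arm trial generator with treatment-confounder feedback.

The generator emulates the structure of an open-label oncology trial with
one-sided crossover: ~275 subjects randomized 137/138, monthly (30-day)
visits over a 48-month horizon, disease progression as an absorbing state
that gates both death and crossover, and loss to follow-up.  All hazards
are discrete-time logistic in the current state, and the time-varying
covariates (ECOG performance state, target-lesion size) respond to the
*previous* month's treatment — the treatment-confounder feedback channel:
prior treatment slows lesion growth and preserves performance status, while
lesion size and performance status drive both subsequent switching and
death.

Because every transition is logistic (or linear-Gaussian) in lagged state,
the weighting and g-formula modules can specify their nuisance models
*correctly* on generated data, which is what turns the generator into a
validation oracle: :func:`simulate_truth` re-runs the same mechanism with
switching and censoring switched off and treatment forced, yielding the
true counterfactual risk curve of each sustained strategy up to Monte-Carlo
error.

Per-subject random streams are derived from ``(seed, arm, index)`` so a
cohort is reproducible and stable under changes to the number of subjects.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass, field, replace
from typing import Optional

import numpy as np
import yaml
from scipy.special import expit

from .core_data import BaselineCovariates, SubjectRecord, expand_to_person_time

__all__ = [
    "BaselineModel",
    "ProgressionHazard",
    "IcpHazard",
    "EcogTransition",
    "TlsTransition",
    "SwitchingHazard",
    "CensoringHazard",
    "DeathHazard",
    "GeneratorConfig",
    "CounterfactualTruth",
    "default_config",
    "null_config",
    "weight_instability_config",
    "generate_trial",
    "generate_person_time",
    "simulate_truth",
]

# covariate centring used inside every hazard: lesion size per 10 mm above
# 40 mm, age per 10 years above 60
def _z_tls(tls):
    return (np.asarray(tls, dtype=float) - 40.0) / 10.0


def _z_age(age):
    return (np.asarray(age, dtype=float) - 60.0) / 10.0


@dataclass(frozen=True)
class BaselineModel:
    """Baseline covariate distributions (probabilities per coded level)."""

    age_mean: float = 58.0
    age_sd: float = 11.0
    age_min: float = 25.0
    age_max: float = 90.0
    ecog_probs: tuple = (0.38, 0.56, 0.06)
    ics_p: float = 0.17
    race_p: float = 0.36
    sex_p: float = 0.55
    smoking_probs: tuple = (0.55, 0.40, 0.05)
    brain_mets_p: float = 0.29
    prior_chemo_p: float = 0.27
    diagnosis_stage_probs: tuple = (0.05, 0.04, 0.18, 0.73)
    lung_involvement_probs: tuple = (0.25, 0.31, 0.35, 0.09)
    prior_radiation_p: float = 0.29
    tls_mean: float = 45.0
    tls_sd: float = 20.0
    tls_min: float = 5.0
    tls_max: float = 1000.0


@dataclass(frozen=True)
class ProgressionHazard:
    """Monthly logistic hazard of progression given no prior progression."""

    intercept: float = -3.10
    treatment: float = -0.25
    tls: float = 0.15       # per 10 mm above 40
    ecog: float = 0.30
    age: float = 0.10       # per 10 y above 60


@dataclass(frozen=True)
class IcpHazard:
    """Monthly logistic hazard of intracranial progression (absorbing)."""

    intercept: float = -4.60
    ics: float = 1.00
    dp: float = 0.80
    treatment: float = -0.50


@dataclass(frozen=True)
class EcogTransition:
    """P(worsened performance state this month) — logistic in lagged state."""

    intercept: float = -3.50
    prev: float = 4.00
    treatment: float = -0.30
    dp: float = 1.20


@dataclass(frozen=True)
class TlsTransition:
    """Linear-Gaussian monthly drift of target-lesion size (mm)."""

    intercept: float = 0.80
    treatment: float = -0.35
    dp: float = 0.80
    sd: float = 2.00


@dataclass(frozen=True)
class SwitchingHazard:
    """Monthly logistic hazard of crossover (control arm, post-progression).

    Structurally zero for the experimental arm and before progression.
    The strong negative time-since-progression slope concentrates
    crossover shortly after progression; lesion size and performance state
    make switching informative (selection on prognosis).
    """

    intercept: float = -2.22
    tls: float = 0.25
    ecog: float = 0.50
    tdp: float = -0.30
    age: float = -0.20


@dataclass(frozen=True)
class CensoringHazard:
    """Monthly logistic hazard of LTFU (time-only by default)."""

    intercept: float = -5.50
    time: float = 0.00


@dataclass(frozen=True)
class DeathHazard:
    """Monthly logistic hazard of death; structurally zero pre-progression."""

    intercept: float = -4.50
    treatment: float = -0.18
    tls: float = 0.15
    ecog: float = 0.50
    icp: float = 0.20


@dataclass(frozen=True)
class GeneratorConfig:
    """Full parameterization of the synthetic trial.

    Defaults are the shipped feedback configuration: a trial of 138 control
    / 137 experimental subjects over 48 months in which prior treatment
    shapes lesion size and performance status, which in turn drive
    switching and death (treatment-confounder feedback), calibrated so that
    close to 47% of control subjects ever cross over.
    """

    n_control: int = 138
    n_experimental: int = 137
    horizon_months: int = 48
    seed: int = 20240
    baseline: BaselineModel = field(default_factory=BaselineModel)
    progression: ProgressionHazard = field(default_factory=ProgressionHazard)
    icp: IcpHazard = field(default_factory=IcpHazard)
    ecog: EcogTransition = field(default_factory=EcogTransition)
    tls: TlsTransition = field(default_factory=TlsTransition)
    switching: SwitchingHazard = field(default_factory=SwitchingHazard)
    censoring: CensoringHazard = field(default_factory=CensoringHazard)
    death: DeathHazard = field(default_factory=DeathHazard)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        nested = {
            "baseline": BaselineModel,
            "progression": ProgressionHazard,
            "icp": IcpHazard,
            "ecog": EcogTransition,
            "tls": TlsTransition,
            "switching": SwitchingHazard,
            "censoring": CensoringHazard,
            "death": DeathHazard,
        }
        for key, klass in nested.items():
            if key in d and isinstance(d[key], dict):
                sub = dict(d[key])
                for fname, value in sub.items():
                    if isinstance(value, list):
                        sub[fname] = tuple(value)
                d[key] = klass(**sub)
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_config(**overrides) -> GeneratorConfig:
    """The shipped feedback configuration (see class docstring)."""
    return replace(GeneratorConfig(), **overrides)


def weight_instability_config(**overrides) -> GeneratorConfig:
    """The shipped configuration demonstrating weighting-model fragility.

    Crossover here concentrates in the first months after progression (a
    steep negative time-since-progression slope) and lesion size is
    strongly prognostic of switching mainly through its baseline value
    (no extra post-progression growth).  The full switching weight model
    — which includes linear and quadratic time-since-progression — yields
    well-behaved stabilized weights; removing time since progression
    leaves the model systematically over-predicting switching for
    long-unswitched survivors with large lesions, and their cumulative
    weights destabilize (SD and maximum inflate by multiples).  The cohort
    is control-heavy because only control-arm subjects can switch.
    """
    base = GeneratorConfig(
        n_control=2500,
        n_experimental=200,
        switching=SwitchingHazard(
            intercept=-1.30, tls=0.35, ecog=0.50, tdp=-1.10, age=-0.20
        ),
        tls=TlsTransition(intercept=0.40, treatment=-0.20, dp=0.0, sd=2.0),
        baseline=BaselineModel(tls_max=75.0),
    )
    return replace(base, **overrides)


def null_config(**overrides) -> GeneratorConfig:
    """A configuration in which treatment enters no hazard or transition.

    Crossover and censoring still occur, but switching treatment has no
    effect on anything, so every sensible estimator should find RR = cHR = 1.
    """
    base = GeneratorConfig(
        progression=ProgressionHazard(treatment=0.0),
        icp=IcpHazard(treatment=0.0),
        ecog=EcogTransition(treatment=0.0),
        tls=TlsTransition(treatment=0.0),
        death=DeathHazard(treatment=0.0),
    )
    return replace(base, **overrides)


@dataclass
class CounterfactualTruth:
    """Oracle counterfactual cumulative risk of death under one strategy."""

    strategy: str
    risk: np.ndarray            # risk by end of month m, m = 1..horizon
    n_oracle: int

    def risk_at(self, month: int) -> float:
        return float(self.risk[month - 1])

    def mc_se(self, month: int) -> float:
        p = self.risk_at(month)
        return float(np.sqrt(p * (1.0 - p) / self.n_oracle))

    def to_frame(self) -> "pd.DataFrame":
        import pandas as pd

        return pd.DataFrame(
            {"month": np.arange(1, len(self.risk) + 1), "risk": self.risk}
        )


# per-subject stream layout: 10 baseline uniforms, 1 age normal, 1 tls normal,
# horizon x 6 event uniforms (ecog, progression, icp, switch, censor, death),
# horizon tls-drift normals
def _subject_randoms(seed: int, arm: int, index: int, horizon: int) -> dict:
    rng = np.random.default_rng([seed, arm, index])
    return {
        "baseline_u": rng.uniform(size=10),
        "age_z": rng.normal(),
        "tls_z": rng.normal(),
        "u": rng.uniform(size=(horizon, 6)),
        "tls_noise": rng.normal(size=horizon),
    }


def _draw_categorical(u: float, probs) -> int:
    return int(np.searchsorted(np.cumsum(probs), u))


def _simulate_cohort(
    config: GeneratorConfig,
    n_per_arm: dict[int, int],
    *,
    force_treatment: Optional[int] = None,
    disable_switching: bool = False,
    disable_censoring: bool = False,
    seed: Optional[int] = None,
) -> list[SubjectRecord]:
    """Shared engine behind :func:`generate_trial` and :func:`simulate_truth`.

    Within-month update order (fixed, documented): time-varying covariates
    (ECOG, TLS) from lagged state -> progression -> intracranial progression
    -> switching -> censoring -> death.  Progression and the TVC updates
    depend only on lagged state; switching and death read the current
    visit's covariates.  When death and censoring fire in the same month,
    death takes precedence.
    """
    seed = config.seed if seed is None else seed
    K = config.horizon_months
    b = config.baseline
    cumulative_hazard_warned = False
    subjects: list[SubjectRecord] = []

    for arm, n_arm in n_per_arm.items():
        if n_arm == 0:
            continue
        draws = [_subject_randoms(seed, arm, i, K) for i in range(n_arm)]
        u_base = np.stack([d["baseline_u"] for d in draws])
        age = np.clip(
            b.age_mean + b.age_sd * np.array([d["age_z"] for d in draws]),
            b.age_min,
            b.age_max,
        )
        tls0 = np.clip(
            b.tls_mean + b.tls_sd * np.array([d["tls_z"] for d in draws]),
            b.tls_min,
            b.tls_max,
        )
        ecog_b = np.array([_draw_categorical(u, b.ecog_probs) for u in u_base[:, 0]])
        ics = (u_base[:, 1] < b.ics_p).astype(int)
        race = (u_base[:, 2] < b.race_p).astype(int)
        sex = (u_base[:, 3] < b.sex_p).astype(int)
        smoking = np.array(
            [_draw_categorical(u, b.smoking_probs) for u in u_base[:, 4]]
        )
        strata = 2 * (u_base[:, 5] < b.brain_mets_p).astype(int) + (
            u_base[:, 6] < b.prior_chemo_p
        ).astype(int)
        ids = np.array(
            [_draw_categorical(u, b.diagnosis_stage_probs) for u in u_base[:, 7]]
        )
        li = np.array(
            [_draw_categorical(u, b.lung_involvement_probs) for u in u_base[:, 8]]
        )
        rt = (u_base[:, 9] < b.prior_radiation_p).astype(int)
        U = np.stack([d["u"] for d in draws])           # (n, K, 6)
        tls_noise = np.stack([d["tls_noise"] for d in draws])

        n = n_arm
        A = np.full(n, arm if force_treatment is None else force_treatment)
        dp = np.zeros(n, dtype=bool)
        icp = np.zeros(n, dtype=bool)
        ecog = (ecog_b >= 2).astype(int)
        tls = tls0.copy()
        switched = np.zeros(n, dtype=bool)
        prog_month = np.full(n, -1)
        icp_month = np.full(n, -1)
        switch_month = np.full(n, -1)
        censor_month = np.full(n, -1)
        death_month = np.full(n, -1)
        ecog_path = np.zeros((n, K), dtype=int)
        tls_path = np.zeros((n, K))
        ecog_path[:, 0] = ecog
        tls_path[:, 0] = tls

        # month 0: progression/switch/death are impossible (dp_0 = 0);
        # LTFU can already occur
        if not disable_censoring:
            p_cens = expit(config.censoring.intercept)
            censor_month[U[:, 0, 4] < p_cens] = 0

        for k in range(1, K):
            active = (death_month < 0) & (censor_month < 0)
            if not active.any():
                break
            lag_A, lag_dp, lag_ecog, lag_tls = A.copy(), dp.copy(), ecog.copy(), tls.copy()

            e = config.ecog
            p_ecog = expit(
                e.intercept + e.prev * lag_ecog + e.treatment * lag_A + e.dp * lag_dp
            )
            ecog = np.where(active, (U[:, k, 0] < p_ecog).astype(int), ecog)

            t = config.tls
            drift = t.intercept + t.treatment * lag_A + t.dp * lag_dp
            tls = np.where(active, lag_tls + drift + t.sd * tls_noise[:, k], tls)

            p = config.progression
            p_prog = expit(
                p.intercept
                + p.treatment * lag_A
                + p.tls * _z_tls(lag_tls)
                + p.ecog * lag_ecog
                + p.age * _z_age(age)
            )
            newly_prog = active & ~dp & (U[:, k, 1] < p_prog)
            dp = dp | newly_prog
            prog_month[newly_prog] = k

            i = config.icp
            p_icp = expit(
                i.intercept + i.ics * ics + i.dp * lag_dp + i.treatment * lag_A
            )
            newly_icp = active & ~icp & (U[:, k, 2] < p_icp)
            icp = icp | newly_icp
            icp_month[newly_icp] = k

            tdp = np.where(dp, k - np.where(prog_month >= 0, prog_month, k), 0)

            if not disable_switching and force_treatment is None:
                s = config.switching
                eligible = active & (np.full(n, arm) == 0) & dp & ~switched
                p_sw = expit(
                    s.intercept
                    + s.tls * _z_tls(tls)
                    + s.ecog * ecog
                    + s.tdp * tdp
                    + s.age * _z_age(age)
                )
                newly_sw = eligible & (U[:, k, 3] < p_sw)
                switched = switched | newly_sw
                switch_month[newly_sw] = k
                A = np.where(switched, 1, A)

            cens_hit = np.zeros(n, dtype=bool)
            if not disable_censoring:
                c = config.censoring
                p_cens = expit(c.intercept + c.time * k)
                cens_hit = active & (U[:, k, 4] < p_cens)

            m = config.death
            p_death = expit(
                m.intercept
                + m.treatment * A
                + m.tls * _z_tls(tls)
                + m.ecog * ecog
                + m.icp * icp
            )
            if not cumulative_hazard_warned and np.any(p_death[active & dp] > 0.8):
                warnings.warn("death hazard above 0.8 for some person-months")
                cumulative_hazard_warned = True
            death_hit = active & dp & (U[:, k, 5] < p_death)
            # death takes precedence over censoring in the same interval
            death_month[death_hit] = k
            censor_month[cens_hit & ~death_hit] = k

            ecog_path[:, k] = ecog
            tls_path[:, k] = tls

        prefix = "E" if arm == 1 else "C"
        for i_subj in range(n):
            end = K - 1
            for col in (death_month, censor_month):
                if col[i_subj] >= 0:
                    end = min(end, col[i_subj])
            baseline = BaselineCovariates(
                age=float(age[i_subj]),
                ecog=int(ecog_b[i_subj]),
                ics=int(ics[i_subj]),
                race=int(race[i_subj]),
                sex=int(sex[i_subj]),
                smoking=int(smoking[i_subj]),
                strata=int(strata[i_subj]),
                diagnosis_stage=int(ids[i_subj]),
                lung_involvement=int(li[i_subj]),
                prior_radiation=int(rt[i_subj]),
            )

            def month_or_none(col):
                v = int(col[i_subj])
                return v if 0 <= v <= end else None

            subjects.append(
                SubjectRecord(
                    subject_id=f"{prefix}{i_subj:05d}",
                    arm=arm,
                    baseline=baseline,
                    progression_month=month_or_none(prog_month),
                    icp_month=month_or_none(icp_month),
                    switch_month=month_or_none(switch_month)
                    if arm == 0 and force_treatment is None
                    else None,
                    censor_month=month_or_none(censor_month),
                    death_month=month_or_none(death_month),
                    max_followup_months=K,
                    baseline_tls=float(tls0[i_subj]),
                    ecog_path=tuple(int(v) for v in ecog_path[i_subj, : end + 1]),
                    tls_path=tuple(float(v) for v in tls_path[i_subj, : end + 1]),
                )
            )
    return subjects


def generate_trial(config: GeneratorConfig) -> list[SubjectRecord]:
    """Simulate one trial cohort; identical config => identical cohort."""
    return _simulate_cohort(
        config, {0: config.n_control, 1: config.n_experimental}
    )


def generate_person_time(config: GeneratorConfig) -> "pd.DataFrame":
    """Generate a cohort and expand it into the person-time table."""
    return expand_to_person_time(generate_trial(config), config.horizon_months)


_STRATEGIES = {"always_control": 0, "always_experimental": 1}


def simulate_truth(
    config: GeneratorConfig,
    strategy: str,
    n_oracle: int = 20_000,
    seed: Optional[int] = None,
) -> CounterfactualTruth:
    """Ground-truth counterfactual risk by direct intervention on the generator.

    Re-runs the mechanism with switching and LTFU hazards forced to zero and
    treatment forced to the strategy's value at every interval; the
    empirical cumulative death risk per month is the estimand's truth up to
    Monte-Carlo error of order sqrt(risk * (1 - risk) / n_oracle).
    """
    if strategy not in _STRATEGIES:
        raise ValueError(
            f"unknown strategy {strategy!r}; expected one of {sorted(_STRATEGIES)}"
        )
    if n_oracle < 1000:
        raise ValueError("n_oracle must be at least 1000 for a usable oracle")
    a = _STRATEGIES[strategy]
    seed = config.seed + 7919 if seed is None else seed
    subjects = _simulate_cohort(
        config,
        {a: n_oracle},
        force_treatment=a,
        disable_switching=True,
        disable_censoring=True,
        seed=seed,
    )
    K = config.horizon_months
    death = np.array(
        [s.death_month if s.death_month is not None else K + 1 for s in subjects]
    )
    months = np.arange(1, K + 1)
    risk = np.array([(death <= m - 1).mean() for m in months])
    return CounterfactualTruth(strategy=strategy, risk=risk, n_oracle=n_oracle)
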