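"""Nonparametric subject-level bootstrap with replicate-failure accounting.

The whole estimation procedure — weight fitting plus outcome fitting, or
g-formula model fitting plus simulation — is re-run on each resample so the
interval reflects both the correlated person-time within subjects and the
nuisance-model estimation step.  Resampling is with replacement *within the
randomized arm*, preserving arm sizes.  Replicates on which any model fails
(non-convergence, empty category, separation) are dropped and counted,
never retried; percentile intervals are formed over the successes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .core_data import SubjectRecord
from .discrete_survival import FitFailure

__all__ = [
    "BootstrapResult",
    "bootstrap_ci",
    "bootstrap_replicates",
    "bootstrap_se",
    "resample_subjects",
]

# defaults mirror the usual practice for these estimators: 1000 resamples
# for the weighting / ITT paths, 500 for the costlier g-formula path
DEFAULT_N_SAMPLES_IPCW = 1000
DEFAULT_N_SAMPLES_GFORMULA = 500


@dataclass
class BootstrapResult:
    point: float
    ci_low: float
    ci_high: float
    level: float
    n_requested: int
    n_failures: int
    seed: int
    replicates: Optional[np.ndarray] = None
    failure_reasons: list = field(default_factory=list)
    unreliable: bool = False

    @property
    def se(self) -> float:
        if self.replicates is None or len(self.replicates) < 2:
            return float("nan")
        return float(np.std(self.replicates, ddof=1))

    def log(self) -> pd.DataFrame:
        """Per-replicate log: estimate or failure reason."""
        reps = self.replicates if self.replicates is not None else []
        rows = [
            {"replicate": i, "estimate": est, "failure": ""}
            for i, est in enumerate(reps)
        ]
        offset = len(rows)
        rows += [
            {"replicate": offset + i, "estimate": np.nan, "failure": reason}
            for i, reason in enumerate(self.failure_reasons)
        ]
        return pd.DataFrame(rows, columns=["replicate", "estimate", "failure"])


def resample_subjects(
    subjects: Sequence[SubjectRecord], rng: np.random.Generator
) -> list[SubjectRecord]:
    """One stratified-by-arm resample with replacement; ids re-keyed so the
    person-time expansion keeps duplicated subjects distinct."""
    out: list[SubjectRecord] = []
    for arm in (0, 1):
        arm_subjects = [s for s in subjects if s.arm == arm]
        if not arm_subjects:
            continue
        idx = rng.integers(0, len(arm_subjects), size=len(arm_subjects))
        for j, i in enumerate(idx):
            out.append(replace(arm_subjects[i], subject_id=f"R{arm}_{j:05d}"))
    return out


def bootstrap_replicates(
    procedure: Callable[[Sequence[SubjectRecord]], float],
    subjects: Sequence[SubjectRecord],
    n_samples: int,
    seed: int,
) -> tuple[np.ndarray, list[str]]:
    """Run the procedure on ``n_samples`` stratified resamples.

    Returns the successful replicate estimates and the failure reasons.
    Identical seed implies identical resample indices and results.
    """
    rng = np.random.default_rng(seed)
    estimates: list[float] = []
    failures: list[str] = []
    for _ in range(n_samples):
        sample = resample_subjects(subjects, rng)
        try:
            value = float(procedure(sample))
        except FitFailure as exc:
            failures.append(str(exc))
            continue
        if not np.isfinite(value):
            failures.append("non-finite estimate")
            continue
        estimates.append(value)
    return np.asarray(estimates), failures


def bootstrap_ci(
    procedure: Callable[[Sequence[SubjectRecord]], float],
    subjects: Sequence[SubjectRecord],
    n_samples: int = DEFAULT_N_SAMPLES_IPCW,
    level: float = 0.95,
    seed: int = 0,
    keep_replicates: bool = True,
) -> BootstrapResult:
    """Percentile bootstrap CI around ``procedure(subjects)``.

    The point estimate is computed on the original cohort; CI bounds are
    the empirical percentiles of the retained replicate estimates.  More
    than 50% replicate failures flags the result unreliable.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    try:
        point = float(procedure(subjects))
    except FitFailure:
        point = float("nan")
    estimates, failures = bootstrap_replicates(procedure, subjects, n_samples, seed)
    if len(estimates) == 0:
        return BootstrapResult(
            point=point,
            ci_low=float("nan"),
            ci_high=float("nan"),
            level=level,
            n_requested=n_samples,
            n_failures=len(failures),
            seed=seed,
            replicates=estimates if keep_replicates else None,
            failure_reasons=failures,
            unreliable=True,
        )
    alpha = (1.0 - level) / 2.0
    ci_low, ci_high = np.percentile(estimates, [100 * alpha, 100 * (1 - alpha)])
    return BootstrapResult(
        point=point,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        level=level,
        n_requested=n_samples,
        n_failures=len(failures),
        seed=seed,
        replicates=estimates if keep_replicates else None,
        failure_reasons=failures,
        unreliable=len(failures) > n_samples / 2,
    )


def bootstrap_se(
    procedure: Callable[[Sequence[SubjectRecord]], float],
    subjects: Sequence[SubjectRecord],
    n_samples: int,
    seed: int,
) -> float:
    """Bootstrap standard error (SD of replicate estimates)."""
    estimates, _ = bootstrap_replicates(procedure, subjects, n_samples, seed)
    if len(estimates) < 2:
        return float("nan")
    return float(np.std(estimates, ddof=1))
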