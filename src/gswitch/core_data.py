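"""Domain types and person-time plumbing shared by every estimator.

A two-arm trial with one-sided crossover is recorded per subject as a small
set of event months (progression, switch, censoring, death) plus baseline
covariates and, optionally, monthly trajectories of the time-varying
covariates.  All estimation happens on the *person-time table*: one row per
subject per 30-day interval, indexed ``k = 0, 1, ...``.  An event "by the end
of interval k+1" (death ``Y_{k+1}``, censoring ``C_{k+1}``) is attached to
the row with index ``k``.

The table is a plain :class:`pandas.DataFrame` with a fixed, documented
column set (:data:`PERSON_TIME_COLUMNS`); helpers here expand subject
records into that shape, validate its structural invariants, build
deterministic design matrices from declarative term lists, and round-trip
the table through headered CSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BaselineCovariates",
    "SubjectRecord",
    "TermSpec",
    "DesignBuilder",
    "StructuralValidationError",
    "ValidationReport",
    "expand_to_person_time",
    "collapse_person_time",
    "validate_person_time",
    "build_design_matrix",
    "read_person_time",
    "write_person_time",
    "write_data_dictionary",
    "PERSON_TIME_COLUMNS",
    "BASELINE_COLUMNS",
]


class StructuralValidationError(ValueError):
    """Raised when subject records or person-time rows violate structure."""


# Fixed category counts for the coded baseline covariates.
_CATEGORY_LEVELS = {
    "ecog": 3,          # ordinal 0/1/2
    "ics": 2,           # measurable intracranial CNS disease
    "race": 2,          # Asian / non-Asian
    "sex": 2,
    "smoking": 3,       # never / former / current
    "strata": 4,        # brain metastases x prior chemotherapy
    "diagnosis_stage": 4,
    "lung_involvement": 4,
    "prior_radiation": 2,
}

BASELINE_COLUMNS = (
    "age",
    "ecog",
    "ics",
    "race",
    "sex",
    "smoking",
    "strata",
    "diagnosis_stage",
    "lung_involvement",
    "prior_radiation",
)

PERSON_TIME_COLUMNS = (
    "subject_id",
    "k",
    "arm",
    "treatment",
    "dp",
    "icp",
    "ecog_tv",
    "tls",
    "tdp",
    "outcome",
    "censored",
    "switched",
) + BASELINE_COLUMNS


@dataclass(frozen=True)
class BaselineCovariates:
    """Time-fixed covariates measured at randomization.

    Categorical fields are integer-coded from 0; ``age`` is in years.
    """

    age: float
    ecog: int = 0
    ics: int = 0
    race: int = 0
    sex: int = 0
    smoking: int = 0
    strata: int = 0
    diagnosis_stage: int = 0
    lung_involvement: int = 0
    prior_radiation: int = 0

    def __post_init__(self) -> None:
        if not self.age > 0:
            raise StructuralValidationError(f"age must be positive, got {self.age}")
        for name, n_levels in _CATEGORY_LEVELS.items():
            code = getattr(self, name)
            if not (isinstance(code, (int, np.integer)) and 0 <= code < n_levels):
                raise StructuralValidationError(
                    f"baseline covariate {name}={code!r} outside 0..{n_levels - 1}"
                )

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in BASELINE_COLUMNS}


@dataclass(frozen=True)
class SubjectRecord:
    """One randomized subject summarized by baseline data and event months.

    ``arm`` is the randomized assignment Z (1 = experimental, 0 = control).
    Event months are interval indices; ``switch_month`` may only be present
    for control subjects and never precedes ``progression_month``.  Optional
    ``ecog_path`` / ``tls_path`` carry the monthly time-varying covariate
    trajectories (index 0 = baseline visit); when absent the person-time
    expansion falls back to the baseline ECOG and ``baseline_tls``.
    """

    subject_id: str
    arm: int
    baseline: BaselineCovariates
    progression_month: Optional[int] = None
    icp_month: Optional[int] = None
    switch_month: Optional[int] = None
    censor_month: Optional[int] = None
    death_month: Optional[int] = None
    max_followup_months: int = 48
    baseline_tls: float = 0.0
    ecog_path: Optional[tuple] = None
    tls_path: Optional[tuple] = None

    def __post_init__(self) -> None:
        if self.arm not in (0, 1):
            raise StructuralValidationError(
                f"{self.subject_id}: arm must be 0/1, got {self.arm}"
            )
        if self.max_followup_months < 1:
            raise StructuralValidationError(
                f"{self.subject_id}: max_followup_months must be >= 1"
            )
        if self.switch_month is not None:
            if self.arm != 0:
                raise StructuralValidationError(
                    f"{self.subject_id}: switch_month present for experimental arm"
                )
            if self.progression_month is None or self.switch_month < self.progression_month:
                raise StructuralValidationError(
                    f"{self.subject_id}: switch_month precedes progression_month"
                )
        if self.death_month is not None and self.censor_month is not None:
            raise StructuralValidationError(
                f"{self.subject_id}: death_month and censor_month both present"
            )
        for name in ("progression_month", "icp_month", "switch_month",
                     "censor_month", "death_month"):
            value = getattr(self, name)
            if value is not None:
                if value < 0:
                    raise StructuralValidationError(
                        f"{self.subject_id}: {name}={value} negative"
                    )
                if value > self.max_followup_months:
                    raise StructuralValidationError(
                        f"{self.subject_id}: {name}={value} beyond "
                        f"max_followup_months={self.max_followup_months}"
                    )

    @property
    def end_month(self) -> int:
        """Index of the subject's final person-time row."""
        candidates = [self.max_followup_months - 1]
        if self.death_month is not None:
            candidates.append(self.death_month)
        if self.censor_month is not None:
            candidates.append(self.censor_month)
        return min(candidates)


@dataclass(frozen=True)
class TermSpec:
    """One declarative model term.

    ``transform`` is one of ``linear``, ``quadratic``, ``spline5`` (natural
    cubic spline, 5 knots at the 5th/27.5th/50th/72.5th/95th empirical
    percentiles of the fitting data) or ``categorical`` (reference = lowest
    observed code, ``n_levels`` indicators minus one).
    """

    name: str
    role: Literal["baseline", "time_varying"] = "time_varying"
    transform: Literal["linear", "quadratic", "spline5", "categorical"] = "linear"
    n_levels: Optional[int] = None

    def __post_init__(self) -> None:
        if self.transform == "categorical":
            if self.n_levels is None or self.n_levels < 2:
                raise StructuralValidationError(
                    f"term {self.name}: categorical requires n_levels >= 2"
                )
        elif self.n_levels is not None:
            raise StructuralValidationError(
                f"term {self.name}: n_levels only valid for categorical"
            )


SPLINE5_PERCENTILES = (5.0, 27.5, 50.0, 72.5, 95.0)


def natural_spline_basis(x: np.ndarray, knots: Sequence[float]) -> np.ndarray:
    """Natural cubic spline basis (truncated-power form) at interior points.

    With K knots ``t_1 < ... < t_K`` the basis has K-1 columns: the identity
    and, for j = 1..K-2, ``d_j(x) - d_{K-1}(x)`` where
    ``d_j(x) = [(x - t_j)^3_+ - (x - t_K)^3_+] / (t_K - t_j)``.  The fitted
    function is linear beyond the boundary knots.
    """
    knots = np.asarray(knots, dtype=float)
    K = len(knots)
    x = np.asarray(x, dtype=float)

    def d(j: int) -> np.ndarray:
        return (
            np.clip(x - knots[j], 0.0, None) ** 3
            - np.clip(x - knots[K - 1], 0.0, None) ** 3
        ) / (knots[K - 1] - knots[j])

    cols = [x]
    d_last = d(K - 2)
    for j in range(K - 2):
        cols.append(d(j) - d_last)
    return np.column_stack(cols)


class DesignBuilder:
    """Deterministic design-matrix construction from :class:`TermSpec` lists.

    ``fit`` freezes spline knots and categorical levels on the fitting data;
    ``transform`` then maps any conforming data frame to the numeric matrix
    with byte-stable column labels.  Unseen category codes at transform time
    raise :class:`StructuralValidationError`.
    """

    def __init__(self, terms: Sequence[TermSpec], add_intercept: bool = True):
        self.terms = list(terms)
        self.add_intercept = add_intercept
        self._knots: dict[str, np.ndarray] = {}
        self._levels: dict[str, list] = {}
        self._fitted = False

    def fit(self, df: pd.DataFrame) -> "DesignBuilder":
        for term in self.terms:
            if term.name not in df.columns:
                raise StructuralValidationError(f"variable {term.name} not in table")
            x = df[term.name].to_numpy()
            if term.transform == "spline5":
                xf = np.asarray(x, dtype=float)
                if not np.all(np.isfinite(xf)):
                    raise StructuralValidationError(
                        f"variable {term.name} has non-finite values"
                    )
                knots = np.percentile(xf, SPLINE5_PERCENTILES)
                if np.unique(knots).size < len(knots):
                    raise StructuralValidationError(
                        f"variable {term.name}: degenerate spline knots "
                        f"(constant or near-constant column)"
                    )
                self._knots[term.name] = knots
            elif term.transform == "categorical":
                levels = sorted(pd.unique(pd.Series(x).dropna()))
                if term.n_levels is not None and len(levels) > term.n_levels:
                    raise StructuralValidationError(
                        f"variable {term.name}: {len(levels)} observed levels "
                        f"exceed declared n_levels={term.n_levels}"
                    )
                self._levels[term.name] = [int(v) for v in levels]
        self._fitted = True
        return self

    def transform(self, df: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
        if not self._fitted:
            raise RuntimeError("DesignBuilder.transform called before fit")
        cols: list[np.ndarray] = []
        labels: list[str] = []
        if self.add_intercept:
            cols.append(np.ones(len(df)))
            labels.append("const")
        for term in self.terms:
            if term.name not in df.columns:
                raise StructuralValidationError(f"variable {term.name} not in table")
            x = df[term.name].to_numpy()
            if term.transform == "linear":
                cols.append(np.asarray(x, dtype=float))
                labels.append(term.name)
            elif term.transform == "quadratic":
                xf = np.asarray(x, dtype=float)
                cols.append(xf)
                cols.append(xf**2)
                labels.extend([term.name, f"{term.name}^2"])
            elif term.transform == "spline5":
                basis = natural_spline_basis(x, self._knots[term.name])
                for j in range(basis.shape[1]):
                    cols.append(basis[:, j])
                    labels.append(f"{term.name}_s{j + 1}")
            elif term.transform == "categorical":
                levels = self._levels[term.name]
                observed = set(int(v) for v in pd.unique(pd.Series(x).dropna()))
                unseen = observed - set(levels)
                if unseen:
                    raise StructuralValidationError(
                        f"variable {term.name}: unseen category code(s) "
                        f"{sorted(unseen)} at prediction time"
                    )
                for level in levels[1:]:
                    cols.append((np.asarray(x) == level).astype(float))
                    labels.append(f"{term.name}[{level}]")
        X = np.column_stack(cols) if cols else np.empty((len(df), 0))
        return X, labels

    def fit_transform(self, df: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
        return self.fit(df).transform(df)

    @property
    def knots(self) -> dict:
        """Frozen spline knots per variable (for output metadata)."""
        return {k: v.tolist() for k, v in self._knots.items()}


def build_design_matrix(
    table: pd.DataFrame, terms: Sequence[TermSpec], add_intercept: bool = True
) -> tuple[np.ndarray, list[str], DesignBuilder]:
    """Fit-and-transform convenience wrapper around :class:`DesignBuilder`."""
    builder = DesignBuilder(terms, add_intercept=add_intercept)
    X, labels = builder.fit_transform(table)
    return X, labels, builder


def expand_to_person_time(
    subjects: Iterable[SubjectRecord], horizon_months: int = 48
) -> pd.DataFrame:
    """Expand subject records into the long-format person-time table.

    One row per subject per complete month from 0 through
    ``min(event month, horizon - 1, max follow-up - 1)``; the terminal row
    carries the outcome / censoring flag.  For control subjects the
    ``treatment`` column switches to 1 from ``switch_month`` onward; ``dp``,
    ``icp``, ``tdp`` derive from the onset months (``tdp`` = months since
    progression, 0 pre-progression with ``dp = 0`` marking the state).
    """
    if horizon_months < 1:
        raise StructuralValidationError("horizon_months must be >= 1")
    chunks: dict[str, list] = {c: [] for c in PERSON_TIME_COLUMNS}
    for s in subjects:
        end = min(s.end_month, horizon_months - 1)
        # event flags only attach if the event falls inside the horizon
        died = s.death_month is not None and s.death_month <= end
        censored = s.censor_month is not None and s.censor_month <= end and not died
        if s.death_month is not None and s.progression_month is not None:
            if s.death_month < s.progression_month:
                raise StructuralValidationError(
                    f"{s.subject_id}: death at {s.death_month} precedes "
                    f"progression at {s.progression_month} (death is gated "
                    f"by progression)"
                )
        k = np.arange(end + 1)
        n = len(k)
        dp = (
            (k >= s.progression_month).astype(np.int64)
            if s.progression_month is not None
            else np.zeros(n, dtype=np.int64)
        )
        icp = (
            (k >= s.icp_month).astype(np.int64)
            if s.icp_month is not None
            else np.zeros(n, dtype=np.int64)
        )
        tdp = np.where(dp == 1, k - (s.progression_month or 0), 0).astype(np.int64)
        switched = (
            (k >= s.switch_month).astype(np.int64)
            if s.switch_month is not None
            else np.zeros(n, dtype=np.int64)
        )
        treatment = np.full(n, s.arm, dtype=np.int64) | switched
        outcome = np.zeros(n, dtype=np.int64)
        censored_col = np.zeros(n, dtype=np.int64)
        if died:
            outcome[-1] = 1
        elif censored:
            censored_col[-1] = 1
        if s.ecog_path is not None:
            if len(s.ecog_path) < n:
                raise StructuralValidationError(
                    f"{s.subject_id}: ecog_path shorter than follow-up"
                )
            ecog_tv = np.asarray(s.ecog_path[:n], dtype=np.int64)
        else:
            ecog_tv = np.full(n, min(s.baseline.ecog, 2), dtype=np.int64)
        if s.tls_path is not None:
            if len(s.tls_path) < n:
                raise StructuralValidationError(
                    f"{s.subject_id}: tls_path shorter than follow-up"
                )
            tls = np.asarray(s.tls_path[:n], dtype=float)
        else:
            tls = np.full(n, float(s.baseline_tls))
        chunks["subject_id"].append(np.full(n, s.subject_id, dtype=object))
        chunks["k"].append(k)
        chunks["arm"].append(np.full(n, s.arm, dtype=np.int64))
        chunks["treatment"].append(treatment)
        chunks["dp"].append(dp)
        chunks["icp"].append(icp)
        chunks["ecog_tv"].append(ecog_tv)
        chunks["tls"].append(tls)
        chunks["tdp"].append(tdp)
        chunks["outcome"].append(outcome)
        chunks["censored"].append(censored_col)
        chunks["switched"].append(switched)
        for name, value in s.baseline.as_dict().items():
            chunks[name].append(np.full(n, value))
    if not chunks["k"]:
        return pd.DataFrame(columns=list(PERSON_TIME_COLUMNS))
    table = pd.DataFrame(
        {c: np.concatenate(chunks[c]) for c in PERSON_TIME_COLUMNS}
    )
    for name in ("ecog", "ics", "race", "sex", "smoking", "strata",
                 "diagnosis_stage", "lung_involvement", "prior_radiation"):
        table[name] = table[name].astype(np.int64)
    return table


def collapse_person_time(table: pd.DataFrame) -> list[SubjectRecord]:
    """Invert :func:`expand_to_person_time` (up to the expansion horizon).

    Event months, baseline covariates and time-varying trajectories are
    recovered from the rows; ``max_followup_months`` is taken as the number
    of rows for event-free subjects.
    """
    records = []
    for sid, g in table.groupby("subject_id", sort=False):
        g = g.sort_values("k")
        baseline = BaselineCovariates(
            age=float(g["age"].iloc[0]),
            **{
                name: int(g[name].iloc[0])
                for name in BASELINE_COLUMNS
                if name != "age"
            },
        )
        def onset(col: str) -> Optional[int]:
            hit = g.loc[g[col] == 1, "k"]
            return int(hit.iloc[0]) if len(hit) else None

        death = int(g["k"].iloc[-1]) if g["outcome"].iloc[-1] == 1 else None
        censor = int(g["k"].iloc[-1]) if g["censored"].iloc[-1] == 1 else None
        last = int(g["k"].iloc[-1])
        records.append(
            SubjectRecord(
                subject_id=str(sid),
                arm=int(g["arm"].iloc[0]),
                baseline=baseline,
                progression_month=onset("dp"),
                icp_month=onset("icp"),
                switch_month=onset("switched"),
                censor_month=censor,
                death_month=death,
                max_followup_months=(last + 1) if death is None and censor is None
                else max(last + 1, 1),
                baseline_tls=float(g["tls"].iloc[0]),
                ecog_path=tuple(int(v) for v in g["ecog_tv"]),
                tls_path=tuple(float(v) for v in g["tls"]),
            )
        )
    return records


@dataclass
class ValidationReport:
    """Structural violations found in a person-time table."""

    violations: list = field(default_factory=list)

    def add(self, subject_id, k, rule: str) -> None:
        self.violations.append({"subject_id": subject_id, "k": k, "rule": rule})

    @property
    def ok(self) -> bool:
        return not self.violations

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.violations, columns=["subject_id", "k", "rule"])


def validate_person_time(table: pd.DataFrame) -> ValidationReport:
    """Check every PersonTimeRow invariant; violations are reported, not raised."""
    report = ValidationReport()
    missing = [c for c in PERSON_TIME_COLUMNS if c not in table.columns]
    if missing:
        report.add(None, None, f"missing columns: {missing}")
        return report
    for sid, g in table.groupby("subject_id", sort=False):
        g = g.sort_values("k")
        k = g["k"].to_numpy()
        if len(k) and (k[0] != 0 or not np.all(np.diff(k) == 1)):
            report.add(sid, int(k[0]), "interval index not contiguous from 0")
        for col in ("dp", "icp", "switched"):
            if np.any(np.diff(g[col].to_numpy()) < 0):
                report.add(sid, None, f"non-absorbing {col}")
        out = g["outcome"].to_numpy()
        if out.sum() > 1:
            report.add(sid, None, "multiple death rows")
        if out.sum() >= 1 and np.any(out[:-1] == 1):
            report.add(sid, None, "rows after death")
        cen = g["censored"].to_numpy()
        if cen.sum() > 1 or (cen.sum() == 1 and cen[-1] != 1):
            report.add(sid, None, "rows after censoring")
        if np.any((out == 1) & (cen == 1)):
            report.add(sid, None, "death and censoring on the same row")
        if np.any((out == 1) & (g["dp"].to_numpy() == 0)):
            report.add(sid, None, "death without progression (gating violated)")
    return report


def write_person_time(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_person_time(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = [c for c in PERSON_TIME_COLUMNS if c not in table.columns]
    if missing:
        raise StructuralValidationError(f"person-time CSV missing columns {missing}")
    return table


_DATA_DICTIONARY = {
    "subject_id": "opaque subject identifier",
    "k": "30-day interval index from 0 (follow-up time, FUT)",
    "arm": "randomized assignment Z (1 = experimental, 0 = control)",
    "treatment": "current treatment A_k (1 = experimental drug)",
    "dp": "disease progression by visit k (absorbing)",
    "icp": "intracranial progression by visit k (absorbing)",
    "ecog_tv": "time-varying ECOG performance state",
    "tls": "target-lesion size, mm",
    "tdp": "months since progression onset (0 pre-progression; dp marks state)",
    "outcome": "death by end of interval k+1 (Y_{k+1})",
    "censored": "LTFU/administrative censoring by end of interval k+1 (C_{k+1})",
    "switched": "crossover to experimental treatment occurred by interval k",
    "age": "baseline age, years",
    "ecog": "baseline ECOG score 0/1/2",
    "ics": "baseline measurable intracranial CNS disease (0/1)",
    "race": "race (0 = non-Asian, 1 = Asian)",
    "sex": "sex (0/1)",
    "smoking": "smoking history (0 never / 1 former / 2 current)",
    "strata": "randomization strata: brain metastases x prior chemotherapy (0-3)",
    "diagnosis_stage": "initial diagnosis stage, 4 categories",
    "lung_involvement": "lung involvement at study entry, 4 categories",
    "prior_radiation": "prior radiation therapy (0/1)",
}


def write_data_dictionary(path) -> None:
    """Write the companion data dictionary for the person-time CSV contract."""
    frame = pd.DataFrame(
        {"column": list(_DATA_DICTIONARY), "description": list(_DATA_DICTIONARY.values())}
    )
    frame.to_csv(path, index=False)
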