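"""Core data model and shared preprocessing for two-arm trial data.

A trial is a vector of continuous outcomes, a binary treatment indicator
(1 = experimental arm, 0 = control arm) and, optionally, one or more
continuous pretreatment covariates.  Everything downstream — the
variance-homogeneity tests, the randomization tests and the quantile
machinery — consumes the :class:`TrialData` container defined here.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TrialData:
    """Outcomes, treatment assignment and optional covariates for one trial.

    Parameters
    ----------
    outcome
        Continuous outcome, one entry per unit.
    treatment
        Indicator with values in {0, 1}, aligned with ``outcome``.
    covariates
        Optional matrix of continuous pretreatment covariates, one row
        per unit.

    Raises
    ------
    ValueError
        If lengths disagree, the treatment is not coded 0/1, either arm
        has fewer than two units, or any outcome is non-finite.
    """

    outcome: np.ndarray
    treatment: np.ndarray
    covariates: np.ndarray | None = None

    def __post_init__(self) -> None:
        outcome = np.asarray(self.outcome, dtype=float).ravel()
        treatment = np.asarray(self.treatment).ravel()
        object.__setattr__(self, "outcome", outcome)
        if treatment.shape[0] != outcome.shape[0]:
            raise ValueError(
                f"outcome has {outcome.shape[0]} units but treatment has "
                f"{treatment.shape[0]}"
            )
        if not np.all(np.isfinite(outcome)):
            raise ValueError("outcome contains non-finite values")
        uniq = np.unique(treatment)
        if not np.all(np.isin(uniq, [0, 1])):
            raise ValueError(
                f"treatment must be coded 0/1; found values {uniq.tolist()}"
            )
        treatment = treatment.astype(int)
        object.__setattr__(self, "treatment", treatment)
        n1 = int(treatment.sum())
        n0 = treatment.shape[0] - n1
        if n0 < 2 or n1 < 2:
            raise ValueError(
                f"each arm needs at least 2 units (control has {n0}, "
                f"treated has {n1})"
            )
        if self.covariates is not None:
            cov = np.asarray(self.covariates, dtype=float)
            if cov.ndim == 1:
                cov = cov[:, None]
            if cov.shape[0] != outcome.shape[0]:
                raise ValueError(
                    f"covariates have {cov.shape[0]} rows but outcome has "
                    f"{outcome.shape[0]} units"
                )
            if not np.all(np.isfinite(cov)):
                raise ValueError("covariates contain non-finite values")
            object.__setattr__(self, "covariates", cov)

    @property
    def n(self) -> int:
        return int(self.outcome.shape[0])

    def arm(self, a: int) -> np.ndarray:
        """Outcome values in arm ``a`` (0 = control, 1 = treated)."""
        return self.outcome[self.treatment == a]

    def with_outcome(self, outcome: np.ndarray) -> "TrialData":
        """Copy of this trial with the outcome vector replaced."""
        return replace(self, outcome=np.asarray(outcome, dtype=float))


@dataclass(frozen=True)
class GroupSummary:
    """Per-arm first and second moments plus the mean-difference ATE.

    ``s2_0``/``s2_1`` carry the usual sample variances (n-1 denominator)
    used by the variance-ratio and variance-difference statistics;
    ``s2ml_0``/``s2ml_1`` carry the maximum-likelihood variances
    (n denominator) implied by the normal-theory model fits.
    """

    n0: int
    n1: int
    mu0: float
    mu1: float
    s2_0: float
    s2_1: float
    s2ml_0: float
    s2ml_1: float

    @property
    def ate_hat(self) -> float:
        return self.mu1 - self.mu0


@dataclass(frozen=True)
class TestResult:
    """Outcome of one heterogeneity test on one dataset."""

    test_name: str
    statistic: float
    p_value: float
    alpha: float = 0.05
    settings: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")

    @property
    def reject(self) -> bool:
        return self.p_value < self.alpha

    def to_record(self) -> dict[str, Any]:
        rec: dict[str, Any] = {
            "test_name": self.test_name,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "alpha": self.alpha,
            "reject": self.reject,
        }
        for key, val in self.settings.items():
            rec[f"setting_{key}"] = val
        return rec


# --------------------------------------------------------------------------
# I/O
# --------------------------------------------------------------------------

def read_trial(
    path,
    outcome_col: str = "outcome",
    treatment_col: str = "treatment",
    covariate_cols: Sequence[str] | None = None,
    sep: str = ",",
) -> TrialData:
    """Read a trial from a delimited text file (header row required).

    Row order is preserved.  The treatment column must be coded 0/1 and
    the outcome numeric; rows with missing values in any mapped column
    are rejected rather than imputed.
    """
    frame = pd.read_csv(path, sep=sep)
    wanted = [outcome_col, treatment_col] + list(covariate_cols or [])
    missing = [c for c in wanted if c not in frame.columns]
    if missing:
        raise ValueError(
            f"column(s) {missing} not found in {path}; available: "
            f"{list(frame.columns)}"
        )
    sub = frame[wanted]
    if sub.isna().any().any():
        bad = sub.columns[sub.isna().any()].tolist()
        raise ValueError(f"missing values in column(s) {bad}; no imputation is done")
    outcome = pd.to_numeric(sub[outcome_col], errors="raise").to_numpy(float)
    treatment = sub[treatment_col].to_numpy()
    covariates = None
    if covariate_cols:
        covariates = sub[list(covariate_cols)].to_numpy(float)
    return TrialData(outcome=outcome, treatment=treatment, covariates=covariates)


# --------------------------------------------------------------------------
# shared preprocessing
# --------------------------------------------------------------------------

def summarize(data: TrialData) -> GroupSummary:
    """Per-arm counts, means and variances (both n-1 and n denominators)."""
    y0, y1 = data.arm(0), data.arm(1)
    n0, n1 = y0.size, y1.size
    s2_0 = float(np.var(y0, ddof=1))
    s2_1 = float(np.var(y1, ddof=1))
    return GroupSummary(
        n0=n0,
        n1=n1,
        mu0=float(y0.mean()),
        mu1=float(y1.mean()),
        s2_0=s2_0,
        s2_1=s2_1,
        s2ml_0=float(np.var(y0)),
        s2ml_1=float(np.var(y1)),
    )


def estimate_ate_ci(data: TrialData, level: float = 0.999) -> tuple[float, float]:
    """Normal-approximation (Neyman) confidence interval for the ATE.

    The interval is ``ate_hat ± z * sqrt(s2_1/n1 + s2_0/n0)`` with ``z``
    the standard-normal quantile at ``(1 + level) / 2``.
    """
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0, 1), got {level}")
    g = summarize(data)
    z = stats.norm.ppf(0.5 * (1.0 + level))
    half = z * np.sqrt(g.s2_1 / g.n1 + g.s2_0 / g.n0)
    return (g.ate_hat - half, g.ate_hat + half)


def rank_transform(data: TrialData) -> TrialData:
    """Replace the outcome by pooled ranks 1..N (ties get average ranks)."""
    return data.with_outcome(stats.rankdata(data.outcome, method="average"))


def residualize(data: TrialData) -> TrialData:
    """Replace the outcome by residuals of a pooled OLS fit on the covariates.

    The regression has an intercept plus all covariates and is fit on the
    pooled sample (treatment is not a regressor), so the arm contrast is
    preserved in the residuals.  Covariates are kept on the returned
    object for provenance.
    """
    if data.covariates is None:
        raise ValueError("residualize requires covariates")
    design = np.column_stack([np.ones(data.n), data.covariates])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("covariate matrix (plus intercept) is rank deficient")
    coef, *_ = np.linalg.lstsq(design, data.outcome, rcond=None)
    return data.with_outcome(data.outcome - design @ coef)
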