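"""Fisher randomization tests (FRTs) for treatment-effect heterogeneity.

Under the sharp null of a constant effect tau, every unit's missing
potential outcome is known once tau is hypothesized, so the exact
randomization distribution of any statistic can be sampled by re-drawing
the treatment assignment (holding arm sizes fixed) and recomputing the
statistic.  The p-value is the exceedance fraction

    p = (1/B) * sum_j I(T_j > T_obs)

with a strict inequality by default, so ties between a draw and the
observed value do not count as exceedances.  The KS-based tests default
to tie-inclusive counting instead; see their docstrings.

Statistics provided here: the variance ratio s2_1/s2_0, the absolute
variance difference |s2_1 - s2_0| (each optionally on pooled ranks), the
absolute mean difference, and the shifted Kolmogorov-Smirnov distance
used by the plug-in tests FRT-PI and FRT-CI.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from math import comb
from typing import Callable

import numpy as np

from .trial_core import (
    TrialData,
    TestResult,
    estimate_ate_ci,
    rank_transform,
    residualize,
    summarize,
)

EXHAUSTIVE_CAP = 100_000


@dataclass(frozen=True)
class FrtSettings:
    """Knobs of the randomization engine.

    B is the number of random re-assignments; with ``exhaustive`` every
    possible assignment (at the observed arm sizes) is enumerated
    instead, which is only allowed up to :data:`EXHAUSTIVE_CAP`
    assignments.  ``tie_inclusive`` switches the exceedance comparison
    from the default strict ``>`` to ``>=``.
    """

    B: int = 2000
    seed: int | None = None
    exhaustive: bool = False
    tie_inclusive: bool = False

    def __post_init__(self) -> None:
        if self.B < 1:
            raise ValueError("B must be >= 1")


@dataclass(frozen=True)
class ScienceTable:
    """Both potential outcomes per unit under a hypothesized constant effect."""

    y0: np.ndarray
    y1: np.ndarray
    tau0: float


def impute_science_table(data: TrialData, tau0: float) -> ScienceTable:
    """Fill in the missing potential outcomes under Y(1) = Y(0) + tau0."""
    A = data.treatment
    y0 = data.outcome - A * tau0
    return ScienceTable(y0=y0, y1=y0 + tau0, tau0=float(tau0))


# --------------------------------------------------------------------------
# plain statistics
# --------------------------------------------------------------------------

def stat_variance_ratio(data: TrialData) -> float:
    """T_V = s2_1 / s2_0 (sample variances, large when the treated arm
    is more dispersed)."""
    g = summarize(data)
    if g.s2_0 <= 0.0:
        raise ValueError("zero control-arm variance; variance ratio undefined")
    return g.s2_1 / g.s2_0


def stat_variance_diff(data: TrialData) -> float:
    """T_D = |s2_1 - s2_0| (sample variances)."""
    g = summarize(data)
    return abs(g.s2_1 - g.s2_0)


def stat_abs_mean_diff(data: TrialData) -> float:
    """|mean(treated) - mean(control)|, the ATE-FRT statistic."""
    g = summarize(data)
    return abs(g.ate_hat)


def _batch_moments(y: np.ndarray, masks: np.ndarray):
    """Per-draw arm sums and sums of squares from boolean treated masks."""
    n = y.size
    n1 = int(masks[0].sum())
    n0 = n - n1
    m = masks.astype(float)
    s1 = m @ y
    q1 = m @ (y * y)
    s0 = y.sum() - s1
    q0 = (y * y).sum() - q1
    var1 = (q1 - s1 * s1 / n1) / (n1 - 1)
    var0 = (q0 - s0 * s0 / n0) / (n0 - 1)
    return s0 / n0, s1 / n1, var0, var1


class _VarianceRatio:
    def __call__(self, data: TrialData) -> float:
        return stat_variance_ratio(data)

    @staticmethod
    def batch(y: np.ndarray, masks: np.ndarray) -> np.ndarray:
        _, _, v0, v1 = _batch_moments(y, masks)
        if np.any(v0 <= 0.0):
            raise ValueError("zero control-arm variance in a randomization draw")
        return v1 / v0


class _VarianceRatioSym:
    """max(T_V, 1/T_V): treats inflation and deflation of the treated-arm
    variance as equally extreme (a two-sided variance-ratio FRT)."""

    def __call__(self, data: TrialData) -> float:
        t = stat_variance_ratio(data)
        return max(t, 1.0 / t)

    @staticmethod
    def batch(y: np.ndarray, masks: np.ndarray) -> np.ndarray:
        t = _VarianceRatio.batch(y, masks)
        return np.maximum(t, 1.0 / t)


class _VarianceDiff:
    def __call__(self, data: TrialData) -> float:
        return stat_variance_diff(data)

    @staticmethod
    def batch(y: np.ndarray, masks: np.ndarray) -> np.ndarray:
        _, _, v0, v1 = _batch_moments(y, masks)
        return np.abs(v1 - v0)


class _AbsMeanDiff:
    def __call__(self, data: TrialData) -> float:
        return stat_abs_mean_diff(data)

    @staticmethod
    def batch(y: np.ndarray, masks: np.ndarray) -> np.ndarray:
        mu0, mu1, _, _ = _batch_moments(y, masks)
        return np.abs(mu1 - mu0)


variance_ratio = _VarianceRatio()
variance_ratio_sym = _VarianceRatioSym()
variance_diff = _VarianceDiff()
abs_mean_diff = _AbsMeanDiff()


# --------------------------------------------------------------------------
# assignment draws and the generic FRT
# --------------------------------------------------------------------------

def _assignment_masks(
    settings: FrtSettings, n: int, n1: int, rng: np.random.Generator
) -> tuple[np.ndarray, bool]:
    """Boolean (draws x units) treated-indicator matrix."""
    if settings.exhaustive:
        total = comb(n, n1)
        if total > EXHAUSTIVE_CAP:
            raise ValueError(
                f"exhaustive enumeration of {total} assignments exceeds the "
                f"cap of {EXHAUSTIVE_CAP}; use sampling"
            )
        masks = np.zeros((total, n), dtype=bool)
        for j, idx in enumerate(itertools.combinations(range(n), n1)):
            masks[j, list(idx)] = True
        return masks, True
    masks = np.zeros((settings.B, n), dtype=bool)
    for j in range(settings.B):
        masks[j, rng.permutation(n)[:n1]] = True
    return masks, False


def _exceedance_p(null_stats: np.ndarray, t_obs: float, settings: FrtSettings) -> float:
    # tolerance keeps exact ties (e.g. the observed assignment, or the
    # mirror-image relabeling of a symmetric statistic) classified as
    # ties even when batch and per-draw arithmetic differ in the last ulp
    tol = 1e-9 * max(1.0, abs(t_obs))
    if settings.tie_inclusive:
        return float(np.mean(null_stats >= t_obs - tol))
    return float(np.mean(null_stats > t_obs + tol))


def frt_pvalue(
    statistic: Callable[[TrialData], float],
    data: TrialData,
    settings: FrtSettings,
    test_name: str = "frt",
    alpha: float = 0.05,
) -> TestResult:
    """Generic FRT: recompute ``statistic`` over re-drawn assignments.

    Group sizes are preserved in every draw (complete randomization).
    If the statistic exposes a vectorized ``batch(y, masks)`` method it
    is used; otherwise the statistic is called on each relabeled trial.
    A constant randomization distribution yields p = 0 under the strict
    comparison and is flagged as degenerate.
    """
    t_obs = float(statistic(data))
    n1 = int(data.treatment.sum())
    rng = np.random.default_rng(settings.seed)
    masks, exhaustive = _assignment_masks(settings, data.n, n1, rng)
    batch = getattr(statistic, "batch", None)
    if batch is not None:
        null_stats = np.asarray(batch(data.outcome, masks), dtype=float)
    else:
        null_stats = np.empty(masks.shape[0])
        for j, mask in enumerate(masks):
            relabeled = TrialData(
                outcome=data.outcome,
                treatment=mask.astype(int),
                covariates=data.covariates,
            )
            try:
                null_stats[j] = statistic(relabeled)
            except Exception as exc:  # noqa: BLE001 - named-draw diagnostics
                raise RuntimeError(f"statistic failed on randomization draw {j}") from exc
    degenerate = bool(np.ptp(null_stats) == 0.0 and null_stats[0] == t_obs)
    if degenerate:
        warnings.warn(
            f"{test_name}: constant randomization distribution; p-value is 0 "
            "under the strict exceedance rule",
            stacklevel=2,
        )
    p = _exceedance_p(null_stats, t_obs, settings)
    return TestResult(
        test_name=test_name,
        statistic=t_obs,
        p_value=p,
        alpha=alpha,
        settings={
            "B": int(masks.shape[0]),
            "seed": settings.seed,
            "exhaustive": exhaustive,
            "tie_inclusive": settings.tie_inclusive,
            "degenerate": degenerate,
        },
    )


def frt_variance_test(
    data: TrialData,
    kind: str = "ratio",
    use_ranks: bool = False,
    use_covariates: bool = False,
    settings: FrtSettings | None = None,
    alpha: float = 0.05,
    symmetrize: bool = True,
) -> TestResult:
    """FRT with the variance ratio or absolute variance difference.

    Optional preprocessing, in order: covariate residualization (pooled
    OLS), then pooled rank transform.  Both are applied once to the
    observed data; the FRT then permutes the arm labels of the
    transformed outcome.

    The variance ratio is symmetrized by default (max of the ratio and
    its reciprocal), making the test two-sided like the absolute
    variance difference; ``symmetrize=False`` gives the one-sided
    large-ratio version.
    """
    if kind not in ("ratio", "diff"):
        raise ValueError(f"kind must be 'ratio' or 'diff', got {kind!r}")
    settings = settings or FrtSettings()
    if use_covariates:
        data = residualize(data)
    if use_ranks:
        data = rank_transform(data)
    if kind == "ratio":
        statistic = variance_ratio_sym if symmetrize else variance_ratio
    else:
        statistic = variance_diff
    name = f"frt_{'v' if kind == 'ratio' else 'd'}{'_rank' if use_ranks else ''}"
    result = frt_pvalue(statistic, data, settings, test_name=name, alpha=alpha)
    result.settings.update(
        use_ranks=use_ranks, use_covariates=use_covariates,
        symmetrize=(symmetrize if kind == "ratio" else None),
    )
    return result


# --------------------------------------------------------------------------
# shifted Kolmogorov-Smirnov statistic and the plug-in FRTs
# --------------------------------------------------------------------------

def _ks_distance(x: np.ndarray, y: np.ndarray) -> float:
    """Exact sup |ecdf(x) - ecdf(y)| over the union of jump points."""
    xs = np.sort(x)
    ys = np.sort(y)
    grid = np.concatenate([xs, ys])
    fx = np.searchsorted(xs, grid, side="right") / xs.size
    fy = np.searchsorted(ys, grid, side="right") / ys.size
    return float(np.max(np.abs(fx - fy)))


def shifted_ks(data: TrialData, shift: float) -> float:
    """T_SKS = sup_y |F0_hat(y) - F1_hat(y + shift)|.

    Shifting the treated arm's ecdf argument by ``shift`` is the same as
    subtracting ``shift`` from every treated outcome, so this is the
    plain two-sample KS distance between the control sample and the
    shifted treated sample.
    """
    return _ks_distance(data.arm(0), data.arm(1) - shift)


def frt_pi(
    data: TrialData,
    settings: FrtSettings | None = None,
    use_covariates: bool = False,
    alpha: float = 0.05,
) -> TestResult:
    """FRT plug-in test: shifted-KS statistic at the estimated ATE.

    The science table is imputed once at tau_hat (the observed mean
    difference).  Each randomization draw re-assigns treatment, rebuilds
    the observed outcomes from the science table, re-estimates the mean
    difference tau*, and evaluates the shifted-KS statistic at tau*.

    When no settings are given, exceedances are counted tie-inclusively
    (``>=``): the KS distance lives on a lattice (multiples of 1/n0 and
    1/n1), so ties with the observed value are common and the strict
    rule would be anti-conservative.
    """
    settings = settings or FrtSettings(B=500, tie_inclusive=True)
    if use_covariates:
        data = residualize(data)
    tau_hat = summarize(data).ate_hat
    table = impute_science_table(data, tau_hat)
    t_obs = shifted_ks(data, tau_hat)
    n1 = int(data.treatment.sum())
    rng = np.random.default_rng(settings.seed)
    masks, exhaustive = _assignment_masks(settings, data.n, n1, rng)
    null_stats = np.empty(masks.shape[0])
    for j, mask in enumerate(masks):
        ctrl = table.y0[~mask]
        trt = table.y1[mask]
        tau_star = trt.mean() - ctrl.mean()
        null_stats[j] = _ks_distance(ctrl, trt - tau_star)
    p = _exceedance_p(null_stats, t_obs, settings)
    return TestResult(
        test_name="frt_pi",
        statistic=t_obs,
        p_value=p,
        alpha=alpha,
        settings={
            "B": int(masks.shape[0]),
            "seed": settings.seed,
            "exhaustive": exhaustive,
            "tie_inclusive": settings.tie_inclusive,
            "tau_hat": tau_hat,
            "use_covariates": use_covariates,
        },
    )


def frt_ci(
    data: TrialData,
    settings: FrtSettings | None = None,
    grid_size: int = 150,
    ci_level: float = 0.999,
    use_covariates: bool = False,
    alpha: float = 0.05,
    early_stop: bool = False,
) -> TestResult:
    """FRT over a grid of hypothesized constant effects (maximum p).

    A grid of ``grid_size`` equally spaced effects spans the
    ``ci_level`` Neyman interval for the ATE.  For each grid value tau0
    the science table is imputed at tau0 and an FRT is run with the
    shifted-KS *statistic* — which, as a statistic of the randomized
    dataset, re-estimates its shift from that dataset's mean
    difference.  The observed value is therefore the same for every
    grid point; only the null draws change.  The reported p-value is
    the maximum over the grid, so the test rejects only when every
    plausible constant effect is rejected.  Like :func:`frt_pi`, the
    default exceedance comparison is tie-inclusive.

    With ``early_stop`` the grid scan (ordered by distance from the
    estimated ATE, where the p-value peaks) aborts once the running
    maximum reaches ``alpha``; the accept/reject decision is unchanged
    but the reported p-value is then only a lower bound for the full
    maximum, flagged in the settings record.
    """
    settings = settings or FrtSettings(B=500, tie_inclusive=True)
    if use_covariates:
        data = residualize(data)
    if grid_size < 1:
        raise ValueError("grid_size must be >= 1")
    tau_hat = summarize(data).ate_hat
    if grid_size == 1:
        grid = np.array([tau_hat])
    else:
        low, high = estimate_ate_ci(data, level=ci_level)
        grid = np.linspace(low, high, grid_size)
    scan = np.argsort(np.abs(grid - tau_hat), kind="stable")
    A = data.treatment.astype(bool)
    n1 = int(A.sum())
    t_obs = shifted_ks(data, tau_hat)
    rng = np.random.default_rng(settings.seed)
    max_p = -1.0
    tau_at_max = float(tau_hat)
    stopped = False
    for k in scan:
        tau0 = grid[k]
        y0 = data.outcome - np.where(A, tau0, 0.0)  # science-table control outcomes
        masks, _ = _assignment_masks(settings, data.n, n1, rng)
        null_stats = np.empty(masks.shape[0])
        for j, mask in enumerate(masks):
            ctrl = y0[~mask]
            trt = y0[mask] + tau0  # science-table treated outcomes
            null_stats[j] = _ks_distance(ctrl, trt - (trt.mean() - ctrl.mean()))
        p_k = _exceedance_p(null_stats, t_obs, settings)
        if p_k > max_p:
            max_p, tau_at_max = p_k, float(tau0)
        if early_stop and max_p >= alpha:
            stopped = True
            break
    return TestResult(
        test_name="frt_ci",
        statistic=t_obs,
        p_value=max_p,
        alpha=alpha,
        settings={
            "B": settings.B,
            "seed": settings.seed,
            "grid_size": grid_size,
            "ci_level": ci_level,
            "tie_inclusive": settings.tie_inclusive,
            "tau_at_max_p": tau_at_max,
            "use_covariates": use_covariates,
            "early_stopped": stopped,
        },
    )
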