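"""Monte-Carlo harness: trial generation, test registry, rejection rates.

Trials follow an additive heterogeneity model: the control potential
outcome Y(0) is a draw from a standard normal, a t(5), or a standard
log-normal distribution (optionally Y(0) = 0.30*X + eps with a standard
normal covariate X), and the unit-level effect is

    tau_i = tau + sigma_tau * Y_i(0),

so Y(1) = (1 + sigma_tau) * Y(0) + tau.  With sigma_tau = 0 the
constant-effect null holds exactly; sigma_tau > 0 scales the treated
arm by (1 + sigma_tau), e.g. a variance ratio of 1.25^2 = 1.5625 at
sigma_tau = 0.25.  Assignment is exactly balanced: n_per_group units
in each arm, chosen uniformly at random.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd

from . import parametric_tests, quantile_subsampling, randomization_tests
from .randomization_tests import FrtSettings, frt_pvalue, abs_mean_diff
from .trial_core import TrialData, TestResult, rank_transform

logger = logging.getLogger(__name__)

DISTRIBUTIONS = ("normal", "t5", "lognormal")


@dataclass(frozen=True)
class ScenarioSpec:
    """One cell of the simulation factorial."""

    distribution: str = "normal"
    tau: float = 0.0
    sigma_tau: float = 0.0
    n_per_group: int = 50
    with_covariate: bool = False
    beta_x: float = 0.30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.distribution not in DISTRIBUTIONS:
            raise ValueError(
                f"unknown distribution {self.distribution!r}; "
                f"choose from {DISTRIBUTIONS}"
            )
        if self.sigma_tau < 0:
            raise ValueError("sigma_tau must be >= 0")
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")

    def label(self) -> str:
        cov = "cov" if self.with_covariate else "nocov"
        return (
            f"{self.distribution}_tau{self.tau:g}_st{self.sigma_tau:g}"
            f"_n{self.n_per_group}_{cov}"
        )


@dataclass(frozen=True)
class RejectionReport:
    """Monte-Carlo rejection rate for one (scenario, test) cell."""

    scenario: ScenarioSpec
    test_name: str
    reps: int
    rejections: int
    errors: int = 0

    @property
    def rate(self) -> float:
        return self.rejections / self.reps

    @property
    def mc_se(self) -> float:
        r = self.rate
        return float(np.sqrt(r * (1.0 - r) / self.reps))

    def to_record(self) -> dict[str, Any]:
        s = self.scenario
        return {
            "distribution": s.distribution,
            "tau": s.tau,
            "sigma_tau": s.sigma_tau,
            "n_per_group": s.n_per_group,
            "with_covariate": s.with_covariate,
            "beta_x": s.beta_x,
            "scenario_seed": s.seed,
            "test_name": self.test_name,
            "reps": self.reps,
            "rejections": self.rejections,
            "errors": self.errors,
            "rate": self.rate,
            "mc_se": self.mc_se,
        }


# --------------------------------------------------------------------------
# data generation
# --------------------------------------------------------------------------

def _draw_noise(rng: np.random.Generator, distribution: str, size: int) -> np.ndarray:
    if distribution == "normal":
        return rng.standard_normal(size)
    if distribution == "t5":
        return rng.standard_t(5, size)
    if distribution == "lognormal":
        return rng.lognormal(mean=0.0, sigma=1.0, size=size)
    raise ValueError(f"unknown distribution {distribution!r}")


def generate_trial(scenario: ScenarioSpec, replicate_index: int = 0) -> TrialData:
    """Draw one trial; the RNG stream is fixed by (seed, replicate_index)."""
    rng = np.random.default_rng(
        np.random.SeedSequence((scenario.seed, replicate_index))
    )
    n = 2 * scenario.n_per_group
    eps = _draw_noise(rng, scenario.distribution, n)
    covariates = None
    if scenario.with_covariate:
        x = rng.standard_normal(n)
        y0 = scenario.beta_x * x + eps
        covariates = x[:, None]
    else:
        y0 = eps
    y1 = y0 + scenario.tau + scenario.sigma_tau * y0
    treatment = np.zeros(n, dtype=int)
    treatment[rng.permutation(n)[: scenario.n_per_group]] = 1
    outcome = np.where(treatment == 1, y1, y0)
    return TrialData(outcome=outcome, treatment=treatment, covariates=covariates)


# --------------------------------------------------------------------------
# ATE randomization test (follow-up study on log-normal data)
# --------------------------------------------------------------------------

def ate_frt(
    data: TrialData,
    use_ranks: bool = False,
    settings: FrtSettings | None = None,
    alpha: float = 0.05,
) -> TestResult:
    """FRT of a zero average effect: |mean difference| on raw or rank data."""
    settings = settings or FrtSettings()
    if use_ranks:
        data = rank_transform(data)
    name = "ate_frt_rank" if use_ranks else "ate_frt_raw"
    result = frt_pvalue(abs_mean_diff, data, settings, test_name=name, alpha=alpha)
    result.settings.update(use_ranks=use_ranks)
    return result


# --------------------------------------------------------------------------
# test registry
# --------------------------------------------------------------------------

def run_test(
    name: str,
    data: TrialData,
    seed: int | None = None,
    alpha: float = 0.05,
    use_covariates: bool = False,
    **overrides: Any,
) -> TestResult:
    """Dispatch a heterogeneity (or ATE) test by registry name.

    ``overrides`` may set B, grid_size, ci_level, b, n_subsamples,
    q_grid or tie_inclusive where the named test accepts them.
    """
    if name not in TEST_NAMES:
        raise ValueError(f"unknown test {name!r}; choose from {sorted(TEST_NAMES)}")
    if name == "t_gamma":
        return parametric_tests.t_gamma(data, use_covariates, alpha)
    if name == "t_lr":
        return parametric_tests.t_lr(data, use_covariates, alpha)
    if name == "t_beta":
        return parametric_tests.t_beta(data, use_covariates, alpha)
    if name in ("frt_v", "frt_d", "frt_v_rank", "frt_d_rank"):
        settings = FrtSettings(
            B=int(overrides.get("B", 2000)),
            seed=seed,
            tie_inclusive=bool(overrides.get("tie_inclusive", False)),
        )
        return randomization_tests.frt_variance_test(
            data,
            kind="ratio" if name.startswith("frt_v") else "diff",
            use_ranks=name.endswith("_rank"),
            use_covariates=use_covariates,
            settings=settings,
            alpha=alpha,
        )
    if name == "frt_pi":
        settings = FrtSettings(
            B=int(overrides.get("B", 500)),
            seed=seed,
            tie_inclusive=bool(overrides.get("tie_inclusive", True)),
        )
        return randomization_tests.frt_pi(data, settings, use_covariates, alpha)
    if name == "frt_ci":
        settings = FrtSettings(
            B=int(overrides.get("B", 500)),
            seed=seed,
            tie_inclusive=bool(overrides.get("tie_inclusive", True)),
        )
        return randomization_tests.frt_ci(
            data,
            settings,
            grid_size=int(overrides.get("grid_size", 150)),
            ci_level=float(overrides.get("ci_level", 0.999)),
            use_covariates=use_covariates,
            alpha=alpha,
            early_stop=bool(overrides.get("early_stop", False)),
        )
    if name == "t_sub":
        kwargs: dict[str, Any] = {
            "b": int(overrides.get("b", 20)),
            "n_subsamples": int(overrides.get("n_subsamples", 500)),
            "seed": seed,
        }
        if "q_grid" in overrides:
            kwargs["q_grid"] = np.asarray(overrides["q_grid"], dtype=float)
        settings = quantile_subsampling.SubsamplingSettings(**kwargs)
        return quantile_subsampling.t_sub_test(data, settings, use_covariates, alpha)
    # ate_frt_raw / ate_frt_rank
    settings = FrtSettings(B=int(overrides.get("B", 2000)), seed=seed)
    return ate_frt(data, use_ranks=name.endswith("_rank"), settings=settings, alpha=alpha)


TEST_NAMES = (
    "t_gamma",
    "t_lr",
    "t_beta",
    "frt_v",
    "frt_v_rank",
    "frt_d",
    "frt_d_rank",
    "frt_pi",
    "frt_ci",
    "t_sub",
    "ate_frt_raw",
    "ate_frt_rank",
)

# the ten heterogeneity tests of the main factorial, in table order
MAIN_TESTS = (
    "t_gamma",
    "frt_v",
    "frt_v_rank",
    "t_lr",
    "t_beta",
    "frt_d",
    "frt_d_rank",
    "frt_pi",
    "frt_ci",
    "t_sub",
)


def _replicate_test_seed(scenario: ScenarioSpec, test_name: str, replicate: int) -> int:
    """Stable per-(cell, test, replicate) seed, independent of run order."""
    tag = zlib.crc32(f"{scenario.label()}|{test_name}".encode())
    return int(
        np.random.SeedSequence((scenario.seed, tag, replicate)).generate_state(1)[0]
        % (2**31)
    )


def rejection_rate(
    scenario: ScenarioSpec,
    test_name: str,
    reps: int = 1000,
    alpha: float = 0.05,
    **test_overrides: Any,
) -> RejectionReport:
    """Monte-Carlo rejection rate of one test in one scenario.

    Replicate-level test failures are logged and counted in ``errors``
    (and treated as non-rejections), never silently dropped.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if test_name == "frt_ci":
        # only the accept/reject decision enters the rate; let the grid
        # scan stop once the running maximum p clears alpha
        test_overrides.setdefault("early_stop", True)
    rejections = 0
    errors = 0
    for rep in range(reps):
        data = generate_trial(scenario, rep)
        try:
            result = run_test(
                test_name,
                data,
                seed=_replicate_test_seed(scenario, test_name, rep),
                alpha=alpha,
                use_covariates=scenario.with_covariate,
                **test_overrides,
            )
        except Exception:  # noqa: BLE001 - per-replicate failures are tallied
            errors += 1
            logger.warning(
                "replicate %d of %s/%s failed", rep, scenario.label(), test_name,
                exc_info=True,
            )
            continue
        rejections += int(result.reject)
    return RejectionReport(
        scenario=scenario,
        test_name=test_name,
        reps=reps,
        rejections=rejections,
        errors=errors,
    )


def run_grid(
    scenarios: Sequence[ScenarioSpec],
    tests: Sequence[str],
    reps: int = 1000,
    alpha: float = 0.05,
    n_jobs: int = 1,
    out_path: str | Path | None = None,
    **test_overrides: Any,
) -> list[RejectionReport]:
    """Evaluate the full scenario x test cross product.

    With ``out_path`` each finished cell is appended to a CSV as it
    completes, and cells already present in that file are skipped on a
    re-run, so interrupted sweeps are resumable.  Per-cell seeds depend
    only on (scenario, test, replicate), so results do not depend on
    the worker count.
    """
    if not scenarios or not tests:
        raise ValueError("scenarios and tests must be non-empty")
    done: set[tuple[str, str]] = set()
    out_file = Path(out_path) if out_path is not None else None
    if out_file is not None and out_file.exists():
        existing = pd.read_csv(out_file)
        for _, row in existing.iterrows():
            scen = ScenarioSpec(
                distribution=row["distribution"],
                tau=float(row["tau"]),
                sigma_tau=float(row["sigma_tau"]),
                n_per_group=int(row["n_per_group"]),
                with_covariate=bool(row["with_covariate"]),
                beta_x=float(row["beta_x"]),
                seed=int(row["scenario_seed"]),
            )
            done.add((scen.label(), str(row["test_name"])))

    cells = [
        (scen, test)
        for scen in scenarios
        for test in tests
        if (scen.label(), test) not in done
    ]

    def _one(cell: tuple[ScenarioSpec, str]) -> RejectionReport | None:
        scen, test = cell
        try:
            return rejection_rate(scen, test, reps=reps, alpha=alpha, **test_overrides)
        except Exception:  # noqa: BLE001 - a broken cell must not kill the grid
            logger.error("cell %s/%s failed", scen.label(), test, exc_info=True)
            return None

    reports: list[RejectionReport] = []
    if n_jobs > 1:
        from joblib import Parallel, delayed

        results = Parallel(n_jobs=n_jobs)(delayed(_one)(cell) for cell in cells)
    else:
        results = (_one(cell) for cell in cells)
    for report in results:
        if report is None:
            continue
        reports.append(report)
        if out_file is not None:
            frame = pd.DataFrame([report.to_record()])
            frame.to_csv(
                out_file,
                mode="a",
                header=not out_file.exists(),
                index=False,
            )
    return reports
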