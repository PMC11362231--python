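import itertools

import numpy as np
import pytest
from scipy import stats

from hetfx import (
    FrtSettings,
    TrialData,
    frt_ci,
    frt_pi,
    frt_pvalue,
    frt_variance_test,
    impute_science_table,
    shifted_ks,
    stat_abs_mean_diff,
    stat_variance_diff,
    stat_variance_ratio,
    summarize,
)
from hetfx.randomization_tests import variance_diff, variance_ratio, variance_ratio_sym


def _two_arm(y0, y1):
    y0, y1 = np.asarray(y0, float), np.asarray(y1, float)
    return TrialData(
        outcome=np.concatenate([y0, y1]),
        treatment=np.concatenate([np.zeros(y0.size, int), np.ones(y1.size, int)]),
    )


def _enumerate_p(statistic, data, tie_inclusive=False):
    """Brute-force FRT oracle: loop all assignments with itertools."""
    n = data.n
    n1 = int(data.treatment.sum())
    t_obs = statistic(data)
    vals = []
    for idx in itertools.combinations(range(n), n1):
        z = np.zeros(n, int)
        z[list(idx)] = 1
        vals.append(statistic(TrialData(outcome=data.outcome, treatment=z)))
    vals = np.array(vals)
    return np.mean(vals >= t_obs) if tie_inclusive else np.mean(vals > t_obs)


class TestStatistics:
    def test_variance_ratio_and_diff(self, tiny_trial):
        assert stat_variance_ratio(tiny_trial) == pytest.approx(4.0)
        assert stat_variance_diff(tiny_trial) == pytest.approx(3.0)

    def test_identity_cases(self):
        data = _two_arm([1.0, 2, 3], [4.0, 5, 6])
        assert stat_variance_ratio(data) == pytest.approx(1.0)
        assert stat_variance_diff(data) == pytest.approx(0.0)

    def test_ratio_scale_invariant_diff_not(self, tiny_trial):
        scaled = tiny_trial.with_outcome(3.0 * tiny_trial.outcome)
        assert stat_variance_ratio(scaled) == pytest.approx(
            stat_variance_ratio(tiny_trial)
        )
        assert stat_variance_diff(scaled) == pytest.approx(9.0 * 3.0)

    def test_zero_control_variance_fails(self):
        with pytest.raises(ValueError, match="control-arm variance"):
            stat_variance_ratio(_two_arm([2.0, 2, 2], [1.0, 2, 3]))

    @pytest.mark.parametrize(
        "stat,batch",
        [
            (stat_variance_ratio, variance_ratio),
            (stat_variance_diff, variance_diff),
            (lambda d: max(stat_variance_ratio(d), 1 / stat_variance_ratio(d)),
             variance_ratio_sym),
        ],
    )
    def test_batch_path_matches_per_draw_evaluation(self, normal_trial, stat, batch):
        rng = np.random.default_rng(0)
        n1 = int(normal_trial.treatment.sum())
        masks = np.zeros((50, normal_trial.n), bool)
        for j in range(50):
            masks[j, rng.permutation(normal_trial.n)[:n1]] = True
        fast = batch.batch(normal_trial.outcome, masks)
        slow = [
            stat(TrialData(outcome=normal_trial.outcome, treatment=m.astype(int)))
            for m in masks
        ]
        np.testing.assert_allclose(fast, slow, rtol=1e-12)


class TestFrtPvalue:
    @pytest.mark.parametrize("n_per_arm", [2, 3, 4])
    @pytest.mark.parametrize("statistic", [stat_variance_diff, stat_abs_mean_diff])
    def test_exhaustive_matches_enumeration_oracle(self, n_per_arm, statistic):
        rng = np.random.default_rng(n_per_arm)
        data = _two_arm(rng.standard_normal(n_per_arm), rng.standard_normal(n_per_arm))
        res = frt_pvalue(statistic, data, FrtSettings(exhaustive=True))
        assert res.p_value == pytest.approx(_enumerate_p(statistic, data), abs=1e-12)

    def test_sampled_p_converges_to_enumerated(self):
        data = _two_arm([0.3, -1.2, 0.7], [2.1, -0.4, 0.9])
        exact = _enumerate_p(stat_variance_diff, data)
        res = frt_pvalue(
            stat_variance_diff, data, FrtSettings(B=100_000, seed=5)
        )
        assert res.p_value == pytest.approx(exact, abs=0.01)

    def test_constant_statistic_gives_zero_p_and_warns(self, tiny_trial):
        with pytest.warns(UserWarning, match="constant randomization"):
            res = frt_pvalue(lambda d: 1.0, tiny_trial, FrtSettings(B=50, seed=0))
        assert res.p_value == 0.0
        assert res.settings["degenerate"]

    def test_deterministic_under_seed(self, normal_trial):
        s = FrtSettings(B=200, seed=77)
        p1 = frt_pvalue(stat_variance_ratio, normal_trial, s).p_value
        p2 = frt_pvalue(stat_variance_ratio, normal_trial, s).p_value
        assert p1 == p2

    def test_exhaustive_cap_enforced(self):
        rng = np.random.default_rng(0)
        data = _two_arm(rng.standard_normal(15), rng.standard_normal(15))
        with pytest.raises(ValueError, match="cap"):
            frt_pvalue(stat_variance_diff, data, FrtSettings(exhaustive=True))

    def test_shift_invariance_of_variance_frts(self, normal_trial):
        s = FrtSettings(B=300, seed=9)
        shifted = normal_trial.with_outcome(normal_trial.outcome + 17.5)
        for kind in ("ratio", "diff"):
            a = frt_variance_test(normal_trial, kind=kind, settings=s).p_value
            b = frt_variance_test(shifted, kind=kind, settings=s).p_value
            assert a == b


class TestFrtVarianceTest:
    def test_rank_variant_invariant_to_monotone_transform(self, normal_trial):
        s = FrtSettings(B=300, seed=4)
        warped = normal_trial.with_outcome(np.exp(normal_trial.outcome))
        a = frt_variance_test(normal_trial, use_ranks=True, settings=s)
        b = frt_variance_test(warped, use_ranks=True, settings=s)
        assert a.p_value == b.p_value

    def test_degenerate_outcome_flagged(self):
        data = TrialData(
            outcome=np.full(8, 3.0), treatment=np.tile([0, 1], 4)
        )
        with pytest.warns(UserWarning, match="constant randomization"):
            res = frt_variance_test(data, kind="diff", settings=FrtSettings(B=20, seed=0))
        assert res.settings["degenerate"]
        assert res.p_value == 0.0

    def test_symmetrized_flag_recorded_and_changes_statistic(self, normal_trial):
        s = FrtSettings(B=100, seed=1)
        sym = frt_variance_test(normal_trial, kind="ratio", settings=s)
        one = frt_variance_test(normal_trial, kind="ratio", settings=s, symmetrize=False)
        tv = stat_variance_ratio(normal_trial)
        assert one.statistic == pytest.approx(tv)
        assert sym.statistic == pytest.approx(max(tv, 1 / tv))

    def test_covariate_residualization_applied(self, covariate_trial):
        s = FrtSettings(B=100, seed=2)
        res = frt_variance_test(covariate_trial, use_covariates=True, settings=s)
        assert res.settings["use_covariates"]
        assert 0.0 <= res.p_value <= 1.0


class TestScienceTable:
    def test_construction_and_consistency(self, normal_trial):
        table = impute_science_table(normal_trial, tau0=1.7)
        np.testing.assert_allclose(table.y1 - table.y0, 1.7)
        observed = np.where(
            normal_trial.treatment == 1, table.y1, table.y0
        )
        np.testing.assert_allclose(observed, normal_trial.outcome)

    def test_zero_effect_collapses(self, normal_trial):
        table = impute_science_table(normal_trial, 0.0)
        np.testing.assert_array_equal(table.y0, table.y1)


class TestShiftedKs:
    def test_perfect_shift_alignment_gives_zero(self):
        y0 = np.array([1.0, 2, 3, 4])
        data = _two_arm(y0, y0 + 2.5)
        assert shifted_ks(data, 2.5) == 0.0

    def test_disjoint_supports_give_one(self):
        data = _two_arm([1.0, 2, 3], [10.0, 11, 12])
        assert shifted_ks(data, 0.0) == 1.0

    @pytest.mark.parametrize("shift", [-0.7, 0.0, 1.3])
    def test_matches_dense_grid_oracle(self, normal_trial, shift):
        y0 = np.sort(normal_trial.arm(0))
        y1 = np.sort(normal_trial.arm(1))
        grid = np.linspace(-6, 6, 100_000)
        f0 = np.searchsorted(y0, grid, side="right") / y0.size
        f1 = np.searchsorted(y1, grid + shift, side="right") / y1.size
        assert shifted_ks(normal_trial, shift) == pytest.approx(
            np.max(np.abs(f0 - f1)), abs=1e-4
        )

    def test_matches_scipy_two_sample_ks(self, normal_trial):
        shift = 0.4
        expected = stats.ks_2samp(
            normal_trial.arm(0), normal_trial.arm(1) - shift
        ).statistic
        assert shifted_ks(normal_trial, shift) == pytest.approx(expected, abs=1e-12)


class TestFrtPi:
    def test_exhaustive_tiny_case_matches_enumeration(self):
        data = _two_arm([0.1, 1.4], [2.0, 0.3])

        def pi_statistic(trial):
            # the full plug-in statistic: SKS at the trial's own ATE
            return shifted_ks(trial, summarize(trial).ate_hat)

        # oracle: enumerate assignments of the science table by hand
        tau_hat = summarize(data).ate_hat
        table = impute_science_table(data, tau_hat)
        t_obs = pi_statistic(data)
        vals = []
        for idx in itertools.combinations(range(4), 2):
            z = np.zeros(4, int)
            z[list(idx)] = 1
            y_star = np.where(z == 1, table.y1, table.y0)
            vals.append(pi_statistic(TrialData(outcome=y_star, treatment=z)))
        expected = np.mean(np.array(vals) >= t_obs)

        res = frt_pi(data, FrtSettings(exhaustive=True, tie_inclusive=True))
        assert res.p_value == pytest.approx(expected, abs=1e-12)

    def test_reproducible_and_bounded(self, normal_trial):
        s = FrtSettings(B=200, seed=8, tie_inclusive=True)
        a = frt_pi(normal_trial, s)
        b = frt_pi(normal_trial, s)
        assert a.p_value == b.p_value
        assert 0.0 <= a.p_value <= 1.0

    def test_overall_shift_invariance(self, normal_trial):
        s = FrtSettings(B=200, seed=8, tie_inclusive=True)
        shifted = normal_trial.with_outcome(normal_trial.outcome + 4.2)
        assert frt_pi(normal_trial, s).p_value == frt_pi(shifted, s).p_value


class TestFrtCi:
    def test_grid_of_one_reduces_to_plug_in(self, normal_trial):
        s = FrtSettings(B=150, seed=12, tie_inclusive=True)
        ci = frt_ci(normal_trial, s, grid_size=1)
        pi = frt_pi(normal_trial, s)
        assert ci.p_value == pytest.approx(pi.p_value)

    def test_max_dominates_central_grid_point(self, normal_trial):
        s = FrtSettings(B=150, seed=12, tie_inclusive=True)
        full = frt_ci(normal_trial, s, grid_size=31)
        single = frt_ci(normal_trial, s, grid_size=1)
        assert full.p_value >= single.p_value - 1e-12

    def test_early_stop_preserves_decision(self, normal_trial):
        s = FrtSettings(B=150, seed=12, tie_inclusive=True)
        full = frt_ci(normal_trial, s, grid_size=31)
        stopped = frt_ci(normal_trial, s, grid_size=31, early_stop=True)
        assert stopped.reject == full.reject
        assert stopped.p_value <= full.p_value + 1e-12
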