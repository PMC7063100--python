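"""Fixed points, exact mean curves, convergence detection, model comparison."""

import numpy as np
import pytest

from gazerl import (
    ModelSpec,
    Variant,
    asymptotic_choice_prob,
    compare_models,
    convergence_report,
    convergence_trial,
    expected_state,
    fixed_point,
    mc_fixed_point_oracle,
    mean_trajectory,
    motivation_sweep,
    run_replicates,
    softmax_policy,
)
from gazerl.model_core import UpdateMode


class TestFixedPoint:
    def test_baseline_values_are_the_expected_rewards(self):
        fp = fixed_point(ModelSpec())
        assert fp.naive_follow == 1.0 and fp.naive_random == 0.5
        assert fp.weighted_follow == 1.0 and fp.weighted_random == 0.5

    def test_negative_motivation_lowers_the_naive_value_to_0_8(self):
        # E[C] = 1, M = -0.2: the expected reward target of gaze following
        # drops from 1.0 to exactly 0.8
        fp = fixed_point(ModelSpec(variant=Variant.ENHANCEMENT, motivation=-0.2))
        assert fp.naive_follow == pytest.approx(0.8, abs=1e-12)
        assert fp.naive_random == pytest.approx(0.4, abs=1e-12)

    def test_naive_equals_weighted_without_cue_state_coupling(self):
        for variant in (Variant.BASELINE, Variant.CUE, Variant.INDEPENDENT_STATE):
            fp = fixed_point(ModelSpec(variant=variant))
            assert fp.weighted_follow == pytest.approx(fp.naive_follow, abs=1e-12)

    def test_enhancement_weighted_value_exceeds_naive(self):
        # the decision tree correlates S with C: large cues get more weight
        fp = fixed_point(ModelSpec(variant=Variant.ENHANCEMENT))
        assert fp.weighted_follow > fp.naive_follow
        assert fp.weighted_follow == pytest.approx(1.0356, abs=0.001)
        assert fp.expected_state == pytest.approx(0.5602, abs=0.001)

    def test_independent_state_halves_the_effective_rate(self):
        assert expected_state(ModelSpec(variant=Variant.INDEPENDENT_STATE)) == (
            pytest.approx(0.5, abs=1e-9)
        )


class TestMonteCarloOracle:
    def test_degenerate_state_recovers_the_mean_cue(self):
        est, se = mc_fixed_point_oracle(ModelSpec(variant=Variant.CUE), 200_000, 3)
        assert abs(est - 1.0) < 3 * se

    def test_independent_state_cancels_in_the_ratio(self):
        est, se = mc_fixed_point_oracle(
            ModelSpec(variant=Variant.INDEPENDENT_STATE), 200_000, 3
        )
        assert abs(est - 1.0) < 3 * se

    def test_rejects_tiny_sample_sizes(self):
        with pytest.raises(ValueError):
            mc_fixed_point_oracle(ModelSpec(), 100, 0)


class TestMeanTrajectory:
    def test_zero_trials_is_zero(self):
        assert mean_trajectory(ModelSpec(variant=Variant.ENHANCEMENT), 0) == 0.0

    def test_baseline_closed_form(self):
        assert mean_trajectory(ModelSpec(), 100) == pytest.approx(
            1 - 0.995**100, abs=1e-12
        )

    def test_long_horizon_reaches_the_weighted_fixed_point(self):
        spec = ModelSpec(variant=Variant.ENHANCEMENT)
        fp = fixed_point(spec)
        assert mean_trajectory(spec, 10_000_000) == pytest.approx(
            fp.weighted_follow, abs=1e-9
        )

    def test_selected_only_mode_is_rejected(self):
        spec = ModelSpec(update_mode=UpdateMode.SELECTED_ONLY)
        with pytest.raises(ValueError):
            mean_trajectory(spec, 100)


def _scan_convergence(q, delta, tail_window):
    """Brute-force oracle: check every candidate start index directly."""
    tail_mean = q[-tail_window:].mean()
    for t in range(1, len(q) + 1):
        if np.all(np.abs(q[t - 1 :] - tail_mean) <= delta):
            return t
    return None


class TestConvergenceTrial:
    def test_constant_trajectory_converges_immediately(self):
        assert convergence_trial(np.full(300, 0.7), tail_window=100) == 1

    def test_all_zero_trajectory_converges_immediately(self):
        assert convergence_trial(np.zeros(300), tail_window=100) == 1

    def test_noiseless_exponential_matches_scan_oracle(self):
        q = 1 - 0.995 ** np.arange(1, 2001)
        got = convergence_trial(q, delta=0.02, tail_window=100)
        assert got == _scan_convergence(q, 0.02, 100)
        assert got == 780  # frozen from the scan oracle

    def test_ramp_never_entering_the_band_is_flagged(self):
        q = np.linspace(0.0, 1.0, 200)
        assert convergence_trial(q, delta=0.02, tail_window=100) is None

    def test_matches_scan_oracle_on_noisy_trajectories(self, rng):
        for _ in range(20):
            q = np.cumsum(rng.normal(0.005, 0.02, 400)).clip(min=0)
            got = convergence_trial(q, delta=0.05, tail_window=50)
            assert got == _scan_convergence(q, 0.05, 50)

    def test_rejects_bad_windows(self):
        with pytest.raises(ValueError):
            convergence_trial(np.zeros(50), tail_window=50)
        with pytest.raises(ValueError):
            convergence_trial(np.zeros(50), delta=0.0, tail_window=10)


class TestAsymptoticChoice:
    def test_baseline_reproduces_the_three_quarters_policy(self):
        assert asymptotic_choice_prob(ModelSpec()) == pytest.approx(0.7478, abs=1e-3)

    def test_naive_motivation_fixed_points_give_70_percent(self):
        # at the naive fixed points 0.8 vs 0.4 the policy follows ~70%
        _, p = softmax_policy(0.4, 0.8, 0.46)
        assert p == pytest.approx(0.705, abs=0.005)

    def test_high_temperature_is_indifferent(self):
        assert asymptotic_choice_prob(ModelSpec(tau=1e9)) == pytest.approx(
            0.5, abs=1e-6
        )


class TestCompareAndSweep:
    def test_single_spec_rejected(self):
        with pytest.raises(ValueError):
            compare_models([ModelSpec()], [0, 1])

    def test_identical_specs_show_no_ordering(self):
        # identical specs on shared seeds produce tied medians under the
        # paired bootstrap, so neither direction comes out significant
        specs = [ModelSpec(variant=Variant.CUE, n_trials=600)] * 2
        out = compare_models(specs, list(range(40)), delta=0.05, tail_window=50)
        p = out["pairwise_p_faster"][("cue", "cue")]
        assert p < 0.95

    def test_motivation_sweep_is_monotone_and_reduces_at_zero(self):
        base = ModelSpec(variant=Variant.ENHANCEMENT, n_trials=800)
        seeds = list(range(30))
        rows = motivation_sweep(base, [-0.2, -0.1, 0.0, 0.1], seeds)
        terminal = [r["mean_terminal_q_follow"] for r in rows]
        assert terminal == sorted(terminal)
        p_follow = [r["asymptotic_p_follow"] for r in rows]
        assert p_follow == sorted(p_follow)
        ens0 = run_replicates(base, seeds)
        m0 = next(r for r in rows if r["motivation"] == 0.0)
        assert m0["mean_terminal_q_follow"] == pytest.approx(
            ens0.terminal_mean_q_follow()
        )

    def test_motivation_sweep_rejects_invalid_m(self):
        base = ModelSpec(variant=Variant.ENHANCEMENT, n_trials=100)
        with pytest.raises(ValueError):
            motivation_sweep(base, [-0.6], [0])
        with pytest.raises(ValueError):
            motivation_sweep(ModelSpec(variant=Variant.CUE, n_trials=100), [0.1], [0])


def test_ensemble_mean_tracks_the_exact_recursion_at_short_horizon():
    # 30-seed cue ensemble at t = 100 vs the closed form 1 - 0.995^100
    spec = ModelSpec(variant=Variant.CUE, n_trials=100)
    ens = run_replicates(spec, list(range(30)))
    expected = mean_trajectory(spec, 100)
    se = ens.sd_q_follow[-1] / np.sqrt(ens.n_seeds)
    assert abs(ens.mean_q_follow[-1] - expected) < 3 * se
    assert expected == pytest.approx(0.3942, abs=1e-4)


def test_convergence_report_censors_unconverged_seeds():
    spec = ModelSpec(variant=Variant.INDEPENDENT_STATE, n_trials=300)
    ens = run_replicates(spec, list(range(10)))
    # 300 trials is far too short for this variant: nothing converges tightly
    rep = convergence_report(ens, delta=0.01, tail_window=50)
    assert rep.frac_not_converged >= 0.0
    assert all(t is None or 1 <= t <= 300 for t in rep.trials)
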