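"""Unit and property tests of the hybrid two-stage race solver."""

import numpy as np
import pandas as pd
import pytest

import dualrace as dr
from dualrace.hybrid import _solve_race


def euler_race_time(r_i, r_e, congruent, gap, theta, accel,
                    response_threshold=1000.0, dt=0.01, horizon=6000.0):
    """Independent fine-grid Euler integration of the race (oracle).

    Vectorized over trials; trajectories are stepped forward explicitly
    (no event-time algebra shared with the closed-form solver).
    """
    r_i = np.atleast_1d(np.asarray(r_i, dtype=float))
    r_e = np.atleast_1d(np.asarray(r_e, dtype=float))
    congruent = np.atleast_1d(np.asarray(congruent, dtype=bool))
    gap = np.atleast_1d(np.asarray(gap, dtype=float))
    theta = np.broadcast_to(np.atleast_1d(np.asarray(theta, float)), r_i.shape)
    accel = np.broadcast_to(np.atleast_1d(np.asarray(accel, float)), r_i.shape)
    n = len(r_i)
    xi = np.zeros(n)
    xe = np.zeros(n)
    t_trans = np.full(n, np.inf)
    r_final = r_i + np.where(congruent, r_e, -r_e)
    t_cross = np.full(n, np.inf)
    active = np.ones(n, dtype=bool)
    n_steps = int(round(horizon / dt))
    for step in range(n_steps):
        t = step * dt
        started = (t_trans == np.inf) & (xi >= theta) & (xe >= theta)
        if started.any():
            # both variables are exactly linear before the transition,
            # so the grid-resolution overshoot can be interpolated away
            t_xi = t - (xi[started] - theta[started]) / r_i[started]
            t_xe = t - (xe[started] - theta[started]) / r_e[started]
            t_trans[started] = np.maximum(t_xi, t_xe)
        # midpoint slope: integrates the piecewise-linear ramp without
        # the first-order quadrature bias of start-of-step slopes
        frac = np.clip((t + 0.5 * dt - t_trans) / accel, 0.0, 1.0)
        slope_i = r_i + np.where(np.isfinite(t_trans),
                                 frac * (r_final - r_i), 0.0)
        xi_prev, xe_prev = xi.copy(), xe.copy()
        xi += np.where(active, slope_i * dt, 0.0)
        xe += np.where(active & (t >= gap), r_e * dt, 0.0)
        done = active & ((xi >= response_threshold) | (xe >= response_threshold))
        if done.any():
            # linear interpolation inside the step removes the O(dt)
            # detection bias without touching the integration itself
            with np.errstate(invalid="ignore", divide="ignore"):
                fi = (response_threshold - xi_prev) / (xi - xi_prev)
                fe = (response_threshold - xe_prev) / (xe - xe_prev)
            fi = np.where(xi >= response_threshold, fi, np.inf)
            fe = np.where(xe >= response_threshold, fe, np.inf)
            t_cross[done] = t + dt * np.minimum(fi, fe)[done]
        active &= ~done
        if not active.any():
            break
    return t_cross


class TestClosedFormSolver:
    def test_worked_congruent_example(self):
        """Hand-derived piecewise solution: theta=500, gap=50, r_I=2,
        r_E=3, A=100 -> internal wins at t=380, rt=480, rpt=430."""
        p = dr.HybridParams(theta=500, mu_int=0, sigma_int=1, mu_ext=0,
                            sigma_ext=1, exec_delay=100, accel=100)
        out = dr.solve_hybrid_race(
            dr.RaceInputs(r_int=2, r_ext=3, internal_side="L"),
            dr.TrialDesign(gap_ms=50, target_side="L"),
            p,
        )
        assert out.winner == "internal"
        assert out.rt_ms == pytest.approx(480.0, abs=1e-9)
        assert out.rpt_ms == pytest.approx(430.0, abs=1e-9)
        assert out.correct and out.congruency == "congruent"

    def test_internal_only_when_gap_exceeds_internal_race(self):
        """With r_I=3 and gap=400 the internal variable finishes
        (1000/3 ms) before the target even appears."""
        p = dr.HybridParams(theta=500, mu_int=0, sigma_int=1, mu_ext=0,
                            sigma_ext=1, exec_delay=20, accel=100)
        out = dr.solve_hybrid_race(
            dr.RaceInputs(r_int=3, r_ext=3, internal_side="R"),
            dr.TrialDesign(gap_ms=400, target_side="L"),
            p,
        )
        assert out.winner == "internal"
        assert out.congruency == "internal_only"
        assert out.rt_ms == pytest.approx(1000.0 / 3.0 + 20.0)
        assert out.rpt_ms < 0

    def test_matches_euler_oracle_on_random_draws(self):
        """Closed-form event times agree with fine-grid Euler
        integration within 0.05 ms over 1000 random parameter draws."""
        rng = np.random.default_rng(2024)
        n = 1000
        r_i = np.exp(rng.uniform(0.2, 2.1, n))
        r_e = np.exp(rng.uniform(0.2, 2.1, n))
        gap = rng.uniform(0, 330, n)
        theta = rng.uniform(100, 900, n)
        accel = rng.uniform(5, 120, n)
        congruent = rng.uniform(size=n) < 0.5
        t_closed = np.empty(n)
        for k in range(n):
            ti, te, _ = _solve_race(
                r_i[k: k + 1], r_e[k: k + 1], congruent[k: k + 1],
                gap[k: k + 1], theta[k], accel[k],
            )
            t_closed[k] = min(ti[0], te[0])
        t_euler = euler_race_time(r_i, r_e, congruent, gap, theta, accel,
                                  dt=0.005, horizon=1500.0)
        assert np.isfinite(t_euler).all()
        np.testing.assert_allclose(t_closed, t_euler, atol=0.05, rtol=0)

    def test_exponential_ramp_close_to_linear_for_small_accel(self):
        p = dr.HybridParams(theta=500, mu_int=0, sigma_int=1, mu_ext=0,
                            sigma_ext=1, exec_delay=0, accel=1e-3)
        inputs = dr.RaceInputs(r_int=2, r_ext=3, internal_side="L")
        design = dr.TrialDesign(gap_ms=50, target_side="L")
        lin = dr.solve_hybrid_race(inputs, design, p, ramp="linear")
        expo = dr.solve_hybrid_race(inputs, design, p, ramp="exponential")
        assert lin.rt_ms == pytest.approx(expo.rt_ms, abs=0.1)

    def test_divergence_guard_raises(self):
        # incongruent with dominant external: internal stalls, external slow
        p = dr.HybridParams(theta=10, mu_int=0, sigma_int=1, mu_ext=0,
                            sigma_ext=1, exec_delay=0, accel=10)
        inputs = dr.RaceInputs(r_int=0.05, r_ext=0.1, internal_side="R")
        design = dr.TrialDesign(gap_ms=0, target_side="L")
        with pytest.raises(dr.DivergedTrialError):
            dr.solve_hybrid_race(inputs, design, p, horizon_ms=5000)


class TestSampling:
    def test_internal_side_unbiased_and_biased(self, basic_params, rng):
        n = 100_000
        design = dr.TrialDesign(gap_ms=100, target_side="L")
        sides = [
            dr.sample_trial_inputs(basic_params, design, rng).internal_side
            for _ in range(3000)
        ]
        frac_l = np.mean([s == "L" for s in sides])
        assert frac_l == pytest.approx(0.5, abs=3 * 0.5 / np.sqrt(3000))

        biased = basic_params.with_alpha(0.65)
        design_b = dr.TrialDesign(gap_ms=100, target_side="L",
                                  more_frequent_side="R")
        sides = np.array([
            dr.sample_trial_inputs(biased, design_b, rng).internal_side
            for _ in range(n // 10)
        ])
        frac_r = np.mean(sides == "R")
        assert frac_r == pytest.approx(0.65, abs=3 * 0.5 / np.sqrt(n // 10))

    def test_lognormal_rate_moments(self, rng):
        p = dr.HybridParams(theta=500, mu_int=1.4, sigma_int=1.2, mu_ext=1.0,
                            sigma_ext=0.3, exec_delay=100, accel=40)
        design = dr.TrialDesign(gap_ms=0, target_side="L")
        log_r = np.log([
            dr.sample_trial_inputs(p, design, rng).r_int for _ in range(20000)
        ])
        assert log_r.mean() == pytest.approx(1.4, abs=3 * 1.2 / np.sqrt(20000))
        assert log_r.std(ddof=1) == pytest.approx(1.2, rel=0.05)


class TestSimulatedBatches:
    def test_seeded_determinism(self, basic_params, designs_factory):
        designs = designs_factory(np.random.default_rng(5), 500)
        a = dr.simulate_trials(basic_params, designs, np.random.default_rng(9))
        b = dr.simulate_trials(basic_params, designs, np.random.default_rng(9))
        pd.testing.assert_frame_equal(a, b)

    def test_outcome_invariants(self, basic_params, designs_factory, rng):
        designs = designs_factory(rng, 20_000)
        df = dr.simulate_trials(basic_params, designs, rng)
        np.testing.assert_allclose(df["rpt_ms"], df["rt_ms"] - df["gap_ms"])
        congruent = df["congruency"] == "congruent"
        assert (df.loc[congruent, "correct"]).all()
        assert (df.loc[~df["correct"], "congruency"] != "congruent").all()

    def test_internal_only_guessing_at_long_gap_with_slow_external(self, rng):
        p = dr.HybridParams(theta=500, mu_int=1.8, sigma_int=0.3, mu_ext=-2.0,
                            sigma_ext=0.3, exec_delay=100, accel=40)
        designs = pd.DataFrame({
            "gap_ms": np.full(10_000, 330.0),
            "target_side": np.where(rng.uniform(size=10_000) < 0.5, "L", "R"),
        })
        df = dr.simulate_trials(p, designs, rng, on_diverged="censor")
        acc = df["correct"].mean()
        assert acc == pytest.approx(0.5, abs=3 * 0.5 / np.sqrt(10_000))

    def test_accuracy_decreases_with_gap(self, rng):
        """Longer gaps leave less room for the stimulus to correct the
        internal guess (matches the decreasing accuracy-vs-gap curve)."""
        p = dr.params_from_row(dr.experiment1_params().iloc[0])
        accs = []
        for gap in (0.0, 150.0, 330.0):
            designs = pd.DataFrame({
                "gap_ms": np.full(20_000, gap),
                "target_side": np.where(rng.uniform(size=20_000) < 0.5, "L", "R"),
            })
            df = dr.simulate_trials(p, designs, rng, on_diverged="censor")
            accs.append(df["correct"].mean())
        assert accs[0] > accs[1] > accs[2]

    def test_long_gap_rt_independent_of_external_params(self, rng):
        """As the gap outlasts any plausible internal race, the RT
        distribution no longer depends on the external rate parameters."""
        from scipy.stats import ks_2samp
        gap = 2000.0
        designs = pd.DataFrame({
            "gap_ms": np.full(10_000, gap),
            "target_side": np.where(rng.uniform(size=10_000) < 0.5, "L", "R"),
        })
        base = dict(theta=500, mu_int=1.8, sigma_int=0.3, exec_delay=100,
                    accel=40)
        rng_a, rng_b = np.random.default_rng(3), np.random.default_rng(3)
        a = dr.simulate_trials(
            dr.HybridParams(mu_ext=1.0, sigma_ext=0.3, **base), designs, rng_a
        )
        b = dr.simulate_trials(
            dr.HybridParams(mu_ext=2.0, sigma_ext=0.6, **base), designs, rng_b
        )
        assert ks_2samp(a["rt_ms"], b["rt_ms"]).pvalue > 0.05

    def test_experiment_table_shape_and_bias(self, rng, designs_factory):
        params = [
            dr.params_from_row(r).with_alpha(0.65)
            for _, r in dr.experiment1_params().head(3).iterrows()
        ]
        designs = [designs_factory(rng, 100, bias=0.65) for _ in params]
        table = dr.simulate_experiment(params, designs, rng)
        assert len(table) == 300
        assert set(table["subject"]) == {1, 2, 3}
        np.testing.assert_allclose(
            table["rpt_ms"], table["rt_ms"] - table["gap_ms"]
        )

    def test_internal_choice_bias_realized(self, rng, designs_factory):
        p = dr.params_from_row(
            dr.experiment1_params().iloc[0]
        ).with_alpha(0.65)
        designs = designs_factory(rng, 50_000, bias=0.65)
        df = dr.simulate_trials(p, designs, rng, on_diverged="censor")
        frac = (df["internal_side"] == df["more_frequent_side"]).mean()
        assert frac == pytest.approx(0.65, abs=3 * 0.5 / np.sqrt(50_000))
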