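"""Two-fork bacterial model: modulation, first-passage law, abundance, forks."""

import math

import numpy as np
import pytest
from scipy import integrate

import repliprog as rp
from repliprog.bacteria import replication_ages


def _params(coli_growth=None, **kw):
    growth = coli_growth or rp.GrowthRate(2.0 / 3600.0)
    defaults = dict(L=5e6, v0=1e3, D=0.0, growth=growth)
    defaults.update(kw)
    return rp.BacterialParams(**defaults)


class TestModulation:
    def test_absent_modulation_is_identity(self):
        assert rp.modulation_integral(None, 123.0) == 123.0
        mod = rp.SpeedModulation(0.0, 1e-3, 0.4)
        assert rp.modulation_integral(mod, 77.0) == 77.0

    def test_full_period_integrates_to_tau(self):
        mod = rp.SpeedModulation(0.5, 2 * math.pi / 1800.0, 1.1)
        assert rp.modulation_integral(mod, 1800.0) == pytest.approx(1800.0, abs=1e-9)

    def test_matches_numeric_quadrature(self):
        mod = rp.SpeedModulation(0.3, 2 * math.pi / 2700.0, 2.0)
        for tau in (137.0, 1000.0, 4321.0):
            val, _ = integrate.quad(lambda u: mod.h(u), 0.0, tau, limit=200)
            assert rp.modulation_integral(mod, tau) == pytest.approx(val, abs=1e-10)

    def test_strictly_increasing(self):
        mod = rp.SpeedModulation(0.9, 1e-2, 0.0)
        taus = np.linspace(0, 5000, 2000)
        assert np.all(np.diff(rp.modulation_integral(mod, taus)) > 0)

    def test_delta_bounds_enforced(self):
        with pytest.raises(ValueError):
            rp.SpeedModulation(1.0, 1e-3, 0.0)
        with pytest.raises(ValueError):
            rp.SpeedModulation(-0.1, 1e-3, 0.0)


class TestForkProgram:
    def test_deterministic_fork_is_step(self):
        p = _params(D=0.0)
        x = 1e6
        assert rp.fork_program(p, x, x / p.v0 * 0.99, 1) == 0.0
        assert rp.fork_program(p, x, x / p.v0 * 1.01, 1) == 1.0

    def test_degenerate_start_positions(self):
        p = _params(D=1e7)
        assert rp.fork_program(p, 0.0, 0.0, 1) == 1.0
        assert rp.fork_program(p, p.L, 0.0, 2) == 1.0

    def test_first_passage_moments(self):
        # numeric moments of the first-passage density d f1 / d tau
        p = _params(D=1e8)
        x = 1e6
        tau = np.linspace(0, 8000, 80001)
        pdf = np.gradient(rp.fork_program(p, x, tau, 1), tau)
        m1 = np.trapezoid(tau * pdf, tau)
        var = np.trapezoid((tau - m1) ** 2 * pdf, tau)
        assert m1 == pytest.approx(x / p.v0, rel=1e-3)
        assert var == pytest.approx(2 * p.D * x / p.v0**3, rel=1e-2)

    def test_monte_carlo_first_passages_match_cdf(self):
        p = _params(D=1.25e7)
        level = 1e6
        fp = rp.first_passage_times(p, level, n_paths=2000, dt=0.1, seed=5)
        fp = np.sort(fp[np.isfinite(fp)])
        cdf = rp.fork_program(p, level, fp, 1)
        emp = np.arange(1, len(fp) + 1) / len(fp)
        assert np.max(np.abs(cdf - emp)) < 1.358 / math.sqrt(len(fp))

    def test_out_of_range_position_rejected(self):
        with pytest.raises(ValueError):
            rp.fork_program(_params(), -1.0, 10.0, 1)

    def test_joint_program_saturates(self):
        p = _params(D=1e8)
        x = 2.5e6
        f1 = rp.fork_program(p, x, 1e6, 1)
        f2 = rp.fork_program(p, x, 1e6, 2)
        assert 1.0 - (1.0 - f1) * (1.0 - f2) == pytest.approx(1.0, abs=1e-9)


class TestAbundance:
    def test_origin_always_present(self):
        for d in (0.0, 1e7):
            assert rp.abundance(_params(D=d), [0.0])[0] == pytest.approx(1.0, abs=1e-9)

    def test_deterministic_closed_form(self):
        # L = 5e6 bp, Lambda = 2/h, v0 = 1e3 bp/s, no stalling
        p = _params(D=0.0)
        lam = p.growth.lam
        xs = np.array([1e6, 2.5e6, 4e6])
        expected = np.exp(-lam * np.minimum(xs, p.L - xs) / p.v0)
        np.testing.assert_allclose(rp.abundance(p, xs), expected, rtol=1e-12)
        assert rp.abundance(p, [p.L / 2])[0] == pytest.approx(
            math.exp(-lam * p.L / (2 * p.v0)), rel=1e-12
        )

    def test_symmetric_and_decreasing_without_modulation(self):
        p = _params(D=2e7)
        xs = np.linspace(0, p.L, 41)
        vals = rp.abundance(p, xs)
        np.testing.assert_allclose(vals, vals[::-1], rtol=1e-6)
        half = vals[: len(vals) // 2 + 1]
        assert np.all(np.diff(half) <= 1e-9)

    def test_small_diffusivity_approaches_deterministic_limit(self):
        lam = rp.GrowthRate(2.0 / 3600.0).lam
        x = 1.5e6  # away from the meeting region
        p_small = _params(D=1e4)
        det = math.exp(-lam * x / 1e3)
        assert rp.abundance(p_small, [x])[0] == pytest.approx(det, rel=1e-3)

    def test_modulated_deterministic_inverts_clock(self):
        mod = rp.SpeedModulation(0.5, 2 * math.pi / 1800.0, 0.3)
        p = _params(D=0.0, modulation=mod)
        x = 1e6
        val = rp.abundance(p, [x])[0]
        tau_rep = -math.log(val) / p.growth.lam
        assert rp.modulation_integral(mod, tau_rep) == pytest.approx(x / p.v0, rel=1e-9)


class TestSimulateForks:
    def test_deterministic_forks_meet_in_the_middle(self):
        mod = rp.SpeedModulation(0.4, 2 * math.pi / 1800.0, 0.7)
        p = _params(D=0.0, modulation=mod)
        tr = rp.simulate_forks(p, n_paths=3, dt=0.05, seed=0)
        np.testing.assert_allclose(tr.meeting_point, p.L / 2, rtol=1e-3)
        # completion age solves H(tau) = L / (2 v0)
        target = p.L / (2 * p.v0)
        for age in tr.completion_age:
            assert rp.modulation_integral(mod, age) == pytest.approx(target, rel=1e-3)

    def test_meeting_point_symmetric(self):
        p = _params(D=1.25e7)
        tr = rp.simulate_forks(p, n_paths=4000, dt=0.25, seed=3)
        se = tr.meeting_point.std(ddof=1) / math.sqrt(len(tr.meeting_point))
        assert abs(tr.meeting_point.mean() - p.L / 2) < 3 * se

    def test_seed_reproducibility(self):
        p = _params(D=1e7)
        t1 = rp.simulate_forks(p, n_paths=100, dt=0.5, seed=11)
        t2 = rp.simulate_forks(p, n_paths=100, dt=0.5, seed=11)
        np.testing.assert_array_equal(t1.meeting_point, t2.meeting_point)
        np.testing.assert_array_equal(t1.completion_age, t2.completion_age)

    def test_recorded_paths_have_running_extrema(self):
        p = _params(D=1e8)
        tr = rp.simulate_forks(p, n_paths=2, dt=0.5, seed=1, record_paths=2)
        assert np.all(np.diff(tr.x1, axis=1) >= 0)
        assert np.all(np.diff(tr.x2, axis=1) <= 0)
        # running extrema include the forks' starting positions 0 and L
        np.testing.assert_allclose(
            tr.x1, np.maximum(np.maximum.accumulate(tr.y1, axis=1), 0.0)
        )
        np.testing.assert_allclose(
            tr.x2, np.minimum(np.minimum.accumulate(tr.y2, axis=1), p.L)
        )


class TestMeetingPointSpread:
    def test_zero_without_diffusion(self):
        assert rp.meeting_point_spread(_params(D=0.0)) == 0.0

    def test_peclet_algebra(self):
        # Pe = 8 gives Delta Z = L / 8
        p = _params(D=0.0)
        d = p.L * p.v0 / (4.0 * 8.0)
        p8 = _params(D=d)
        assert p8.peclet == pytest.approx(8.0)
        assert rp.meeting_point_spread(p8) == pytest.approx(p8.L / 8.0)

    def test_matches_simulation_across_parameters(self):
        for v0, d_over in ((1e3, 1.25e7), (6e2, 5e6)):
            p = _params(v0=v0, D=d_over)
            tr = rp.simulate_forks(p, n_paths=4000, dt=0.25, seed=7)
            sd = tr.meeting_point.std(ddof=1)
            theory = rp.meeting_point_spread(p)
            # SE of the sd is about sd / sqrt(2 n)
            se = sd / math.sqrt(2 * len(tr.meeting_point))
            assert abs(sd - theory) < 3 * se + 0.02 * theory

    def test_replication_ages_match_joint_program(self):
        # small-n smoke check of the simulation used by the acceptance suite
        p = _params(D=1.25e7)
        xs = np.array([1e6, 2.5e6])
        ages = replication_ages(p, xs, n_paths=1500, dt=0.25, seed=2)
        w = np.exp(-p.growth.lam * ages)
        se = w.std(axis=0, ddof=1) / math.sqrt(w.shape[0])
        np.testing.assert_array_less(
            np.abs(rp.abundance(p, xs) - w.mean(axis=0)), 3 * se
        )
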