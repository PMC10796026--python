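"""Age-structured theory: age density, forward map, deterministic inversion."""

import math

import numpy as np
import pytest
from scipy import integrate

import repliprog as rp


class TestAgeDensity:
    def test_closed_form_values(self):
        assert rp.age_density(rp.GrowthRate(1.0), 0.0) == pytest.approx(1.0)
        assert rp.age_density(rp.GrowthRate(0.01), 100.0) == pytest.approx(
            0.01 * math.exp(-1.0)
        )

    def test_normalises_to_one(self):
        g = rp.GrowthRate(3.7e-4)
        val, _ = integrate.quad(lambda t: rp.age_density(g, t), 0, np.inf)
        assert val == pytest.approx(1.0, abs=1e-9)

    def test_negative_age_rejected(self):
        with pytest.raises(ValueError):
            rp.age_density(rp.GrowthRate(1.0), -0.1)

    def test_growth_rate_must_be_positive(self):
        for bad in (0.0, -1.0, math.inf):
            with pytest.raises(ValueError):
                rp.GrowthRate(bad)


class TestAbundanceFromProgram:
    def test_always_replicated_genome(self):
        g = rp.GrowthRate(0.01)
        out = rp.abundance_from_program(lambda x, t: 1.0, g, [0.0, 5.0])
        assert out == pytest.approx([1.0, 1.0], abs=1e-8)

    def test_step_program_reduces_to_deterministic(self):
        g, v, x0 = rp.GrowthRate(1e-4), 30.0, 1e4
        prog = lambda x, t: float(t >= abs(x - x0) / v)  # noqa: E731
        xs = [0.0, 5e3, 2e4]
        out = rp.abundance_from_program(prog, g, xs)
        expected = [math.exp(-g.lam * abs(x - x0) / v) for x in xs]
        assert out == pytest.approx(expected, rel=1e-6)

    def test_exponential_firing_closed_form(self):
        # Lambda * int e^{-Lambda t} (1 - e^{-I t}) dt = I / (I + Lambda)
        g, intensity = rp.GrowthRate(0.01), 0.025
        out = rp.abundance_from_program(lambda x, t: 1.0 - math.exp(-intensity * t), g, [0.0])
        assert out[0] == pytest.approx(intensity / (intensity + g.lam), abs=1e-9)

    def test_monotone_under_pointwise_program_ordering(self):
        g = rp.GrowthRate(0.02)
        f1 = lambda x, t: 1.0 - math.exp(-0.01 * t)  # noqa: E731
        f2 = lambda x, t: 1.0 - math.exp(-0.05 * t)  # noqa: E731
        p1 = rp.abundance_from_program(f1, g, [0.0])
        p2 = rp.abundance_from_program(f2, g, [0.0])
        assert p1[0] <= p2[0] <= 1.0

    def test_age_average_equals_monte_carlo_sampling(self):
        # P(x) = <e^{-Lambda tau}> over the replication-age density: sample
        # tau = d/v + Exp(I) directly and compare against the quadrature
        g, intensity, delay = rp.GrowthRate(0.01), 0.02, 35.0
        prog = lambda x, t: 1.0 - math.exp(-intensity * max(t - delay, 0.0))  # noqa: E731
        quad_val = rp.abundance_from_program(prog, g, [0.0])[0]
        rng = np.random.default_rng(4)
        tau = delay + rng.exponential(1.0 / intensity, size=200_000)
        w = np.exp(-g.lam * tau)
        se = w.std(ddof=1) / math.sqrt(len(w))
        assert abs(quad_val - w.mean()) < 3 * se
        analytic = math.exp(-g.lam * delay) * intensity / (intensity + g.lam)
        assert quad_val == pytest.approx(analytic, abs=1e-9)


class TestDeterministicAbundance:
    def test_origin_replicated_at_birth(self):
        g = rp.GrowthRate(1e-4)
        assert rp.deterministic_abundance(5e3, 0.0, 25.0, g, [5e3])[0] == 1.0

    def test_one_doubling_time_of_travel(self):
        g, v = rp.GrowthRate(1e-4), 25.0
        dist = v * math.log(2.0) / g.lam
        out = rp.deterministic_abundance(0.0, 0.0, v, g, [dist])
        assert out[0] == pytest.approx(0.5, rel=1e-9)

    def test_piecewise_speed_cross_check_with_forward_map(self):
        # the delta-density program evaluated through the generic age
        # integral must agree with the direct exponential of travel times
        g = rp.GrowthRate(2e-4)
        v = lambda x: 20.0 if x < 5e3 else 40.0  # noqa: E731

        def travel(x):
            val, _ = integrate.quad(lambda u: 1.0 / v(u), 0.0, x, points=[5e3], limit=100)
            return val

        xs = [2e3, 5e3, 9e3]
        direct = rp.deterministic_abundance(0.0, 0.0, v, g, xs)
        via_program = rp.abundance_from_program(
            lambda x, t: float(t >= travel(x)), g, xs
        )
        assert direct == pytest.approx(list(via_program), rel=1e-5)

    def test_zero_speed_on_path_raises(self):
        g = rp.GrowthRate(1e-4)
        with pytest.raises(ZeroDivisionError):
            rp.deterministic_abundance(0.0, 0.0, lambda x: 0.0, g, [1e3])


def _grid_profile(values, bin_bp=1000):
    n = len(values)
    start = np.arange(n) * bin_bp
    return rp.AbundanceProfile.from_arrays("chr", start, start + bin_bp, values)


class TestSpeedFromAbundance:
    def test_constant_speed_recovered_exactly(self):
        g, v0 = rp.GrowthRate(1e-4), 30.0
        x = np.arange(500) * 1000.0 + 500.0
        prof = _grid_profile(np.exp(-g.lam * x / v0))
        sp = rp.speed_from_abundance(prof, g)
        ok = ~sp.flagged
        assert np.allclose(sp.speed[ok], v0, rtol=1e-6)

    def test_linear_speed_round_trip_within_one_percent(self):
        g = rp.GrowthRate(9.6e-5)
        vfn = lambda x: 20.0 + 2e-5 * x  # noqa: E731
        edges = np.arange(0, 300_001, 1000.0)
        mid = 0.5 * (edges[:-1] + edges[1:])
        prof = _grid_profile(rp.deterministic_abundance(0.0, 0.0, vfn, g, mid))
        sp = rp.speed_from_abundance(prof, g)
        ok = ~sp.flagged
        rel = np.abs(sp.speed[ok] - vfn(sp.position[ok])) / vfn(sp.position[ok])
        assert rel.max() < 0.01

    def test_flat_profile_flagged_infinite(self):
        g = rp.GrowthRate(1e-4)
        prof = _grid_profile(np.ones(50))
        with pytest.warns(UserWarning, match="zero log-slope"):
            sp = rp.speed_from_abundance(prof, g)
        assert np.all(np.isinf(sp.speed))
        assert sp.flagged.all()

    def test_non_positive_values_rejected(self):
        g = rp.GrowthRate(1e-4)
        vals = np.ones(50)
        vals[10] = 0.0
        with pytest.raises(ValueError):
            rp.speed_from_abundance(_grid_profile(vals), g)


class TestAbundanceProfile:
    def test_unsorted_input_sorted_with_warning(self):
        df_start = np.array([2000, 0, 1000])
        with pytest.warns(UserWarning, match="unsorted"):
            prof = rp.AbundanceProfile.from_arrays(
                "chr", df_start, df_start + 1000, [3.0, 1.0, 2.0]
            )
        assert list(prof.df["value"]) == [1.0, 2.0, 3.0]

    def test_overlapping_bins_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            rp.AbundanceProfile.from_arrays("chr", [0, 500], [1000, 1500], [1.0, 1.0])

    def test_negative_values_rejected(self):
        with pytest.raises(ValueError):
            rp.AbundanceProfile.from_arrays("chr", [0], [1000], [-1.0])
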