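import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from regulonkit import expression_data as ed
from regulonkit import kinetic_models as km


def smaller_root_oracle(ya, yb, q):
    """Independent oracle: smaller root of y^2 - (ya+yb+q) y + ya*yb = 0."""
    roots = np.roots([1.0, -(ya + yb + q), ya * yb])
    return float(np.min(roots.real))


def flat_profile(value, t0=0.0, t1=10.0, name="flat"):
    t = np.linspace(t0, t1, 50)
    return ed.SmoothedProfile.from_samples(name, t, np.full(50, float(value)))


class TestKineticParams:
    def test_negative_rates_rejected(self):
        with pytest.raises(ValueError):
            km.KineticParams("constant", k1=-1, k2=1, x0=0)
        with pytest.raises(ValueError):
            km.KineticParams("constant", k1=1, k2=-1, x0=0)
        with pytest.raises(ValueError):
            km.KineticParams("cooperative", k1=1, k2=1, x0=0, w=1, b=0, q=-1)

    def test_irrelevant_fields_rejected(self):
        with pytest.raises(ValueError):
            km.KineticParams("constant", k1=1, k2=1, x0=0, w=1)
        with pytest.raises(ValueError):
            km.KineticParams("direct", k1=1, k2=1, x0=0, w=1, b=0, q=1)

    def test_missing_fields_rejected(self):
        with pytest.raises(ValueError):
            km.KineticParams("direct", k1=1, k2=1, x0=0)


class TestComplexConcentration:
    def test_q_zero_gives_min(self):
        assert km.complex_concentration(2, 3, 0) == pytest.approx(2.0)
        assert km.complex_concentration(3, 2, 0) == pytest.approx(2.0)

    def test_large_q_gives_zero(self):
        val = km.complex_concentration(2, 3, 1e12)
        assert 0 <= val <= 1e-6 * 2

    def test_unit_case_derived(self):
        # smaller root of y^2 - 3y + 1 = 0 is (3 - sqrt(5)) / 2
        expected = (3 - np.sqrt(5)) / 2
        assert km.complex_concentration(1, 1, 1) == pytest.approx(expected,
                                                                  abs=1e-12)
        assert smaller_root_oracle(1, 1, 1) == pytest.approx(expected,
                                                             abs=1e-9)

    def test_matches_quadratic_oracle_on_grid(self, rng):
        triples = rng.uniform(0, 100, size=(2000, 3))
        for ya, yb, q in triples:
            assert km.complex_concentration(ya, yb, q) == pytest.approx(
                smaller_root_oracle(ya, yb, q), abs=1e-10)

    def test_zero_concentration_edge(self):
        assert km.complex_concentration(0, 5, 1) == 0.0
        assert km.complex_concentration(5, 0, 0) == 0.0
        assert km.complex_concentration(0, 0, 0) == 0.0

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            km.complex_concentration(-1, 1, 1)
        with pytest.raises(ValueError):
            km.complex_concentration(1, 1, -1)

    def test_vectorized(self):
        ya = np.array([1.0, 2.0, 3.0])
        out = km.complex_concentration(ya, 2.0, 0.0)
        np.testing.assert_allclose(out, np.minimum(ya, 2.0))

    @settings(max_examples=200, deadline=None)
    @given(ya=st.floats(0, 100), yb=st.floats(0, 100), q=st.floats(0, 100))
    def test_symmetry_and_bounds(self, ya, yb, q):
        v = km.complex_concentration(ya, yb, q)
        assert v == pytest.approx(km.complex_concentration(yb, ya, q),
                                  abs=1e-12)
        assert -1e-12 <= v <= min(ya, yb) + 1e-9

    @settings(max_examples=100, deadline=None)
    @given(ya=st.floats(0.01, 100), yb=st.floats(0.01, 100),
           q1=st.floats(0, 50), dq=st.floats(0, 50), dy=st.floats(0, 50))
    def test_monotonicity(self, ya, yb, q1, dq, dy):
        base = km.complex_concentration(ya, yb, q1)
        assert km.complex_concentration(ya, yb, q1 + dq) <= base + 1e-9
        assert km.complex_concentration(ya + dy, yb, q1) >= base - 1e-9


class TestComplexProfile:
    def test_bounded_by_constituents(self):
        t = np.linspace(0, 10, 50)
        a = ed.SmoothedProfile.from_samples("a", t, 2 + np.sin(t))
        b = ed.SmoothedProfile.from_samples("b", t, 3 + np.cos(t))
        comp = km.ComplexProfile(a, b, q=1.0)
        vals = comp(t)
        assert np.all(vals >= 0)
        assert np.all(vals <= np.minimum(a(t), b(t)) + 1e-9)

    def test_disjoint_domains_rejected(self):
        a = flat_profile(1, 0, 1)
        b = flat_profile(1, 2, 3)
        with pytest.raises(ValueError, match="domain"):
            km.ComplexProfile(a, b, q=1.0)


class TestSimulate:
    times = np.linspace(0, 8, 30)

    def test_constant_fixed_point(self):
        p = km.KineticParams("constant", k1=2, k2=1, x0=2)
        x = km.simulate(p, (), self.times)
        np.testing.assert_allclose(x, 2.0, atol=1e-10)

    def test_constant_closed_form_decay(self):
        # k1=0, k2=1, x0=1 at t-t0=1 gives e^-1
        p = km.KineticParams("constant", k1=0, k2=1, x0=1)
        x = km.simulate(p, (), np.array([0.0, 1.0]))
        assert x[1] == pytest.approx(np.exp(-1), abs=1e-10)

    def test_constant_matches_closed_form(self, rng):
        for _ in range(10):
            k1, k2, x0 = rng.uniform(0.1, 5, 3)
            p = km.KineticParams("constant", k1=k1, k2=k2, x0=x0)
            x = km.simulate(p, (), self.times)
            expected = k1 / k2 + (x0 - k1 / k2) * np.exp(-k2 * self.times)
            np.testing.assert_allclose(x, expected, atol=1e-8)

    def test_constant_k2_zero_accumulates(self):
        p = km.KineticParams("constant", k1=2, k2=0, x0=1)
        x = km.simulate(p, (), np.array([0.0, 3.0]))
        assert x[1] == pytest.approx(7.0)

    def test_direct_w_zero_equals_scaled_constant(self):
        # oracle: closed-form constant model with synthesis k1 * sigma(b)
        reg = flat_profile(5.0, 0, 8)
        b = 0.7
        p = km.KineticParams("direct", k1=3, k2=0.8, x0=1, w=0.0, b=b)
        x = km.simulate(p, (reg,), self.times)
        k1_eff = 3 / (1 + np.exp(-b))
        expected = k1_eff / 0.8 + (1 - k1_eff / 0.8) * np.exp(-0.8 * self.times)
        np.testing.assert_allclose(x, expected, atol=1e-6)

    def test_direct_saturated_w_equals_full_synthesis(self):
        reg = flat_profile(5.0, 0, 8)
        p = km.KineticParams("direct", k1=3, k2=0.8, x0=1, w=1000.0, b=0.0)
        x = km.simulate(p, (reg,), self.times)
        expected = 3 / 0.8 + (1 - 3 / 0.8) * np.exp(-0.8 * self.times)
        np.testing.assert_allclose(x, expected, atol=1e-6)

    def test_cooperative_q_zero_equal_profiles_matches_direct(self):
        # oracle: direct simulation, since y_AB = min(y, y) = y at q = 0
        t = np.linspace(0, 8, 60)
        y = 2 + np.sin(t / 2)
        prof = ed.SmoothedProfile.from_samples("y", t, y)
        coop = km.KineticParams("cooperative", k1=2, k2=0.5, x0=1, w=1.5,
                                b=-2, q=0.0)
        direct = km.KineticParams("direct", k1=2, k2=0.5, x0=1, w=1.5, b=-2)
        xc = km.simulate(coop, (prof, prof), self.times)
        xd = km.simulate(direct, (prof,), self.times)
        np.testing.assert_allclose(xc, xd, atol=1e-6)

    def test_direct_bounds_invariant(self, rng):
        t = np.linspace(0, 8, 40)
        y = rng.uniform(0, 5, size=40)
        prof = ed.smooth_profile(t, y, gene_id="y")
        p = km.KineticParams("direct", k1=2, k2=1, x0=1, w=1.0, b=0.0)
        x = km.simulate(p, (prof,), self.times)
        assert np.all(x >= -1e-9)
        assert np.all(x <= 2 / 1 + 1e-9)

    def test_regulator_count_mismatch(self):
        p = km.KineticParams("direct", k1=1, k2=1, x0=0, w=1, b=0)
        with pytest.raises(ValueError, match="regulator"):
            km.simulate(p, (), self.times)

    def test_times_outside_domain_rejected(self):
        reg = flat_profile(1.0, 0, 5)
        p = km.KineticParams("direct", k1=1, k2=1, x0=0, w=1, b=0)
        with pytest.raises(ValueError, match="domain"):
            km.simulate(p, (reg,), np.array([0.0, 6.0]))


class TestLinearOdeResponse:
    def test_matches_constant_closed_form(self):
        h = 0.01
        n = 1000
        synth = np.full(n, 2.0)
        x = km.linear_ode_response(synth, k2=1.0, x0=5.0, h=h)
        t = h * np.arange(n)
        expected = 2.0 + 3.0 * np.exp(-t)
        np.testing.assert_allclose(x, expected, atol=2e-4)

    def test_k2_zero_is_cumulative_integral(self):
        h = 0.01
        t = h * np.arange(1000)
        synth = np.sin(t) + 1.5
        x = km.linear_ode_response(synth, k2=0.0, x0=0.0, h=h)
        expected = 1.5 * t + (1 - np.cos(t))
        np.testing.assert_allclose(x, expected, atol=1e-3)

    def test_matches_adaptive_solver_on_varying_input(self):
        t = np.linspace(0, 8, 25)
        y = 2 + np.sin(t)
        prof = ed.SmoothedProfile.from_samples("y", t, y)
        p = km.KineticParams("direct", k1=3, k2=0.7, x0=1, w=1.2, b=-2)
        ref = km.simulate(p, (prof,), t, rtol=1e-9, atol=1e-12)
        fine_t = np.linspace(0, 8, 801)
        synth = p.k1 / (1 + np.exp(-(p.w * prof(fine_t) + p.b)))
        fast = km.linear_ode_response(synth, p.k2, p.x0,
                                      fine_t[1] - fine_t[0])
        np.testing.assert_allclose(np.interp(t, fine_t, fast), ref, atol=2e-4)
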