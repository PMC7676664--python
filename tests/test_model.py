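"""Model definitions: sigmoid, right-hand sides, conversions, singular limits."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nmburst import (
    ModelParams,
    SigmoidParams,
    StimCoupling,
    TimescaleParams,
    fast_layer_equilibrium,
    fast_layer_jacobian,
    full_jacobian,
    full_rhs,
    full_to_rescaled,
    rescaled_rhs,
    rescaled_to_full,
    sigmoid,
    sigmoid_deriv,
)
from nmburst.model import subsystem_rhs
from nmburst.continuation import find_equilibria


class TestSigmoid:
    def test_midpoint_is_half_ceiling(self):
        assert sigmoid(6.0) == pytest.approx(2.5, abs=1e-14)

    def test_value_at_zero(self):
        # direct arithmetic: 5 / (1 + e^{0.56*6})
        expected = 5.0 / (1.0 + math.exp(3.36))
        assert sigmoid(0.0) == pytest.approx(expected, rel=1e-14)
        assert expected == pytest.approx(0.1678, abs=1e-4)

    def test_asymptotes(self):
        assert sigmoid(1e4) == pytest.approx(5.0, abs=1e-12)
        assert sigmoid(-1e4) == pytest.approx(0.0, abs=1e-12)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            sigmoid(float("nan"))
        with pytest.raises(ValueError):
            sigmoid(np.array([1.0, np.inf]))

    @given(st.floats(min_value=-1e6, max_value=1e6),
           st.floats(min_value=-1e6, max_value=1e6))
    @settings(max_examples=200, deadline=None)
    def test_monotone_and_bounded(self, a, b):
        sa, sb = sigmoid(a), sigmoid(b)
        assert 0.0 <= sa <= 5.0 and 0.0 <= sb <= 5.0
        if a < b:
            assert sa <= sb

    def test_derivative_matches_finite_difference(self):
        for v in (-3.0, 0.0, 6.0, 12.0):
            h = 1e-6
            fd = (sigmoid(v + h) - sigmoid(v - h)) / (2 * h)
            assert sigmoid_deriv(v) == pytest.approx(fd, rel=1e-7)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            SigmoidParams(vmax=-1.0)
        with pytest.raises(ValueError):
            SigmoidParams(steepness=0.0)


class TestFullRHS:
    def test_origin_closed_form(self, table_params):
        pr = table_params.replace(p_mean=0.0)
        d = full_rhs(np.zeros(10), pr)
        s0 = sigmoid(0.0)
        assert d[:5] == pytest.approx(np.zeros(5))
        assert d[5] == pytest.approx(pr.A / pr.tau_a * s0)
        assert d[6] == pytest.approx(pr.A / pr.tau_a * pr.C2 * s0)
        assert d[7] == pytest.approx(pr.B / pr.tau_b * pr.C4 * s0)
        assert d[9] == pytest.approx(pr.B / pr.tau_b * s0)

    def test_vanishes_at_equilibrium(self, table_params):
        eq = find_equilibria(table_params)[0]
        assert np.max(np.abs(full_rhs(eq.state, table_params))) < 1e-9

    def test_zero_coupling_decouples_stimulation(self, table_params):
        x = np.linspace(-0.5, 0.5, 10)
        base = full_rhs(x, table_params, i_ext=0.0)
        stim = full_rhs(x, table_params, i_ext=7.3, coupling=StimCoupling())
        np.testing.assert_array_equal(base, stim)

    def test_jacobian_matches_finite_difference(self, table_params):
        rng = np.random.default_rng(7)
        x = rng.normal(scale=0.1, size=10)
        J = full_jacobian(x, table_params)
        h = 1e-7
        for j in range(10):
            e = np.zeros(10)
            e[j] = h
            fd = (full_rhs(x + e, table_params) - full_rhs(x - e, table_params)) / (2 * h)
            np.testing.assert_allclose(J[:, j], fd, rtol=1e-5, atol=1e-4)


class TestRescaledSystem:
    def test_v3_rate_is_y8(self, table_params):
        x = np.zeros(8)
        x[1] = 0.37     # y8
        d = rescaled_rhs(x, table_params)
        assert d[0] == pytest.approx(0.37)

    def test_delta_zero_limit_is_fast_layer(self, table_params):
        """As delta -> 0 the slow and superslow components vanish, leaving
        the fast layer problem for (v3, y8)."""
        rng = np.random.default_rng(3)
        x = rng.normal(scale=0.5, size=8)
        ts = TimescaleParams(delta=1e-12, epsilon=0.2, independent=True)
        d = rescaled_rhs(x, table_params, ts)
        assert np.max(np.abs(d[2:])) < 1e-9
        layer = subsystem_rhs("fast_layer", {"v0": x[2], "v2": x[6]},
                              x[:2], table_params)
        np.testing.assert_allclose(d[:2], layer, rtol=1e-12)

    def test_conversion_round_trip(self, table_params):
        rng = np.random.default_rng(11)
        x = rng.normal(scale=0.3, size=10)
        x[2] = table_params.C4 * x[4]   # y2 is slaved to y4 in the reduction
        x[7] = table_params.C4 * x[9]
        back = rescaled_to_full(full_to_rescaled(x, table_params), table_params)
        np.testing.assert_allclose(back, x, rtol=1e-12, atol=1e-12)

    def test_conversion_commutes_with_dynamics(self, table_params):
        """d/dt~ of the converted state equals the rescaled RHS: the
        variable conversion maps trajectories of the full system onto
        trajectories of the rescaled one."""
        pr = table_params
        rng = np.random.default_rng(5)
        x = rng.normal(scale=0.2, size=10)
        x[2] = pr.C4 * x[4]
        x[7] = pr.C4 * x[9]
        dx = full_rhs(x, pr)
        h = 1e-8
        fd = (full_to_rescaled(x + h * dx, pr) - full_to_rescaled(x - h * dx, pr)) / (2 * h)
        want = rescaled_rhs(full_to_rescaled(x, pr), pr) / pr.tau_g  # per second
        np.testing.assert_allclose(fd, want, rtol=1e-5, atol=1e-6)


class TestSingularLimits:
    def test_fast_layer_equilibrium_on_s0(self, table_params):
        pr = table_params
        rng = np.random.default_rng(1)
        for _ in range(20):
            v0, v2 = rng.uniform(0, 20), rng.uniform(0, 25)
            v3, y8 = fast_layer_equilibrium(v0, v2, pr)
            assert y8 == 0.0
            a = pr.C5 * pr.tau_a * v0 - pr.C6 * pr.tau_b * v2
            assert v3 == pytest.approx(pr.G * sigmoid(a), rel=1e-14)
            d = subsystem_rhs("fast_layer", {"v0": v0, "v2": v2},
                              [v3, y8], pr)
            assert np.max(np.abs(d)) < 1e-12

    def test_fast_layer_eigenvalues_minus_one(self, table_params):
        J = fast_layer_jacobian(1.0, 2.0, table_params)
        assert np.trace(J) == -2.0 and np.linalg.det(J) == 1.0
        ev = np.linalg.eigvals(J)
        np.testing.assert_allclose(ev, [-1.0, -1.0], atol=1e-6)

    def test_superslow_relaxes_to_b_s0(self, table_params):
        """With v0 frozen at 0 the (v2, y7) pair has the linear fixed point
        v2* = B S(0), y7* = 0."""
        pr = table_params
        v2_star = pr.B * sigmoid(0.0)
        d = subsystem_rhs("superslow_reduced", {"v0": 0.0},
                          [v2_star, 0.0], pr)
        assert np.max(np.abs(d)) < 1e-12
        # off the fixed point the flow points back toward it
        d = subsystem_rhs("superslow_reduced", {"v0": 0.0},
                          [v2_star + 1.0, 0.0], pr)
        assert d[1] < 0

    def test_frozen_mismatch_raises(self, table_params):
        with pytest.raises(ValueError, match="frozen"):
            subsystem_rhs("slow_layer", {"v0": 1.0}, np.zeros(4), table_params)


class TestParams:
    def test_timescale_ratios_at_defaults(self, table_params):
        assert table_params.delta == pytest.approx(0.3)
        assert table_params.epsilon == pytest.approx(0.2)

    def test_invalid_rejected(self):
        with pytest.raises(ValueError):
            ModelParams(tau_a=0.0)
        with pytest.raises(ValueError):
            ModelParams(B=-1.0)
        with pytest.raises(ValueError):
            TimescaleParams(delta=0.0)

    def test_config_round_trip(self, tmp_path, table_params):
        from nmburst import load_params, save_params

        p = table_params.replace(B=12.5, sigma=3.0)
        c = StimCoupling(kSOM=1.0)
        for name in ("params.yaml", "params.json"):
            save_params(tmp_path / name, p, c)
            p2, c2 = load_params(tmp_path / name)
            assert p2 == p and c2 == c

    def test_unknown_key_rejected(self, tmp_path):
        from nmburst import load_params

        (tmp_path / "bad.yaml").write_text("A: 5\nbogus_key: 1\n")
        with pytest.raises(KeyError, match="bogus_key"):
            load_params(tmp_path / "bad.yaml")
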