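import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_

from srnasilence.model_core import (
    ConvergenceError,
    KineticParameters,
    ParameterError,
    UndefinedEfficacyError,
    classify_regime,
    dump_params,
    effective_rates,
    efficacy,
    find_max_efficacy,
    get_preset,
    load_params,
    response_curve,
    steady_state_closed_form,
    steady_state_numeric,
    unregulated_expression,
)

from .conftest import random_valid_params

positive = st_.floats(min_value=1e-3, max_value=1e3)
nonneg = st_.floats(min_value=0.0, max_value=1e3)


def params_strategy():
    return st_.builds(
        KineticParameters,
        alpha_m=positive,
        alpha_s=nonneg,
        beta_m0=positive,
        beta_s=positive,
        beta_p=positive,
        k0=positive,
        gamma0=positive,
        x=nonneg,
        w=positive,
        y=positive,
        z=nonneg,
    )


class TestParameters:
    def test_rejects_negative_x(self, fig2_params):
        with pytest.raises(ParameterError):
            fig2_params.with_(x=-0.1)

    @pytest.mark.parametrize("field", ["alpha_m", "beta_m0", "beta_s", "beta_p", "k0", "gamma0", "w", "y"])
    def test_rejects_nonpositive_rates(self, fig2_params, field):
        with pytest.raises(ParameterError):
            fig2_params.with_(**{field: 0.0})

    def test_presets(self):
        p2 = get_preset("fig2")
        p5 = get_preset("fig5")
        assert p2.beta_m0 == 0.4 and p2.k0 == 0.04
        assert p5.beta_m0 == 0.42
        # the second preset is pinned by a unit basal leakage rate
        assert p5.beta_m0 * p5.beta_s / p5.k0 == pytest.approx(1.0)
        with pytest.raises(KeyError):
            get_preset("nope")

    def test_config_round_trip(self, tmp_path, fig5_params):
        path = tmp_path / "params.yaml"
        dump_params(fig5_params, path)
        assert load_params(path) == fig5_params

    def test_config_rejects_bad_keys(self, tmp_path):
        path = tmp_path / "bad.yaml"
        path.write_text("alpha_m: 1\nbogus: 2\n")
        with pytest.raises(ParameterError):
            load_params(path)


class TestEffectiveRates:
    def test_w_one_identity(self, fig2_params):
        for x in (0.0, 0.3, 1.0, 42.0):
            eff = effective_rates(fig2_params.with_(w=1.0, x=x))
            assert eff.beta_m == pytest.approx(fig2_params.beta_m0)

    def test_x_zero(self, fig2_params):
        eff = effective_rates(fig2_params.with_(x=0.0, z=0.5))
        assert eff.gamma == 0.0
        assert eff.k == pytest.approx(fig2_params.k0 / 1.5)

    def test_interaction_rate_example(self):
        # hand evaluation: 0.04 * 101 / (2 * 1.101)
        p = get_preset("fig2", k0=0.04, x=1.0, y=100.0, z=0.001)
        assert effective_rates(p).k == pytest.approx(1.8346957311534968, rel=1e-12)

    @settings(max_examples=100, deadline=None)
    @given(params=params_strategy())
    def test_invariants(self, params):
        eff = effective_rates(params)
        assert eff.beta_m > 0
        assert 0 <= eff.gamma < params.gamma0
        assert 0 < eff.k <= params.k0 * max(1.0, params.y) * (1 + 1e-12)
        assert eff.lam > 0
        assert eff.b >= 0

    def test_gamma_monotone_in_x(self, fig2_params):
        xs = np.logspace(-3, 4, 200)
        gam = [effective_rates(fig2_params.with_(x=float(x))).gamma for x in xs]
        assert np.all(np.diff(gam) > 0)
        assert gam[-1] < fig2_params.gamma0
        assert fig2_params.gamma0 - gam[-1] < 1e-3


class TestSteadyState:
    def test_no_srna(self, fig2_params):
        p = fig2_params.with_(alpha_s=0.0)
        ss = steady_state_closed_form(p)
        eff = effective_rates(p)
        assert ss.m == pytest.approx(p.alpha_m / eff.beta_m, rel=1e-12)
        assert ss.s == 0.0
        assert ss.p == pytest.approx(eff.gamma * p.alpha_m / (eff.beta_m * p.beta_p), rel=1e-12)

    def test_quadratic_root_example(self):
        # effective beta_m=0.4, beta_s=0.1, k=0.04 -> lam=1; alpha_m=1, alpha_s=2
        # m = (-2 + sqrt(8)) / 0.8 = (2*sqrt(2) - 2)/0.8, s = 10*sqrt(2)
        p = KineticParameters(
            alpha_m=1.0, alpha_s=2.0, beta_m0=0.4, beta_s=0.1, beta_p=1 / 60,
            k0=0.04, gamma0=1.0, x=1.0, w=1.0, y=1.0, z=0.0,
        )
        ss = steady_state_closed_form(p)
        assert ss.m == pytest.approx((2 * math.sqrt(2) - 2) / 0.8, rel=1e-12)
        assert ss.s == pytest.approx(10 * math.sqrt(2), rel=1e-12)
        assert ss.residual_norm < 1e-10

    def test_threshold_linear_limit(self):
        # lam -> 0+ with alpha_s < alpha_m: m -> (alpha_m - alpha_s)/beta_m
        p = KineticParameters(
            alpha_m=1.0, alpha_s=0.4, beta_m0=0.4, beta_s=0.1, beta_p=1 / 60,
            k0=400.0, gamma0=1.0, x=1.0, w=1.0, y=1.0, z=0.0,
        )
        ss = steady_state_closed_form(p)
        assert ss.m == pytest.approx(0.6 / 0.4, rel=1e-3)

    def test_numeric_matches_closed_form_sweep(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            p = random_valid_params(rng)
            m_c = steady_state_closed_form(p).m
            m_n = steady_state_numeric(p).m
            assert m_n == pytest.approx(m_c, rel=1e-8)

    def test_numeric_crossover_degenerate(self):
        # alpha_m = alpha_s with lam = alpha_m
        p = KineticParameters(
            alpha_m=1.0, alpha_s=1.0, beta_m0=0.4, beta_s=0.1, beta_p=1 / 60,
            k0=0.04, gamma0=1.0, x=1.0, w=1.0, y=1.0, z=0.0,
        )
        ss = steady_state_numeric(p, tol=1e-10)
        assert ss.residual_norm <= 1e-10

    def test_numeric_rejects_bad_tol(self, fig2_params):
        with pytest.raises(ValueError):
            steady_state_numeric(fig2_params, tol=0.0)

    @settings(max_examples=60, deadline=None)
    @given(params=params_strategy())
    def test_mass_balance(self, params):
        eff = effective_rates(params)
        ss = steady_state_closed_form(params)
        flux = eff.k * ss.s * ss.m
        assert eff.beta_m * ss.m + flux == pytest.approx(params.alpha_m, rel=1e-9)
        assert params.beta_s * ss.s + flux == pytest.approx(params.alpha_s, rel=1e-9, abs=1e-9)


class TestEfficacy:
    def test_no_interaction_limit(self, fig2_params):
        assert efficacy(fig2_params.with_(k0=1e-12)) == pytest.approx(1.0, rel=1e-6)

    def test_derived_ratio(self):
        p = KineticParameters(
            alpha_m=1.0, alpha_s=2.0, beta_m0=0.4, beta_s=0.1, beta_p=1 / 60,
            k0=0.04, gamma0=1.0, x=1.0, w=1.0, y=1.0, z=0.0,
        )
        # m_off = 2.5, m_on = (2 sqrt 2 - 2)/0.8 -> ratio = 1 + sqrt(2)
        assert efficacy(p) == pytest.approx(1 + math.sqrt(2), rel=1e-12)
        assert efficacy(p, as_ratio=True) == pytest.approx(1 / (1 + math.sqrt(2)), rel=1e-12)

    def test_undefined_at_zero_x(self, fig2_params):
        with pytest.raises(UndefinedEfficacyError):
            efficacy(fig2_params.with_(x=0.0))

    def test_requires_srna(self, fig2_params):
        with pytest.raises(ParameterError):
            efficacy(fig2_params.with_(alpha_s=0.0))

    @settings(max_examples=80, deadline=None)
    @given(params=params_strategy().filter(lambda p: p.alpha_s > 0 and p.x > 0))
    def test_at_least_one_and_translation_invariant(self, params):
        f = efficacy(params)
        assert f >= 1.0 - 1e-12
        # gamma0 and beta_p cancel in the ratio
        f2 = efficacy(params.with_(gamma0=params.gamma0 * 7.0, beta_p=params.beta_p * 3.0))
        assert f2 == pytest.approx(f, rel=1e-10)


class TestResponseCurve:
    GRID = np.logspace(-2, 2, 41)

    def test_competition_monotone(self, fig2_params):
        rc = response_curve(fig2_params.with_(y=0.01), "x", self.GRID)
        assert np.all(np.diff(rc.efficacy) < 0)

    def test_recruitment_unimodal(self, fig2_params):
        rc = response_curve(fig2_params.with_(y=100.0), "x", self.GRID)
        i = int(np.argmax(rc.efficacy))
        assert 0 < i < len(self.GRID) - 1
        d = np.diff(rc.efficacy)
        assert np.all(d[:i] > 0) and np.all(d[i:] < 0)

    def test_no_srna_unit_efficacy(self, fig2_params):
        rc = response_curve(fig2_params.with_(alpha_s=0.0), "x", self.GRID)
        assert np.allclose(rc.efficacy, 1.0)

    def test_axis_mappings(self, fig2_params):
        rc_x = response_curve(fig2_params, "x", [0.5, 1.0, 2.0])
        rc_a = response_curve(
            fig2_params, "translational_activity", [0.5 / 1.5, 0.5, 2.0 / 3.0]
        )
        assert np.allclose(rc_x.efficacy, rc_a.efficacy, rtol=1e-9)
        rc_u = response_curve(fig2_params, "unregulated_expression", [0.5, 1.0, 2.0])
        assert np.allclose(
            rc_u.axis_values,
            [unregulated_expression(fig2_params.with_(x=v)) for v in (0.5, 1.0, 2.0)],
        )

    def test_alpha_s_axis(self, fig2_params):
        rc = response_curve(fig2_params, "alpha_s", [0.5, 1.0, 2.0])
        assert np.all(np.diff(rc.efficacy) > 0)
        assert np.allclose(rc.expression_off, rc.expression_off[0])

    def test_grid_validation(self, fig2_params):
        with pytest.raises(ValueError):
            response_curve(fig2_params, "x", [])
        with pytest.raises(ValueError):
            response_curve(fig2_params, "x", [1.0, 2.0])
        with pytest.raises(ValueError):
            response_curve(fig2_params, "x", [1.0, 1.0, 2.0])

    def test_csv_round_trip(self, tmp_path, fig2_params):
        import pandas as pd

        rc = response_curve(fig2_params, "x", [0.5, 1.0, 2.0])
        path = tmp_path / "curve.csv"
        rc.to_csv(path)
        df = pd.read_csv(path)
        assert list(df.columns) == ["axis_kind", "axis_value", "expression_off", "expression_on", "efficacy"]
        assert np.allclose(df["efficacy"], rc.efficacy)


class TestMaxEfficacy:
    def test_competition_boundary(self, fig2_params):
        res = find_max_efficacy(fig2_params.with_(y=0.01), (1e-2, 1e2))
        assert res.at_boundary
        assert res.x_opt == pytest.approx(1e-2)

    def test_recruitment_interior_matches_brute_force(self, fig2_params):
        p = fig2_params.with_(y=100.0)
        res = find_max_efficacy(p, (1e-2, 1e2))
        assert not res.at_boundary
        dense = np.logspace(-2, 2, 4001)
        effs = [efficacy(p.with_(x=float(x))) for x in dense]
        i = int(np.argmax(effs))
        assert res.x_opt == pytest.approx(dense[i], rel=1e-2)
        assert res.efficacy_opt >= effs[i] - 1e-9
        assert res.efficacy_opt > effs[0] and res.efficacy_opt > effs[-1]

    def test_gamma0_cancels(self, fig2_params):
        p = fig2_params.with_(y=100.0)
        r1 = find_max_efficacy(p, (1e-2, 1e2))
        r2 = find_max_efficacy(p.with_(gamma0=2 * p.gamma0), (1e-2, 1e2))
        assert r2.x_opt == pytest.approx(r1.x_opt, rel=1e-6)


class TestUnregulatedExpression:
    def test_zero_at_x_zero(self, fig2_params):
        assert unregulated_expression(fig2_params.with_(x=0.0)) == 0.0

    def test_saturation(self, fig2_params):
        p = fig2_params.with_(x=1e9, w=1.0)
        expected = p.gamma0 * p.alpha_m / (p.beta_m0 * p.beta_p)
        assert unregulated_expression(p) == pytest.approx(expected, rel=1e-6)

    def test_saturation_value_fig5(self, fig5_params):
        # gamma0=1, alpha_m=1, beta_m0=0.42, beta_p=1/60 -> 60/0.42 = 142.857...
        val = unregulated_expression(fig5_params.with_(x=1e12))
        assert val == pytest.approx(1.0 / (0.42 / 60.0), rel=1e-6)
        num = steady_state_numeric(fig5_params.with_(x=1e12, alpha_s=0.0)).p
        assert num == pytest.approx(val, rel=1e-8)


class TestRegime:
    @pytest.mark.parametrize(
        "alpha_s,label",
        [(0.0, "expressed"), (0.49, "expressed"), (0.5, "crossover"), (1.0, "crossover"),
         (1.99, "crossover"), (2.0, "silenced")],
    )
    def test_default_thresholds(self, fig2_params, alpha_s, label):
        assert classify_regime(fig2_params.with_(alpha_s=alpha_s)).label == label

    def test_custom_thresholds(self, fig2_params):
        res = classify_regime(fig2_params.with_(alpha_s=0.8), t_lo=0.9, t_hi=1.1)
        assert res.label == "expressed"
        with pytest.raises(ValueError):
            classify_regime(fig2_params, t_lo=1.5, t_hi=2.0)
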