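"""Closed-form degradation laws, steady states and knockdown ratios."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

from rnaifit import (
    MODEL_IDS,
    SharedRates,
    delta_rate,
    knockdown_ratio,
    make_params,
    michaelis_menten_view,
    protein_steady_state,
    steady_state_mrna,
)

DM = 0.0173


def _random_params(model, rng):
    u = rng.uniform
    if model == "model1":
        return make_params("model1", k1=10 ** u(-6, -3))
    if model == "model2":
        return make_params("model2", k2=10 ** u(-6, -3), h2=u(0.3, 3.0))
    if model == "model3":
        return make_params(
            "model3", k3h3=10 ** u(-6, -3), c3_over_km=10 ** u(1, 5)
        )
    return make_params(
        "model4", d4=10 ** u(-4, -1), theta4=10 ** u(-2, 2), h4=u(0.5, 6.0)
    )


class TestDeltaRate:
    def test_zero_sirna_or_mrna_gives_zero(self, shared, egfp_mrna_fits):
        for model in MODEL_IDS:
            p = egfp_mrna_fits[model]
            assert delta_rate(model, p, 1.0, 0.0, shared) == 0.0
            assert delta_rate(model, p, 0.0, 5.0, shared) == 0.0

    def test_hill_half_max_identity(self, shared):
        # At xs = theta4 the Hill term is exactly 1/2, so delta = d4/2 * xm.
        p = make_params("model4", d4=8.1e-3, theta4=0.105, h4=4.47)
        assert delta_rate("model4", p, 1.0, 0.105, shared) == pytest.approx(
            4.05e-3, rel=1e-12
        )

    def test_cooperative_law_with_unit_exponent_is_mass_action(self, shared):
        p2 = make_params("model2", k2=3.3e-4, h2=1.0)
        p1 = make_params("model1", k1=3.3e-4)
        xm = np.linspace(0, 50, 7)
        xs = np.linspace(0, 200, 7)
        np.testing.assert_allclose(
            delta_rate("model2", p2, xm, xs, shared),
            delta_rate("model1", p1, xm, xs, shared),
            rtol=1e-14,
        )

    def test_rejects_mismatched_params_and_negative_inputs(self, shared):
        p1 = make_params("model1", k1=1e-4)
        with pytest.raises(TypeError):
            delta_rate("model2", p1, 1.0, 1.0, shared)
        with pytest.raises(ValueError):
            delta_rate("model1", p1, -1.0, 1.0, shared)
        with pytest.raises(ValueError):
            delta_rate("nonsense", p1, 1.0, 1.0, shared)


class TestSteadyState:
    def test_zero_dose_returns_control_level(self, shared, egfp_mrna_fits):
        for model in MODEL_IDS:
            assert steady_state_mrna(
                model, egfp_mrna_fits[model], shared, 0.0
            ) == pytest.approx(shared.km / shared.dm, rel=1e-12)

    def test_enzymatic_quadratic_unit_case(self):
        # km = dm = k3h3 = 1 and c3/km = 1 at xs = 0 collapses the linear
        # coefficient of the quadratic, leaving the root km/dm = 1.
        shared = SharedRates(km=1.0, dm=1.0)
        p = make_params("model3", k3h3=1.0, c3_over_km=1.0)
        assert steady_state_mrna("model3", p, shared, 0.0) == pytest.approx(1.0)

    def test_hill_saturation_limit(self, shared):
        p = make_params("model4", d4=8.1e-3, theta4=0.105, h4=4.47)
        # At saturating dose the extra degradation reaches d4 exactly.
        limit = shared.km / (shared.dm + 8.1e-3)
        assert steady_state_mrna("model4", p, shared, 1e9) == pytest.approx(
            limit, rel=1e-6
        )
        assert limit == pytest.approx(39.37, abs=0.005)

    def test_balance_residual_vanishes(self, shared, rng):
        # Root-consistency oracle: every returned equilibrium must satisfy
        # km - dm*X - delta(X, xs) = 0, checked against delta_rate directly.
        for model in MODEL_IDS:
            for _ in range(20):
                p = _random_params(model, rng)
                xs = rng.choice([0.0, 0.01, 0.5, 10.0, 200.0])
                x_eq = steady_state_mrna(model, p, shared, xs)
                resid = shared.km - shared.dm * x_eq - delta_rate(
                    model, p, x_eq, xs, shared
                )
                assert abs(resid) <= 1e-9 * shared.km

    def test_matches_independent_bracketing_root(self, shared, rng):
        # Second route: solve the balance equation numerically by brentq
        # and compare to the closed forms.
        for model in MODEL_IDS:
            p = _random_params(model, rng)
            for xs in (0.05, 1.0, 80.0):
                f = lambda x: shared.km - shared.dm * x - delta_rate(
                    model, p, x, xs, shared
                )
                root = brentq(f, 1e-12, 2 * shared.km / shared.dm, xtol=1e-12)
                assert steady_state_mrna(model, p, shared, xs) == pytest.approx(
                    root, rel=1e-8
                )


class TestKnockdownRatio:
    def test_zero_dose_ratio_is_exactly_one(self, shared, rng):
        for model in MODEL_IDS:
            for _ in range(5):
                p = _random_params(model, rng)
                assert knockdown_ratio(model, p, shared, 0.0) == 1.0

    @pytest.mark.parametrize(
        "model,kwargs,xs,expected",
        [
            ("model1", {"k1": 1.38e-4}, 200.0, DM / (DM + 1.38e-4 * 200)),
            (
                "model4",
                {"d4": 8.1e-3, "theta4": 0.105, "h4": 4.47},
                0.105,
                2 * DM / (2 * DM + 8.1e-3),
            ),
        ],
    )
    def test_hand_computed_ratios(self, shared, model, kwargs, xs, expected):
        p = make_params(model, **kwargs)
        assert knockdown_ratio(model, p, shared, xs) == pytest.approx(
            expected, rel=1e-12
        )
        # Spot values: 0.3853 and 0.8103 at 4 significant figures.
        if model == "model1":
            assert expected == pytest.approx(0.3853, abs=5e-5)
        else:
            assert expected == pytest.approx(0.8103, abs=5e-5)

    def test_monotone_nonincreasing_in_dose(self, shared, rng, dose_grid):
        grid = np.linspace(0, 200, 300)
        for model in MODEL_IDS:
            for _ in range(10):
                p = _random_params(model, rng)
                r = knockdown_ratio(model, p, shared, grid)
                assert np.all(np.diff(r) <= 1e-12)
                assert np.all((r > 0) & (r <= 1.0 + 1e-12))

    def test_tail_limits(self, shared, egfp_mrna_fits):
        # Mass-action-like models silence completely at infinite dose (the
        # cooperative law decays slowly when h2 < 1, hence the very large
        # probe dose); the Hill model saturates at dm/(dm + d4).
        huge = 1e30
        for model in ("model1", "model2", "model3"):
            assert knockdown_ratio(
                model, egfp_mrna_fits[model], shared, huge
            ) < 1e-3
        p4 = egfp_mrna_fits["model4"]
        assert knockdown_ratio("model4", p4, shared, 1e12) == pytest.approx(
            DM / (DM + p4.d4), rel=1e-6
        )

    def test_enzymatic_reduces_to_mass_action_at_large_c3(self, shared, dose_grid):
        # With c3 >> k3h3*Xm the enzymatic law is effectively unsaturated,
        # so its ratio matches the mass-action model with k1 = k3h3.
        kh = 1.40e-4
        p3 = make_params("model3", k3h3=kh, c3_over_km=1e8)
        p1 = make_params("model1", k1=kh)
        r3 = knockdown_ratio("model3", p3, shared, dose_grid)
        r1 = knockdown_ratio("model1", p1, shared, dose_grid)
        np.testing.assert_allclose(r3, r1, rtol=0.01)

    def test_hill_small_dose_matches_cooperative_law(self, shared):
        # For xs << theta4 the Hill term linearizes to (xs/theta4)^h4, i.e.
        # the cooperative law with k2 = d4/theta4^h4 and h2 = h4.
        d4, theta4, h4 = 8.1e-3, 0.105, 2.2
        p4 = make_params("model4", d4=d4, theta4=theta4, h4=h4)
        p2 = make_params("model2", k2=d4 / theta4**h4, h2=h4)
        xs = theta4 * np.array([1e-3, 1e-2, 3e-2])
        d_hill = delta_rate("model4", p4, 1.0, xs, shared)
        d_coop = delta_rate("model2", p2, 1.0, xs, shared)
        np.testing.assert_allclose(d_hill, d_coop, rtol=1e-3)

    def test_hill_efficacy_independent_of_km_increasing_in_dm(self):
        p4 = make_params("model4", d4=8.1e-3, theta4=0.105, h4=4.47)
        xs = 1.0
        r_km1 = knockdown_ratio("model4", p4, SharedRates(km=1.0), xs)
        r_km7 = knockdown_ratio("model4", p4, SharedRates(km=7.0), xs)
        assert r_km1 == r_km7
        # Faster basal turnover weakens the relative silencing effect.
        dms = [0.005, 0.0173, 0.05, 0.2]
        ratios = [
            knockdown_ratio("model4", p4, SharedRates(dm=dm), xs) for dm in dms
        ]
        assert all(a < b for a, b in zip(ratios, ratios[1:]))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        xs=st.floats(0, 200),
        d4=st.floats(1e-4, 0.1),
        theta4=st.floats(0.01, 50),
        h4=st.floats(0.3, 6),
    )
    def test_hill_ratio_bounds_property(self, xs, d4, theta4, h4):
        shared = SharedRates()
        p = make_params("model4", d4=d4, theta4=theta4, h4=h4)
        r = knockdown_ratio("model4", p, shared, xs)
        assert DM / (DM + d4) - 1e-12 <= r <= 1.0


class TestProteinLevel:
    def test_linear_gain(self, shared):
        assert protein_steady_state(SharedRates(kT=1.0, dp=1.0), 5.0) == 5.0
        assert protein_steady_state(SharedRates(kT=2.0, dp=1.0), 3.0) == 6.0

    def test_protein_ratio_equals_mrna_ratio(self, egfp_mrna_fits):
        # kT/dp cancels between treated and control, so the protein-level
        # knockdown ratio is the mRNA one for any translation parameters.
        shared = SharedRates(kT=3.7, dp=0.11)
        p = egfp_mrna_fits["model4"]
        for xs in (0.0, 0.1, 20.0):
            xm = steady_state_mrna("model4", p, shared, xs)
            ratio = protein_steady_state(shared, xm) / shared.control_protein
            assert ratio == pytest.approx(
                knockdown_ratio("model4", p, shared, xs), rel=1e-12
            )


class TestMichaelisMentenView:
    def test_reference_km_constant(self, shared):
        p = make_params("model3", k3h3=1.40e-4, c3_over_km=1.33e3)
        vm, km_const = michaelis_menten_view(p, shared, 200.0)
        assert km_const == pytest.approx(1.33e3 / 1.40e-4, rel=1e-12)
        assert km_const == pytest.approx(9.5e6, rel=0.005)
        assert vm == pytest.approx(1.33e3 * 200.0, rel=1e-12)

    def test_zero_dose_zero_vmax(self, shared):
        p = make_params("model3", k3h3=1e-4, c3_over_km=50.0)
        vm, km_const = michaelis_menten_view(p, shared, 0.0)
        assert vm == 0.0 and km_const > 0

    def test_consistent_with_delta_on_grid(self, shared, rng):
        p = make_params("model3", k3h3=2.3e-4, c3_over_km=440.0)
        xm = rng.uniform(0, 5e4, size=30)
        xs = rng.uniform(0, 200, size=30)
        vm, km_const = michaelis_menten_view(p, shared, xs)
        np.testing.assert_allclose(
            delta_rate("model3", p, xm, xs, shared),
            vm * xm / (km_const + xm),
            rtol=1e-12,
        )


class TestSharedRates:
    def test_default_dm_is_40_minute_halflife(self):
        assert SharedRates().dm == pytest.approx(math.log(2) / 40, abs=5e-5)

    def test_rejects_nonpositive_rates(self):
        with pytest.raises(ValueError):
            SharedRates(dm=0.0)
        with pytest.raises(ValueError):
            make_params("model4", d4=-1.0, theta4=1.0, h4=1.0)
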