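"""Binding-equilibrium model: steady state, inversion, error propagation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from dropletkd.equilibrium import (
    DomainError,
    EquilibriumSystem,
    bulk_to_layer,
    estimate_kd_table,
    invert_kd,
    layer_to_bulk,
    predict_ratio,
    propagate_error,
    steady_state,
)

from conftest import REF_C_EQ, REF_RATIO, REF_T_EQ


def teq_bruteforce(sys: EquilibriumSystem) -> float:
    """Independent oracle: root-find the mass-action + conservation system
    directly, without the quadratic formula."""
    g = sys.g

    def resid(T_eq):
        C = sys.S_tot * T_eq / (sys.K_D + T_eq) if sys.K_D + T_eq > 0 else 0.0
        return sys.T_tot - T_eq - g * C

    if sys.T_tot == 0:
        return 0.0
    return brentq(resid, 0.0, sys.T_tot, xtol=1e-15, rtol=8.9e-16)


def random_systems(rng, n):
    S = 10.0 ** rng.uniform(-2, 2, n)
    T = 10.0 ** rng.uniform(-2, 1, n)
    K = 10.0 ** rng.uniform(-3, 3, n)
    r0 = rng.uniform(10, 50, n)
    eps = r0 * rng.uniform(0.005, 0.3, n)
    return [EquilibriumSystem(S_tot=s, T_tot=t, K_D=k, eps=e, r0=r)
            for s, t, k, e, r in zip(S, T, K, eps, r0)]


class TestSteadyState:
    def test_reference_system_matches_bruteforce_oracle(self, ref_system):
        st_ = steady_state(ref_system)
        assert st_.T_eq == pytest.approx(REF_T_EQ, rel=1e-12)
        assert st_.ratio == pytest.approx(REF_RATIO, rel=1e-12)
        assert st_.C_eq == pytest.approx(REF_C_EQ, rel=1e-12)
        assert st_.T_eq == pytest.approx(teq_bruteforce(ref_system), rel=1e-10)

    def test_no_sites_means_all_free(self):
        sys = EquilibriumSystem(S_tot=0.0, T_tot=1.25, K_D=0.5, eps=1.0, r0=22.5)
        st_ = steady_state(sys)
        assert st_.T_eq == pytest.approx(1.25)
        assert st_.ratio == pytest.approx(1.0)

    def test_no_tsdna_means_empty(self):
        sys = EquilibriumSystem(S_tot=1.66, T_tot=0.0, K_D=0.5, eps=1.0, r0=22.5)
        st_ = steady_state(sys)
        assert st_.T_eq == 0.0
        assert st_.C_eq == 0.0

    def test_mass_action_and_conservation_residuals(self, rng):
        for sys in random_systems(rng, 10_000):
            st_ = steady_state(sys)
            # conservation: T_tot = T_eq + g*C_eq
            cons = sys.T_tot - st_.T_eq - sys.g * st_.C_eq
            assert abs(cons) <= 1e-9 * max(sys.T_tot, 1e-30)
            # mass action: C_eq*(K_D + T_eq) = S_tot*T_eq
            ma = st_.C_eq * (sys.K_D + st_.T_eq) - sys.S_tot * st_.T_eq
            scale = max(sys.S_tot * st_.T_eq, 1e-30)
            assert abs(ma) <= 1e-9 * scale

    def test_state_invariants(self, rng):
        for sys in random_systems(rng, 200):
            st_ = steady_state(sys)
            assert 0.0 <= st_.T_eq <= sys.T_tot * (1 + 1e-12)
            assert st_.C_eq >= 0.0
            assert st_.ratio >= 1.0

    def test_thin_layer_limit_frees_all_tsdna(self):
        sys = EquilibriumSystem(S_tot=1.66, T_tot=1.25, K_D=0.5,
                                eps=1e-7, r0=22.5)
        assert steady_state(sys).T_eq == pytest.approx(1.25, rel=1e-6)

    @pytest.mark.parametrize("field,value", [
        ("S_tot", -1.0), ("T_tot", -0.1), ("K_D", -1e-9),
        ("eps", 0.0), ("r0", -5.0),
    ])
    def test_invalid_parameters_name_the_field(self, field, value):
        kwargs = dict(S_tot=1.66, T_tot=1.25, K_D=0.5, eps=1.0, r0=22.5)
        kwargs[field] = value
        with pytest.raises(DomainError, match=field):
            EquilibriumSystem(**kwargs)

    def test_layer_thicker_than_droplet_rejected(self):
        with pytest.raises(DomainError):
            EquilibriumSystem(S_tot=1.0, T_tot=1.0, K_D=1.0, eps=30.0, r0=22.5)


class TestPredictRatio:
    def test_no_binding_limit(self, ref_system):
        from dataclasses import replace
        weak = replace(ref_system, K_D=1e9)
        assert predict_ratio(weak) == pytest.approx(1.0, abs=1e-6)

    def test_reference_value(self, ref_system):
        assert predict_ratio(ref_system) == pytest.approx(REF_RATIO, rel=1e-12)

    def test_monotone_in_kd_and_sites(self, rng):
        from dataclasses import replace
        for sys in random_systems(rng, 50):
            r_mid = predict_ratio(sys)
            assert predict_ratio(replace(sys, K_D=sys.K_D * 2 + 0.01)) < r_mid
            if sys.S_tot > 0:
                assert predict_ratio(replace(sys, S_tot=sys.S_tot * 2)) > r_mid


class TestInvertKd:
    def test_reference_round_trip(self, ref_system):
        est = invert_kd(REF_RATIO, S_tot=1.66, T_tot=1.25, eps=1.0, r0=22.5)
        assert est.kd == pytest.approx(0.5, rel=1e-8)
        assert not est.is_unbound_sentinel

    def test_round_trip_over_random_systems(self, rng):
        for sys in random_systems(rng, 300):
            ratio = predict_ratio(sys)
            if ratio <= 1.001:
                continue
            est = invert_kd(ratio, sys.S_tot, sys.T_tot, sys.eps, sys.r0)
            assert est.kd == pytest.approx(sys.K_D, rel=1e-8, abs=1e-12)

    def test_ratio_one_gives_unbound_sentinel(self):
        est = invert_kd(1.0, S_tot=1.66, T_tot=1.25, eps=1.0, r0=22.5)
        assert est.is_unbound_sentinel
        assert math.isinf(est.kd)

    def test_tight_binding_limit(self):
        # eps -> 0 (g -> 0): ratio = 1 + S_tot/T_tot corresponds to K_D -> 0.
        est = invert_kd(1.0 + 1.66 / 1.25, S_tot=1.66, T_tot=1.25,
                        eps=1e-6, r0=22.5)
        assert est.kd == pytest.approx(0.0, abs=1e-6)

    def test_inconsistent_ratio_raises_diagnostic(self):
        # A ratio above the K_D=0 maximum implies negative free tsDNA.
        sys0 = EquilibriumSystem(S_tot=1.66, T_tot=1.25, K_D=0.0,
                                 eps=1.0, r0=22.5)
        rmax = steady_state(sys0).ratio
        with pytest.raises(DomainError, match="negative free"):
            invert_kd(rmax * 1.5, S_tot=1.66, T_tot=1.25, eps=1.0, r0=22.5)

    def test_closed_form_cross_check(self, ref_system):
        u = 1.66 / (REF_RATIO - 1.0)
        g = ref_system.g
        kd_cf = u * (u + g * 1.66 - 1.25) / (u + g * 1.66)
        est = invert_kd(REF_RATIO, 1.66, 1.25, 1.0, 22.5)
        assert est.kd == pytest.approx(kd_cf, rel=1e-10)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    S=st.floats(0.01, 100.0),
    T=st.floats(0.01, 10.0),
    K=st.floats(1e-3, 1e3),
    frac=st.floats(0.005, 0.3),
    r0=st.floats(10.0, 50.0),
)
def test_forward_inverse_property(S, T, K, frac, r0):
    sys = EquilibriumSystem(S_tot=S, T_tot=T, K_D=K, eps=frac * r0, r0=r0)
    ratio = predict_ratio(sys)
    if ratio <= 1.001:
        return
    est = invert_kd(ratio, S, T, sys.eps, r0)
    assert est.kd == pytest.approx(K, rel=1e-8)


class TestErrorPropagation:
    BASE = dict(I_in=100.0, I_peri=100.0 * REF_RATIO, r0=22.5, eps=1.0,
                S_tot=1.66, T_tot=1.25)

    def test_zero_uncertainty_zero_sigma(self):
        sig = propagate_error(**self.BASE, sigma_inputs={
            "I_in": 0.0, "I_peri": 0.0, "r0": 0.0, "eps": 0.0})
        assert sig == 0.0

    def test_first_order_linearity(self):
        s1 = propagate_error(**self.BASE, sigma_inputs={"I_peri": 5.0})
        s2 = propagate_error(**self.BASE, sigma_inputs={"I_peri": 10.0})
        assert s2 == pytest.approx(2.0 * s1, rel=1e-9)

    def test_matches_monte_carlo_at_5pct_noise(self, rng):
        """First-order propagation vs 1e5-draw Monte-Carlo oracle."""
        sigmas = {k: 0.05 * self.BASE[k]
                  for k in ("I_in", "I_peri", "r0", "eps")}
        sig_lin = propagate_error(**self.BASE, sigma_inputs=sigmas)
        n = 100_000
        draws = {k: rng.normal(self.BASE[k], sigmas[k], n)
                 for k in ("I_in", "I_peri", "r0", "eps")}
        # Vectorized algebraic inversion for the MC oracle (the root-finding
        # path is checked against it elsewhere).
        S, T = 1.66, 1.25
        ratio = draws["I_peri"] / draws["I_in"]
        g = 3.0 * draws["eps"] / draws["r0"]
        u = S / (ratio - 1.0)
        kds = u * (u + g * S - T) / (u + g * S)
        assert sig_lin == pytest.approx(np.std(kds), rel=0.05)

    def test_sentinel_flagged(self):
        with pytest.raises(DomainError, match="undefined"):
            propagate_error(I_in=100.0, I_peri=90.0, r0=22.5, eps=1.0,
                            S_tot=1.66, T_tot=1.25,
                            sigma_inputs={"I_in": 1.0})


class TestTableInterface:
    def test_batch_csv_columns(self):
        import pandas as pd
        df = pd.DataFrame([{
            "droplet_id": 0, "r0_um": 22.5, "eps_um": 1.0,
            "I_in": 100.0, "I_peri": 100.0 * REF_RATIO,
            "sd_I_in": 2.0, "sd_I_peri": 3.0,
            "S_tot_uM": 1.66, "T_tot_uM": 1.25,
        }])
        out = estimate_kd_table(df, concentration_reference="layer")
        assert out.loc[0, "K_D_uM"] == pytest.approx(0.5, rel=1e-6)
        assert out.loc[0, "sigma_K_D_uM"] > 0
        assert not out.loc[0, "sentinel"]

    def test_bulk_layer_round_trip(self):
        c = 1.66
        assert layer_to_bulk(bulk_to_layer(c, 22.5, 1.0), 22.5, 1.0) == \
            pytest.approx(c, rel=1e-12)
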