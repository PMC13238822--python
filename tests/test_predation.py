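"""Gape window, consumption allometry, kernel construction, type-II response."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import rebuildsim as rs
from rebuildsim.dynamics import ModelState, within_year_step
from rebuildsim.life_history import build_schedules
from rebuildsim.predation import build_kernel, predation_mortality, size_preference


class TestSizePreference:
    def test_window_boundaries_inclusive(self):
        assert size_preference(29.0, 100.0, 0.05, 0.29) == 1.0
        assert size_preference(30.0, 100.0, 0.05, 0.29) == 0.0
        assert size_preference(4.9, 100.0, 0.05, 0.29) == 0.0
        assert size_preference(5.0, 100.0, 0.05, 0.29) == 1.0

    def test_inverted_quantiles_rejected(self):
        with pytest.raises(ValueError):
            size_preference(10.0, 100.0, 0.3, 0.29)


class TestAnnualConsumption:
    def test_unit_weight_equals_intercept(self):
        assert rs.annual_consumption(1.0, 3.01, 0.77) == pytest.approx(3.01)
        assert rs.annual_consumption(1.0, 3.31, 0.71) == pytest.approx(3.31)

    @given(st.floats(0.1, 30.0))
    @settings(max_examples=25, deadline=None)
    def test_power_law_doubling(self, w):
        c1 = rs.annual_consumption(w, 3.01, 0.77)
        c2 = rs.annual_consumption(2 * w, 3.01, 0.77)
        assert c2 == pytest.approx(2**0.77 * c1, rel=1e-12)


class TestBuildKernel:
    def test_gamma_zero_is_zero_kernel(self, yelloweye_sched, lingcod_sched):
        k = build_kernel(yelloweye_sched, lingcod_sched, gamma=0.0)
        assert k.is_zero
        assert not np.any(k.a)
        rate = predation_mortality(np.ones(65), np.ones(40), k)
        assert not np.any(rate)

    def test_attack_rates_scale_linearly_in_gamma(self, yelloweye_sched, lingcod_sched):
        """In the small-p limit -ln(1-p) ~ p, so a(50 g) = 50 x a(g)."""
        k_lo = build_kernel(yelloweye_sched, lingcod_sched, gamma=2e-5)
        k_hi = build_kernel(yelloweye_sched, lingcod_sched, gamma=1e-3)
        nz = k_lo.a > 0
        ratio = k_hi.a[nz] / k_lo.a[nz]
        assert np.allclose(ratio, 50.0, rtol=5e-3)

    def test_zero_outside_preference_window(self, yelloweye_sched, lingcod_sched):
        k = build_kernel(yelloweye_sched, lingcod_sched, gamma=0.05)
        assert np.all(k.a[k.pref == 0] == 0)

    def test_gape_limitation_spares_largest_prey(self, yelloweye_sched, lingcod_sched):
        """Oldest/largest yelloweye exceed every predator's gape window."""
        k = build_kernel(yelloweye_sched, lingcod_sched, gamma=0.05)
        per_age = k.a.sum(axis=1)
        assert np.all(per_age[-40:] == 0)  # ages ~26+ are invulnerable
        assert per_age[0] > 0  # youngest are eaten

    def test_demand_exceeding_prey_rejected(self, yelloweye_sched, lingcod_sched):
        tiny_ref = build_kernel(yelloweye_sched, lingcod_sched, 0.0).reference_prey * 1e-9
        with pytest.raises(ValueError, match="demand"):
            build_kernel(
                yelloweye_sched, lingcod_sched, gamma=0.5, reference_prey=tiny_ref
            )

    def test_empty_window_warns_and_zeroes(self, yelloweye_sched, lingcod_sched):
        import dataclasses

        sp = lingcod_sched.species.replace(diet_Y5=1e-4, diet_Y95=2e-4)
        sched = dataclasses.replace(lingcod_sched, species=sp)
        with pytest.warns(UserWarning, match="gape window is empty"):
            k = build_kernel(yelloweye_sched, sched, gamma=0.05)
        assert k.is_zero

    def test_realized_intake_matches_target_when_delta_zero(self, yelloweye):
        """2-prey-age x 1-predator toy: one simulated year consumes ~gamma*C."""
        prey_sp = yelloweye.replace(plus_group_age=2, natural_mortality=(1e-8, 1e-8))
        prey = build_schedules(prey_sp)
        # single predator class held ~constant over the year (M ~ 0) so the
        # annual proportion -> instantaneous rate conversion is exact
        pred_sp = rs.default_parameters()[0].replace(
            plus_group_age=2, natural_mortality=(1e-9, 1e-9)
        )
        pred = build_schedules(pred_sp)
        ref = np.array([1e4, 1e4])
        gamma = 0.01
        k = build_kernel(prey, pred, gamma=gamma, delta=0.0, reference_prey=ref)
        # predator abundance: one female of the largest class, nothing else
        L = np.zeros((2, 2))
        L[1, 0] = 1.0
        state = ModelState(Y=ref[None, :].copy(), L=L[None, ...])
        new = within_year_step(state, F=0.0, b=0.0, kernel=k, prey=prey, predator=pred)
        consumed_kg = float(((ref - new.Y[0]) * prey.weight[:, 0]).sum())
        W_pred = pred.weight[1, 0]
        target = gamma * rs.annual_consumption(W_pred, 3.31, 0.71)
        assert consumed_kg == pytest.approx(target, rel=0.01)

    def test_kernel_long_format_export(self, yelloweye_sched, lingcod_sched):
        k = build_kernel(yelloweye_sched, lingcod_sched, gamma=0.014)
        df = k.to_frame()
        assert list(df.columns) == ["prey_age", "pred_age", "pred_sex", "a"]
        assert len(df) == k.a.size
        assert df.a.min() >= 0


class TestPredationMortality:
    def test_hand_evaluation(self, toy_kernel):
        # a = 2, delta = 0.3, q = 0, Y = L = 1: rate = 2 / 1.6
        k = toy_kernel(a=2.0, delta=0.3, q=0.0)
        rate = predation_mortality([1.0], [1.0], k)
        assert rate[0] == pytest.approx(1.25, rel=1e-12)

    def test_mass_action_limit(self, yelloweye_sched, lingcod_sched):
        k = build_kernel(yelloweye_sched, lingcod_sched, gamma=0.05, delta=0.0)
        Y = k.reference_prey
        L = np.full(40, 3.0)
        rate = predation_mortality(Y, L, k)
        assert np.allclose(rate, k.a @ L)

    def test_type_ii_saturation(self, toy_kernel):
        """Per-predator intake sum a Y / (1 + delta sum a Y) -> 1/delta."""
        k = toy_kernel(a=2.0, delta=0.3, q=0.0)
        Y = np.array([1e12])
        intake = (k.a[0, 0] * Y[0]) / (1 + k.delta * k.a[0, 0] * Y[0])
        assert intake == pytest.approx(1 / k.delta, rel=1e-9)
        rate = predation_mortality(Y, [1.0], k)
        assert rate[0] * Y[0] == pytest.approx(1 / k.delta, rel=1e-9)

    @given(
        q=st.floats(0.0, 5.0),
        delta=st.floats(0.0, 2.0),
        Lscale=st.floats(1.0, 4.0),
    )
    @settings(max_examples=30, deadline=None)
    def test_monotonicity_in_q_delta_L(self, toy_kernel, q, delta, Lscale):
        base = predation_mortality([1.0], [1.0], toy_kernel(delta=delta, q=q))[0]
        more_q = predation_mortality([1.0], [1.0], toy_kernel(delta=delta, q=q + 1))[0]
        more_d = predation_mortality([1.0], [1.0], toy_kernel(delta=delta + 0.5, q=q))[0]
        more_L = predation_mortality([1.0], [Lscale], toy_kernel(delta=delta, q=q))[0]
        assert more_q <= base + 1e-12
        assert more_d <= base + 1e-12
        assert more_L >= base - 1e-12

    def test_negative_abundance_rejected(self, toy_kernel):
        with pytest.raises(ValueError):
            predation_mortality([-1.0], [1.0], toy_kernel())
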