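"""Within-year mortality, recruitment pulses, aging, and full simulation."""

import numpy as np
import pytest

import rebuildsim as rs
from rebuildsim.dynamics import (
    ModelState,
    Simulator,
    age_advance,
    ar1_deviates,
    initial_state,
    recruitment_pulse,
    spawning_biomass,
    within_year_step,
)
from rebuildsim.scenarios import predator_equilibrium_ssb


class TestAr1Deviates:
    def test_stationary_moments(self):
        """Variance sigma^2 and lag-1 autocorrelation rho within 3 SE."""
        rho, sigma, n = 0.23, 0.5, 100_000
        eps = ar1_deviates(rho, sigma, n, seed=5).eps[0]
        var = eps.var()
        se_var = sigma**2 * np.sqrt(2.0 / n)
        assert abs(var - sigma**2) < 3 * se_var * 2  # AR(1) inflates the SE
        r1 = np.corrcoef(eps[:-1], eps[1:])[0, 1]
        assert abs(r1 - rho) < 3 / np.sqrt(n) * 2

    def test_rho_zero_is_iid(self):
        eps = ar1_deviates(0.0, 0.5, 20_000, seed=1).eps[0]
        r1 = np.corrcoef(eps[:-1], eps[1:])[0, 1]
        assert abs(r1) < 0.03

    def test_sigma_zero_is_all_zero(self):
        assert not np.any(ar1_deviates(0.4, 0.0, 100, seed=0).eps)

    def test_nonstationary_rho_rejected(self):
        with pytest.raises(ValueError):
            ar1_deviates(1.0, 0.5, 10, seed=0)

    def test_reproducible(self):
        a = ar1_deviates(0.23, 0.5, 50, seed=9).eps
        b = ar1_deviates(0.23, 0.5, 50, seed=9).eps
        assert np.array_equal(a, b)


class TestWithinYearStep:
    def test_exponential_decay_no_predation(self, system):
        """With a zero kernel both species decay exactly exponentially."""
        sim = system.simulator(0.0)
        state = initial_state(sim.prey, sim.predator)
        new = within_year_step(state, F=0.0, b=0.0, kernel=sim.kernel,
                               prey=sim.prey, predator=sim.predator)
        assert np.allclose(new.Y / state.Y, np.exp(-0.044), rtol=1e-10)
        assert np.allclose(new.L[0, :, 0] / state.L[0, :, 0], np.exp(-0.18), rtol=1e-12)
        assert np.allclose(new.L[0, :, 1] / state.L[0, :, 1], np.exp(-0.32), rtol=1e-12)

    def test_lingcod_closed_form_with_fishing(self, system):
        sim = system.simulator(0.0)
        state = initial_state(sim.prey, sim.predator)
        F = 0.2
        new = within_year_step(state, F=F, b=0.0, kernel=sim.kernel,
                               prey=sim.prey, predator=sim.predator)
        Z = np.array(sim.predator.species.natural_mortality)[None, :] \
            + sim.predator.vulnerability * F
        assert np.allclose(new.L[0], state.L[0] * np.exp(-Z), rtol=1e-12)

    def test_integrator_matches_closed_form_when_decoupled(self, system):
        """gamma = 0 numerical path equals the pure-exponential solution."""
        sim = system.simulator(0.0)
        state = initial_state(sim.prey, sim.predator)
        for method in ("LSODA", "RK45"):
            new = within_year_step(
                state, F=0.1, b=0.05, kernel=sim.kernel,
                prey=sim.prey, predator=sim.predator, method=method,
            )
            Z = 0.044 + sim.prey.vulnerability[:, 0] * 0.05 * 0.1
            assert np.allclose(new.Y[0], state.Y[0] * np.exp(-Z), rtol=1e-8)

    def test_batched_integration_matches_single(self, system):
        """RK45 batch of identical replicates equals the single LSODA path."""
        sim = system.simulator(0.05)
        single = initial_state(sim.prey, sim.predator)
        batch = single.tile(4)
        out1 = within_year_step(single, 0.0, 0.0, sim.kernel, sim.prey, sim.predator,
                                method="LSODA")
        outN = within_year_step(batch, 0.0, 0.0, sim.kernel, sim.prey, sim.predator,
                                method="RK45")
        for r in range(4):
            assert np.allclose(outN.Y[r], out1.Y[0], rtol=1e-5)


class TestPulse:
    def test_spawning_biomass_arithmetic(self, yelloweye_sched, lingcod_sched):
        Y = np.zeros((1, 65))
        L = np.zeros((1, 20, 2))
        state = ModelState(Y=Y, L=L)
        assert spawning_biomass(state, yelloweye_sched, "prey")[0] == 0.0
        # 10 fully mature females of one lingcod age class
        j = 15
        L[0, j, 0] = 10.0
        expected = 10 * lingcod_sched.weight[j, 0] * lingcod_sched.maturity[j, 0]
        assert spawning_biomass(state, lingcod_sched, "predator")[0] == pytest.approx(expected)
        # linearity
        state2 = ModelState(Y=2 * Y, L=2 * L)
        assert spawning_biomass(state2, lingcod_sched, "predator")[0] == pytest.approx(2 * expected)

    def test_recruitment_zero_spawners(self):
        assert recruitment_pulse(0.0, 2.0, 0.001) == 0.0

    def test_lognormal_bias_correction_unit_mean(self):
        rng = np.random.default_rng(3)
        sigma = 0.5
        eps = rng.normal(0, sigma, 1_000_000)
        mult = np.exp(eps - 0.5 * sigma**2)
        se = mult.std() / 1000.0
        assert abs(mult.mean() - 1.0) < 3 * se

    def test_deterministic_recruitment_at_S0_is_R0(self, yelloweye_sched):
        S0 = yelloweye_sched.S0
        R = recruitment_pulse(S0, yelloweye_sched.alpha, yelloweye_sched.beta)
        assert R == pytest.approx(yelloweye_sched.species.R0, rel=1e-12)

    def test_age_advance_conserves_numbers(self):
        rng = np.random.default_rng(0)
        N = rng.uniform(0, 10, size=(3, 8))
        out = age_advance(N, np.zeros(3))
        assert np.allclose(out.sum(axis=1), N.sum(axis=1))

    def test_plus_group_absorbing(self):
        N = np.zeros((1, 5))
        N[0, -1] = 7.0
        out = age_advance(N, np.zeros(1))
        assert out[0, -1] == 7.0 and out.sum() == 7.0

    def test_cohort_reaches_plus_group_after_A_minus_1_pulses(self):
        A = 6
        N = np.zeros((1, A))
        N = age_advance(N, np.ones(1))  # cohort enters at age 1
        for _ in range(A - 1):
            assert N[0, -1] == 0.0
            N = age_advance(N, np.zeros(1))
        assert N[0, -1] == 1.0 and N.sum() == 1.0


class TestSimulate:
    def test_unfished_fixed_point(self, system):
        """sigma = 0, F = 0, gamma = 0: both species settle at S0 = R0 phi."""
        sim = system.simulator(0.0)
        state = initial_state(sim.prey, sim.predator, scale=1.5)
        out = sim.run(state, 400, stochastic=False)
        S_L = out.ssb_pred[0]
        assert abs(S_L[-1] - system.predator.S0) < 1e-6 * system.predator.S0
        assert np.all(np.abs(np.diff(S_L[-50:])) < 1e-6 * system.predator.S0)

    def test_prey_decoupled_from_predator_when_gamma_zero(self, system):
        sim = system.simulator(0.0)
        state = initial_state(sim.prey, sim.predator, scale=1.5)
        out_a = sim.run(state, 60, F=0.3, b=0.05, stochastic=False)
        # perturb the predator: different M -> different lingcod trajectory
        import dataclasses
        pred2 = dataclasses.replace(
            system.predator, species=system.predator.species.replace(
                natural_mortality=(0.25, 0.40))
        )
        sim2 = Simulator(system.prey, pred2, sim.kernel)
        out_b = sim2.run(state, 60, F=0.3, b=0.05, stochastic=False)
        assert np.allclose(out_a.ssb_prey, out_b.ssb_prey, rtol=1e-10)
        assert not np.allclose(out_a.ssb_pred, out_b.ssb_pred, rtol=1e-3)

    def test_fished_equilibrium_matches_per_recruit_closed_form(self, system):
        """Deterministic lingcod equilibrium equals (alpha phi_F - 1)/beta."""
        sim = system.simulator(0.0)
        for F in (0.05, 0.1, 0.152, 0.25, 0.35):
            state = initial_state(sim.prey, sim.predator, scale=1.5)
            out = sim.run(state, 300, F=F, stochastic=False, record=False)
            S = spawning_biomass(out.final_state, sim.predator, "predator")[0]
            assert S == pytest.approx(predator_equilibrium_ssb(system.predator, F), rel=1e-3)

    def test_seeded_runs_identical(self, system):
        sim = system.simulator(0.001)
        state = initial_state(sim.prey, sim.predator).tile(5)
        a = sim.run(state, 30, stochastic=True, seed=42)
        b = sim.run(state, 30, stochastic=True, seed=42)
        assert np.array_equal(a.ssb_prey, b.ssb_prey)

    def test_no_negative_or_nonfinite_abundance(self, system):
        sim = system.simulator(0.05)
        state = initial_state(sim.prey, sim.predator).tile(8)
        out = sim.run(state, 80, F=0.4, b=0.1, stochastic=True, seed=7)
        assert np.all(out.final_state.Y >= 0)
        assert np.all(np.isfinite(out.ssb_prey))
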