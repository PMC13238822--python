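"""Semi-discrete predator-prey simulator.

Continuous within-year mortality (natural, fishing, and — for the prey —
size-selective type-II predation) punctuated by discrete annual pulses of
Beverton-Holt recruitment and aging.

Timing convention: spawning biomass is measured at the annual pulse instant
(start of year, after aging and recruitment).  Recruits entering at pulse
k+1 derive from spawning biomass at pulse k, so the deterministic unfished
fixed point satisfies S0 = R0 * phi exactly with the l_1 = 1 survivorship
convention of :mod:`rebuildsim.life_history`.

The predator (lingcod) system is linear and autonomous within a year and is
advanced by its exact exponential solution.  The prey (yelloweye) system is
integrated numerically (adaptive solver, rtol 1e-6, atol 1e-8) with the
predator trajectory substituted in closed form.  All replicates of a
Monte-Carlo ensemble are advanced together as one batched ODE system.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .life_history import LifeHistorySchedules, unfished_numbers_at_age
from .params import FEMALE
from .predation import PredationKernel

__all__ = [
    "RecruitmentDeviationSeries",
    "ar1_deviates",
    "ModelState",
    "within_year_step",
    "spawning_biomass",
    "recruitment_pulse",
    "age_advance",
    "Simulator",
    "SimulationOutput",
]

# Integration noise floor: undershoots within ~100x the absolute solver
# tolerance are clamped to zero; anything more negative is a genuine error.
_NEG_TOL = -1e-6


@dataclass
class RecruitmentDeviationSeries:
    """AR(1) log-recruitment deviates with stationary N(0, sigma^2) marginal."""

    eps: np.ndarray  # (n_series, n_years)
    rho: float
    sigma: float
    seed: int | None = None


def ar1_deviates(
    rho: float,
    sigma: float,
    n_years: int,
    seed=None,
    n_series: int = 1,
) -> RecruitmentDeviationSeries:
    """Stationary AR(1) series: eps_k | eps_{k-1} ~ N(rho eps_{k-1}, sigma^2 (1-rho^2)).

    eps_0 is drawn from the stationary distribution N(0, sigma^2).  ``seed``
    may be an int or a ``numpy.random.Generator``.
    """
    if not abs(rho) < 1:
        raise ValueError("|rho| must be < 1")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    eps = np.empty((n_series, n_years))
    if n_years == 0:
        return RecruitmentDeviationSeries(eps, rho, sigma)
    eps[:, 0] = rng.normal(0.0, sigma, size=n_series)
    innov_sd = sigma * np.sqrt(1.0 - rho**2)
    for k in range(1, n_years):
        eps[:, k] = rho * eps[:, k - 1] + rng.normal(0.0, innov_sd, size=n_series)
    return RecruitmentDeviationSeries(eps, rho, sigma)


@dataclass
class ModelState:
    """Abundances at an annual pulse instant, batched over replicates.

    ``Y``: prey numbers-at-age, shape (R, I); ``L``: predator numbers at age
    and sex, shape (R, A, 2).  ``year`` counts completed pulses.
    """

    Y: np.ndarray
    L: np.ndarray
    year: int = 0

    @property
    def n_replicates(self) -> int:
        return self.Y.shape[0]

    def copy(self) -> "ModelState":
        return ModelState(self.Y.copy(), self.L.copy(), self.year)

    def tile(self, n: int) -> "ModelState":
        """Broadcast a single-replicate state to ``n`` replicates."""
        if self.n_replicates != 1:
            raise ValueError("tile requires a single-replicate state")
        return ModelState(np.repeat(self.Y, n, axis=0), np.repeat(self.L, n, axis=0), self.year)


def initial_state(
    prey: LifeHistorySchedules,
    predator: LifeHistorySchedules,
    scale: float = 1.5,
    n_replicates: int = 1,
) -> ModelState:
    """High-biomass start: unfished no-predation stable age structure x scale."""
    Y = unfished_numbers_at_age(prey)[:, FEMALE][None, :] * scale  # (1, I)
    L = unfished_numbers_at_age(predator)[None, ...] * scale  # (1, A, S)
    state = ModelState(Y=Y, L=L)
    return state.tile(n_replicates) if n_replicates > 1 else state


def _clamp_nonnegative(x: np.ndarray, label: str) -> np.ndarray:
    if np.any(x < _NEG_TOL):
        raise FloatingPointError(f"{label} went negative beyond tolerance")
    return np.maximum(x, 0.0)


def within_year_step(
    state: ModelState,
    F: float,
    b: float,
    kernel: PredationKernel,
    prey: LifeHistorySchedules,
    predator: LifeHistorySchedules,
    F_prey_direct: float = 0.0,
    method: str | None = None,
    rtol: float = 1e-6,
    atol: float = 1e-8,
) -> ModelState:
    """Advance one year of continuous mortality (t: 0 -> 1, no pulse).

    Predator: exact exponential decay at M_s + nu_{j,s} F.  Prey: numerical
    integration of dY_i/dt = -(M + nu_i (b F + F_direct)) Y_i
    - Y_i * predation_rate_i(Y(t), L(t)).  ``F_prey_direct`` is the prey's
    own (historical) fishing rate on vulnerable ages, used during burn-in.
    """
    sp_pred = predator.species
    sp_prey = prey.species
    R = state.n_replicates

    M_pred = np.array(sp_pred.natural_mortality)[None, None, :]  # (1,1,S)
    Z_L = M_pred + predator.vulnerability[None, :, :] * F  # (1, A, S)
    L0 = state.L
    L1 = L0 * np.exp(-Z_L)

    MY = sp_prey.natural_mortality[FEMALE]
    Z_Y = MY + prey.vulnerability[:, FEMALE] * (b * F + F_prey_direct)  # (I,)

    if kernel.is_zero:
        Y1 = state.Y * np.exp(-Z_Y)[None, :]
        return ModelState(_clamp_nonnegative(Y1, "prey"), L1, state.year)

    A = kernel.a  # (I, P)
    delta, q = kernel.delta, kernel.q
    I = A.shape[0]
    L0_flat = L0.reshape(R, -1)  # (R, P) in kernel class order
    Z_L_flat = np.broadcast_to(Z_L, L0.shape).reshape(R, -1)

    def rhs(t, y):
        Y = y.reshape(R, I)
        Lt = L0_flat * np.exp(-Z_L_flat * t)
        u = Y @ A  # (R, P)
        denom = 1.0 + delta * u + delta * q
        rate = (Lt / denom) @ A.T  # (R, I)
        return (-(Z_Y[None, :] + rate) * Y).ravel()

    if method is None:
        method = "LSODA" if R == 1 else "RK45"
    sol = solve_ivp(
        rhs,
        (0.0, 1.0),
        state.Y.ravel(),
        method=method,
        rtol=rtol,
        atol=atol,
        dense_output=False,
    )
    if not sol.success:
        raise RuntimeError(f"within-year integration failed: {sol.message}")
    Y1 = sol.y[:, -1].reshape(R, I)
    return ModelState(_clamp_nonnegative(Y1, "prey"), L1, state.year)


def spawning_biomass(state: ModelState, sched: LifeHistorySchedules, species: str) -> np.ndarray:
    """Spawning biomass (kg) per replicate.

    Predator: mature females only; prey: sex-aggregated.
    """
    if species in ("predator", "lingcod"):
        W = sched.weight[:, FEMALE] * sched.maturity[:, FEMALE]
        return state.L[:, :, FEMALE] @ W
    W = sched.weight[:, FEMALE] * sched.maturity[:, FEMALE]
    return state.Y @ W


def recruitment_pulse(
    S,
    alpha: float,
    beta: float,
    eps=0.0,
    sigma: float = 0.0,
    stochastic: bool = False,
) -> np.ndarray:
    """Beverton-Holt recruits from spawning biomass ``S``.

    base = alpha S / (1 + beta S); stochastic mode multiplies by
    exp(eps - sigma^2 / 2) (lognormal with unit mean); deterministic mode
    uses multiplier 1.  Returns *total* recruits (callers split 0.5 per sex
    for sex-structured species).
    """
    S = np.asarray(S, dtype=float)
    if np.any(S < 0):
        raise ValueError("spawning biomass must be >= 0")
    base = alpha * S / (1.0 + beta * S)
    if stochastic:
        return base * np.exp(np.asarray(eps) - 0.5 * sigma**2)
    return base


def age_advance(N: np.ndarray, recruits: np.ndarray) -> np.ndarray:
    """Shift ages by one pulse along axis 1 with an absorbing plus group.

    ``N``: (R, A[, S]) pre-pulse numbers; ``recruits``: (R[, S]) entering at
    age 1.  Plus group receives its own survivors plus the penultimate class;
    total numbers are conserved apart from the added recruits.
    """
    out = np.empty_like(N)
    out[:, 1:-1, ...] = N[:, :-2, ...]
    out[:, -1, ...] = N[:, -1, ...] + N[:, -2, ...]
    out[:, 0, ...] = recruits
    return out


@dataclass
class SimulationOutput:
    """Annual start-of-year summaries of one simulation phase.

    Arrays are (R, T): replicate by year.  ``ssb_prey``/``ssb_pred`` in kg;
    ``plus_prop`` is the prey plus-group share of total numbers;
    ``recruits_prey`` are the recruits that entered at each year's pulse.
    """

    ssb_prey: np.ndarray
    ssb_pred: np.ndarray
    plus_prop: np.ndarray
    recruits_prey: np.ndarray
    final_state: ModelState
    eps_prey: np.ndarray | None = None
    eps_pred: np.ndarray | None = None
    N_prey: np.ndarray | None = None  # (R, T, I) start-of-year numbers
    N_pred: np.ndarray | None = None  # (R, T, A, S)
    meta: dict = field(default_factory=dict)

    @property
    def n_years(self) -> int:
        return self.ssb_prey.shape[1]

    def concat(self, other: "SimulationOutput") -> "SimulationOutput":
        """Join two consecutive phases along the year axis."""
        a, b = self, other
        R = max(a.ssb_prey.shape[0], b.ssb_prey.shape[0])

        def _cat(x, y):
            x = np.repeat(x, R, axis=0) if x.shape[0] == 1 and R > 1 else x
            y = np.repeat(y, R, axis=0) if y.shape[0] == 1 and R > 1 else y
            return np.concatenate([x, y], axis=1)

        return SimulationOutput(
            ssb_prey=_cat(a.ssb_prey, b.ssb_prey),
            ssb_pred=_cat(a.ssb_pred, b.ssb_pred),
            plus_prop=_cat(a.plus_prop, b.plus_prop),
            recruits_prey=_cat(a.recruits_prey, b.recruits_prey),
            final_state=b.final_state,
            meta={**a.meta, **b.meta},
        )


class Simulator:
    """Year-stepping engine for a fixed (prey, predator, kernel) system."""

    def __init__(
        self,
        prey: LifeHistorySchedules,
        predator: LifeHistorySchedules,
        kernel: PredationKernel,
        method: str | None = None,
        rtol: float = 1e-6,
        atol: float = 1e-8,
    ):
        self.prey = prey
        self.predator = predator
        self.kernel = kernel
        self.method = method
        self.rtol = rtol
        self.atol = atol

    def run(
        self,
        state: ModelState,
        n_years: int,
        F: float = 0.0,
        b: float = 0.0,
        F_prey_direct: float = 0.0,
        stochastic: bool = False,
        seed=None,
        record: bool = True,
        record_ages: bool = False,
    ) -> SimulationOutput:
        """Advance ``n_years`` annual cycles from ``state``.

        Stochastic mode draws one AR(1) deviate series per species per
        replicate from ``seed``; deterministic mode uses multiplier 1.
        ``record_ages`` additionally stores the full start-of-year
        numbers-at-age arrays (memory grows as R x T x ages).
        """
        prey, pred = self.prey, self.predator
        sp_prey, sp_pred = prey.species, pred.species
        R = state.n_replicates
        T = n_years

        eps_Y = eps_L = None
        if stochastic:
            rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
            eps_Y = ar1_deviates(sp_prey.recruit_rho, sp_prey.recruit_sigma, T, rng, R).eps
            eps_L = ar1_deviates(sp_pred.recruit_rho, sp_pred.recruit_sigma, T, rng, R).eps

        ssb_Y = np.empty((R, T)) if record else None
        ssb_L = np.empty((R, T)) if record else None
        plus = np.empty((R, T)) if record else None
        rec_Y = np.empty((R, T)) if record else None
        N_Y = np.empty((R, T) + state.Y.shape[1:]) if record_ages else None
        N_L = np.empty((R, T) + state.L.shape[1:]) if record_ages else None

        state = state.copy()
        for k in range(T):
            S_Y = spawning_biomass(state, prey, "prey")
            S_L = spawning_biomass(state, pred, "predator")
            if record:
                ssb_Y[:, k] = S_Y
                ssb_L[:, k] = S_L
                tot = state.Y.sum(axis=1)
                plus[:, k] = np.divide(
                    state.Y[:, -1], tot, out=np.zeros(R), where=tot > 0
                )
            if record_ages:
                N_Y[:, k] = state.Y
                N_L[:, k] = state.L
            state = within_year_step(
                state, F, b, self.kernel, prey, pred,
                F_prey_direct=F_prey_direct,
                method=self.method, rtol=self.rtol, atol=self.atol,
            )
            if stochastic:
                r_Y = recruitment_pulse(
                    S_Y, prey.alpha, prey.beta, eps_Y[:, k], sp_prey.recruit_sigma, True
                )
                r_L = recruitment_pulse(
                    S_L, pred.alpha, pred.beta, eps_L[:, k], sp_pred.recruit_sigma, True
                )
            else:
                r_Y = recruitment_pulse(S_Y, prey.alpha, prey.beta)
                r_L = recruitment_pulse(S_L, pred.alpha, pred.beta)
            if record:
                rec_Y[:, k] = r_Y
            state = ModelState(
                Y=age_advance(state.Y, r_Y),
                L=age_advance(state.L, 0.5 * r_L[:, None] * np.ones((1, 2))),
                year=state.year + 1,
            )
            if not np.all(np.isfinite(state.Y)) or not np.all(np.isfinite(state.L)):
                raise FloatingPointError("non-finite abundance encountered")

        return SimulationOutput(
            ssb_prey=ssb_Y if record else np.empty((R, 0)),
            ssb_pred=ssb_L if record else np.empty((R, 0)),
            plus_prop=plus if record else np.empty((R, 0)),
            recruits_prey=rec_Y if record else np.empty((R, 0)),
            final_state=state,
            eps_prey=eps_Y,
            eps_pred=eps_L,
            N_prey=N_Y,
            N_pred=N_L,
        )
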