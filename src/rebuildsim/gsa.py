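"""Global sensitivity analysis: Monte-Carlo draws -> random-forest importance.

Draws ``n`` uniform parameter sets over the predation/recruitment parameters
{gamma, delta, q_scale, sigma, rho_L, rho_Y, Y95}, runs one stochastic
unfished (F = 0) simulation per draw with the kernel rebuilt for that draw,
computes the steady-state outcomes (mean spawning biomass, stability, plus-
group proportion), and scores parameter influence with out-of-bag
permutation importance (% increase in MSE) from a bagged regression-tree
ensemble, including an injected standard-normal noise column as a reference
predictor.

The importance computation is done directly (own bootstrap over
``DecisionTreeRegressor`` trees, OOB permutation) so the scores do not
depend on any specific forest implementation's internals.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from sklearn.tree import DecisionTreeRegressor

from .dynamics import ar1_deviates, recruitment_pulse, age_advance
from .life_history import unfished_numbers_at_age
from .metrics import steady_state_metrics
from .params import FEMALE, GsaSample, sample_gsa_parameters
from .predation import build_kernel

__all__ = ["GsaResult", "run_gsa", "simulate_gsa_draws", "oob_permutation_importance"]

OUTCOMES = ("mean_ssb", "stability", "plus_group_proportion")


@dataclass
class GsaResult:
    """Importance table plus the raw per-draw outcomes."""

    importance: pd.DataFrame  # rows: parameters + "noise"; cols: outcomes
    outcomes: pd.DataFrame  # per-draw parameters and outcome values
    n_draws: int
    seed: int
    n_skipped: int = 0

    def ranking(self, outcome: str) -> list[str]:
        """Parameter names sorted by decreasing importance for ``outcome``."""
        return list(self.importance[outcome].sort_values(ascending=False).index)


def _draw_kernel(system, sample: GsaSample):
    pred_sched = system.predator
    if sample["Y95"] != pred_sched.species.diet_Y95:
        sp = pred_sched.species.replace(diet_Y95=float(sample["Y95"]))
        pred_sched = dataclasses.replace(pred_sched, species=sp)
    return build_kernel(
        system.prey,
        pred_sched,
        gamma=float(sample["gamma"]),
        delta=float(sample["delta"]),
        q_scale=float(sample["q_scale"]) * system.q_scale,
    )


def simulate_gsa_draws(
    system,
    samples: list[GsaSample],
    n_years: int = 450,
    window: int = 150,
    rtol: float = 1e-6,
    atol: float = 1e-8,
) -> pd.DataFrame:
    """One stochastic unfished simulation per draw, batched into one ODE.

    Returns a tidy frame with one row per draw: the drawn parameter values
    and the three steady-state outcomes.  Failed draws get NaN outcomes.
    """
    prey, pred = system.prey, system.predator
    sp_prey, sp_pred = prey.species, pred.species
    I = prey.n_ages
    A_pred, S = pred.length.shape
    P = A_pred * S

    # Build kernels; draws whose kernel is infeasible (per-predator demand
    # exceeding the reference prey pool) are recorded and skipped.
    kernels, kept, failed = [], [], []
    for d, s in enumerate(samples):
        try:
            kernels.append(_draw_kernel(system, s))
            kept.append(d)
        except ValueError:
            failed.append(d)
    samples_all = samples
    samples = [samples_all[d] for d in kept]
    D = len(samples)
    if D == 0:
        raise RuntimeError("every GSA draw produced an infeasible kernel")
    A3 = np.stack([k.a for k in kernels])  # (D, I, P)
    delta = np.array([k.delta for k in kernels])[:, None]
    dq = np.array([k.delta * k.q for k in kernels])[:, None]

    # Per-draw recruitment deviates; the per-draw seed is part of the draw.
    T = n_years
    eps_Y = np.empty((D, T))
    eps_L = np.empty((D, T))
    sigma = np.empty(D)
    for d, s in enumerate(samples):
        rng = np.random.default_rng(s.seed)
        sigma[d] = s["sigma"]
        eps_Y[d] = ar1_deviates(s["rho_Y"], sigma[d], T, rng).eps[0]
        eps_L[d] = ar1_deviates(s["rho_L"], sigma[d], T, rng).eps[0]

    Y = np.repeat(unfished_numbers_at_age(prey)[:, FEMALE][None, :] * 1.5, D, axis=0)
    L = np.repeat(unfished_numbers_at_age(pred)[None, ...] * 1.5, D, axis=0)

    M_pred = np.array(sp_pred.natural_mortality)[None, None, :]
    Z_L = np.broadcast_to(M_pred, (1, A_pred, S)).reshape(1, P)  # F = 0
    surv_L = np.exp(-Z_L)
    MY = sp_prey.natural_mortality[FEMALE]

    Wm_Y = prey.weight[:, FEMALE] * prey.maturity[:, FEMALE]
    Wm_L = pred.weight[:, FEMALE] * pred.maturity[:, FEMALE]

    ssb_Y = np.empty((D, T))
    plus = np.empty((D, T))

    def rhs(t, y):
        Yt = y.reshape(D, I)
        Lt = L.reshape(D, P) * np.exp(-Z_L * t)
        u = np.einsum("dip,di->dp", A3, Yt)
        denom = 1.0 + delta * u + dq
        rate = np.einsum("dip,dp->di", A3, Lt / denom)
        return (-(MY + rate) * Yt).ravel()

    for k in range(T):
        S_Y = Y @ Wm_Y
        S_L = L[:, :, FEMALE] @ Wm_L
        ssb_Y[:, k] = S_Y
        tot = Y.sum(axis=1)
        plus[:, k] = np.divide(Y[:, -1], tot, out=np.zeros(D), where=tot > 0)

        sol = solve_ivp(rhs, (0.0, 1.0), Y.ravel(), method="RK45", rtol=rtol, atol=atol)
        if not sol.success:
            raise RuntimeError(f"GSA batch integration failed: {sol.message}")
        Y = np.maximum(sol.y[:, -1].reshape(D, I), 0.0)
        L = L * surv_L.reshape(1, A_pred, S)

        # sigma varies per draw, so apply the bias-corrected multiplier here
        r_Y = recruitment_pulse(S_Y, prey.alpha, prey.beta) * np.exp(eps_Y[:, k] - 0.5 * sigma**2)
        r_L = recruitment_pulse(S_L, pred.alpha, pred.beta) * np.exp(eps_L[:, k] - 0.5 * sigma**2)
        Y = age_advance(Y[:, :, None], r_Y[:, None])[:, :, 0]
        L = age_advance(L, 0.5 * r_L[:, None] * np.ones((1, 2)))

    rows = []
    for d, s in enumerate(samples):
        m = steady_state_metrics(ssb_Y[d], plus[d], window=window)
        rows.append(
            {**{k: s[k] for k in s.values}, "draw": s.index, "sim_seed": s.seed,
             "mean_ssb": m.mean_ssb, "stability": m.stability,
             "plus_group_proportion": m.plus_group_proportion}
        )
    for d in failed:
        s = samples_all[d]
        rows.append(
            {**{k: s[k] for k in s.values}, "draw": s.index, "sim_seed": s.seed,
             "mean_ssb": np.nan, "stability": np.nan,
             "plus_group_proportion": np.nan}
        )
    return pd.DataFrame(rows).sort_values("draw", ignore_index=True)


def oob_permutation_importance(
    X: np.ndarray,
    y: np.ndarray,
    n_trees: int = 500,
    seed: int = 0,
    max_features=None,
) -> np.ndarray:
    """%IncMSE per feature from a bagged-tree ensemble.

    For each bootstrap tree the MSE on its out-of-bag samples is compared
    with the MSE after permuting one feature; the mean increase across trees
    is reported as a percentage of the mean OOB MSE.  Negative values occur
    when a feature is less predictive than noise.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if max_features is None:
        max_features = max(1, p // 3)  # regression-forest convention
    rng = np.random.default_rng(seed)
    base_mses = []
    increases = np.zeros((n_trees, p))
    used = np.zeros(n_trees, dtype=bool)
    for t in range(n_trees):
        boot = rng.integers(0, n, n)
        oob = np.setdiff1d(np.arange(n), boot)
        if oob.size == 0:
            continue
        tree = DecisionTreeRegressor(
            max_features=max_features, random_state=int(rng.integers(2**31 - 1))
        )
        tree.fit(X[boot], y[boot])
        pred = tree.predict(X[oob])
        base = np.mean((y[oob] - pred) ** 2)
        base_mses.append(base)
        used[t] = True
        for f in range(p):
            Xp = X[oob].copy()
            Xp[:, f] = Xp[rng.permutation(oob.size), f]
            mse_p = np.mean((y[oob] - tree.predict(Xp)) ** 2)
            increases[t, f] = mse_p - base
    denom = np.mean(base_mses)
    if denom == 0:
        return np.zeros(p)
    return 100.0 * increases[used].mean(axis=0) / denom


def run_gsa(
    system,
    n: int = 2000,
    bounds: dict | None = None,
    seed: int = 0,
    n_years: int = 450,
    window: int = 150,
    n_trees: int = 500,
) -> GsaResult:
    """Full GSA: sample, simulate (F = 0), fit, score.

    Draws with undefined outcomes (e.g. an extinct trajectory with no
    variability) are skipped for the affected outcome and counted.
    """
    samples = sample_gsa_parameters(n, bounds=bounds, seed=seed)
    outcomes = simulate_gsa_draws(system, samples, n_years=n_years, window=window)
    param_names = list(samples[0].values)

    rng = np.random.default_rng(seed + 1)
    noise = rng.normal(size=len(outcomes))
    X_full = np.column_stack([outcomes[param_names].to_numpy(), noise])

    importance = {}
    n_skipped = 0
    for outcome in OUTCOMES:
        y = outcomes[outcome].to_numpy()
        ok = np.isfinite(y)
        n_skipped = max(n_skipped, int((~ok).sum()))
        importance[outcome] = oob_permutation_importance(
            X_full[ok], y[ok], n_trees=n_trees, seed=seed + 2
        )
    imp = pd.DataFrame(importance, index=param_names + ["noise"])
    return GsaResult(
        importance=imp, outcomes=outcomes, n_draws=n, seed=seed, n_skipped=n_skipped
    )
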