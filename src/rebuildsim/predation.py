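"""Size-selective Holling type-II predation kernel.

Lingcod consume yelloweye within a gape-limitation window given by the 5th
and 95th quantile slopes of the predator diet size spectra: an age-i prey of
length ``l_i`` is acceptable to a predator of length ``l_p`` iff
``Y5 * l_p <= l_i <= Y95 * l_p``.  The per-capita attack-rate array
``a[i, p]`` (prey age i, predator class p = age x sex) is reconstructed from
three ingredients: the predator's annual ration ``C = a_c W^b_c``, the gape
window, and the prey-specialization parameter ``gamma`` (the proportion of
consumed biomass that is yelloweye).  Annual per-predator consumed
proportions at a fixed reference prey state are converted to instantaneous
rates, and the alternate-prey availability ``q`` is set from the (1-gamma)
diet share so that alternate prey occupy the predator in proportion to the
rest of its ration.

The realized predation mortality on prey age i is the type-II response

    rate_i = sum_p a[i, p] L_p / (1 + delta * sum_i' a[i', p] Y_i' + delta q)

with handling time ``delta``.  Because the reconstruction of the kernel's
absolute scale is not identifiable from the printed parameter table alone,
``q_scale`` multiplies q and is set by the calibration in
:mod:`rebuildsim.scenarios` (see docs/methods.md).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .life_history import LifeHistorySchedules, unfished_numbers_at_age
from .params import FEMALE, SEX_LABELS

__all__ = [
    "size_preference",
    "annual_consumption",
    "PredationKernel",
    "build_kernel",
    "predation_mortality",
]


def size_preference(prey_length, predator_length, Y5: float, Y95: float):
    """Gape-limitation indicator: 1 iff Y5*pred <= prey <= Y95*pred.

    Accepts scalars or arrays (broadcast); boundaries are inclusive.
    """
    if Y5 >= Y95:
        raise ValueError("Y5 must be below Y95")
    prey = np.asarray(prey_length, dtype=float)
    pred = np.asarray(predator_length, dtype=float)
    if np.any(prey <= 0) or np.any(pred <= 0):
        raise ValueError("lengths must be positive")
    # relative epsilon keeps the boundary inclusive under float rounding
    lo = Y5 * pred * (1.0 - 1e-12)
    hi = Y95 * pred * (1.0 + 1e-12)
    return ((prey >= lo) & (prey <= hi)).astype(float)


def annual_consumption(weight, a_c: float, b_c: float):
    """Annual ration (kg/yr) of a predator of ``weight`` kg: a_c * W**b_c."""
    weight = np.asarray(weight, dtype=float)
    if np.any(weight <= 0):
        raise ValueError("weight must be positive")
    return a_c * weight**b_c


@dataclass
class PredationKernel:
    """Attack-rate array plus functional-response constants.

    ``a`` has shape (n_prey_ages, n_predator_classes); predator classes
    enumerate (age, sex) pairs in the order given by ``pred_age`` /
    ``pred_sex``.
    """

    a: np.ndarray  # (I, P) instantaneous per-capita attack rates (yr^-1)
    pref: np.ndarray  # (I, P) gape-window indicator
    delta: float  # handling time (yr)
    q: float  # alternate-prey availability (units of sum a*Y)
    gamma: float  # yelloweye share of consumed biomass
    pred_age: np.ndarray  # (P,) predator age class
    pred_sex: np.ndarray  # (P,) predator sex index
    reference_prey: np.ndarray  # (I,) prey numbers used for calibration

    @property
    def is_zero(self) -> bool:
        return self.gamma == 0.0 or not np.any(self.a)

    def to_frame(self) -> pd.DataFrame:
        """Long-format (prey_age, pred_age, pred_sex, a) table."""
        I, P = self.a.shape
        prey_age = np.repeat(np.arange(1, I + 1), P)
        return pd.DataFrame(
            {
                "prey_age": prey_age,
                "pred_age": np.tile(self.pred_age, I),
                "pred_sex": np.tile([SEX_LABELS[s] for s in self.pred_sex], I),
                "a": self.a.ravel(),
            }
        )


def build_kernel(
    prey: LifeHistorySchedules,
    predator: LifeHistorySchedules,
    gamma: float,
    delta: float | None = None,
    q_scale: float = 1.0,
    reference_prey: np.ndarray | None = None,
    allocation: str = "biomass",
) -> PredationKernel:
    """Construct the attack-rate array a[i, j, s] and the availability q.

    Procedure (per predator age/sex class):

    1. gape window from :func:`size_preference` using the predator's diet
       quantile slopes;
    2. target annual yelloweye biomass intake gamma * C(W);
    3. allocation of that biomass across acceptable prey ages, proportional
       to available prey biomass at the reference state (``allocation =
       "biomass"``) or uniformly (``"uniform"``);
    4. per-age annual consumed proportion p = allocated biomass / reference
       prey biomass, converted to an instantaneous rate a = -ln(1 - p);
    5. q chosen so the alternate-prey handling term delta*q equals
       delta*(1-gamma)/gamma times the yelloweye handling term
       delta * sum_i a_i Y_i^ref averaged over predator classes, times
       ``q_scale``.

    The default reference prey state is the deterministic unfished
    no-predation stable age distribution (R0-scaled).
    """
    if gamma < 0 or gamma > 1:
        raise ValueError("gamma must lie in [0, 1]")
    sp = predator.species
    if sp.diet_Y5 is None or sp.consumption_a is None:
        raise ValueError(f"{sp.name} has no consumption/diet parameterization")
    if delta is None:
        delta = sp.handling_time
    if delta is None or delta < 0:
        raise ValueError("handling time delta must be >= 0")
    if allocation not in ("biomass", "uniform"):
        raise ValueError("allocation must be 'biomass' or 'uniform'")

    if reference_prey is None:
        reference_prey = unfished_numbers_at_age(prey)[:, FEMALE]
    Y_ref = np.asarray(reference_prey, dtype=float)

    I = prey.n_ages
    A, S = predator.length.shape
    pred_age = np.repeat(predator.ages, S)
    pred_sex = np.tile(np.arange(S), A)
    P = A * S

    prey_len = prey.length[:, FEMALE]
    prey_W = prey.weight[:, FEMALE]
    pred_len = predator.length.ravel()  # matches (age, sex) enumeration
    pred_W = predator.weight.ravel()
    cons_a = np.array([sp.consumption_a[s] for s in pred_sex])
    cons_b = np.array([sp.consumption_b[s] for s in pred_sex])

    pref = size_preference(prey_len[:, None], pred_len[None, :], sp.diet_Y5, sp.diet_Y95)

    if gamma == 0.0:
        a = np.zeros((I, P))
        return PredationKernel(a, pref, delta, 0.0, gamma, pred_age, pred_sex, Y_ref)

    if not np.any(np.sum(pref * (Y_ref[:, None] > 0), axis=0)):
        warnings.warn(
            "gamma > 0 but the gape window is empty for every predator class; "
            "returning a zero kernel",
            stacklevel=2,
        )
        a = np.zeros((I, P))
        return PredationKernel(a, pref, delta, 0.0, gamma, pred_age, pred_sex, Y_ref)

    C = annual_consumption(pred_W, cons_a, cons_b)  # (P,) kg/yr
    target = gamma * C  # annual yelloweye biomass per predator

    ref_biomass = prey_W * Y_ref  # (I,) kg available at reference
    if allocation == "biomass":
        w = pref * ref_biomass[:, None]
    else:
        w = pref * (ref_biomass[:, None] > 0)
    totals = w.sum(axis=0)
    ok = totals > 0
    share = np.zeros_like(w)
    share[:, ok] = w[:, ok] / totals[ok]

    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(
            ref_biomass[:, None] > 0,
            target[None, :] * share / ref_biomass[:, None],
            0.0,
        )
    if np.any(p >= 1.0):
        raise ValueError(
            "annual per-predator demand meets or exceeds available prey in at "
            "least one age class (p >= 1); reduce gamma or increase the "
            "reference prey abundance"
        )
    a = -np.log1p(-p)

    # Alternate prey occupy the predator in proportion to their (1 - gamma)
    # diet share; a single global q averaged over predator classes.
    yelloweye_term = a.T @ Y_ref  # (P,) sum_i a_i Y_i at reference
    q = q_scale * delta * (1.0 - gamma) / gamma * float(np.mean(yelloweye_term[ok]))
    return PredationKernel(a, pref, delta, q, gamma, pred_age, pred_sex, Y_ref)


def predation_mortality(Y, L, kernel: PredationKernel) -> np.ndarray:
    """Instantaneous predation mortality rate (yr^-1) per prey age.

    ``Y``: prey numbers-at-age (I,); ``L``: predator numbers, either flat
    (P,) in kernel class order or (A, S).  Implements the type-II response
    rate_i = sum_p a[i,p] L_p / (1 + delta sum_i' a[i',p] Y_i' + delta q).
    """
    Y = np.asarray(Y, dtype=float)
    L = np.asarray(L, dtype=float).ravel()
    if np.any(Y < 0) or np.any(L < 0):
        raise ValueError("abundances must be >= 0")
    if kernel.is_zero:
        return np.zeros_like(Y)
    denom = 1.0 + kernel.delta * (Y @ kernel.a) + kernel.delta * kernel.q  # (P,)
    return kernel.a @ (L / denom)
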