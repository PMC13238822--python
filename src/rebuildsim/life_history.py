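"""Per-age life-history schedules and Beverton-Holt parameterization.

Builds length, weight, maturity and fishery-vulnerability schedules from a
:class:`~rebuildsim.params.SpeciesParams`, computes unfished spawning biomass
per recruit (phi) and derives the Beverton-Holt alpha/beta from steepness.

Conventions
-----------
* von Bertalanffy growth with t0 = 0: L(a) = L_inf * (1 - exp(-k a)).
* Fishery vulnerability is knife-edge and boundary-inclusive:
  length >= L_min is fully vulnerable.
* Survivorship for phi uses l_1 = 1 at age 1 with geometric plus-group
  closure, matching spawning biomass measured at the annual pulse instant
  (start of year).  For sex-structured species phi is spawning biomass of
  mature females per *total* age-1 recruit, i.e. the 0.5 birth sex ratio is
  folded into phi so that S0 = R0 * phi holds in simulation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import FEMALE, SEX_LABELS, SpeciesParams

__all__ = [
    "length_at_age",
    "weight_at_age",
    "vulnerability_at_age",
    "maturity_at_age",
    "LifeHistorySchedules",
    "build_schedules",
    "spawning_biomass_per_recruit",
    "bh_parameters",
]


def length_at_age(age, k: float, L_inf: float):
    """von Bertalanffy length (cm) at ``age`` years, t0 = 0."""
    if k <= 0 or L_inf <= 0:
        raise ValueError("k and L_inf must be positive")
    age = np.asarray(age, dtype=float)
    if np.any(age < 0):
        raise ValueError("age must be >= 0")
    return L_inf * (1.0 - np.exp(-k * age))


def weight_at_age(length, a_w: float, b_w: float):
    """Allometric weight (kg) from length (cm): a_w * length**b_w."""
    length = np.asarray(length, dtype=float)
    if np.any(length < 0):
        raise ValueError("length must be >= 0")
    return a_w * length**b_w


def vulnerability_at_age(length, L_min: float):
    """Knife-edge fishery vulnerability: 1 iff length >= L_min (inclusive)."""
    length = np.asarray(length, dtype=float)
    return (length >= L_min).astype(float)


def maturity_at_age(age, a50: float, slope: float):
    """Logistic maturity ogive; equals 0.5 at ``a50``."""
    if slope <= 0:
        raise ValueError("maturity slope must be positive")
    age = np.asarray(age, dtype=float)
    return 1.0 / (1.0 + np.exp(-slope * (age - a50)))


@dataclass
class LifeHistorySchedules:
    """Per-age (and per-sex) schedules plus derived recruitment scalars.

    Arrays have shape ``(n_ages, n_sexes)`` with ages 1..plus_group_age along
    axis 0 and sexes ordered (female, male); sex-aggregated species have a
    single column.
    """

    species: SpeciesParams
    ages: np.ndarray  # (A,) integer ages 1..A
    length: np.ndarray  # (A, S) cm
    weight: np.ndarray  # (A, S) kg
    maturity: np.ndarray  # (A, S) proportion
    vulnerability: np.ndarray  # (A, S) in {0, 1}
    phi: float  # unfished spawning biomass per recruit (kg)
    alpha: float  # BH recruits per unit spawning biomass at low biomass
    beta: float  # BH density-dependence strength (kg^-1)

    @property
    def n_ages(self) -> int:
        return self.ages.size

    @property
    def S0(self) -> float:
        """Unfished spawning biomass implied per-recruit: R0 * phi (kg)."""
        return self.species.R0 * self.phi

    def to_frame(self) -> pd.DataFrame:
        """Tidy (age, sex, length, weight, maturity, vulnerability) table."""
        rows = []
        for s in range(self.length.shape[1]):
            label = SEX_LABELS[s] if self.species.sex_structured else "both"
            rows.append(
                pd.DataFrame(
                    {
                        "age": self.ages,
                        "sex": label,
                        "length_cm": self.length[:, s],
                        "weight_kg": self.weight[:, s],
                        "maturity": self.maturity[:, s],
                        "vulnerability": self.vulnerability[:, s],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def _survivorship(Z: np.ndarray) -> np.ndarray:
    """Start-of-year survivorship l_1 = 1, l_{a+1} = l_a exp(-Z_a).

    ``Z`` is the (A,) total instantaneous mortality at age; the returned
    vector excludes the plus-group geometric closure (handled by callers).
    """
    l = np.ones_like(Z)
    l[1:] = np.cumprod(np.exp(-Z[:-1]))
    return l


def spawning_biomass_per_recruit(
    schedules_or_params,
    F: float = 0.0,
) -> float:
    """Spawning biomass per recruit (kg) at fishing rate ``F``.

    phi = sum_a l_a W_a m_a over spawning ages with plus-group closure
    l_A e^{-Z_A} / (1 - e^{-Z_A}) W_A m_A.  Natural mortality only at F = 0
    (no predation).  For sex-structured species only mature females spawn and
    phi is per total recruit (0.5 factor applied here).
    """
    sched = schedules_or_params
    if isinstance(sched, SpeciesParams):
        sched = build_schedules(sched)
    sp = sched.species
    M = sp.natural_mortality[FEMALE]
    if M <= 0:
        raise ValueError("natural mortality must be positive")
    Z = M + sched.vulnerability[:, FEMALE] * F
    l = _survivorship(Z)
    W = sched.weight[:, FEMALE]
    m = sched.maturity[:, FEMALE]
    phi = float(np.sum(l * W * m))
    zA = Z[-1]
    phi += float(l[-1] * np.exp(-zA) / (1.0 - np.exp(-zA)) * W[-1] * m[-1])
    if sp.sex_structured:
        phi *= 0.5
    return phi


def bh_parameters(h: float, R0: float, phi: float) -> tuple[float, float]:
    """Beverton-Holt (alpha, beta) from steepness, R0 and phi.

    alpha = 4h / ((1-h) phi); beta = (5h-1) / ((1-h) phi R0).  Satisfies
    R(S0) = R0 and R(0.2 S0) = h R0 exactly.  h = 1 (recruitment independent
    of spawning biomass) is not representable with finite alpha and raises.
    """
    if h <= 0.2:
        raise ValueError("steepness must exceed 0.2")
    if h >= 1.0:
        raise ValueError(
            "h = 1 implies constant recruitment (infinite alpha); "
            "use a constant-recruitment mode instead"
        )
    if phi <= 0 or R0 <= 0:
        raise ValueError("phi and R0 must be positive")
    alpha = 4.0 * h / ((1.0 - h) * phi)
    beta = (5.0 * h - 1.0) / ((1.0 - h) * phi * R0)
    return alpha, beta


def unfished_numbers_at_age(sched: LifeHistorySchedules, F: float = 0.0) -> np.ndarray:
    """Deterministic no-predation stable age distribution, shape (A, S).

    Start-of-year numbers per year-class of R0 recruits (0.5 R0 per sex for
    sex-structured species), with geometric plus-group closure, at fishing
    rate ``F`` and mean recruitment.
    """
    sp = sched.species
    A, S = sched.length.shape
    N = np.empty((A, S))
    recruits = sp.R0 * (0.5 if sp.sex_structured else 1.0)
    for s in range(S):
        M = sp.natural_mortality[s]
        Z = M + sched.vulnerability[:, s] * F
        l = _survivorship(Z)
        l[-1] /= 1.0 - np.exp(-Z[-1])
        N[:, s] = recruits * l
    return N


def build_schedules(species: SpeciesParams) -> LifeHistorySchedules:
    """Assemble full per-age schedules and derive phi, alpha, beta."""
    A = species.plus_group_age
    S = species.n_sexes
    ages = np.arange(1, A + 1)
    length = np.empty((A, S))
    weight = np.empty((A, S))
    maturity = np.empty((A, S))
    vulnerability = np.empty((A, S))
    for s in range(S):
        length[:, s] = length_at_age(ages, species.growth_k[s], species.L_inf[s])
        weight[:, s] = weight_at_age(length[:, s], species.weight_a[s], species.weight_b[s])
        maturity[:, s] = maturity_at_age(ages, species.maturity_a50, species.maturity_slope)
        vulnerability[:, s] = vulnerability_at_age(length[:, s], species.L_min_caught)

    sched = LifeHistorySchedules(
        species=species,
        ages=ages,
        length=length,
        weight=weight,
        maturity=maturity,
        vulnerability=vulnerability,
        phi=np.nan,
        alpha=np.nan,
        beta=np.nan,
    )
    sched.phi = spawning_biomass_per_recruit(sched, F=0.0)
    sched.alpha, sched.beta = bh_parameters(species.steepness, species.R0, sched.phi)
    return sched
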