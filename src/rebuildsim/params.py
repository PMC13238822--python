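"""Species parameterizations and random parameter draws.

This module is the single source of truth for the default lingcod
(*Ophiodon elongatus*) and yelloweye rockfish (*Sebastes ruberrimus*)
life-history, recruitment, consumption and fishery constants, for the
prey-specialization scenario grid, and for the uniform Monte-Carlo parameter
draws used by the global sensitivity analysis.

Sex-structured quantities are stored as length-2 arrays indexed
``[FEMALE, MALE]`` (``FEMALE = 0``).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

FEMALE = 0
MALE = 1
SEX_LABELS = ("F", "M")

__all__ = [
    "FEMALE",
    "MALE",
    "SEX_LABELS",
    "SpeciesParams",
    "GlobalParams",
    "GsaSample",
    "default_lingcod",
    "default_yelloweye",
    "default_globals",
    "default_parameters",
    "default_gsa_bounds",
    "sample_gsa_parameters",
]


@dataclass
class SpeciesParams:
    """Per-species life-history, recruitment and fishery constants.

    Rates are instantaneous annual rates (yr^-1), lengths in cm, weights in
    kg.  For sex-structured species every per-sex field holds
    ``(female, male)``; for sex-aggregated species both entries are equal and
    the female slot is read.
    """

    name: str
    sex_structured: bool
    natural_mortality: tuple[float, float]  # yr^-1, (F, M)
    steepness: float  # Beverton-Holt h, 0.2 < h <= 1
    R0: float  # recruits at carrying capacity
    growth_k: tuple[float, float]  # von Bertalanffy k (yr^-1)
    L_inf: tuple[float, float]  # asymptotic length (cm)
    weight_a: tuple[float, float]  # mass-length intercept (kg cm^-b)
    weight_b: tuple[float, float]  # mass-length exponent
    L_min_caught: float  # minimum length captured by the fishery (cm)
    plus_group_age: int  # terminal absorbing age class
    maturity_a50: float  # age at 50% maturity (yr)
    maturity_slope: float  # logistic slope (yr^-1)
    recruit_rho: float  # lag-1 autocorrelation of recruitment deviates
    recruit_sigma: float  # SD of log recruitment deviates
    # Consumption allometry (predators only): annual ration = a * W^b (kg/yr)
    consumption_a: tuple[float, float] | None = None
    consumption_b: tuple[float, float] | None = None
    # Diet size-spectra quantile slopes (predators only)
    diet_Y5: float | None = None
    diet_Y95: float | None = None
    handling_time: float | None = None  # Holling type-II delta (yr)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for label, pair in (
            ("natural_mortality", self.natural_mortality),
            ("growth_k", self.growth_k),
            ("L_inf", self.L_inf),
            ("weight_a", self.weight_a),
            ("weight_b", self.weight_b),
        ):
            if any(v <= 0 for v in pair):
                raise ValueError(f"{self.name}: {label} must be positive, got {pair}")
        if not 0.2 < self.steepness <= 1.0:
            raise ValueError(
                f"{self.name}: steepness must satisfy 0.2 < h <= 1, got {self.steepness}"
            )
        if self.R0 <= 0:
            raise ValueError(f"{self.name}: R0 must be positive")
        if not abs(self.recruit_rho) < 1:
            raise ValueError(f"{self.name}: |rho| must be < 1")
        if self.recruit_sigma < 0:
            raise ValueError(f"{self.name}: sigma must be >= 0")
        if self.plus_group_age < 2:
            raise ValueError(f"{self.name}: plus-group age must be >= 2")
        if self.L_min_caught >= max(self.L_inf):
            raise ValueError(f"{self.name}: L_min_caught must be below L_inf")
        if self.maturity_slope <= 0:
            raise ValueError(f"{self.name}: maturity slope must be positive")
        if self.diet_Y5 is not None and self.diet_Y95 is not None:
            if self.diet_Y5 >= self.diet_Y95:
                raise ValueError(f"{self.name}: diet_Y5 must be below diet_Y95")

    @property
    def n_sexes(self) -> int:
        return 2 if self.sex_structured else 1

    def replace(self, **changes) -> "SpeciesParams":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class GlobalParams:
    """Scenario grid constants shared across species."""

    gamma_scenarios: dict[str, float] = field(
        default_factory=lambda: {
            "none": 0.0,
            "generalist": 0.001,
            "intermediate": 0.014,
            "specialist": 0.05,
        }
    )
    bycatch: float = 0.05  # yelloweye fishing rate as a fraction of lingcod F
    F_grid: np.ndarray = field(default_factory=lambda: np.linspace(0.0, 0.4, 41))
    #: alternate-prey availability multiplier; None means "condition at run
    #: time on the specialist reference depletion" (see rebuildsim.scenarios)
    q_scale: float | None = None

    def to_dict(self) -> dict:
        return {
            "gamma_scenarios": dict(self.gamma_scenarios),
            "bycatch": self.bycatch,
            "F_grid": np.asarray(self.F_grid).tolist(),
            "q_scale": self.q_scale,
        }


def default_lingcod() -> SpeciesParams:
    """Default lingcod parameterization (southern-stock assessment values)."""
    return SpeciesParams(
        name="lingcod",
        sex_structured=True,
        natural_mortality=(0.18, 0.32),
        steepness=0.8,
        R0=4848.0,
        growth_k=(0.191, 0.214),
        L_inf=(100.9, 86.3),
        weight_a=(3.308e-6, 2.179e-6),
        weight_b=(3.248, 3.36),
        L_min_caught=56.0,
        plus_group_age=20,
        maturity_a50=4.0,  # midpoint of the reported 3-5 yr female range
        maturity_slope=0.5,
        recruit_rho=0.23,
        recruit_sigma=0.5,
        consumption_a=(3.31, 3.01),
        consumption_b=(0.71, 0.77),
        diet_Y5=0.05,
        diet_Y95=0.29,
        handling_time=0.3,
    )


def default_yelloweye() -> SpeciesParams:
    """Default yelloweye rockfish parameterization (sex-aggregated)."""
    return SpeciesParams(
        name="yelloweye",
        sex_structured=False,
        natural_mortality=(0.044, 0.044),
        steepness=0.718,
        R0=220.0,
        growth_k=(0.049, 0.049),
        L_inf=(63.9, 63.9),
        weight_a=(7.313e-6, 7.313e-6),
        weight_b=(3.242, 3.242),
        L_min_caught=25.0,
        plus_group_age=65,
        maturity_a50=17.5,  # midpoint of the reported 15-20 yr range
        maturity_slope=0.5,
        recruit_rho=0.23,
        recruit_sigma=0.5,
    )


def default_globals() -> GlobalParams:
    return GlobalParams()


def default_parameters() -> tuple[SpeciesParams, SpeciesParams, GlobalParams]:
    """Return (lingcod, yelloweye, globals) with the printed default values.

    Idempotent: repeated calls return bit-identical values.
    """
    return default_lingcod(), default_yelloweye(), default_globals()


# ---------------------------------------------------------------------------
# Global sensitivity analysis sampling
# ---------------------------------------------------------------------------

#: Parameters varied in the GSA and their default uniform bounds.  Bounds are
#: +/-50% of each default value, except that parameters whose admissible
#: range is itself the object of interest span that range: gamma covers the
#: full none-to-beyond-specialist interval [0, 0.1] and the recruitment
#: deviate autocorrelations cover the stationary range [0, 0.9].  The
#: q-scale multiplier varies around its conditioned value.
GSA_PARAMETERS = ("gamma", "delta", "q_scale", "sigma", "rho_L", "rho_Y", "Y95")


def default_gsa_bounds() -> dict[str, tuple[float, float]]:
    return {
        "gamma": (0.0, 0.1),
        "delta": (0.15, 0.45),
        "q_scale": (0.5, 1.5),
        "sigma": (0.25, 0.75),
        "rho_L": (0.0, 0.9),
        "rho_Y": (0.0, 0.9),
        "Y95": (0.145, 0.435),
    }


@dataclass
class GsaSample:
    """One Monte-Carlo parameter draw for the global sensitivity analysis."""

    values: dict[str, float]
    index: int
    seed: int

    def __getitem__(self, key: str) -> float:
        return self.values[key]


def sample_gsa_parameters(
    n: int,
    bounds: dict[str, tuple[float, float]] | None = None,
    seed: int | None = None,
) -> list[GsaSample]:
    """Draw ``n`` independent uniform parameter sets for the GSA.

    Each coordinate is uniform on its ``(lo, hi)`` bounds; draws are
    reproducible under a fixed ``seed``.  Raises on unknown parameter names
    or non-increasing bounds.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if bounds is None:
        bounds = default_gsa_bounds()
    for name, (lo, hi) in bounds.items():
        if name not in GSA_PARAMETERS:
            raise KeyError(f"unknown GSA parameter {name!r}")
        if not lo < hi:
            raise ValueError(f"bounds for {name!r} must satisfy lo < hi, got ({lo}, {hi})")
    rng = np.random.default_rng(seed)
    names = list(bounds)
    lo = np.array([bounds[k][0] for k in names])
    hi = np.array([bounds[k][1] for k in names])
    draws = rng.uniform(lo, hi, size=(n, len(names)))
    # Per-draw stochastic-simulation seeds are part of the draw.
    sim_seeds = rng.integers(0, 2**31 - 1, size=n)
    return [
        GsaSample(values=dict(zip(names, row)), index=i, seed=int(sim_seeds[i]))
        for i, row in enumerate(draws)
    ]
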