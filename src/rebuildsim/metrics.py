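"""Steady-state and rebuilding outcome measures.

Long-term outcomes are computed over the last ``window`` years of each
trajectory: mean spawning biomass, stability (the inverse of the mean
temporal coefficient of variation of annual spawning biomass), and the mean
share of total numbers in the plus group.  The transient outcome is
rebuilding time: the first rebuilding-phase year at which spawning biomass
reaches 40% of the scenario's deterministic unfished level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SteadyStateMetrics",
    "RebuildingResult",
    "steady_state_metrics",
    "rebuilding_time",
    "relative_change",
]


@dataclass
class SteadyStateMetrics:
    """Pooled steady-state summaries plus per-replicate values.

    ``stability`` is 1 / mean(per-replicate temporal CV); CVs use the
    population (ddof = 0) standard deviation.  A constant series has CV = 0
    and stability is reported as missing (NaN) rather than infinite.
    """

    mean_ssb: float
    stability: float
    plus_group_proportion: float
    window: int
    per_replicate_mean_ssb: np.ndarray
    per_replicate_cv: np.ndarray
    per_replicate_plus: np.ndarray


def steady_state_metrics(
    ssb: np.ndarray,
    plus_prop: np.ndarray | None = None,
    window: int = 150,
) -> SteadyStateMetrics:
    """Summaries over the last ``window`` years of (R, T) trajectories."""
    ssb = np.atleast_2d(np.asarray(ssb, dtype=float))
    if window > ssb.shape[1]:
        raise ValueError("window longer than trajectory")
    tail = ssb[:, -window:]
    mean_rep = tail.mean(axis=1)
    sd_rep = tail.std(axis=1, ddof=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv_rep = np.where(mean_rep > 0, sd_rep / mean_rep, np.nan)
    mean_cv = float(np.nanmean(cv_rep)) if np.any(np.isfinite(cv_rep)) else np.nan
    stability = 1.0 / mean_cv if mean_cv > 0 else np.nan

    if plus_prop is not None:
        plus_prop = np.atleast_2d(np.asarray(plus_prop, dtype=float))
        plus_rep = plus_prop[:, -window:].mean(axis=1)
        plus_pooled = float(np.nanmean(plus_rep)) if np.any(np.isfinite(plus_rep)) else np.nan
    else:
        plus_rep = np.full(ssb.shape[0], np.nan)
        plus_pooled = np.nan

    return SteadyStateMetrics(
        mean_ssb=float(mean_rep.mean()),
        stability=stability,
        plus_group_proportion=plus_pooled,
        window=window,
        per_replicate_mean_ssb=mean_rep,
        per_replicate_cv=cv_rep,
        per_replicate_plus=plus_rep,
    )


@dataclass
class RebuildingResult:
    """Per-replicate years to reach the rebuilding threshold.

    ``times`` holds NaN for replicates that never reach the threshold within
    the phase; those are censored at the phase length, counted in
    ``n_censored`` and excluded from the mean/SD.
    """

    times: np.ndarray
    mean: float
    sd: float
    threshold: float
    n_censored: int
    horizon: int


def rebuilding_time(
    rebuild_ssb: np.ndarray,
    S0: float,
    threshold: float = 0.4,
) -> RebuildingResult:
    """First rebuilding-phase year (1-based) with SSB >= threshold * S0.

    ``rebuild_ssb`` is (R, T_rebuild) with year 1 = first rebuilding year.
    """
    ssb = np.atleast_2d(np.asarray(rebuild_ssb, dtype=float))
    R, T = ssb.shape
    level = threshold * S0
    reached = ssb >= level
    any_reached = reached.any(axis=1)
    first = np.argmax(reached, axis=1) + 1.0
    times = np.where(any_reached, first, np.nan)
    n_cens = int(R - any_reached.sum())
    ok = times[~np.isnan(times)]
    return RebuildingResult(
        times=times,
        mean=float(ok.mean()) if ok.size else np.nan,
        sd=float(ok.std(ddof=0)) if ok.size else np.nan,
        threshold=level,
        n_censored=n_cens,
        horizon=T,
    )


def relative_change(metric_scenario: float, metric_baseline: float) -> float:
    """Percent change of a scenario outcome relative to a baseline.

    100 * (scenario - baseline) / baseline; decreases are negative.
    """
    if metric_baseline == 0:
        raise ZeroDivisionError("baseline metric is zero")
    return 100.0 * (metric_scenario - metric_baseline) / metric_baseline
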