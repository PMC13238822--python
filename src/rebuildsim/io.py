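"""Configuration loading, tidy output tables, and run manifests."""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .metrics import rebuilding_time, steady_state_metrics
from .params import GlobalParams, SpeciesParams, default_parameters
from .scenarios import ScenarioResult

__all__ = [
    "load_config",
    "apply_override",
    "summarize_scenario",
    "scenario_table",
    "RunManifest",
    "write_outputs",
]

_SPECIES_KEYS = ("lingcod", "yelloweye")
_ALIASES = {
    "M": "natural_mortality",
    "h": "steepness",
    "sigma": "recruit_sigma",
    "rho": "recruit_rho",
    "delta": "handling_time",
}
_PAIRED_FIELDS = {
    "natural_mortality", "growth_k", "L_inf", "weight_a", "weight_b",
    "consumption_a", "consumption_b",
}


def _apply_species_block(base: SpeciesParams, block: dict) -> SpeciesParams:
    changes = {}
    for key, value in block.items():
        name = _ALIASES.get(key, key)
        if name not in base.__dataclass_fields__:
            raise KeyError(f"unknown field {key!r} for species {base.name!r}")
        if name in _PAIRED_FIELDS and np.isscalar(value):
            value = (float(value), float(value))
        elif isinstance(value, list):
            value = tuple(value)
        changes[name] = value
    return base.replace(**changes)


def load_config(path: str | Path | None = None, overrides: dict | None = None):
    """Load a YAML config; missing fields fall back to the printed defaults.

    The file holds one block per species plus an optional ``globals`` block;
    unknown keys are rejected with a field-level message.  ``overrides`` maps
    dotted paths (e.g. ``"yelloweye.M"``) to values and is applied last.
    An empty or absent file yields the full default parameterization.
    """
    lingcod, yelloweye, glob = default_parameters()
    raw = {}
    if path is not None:
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise ValueError("config root must be a mapping")
    for key in raw:
        if key not in (*_SPECIES_KEYS, "globals"):
            raise KeyError(f"unknown config section {key!r}")
    if overrides:
        for dotted, value in overrides.items():
            section, _, fieldname = dotted.partition(".")
            if not fieldname:
                raise KeyError(f"override {dotted!r} must be 'section.field'")
            raw.setdefault(section, {})[fieldname] = value

    if "lingcod" in raw:
        lingcod = _apply_species_block(lingcod, raw["lingcod"] or {})
    if "yelloweye" in raw:
        yelloweye = _apply_species_block(yelloweye, raw["yelloweye"] or {})
    if "globals" in raw:
        gblock = dict(raw["globals"] or {})
        gdict = glob.to_dict()
        for key, value in gblock.items():
            if key not in gdict:
                raise KeyError(f"unknown global field {key!r}")
            gdict[key] = value
        glob = GlobalParams(
            gamma_scenarios=dict(gdict["gamma_scenarios"]),
            bycatch=float(gdict["bycatch"]),
            F_grid=np.asarray(gdict["F_grid"], dtype=float),
            q_scale=None if gdict["q_scale"] is None else float(gdict["q_scale"]),
        )
    return lingcod, yelloweye, glob


def apply_override(config_tuple, dotted: str, value):
    """Return a new (lingcod, yelloweye, globals) with one dotted override."""
    lingcod, yelloweye, glob = config_tuple
    section, _, fieldname = dotted.partition(".")
    if section == "lingcod":
        return _apply_species_block(lingcod, {fieldname: value}), yelloweye, glob
    if section == "yelloweye":
        return lingcod, _apply_species_block(yelloweye, {fieldname: value}), glob
    if section == "globals":
        gdict = glob.to_dict()
        if fieldname not in gdict:
            raise KeyError(f"unknown global field {fieldname!r}")
        gdict[fieldname] = value
        return lingcod, yelloweye, GlobalParams(
            gamma_scenarios=dict(gdict["gamma_scenarios"]),
            bycatch=float(gdict["bycatch"]),
            F_grid=np.asarray(gdict["F_grid"], dtype=float),
            q_scale=None if gdict["q_scale"] is None else float(gdict["q_scale"]),
        )
    raise KeyError(f"unknown config section {section!r}")


# ---------------------------------------------------------------------------
# Output tables
# ---------------------------------------------------------------------------


def summarize_scenario(result: ScenarioResult, window: int = 150) -> dict:
    """Steady-state and rebuilding summaries for one scenario run."""
    out = result.output
    ss = steady_state_metrics(out.ssb_prey, out.plus_prop, window=window)
    rb = rebuilding_time(result.rebuild_ssb_prey, result.reference.S0_prey)
    return {
        "gamma": result.spec.gamma,
        "F": result.spec.F,
        "b": result.spec.b,
        "n_replicates": result.spec.n_replicates,
        "mean_ssb": ss.mean_ssb,
        "stability": ss.stability,
        "plus_group_proportion": ss.plus_group_proportion,
        "rebuild_mean": rb.mean,
        "rebuild_sd": rb.sd,
        "rebuild_censored": rb.n_censored,
        "S0_prey": result.reference.S0_prey,
        "S0_pred": result.reference.S0_pred,
        "F40": result.reference.F40,
    }


def scenario_table(results: list[ScenarioResult], window: int = 150) -> pd.DataFrame:
    return pd.DataFrame([summarize_scenario(r, window) for r in results])


def annual_table(results: list[ScenarioResult]) -> pd.DataFrame:
    """Per-scenario per-year replicate means of SSB and recruits."""
    frames = []
    for r in results:
        out = r.output
        frames.append(
            pd.DataFrame(
                {
                    "gamma": r.spec.gamma,
                    "F": r.spec.F,
                    "b": r.spec.b,
                    "year": np.arange(1, out.n_years + 1),
                    "ssb_prey_mean": out.ssb_prey.mean(axis=0),
                    "ssb_pred_mean": out.ssb_pred.mean(axis=0),
                    "plus_prop_mean": out.plus_prop.mean(axis=0),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def trajectory_table(output) -> pd.DataFrame:
    """Tidy (replicate, year, species, sex, age, N) table from a
    :class:`~rebuildsim.dynamics.SimulationOutput` recorded with
    ``record_ages=True``."""
    if output.N_prey is None or output.N_pred is None:
        raise ValueError("run the simulation with record_ages=True")
    frames = []
    R, T, I = output.N_prey.shape
    rep, yr, age = np.meshgrid(
        np.arange(R), np.arange(1, T + 1), np.arange(1, I + 1), indexing="ij"
    )
    frames.append(pd.DataFrame({
        "replicate": rep.ravel(), "year": yr.ravel(), "species": "yelloweye",
        "sex": "both", "age": age.ravel(), "N": output.N_prey.ravel(),
    }))
    R, T, A, S = output.N_pred.shape
    for s, label in enumerate(("F", "M")[:S]):
        rep, yr, age = np.meshgrid(
            np.arange(R), np.arange(1, T + 1), np.arange(1, A + 1), indexing="ij"
        )
        frames.append(pd.DataFrame({
            "replicate": rep.ravel(), "year": yr.ravel(), "species": "lingcod",
            "sex": label, "age": age.ravel(), "N": output.N_pred[..., s].ravel(),
        }))
    return pd.concat(frames, ignore_index=True)


@dataclass
class RunManifest:
    """Record sufficient to re-run a stage bit-identically."""

    config_hash: str
    seeds: dict
    version: str
    reference_points: dict = field(default_factory=dict)
    wall_time_s: dict = field(default_factory=dict)
    files: list = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True, default=str)


def _config_hash(config_tuple) -> str:
    lingcod, yelloweye, glob = config_tuple
    payload = json.dumps(
        {
            "lingcod": lingcod.to_dict(),
            "yelloweye": yelloweye.to_dict(),
            "globals": glob.to_dict(),
        },
        sort_keys=True,
        default=str,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def write_outputs(
    results: list[ScenarioResult],
    outdir: str | Path,
    config_tuple=None,
    seeds: dict | None = None,
    window: int = 150,
) -> RunManifest:
    """Write tidy CSV tables plus a manifest JSON; idempotent overwrite."""
    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    files = []

    metrics_path = outdir / "scenario_metrics.csv"
    annual_path = outdir / "annual_summary.csv"
    for p in (metrics_path, annual_path):
        if p.exists():
            warnings.warn(f"overwriting {p}", stacklevel=2)
    scenario_table(results, window).to_csv(metrics_path, index=False)
    files.append(metrics_path.name)
    annual_table(results).to_csv(annual_path, index=False)
    files.append(annual_path.name)

    if config_tuple is None:
        config_tuple = default_parameters()
    refs = {}
    for r in results:
        refs[str(r.spec.gamma)] = {
            "S0_prey": r.reference.S0_prey,
            "S0_pred": r.reference.S0_pred,
            "F40": r.reference.F40,
            "F_hist_pred": r.reference.F_hist_pred,
            "F_hist_prey": r.reference.F_hist_prey,
        }
    manifest = RunManifest(
        config_hash=_config_hash(config_tuple),
        seeds=seeds or {"master_seed": results[0].spec.seed if results else None},
        version=__version__,
        reference_points=refs,
        wall_time_s={"write": round(time.perf_counter() - t0, 3)},
        files=files + ["manifest.json"],
    )
    (outdir / "manifest.json").write_text(manifest.to_json())
    return manifest
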