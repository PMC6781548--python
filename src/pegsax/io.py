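"""CSV/JSON/TOML plumbing: study tables, parameter files, run config.

Study observations travel as a long-format CSV (``condition_id,
time_days, species, value, unit, below_loq``) paired with a conditions
CSV (``condition_id, temp_C, aw, peg_saxa_ratio, peg_hpmc_ratio,
ph_measured, saxa_mass_fraction``; the last two optional).  Values may
be stored in ppm w/w — the assay-facing convention — or directly in
mol/kg; they are converted to model units on read.

Dialect: comma separator, '.' decimal, UTF-8, mandatory header row.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .core import (
    ArrheniusRate,
    Environment,
    InitialComposition,
    KineticParameters,
    PhMode,
)
from .fit import FitResult, StabilityDataset
from .synth import make_initial_composition
from .units import convert_units

__all__ = [
    "write_study",
    "read_study",
    "write_params",
    "read_params",
    "write_fit_report",
    "RunConfig",
    "load_config",
]

_RATE_FIELDS = ("k1", "k2", "k3", "k4", "k5", "k6", "k7", "k8", "kHp")


def write_study(
    datasets: list[StabilityDataset],
    obs_path,
    cond_path,
    unit: str = "ppm_ww",
) -> None:
    """Write observation and condition tables for a list of datasets."""
    obs_rows = []
    cond_rows = []
    for ds in datasets:
        for row in ds.observations.itertuples(index=False):
            value = convert_units(
                float(row.value), "molkg", unit, species=row.species
            )
            obs_rows.append(
                {
                    "condition_id": ds.condition_id,
                    "time_days": row.time_days,
                    "species": row.species,
                    "value": value,
                    "unit": unit,
                    "below_loq": int(row.below_loq),
                }
            )
        cond_rows.append(
            {
                "condition_id": ds.condition_id,
                "temp_C": ds.env.T - 273.15,
                "aw": ds.env.aw,
                "peg_saxa_ratio": ds.env.peg_saxa_ratio,
                "peg_hpmc_ratio": ds.env.peg_hpmc_ratio,
                "ph_measured": (
                    "" if ds.env.ph_measured is None else ds.env.ph_measured
                ),
                "saxa_mass_fraction": _saxa_mass_fraction(ds.init),
            }
        )
    pd.DataFrame(obs_rows).to_csv(obs_path, index=False)
    pd.DataFrame(cond_rows).to_csv(cond_path, index=False)


def _saxa_mass_fraction(init: InitialComposition) -> float:
    return convert_units(init.c_saxa_tot_0, "molkg", "massfrac", species="SAXA")


def read_study(
    obs_path,
    cond_path,
    loq: dict[str, float] | None = None,
) -> list[StabilityDataset]:
    """Load a study written by :func:`write_study` (or hand-prepared).

    A condition with a ``ph_measured`` entry runs in measured-pH mode;
    otherwise the dynamic FA-driven closure applies.  ``loq`` gives
    per-species quantitation limits in mol/kg for censored rows.
    """
    obs = pd.read_csv(obs_path)
    cond = pd.read_csv(cond_path)
    required = {"condition_id", "time_days", "species", "value", "unit", "below_loq"}
    if missing := required - set(obs.columns):
        raise ValueError(f"observations file missing columns {sorted(missing)}")

    datasets = []
    for crow in cond.itertuples(index=False):
        ph_measured = getattr(crow, "ph_measured", None)
        if ph_measured is not None and (
            ph_measured == "" or (isinstance(ph_measured, float) and math.isnan(ph_measured))
        ):
            ph_measured = None
        env = Environment.at_celsius(
            float(crow.temp_C),
            aw=float(crow.aw),
            peg_saxa_ratio=float(crow.peg_saxa_ratio),
            peg_hpmc_ratio=float(crow.peg_hpmc_ratio),
            ph_mode=PhMode.MEASURED if ph_measured is not None else PhMode.DYNAMIC,
            ph_measured=None if ph_measured is None else float(ph_measured),
        )
        w_s = float(getattr(crow, "saxa_mass_fraction", 0.20))
        init = make_initial_composition(float(crow.peg_saxa_ratio), w_s)
        sub = obs[obs["condition_id"] == crow.condition_id]
        if sub.empty:
            raise ValueError(f"no observations for condition {crow.condition_id!r}")
        rows = []
        for row in sub.itertuples(index=False):
            rows.append(
                {
                    "time_days": float(row.time_days),
                    "species": row.species,
                    "value": convert_units(
                        float(row.value), row.unit, "molkg", species=row.species
                    ),
                    "below_loq": bool(row.below_loq),
                }
            )
        datasets.append(
            StabilityDataset(
                condition_id=str(crow.condition_id),
                env=env,
                init=init,
                observations=pd.DataFrame(rows),
                loq=dict(loq or {}),
            )
        )
    return datasets


def params_to_dict(params: KineticParameters) -> dict:
    d: dict = {}
    for name in _RATE_FIELDS:
        rate: ArrheniusRate = getattr(params, name)
        d[name] = {"k_ref": rate.k_ref, "Ea": rate.Ea}
    d.update(
        x_saxa=params.x_saxa,
        Kw=params.Kw,
        ph_slope=params.ph_slope,
        ph_intercept=params.ph_intercept,
        ph_floor=params.ph_floor,
        consume_fa=params.consume_fa,
        phase_corrected=params.phase_corrected,
    )
    if params.kw_table:
        d["kw_table"] = {str(k): v for k, v in params.kw_table.items()}
    return d


def params_from_dict(d: dict) -> KineticParameters:
    kwargs = {}
    for name in _RATE_FIELDS:
        if name in d:
            spec = d[name]
            kwargs[name] = ArrheniusRate(float(spec["k_ref"]), float(spec.get("Ea", 0.0)))
    for key in (
        "x_saxa", "Kw", "ph_slope", "ph_intercept", "ph_floor",
        "consume_fa", "phase_corrected",
    ):
        if key in d:
            kwargs[key] = d[key]
    if "kw_table" in d:
        kwargs["kw_table"] = {float(k): float(v) for k, v in d["kw_table"].items()}
    return KineticParameters(**kwargs)


def write_params(params: KineticParameters, path) -> None:
    Path(path).write_text(json.dumps(params_to_dict(params), indent=2) + "\n")


def read_params(path) -> KineticParameters:
    return params_from_dict(json.loads(Path(path).read_text()))


def write_fit_report(result: FitResult, txt_path, json_path) -> None:
    """Human-readable summary plus a parameter file usable for simulation."""
    payload = {
        "converged": result.converged,
        "residual_sum": result.residual_sum,
        "n_obs": result.n_obs,
        "n_params": result.n_params,
        "iterations": result.iterations,
        "free": list(result.free),
        "message": result.message,
        "params": params_to_dict(result.params),
    }
    Path(json_path).write_text(json.dumps(payload, indent=2) + "\n")
    lines = [
        "kinetic model fit report",
        f"  converged : {result.converged}",
        f"  SSE       : {result.residual_sum:.6e}",
        f"  n_obs     : {result.n_obs}",
        f"  n_params  : {result.n_params}",
        f"  iterations: {result.iterations}",
        f"  free      : {', '.join(result.free)}",
        "",
        "  parameters (k_ref at 313.15 K [1/day...], Ea [kJ/mol]):",
    ]
    for name in _RATE_FIELDS:
        rate = getattr(result.params, name)
        lines.append(f"    {name:4s}  k_ref={rate.k_ref:.6g}  Ea={rate.Ea:.6g}")
    Path(txt_path).write_text("\n".join(lines) + "\n")


@dataclass
class RunConfig:
    """Pipeline run configuration (TOML-dialect file, flat key-value)."""

    ph_mode: str = "dynamic"
    consume_fa: bool = True
    phase_corrected: bool = True
    k8_enabled: bool = False
    params_path: str | None = None
    design_path: str | None = None
    out_dir: str = "."
    seed: int = 0
    tol: float = 1e-5
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.tol <= 0:
            raise ValueError("tolerance must be positive")
        if self.ph_mode not in ("dynamic", "measured"):
            raise ValueError("ph_mode must be 'dynamic' or 'measured'")


def load_config(path) -> RunConfig:
    import tomllib

    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys {sorted(unknown)}")
    return RunConfig(**data)


def load_design(path) -> "StudyDesign":
    """Load a :class:`~pegsax.synth.StudyDesign` from a TOML file.

    Keys mirror the dataclass fields; list values become tuples.
    """
    import tomllib

    from .synth import StudyDesign

    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    known = set(StudyDesign.__dataclass_fields__)
    if unknown := set(data) - known:
        raise ValueError(f"unknown design keys {sorted(unknown)}")
    for key in ("peg_saxa_ratios", "temperatures_c", "water_activities", "time_days"):
        if key in data:
            data[key] = tuple(float(v) for v in data[key])
    if "ph_mode" in data:
        data["ph_mode"] = PhMode(data["ph_mode"])
    return StudyDesign(**data)
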