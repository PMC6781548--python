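"""Levenberg-Marquardt regression of kinetic parameters.

Multi-condition stability datasets are fitted by minimizing per-species
range-weighted residuals between simulated and observed concentrations.
Parameters are optimized in log space (all are positive); rate constants
are parameterized as their value at the 40 degC reference temperature
plus an activation energy, which keeps the pre-exponential factor and
the activation energy from trading off against each other during the
staged model build.

The staged procedure mirrors accelerated-stability practice: apparent
constants are first regressed at the 40 degC / 10% water-activity
reference block, the humidity proportionality is then fitted on the
remaining humidities at 40 degC, and finally the activation energies are
regressed across temperatures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import lmfit
import numpy as np
import pandas as pd

from .core import (
    ArrheniusRate,
    ConfigurationError,
    Environment,
    InitialComposition,
    KineticParameters,
    SPECIES,
    T_REF,
)
from .integrate import DEFAULT_TOL, simulate

__all__ = [
    "StabilityDataset",
    "FitResult",
    "species_weights",
    "residuals",
    "fit",
    "fit_sequence",
]

logger = logging.getLogger(__name__)

#: Names accepted in ``free`` masks: rate constants at the reference
#: temperature, activation energies, and the humidity proportionality.
RATE_NAMES = tuple(f"k{i}" for i in range(1, 9))
EA_NAMES = tuple(f"Ea{i}" for i in range(1, 9))
FREE_NAMES = RATE_NAMES + EA_NAMES + ("kH", "EaH")


@dataclass(frozen=True)
class StabilityDataset:
    """Observed time series for one storage condition.

    ``observations`` columns: ``time_days``, ``species``, ``value``
    (mol/kg), ``below_loq`` (bool); censored observations are stored at
    the quantitation limit with the flag set.
    """

    condition_id: str
    env: Environment
    init: InitialComposition
    observations: pd.DataFrame
    loq: dict[str, float] = field(default_factory=dict)
    true_params: KineticParameters | None = None

    def __post_init__(self) -> None:
        required = {"time_days", "species", "value", "below_loq"}
        missing = required - set(self.observations.columns)
        if missing:
            raise ValueError(f"observations missing columns {sorted(missing)}")
        if (self.observations["value"] < 0).any():
            raise ValueError("observed values must be >= 0")
        unknown = set(self.observations["species"]) - set(SPECIES)
        if unknown:
            raise ValueError(f"unknown species {sorted(unknown)}")

    @property
    def times(self) -> np.ndarray:
        """Simulation grid: observation times with t=0 prepended."""
        t = np.unique(self.observations["time_days"].to_numpy(dtype=float))
        if len(t) == 0 or t[0] != 0.0:
            t = np.concatenate([[0.0], t])
        return t


@dataclass
class FitResult:
    """Outcome of one LM regression."""

    params: KineticParameters
    residual_sum: float
    n_obs: int
    n_params: int
    converged: bool
    iterations: int
    free: tuple[str, ...]
    message: str = ""
    history: list[dict] = field(default_factory=list)

    def recovery_errors(self, truth: KineticParameters) -> dict[str, float]:
        """Relative error of each free parameter against a known truth."""
        out = {}
        for name in self.free:
            est = _get_param(self.params, name)
            ref = _get_param(truth, name)
            out[name] = abs(est - ref) / abs(ref) if ref != 0 else abs(est)
        return out


def _get_param(params: KineticParameters, name: str) -> float:
    if name == "kH":
        return params.kHp.k_ref
    if name == "EaH":
        return params.kHp.Ea
    if name.startswith("Ea"):
        return getattr(params, "k" + name[2:]).Ea
    if name in RATE_NAMES:
        return getattr(params, name).k_ref
    raise KeyError(f"unknown parameter name {name!r}")


def _set_params(params: KineticParameters, values: dict[str, float]) -> KineticParameters:
    updates: dict[str, ArrheniusRate] = {}
    rates = {f"k{i}": getattr(params, f"k{i}") for i in range(1, 9)}
    rates["kH"] = params.kHp
    for name, value in values.items():
        if name in RATE_NAMES:
            key = name
            rates[key] = ArrheniusRate(value, rates[key].Ea)
        elif name in EA_NAMES:
            key = "k" + name[2:]
            rates[key] = ArrheniusRate(rates[key].k_ref, value)
        elif name == "kH":
            rates["kH"] = ArrheniusRate(value, rates["kH"].Ea)
        elif name == "EaH":
            rates["kH"] = ArrheniusRate(rates["kH"].k_ref, value)
        else:
            raise KeyError(f"unknown parameter name {name!r}")
    for i in range(1, 9):
        updates[f"k{i}"] = rates[f"k{i}"]
    updates["kHp"] = rates["kH"]
    return params.with_updates(**updates)


def species_weights(datasets: list[StabilityDataset]) -> dict[str, float]:
    """Per-species range weights: the maximum observed value of each
    species across all datasets (1.0 for species never observed above
    zero), so that trace impurities and the drug assay contribute on
    comparable scales."""
    w: dict[str, float] = {}
    for ds in datasets:
        for sp, grp in ds.observations.groupby("species"):
            w[sp] = max(w.get(sp, 0.0), float(grp["value"].max()))
    return {sp: (v if v > 0 else 1.0) for sp, v in w.items()}


class SimulationFailure(RuntimeError):
    """Simulation failed for one condition during residual evaluation."""

    def __init__(self, condition_id: str, cause: Exception):
        super().__init__(f"simulation failed for condition {condition_id}: {cause}")
        self.condition_id = condition_id


def residuals(
    params: KineticParameters,
    datasets: list[StabilityDataset],
    weights: dict[str, float] | None = None,
    tol: float = DEFAULT_TOL,
) -> np.ndarray:
    """Weighted residual vector over all observations.

    Quantified observations contribute ``(simulated - observed) / w_s``;
    censored ones contribute one-sidedly, ``max(0, simulated - LOQ) / w_s``,
    penalizing only predictions above the quantitation limit.
    """
    if weights is None:
        weights = species_weights(datasets)
    res: list[float] = []
    for ds in datasets:
        t = ds.times
        try:
            traj = simulate(ds.init, params, ds.env, t, tol=tol)
        except Exception as exc:  # noqa: BLE001 - re-raised with context
            raise SimulationFailure(ds.condition_id, exc) from exc
        t_index = {tv: i for i, tv in enumerate(t)}
        for row in ds.observations.itertuples(index=False):
            sim = traj.states[t_index[float(row.time_days)], SPECIES.index(row.species)]
            w = weights.get(row.species, 1.0)
            if row.below_loq:
                loq = ds.loq.get(row.species, float(row.value))
                res.append(max(0.0, sim - loq) / w)
            else:
                res.append((sim - float(row.value)) / w)
    return np.array(res)


def _distinct_temperatures(datasets: list[StabilityDataset]) -> set[float]:
    return {round(ds.env.T, 6) for ds in datasets}


_LOG_FLOOR = 1e-12


def fit(
    init_params: KineticParameters,
    datasets: list[StabilityDataset],
    free: tuple[str, ...],
    tol: float = DEFAULT_TOL,
    max_iter: int = 500,
) -> FitResult:
    """LM minimization of :func:`residuals` over the ``free`` parameters.

    Returns ``converged=False`` (never raises) on non-convergence, and
    flags single-temperature designs with free activation energies as
    non-identifiable without running the optimizer: one temperature
    cannot separate a pre-exponential factor from an activation energy.
    """
    if not datasets:
        raise ValueError("at least one dataset is required")
    unknown = set(free) - set(FREE_NAMES)
    if unknown:
        raise KeyError(f"unknown free parameters {sorted(unknown)}")
    needs_temps = [n for n in free if n.startswith("Ea")]
    if needs_temps and len(_distinct_temperatures(datasets)) < 2:
        return FitResult(
            params=init_params,
            residual_sum=float(np.sum(residuals(init_params, datasets, tol=tol) ** 2)),
            n_obs=sum(len(ds.observations) for ds in datasets),
            n_params=len(free),
            converged=False,
            iterations=0,
            free=tuple(free),
            message=(
                "non-identifiable: activation energies "
                f"{needs_temps} free but all data at a single temperature"
            ),
        )

    weights = species_weights(datasets)
    r0 = residuals(init_params, datasets, weights, tol)
    if not np.all(np.isfinite(r0)):
        raise ValueError("non-finite residuals at the initial parameters")

    lm_params = lmfit.Parameters()
    for name in free:
        value = np.log(max(_get_param(init_params, name), _LOG_FLOOR))
        # six decades of freedom either side: wide enough for any
        # physically meaningful correction, narrow enough to keep trial
        # steps out of overflow/stiffness territory
        lm_params.add(name, value=value, min=value - 13.8, max=value + 13.8)

    history: list[dict] = []
    _penalty = np.full(len(r0), 1e3)

    def objective(p):
        values = {name: float(np.exp(p[name].value)) for name in free}
        kp = _set_params(init_params, values)
        try:
            r = residuals(kp, datasets, weights, tol)
        except SimulationFailure:
            # inadmissible trial point (integration blew up); return a
            # large finite misfit so LM retreats
            return _penalty
        history.append({"sse": float(np.sum(r**2)), **values})
        return r

    minres = lmfit.minimize(
        objective,
        lm_params,
        method="leastsq",
        xtol=1e-10,
        ftol=1e-10,
        epsfcn=1e-6,
        max_nfev=max_iter * (len(free) + 1),
    )
    best = {name: float(np.exp(minres.params[name].value)) for name in free}
    params = _set_params(init_params, best)
    r = residuals(params, datasets, weights, tol)
    return FitResult(
        params=params,
        residual_sum=float(np.sum(r**2)),
        n_obs=len(r),
        n_params=len(free),
        converged=bool(minres.success),
        iterations=int(minres.nfev),
        free=tuple(free),
        message=str(minres.message),
        history=history,
    )


def _is_ref_block(env: Environment, T_ref: float, aw_ref: float) -> bool:
    return abs(env.T - T_ref) < 0.5 and abs(env.aw - aw_ref) < 0.02


def fit_sequence(
    datasets: list[StabilityDataset],
    init_params: KineticParameters,
    stage1_free: tuple[str, ...] | None = None,
    stage3_free: tuple[str, ...] | None = None,
    ref_temperature: float = T_REF,
    ref_aw: float = 0.10,
    tol: float = DEFAULT_TOL,
) -> FitResult:
    """Staged model build across the full stability design.

    Stage 1 regresses the apparent rate constants on the reference block
    (40 degC, a_w 0.10 by default); stage 2 fits the humidity
    proportionality ``k_H'`` on the other humidities at the reference
    temperature; stage 3 fits activation energies across temperatures.
    The returned result carries the final parameters and the SSE over
    all datasets.
    """
    block1 = [ds for ds in datasets if _is_ref_block(ds.env, ref_temperature, ref_aw)]
    if not block1:
        raise ConfigurationError(
            f"staged fit requires a block at T={ref_temperature:.2f} K, "
            f"a_w={ref_aw:.2f}"
        )
    if stage1_free is None:
        # The reference-block regression includes the humidity
        # proportionality: at a single (T, a_w) it is exactly the reactive
        # PEG fraction x_PEG, which the base model regresses alongside the
        # apparent constants.
        stage1_free = tuple(
            f"k{i}" for i in range(1, 9)
            if _get_param(init_params, f"k{i}") > 0
        ) + ("kH",)
    res1 = fit(init_params, block1, stage1_free, tol=tol)
    params = res1.params
    history = list(res1.history)

    block2 = [
        ds for ds in datasets
        if abs(ds.env.T - ref_temperature) < 0.5
        and not _is_ref_block(ds.env, ref_temperature, ref_aw)
    ]
    if block2:
        res2 = fit(params, block2, ("kH",), tol=tol)
        params = res2.params
        history += res2.history
    else:
        logger.info("no additional-humidity block at the reference temperature; "
                    "skipping stage 2")

    if stage3_free is None:
        stage3_free = tuple(
            f"Ea{i}" for i in range(1, 9)
            if _get_param(init_params, f"k{i}") > 0
        )
    res3 = fit(params, datasets, stage3_free, tol=tol)
    history += res3.history

    all_free = tuple(dict.fromkeys(stage1_free + ("kH",) * bool(block2) + stage3_free))
    r = residuals(res3.params, datasets, tol=tol)
    return FitResult(
        params=res3.params,
        residual_sum=float(np.sum(r**2)),
        n_obs=len(r),
        n_params=len(all_free),
        converged=res1.converged and res3.converged,
        iterations=res1.iterations + res3.iterations,
        free=all_free,
        message=res3.message,
        history=history,
    )
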