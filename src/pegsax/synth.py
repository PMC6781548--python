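"""Synthetic stability-study generation.

Emulates an active film-coated tablet stability program: a full
factorial of film-coat compositions (PEG:SAXA weight ratios 0.8-1.4 at
fixed drug load, HPMC making up the balance), ICH-style temperatures
(30/40/50 degC) and nominal water activities (0.10/0.30/0.50), sampled
at fixed time points from day 0 to day 180.  Each condition is simulated
with the mechanistic model, observed with multiplicative Gaussian assay
noise and censored at per-species quantitation limits, which is the
statistical structure the fitting and DoE stages assume.

The generator does not emulate analytical drift, tablet-to-tablet
variability, or assay artefacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    Environment,
    InitialComposition,
    KineticParameters,
    PhMode,
    SPECIES,
    default_parameters,
)
from .fit import StabilityDataset
from .integrate import DEFAULT_TOL, simulate
from .units import convert_units

__all__ = [
    "StudyDesign",
    "make_initial_composition",
    "film_coat_composition",
    "generate_study",
]

#: Species reported by the assays (the PEG polymer itself is not
#: chromatographically quantifiable).
OBSERVED_SPECIES: tuple[str, ...] = (
    "GA", "A", "F", "FA", "SAXA", "SCA", "ESCA", "SFA",
)

#: Default quantitation limits, ppm w/w against the film coat: trace
#: organic impurities by derivatization UHPLC, drug-related substances by
#: UHPLC area normalization; the drug assay itself is never censored.
DEFAULT_LOQ_PPM: dict[str, float] = {
    "GA": 10.0, "A": 10.0, "F": 10.0, "FA": 10.0,
    "SAXA": 0.0, "SCA": 50.0, "ESCA": 50.0, "SFA": 50.0,
}


@dataclass(frozen=True)
class StudyDesign:
    """Factorial stability design plus the observation model."""

    peg_saxa_ratios: tuple[float, ...] = (0.8, 1.0, 1.2, 1.4)
    temperatures_c: tuple[float, ...] = (30.0, 40.0, 50.0)
    water_activities: tuple[float, ...] = (0.10, 0.30, 0.50)
    time_days: tuple[float, ...] = (0.0, 7.0, 14.0, 30.0, 60.0, 108.0, 180.0)
    noise_sigma: float = 0.05          # multiplicative Gaussian assay error
    loq_ppm: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_LOQ_PPM))
    saxa_mass_fraction: float = 0.20   # drug load of the film coat, kg/kg
    ph_mode: PhMode = PhMode.DYNAMIC
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.peg_saxa_ratios and self.temperatures_c and self.water_activities):
            raise ValueError("all design factors must be non-empty")
        if len(self.time_days) < 4:
            raise ValueError("at least four time points per condition are required")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be >= 0")
        if not 0 < self.saxa_mass_fraction < 1:
            raise ValueError("drug mass fraction must lie in (0, 1)")

    @property
    def n_conditions(self) -> int:
        return (
            len(self.peg_saxa_ratios)
            * len(self.temperatures_c)
            * len(self.water_activities)
        )

    def loq_molkg(self) -> dict[str, float]:
        return {
            sp: convert_units(ppm, "ppm_ww", "molkg", species=sp)
            for sp, ppm in self.loq_ppm.items()
        }


def film_coat_composition(
    peg_saxa_ratio: float, saxa_mass_fraction: float = 0.20
) -> tuple[float, float]:
    """(w_PEG, w_HPMC) weight fractions of the film coat.

    The drug load is fixed across compositions; PEG scales with the
    PEG:SAXA ratio and HPMC makes up the balance of the coat.
    """
    if peg_saxa_ratio <= 0:
        raise ValueError("PEG:SAXA ratio must be positive")
    w_peg = peg_saxa_ratio * saxa_mass_fraction
    w_hpmc = 1.0 - saxa_mass_fraction - w_peg
    if w_hpmc <= 0:
        raise ValueError(
            f"PEG:SAXA ratio {peg_saxa_ratio} leaves no film polymer at drug "
            f"load {saxa_mass_fraction}"
        )
    return w_peg, w_hpmc


def make_initial_composition(
    peg_saxa_ratio: float, saxa_mass_fraction: float = 0.20
) -> InitialComposition:
    """Total prepared amounts (mol/kg film coat) for one composition."""
    w_peg, _ = film_coat_composition(peg_saxa_ratio, saxa_mass_fraction)
    return InitialComposition(
        c_peg_tot_0=convert_units(w_peg, "massfrac", "molkg", species="PEG"),
        c_saxa_tot_0=convert_units(
            saxa_mass_fraction, "massfrac", "molkg", species="SAXA"
        ),
    )


def _condition_id(ratio: float, temp_c: float, aw: float) -> str:
    return f"r{ratio:g}_T{temp_c:g}_aw{aw:.2f}"


def generate_study(
    design: StudyDesign,
    params: KineticParameters | None = None,
    seed: int | None = None,
    tol: float = DEFAULT_TOL,
) -> list[StabilityDataset]:
    """Simulate the full design and observe it through the assay model.

    Deterministic given the seed.  A time-zero sample with all
    degradation products at zero is always included (no degradation
    before study initiation).  Values falling below the species LOQ are
    stored at the LOQ with the censoring flag set.
    """
    if params is None:
        params = default_parameters()
    rng = np.random.default_rng(design.seed if seed is None else seed)
    loq = design.loq_molkg()
    t_grid = np.asarray(design.time_days, dtype=float)
    if t_grid[0] != 0.0:
        t_grid = np.concatenate([[0.0], t_grid])

    datasets: list[StabilityDataset] = []
    for ratio in design.peg_saxa_ratios:
        w_peg, w_hpmc = film_coat_composition(ratio, design.saxa_mass_fraction)
        init = make_initial_composition(ratio, design.saxa_mass_fraction)
        for temp_c in design.temperatures_c:
            for aw in design.water_activities:
                env = Environment.at_celsius(
                    temp_c,
                    aw=aw,
                    peg_saxa_ratio=ratio,
                    peg_hpmc_ratio=w_peg / w_hpmc,
                    ph_mode=design.ph_mode,
                )
                traj = simulate(init, params, env, t_grid, tol=tol)
                rows = []
                for i, t in enumerate(t_grid):
                    for sp in OBSERVED_SPECIES:
                        true_val = traj.states[i, SPECIES.index(sp)]
                        if design.noise_sigma > 0:
                            val = true_val * (
                                1.0 + design.noise_sigma * rng.standard_normal()
                            )
                            val = max(0.0, val)
                        else:
                            val = true_val
                        sp_loq = loq.get(sp, 0.0)
                        censored = val < sp_loq
                        rows.append(
                            {
                                "time_days": float(t),
                                "species": sp,
                                "value": sp_loq if censored else float(val),
                                "below_loq": bool(censored),
                            }
                        )
                datasets.append(
                    StabilityDataset(
                        condition_id=_condition_id(ratio, temp_c, aw),
                        env=env,
                        init=init,
                        observations=pd.DataFrame(rows),
                        loq=dict(loq),
                        true_params=params,
                    )
                )
    return datasets
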