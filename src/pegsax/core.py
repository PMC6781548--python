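"""Reaction network, rate laws and environmental couplings.

The model tracks nine molar-equivalent concentrations in a tablet film
coat (mol per kg of film coat): reactive PEG monomer units and their
oxidation products glycolic acid (GA), acetaldehyde (A), formaldehyde
(F) and formic acid (FA), plus the drug substance saxagliptin (SAXA) and
its degradation products — the cyclic amidine (SCA), its epimer (ESCA)
and the formyl amide (SFA).

Seven reactions couple the two families.  With surplus oxygen folded
into apparent rate constants ``k_i'``:

* ``r1..r3``: parallel first-order oxidations of reactive PEG units to
  GA, A and F;
* ``r4``: oxidation of F to FA (FA forms exclusively through F);
* ``r5``: OH⁻-catalysed intramolecular cyclization SAXA -> SCA;
* ``r6``: OH⁻-catalysed epimerization SCA -> ESCA;
* ``r7``: H⁺-catalysed formylation SAXA + FA -> SFA, optionally
  reversible with constant ``k8'``.

H⁺/OH⁻ come either from a measured micro-environmental pH or, in
dynamic mode, from a linear closure pH(FA) driven by the accumulating
formic acid; only a humidity- and phase-compatibility-dependent fraction
``x_PEG`` of the total PEG is reactive.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, fields, replace
from enum import Enum
from typing import Mapping

import numpy as np

from .units import CONSTANTS, GAS_CONSTANT, MOLAR_MASS

__all__ = [
    "R_GAS",
    "T_REF",
    "SPECIES",
    "PEG_FAMILY",
    "SAXA_FAMILY",
    "PhMode",
    "ArrheniusRate",
    "KineticParameters",
    "Environment",
    "InitialComposition",
    "SpeciesState",
    "RateVector",
    "ConfigurationError",
    "arrhenius",
    "ph_from_fa",
    "hydrogen_hydroxide",
    "out_of_phase_fraction",
    "reactive_peg_fraction",
    "mixing_enthalpy",
    "compute_rates",
    "ode_rhs",
    "default_parameters",
]

logger = logging.getLogger(__name__)

R_GAS: float = GAS_CONSTANT
#: Reference temperature for rate-constant parameterization, K (40 degC, the
#: condition the base model is built at).
T_REF: float = 313.15

#: Canonical species order used by state vectors, trajectories and I/O.
SPECIES: tuple[str, ...] = (
    "PEG", "GA", "A", "F", "FA", "SAXA", "SCA", "ESCA", "SFA",
)
#: Species whose molar sum is conserved because every reaction converts one
#: PEG-derived unit into another (r7 moves FA into SFA).
PEG_FAMILY: tuple[str, ...] = ("PEG", "GA", "A", "F", "FA", "SFA")
#: Species sharing the saxagliptin skeleton.
SAXA_FAMILY: tuple[str, ...] = ("SAXA", "SCA", "ESCA", "SFA")

_PH = CONSTANTS["ph_closure"]
_PHASE_X = tuple(CONSTANTS["phase_lookup"]["ratios"])
_PHASE_Y = tuple(CONSTANTS["phase_lookup"]["fractions"])
_M_FA_KG = MOLAR_MASS["FA"] * 1e-3  # kg/mol, for mol/kg -> mass fraction


class ConfigurationError(ValueError):
    """Inconsistent model configuration (e.g. dynamic pH without closure)."""


class PhMode(str, Enum):
    """Source of the micro-environmental pH during simulation."""

    MEASURED = "measured"  # fixed, externally measured pH
    DYNAMIC = "dynamic"    # pH follows the formic-acid closure


def arrhenius(A: float, Ea: float, T: float) -> float:
    """Arrhenius rate constant ``A * exp(-Ea / (R T))``.

    ``A`` in day^-1 (times any catalytic concentration units), ``Ea`` in
    kJ/mol, ``T`` in K.
    """
    if T <= 0:
        raise ValueError(f"temperature must be positive, got {T}")
    if A < 0:
        raise ValueError(f"pre-exponential factor must be >= 0, got {A}")
    return A * math.exp(-Ea * 1e3 / (R_GAS * T))


@dataclass(frozen=True)
class ArrheniusRate:
    """Temperature-dependent apparent rate constant.

    Stored as the value ``k_ref`` at :data:`T_REF` together with the
    activation energy ``Ea`` (kJ/mol).  This is numerically equivalent to
    an ``(A, Ea)`` pair but decorrelates the two parameters during
    regression: at the reference temperature the constant does not depend
    on ``Ea`` at all.
    """

    k_ref: float
    Ea: float = 0.0

    def __post_init__(self) -> None:
        if self.k_ref < 0:
            raise ValueError(f"rate constant must be >= 0, got {self.k_ref}")
        if self.Ea < 0:
            raise ValueError(f"activation energy must be >= 0, got {self.Ea}")

    def k(self, T: float) -> float:
        """Rate constant at temperature ``T`` (K)."""
        if T <= 0:
            raise ValueError(f"temperature must be positive, got {T}")
        return self.k_ref * math.exp(
            -self.Ea * 1e3 / R_GAS * (1.0 / T - 1.0 / T_REF)
        )

    @property
    def A(self) -> float:
        """Equivalent pre-exponential factor."""
        return self.k_ref * math.exp(self.Ea * 1e3 / (R_GAS * T_REF))

    @classmethod
    def from_A(cls, A: float, Ea: float = 0.0) -> "ArrheniusRate":
        """Build from a conventional ``(A, Ea)`` pair."""
        return cls(k_ref=arrhenius(A, Ea, T_REF), Ea=Ea)


@dataclass(frozen=True)
class KineticParameters:
    """Apparent rate constants and coupling coefficients of the network.

    ``k1..k4`` are per-day constants of the PEG oxidation steps; ``k5``
    and ``k6`` carry an extra 1/(mol OH⁻ per L), ``k7`` an extra
    1/(mol H⁺ per L) · 1/(mol FA per kg); ``k8`` (per day) is the reverse
    formylation constant, zero in the base model.  ``kHp`` is the
    humidity proportionality of the reactive PEG fraction (per unit water
    activity, optionally temperature-dependent).
    """

    k1: ArrheniusRate  # PEG -> GA
    k2: ArrheniusRate  # PEG -> A
    k3: ArrheniusRate  # PEG -> F
    k4: ArrheniusRate  # F -> FA
    k5: ArrheniusRate  # SAXA -> SCA  (OH- catalysed)
    k6: ArrheniusRate  # SCA -> ESCA (OH- catalysed)
    k7: ArrheniusRate  # SAXA + FA -> SFA (H+ catalysed)
    k8: ArrheniusRate = ArrheniusRate(0.0)  # SFA -> SAXA + FA (reverse)
    kHp: ArrheniusRate = ArrheniusRate(0.0)
    x_saxa: float = 1.0  # reactive drug fraction; regression gives unity
    Kw: float = 1.0e-14  # mol^2 L^-2
    kw_table: Mapping[float, float] | None = None  # optional per-T override (K -> Kw)
    ph_slope: float | None = _PH["slope"]      # per unit FA mass fraction
    ph_intercept: float | None = _PH["intercept"]
    ph_floor: float = _PH["floor"]
    consume_fa: bool = True        # debit FA for net formylation
    phase_corrected: bool = True   # apply out-of-phase lookup to x_PEG

    def __post_init__(self) -> None:
        if not 0.0 <= self.x_saxa <= 1.0:
            raise ValueError("x_saxa must lie in [0, 1]")
        if self.Kw <= 0:
            raise ValueError("Kw must be positive")

    def kw_at(self, T: float) -> float:
        """Water ionization constant at ``T``, honouring the override table."""
        if self.kw_table:
            key = min(self.kw_table, key=lambda t: abs(t - T))
            return self.kw_table[key]
        return self.Kw

    def with_updates(self, **updates) -> "KineticParameters":
        """Return a copy with fields replaced."""
        return replace(self, **updates)


@dataclass(frozen=True)
class Environment:
    """Storage/stability condition a trajectory is computed for."""

    T: float                 # K
    aw: float                # water activity, 0-1
    peg_saxa_ratio: float    # w/w
    peg_hpmc_ratio: float    # w/w
    ph_mode: PhMode = PhMode.DYNAMIC
    ph_measured: float | None = None

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError("temperature must be positive (K)")
        if not 0.0 <= self.aw <= 1.0:
            raise ValueError("water activity must lie in [0, 1]")
        if self.peg_saxa_ratio <= 0 or self.peg_hpmc_ratio <= 0:
            raise ValueError("composition ratios must be positive")
        if self.ph_mode == PhMode.MEASURED and self.ph_measured is None:
            raise ConfigurationError("measured pH mode requires ph_measured")

    @property
    def peg_polymer_fraction(self) -> float:
        """PEG weight fraction relative to total film polymer (PEG + HPMC)."""
        return self.peg_hpmc_ratio / (1.0 + self.peg_hpmc_ratio)

    @classmethod
    def at_celsius(cls, temp_c: float, **kwargs) -> "Environment":
        return cls(T=temp_c + 273.15, **kwargs)


@dataclass(frozen=True)
class InitialComposition:
    """Total prepared amounts on the film-coat basis (mol/kg)."""

    c_peg_tot_0: float
    c_saxa_tot_0: float

    def __post_init__(self) -> None:
        if self.c_peg_tot_0 < 0 or self.c_saxa_tot_0 < 0:
            raise ValueError("initial totals must be >= 0")


@dataclass(frozen=True)
class SpeciesState:
    """Molar-equivalent concentrations (mol/kg film coat) at one instant."""

    c_peg: float
    c_ga: float
    c_a: float
    c_f: float
    c_fa: float
    c_saxa: float
    c_sca: float
    c_esca: float
    c_sfa: float

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"{f.name} must be >= 0")

    def as_array(self) -> np.ndarray:
        """Concentrations in :data:`SPECIES` order."""
        return np.array(
            [self.c_peg, self.c_ga, self.c_a, self.c_f, self.c_fa,
             self.c_saxa, self.c_sca, self.c_esca, self.c_sfa]
        )

    @classmethod
    def from_array(cls, y) -> "SpeciesState":
        return cls(*[float(v) for v in y])

    @property
    def saxa_family_total(self) -> float:
        return self.c_saxa + self.c_sca + self.c_esca + self.c_sfa

    @property
    def peg_family_total(self) -> float:
        return self.c_peg + self.c_ga + self.c_a + self.c_f + self.c_fa + self.c_sfa


@dataclass(frozen=True)
class RateVector:
    """Reaction rates (mol kg^-1 day^-1); ``r7`` is net forward - reverse."""

    r1: float
    r2: float
    r3: float
    r4: float
    r5: float
    r6: float
    r7: float


def ph_from_fa(
    c_fa_massfrac: float,
    slope: float = _PH["slope"],
    intercept: float = _PH["intercept"],
    floor: float = _PH["floor"],
) -> float:
    """Micro-environmental pH from the formic-acid mass fraction.

    Linear closure ``pH = intercept + slope * w_FA`` calibrated on
    averaged tablet-extract measurements; clipped at ``floor`` (the
    linear form is an interpolation, not valid at extreme acid loads).
    """
    if c_fa_massfrac < 0:
        raise ValueError("FA mass fraction must be >= 0")
    ph = intercept + slope * c_fa_massfrac
    if ph < floor:
        logger.warning(
            "pH closure extrapolated below floor (%.3g < %.3g); clipping",
            ph, floor,
        )
        return floor
    return ph


def hydrogen_hydroxide(ph: float, Kw: float = 1.0e-14) -> tuple[float, float]:
    """(c_H+, c_OH-) in mol/L from pH via the water ionization constant."""
    if Kw <= 0:
        raise ValueError("Kw must be positive")
    c_h = 10.0 ** (-ph)
    return c_h, Kw / c_h


def out_of_phase_fraction(peg_polymer_ratio: float) -> float:
    """Fraction of PEG out of phase with the film polymer, in [0, 1].

    Piecewise-linear interpolation through literature DSC anchor points
    (10% w/w -> 0, 20% -> 5%, 30% -> 22%); zero below the first anchor,
    linear extrapolation on the last segment above it, clipped to [0, 1].
    Out-of-phase PEG is the mobile, degradation-susceptible part.
    """
    if peg_polymer_ratio < 0:
        raise ValueError("ratio must be >= 0")
    r = peg_polymer_ratio
    if r <= _PHASE_X[0]:
        return 0.0
    if r <= _PHASE_X[-1]:
        return float(np.interp(r, _PHASE_X, _PHASE_Y))
    slope = (_PHASE_Y[-1] - _PHASE_Y[-2]) / (_PHASE_X[-1] - _PHASE_X[-2])
    return float(min(1.0, _PHASE_Y[-1] + slope * (r - _PHASE_X[-1])))


def reactive_peg_fraction(env: Environment, params: KineticParameters) -> float:
    """Reactive PEG fraction ``x_PEG`` in [0, 1].

    Humidity term ``k_H'(T) * a_w`` (surface water provides the reaction
    medium), multiplied — when phase correction is enabled — by the
    out-of-phase fraction from the PEG:polymer composition.
    """
    x = params.kHp.k(env.T) * env.aw
    if params.phase_corrected:
        x *= out_of_phase_fraction(env.peg_polymer_fraction)
    return float(min(1.0, max(0.0, x)))


def mixing_enthalpy(x1: float, dh1: float, x2: float, dh2: float) -> float:
    """Ideal two-component mixing enthalpy ``x1*dH1 + x2*dH2`` (J/g).

    Weight fractions must sum to one; used to interpret DSC melting
    enthalpies of PEG/polymer films in terms of the free-PEG fraction.
    """
    if x1 < 0 or x2 < 0:
        raise ValueError("weight fractions must be >= 0")
    if abs(x1 + x2 - 1.0) > 1e-9:
        raise ValueError(f"weight fractions must sum to 1, got {x1 + x2}")
    return x1 * dh1 + x2 * dh2


def _acid_base(state_fa: float, params: KineticParameters, env: Environment) -> tuple[float, float]:
    """(c_H+, c_OH-) for the current state under the configured pH mode."""
    kw = params.kw_at(env.T)
    if env.ph_mode == PhMode.MEASURED:
        ph = env.ph_measured
    else:
        if params.ph_slope is None or params.ph_intercept is None:
            raise ConfigurationError(
                "dynamic pH mode requires the FA->pH closure coefficients"
            )
        ph = ph_from_fa(
            state_fa * _M_FA_KG, params.ph_slope, params.ph_intercept, params.ph_floor
        )
    return hydrogen_hydroxide(ph, kw)


def compute_rates(
    state: SpeciesState, params: KineticParameters, env: Environment
) -> RateVector:
    """Evaluate all reaction rates for one state."""
    c_h, c_oh = _acid_base(state.c_fa, params, env)
    T = env.T
    return RateVector(
        r1=params.k1.k(T) * state.c_peg,
        r2=params.k2.k(T) * state.c_peg,
        r3=params.k3.k(T) * state.c_peg,
        r4=params.k4.k(T) * state.c_f,
        r5=params.k5.k(T) * c_oh * state.c_saxa,
        r6=params.k6.k(T) * c_oh * state.c_sca,
        r7=params.k7.k(T) * c_h * state.c_saxa * state.c_fa
        - params.k8.k(T) * state.c_sfa,
    )


def ode_rhs(
    state: SpeciesState, params: KineticParameters, env: Environment
) -> np.ndarray:
    """Time derivative of the state, in :data:`SPECIES` order (per day).

    Stoichiometry: each of r1-r3 consumes one reactive PEG unit; r4
    converts F to FA; r5/r6 move SAXA along the serial cyclization/
    epimerization branch; net formylation r7 converts SAXA (and, when
    ``consume_fa`` is set, one FA) into SFA.  Both family sums are
    conserved by construction.
    """
    r = compute_rates(state, params, env)
    d_fa = r.r4 - (r.r7 if params.consume_fa else 0.0)
    return np.array(
        [
            -(r.r1 + r.r2 + r.r3),  # PEG
            r.r1,                   # GA
            r.r2,                   # A
            r.r3 - r.r4,            # F
            d_fa,                   # FA
            -r.r5 - r.r7,           # SAXA
            r.r5 - r.r6,            # SCA
            r.r6,                   # ESCA
            r.r7,                   # SFA
        ]
    )


def default_parameters() -> KineticParameters:
    """Package default parameter set.

    The two anchored activation energies are the regression values for
    the OH⁻-catalysed cyclization (88.54 kJ/mol) and the H⁺-catalysed
    formylation (151.6 kJ/mol).  All remaining constants are package
    calibration values chosen so that desk-scale simulations of the
    default study design reproduce the observed qualitative behaviour:
    PEG oxidation essentially complete within ~50 days, formaldehyde
    peaking within the first weeks, formic acid reaching a few hundred
    ppm and depressing the micro-environmental pH by ~0.1 under the
    accelerated condition, cyclization products dominating at low
    PEG:SAXA ratios, formyl amide growing with the ratio, epimerization
    nearly thermally insensitive.
    """
    return KineticParameters(
        k1=ArrheniusRate(0.02, 90.0),
        k2=ArrheniusRate(0.01, 85.0),
        k3=ArrheniusRate(0.04, 95.0),
        k4=ArrheniusRate(0.15, 100.0),
        k5=ArrheniusRate(6.0e4, 88.54),
        k6=ArrheniusRate(2.0e6, 20.0),
        k7=ArrheniusRate(1.0e3, 151.6),
        k8=ArrheniusRate(0.0, 0.0),
        kHp=ArrheniusRate(0.025, 0.0),
    )
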