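"""Design-of-experiments style evaluation of stability tables.

Two complementary summaries of a (synthetic) stability study:

* scaled-and-centered multiple linear regression of one response on the
  main effects time, temperature and humidity (each centered to the
  middle of its design span and scaled to +/-1 at the extremes) plus the
  tablet composition as a sum-to-zero categorical factor — coefficient
  magnitudes are then directly comparable across factors;
* a Pearson correlation matrix between responses, to flag strong linear
  relationships (|r| > 0.7 is the conventional screen).

Only main effects are modeled (no interactions or quadratics); Q² is
the leave-one-out PRESS-based predictive R².
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ph_from_fa
from .fit import StabilityDataset
from .units import convert_units

__all__ = [
    "FACTOR_COLUMNS",
    "build_factor_table",
    "MLRResult",
    "mlr_scaled_centered",
    "correlation_matrix",
]

logger = logging.getLogger(__name__)

FACTOR_COLUMNS = ("time_days", "temp_C", "aw", "composition")


def build_factor_table(
    datasets: list[StabilityDataset],
    responses: tuple[str, ...] = ("SCA", "ESCA", "SFA", "F", "FA"),
    include_ph: bool = True,
) -> pd.DataFrame:
    """Wide factor/response table: one row per condition and time point.

    Composition enters as a categorical PEG:SAXA ratio.  The
    micro-environmental pH response is derived from the observed formic
    acid level through the linear closure (the film-coat pH is not an
    independently generated observable of the synthetic assay).
    """
    frames = []
    for ds in datasets:
        wide = (
            ds.observations.pivot_table(
                index="time_days", columns="species", values="value"
            )
            .reset_index()
        )
        wide["temp_C"] = ds.env.T - 273.15
        wide["aw"] = ds.env.aw
        wide["composition"] = f"{ds.env.peg_saxa_ratio:g}"
        frames.append(wide)
    table = pd.concat(frames, ignore_index=True)
    missing = [r for r in responses if r not in table.columns]
    if missing:
        raise ValueError(f"responses {missing} not present in the observations")
    if include_ph and "FA" in table.columns:
        table["pH"] = [
            ph_from_fa(convert_units(v, "molkg", "massfrac", species="FA"))
            for v in table["FA"]
        ]
    keep = [c for c in FACTOR_COLUMNS if c in table.columns]
    keep += [r for r in responses if r in table.columns]
    if include_ph and "pH" in table.columns:
        keep.append("pH")
    return table[keep]


@dataclass
class MLRResult:
    """Scaled-and-centered main-effects MLR summary."""

    response: str
    coefficients: pd.Series  # intercept, continuous factors, composition levels
    r2: float
    q2: float
    n: int
    log_transformed: bool

    def composition_coefficients(self) -> pd.Series:
        return self.coefficients[
            [i for i in self.coefficients.index if i.startswith("composition=")]
        ]


def _scale_center(x: np.ndarray) -> np.ndarray:
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi == lo:
        raise ValueError("factor has zero design span")
    mid, half = (hi + lo) / 2.0, (hi - lo) / 2.0
    return (x - mid) / half


def mlr_scaled_centered(
    table: pd.DataFrame,
    response: str,
    log_transform: bool = False,
) -> MLRResult:
    """Fit ``response`` on scaled/centered main effects by OLS.

    Continuous factors are mid-range centered and half-range scaled so
    every coefficient measures the response change from design center to
    factor extreme.  The categorical composition uses sum-to-zero
    (deviation) coding and is reported expanded, one coefficient per
    level summing to zero.  A constant response yields all-zero
    coefficients with R² and Q² reported as 0 (with a warning).
    """
    if response not in table.columns:
        raise KeyError(f"response {response!r} not in table")
    y = table[response].to_numpy(dtype=float)
    if log_transform:
        if np.any(y <= 0):
            raise ValueError("log transform requires strictly positive response")
        y = np.log(y)
    n = len(y)

    cont = [c for c in ("time_days", "temp_C", "aw") if c in table.columns]
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["intercept"]
    for c in cont:
        cols.append(_scale_center(table[c].to_numpy(dtype=float)))
        names.append(c)
    levels: list[str] = []
    if "composition" in table.columns:
        levels = sorted(table["composition"].astype(str).unique(), key=float)
        base = levels[0]
        comp = table["composition"].astype(str).to_numpy()
        for lev in levels[1:]:
            col = np.where(comp == lev, 1.0, np.where(comp == base, -1.0, 0.0))
            cols.append(col)
            names.append(f"composition={lev}")
    X = np.column_stack(cols)
    if n < X.shape[1] + 2:
        raise ValueError(
            f"need at least {X.shape[1] + 2} rows for {X.shape[1]} parameters"
        )
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, r = np.linalg.qr(X)
        aliased = [names[j] for j in range(X.shape[1]) if abs(r[j, j]) < 1e-10]
        raise ValueError(f"rank-deficient design; aliased columns: {aliased}")

    sst = float(np.sum((y - y.mean()) ** 2))
    if sst <= n * (1e-12 * max(1.0, abs(float(y.mean())))) ** 2:
        logger.warning(
            "response %s is constant; coefficients set to 0, R2/Q2 reported as 0",
            response,
        )
        coeffs = pd.Series(0.0, index=_expanded_names(names, levels))
        return MLRResult(response, coeffs, 0.0, 0.0, n, log_transform)

    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    r2 = 1.0 - float(np.sum(resid**2)) / sst
    # Leave-one-out PRESS through the hat matrix diagonal.
    h = np.einsum("ij,jk,ik->i", X, np.linalg.pinv(X.T @ X), X)
    denom = np.clip(1.0 - h, 1e-12, None)
    press = float(np.sum((resid / denom) ** 2))
    q2 = 1.0 - press / sst

    values = dict(zip(names, beta))
    if levels:
        dev = {lev: values.pop(f"composition={lev}") for lev in levels[1:]}
        dev[levels[0]] = -sum(dev.values())
        for lev in levels:
            values[f"composition={lev}"] = dev[lev]
    coeffs = pd.Series(values)[_expanded_names(names, levels)]
    return MLRResult(response, coeffs, r2, q2, n, log_transform)


def _expanded_names(names: list[str], levels: list[str]) -> list[str]:
    out = [nm for nm in names if not nm.startswith("composition=")]
    out += [f"composition={lev}" for lev in levels]
    return out


def correlation_matrix(
    table: pd.DataFrame, responses: tuple[str, ...]
) -> pd.DataFrame:
    """Pearson correlations between responses.

    Zero-variance responses yield NaN in their row/column (undefined,
    deliberately not coerced to 0).
    """
    if len(table) < 3:
        raise ValueError("need at least three rows for a correlation matrix")
    missing = [r for r in responses if r not in table.columns]
    if missing:
        raise KeyError(f"responses {missing} not in table")
    sub = table[list(responses)].astype(float)
    corr = sub.corr(method="pearson")
    # pandas leaves the diagonal at 1 even for constant columns; mark those
    # undefined instead.
    for r in responses:
        if sub[r].nunique() <= 1:
            corr.loc[r, :] = np.nan
            corr.loc[:, r] = np.nan
    return corr
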