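"""Deterministic derived quantities for stream-site gradient analysis.

Phytoclimatic aridity indices (UNEP PP/PET ratio, de Martonne, Emberger Q2),
Simpson diversity, the Domin-Krajina ordinal cover scale, and the arcsine
square-root transform applied to percent-cover responses.

All functions are vectorised: scalar inputs return scalars, array-likes
return :class:`numpy.ndarray`.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "unep_aridity",
    "de_martonne",
    "emberger_q2",
    "simpson_diversity",
    "arcsine_sqrt",
    "inverse_arcsine_sqrt",
    "DOMIN_KRAJINA_MIDPOINTS",
    "domin_krajina_to_percent",
    "percent_to_domin_krajina",
]

_KELVIN = 273.15


def _maybe_scalar(x: np.ndarray, scalar_in: bool):
    return float(x) if scalar_in else x


def unep_aridity(pp, pet):
    """UNEP aridity index: annual precipitation over potential evapotranspiration.

    Parameters
    ----------
    pp : float or array-like
        Mean annual precipitation (mm).
    pet : float or array-like
        Potential evapotranspiration (mm/year); must be > 0.

    Returns
    -------
    float or ndarray
        Dimensionless PP/PET ratio; < 1 indicates water deficit.
    """
    scalar = np.isscalar(pp) and np.isscalar(pet)
    pp = np.asarray(pp, dtype=float)
    pet = np.asarray(pet, dtype=float)
    if np.any(pet <= 0):
        raise ValueError("PET must be strictly positive")
    return _maybe_scalar(pp / pet, scalar)


def de_martonne(pp, tmean):
    """De Martonne aridity index, annual form PP / (T + 10).

    Parameters
    ----------
    pp : float or array-like
        Mean annual precipitation (mm).
    tmean : float or array-like
        Mean annual temperature (degrees C); must be > -10.
    """
    scalar = np.isscalar(pp) and np.isscalar(tmean)
    pp = np.asarray(pp, dtype=float)
    tmean = np.asarray(tmean, dtype=float)
    if np.any(tmean <= -10):
        raise ValueError("mean annual temperature must exceed -10 degC")
    return _maybe_scalar(pp / (tmean + 10.0), scalar)


def emberger_q2(pp, tmax_jul, tmin_jan):
    """Emberger pluviothermic coefficient Q2 = 2000 PP / (M^2 - m^2).

    M and m are the mean maximum of the warmest month and the mean minimum of
    the coldest month, converted to Kelvin. Higher Q2 means a wetter, more
    thermally buffered (less continental) climate.

    Parameters
    ----------
    pp : float or array-like
        Mean annual precipitation (mm).
    tmax_jul : float or array-like
        Mean maximum temperature of the warmest month (degrees C).
    tmin_jan : float or array-like
        Mean minimum temperature of the coldest month (degrees C);
        must be strictly below ``tmax_jul``.
    """
    scalar = np.isscalar(pp) and np.isscalar(tmax_jul) and np.isscalar(tmin_jan)
    pp = np.asarray(pp, dtype=float)
    big_m = np.asarray(tmax_jul, dtype=float) + _KELVIN
    small_m = np.asarray(tmin_jan, dtype=float) + _KELVIN
    if np.any(big_m <= small_m):
        raise ValueError("warmest-month maximum must exceed coldest-month minimum")
    return _maybe_scalar(2000.0 * pp / (big_m**2 - small_m**2), scalar)


def simpson_diversity(abundances):
    """Simpson diversity 1 - D = 1 - sum(p_i^2) from an abundance vector.

    Probability that two randomly drawn individuals belong to different taxa.
    Bounded by 1 - 1/S for S taxa, attained at perfect evenness.

    Parameters
    ----------
    abundances : array-like
        Nonnegative abundances (counts, covers, ...); at least one positive.
    """
    a = np.asarray(abundances, dtype=float)
    if a.ndim != 1:
        raise ValueError("abundances must be one-dimensional")
    if np.any(a < 0):
        raise ValueError("abundances must be nonnegative")
    total = a.sum()
    if total <= 0:
        raise ValueError("at least one abundance must be positive")
    p = a / total
    return float(1.0 - np.sum(p**2))


def arcsine_sqrt(p):
    """Arcsine square-root transform asin(sqrt(p)) for proportions in [0, 1].

    The variance-stabilising transform used for percent-cover responses;
    strictly increasing, mapping [0, 1] onto [0, pi/2] radians.
    """
    scalar = np.isscalar(p)
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("proportion must lie in [0, 1]")
    return _maybe_scalar(np.arcsin(np.sqrt(p)), scalar)


def inverse_arcsine_sqrt(theta):
    """Inverse of :func:`arcsine_sqrt`: sin(theta)^2, for theta in [0, pi/2]."""
    scalar = np.isscalar(theta)
    theta = np.asarray(theta, dtype=float)
    if np.any((theta < 0) | (theta > np.pi / 2 + 1e-12)):
        raise ValueError("angle must lie in [0, pi/2]")
    return _maybe_scalar(np.sin(theta) ** 2, scalar)


#: Default 10-class Domin-Krajina midpoint table (class -> percent cover).
#: Class bounds: 1 = solitary/minimal presence, 2 = <1%, 3 = 1-4%, 4 = 4-10%,
#: 5 = 10-25%, 6 = 25-33%, 7 = 33-50%, 8 = 50-75%, 9 = 75-95%, 10 = 95-100%.
#: Published variants differ; an alternative table may be passed explicitly.
DOMIN_KRAJINA_MIDPOINTS: dict[int, float] = {
    1: 0.1,
    2: 0.5,
    3: 2.5,
    4: 7.0,
    5: 17.5,
    6: 29.0,
    7: 41.5,
    8: 62.5,
    9: 85.0,
    10: 97.5,
}


def domin_krajina_to_percent(code: int, table: dict[int, float] | None = None) -> float:
    """Convert an ordinal Domin-Krajina cover class to its percent midpoint."""
    table = DOMIN_KRAJINA_MIDPOINTS if table is None else table
    try:
        return float(table[int(code)])
    except (KeyError, TypeError) as exc:
        raise ValueError(f"unknown Domin-Krajina class: {code!r}") from exc


def percent_to_domin_krajina(percent: float, table: dict[int, float] | None = None) -> int:
    """Map a percent cover back to the nearest-midpoint Domin-Krajina class.

    Round-trips exactly with :func:`domin_krajina_to_percent` for every class
    in the table.
    """
    table = DOMIN_KRAJINA_MIDPOINTS if table is None else table
    if not 0 <= percent <= 100:
        raise ValueError("percent cover must lie in [0, 100]")
    return min(table, key=lambda c: (abs(table[c] - percent), c))
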