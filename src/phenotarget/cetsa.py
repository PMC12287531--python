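"""Thermal-shift (CETSA-style) melt-curve quantification.

Band densities measured over a temperature gradient (typically 40-67 °C in
3 °C steps) are normalized to the lowest-temperature value and fitted with a
two-state denaturation sigmoid

    f(T) = plateau + (1 - plateau) / (1 + exp(slope * (T - Tm)))

with slope > 0, so f decreases from ~1 toward the lower plateau as the
protein denatures.  Tm is the inflection (half-denaturation) temperature;
ligand engagement shifts it: dTm = Tm(treated) - Tm(control) > 0 means
stabilization.

Also hosts the standalone thermodynamic helper dG = -R*T*ln(Keq).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import UnconvergedFitError

GAS_CONSTANT = 8.314  # J/(mol K)

#: minimum normalized-density span below which no transition is fit
_MIN_SPAN = 0.05


@dataclass(frozen=True)
class MeltCurveFit:
    temperatures: np.ndarray
    normalized_density: np.ndarray
    tm: float
    plateau: float
    slope: float
    rss: float
    converged: bool


def _sigmoid(temp, tm, plateau, slope):
    return plateau + (1.0 - plateau) / (1.0 + np.exp(slope * (temp - tm)))


def fit_melt_curve(temperatures: Sequence[float], densities: Sequence[float],
                   floor_epsilon: float = 1e-9) -> MeltCurveFit:
    """Fit a two-state melt curve to band densities over a temperature grid.

    Densities are floored at ``floor_epsilon`` (bands below detection) and
    normalized to the lowest-temperature value, which is 1 by construction.
    A flat profile (span < 5% after normalization) or optimizer failure is
    returned with ``converged=False`` and ``tm=nan``.
    """
    temps = np.asarray(temperatures, dtype=float)
    dens = np.asarray(densities, dtype=float)
    if temps.size < 5:
        raise ValueError("need at least 5 temperature points")
    if temps.shape != dens.shape:
        raise ValueError("temperature and density lengths differ")
    if np.any(np.diff(temps) <= 0):
        raise ValueError("temperatures must be strictly increasing")
    if np.any(dens < 0):
        raise ValueError("densities must be >= 0")

    dens = np.maximum(dens, floor_epsilon)
    norm = dens / dens[0]

    if norm.max() - norm.min() < _MIN_SPAN:
        return MeltCurveFit(temps, norm, math.nan, math.nan, math.nan,
                            float(np.sum((norm - norm.mean()) ** 2)), False)

    p_lo = float(norm.min())
    half = (1.0 + p_lo) / 2.0
    tm0 = float(temps[np.argmin(np.abs(norm - half))])
    t_lo, t_hi = temps.min() - 5.0, temps.max() + 5.0
    try:
        popt, _ = curve_fit(
            _sigmoid, temps, norm,
            p0=[tm0, max(p_lo, 1e-3), 0.5],
            bounds=([t_lo, 0.0, 1e-3], [t_hi, 0.95, 5.0]),
            maxfev=10000)
    except RuntimeError:
        return MeltCurveFit(temps, norm, math.nan, math.nan, math.nan,
                            math.inf, False)
    tm, plateau, slope = (float(v) for v in popt)
    rss = float(np.sum((_sigmoid(temps, *popt) - norm) ** 2))
    return MeltCurveFit(temps, norm, tm, plateau, slope, rss, True)


def delta_tm(control: MeltCurveFit, treated: MeltCurveFit) -> float:
    """Tm(treated) - Tm(control); positive = ligand-induced stabilization."""
    if not (control.converged and treated.converged):
        raise UnconvergedFitError("both melt fits must converge for a dTm")
    return treated.tm - control.tm


def read_melt_tsv(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a CETSA TSV with columns temperature_c, density."""
    df = pd.read_csv(path, sep="\t")
    if not {"temperature_c", "density"} <= set(df.columns):
        raise ValueError("CETSA TSV needs columns temperature_c, density")
    df = df.sort_values("temperature_c")
    return df["temperature_c"].to_numpy(float), df["density"].to_numpy(float)


def gibbs_from_keq(keq: float, temperature: float) -> float:
    """Gibbs free energy (kJ/mol) from an equilibrium constant: -R*T*ln(Keq)."""
    if keq <= 0:
        raise ValueError("Keq must be > 0")
    if temperature <= 0:
        raise ValueError("temperature must be > 0 K")
    return -GAS_CONSTANT * temperature * math.log(keq) / 1000.0


__all__ = ["MeltCurveFit", "GAS_CONSTANT", "fit_melt_curve", "delta_tm",
           "read_melt_tsv", "gibbs_from_keq"]
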