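"""Inhibitor-vs-normalized-response curve fitting and IC50 reporting.

The model is the normalized-response Hill equation

    Y(X) = 100 / (1 + (X / IC50)^h)

with viability already expressed in percent of control, so there are no
floor/ceiling parameters.  The default variant fixes the Hill slope at
h = 1; a variable-slope variant (h bounded to [0.1, 10]) is available for
shallow spheroid curves.  IC50 is optimized in log10 space, started at the
dose whose observed response is closest to 50%, and bounded to
[min dose / 100, max dose * 100].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .errors import InsufficientDataError, UnconvergedFitError

VARIANTS = ("fixed_slope", "variable_slope")
_HILL_BOUNDS = (0.1, 10.0)


@dataclass(frozen=True)
class DoseResponseFit:
    """Result of a dose-response fit; ``ic50`` is None unless converged."""

    ic50: float | None
    hill_slope: float
    variant: str
    r_squared: float
    n_points: int
    converged: bool


def _model(conc: np.ndarray, ic50: float, h: float) -> np.ndarray:
    return 100.0 / (1.0 + (conc / ic50) ** h)


def fit_ic50(concentrations: Sequence[float], viabilities: Sequence[float],
             variant: str = "fixed_slope") -> DoseResponseFit:
    """Least-squares fit of the normalized-response model.

    Zero-dose points (by definition 100%) are excluded from the residuals;
    at least 3 distinct nonzero concentrations are required.  A fit whose
    log10(IC50) lands on the search bound is reported as unconverged —
    typically a flat (non-responding) profile.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    conc = np.asarray(concentrations, dtype=float)
    viab = np.asarray(viabilities, dtype=float)
    if conc.shape != viab.shape:
        raise ValueError("concentrations and viabilities differ in length")
    if not np.all(np.isfinite(viab)):
        raise ValueError("non-finite viability values")
    mask = conc > 0
    conc, viab = conc[mask], viab[mask]
    if np.unique(conc).size < 3:
        raise InsufficientDataError(
            "need >=3 distinct nonzero concentrations for a dose-response fit")

    lo, hi = np.log10(conc.min() / 100.0), np.log10(conc.max() * 100.0)
    x0_log = np.log10(conc[np.argmin(np.abs(viab - 50.0))])
    free_slope = variant == "variable_slope"

    def residuals(p):
        h = p[1] if free_slope else 1.0
        return _model(conc, 10.0 ** p[0], h) - viab

    p0 = [x0_log, 1.0] if free_slope else [x0_log]
    bounds = ([lo, _HILL_BOUNDS[0]], [hi, _HILL_BOUNDS[1]]) if free_slope else ([lo], [hi])
    sol = least_squares(residuals, p0, bounds=bounds)

    log_ic50 = sol.x[0]
    hill = float(sol.x[1]) if free_slope else 1.0
    at_bound = log_ic50 <= lo + 1e-6 or log_ic50 >= hi - 1e-6
    converged = bool(sol.success) and not at_bound

    sse = float(np.sum(sol.fun ** 2))
    sst = float(np.sum((viab - viab.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else -np.inf

    return DoseResponseFit(
        ic50=float(10.0 ** log_ic50) if converged else None,
        hill_slope=hill,
        variant=variant,
        r_squared=r2,
        n_points=int(conc.size),
        converged=converged,
    )


def predict_viability(fit: DoseResponseFit, concentration: float) -> float:
    """Model-predicted viability (%) at a concentration; 0 nM -> 100%."""
    if not fit.converged or fit.ic50 is None:
        raise UnconvergedFitError("cannot predict from an unconverged fit")
    if concentration < 0:
        raise ValueError("concentration must be >= 0")
    if concentration == 0:
        return 100.0
    return float(_model(np.asarray(concentration, dtype=float), fit.ic50, fit.hill_slope))


__all__ = ["DoseResponseFit", "VARIANTS", "fit_ic50", "predict_viability"]
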