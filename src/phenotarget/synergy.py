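"""Drug-combination analysis: CDI, Bliss independence, synergy volumes.

Two complementary dialects are carried side by side without unit confusion:

* CDI (coefficient of drug interaction) works on **viability fractions**:
  CDI = AB / (A x B), where A and B are single-agent viabilities and AB the
  combination viability.  CDI > 1 antagonistic, = 1 additive, < 1
  synergistic, < 0.7 significantly synergistic.

* Bliss independence works on **inhibition fractions** (f = 1 - viability):
  expected combined inhibition is fa + fb - fa*fb, and the per-cell excess
  is observed minus expected.  The matrix-level score is 100 x the mean
  excess over all nonzero-dose cells, classified additive within [-10, +10].

* Confidence-bounded volumes sum, over nonzero-dose cells, the part of the
  excess whose t-based confidence interval excludes zero (in
  percentage-point x cell units): synergy volume from positive lower bounds,
  antagonism volume from negative upper bounds.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (CoverageError, InsufficientReplicatesError,
                     UndefinedCDIError)

CDI_SIGNIFICANT_SYNERGY = 0.7
CDI_ADDITIVE_TOL = 1e-9
BLISS_CLASS_BAND = 10.0  # percentage points

COMBO_COLUMNS = ("drug_a", "drug_b", "dose_a_nM", "dose_b_nM",
                 "replicate", "viability_fraction")


@dataclass(frozen=True)
class CombinationMatrix:
    """Checkerboard of viability fractions over a dose grid (0 doses included).

    ``data`` is long format with columns dose_a_nM, dose_b_nM, replicate,
    viability_fraction; the (0, 0) vehicle cell is 1 by construction.
    """

    drug_a: str
    drug_b: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"dose_a_nM", "dose_b_nM", "replicate", "viability_fraction"}
        if not need <= set(self.data.columns):
            raise ValueError(f"combination data needs columns {sorted(need)}")
        if (self.data["viability_fraction"] < 0).any():
            raise ValueError("viability fractions must be >= 0")
        cells = set(zip(self.data["dose_a_nM"], self.data["dose_b_nM"]))
        if (0.0, 0.0) not in cells:
            raise ValueError("the (0, 0) vehicle cell is required")

    @property
    def doses_a(self) -> np.ndarray:
        return np.sort(self.data["dose_a_nM"].unique())

    @property
    def doses_b(self) -> np.ndarray:
        return np.sort(self.data["dose_b_nM"].unique())

    def mean_viability(self) -> pd.DataFrame:
        """Replicate-mean viability grid (rows: dose_a, columns: dose_b)."""
        grid = self.data.pivot_table(index="dose_a_nM", columns="dose_b_nM",
                                     values="viability_fraction", aggfunc="mean")
        if grid.isna().any().any():
            raise CoverageError("dose grid has empty cells")
        return grid

    def replicates(self, dose_a: float, dose_b: float) -> np.ndarray:
        sel = (self.data["dose_a_nM"] == dose_a) & (self.data["dose_b_nM"] == dose_b)
        return self.data.loc[sel, "viability_fraction"].to_numpy(float)

    @classmethod
    def from_csv(cls, path) -> "CombinationMatrix":
        df = pd.read_csv(path)
        missing = set(COMBO_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"missing column(s): {sorted(missing)}")
        drugs_a, drugs_b = df["drug_a"].unique(), df["drug_b"].unique()
        if len(drugs_a) != 1 or len(drugs_b) != 1:
            raise ValueError("one combination (drug pair) per file")
        return cls(drug_a=drugs_a[0], drug_b=drugs_b[0],
                   data=df[["dose_a_nM", "dose_b_nM", "replicate",
                            "viability_fraction"]].astype(float))

    def to_csv(self, path) -> None:
        out = self.data.copy()
        out.insert(0, "drug_b", self.drug_b)
        out.insert(0, "drug_a", self.drug_a)
        out.to_csv(path, index=False, float_format="%.6g")


def cdi(a: float, b: float, ab: float) -> float:
    """Coefficient of drug interaction on viability fractions: ab / (a*b)."""
    if a <= 0 or b <= 0:
        raise UndefinedCDIError(
            f"CDI undefined for single-agent viabilities a={a}, b={b}")
    return ab / (a * b)


def classify_cdi(value: float) -> str:
    """Threshold classification of a CDI value (additive band is 1 +/- 1e-9)."""
    if value < 0:
        raise ValueError("CDI cannot be negative")
    if abs(value - 1.0) <= CDI_ADDITIVE_TOL:
        return "additive"
    if value > 1.0:
        return "antagonistic"
    if value < CDI_SIGNIFICANT_SYNERGY:
        return "significantly_synergistic"
    return "synergistic"


def bliss_excess(fa: float, fb: float, fab: float) -> float:
    """Observed minus Bliss-expected inhibition: fab - (fa + fb - fa*fb).

    Single-agent inhibitions are clamped to [0, 1] for the expected term;
    the observed fab is left raw.  Inputs far outside [0, 1] (beyond 0.25)
    trigger a warning since that exceeds plausible measurement noise.
    """
    for name, f in (("fa", fa), ("fb", fb), ("fab", fab)):
        if not -0.25 <= f <= 1.25:
            warnings.warn(f"inhibition {name}={f:.3g} far outside [0, 1]",
                          stacklevel=2)
    fa_c, fb_c = min(max(fa, 0.0), 1.0), min(max(fb, 0.0), 1.0)
    return fab - (fa_c + fb_c - fa_c * fb_c)


def _excess_grid(m: CombinationMatrix) -> pd.DataFrame:
    """Per-cell Bliss excess (inhibition units) from replicate-mean viability."""
    grid = m.mean_viability()
    if 0.0 not in grid.index or 0.0 not in grid.columns:
        raise CoverageError("single-agent row/column (dose 0) missing")
    inh = 1.0 - grid
    fa = inh.loc[:, 0.0]  # inhibition of drug A alone, per dose_a
    fb = inh.loc[0.0, :]  # inhibition of drug B alone, per dose_b
    excess = inh.copy()
    for da in grid.index:
        for db in grid.columns:
            excess.loc[da, db] = bliss_excess(fa[da], fb[db], inh.loc[da, db])
    return excess


def bliss_score(m: CombinationMatrix) -> tuple[float, str]:
    """Matrix-level Bliss synergy score and its classification.

    Score = 100 x mean per-cell excess over all cells where both doses are
    nonzero; |score| <= 10 is additive, above synergistic, below antagonistic.
    """
    excess = _excess_grid(m)
    nz = excess.loc[excess.index > 0, excess.columns > 0]
    if nz.size == 0:
        raise CoverageError("no nonzero-dose combination cells")
    score = float(nz.to_numpy().mean() * 100.0)
    if score > BLISS_CLASS_BAND:
        label = "synergistic"
    elif score < -BLISS_CLASS_BAND:
        label = "antagonistic"
    else:
        label = "additive"
    return score, label


def macsynergy_volumes(m: CombinationMatrix,
                       ci_level: float = 0.95) -> tuple[float, float]:
    """Confidence-bounded synergy and antagonism volumes.

    Per nonzero-dose cell, replicate-level excesses (observed inhibition
    minus the Bliss expectation from mean single-agent inhibitions) yield a
    t-distribution confidence interval; synergy volume sums positive lower
    bounds, antagonism volume sums negative upper bounds, in
    percentage-point x cell units.  Exactly-Bliss data give (0, 0).
    """
    if not 0 < ci_level < 1:
        raise ValueError("ci_level must be in (0, 1)")
    grid = m.mean_viability()
    if 0.0 not in grid.index or 0.0 not in grid.columns:
        raise CoverageError("single-agent row/column (dose 0) missing")
    fa = 1.0 - grid.loc[:, 0.0]
    fb = 1.0 - grid.loc[0.0, :]
    synergy = 0.0
    antagonism = 0.0
    for da in grid.index[grid.index > 0]:
        for db in grid.columns[grid.columns > 0]:
            obs = 1.0 - m.replicates(da, db)
            n = obs.size
            if n < 2:
                raise InsufficientReplicatesError(
                    f"cell ({da:g}, {db:g}) has {n} replicate(s); need >=2")
            fa_c = min(max(fa[da], 0.0), 1.0)
            fb_c = min(max(fb[db], 0.0), 1.0)
            expected = fa_c + fb_c - fa_c * fb_c
            exc = (obs - expected) * 100.0
            hw = stats.t.ppf(0.5 + ci_level / 2.0, n - 1) * exc.std(ddof=1) / np.sqrt(n)
            lower, upper = exc.mean() - hw, exc.mean() + hw
            synergy += max(0.0, lower)
            antagonism += min(0.0, upper)
    return synergy, antagonism


@dataclass(frozen=True)
class SynergyReport:
    """Per-cell CDI/excess plus matrix-level scores for one combination."""

    drug_a: str
    drug_b: str
    cells: pd.DataFrame  # dose_a_nM, dose_b_nM, viability, cdi, cdi_class, bliss_excess
    bliss_score: float
    bliss_class: str
    synergy_volume: float | None
    antagonism_volume: float | None
    ci_level: float

    def to_dict(self) -> dict:
        return {
            "drug_a": self.drug_a,
            "drug_b": self.drug_b,
            "bliss_score": self.bliss_score,
            "bliss_class": self.bliss_class,
            "synergy_volume": self.synergy_volume,
            "antagonism_volume": self.antagonism_volume,
            "ci_level": self.ci_level,
            "cells": self.cells.to_dict(orient="records"),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)


def synergy_report(m: CombinationMatrix, ci_level: float = 0.95) -> SynergyReport:
    """Assemble per-cell CDI + class, Bliss excess, matrix score and volumes.

    Volumes require >= 2 replicates per cell; with single replicates they
    are reported as None (the point estimates remain available).
    """
    grid = m.mean_viability()
    excess = _excess_grid(m)
    rows = []
    for da in grid.index[grid.index > 0]:
        for db in grid.columns[grid.columns > 0]:
            a, b, ab = grid.loc[da, 0.0], grid.loc[0.0, db], grid.loc[da, db]
            value = cdi(a, b, ab)
            rows.append({
                "dose_a_nM": float(da), "dose_b_nM": float(db),
                "viability": float(ab),
                "cdi": float(value), "cdi_class": classify_cdi(value),
                "bliss_excess": float(excess.loc[da, db]),
            })
    score, label = bliss_score(m)
    try:
        vol_syn, vol_ant = macsynergy_volumes(m, ci_level)
    except InsufficientReplicatesError:
        vol_syn = vol_ant = None
    return SynergyReport(drug_a=m.drug_a, drug_b=m.drug_b,
                         cells=pd.DataFrame(rows), bliss_score=score,
                         bliss_class=label, synergy_volume=vol_syn,
                         antagonism_volume=vol_ant, ci_level=ci_level)


__all__ = [
    "CombinationMatrix", "SynergyReport", "COMBO_COLUMNS", "cdi",
    "classify_cdi", "bliss_excess", "bliss_score", "macsynergy_volumes",
    "synergy_report", "CDI_SIGNIFICANT_SYNERGY", "BLISS_CLASS_BAND",
]
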