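"""Viability normalization and derived-signal arithmetic.

The central quantity is background-subtracted viability expressed as a
percentage of the vehicle (DMSO) control:

    viability% = (signal - mean background) / (mean control - mean background) * 100

Controls and backgrounds are pooled per (plate_id, model_id, timepoint) so
that inter-plate gain drift never leaks between plates.  Values are *not*
clamped to [0, 100]: growth stimulation (>100%) and over-kill (<0%) are real
observations that the screening cascade must see.

Also implemented here: death %, spheroid volume from radius, assay signal
normalized to parallel-plate viability, fold change vs control, and the
Seahorse mito-stress-test respiration metrics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DegeneratePlateError, GroupingError
from .plate_data import VIABILITY_COLUMNS, WellRecord, records_to_frame

#: injection phases of a mito stress test, in protocol order
OCR_PHASES = ("basal", "post_oligomycin", "post_FCCP", "post_rot_anti")


def normalize_viability(records: Iterable[WellRecord]) -> pd.DataFrame:
    """Normalize raw well signals to percent viability.

    Returns a viability table: one row per (compound_id, model_id, culture,
    concentration_nm, timepoint_h) with mean_viability, sd (sample SD,
    ddof=1; NaN for n=1) and n (number of contributing sample wells).

    Raises
    ------
    GroupingError
        if a (plate, model, timepoint) group lacks vehicle_control or
        background wells.
    DegeneratePlateError
        if the control mean does not exceed the background mean.
    """
    df = records_to_frame(records)
    if df.empty:
        raise GroupingError("no well records supplied")

    group_cols = ["plate_id", "model_id", "timepoint_h"]
    out_rows = []
    for key, grp in df.groupby(group_cols, sort=False):
        ctrl = grp.loc[grp.role == "vehicle_control", "raw_signal"]
        bg = grp.loc[grp.role == "background", "raw_signal"]
        if ctrl.empty or bg.empty:
            raise GroupingError(
                f"plate group {key} lacks "
                f"{'vehicle_control' if ctrl.empty else 'background'} wells")
        ctrl_mean, bg_mean = ctrl.mean(), bg.mean()
        if ctrl_mean <= bg_mean:
            raise DegeneratePlateError(
                f"plate group {key}: control mean {ctrl_mean:.4g} <= "
                f"background mean {bg_mean:.4g}")
        samples = grp[grp.role == "sample"].copy()
        samples["viability"] = (samples.raw_signal - bg_mean) / (ctrl_mean - bg_mean) * 100.0
        out_rows.append(samples)

    samples = pd.concat(out_rows, ignore_index=True)
    agg = (samples
           .groupby(["compound_id", "model_id", "culture", "concentration",
                     "timepoint_h"], sort=True)["viability"]
           .agg(mean_viability="mean", sd=lambda s: s.std(ddof=1), n="count")
           .reset_index()
           .rename(columns={"concentration": "concentration_nm"}))
    return agg[list(VIABILITY_COLUMNS)]


def death_percent(viability):
    """Percent cell death complementary to viability: 100 - viability.

    Extends below zero for stimulated wells (viability > 100%).
    """
    return 100.0 - np.asarray(viability, dtype=float) if np.ndim(viability) else 100.0 - float(viability)


def spheroid_volume(radius: float) -> float:
    """Spheroid volume (µm³) from radius (µm): V = (4/3)·π·r³."""
    if radius <= 0:
        raise ValueError(f"radius must be > 0, got {radius}")
    return (4.0 / 3.0) * math.pi * radius ** 3


def signal_per_viability(assay_signal: float, viability: float) -> float:
    """Assay signal normalized to the viability of duplicate-plated cells.

    ``viability`` is in percent; a signal of 200 at 50% viability yields 400.
    """
    if viability <= 0:
        raise ValueError(f"viability must be > 0 to normalize, got {viability}")
    return assay_signal / (viability / 100.0)


def fold_change_vs_control(values: Sequence[float], control_values: Sequence[float]) -> float:
    """mean(values) / mean(control_values); control mean must be positive."""
    control_mean = float(np.mean(control_values))
    if control_mean <= 0:
        raise ValueError(f"control mean must be > 0, got {control_mean}")
    return float(np.mean(values)) / control_mean


@dataclass(frozen=True)
class OcrTrace:
    """Oxygen-consumption-rate measurements grouped by injection phase."""

    phases: Mapping[str, Sequence[float]]

    def __post_init__(self) -> None:
        for phase in OCR_PHASES:
            vals = self.phases.get(phase)
            if vals is None or len(vals) == 0:
                raise ValueError(f"OCR phase {phase!r} missing or empty")

    @classmethod
    def from_tsv(cls, path) -> "OcrTrace":
        df = pd.read_csv(path, sep="\t")
        need = {"phase", "measurement_index", "ocr"}
        if not need <= set(df.columns):
            raise ValueError(f"OCR TSV needs columns {sorted(need)}")
        phases = {p: g.sort_values("measurement_index")["ocr"].tolist()
                  for p, g in df.groupby("phase")}
        return cls(phases=phases)


@dataclass(frozen=True)
class MitoMetrics:
    """Respiration metrics in pmol O2/min; spare = maximal - basal."""

    basal: float
    atp_linked: float
    maximal: float
    spare: float


def mito_stress_metrics(trace: OcrTrace) -> MitoMetrics:
    """Derive respiration metrics from a mito stress test.

    atp_linked = basal - mean(post-oligomycin);
    maximal    = mean(post-FCCP) - mean(post-rotenone/antimycin);
    spare      = maximal - basal.
    """
    means = {p: float(np.mean(trace.phases[p])) for p in OCR_PHASES}
    basal = means["basal"]
    atp_linked = basal - means["post_oligomycin"]
    maximal = means["post_FCCP"] - means["post_rot_anti"]
    return MitoMetrics(basal=basal, atp_linked=atp_linked,
                       maximal=maximal, spare=maximal - basal)


__all__ = [
    "OCR_PHASES", "OcrTrace", "MitoMetrics", "normalize_viability",
    "death_percent", "spheroid_volume", "signal_per_viability",
    "fold_change_vs_control", "mito_stress_metrics",
]
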