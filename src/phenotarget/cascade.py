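"""Multi-stage hit-filtering engine for phenotypic screens.

A screening funnel is an ordered list of stages.  Each stage names a
concentration, a culture format, a set of cell models, a percent-death
threshold and an aggregation rule: a compound survives a stage iff its
replicate-mean death strictly exceeds the threshold in at least one
(``any_model``) or in every (``all_models``) listed model.  Thresholds are
strict by convention ("more than X% cell death"), so a compound at exactly
the threshold is eliminated.  Survivor sets are nested by construction.

Missing measurements are a hard error, never an implicit pass or fail: a
funnel must not make calls on compounds it did not measure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
import yaml

from .errors import CoverageError
from .plate_data import CULTURES

AGGREGATIONS = ("any_model", "all_models")

#: neuroblastoma models used in the reference spheroid panel
SPHEROID_PANEL = ("SK-N-BE2", "IMR-32", "CHP-212", "SH-SY5Y", "SK-N-AS")


@dataclass(frozen=True)
class CascadeStage:
    """One filtering stage of a screening funnel."""

    name: str
    concentration_nm: float
    culture: str
    models: tuple[str, ...]
    death_threshold_pct: float
    aggregation: str
    timepoint_h: float = 72.0

    def __post_init__(self) -> None:
        if not self.models:
            raise ValueError(f"stage {self.name!r}: empty model set")
        if not 0 < self.death_threshold_pct < 100:
            raise ValueError(
                f"stage {self.name!r}: death threshold must be in (0, 100)")
        if self.aggregation not in AGGREGATIONS:
            raise ValueError(f"stage {self.name!r}: bad aggregation "
                             f"{self.aggregation!r}")
        if self.culture not in CULTURES:
            raise ValueError(f"stage {self.name!r}: bad culture {self.culture!r}")


@dataclass(frozen=True)
class CascadeReport:
    """Ordered survivor sets; stage k+1 survivors are a subset of stage k."""

    input_count: int
    input_compounds: tuple[str, ...]
    stages: tuple[CascadeStage, ...]
    survivors: tuple[frozenset[str], ...]

    @property
    def survivor_counts(self) -> tuple[int, ...]:
        return tuple(len(s) for s in self.survivors)

    @property
    def final_survivors(self) -> frozenset[str]:
        return self.survivors[-1] if self.survivors else frozenset(self.input_compounds)

    def to_dict(self) -> dict:
        return {
            "input_count": self.input_count,
            "stages": [
                {
                    "name": st.name,
                    "concentration_nm": st.concentration_nm,
                    "culture": st.culture,
                    "models": list(st.models),
                    "death_threshold_pct": st.death_threshold_pct,
                    "aggregation": st.aggregation,
                    "timepoint_h": st.timepoint_h,
                    "survivor_count": len(surv),
                    "survivors": sorted(surv),
                }
                for st, surv in zip(self.stages, self.survivors)
            ],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)


def default_screen_stages() -> list[CascadeStage]:
    """The reference four-stage neuroblastoma screening funnel.

    (1) monolayer CHP-212 at 10 µM, >20% death;
    (2) chemoresistant SK-N-BE2 spheroids at 10 µM, >20% death;
    (3) five spheroid models at 1 µM, >20% death in every model;
    (4) the same five spheroid models at 1 µM, >50% death in every model;
    all read at 72 h.
    """
    return [
        CascadeStage("monolayer_10uM", 10000.0, "monolayer", ("CHP-212",),
                     20.0, "any_model"),
        CascadeStage("spheroid_SK-N-BE2_10uM", 10000.0, "spheroid",
                     ("SK-N-BE2",), 20.0, "any_model"),
        CascadeStage("spheroid_panel_1uM_gt20", 1000.0, "spheroid",
                     SPHEROID_PANEL, 20.0, "all_models"),
        CascadeStage("spheroid_panel_1uM_gt50", 1000.0, "spheroid",
                     SPHEROID_PANEL, 50.0, "all_models"),
    ]


def run_cascade(viability: pd.DataFrame,
                stages: Sequence[CascadeStage]) -> CascadeReport:
    """Run a funnel over a viability table.

    ``viability`` is the table produced by
    :func:`phenotarget.viability.normalize_viability`.  Stage decisions use
    the replicate-mean viability.  A missing (compound, model, culture,
    dose, timepoint) measurement for a compound still in play raises
    :class:`CoverageError` naming the gap.
    """
    lookup: dict[tuple, float] = {}
    for row in viability.itertuples(index=False):
        key = (row.compound_id, row.model_id, row.culture,
               float(row.concentration_nm), float(row.timepoint_h))
        lookup[key] = float(row.mean_viability)

    compounds = tuple(sorted(viability["compound_id"].unique()))
    alive: set[str] = set(compounds)
    survivor_sets: list[frozenset[str]] = []

    for stage in stages:
        next_alive: set[str] = set()
        for cpd in sorted(alive):
            deaths = []
            for model in stage.models:
                key = (cpd, model, stage.culture, float(stage.concentration_nm),
                       float(stage.timepoint_h))
                if key not in lookup:
                    raise CoverageError(
                        f"stage {stage.name!r}: no viability for compound "
                        f"{cpd!r}, model {model!r} ({stage.culture}, "
                        f"{stage.concentration_nm:g} nM, {stage.timepoint_h:g} h)")
                deaths.append(100.0 - lookup[key])
            hits = [d > stage.death_threshold_pct for d in deaths]
            passed = any(hits) if stage.aggregation == "any_model" else all(hits)
            if passed:
                next_alive.add(cpd)
        alive = next_alive
        survivor_sets.append(frozenset(alive))

    return CascadeReport(input_count=len(compounds), input_compounds=compounds,
                         stages=tuple(stages), survivors=tuple(survivor_sets))


def cascade_confusion(report: CascadeReport,
                      truth: Iterable[str]) -> tuple[float, float]:
    """Sensitivity and specificity of the final survivor set vs known truth."""
    truth_set = set(truth)
    if not truth_set:
        raise ValueError("truth set is empty")
    all_compounds = set(report.input_compounds)
    if not truth_set <= all_compounds:
        raise ValueError("truth contains compounds absent from the screen")
    final = set(report.final_survivors)
    negatives = all_compounds - truth_set
    tp = len(final & truth_set)
    tn = len(negatives - final)
    sensitivity = tp / len(truth_set)
    specificity = tn / len(negatives) if negatives else 1.0
    return sensitivity, specificity


_STAGE_KEYS = {"name", "concentration_nM", "culture", "models",
               "death_threshold_pct", "aggregation", "timepoint_h"}


def load_stages(path) -> list[CascadeStage]:
    """Load a funnel configuration from YAML (list of stage mappings)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, list) or not raw:
        raise ValueError("stage file must contain a non-empty list of stages")
    stages = []
    for entry in raw:
        unknown = set(entry) - _STAGE_KEYS
        if unknown:
            raise ValueError(f"unknown stage key(s): {sorted(unknown)}")
        stages.append(CascadeStage(
            name=str(entry["name"]),
            concentration_nm=float(entry["concentration_nM"]),
            culture=str(entry["culture"]),
            models=tuple(entry["models"]),
            death_threshold_pct=float(entry["death_threshold_pct"]),
            aggregation=str(entry["aggregation"]),
            timepoint_h=float(entry.get("timepoint_h", 72.0)),
        ))
    return stages


__all__ = [
    "CascadeStage", "CascadeReport", "SPHEROID_PANEL", "AGGREGATIONS",
    "default_screen_stages", "run_cascade", "cascade_confusion", "load_stages",
]
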