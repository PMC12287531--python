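"""Ground-truth generators for every pipeline input.

Each generator is a right-inverse of its analysis stage at zero noise:
feeding its output through the corresponding analysis recovers the planted
truth exactly.  All randomness flows from an explicit integer seed through
:class:`numpy.random.Generator`; no global state is touched.

Noise conventions: fluorescence/abundance noise is multiplicative
log-normal with unit mean (positivity-preserving, like instrument noise);
OCR noise is additive Gaussian.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .cascade import SPHEROID_PANEL
from .plate_data import WellRecord
from .synergy import CombinationMatrix
from .pisa import SolubilityMatrix
from .viability import OcrTrace

_ROWS = "ABCDEFGH"
_COLS = list(range(1, 13))


@dataclass
class TruthTable:
    """Planted ground truth emitted alongside every generated dataset."""

    compound_class: dict[str, str] = field(default_factory=dict)
    true_viability: dict[tuple[str, str, float], float] = field(default_factory=dict)
    spiked: dict[str, float] = field(default_factory=dict)
    true_tm: dict[str, float] = field(default_factory=dict)
    excess_field: np.ndarray | None = None
    extras: dict = field(default_factory=dict)

    def toxic_compounds(self) -> set[str]:
        return {c for c, cls in self.compound_class.items() if cls == "pan_toxic"}

    def to_dict(self) -> dict:
        return {
            "compound_class": self.compound_class,
            "true_viability": {f"{c}|{m}|{d:g}": v
                               for (c, m, d), v in self.true_viability.items()},
            "spiked": self.spiked,
            "true_tm": self.true_tm,
            "excess_field": (self.excess_field.tolist()
                             if self.excess_field is not None else None),
            "extras": self.extras,
        }


def _mean_one_lognormal(rng: np.random.Generator, cv: float, size=None) -> np.ndarray:
    """Multiplicative noise factors with E[X] = 1 and the given CV."""
    if cv == 0:
        return np.ones(size if size is not None else ())
    sigma = np.sqrt(np.log1p(cv ** 2))
    return rng.lognormal(mean=-sigma ** 2 / 2.0, sigma=sigma, size=size)


@dataclass(frozen=True)
class ScreenLibrarySpec:
    """Conditions of a synthetic phenotypic screen.

    The default plan covers the reference funnel: one monolayer model at
    10 µM, the chemoresistant spheroid model at 10 µM, and the five-model
    spheroid panel at 1 µM.
    """

    n_compounds: int = 200
    n_toxic: int = 12
    n_partial: int = 0
    models: tuple[str, ...] = SPHEROID_PANEL
    replicates: int = 3
    noise_cv: float = 0.05
    background_mean: float = 100.0
    control_mean: float = 1000.0
    timepoint_h: float = 72.0
    seed: int = 0
    # (culture, model, dose_nM) combinations to plate; None -> funnel default
    plan: tuple[tuple[str, str, float], ...] | None = None

    def __post_init__(self) -> None:
        if self.n_toxic + self.n_partial > self.n_compounds:
            raise ValueError("n_toxic + n_partial exceeds n_compounds")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.control_mean <= self.background_mean:
            raise ValueError("control_mean must exceed background_mean")

    def effective_plan(self) -> list[tuple[str, str, float]]:
        if self.plan is not None:
            return list(self.plan)
        plan = [("monolayer", "CHP-212", 10000.0),
                ("spheroid", "SK-N-BE2", 10000.0)]
        plan += [("spheroid", m, 1000.0) for m in self.models]
        return plan


def _plate_wells():
    """Per-plate well layout: 88 sample wells, column 12 reserved for
    4 vehicle-control and 4 background wells."""
    sample_wells = [(r, c) for c in _COLS[:-1] for r in _ROWS]
    control_wells = [(r, 12) for r in _ROWS[:4]]
    background_wells = [(r, 12) for r in _ROWS[4:]]
    return sample_wells, control_wells, background_wells


def simulate_screen_library(spec: ScreenLibrarySpec) -> tuple[list[WellRecord], TruthTable]:
    """Generate raw plate wells for a compound library with known toxicity.

    True per-model viabilities: pan-toxic compounds sit at > 60% death in
    every model at 1 µM (and deeper at 10 µM); inert compounds at < 10%
    death everywhere; partial compounds are toxic in a strict subset of
    models.  Raw signal = background + (control - background) x viability/100
    x log-normal noise.
    """
    rng = np.random.default_rng(spec.seed)
    compounds = [f"CPD-{i + 1:04d}" for i in range(spec.n_compounds)]
    order = rng.permutation(spec.n_compounds)
    toxic = {compounds[i] for i in order[:spec.n_toxic]}
    partial = {compounds[i] for i in order[spec.n_toxic:spec.n_toxic + spec.n_partial]}

    truth = TruthTable()
    partial_models: dict[str, set[str]] = {}
    for cpd in compounds:
        if cpd in toxic:
            truth.compound_class[cpd] = "pan_toxic"
        elif cpd in partial:
            truth.compound_class[cpd] = "partial"
            k = int(rng.integers(1, len(spec.models)))
            partial_models[cpd] = set(rng.choice(spec.models, size=k, replace=False))
        else:
            truth.compound_class[cpd] = "inert"

    def draw_true_viability(cpd: str, model: str, dose: float) -> float:
        cls = truth.compound_class[cpd]
        toxic_here = cls == "pan_toxic" or (
            cls == "partial" and model in partial_models[cpd])
        if toxic_here:
            v1 = rng.uniform(5.0, 35.0)       # death 65-95% at 1 uM
            return v1 if dose <= 1000.0 else rng.uniform(2.0, min(15.0, v1))
        return rng.uniform(92.0, 99.0)        # death 1-8% at any dose

    plan = spec.effective_plan()
    # truth per (compound, model, dose); independent of culture format
    for culture, model, dose in plan:
        for cpd in compounds:
            key = (cpd, model, dose)
            if key not in truth.true_viability:
                truth.true_viability[key] = draw_true_viability(cpd, model, dose)

    records: list[WellRecord] = []
    sample_wells, control_wells, background_wells = _plate_wells()
    for culture, model, dose in plan:
        assignments = [(cpd, rep) for cpd in compounds
                       for rep in range(1, spec.replicates + 1)]
        for chunk_idx in range(0, len(assignments), len(sample_wells)):
            chunk = assignments[chunk_idx:chunk_idx + len(sample_wells)]
            plate_id = f"{culture[:3].upper()}-{model}-{dose:g}-{chunk_idx // len(sample_wells) + 1:02d}"
            for (cpd, rep), well in zip(chunk, sample_wells):
                v = truth.true_viability[(cpd, model, dose)]
                signal = spec.background_mean + (
                    spec.control_mean - spec.background_mean) * v / 100.0
                signal *= _mean_one_lognormal(rng, spec.noise_cv, None)
                records.append(WellRecord(plate_id, well, "sample", cpd, dose,
                                          model, culture, spec.timepoint_h,
                                          rep, float(signal)))
            for i, well in enumerate(control_wells):
                signal = spec.control_mean * _mean_one_lognormal(rng, spec.noise_cv, None)
                records.append(WellRecord(plate_id, well, "vehicle_control", "",
                                          0.0, model, culture, spec.timepoint_h,
                                          i + 1, float(signal)))
            for i, well in enumerate(background_wells):
                signal = spec.background_mean * _mean_one_lognormal(rng, spec.noise_cv, None)
                records.append(WellRecord(plate_id, well, "background", "",
                                          0.0, model, culture, spec.timepoint_h,
                                          i + 1, float(signal)))
    return records, truth


def simulate_pisa_proteome(n_proteins: int = 5000,
                           spiked: Sequence[tuple[str | int, float]] = (),
                           cv: float = 0.05,
                           n_control: int = 4,
                           n_treated: int = 3,
                           frac_low_peptides: float = 0.05,
                           seed: int = 0) -> tuple[SolubilityMatrix, TruthTable]:
    """Log-normal proteome with condition-specific soluble-fraction spikes.

    ``spiked`` lists (protein id or index, fold shift) pairs; treated
    samples carry the spiked proteins' abundance multiplied by the fold.
    Unique-peptide counts are drawn >= 1 with ``frac_low_peptides`` of
    proteins set to a single peptide (spiked proteins always keep >= 2 so
    the planted truth survives the quantification filter).
    """
    if any(fold <= 0 for _, fold in spiked):
        raise ValueError("fold shifts must be > 0")
    if cv < 0:
        raise ValueError("cv must be >= 0")
    rng = np.random.default_rng(seed)
    ids = [f"PROT{i + 1:05d}" for i in range(n_proteins)]

    def resolve(p) -> str:
        if isinstance(p, str):
            if p not in ids:
                raise ValueError(f"spiked protein {p!r} not in matrix")
            return p
        if not 0 <= p < n_proteins:
            raise ValueError(f"spiked protein index {p} out of range")
        return ids[p]

    spike_map = {resolve(p): float(fold) for p, fold in spiked}

    base = rng.lognormal(mean=13.8, sigma=1.2, size=n_proteins)
    folds = np.array([spike_map.get(pid, 1.0) for pid in ids])

    cols, names, conds = [], [], []
    for r in range(1, n_control + 1):
        cols.append(base * _mean_one_lognormal(rng, cv, n_proteins))
        names.append(f"control_{r}")
        conds.append("control")
    for r in range(1, n_treated + 1):
        cols.append(base * folds * _mean_one_lognormal(rng, cv, n_proteins))
        names.append(f"treated_{r}")
        conds.append("treated")

    abundance = pd.DataFrame(np.column_stack(cols), index=pd.Index(ids, name="protein_id"),
                             columns=names)
    peptides = 2 + rng.poisson(5, size=n_proteins)
    low = rng.random(n_proteins) < frac_low_peptides
    peptides[low] = 1
    for pid in spike_map:
        peptides[ids.index(pid)] = max(peptides[ids.index(pid)], 2)

    matrix = SolubilityMatrix(
        abundance=abundance,
        unique_peptides=pd.Series(peptides, index=abundance.index),
        conditions=pd.Series(conds, index=names, name="condition"))
    truth = TruthTable(spiked=spike_map)
    return matrix, truth


def simulate_cetsa(tm_control: float = 52.0,
                   delta_tm: float = 3.0,
                   grid: Sequence[float] | None = None,
                   noise_cv: float = 0.05,
                   plateau: float = 0.05,
                   slope: float = 0.6,
                   base_density: float = 10000.0,
                   seed: int = 0):
    """Paired control/treated melt curves with a known Tm shift.

    Returns ((temps, control densities), (temps, treated densities), truth).
    The default grid is 40-67 °C in 3 °C steps.  A Tm pushed more than 5 °C
    off the grid triggers a warning: the transition becomes unobservable.
    """
    temps = np.asarray(grid if grid is not None else np.arange(40.0, 68.0, 3.0),
                       dtype=float)
    if temps.min() < 30.0 or temps.max() > 80.0:
        raise ValueError("temperature grid must lie within 30-80 C")
    rng = np.random.default_rng(seed)
    tm_treated = tm_control + delta_tm
    for tm in (tm_control, tm_treated):
        if tm < temps.min() - 5.0 or tm > temps.max() + 5.0:
            warnings.warn(f"Tm {tm:.1f} C is more than 5 C off the grid",
                          stacklevel=2)

    def curve(tm: float) -> np.ndarray:
        frac = plateau + (1.0 - plateau) / (1.0 + np.exp(slope * (temps - tm)))
        return base_density * frac * _mean_one_lognormal(rng, noise_cv, temps.size)

    control = (temps.copy(), curve(tm_control))
    treated = (temps.copy(), curve(tm_treated))
    truth = TruthTable(true_tm={"control": tm_control, "treated": tm_treated},
                       extras={"delta_tm": delta_tm})
    return control, treated, truth


def simulate_combination(doses_a: Sequence[float],
                         doses_b: Sequence[float],
                         single_agent_ic50s: tuple[float, float],
                         excess_field: np.ndarray | None = None,
                         replicates: int = 3,
                         noise_cv: float = 0.05,
                         drug_a: str = "drug_A",
                         drug_b: str = "drug_B",
                         seed: int = 0) -> tuple[CombinationMatrix, TruthTable]:
    """Checkerboard viability matrix built on a Bliss-consistent backbone.

    Single-agent inhibitions follow fixed-slope Hill curves at the given
    IC50s; each nonzero-dose cell's inhibition is the Bliss expectation plus
    the matching entry of ``excess_field`` (zeros if omitted), truncated to
    [0, 1].  The (0, 0) vehicle cell is exactly 1.
    """
    da = np.asarray(sorted(set([0.0] + [float(d) for d in doses_a])))
    db = np.asarray(sorted(set([0.0] + [float(d) for d in doses_b])))
    da_nz, db_nz = da[da > 0], db[db > 0]
    if excess_field is None:
        excess_field = np.zeros((da_nz.size, db_nz.size))
    excess_field = np.asarray(excess_field, dtype=float)
    if excess_field.shape != (da_nz.size, db_nz.size):
        raise ValueError(f"excess_field shape {excess_field.shape} does not "
                         f"match nonzero grid {(da_nz.size, db_nz.size)}")
    ic50_a, ic50_b = single_agent_ic50s
    rng = np.random.default_rng(seed)

    def hill_inhibition(dose: float, ic50: float) -> float:
        return 0.0 if dose == 0 else 1.0 - 1.0 / (1.0 + dose / ic50)

    rows = []
    for i, dose_a in enumerate(da):
        for j, dose_b in enumerate(db):
            fa = hill_inhibition(dose_a, ic50_a)
            fb = hill_inhibition(dose_b, ic50_b)
            inh = fa + fb - fa * fb
            if dose_a > 0 and dose_b > 0:
                inh += excess_field[np.searchsorted(da_nz, dose_a),
                                    np.searchsorted(db_nz, dose_b)]
            inh = min(max(inh, 0.0), 1.0)
            for rep in range(1, replicates + 1):
                if dose_a == 0 and dose_b == 0:
                    v = 1.0  # vehicle cell is 1 by construction
                else:
                    v = (1.0 - inh) * float(_mean_one_lognormal(rng, noise_cv, None))
                rows.append({"dose_a_nM": dose_a, "dose_b_nM": dose_b,
                             "replicate": rep, "viability_fraction": v})
    matrix = CombinationMatrix(drug_a=drug_a, drug_b=drug_b,
                               data=pd.DataFrame(rows))
    truth = TruthTable(excess_field=excess_field,
                       extras={"ic50_a": ic50_a, "ic50_b": ic50_b,
                               "doses_a": da_nz.tolist(), "doses_b": db_nz.tolist()})
    return matrix, truth


def simulate_ocr_trace(basal: float = 100.0,
                       atp_linked: float = 60.0,
                       maximal: float = 150.0,
                       non_mito: float = 15.0,
                       noise_sd: float = 0.0,
                       n_measurements: int = 3,
                       seed: int = 0) -> OcrTrace:
    """Mito-stress-test OCR trace with three measurements per phase.

    Phase means are constructed so the respiration metrics recover
    (basal, atp_linked, maximal) exactly at zero noise; ``non_mito`` is the
    rotenone/antimycin-resistant floor.
    """
    if not basal >= atp_linked >= 0:
        raise ValueError("need basal >= atp_linked >= 0")
    if non_mito < 0 or noise_sd < 0:
        raise ValueError("non_mito and noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    means = {
        "basal": basal,
        "post_oligomycin": basal - atp_linked,
        "post_FCCP": maximal + non_mito,
        "post_rot_anti": non_mito,
    }
    phases = {p: (m + rng.normal(0.0, noise_sd, n_measurements)).tolist()
              for p, m in means.items()}
    return OcrTrace(phases=phases)


__all__ = [
    "TruthTable", "ScreenLibrarySpec", "simulate_screen_library",
    "simulate_pisa_proteome", "simulate_cetsa", "simulate_combination",
    "simulate_ocr_trace",
]
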