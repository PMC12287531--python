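# Methods

This note documents the models, conventions and design choices behind
`phenotarget`, in the order of the analysis chain. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Plate data model

Plate measurements travel as long-format CSV with explicit well roles
(`sample`, `vehicle_control`, `background`, `blank`). A grid layout was
rejected because it is ambiguous about roles and replicates; the tidy
layout makes every downstream join unambiguous. Wells are addressed as row
letter plus 1-based column (A1…H12); concentrations are stored in nM
internally and converted from nM/µM/M on ingest. Duplicated
`(plate_id, well)` pairs, unknown roles, controls carrying a compound, and
nonzero concentrations on non-sample wells are hard errors at parse time.

## Viability normalization

viability% = (signal − mean background) / (mean control − mean background) × 100.

* **Pooling scope** is per `(plate_id, model_id, timepoint)`. Pooling
  controls per plate guards against inter-plate gain drift; pooling across
  plates would let a bright plate silently rescale a dim one.
* **No clamping** to [0, 100]. Stimulated wells (>100%) and over-killed
  wells (<0%) carry information, and the cascade's strict threshold
  comparisons must see the raw normalized value.
* Replicates aggregate as arithmetic mean with sample SD (ddof = 1, NaN
  for n = 1), matching the mean ± SD convention of screening reports.
* A plate whose control mean does not exceed its background mean is
  degenerate and refuses to normalize rather than emitting sign-flipped
  viabilities.

Derived-signal helpers follow the same percent conventions: death% =
100 − viability%; spheroid volume V = (4/3)πr³ from the measured radius;
assay signal per viability = signal/(viability/100) for ATP/apoptosis
readouts normalized to duplicate-plated viability; fold change =
mean(condition)/mean(control). Mito stress metrics use per-phase means over
all measurements (no outlier rejection): ATP-linked = basal −
post-oligomycin; maximal = post-FCCP − post-rotenone/antimycin; spare =
maximal − basal.

## Dose–response

The normalized-response model Y = 100/(1 + (X/IC50)^h) has no floor or
ceiling parameters — viability is assumed already normalized. The default
variant fixes h = 1; the variable-slope variant bounds h to [0.1, 10]
because spheroid curves are often shallow. IC50 is optimized as log10(IC50)
(scale-equivariant, keeps the parameter positive), started at the measured
dose closest to 50% response, and bounded to [min dose/100, max dose·100].
A solution on the bound is reported unconverged — the typical signature of
a flat, non-responding profile — and no IC50 is emitted. R² is computed
against the mean-viability null model, so a fit can score below zero when
it is worse than a constant. Zero-dose points are excluded from the
residuals (the model is exactly 100 there and they carry no information
about IC50).

## Screening cascade

Stages are data (`name`, concentration, culture, model set, death
threshold, any/all aggregation, timepoint), so alternative funnels are
configuration, not code. Conventions:

* **Strict inequalities**: "more than 20% death" eliminates a compound at
  exactly 20.0%.
* Decisions use **replicate-mean viability**, not per-replicate voting.
* **Missing data is a hard error** naming the gap. A funnel that silently
  passes or fails unmeasured compounds corrupts every downstream count.
* Survivor sets are nested by construction; with identical thresholds and
  the all-models rule, stage order does not change the final set
  (intersection property), which the tests assert on random instances.
* A repeat of a stage on fresh data is modeled as just that — re-running
  the stage; no meta-analysis is performed across repeated screens, and
  only replicate-mean combination of repeated single-dose screens is
  offered.

The built-in default funnel is the four-stage design used for the
neuroblastoma campaign this package accompanies: monolayer CHP-212 at
10 µM (>20% death), SK-N-BE2 spheroids at 10 µM (>20%), then the
five-spheroid panel (SK-N-BE2, IMR-32, CHP-212, SH-SY5Y, SK-N-AS) at 1 µM
with >20% and finally >50% death required in every model, all at 72 h.

## Solubility-shift (PISA) ranking

* **Total-intensity normalization** scales every sample column to the
  grand-mean column sum (idempotent by construction).
* **Quantification filter**: ≥2 unique peptides and no missing abundance in
  any sample; missing values are excluded, never imputed.
* **Statistics**: "Student's t-test" is taken literally as the
  pooled-variance two-sample t, two-sided; Welch is available as an option.
  The test runs on log2-transformed abundances for variance stabilization
  (a choice this package makes and documents, since raw-vs-log is
  commonly left unstated in PISA reports). Control-average normalization
  divides each protein by its control mean; being a per-protein constant
  it cancels in the t statistic and makes log2 FC = log2(treated mean).
* **Score** = (−log10 p) · log2 FC, signed; ranking is by |score|
  descending (both stabilized and destabilized targets count), ties broken
  by smaller p then protein id. Zero variance in both groups with equal
  means yields p = 1 and score 0; proteins with zero control mean or
  non-positive abundances are excluded with a warning.
* **No multiple-testing correction** enters the ranking (the score is a
  prioritization heuristic, not an error-rate guarantee); a
  Benjamini–Hochberg column is emitted for information.

The fold-change definition follows the soluble-fraction
treated-over-control convention; where figure legends describe it as
soluble-to-insoluble, that phrasing is treated as descriptive of the assay,
not as a different ratio.

## Thermal shift (CETSA)

Band densities are floored at a configurable epsilon (bands below
detection), normalized to the lowest-temperature value, and fitted with a
single-sigmoid two-state model with a free lower plateau; Tm is the
inflection point, constrained to the grid ± 5 °C. Normalizing by the first
grid point is an anchor choice, not a model statement: the true curve at
the lowest temperature is slightly below its asymptote, which biases
recovered Tm by a few hundredths of a degree — negligible against the 3 °C
grid spacing. Flat profiles (span < 5% after normalization) are flagged
unconverged rather than fitted. ΔTm is a plain difference of converged Tm
values. The helper ΔG = −RT ln(Keq) (R = 8.314 J mol⁻¹ K⁻¹, output in
kJ/mol) is included as a standalone thermodynamics utility.

## Combination synergy

CDI is computed on viability fractions from replicate-mean cells;
Bliss excess on inhibition fractions. The two nulls coincide (CDI = 1 ⇔
excess = 0), which the tests assert algebraically. Conventions:

* CDI classification: >1 antagonistic, =1 (±1e−9) additive, <1
  synergistic, <0.7 significantly synergistic. Measured data essentially
  never hit the additive band; classification is threshold-driven as
  printed.
* Matrix score = 100 × mean excess over nonzero-dose cells, additive in
  [−10, +10]. This is the documented mean-excess Bliss summary; no other
  aggregate is defined here.
* Single-agent inhibitions are clamped to [0, 1] before the expected term;
  observed combination inhibition is left raw (noise can push it mildly
  outside, which is information about the cell, not the reference model).
* **Volumes**: per nonzero-dose cell, replicate-level excesses give a
  t-based confidence interval at the chosen level; synergy volume sums
  positive lower bounds, antagonism volume negative upper bounds, in
  percentage-point·cell units. Classic implementations express volumes in
  dose-spacing-dependent units (µM²·%); since those units are not
  portable across dose grids, this package uses the per-cell dialect with
  the same sign convention (volume > 0 ⇒ synergy). With a single
  replicate volumes are reported as None — a CI requires variance — while
  point estimates remain available.

## Synthetic-data generators

Each generator is the exact inverse of its analysis stage at zero noise,
and every dataset ships with its truth table, so recovery tests never
hard-code expectations. Defaults are the study conditions of the campaign
the package models:

* **Screen**: 200 compounds, 12 pan-toxic, 3 replicates, 5% multiplicative
  CV, control/background means 1000/100 AU; plates hold 88 sample wells
  plus 4 vehicle-control and 4 background wells in column 12. Pan-toxic
  compounds draw >60% death in every model at 1 µM (deeper at 10 µM),
  inert compounds <10% death, partial compounds are toxic in a strict
  subset of models.
* **Proteome**: log-normal base abundances (ln-scale mean 13.8, σ 1.2,
  i.e. media ~10⁶ intensity units), n = 4 control vs n = 3 treated, 5%
  within-group CV, 5% of proteins below the 2-peptide filter; the default
  spike is a conservative 1.6-fold soluble-fraction increase.
* **Melt curves**: the 40–67 °C / 3 °C grid with plateau 0.05 and slope
  0.6 °C⁻¹ (a transition ~8 °C wide, typical of immunoblot CETSA), 5%
  density noise.
* **Combinations**: fixed-slope Hill single agents, Bliss-consistent
  backbone plus an arbitrary per-cell excess field, truncated to [0, 1];
  the vehicle cell is exactly 1.
* **OCR**: three measurements per phase, additive Gaussian noise, with a
  non-mitochondrial floor parameter so maximal respiration recovers
  exactly.

Noise character: multiplicative mean-one log-normal for
fluorescence/abundance (positivity-preserving), additive Gaussian for OCR.
All draws flow from one explicit integer seed; nothing touches global
random state.

What the generators do **not** emulate: plate spatial (edge) effects,
peptide-to-protein rollup and TMT reporter-ion artifacts, cell-growth
kinetics, or dose–response hysteresis. Passing recovery tests therefore
demonstrates correctness of the analysis arithmetic and its statistical
calibration under idealized instrument noise — not robustness to every
systematic artifact of real plates or LC-MS runs.

## Problem sizes and reproducibility

The test suite and acceptance script use the generators' default
conditions: a 200-compound screen, 200 simulations each for the null
false-positive calibration (1000-protein matrices) and the 5000-protein
spike-recovery study, 100 noisy IC50 profiles, and 100 melt-curve pairs.
These sizes give binomial standard errors comfortably inside the asserted
tolerances (e.g. ±0.0005 on the pooled 0.05 false-positive rate). The demo
pipeline and acceptance script derive all per-stage seeds from one root
seed via `numpy.random.SeedSequence`, and all numeric file output is
formatted to 6 significant digits, so repeated runs are byte-identical.

## Known limitations

* The cascade exposes replicate-mean decisions only; a screen whose
  repeats were combined by another rule (e.g. majority vote across three
  independent runs) needs custom pre-aggregation.
* IC50 confidence intervals (profile likelihood) and biphasic models are
  out of scope; `r_squared` and `converged` are the only fit diagnostics.
* The melt-curve model is two-state with a free lower plateau; proteins
  with multi-domain melting or aggregation artifacts will fit poorly
  (visible as high RSS) rather than being detected explicitly.
* Synergy volumes are a dialect (percentage-point·cell units); absolute
  values are not comparable to µM²·% volumes from legacy software, though
  signs and zero/nonzero behaviour are.
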