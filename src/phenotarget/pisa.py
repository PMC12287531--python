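"""Solubility-shift (PISA-style) target deconvolution.

A drug that engages a protein changes that protein's thermal solubility, so
the soluble-fraction abundance of the target shifts between treated and
control TMT channels.  The ranking chain is:

1. total-intensity normalization (every sample column scaled to the grand
   mean column sum),
2. filtering to proteins quantified with >= 2 unique peptides and no
   missing values,
3. per protein: control-average normalization, log2 fold change of the
   treated mean over the control mean, a two-sided pooled-variance
   (Student's) two-sample t-test on log2 abundances,
4. score = (-log10 p) * log2 fold change, ranked by |score| descending.

The raw p-value drives the ranking; a Benjamini-Hochberg adjusted column is
emitted for information only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateSampleError, InsufficientDataError

CONDITIONS = ("control", "treated")

#: columns of a ranking table
RANKING_COLUMNS = ("protein_id", "log2_fc", "p_value", "p_adj_bh", "score", "rank")


@dataclass(frozen=True)
class SolubilityMatrix:
    """Protein x sample abundance matrix with condition labels.

    ``abundance`` is indexed by protein_id with one column per sample;
    ``conditions`` maps each sample column to 'control' or 'treated';
    ``unique_peptides`` holds per-protein unique-peptide counts.
    """

    abundance: pd.DataFrame
    unique_peptides: pd.Series
    conditions: pd.Series

    def __post_init__(self) -> None:
        if not self.abundance.columns.equals(self.conditions.index):
            raise ValueError("conditions must be indexed by the sample columns")
        bad = set(self.conditions.unique()) - set(CONDITIONS)
        if bad:
            raise ValueError(f"unknown condition label(s): {sorted(bad)}")
        if (self.abundance.to_numpy(dtype=float, na_value=np.nan) < 0).any():
            raise ValueError("negative abundances are not allowed")
        if not self.unique_peptides.index.equals(self.abundance.index):
            raise ValueError("unique_peptides must be indexed by protein_id")

    def samples(self, condition: str) -> list[str]:
        return list(self.conditions.index[self.conditions == condition])

    @classmethod
    def from_tsv(cls, path) -> "SolubilityMatrix":
        """Read the TSV dialect: protein_id, unique_peptides, <cond>_<rep>..."""
        df = pd.read_csv(path, sep="\t")
        if "protein_id" not in df.columns or "unique_peptides" not in df.columns:
            raise ValueError("TSV needs 'protein_id' and 'unique_peptides' columns")
        df = df.set_index("protein_id")
        sample_cols = [c for c in df.columns if c != "unique_peptides"]
        conditions = pd.Series(
            {c: c.rsplit("_", 1)[0] for c in sample_cols}, name="condition")
        return cls(abundance=df[sample_cols].astype(float),
                   unique_peptides=df["unique_peptides"].astype(int),
                   conditions=conditions)

    def to_tsv(self, path) -> None:
        out = self.abundance.copy()
        out.insert(0, "unique_peptides", self.unique_peptides)
        out.reset_index().rename(columns={"index": "protein_id"}).to_csv(
            path, sep="\t", index=False, float_format="%.6g")


def normalize_total_intensity(m: SolubilityMatrix) -> SolubilityMatrix:
    """Scale each sample column so all column sums equal their grand mean."""
    sums = m.abundance.sum(axis=0)
    if (sums <= 0).any():
        bad = list(sums.index[sums <= 0])
        raise DegenerateSampleError(f"zero total intensity in sample(s) {bad}")
    target = sums.mean()
    return replace(m, abundance=m.abundance * (target / sums))


def filter_quantified(m: SolubilityMatrix,
                      min_unique_peptides: int = 2) -> SolubilityMatrix:
    """Keep proteins with >= min unique peptides and complete quantification."""
    complete = m.abundance.notna().all(axis=1)
    keep = (m.unique_peptides >= min_unique_peptides) & complete
    if not keep.any():
        warnings.warn("no proteins pass the quantification filter", stacklevel=2)
    return replace(m, abundance=m.abundance.loc[keep],
                   unique_peptides=m.unique_peptides.loc[keep])


def pisa_scores(m: SolubilityMatrix, equal_var: bool = True) -> pd.DataFrame:
    """Per-protein fold change, t-test p-value, score and rank.

    Proteins with a zero control mean, or with non-positive abundances that
    preclude the log transform, are excluded from the ranking with a warning.
    Zero within-group variance with equal group means yields p = 1 (score 0).

    ``equal_var=False`` switches to Welch's t-test.
    """
    ctrl_cols = m.samples("control")
    trt_cols = m.samples("treated")
    if len(ctrl_cols) < 2 or len(trt_cols) < 2:
        raise InsufficientDataError("need >=2 samples per condition for the t-test")

    ab = m.abundance
    ctrl_mean = ab[ctrl_cols].mean(axis=1)
    usable = (ctrl_mean > 0) & (ab > 0).all(axis=1)
    if not usable.all():
        warnings.warn(f"{int((~usable).sum())} protein(s) excluded "
                      "(zero control mean or non-positive abundance)", stacklevel=2)
    ab = ab.loc[usable]
    ctrl_mean = ctrl_mean.loc[usable]

    # control-average normalization; a per-protein constant, so it shifts
    # both groups' log2 values identically and leaves the t statistic intact
    normed = ab.div(ctrl_mean, axis=0)
    log2 = np.log2(normed)

    log2_fc = np.log2(normed[trt_cols].mean(axis=1) / normed[ctrl_cols].mean(axis=1))

    with np.errstate(divide="ignore", invalid="ignore"):
        t_res = stats.ttest_ind(log2[trt_cols], log2[ctrl_cols], axis=1,
                                equal_var=equal_var)
    p = np.asarray(t_res.pvalue, dtype=float)
    # zero variance in both groups: equal means -> no evidence (p = 1)
    both_const = (log2[trt_cols].var(axis=1, ddof=1).to_numpy() == 0) & \
                 (log2[ctrl_cols].var(axis=1, ddof=1).to_numpy() == 0)
    equal_means = np.isclose(log2[trt_cols].mean(axis=1), log2[ctrl_cols].mean(axis=1))
    p = np.where(np.isnan(p) & both_const & equal_means, 1.0, p)
    # degenerate zero-variance, unequal-mean case: certain difference
    p = np.where(np.isnan(p) & both_const & ~equal_means, 0.0, p)

    with np.errstate(divide="ignore"):
        score = -np.log10(p) * log2_fc.to_numpy()

    out = pd.DataFrame({
        "protein_id": ab.index,
        "log2_fc": log2_fc.to_numpy(),
        "p_value": p,
        "p_adj_bh": multipletests(np.clip(p, 0.0, 1.0), method="fdr_bh")[1],
        "score": score,
    })
    out["abs_score"] = out["score"].abs()
    out = out.sort_values(["abs_score", "p_value", "protein_id"],
                          ascending=[False, True, True], kind="mergesort")
    out = out.drop(columns="abs_score").reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out[list(RANKING_COLUMNS)]


def top_targets(ranking: pd.DataFrame, k: int = 10) -> list[str]:
    """First k protein ids by rank."""
    if k <= 0:
        raise ValueError("k must be positive")
    if k > len(ranking):
        raise ValueError(f"k={k} exceeds the {len(ranking)}-protein ranking")
    return ranking.sort_values("rank")["protein_id"].head(k).tolist()


__all__ = [
    "SolubilityMatrix", "RANKING_COLUMNS", "normalize_total_intensity",
    "filter_quantified", "pisa_scores", "top_targets",
]
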