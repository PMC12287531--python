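"""Solubility-shift ranking tests, including a from-scratch oracle.

The oracle recomputes log2 fold change, the pooled-variance two-sample t
statistic, its p-value and the score with explicit per-protein loops and
the textbook formulas, independent of the vectorized implementation.
"""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from phenotarget.errors import DegenerateSampleError, InsufficientDataError
from phenotarget.pisa import (SolubilityMatrix, filter_quantified,
                              normalize_total_intensity, pisa_scores,
                              top_targets)
from phenotarget.simulate import simulate_pisa_proteome


def make_matrix(values, peptides=None, n_control=2, n_treated=2):
    """SolubilityMatrix from a 2-D array (proteins x samples)."""
    values = np.asarray(values, dtype=float)
    names = [f"control_{i+1}" for i in range(n_control)] + \
            [f"treated_{i+1}" for i in range(n_treated)]
    ids = [f"P{i+1:03d}" for i in range(values.shape[0])]
    ab = pd.DataFrame(values, index=pd.Index(ids, name="protein_id"),
                      columns=names)
    pep = pd.Series(peptides if peptides is not None else [5] * len(ids),
                    index=ab.index)
    cond = pd.Series(["control"] * n_control + ["treated"] * n_treated,
                     index=names)
    return SolubilityMatrix(ab, pep, cond)


def oracle_scores(matrix):
    """Textbook per-protein recomputation (explicit loops)."""
    ctrl = matrix.samples("control")
    trt = matrix.samples("treated")
    rows = []
    for pid in matrix.abundance.index:
        c = [matrix.abundance.loc[pid, s] for s in ctrl]
        t = [matrix.abundance.loc[pid, s] for s in trt]
        cm = sum(c) / len(c)
        c_n = [v / cm for v in c]
        t_n = [v / cm for v in t]
        log2_fc = math.log2((sum(t_n) / len(t_n)) / (sum(c_n) / len(c_n)))
        lc = [math.log2(v) for v in c_n]
        lt = [math.log2(v) for v in t_n]
        mc, mt = sum(lc) / len(lc), sum(lt) / len(lt)
        ssc = sum((v - mc) ** 2 for v in lc)
        sst = sum((v - mt) ** 2 for v in lt)
        df = len(lc) + len(lt) - 2
        sp2 = (ssc + sst) / df
        se = math.sqrt(sp2 * (1 / len(lc) + 1 / len(lt)))
        tstat = (mt - mc) / se
        p = 2 * stats.t.sf(abs(tstat), df)
        rows.append((pid, log2_fc, p, -math.log10(p) * log2_fc))
    return rows


class TestNormalization:
    def test_column_sums_equalized(self):
        m = make_matrix([[100, 40, 60, 30], [100, 60, 90, 45]])
        out = normalize_total_intensity(m)
        sums = out.abundance.sum(axis=0)
        assert np.allclose(sums, sums.iloc[0])
        assert sums.iloc[0] == pytest.approx(m.abundance.sum(axis=0).mean())

    def test_two_sample_definition(self):
        m = make_matrix([[2.0, 4.0]], n_control=1, n_treated=1)
        out = normalize_total_intensity(m)
        assert np.allclose(out.abundance.to_numpy(), [[3.0, 3.0]])

    def test_idempotent(self):
        m = make_matrix(np.random.default_rng(0).uniform(1, 100, (20, 4)))
        once = normalize_total_intensity(m)
        twice = normalize_total_intensity(once)
        pd.testing.assert_frame_equal(once.abundance, twice.abundance)

    def test_zero_sum_sample(self):
        with pytest.raises(DegenerateSampleError):
            normalize_total_intensity(make_matrix([[0.0, 1.0, 1.0, 1.0]]))


class TestFilter:
    def test_peptide_threshold(self):
        m = make_matrix([[1] * 4, [1] * 4, [1] * 4], peptides=[1, 2, 3])
        assert len(filter_quantified(m, 2).abundance) == 2
        assert len(filter_quantified(m, 0).abundance) == 3

    def test_missing_value_excluded(self):
        vals = np.ones((2, 4))
        vals[1, 2] = np.nan
        m = make_matrix(vals)
        assert filter_quantified(m, 0).abundance.index.tolist() == ["P001"]


class TestScores:
    def test_score_formula(self):
        # protein engineered to p ~ known, fc = 2; score = -log10(p) * 1
        m = make_matrix([[1.0, 1.1, 2.0, 2.2],
                         [1.0, 1.0, 1.0, 1.0]])
        out = pisa_scores(m)
        null_row = out[out.protein_id == "P002"].iloc[0]
        assert null_row["log2_fc"] == 0.0
        assert null_row["p_value"] == 1.0
        assert null_row["score"] == 0.0
        fc_row = out[out.protein_id == "P001"].iloc[0]
        expected = -math.log10(fc_row["p_value"]) * fc_row["log2_fc"]
        assert fc_row["score"] == pytest.approx(expected, rel=1e-12)

    def test_oracle_equivalence_200x7(self):
        rng = np.random.default_rng(5)
        vals = rng.lognormal(10, 1, (200, 7))
        m = make_matrix(vals, n_control=4, n_treated=3)
        out = pisa_scores(m).set_index("protein_id")
        for pid, log2_fc, p, score in oracle_scores(m):
            assert out.loc[pid, "log2_fc"] == pytest.approx(log2_fc, abs=1e-10)
            assert out.loc[pid, "p_value"] == pytest.approx(p, abs=1e-10)
            assert out.loc[pid, "score"] == pytest.approx(score, abs=1e-10)

    def test_condition_swap_antisymmetry(self):
        rng = np.random.default_rng(6)
        vals = rng.lognormal(8, 1, (50, 7))
        m = make_matrix(vals, n_control=4, n_treated=3)
        swapped_names = [c.replace("control", "X").replace("treated", "control")
                         .replace("X", "treated") for c in m.abundance.columns]
        m_swap = SolubilityMatrix(
            m.abundance.set_axis(swapped_names, axis=1),
            m.unique_peptides,
            pd.Series([c.rsplit("_", 1)[0] for c in swapped_names],
                      index=swapped_names))
        a = pisa_scores(m).set_index("protein_id")
        b = pisa_scores(m_swap).set_index("protein_id")
        # swapping labels negates every log2_fc; |score| ranking is identical
        np.testing.assert_allclose(a["log2_fc"], -b.loc[a.index, "log2_fc"],
                                   atol=1e-10)
        np.testing.assert_allclose(a["p_value"], b.loc[a.index, "p_value"],
                                   atol=1e-10)
        assert a["rank"].equals(b.loc[a.index, "rank"])

    def test_insufficient_replicates(self):
        with pytest.raises(InsufficientDataError):
            pisa_scores(make_matrix([[1, 2, 3]], n_control=1, n_treated=2))

    def test_spiked_target_ranks_first(self):
        m, truth = simulate_pisa_proteome(n_proteins=800,
                                          spiked=[("PROT00400", 1.6)],
                                          cv=0.05, seed=9)
        ranking = pisa_scores(filter_quantified(normalize_total_intensity(m)))
        assert top_targets(ranking, 1) == ["PROT00400"]

    def test_null_matrix_all_zero_fc_at_zero_cv(self):
        m, _ = simulate_pisa_proteome(n_proteins=50, spiked=[], cv=0.0, seed=1)
        out = pisa_scores(filter_quantified(normalize_total_intensity(m)))
        np.testing.assert_allclose(out["log2_fc"], 0.0, atol=1e-12)
        np.testing.assert_allclose(out["score"], 0.0, atol=1e-12)

    def test_exact_fold_at_zero_cv(self):
        # no total-intensity rescaling here: on a tiny matrix the spike
        # itself shifts the treated column sums, so the raw generated
        # abundances are the exact inverse construction
        m, _ = simulate_pisa_proteome(n_proteins=50,
                                      spiked=[("PROT00025", 4.0)],
                                      cv=0.0, seed=2)
        out = pisa_scores(filter_quantified(m))
        row = out[out.protein_id == "PROT00025"].iloc[0]
        assert row["log2_fc"] == pytest.approx(2.0, abs=1e-9)


class TestTopTargets:
    def test_rank_order_and_bounds(self):
        rng = np.random.default_rng(3)
        m = make_matrix(rng.lognormal(8, 1, (10, 7)), n_control=4, n_treated=3)
        ranking = pisa_scores(m)
        assert top_targets(ranking, 10) == ranking.sort_values("rank")[
            "protein_id"].tolist()
        assert top_targets(ranking, 1)[0] == ranking.loc[
            ranking["score"].abs().idxmax(), "protein_id"]
        with pytest.raises(ValueError):
            top_targets(ranking, 0)
        with pytest.raises(ValueError):
            top_targets(ranking, 11)
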