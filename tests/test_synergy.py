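import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from phenotarget.errors import (InsufficientReplicatesError, UndefinedCDIError)
from phenotarget.simulate import simulate_combination
from phenotarget.synergy import (bliss_excess, bliss_score, cdi, classify_cdi,
                                 macsynergy_volumes, synergy_report)

from conftest import make_combo


def bliss_grid(viab_a, viab_b):
    """Exactly Bliss-consistent viability grid from single-agent viabilities."""
    grid = {(0.0, 0.0): 1.0}
    for da, va in viab_a.items():
        grid[(da, 0.0)] = va
    for db, vb in viab_b.items():
        grid[(0.0, db)] = vb
    for da, va in viab_a.items():
        for db, vb in viab_b.items():
            grid[(da, db)] = va * vb
    return grid


VIAB_A = {10.0: 0.8, 30.0: 0.5, 90.0: 0.25}
VIAB_B = {100.0: 0.7, 300.0: 0.4, 900.0: 0.2}


class TestCdi:
    @pytest.mark.parametrize("a,b,ab,expected", [
        (0.5, 0.5, 0.25, 1.0),
        (0.8, 0.8, 0.32, 0.5),
    ])
    def test_arithmetic(self, a, b, ab, expected):
        assert cdi(a, b, ab) == pytest.approx(expected)

    def test_zero_single_agent_rejected(self):
        with pytest.raises(UndefinedCDIError):
            cdi(0.5, 0.0, 0.1)

    @given(a=st.floats(0.01, 1.2), b=st.floats(0.01, 1.2),
           ab=st.floats(0.0, 1.2))
    def test_symmetry_under_drug_swap(self, a, b, ab):
        assert cdi(a, b, ab) == cdi(b, a, ab)

    @given(a=st.floats(0.05, 1.0), b=st.floats(0.05, 1.0))
    def test_cdi_one_iff_bliss_excess_zero(self, a, b):
        """Both null models agree: CDI = 1 exactly when excess = 0."""
        ab = a * b  # Bliss-expected combination viability
        assert cdi(a, b, ab) == pytest.approx(1.0, rel=1e-12)
        assert bliss_excess(1 - a, 1 - b, 1 - ab) == pytest.approx(0.0, abs=1e-12)


class TestClassifyCdi:
    @pytest.mark.parametrize("value,label", [
        (1.3, "antagonistic"),
        (1.0, "additive"),
        (1.0 + 5e-10, "additive"),
        (0.85, "synergistic"),
        (0.7, "synergistic"),
        (0.69, "significantly_synergistic"),
    ])
    def test_thresholds(self, value, label):
        assert classify_cdi(value) == label

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            classify_cdi(-0.1)


class TestBlissExcess:
    @pytest.mark.parametrize("fa,fb,fab,expected", [
        (0.3, 0.4, 0.58, 0.0),
        (0.3, 0.4, 0.70, 0.12),
        (0.0, 0.0, 0.0, 0.0),
    ])
    def test_arithmetic(self, fa, fb, fab, expected):
        assert bliss_excess(fa, fb, fab) == pytest.approx(expected)

    def test_far_out_of_range_warns(self):
        with pytest.warns(UserWarning):
            bliss_excess(1.5, 0.2, 0.5)


class TestBlissScore:
    def test_exact_bliss_matrix_scores_zero(self):
        m = make_combo(bliss_grid(VIAB_A, VIAB_B))
        score, label = bliss_score(m)
        assert abs(score) < 1e-9
        assert label == "additive"
        report = synergy_report(m)
        assert all(c == pytest.approx(1.0, abs=1e-9)
                   for c in report.cells["cdi"])

    @pytest.mark.parametrize("excess,expected,label", [
        (0.15, 15.0, "synergistic"), (-0.15, -15.0, "antagonistic")])
    def test_uniform_injected_excess(self, excess, expected, label):
        # moderate single-agent effects keep all shifted viabilities in [0, 1]
        viab_a = {10.0: 0.95, 30.0: 0.85, 90.0: 0.75}
        viab_b = {100.0: 0.9, 300.0: 0.8, 900.0: 0.7}
        grid = bliss_grid(viab_a, viab_b)
        for (da, db) in list(grid):
            if da > 0 and db > 0:
                grid[(da, db)] -= excess  # inhibition +excess = viability -excess
        m = make_combo(grid)
        score, got = bliss_score(m)
        assert score == pytest.approx(expected, abs=1e-9)
        assert got == label

    def test_row_column_permutation_invariance(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            grid = bliss_grid(VIAB_A, VIAB_B)
            noisy = {k: max(v * (1 + rng.normal(0, 0.1)), 0.0)
                     for k, v in grid.items()}
            noisy[(0.0, 0.0)] = 1.0
            score1, _ = bliss_score(make_combo(noisy))
            relabel_a = {10.0: 90.0, 30.0: 10.0, 90.0: 30.0, 0.0: 0.0}
            permuted = {(relabel_a[da], db): v for (da, db), v in noisy.items()}
            score2, _ = bliss_score(make_combo(permuted))
            assert score2 == pytest.approx(score1, rel=1e-12)


class TestVolumes:
    def test_exact_bliss_gives_zero_volumes(self):
        m = make_combo(bliss_grid(VIAB_A, VIAB_B), replicates=3)
        syn, ant = macsynergy_volumes(m)
        assert syn == pytest.approx(0.0, abs=1e-9)
        assert ant == pytest.approx(0.0, abs=1e-9)

    def test_single_cell_excess_recovered(self):
        grid = bliss_grid(VIAB_A, VIAB_B)
        grid[(30.0, 300.0)] -= 0.20  # +20 percentage points inhibition
        m = make_combo(grid, replicates=3, jitter=1e-6)
        syn, ant = macsynergy_volumes(m)
        assert syn == pytest.approx(20.0, abs=0.5)
        assert ant == pytest.approx(0.0, abs=0.5)

    def test_sign_flip_symmetry(self):
        grid = bliss_grid(VIAB_A, VIAB_B)
        grid[(30.0, 300.0)] += 0.20
        m = make_combo(grid, replicates=3, jitter=1e-6)
        syn, ant = macsynergy_volumes(m)
        assert syn == pytest.approx(0.0, abs=0.5)
        assert ant == pytest.approx(-20.0, abs=0.5)

    def test_monotone_in_injected_excess(self):
        volumes = []
        for excess in (0.05, 0.10, 0.20):
            grid = bliss_grid(VIAB_A, VIAB_B)
            grid[(30.0, 300.0)] -= excess
            m = make_combo(grid, replicates=3, jitter=1e-6)
            volumes.append(macsynergy_volumes(m)[0])
        assert volumes == sorted(volumes)

    def test_single_replicate_rejected(self):
        m = make_combo(bliss_grid(VIAB_A, VIAB_B), replicates=1)
        with pytest.raises(InsufficientReplicatesError):
            macsynergy_volumes(m)


class TestSynergyReport:
    def test_hand_computed_toy_matrix(self):
        grid = {(0.0, 0.0): 1.0, (10.0, 0.0): 0.8, (0.0, 100.0): 0.5,
                (10.0, 100.0): 0.3, (20.0, 0.0): 0.6, (0.0, 200.0): 0.4,
                (20.0, 100.0): 0.2, (10.0, 200.0): 0.25, (20.0, 200.0): 0.1}
        report = synergy_report(make_combo(grid))
        cell = report.cells.set_index(["dose_a_nM", "dose_b_nM"])
        assert cell.loc[(10.0, 100.0), "cdi"] == pytest.approx(0.3 / (0.8 * 0.5))
        assert cell.loc[(20.0, 200.0), "cdi"] == pytest.approx(0.1 / (0.6 * 0.4))
        # excess on inhibitions: fab - (fa + fb - fa*fb)
        fa, fb, fab = 0.2, 0.5, 0.7
        assert cell.loc[(10.0, 100.0), "bliss_excess"] == pytest.approx(
            fab - (fa + fb - fa * fb))
        assert report.synergy_volume is None  # single replicate

    def test_all_additive_matrix(self):
        report = synergy_report(make_combo(bliss_grid(VIAB_A, VIAB_B)))
        assert set(report.cells["cdi_class"]) == {"additive"}
        assert report.bliss_class == "additive"

    def test_generator_synergy_window_localized(self):
        field = np.zeros((3, 3))
        field[0, 0] = 0.25  # synergy confined to the low-dose corner
        m, _ = simulate_combination([25, 50, 100], [250, 500, 1000],
                                    (100.0, 1000.0), excess_field=field,
                                    noise_cv=0.0, seed=0)
        report = synergy_report(m)
        cells = report.cells
        top = cells.loc[cells["bliss_excess"].abs().idxmax()]
        assert (top["dose_a_nM"], top["dose_b_nM"]) == (25.0, 250.0)
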