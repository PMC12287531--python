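import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


def make_plate_frame(rows):
    """Build a plate CSV DataFrame from (well, role, compound, conc_nM, signal)."""
    return pd.DataFrame([{
        "plate_id": r.get("plate_id", "P1"),
        "well": r["well"],
        "role": r["role"],
        "compound_id": r.get("compound_id", ""),
        "concentration": r.get("concentration", 0.0),
        "concentration_unit": r.get("concentration_unit", "nM"),
        "model_id": r.get("model_id", "CHP-212"),
        "culture": r.get("culture", "monolayer"),
        "timepoint_h": r.get("timepoint_h", 72.0),
        "replicate": r.get("replicate", 1),
        "raw_signal": r["raw_signal"],
    } for r in rows])


@pytest.fixture
def simple_plate_csv(tmp_path):
    """3-well plate: one sample, one vehicle control, one background."""
    df = make_plate_frame([
        {"well": "A1", "role": "sample", "compound_id": "CPD-1",
         "concentration": 1000.0, "raw_signal": 500.0},
        {"well": "A2", "role": "vehicle_control", "raw_signal": 1000.0},
        {"well": "A3", "role": "background", "raw_signal": 100.0},
    ])
    path = tmp_path / "plate.csv"
    df.to_csv(path, index=False)
    return path


@pytest.fixture
def viability_table():
    """Hand-written viability table for cascade threshold tests."""
    viabs = {"CPD-1": 10.0, "CPD-2": 30.0, "CPD-3": 45.0,
             "CPD-4": 55.0, "CPD-5": 79.0, "CPD-6": 81.0}
    return pd.DataFrame([{
        "compound_id": c, "model_id": "CHP-212", "culture": "monolayer",
        "concentration_nm": 10000.0, "timepoint_h": 72.0,
        "mean_viability": v, "sd": 0.0, "n": 3,
    } for c, v in viabs.items()])


def make_combo(grid, replicates=1, drug_a="A", drug_b="B", jitter=None):
    """CombinationMatrix from a dict {(dose_a, dose_b): viability fraction}."""
    from phenotarget.synergy import CombinationMatrix
    rows = []
    rng = np.random.default_rng(0)
    for (da, db), v in grid.items():
        for rep in range(1, replicates + 1):
            vv = v if jitter is None else v * (1 + rng.normal(0, jitter))
            rows.append({"dose_a_nM": float(da), "dose_b_nM": float(db),
                         "replicate": rep, "viability_fraction": float(max(vv, 0))})
    return CombinationMatrix(drug_a=drug_a, drug_b=drug_b, data=pd.DataFrame(rows))
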