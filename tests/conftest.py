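import numpy as np
import pandas as pd
import pytest

from epitomics import biochip, synthetic


@pytest.fixture(scope="session")
def small_cohort():
    """40-sample cohort with one planted effect mAb (log effect 0.5)."""
    cfg = synthetic.CohortConfig(
        n_cases=20, n_controls=20, n_mabs=5, effect_mabs=[("mab_001", 0.5)], seed=11
    )
    meta, abundance = synthetic.generate_cohort(cfg)
    return cfg, meta, abundance


@pytest.fixture(scope="session")
def noise_free_run(small_cohort):
    _, _, abundance = small_cohort
    return synthetic.generate_biochip_runs(
        abundance, "QP69", synthetic.NoiseModel.noise_free(), seed=7, n_replicates=2
    )


def make_records(rows):
    """Build a measurement table from (sample_id, mab_id, run_id, position, role,
    dilution, replicate, rlu) shorthand tuples."""
    full = [
        {
            "sample_id": r[0],
            "mab_id": r[1],
            "run_id": r[2],
            "rack": 1,
            "position": r[3],
            "role": r[4],
            "operator": "op_1",
            "lot": "lot_1",
            "dilution": r[5],
            "replicate": r[6],
            "rlu": r[7],
        }
        for r in rows
    ]
    return pd.DataFrame(full, columns=biochip.MEASUREMENT_COLUMNS)


@pytest.fixture
def tiny_qp69_run():
    """One QP69 run: two tracer positions (90, 110) and one sample at RLU 50."""
    rows = [
        ("", "mab_001", "run_1", 1, "tracer_only", np.nan, 1, 90.0),
        ("", "mab_001", "run_1", 2, "tracer_only", np.nan, 1, 110.0),
        ("s1", "mab_001", "run_1", 3, "sample", 100.0, 1, 50.0),
    ]
    return biochip.BiochipRun(layout_kind="QP69", records=make_records(rows))
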