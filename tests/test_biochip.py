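"""Normalization arithmetic, the 120 cap, scale invariance, and TSV round-trips."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epitomics import biochip, synthetic
from epitomics.biochip import BiochipRun, NormalizationError

from conftest import make_records


class TestNormalizeQP69:
    def test_hand_arithmetic(self, tiny_qp69_run):
        prof = biochip.normalize_qp69(tiny_qp69_run)
        # tracer mean (90+110)/2 = 100 -> 100*50/100
        assert prof.values["value"].tolist() == [50.0]

    def test_tracer_self_normalization(self):
        rows = [
            ("", "m1", "r1", 1, "tracer_only", np.nan, 1, 400.0),
            ("", "m1", "r1", 2, "tracer_only", np.nan, 1, 400.0),
            ("s1", "m1", "r1", 3, "sample", 100.0, 1, 400.0),
        ]
        run = BiochipRun("QP69", make_records(rows))
        assert biochip.normalize_qp69(run).values["value"].iloc[0] == 100.0

    def test_zero_rlu_maps_to_zero(self):
        rows = [
            ("", "m1", "r1", 1, "tracer_only", np.nan, 1, 90.0),
            ("", "m1", "r1", 2, "tracer_only", np.nan, 1, 110.0),
            ("s1", "m1", "r1", 3, "sample", 100.0, 1, 0.0),
        ]
        run = BiochipRun("QP69", make_records(rows))
        assert biochip.normalize_qp69(run).values["value"].iloc[0] == 0.0

    def test_missing_tracers_error_names_run(self):
        rows = [("s1", "m1", "runX", 3, "sample", 100.0, 1, 50.0)]
        run = BiochipRun("QP69", make_records(rows))
        with pytest.raises(NormalizationError, match="runX"):
            biochip.normalize_qp69(run)

    def test_zero_rlumax_flags_mab(self):
        rows = [
            ("", "m1", "r1", 1, "tracer_only", np.nan, 1, 0.0),
            ("", "m1", "r1", 2, "tracer_only", np.nan, 1, 0.0),
            ("s1", "m1", "r1", 3, "sample", 100.0, 1, 50.0),
        ]
        run = BiochipRun("QP69", make_records(rows))
        prof = biochip.normalize_qp69(run)
        assert len(prof.values) == 0
        assert prof.flagged == [("r1", "m1", "zero or missing RLUmax")]

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(c=st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariance(self, c):
        rows = [
            ("", "m1", "r1", 1, "tracer_only", np.nan, 1, 90.0),
            ("", "m1", "r1", 2, "tracer_only", np.nan, 1, 110.0),
            ("s1", "m1", "r1", 3, "sample", 100.0, 1, 50.0),
            ("s2", "m1", "r1", 4, "sample", 100.0, 1, 77.0),
        ]
        base = BiochipRun("QP69", make_records(rows))
        scaled_records = base.records.copy()
        scaled_records["rlu"] *= c
        scaled = BiochipRun("QP69", scaled_records)
        np.testing.assert_allclose(
            biochip.normalize_qp69(scaled).values["value"],
            biochip.normalize_qp69(base).values["value"],
            rtol=1e-12,
        )


class TestNormalizeQP300:
    def test_hand_arithmetic(self):
        rows = [
            ("", "m1", "r1", 1, "tracer_only", np.nan, 1, 120.0),
            ("s1", "m1", "r1", 2, "sample", 300.0, 1, 30.0),
        ]
        run = BiochipRun("QP300", make_records(rows))
        assert biochip.normalize_qp300(run).values["value"].iloc[0] == 25.0

    def test_two_tracer_positions_is_layout_violation(self):
        rows = [
            ("", "m1", "r1", 1, "tracer_only", np.nan, 1, 100.0),
            ("", "m1", "r1", 2, "tracer_only", np.nan, 1, 100.0),
            ("s1", "m1", "r1", 3, "sample", 300.0, 1, 30.0),
        ]
        run = BiochipRun("QP300", make_records(rows))
        with pytest.raises(NormalizationError):
            biochip.normalize_qp300(run)

    def test_per_run_isolation(self, small_cohort):
        _, _, ab = small_cohort
        run = synthetic.generate_biochip_runs(
            ab, "QP300", synthetic.NoiseModel(0.05, 0.1, 0, 0), seed=13, n_replicates=1
        )
        full = biochip.normalize_qp300(run)
        first_run = run.records["run_id"].iloc[0]
        only = BiochipRun("QP300", run.records[run.records["run_id"] == first_run].copy())
        sub = biochip.normalize_qp300(only).values
        ref = full.values[full.values["run_id"] == first_run].reset_index(drop=True)
        pd.testing.assert_frame_equal(sub.reset_index(drop=True), ref)


class TestAggregateReplicates:
    @pytest.mark.parametrize(
        "reps,expected",
        [([95.0, 105.0], 100.0), ([130.0, 140.0], 120.0), ([47.3], 47.3)],
    )
    def test_mean_then_cap(self, reps, expected):
        values = pd.DataFrame(
            {
                "sample_id": ["s1"] * len(reps),
                "mab_id": ["m1"] * len(reps),
                "dilution": [100.0] * len(reps),
                "value": reps,
                "n_replicates": [1] * len(reps),
            }
        )
        agg = biochip.aggregate_replicates(biochip.NormalizedProfile(values))
        assert agg.values["value"].iloc[0] == expected
        assert agg.values["n_replicates"].iloc[0] == len(reps)

    def test_cap_idempotence(self, noise_free_run):
        prof = biochip.normalize_qp69(noise_free_run)
        once = biochip.aggregate_replicates(prof)
        twice = biochip.aggregate_replicates(once)
        pd.testing.assert_frame_equal(once.values, twice.values)


class TestIO:
    def test_measurement_round_trip(self, noise_free_run, tmp_path):
        path = tmp_path / "measurements.tsv"
        biochip.write_measurements(noise_free_run, path)
        back = biochip.read_measurements(path)
        assert back.layout_kind == "QP69"
        pd.testing.assert_frame_equal(
            back.records.reset_index(drop=True),
            noise_free_run.records.reset_index(drop=True),
            check_dtype=False,
        )

    def test_empty_file_with_header(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("\t".join(biochip.MEASUREMENT_COLUMNS) + "\n")
        run = biochip.read_measurements(path, layout_kind="QP69")
        assert len(run.records) == 0

    def test_negative_rlu_rejected_with_line_number(self, tmp_path):
        path = tmp_path / "bad.tsv"
        header = "\t".join(biochip.MEASUREMENT_COLUMNS)
        good = "s1\tm1\tr1\t1\t3\tsample\top_1\tlot_1\t100\t1\t50"
        bad = "s2\tm1\tr1\t1\t4\tsample\top_1\tlot_1\t100\t1\t-5"
        path.write_text(f"{header}\n{good}\n{bad}\n")
        with pytest.raises(ValueError, match="line 3"):
            biochip.read_measurements(path, layout_kind="QP69")

    def test_profile_round_trip(self, noise_free_run, tmp_path):
        agg = biochip.aggregate_replicates(biochip.normalize_qp69(noise_free_run))
        path = tmp_path / "profiles.tsv"
        biochip.write_profile(agg, path)
        back = biochip.read_profile(path)
        pd.testing.assert_frame_equal(
            back.values.reset_index(drop=True),
            agg.values[["sample_id", "mab_id", "dilution", "value", "n_replicates"]].reset_index(
                drop=True
            ),
            check_dtype=False,
        )
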