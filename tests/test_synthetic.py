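"""Generator ground truth: planted effects, noise calibration, determinism."""

import numpy as np
import pandas as pd
import pytest

from epitomics import biochip, mimotopes, qualification, spr, synthetic


class TestCohort:
    def test_null_model_group_means_agree(self):
        cfg = synthetic.CohortConfig(n_cases=2000, n_controls=2000, n_mabs=3, seed=1)
        meta, ab = synthetic.generate_cohort(cfg)
        log_ab = np.log(ab)
        diff = (
            log_ab[meta["group"] == "case"].mean() - log_ab[meta["group"] == "control"].mean()
        )
        # SE of the log-mean difference is sigma*sqrt(2/n)
        se = cfg.baseline_log_sd * np.sqrt(2 / 2000)
        assert (diff.abs() < 4 * se).all()

    def test_planted_effect_shifts_geometric_mean(self):
        cfg = synthetic.CohortConfig(
            n_cases=5000, n_controls=5000, n_mabs=8, effect_mabs=[("mab_007", 0.5)], seed=2
        )
        meta, ab = synthetic.generate_cohort(cfg)
        case = np.exp(np.log(ab.loc[meta["group"] == "case", "mab_007"]).mean())
        ctrl = np.exp(np.log(ab.loc[meta["group"] == "control", "mab_007"]).mean())
        se = cfg.baseline_log_sd * np.sqrt(2 / 5000)
        assert np.log(case / ctrl) == pytest.approx(0.5, abs=4 * se)
        assert np.exp(0.5) == pytest.approx(1.6487, abs=1e-4)

    def test_determinism(self):
        cfg = synthetic.CohortConfig(n_cases=5, n_controls=5, n_mabs=3, seed=42)
        meta1, ab1 = synthetic.generate_cohort(cfg)
        meta2, ab2 = synthetic.generate_cohort(cfg)
        pd.testing.assert_frame_equal(meta1, meta2)
        pd.testing.assert_frame_equal(ab1, ab2)

    def test_invalid_effect_mab_rejected(self):
        with pytest.raises(synthetic.ConfigurationError):
            synthetic.CohortConfig(n_cases=2, n_controls=2, n_mabs=3, effect_mabs=[("mab_099", 1.0)])

    def test_abundance_strictly_positive(self, small_cohort):
        _, _, ab = small_cohort
        assert (ab > 0).all().all()


class TestBiochipRuns:
    def test_zero_abundance_gives_rlumax(self):
        ab = pd.DataFrame(0.0, index=["s1", "s2"], columns=["mab_001"])
        run = synthetic.generate_biochip_runs(
            ab, "QP300", synthetic.NoiseModel.noise_free(), seed=0, n_replicates=1, rlumax=5000.0
        )
        samples = run.records[run.records["role"] == "sample"]
        assert (samples["rlu"] == 5000.0).all()

    def test_noise_free_replicates_identical(self, noise_free_run):
        rec = noise_free_run.records
        per = rec[rec["role"] == "sample"].groupby(["sample_id", "mab_id", "dilution"])["rlu"]
        assert (per.nunique() == 1).all()

    def test_layout_tracer_structure(self, noise_free_run):
        rec = noise_free_run.records
        per_run = rec[rec["role"] == "tracer_only"].groupby("run_id")["position"].nunique()
        assert (per_run == 2).all()  # QP69: two tracer-only positions per run

    def test_unknown_layout_rejected(self, small_cohort):
        _, _, ab = small_cohort
        with pytest.raises(synthetic.ConfigurationError):
            synthetic.generate_biochip_runs(ab, "QP999", synthetic.NoiseModel.noise_free(), seed=0)

    def test_intra_noise_cv_calibration(self):
        # 1000 replicate aliquots of the same material: empirical CV -> cv_intra
        ab = pd.DataFrame(1.0, index=[f"a{i}" for i in range(1000)], columns=["mab_001"])
        noise = synthetic.NoiseModel(cv_intra=0.10, cv_inter_run=0, cv_operator=0, cv_lot=0)
        run = synthetic.generate_biochip_runs(ab, "QP69", noise, seed=5, n_replicates=1,
                                              dilutions=(100.0,))
        vals = run.records.loc[run.records["role"] == "sample", "rlu"]
        cv = vals.std(ddof=1) / vals.mean()
        se = 0.10 / np.sqrt(2 * len(vals))
        assert cv == pytest.approx(0.10, abs=3 * se)

    def test_run_determinism(self, small_cohort):
        _, _, ab = small_cohort
        noise = synthetic.NoiseModel()
        r1 = synthetic.generate_biochip_runs(ab, "QP69", noise, seed=3, n_replicates=1)
        r2 = synthetic.generate_biochip_runs(ab, "QP69", noise, seed=3, n_replicates=1)
        pd.testing.assert_frame_equal(r1.records, r2.records)


class TestMimotopeGeneration:
    @pytest.mark.parametrize(
        "target,expected",
        [(1.0, 100.0), (0.0, 0.0), (0.5, 25.0)],
    )
    def test_planted_pair_redundancy(self, target, expected):
        spec = synthetic.RedundancySpec(pairs=[("mab_001", "mab_002", target)], clones_per_mab=12)
        sets = {s.mab_id: s for s in synthetic.generate_mimotope_sets(4, spec, seed=9)}
        red = mimotopes.redundancy(sets["mab_001"], sets["mab_002"])
        assert red == pytest.approx(expected, abs=5.0)
        if target in (0.0, 0.5, 1.0):  # exact at fractions that divide 12 clones evenly
            assert red == pytest.approx(expected, abs=1e-9)

    def test_unplanted_pairs_disjoint(self):
        spec = synthetic.RedundancySpec(pairs=[("mab_001", "mab_002", 0.5)])
        sets = {s.mab_id: s for s in synthetic.generate_mimotope_sets(4, spec, seed=9)}
        assert mimotopes.redundancy(sets["mab_003"], sets["mab_004"]) == 0.0

    def test_clone_depth_enforced(self):
        with pytest.raises(synthetic.ConfigurationError):
            synthetic.RedundancySpec(clones_per_mab=5)


class TestCurveAndSensorgramGeneration:
    def test_noise_free_4pl_round_trip(self):
        truth = (100.0, 1.0, 100.0, 0.0)
        df = synthetic.generate_inhibition_curves({"m1": truth}, noise_cv=0.0)
        curve = qualification.InhibitionCurve(
            "m1", "total_plasma", df["dilution"].to_numpy(), df["response"].to_numpy()
        )
        fit = qualification.fit_4pl(curve)
        for got, want in zip((fit.a, fit.b, fit.c, fit.d), truth):
            assert got == pytest.approx(want, rel=1e-6, abs=1e-6)
        assert fit.r2 == pytest.approx(1.0)

    def test_langmuir_limit_at_ka2_zero(self):
        p = spr.TwoStateParams(ka1=1e5, kd1=1e-2, ka2=0.0, kd2=1e-2, Rmax=100.0)
        [g] = synthetic.generate_sensorgrams(p, [1e-7], t_assoc=5000.0, t_dissoc=0.0)
        eq = 100.0 * 1e-7 / (1e-7 + 1e-2 / 1e5)
        assert g.response[-1] == pytest.approx(eq, rel=1e-3)

    def test_seeded_noise_reproducible_and_seed_sensitive(self):
        p = spr.TwoStateParams(ka1=1e5, kd1=1e-2, ka2=1e-3, kd2=1e-3, Rmax=100.0)
        a = synthetic.generate_sensorgrams(p, [1e-7], noise_sd=2.0, seed=1)
        b = synthetic.generate_sensorgrams(p, [1e-7], noise_sd=2.0, seed=1)
        c = synthetic.generate_sensorgrams(p, [1e-7], noise_sd=2.0, seed=2)
        np.testing.assert_array_equal(a[0].response, b[0].response)
        assert not np.array_equal(a[0].response, c[0].response)

    def test_nonpositive_concentration_rejected(self):
        p = spr.TwoStateParams(ka1=1e5, kd1=1e-2, ka2=1e-3, kd2=1e-3, Rmax=100.0)
        with pytest.raises(synthetic.ConfigurationError):
            synthetic.generate_sensorgrams(p, [0.0, 1e-7])
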