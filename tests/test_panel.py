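"""Feature statistics, logistic panel report, and the split/CV protocol."""

import numpy as np
import pandas as pd
import pytest

from epitomics import panel, synthetic


class TestMannWhitney:
    def test_all_pairs_won(self):
        u, _ = panel.mann_whitney([3, 4], [1, 2])
        assert u == 4.0

    def test_constant_data(self):
        u, p = panel.mann_whitney([5.0, 5.0, 5.0], [5.0, 5.0])
        assert u == 3.0 and p == 1.0

    @pytest.mark.parametrize("seed", range(20))
    def test_brute_force_pair_count_oracle(self, seed):
        rng = np.random.default_rng(seed)
        case = rng.integers(0, 6, size=rng.integers(2, 8)).astype(float)
        ctrl = rng.integers(0, 6, size=rng.integers(2, 8)).astype(float)
        u, _ = panel.mann_whitney(case, ctrl)
        oracle = sum(
            1.0 if c > k else (0.5 if c == k else 0.0) for c in case for k in ctrl
        )
        assert u == pytest.approx(oracle)


class TestROC:
    def test_perfect_separation(self):
        res = panel.roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert res.auc == 1.0 and res.sensitivity == 1.0 and res.specificity == 1.0

    def test_antisymmetry(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=100)
        labels = rng.integers(0, 2, size=100)
        a = panel.roc_auc(scores, labels).auc
        b = panel.roc_auc(-scores, labels).auc
        assert a + b == pytest.approx(1.0)

    def test_shuffled_labels_near_half(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(size=2000)
        labels = rng.permutation([1] * 1000 + [0] * 1000)
        assert panel.roc_auc(scores, labels).auc == pytest.approx(0.5, abs=0.05)

    @pytest.mark.parametrize("seed", range(30))
    def test_auc_u_identity(self, seed):
        rng = np.random.default_rng(seed)
        n1, n0 = rng.integers(3, 20), rng.integers(3, 20)
        scores = np.concatenate([rng.integers(0, 8, n1), rng.integers(0, 8, n0)]).astype(float)
        labels = np.array([1] * n1 + [0] * n0)
        u, _ = panel.mann_whitney(scores[:n1], scores[n1:])
        assert panel.roc_auc(scores, labels).auc == pytest.approx(u / (n1 * n0))

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            panel.roc_auc([0.1, 0.2], [1, 1])


class TestFDRSelection:
    def test_single_p(self):
        assert panel.bh_fdr([0.04])[0] == pytest.approx(0.04)

    def test_hand_computation(self):
        # q_i = min over j>=i of p_j * m / j: all become 0.04
        np.testing.assert_allclose(panel.bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_monotone_in_rank(self):
        rng = np.random.default_rng(3)
        p = np.sort(rng.uniform(size=50))
        q = panel.bh_fdr(p)
        assert (np.diff(q) >= -1e-12).all()
        assert (q >= p - 1e-12).all()

    def test_nothing_selected_at_p_one(self):
        stats = pd.DataFrame(
            {"U": [1.0] * 3, "p": [1.0] * 3, "auc": [0.5] * 3},
            index=["m1", "m2", "m3"],
        )
        stats["q"] = panel.bh_fdr(stats["p"])
        assert panel.select_features(stats) == []

    def test_selection_ranked_by_auc_distance(self):
        stats = pd.DataFrame(
            {"U": [0, 0, 0], "p": [1e-5, 1e-5, 0.5], "auc": [0.7, 0.1, 0.9],
             "q": [1e-4, 1e-4, 0.5]},
            index=["weak", "strong", "null"],
        )
        assert panel.select_features(stats) == ["strong", "weak"]


class TestLogisticPanel:
    def _data(self, n=2000, seed=4, betas=(0.8, -0.5)):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, len(betas)))
        logits = -0.3 + X @ np.array(betas)
        y = (rng.uniform(size=n) < 1 / (1 + np.exp(-logits))).astype(int)
        return pd.DataFrame(X, columns=[f"m{i}" for i in range(len(betas))]), y

    def test_report_self_consistency(self):
        X, y = self._data()
        model = panel.fit_logistic_panel(X, y)
        t = model.table
        np.testing.assert_allclose(t["ExpB"], np.exp(t["B"]), atol=5e-4)
        np.testing.assert_allclose(t["Wald"], (t["B"] / t["SE"]) ** 2, atol=1e-6)
        assert (t["ExpB"] > 0).all()
        assert list(t.index)[-1] == "Constant"

    def test_parameter_recovery_within_3se(self):
        hits = 0
        runs = 20
        for seed in range(runs):
            X, y = self._data(seed=seed)
            t = panel.fit_logistic_panel(X, y).table
            ok = (
                abs(t.loc["m0", "B"] - 0.8) < 3 * t.loc["m0", "SE"]
                and abs(t.loc["m1", "B"] + 0.5) < 3 * t.loc["m1", "SE"]
            )
            hits += ok
        assert hits / runs >= 0.9

    def test_constant_column_rejected(self):
        X, y = self._data(n=100)
        X["flat"] = 1.0
        with pytest.raises(ValueError, match="constant"):
            panel.fit_logistic_panel(X, y)

    def test_perfect_separation_flagged(self):
        X = pd.DataFrame({"m0": np.r_[np.zeros(20), np.ones(20)]})
        X["m0"] += np.linspace(0, 0.01, 40)  # avoid constant column, keep separation
        y = np.r_[np.zeros(20, dtype=int), np.ones(20, dtype=int)]
        model = panel.fit_logistic_panel(X, y)
        assert model.separation_warning


class TestProtocol:
    def _cohort(self, seed=5, effect=1.0, n=200):
        cfg = synthetic.CohortConfig(
            n_cases=n // 2, n_controls=n // 2, n_mabs=10,
            effect_mabs=[(f"mab_{i:03d}", effect) for i in range(1, 4)], seed=seed,
        )
        meta, ab = synthetic.generate_cohort(cfg)
        return np.log(ab), (meta["group"] == "case").astype(int).to_numpy(), meta

    def test_same_seed_identical_result(self):
        X, y, _ = self._cohort()
        proto = panel.CVProtocol(seed=9)
        r1 = panel.evaluate_protocol(X, y, proto)
        r2 = panel.evaluate_protocol(X, y, proto)
        np.testing.assert_array_equal(r1["test_idx"], r2["test_idx"])
        assert r1["test_roc"].auc == r2["test_roc"].auc

    def test_planted_effect_detected(self):
        X, y, _ = self._cohort(effect=1.5)
        res = panel.evaluate_protocol(X, y, panel.CVProtocol(seed=1))
        assert res["test_roc"].auc > 0.85

    def test_too_few_samples_for_folds(self):
        X, y, _ = self._cohort(n=16)
        with pytest.raises(ValueError, match="fold"):
            panel.evaluate_protocol(X, y, panel.CVProtocol(folds=10, seed=0))

    @pytest.mark.parametrize("kind", ["svm", "knn", "rf"])
    def test_alternative_model_kinds_run(self, kind):
        X, y, _ = self._cohort(effect=1.5, n=100)
        res = panel.evaluate_protocol(X, y, panel.CVProtocol(folds=5, repeats=1, seed=2), kind)
        assert 0.0 <= res["test_roc"].auc <= 1.0


class TestSubgroupROC:
    def test_whole_cohort_level_matches_overall(self):
        rng = np.random.default_rng(7)
        scores = rng.normal(size=100)
        labels = rng.integers(0, 2, size=100)
        meta = pd.DataFrame({"all": ["whole"] * 100}, index=[f"s{i}" for i in range(100)])
        out = panel.subgroup_roc(scores, labels, meta, "all")
        assert out["levels"]["whole"].auc == panel.roc_auc(scores, labels).auc

    def test_single_class_level_skipped(self):
        scores = np.array([0.1, 0.9, 0.4, 0.6])
        labels = np.array([0, 1, 0, 0])
        meta = pd.DataFrame({"grp": ["a", "a", "b", "b"]}, index=list("wxyz"))
        out = panel.subgroup_roc(scores, labels, meta, "grp")
        assert out["skipped"] == ["b"] and set(out["levels"]) == {"a"}

    def test_zero_interaction_confounder_stable(self):
        # confounder shifts a non-effect mAb only: subgroup AUCs track the overall AUC
        cfg = synthetic.CohortConfig(
            n_cases=500, n_controls=500, n_mabs=6,
            effect_mabs=[("mab_001", 1.2)],
            confounder_effects={"copd_grade": {"mab_004": 0.8}},
            seed=8,
        )
        meta, ab = synthetic.generate_cohort(cfg)
        scores = np.log(ab["mab_001"]).to_numpy()
        labels = (meta["group"] == "case").astype(int).to_numpy()
        overall = panel.roc_auc(scores, labels).auc
        out = panel.subgroup_roc(scores, labels, meta, "copd_grade")
        for level, roc in out["levels"].items():
            assert roc.auc == pytest.approx(overall, abs=0.07)
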