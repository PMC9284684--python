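"""Feature assembly, selection, metrics and nested leave-one-site-out CV."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tdncd import (
    ClassifierSpec,
    LosoClassifier,
    compare_models_paired_t,
    compute_metrics,
    decision_mmse_correlation,
    nested_loso_evaluate,
    select_features,
)
from tdncd.classify import FCNET_GRID, make_estimator
from tdncd.dfc import DFCStack, SFCMatrix
from tdncd.diversity import TdNCDMatrix
from tdncd.features import FeatureTable, build_feature_table


def toy_matrices(n_subjects=3, r=6, d=4, n_windows=5, seed=0):
    rng = np.random.default_rng(seed)
    out = {}
    for i in range(n_subjects):
        sfc = np.corrcoef(rng.standard_normal((30, r)), rowvar=False)
        tens = np.array(
            [np.corrcoef(rng.standard_normal((20, r)), rowvar=False)
             for _ in range(n_windows)]
        )
        out[f"sub{i}"] = {
            "sfc": SFCMatrix(matrix=sfc),
            "tdncd": TdNCDMatrix(matrix=rng.random((r, d)), step_seconds=10.0),
            "dfc": DFCStack(
                tensor=tens,
                window_starts=np.arange(n_windows) * 5,
                window_frames=20,
                step_frames=5,
                tr_seconds=2.0,
            ),
        }
    return out


def indicator_table(manifest, kind="tdncd_roi_distance", n_noise=40, seed=0):
    """Noise features plus one-hot site indicator columns."""
    rng = np.random.default_rng(seed)
    n = len(manifest)
    cols = {f"{kind}:noise{j:03d}": rng.standard_normal(n) for j in range(n_noise)}
    for s in sorted(manifest["site_id"].unique()):
        cols[f"{kind}:site_{s}"] = (manifest["site_id"] == s).astype(float).to_numpy()
    X = pd.DataFrame(cols, index=manifest["subject_id"])
    kinds = pd.Series(kind, index=X.columns)
    return FeatureTable(X=X, kinds=kinds, meta=pd.DataFrame(index=X.columns))


def toy_manifest(n_sites=4, per_group=6, diagnoses=("NC", "AD"), seed=0,
                 mmse=None):
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_sites):
        for diag in diagnoses:
            for j in range(per_group):
                rows.append(
                    {
                        "subject_id": f"s{s}_{diag}_{j}",
                        "site_id": f"site{s}",
                        "diagnosis": diag,
                        "mmse": float(rng.integers(10, 30)) if mmse is None else mmse,
                    }
                )
    return pd.DataFrame(rows)


def separable_table(manifest, strength=5.0, n_noise=20, seed=0,
                    kind="tdncd_roi_distance"):
    rng = np.random.default_rng(seed)
    n = len(manifest)
    is_ad = (manifest["diagnosis"] == "AD").to_numpy(float)
    is_mci = (manifest["diagnosis"] == "MCI").to_numpy(float)
    cols = {f"{kind}:sig": strength * (is_ad + 0.5 * is_mci) + rng.standard_normal(n)}
    for j in range(n_noise):
        cols[f"{kind}:noise{j:03d}"] = rng.standard_normal(n)
    X = pd.DataFrame(cols, index=manifest["subject_id"])
    kinds = pd.Series(kind, index=X.columns)
    return FeatureTable(X=X, kinds=kinds, meta=pd.DataFrame(index=X.columns))


class TestFeatureTable:
    def test_column_counts_at_full_scale_dimensions(self):
        r, d = 264, 24
        rng = np.random.default_rng(0)
        mats = {
            "a": {
                "sfc": SFCMatrix(matrix=np.corrcoef(rng.standard_normal((300, r)), rowvar=False)),
                "tdncd": TdNCDMatrix(matrix=rng.random((r, d)), step_seconds=10.0),
            }
        }
        table = build_feature_table(mats, ["sfc_edge", "tdncd_roi_distance"])
        assert table.n_features == r * (r - 1) // 2 + r * d == 41052

    def test_dfc_block_counts(self):
        mats = toy_matrices()
        table = build_feature_table(mats, ["dfc_window_edge"])
        assert table.n_features == 5 * 6 * 5 // 2

    def test_empty_kind_request_rejected(self):
        with pytest.raises(ValueError, match="empty feature-kind"):
            build_feature_table(toy_matrices(), [])

    def test_identical_subjects_get_identical_rows(self):
        mats = toy_matrices(n_subjects=1)
        mats["clone"] = mats["sub0"]
        table = build_feature_table(
            mats, ["sfc_edge", "tdncd_roi_distance", "dfc_window_edge"]
        )
        np.testing.assert_array_equal(
            table.X.loc["sub0"].to_numpy(), table.X.loc["clone"].to_numpy()
        )

    def test_mismatched_dimensions_name_subject(self):
        mats = toy_matrices(n_subjects=2)
        mats["sub1"]["tdncd"] = TdNCDMatrix(
            matrix=np.random.default_rng(1).random((6, 7)), step_seconds=10.0
        )
        with pytest.raises(ValueError, match="sub1"):
            build_feature_table(mats, ["tdncd_roi_distance"])

    def test_deterministic_column_order(self):
        t1 = build_feature_table(toy_matrices(), ["tdncd_roi_distance", "sfc_edge"])
        t2 = build_feature_table(toy_matrices(), ["sfc_edge", "tdncd_roi_distance"])
        assert list(t1.X.columns) == list(t2.X.columns)
        assert t1.X.columns[0].startswith("sfc_edge:")


class TestFeatureSelection:
    def test_perfect_separator_always_kept(self):
        man = toy_manifest(n_sites=1, per_group=10)
        table = separable_table(man, strength=50.0)
        keep = select_features(
            table.X, man.set_index("subject_id")["diagnosis"], table.kinds,
            {"tdncd_roi_distance": 0.05},
        )
        assert "tdncd_roi_distance:sig" in keep

    def test_null_survival_rate_near_threshold(self):
        rng = np.random.default_rng(5)
        n_feat = 4000
        X = pd.DataFrame(
            rng.standard_normal((40, n_feat)),
            index=[f"s{i}" for i in range(40)],
            columns=[f"tdncd_roi_distance:f{j}" for j in range(n_feat)],
        )
        labels = pd.Series(["NC"] * 20 + ["AD"] * 20, index=X.index)
        kinds = pd.Series("tdncd_roi_distance", index=X.columns)
        keep = select_features(X, labels, kinds, {"tdncd_roi_distance": 0.05})
        rate = len(keep) / n_feat
        se = np.sqrt(0.05 * 0.95 / n_feat)
        assert abs(rate - 0.05) < 2 * se + 1e-12

    def test_zero_survivors_advise_relaxation(self):
        rng = np.random.default_rng(6)
        X = pd.DataFrame(
            rng.standard_normal((20, 5)),
            index=[f"s{i}" for i in range(20)],
            columns=[f"sfc_edge:f{j}" for j in range(5)],
        )
        labels = pd.Series(["NC"] * 10 + ["AD"] * 10, index=X.index)
        kinds = pd.Series("sfc_edge", index=X.columns)
        with pytest.raises(ValueError, match="relax"):
            select_features(X, labels, kinds, {"sfc_edge": 1e-12})


class TestMetrics:
    def test_perfect_predictions(self):
        m = compute_metrics(["AD", "NC", "AD"], ["AD", "NC", "AD"])
        assert all(m[k] == pytest.approx(100.0) for k in ("acc", "sen", "spe", "f1"))

    def test_hand_computed_confusion_table(self):
        m = compute_metrics(["AD", "AD", "NC", "NC"], ["AD", "NC", "NC", "NC"])
        assert m["acc"] == pytest.approx(75.0)
        assert m["sen"] == pytest.approx(50.0)
        assert m["spe"] == pytest.approx(100.0)
        assert m["f1"] == pytest.approx(200.0 / 3.0)

    def test_random_three_class_macro_near_chance(self):
        rng = np.random.default_rng(7)
        classes = np.array(["NC", "MCI", "AD"])
        truth = np.repeat(classes, 1000)
        pred = rng.choice(classes, size=3000)
        m = compute_metrics(truth, pred, positive_class="macro")
        assert m["f1"] == pytest.approx(33.3, abs=3.5)
        assert m["sen"] == pytest.approx(33.3, abs=3.5)

    def test_absent_class_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="absent"):
            m = compute_metrics(
                ["NC", "NC", "AD", "AD"], ["NC", "MCI", "AD", "AD"],
                positive_class="macro",
            )
        assert np.isfinite(m["sen"])

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics([], [])


class TestFCnetContract:
    def test_four_layers_and_two_hyperparameters(self):
        spec = ClassifierSpec(model="fcnet", seed=0)
        assert {tuple(sorted(g)) for g in spec.grid} == {
            ("learning_rate", "n_passes")
        }
        est = make_estimator(spec, spec.grid[0])
        rng = np.random.default_rng(0)
        X = rng.standard_normal((30, 12))
        y = np.array(["NC", "AD"] * 15)
        import warnings as w

        with w.catch_warnings():
            w.simplefilter("ignore")
            est.fit(X, y)
        # input -> 64 -> 32 -> output: 3 weight matrices = 4 layers
        # (binary output collapses to one logistic unit)
        assert [c.shape for c in est.coefs_] == [(12, 64), (64, 32), (32, 1)]
        y3 = np.array(["NC", "MCI", "AD"] * 10)
        est3 = make_estimator(spec, spec.grid[0])
        with w.catch_warnings():
            w.simplefilter("ignore")
            est3.fit(X, y3)
        # three-class output is a 1 x 3 probability vector
        assert est3.coefs_[-1].shape == (32, 3)
        assert est3.predict_proba(X[:1]).shape == (1, 3)

    def test_grid_orders_ties_toward_small_settings(self):
        lrs = [g["learning_rate"] for g in FCNET_GRID]
        assert lrs == sorted(lrs)


class TestNestedLoso:
    def test_perfectly_separable_feature_hits_ceiling(self):
        man = toy_manifest(n_sites=4, per_group=6)
        table = separable_table(man, strength=50.0)
        res = nested_loso_evaluate(
            table, man, ClassifierSpec(model="lr", seed=0), task="nc_vs_ad",
            thresholds={"tdncd_roi_distance": 0.05},
        )
        assert len(res.folds) == 4
        for m in ("acc", "sen", "spe", "f1"):
            assert np.all(res.ok_folds[m] == 100.0)

    def test_three_class_task_reports_macro_metrics(self):
        man = toy_manifest(n_sites=3, per_group=5, diagnoses=("NC", "MCI", "AD"))
        table = separable_table(man, strength=50.0)
        res = nested_loso_evaluate(
            table, man, ClassifierSpec(model="lda", seed=0), task="nc_mci_ad",
            thresholds={"tdncd_roi_distance": 0.05},
        )
        assert len(res.ok_folds) == 3
        assert res.ok_folds["acc"].mean() > 90.0

    def test_deterministic_reports_for_all_model_families(self):
        man = toy_manifest(n_sites=3, per_group=5)
        table = separable_table(man, strength=2.0, seed=3)
        small_grid = [
            {"learning_rate": 1e-3, "n_passes": 20},
            {"learning_rate": 1e-2, "n_passes": 20},
        ]
        for model in ("fcnet", "svm", "knn", "lr", "lda"):
            grid = small_grid if model == "fcnet" else None
            runs = []
            for _ in range(2):
                spec = ClassifierSpec(model=model, seed=11, grid=grid)
                res = nested_loso_evaluate(
                    table, man, spec, task="nc_vs_ad",
                    thresholds={"tdncd_roi_distance": 0.2},
                )
                runs.append(res)
            pd.testing.assert_frame_equal(runs[0].folds, runs[1].folds)
            pd.testing.assert_frame_equal(runs[0].scores, runs[1].scores)

    def test_site_indicator_feature_cannot_leak(self):
        """A feature encoding the held-out site is useless under clean
        split hygiene: accuracy stays at chance on label-balanced data."""
        man = toy_manifest(n_sites=5, per_group=8)
        table = indicator_table(man, n_noise=40, seed=2)
        res = nested_loso_evaluate(
            table, man, ClassifierSpec(model="lr", seed=0), task="nc_vs_ad",
            thresholds={"tdncd_roi_distance": 1.0},
        )
        acc = res.pooled_accuracy() / 100.0
        n = int(res.ok_folds["n_test"].sum())
        # within 3 binomial SE of the 50% majority rate
        assert abs(acc - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_chance_floor_on_shuffled_labels(self):
        rng = np.random.default_rng(9)
        man = toy_manifest(n_sites=4, per_group=8)
        man["diagnosis"] = rng.permutation(man["diagnosis"].to_numpy())
        # shuffling within the whole cohort keeps sites label-balanced enough
        table = separable_table(man, strength=0.0, n_noise=30, seed=4)
        res = nested_loso_evaluate(
            table, man, ClassifierSpec(model="lda", seed=0), task="nc_vs_ad",
            thresholds={"tdncd_roi_distance": 1.0},
        )
        acc = res.pooled_accuracy() / 100.0
        n = int(res.ok_folds["n_test"].sum())
        assert abs(acc - 0.5) < 3.5 * np.sqrt(0.25 / n)

    def test_missing_class_fold_reported_and_run_continues(self):
        man = toy_manifest(n_sites=4, per_group=5)
        man = man[~((man.site_id == "site2") & (man.diagnosis == "AD"))]
        table = separable_table(man.reset_index(drop=True), strength=50.0)
        with pytest.warns(UserWarning, match="missing"):
            res = nested_loso_evaluate(
                table, man, ClassifierSpec(model="lr", seed=0),
                thresholds={"tdncd_roi_distance": 0.05},
            )
        assert (res.folds["status"] == "missing").sum() == 1
        assert (res.folds["status"] == "ok").sum() == 3

    def test_mci_subjects_scored_in_two_class_task(self):
        man = toy_manifest(n_sites=3, per_group=5, diagnoses=("NC", "MCI", "AD"))
        table = separable_table(man, strength=50.0)
        res = nested_loso_evaluate(
            table, man, ClassifierSpec(model="lr", seed=0), task="nc_vs_ad",
            thresholds={"tdncd_roi_distance": 0.05},
        )
        assert (res.scores["diagnosis"] == "MCI").sum() == 15
        scores = res.scores
        assert scores["score"].between(0, 1).all()
        # MCI carries half the planted signal: scores sit between groups
        by_diag = scores.groupby("diagnosis")["score"].mean()
        assert by_diag["NC"] < by_diag["MCI"] < by_diag["AD"]


class TestDecisionScoreCorrelation:
    def test_perfect_inverse_relation(self):
        mmse = np.linspace(5, 30, 20)
        scores = pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(20)],
                "site_id": "site0",
                "diagnosis": ["AD"] * 10 + ["MCI"] * 10,
                "mmse": mmse,
                "score": (30 - mmse) / 30,
            }
        )
        rec = decision_mmse_correlation(scores)
        assert rec["r"] == pytest.approx(-1.0)
        assert rec["n"] == 20

    def test_independent_scores_show_no_correlation(self):
        rng = np.random.default_rng(10)
        n = 500
        scores = pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(n)],
                "site_id": "site0",
                "diagnosis": rng.choice(["AD", "MCI"], n),
                "mmse": rng.integers(5, 30, n).astype(float),
                "score": rng.random(n),
            }
        )
        rec = decision_mmse_correlation(scores)
        assert abs(rec["r"]) < 0.1

    def test_nc_subjects_excluded(self):
        scores = pd.DataFrame(
            {
                "subject_id": ["a", "b", "c", "d"],
                "site_id": "s",
                "diagnosis": ["NC", "NC", "NC", "NC"],
                "mmse": [28.0, 29.0, 30.0, 27.0],
                "score": [0.1, 0.2, 0.3, 0.4],
            }
        )
        with pytest.warns(UserWarning):
            rec = decision_mmse_correlation(scores)
        assert np.isnan(rec["r"])

    def test_constant_scores_reported_missing(self):
        scores = pd.DataFrame(
            {
                "subject_id": ["a", "b", "c", "d"],
                "site_id": "s",
                "diagnosis": ["AD"] * 4,
                "mmse": [10.0, 15.0, 20.0, 25.0],
                "score": [0.5] * 4,
            }
        )
        with pytest.warns(UserWarning, match="constant"):
            rec = decision_mmse_correlation(scores)
        assert np.isnan(rec["r"])


class TestModelComparison:
    def _report(self, accs, sites=None):
        sites = sites or [f"site{i}" for i in range(len(accs))]
        folds = pd.DataFrame(
            {
                "site_id": sites,
                "status": "ok",
                "n_test": 10,
                "acc": accs,
                "sen": accs,
                "spe": accs,
                "f1": accs,
            }
        )
        from tdncd.classify import ClassificationResults

        return ClassificationResults(model=None, folds=folds, scores=pd.DataFrame(), seed=0)

    def test_identical_reports_are_null(self):
        a = self._report([70, 75, 80, 85])
        out = compare_models_paired_t(a, self._report([70, 75, 80, 85]))
        assert np.all(out["t_stat"] == 0.0)
        assert np.all(out["p_two_sided"] == 1.0)

    def test_constant_shift_flagged_degenerate(self):
        accs = [70, 72, 74, 76, 78, 80, 82]
        a = self._report(accs)
        b = self._report([x + 3 for x in accs])
        out = compare_models_paired_t(b, a).set_index("metric")
        assert out.loc["acc", "degenerate"]
        assert out.loc["acc", "p_two_sided"] == 0.0
        assert out.loc["acc", "t_stat"] == np.inf

    def test_matches_scipy_paired_t(self):
        rng = np.random.default_rng(11)
        accs_a = 70 + rng.random(7) * 10
        accs_b = accs_a + rng.standard_normal(7)
        out = compare_models_paired_t(
            self._report(accs_a), self._report(accs_b)
        ).set_index("metric")
        t, p = stats.ttest_rel(accs_a, accs_b)
        assert out.loc["acc", "t_stat"] == pytest.approx(t)
        assert out.loc["acc", "p_two_sided"] == pytest.approx(p)

    def test_same_distribution_rejection_rate_calibrated(self):
        rng = np.random.default_rng(12)
        rejections = 0
        n_rep = 400
        for _ in range(n_rep):
            a = 70 + rng.standard_normal(7)
            b = 70 + rng.standard_normal(7)
            _, p = stats.ttest_rel(a, b)
            rejections += p < 0.05
        rate = rejections / n_rep
        assert abs(rate - 0.05) < 2 * np.sqrt(0.05 * 0.95 / n_rep) + 0.005

    def test_fold_mismatch_rejected(self):
        a = self._report([70, 75, 80])
        b = self._report([70, 75, 80], sites=["x", "y", "z"])
        with pytest.raises(ValueError, match="fold structure"):
            compare_models_paired_t(a, b)


def test_loso_fold_count_matches_site_count():
    man = toy_manifest(n_sites=5, per_group=4)
    table = separable_table(man, strength=50.0)
    res = nested_loso_evaluate(
        table, man, ClassifierSpec(model="lr", seed=0),
        thresholds={"tdncd_roi_distance": 0.05},
    )
    assert len(res.folds) == 5
    assert len(res.ok_folds) == 5
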