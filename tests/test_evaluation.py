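"""Clinical-table preparation, cross-validated prediction, scoring,
survival stratification, method comparison, CCA and projection."""

import numpy as np
import pandas as pd
import pytest

from neuroembed import evaluation as ev


def quant_map(*names, category="c"):
    return {n: {"category": category, "type": "quantitative"} for n in names}


class TestPrepareClinicalTable:
    def test_missingness_filter(self):
        raw = pd.DataFrame({"patient_id": [f"p{i}" for i in range(10)],
                            "mostly_missing": [1.0] + [np.nan] * 2 + [2.0] * 7,
                            "complete": np.arange(10.0)})
        table = ev.prepare_clinical_table(
            raw, quant_map("mostly_missing", "complete"), missing_threshold=0.15)
        assert table.dropped == ["mostly_missing"]
        assert table.variables() == ["complete"]

    def test_complete_table_standardized_invertibly(self):
        raw = pd.DataFrame({"patient_id": list("abcd"),
                            "x": [1.0, 2.0, 3.0, 4.0]})
        table = ev.prepare_clinical_table(raw, quant_map("x"))
        x = raw["x"].to_numpy()
        restored = table.data["x"].to_numpy() * x.std() + x.mean()
        assert restored == pytest.approx(x)

    def test_knn_impute_hand_oracle(self):
        """3 rows, k=2, one missing cell: the imputed value is the mean
        of the two nearest rows' values (verified by hand)."""
        raw = pd.DataFrame({"patient_id": list("abc"),
                            "u": [0.0, 0.1, 10.0],
                            "v": [1.0, np.nan, 5.0]})
        cm = quant_map("u", "v")
        table = ev.prepare_clinical_table(raw, cm, missing_threshold=0.5, k=2)
        # with k=2 (= n-1) the imputed standardized v is the mean of the
        # other two rows' standardized values -> exactly 0
        v = raw["v"].to_numpy()
        vz = (v - np.nanmean(v)) / np.nanstd(v)
        expected = (vz[0] + vz[2]) / 2
        assert table.data.loc["b", "v"] == pytest.approx(expected)

    def test_all_dropped_raises(self):
        raw = pd.DataFrame({"patient_id": list("ab"), "x": [np.nan, np.nan]})
        with pytest.raises(ValueError, match="dropped"):
            ev.prepare_clinical_table(raw, quant_map("x"))

    def test_bad_k(self):
        raw = pd.DataFrame({"patient_id": list("ab"), "x": [1.0, 2.0]})
        with pytest.raises(ValueError, match="k"):
            ev.prepare_clinical_table(raw, quant_map("x"), k=0)


@pytest.fixture(scope="module")
def planted():
    rng = np.random.default_rng(0)
    n = 120
    X = rng.standard_normal((n, 12))
    y_bin = (X[:, 0] + 0.4 * rng.standard_normal(n) > 0).astype(int)
    y_quant = 2.0 * X[:, 1] + 0.5 * rng.standard_normal(n)
    t_event = rng.exponential(1.0 / np.exp(0.8 * X[:, 2] - 1.0))
    censor = rng.uniform(0, 8, n)
    y_surv = {"time": np.minimum(t_event, censor),
              "event": (t_event <= censor).astype(int)}
    return X, y_bin, y_quant, y_surv


class TestFitPredictCV:
    def test_every_patient_predicted_once(self, planted):
        X, y_bin, _, _ = planted
        res = ev.fit_predict_cv(X, y_bin, "categorical", seed=1)
        assert not np.isnan(res.oof_pred).any()
        assert sorted(np.unique(res.fold_of)) == [0, 1, 2, 3, 4]
        assert len(res.fold_params) == 5

    def test_planted_binary_signal_recovered(self, planted):
        X, y_bin, _, _ = planted
        res = ev.fit_predict_cv(X, y_bin, "categorical", seed=1)
        assert ev.score(res)["auroc"] >= 0.85

    def test_permuted_labels_give_chance(self, planted):
        """Null calibration: mean AUROC over label permutations in
        [0.45, 0.55]."""
        X, y_bin, _, _ = planted
        rng = np.random.default_rng(2)
        aucs = [ev.score(ev.fit_predict_cv(X, rng.permutation(y_bin),
                                           "categorical", seed=p))["auroc"]
                for p in range(6)]
        assert 0.45 <= float(np.mean(aucs)) <= 0.55

    def test_small_class_rejected(self):
        X = np.zeros((10, 2))
        y = np.array([0] * 8 + [1] * 2)
        with pytest.raises(ValueError, match="class"):
            ev.fit_predict_cv(X, y, "categorical", folds=5)

    def test_constant_quantitative_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            ev.fit_predict_cv(np.zeros((20, 2)), np.ones(20), "quantitative")

    def test_leakage_injection_inflates_null_auroc(self):
        """Feature screening on ALL data (leaky) vs inside training
        folds (guarded), on pure-noise data with p >> n: the leaky
        pipeline must look measurably better than the guarded one."""
        rng = np.random.default_rng(3)
        n, p = 60, 400
        X = rng.standard_normal((n, p))
        y = rng.integers(0, 2, n)
        leaky = ev.score(ev.fit_predict_cv(X, y, "categorical", seed=0,
                                           leaky_select=10))["auroc"]
        guarded = ev.score(ev.fit_predict_cv(X, y, "categorical", seed=0,
                                             guarded_select=10))["auroc"]
        assert leaky > guarded + 0.1


class TestScore:
    def test_perfect_categorical(self):
        res = ev.CVResult(task="categorical", ids=list(range(4)),
                          y=np.array([0, 1, 0, 1]),
                          oof_pred=np.array([0.1, 0.9, 0.2, 0.8]),
                          oof_label=np.array([0, 1, 0, 1], dtype=object),
                          fold_of=np.zeros(4, int), fold_params=[])
        s = ev.score(res)
        assert s["f1_weighted"] == 1.0 and s["auroc"] == 1.0
        assert {"fpr", "tpr"} <= set(s["roc_points"].columns)

    def test_mean_prediction_r2_zero(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        res = ev.CVResult(task="quantitative", ids=list(range(4)), y=y,
                          oof_pred=np.full(4, y.mean()), oof_label=None,
                          fold_of=np.zeros(4, int), fold_params=[])
        assert ev.score(res)["r2"] == pytest.approx(0.0)

    def test_cindex_negation_symmetry(self, planted):
        X, _, _, y_surv = planted
        from sksurv.util import Surv

        y = Surv.from_arrays(event=y_surv["event"].astype(bool),
                             time=y_surv["time"])
        risks = np.random.default_rng(4).standard_normal(len(X))
        mk = lambda r: ev.CVResult(task="survival", ids=list(range(len(X))),
                                   y=y, oof_pred=r, oof_label=None,
                                   fold_of=np.zeros(len(X), int), fold_params=[])
        c1 = ev.score(mk(risks))["c_index"]
        c2 = ev.score(mk(-risks))["c_index"]
        assert c1 + c2 == pytest.approx(1.0)


class TestSurvival:
    def test_median_split_sizes(self):
        rng = np.random.default_rng(5)
        out = ev.stratify_survival(np.arange(10.0), rng.uniform(1, 5, 10),
                                   np.ones(10, int))
        assert out["group_sizes"] == {"high": 5, "low": 5}

    def test_planted_hazard_detected(self):
        """Risks = true lesion-linked hazard driver, n=300: log-rank
        p < 0.01."""
        from neuroembed.phantoms import CovariateModel, generate_cohort

        cohort = generate_cohort(300, CovariateModel(), seed=8, render=False,
                                 grid_shape=(32, 32, 32))
        df = cohort.truth.merge(cohort.clinical, on="patient_id")
        out = ev.stratify_survival(df["lesion_permille"].to_numpy()
                                   + 1e-9 * np.arange(len(df)),
                                   df["time"], df["event"])
        assert out["p_value"] < 0.01

    def test_random_risks_null(self):
        """Random risks on the same phantoms: median log-rank p > 0.1
        and mean C-index within [0.45, 0.55] over 10 seeds."""
        from neuroembed.phantoms import CovariateModel, generate_cohort
        from sksurv.metrics import concordance_index_censored

        cohort = generate_cohort(300, CovariateModel(), seed=8, render=False,
                                 grid_shape=(32, 32, 32))
        cl = cohort.clinical
        pvals, cis = [], []
        for seed in range(10):
            risks = np.random.default_rng(seed).standard_normal(len(cl))
            out = ev.stratify_survival(risks, cl["time"], cl["event"])
            pvals.append(out["p_value"])
            cis.append(concordance_index_censored(
                cl["event"].astype(bool), cl["time"], risks)[0])
        assert float(np.median(pvals)) > 0.1
        assert 0.45 <= float(np.mean(cis)) <= 0.55

    def test_constant_risks_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            ev.stratify_survival(np.ones(10), np.arange(1, 11.0), np.ones(10, int))

    def test_km_null_bounds_informed_model(self, planted):
        """The KM-marginal integrated Brier score bounds a real model's
        from above on planted-hazard data."""
        X, _, _, y_surv = planted
        res = ev.fit_predict_cv(X, y_surv, "survival", seed=0,
                                rsf_grid={"n_estimators": [50], "max_depth": [3]})
        s = ev.score(res)
        null_ibs = ev.km_null_integrated_brier(res.y)
        assert s["integrated_brier"] <= null_ibs + 0.01


class TestCompareMethods:
    def test_identical_scores_p_one(self):
        table = pd.DataFrame({"m1": [0.5, 0.6, 0.7], "m2": [0.5, 0.6, 0.7]})
        out = ev.compare_methods(table)
        assert out["p_raw"].iloc[0] == 1.0

    def test_six_positive_differences_exact(self):
        """n=6 all-positive differences: exact two-sided signed-rank
        p = 2/2**6 = 0.03125."""
        table = pd.DataFrame({"a": np.arange(6) + 1.0, "b": np.arange(6) * 1.0})
        out = ev.compare_methods(table)
        assert out["p_raw"].iloc[0] == pytest.approx(0.03125)

    def test_bonferroni_multiplies_and_caps(self):
        table = pd.DataFrame({"a": [1.0, 2, 3, 4, 5, 6],
                              "b": [0.0, 1, 2, 3, 4, 5],
                              "c": [0.5, 1.5, 2.5, 3.5, 4.5, 5.5]})
        out = ev.compare_methods(table)  # 3 pairwise comparisons
        for _, row in out.iterrows():
            assert row["p_bonferroni"] == min(1.0, 3 * row["p_raw"])

    def test_mismatched_sets_rejected(self):
        table = pd.DataFrame({"a": [1.0, 2.0], "b": [1.0, np.nan]})
        with pytest.raises(ValueError, match="mismatch"):
            ev.compare_methods(table)


class TestCCA:
    def test_exact_recovery_construction(self):
        """A clinical category built as an invertible linear map of two
        embedding columns (plus tiny noise) has first-variate R**2
        >= 0.99."""
        rng = np.random.default_rng(6)
        X = rng.standard_normal((300, 8))
        Y = X[:, :2] @ np.array([[1.0, 0.4], [-0.6, 1.1]]) \
            + 0.01 * rng.standard_normal((300, 2))
        table = ev.ClinicalTable(
            data=pd.DataFrame({"v1": Y[:, 0], "v2": Y[:, 1]}),
            category_map={"v1": {"category": "g", "type": "quantitative"},
                          "v2": {"category": "g", "type": "quantitative"}})
        out = ev.cca_radar(X, table)
        assert out["per_category"]["g"] >= 0.99

    def test_independent_category_near_zero(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((500, 10))
        Y = rng.standard_normal((500, 5))
        table = ev.ClinicalTable(
            data=pd.DataFrame(Y, columns=[f"v{i}" for i in range(5)]),
            category_map={f"v{i}": {"category": "noise", "type": "quantitative"}
                          for i in range(5)})
        out = ev.cca_radar(X, table)
        assert out["per_category"]["noise"] < 0.1

    def test_total_is_sum_and_single_var_flagged(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((100, 6))
        table = ev.ClinicalTable(
            data=pd.DataFrame({"a": X[:, 0] + 0.1 * rng.standard_normal(100),
                               "b": rng.standard_normal(100)}),
            category_map={"a": {"category": "one", "type": "quantitative"},
                          "b": {"category": "two", "type": "quantitative"}})
        out = ev.cca_radar(X, table)
        assert out["total_area"] == pytest.approx(sum(out["per_category"].values()))
        assert out["flags"]["one"] == "reduced_components"


class TestProject2D:
    def test_shape_determinism_and_separation(self):
        """n x 2 output, identical under a fixed seed, and preserving
        the separation of two well-separated Gaussian clusters
        (silhouette > 0.5)."""
        from sklearn.metrics import silhouette_score

        rng = np.random.default_rng(9)
        labels = np.repeat([0, 1], 40)
        X = rng.standard_normal((80, 6)) + 8.0 * labels[:, None]
        P1 = ev.project_2d(X, n_neighbors=15, seed=3)
        P2 = ev.project_2d(X, n_neighbors=15, seed=3)
        assert P1.shape == (80, 2)
        assert np.allclose(P1, P2)
        assert silhouette_score(P1, labels) > 0.5

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="n_neighbors"):
            ev.project_2d(np.zeros((10, 3)), n_neighbors=15)
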