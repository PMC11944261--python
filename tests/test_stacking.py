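"""Feature assembly, grid search, weight extraction and meta-learners."""

import numpy as np
import pandas as pd
import pytest

from vfstack import stacking
from vfstack.nn import MiniMLP
from vfstack.stacking import (build_features, extract_meta_features,
                              hyperparameter_search, predict, train_base,
                              train_meta, META_DIM, PENULTIMATE_WIDTH)
from vfstack.synthdata import SimulationConfig, simulate_cohort


@pytest.fixture(scope="module")
def small_cohort():
    cfg = SimulationConfig(n_patients=60, seed=21, defect_depth_db=15.0,
                           noise_sd_db=1.0)
    return simulate_cohort(cfg)


@pytest.fixture(scope="module")
def trained_bundles(small_cohort):
    cohort, truth = small_cohort
    from vfstack.criteria import default_criteria, run_all_criteria
    from vfstack.grid import build_grid
    grid = build_grid("OD")
    verdicts, _ = run_all_criteria(cohort, default_criteria(), grid)
    td = build_features(cohort, "TD")
    pdf = build_features(cohort, "PD")
    td_b = train_base(td, verdicts, stacking.TD_CRITERIA, seed=1)
    pd_b = train_base(pdf, verdicts, stacking.PD_CRITERIA, seed=2)
    return td_b, pd_b, td, pdf


class TestFeatures:
    def test_dimension_and_alignment(self, small_cohort):
        cohort, _ = small_cohort
        fv = build_features(cohort, "TD")
        assert fv.X.shape[1] == 56
        assert len(fv.sample_ids) == fv.X.shape[0]
        assert fv.encodings["gender"] == {"female": 0, "male": 1}

    def test_standardization_reused_for_held_out(self, small_cohort):
        cohort, _ = small_cohort
        tr = build_features(cohort, "TD")
        te = build_features(cohort, "TD", stats_from=tr)
        np.testing.assert_array_equal(tr.mean, te.mean)
        np.testing.assert_allclose(tr.X, te.X)

    def test_median_imputation(self):
        X = np.array([[1.0, np.nan], [3.0, 2.0], [np.nan, 4.0]])
        out = stacking._impute_median(X)
        assert out[2, 0] == 2.0 and out[0, 1] == 3.0


class TestHyperparameterSearch:
    def test_full_grid_cardinality(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(50, 4))
        y = (X[:, 0] > 0).astype(float)
        _, table = hyperparameter_search(X, y, folds=5, seed=0, max_epochs=2,
                                         hidden=(8, PENULTIMATE_WIDTH))
        assert len(table) == 27
        assert table["fold_scores"].map(len).eq(5).all()  # 135 fits

    def test_separable_data_selects_strong_config(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(120, 3))
        y = (X[:, 0] > 0).astype(float)
        X[:, 0] += np.where(y == 1, 2.0, -2.0)  # wide margin
        cfg, table = hyperparameter_search(
            X, y, grid={"activation": ("sigmoid", "relu"),
                        "lr": (1e-2, 1e-5), "optimizer": ("adam",)},
            folds=5, seed=0, max_epochs=10, hidden=(8, PENULTIMATE_WIDTH))
        best = table.loc[table["mean_score"].idxmax()]
        assert table[(table["activation"] == cfg["activation"])
                     & (table["lr"] == cfg["lr"])]["mean_score"].iloc[0] == \
            best["mean_score"]
        assert best["mean_score"] > 0.9

    def test_class_starved_folds_rejected(self):
        X = np.zeros((10, 2))
        y = np.array([1, 0, 0, 0, 0, 0, 0, 0, 0, 0])
        with pytest.raises(ValueError, match="per class"):
            hyperparameter_search(X, y, folds=5)


class TestMetaFeatures:
    def test_dimension_conservation(self, trained_bundles):
        td_b, pd_b, td, pdf = trained_bundles
        clin = np.zeros((td.X.shape[0], 4))
        meta = extract_meta_features(td_b, pd_b, td.X, pdf.X, clin)
        assert meta.shape == (td.X.shape[0], META_DIM)

    def test_zero_output_weights_zero_block(self, trained_bundles):
        td_b, pd_b, td, pdf = trained_bundles
        saved = td_b.network.layers[-1].W.copy()
        td_b.network.layers[-1].W = np.zeros_like(saved)
        try:
            meta = extract_meta_features(td_b, pd_b, td.X, pdf.X,
                                         np.ones((td.X.shape[0], 4)))
            assert np.all(meta[:, :PENULTIMATE_WIDTH] == 0)
            assert np.any(meta[:, PENULTIMATE_WIDTH:2 * PENULTIMATE_WIDTH] != 0)
        finally:
            td_b.network.layers[-1].W = saved

    def test_identical_exams_identical_features(self, trained_bundles):
        td_b, pd_b, td, pdf = trained_bundles
        X2 = np.vstack([td.X[:1], td.X[:1]])
        P2 = np.vstack([pdf.X[:1], pdf.X[:1]])
        meta = extract_meta_features(td_b, pd_b, X2, P2, np.zeros((2, 4)))
        np.testing.assert_array_equal(meta[0], meta[1])

    @pytest.mark.parametrize("variant", ["weighted", "activations", "weights"])
    def test_variants_all_132(self, trained_bundles, variant):
        td_b, pd_b, td, pdf = trained_bundles
        meta = extract_meta_features(td_b, pd_b, td.X, pdf.X,
                                     np.zeros((td.X.shape[0], 4)),
                                     variant=variant)
        assert meta.shape[1] == META_DIM


class TestMetaLearners:
    def _separable(self, n=240, seed=0):
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 2, n)
        X = rng.normal(size=(n, META_DIM)) * 0.3
        X[:, 0] += np.where(y == 1, 3.0, -3.0)
        return X, y

    @pytest.mark.parametrize("kind", ["lr", "xgb", "mlp"])
    def test_probabilities_in_unit_interval(self, kind):
        X, y = self._separable()
        model = train_meta(X[:200], y[:200], kind, seed=0)
        p, labels = predict(model, X[200:])
        assert np.all((p >= 0) & (p <= 1))
        assert set(labels) <= {0, 1}

    def test_lr_separable_accuracy(self):
        X, y = self._separable()
        model = train_meta(X[:200], y[:200], "lr", seed=0)
        _, labels = predict(model, X[200:])
        assert (labels == y[200:]).mean() > 0.95

    def test_xgb_on_permuted_labels_near_chance(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(400, META_DIM))
        y = rng.integers(0, 2, 400)  # labels independent of features
        model = train_meta(X[:300], y[:300], "xgb", seed=0)
        _, labels = predict(model, X[300:])
        acc = (labels == y[300:]).mean()
        # binomial 99% interval around 0.5 at n=100
        assert 0.35 <= acc <= 0.65

    def test_single_class_labels_rejected(self):
        X = np.zeros((20, META_DIM))
        with pytest.raises(ValueError, match="both classes"):
            train_meta(X, np.ones(20), "lr")

    def test_class_separation_on_generator_data(self, trained_bundles,
                                                small_cohort):
        td_b, pd_b, td, pdf = trained_bundles
        cohort, truth = small_cohort
        labels = truth.set_index(["patient_id", "eye"])["label"]
        y = np.array([labels.loc[sid] for sid in td.sample_ids])
        clin = np.zeros((td.X.shape[0], 4))
        meta = extract_meta_features(td_b, pd_b, td.X, pdf.X, clin)
        model = train_meta(meta, y, "lr", seed=0)
        p, _ = predict(model, meta)
        assert p[y == 1].mean() > p[y == 0].mean()

    def test_decision_threshold(self):
        X, y = self._separable()
        model = train_meta(X[:200], y[:200], "lr", seed=0)
        p, lab_default = predict(model, X[200:])
        _, lab_high = predict(model, X[200:], threshold=0.9)
        assert lab_high.sum() <= lab_default.sum()
        assert (p >= 0.5).astype(int).tolist() == lab_default.tolist()
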