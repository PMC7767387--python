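"""Maximum-likelihood crop masking and the Random-Forest lodging classifier."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from lodgemap import reference as ref
from lodgemap.classify import (
    ClassifierSpec,
    GaussianMLC,
    LodgingRandomForest,
    case_features,
    crop_mask,
    mlc_fit,
    mlc_predict,
    rf_train_predict,
)
from lodgemap.geo import GridTransform, RasterStack


class TestMLC:
    def test_symmetric_1d_boundary_at_midpoint(self, rng):
        X = np.r_[rng.normal(0, 1, 200), rng.normal(10, 1, 200)][:, None]
        y = np.r_[np.zeros(200, int), np.ones(200, int)]
        m = mlc_fit(X, y)
        grid = np.linspace(-5, 15, 401)[:, None]
        pred = m.predict(grid)
        flip = grid[np.nonzero(np.diff(pred))[0][0], 0]
        assert flip == pytest.approx(5.0, abs=0.5)

    def test_degenerate_constant_class_is_regularised(self):
        X = np.r_[np.full((10, 2), 3.0), np.random.default_rng(0).normal(size=(10, 2))]
        y = np.r_[np.zeros(10, int), np.ones(10, int)]
        m = mlc_fit(X, y)  # no failure
        assert m.predict(np.array([[3.0, 3.0]]))[0] == 0

    def test_matches_direct_gaussian_density_argmax(self, rng):
        means = np.array([[0.0, 0.0], [3.0, 0.0], [0.0, 3.0]])
        y = rng.integers(0, 3, 120)
        X = rng.normal(size=(120, 2)) + means[y]
        m = mlc_fit(X, y)
        Xt = rng.normal(scale=3.0, size=(200, 2))
        dens = np.column_stack(
            [multivariate_normal(m.means_[k], m.covs_[k]).logpdf(Xt) for k in range(3)]
        )
        np.testing.assert_array_equal(m.predict(Xt), m.classes_[np.argmax(dens, axis=1)])

    def test_too_few_samples_rejected(self):
        X = np.zeros((5, 4))
        with pytest.raises(ValueError, match="class 0"):
            mlc_fit(X, np.zeros(5, int))

    def test_predict_raster_and_feature_mismatch(self, rng):
        X = np.r_[rng.normal(0, 1, (50, 1)), rng.normal(8, 1, (50, 1))]
        y = np.r_[np.zeros(50, int), np.ones(50, int)]
        m = mlc_fit(X, y)
        stack = RasterStack({"f": np.full((4, 4), 8.0)}, GridTransform())
        labels = mlc_predict(m, stack, ["f"])
        assert (labels.grid == 1).all()
        with pytest.raises(ValueError, match="missing"):
            mlc_predict(m, stack, ["g"])

    def test_crop_mask_recovers_crop_region(self, small_scene):
        mask = crop_mask(small_scene.optical_after, small_scene.mask_train_pixels)
        truth_crop = np.isin(small_scene.truth, ref.CROP_CODES)
        agree = (mask == truth_crop).mean()
        assert agree > 0.9


def toy_training(rng, n=400, sep=6.0, sd=1.0, n_features=3):
    X = rng.normal(scale=sd, size=(n, n_features))
    y = rng.integers(0, 2, n)
    X[:, 0] += sep * y
    return X, y


class TestRandomForest:
    def spec(self, **kw):
        base = dict(case="OSF", n_trees=25, seed=0)
        base.update(kw)
        return ClassifierSpec(**base)

    def test_separable_training_data_fit_perfectly(self, rng):
        X, y = toy_training(rng, sep=20.0)
        model = LodgingRandomForest(self.spec()).fit(X, y)
        assert (model.predict(X) == y).all()

    def test_same_seed_identical_predictions(self, rng):
        X, y = toy_training(rng, sep=2.0)
        Xt = rng.normal(size=(300, 3))
        p1 = LodgingRandomForest(self.spec(n_trees=40)).fit(X, y).predict(Xt)
        p2 = LodgingRandomForest(self.spec(n_trees=40)).fit(X, y).predict(Xt)
        assert np.array_equal(p1, p2)

    def test_ensemble_beats_single_tree_usually(self):
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            X, y = toy_training(rng, sep=1.5)
            Xt, yt = toy_training(rng, sep=1.5, n=500)
            acc = {}
            for n_trees in (1, 100):
                m = LodgingRandomForest(self.spec(n_trees=n_trees, seed=seed)).fit(X, y)
                acc[n_trees] = (m.predict(Xt) == yt).mean()
            wins += acc[100] >= acc[1]
        assert wins >= 8

    def test_node_impurity_threshold_prunes(self, rng):
        """With the node-threshold reading, a node at Gini <= 0.2 is a leaf;
        threshold 0.5 therefore predicts the root majority everywhere."""
        X, y = toy_training(rng, sep=8.0)
        y[:10] = 1 - y[:10]
        majority = np.bincount(y).argmax()
        m = LodgingRandomForest(self.spec(min_impurity=0.5, bootstrap=False, n_trees=5)).fit(X, y)
        assert (m.predict(X) == majority).all()

    def test_decrease_mode_runs(self, rng):
        X, y = toy_training(rng)
        m = LodgingRandomForest(self.spec(impurity_mode="decrease", min_impurity=0.01)).fit(X, y)
        assert set(np.unique(m.predict(X))) <= {0, 1}

    @pytest.mark.parametrize(
        "kw", [dict(n_trees=0), dict(min_impurity=0.7), dict(case="BAD"), dict(max_features_per_split=0)]
    )
    def test_invalid_spec_rejected(self, kw):
        with pytest.raises(ValueError):
            self.spec(**kw).validate()


class TestCaseFeaturesAndMapping:
    def test_case_feature_lists(self):
        osf, osi = ["VV", "VH"], ["B11"]
        assert case_features("OSF", osf, osi) == ["VV", "VH"]
        assert case_features("OSI", osf, osi) == ["B11"]
        assert case_features("OSF_OSI", osf, osi) == ["VV", "VH", "B11"]
        with pytest.raises(ValueError, match="no features"):
            case_features("OSI", osf, [])

    def make_scene_stack(self, rng):
        h = w = 30
        truth = (np.arange(h * w).reshape(h, w) % 2).astype(int)  # checkerboard-ish classes
        f = truth * 5.0 + rng.normal(scale=0.3, size=(h, w))
        stack = RasterStack({"VV": f, "B11": f + 1.0}, GridTransform())
        import pandas as pd

        idx = rng.choice(h * w, 200, replace=False)
        train = pd.DataFrame({"row": idx // w, "col": idx % w, "class_code": truth.ravel()[idx]})
        return truth, stack, train

    def test_masked_pixels_never_carry_crop_class(self, rng):
        truth, stack, train = self.make_scene_stack(rng)
        mask = np.zeros(truth.shape, dtype=bool)
        mask[:10] = True
        labels = rf_train_predict(ClassifierSpec(case="OSF_OSI", n_trees=10, seed=1), train, stack, ["VV", "B11"], mask)
        assert (labels.grid[~mask] == ref.NONCROP_LABEL).all()
        assert np.isin(labels.grid[mask], ref.CROP_CODES).all()
        # masking idempotence: applying the mask again changes nothing
        again = labels.grid.copy()
        again[~mask] = ref.NONCROP_LABEL
        assert np.array_equal(again, labels.grid)

    def test_prediction_invariant_to_band_order(self, rng):
        truth, stack, train = self.make_scene_stack(rng)
        mask = np.ones(truth.shape, dtype=bool)
        reordered = stack.select(["B11", "VV"])
        spec = ClassifierSpec(case="OSF_OSI", n_trees=10, seed=3)
        l1 = rf_train_predict(spec, train, stack, ["VV", "B11"], mask)
        l2 = rf_train_predict(spec, train, reordered, ["VV", "B11"], mask)
        assert np.array_equal(l1.grid, l2.grid)

    def test_missing_case_features_listed(self, rng):
        truth, stack, train = self.make_scene_stack(rng)
        with pytest.raises(ValueError, match="Entropy"):
            rf_train_predict(ClassifierSpec(case="OSF"), train, stack, ["VV", "Entropy"], np.ones_like(truth, bool))
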