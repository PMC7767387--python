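"""Crop masking and lodged/healthy mapping.

Two classifiers:

* Gaussian maximum-likelihood classification (MLC) with equal priors,
  used on the optical bands to separate crop from non-crop land cover and
  derive the rice mask.  The union of the two rice classes is the mask.
* A Random-Forest ensemble (bootstrap resampling, Gini criterion, a small
  random feature subset per node) that maps lodged vs. healthy rice inside
  the mask under three feature cases: OSF (selected SAR features), OSI
  (selected optical indices) and their union OSF–OSI.

The forest's "minimum impurity" setting is interpreted as a node-split
threshold: a node whose Gini impurity is at or below the threshold is
treated as a leaf (prediction stops there and takes the node majority).
Standard scikit-learn trees provide the fitted ensemble; the thresholded
descent is applied at prediction time, which is equivalent to pruning every
subtree rooted at a node with impurity <= threshold.  The alternative
reading, a minimum impurity *decrease* per split, is available via
``impurity_mode="decrease"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_triangular
from sklearn.ensemble import RandomForestClassifier

from . import reference as ref
from .geo import GridTransform, RasterStack

log = logging.getLogger(__name__)

CASES = ("OSF", "OSI", "OSF_OSI")


@dataclass
class ClassifierSpec:
    case: str = "OSF_OSI"
    n_trees: int = 100
    max_features_per_split: int = 2
    min_impurity: float = 0.2
    impurity_mode: str = "node_threshold"  # or "decrease"
    bootstrap: bool = True
    seed: int = 0

    def validate(self, n_features: int | None = None) -> None:
        if self.case not in CASES:
            raise ValueError(f"case must be one of {CASES}")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.max_features_per_split < 1:
            raise ValueError("max_features_per_split must be >= 1")
        if n_features is not None and self.max_features_per_split > n_features:
            raise ValueError("max_features_per_split exceeds the number of input features")
        if not 0.0 <= self.min_impurity <= 0.5:
            raise ValueError("min_impurity must lie in [0, 0.5]")
        if self.impurity_mode not in ("node_threshold", "decrease"):
            raise ValueError("impurity_mode must be 'node_threshold' or 'decrease'")


@dataclass
class LabelRaster:
    """Integer class map with legend and provenance."""

    grid: np.ndarray
    legend: dict[int, str]
    transform: GridTransform = field(default_factory=GridTransform)
    provenance: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Maximum-likelihood classification
# ---------------------------------------------------------------------------


@dataclass
class GaussianMLC:
    """Class-conditional Gaussian classifier with equal priors.

    Covariances are regularised with delta·I where delta is 1e-6 times the
    mean feature variance of the class, so degenerate (constant) classes
    still fit.
    """

    classes_: np.ndarray = None
    means_: np.ndarray = None
    covs_: np.ndarray = None
    _chol: list = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "GaussianMLC":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be (n_samples, n_features)")
        dim = X.shape[1]
        self.classes_ = np.unique(y)
        means, covs, chols = [], [], []
        for c in self.classes_:
            Xc = X[y == c]
            if len(Xc) < dim + 2:
                raise ValueError(
                    f"class {c}: needs at least {dim + 2} samples, got {len(Xc)}"
                )
            mu = Xc.mean(axis=0)
            cov = np.cov(Xc, rowvar=False, bias=False)
            cov = np.atleast_2d(cov)
            delta = 1e-6 * max(np.trace(cov) / dim, np.finfo(float).tiny)
            cov = cov + delta * np.eye(dim)
            try:
                chol = np.linalg.cholesky(cov)
            except np.linalg.LinAlgError as e:
                raise ValueError(f"class {c}: covariance singular after regularisation") from e
            means.append(mu)
            covs.append(cov)
            chols.append(chol)
        self.means_ = np.array(means)
        self.covs_ = np.array(covs)
        self._chol = chols
        return self

    def log_likelihood(self, X: np.ndarray) -> np.ndarray:
        """(n_samples, n_classes) Gaussian log-densities (equal priors omitted)."""
        X = np.asarray(X, dtype=float)
        out = np.empty((X.shape[0], len(self.classes_)))
        for k, (mu, chol) in enumerate(zip(self.means_, self._chol)):
            z = solve_triangular(chol, (X - mu).T, lower=True)
            maha = np.sum(z**2, axis=0)
            logdet = 2.0 * np.sum(np.log(np.diag(chol)))
            out[:, k] = -0.5 * (maha + logdet + X.shape[1] * np.log(2 * np.pi))
        return out

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Argmax of class log-likelihood; ties break toward the lower class code."""
        return self.classes_[np.argmax(self.log_likelihood(X), axis=1)]


def mlc_fit(X: np.ndarray, y: np.ndarray) -> GaussianMLC:
    return GaussianMLC().fit(X, y)


def mlc_predict(model: GaussianMLC, stack: RasterStack, feature_names: list[str]) -> LabelRaster:
    """Classify every pixel of ``stack`` with a fitted MLC model."""
    missing = [n for n in feature_names if n not in stack.bands]
    if missing:
        raise ValueError(f"features missing from stack: {missing}")
    h, w = stack.shape
    X = np.column_stack([stack[n].ravel() for n in feature_names])
    labels = model.predict(X).reshape(h, w)
    return LabelRaster(
        grid=labels.astype(np.uint8),
        legend=dict(ref.LEGEND),
        transform=stack.transform,
        provenance={"classifier": "mlc", "features": list(feature_names)},
    )


def crop_mask(
    optical: RasterStack, train_pixels, feature_names: list[str] | None = None
) -> np.ndarray:
    """Boolean rice mask from MLC over all land-cover classes.

    Crop = union of the rice classes in the predicted map.
    """
    feature_names = feature_names or optical.names
    X = optical.pixel_matrix(train_pixels["row"], train_pixels["col"], feature_names)
    model = mlc_fit(X, train_pixels["class_code"].to_numpy())
    labels = mlc_predict(model, optical, feature_names)
    return np.isin(labels.grid, ref.CROP_CODES)


# ---------------------------------------------------------------------------
# Random Forest with node-impurity stopping
# ---------------------------------------------------------------------------


class LodgingRandomForest:
    """Bootstrap tree ensemble with an early-stop impurity threshold."""

    def __init__(self, spec: ClassifierSpec):
        self.spec = spec
        self._rf: RandomForestClassifier | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "LodgingRandomForest":
        self.spec.validate()
        if self.spec.max_features_per_split > X.shape[1]:
            log.info(
                "case %s: clamping max_features_per_split to the %d available features",
                self.spec.case, X.shape[1],
            )
        self._rf = RandomForestClassifier(
            n_estimators=self.spec.n_trees,
            criterion="gini",
            max_features=min(self.spec.max_features_per_split, X.shape[1]),
            bootstrap=self.spec.bootstrap,
            min_impurity_decrease=(
                self.spec.min_impurity if self.spec.impurity_mode == "decrease" else 0.0
            ),
            random_state=self.spec.seed,
            n_jobs=1,
        )
        self._rf.fit(X, y)
        return self

    def _tree_votes(self, X: np.ndarray) -> np.ndarray:
        """(n_samples, n_classes) vote counts under thresholded tree descent."""
        rf = self._rf
        n_classes = len(rf.classes_)
        votes = np.zeros((X.shape[0], n_classes), dtype=np.int32)
        thr = self.spec.min_impurity
        for est in rf.estimators_:
            t = est.tree_
            node = np.zeros(X.shape[0], dtype=np.int64)
            while True:
                is_stop = (t.children_left[node] == -1) | (t.impurity[node] <= thr)
                if is_stop.all():
                    break
                act = ~is_stop
                nd = node[act]
                feat = t.feature[nd]
                go_left = X[act, feat] <= t.threshold[nd]
                node[act] = np.where(go_left, t.children_left[nd], t.children_right[nd])
            counts = t.value[node, 0, :]  # per-node class distribution
            votes[np.arange(X.shape[0]), np.argmax(counts, axis=1)] += 1
        return votes

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self._rf is None:
            raise RuntimeError("fit first")
        X = np.asarray(X, dtype=float)
        if self.spec.impurity_mode == "decrease":
            return self._rf.predict(X)
        votes = self._tree_votes(X)
        return self._rf.classes_[np.argmax(votes, axis=1)]


def case_features(case: str, osf: list[str], osi: list[str]) -> list[str]:
    """Feature-name list for a classification case from the screening output."""
    if case == "OSF":
        names = list(osf)
    elif case == "OSI":
        names = list(osi)
    elif case == "OSF_OSI":
        names = list(osf) + list(osi)
    else:
        raise ValueError(f"unknown case {case!r}")
    if not names:
        raise ValueError(f"case {case}: screening selected no features")
    return names


def fit_rf(
    spec: ClassifierSpec, train_pixels, stack: RasterStack, feature_names: list[str]
) -> LodgingRandomForest:
    """Fit the forest on the crop-labelled subset of the training pixels."""
    missing = [n for n in feature_names if n not in stack.bands]
    if missing:
        raise ValueError(f"case {spec.case}: features missing from stack: {missing}")
    crop_train = train_pixels[np.isin(train_pixels["class_code"], ref.CROP_CODES)]
    X = stack.pixel_matrix(crop_train["row"], crop_train["col"], feature_names)
    y = crop_train["class_code"].to_numpy()
    return LodgingRandomForest(spec).fit(X, y)


def rf_predict_pixels(
    model: LodgingRandomForest, stack: RasterStack, feature_names: list[str], rows, cols
) -> np.ndarray:
    return model.predict(stack.pixel_matrix(rows, cols, feature_names))


def rf_train_predict(
    spec: ClassifierSpec,
    train_pixels,
    stack: RasterStack,
    feature_names: list[str],
    mask: np.ndarray,
) -> LabelRaster:
    """Train the forest on labelled crop pixels and map the masked scene.

    Non-crop pixels carry :data:`reference.NONCROP_LABEL`.
    """
    model = fit_rf(spec, train_pixels, stack, feature_names)

    h, w = stack.shape
    grid = np.full((h, w), ref.NONCROP_LABEL, dtype=np.uint8)
    rows, cols = np.nonzero(mask)
    if rows.size:
        Xm = stack.pixel_matrix(rows, cols, feature_names)
        grid[rows, cols] = model.predict(Xm)
    legend = {c: ref.LEGEND[c] for c in ref.CROP_CODES}
    legend[ref.NONCROP_LABEL] = "non_crop"
    return LabelRaster(
        grid=grid,
        legend=legend,
        transform=stack.transform,
        provenance={
            "classifier": "random_forest",
            "case": spec.case,
            "features": list(feature_names),
            "n_trees": spec.n_trees,
            "max_features_per_split": spec.max_features_per_split,
            "min_impurity": spec.min_impurity,
            "impurity_mode": spec.impurity_mode,
            "seed": spec.seed,
        },
    )
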