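"""Pixel classifiers: spectral angle mapper, random forest, SVM and CNN.

All four are scikit-learn-style estimators over pixel spectra: ``fit(X, y)``
with ``y`` in {0 healthy, 1 defect}, ``predict(X)`` returning the same
labels, and get/set_params for pipeline composition.  :func:`predict_map`
lifts any fitted estimator to a full decision map over a reflectance cube
and object mask, with the spectral angle mapper additionally applying its
glare-exclusion rule (glare carries no tissue information and is treated
as healthy surface).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from ._nn import SpectralConvNet
from .calib import otsu_threshold
from .dataset import LABEL_DEFECT, LABEL_HEALTHY, PixelDataset, ReferenceSpectra
from .spectra import ReflectanceCube

__all__ = [
    "SAMClassifier",
    "SpectralForestClassifier",
    "SpectralSVMClassifier",
    "SpectralCNNClassifier",
    "SimilarityMaps",
    "DecisionMap",
    "sam_similarity_maps",
    "sam_classify",
    "glare_mask",
    "predict_map",
    "make_classifier",
]

# decision-map codes
MAP_EXCLUDED = 0
MAP_HEALTHY = 1
MAP_DEFECT = 2


def _check_Xy(X, y=None):
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("X must be a non-empty (N, B) matrix")
    if not np.isfinite(X).all():
        raise ValueError("X contains non-finite values")
    if y is None:
        return X
    y = np.asarray(y)
    if y.shape != (X.shape[0],):
        raise ValueError("y length must match X")
    if np.unique(y).size < 2:
        raise ValueError("training data must contain both classes")
    return X, y


# ---------------------------------------------------------------------------
# spectral angle mapper
# ---------------------------------------------------------------------------

@dataclass
class SimilarityMaps:
    """Cosine-similarity maps against the class references."""

    healthy: np.ndarray          # (H, W) cosine to the healthy reference
    defect: np.ndarray           # (H, W) cosine to the defect reference
    glare: np.ndarray            # (H, W) bool
    valid: np.ndarray            # (H, W) bool: masked and well-defined

    @property
    def healthy_angle(self) -> np.ndarray:
        """Spectral angle (radians) to the healthy reference."""
        return np.arccos(np.clip(self.healthy, -1.0, 1.0))


@dataclass
class DecisionMap:
    """Per-pixel {0 excluded, 1 healthy, 2 defect} grid with method tags."""

    values: np.ndarray
    method: str = ""
    mode: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.uint8)


def glare_mask(cube: ReflectanceCube, mask: np.ndarray,
               percentile: float = 99.5, absolute: float = 0.9) -> np.ndarray:
    """Glare pixels: brightest masked pixels above an absolute floor.

    A pixel is glare when its broadband mean reflectance exceeds both the
    given percentile of masked pixels and the absolute level; the region
    is dilated by one pixel to catch glint rims.
    """
    mask = np.asarray(mask, dtype=bool)
    mean_map = cube.data.mean(axis=2)
    vals = mean_map[mask]
    if vals.size == 0:
        return np.zeros_like(mask)
    cut = max(np.percentile(vals, percentile), absolute)
    glare = mask & (mean_map > cut)
    if glare.any():
        glare = ndimage.binary_dilation(glare, structure=np.ones((3, 3), bool))
    return glare & mask


def sam_similarity_maps(cube: ReflectanceCube, mask: np.ndarray,
                        refs: ReferenceSpectra,
                        glare_percentile: float = 99.5,
                        glare_absolute: float = 0.9) -> SimilarityMaps:
    """Per-pixel cosine similarity with each normalized class reference."""
    if cube.data.shape[2] != refs.healthy.shape[0]:
        raise ValueError("cube band count does not match the references")
    mask = np.asarray(mask, dtype=bool) & ~cube.invalid
    H, W, _ = cube.data.shape
    healthy = np.zeros((H, W))
    defect = np.zeros((H, W))
    spectra = cube.data[mask]
    norms = np.linalg.norm(spectra, axis=1)
    defined = norms > 0
    unit = np.zeros_like(spectra)
    unit[defined] = spectra[defined] / norms[defined, None]
    healthy[mask] = unit @ refs.healthy_unit
    defect[mask] = unit @ refs.defect_unit
    valid = mask.copy()
    valid[mask] &= defined
    return SimilarityMaps(healthy=healthy, defect=defect,
                          glare=glare_mask(cube, mask, glare_percentile,
                                           glare_absolute),
                          valid=valid)


def _trimmed_otsu(score: np.ndarray, defect_side_low: bool,
                  trim: float) -> float:
    """Otsu threshold over a tail-trimmed histogram range.

    A handful of extreme outliers (deep glare rims, heavily shaded defect
    pixels) can stretch the histogram so far that every class crowds into
    a few bins and the split degenerates to outliers-versus-everything.
    Trimming the defect-side tail before histogramming stabilizes the
    range; trimmed pixels are the most dissimilar ones and fall on the
    defect side of the returned threshold by construction.
    """
    if trim <= 0:
        return otsu_threshold(score)
    if defect_side_low:
        lo = np.quantile(score, trim)
        kept = score[score >= lo]
    else:
        hi = np.quantile(score, 1.0 - trim)
        kept = score[score <= hi]
    if np.unique(kept).size < 2:
        kept = score
    return otsu_threshold(kept)


def sam_classify(maps: SimilarityMaps, thresholding: str = "fixed",
                 fixed_threshold: float | None = 0.2,
                 use_angle: bool = False, otsu_trim: float = 0.01) -> DecisionMap:
    """Binarize the healthy-similarity map into a decision map.

    Pixels whose similarity to the healthy reference falls below the
    threshold become defect; glare pixels are forced to healthy.  With
    ``thresholding='otsu'`` the threshold is chosen by Otsu's method on
    the valid non-glare similarity values over a tail-trimmed histogram
    range (see :func:`_trimmed_otsu`); ``use_angle`` thresholds the
    spectral-angle map instead (defect above the threshold).
    """
    if not maps.valid.any():
        raise ValueError("no valid pixels to classify")
    score = maps.healthy_angle if use_angle else maps.healthy
    sel = maps.valid & ~maps.glare
    if thresholding == "fixed":
        if fixed_threshold is None:
            raise ValueError("fixed thresholding requires a threshold value")
        thr = float(fixed_threshold)
    elif thresholding == "otsu":
        thr = _trimmed_otsu(score[sel], defect_side_low=not use_angle,
                            trim=otsu_trim)
    else:
        raise ValueError("thresholding must be 'fixed' or 'otsu'")
    out = np.zeros(maps.valid.shape, dtype=np.uint8)
    is_defect = (score > thr) if use_angle else (score < thr)
    out[maps.valid] = MAP_HEALTHY
    out[maps.valid & is_defect] = MAP_DEFECT
    out[maps.valid & maps.glare] = MAP_HEALTHY
    return DecisionMap(out, method="SAM")


class SAMClassifier(ClassifierMixin, BaseEstimator):
    """Spectral angle mapper: nearest class by cosine to reference spectra.

    Fitting only computes per-class mean reference spectra.  Prediction
    thresholds the cosine similarity to the healthy reference: below the
    threshold means defect.  ``thresholding='otsu'`` derives the cut from
    the similarity distribution of the pixels being predicted instead of
    using the fixed value.
    """

    def __init__(self, thresholding: str = "fixed", threshold: float = 0.2,
                 use_angle: bool = False, otsu_trim: float = 0.01):
        self.thresholding = thresholding
        self.threshold = threshold
        self.use_angle = use_angle
        self.otsu_trim = otsu_trim

    def fit(self, X, y) -> "SAMClassifier":
        X, y = _check_Xy(X, y)
        ds = PixelDataset(X, y, np.zeros(len(y), dtype=int))
        from .dataset import compute_reference_spectra
        self.references_ = compute_reference_spectra(ds)
        self.classes_ = np.array([LABEL_HEALTHY, LABEL_DEFECT])
        self.n_features_in_ = X.shape[1]
        return self

    def similarity(self, X) -> np.ndarray:
        """Cosine similarity of each spectrum to the healthy reference."""
        check_is_fitted(self, "references_")
        X = _check_Xy(X)
        norms = np.linalg.norm(X, axis=1)
        unit = np.divide(X, norms[:, None], out=np.zeros_like(X),
                         where=norms[:, None] > 0)
        return unit @ self.references_.healthy_unit

    def predict(self, X) -> np.ndarray:
        sim = self.similarity(X)
        score = np.arccos(np.clip(sim, -1, 1)) if self.use_angle else sim
        if self.thresholding == "otsu":
            thr = _trimmed_otsu(score, defect_side_low=not self.use_angle,
                                trim=self.otsu_trim)
        elif self.thresholding == "fixed":
            if self.threshold is None:
                raise ValueError("fixed thresholding requires a threshold")
            thr = self.threshold
        else:
            raise ValueError("thresholding must be 'fixed' or 'otsu'")
        defect = (score > thr) if self.use_angle else (score < thr)
        return np.where(defect, LABEL_DEFECT, LABEL_HEALTHY)


# ---------------------------------------------------------------------------
# random forest / SVM / CNN
# ---------------------------------------------------------------------------

class SpectralForestClassifier(ClassifierMixin, BaseEstimator):
    """Bagged decision-tree ensemble over pixel spectra.

    100 trees by default, Gini splits, unlimited depth, sqrt(B) features
    per split, with the out-of-bag error recorded as ``oob_error_``.
    """

    def __init__(self, n_trees: int = 100, seed: int = 0):
        self.n_trees = n_trees
        self.seed = seed

    def fit(self, X, y) -> "SpectralForestClassifier":
        X, y = _check_Xy(X, y)
        if self.n_trees < 1:
            raise ValueError("n_trees must be at least 1")
        with warnings.catch_warnings():
            # with very few trees some samples have no OOB vote
            warnings.simplefilter("ignore", UserWarning)
            self.forest_ = RandomForestClassifier(
                n_estimators=self.n_trees, criterion="gini", max_depth=None,
                max_features="sqrt", oob_score=True,
                random_state=self.seed, n_jobs=1).fit(X, y)
        self.oob_error_ = float(1.0 - self.forest_.oob_score_)
        self.classes_ = self.forest_.classes_
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "forest_")
        return self.forest_.predict(_check_Xy(X))


class SpectralSVMClassifier(ClassifierMixin, BaseEstimator):
    """RBF-kernel maximum-margin classifier with automatic kernel scale.

    The kernel scale is the median pairwise distance over a seeded
    subsample of up to 1,000 training spectra (``gamma = 1/(2 s^2)``).
    Training is capped at ``subsample_cap`` stratified pixels for
    tractability; the cap and convergence status are recorded.
    """

    def __init__(self, max_iter: int = 10_000, subsample_cap: int = 20_000,
                 C: float = 1.0, seed: int = 0):
        self.max_iter = max_iter
        self.subsample_cap = subsample_cap
        self.C = C
        self.seed = seed

    @staticmethod
    def _stratified_subsample(y: np.ndarray, cap: int,
                              rng: np.random.Generator) -> np.ndarray:
        if y.size <= cap:
            return np.arange(y.size)
        keep = []
        classes, counts = np.unique(y, return_counts=True)
        quota = (counts / y.size * cap).astype(int)
        quota = np.maximum(quota, 1)
        for cls, q in zip(classes, quota):
            idx = np.flatnonzero(y == cls)
            keep.append(rng.choice(idx, size=min(q, idx.size), replace=False))
        return np.sort(np.concatenate(keep))

    def fit(self, X, y) -> "SpectralSVMClassifier":
        X, y = _check_Xy(X, y)
        rng = np.random.default_rng(self.seed)
        keep = self._stratified_subsample(y, self.subsample_cap, rng)
        Xs, ys = X[keep], y[keep]
        self.n_train_used_ = int(keep.size)

        probe = Xs[rng.choice(Xs.shape[0], size=min(1000, Xs.shape[0]),
                              replace=False)]
        diff = probe[:, None, :] - probe[None, :, :]
        dists = np.sqrt((diff**2).sum(-1))
        scale = np.median(dists[np.triu_indices_from(dists, k=1)])
        if not np.isfinite(scale) or scale <= 0:
            scale = 1.0
        self.kernel_scale_ = float(scale)

        self.converged_ = True
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            self.svc_ = SVC(kernel="rbf", gamma=1.0 / (2 * scale**2), C=self.C,
                            max_iter=self.max_iter, random_state=self.seed,
                            decision_function_shape="ovo").fit(Xs, ys)
            if any(issubclass(w.category, ConvergenceWarning) for w in caught):
                self.converged_ = False
                warnings.warn("SVM hit its iteration limit; returning the "
                              "current model", stacklevel=2)
        self.classes_ = self.svc_.classes_
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "svc_")
        return self.svc_.decision_function(_check_Xy(X))

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "svc_")
        return self.svc_.predict(_check_Xy(X))


class SpectralCNNClassifier(ClassifierMixin, BaseEstimator):
    """Shallow 1-D convolutional network over the spectral axis.

    Three conv blocks (kernel 5, 8 maps, batch norm, ReLU), global
    average pooling, dense 64 and 16 with ReLU, 2-way softmax; trained
    with Adam (initial rate 1e-3) on mini-batches of 4096 spectra for a
    fixed number of epochs, no early stopping.  Pure-numpy and therefore
    bit-deterministic for a given seed.
    """

    def __init__(self, epochs: int = 30, batch_size: int = 4096,
                 learning_rate: float = 1e-3, seed: int = 0):
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.seed = seed

    def fit(self, X, y) -> "SpectralCNNClassifier":
        X, y = _check_Xy(X, y)
        self.classes_ = np.unique(y)
        codes = np.searchsorted(self.classes_, y)
        self.net_ = SpectralConvNet(n_bands=X.shape[1], seed=self.seed)
        self.loss_history_ = self.net_.train(
            X, codes, epochs=self.epochs, batch_size=self.batch_size,
            lr=self.learning_rate, seed=self.seed + 1)
        self.final_loss_ = self.loss_history_[-1]
        self.n_parameters_ = self.net_.n_parameters
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "net_")
        X = _check_Xy(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("band count does not match the trained network")
        return self.net_.predict_proba(X)

    def predict(self, X) -> np.ndarray:
        return self.classes_[self.predict_proba(X).argmax(axis=1)]


METHODS = ("sam", "rf", "svm", "nn")


def make_classifier(method: str, seed: int = 0, **overrides):
    """Construct one of the four classifiers by its short method name."""
    method = method.lower()
    if method == "sam":
        return SAMClassifier(**overrides)
    if method == "rf":
        return SpectralForestClassifier(seed=seed, **overrides)
    if method == "svm":
        return SpectralSVMClassifier(seed=seed, **overrides)
    if method == "nn":
        return SpectralCNNClassifier(seed=seed, **overrides)
    raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")


def predict_map(model, cube: ReflectanceCube, mask: np.ndarray,
                mode: str = "") -> DecisionMap:
    """Apply a fitted classifier to every masked pixel of a cube.

    The spectral angle mapper routes through its similarity maps so the
    glare-exclusion rule applies; other models predict pixel spectra
    directly.  Background (unmasked or invalid) pixels stay 0.
    """
    mask = np.asarray(mask, dtype=bool) & ~cube.invalid
    if isinstance(model, SAMClassifier):
        check_is_fitted(model, "references_")
        if cube.data.shape[2] != model.n_features_in_:
            raise ValueError("band count does not match the trained model")
        if not mask.any():
            return DecisionMap(np.zeros(mask.shape, dtype=np.uint8),
                               method="SAM", mode=mode)
        maps = sam_similarity_maps(cube, mask, model.references_)
        out = sam_classify(maps, thresholding=model.thresholding,
                           fixed_threshold=model.threshold,
                           use_angle=model.use_angle,
                           otsu_trim=model.otsu_trim)
        out.mode = mode
        return out
    check_is_fitted(model)
    if cube.data.shape[2] != model.n_features_in_:
        raise ValueError("band count does not match the trained model")
    out = np.zeros(mask.shape, dtype=np.uint8)
    if mask.any():
        labels = model.predict(cube.data[mask])
        out[mask] = np.where(labels == LABEL_DEFECT, MAP_DEFECT, MAP_HEALTHY)
    name = {SpectralForestClassifier: "RF", SpectralSVMClassifier: "SVM",
            SpectralCNNClassifier: "NN"}.get(type(model),
                                             type(model).__name__)
    return DecisionMap(out, method=name, mode=mode)
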