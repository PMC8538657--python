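"""Stage 2: voxel classification into cortex, medulla and pelvis.

Each in-mask voxel is described by its signal-intensity time-course.
Curves are first normalized by the voxel's mean baseline signal (to
remove coil-gain scale, which does not transfer across subjects) and
compressed with principal component analysis into k feature aggregates
(k = 20 by default, raised if needed so the retained components explain
at least 90% of the training-set variance).  A supervised classifier —
an RBF-kernel SVM by default, alternatively multinomial logistic
regression or XGBoost trees — assigns each feature vector to one of the
three compartments.  Because the cortex/medulla/pelvis class mix is
skewed (roughly 58/31/11), the cortex and medulla training subsets are
resampled to the pelvis count before fitting.

Two literature baselines are provided for comparison: Daubechies-4
discrete-wavelet-transform features (classified with the same SVM) and
unsupervised k-means (k = 3) on the PCA features, whose clusters are
mapped to classes by majority ground-truth vote at evaluation time
only.

Leave-one-subject-out discipline: the PCA model and classifier each
record the subjects they were fitted on, and :func:`classify_voxels`
refuses to combine artifacts from different training cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import balanced_accuracy_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .dataio import CompartmentLabelMap, DynamicSeries, KidneyMask
from .errors import (
    ConfigurationError,
    EmptyRegionError,
    MissingClassError,
    ParameterError,
    ProvenanceError,
    ShapeError,
)

__all__ = [
    "TimeCourseSet",
    "PCAModel",
    "ClassifierConfig",
    "VoxelClassifier",
    "KMeansResult",
    "extract_time_courses",
    "concat_time_courses",
    "baseline_normalize",
    "fit_pca",
    "transform_pca",
    "balance_classes",
    "train_classifier",
    "grid_search_svm",
    "classify_voxels",
    "dwt_features",
    "kmeans_partition",
]


@dataclass
class TimeCourseSet:
    """Per-voxel signal time-courses with indices, optional labels and provenance."""

    values: np.ndarray               # (n_voxels, n_frames)
    voxels: np.ndarray               # (n_voxels, 3) integer indices
    labels: np.ndarray | None = None
    subjects: np.ndarray | None = None
    frame_times: np.ndarray | None = None
    n_baseline: int = 8

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.voxels = np.asarray(self.voxels)
        if self.values.ndim != 2 or len(self.voxels) != len(self.values):
            raise ShapeError("row count of values must equal voxel index count")
        if self.labels is not None and len(self.labels) != len(self.values):
            raise ShapeError("labels must have one entry per voxel")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]


@dataclass
class PCAModel:
    """Fitted PCA compression of (baseline-normalized) time-courses."""

    mean: np.ndarray
    components: np.ndarray           # (k, n_frames)
    explained_variance_ratio: np.ndarray
    k: int
    normalized: bool
    n_baseline: int
    frame_times: np.ndarray | None
    training_subjects: frozenset

    def __post_init__(self) -> None:
        gram = self.components @ self.components.T
        if not np.allclose(gram, np.eye(self.k), atol=1e-8):
            raise ShapeError("PCA components must be orthonormal")


@dataclass
class ClassifierConfig:
    """Hyperparameters of the three supported classifiers."""

    algorithm: str = "svm_rbf"       # {"svm_rbf", "logistic", "xgboost"}
    svm_gamma: float = 0.05
    svm_c: float = 1.0
    logistic_max_iter: int = 500
    xgb_n_trees: int = 10
    xgb_max_depth: int = 4
    xgb_gamma: float = 0.1
    xgb_lambda: float = 0.9
    seed: int = 0

    def validate(self) -> None:
        if self.algorithm not in ("svm_rbf", "logistic", "xgboost"):
            raise ConfigurationError(f"unknown classifier algorithm '{self.algorithm}'")
        if min(self.svm_gamma, self.svm_c, self.xgb_gamma, self.xgb_lambda) <= 0:
            raise ConfigurationError("classifier hyperparameters must be positive")


@dataclass
class VoxelClassifier:
    """A fitted compartment classifier plus its training provenance."""

    estimator: object
    algorithm: str
    training_subjects: frozenset
    config: ClassifierConfig

    def predict(self, features: np.ndarray) -> np.ndarray:
        pred = self.estimator.predict(features)
        return pred + 1 if self.algorithm == "xgboost" else pred

    def scores(self, features: np.ndarray) -> np.ndarray:
        """Per-class scores (probabilities where available, else decision values)."""
        if hasattr(self.estimator, "predict_proba") and self.algorithm != "svm_rbf":
            return self.estimator.predict_proba(features)
        return self.estimator.decision_function(features)


@dataclass
class KMeansResult:
    cluster_labels: np.ndarray
    inertia: float
    mapping: dict | None = None
    mapped_labels: np.ndarray | None = None


# ---------------------------------------------------------------------------
# time-courses and features
# ---------------------------------------------------------------------------

def extract_time_courses(
    series: DynamicSeries,
    mask: KidneyMask | np.ndarray,
    labels: CompartmentLabelMap | None = None,
    subject: str = "",
) -> TimeCourseSet:
    """One row per in-mask voxel; ground-truth labels attached where provided."""
    mask_data = mask.data if isinstance(mask, KidneyMask) else np.asarray(mask, dtype=bool)
    if mask_data.shape != series.shape[:3]:
        raise ShapeError("mask grid does not match series grid")
    if not mask_data.any():
        raise EmptyRegionError("mask contains no voxels")
    voxels = np.argwhere(mask_data)
    values = series.data[mask_data]
    lab = labels.data[mask_data] if labels is not None else None
    return TimeCourseSet(
        values=values,
        voxels=voxels,
        labels=lab,
        subjects=np.full(len(values), subject),
        frame_times=series.frame_times.copy(),
        n_baseline=series.n_baseline_frames,
    )


def concat_time_courses(sets: list[TimeCourseSet]) -> TimeCourseSet:
    return TimeCourseSet(
        values=np.concatenate([s.values for s in sets]),
        voxels=np.concatenate([s.voxels for s in sets]),
        labels=None if sets[0].labels is None else np.concatenate([s.labels for s in sets]),
        subjects=np.concatenate([s.subjects for s in sets]),
        frame_times=sets[0].frame_times,
        n_baseline=sets[0].n_baseline,
    )


def baseline_normalize(values: np.ndarray, n_baseline: int) -> np.ndarray:
    """Divide each voxel curve by its mean pre-contrast signal."""
    base = values[:, :n_baseline].mean(axis=1, keepdims=True)
    base = np.where(base <= 0, 1.0, base)
    return values / base


def fit_pca(
    train: TimeCourseSet,
    k: int = 20,
    min_variance: float = 0.90,
    normalize: bool = True,
) -> PCAModel:
    """Fit the PCA compression on training-cohort voxels only.

    Uses ``k`` components, raised if necessary so the cumulative
    explained variance reaches ``min_variance``.
    """
    n, f = train.values.shape
    if k > f:
        raise ParameterError(f"k = {k} exceeds the number of frames ({f})")
    if n <= k:
        raise ParameterError("need more voxels than components to fit the PCA")
    x = baseline_normalize(train.values, train.n_baseline) if normalize else train.values
    full = PCA(n_components=min(f, n - 1), svd_solver="full").fit(x)
    cum = np.cumsum(full.explained_variance_ratio_)
    k_needed = int(np.searchsorted(cum, min_variance) + 1)
    k_use = min(max(k, k_needed), full.n_components_)
    subjects = frozenset(np.unique(train.subjects)) if train.subjects is not None else frozenset()
    return PCAModel(
        mean=full.mean_.copy(),
        components=full.components_[:k_use].copy(),
        explained_variance_ratio=full.explained_variance_ratio_[:k_use].copy(),
        k=k_use,
        normalized=normalize,
        n_baseline=train.n_baseline,
        frame_times=None if train.frame_times is None else train.frame_times.copy(),
        training_subjects=subjects,
    )


def transform_pca(model: PCAModel, tcs: TimeCourseSet) -> np.ndarray:
    """Project time-courses onto the fitted components (centered projection).

    Inputs acquired on a different time grid are linearly resampled
    onto the training grid first (both grids must then be known).
    """
    values = tcs.values
    if values.shape[1] != model.mean.size:
        if model.frame_times is None or tcs.frame_times is None:
            raise ShapeError(
                f"frame count {values.shape[1]} does not match the PCA model "
                f"({model.mean.size}) and no time grids are available for resampling"
            )
        values = np.stack([np.interp(model.frame_times, tcs.frame_times, row) for row in values])
    if model.normalized:
        values = baseline_normalize(values, model.n_baseline)
    return (values - model.mean) @ model.components.T


def dwt_features(tcs: TimeCourseSet, wavelet: str = "db4", level: int | None = None) -> np.ndarray:
    """Multilevel DWT coefficients per voxel (baseline feature set).

    Signals are zero-padded to the next multiple of 2**level so every
    decomposition level keeps an even length; the periodized transform
    is then non-redundant and, for an orthogonal wavelet, exactly
    energy-preserving (Parseval).
    """
    try:
        wav = pywt.Wavelet(wavelet)
    except ValueError as exc:
        raise ConfigurationError(f"unknown wavelet '{wavelet}'") from exc
    if tcs.n_frames < wav.dec_len:
        raise ParameterError("time-course shorter than the wavelet filter")
    if level is None:
        level = pywt.dwt_max_level(tcs.n_frames, wav.dec_len)
    block = 2**level
    padded_len = -(-tcs.n_frames // block) * block
    values = tcs.values
    if padded_len != tcs.n_frames:
        values = np.pad(values, ((0, 0), (0, padded_len - tcs.n_frames)))
    coeffs = pywt.wavedec(values, wav, mode="periodization", level=level, axis=1)
    return np.concatenate(coeffs, axis=1)


# ---------------------------------------------------------------------------
# class balance, classifiers
# ---------------------------------------------------------------------------

def balance_classes(features, labels, seed: int = 0):
    """Resample cortex and medulla to the pelvis count (all classes equal).

    Undersampling without replacement (oversampling with replacement if
    a class is smaller than the pelvis class); seeded and deterministic.
    """
    features = np.asarray(features)
    labels = np.asarray(labels)
    for cls in (1, 2, 3):
        if not (labels == cls).any():
            raise MissingClassError(f"class {cls} is absent from the training labels")
    rng = np.random.default_rng(seed)
    target = int((labels == 3).sum())
    keep = []
    for cls in (1, 2, 3):
        idx = np.flatnonzero(labels == cls)
        if len(idx) >= target:
            keep.append(rng.choice(idx, size=target, replace=False))
        else:
            keep.append(rng.choice(idx, size=target, replace=True))
    keep = np.concatenate(keep)
    rng.shuffle(keep)
    return features[keep], labels[keep]


def _build_estimator(config: ClassifierConfig):
    if config.algorithm == "svm_rbf":
        return SVC(kernel="rbf", gamma=config.svm_gamma, C=config.svm_c, random_state=config.seed)
    if config.algorithm == "logistic":
        # L2 penalty (sklearn default) with the stochastic-average-gradient solver
        return LogisticRegression(
            solver="sag", max_iter=config.logistic_max_iter, random_state=config.seed
        )
    from xgboost import XGBClassifier

    return XGBClassifier(
        n_estimators=config.xgb_n_trees,
        max_depth=config.xgb_max_depth,
        gamma=config.xgb_gamma,
        reg_lambda=config.xgb_lambda,
        objective="multi:softprob",
        random_state=config.seed,
        n_jobs=1,
    )


def train_classifier(
    features,
    labels,
    config: ClassifierConfig | None = None,
    training_subjects=(),
) -> VoxelClassifier:
    """Fit the configured compartment classifier on feature vectors."""
    config = config or ClassifierConfig()
    config.validate()
    features = np.asarray(features)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ParameterError("training data contain a single class; cannot fit a classifier")
    est = _build_estimator(config)
    y = labels - 1 if config.algorithm == "xgboost" else labels
    est.fit(features, y)
    return VoxelClassifier(
        estimator=est,
        algorithm=config.algorithm,
        training_subjects=frozenset(training_subjects),
        config=config,
    )


def grid_search_svm(features, labels, gammas, cs, folds: int = 5, seed: int = 0):
    """Exhaustive (gamma, C) grid search by mean balanced accuracy over CV folds.

    Ties are broken toward the simpler model: smaller C, then smaller
    gamma.  Returns ``(best_gamma, best_c, results)`` where results maps
    each pair to its mean score.
    """
    gammas, cs = list(gammas), list(cs)
    if not gammas or not cs:
        raise ParameterError("gamma and C grids must be non-empty")
    features = np.asarray(features)
    labels = np.asarray(labels)
    if len(labels) < folds:
        raise ParameterError("fewer samples than folds")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(features, labels))
    results = {}
    for c in sorted(cs):
        for gamma in sorted(gammas):
            scores = []
            for tr, te in splits:
                est = SVC(kernel="rbf", gamma=gamma, C=c)
                est.fit(features[tr], labels[tr])
                scores.append(balanced_accuracy_score(labels[te], est.predict(features[te])))
            results[(gamma, c)] = float(np.mean(scores))
    best_score = max(results.values())
    for c in sorted(cs):
        for gamma in sorted(gammas):
            if results[(gamma, c)] >= best_score - 1e-12:
                return gamma, c, results
    raise RuntimeError("unreachable")


def classify_voxels(
    classifier: VoxelClassifier,
    pca: PCAModel,
    series: DynamicSeries,
    mask: KidneyMask | np.ndarray,
) -> CompartmentLabelMap:
    """Label every in-mask voxel 1/2/3; out-of-mask voxels stay 0.

    The classifier and PCA model must originate from the same training
    cohort (checked via recorded provenance).
    """
    if classifier.training_subjects != pca.training_subjects:
        raise ProvenanceError(
            "classifier and PCA model were fitted on different training cohorts"
        )
    mask_data = mask.data if isinstance(mask, KidneyMask) else np.asarray(mask, dtype=bool)
    out = np.zeros(series.shape[:3], dtype=np.uint8)
    if not mask_data.any():
        return CompartmentLabelMap(out)
    tcs = extract_time_courses(series, mask_data)
    features = transform_pca(pca, tcs)
    out[mask_data] = classifier.predict(features).astype(np.uint8)
    return CompartmentLabelMap(out)


def kmeans_partition(features, k: int = 3, seed: int = 0, true_labels=None) -> KMeansResult:
    """Unsupervised k-means baseline on feature vectors.

    When ground-truth labels are supplied (evaluation only), clusters
    are mapped to classes by majority vote.
    """
    features = np.asarray(features)
    if len(features) < k:
        raise ParameterError("fewer samples than clusters")
    km = KMeans(n_clusters=k, random_state=seed, n_init=10).fit(features)
    result = KMeansResult(cluster_labels=km.labels_.copy(), inertia=float(km.inertia_))
    if true_labels is not None:
        true_labels = np.asarray(true_labels)
        mapping = {}
        for cluster in range(k):
            members = true_labels[km.labels_ == cluster]
            mapping[cluster] = int(np.bincount(members).argmax()) if len(members) else 0
        result.mapping = mapping
        result.mapped_labels = np.array([mapping[c] for c in km.labels_])
    return result
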