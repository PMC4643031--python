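"""Uniform probabilistic harness over five classifier backends.

All five backends — random forest (RF), support vector machine (SVM),
weighted k-nearest neighbours (WKNN), a single-hidden-layer neural network
(ANN) and Gaussian naive Bayes (NB) — are exposed through one interface:
``train_backend`` fits on a labelled feature table, ``predict_proba``
returns class-membership probabilities on the full legend simplex, aligned
to the class scheme order.  Distance/margin-based backends (SVM, WKNN, ANN)
are z-score standardized on the training data; tree and Bayes backends are
not.  SVM probabilities come from pairwise Platt-style sigmoid coupling;
RF probabilities are tree-vote fractions; WKNN uses triangular-kernel
neighbour weighting.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import cohen_kappa_score, make_scorer
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .types import ClassScheme, FeatureTable, ProbabilityCube, SampleSet

log = logging.getLogger(__name__)

__all__ = [
    "KINDS",
    "ClassifierModel",
    "stratified_split",
    "train_backend",
    "predict_proba",
    "tune_hyperparameters",
    "default_hyperparameters",
    "save_model",
    "load_model",
    "triangular_weights",
]

KINDS = ("rf", "svm", "wknn", "ann", "nb")
_SCALED_KINDS = frozenset({"svm", "wknn", "ann"})

_ARCHIVE_VERSION = 1


def triangular_weights(distances: np.ndarray) -> np.ndarray:
    """Triangular-kernel neighbour weights ``max(1 − d/d_max, ε)`` per query.

    Distances are normalized by each query's largest neighbour distance so
    the furthest neighbour gets near-zero weight; degenerate all-zero rows
    fall back to uniform weights.
    """
    d = np.asarray(distances, dtype=np.float64)
    dmax = d.max(axis=1, keepdims=True)
    dmax = np.where(dmax > 0, dmax, 1.0)
    w = 1.0 - d / (dmax * (1.0 + 1e-9))
    return np.maximum(w, 1e-12)


def default_hyperparameters(kind: str, n_features: int) -> dict[str, Any]:
    """Ecosystem-standard defaults used when tuning is skipped."""
    p = max(int(n_features), 1)
    if kind == "rf":
        return {"n_estimators": 500, "max_features": "sqrt"}
    if kind == "svm":
        return {"kernel": "rbf", "C": 10.0, "gamma": 1.0 / p}
    if kind == "wknn":
        return {"n_neighbors": 11, "p": 2}
    if kind == "ann":
        return {"hidden_layer_sizes": (max(2 * p // 3, 2),), "max_iter": 500}
    if kind == "nb":
        return {"var_smoothing": 1e-9}
    raise ValueError(f"unknown classifier kind {kind!r}; expected one of {KINDS}")


def stratified_split(
    samples: SampleSet,
    train_fraction: float = 0.7,
    seed: int = 0,
) -> SampleSet:
    """Tag each point as train/test, stratified per class.

    Per class, ``round(train_fraction·n)`` points (half-up, clamped so both
    splits stay non-empty) go to training and the rest to testing; the
    assignment is a seeded permutation, deterministic given the seed.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    codes = samples.codes
    split = np.empty(codes.size, dtype=object)
    rng = np.random.default_rng(seed)
    for code in np.unique(codes):
        idx = np.nonzero(codes == code)[0]
        n = idx.size
        if n < 2:
            raise ValueError(
                f"class code {code} has {n} sample(s); at least 2 are required"
            )
        n_train = int(np.floor(train_fraction * n + 0.5))
        n_train = min(max(n_train, 1), n - 1)
        perm = rng.permutation(idx)
        split[perm[:n_train]] = "train"
        split[perm[n_train:]] = "test"
    out = SampleSet(
        rows=samples.rows,
        cols=samples.cols,
        codes=samples.codes,
        split=split,
        features=samples.features,
        xs=samples.xs,
        ys=samples.ys,
    )
    return out


@dataclass
class ClassifierModel:
    """A fitted backend plus everything needed to apply it consistently."""

    kind: str
    estimator: Any
    feature_names: tuple[str, ...]
    classes: tuple[int, ...]
    hyperparams: dict[str, Any]
    scaler: StandardScaler | None = None
    impute_medians: np.ndarray | None = None
    seed: int = 0
    n_per_class: dict[int, int] = field(default_factory=dict)


def _build_estimator(kind: str, hp: Mapping[str, Any], seed: int):
    hp = dict(hp)
    if kind == "rf":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **hp)
    if kind == "svm":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FutureWarning)
            return SVC(probability=True, random_state=seed, **hp)
    if kind == "wknn":
        return KNeighborsClassifier(weights=triangular_weights, **hp)
    if kind == "ann":
        return MLPClassifier(random_state=seed, **hp)
    if kind == "nb":
        return GaussianNB(**hp)
    raise ValueError(f"unknown classifier kind {kind!r}; expected one of {KINDS}")


def _resolve_xy(
    samples: SampleSet | FeatureTable | np.ndarray,
    codes: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray | None, tuple[str, ...] | None]:
    if isinstance(samples, SampleSet):
        if samples.features is None:
            raise ValueError("sample set carries no features")
        return samples.features.values, samples.codes, samples.features.feature_names
    if isinstance(samples, FeatureTable):
        return samples.values, codes, samples.feature_names
    return np.asarray(samples, dtype=np.float64), codes, None


def train_backend(
    kind: str,
    train_samples: SampleSet | FeatureTable | np.ndarray,
    codes: np.ndarray | None = None,
    hyperparams: Mapping[str, Any] | None = None,
    seed: int = 0,
    scheme: ClassScheme | None = None,
) -> ClassifierModel:
    """Fit one backend and wrap it as a :class:`ClassifierModel`.

    ``train_samples`` may be a tagged :class:`SampleSet` (its "train" part
    is used if split tags are present), a :class:`FeatureTable` plus
    ``codes``, or a bare array plus ``codes``.
    """
    if isinstance(train_samples, SampleSet) and train_samples.split is not None:
        train_samples = train_samples.split_part("train")
    x, y, names = _resolve_xy(train_samples, codes)
    if y is None:
        raise ValueError("training labels are required")
    y = np.asarray(y)
    if x.shape[0] == 0:
        raise ValueError("training set is empty")
    if scheme is not None:
        missing = set(scheme.codes) - set(np.unique(y).tolist())
        if missing:
            raise ValueError(f"training set lacks classes with codes {sorted(missing)}")
    variances = x.var(axis=0)
    if np.any(variances == 0):
        warnings.warn(
            f"{int((variances == 0).sum())} feature(s) have zero variance in training"
        )
    hp = dict(default_hyperparameters(kind, x.shape[1]))
    if hyperparams:
        hp.update(hyperparams)
    if kind == "wknn":
        n_min = x.shape[0]
        if hp.get("n_neighbors", 11) > n_min:
            warnings.warn(
                f"wknn k={hp['n_neighbors']} exceeds {n_min} training points; truncated"
            )
            hp["n_neighbors"] = n_min
    medians = np.nanmedian(x, axis=0)
    x = _impute(x, medians)
    scaler = None
    if kind in _SCALED_KINDS:
        scaler = StandardScaler().fit(x)
        x = scaler.transform(x)
    est = _build_estimator(kind, hp, seed)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est.fit(x, y)
    except Exception as exc:  # pragma: no cover - backend-specific failures
        raise RuntimeError(f"backend {kind!r} failed to fit: {exc}") from exc
    uniq, counts = np.unique(y, return_counts=True)
    if names is None:
        names = tuple(f"f{i}" for i in range(x.shape[1]))
    return ClassifierModel(
        kind=kind,
        estimator=est,
        feature_names=tuple(names),
        classes=tuple(int(c) for c in est.classes_),
        hyperparams=hp,
        scaler=scaler,
        impute_medians=medians,
        seed=seed,
        n_per_class={int(c): int(n) for c, n in zip(uniq, counts)},
    )


def _impute(x: np.ndarray, medians: np.ndarray) -> np.ndarray:
    mask = ~np.isfinite(x)
    if mask.any():
        log.info("imputing %d missing feature values with training medians", mask.sum())
        x = x.copy()
        fill = np.where(np.isfinite(medians), medians, 0.0)
        x[mask] = np.take(fill, np.nonzero(mask)[1])
    return x


def _align_features(
    model: ClassifierModel, table: FeatureTable | np.ndarray
) -> np.ndarray:
    if isinstance(table, FeatureTable):
        have = set(table.feature_names)
        want = set(model.feature_names)
        if have != want:
            missing = sorted(want - have)
            extra = sorted(have - want)
            raise ValueError(
                f"feature names do not match training: missing {missing}, extra {extra}"
            )
        idx = [table.feature_names.index(n) for n in model.feature_names]
        x = table.values[:, idx]
    else:
        x = np.asarray(table, dtype=np.float64)
        if x.shape[1] != len(model.feature_names):
            raise ValueError(
                f"expected {len(model.feature_names)} features, got {x.shape[1]}"
            )
    x = _impute(x, model.impute_medians)
    if model.scaler is not None:
        x = model.scaler.transform(x)
    return x


def predict_proba(
    model: ClassifierModel,
    features: FeatureTable | np.ndarray,
    scheme: ClassScheme | None = None,
) -> np.ndarray:
    """Class-membership probabilities ``(n, M)`` in scheme (or model) order.

    Rows are simplex-valid.  If ``scheme`` is given, columns follow
    ``scheme.classes`` order and classes unseen in training get zero
    probability.
    """
    x = _align_features(model, features)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        probs = model.estimator.predict_proba(x)
    probs = np.asarray(probs, dtype=np.float64)
    probs = np.clip(probs, 0.0, None)
    sums = probs.sum(axis=1, keepdims=True)
    probs = np.where(sums > 0, probs / np.where(sums > 0, sums, 1.0), 1.0 / probs.shape[1])
    if scheme is None:
        return probs
    out = np.zeros((probs.shape[0], scheme.n_classes))
    for j, code in enumerate(model.classes):
        out[:, scheme.index_of(code)] = probs[:, j]
    return out


def predict_proba_cube(
    model: ClassifierModel,
    features: FeatureTable,
    grid_shape: tuple[int, int],
    scheme: ClassScheme,
    geotransform=None,
) -> ProbabilityCube:
    """Full-raster probabilities reshaped to ``(class, row, col)``."""
    probs = predict_proba(model, features, scheme=scheme)
    r, c = grid_shape
    if probs.shape[0] != r * c:
        raise ValueError("feature table does not cover the full grid")
    cube = ProbabilityCube(
        probs=probs.T.reshape(scheme.n_classes, r, c),
        scheme=scheme,
        source=model.kind,
    )
    if geotransform is not None:
        cube.geotransform = tuple(geotransform)
    return cube


def tune_hyperparameters(
    kind: str,
    train_samples: SampleSet | FeatureTable | np.ndarray,
    grid: Mapping[str, Sequence[Any]],
    codes: np.ndarray | None = None,
    folds: int = 5,
    seed: int = 0,
) -> dict[str, Any]:
    """Stratified cross-validated grid search maximizing Cohen's kappa."""
    if not grid:
        raise ValueError("hyperparameter grid must be non-empty")
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if isinstance(train_samples, SampleSet) and train_samples.split is not None:
        train_samples = train_samples.split_part("train")
    x, y, _ = _resolve_xy(train_samples, codes)
    y = np.asarray(y)
    smallest = np.bincount(np.unique(y, return_inverse=True)[1]).min()
    if folds > smallest:
        raise ValueError(
            f"folds={folds} exceeds the smallest class count ({smallest})"
        )
    x = _impute(x, np.nanmedian(x, axis=0))
    if kind in _SCALED_KINDS:
        x = StandardScaler().fit_transform(x)
    base = default_hyperparameters(kind, x.shape[1])
    base.update({k: v[0] for k, v in grid.items()})
    est = _build_estimator(kind, base, seed)
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    search = GridSearchCV(
        est,
        param_grid=dict(grid),
        scoring=make_scorer(cohen_kappa_score),
        cv=cv,
        n_jobs=1,
        refit=False,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        search.fit(x, y)
    best = dict(search.best_params_)
    log.info("tuned %s: %s (kappa=%.4f)", kind, best, search.best_score_)
    return best


def save_model(model: ClassifierModel, path) -> None:
    """Serialize a fitted model to a versioned joblib archive."""
    payload = {
        "format": "lulcfuse-classifier",
        "version": _ARCHIVE_VERSION,
        "kind": model.kind,
        "feature_names": list(model.feature_names),
        "classes": list(model.classes),
        "hyperparams": model.hyperparams,
        "seed": model.seed,
        "n_per_class": model.n_per_class,
        "estimator": model.estimator,
        "scaler": model.scaler,
        "impute_medians": model.impute_medians,
    }
    joblib.dump(payload, path)


def load_model(path) -> ClassifierModel:
    payload = joblib.load(path)
    if payload.get("format") != "lulcfuse-classifier":
        raise ValueError(f"{path}: not a classifier archive")
    if payload.get("version") != _ARCHIVE_VERSION:
        raise ValueError(f"{path}: unsupported archive version {payload.get('version')}")
    return ClassifierModel(
        kind=payload["kind"],
        estimator=payload["estimator"],
        feature_names=tuple(payload["feature_names"]),
        classes=tuple(payload["classes"]),
        hyperparams=payload["hyperparams"],
        scaler=payload["scaler"],
        impute_medians=payload["impute_medians"],
        seed=payload["seed"],
        n_per_class=payload["n_per_class"],
    )
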