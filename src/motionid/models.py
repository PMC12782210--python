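"""Per-user (one-vs-rest) authentication classifiers.

Three classical models on the 56-feature windows — k-nearest neighbors,
random forest, and a feed-forward neural network — are tuned by exhaustive
grid search with stratified threefold cross-validation on the training rows,
selecting the setting with the best positive-class F1 (ties broken by
first-in-grid order) and refitting on all training rows.  A fourth model, a
dual-stream temporal/frequency self-attention network, consumes the raw
6-channel window sequences directly.

Grids follow the study design: k in {5, 10, 100, 200}, random-forest maximum
depth in {10, 50, 100}, and the neural network's L2 strength alpha in
{1e-1 ... 1e-5} (topology fixed at one hidden layer of 100 rectified units;
the grid varies only the regularization strength).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier, NearestNeighbors
from sklearn.neural_network import MLPClassifier

from .metrics import compute_metrics
from .transformer import DualStreamClassifier

__all__ = [
    "CLASSICAL_KINDS",
    "HyperparameterGrid",
    "TransformerConfig",
    "FittedModel",
    "fit_classical",
    "fit_swipeformer",
    "predict",
]

CLASSICAL_KINDS = ("knn", "rf", "nn")


@dataclass(frozen=True)
class HyperparameterGrid:
    knn_k: tuple[int, ...] = (5, 10, 100, 200)
    rf_max_depth: tuple[int, ...] = (10, 50, 100)
    nn_l2_alpha: tuple[float, ...] = (1e-1, 1e-2, 1e-3, 1e-4, 1e-5)
    cv_folds: int = 3

    def __post_init__(self) -> None:
        if not (self.knn_k and self.rf_max_depth and self.nn_l2_alpha):
            raise ValueError("hyperparameter sets must be non-empty")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")

    def settings_for(self, kind: str) -> list[dict[str, Any]]:
        if kind == "knn":
            return [{"n_neighbors": int(k)} for k in self.knn_k]
        if kind == "rf":
            return [{"max_depth": int(d)} for d in self.rf_max_depth]
        if kind == "nn":
            return [{"alpha": float(a)} for a in self.nn_l2_alpha]
        raise ValueError(f"unknown classical model kind: {kind!r}")


@dataclass(frozen=True)
class TransformerConfig:
    sequence_length: int = 100
    channels: int = 6
    conv_kernel: int = 5
    attention_heads: int = 2
    encoder_layers: int = 1
    embedding_dim: int = 32
    mlp_hidden_sizes: tuple[int, ...] = (32,)
    # Defaults sized so one per-user model trains on ~1,000 windows in well
    # under a minute on a single CPU core.
    epochs: int = 15
    batch_size: int = 128
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "sequence_length",
            "channels",
            "conv_kernel",
            "attention_heads",
            "encoder_layers",
            "embedding_dim",
            "batch_size",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.conv_kernel % 2 == 0:
            raise ValueError("conv_kernel must be odd")
        if self.embedding_dim % self.attention_heads != 0:
            raise ValueError("embedding_dim must be divisible by attention_heads")
        if self.epochs < 0 or self.learning_rate <= 0:
            raise ValueError("epochs must be >= 0 and learning_rate positive")


@dataclass
class FittedModel:
    """A trained per-user model with full provenance."""

    model_kind: str  # knn | rf | nn | swipeformer
    target_user_id: str | None
    estimator: Any  # sklearn estimator or DualStreamClassifier
    chosen_hyperparameters: dict[str, Any]
    cv_results: list[dict[str, Any]] = field(default_factory=list)
    seed: int = 0
    train_window_ids: tuple[str, ...] = ()
    n_train: int = 0


def _make_estimator(kind: str, setting: dict[str, Any], seed: int):
    if kind == "knn":
        return KNeighborsClassifier(algorithm="brute", **setting)
    if kind == "rf":
        return RandomForestClassifier(n_estimators=100, random_state=seed, **setting)
    if kind == "nn":
        return MLPClassifier(
            hidden_layer_sizes=(100,),
            activation="relu",
            solver="adam",
            max_iter=300,
            random_state=seed,
            **setting,
        )
    raise ValueError(f"unknown classical model kind: {kind!r}")


def _f1_of_decisions(y_true: np.ndarray, decisions: np.ndarray) -> float:
    return compute_metrics(y_true, decisions).f1


def _knn_cv_scores(
    X: np.ndarray,
    y: np.ndarray,
    ks: list[int],
    splits: list[tuple[np.ndarray, np.ndarray]],
) -> list[float]:
    """Mean CV F1 per k, sharing one neighbor query per fold across all k.

    Equivalent to fitting a k-NN per (fold, k): the k nearest training-fold
    neighbors of each validation row are the first k columns of the sorted
    neighbor list for the largest k.  Scores match an exhaustive per-setting
    grid search; ties in the neighbor vote (score exactly 0.5) are positive,
    consistent with :func:`predict`.
    """
    kmax = max(ks)
    fold_scores = np.zeros((len(splits), len(ks)))
    for f, (tr, va) in enumerate(splits):
        nn = NearestNeighbors(n_neighbors=min(kmax, len(tr)), algorithm="brute")
        nn.fit(X[tr])
        _, ind = nn.kneighbors(X[va])
        labels = y[tr][ind]  # (n_val, kmax)
        for j, k in enumerate(ks):
            score = labels[:, :k].mean(axis=1)
            fold_scores[f, j] = _f1_of_decisions(y[va], score >= 0.5)
    return fold_scores.mean(axis=0).tolist()


def fit_classical(
    kind: str,
    X: np.ndarray,
    y: np.ndarray,
    grid: HyperparameterGrid | None = None,
    seed: int = 0,
    target_user_id: str | None = None,
    train_window_ids: tuple[str, ...] = (),
) -> FittedModel:
    """Grid-search, cross-validate and refit one classical per-user model.

    ``X`` is the (windows x 56) normalized feature matrix and ``y`` the binary
    target-user labels.  k values too large for the smallest cross-validation
    training fold are skipped with a warning; it is an error if every k is
    skipped or if ``y`` contains a single class (authentication is undefined
    without both classes).
    """
    grid = grid or HyperparameterGrid()
    if kind not in CLASSICAL_KINDS:
        raise ValueError(f"unknown classical model kind: {kind!r}")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X must be 2-D with one label per row")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("training labels contain a single class")
    if len(X) < grid.cv_folds:
        raise ValueError("fewer training rows than CV folds")

    skf = StratifiedKFold(n_splits=grid.cv_folds, shuffle=False)
    splits = [(tr, va) for tr, va in skf.split(X, y)]
    settings = grid.settings_for(kind)

    if kind == "knn":
        min_fold = min(len(tr) for tr, _ in splits)
        usable = [s for s in settings if s["n_neighbors"] <= min_fold]
        skipped = [s["n_neighbors"] for s in settings if s not in usable]
        if skipped:
            warnings.warn(
                f"skipping k={skipped}: not enough training rows "
                f"(smallest CV fold has {min_fold})",
                stacklevel=2,
            )
        if not usable:
            raise ValueError("every k in the grid exceeds the training-set size")
        ks = [s["n_neighbors"] for s in usable]
        mean_scores = _knn_cv_scores(X, y, ks, splits)
        settings = usable
    else:
        mean_scores = []
        for setting in settings:
            scores = []
            for tr, va in splits:
                est = _make_estimator(kind, setting, seed)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")  # MLP convergence chatter
                    est.fit(X[tr], y[tr])
                scores.append(_f1_of_decisions(y[va], est.predict(X[va]) == 1))
            mean_scores.append(float(np.mean(scores)))

    best_idx = int(np.argmax(mean_scores))  # first-in-grid wins ties
    best = settings[best_idx]
    final = _make_estimator(kind, best, seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        final.fit(X, y)
    return FittedModel(
        model_kind=kind,
        target_user_id=target_user_id,
        estimator=final,
        chosen_hyperparameters=dict(best),
        cv_results=[
            {"setting": dict(s), "mean_cv_f1": float(m)}
            for s, m in zip(settings, mean_scores)
        ],
        seed=seed,
        train_window_ids=tuple(train_window_ids),
        n_train=len(X),
    )


def fit_swipeformer(
    sequences: np.ndarray,
    y: np.ndarray,
    config: TransformerConfig | None = None,
    target_user_id: str | None = None,
    train_window_ids: tuple[str, ...] = (),
) -> FittedModel:
    """Train the dual-stream attention network on raw window sequences."""
    config = config or TransformerConfig()
    y = np.asarray(y).astype(int)
    sequences = np.asarray(sequences, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    clf = DualStreamClassifier(config).fit(sequences, y)
    return FittedModel(
        model_kind="swipeformer",
        target_user_id=target_user_id,
        estimator=clf,
        chosen_hyperparameters={"config": config},
        seed=config.seed,
        train_window_ids=tuple(train_window_ids),
        n_train=len(y),
    )


def predict(model: FittedModel, inputs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-window scores in [0, 1] and binary decisions (score >= 0.5).

    Classical models score with their positive-class probability estimate;
    the transformer with its sigmoid output.  Inputs must be shaped exactly
    as at fit time (56 features for classical models, raw sequences for the
    transformer) and already normalized with the model's stored parameters.
    """
    inputs = np.asarray(inputs, dtype=float)
    if model.model_kind == "swipeformer":
        scores = model.estimator.predict_scores(inputs)
    elif model.model_kind in CLASSICAL_KINDS:
        if inputs.ndim != 2 or inputs.shape[1] != model.estimator.n_features_in_:
            raise ValueError(
                f"expected (n, {model.estimator.n_features_in_}) features, "
                f"got {inputs.shape}"
            )
        proba = model.estimator.predict_proba(inputs)
        pos_col = int(np.flatnonzero(model.estimator.classes_ == 1)[0])
        scores = proba[:, pos_col]
    else:
        raise ValueError(f"unknown model kind: {model.model_kind!r}")
    decisions = scores >= 0.5  # documented tie rule: exactly 0.5 is positive
    return decisions, scores
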