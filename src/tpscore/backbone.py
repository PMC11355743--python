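"""Mortality-prediction backbones and their evaluation.

Two families share one prediction contract:

* temporal kinds (``rnn``, ``gru``, ``lstm``) consume the full N x T x F
  binary tensor through a recurrent network (:mod:`tpscore.nn`);
* non-temporal kinds (``logistic``, ``decision_tree``, ``random_forest``,
  ``gradient_boosting``) consume the time-collapsed N x F union matrix
  through scikit-learn estimators.

Model comparison uses repeated stratified 80/20 splits scored by AUROC.
The backbone used for pattern scoring is trained once on the full dataset
with an internal validation split for early stopping.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedShuffleSplit, train_test_split
from sklearn.tree import DecisionTreeClassifier

from .datatypes import EventTensor, OutcomeVector
from .ehr import collapse_time
from .nn import Adam, RecurrentNet, bce

TEMPORAL_KINDS = ("rnn", "gru", "lstm")
NONTEMPORAL_KINDS = ("logistic", "decision_tree", "random_forest", "gradient_boosting")


def layout_hash(feature_ids: list[str]) -> str:
    """Stable fingerprint of the feature axis a model was trained on."""
    return hashlib.sha256("\n".join(feature_ids).encode()).hexdigest()[:16]


@dataclass
class TrainConfig:
    kind: str = "gru"
    hidden: int = 32
    max_epochs: int = 300
    patience: int = 10
    val_fraction: float = 0.2
    learning_rate: float = 1e-3
    weight_decay: float = 1e-3
    batch_size: int = 64
    seed: int = 0
    n_estimators: int = 200  # tree ensembles

    def __post_init__(self) -> None:
        if self.kind not in TEMPORAL_KINDS + NONTEMPORAL_KINDS:
            raise ValueError(f"unknown model kind {self.kind!r}")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if not 0.0 < self.val_fraction < 1.0:
            raise ValueError("val_fraction must be in (0, 1)")


class PredictorModel:
    """A fitted backbone: maps an EventTensor to per-case death probabilities."""

    def __init__(self, kind: str, impl, feature_ids: list[str]):
        self.kind = kind
        self.impl = impl
        self.feature_ids = list(feature_ids)
        self.layout = layout_hash(self.feature_ids)

    @property
    def is_temporal(self) -> bool:
        return self.kind in TEMPORAL_KINDS

    def predict_proba(self, X: EventTensor | np.ndarray) -> np.ndarray:
        """Per-case probability of mortality, in input case order."""
        if isinstance(X, EventTensor):
            if X.feature_ids != self.feature_ids:
                raise ValueError("feature axis does not match the training layout")
            arr = X.data
        else:
            arr = np.asarray(X)
        if self.is_temporal:
            if arr.ndim != 3 or arr.shape[2] != len(self.feature_ids):
                raise ValueError(
                    f"feature axis mismatch: expected (N, T, {len(self.feature_ids)}) "
                    f"input, got {arr.shape}"
                )
            return self.impl.predict_proba(arr.astype(float))
        if arr.ndim == 3:
            arr = arr.max(axis=1)
        if arr.shape[1] != len(self.feature_ids):
            raise ValueError(
                f"expected {len(self.feature_ids)} features, got {arr.shape[1]}"
            )
        return self.impl.predict_proba(arr.astype(float))[:, 1]


class FixtureModel(PredictorModel):
    """A closed-form predictor built from an arbitrary function of the tensor.

    Used for oracle tests: ``fn`` maps a float (N, T, F) array to per-case
    probabilities, so every pattern score has a hand-computable value.
    """

    def __init__(self, fn, feature_ids: list[str], temporal: bool = True):
        super().__init__("other", None, feature_ids)
        self._fn = fn
        self._temporal = temporal

    @property
    def is_temporal(self) -> bool:
        return self._temporal

    def predict_proba(self, X: EventTensor | np.ndarray) -> np.ndarray:
        arr = X.data if isinstance(X, EventTensor) else np.asarray(X)
        out = np.asarray(self._fn(arr.astype(float)), dtype=float)
        if out.ndim != 1 or out.shape[0] != arr.shape[0]:
            raise ValueError("fixture function must return one probability per case")
        return out


def _make_sklearn(kind: str, config: TrainConfig):
    if kind == "logistic":
        return LogisticRegression(max_iter=2000, random_state=config.seed)
    if kind == "decision_tree":
        return DecisionTreeClassifier(random_state=config.seed)
    if kind == "random_forest":
        return RandomForestClassifier(
            n_estimators=config.n_estimators, random_state=config.seed, n_jobs=1
        )
    if kind == "gradient_boosting":
        return GradientBoostingClassifier(random_state=config.seed)
    raise ValueError(kind)


def train_model(X: EventTensor, Y: OutcomeVector, config: TrainConfig) -> PredictorModel:
    """Fit one backbone of the configured kind on (X, Y)."""
    y = Y.labels.astype(float)
    if len(Y) != X.n_cases:
        raise ValueError("X and Y disagree on the number of cases")
    if y.min() == y.max():
        raise ValueError("training outcomes contain a single class")

    if config.kind in NONTEMPORAL_KINDS:
        est = _make_sklearn(config.kind, config)
        est.fit(collapse_time(X).astype(float), Y.labels)
        return PredictorModel(config.kind, est, X.feature_ids)

    net = RecurrentNet(config.kind, X.n_features, config.hidden, seed=config.seed)
    data = X.data.astype(float)
    idx_train, idx_val = train_test_split(
        np.arange(X.n_cases),
        test_size=config.val_fraction,
        stratify=Y.labels,
        random_state=config.seed,
    )
    Xtr, ytr = data[idx_train], y[idx_train]
    Xval, yval = data[idx_val], y[idx_val]

    opt = Adam(net.params, lr=config.learning_rate, weight_decay=config.weight_decay)
    rng = np.random.default_rng(config.seed)
    best_val = np.inf
    best_weights = net.get_weights()
    stall = 0
    for _ in range(config.max_epochs):
        order = rng.permutation(len(Xtr))
        for start in range(0, len(order), config.batch_size):
            sel = order[start : start + config.batch_size]
            probs, cache = net.forward(Xtr[sel], return_cache=True)
            grads = net.backward(probs, cache, ytr[sel])
            opt.step(net.params, grads)
        val_loss = bce(net.forward(Xval), yval)
        if not np.isfinite(val_loss):
            raise FloatingPointError(
                f"non-finite validation loss ({val_loss}) for kind={config.kind}, "
                f"lr={config.learning_rate}"
            )
        if val_loss < best_val - 1e-6:
            best_val = val_loss
            best_weights = net.get_weights()
            stall = 0
        else:
            stall += 1
            if stall >= config.patience:
                break
    net.set_weights(best_weights)
    return PredictorModel(config.kind, net, X.feature_ids)


def predict_proba(model: PredictorModel, X: EventTensor | np.ndarray) -> np.ndarray:
    """Functional alias for :meth:`PredictorModel.predict_proba`."""
    return model.predict_proba(X)


@dataclass
class CVResult:
    kind: str
    fold_auroc: list[float] = field(default_factory=list)

    @property
    def mean_auroc(self) -> float:
        return float(np.mean(self.fold_auroc))


def subset_cases(X: EventTensor, idx: np.ndarray) -> EventTensor:
    return EventTensor(
        X.data[idx],
        [X.case_ids[i] for i in idx],
        list(X.day_labels),
        list(X.feature_ids),
        list(X.feature_category),
    )


def crossval_auroc(
    X: EventTensor,
    Y: OutcomeVector,
    kinds: list[str],
    folds: int = 10,
    test_fraction: float = 0.2,
    seed: int = 0,
    config: TrainConfig | None = None,
) -> list[CVResult]:
    """Repeated stratified train/test splits, mean AUROC per model kind.

    Stratified splitting guarantees both classes in every test fold.
    """
    splitter = StratifiedShuffleSplit(
        n_splits=folds, test_size=test_fraction, random_state=seed
    )
    results = []
    base = config or TrainConfig()
    for kind in kinds:
        res = CVResult(kind=kind)
        for k, (tr, te) in enumerate(splitter.split(np.zeros(X.n_cases), Y.labels)):
            cfg = TrainConfig(
                kind=kind,
                hidden=base.hidden,
                max_epochs=base.max_epochs,
                patience=base.patience,
                val_fraction=base.val_fraction,
                learning_rate=base.learning_rate,
                weight_decay=base.weight_decay,
                batch_size=base.batch_size,
                seed=base.seed + k,
                n_estimators=base.n_estimators,
            )
            model = train_model(subset_cases(X, tr), OutcomeVector(Y.labels[tr]), cfg)
            probs = model.predict_proba(subset_cases(X, te))
            res.fold_auroc.append(float(roc_auc_score(Y.labels[te], probs)))
        results.append(res)
    return results


# ------------------------------------------------------------- checkpoints


def save_model(path: str | Path, model: PredictorModel, config: TrainConfig) -> None:
    """Write a recurrent model checkpoint: JSON manifest + JSON weights."""
    if not model.is_temporal:
        raise ValueError("checkpointing is provided for recurrent backbones only")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    net: RecurrentNet = model.impl
    manifest = {
        "kind": model.kind,
        "hidden": net.hidden,
        "n_features": net.n_features,
        "feature_ids": model.feature_ids,
        "layout_hash": model.layout,
        "train_config": {
            "max_epochs": config.max_epochs,
            "patience": config.patience,
            "learning_rate": config.learning_rate,
            "seed": config.seed,
        },
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=1))
    weights = {k: v.tolist() for k, v in net.params.items()}
    (path / "weights.json").write_text(json.dumps(weights))


def load_model(path: str | Path) -> PredictorModel:
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    net = RecurrentNet(manifest["kind"], manifest["n_features"], manifest["hidden"])
    net.set_weights(json.loads((path / "weights.json").read_text()))
    model = PredictorModel(manifest["kind"], net, manifest["feature_ids"])
    if model.layout != manifest["layout_hash"]:
        raise ValueError("checkpoint layout hash mismatch")
    return model
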