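"""Core containers for the binary patient-day-event dataset.

The explanatory dataset is a binary tensor ``X`` of shape (N cases, T days,
F event variables): ``X[i, t, f] = 1`` means medical event ``f`` occurred
(or a lab result was abnormal) for case ``i`` on day ``D-(T-t)``, the
``T-t``-th day before that case's discharge-or-death reference date ``D0``.
The outcome vector ``Y`` holds 1 for death at discharge, 0 for recovery.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

CATEGORIES = ("lab", "procedure", "prescription")


def day_labels_for(n_days: int) -> list[str]:
    """Day axis labels D-T ... D-1, oldest first."""
    return [f"D-{k}" for k in range(n_days, 0, -1)]


@dataclass
class EventTensor:
    """Binary N x T x F event tensor with axis labels and feature provenance.

    Attributes
    ----------
    data : np.ndarray of uint8, shape (N, T, F), entries in {0, 1}
    case_ids : case identifiers, length N
    day_labels : day axis labels ordered oldest -> newest, length T
    feature_ids : unique event-variable identifiers, length F
    feature_category : source table of each feature, length F
    """

    data: np.ndarray
    case_ids: list[str]
    day_labels: list[str]
    feature_ids: list[str]
    feature_category: list[str]

    def __post_init__(self) -> None:
        self.data = np.ascontiguousarray(self.data, dtype=np.uint8)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D tensor, got shape {self.data.shape}")
        n, t, f = self.data.shape
        if len(self.case_ids) != n:
            raise ValueError(f"{len(self.case_ids)} case_ids for N={n}")
        if len(self.day_labels) != t:
            raise ValueError(f"{len(self.day_labels)} day_labels for T={t}")
        if len(self.feature_ids) != f:
            raise ValueError(f"{len(self.feature_ids)} feature_ids for F={f}")
        if len(self.feature_category) != f:
            raise ValueError("feature_category length must equal F")
        if len(set(self.feature_ids)) != f:
            raise ValueError("feature_ids must be unique")
        bad = set(self.feature_category) - set(CATEGORIES)
        if bad:
            raise ValueError(f"unknown feature categories: {sorted(bad)}")
        if self.data.size and self.data.max() > 1:
            raise ValueError("tensor entries must be 0 or 1")

    @property
    def n_cases(self) -> int:
        return self.data.shape[0]

    @property
    def n_days(self) -> int:
        return self.data.shape[1]

    @property
    def n_features(self) -> int:
        return self.data.shape[2]

    def feature_index(self, feature_id: str) -> int:
        try:
            return self.feature_ids.index(feature_id)
        except ValueError:
            raise KeyError(f"unknown feature_id {feature_id!r}") from None

    def copy(self) -> "EventTensor":
        return EventTensor(
            self.data.copy(),
            list(self.case_ids),
            list(self.day_labels),
            list(self.feature_ids),
            list(self.feature_category),
        )


@dataclass
class OutcomeVector:
    """Binary outcome per case: 1 = death at discharge, 0 = recovery."""

    labels: np.ndarray
    case_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8).ravel()
        if self.labels.size and not np.isin(self.labels, (0, 1)).all():
            raise ValueError("outcome labels must be 0 or 1")
        if self.case_ids and len(self.case_ids) != self.labels.size:
            raise ValueError("case_ids length must match labels")

    def __len__(self) -> int:
        return int(self.labels.size)


def save_dataset(path: str | Path, X: EventTensor, Y: OutcomeVector | None = None) -> None:
    """Serialize a dataset to a directory of plain-text files.

    Layout: ``meta.json`` (axis labels, shape, outcomes) plus ``events.csv``
    listing the coordinates of every nonzero cell. Round-trips bit-exactly.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "shape": list(X.data.shape),
        "case_ids": list(map(str, X.case_ids)),
        "day_labels": list(X.day_labels),
        "feature_ids": list(X.feature_ids),
        "feature_category": list(X.feature_category),
    }
    if Y is not None:
        if len(Y) != X.n_cases:
            raise ValueError("outcome length does not match tensor N")
        meta["outcomes"] = [int(v) for v in Y.labels]
    (path / "meta.json").write_text(json.dumps(meta, indent=1))
    i, t, f = np.nonzero(X.data)
    pd.DataFrame({"case": i, "day": t, "feature": f}).to_csv(path / "events.csv", index=False)


def load_dataset(path: str | Path) -> tuple[EventTensor, OutcomeVector | None]:
    """Inverse of :func:`save_dataset`."""
    path = Path(path)
    meta = json.loads((path / "meta.json").read_text())
    data = np.zeros(tuple(meta["shape"]), dtype=np.uint8)
    coo = pd.read_csv(path / "events.csv")
    if len(coo):
        data[coo["case"].to_numpy(), coo["day"].to_numpy(), coo["feature"].to_numpy()] = 1
    X = EventTensor(
        data,
        meta["case_ids"],
        meta["day_labels"],
        meta["feature_ids"],
        meta["feature_category"],
    )
    Y = None
    if "outcomes" in meta:
        Y = OutcomeVector(np.array(meta["outcomes"]), list(meta["case_ids"]))
    return X, Y
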