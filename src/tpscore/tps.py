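"""Time-series pattern scores (TPS) via counterfactual occurrence simulation.

Given a trained mortality predictor M and the binary event tensor X, the
effect of a variable f over a set of days D is measured by counterfactual
simulation: set x[:, D, f] to all-1 ("occurred") or all-0 ("did not
occur"), re-predict, and take the difference of mean predicted mortality,

    delta(D) = mean M(X[:, D, f] <- 1) - mean M(X[:, D, f] <- 0).

Each score is weighted by the Bernoulli entropy H(f) of the feature's
pooled occurrence rate (raised to a configurable exponent w), so variables
that almost never or almost always occur are down-weighted.

Six queryable trend patterns:

* ``monotonic_mortality`` / ``monotonic_recovery``:
  TPS(f) = delta(all days) * H^w — large positive for mortality markers,
  negative for recovery markers (one score, two ranking directions).
* ``none_to_mortality`` / ``none_to_recovery``:
  PS(f) = exp(-c * |delta(far)|) * (+/- delta(near)) * H^w — the
  exponential gate suppresses variables with a far-period effect. The
  sharpness c defaults to 10: deltas are differences of mean predicted
  probabilities, so c = 10 puts the gate's e-folding at a far-period
  effect of 0.1 while leaving it ~1 within the O(n^-1/2) estimation
  noise of the means. Orders of magnitude beyond that (c ~ 10^4) the
  gate underflows double precision for |delta(far)| > 0.075 and
  essentially every score collapses to an exact-zero tie, which reduces
  the ranking to tie-breaks; c is configurable for sensitivity studies.
* ``recovery_to_mortality`` / ``mortality_to_recovery``:
  PS(f) = relu(-/+ delta(far)) * relu(+/- delta(near)) * H^w — nonzero
  only when the effect sign actually flips between periods.

Subperiod simulation modifies only the stated subperiod's cells and leaves
the complementary period at its observed values; the predictor then sees
the full, partially modified sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .backbone import PredictorModel
from .cohort import PATTERNS, far_near_split
from .datatypes import EventTensor

MONOTONIC_PATTERNS = ("monotonic_mortality", "monotonic_recovery")
FLUCTUATING_PATTERNS = (
    "none_to_mortality",
    "none_to_recovery",
    "recovery_to_mortality",
    "mortality_to_recovery",
)

#: patterns whose markers live at the top of the descending-score ranking
_DESCENDING = {
    "monotonic_mortality": True,
    "monotonic_recovery": False,  # recovery markers are the most negative scores
    "none_to_mortality": True,
    "none_to_recovery": True,
    "recovery_to_mortality": True,
    "mortality_to_recovery": True,
}


@dataclass
class PatternSpec:
    """One queried trend pattern plus the knobs of the scoring formulas.

    Parameters
    ----------
    pattern : one of the six trend patterns
    far_days, near_days : day-index sets partitioning the window; default
        first/second half of T=10 (D-10..D-6 vs D-5..D-1)
    sharpness : the constant c of the exponential no-far-effect gate
        (see the module docstring for the choice of default)
    entropy_weight : exponent w on the Bernoulli entropy factor
    """

    pattern: str
    far_days: np.ndarray | None = None
    near_days: np.ndarray | None = None
    sharpness: float = 10.0
    entropy_weight: float = 1.0

    def __post_init__(self) -> None:
        if self.pattern not in PATTERNS:
            raise ValueError(f"unknown pattern {self.pattern!r}")
        if self.sharpness <= 0:
            raise ValueError("sharpness must be positive")
        if self.entropy_weight < 0:
            raise ValueError("entropy_weight must be nonnegative")

    def resolve_days(self, n_days: int) -> tuple[np.ndarray, np.ndarray]:
        far, near = self.far_days, self.near_days
        if far is None or near is None:
            far, near = far_near_split(n_days)
        far = np.asarray(far, dtype=int)
        near = np.asarray(near, dtype=int)
        both = np.concatenate([far, near])
        if sorted(both.tolist()) != list(range(n_days)):
            raise ValueError("far_days and near_days must partition the day axis")
        return far, near


def simulate_assign(
    X: EventTensor, feature: int | str, value: int, days: np.ndarray | None = None
) -> EventTensor:
    """Copy of X with x[:, days, f] set to ``value``; X itself is untouched."""
    j = X.feature_index(feature) if isinstance(feature, str) else int(feature)
    if not 0 <= j < X.n_features:
        raise IndexError(f"feature index {j} out of range")
    if value not in (0, 1):
        raise ValueError("value must be 0 or 1")
    if days is None:
        days = np.arange(X.n_days)
    days = np.asarray(days, dtype=int)
    if days.size and (days.min() < 0 or days.max() >= X.n_days):
        raise IndexError("day index out of range")
    out = X.copy()
    out.data[:, days, j] = value
    return out


def bernoulli_entropy(X: EventTensor, feature: int | str) -> float:
    """Shannon entropy (base 2) of the feature's pooled occurrence rate.

    p is the mean of x[:, :, f] over all cases and days; H = -p log2 p -
    (1-p) log2 (1-p), with 0 log 0 := 0. Zero for constant columns.
    """
    j = X.feature_index(feature) if isinstance(feature, str) else int(feature)
    p = float(X.data[:, :, j].mean())
    if p <= 0.0 or p >= 1.0:
        return 0.0
    return float(-p * np.log2(p) - (1.0 - p) * np.log2(1.0 - p))


def _delta(model: PredictorModel, X: EventTensor, j: int, days: np.ndarray) -> float:
    """Mean-prediction difference between occurrence and non-occurrence."""
    up = model.predict_proba(simulate_assign(X, j, 1, days))
    down = model.predict_proba(simulate_assign(X, j, 0, days))
    return float(up.mean() - down.mean())


def tps_monotonic(
    model: PredictorModel, X: EventTensor, feature: int | str, spec: PatternSpec | None = None
) -> float:
    """Monotonic trend pattern score: delta(all days) * entropy^w."""
    spec = spec or PatternSpec("monotonic_mortality")
    if spec.pattern not in MONOTONIC_PATTERNS:
        raise ValueError(f"{spec.pattern!r} is a fluctuating pattern; use tps_fluctuating")
    j = X.feature_index(feature) if isinstance(feature, str) else int(feature)
    H = bernoulli_entropy(X, j)
    if H == 0.0:
        return 0.0
    return _delta(model, X, j, np.arange(X.n_days)) * H**spec.entropy_weight


def tps_fluctuating(
    model: PredictorModel, X: EventTensor, feature: int | str, spec: PatternSpec
) -> float:
    """Fluctuating trend pattern score for the four trend-change patterns."""
    if spec.pattern in MONOTONIC_PATTERNS:
        raise ValueError(f"{spec.pattern!r} is monotonic; use tps_monotonic")
    j = X.feature_index(feature) if isinstance(feature, str) else int(feature)
    H = bernoulli_entropy(X, j)
    if H == 0.0:
        return 0.0
    far, near = spec.resolve_days(X.n_days)
    d_far = _delta(model, X, j, far)
    d_near = _delta(model, X, j, near)
    relu = lambda z: max(0.0, z)  # noqa: E731
    if spec.pattern == "none_to_mortality":
        core = np.exp(-spec.sharpness * abs(d_far)) * d_near
    elif spec.pattern == "none_to_recovery":
        core = np.exp(-spec.sharpness * abs(d_far)) * (-d_near)
    elif spec.pattern == "recovery_to_mortality":
        core = relu(-d_far) * relu(d_near)
    else:  # mortality_to_recovery
        core = relu(d_far) * relu(-d_near)
    return float(core * H**spec.entropy_weight)


@dataclass
class ScoreTable:
    """Per-feature scores and ranks for one pattern query."""

    table: pd.DataFrame  # columns: feature_id, pattern, score, rank
    pattern: str
    backbone_kind: str
    metadata: dict = field(default_factory=dict)

    def rank_of(self, feature_id: str) -> int:
        row = self.table.loc[self.table["feature_id"] == feature_id, "rank"]
        if row.empty:
            raise KeyError(feature_id)
        return int(row.iloc[0])

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def score_all(model: PredictorModel, X: EventTensor, spec: PatternSpec) -> ScoreTable:
    """Score every feature under ``spec`` and attach ranks.

    Rank 1 is the strongest marker for the queried pattern: descending
    score order, except ``monotonic_recovery`` whose markers are the most
    negative monotonic scores (ascending order). Ties break by feature_id.
    """
    scorer = tps_monotonic if spec.pattern in MONOTONIC_PATTERNS else tps_fluctuating
    scores = []
    for j, fid in enumerate(X.feature_ids):
        try:
            scores.append(scorer(model, X, j, spec))
        except Exception as exc:  # pragma: no cover - context for debugging
            raise RuntimeError(f"scoring failed for feature {fid!r}") from exc
    df = pd.DataFrame({"feature_id": X.feature_ids, "pattern": spec.pattern, "score": scores})
    ascending = not _DESCENDING[spec.pattern]
    df = df.sort_values(
        ["score", "feature_id"], ascending=[ascending, True], kind="mergesort"
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return ScoreTable(df, spec.pattern, model.kind, {"entropy_weight": spec.entropy_weight})


def rank_markers(table: ScoreTable, k: int = 10) -> list[str]:
    """Top-k feature ids of a score table (rank order, documented tie-break)."""
    if k > len(table.table):
        raise ValueError(f"k={k} exceeds the number of features {len(table.table)}")
    return table.table.nsmallest(k, "rank")["feature_id"].tolist()
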