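"""Synthetic binary cohorts with planted temporal-pattern markers.

The generator emulates the structure of the pneumonia study data: N cases
observed over T=10 pre-discharge days and F binary event variables, with a
~61% mortality fraction. Background (non-marker) features occur with an
outcome-independent Bernoulli rate, so any importance assigned to them
downstream is estimation noise — they define the null. Marker features
occur with group-specific (mortality vs recovery) and period-specific
(far = first ceil(T/2) days, near = remainder) rates, which is exactly the
structure the six trend patterns are designed to detect:

* ``monotonic_mortality`` / ``monotonic_recovery`` — one group's rate is
  higher across the whole window;
* ``none_to_mortality`` / ``none_to_recovery`` — group rates equal in the
  far period, separated in the near period;
* ``recovery_to_mortality`` / ``mortality_to_recovery`` — the higher-rate
  group switches between the two periods.

Draw order is fixed (outcomes first, then features in index order) so a
seed pins the whole cohort bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import EventTensor, OutcomeVector, day_labels_for

PATTERNS = (
    "monotonic_mortality",
    "monotonic_recovery",
    "none_to_mortality",
    "none_to_recovery",
    "recovery_to_mortality",
    "mortality_to_recovery",
)


@dataclass
class MarkerSpec:
    """A planted marker: which feature, which pattern, which Bernoulli rates.

    ``rate_<group>_<period>`` is the per-day occurrence probability for cases
    in that outcome group during that half of the window.
    """

    feature_index: int
    pattern: str
    rate_mortality_far: float
    rate_mortality_near: float
    rate_recovery_far: float
    rate_recovery_near: float

    def __post_init__(self) -> None:
        if self.pattern not in PATTERNS:
            raise ValueError(f"unknown pattern {self.pattern!r}")
        for name in ("rate_mortality_far", "rate_mortality_near",
                     "rate_recovery_far", "rate_recovery_near"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        dfar = self.rate_mortality_far - self.rate_recovery_far
        dnear = self.rate_mortality_near - self.rate_recovery_near
        consistent = {
            "monotonic_mortality": dfar > 0 and dnear > 0,
            "monotonic_recovery": dfar < 0 and dnear < 0,
            "none_to_mortality": dfar == 0 and dnear > 0,
            "none_to_recovery": dfar == 0 and dnear < 0,
            "recovery_to_mortality": dfar < 0 and dnear > 0,
            "mortality_to_recovery": dfar > 0 and dnear < 0,
        }[self.pattern]
        if not consistent:
            raise ValueError(
                f"rates (far diff {dfar:+.3f}, near diff {dnear:+.3f}) are "
                f"inconsistent with pattern {self.pattern!r}"
            )


@dataclass
class CohortConfig:
    """Study-condition knobs for one synthetic cohort."""

    n_cases: int
    n_features: int
    n_days: int = 10
    mortality_fraction: float = 0.61
    background_rate: float = 0.3
    markers: list[MarkerSpec] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 2:
            raise ValueError("n_cases must be >= 2")
        if not 0.0 < self.mortality_fraction < 1.0:
            raise ValueError("mortality_fraction must be in (0, 1)")
        if not 0.0 <= self.background_rate <= 1.0:
            raise ValueError("background_rate outside [0, 1]")
        idx = [m.feature_index for m in self.markers]
        if len(set(idx)) != len(idx):
            raise ValueError("marker feature indices must be distinct")
        if any(i < 0 or i >= self.n_features for i in idx):
            raise ValueError("marker feature index out of range")


def far_near_split(n_days: int) -> tuple[np.ndarray, np.ndarray]:
    """Far = first ceil(T/2) day indices, near = the rest."""
    cut = (n_days + 1) // 2
    return np.arange(cut), np.arange(cut, n_days)


def generate_cohort(
    config: CohortConfig,
) -> tuple[EventTensor, OutcomeVector, list[MarkerSpec]]:
    """Draw one cohort; identical config (incl. seed) gives identical output."""
    rng = np.random.default_rng(config.seed)
    n, t, f = config.n_cases, config.n_days, config.n_features
    y = (rng.random(n) < config.mortality_fraction).astype(np.int8)
    if y.min() == y.max():
        raise ValueError(
            "drawn cohort contains a single outcome class; increase n_cases "
            "or adjust mortality_fraction"
        )
    far, near = far_near_split(t)
    by_index = {m.feature_index: m for m in config.markers}

    rates = np.empty((n, t), dtype=float)
    data = np.empty((n, t, f), dtype=np.uint8)
    for j in range(f):
        m = by_index.get(j)
        if m is None:
            rates[:] = config.background_rate
        else:
            rates[np.ix_(y == 1, far)] = m.rate_mortality_far
            rates[np.ix_(y == 1, near)] = m.rate_mortality_near
            rates[np.ix_(y == 0, far)] = m.rate_recovery_far
            rates[np.ix_(y == 0, near)] = m.rate_recovery_near
        data[:, :, j] = rng.random((n, t)) < rates

    case_ids = [f"case{i:05d}" for i in range(n)]
    X = EventTensor(
        data,
        case_ids,
        day_labels_for(t),
        [f"lab:F{j:04d}" for j in range(f)],
        ["lab"] * f,
    )
    return X, OutcomeVector(y, case_ids), list(config.markers)


def occurrence_frequency(
    X: EventTensor, Y: OutcomeVector, feature: int | str
) -> tuple[np.ndarray, np.ndarray]:
    """Per-day occurrence percentage in the mortality and recovery groups.

    Returns (mortality_curve, recovery_curve), each length T, in percent:
    100 * (#cases in the group with the event on that day) / group size.
    """
    j = X.feature_index(feature) if isinstance(feature, str) else int(feature)
    y = Y.labels
    if (y == 1).sum() == 0 or (y == 0).sum() == 0:
        raise ValueError("both outcome groups must be non-empty")
    col = X.data[:, :, j]
    mort = 100.0 * col[y == 1].mean(axis=0)
    recov = 100.0 * col[y == 0].mean(axis=0)
    return mort, recov
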