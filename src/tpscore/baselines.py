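"""Classical variable-importance baselines and the rank comparison with TPS.

Three baselines, each defined on the time-collapsed N x F matrix (they are
pattern-blind by construction, which is the point of the comparison):

* Gini feature importance of tree ensembles — per-node impurity decreases
  summed per split feature, normalized within each tree, averaged over the
  ensemble. Computed from the fitted trees' node statistics (class
  proportions and weighted sample shares), not from a library attribute,
  and cross-checked against scikit-learn in the tests.
* Permutation importance — baseline score minus the mean score after
  independently permuting one feature column, any scorer (default AUROC).
* Shapley values — exact subset enumeration for small feature sets with a
  mask-to-0 value function (0 = "event never occurred", the natural
  reference for an occurrence encoding); Monte Carlo permutation sampling
  above the exact-enumeration limit; optional retrain-per-subset mode for
  tiny feature sets as an oracle for the masking shortcut.

``union_top_k`` assembles the cross-method comparison: the union of each
method's top-k features by absolute score and every union feature's
full-universe rank in every method, ready for heatmap rendering.
"""

from __future__ import annotations

from itertools import combinations
from math import factorial

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .datatypes import EventTensor

EXACT_SHAPLEY_LIMIT = 12


# ------------------------------------------------------------------ Gini FI


def _tree_importances(tree, n_features: int) -> np.ndarray:
    """Normalized per-feature Gini importance of one fitted classification tree."""
    value = tree.value[:, 0, :]  # (nodes, classes), counts or proportions
    totals = value.sum(axis=1, keepdims=True)
    p = np.divide(value, totals, out=np.zeros_like(value, dtype=float), where=totals > 0)
    gini = 1.0 - (p**2).sum(axis=1)
    w = tree.weighted_n_node_samples / tree.weighted_n_node_samples[0]
    left, right = tree.children_left, tree.children_right
    node_importance = np.zeros(tree.node_count)
    internal = left != -1
    node_importance[internal] = (
        w[internal] * gini[internal]
        - w[left[internal]] * gini[left[internal]]
        - w[right[internal]] * gini[right[internal]]
    )
    per_feature = np.zeros(n_features)
    np.add.at(per_feature, tree.feature[internal], node_importance[internal])
    total = per_feature.sum()
    if total <= 0:
        return per_feature  # tree with no informative split
    return per_feature / total


def gini_feature_importance(ensemble) -> np.ndarray:
    """Mean normalized Gini importance across the trees of a fitted ensemble.

    Accepts a fitted DecisionTreeClassifier or an ensemble exposing
    ``estimators_`` of classification trees. Recurrent backbones have no
    node statistics and are rejected.
    """
    if getattr(ensemble, "is_temporal", False):
        raise TypeError("Gini feature importance is undefined for recurrent backbones")
    if hasattr(ensemble, "tree_"):
        trees = [ensemble]
    elif hasattr(ensemble, "estimators_"):
        trees = list(np.asarray(ensemble.estimators_, dtype=object).ravel())
    else:
        raise ValueError("expected a fitted tree or tree ensemble")
    if not trees:
        raise ValueError("ensemble has no fitted trees")
    mats = []
    for est in trees:
        tree = est.tree_
        if tree.value.shape[2] < 2:
            raise ValueError("Gini importance requires classification trees")
        mats.append(_tree_importances(tree, est.n_features_in_))
    return np.mean(mats, axis=0)


# ------------------------------------------------------- permutation importance


def _as_matrix(X) -> np.ndarray:
    if isinstance(X, EventTensor):
        return X.data.astype(float)
    return np.asarray(X, dtype=float)


def permutation_importance(
    model,
    X,
    y: np.ndarray,
    scorer=None,
    n_repeats: int = 10,
    seed: int = 0,
) -> np.ndarray:
    """P_j = s(y, f(X)) - mean over repeats of s(y, f(X with column j permuted)).

    ``model`` is anything with ``predict_proba`` returning per-case
    probabilities (a PredictorModel, or a scikit-learn classifier whose
    positive-class column is taken). For a 3-D tensor input the whole
    day-vector of feature j is permuted across cases, so within-case
    temporal structure is preserved.
    """
    scorer = scorer or roc_auc_score
    y = np.asarray(y).ravel()
    if y.min() == y.max():
        raise ValueError("scorer is undefined for single-class labels")
    data = _as_matrix(X)

    def predict(arr):
        out = np.asarray(model.predict_proba(arr))
        return out[:, 1] if out.ndim == 2 else out

    baseline = scorer(y, predict(data))
    rng = np.random.default_rng(seed)
    n_features = data.shape[-1]
    importances = np.zeros(n_features)
    for j in range(n_features):
        drops = []
        for _ in range(n_repeats):
            perm = rng.permutation(data.shape[0])
            shuffled = data.copy()
            shuffled[..., j] = data[perm, ..., j]
            drops.append(baseline - scorer(y, predict(shuffled)))
        importances[j] = np.mean(drops)
    return importances


# ------------------------------------------------------------------- Shapley


def _masked_prediction(predict, X: np.ndarray, keep: tuple[int, ...], baseline: float):
    masked = np.full_like(X, baseline, dtype=float)
    if keep:
        masked[:, list(keep)] = X[:, list(keep)]
    return np.asarray(predict(masked), dtype=float)


def shapley_values(
    predict,
    X,
    baseline: float = 0.0,
    n_permutations: int | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Per-case Shapley values phi (n_cases, F) of a prediction function.

    ``predict`` maps an (n, F) float matrix to per-case outputs. The value
    of a coalition S is the prediction with every feature outside S set to
    ``baseline``. Exact enumeration over all 2^F coalitions when
    F <= 12; beyond that an explicit Monte Carlo budget
    (``n_permutations`` random feature orderings) is required.

    Exact mode satisfies efficiency per case:
    sum_i phi_i = f(x) - f(baseline).
    """
    X = _as_matrix(X)
    if X.ndim != 2:
        raise ValueError("shapley_values expects a 2-D case-by-feature matrix")
    n, F = X.shape
    if F > EXACT_SHAPLEY_LIMIT and n_permutations is None:
        raise ValueError(
            f"{F} features exceeds the exact-enumeration limit "
            f"({EXACT_SHAPLEY_LIMIT}); pass an n_permutations budget"
        )
    phi = np.zeros((n, F))
    if n_permutations is None:
        values: dict[tuple[int, ...], np.ndarray] = {}
        for size in range(F + 1):
            for S in combinations(range(F), size):
                values[S] = _masked_prediction(predict, X, S, baseline)
        for i in range(F):
            others = [j for j in range(F) if j != i]
            for size in range(F):
                K = factorial(size) * factorial(F - size - 1) / factorial(F)
                for S in combinations(others, size):
                    with_i = tuple(sorted(S + (i,)))
                    phi[:, i] += K * (values[with_i] - values[S])
        return phi
    rng = np.random.default_rng(seed)
    for _ in range(n_permutations):
        order = rng.permutation(F)
        prev = _masked_prediction(predict, X, (), baseline)
        keep: list[int] = []
        for i in order:
            keep.append(int(i))
            cur = _masked_prediction(predict, X, tuple(keep), baseline)
            phi[:, i] += cur - prev
            prev = cur
    return phi / n_permutations


def shapley_values_retrain(
    model_factory,
    X,
    y: np.ndarray,
) -> np.ndarray:
    """Literal retrain-per-coalition Shapley values (oracle mode, tiny F only).

    The value of coalition S is the per-case prediction of a fresh model
    fitted on the columns in S alone; the empty coalition predicts the
    base rate mean(y). Exponential in F — intended as a cross-check for
    the masking shortcut on toy problems, not for production use.
    """
    X = _as_matrix(X)
    y = np.asarray(y).ravel()
    n, F = X.shape
    if F > 6:
        raise ValueError("retrain mode is an oracle for F <= 6 only")
    values: dict[tuple[int, ...], np.ndarray] = {(): np.full(n, y.mean())}
    for size in range(1, F + 1):
        for S in combinations(range(F), size):
            est = model_factory()
            est.fit(X[:, list(S)], y)
            out = est.predict_proba(X[:, list(S)])
            values[S] = out[:, 1] if out.ndim == 2 else out
    phi = np.zeros((n, F))
    for i in range(F):
        others = [j for j in range(F) if j != i]
        for size in range(F):
            K = factorial(size) * factorial(F - size - 1) / factorial(F)
            for S in combinations(others, size):
                with_i = tuple(sorted(S + (i,)))
                phi[:, i] += K * (values[with_i] - values[S])
    return phi


def shapley_temporal(model, X: EventTensor, n_permutations: int | None = None, seed: int = 0):
    """Mean |phi| per event variable for a temporal backbone.

    Flattens the T x F day-feature grid into T*F players, runs
    :func:`shapley_values` on the flattened input, and aggregates |phi|
    per feature by summing over days.
    """
    n, T, F = X.data.shape
    flat = X.data.reshape(n, T * F).astype(float)

    def predict(mat):
        return model.predict_proba(mat.reshape(-1, T, F))

    phi = shapley_values(predict, flat, n_permutations=n_permutations, seed=seed)
    return np.abs(phi).reshape(n, T, F).sum(axis=1).mean(axis=0)


# ------------------------------------------------------------- union top-k


def union_top_k(columns: dict[str, pd.Series], k: int = 10):
    """Union of each method's top-k features by |score| plus the rank matrix.

    ``columns`` maps a method label to a Series of scores indexed by
    feature_id; all columns must share one feature universe. Returns
    (union_features, rank_df) where rank_df[method][feature] is the
    feature's 1-based position in that method's full |score| ranking
    (ties broken by feature_id).
    """
    labels = list(columns)
    if not labels:
        raise ValueError("no importance columns given")
    universe = list(columns[labels[0]].index)
    for lab in labels[1:]:
        if list(columns[lab].index) != universe:
            raise ValueError(f"column {lab!r} is over a different feature universe")
    if k > len(universe):
        raise ValueError(f"k={k} exceeds the feature universe size {len(universe)}")

    ranks = {}
    union: list[str] = []
    for lab in labels:
        df = pd.DataFrame({"feature_id": universe, "a": columns[lab].abs().to_numpy()})
        df = df.sort_values(["a", "feature_id"], ascending=[False, True], kind="mergesort")
        df["rank"] = np.arange(1, len(df) + 1)
        ranks[lab] = df.set_index("feature_id")["rank"]
        for fid in df["feature_id"].head(k):
            if fid not in union:
                union.append(fid)
    rank_df = pd.DataFrame({lab: ranks[lab].loc[union] for lab in labels})
    return union, rank_df
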