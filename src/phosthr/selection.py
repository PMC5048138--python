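"""mRMR feature ranking and incremental feature selection (IFS).

Features are discretized into three states at mean +/- one standard
deviation, mutual information is estimated with the plug-in formula on
the joint contingency table (bits), and ranking follows the greedy MID
(mutual-information difference) criterion: the first feature maximizes
relevance I(f; y); each subsequent feature maximizes

    I(f; y) - mean_{s in selected} I(f; s)

Ties break toward the lower feature index.  IFS then evaluates every
nested prefix of the ranking with a caller-supplied evaluator
(jackknife auROC in the full pipeline) and reports the prefix length
with the best score (ties toward the smaller prefix).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .errors import ParameterError


def discretize(values: Sequence[float]) -> np.ndarray:
    """Three-state codes (0=low, 1=mid, 2=high) split at mean +/- sigma.

    Constant features (sigma == 0) map to all-mid.  The cut points are
    affine-equivariant, so affine transforms of a feature yield
    identical codes.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ParameterError("discretize needs a 1-D feature with >= 2 samples")
    mu = x.mean()
    sd = x.std()  # population sigma
    codes = np.ones(x.size, dtype=np.int64)
    if sd > 0:
        codes[x < mu - sd] = 0
        codes[x > mu + sd] = 2
    return codes


def mutual_information(codes_x: Sequence[int], codes_y: Sequence[int]) -> float:
    """Plug-in mutual information of two code vectors, in bits."""
    x = np.asarray(codes_x)
    y = np.asarray(codes_y)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("code vectors must be 1-D and of equal length")
    n = x.size
    _, xi = np.unique(x, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    joint = np.zeros((xi.max() + 1, yi.max() + 1))
    np.add.at(joint, (xi, yi), 1.0)
    joint /= n
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(joint > 0, joint * np.log2(joint / (px * py)), 0.0)
    return float(max(terms.sum(), 0.0))


def discretize_matrix(X: np.ndarray) -> np.ndarray:
    """Column-wise three-state discretization of a feature matrix."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ParameterError("discretize_matrix needs a 2-D matrix with >= 2 rows")
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    codes = np.ones(X.shape, dtype=np.int8)
    codes[X < mu - sd] = 0
    codes[X > mu + sd] = 2
    return codes


def _state_indicators(codes: np.ndarray) -> list[np.ndarray]:
    return [(codes == s).astype(float) for s in np.unique(codes)]


def mi_matrix(codes: np.ndarray) -> np.ndarray:
    """All-pairs plug-in MI (bits) between the columns of a code matrix.

    Joint counts for every column pair come from indicator-matrix
    products, so the full d x d table costs a handful of matmuls.
    """
    n, d = codes.shape
    ind = _state_indicators(codes)
    marg = [m.mean(axis=0) for m in ind]  # per-state column probabilities
    M = np.zeros((d, d))
    for a, Ia in enumerate(ind):
        for b, Ib in enumerate(ind):
            J = (Ia.T @ Ib) / n
            denom = np.outer(marg[a], marg[b])
            with np.errstate(divide="ignore", invalid="ignore"):
                M += np.where(J > 0, J * np.log2(J / denom), 0.0)
    return np.maximum(M, 0.0)


def mi_with_labels(codes: np.ndarray, y: Sequence[int]) -> np.ndarray:
    """Plug-in MI (bits) between every column of ``codes`` and labels."""
    _, yi = np.unique(np.asarray(y), return_inverse=True)
    n, d = codes.shape
    ind = _state_indicators(codes)
    marg = [m.mean(axis=0) for m in ind]
    rel = np.zeros(d)
    for c in range(yi.max() + 1):
        w = (yi == c).astype(float)
        pc = w.mean()
        for a, Ia in enumerate(ind):
            J = (w @ Ia) / n  # (d,) joint P(x=a, y=c)
            denom = marg[a] * pc
            with np.errstate(divide="ignore", invalid="ignore"):
                rel += np.where(J > 0, J * np.log2(J / denom), 0.0)
    return np.maximum(rel, 0.0)


@dataclass
class MrmrRanking:
    """A full mRMR ordering of feature indices."""

    order: np.ndarray  # permutation of 0..n_features-1
    relevance: np.ndarray  # I(f; y) per feature, original index order
    scheme: str = "MID"


def mrmr_rank(X: np.ndarray, y: Sequence[int]) -> MrmrRanking:
    """Greedy MID ranking of all columns of ``X`` against labels ``y``."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ParameterError("mrmr_rank needs a 2-D matrix with >= 2 features")
    if X.shape[0] != y.size:
        raise ParameterError("row count does not match label count")
    n_feat = X.shape[1]
    codes = discretize_matrix(X)
    relevance = mi_with_labels(codes, y)
    M = mi_matrix(codes)

    selected = np.zeros(n_feat, dtype=bool)
    cum_red = np.zeros(n_feat)  # sum of MI(f, s) over selected s
    order: list[int] = []
    # np.argmax picks the first (lowest-index) maximizer, our tie-break
    first = int(np.argmax(relevance))
    order.append(first)
    selected[first] = True
    while len(order) < n_feat:
        cum_red += M[:, order[-1]]
        scores = relevance - cum_red / len(order)
        scores[selected] = -np.inf
        pick = int(np.argmax(scores))
        order.append(pick)
        selected[pick] = True
    return MrmrRanking(order=np.array(order), relevance=relevance)


@dataclass
class IfsCurve:
    """auROC of every nested prefix of a feature ranking."""

    k: np.ndarray  # 1..n_features
    auroc: np.ndarray
    best_k: int

    def __post_init__(self) -> None:
        if len(self.k) != len(self.auroc):
            raise ParameterError("curve arrays differ in length")


def ifs(
    X: np.ndarray,
    y: Sequence[int],
    ranking: MrmrRanking | Sequence[int],
    evaluator: Callable[[np.ndarray, np.ndarray], float],
) -> IfsCurve:
    """Evaluate nested prefixes of ``ranking``; one evaluation per k.

    ``evaluator`` maps (X_subset, y) to a score.  ``best_k`` attains the
    maximum score; ties break toward the smallest prefix.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    order = ranking.order if isinstance(ranking, MrmrRanking) else np.asarray(ranking)
    if sorted(order.tolist()) != list(range(X.shape[1])):
        raise ParameterError("ranking must be a permutation of all feature indices")
    ks = np.arange(1, X.shape[1] + 1)
    scores = np.empty(len(ks))
    for i, k in enumerate(ks):
        sub = X[:, order[:k]]
        try:
            scores[i] = float(evaluator(sub, y))
        except Exception as exc:  # noqa: BLE001 - annotate the failing prefix
            raise RuntimeError(f"evaluator failed at prefix k={k}: {exc}") from exc
    best_k = int(ks[int(np.argmax(scores))])  # argmax -> smallest k on ties
    return IfsCurve(k=ks, auroc=scores, best_k=best_k)
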