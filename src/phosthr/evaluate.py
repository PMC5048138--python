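"""RBF-SVM training, jackknife (leave-one-out) evaluation, ROC/auROC.

The classifier is a maximum-margin SVM with an RBF kernel (LIBSVM via
scikit-learn's ``SVC``).  Hyperparameters (C, gamma) are tuned by
exhaustive grid search over C in {2^-5 .. 2^15} and gamma in
{2^-15 .. 2^-5} (exponent step 1), scored by jackknife auROC; ties
break toward the smaller C, then the smaller gamma.

Because the F1 feature group is derived from class-specific PWMs, a
window-level jackknife (:func:`jackknife_windows`) rebuilds both PWMs
and the accessibility scale on each leave-one-out training fold, so no
information about the held-out label leaks into its features.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.svm import SVC

from .dataset import ResidueWindow
from .encoding import PropertyTable, WindowConfig, assemble_features_loo
from .errors import ParameterError


def _default_c_grid() -> np.ndarray:
    return 2.0 ** np.arange(-5, 16)


def _default_gamma_grid() -> np.ndarray:
    return 2.0 ** np.arange(-15, -4)


@dataclass
class SvmConfig:
    """RBF-SVM hyperparameters and the search grids.

    The defaults sit at the midpoints of the search grids (C = 2^5,
    gamma = 2^-10), a neutral operating point when no grid search is
    run.  ``gamma=None`` falls back to scikit-learn's 'scale'
    heuristic (1 / (n_features * Var(X))).
    """

    C: float = 2.0**5
    gamma: float | None = 2.0**-10
    C_grid: np.ndarray = field(default_factory=_default_c_grid)
    gamma_grid: np.ndarray = field(default_factory=_default_gamma_grid)

    def __post_init__(self) -> None:
        self.C_grid = np.asarray(self.C_grid, dtype=float)
        self.gamma_grid = np.asarray(self.gamma_grid, dtype=float)
        for name, grid in (("C_grid", self.C_grid), ("gamma_grid", self.gamma_grid)):
            if grid.size == 0 or np.any(np.diff(grid) <= 0):
                raise ParameterError(f"{name} must be non-empty and strictly increasing")

    def _sk_gamma(self) -> float | str:
        return "scale" if self.gamma is None else float(self.gamma)


@dataclass
class EvalResult:
    """Jackknife decision scores, the ROC curve and its area."""

    scores: np.ndarray
    labels: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auroc: float
    config: SvmConfig


def train(X: np.ndarray, y: Sequence[int], config: SvmConfig | None = None) -> SVC:
    """Fit an RBF-kernel SVM; returns the fitted decision function."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ParameterError("training requires both classes to be present")
    config = config or SvmConfig()
    clf = SVC(kernel="rbf", C=config.C, gamma=config._sk_gamma())
    clf.fit(X, y)
    return clf


def roc_points(
    scores: Sequence[float], labels: Sequence[int]
) -> tuple[np.ndarray, np.ndarray]:
    """ROC curve (FPR, TPR) with thresholds swept over the unique scores.

    Equal scores collapse into a single step; the curve starts at (0, 0)
    and ends at (1, 1).
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ParameterError("ROC needs both classes among the labels")
    fpr, tpr, _ = _sk_roc_curve(labels, np.asarray(scores, dtype=float),
                                drop_intermediate=False)
    return fpr, tpr


def auroc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Trapezoid area under the ROC curve.

    Equals the pairwise-comparison (rank-sum) probability that a random
    positive outscores a random negative, ties counted one half.
    """
    fpr, tpr = roc_points(scores, labels)
    return float(_sk_auc(fpr, tpr))


def jackknife_eval(
    X: np.ndarray, y: Sequence[int], config: SvmConfig | None = None
) -> EvalResult:
    """Leave-one-out evaluation on a fixed feature matrix.

    Each sample's decision score comes from a model trained on the other
    n-1 samples; ROC and auROC are computed from the n held-out scores.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = X.shape[0]
    if n < 3:
        raise ParameterError("jackknife needs at least 3 samples")
    config = config or SvmConfig()
    scores = np.empty(n)
    idx = np.arange(n)
    for i in range(n):
        mask = idx != i
        clf = train(X[mask], y[mask], config)
        scores[i] = float(clf.decision_function(X[i : i + 1])[0])
    fpr, tpr = roc_points(scores, y)
    return EvalResult(
        scores=scores, labels=y, fpr=fpr, tpr=tpr,
        auroc=float(_sk_auc(fpr, tpr)), config=config,
    )


def jackknife_auroc(
    X: np.ndarray, y: Sequence[int], config: SvmConfig | None = None
) -> float:
    """Convenience evaluator: jackknife auROC of a feature matrix."""
    return jackknife_eval(X, y, config).auroc


def jackknife_windows(
    positives: Sequence[ResidueWindow],
    negatives: Sequence[ResidueWindow],
    window_config: WindowConfig | None = None,
    svm_config: SvmConfig | None = None,
    table: PropertyTable | None = None,
    p0: float = 0.05,
    alpha: float = 1.0,
    select_k: int | None = None,
) -> EvalResult:
    """Window-level jackknife with leakage-controlled F1 encoding.

    The F1 group is encoded leave-one-out: every window's PWM-difference
    scores come from class PWMs rebuilt without that window, so train
    and held-out F1 values follow the same distribution and no window's
    own label enters its features (see
    :func:`~phosthr.encoding.assemble_features_loo`).

    With ``select_k`` set, an mRMR ranking is recomputed on each
    training fold and the SVM sees only that fold's top-k features —
    feature selection then never observes the held-out label.
    """
    from .selection import mrmr_rank

    window_config = window_config or WindowConfig()
    svm_config = svm_config or SvmConfig()
    table = table or PropertyTable.load()
    windows = list(positives) + list(negatives)
    n = len(windows)
    if n < 3 or not positives or not negatives:
        raise ParameterError("jackknife needs >= 3 windows and both classes")

    fm = assemble_features_loo(
        windows, window_config, table, p0=p0, alpha=alpha
    )
    X, y = fm.X, fm.y
    if select_k is not None and not 1 <= select_k <= X.shape[1]:
        raise ParameterError(f"select_k={select_k} outside 1..{X.shape[1]}")

    scores = np.empty(n)
    idx = np.arange(n)
    for i in range(n):
        mask = idx != i
        cols = slice(None)
        if select_k is not None:
            order = mrmr_rank(X[mask], y[mask]).order
            cols = order[:select_k]
        clf = train(X[mask][:, cols], y[mask], svm_config)
        scores[i] = float(clf.decision_function(X[i : i + 1, cols])[0])
    fpr, tpr = roc_points(scores, y)
    return EvalResult(
        scores=scores, labels=y, fpr=fpr, tpr=tpr,
        auroc=float(_sk_auc(fpr, tpr)), config=svm_config,
    )


def grid_search(
    X: np.ndarray,
    y: Sequence[int],
    config: SvmConfig | None = None,
    evaluator: Callable[[np.ndarray, np.ndarray, SvmConfig], float] | None = None,
) -> tuple[SvmConfig, list[tuple[float, float, float]]]:
    """Exhaustive (C, gamma) search scored by jackknife auROC.

    Returns the winning :class:`SvmConfig` and the full results table
    ``[(C, gamma, score), ...]``.  Ties break toward the smaller C, then
    the smaller gamma (grids are scanned in ascending order with a
    strict improvement rule).
    """
    config = config or SvmConfig()
    if evaluator is None:
        evaluator = lambda Xs, ys, cfg: jackknife_auroc(Xs, ys, cfg)  # noqa: E731
    results: list[tuple[float, float, float]] = []
    best: tuple[float, float] | None = None
    best_score = -np.inf
    for C in config.C_grid:
        for g in config.gamma_grid:
            cfg = SvmConfig(C=float(C), gamma=float(g),
                            C_grid=config.C_grid, gamma_grid=config.gamma_grid)
            score = float(evaluator(X, y, cfg))
            results.append((float(C), float(g), score))
            if score > best_score:
                best, best_score = (float(C), float(g)), score
    assert best is not None
    return (
        SvmConfig(C=best[0], gamma=best[1],
                  C_grid=config.C_grid, gamma_grid=config.gamma_grid),
        results,
    )
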