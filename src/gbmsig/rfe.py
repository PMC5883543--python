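"""Modified SVM-RFE: recursive feature elimination with embedded CV error.

Standard SVM-RFE ranks features by the squared weights of a linear
soft-margin SVM and discards the lowest-ranked fraction each recursion. The
modification here records, at every recursion level, a stratified k-fold
cross-validated error rate; the signature is the feature set of the level
with the minimal CV error (ties resolved toward fewer genes).

Two CV schemes are available. The default, ``per_fold_path`` (the R-SVM
scheme), re-runs the whole elimination inside each training fold and scores
the held-out fold at every level, so the error estimate is not contaminated
by feature selection performed on the test samples — under a pure-noise
null it stays near chance at every level. ``fixed_subset`` is the naive
variant that cross-validates the full-data surviving subset directly; it is
optimistically biased (features were chosen using the test folds) and is
kept only for comparison.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

RANKING_CRITERIA = ("w2", "rsvm")
CV_SCHEMES = ("per_fold_path", "fixed_subset")


def derive_seed(seed: int, *tokens) -> int:
    """Stable sub-seed below 2**31 from a base seed and context tokens."""
    key = ":".join(str(t) for t in (seed, *tokens)).encode()
    return int.from_bytes(hashlib.blake2b(key, digest_size=4).digest(), "big") % (2**31)


@dataclass(frozen=True)
class RFEConfig:
    """Knobs of the elimination loop.

    ``cost`` is the SVM soft-margin parameter C (default 10);
    only the linear kernel is supported. ``elimination_fraction`` of the
    surviving features (at least one) is dropped per recursion. ``ranking``
    is "w2" (squared weight, the classical criterion) or "rsvm"
    (weight times class-mean difference).
    """

    cost: float = 10.0
    kernel: str = "linear"
    n_folds: int = 5
    elimination_fraction: float = 0.10
    ranking: str = "w2"
    cv_scheme: str = "per_fold_path"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cost <= 0:
            raise ValueError("cost must be positive")
        if self.kernel != "linear":
            raise ValueError("only the linear kernel is supported")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if not 0.0 < self.elimination_fraction < 1.0:
            raise ValueError("elimination_fraction must lie in (0, 1)")
        if self.ranking not in RANKING_CRITERIA:
            raise ValueError(f"ranking must be one of {RANKING_CRITERIA}")
        if self.cv_scheme not in CV_SCHEMES:
            raise ValueError(f"cv_scheme must be one of {CV_SCHEMES}")


@dataclass(frozen=True)
class RFEStep:
    n_features: int
    feature_ids: tuple[str, ...]
    cv_error: float


@dataclass(frozen=True)
class RFETrace:
    """Per-recursion record of surviving features and their CV error."""

    steps: tuple[RFEStep, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(i, s.n_features, s.cv_error) for i, s in enumerate(self.steps)],
            columns=["step", "n_features", "cv_error"],
        )


@dataclass(frozen=True)
class SelectedSignature:
    gene_ids: tuple[str, ...]
    cv_error_at_selection: float
    n_genes: int


def _check_two_classes(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {list(classes)}")
    return classes, counts


def cv_error(
    expr_subset: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    config: RFEConfig,
    fold_seed: int | None = None,
) -> float:
    """Stratified k-fold CV error rate of the linear SVM on these features.

    ``expr_subset`` is samples x features. The error is the pooled fraction
    of held-out samples misclassified across folds.
    """
    x = np.asarray(expr_subset, dtype=float)
    y = np.asarray(labels)
    _, counts = _check_two_classes(y)
    if config.n_folds > counts.min():
        raise ValueError(
            f"n_folds={config.n_folds} exceeds the smaller class "
            f"size {counts.min()}")
    skf = StratifiedKFold(
        n_splits=config.n_folds, shuffle=True,
        random_state=config.seed if fold_seed is None else fold_seed)
    wrong = 0
    for train, test in skf.split(x, y):
        clf = SVC(kernel="linear", C=config.cost)
        clf.fit(x[train], y[train])
        wrong += int(np.sum(clf.predict(x[test]) != y[test]))
    return wrong / len(y)


def rank_features(
    weights: np.ndarray,
    feature_ids: list[str],
    criterion: str = "w2",
    class_mean_diff: np.ndarray | None = None,
) -> list[str]:
    """Feature ids ordered best -> worst by the ranking criterion.

    "w2" scores each feature by its squared SVM weight; "rsvm" by
    w_j * (mean difference of feature j between classes). Ties break by
    lexicographic feature id for determinism.
    """
    w = np.asarray(weights, dtype=float)
    if not np.all(np.isfinite(w)):
        raise ArithmeticError("non-finite SVM weights")
    if criterion == "w2":
        scores = w**2
    elif criterion == "rsvm":
        if class_mean_diff is None:
            raise ValueError("rsvm ranking needs the class mean differences")
        scores = w * np.asarray(class_mean_diff, dtype=float)
    else:
        raise ValueError(f"unknown ranking criterion {criterion!r}")
    order = sorted(range(len(w)), key=lambda j: (-scores[j], feature_ids[j]))
    return [feature_ids[j] for j in order]


def _level_schedule(n_features: int, fraction: float) -> list[int]:
    """Feature counts visited by the elimination loop, ending at 1."""
    levels = [n_features]
    n = n_features
    while n > 1:
        n -= min(max(1, math.ceil(fraction * n)), n - 1)
        levels.append(n)
    return levels


def _elimination_path(
    x: np.ndarray,
    y: np.ndarray,
    feature_ids: list[str],
    config: RFEConfig,
    levels: list[int],
) -> dict[int, list[str]]:
    """Nested surviving-feature sets at each requested level.

    One SVM fit + ranking per level transition; the subset at each level is
    kept in ranked (best-first) order.
    """
    classes = np.unique(y)
    pos, neg = (y == classes[1]), (y == classes[0])
    col_of = {g: j for j, g in enumerate(feature_ids)}
    surviving = list(feature_ids)
    subsets = {levels[0]: list(surviving)}
    for target in levels[1:]:
        cols = [col_of[g] for g in surviving]
        xs = x[:, cols]
        clf = SVC(kernel="linear", C=config.cost)
        clf.fit(xs, y)
        diff = xs[pos].mean(axis=0) - xs[neg].mean(axis=0)
        ranked = rank_features(
            clf.coef_.ravel(), surviving, config.ranking, class_mean_diff=diff)
        surviving = ranked[:target]
        subsets[target] = list(surviving)
    return subsets


def run_rfe(
    expr: pd.DataFrame,
    labels: pd.Series,
    config: RFEConfig | None = None,
) -> RFETrace:
    """Recursive elimination over a genes x samples matrix.

    ``expr`` holds the candidate (pathway-filtered) genes for the samples of
    the two progression classes; ``labels`` maps those samples to their
    class. The reported feature set at each level comes from the elimination
    path on all samples; the CV error at each level comes from the scheme
    selected in the config (per-fold elimination paths by default). The
    trace ends with the singleton level.
    """
    config = config or RFEConfig()
    if expr.shape[0] == 0:
        raise ValueError("empty feature pool")
    labels = pd.Series(labels).loc[expr.columns]
    x_full = expr.to_numpy(dtype=float).T  # samples x features
    y = labels.to_numpy()
    _, counts = _check_two_classes(y)
    if config.n_folds > counts.min():
        raise ValueError(
            f"n_folds={config.n_folds} exceeds the smaller class "
            f"size {counts.min()}")

    feature_ids = list(expr.index)
    levels = _level_schedule(len(feature_ids), config.elimination_fraction)
    full_subsets = _elimination_path(x_full, y, feature_ids, config, levels)

    errors: dict[int, float] = {}
    if config.cv_scheme == "per_fold_path":
        skf = StratifiedKFold(
            n_splits=config.n_folds, shuffle=True,
            random_state=derive_seed(config.seed, "folds"))
        wrong = {level: 0 for level in levels}
        col_of = {g: j for j, g in enumerate(feature_ids)}
        for train, test in skf.split(x_full, y):
            fold_subsets = _elimination_path(
                x_full[train], y[train], feature_ids, config, levels)
            for level in levels:
                cols = [col_of[g] for g in fold_subsets[level]]
                clf = SVC(kernel="linear", C=config.cost)
                clf.fit(x_full[np.ix_(train, cols)], y[train])
                pred = clf.predict(x_full[np.ix_(test, cols)])
                wrong[level] += int(np.sum(pred != y[test]))
        errors = {level: wrong[level] / len(y) for level in levels}
    else:  # fixed_subset: the naive, optimistically biased variant
        col_of = {g: j for j, g in enumerate(feature_ids)}
        for step, level in enumerate(levels):
            cols = [col_of[g] for g in full_subsets[level]]
            errors[level] = cv_error(
                pd.DataFrame(x_full[:, cols]), y, config,
                fold_seed=derive_seed(config.seed, "fold", step))

    steps = tuple(
        RFEStep(level, tuple(full_subsets[level]), errors[level])
        for level in levels
    )
    return RFETrace(steps=steps)


def select_signature(trace: RFETrace) -> SelectedSignature:
    """Feature set of the minimal-CV-error recursion; ties -> fewest genes."""
    if not trace.steps:
        raise ValueError("empty trace")
    best = min(trace.steps, key=lambda s: (s.cv_error, s.n_features))
    return SelectedSignature(
        gene_ids=best.feature_ids,
        cv_error_at_selection=best.cv_error,
        n_genes=best.n_features,
    )
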