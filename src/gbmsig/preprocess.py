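"""Gene variance filtering, progression-class assignment and batch testing.

``mad_filter`` keeps genes whose raw (unscaled) median absolute deviation
meets a cutoff — the conventional robust variance filter on log2 expression.
``assign_progression_classes`` splits patients with uncensored
progression-free survival (PFS) into rapid (class 1), slow (class 2) and
intermediate (class 3) progressors at the Q1/Q3 quartiles of eligible PFS.
``gpca_batch_test`` is guided principal component analysis: a permutation
test for whether batch labels explain the leading variance of the matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


class StratificationError(ValueError):
    """Degenerate spread: the requested split is undefined."""


@dataclass(frozen=True)
class ProgressionClasses:
    """Quartile-based three-class progression stratification.

    class1 (rapid): PFS <= q1; class2 (slow): PFS > q3;
    class3 (intermediate): the inter-quartile remainder. Boundaries are on
    the eligible (uncensored, in-window) PFS times.
    """

    q1: float
    q3: float
    class1_ids: list[str]
    class2_ids: list[str]
    class3_ids: list[str]


@dataclass(frozen=True)
class GPCAResult:
    delta: float
    p_perm: float
    n_perm: int


def mad_filter(expr: pd.DataFrame, threshold: float = 0.5) -> list[str]:
    """Genes whose per-gene MAD (unscaled) is >= threshold, boundary inclusive."""
    if expr.shape[1] < 1 or expr.shape[0] < 1:
        raise ValueError("expression matrix must be non-empty")
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    values = expr.to_numpy(dtype=float)
    med = np.median(values, axis=1, keepdims=True)
    mad = np.median(np.abs(values - med), axis=1)
    return [g for g, m in zip(expr.index, mad) if m >= threshold]


def assign_progression_classes(
    clinical: pd.DataFrame,
    pfs_floor: float = 6.0,
    pfs_ceiling: float = 720.0,
    quantile_method: str = "linear",
) -> ProgressionClasses:
    """Three-class split of uncensored-PFS patients at the Q1/Q3 quartiles.

    Eligibility: pfs_event == 1 and pfs_floor <= pfs_days <= pfs_ceiling.
    Quartiles use linear interpolation (NumPy's default, R type 7) unless
    another ``quantile_method`` is requested.
    """
    eligible = clinical[
        (clinical["pfs_event"] == 1)
        & (clinical["pfs_days"] >= pfs_floor)
        & (clinical["pfs_days"] <= pfs_ceiling)
    ]
    if len(eligible) < 4:
        raise ValueError(
            f"need >=4 eligible uncensored-PFS samples, got {len(eligible)}")
    pfs = eligible["pfs_days"].to_numpy(dtype=float)
    q1, q3 = np.quantile(pfs, [0.25, 0.75], method=quantile_method)
    if q1 == q3:
        raise StratificationError(
            f"degenerate PFS spread: Q1 == Q3 == {q1}")
    ids = eligible["sample_id"]
    return ProgressionClasses(
        q1=float(q1),
        q3=float(q3),
        class1_ids=list(ids[pfs <= q1]),
        class2_ids=list(ids[pfs > q3]),
        class3_ids=list(ids[(pfs > q1) & (pfs <= q3)]),
    )


def _leading_variance(matrix: np.ndarray) -> float:
    # squared top singular value = variance captured by the first
    # singular direction (up to the common 1/n factor, which cancels in delta)
    return float(np.linalg.svd(matrix, compute_uv=False)[0] ** 2)


def gpca_batch_test(
    expr: pd.DataFrame,
    batch: pd.Series | list[str],
    n_perm: int = 999,
    seed: int = 0,
) -> GPCAResult:
    """Guided PCA batch-effect permutation test.

    delta = (variance captured by the first singular direction of the
    batch-indicator-projected, per-gene-centered data) / (same for the raw
    centered data). Significance by permuting batch labels: p has resolution
    1/(n_perm + 1) and is never exactly zero.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    labels = pd.Series(list(batch), index=expr.columns)
    levels = labels.unique()
    if len(levels) < 2:
        raise ValueError("gPCA requires >= 2 non-empty batches")

    # samples x genes, centered per gene
    y = expr.to_numpy(dtype=float).T
    y = y - y.mean(axis=0, keepdims=True)
    unguided = _leading_variance(y)

    codes = pd.Categorical(labels).codes
    indicator = np.eye(len(levels))[codes]  # n x b

    def guided_variance(a: np.ndarray) -> float:
        _, _, vt = np.linalg.svd(a.T @ y, full_matrices=False)
        return float(np.sum((y @ vt[0]) ** 2))

    delta = guided_variance(indicator) / unguided
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(indicator)
        if guided_variance(perm) / unguided >= delta:
            hits += 1
    return GPCAResult(
        delta=float(delta),
        p_perm=(1 + hits) / (n_perm + 1),
        n_perm=n_perm,
    )
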