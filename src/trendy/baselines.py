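"""Information-based baseline GRN inference methods.

GENIE3 scores regulator->target edges by random-forest feature importance
on a single snapshot.  SINCERITIES tracks how the marginal distribution of
each gene shifts between consecutive time points (Kolmogorov-Smirnov
distance) and ridge-regresses each gene's next-interval shift on all
genes' current-interval shifts, signing coefficients by partial Spearman
correlation.

These are faithful-in-spirit reimplementations meant to produce base
score matrices for the transformer enhancer; exact replication of the
original codebases is out of scope.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import ks_2samp, rankdata
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import Ridge, RidgeCV

from .pipeline import InferredGRN
from .synthetic_data import SnapshotDataset

__all__ = ["genie3", "sincerities"]


def genie3(
    snapshot: np.ndarray,
    n_trees: int = 100,
    rng_seed: int = 0,
    gene_names: list[str] | None = None,
) -> InferredGRN:
    """Random-forest importance scores AG from one cells x genes snapshot.

    For each target gene j a forest regresses its level on all other
    genes; AG[i, j] is the importance of regulator i.  The diagonal is 0
    (self-prediction excluded) and all scores are nonnegative.  A constant
    target column yields a zero importance column.
    """
    x = np.asarray(snapshot, dtype=float)
    if x.ndim != 2:
        raise ValueError("snapshot must be 2-D (cells x genes)")
    m, n = x.shape
    if n < 2:
        raise ValueError("need at least 2 genes")
    scores = np.zeros((n, n))
    for j in range(n):
        others = [i for i in range(n) if i != j]
        y = x[:, j]
        if np.ptp(y) == 0.0:
            continue
        forest = RandomForestRegressor(
            n_estimators=n_trees,
            max_features="sqrt",
            random_state=int((rng_seed + j) % 2**31),
            n_jobs=1,
        )
        forest.fit(x[:, others], y)
        scores[others, j] = forest.feature_importances_
    return InferredGRN(scores, method_label="GENIE3/AG", gene_names=gene_names)


def _partial_spearman(x: np.ndarray) -> np.ndarray:
    """Partial Spearman correlation matrix from pooled cells x genes data."""
    ranks = np.column_stack([rankdata(x[:, j]) for j in range(x.shape[1])])
    corr = np.corrcoef(ranks, rowvar=False)
    # regularize before inversion: pooled rank correlations can be singular
    n = corr.shape[0]
    prec = np.linalg.pinv(corr + 1e-8 * np.eye(n))
    d = np.sqrt(np.abs(np.diag(prec)))
    partial = -prec / np.outer(d, d)
    np.fill_diagonal(partial, 1.0)
    return partial


def sincerities(
    snapshots: SnapshotDataset,
    ridge_penalty: float | None = None,
    gene_names: list[str] | None = None,
) -> InferredGRN:
    """SINCERITIES-style signed scores AS from multi-time snapshot data.

    Needs at least 3 inter-time intervals (4 time points).  When
    ``ridge_penalty`` is None the penalty is chosen by efficient
    leave-one-out ridge cross-validation, falling back to 1.0 on failure.
    """
    times = snapshots.times
    if len(times) < 4:
        raise ValueError("SINCERITIES needs at least 4 time points (3 intervals)")
    n = snapshots.n
    n_intervals = len(times) - 1
    # DD[l, j] = KS distance of gene j's marginal across interval l,
    # normalized by the interval length as in the original method.
    dd = np.zeros((n_intervals, n))
    for l in range(n_intervals):
        a, b = snapshots.snapshots[l], snapshots.snapshots[l + 1]
        dt = times[l + 1] - times[l]
        for j in range(n):
            dd[l, j] = ks_2samp(a[:, j], b[:, j]).statistic / max(dt, 1e-12)

    x_reg, y_reg = dd[:-1], dd[1:]
    coeffs = np.zeros((n, n))
    for j in range(n):
        if ridge_penalty is not None:
            model = Ridge(alpha=ridge_penalty)
            model.fit(x_reg, y_reg[:, j])
        else:
            try:
                model = RidgeCV(alphas=np.logspace(-3, 3, 25))
                model.fit(x_reg, y_reg[:, j])
            except Exception:
                model = Ridge(alpha=1.0)
                model.fit(x_reg, y_reg[:, j])
        coeffs[:, j] = model.coef_

    pooled = np.vstack(snapshots.snapshots)
    signs = np.sign(_partial_spearman(pooled))
    scores = np.abs(coeffs) * signs
    np.fill_diagonal(scores, 0.0)
    return InferredGRN(scores, method_label="SINCERITIES/AS", gene_names=gene_names)
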