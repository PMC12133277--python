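"""AUROC / AUPRC scoring of inferred networks against signed ground truth.

The signed truth is binarized by nonzero-ness ("a regulation exists") and
predictions are ranked by absolute score; diagonal entries are excluded
from both.  AUROC uses midrank tie handling; AUPRC is the step-wise
(non-interpolated) precision sum, which matters on sparse truths.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from .pipeline import InferredGRN
from .synthetic_data import GroundTruthGRN

__all__ = ["EvalResult", "score_grn", "benchmark", "total_score"]


@dataclass(frozen=True)
class EvalResult:
    auroc: float
    auprc: float
    n_positives: int
    n_negatives: int


def _offdiag(m: np.ndarray) -> np.ndarray:
    n = m.shape[0]
    return m[~np.eye(n, dtype=bool)]


def score_grn(truth: GroundTruthGRN | np.ndarray, pred: InferredGRN | np.ndarray) -> EvalResult:
    """AUROC and AUPRC of |pred| against 1{truth != 0} over off-diagonal entries."""
    t = truth.matrix if isinstance(truth, GroundTruthGRN) else np.asarray(truth, float)
    p = pred.scores if isinstance(pred, InferredGRN) else np.asarray(pred, float)
    if t.shape != p.shape:
        raise ValueError(f"shape mismatch: truth {t.shape} vs prediction {p.shape}")
    labels = (_offdiag(t) != 0).astype(int)
    scores = np.abs(_offdiag(p))
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError(
            "AUROC/AUPRC undefined: ground truth has no off-diagonal "
            + ("positives" if n_pos == 0 else "negatives")
        )
    return EvalResult(
        auroc=float(roc_auc_score(labels, scores)),
        auprc=float(average_precision_score(labels, scores)),
        n_positives=n_pos,
        n_negatives=n_neg,
    )


def benchmark(
    methods: dict[str, Callable],
    test_corpus,
) -> pd.DataFrame:
    """Score every method on every corpus sample.

    ``methods`` maps a label to a callable taking a (grn, SnapshotDataset)
    sample and returning an InferredGRN or score matrix.  Per-method
    failures are recorded as NaN rows; the sweep never aborts.  Returns a
    tidy frame with columns (sample, method, auroc, auprc).
    """
    rows = []
    for idx, (grn, data) in enumerate(test_corpus):
        truth = grn if grn is not None else data.grn
        for label, fn in methods.items():
            try:
                pred = fn((grn, data))
                res = score_grn(truth, pred)
                rows.append((idx, label, res.auroc, res.auprc))
            except Exception:
                rows.append((idx, label, np.nan, np.nan))
    return pd.DataFrame(rows, columns=["sample", "method", "auroc", "auprc"])


def total_score(per_dataset: pd.DataFrame) -> pd.Series:
    """Sum of mean AUROC and mean AUPRC per method across datasets."""
    means = per_dataset.groupby("method")[["auroc", "auprc"]].mean()
    return means.sum(axis=1)
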