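"""Gene-signature KNN classification with leave-one-out cross-validation.

Each sample is predicted from all the others: distances are computed on
the signature genes only, the k nearest neighbours vote, and the
majority class wins.  Per-gene standardization (z-scoring) is recomputed
from the training fold for every left-out sample, so the held-out sample
never influences its own scaling.  Robustness to the choice of k is
summarized by sweeping k and reporting the accuracy spread.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import ExpressionDataset
from .preprocess import GeneSignature

logger = logging.getLogger(__name__)


class ClassificationError(ValueError):
    pass


@dataclass
class ClassificationReport:
    """LOOCV results: confusion matrix (rows true, columns predicted),
    per-class sensitivity/specificity, accuracy per k, per-sample votes."""

    confusion: pd.DataFrame
    per_class: pd.DataFrame
    per_k_accuracy: pd.DataFrame
    per_sample_vote: pd.DataFrame
    headline_k: int

    @property
    def accuracy(self) -> float:
        total = self.confusion.to_numpy().sum()
        return float(np.trace(self.confusion.to_numpy()) / total)

    @property
    def accuracy_sd_over_k(self) -> float | None:
        """Stdev of accuracy over the swept k values; None for a single k."""
        accs = self.per_k_accuracy["accuracy"].tolist()
        if len(accs) < 2:
            return None
        return float(statistics.stdev(accs))

    def to_frame(self) -> pd.DataFrame:
        """Flat tabular summary (one row per class + per k) for TSV export."""
        rows = [
            {"section": "per_class", "key": r.Index, "sensitivity": r.sensitivity,
             "specificity": r.specificity}
            for r in self.per_class.itertuples()
        ]
        rows += [
            {"section": "per_k", "key": int(r.k), "accuracy": r.accuracy}
            for r in self.per_k_accuracy.itertuples()
        ]
        return pd.DataFrame(rows)


def _signature_matrix(
    data: ExpressionDataset, signature: GeneSignature
) -> np.ndarray:
    present = [g for g in signature.members if g in data.values.index]
    n_missing = len(signature.members) - len(present)
    if n_missing:
        logger.info(
            "signature %r: %d member(s) absent from the matrix, dropped",
            signature.name, n_missing,
        )
    if not present:
        raise ClassificationError(
            f"signature {signature.name!r} shares no genes with the matrix"
        )
    return data.values.loc[present].to_numpy().T  # samples × genes


def _loocv_predict(
    X: np.ndarray, labels: np.ndarray, k: int, standardize: bool
) -> tuple[np.ndarray, np.ndarray]:
    """Predict each sample from the rest; returns (predictions, vote_fractions)."""
    n = X.shape[0]
    preds = np.empty(n, dtype=object)
    votes = np.empty(n, dtype=float)
    for i in range(n):
        train = np.delete(np.arange(n), i)
        Xt, Xq = X[train], X[i]
        if standardize:
            mu = Xt.mean(axis=0)
            sd = Xt.std(axis=0, ddof=1)
            sd = np.where(sd == 0, 1.0, sd)
            Xt = (Xt - mu) / sd
            Xq = (Xq - mu) / sd
        dist = np.sqrt(((Xt - Xq) ** 2).sum(axis=1))
        order = np.argsort(dist, kind="stable")  # distance ties → sample order
        nearest = order[:k]
        nn_labels = labels[train][nearest]
        classes, counts = np.unique(nn_labels, return_counts=True)
        top = counts.max()
        tied = [c for c, ct in zip(classes, counts) if ct == top]
        if len(tied) == 1:
            winner = tied[0]
        else:
            # vote tie: smallest mean distance among tied classes, then label
            mean_d = {c: dist[nearest][nn_labels == c].mean() for c in tied}
            best = min(mean_d.values())
            winner = min(c for c, m in mean_d.items() if m == best)
        preds[i] = winner
        votes[i] = top / k
    return preds, votes


def knn_loocv(
    data: ExpressionDataset,
    signature: GeneSignature,
    labels: pd.Series,
    k: int = 5,
    standardize: bool = True,
) -> ClassificationReport:
    """Leave-one-out KNN classification on signature genes.

    Parameters
    ----------
    labels
        Per-sample class, indexed like the dataset's samples (any
        annotation column works: ``data.annotation["disease"]``).
    k
        Neighbourhood size; the common sweep is k in 3..9.
    standardize
        Per-gene z-scoring with statistics from the training fold
        (recommended; prevents high-variance genes dominating the
        Euclidean metric).
    """
    return k_sweep(data, signature, labels, [k], standardize=standardize)


def k_sweep(
    data: ExpressionDataset,
    signature: GeneSignature,
    labels: pd.Series,
    k_values,
    standardize: bool = True,
) -> ClassificationReport:
    """Run LOOCV over several k; headline confusion taken at the median k.

    For an even number of k values the lower middle is used, keeping the
    headline k one actually swept.
    """
    k_values = sorted(int(k) for k in k_values)
    if not k_values:
        raise ClassificationError("k_values must be non-empty")
    y = labels.reindex(data.samples)
    if y.isna().any():
        missing = y.index[y.isna()][0]
        raise ClassificationError(f"no class label for sample {missing!r}")
    y = y.astype(str).to_numpy()
    classes = sorted(set(y))
    if len(classes) < 2:
        raise ClassificationError("need >= 2 classes")
    n = len(y)
    for k in k_values:
        if not 1 <= k < n:
            raise ClassificationError(f"k={k} out of range for {n} samples")
    _, class_counts = np.unique(y, return_counts=True)
    if (class_counts == 1).any() and max(k_values) >= n - 1:
        logger.warning(
            "a singleton class with k >= n-1: that sample can never be "
            "predicted correctly (it cannot vote for itself)"
        )

    X = _signature_matrix(data, signature)
    per_k = []
    results: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for k in k_values:
        preds, votes = _loocv_predict(X, y, k, standardize)
        results[k] = (preds, votes)
        per_k.append({"k": k, "accuracy": float((preds == y).mean())})

    headline_k = k_values[(len(k_values) - 1) // 2]
    preds, votes = results[headline_k]

    confusion = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    for true, pred in zip(y, preds):
        confusion.loc[true, pred] += 1
    total = confusion.to_numpy().sum()
    per_class_rows = []
    for c in classes:
        tp = confusion.loc[c, c]
        pos = confusion.loc[c].sum()
        fp = confusion[c].sum() - tp
        neg = total - pos
        per_class_rows.append({
            "class": c,
            "sensitivity": tp / pos if pos else np.nan,
            "specificity": (neg - fp) / neg if neg else np.nan,
        })
    per_class = pd.DataFrame(per_class_rows).set_index("class")

    per_sample = pd.DataFrame({
        "sample_id": data.samples,
        "true_class": y,
        "predicted_class": preds.astype(str),
        "vote_fraction": votes,
    }).set_index("sample_id")

    return ClassificationReport(
        confusion=confusion,
        per_class=per_class,
        per_k_accuracy=pd.DataFrame(per_k),
        per_sample_vote=per_sample,
        headline_k=headline_k,
    )
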