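"""In-silico validation: per-gene random-forest AUC under cross-validation.

Each candidate gene is scored by a random-forest classifier (500 trees,
``mtry = max(1, ceil(sqrt(p)))``) trained on that gene's expression alone
under stratified k-fold cross-validation (k = 10 by default).  Out-of-fold
tumour-class probabilities are pooled across folds and summarised as a
single ROC AUC per gene; genes are then ranked by AUC (ties broken by gene
symbol) for top-k reporting.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .datatypes import NORMAL, TUMOUR, ExpressionMatrix, SampleLabels

__all__ = [
    "RFConfig",
    "AucRecord",
    "stratified_folds",
    "per_gene_auc",
    "auc_table",
    "rank_top_k",
    "rank_band_mean_auc",
]


@dataclass
class RFConfig:
    """Random-forest and cross-validation settings."""

    n_trees: int = 500
    mtry_rule: str = "sqrt_p"
    n_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.mtry_rule != "sqrt_p":
            raise ValueError(f"unknown mtry rule {self.mtry_rule!r}")

    def mtry(self, p: int) -> int:
        return max(1, math.ceil(math.sqrt(p)))


@dataclass(frozen=True)
class AucRecord:
    """Cross-validated AUC of one gene's expression as a tumour classifier."""

    gene: str
    auc: float
    n_positive: int
    n_negative: int


def _ordered_samples_and_y(
    labels: SampleLabels, samples: Sequence[str]
) -> tuple[list[str], np.ndarray]:
    labelled = [s for s in samples if s in labels.labels.index]
    y = np.array([1 if labels.labels[s] == TUMOUR else 0 for s in labelled])
    return labelled, y


def stratified_folds(
    labels: SampleLabels, k: int, seed: int
) -> list[set[str]]:
    """Partition sample ids into k class-stratified folds, deterministically.

    If the smaller class has fewer than k members, k is reduced to that
    class size with a warning; an empty class is an error.
    """
    counts = labels.class_counts()
    if counts[NORMAL] == 0 or counts[TUMOUR] == 0:
        raise ValueError(f"both classes required; got {counts}")
    smallest = min(counts.values())
    if smallest < k:
        warnings.warn(
            f"reducing n_folds from {k} to {smallest} (smallest class size)",
            stacklevel=2,
        )
        k = smallest
    if k < 2:
        raise ValueError("cannot cross-validate with fewer than 2 folds")
    samples = sorted(labels.samples)
    _, y = _ordered_samples_and_y(labels, samples)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [
        {samples[i] for i in test_idx}
        for _, test_idx in skf.split(np.zeros(len(samples)), y)
    ]


def per_gene_auc(
    expr: ExpressionMatrix,
    labels: SampleLabels,
    gene: str,
    config: RFConfig | None = None,
) -> AucRecord:
    """Pooled out-of-fold AUC of a single-gene random-forest classifier.

    A gene constant across all samples carries no class signal; its AUC is
    defined as 0.5 with a warning.
    """
    config = config or RFConfig()
    if gene not in expr.counts.index:
        raise KeyError(f"gene {gene!r} not in expression matrix")
    samples, y = _ordered_samples_and_y(labels, sorted(expr.samples))
    if len(samples) < len(labels):
        warnings.warn("some labelled samples are absent from the matrix", stacklevel=2)
    n_pos, n_neg = int(y.sum()), int((y == 0).sum())
    values = expr.counts.loc[gene, samples].to_numpy(dtype=float)
    if np.ptp(values) == 0:
        warnings.warn(f"gene {gene!r} is constant; AUC defined as 0.5", stacklevel=2)
        return AucRecord(gene=gene, auc=0.5, n_positive=n_pos, n_negative=n_neg)

    folds = stratified_folds(
        SampleLabels(labels=labels.labels.loc[samples]), config.n_folds, config.seed
    )
    sample_pos = {s: i for i, s in enumerate(samples)}
    scores = np.empty(len(samples))
    X = values.reshape(-1, 1)
    for fold_idx, test_samples in enumerate(folds):
        test = np.array([sample_pos[s] for s in sorted(test_samples)])
        train = np.setdiff1d(np.arange(len(samples)), test)
        clf = RandomForestClassifier(
            n_estimators=config.n_trees,
            max_features=config.mtry(X.shape[1]),
            random_state=config.seed * 1000 + fold_idx,
            n_jobs=1,
        )
        clf.fit(X[train], y[train])
        proba = clf.predict_proba(X[test])
        tumour_col = list(clf.classes_).index(1)
        scores[test] = proba[:, tumour_col]
    auc = float(roc_auc_score(y, scores))
    return AucRecord(gene=gene, auc=auc, n_positive=n_pos, n_negative=n_neg)


def auc_table(
    expr: ExpressionMatrix,
    labels: SampleLabels,
    genes: Iterable[str],
    config: RFConfig | None = None,
) -> list[AucRecord]:
    """Per-gene AUC records for every requested gene present in the matrix."""
    config = config or RFConfig()
    present = set(expr.counts.index)
    return [per_gene_auc(expr, labels, g, config) for g in sorted(genes) if g in present]


def rank_top_k(records: Iterable[AucRecord], k: int = 10) -> list[AucRecord]:
    """Top-k records by descending AUC, ties broken by ascending gene symbol."""
    if k < 1:
        raise ValueError("k must be >= 1")
    ranked = sorted(records, key=lambda r: (-r.auc, r.gene))
    return ranked[:k]


def rank_band_mean_auc(records: Sequence[AucRecord], lo: int, hi: int) -> float:
    """Mean AUC over the 1-indexed rank band [lo, hi] of the full ranking."""
    records = list(records)
    if not (1 <= lo <= hi <= len(records)):
        raise ValueError(
            f"band [{lo}, {hi}] outside the 1..{len(records)} rank range"
        )
    ranked = sorted(records, key=lambda r: (-r.auc, r.gene))
    band = ranked[lo - 1 : hi]
    return float(np.mean([r.auc for r in band]))


def auc_records_to_frame(records: Iterable[AucRecord]) -> pd.DataFrame:
    ranked = sorted(records, key=lambda r: (-r.auc, r.gene))
    return pd.DataFrame(
        {
            "gene": [r.gene for r in ranked],
            "auc": [r.auc for r in ranked],
            "rank": np.arange(1, len(ranked) + 1),
            "n_positive": [r.n_positive for r in ranked],
            "n_negative": [r.n_negative for r in ranked],
        }
    )
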