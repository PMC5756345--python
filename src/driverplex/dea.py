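"""Differential expression between normal and tumour sample classes.

Counts are normalised to log2 counts-per-million with a pseudo-count of 1,
tested per gene with a two-sided Welch t-test, and adjusted with the
Benjamini–Hochberg step-up procedure.  A gene is flagged as differentially
expressed when ``|logFC| > 1`` and ``FDR < 0.01`` (both strict, both
configurable), with logFC defined as tumour minus normal on the log2 scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import NORMAL, TUMOUR, ExpressionMatrix, SampleLabels

__all__ = [
    "DEGTable",
    "normalize_counts",
    "differential_test",
    "bh_adjust",
    "select_degs",
    "run_dea",
]


@dataclass
class DEGTable:
    """Per-gene differential expression results for one condition.

    ``df`` columns: gene, log_fc, p_value, fdr, is_deg.
    """

    condition_id: str
    df: pd.DataFrame

    def __post_init__(self) -> None:
        if self.df["gene"].duplicated().any():
            raise ValueError("duplicate genes in DEG table")

    @property
    def degs(self) -> set[str]:
        return set(self.df.loc[self.df["is_deg"], "gene"])

    @property
    def genes(self) -> set[str]:
        return set(self.df["gene"])

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, condition_id: str | None = None) -> "DEGTable":
        path = Path(path)
        df = pd.read_csv(path, sep="\t")
        return cls(condition_id=condition_id or path.stem, df=df)


def normalize_counts(matrix: ExpressionMatrix) -> pd.DataFrame:
    """log2 counts-per-million with pseudo-count 1.

    ``value(g, s) = log2(1e6 * (count + 1) / (libsize_s + n_genes))`` where
    the library size is the raw column sum; the ``+ n_genes`` in the
    denominator accounts for the pseudo-count added to every gene.
    """
    counts = matrix.counts
    if counts.shape[1] < 1:
        raise ValueError("need at least one sample")
    libsize = counts.sum(axis=0)
    zero = libsize.index[libsize == 0].tolist()
    if zero:
        raise ValueError(f"sample(s) with all-zero counts: {zero}")
    n_genes = counts.shape[0]
    cpm = 1e6 * (counts + 1).div(libsize + n_genes, axis=1)
    return np.log2(cpm)


def differential_test(norm: pd.DataFrame, labels: SampleLabels) -> pd.DataFrame:
    """Per-gene log2 fold change and Welch t-test p-value (tumour vs normal).

    Genes with zero variance in both classes are assigned p = 1 (and logFC
    from the class means, 0 for a globally constant gene).  Requires at
    least two samples per class.
    """
    normal_ids = [s for s in labels.samples_of(NORMAL) if s in norm.columns]
    tumour_ids = [s for s in labels.samples_of(TUMOUR) if s in norm.columns]
    missing = [s for s in labels.samples if s not in norm.columns]
    if missing:
        warnings.warn(
            f"{len(missing)} labelled sample(s) absent from the matrix; ignored",
            stacklevel=2,
        )
    if len(normal_ids) < 2 or len(tumour_ids) < 2:
        raise ValueError(
            f"need >=2 samples per class; got {len(normal_ids)} normal, "
            f"{len(tumour_ids)} tumour"
        )
    a = norm[tumour_ids].to_numpy()
    b = norm[normal_ids].to_numpy()
    log_fc = a.mean(axis=1) - b.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    degenerate = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)
    p[degenerate] = 1.0
    p = np.clip(p, 0.0, 1.0)
    return pd.DataFrame(
        {"gene": norm.index, "log_fc": log_fc, "p_value": p}
    ).reset_index(drop=True)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def select_degs(
    test_output: pd.DataFrame,
    condition_id: str = "condition",
    logfc_thr: float = 1.0,
    fdr_thr: float = 0.01,
) -> DEGTable:
    """Flag DEGs: ``|logFC| > logfc_thr`` and ``FDR < fdr_thr`` (strict)."""
    if logfc_thr <= 0 or fdr_thr <= 0:
        raise ValueError("thresholds must be positive")
    df = test_output.copy()
    df["fdr"] = bh_adjust(df["p_value"].to_numpy())
    df["is_deg"] = (df["log_fc"].abs() > logfc_thr) & (df["fdr"] < fdr_thr)
    return DEGTable(condition_id=condition_id, df=df)


def run_dea(
    matrix: ExpressionMatrix,
    labels: SampleLabels,
    condition_id: str = "condition",
    logfc_thr: float = 1.0,
    fdr_thr: float = 0.01,
) -> DEGTable:
    """Full DEA stage: drop all-zero genes, normalise, test, adjust, flag."""
    counts = matrix.counts
    nonzero = counts.sum(axis=1) > 0
    n_dropped = int((~nonzero).sum())
    if n_dropped:
        warnings.warn(
            f"dropped {n_dropped} gene(s) with all-zero counts before testing",
            stacklevel=2,
        )
        matrix = ExpressionMatrix(counts=counts.loc[nonzero])
    norm = normalize_counts(matrix)
    tested = differential_test(norm, labels)
    return select_degs(tested, condition_id, logfc_thr=logfc_thr, fdr_thr=fdr_thr)
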