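"""Quality control and log-normalization.

Cells with fewer than 200 or more than 6,000 detected genes, or more
than 10% mitochondrial counts, are excluded (strict inequalities:
boundary cells are retained).  Normalization is
log(1 + scale_factor * count / cell_total) with the natural log and a
scale factor of 10,000.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import sparse

from .io import CountMatrix, NormalizedMatrix

log = logging.getLogger(__name__)


def qc_metrics(counts: CountMatrix, annotation: pd.DataFrame) -> pd.DataFrame:
    """Per-cell detected-gene counts and mitochondrial fraction."""
    missing = set(counts.gene_ids) - set(annotation.index)
    if missing:
        raise ValueError(f"annotation missing {len(missing)} genes")
    X = counts.X.tocsc()
    n_detected = np.asarray((X > 0).sum(axis=0)).ravel()
    totals = np.asarray(X.sum(axis=0)).ravel().astype(float)
    mito = annotation.reindex(counts.gene_ids)["is_mitochondrial"].to_numpy()
    mito_counts = np.asarray(X[mito, :].sum(axis=0)).ravel().astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, mito_counts / np.maximum(totals, 1e-300), 0.0)
    return pd.DataFrame(
        {"n_genes_detected": n_detected, "mito_fraction": mito_frac,
         "total_counts": totals},
        index=pd.Index(counts.cell_ids, name="cell_id"),
    )


def qc_filter(
    counts: CountMatrix,
    annotation: pd.DataFrame,
    min_genes: int = 200,
    max_genes: int = 6000,
    max_mito: float = 0.10,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Filter cells at the stated thresholds.

    Retains cells with min_genes <= detected <= max_genes and
    mito_fraction <= max_mito.  Returns the filtered matrix and a QC
    report covering every input cell with its metrics, pass flag and
    failure reason.
    """
    if counts.n_cells == 0 or counts.n_genes == 0:
        raise ValueError("empty count matrix")
    if min(min_genes, max_genes) <= 0 or max_mito <= 0:
        raise ValueError("thresholds must be positive")
    report = qc_metrics(counts, annotation)
    too_few = report["n_genes_detected"] < min_genes
    too_many = report["n_genes_detected"] > max_genes
    high_mito = report["mito_fraction"] > max_mito
    report["pass"] = ~(too_few | too_many | high_mito)
    reason = np.select(
        [too_few, too_many, high_mito],
        ["too_few_genes", "too_many_genes", "high_mito"],
        default="",
    )
    report["reason"] = reason
    if not report["pass"].any():
        warnings.warn("all cells removed by QC", stacklevel=2)
    filtered = counts.subset_cells(report["pass"].to_numpy())
    log.info("QC retained %d / %d cells", filtered.n_cells, counts.n_cells)
    return filtered, report


def normalize(counts: CountMatrix, scale_factor: float = 10_000.0) -> NormalizedMatrix:
    """Library-size normalize and log-transform.

    value = ln(1 + scale_factor * count / cell_total); zeros map to
    zero, so sparsity is preserved.
    """
    X = counts.X.tocsc().astype(float)
    totals = np.asarray(X.sum(axis=0)).ravel()
    if np.any(totals <= 0):
        bad = int((totals <= 0).sum())
        raise ValueError(f"{bad} cell(s) with zero total counts; run QC first")
    X = X.multiply(scale_factor / totals[None, :]).tocsc()
    X.data = np.log1p(X.data)
    return NormalizedMatrix(
        sparse.csr_matrix(X), counts.gene_ids, counts.cell_ids,
        scale_factor=scale_factor, log_base="e",
    )
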