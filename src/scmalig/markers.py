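"""One-vs-rest differential expression with rank-sum tests.

Per (gene, cluster): expression fractions inside/outside the cluster, a
log2 fold change on de-logged means with a pseudocount of 1, a Wilcoxon
rank-sum p-value, and Benjamini-Hochberg adjustment across all tested
pairs.  Default filters: min.pct 0.25, log-fold threshold 0.25,
positive effects only, adjusted p < 0.05.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import NormalizedMatrix
from .stats import _EXACT_ENUM_LIMIT, _exact_rank_sum_pvalue, benjamini_hochberg

log = logging.getLogger(__name__)


def _fold_change(mean_in, mean_out, base: str = "log2"):
    """Fold change on de-logged (expm1) means with pseudocount 1."""
    ratio = (mean_in + 1.0) / (mean_out + 1.0)
    return np.log2(ratio) if base == "log2" else np.log(ratio)


def rank_markers(
    norm: NormalizedMatrix,
    cluster_labels: pd.Series,
    logfc_thresh: float = 0.25,
    min_pct: float = 0.25,
    only_pos: bool = True,
    alpha: float = 0.05,
    fc_base: str = "log2",
    adjust: str = "bh",
    exact_max_n: int = 8,
) -> pd.DataFrame:
    """One-vs-rest marker detection across clusters.

    For every cluster with >= 3 cells: pct_in / pct_out are the
    fractions of cells with expression > 0 inside / outside the
    cluster; genes with max(pct_in, pct_out) >= min_pct and a fold
    change past ``logfc_thresh`` (positive only when ``only_pos``) are
    tested by Wilcoxon rank-sum; p-values are adjusted jointly across
    all tested (gene, cluster) pairs and rows with p_adjusted < alpha
    are returned, sorted by cluster then adjusted p.
    """
    if adjust not in ("bh", "bonferroni"):
        raise ValueError("adjust must be 'bh' or 'bonferroni'")
    labels = cluster_labels.reindex(norm.cell_ids)
    if labels.isna().any():
        raise ValueError("every cell needs a cluster label")
    uniq = sorted(pd.unique(labels), key=str)
    if len(uniq) < 2:
        raise ValueError("need at least two clusters")
    X = np.asarray(norm.X.todense(), dtype=float)
    expm1 = np.expm1(X)
    rows = []
    for cl in uniq:
        in_mask = (labels == cl).to_numpy()
        n_in = int(in_mask.sum())
        n_out = X.shape[1] - n_in
        if n_in < 3:
            warnings.warn(f"cluster {cl!r} has {n_in} cells; skipped", stacklevel=2)
            continue
        if n_out == 0:
            continue
        pct_in = (X[:, in_mask] > 0).mean(axis=1)
        pct_out = (X[:, ~in_mask] > 0).mean(axis=1)
        lfc = _fold_change(
            expm1[:, in_mask].mean(axis=1), expm1[:, ~in_mask].mean(axis=1), fc_base
        )
        keep = np.maximum(pct_in, pct_out) >= min_pct
        keep &= (lfc >= logfc_thresh) if only_pos else (np.abs(lfc) >= logfc_thresh)
        gidx = np.flatnonzero(keep)
        if gidx.size == 0:
            continue
        x_in = X[np.ix_(gidx, in_mask)]
        x_out = X[np.ix_(gidx, ~in_mask)]
        small = min(n_in, n_out)
        use_exact = small <= exact_max_n and _comb_ok(n_in + n_out, small)
        if use_exact:
            pvals = np.array(
                [_exact_rank_sum_pvalue(x_in[i], x_out[i]) for i in range(gidx.size)]
            )
        else:
            pvals = sps.mannwhitneyu(
                x_in, x_out, axis=1, alternative="two-sided", method="asymptotic"
            ).pvalue
        for i, g in enumerate(gidx):
            rows.append(
                (
                    norm.gene_ids[g], cl, float(lfc[g]),
                    float(pct_in[g]), float(pct_out[g]), float(pvals[i]),
                )
            )
    table = pd.DataFrame(
        rows,
        columns=["gene", "cluster", "log2_fold_change", "pct_in", "pct_out", "p_value"],
    )
    if table.empty:
        table["p_adjusted"] = pd.Series(dtype=float)
        return table
    if adjust == "bh":
        table["p_adjusted"] = benjamini_hochberg(table["p_value"].to_numpy())
    else:
        table["p_adjusted"] = np.minimum(table["p_value"] * len(table), 1.0)
    table = table[table["p_adjusted"] < alpha]
    table = table.sort_values(["cluster", "p_adjusted", "gene"], kind="stable")
    return table.reset_index(drop=True)


def _comb_ok(n: int, k: int) -> bool:
    import math

    return math.comb(n, k) <= _EXACT_ENUM_LIMIT
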