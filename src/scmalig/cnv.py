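"""Expression-based CNV inference against a normal reference.

The procedure follows the standard single-cell CNV-from-expression
recipe: order genes along the genome, subtract the reference-cell mean
per gene, clip extreme residuals, smooth with a moving average inside
each chromosome (truncated windows at the edges, so chromosomes never
mix), recenter each cell at its median, and finally subtract the mean
smoothed profile of the reference cells so that reference residuals
center on zero.  A per-cell CNV score summarizes the residual profile
as the mean squared residual.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import NormalizedMatrix

log = logging.getLogger(__name__)


def _chrom_sort_key(name: str):
    """Natural chromosome order: chr1 < chr2 < ... < chr10 < chrX < chrM."""
    m = re.match(r"(?:chr)?(\d+|[A-Za-z]+)$", str(name))
    token = m.group(1) if m else str(name)
    if token.isdigit():
        return (0, int(token), "")
    special = {"X": 0, "Y": 1, "M": 2, "MT": 2}
    return (1, special.get(token.upper(), 9), token.upper())


def order_genes(annotation: pd.DataFrame) -> pd.DataFrame:
    """Position-ordered gene index: stable sort by (chromosome, start).

    Genes lacking chromosome or start are dropped with a logged count.
    Returns the annotation rows in genome order.
    """
    if annotation.empty:
        raise ValueError("empty annotation")
    ok = annotation["chromosome"].notna() & annotation["start"].notna()
    dropped = int((~ok).sum())
    if dropped:
        log.warning("dropping %d genes without coordinates", dropped)
    ann = annotation.loc[ok].copy()
    ann["_ckey"] = [_chrom_sort_key(c) for c in ann["chromosome"]]
    ann = ann.sort_values(["_ckey", "start"], kind="stable").drop(columns="_ckey")
    return ann


@dataclass
class CNVProfile:
    """Genome-ordered residual CNV values plus bookkeeping.

    values: ordered genes x cells, 0 = copy-neutral.
    gene_index: annotation rows in genome order (defines chromosome
    boundaries).  reference_cells: ids of the normal reference.
    """

    values: np.ndarray
    gene_index: pd.DataFrame
    cell_ids: np.ndarray
    reference_cells: list
    clip: float
    window: int

    @property
    def gene_ids(self) -> np.ndarray:
        return self.gene_index.index.to_numpy()

    def chromosome_blocks(self) -> list:
        """(chromosome, start_row, end_row) half-open blocks in order."""
        chroms = self.gene_index["chromosome"].to_numpy()
        blocks = []
        start = 0
        for i in range(1, len(chroms) + 1):
            if i == len(chroms) or chroms[i] != chroms[start]:
                blocks.append((chroms[start], start, i))
                start = i
        return blocks


def relative_expression(
    norm: NormalizedMatrix,
    reference_cells,
    clip: float = 3.0,
) -> np.ndarray:
    """Center each gene at its reference-cell mean and clip to [-clip, clip].

    Returns a dense genes x cells array in the gene order of ``norm``.
    """
    ref = [c for c in reference_cells if c in set(norm.cell_ids)]
    if not ref:
        raise ValueError("reference set empty after intersecting with matrix")
    X = np.asarray(norm.X.todense(), dtype=float)
    pos = {c: i for i, c in enumerate(norm.cell_ids)}
    ref_idx = np.array([pos[c] for c in ref], dtype=int)
    centered = X - X[:, ref_idx].mean(axis=1, keepdims=True)
    np.clip(centered, -clip, clip, out=centered)
    return centered


def _moving_average_block(block: np.ndarray, window: int) -> np.ndarray:
    """Column-wise moving average with truncated (shrinking) edge windows."""
    n = block.shape[0]
    half = window // 2
    cs = np.vstack([np.zeros((1, block.shape[1])), np.cumsum(block, axis=0)])
    hi = np.minimum(np.arange(n) + half + 1, n)
    lo = np.maximum(np.arange(n) - half, 0)
    sums = cs[hi, :] - cs[lo, :]
    return sums / (hi - lo)[:, None]


def smooth_genome(
    centered: np.ndarray,
    ordered_index: pd.DataFrame,
    window: int = 101,
) -> np.ndarray:
    """Per-chromosome moving average along the genome.

    Each chromosome is smoothed independently (truncated windows at the
    edges), so a gene's smoothed value never depends on another
    chromosome.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    if centered.shape[0] != len(ordered_index):
        raise ValueError("matrix rows do not match ordered gene index")
    chroms = ordered_index["chromosome"].to_numpy()
    smoothed = np.empty_like(centered, dtype=float)
    start = 0
    max_block = 0
    for i in range(1, len(chroms) + 1):
        if i == len(chroms) or chroms[i] != chroms[start]:
            block = centered[start:i, :]
            max_block = max(max_block, i - start)
            smoothed[start:i, :] = _moving_average_block(block, window)
            start = i
    if window > max_block:
        log.warning(
            "window %d exceeds every chromosome (max %d genes); "
            "all windows are truncated", window, max_block,
        )
    return smoothed


def smooth_and_center(
    centered: np.ndarray,
    ordered_index: pd.DataFrame,
    cell_ids,
    reference_cells,
    window: int = 101,
    clip: float = 3.0,
) -> CNVProfile:
    """Smooth within chromosomes, recenter per cell, re-zero the reference.

    ``centered`` rows must already be in the genome order given by
    ``ordered_index``.  Steps: per-chromosome moving average of length
    ``window`` (edges use truncated windows), per-cell median
    subtraction, then subtraction of the mean reference-cell profile so
    reference residuals center on zero.
    """
    smoothed = smooth_genome(centered, ordered_index, window=window)
    smoothed -= np.median(smoothed, axis=0, keepdims=True)
    cell_ids = np.asarray(cell_ids, dtype=object)
    pos = {c: i for i, c in enumerate(cell_ids)}
    ref = [c for c in reference_cells if c in pos]
    if not ref:
        raise ValueError("no reference cells present")
    ref_idx = np.array([pos[c] for c in ref], dtype=int)
    smoothed -= smoothed[:, ref_idx].mean(axis=1, keepdims=True)
    return CNVProfile(
        values=smoothed,
        gene_index=ordered_index,
        cell_ids=cell_ids,
        reference_cells=list(ref),
        clip=clip,
        window=window,
    )


def cnv_score(profile: CNVProfile, method: str = "mean_square") -> pd.Series:
    """Per-cell CNV score: mean (default) or sum of squared residuals.

    Zero iff the cell's residual profile is identically zero.
    """
    if profile.values.shape[0] == 0:
        raise ValueError("profile has zero genes")
    if not np.all(np.isfinite(profile.values)):
        raise ValueError("profile contains non-finite values")
    sq = profile.values**2
    if method == "mean_square":
        s = sq.mean(axis=0)
    elif method == "sum_square":
        s = sq.sum(axis=0)
    else:
        raise ValueError(f"unknown CNV score method {method!r}")
    return pd.Series(s, index=pd.Index(profile.cell_ids, name="cell_id"),
                     name="cnv_score")


def infer_cnv(
    norm: NormalizedMatrix,
    annotation: pd.DataFrame,
    reference_cells,
    window: int = 101,
    clip: float = 3.0,
    include_mito: bool = False,
) -> CNVProfile:
    """Full CNV inference: order genes, center on the reference, clip,
    smooth, recenter.

    Mitochondrial genes are excluded by default: their abundance tracks
    cell quality, not copy number.
    """
    ann = annotation.loc[annotation.index.intersection(norm.gene_ids)]
    if not include_mito and "is_mitochondrial" in ann:
        ann = ann.loc[~ann["is_mitochondrial"].astype(bool)]
    ordered = order_genes(ann)
    sub_idx = [norm.gene_index()[g] for g in ordered.index]
    sub = NormalizedMatrix(
        norm.X[sub_idx, :], ordered.index.to_numpy(), norm.cell_ids,
        norm.scale_factor, norm.log_base,
    )
    centered = relative_expression(sub, reference_cells, clip=clip)
    return smooth_and_center(
        centered, ordered, norm.cell_ids, reference_cells,
        window=window, clip=clip,
    )
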