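"""Data containers and on-disk formats.

Expression matrices travel as genes x cells Matrix Market files with
``genes.tsv`` / ``cells.tsv`` sidecars (10x-style triplet layout); gene
sets as GMT; ground truth as JSON.  Everything here is deliberately
plain text so that cohorts round-trip byte-identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

GENE_COLUMNS = ["gene_id", "chromosome", "start", "is_mitochondrial"]
CELL_COLUMNS = ["cell_id", "sample_id", "group", "clone_id", "subtype", "cluster"]


@dataclass
class CountMatrix:
    """Raw genes x cells counts with aligned identifiers."""

    X: sparse.csr_matrix  # genes x cells, non-negative integers
    gene_ids: np.ndarray
    cell_ids: np.ndarray

    def __post_init__(self):
        self.X = sparse.csr_matrix(self.X)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if self.X.shape != (self.gene_ids.size, self.cell_ids.size):
            raise ValueError(
                f"matrix shape {self.X.shape} does not match "
                f"{self.gene_ids.size} genes x {self.cell_ids.size} cells"
            )
        if len(set(self.gene_ids)) != self.gene_ids.size:
            raise ValueError("gene ids not unique")
        if len(set(self.cell_ids)) != self.cell_ids.size:
            raise ValueError("cell ids not unique")
        if self.X.nnz and self.X.data.min() < 0:
            raise ValueError("negative counts")

    @property
    def n_genes(self) -> int:
        return self.gene_ids.size

    @property
    def n_cells(self) -> int:
        return self.cell_ids.size

    def subset_cells(self, mask_or_ids) -> "CountMatrix":
        idx = _cell_indexer(self.cell_ids, mask_or_ids)
        return CountMatrix(self.X[:, idx], self.gene_ids, self.cell_ids[idx])


@dataclass
class NormalizedMatrix:
    """Log-normalized genes x cells expression.

    value = log(1 + scale_factor * count / cell_total), natural log.
    """

    X: sparse.csr_matrix
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    scale_factor: float = 10_000.0
    log_base: str = "e"

    def __post_init__(self):
        self.X = sparse.csr_matrix(self.X)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)

    @property
    def n_genes(self) -> int:
        return self.gene_ids.size

    @property
    def n_cells(self) -> int:
        return self.cell_ids.size

    def gene_index(self) -> dict:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def subset_cells(self, mask_or_ids) -> "NormalizedMatrix":
        idx = _cell_indexer(self.cell_ids, mask_or_ids)
        return NormalizedMatrix(
            self.X[:, idx], self.gene_ids, self.cell_ids[idx],
            self.scale_factor, self.log_base,
        )


def _cell_indexer(cell_ids: np.ndarray, mask_or_ids) -> np.ndarray:
    arr = np.asarray(mask_or_ids)
    if arr.dtype == bool:
        if arr.size != cell_ids.size:
            raise ValueError("boolean mask length mismatch")
        return np.flatnonzero(arr)
    pos = {c: i for i, c in enumerate(cell_ids)}
    try:
        return np.array([pos[c] for c in arr], dtype=int)
    except KeyError as e:  # pragma: no cover - defensive
        raise KeyError(f"unknown cell id {e.args[0]!r}") from None


@dataclass
class GeneSet:
    """A named gene list for module scoring."""

    name: str
    genes: list = field(default_factory=list)

    def __post_init__(self):
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def write_cohort(
    outdir,
    counts: CountMatrix,
    annotation: pd.DataFrame,
    cells: pd.DataFrame,
    truth: dict | None = None,
) -> None:
    """Write counts as MTX plus genes.tsv / cells.tsv (and truth.json)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(str(outdir / "matrix.mtx"), counts.X.tocoo(), field="integer")
    ann = annotation.reindex(counts.gene_ids)
    genes = pd.DataFrame(
        {
            "gene_id": counts.gene_ids,
            "chromosome": ann["chromosome"].to_numpy(),
            "start": ann["start"].to_numpy(),
            "is_mitochondrial": ann["is_mitochondrial"].astype(int).to_numpy(),
        }
    )
    genes.to_csv(outdir / "genes.tsv", sep="\t", index=False)
    meta = cells.reindex(counts.cell_ids)
    out = pd.DataFrame({"cell_id": counts.cell_ids})
    for col in CELL_COLUMNS[1:]:
        out[col] = meta[col].to_numpy() if col in meta else ""
    out.to_csv(outdir / "cells.tsv", sep="\t", index=False)
    if truth is not None:
        with open(outdir / "truth.json", "w") as fh:
            json.dump(truth, fh, indent=1, sort_keys=True)


def read_cohort(indir) -> tuple[CountMatrix, pd.DataFrame, pd.DataFrame]:
    """Read a cohort directory written by :func:`write_cohort`.

    Returns (counts, annotation, cell metadata); annotation and metadata
    are indexed by gene_id / cell_id.
    """
    indir = Path(indir)
    X = sparse.csr_matrix(spio.mmread(str(indir / "matrix.mtx")))
    genes = pd.read_csv(indir / "genes.tsv", sep="\t")
    cells = pd.read_csv(indir / "cells.tsv", sep="\t")
    annotation = genes.set_index("gene_id")
    annotation["is_mitochondrial"] = annotation["is_mitochondrial"].astype(bool)
    counts = CountMatrix(X, genes["gene_id"].to_numpy(), cells["cell_id"].to_numpy())
    return counts, annotation, cells.set_index("cell_id")


def read_truth(indir) -> dict:
    with open(Path(indir) / "truth.json") as fh:
        return json.load(fh)


def write_matrix_mtx(path, matrix: np.ndarray) -> None:
    """Write a dense real matrix in Matrix Market array format."""
    spio.mmwrite(str(path), np.asarray(matrix, dtype=float))


def read_gmt(path) -> list[GeneSet]:
    """Read gene sets from a GMT file (name, description, genes...)."""
    sets = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets.append(GeneSet(parts[0], [g for g in parts[2:] if g]))
    return sets


def write_gmt(path, sets) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, "scmalig"] + list(s.genes)) + "\n")
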