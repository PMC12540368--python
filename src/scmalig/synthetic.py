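"""Synthetic esophageal scRNA-seq cohorts with ground truth.

Emulates the statistical structure the downstream analysis relies on:
normal (NT) and tumor epithelial cells under a negative-binomial count
model with log-normal gene means, implanted chromosomal gain/loss
segments per malignant clone (including a whole-chromosome gain
mimicking broad chromosome-level amplification), mutually exclusive
NEUROG3 / POU2F3 / ASCL1 subtype marker programs, an 8-gene
neuroendocrine program in malignant cells, Beta-distributed
mitochondrial fractions, and log-normal library-size variation.

Every draw flows from a single seeded generator, so a config + seed
fixes the cohort exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import sparse

from .io import CountMatrix

NE_SIGNATURE = ["ASCL1", "NEUROD1", "NKX2-1", "INSM1", "CHGA", "CHGB", "NCAM1", "SYP"]
SUBTYPE_MARKERS = {"N": "NEUROG3", "P": "POU2F3", "A": "ASCL1"}


@dataclass
class CnvSegment:
    """Half-open interval over position-ordered genes of one chromosome.

    copy_ratio multiplies the expected expression of the covered genes
    (1.0 neutral, >1 gain, <1 loss).
    """

    chromosome: str
    start_gene_index: int
    end_gene_index: int
    copy_ratio: float

    def __post_init__(self):
        if self.end_gene_index <= self.start_gene_index:
            raise ValueError("segment interval is empty")
        if self.copy_ratio <= 0:
            raise ValueError("copy_ratio must be positive")


@dataclass
class CloneSpec:
    name: str
    n_cells: int
    segments: list = field(default_factory=list)

    def __post_init__(self):
        if self.n_cells < 0:
            raise ValueError("n_cells must be non-negative")
        if self.n_cells > 0 and not self.segments:
            raise ValueError(f"malignant clone {self.name!r} needs >=1 segment")


@dataclass
class SimConfig:
    """Full description of a synthetic cohort.

    The defaults are the reference study conditions used throughout the
    test suite: a 2,000-gene / 10-autosome genome, 250 NT reference
    cells, 250 non-malignant tumor epithelial cells, and one 500-cell
    malignant clone carrying a whole-chromosome gain (copy ratio 2) on
    the last autosome plus scattered 0.5-ratio losses, 20% of genes
    aberrant in total.
    """

    n_genes: int = 2000
    n_chromosomes: int = 10
    n_mito_genes: int = 10
    seed: int = 7
    # count model
    sigma_log_mu: float = 1.0
    target_libsize: float = 5000.0
    libsize_sigma: float = 0.3
    nb_dispersion: float = 2.0
    # QC structure
    mito_beta: tuple = (2.0, 38.0)
    frac_low_quality: float = 0.02
    low_quality_scale: float = 0.02
    # populations
    n_nt: int = 250
    tumor_group: str = "SCCE"
    tumor_samples: tuple = ("SCCE_s1", "SCCE_s2", "SCCE_s3")
    sample_subtypes: tuple = ("N", "P", "A")
    n_tumor_normal: int = 250
    clones: list = field(default_factory=list)
    # expression programs
    subtype_fold: float = 6.0
    subtype_program_size: int = 15
    ne_fold: float = 4.0
    marker_floor_mean: float = 2.0

    def __post_init__(self):
        if self.n_genes < self.n_chromosomes or self.n_chromosomes < 1:
            raise ValueError("need n_genes >= n_chromosomes >= 1")
        if self.nb_dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if min(self.n_nt, self.n_tumor_normal) < 0:
            raise ValueError("cell counts must be non-negative")
        if len(self.tumor_samples) != len(self.sample_subtypes):
            raise ValueError("one subtype per tumor sample required")
        needed = 3 * self.subtype_program_size + len(NE_SIGNATURE)
        if needed > self.n_genes - self.n_mito_genes:
            raise ValueError(
                f"config requests {needed} marker genes but only "
                f"{self.n_genes - self.n_mito_genes} non-mito genes exist"
            )


def generate_gene_annotation(
    n_genes: int,
    n_chromosomes: int,
    seed: int,
    n_mito: int = 0,
    mito_chromosome: str = "chrM",
) -> pd.DataFrame:
    """Gene annotation table: unique ids, chromosome, strictly increasing
    start positions per chromosome, mitochondrial flags.

    Mitochondrial genes (if any) are placed on their own chromosome so
    that no naming convention is needed to recognize them.
    """
    if n_genes < 1 or n_chromosomes < 1 or n_genes < n_chromosomes:
        raise ValueError("need n_genes >= n_chromosomes >= 1")
    if not 0 <= n_mito < n_genes:
        raise ValueError("0 <= n_mito < n_genes required")
    rng = np.random.default_rng(seed)
    n_auto = n_genes - n_mito
    sizes = np.full(n_chromosomes, n_auto // n_chromosomes)
    sizes[: n_auto % n_chromosomes] += 1
    if sizes.min() < 1:
        raise ValueError("too few genes for the requested chromosomes")
    chroms, starts = [], []
    for c, size in enumerate(sizes, start=1):
        gaps = rng.integers(1_000, 100_000, size=size)
        chroms.extend([f"chr{c}"] * size)
        starts.extend(np.cumsum(gaps).tolist())
    mito_flags = [False] * n_auto
    if n_mito:
        gaps = rng.integers(100, 1_000, size=n_mito)
        chroms.extend([mito_chromosome] * n_mito)
        starts.extend(np.cumsum(gaps).tolist())
        mito_flags.extend([True] * n_mito)
    gene_ids = [f"G{i:05d}" for i in range(n_genes)]
    return pd.DataFrame(
        {
            "chromosome": chroms,
            "start": np.asarray(starts, dtype=int),
            "is_mitochondrial": mito_flags,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )


def default_config(seed: int = 7, **overrides) -> SimConfig:
    """Reference single-clone cohort: 500 malignant cells whose clone
    carries a 2.0 whole-chromosome gain on the last autosome (10% of
    genes) plus 0.5-ratio losses over another 10%, and 500 normal cells
    (250 NT + 250 tumor-resident)."""
    cfg = SimConfig(seed=seed, **overrides)
    if not cfg.clones:
        per_chr = (cfg.n_genes - cfg.n_mito_genes) // cfg.n_chromosomes
        last = f"chr{cfg.n_chromosomes}"
        segments = [CnvSegment(last, 0, per_chr, 2.0)]
        # losses: one block in the back half of each remaining autosome
        loss_total = per_chr
        n_src = cfg.n_chromosomes - 1
        block = loss_total // n_src
        extra = loss_total % n_src
        for c in range(1, cfg.n_chromosomes):
            b = block + (1 if c <= extra else 0)
            if b == 0:
                continue
            start = per_chr // 2
            segments.append(CnvSegment(f"chr{c}", start, start + b, 0.5))
        cfg.clones = [CloneSpec("clone1", 500, segments)]
    return cfg


def two_clone_config(seed: int = 7, **overrides) -> SimConfig:
    """Two malignant clones of unequal CNV burden (10% vs 40% of genes
    aberrant, 300 cells each) to produce a bimodal CNV-score
    distribution over malignant cells."""
    cfg = SimConfig(seed=seed, **overrides)
    per_chr = (cfg.n_genes - cfg.n_mito_genes) // cfg.n_chromosomes
    n_chr = cfg.n_chromosomes
    lo = [CnvSegment(f"chr{n_chr}", 0, per_chr, 2.0)]  # 10%
    hi = [
        CnvSegment(f"chr{n_chr}", 0, per_chr, 3.0),
        CnvSegment(f"chr{n_chr - 1}", 0, per_chr, 2.0),
    ]
    half = per_chr // 2
    for c in range(1, n_chr - 1):  # 8 chromosomes x half-chromosome losses
        hi.append(CnvSegment(f"chr{c}", half, half + half, 0.5))
    cfg.clones = [CloneSpec("clone_lo", 300, lo), CloneSpec("clone_hi", 300, hi)]
    return cfg


def _program_genes(config: SimConfig) -> dict:
    """Subtype marker programs; mutually exclusive by construction."""
    progs = {}
    for st, tf in SUBTYPE_MARKERS.items():
        progs[st] = [tf] + [
            f"PRG_{st}_{i:02d}" for i in range(1, config.subtype_program_size)
        ]
    return progs


def _named_gene_slots(config: SimConfig, annotation: pd.DataFrame) -> dict:
    """Map marker/program/NE gene names onto annotation slots.

    Named genes occupy the front of autosomes 1..n-1 (never the last
    autosome, which hosts the whole-chromosome gain, and never inside
    the back-half loss blocks), so implanted CNVs and implanted
    expression programs stay orthogonal.
    """
    progs = _program_genes(config)
    named = []
    for st in progs:
        named.extend(progs[st])
    named.extend(g for g in NE_SIGNATURE if g not in named)
    host_chroms = [f"chr{c}" for c in range(1, config.n_chromosomes)] or ["chr1"]
    slots = {}
    counters = {c: 0 for c in host_chroms}
    order = annotation.index.to_numpy()
    by_chrom = {
        c: order[(annotation["chromosome"] == c).to_numpy()] for c in host_chroms
    }
    for i, name in enumerate(named):
        c = host_chroms[i % len(host_chroms)]
        k = counters[c]
        counters[c] += 1
        if k >= len(by_chrom[c]) // 2:
            raise ValueError("too many named genes for the genome size")
        slots[name] = by_chrom[c][k]
    return slots


def generate_cohort(config: SimConfig):
    """Generate (counts, annotation, cell metadata, truth).

    Counts are negative-binomial around per-gene log-normal means times
    a per-cell library factor; clone segments multiply means by their
    copy ratio; subtype programs and the NE program multiply means in
    their carrier cells; mitochondrial means are inflated per cell to a
    Beta-distributed fraction.
    """
    rng = np.random.default_rng(config.seed)
    annotation = generate_gene_annotation(
        config.n_genes,
        config.n_chromosomes,
        int(rng.integers(2**31)),
        n_mito=config.n_mito_genes,
    )
    # rename reserved slots to their marker names
    slots = _named_gene_slots(config, annotation)
    rename = {slot: name for name, slot in slots.items()}
    annotation = annotation.rename(index=rename)
    gene_ids = annotation.index.to_numpy()
    n_genes = gene_ids.size
    mito_mask = annotation["is_mitochondrial"].to_numpy()

    # per-gene base means (log-normal), scaled to the target library size
    base = rng.lognormal(mean=0.0, sigma=config.sigma_log_mu, size=n_genes)
    gpos = {g: i for i, g in enumerate(gene_ids)}
    named_idx = np.array([gpos[n] for n in slots], dtype=int)
    base[named_idx] = np.maximum(base[named_idx], config.marker_floor_mean)
    base = base / base[~mito_mask].sum() * config.target_libsize

    # --- assemble cells ---------------------------------------------------
    rows = []  # (cell_id, sample, group, clone, subtype)
    n_samples = len(config.tumor_samples)
    for i in range(config.n_nt):
        rows.append((f"NT_c{i:04d}", "NT_s1", "NT", "normal", "none"))
    for i in range(config.n_tumor_normal):
        s = config.tumor_samples[i % n_samples]
        rows.append((f"TN_c{i:04d}", s, config.tumor_group, "normal", "none"))
    for clone in config.clones:
        for i in range(clone.n_cells):
            j = i % n_samples
            rows.append(
                (
                    f"{clone.name}_c{i:04d}",
                    config.tumor_samples[j],
                    config.tumor_group,
                    clone.name,
                    config.sample_subtypes[j],
                )
            )
    cells = pd.DataFrame(
        rows, columns=["cell_id", "sample_id", "group", "clone_id", "subtype"]
    ).set_index("cell_id")
    subtype_order = list(SUBTYPE_MARKERS)
    cells["cluster"] = [
        subtype_order.index(st) if st in subtype_order else len(subtype_order)
        for st in cells["subtype"]
    ]
    n_cells = len(cells)

    # --- expected means ---------------------------------------------------
    mu = np.tile(base[:, None], (1, n_cells))

    # CNV segments per clone
    clone_segments = {}
    chrom_genes = {
        c: gene_ids[(annotation["chromosome"] == c).to_numpy()]
        for c in annotation["chromosome"].unique()
    }
    for clone in config.clones:
        seg_records = []
        for seg in clone.segments:
            genes_on = chrom_genes[seg.chromosome]
            if seg.end_gene_index > genes_on.size:
                raise ValueError(
                    f"segment exceeds {seg.chromosome} ({genes_on.size} genes)"
                )
            seg_genes = genes_on[seg.start_gene_index : seg.end_gene_index]
            idx = np.array([gpos[g] for g in seg_genes], dtype=int)
            cmask = (cells["clone_id"] == clone.name).to_numpy()
            mu[np.ix_(idx, cmask)] *= seg.copy_ratio
            rec = asdict(seg)
            rec["gene_ids"] = seg_genes.tolist()
            seg_records.append(rec)
        clone_segments[clone.name] = seg_records

    # subtype programs (mutually exclusive) and the NE program
    progs = _program_genes(config)
    malignant = (cells["clone_id"] != "normal").to_numpy()
    for st, genes in progs.items():
        idx = np.array([gpos[g] for g in genes], dtype=int)
        cmask = (cells["subtype"] == st).to_numpy()
        if cmask.any():
            mu[np.ix_(idx, cmask)] *= config.subtype_fold
    ne_only = [g for g in NE_SIGNATURE if g not in SUBTYPE_MARKERS.values()]
    if malignant.any() and config.ne_fold != 1.0:
        idx = np.array([gpos[g] for g in ne_only], dtype=int)
        mu[np.ix_(idx, malignant)] *= config.ne_fold

    # library sizes, low-quality cells, mitochondrial inflation
    lib = rng.lognormal(mean=0.0, sigma=config.libsize_sigma, size=n_cells)
    low_q = rng.random(n_cells) < config.frac_low_quality
    lib[low_q] *= config.low_quality_scale
    mu *= lib[None, :]
    a, b = config.mito_beta
    mito_frac = rng.beta(a, b, size=n_cells)
    if mito_mask.any():
        w = base[mito_mask] / base[mito_mask].sum()
        nonmito_tot = mu[~mito_mask, :].sum(axis=0)
        mu[np.ix_(mito_mask, np.arange(n_cells))] = (
            w[:, None] * (mito_frac / (1 - mito_frac) * nonmito_tot)[None, :]
        )

    # negative-binomial draws: var = mu + mu^2 / r
    r = config.nb_dispersion
    counts = rng.negative_binomial(r, r / (r + mu))
    X = sparse.csr_matrix(counts)
    cm = CountMatrix(X, gene_ids, cells.index.to_numpy())

    truth = {
        "cells": {
            cid: {
                "clone_id": row.clone_id,
                "is_malignant": bool(row.clone_id != "normal"),
                "subtype_label": row.subtype,
                "sample_id": row.sample_id,
                "group": row.group,
            }
            for cid, row in cells.iterrows()
        },
        "clones": clone_segments,
        "programs": {st: genes for st, genes in progs.items()},
        "ne_program": ne_only,
    }
    return cm, annotation, cells, truth


def truth_frame(truth: dict) -> pd.DataFrame:
    """Per-cell ground truth as a DataFrame indexed by cell id."""
    df = pd.DataFrame.from_dict(truth["cells"], orient="index")
    df.index.name = "cell_id"
    return df


def state_pattern_fixture():
    """A 9-cluster program-score matrix following the published verbal
    pattern of the three malignant functional states.

    gamma clusters (0, 3): elevated proliferation and CNV, lowest
    antigen presentation; beta clusters (1, 5, 7, 8): high EMT, low
    antigen activity; alpha clusters (2, 4, 6): high EMT with moderate
    proliferation and preserved antigen presentation.  Returns
    (cluster x program means, expected state per cluster).
    """
    values = {
        0: (0.0, 2.0, 2.0, -2.0),
        3: (0.0, 2.0, 2.0, -2.0),
        1: (1.5, 0.0, 0.0, -0.5),
        5: (1.5, 0.0, 0.0, -0.5),
        7: (1.5, 0.0, 0.0, -0.5),
        8: (1.5, 0.0, 0.0, -0.5),
        2: (1.8, 0.8, 0.2, 1.0),
        4: (1.8, 0.8, 0.2, 1.0),
        6: (1.8, 0.8, 0.2, 1.0),
    }
    df = pd.DataFrame.from_dict(
        values,
        orient="index",
        columns=["emt", "proliferation", "cnv", "antigen_presentation"],
    ).sort_index()
    df.index.name = "cluster"
    expected = {0: "gamma", 3: "gamma", 1: "beta", 5: "beta", 7: "beta",
                8: "beta", 2: "alpha", 4: "alpha", 6: "alpha"}
    return df, expected
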