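"""Dual-criterion malignant / non-malignant classification.

Within each pathological group the top 5% of epithelial cells by CNV
score define a high-CNV reference profile; every cell is then scored by
its Pearson correlation with its own group's profile, and called
malignant iff CNV score > 0.001 AND correlation > 0.5 (both strict).
Cells of the normal reference group are never called malignant.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cnv import CNVProfile

log = logging.getLogger(__name__)

MALIGNANT = "malignant"
NON_MALIGNANT = "non_malignant"
UNCLASSIFIED = "unclassified"


@dataclass
class HighCnvReference:
    """Per-group high-CNV cell selections and mean residual profiles."""

    selected: dict  # group -> list of cell ids (score-desc, id-asc order)
    profiles: dict  # group -> mean residual profile over ordered genes
    top_fraction: float


def build_reference(
    profile: CNVProfile,
    scores: pd.Series,
    groups: pd.Series,
    top_fraction: float = 0.05,
    exclude_groups: tuple = ("NT",),
) -> HighCnvReference:
    """Select the top ``top_fraction`` of cells by CNV score per group.

    Per group, cells are ranked by (score desc, cell_id asc) and the
    top ceil(fraction * n) are averaged into the group's reference
    profile.  Groups listed in ``exclude_groups`` (the normal reference)
    get no profile.
    """
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    pos = {c: i for i, c in enumerate(profile.cell_ids)}
    selected, profiles = {}, {}
    for group in pd.unique(groups):
        if group in exclude_groups:
            continue
        ids = groups.index[groups == group]
        ids = [c for c in ids if c in pos]
        if not ids:
            raise ValueError(f"group {group!r} has no cells in the profile")
        sc = scores.reindex(ids)
        if sc.isna().any():
            raise ValueError(f"group {group!r} has cells without scores")
        order = sorted(ids, key=lambda c: (-sc[c], c))
        k = math.ceil(top_fraction * len(order))
        chosen = order[:k]
        idx = np.array([pos[c] for c in chosen], dtype=int)
        selected[group] = chosen
        profiles[group] = profile.values[:, idx].mean(axis=1)
    return HighCnvReference(selected, profiles, top_fraction)


def correlate(cell_profile: np.ndarray, reference_profile: np.ndarray) -> float:
    """Pearson product-moment correlation of two residual profiles.

    Constant input makes r undefined; by convention 0 is returned with
    a warning.
    """
    x = np.asarray(cell_profile, dtype=float)
    y = np.asarray(reference_profile, dtype=float)
    if x.size != y.size:
        raise ValueError("length mismatch")
    if x.size < 3:
        raise ValueError("need profiles of length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        warnings.warn("constant profile: Pearson r undefined, returning 0",
                      stacklevel=2)
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def correlate_all(
    profile: CNVProfile,
    reference: HighCnvReference,
    groups: pd.Series,
) -> pd.Series:
    """Pearson r of every cell against its own group's high-CNV profile.

    Cells of groups without a reference profile (the normal reference
    group) get NaN.
    """
    r = pd.Series(np.nan, index=pd.Index(profile.cell_ids, name="cell_id"),
                  name="correlation_r")
    pos = {c: i for i, c in enumerate(profile.cell_ids)}
    for group, ref_prof in reference.profiles.items():
        ids = [c for c in groups.index[groups == group] if c in pos]
        if not ids:
            continue
        idx = np.array([pos[c] for c in ids], dtype=int)
        block = profile.values[:, idx]
        ref_c = ref_prof - ref_prof.mean()
        ref_norm = np.sqrt((ref_c**2).sum())
        cell_c = block - block.mean(axis=0, keepdims=True)
        cell_norm = np.sqrt((cell_c**2).sum(axis=0))
        with np.errstate(invalid="ignore", divide="ignore"):
            rr = (cell_c * ref_c[:, None]).sum(axis=0) / (cell_norm * ref_norm)
        degenerate = (cell_norm == 0) | (ref_norm == 0)
        if degenerate.any():
            warnings.warn(
                f"{int(degenerate.sum())} constant profile(s): r set to 0",
                stacklevel=2,
            )
            rr = np.where(degenerate, 0.0, rr)
        r.loc[ids] = rr
    return r


def classify(
    scores: pd.Series,
    correlations: pd.Series,
    groups: pd.Series | None = None,
    score_thresh: float = 0.001,
    r_thresh: float = 0.5,
    reference_groups: tuple = ("NT",),
) -> pd.DataFrame:
    """Label cells malignant iff score > score_thresh AND r > r_thresh.

    Strict inequalities on both criteria.  Cells of a reference group
    are always non-malignant; cells with a missing score or correlation
    (outside reference groups) are flagged unclassified and logged.
    """
    df = pd.DataFrame({"cnv_score": scores, "correlation_r": correlations})
    if groups is not None:
        df["group"] = groups.reindex(df.index)
    in_ref = (
        df["group"].isin(reference_groups)
        if groups is not None
        else pd.Series(False, index=df.index)
    )
    missing = (df["cnv_score"].isna() | df["correlation_r"].isna()) & ~in_ref
    if missing.any():
        log.warning("%d cell(s) lack score or correlation: unclassified",
                    int(missing.sum()))
    call = np.where(
        (df["cnv_score"] > score_thresh) & (df["correlation_r"] > r_thresh),
        MALIGNANT,
        NON_MALIGNANT,
    )
    call = np.where(in_ref, NON_MALIGNANT, call)
    call = np.where(missing, UNCLASSIFIED, call)
    df["label"] = call
    df.attrs["score_thresh"] = score_thresh
    df.attrs["r_thresh"] = r_thresh
    df.index.name = "cell_id"
    return df


def call_malignancy(
    profile: CNVProfile,
    scores: pd.Series,
    groups: pd.Series,
    top_fraction: float = 0.05,
    score_thresh: float = 0.001,
    r_thresh: float = 0.5,
    reference_groups: tuple = ("NT",),
    correlate_on: str = "cnv",
    norm=None,
) -> pd.DataFrame:
    """Reference building, correlation and classification in one call.

    ``correlate_on`` selects what the high-CNV average profile and the
    per-cell correlations are computed on: ``"cnv"`` (default) uses the
    inferred residual profiles, which are library- and program-
    corrected; ``"expression"`` uses the normalized expression of the
    same genome-ordered genes (pass the :class:`NormalizedMatrix` as
    ``norm``).  Scores always come from the residual profile.
    """
    if correlate_on == "cnv":
        basis = profile
    elif correlate_on == "expression":
        if norm is None:
            raise ValueError("correlate_on='expression' needs the norm matrix")
        gpos = norm.gene_index()
        rows = [gpos[g] for g in profile.gene_ids]
        idx = {c: i for i, c in enumerate(norm.cell_ids)}
        cols = [idx[c] for c in profile.cell_ids]
        values = np.asarray(norm.X[rows, :].todense(), dtype=float)[:, cols]
        basis = CNVProfile(values, profile.gene_index, profile.cell_ids,
                           profile.reference_cells, profile.clip,
                           profile.window)
    else:
        raise ValueError("correlate_on must be 'cnv' or 'expression'")
    ref = build_reference(
        basis, scores, groups, top_fraction, exclude_groups=reference_groups
    )
    r = correlate_all(basis, ref, groups)
    return classify(
        scores, r, groups,
        score_thresh=score_thresh, r_thresh=r_thresh,
        reference_groups=reference_groups,
    )
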