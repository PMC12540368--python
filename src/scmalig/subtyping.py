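"""Functional states and molecular subtypes of malignant cells.

Malignant clusters are summarized by four program scores (EMT,
proliferation, CNV, antigen presentation), z-scored across clusters,
and assigned one of three functional states by a deterministic rule
cascade: gamma when proliferation+CNV sit above the cross-cluster mean
while antigen presentation sits below it, otherwise beta when EMT is
high and antigen presentation low, otherwise alpha.  Molecular subtype
calls (SCCE_N / SCCE_P / SCCE_A) take the argmax of scaled
NEUROG3 / POU2F3 / ASCL1 expression per cluster or sample.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .io import NormalizedMatrix

log = logging.getLogger(__name__)

PROGRAMS = ["emt", "proliferation", "cnv", "antigen_presentation"]
MARKER_SUBTYPES = [("NEUROG3", "SCCE_N"), ("POU2F3", "SCCE_P"), ("ASCL1", "SCCE_A")]


def summarize_clusters(
    scores: pd.DataFrame,
    cluster_labels: pd.Series,
) -> pd.DataFrame:
    """Per-cluster mean of each program score, with cross-cluster z-scores.

    ``scores`` is a cells x programs frame (must include the four
    programs); z columns (``<program>_z``) use the population standard
    deviation across clusters.  A single cluster yields raw means only,
    flagged via ``attrs['z_valid'] = False``.
    """
    missing = [p for p in PROGRAMS if p not in scores.columns]
    if missing:
        raise ValueError(f"missing program scores: {missing}")
    labels = cluster_labels.reindex(scores.index)
    if labels.isna().any():
        raise ValueError("every cell needs a cluster label")
    small = labels.value_counts()
    for cl, n in small.items():
        if n < 3:
            warnings.warn(f"cluster {cl!r} has only {n} cells", stacklevel=2)
    means = scores[PROGRAMS].groupby(labels).mean().sort_index()
    means.index.name = "cluster"
    z_valid = len(means) >= 2
    for p in PROGRAMS:
        if z_valid:
            mu = means[p].mean()
            sd = means[p].std(ddof=0)
            means[p + "_z"] = 0.0 if sd == 0 else (means[p] - mu) / sd
        else:
            means[p + "_z"] = np.nan
    means.attrs["z_valid"] = z_valid
    return means


def assign_states(
    cluster_scores: pd.DataFrame,
    gamma_sum_thresh: float = 0.0,
    antigen_thresh: float = 0.0,
    emt_thresh: float = 0.0,
) -> pd.DataFrame:
    """Assign alpha/beta/gamma states to clusters by the z-score cascade.

    gamma: proliferation_z + cnv_z > gamma_sum_thresh AND
    antigen_z < antigen_thresh; else beta: emt_z > emt_thresh AND
    antigen_z < antigen_thresh; else alpha.  Returns the state plus the
    rule trace per cluster.
    """
    if len(cluster_scores) < 3:
        raise ValueError("need >= 3 clusters to derive three states")
    zcols = [p + "_z" for p in PROGRAMS]
    missing = [c for c in zcols if c not in cluster_scores.columns]
    if missing:
        raise ValueError(f"missing z-score columns: {missing}")
    out = []
    for cl, row in cluster_scores.iterrows():
        pc = row["proliferation_z"] + row["cnv_z"]
        low_antigen = row["antigen_presentation_z"] < antigen_thresh
        if pc > gamma_sum_thresh and low_antigen:
            state = "gamma"
            trace = f"proliferation_z+cnv_z={pc:.3f}>{gamma_sum_thresh} & low antigen"
        elif row["emt_z"] > emt_thresh and low_antigen:
            state = "beta"
            trace = f"emt_z={row['emt_z']:.3f}>{emt_thresh} & low antigen"
        else:
            state = "alpha"
            trace = "default (high EMT with preserved antigen presentation)"
        out.append((cl, state, trace))
    df = pd.DataFrame(out, columns=["cluster", "state", "trace"]).set_index("cluster")
    return df


def call_subtype(
    norm: NormalizedMatrix,
    unit_labels: pd.Series,
    markers: tuple = ("NEUROG3", "POU2F3", "ASCL1"),
) -> pd.DataFrame:
    """Call SCCE_N / SCCE_P / SCCE_A per unit (cluster or sample).

    Mean normalized marker expression per unit is z-scaled across units
    (population sd; a single unit or a flat marker falls back to the
    raw mean / zero); the subtype is the argmax with ties broken by the
    fixed marker priority (NEUROG3, POU2F3, ASCL1) under a warning.
    """
    subtype_of = dict(MARKER_SUBTYPES)
    gpos = norm.gene_index()
    missing = [m for m in markers if m not in gpos]
    if missing:
        raise ValueError(f"marker gene(s) absent from matrix: {missing}")
    labels = unit_labels.reindex(norm.cell_ids)
    if labels.isna().any():
        raise ValueError("every cell needs a unit label")
    X = np.asarray(norm.X[[gpos[m] for m in markers], :].todense(), dtype=float)
    expr = pd.DataFrame(X.T, index=norm.cell_ids, columns=list(markers))
    unit_means = expr.groupby(labels.to_numpy()).mean().sort_index()
    if len(unit_means) >= 2:
        mu = unit_means.mean(axis=0)
        sd = unit_means.std(axis=0, ddof=0)
        evidence = (unit_means - mu) / sd.replace(0.0, np.inf)
    else:
        evidence = unit_means.copy()
    calls = []
    priority = {m: i for i, m in enumerate(markers)}
    for unit, row in evidence.iterrows():
        best = row.max()
        winners = [m for m in markers if row[m] == best]
        if len(winners) > 1:
            warnings.warn(
                f"unit {unit!r}: marker tie {winners}; using priority order",
                stacklevel=2,
            )
        winner = min(winners, key=lambda m: priority[m])
        margin = best - row.drop(winner).max() if len(markers) > 1 else np.inf
        calls.append((unit, subtype_of.get(winner, winner), winner, best, margin))
    out = pd.DataFrame(
        calls, columns=["unit", "subtype", "marker", "evidence", "margin"]
    ).set_index("unit")
    for m in markers:
        out["mean_" + m] = unit_means[m]
    return out
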