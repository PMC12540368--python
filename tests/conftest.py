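import numpy as np
import pytest
from scipy import sparse

import scmalig as sm


@pytest.fixture(scope="session")
def default_cohort():
    """Reference single-clone cohort (500 malignant / 500 normal, seed 7)."""
    return sm.generate_cohort(sm.default_config(7))


@pytest.fixture(scope="session")
def processed(default_cohort):
    """Default cohort pushed through QC, normalization, CNV and calling."""
    counts, ann, cells, truth = default_cohort
    filt, report = sm.qc_filter(counts, ann)
    norm = sm.normalize(filt)
    meta = cells.reindex(filt.cell_ids)
    ref = meta.index[meta["group"] == "NT"].tolist()
    profile = sm.infer_cnv(norm, ann, ref)
    scores = sm.cnv_score(profile)
    calls = sm.call_malignancy(profile, scores, meta["group"])
    truth_df = sm.truth_frame(truth).reindex(filt.cell_ids)
    return {
        "counts": counts, "annotation": ann, "cells": cells, "truth": truth,
        "filtered": filt, "report": report, "norm": norm, "meta": meta,
        "profile": profile, "scores": scores, "calls": calls,
        "truth_df": truth_df,
    }


@pytest.fixture(scope="session")
def two_clone_malignant_scores():
    """CNV scores of malignant cells from the unequal two-clone cohort."""
    counts, ann, cells, _ = sm.generate_cohort(sm.two_clone_config(7))
    filt, _ = sm.qc_filter(counts, ann)
    norm = sm.normalize(filt)
    meta = cells.reindex(filt.cell_ids)
    ref = meta.index[meta["group"] == "NT"].tolist()
    profile = sm.infer_cnv(norm, ann, ref)
    scores = sm.cnv_score(profile)
    mal = (meta["clone_id"] != "normal").to_numpy()
    return scores[mal].to_numpy()


def make_norm(values, gene_ids=None, cell_ids=None):
    """Build a NormalizedMatrix straight from a dense genes x cells array."""
    values = np.asarray(values, dtype=float)
    g, c = values.shape
    gene_ids = gene_ids or [f"g{i}" for i in range(g)]
    cell_ids = cell_ids or [f"c{j}" for j in range(c)]
    return sm.NormalizedMatrix(sparse.csr_matrix(values), gene_ids, cell_ids)


@pytest.fixture
def toy_norm():
    """10 genes x 6 cells with two marker-like genes high in cells 0-2."""
    rng = np.random.default_rng(11)
    X = rng.uniform(0.1, 2.0, size=(10, 6))
    X[0, :3] += 3.0
    X[1, :3] += 3.0
    return make_norm(X)
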