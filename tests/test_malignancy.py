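"""High-CNV reference building and the dual-criterion classifier."""

import numpy as np
import pandas as pd
import pytest

import scmalig as sm
from scmalig.cnv import CNVProfile


def toy_profile(n_genes=6, cells=None, seed=0):
    cells = list(cells) if cells is not None else [f"c{i}" for i in range(20)]
    rng = np.random.default_rng(seed)
    idx = pd.DataFrame(
        {"chromosome": ["chr1"] * n_genes, "start": np.arange(n_genes) + 1},
        index=pd.Index([f"g{i}" for i in range(n_genes)], name="gene_id"),
    )
    values = rng.normal(size=(n_genes, len(cells)))
    return CNVProfile(values, idx, np.array(cells, dtype=object), [], 3.0, 101)


class TestBuildReference:
    def test_ceil_selection_and_max_cell(self):
        prof = toy_profile()
        scores = pd.Series(np.arange(20, dtype=float), index=prof.cell_ids)
        groups = pd.Series(["T"] * 20, index=prof.cell_ids)
        ref = sm.build_reference(prof, scores, groups, top_fraction=0.05)
        assert ref.selected["T"] == ["c19"]  # ceil(0.05*20)=1, the max scorer

    def test_tie_break_by_cell_id(self):
        prof = toy_profile()
        scores = pd.Series(1.0, index=prof.cell_ids)
        groups = pd.Series(["T"] * 20, index=prof.cell_ids)
        ref = sm.build_reference(prof, scores, groups, top_fraction=0.10)
        assert ref.selected["T"] == sorted(prof.cell_ids)[:2]

    def test_mean_profile_matches_brute_force(self):
        prof = toy_profile(seed=3)
        rng = np.random.default_rng(1)
        scores = pd.Series(rng.uniform(size=20), index=prof.cell_ids)
        groups = pd.Series(["A"] * 10 + ["B"] * 10, index=prof.cell_ids)
        ref = sm.build_reference(prof, scores, groups, top_fraction=0.3)
        for grp in ["A", "B"]:
            cols = [list(prof.cell_ids).index(c) for c in ref.selected[grp]]
            np.testing.assert_allclose(
                ref.profiles[grp], prof.values[:, cols].mean(axis=1),
                atol=1e-12,
            )

    def test_reference_group_excluded(self):
        prof = toy_profile()
        scores = pd.Series(1.0, index=prof.cell_ids)
        groups = pd.Series(["NT"] * 10 + ["T"] * 10, index=prof.cell_ids)
        ref = sm.build_reference(prof, scores, groups)
        assert set(ref.profiles) == {"T"}


class TestCorrelate:
    def test_self_and_negation(self):
        v = np.array([0.3, -1.2, 0.8, 2.0])
        assert sm.correlate(v, v) == pytest.approx(1.0)
        assert sm.correlate(v, -v) == pytest.approx(-1.0)

    def test_closed_form(self):
        r = sm.correlate([1, 2, 3], [1, 2, 4])
        assert r == pytest.approx(9 / np.sqrt(84), abs=1e-12)  # 0.98198...

    def test_constant_vector_warns_zero(self):
        with pytest.warns(UserWarning):
            assert sm.correlate([1.0, 1.0, 1.0], [1, 2, 3]) == 0.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            sm.correlate([1, 2, 3], [1, 2])


class TestClassify:
    @pytest.mark.parametrize(
        "score,r,expected",
        [
            (0.002, 0.6, "malignant"),
            (0.001, 0.9, "non_malignant"),  # strict: score must exceed 0.001
            (0.002, 0.5, "non_malignant"),  # strict: r must exceed 0.5
            (0.0009, 0.4, "non_malignant"),
        ],
    )
    def test_dual_criterion_boundaries(self, score, r, expected):
        calls = sm.classify(
            pd.Series({"c": score}), pd.Series({"c": r})
        )
        assert calls.loc["c", "label"] == expected

    def test_missing_values_unclassified(self):
        calls = sm.classify(
            pd.Series({"a": 0.1, "b": np.nan}),
            pd.Series({"a": 0.9, "b": 0.9}),
        )
        assert calls.loc["a", "label"] == "malignant"
        assert calls.loc["b", "label"] == "unclassified"

    def test_reference_group_never_malignant(self):
        calls = sm.classify(
            pd.Series({"a": 0.5}), pd.Series({"a": 0.99}),
            groups=pd.Series({"a": "NT"}),
        )
        assert calls.loc["a", "label"] == "non_malignant"

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(2)
        scores = pd.Series(rng.uniform(0, 0.01, 200))
        rs = pd.Series(rng.uniform(-1, 1, 200))
        n_prev = None
        for st in [0.0005, 0.001, 0.002, 0.004]:
            n = (sm.classify(scores, rs, score_thresh=st)["label"]
                 == "malignant").sum()
            if n_prev is not None:
                assert n <= n_prev
            n_prev = n

    def test_order_invariance(self):
        rng = np.random.default_rng(3)
        idx = [f"c{i}" for i in range(50)]
        scores = pd.Series(rng.uniform(0, 0.01, 50), index=idx)
        rs = pd.Series(rng.uniform(-1, 1, 50), index=idx)
        a = sm.classify(scores, rs)
        perm = rng.permutation(idx)
        b = sm.classify(scores[perm], rs[perm])
        assert (a["label"].sort_index() == b["label"].sort_index()).all()


class TestEndToEndCalling:
    def test_f1_on_default_cohort(self, processed):
        calls, truth_df = processed["calls"], processed["truth_df"]
        pred = calls["label"] == "malignant"
        truth = truth_df["is_malignant"]
        tp = int((pred & truth).sum())
        fp = int((pred & ~truth).sum())
        fn = int((~pred & truth).sum())
        f1 = 2 * tp / (2 * tp + fp + fn)
        assert f1 >= 0.95

    def test_error_rates_at_default_effect_sizes(self, processed):
        calls, truth_df = processed["calls"], processed["truth_df"]
        pred = (calls["label"] == "malignant")
        normal = ~truth_df["is_malignant"]
        assert pred[normal].mean() <= 0.05
        assert pred[~normal].mean() >= 0.90

    def test_expression_correlation_mode(self, processed):
        """correlate_on='expression' runs and gives valid, distinct r."""
        calls = sm.call_malignancy(
            processed["profile"], processed["scores"],
            processed["meta"]["group"],
            correlate_on="expression", norm=processed["norm"],
        )
        r = calls["correlation_r"].dropna()
        assert ((r >= -1 - 1e-12) & (r <= 1 + 1e-12)).all()
        assert not np.allclose(
            r.to_numpy(),
            processed["calls"]["correlation_r"].dropna().to_numpy(),
        )
        with pytest.raises(ValueError, match="norm"):
            sm.call_malignancy(
                processed["profile"], processed["scores"],
                processed["meta"]["group"], correlate_on="expression",
            )

    def test_malignant_scores_higher_within_group(self, processed):
        calls, meta = processed["calls"], processed["meta"]
        sub = calls[meta["group"].to_numpy() == "SCCE"]
        mal = sub.loc[sub["label"] == "malignant", "cnv_score"].to_numpy()
        non = sub.loc[sub["label"] == "non_malignant", "cnv_score"].to_numpy()
        _, p = sm.rank_sum_test(mal, non)
        assert mal.mean() > non.mean() and p < 0.01
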