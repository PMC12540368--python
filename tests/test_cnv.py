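"""CNV inference: gene ordering, centering, smoothing, scoring."""

import numpy as np
import pandas as pd
import pytest

import scmalig as sm
from scmalig.cnv import _moving_average_block
from conftest import make_norm


def brute_force_smooth(block, window):
    """O(n*w) truncated-window moving average oracle."""
    n, c = block.shape
    half = window // 2
    out = np.empty_like(block, dtype=float)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        out[i] = block[lo:hi].mean(axis=0)
    return out


def ordered_index(chroms, starts, gene_ids=None):
    gene_ids = gene_ids or [f"g{i}" for i in range(len(chroms))]
    return pd.DataFrame(
        {"chromosome": chroms, "start": starts},
        index=pd.Index(gene_ids, name="gene_id"),
    )


class TestOrderGenes:
    def test_lexicographic_by_position(self):
        ann = ordered_index(["chr2", "chr1", "chr1"], [50, 200, 100],
                            ["a", "b", "c"])
        out = sm.order_genes(ann)
        assert list(out.index) == ["c", "b", "a"]

    def test_stable_on_ties(self):
        ann = ordered_index(["chr1", "chr1"], [100, 100], ["first", "second"])
        assert list(sm.order_genes(ann).index) == ["first", "second"]

    def test_natural_chromosome_order(self):
        ann = ordered_index(["chr10", "chr2", "chrM", "chrX"], [1, 1, 1, 1],
                            list("abcd"))
        assert list(sm.order_genes(ann)["chromosome"]) == [
            "chr2", "chr10", "chrX", "chrM"
        ]

    def test_matches_sort_oracle_and_drops_unannotated(self):
        rng = np.random.default_rng(4)
        n = 1000
        chroms = [f"chr{c}" for c in rng.integers(1, 9, size=n)]
        starts = rng.integers(1, 10**7, size=n).astype(float)
        ann = ordered_index(chroms, starts)
        ann.loc[ann.index[5], "start"] = np.nan
        out = sm.order_genes(ann)
        kept = ann.dropna()
        expect = sorted(
            kept.index,
            key=lambda g: (int(kept.loc[g, "chromosome"][3:]),
                           kept.loc[g, "start"]),
        )
        assert list(out.index) == expect

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            sm.order_genes(ordered_index([], []))


class TestRelativeExpression:
    def test_reference_centering_identity(self):
        rng = np.random.default_rng(1)
        X = rng.uniform(0, 4, size=(6, 5))
        norm = make_norm(X)
        out = sm.relative_expression(norm, ["c0", "c1", "c2"])
        np.testing.assert_allclose(out[:, :3].mean(axis=1), 0.0, atol=1e-12)

    def test_clipping(self):
        X = np.zeros((3, 4))
        X[0, 3] = 9.0  # centered against zero reference -> 9, clipped to 3
        norm = make_norm(X)
        out = sm.relative_expression(norm, ["c0", "c1"], clip=3.0)
        assert out[0, 3] == 3.0

    def test_hand_computed_centering(self):
        X = np.array([[1.0, 2.0, 3.0],
                      [0.0, 4.0, 2.0],
                      [5.0, 1.0, 0.0],
                      [2.0, 2.0, 2.0]])
        out = sm.relative_expression(make_norm(X), ["c0", "c1"], clip=10)
        ref_mean = X[:, :2].mean(axis=1)
        np.testing.assert_allclose(out, X - ref_mean[:, None], atol=1e-12)

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            sm.relative_expression(make_norm(np.ones((3, 3))), ["nope"])


class TestSmoothing:
    def test_constant_profile_unchanged(self):
        block = np.full((20, 2), 1.7)
        np.testing.assert_allclose(
            _moving_average_block(block, 5), block, atol=1e-14
        )

    def test_edge_truncation_arithmetic(self):
        # spike 3.0 at a chromosome end, window 3: edge mean over 2 entries
        block = np.zeros((5, 1))
        block[0, 0] = 3.0
        out = _moving_average_block(block, 3)
        assert out[0, 0] == pytest.approx(1.5)
        assert out[1, 0] == pytest.approx(1.0)

    @pytest.mark.parametrize("window", [3, 11, 101])
    def test_matches_brute_force_oracle(self, window):
        rng = np.random.default_rng(window)
        block = rng.normal(size=(200, 7))
        np.testing.assert_allclose(
            _moving_average_block(block, window),
            brute_force_smooth(block, window),
            atol=1e-12,
        )

    def test_no_leakage_across_chromosomes(self):
        from scmalig.cnv import smooth_genome

        idx = ordered_index(["chr1"] * 30 + ["chr2"] * 30,
                            list(range(1, 31)) + list(range(1, 31)))
        rng = np.random.default_rng(8)
        centered = rng.normal(size=(60, 10))
        s1 = smooth_genome(centered, idx, window=5)
        permuted = centered.copy()
        permuted[:30] = centered[:30][rng.permutation(30)]
        s2 = smooth_genome(permuted, idx, window=5)
        np.testing.assert_allclose(s1[30:], s2[30:], atol=1e-12)
        assert np.abs(s1[:30] - s2[:30]).max() > 0.01  # chr1 did change

    def test_reference_residuals_center_on_zero(self, processed):
        prof = processed["profile"]
        ref_idx = [list(prof.cell_ids).index(c) for c in prof.reference_cells]
        per_gene = prof.values[:, ref_idx].mean(axis=1)
        assert np.abs(per_gene).max() < 1e-10

    def test_even_window_rejected(self):
        idx = ordered_index(["chr1"] * 4, [1, 2, 3, 4])
        with pytest.raises(ValueError):
            sm.smooth_and_center(np.zeros((4, 2)), idx, ["a", "b"], ["a"],
                                 window=4)


class TestCnvScore:
    def test_closed_forms(self):
        idx = ordered_index(["chr1"] * 3, [1, 2, 3])
        prof = sm.CNVProfile(np.array([[0.1, 0.0], [-0.1, 0.0], [0.2, 0.0]]),
                             idx, np.array(["a", "b"], dtype=object), ["b"],
                             3.0, 101)
        s = sm.cnv_score(prof)
        assert s["a"] == pytest.approx(0.02, abs=1e-15)
        assert s["b"] == 0.0
        assert sm.cnv_score(prof, method="sum_square")["a"] == pytest.approx(0.06)

    def test_clone_scores_exceed_normal(self, processed):
        meta, scores = processed["meta"], processed["scores"]
        clone = scores[(meta["clone_id"] == "clone1").to_numpy()]
        normal = scores[(meta["clone_id"] == "normal").to_numpy()]
        assert clone.mean() > normal.mean()
        _, p = sm.rank_sum_test(clone.to_numpy(), normal.to_numpy())
        assert p < 0.01

    def test_monotone_in_copy_ratio(self):
        """Mean CNV score rises with |copy_ratio - 1| across a ratio grid."""
        from scmalig.synthetic import CloneSpec, CnvSegment

        ratios = [1.25, 1.5, 2.0, 3.0]
        means = []
        for ratio in ratios:
            cfg = sm.default_config(
                11, n_genes=400, n_chromosomes=5, n_mito_genes=5, n_nt=80,
                n_tumor_normal=20, subtype_program_size=5,
                frac_low_quality=0.0,
            )
            cfg.clones = [CloneSpec("cl", 100,
                                    [CnvSegment("chr3", 0, 40, ratio)])]
            counts, ann, cells, _ = sm.generate_cohort(cfg)
            filt, _ = sm.qc_filter(counts, ann)
            norm = sm.normalize(filt)
            meta = cells.reindex(filt.cell_ids)
            ref = meta.index[meta["group"] == "NT"].tolist()
            prof = sm.infer_cnv(norm, ann, ref, window=21)
            sc = sm.cnv_score(prof)
            means.append(sc[(meta["clone_id"] == "cl").to_numpy()].mean())
        rho, _ = sm.spearman_corr(ratios, means)
        assert rho == pytest.approx(1.0)

    def test_two_clone_scores_bimodal(self, two_clone_malignant_scores):
        _, p = sm.dip_pvalue(two_clone_malignant_scores, n_boot=200, seed=5)
        assert p < 0.05
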