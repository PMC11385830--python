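import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import polygamma

from emtstage import bulk_dsp, simdata
from emtstage.bulk_dsp import (
    GSEAResult,
    _trigamma_inverse,
    estimate_variance_prior,
    hier_cluster,
    moderated_t_test,
    paired_t_per_gene,
    preranked_gsea,
    q3_normalize,
)
from emtstage.containers import PairedSegmentsMatrix
from emtstage.scoring import GeneSetCollection


def _expr(values):
    values = np.asarray(values, dtype=float)
    return pd.DataFrame(
        values,
        index=pd.Index([f"g{i}" for i in range(values.shape[0])], name="gene"),
        columns=[f"s{i}" for i in range(values.shape[1])],
    )


def _segments(pos, neg, rois=None):
    pos, neg = np.asarray(pos, float), np.asarray(neg, float)
    n_rois = pos.shape[1]
    rois = rois or [f"ROI{i+1}" for i in range(n_rois)]
    cols, ann, vals = [], [], []
    for i, r in enumerate(rois):
        for seg, block in (("vim_pos", pos), ("vim_neg", neg)):
            cols.append(f"{r}_{seg}")
            ann.append({"roi_id": r, "segment": seg})
            vals.append(block[:, i])
    values = pd.DataFrame(
        np.column_stack(vals),
        index=pd.Index([f"g{i}" for i in range(pos.shape[0])], name="gene"),
        columns=cols,
    )
    return PairedSegmentsMatrix(values, pd.DataFrame(ann, index=cols))


class TestTrigammaInverse:
    @pytest.mark.parametrize("x", [0.1, 0.5, 2.0, 10.0, 100.0])
    def test_roundtrip(self, x):
        assert _trigamma_inverse(float(polygamma(1, x))) == pytest.approx(x, rel=1e-6)


class TestVariancePrior:
    def test_recovers_simulated_prior(self):
        rng = np.random.default_rng(0)
        d0, s0_sq, d_g = 8.0, 2.0, 4
        s2 = s0_sq * rng.f(d_g, d0, size=20000) * 1.0
        d0_hat, s0_hat = estimate_variance_prior(s2, d_g)
        assert d0_hat == pytest.approx(d0, rel=0.15)
        assert s0_hat == pytest.approx(s0_sq, rel=0.1)

    def test_underdispersed_gives_infinite_d0(self):
        s2 = np.full(100, 3.0)  # no spread at all
        d0, s0 = estimate_variance_prior(s2, 4)
        assert np.isinf(d0)


class TestModeratedT:
    def test_d0_zero_equals_ordinary_t(self):
        rng = np.random.default_rng(1)
        expr = _expr(rng.normal(5, 1, size=(50, 6)))
        res = moderated_t_test(expr, ["E"] * 3 + ["M"] * 3, d0_override=0.0)
        np.testing.assert_allclose(
            res.table["t_moderated"], res.table["t_ordinary"], atol=1e-12
        )

    def test_hand_shrinkage_formula_3v3(self):
        rng = np.random.default_rng(2)
        expr = _expr(rng.normal(0, 1, size=(40, 6)))
        res = moderated_t_test(expr, ["E"] * 3 + ["M"] * 3)
        d_g = 4
        # formula oracle recomputed by hand from the reported prior
        expected = (res.d0 * res.s0_sq + d_g * res.table["s2"]) / (res.d0 + d_g)
        np.testing.assert_allclose(res.table["s2_post"], expected, atol=1e-12)
        # moderated t from first principles
        m1 = expr.iloc[:, :3].mean(axis=1)
        m2 = expr.iloc[:, 3:].mean(axis=1)
        t_hand = (m2 - m1) / np.sqrt(res.table["s2_post"] * (1 / 3 + 1 / 3))
        np.testing.assert_allclose(res.table["t_moderated"], t_hand, atol=1e-12)

    def test_s2_post_between_prior_and_sample(self):
        rng = np.random.default_rng(3)
        expr = _expr(rng.normal(0, 1, size=(60, 8)))
        res = moderated_t_test(expr, ["E"] * 4 + ["M"] * 4)
        lo = np.minimum(res.table["s2"], res.s0_sq)
        hi = np.maximum(res.table["s2"], res.s0_sq)
        assert ((res.table["s2_post"] >= lo - 1e-12) & (res.table["s2_post"] <= hi + 1e-12)).all()

    def test_d0_infinite_limit_uses_prior_variance(self):
        rng = np.random.default_rng(4)
        expr = _expr(rng.normal(0, 1, size=(30, 6)))
        res = moderated_t_test(expr, ["E"] * 3 + ["M"] * 3, d0_override=np.inf)
        m1 = expr.iloc[:, :3].mean(axis=1)
        m2 = expr.iloc[:, 3:].mean(axis=1)
        z = (m2 - m1) / np.sqrt(res.s0_sq * (2 / 3))
        np.testing.assert_allclose(res.table["t_moderated"], z, atol=1e-10)

    def test_null_fdr_calibrated(self):
        frac = []
        for seed in range(20):
            counts, _ = simdata.simulate_bulk_groups(3, 300, 0.0, 0.0, seed=seed)
            logc = np.log2(1 + counts.to_dense())
            res = moderated_t_test(logc, counts.cell_meta["group"])
            frac.append((res.table["p_adj"] < 0.05).mean())
        assert np.mean(frac) <= 0.05

    def test_group_size_validation(self):
        expr = _expr(np.ones((5, 3)))
        with pytest.raises(ValueError, match=">= 2"):
            moderated_t_test(expr, ["E", "E", "M"])

    def test_two_labels_required(self):
        expr = _expr(np.ones((5, 4)))
        with pytest.raises(ValueError, match="2 group labels"):
            moderated_t_test(expr, ["E", "M", "X", "E"])


class TestQ3:
    def test_identical_aois_factor_one(self):
        rng = np.random.default_rng(5)
        col = rng.uniform(1, 100, 50)
        seg = _segments(np.column_stack([col] * 3), np.column_stack([col] * 3))
        _, factors = q3_normalize(seg)
        np.testing.assert_allclose(factors, 1.0)

    def test_two_aoi_closed_form(self):
        rng = np.random.default_rng(6)
        col = rng.uniform(1, 100, 50)
        seg = _segments(col[:, None] * 2.0, col[:, None])  # vim_pos exactly 2x
        normed, factors = q3_normalize(seg)
        np.testing.assert_allclose(
            sorted(factors), [1 / np.sqrt(2), np.sqrt(2)], rtol=1e-12
        )
        # after scaling the two AOIs agree exactly
        np.testing.assert_allclose(
            normed.segment_columns("vim_pos").to_numpy(),
            normed.segment_columns("vim_neg").to_numpy(),
            rtol=1e-12,
        )

    def test_ranking_preserved(self):
        seg = simdata.simulate_dsp_rois(3, 40, ["E1"], 1.0, seed=7)
        normed, _ = q3_normalize(seg)
        for c in seg.values.columns:
            a = seg.values[c].rank().to_numpy()
            b = normed.values[c].rank().to_numpy()
            np.testing.assert_array_equal(a, b)

    def test_all_zero_aoi_error(self):
        vals = np.ones((4, 2))
        vals[:, 1] = 0
        seg = _segments(vals[:, :1], vals[:, 1:])
        with pytest.raises(ValueError, match="zero"):
            q3_normalize(seg)


class TestPairedT:
    def test_identical_segments_p_one(self):
        rng = np.random.default_rng(8)
        block = rng.uniform(1, 50, size=(20, 4))
        seg = _segments(block, block)
        res = paired_t_per_gene(seg)
        assert (res["t"] == 0).all() and (res["p_raw"] == 1).all()

    def test_four_roi_hand_arithmetic(self):
        # raw-scale differences (1, 2, 1, 2): t = 1.5 / (sd/2)
        neg = np.full((1, 4), 10.0)
        pos = neg + np.array([[1.0, 2.0, 1.0, 2.0]])
        seg = _segments(pos, neg)
        res = paired_t_per_gene(seg, log_transform=False)
        d = np.array([1.0, 2.0, 1.0, 2.0])
        t_hand = d.mean() / (d.std(ddof=1) / 2)
        assert res["t"].iloc[0] == pytest.approx(t_hand)
        assert res["p_raw"].iloc[0] == pytest.approx(
            2 * stats.t.sf(t_hand, df=3)
        )

    def test_sign_flip_negates_t(self):
        seg = simdata.simulate_dsp_rois(5, 30, ["E1", "E2"], 1.0, seed=9)
        res = paired_t_per_gene(seg)
        flipped_ann = seg.annotations.copy()
        flipped_ann["segment"] = flipped_ann["segment"].map(
            {"vim_pos": "vim_neg", "vim_neg": "vim_pos"}
        )
        flipped = PairedSegmentsMatrix(seg.values, flipped_ann)
        res_f = paired_t_per_gene(flipped)
        np.testing.assert_allclose(res["t"], -res_f["t"], atol=1e-12)

    def test_injected_genes_have_smallest_p(self):
        emt = [f"EMT{i}" for i in range(30)]
        seg = simdata.simulate_dsp_rois(9, 300, emt, 1.5, seed=10)
        res = paired_t_per_gene(seg)
        ranks = res["p_raw"].rank()
        assert ranks.loc[emt].mean() < ranks.drop(emt).mean() / 2

    def test_min_pairs(self):
        seg = _segments(np.ones((3, 2)), np.ones((3, 2)))
        with pytest.raises(ValueError, match="3 complete"):
            paired_t_per_gene(seg)

    def test_unpaired_roi_rejected_at_construction(self):
        vals = pd.DataFrame(
            np.ones((3, 3)),
            index=pd.Index(["g0", "g1", "g2"], name="gene"),
            columns=["R1_vim_pos", "R1_vim_neg", "R2_vim_pos"],
        )
        ann = pd.DataFrame(
            {
                "roi_id": ["R1", "R1", "R2"],
                "segment": ["vim_pos", "vim_neg", "vim_pos"],
            },
            index=vals.columns,
        )
        with pytest.raises(ValueError, match="R2"):
            PairedSegmentsMatrix(vals, ann)


class TestPrerankedGSEA:
    def test_top_set_extreme_p(self):
        rng = np.random.default_rng(11)
        ranking = pd.Series(
            np.sort(rng.normal(0, 1, 100))[::-1], index=[f"g{i}" for i in range(100)]
        )
        res = preranked_gsea(
            ranking, GeneSetCollection({"top": [f"g{i}" for i in range(5)]}),
            n_perm=1000, seed=0,
        )
        assert res.table.loc["top", "es"] > 0
        assert res.table.loc["top", "p_nominal"] <= 1.5 / 1001

    def test_random_set_null_behavior(self):
        rng = np.random.default_rng(12)
        genes = [f"g{i}" for i in range(200)]
        ranking = pd.Series(rng.normal(0, 1, 200), index=genes)
        pick = rng.choice(genes, 20, replace=False).tolist()
        res = preranked_gsea(
            ranking, GeneSetCollection({"rand": pick}), n_perm=500, seed=1
        )
        assert res.table.loc["rand", "q"] > 0.05
        assert abs(res.table.loc["rand", "nes"]) < 2.5

    def test_complement_antisymmetry_unweighted(self):
        rng = np.random.default_rng(13)
        genes = [f"g{i}" for i in range(40)]
        ranking = pd.Series(rng.normal(0, 1, 40), index=genes)
        s = genes[:10]
        comp = genes[10:]
        res = preranked_gsea(
            ranking,
            GeneSetCollection({"s": s, "comp": comp}),
            n_perm=50,
            seed=2,
            weight_exponent=0.0,
        )
        assert res.table.loc["s", "es"] == pytest.approx(
            -res.table.loc["comp", "es"], abs=1e-12
        )

    def test_seed_determinism(self):
        rng = np.random.default_rng(14)
        genes = [f"g{i}" for i in range(60)]
        ranking = pd.Series(rng.normal(0, 1, 60), index=genes)
        sets = GeneSetCollection({"s": genes[5:15]})
        a = preranked_gsea(ranking, sets, n_perm=200, seed=7)
        b = preranked_gsea(ranking, sets, n_perm=200, seed=7)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_small_set_skipped(self):
        rng = np.random.default_rng(15)
        genes = [f"g{i}" for i in range(30)]
        ranking = pd.Series(rng.normal(0, 1, 30), index=genes)
        with pytest.warns(UserWarning, match="skipped"):
            res = preranked_gsea(
                ranking,
                GeneSetCollection({"ok": genes[:8], "tiny": genes[:3]}),
                n_perm=50,
                seed=3,
            )
        assert res.skipped_sets == ["tiny"]

    def test_short_ranking_rejected(self):
        ranking = pd.Series([1.0] * 5, index=[f"g{i}" for i in range(5)])
        with pytest.raises(ValueError, match=">= 10"):
            preranked_gsea(ranking, GeneSetCollection({"s": ["g0"]}), 10, 0)

    def test_leading_edge_subset_of_set(self):
        rng = np.random.default_rng(16)
        genes = [f"g{i}" for i in range(50)]
        ranking = pd.Series(rng.normal(0, 1, 50), index=genes)
        sets = GeneSetCollection({"s": genes[:12]})
        res = preranked_gsea(ranking, sets, n_perm=100, seed=4)
        assert set(res.leading_edge["s"]) <= set(genes[:12])


class TestHierCluster:
    def test_duplicated_groups_split_at_root(self):
        rng = np.random.default_rng(17)
        a = rng.uniform(0, 10, 30)
        b = rng.uniform(0, 10, 30)
        mat = pd.DataFrame(
            {
                "a1": a, "a2": a + rng.normal(0, 0.01, 30),
                "b1": b, "b2": b + rng.normal(0, 0.01, 30),
            }
        )
        Z, order = hier_cluster(mat)
        left = {c[0] for c in order[:2]}
        right = {c[0] for c in order[2:]}
        assert len(left) == 1 and len(right) == 1 and left != right

    def test_four_column_manual_trace(self):
        # x ~ y (r=1), z ~ w (r=1), x anti z: merges (x,y) and (z,w) first
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        mat = pd.DataFrame({"x": x, "y": 2 * x, "z": -x, "w": -3 * x + 1})
        Z, order = hier_cluster(mat)
        # first two merges join the perfectly correlated pairs at height 0
        merged = {frozenset(Z[0, :2].astype(int)), frozenset(Z[1, :2].astype(int))}
        assert merged == {frozenset({0, 1}), frozenset({2, 3})}
        assert Z[0, 2] == pytest.approx(0.0, abs=1e-12)
        # root joins the two pairs at average-linkage distance 1 - (-1) = 2
        assert Z[2, 2] == pytest.approx(2.0, abs=1e-9)

    def test_constant_column_error_names_column(self):
        mat = pd.DataFrame({"a": [1.0, 2.0, 3.0], "flat": [5.0, 5.0, 5.0]})
        with pytest.raises(ValueError, match="flat"):
            hier_cluster(mat)

    def test_simulated_segments_split_by_segment(self):
        emt = [f"EMT{i}" for i in range(60)]
        seg = simdata.simulate_dsp_rois(6, 200, emt, 2.0, seed=18, roi_sigma=0.05)
        logv = np.log2(seg.values + 1)
        _, order = hier_cluster(logv)
        labels = [seg.annotations.loc[c, "segment"] for c in order]
        k = labels.count("vim_pos")
        first_half = set(labels[:6])
        assert len(first_half) == 1  # one segment type occupies one side

    def test_single_column_error(self):
        with pytest.raises(ValueError, match="2 columns"):
            hier_cluster(pd.DataFrame({"a": [1.0, 2.0]}))
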