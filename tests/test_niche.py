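"""Niche index, composition, ordering, expression, neighborhoods, dissection."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom, spearmanr

from conftest import make_cells
from nichetrace.niche import (
    NeighborhoodSet,
    annotate_neighborhoods,
    build_niche_index,
    canonical_niche_sets,
    conditional_density,
    dissect_parenchyma,
    enrichment_score,
    gene_trends,
    group_score_test,
    neighborhood_condition_test,
    niche_composition,
    niche_expression,
    order_niches,
    sample_neighborhoods,
    select_enriched_anchors,
)


class TestNicheIndex:
    def test_isolated_cell_is_its_own_niche(self):
        cells = make_cells([[0, 0], [500, 500]])
        idx = build_niche_index(cells, radius=60)
        assert idx.member_counts.tolist() == [1, 1]
        assert idx.members(0).tolist() == [0]

    def test_boundary_inclusive_at_radius(self):
        cells = make_cells([[0, 0], [59, 0]])
        assert build_niche_index(cells, 60).member_counts.tolist() == [2, 2]
        cells = make_cells([[0, 0], [61, 0]])
        assert build_niche_index(cells, 60).member_counts.tolist() == [1, 1]
        cells = make_cells([[0, 0], [60, 0]])
        assert build_niche_index(cells, 60).member_counts.tolist() == [2, 2]

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        cells = make_cells(rng.uniform(0, 400, (400, 2)))
        idx = build_niche_index(cells, radius=60)
        xy = cells[["x_um", "y_um"]].to_numpy()
        d = np.hypot(*(xy[:, None, :] - xy[None, :, :]).transpose(2, 0, 1))
        oracle = d <= 60
        np.testing.assert_array_equal(idx.membership.toarray(), oracle)

    def test_niches_never_span_samples(self):
        cells = make_cells([[0, 0], [10, 0]])
        cells.loc[cells.index[1], "sample"] = "s1"
        idx = build_niche_index(cells, radius=60)
        assert idx.member_counts.tolist() == [1, 1]

    def test_anchor_filter(self):
        cells = make_cells([[0, 0], [10, 0], [20, 0]])
        idx = build_niche_index(cells, 60, anchor_filter=[True, False, True])
        assert idx.membership.shape == (2, 3)
        assert idx.anchors.tolist() == [0, 2]

    def test_bad_radius(self):
        with pytest.raises(ValueError):
            build_niche_index(make_cells([[0, 0]]), radius=0)


class TestComposition:
    def test_small_compartment_masked_in_state_fractions(self):
        xy = np.zeros((10, 2))
        cells = make_cells(xy)
        comp = ["epithelial"] * 5 + ["fibroblast"] * 5
        cells["compartment"] = comp
        cells["state"] = ["gastric-like"] * 5 + ["Tnc-myCAF"] * 5
        idx = build_niche_index(cells, radius=60)
        counts, frac = niche_composition(idx, cells, level="compartment")
        np.testing.assert_allclose(frac["epithelial"], 0.5)
        _, sfrac = niche_composition(idx, cells, level="state",
                                     min_compartment_cells=10)
        assert sfrac["Tnc-myCAF"].isna().all()  # 5 fibroblasts < 10

    def test_single_cell_niche_fraction_one(self):
        cells = make_cells([[0, 0]])
        idx = build_niche_index(cells, 60)
        counts, frac = niche_composition(idx, cells, level="compartment")
        assert frac.loc["c0", "epithelial"] == 1.0

    def test_matches_hand_count(self):
        rng = np.random.default_rng(1)
        xy = rng.uniform(0, 150, (30, 2))
        cells = make_cells(xy)
        comps = rng.choice(["epithelial", "fibroblast", "myeloid"], 30)
        cells["compartment"] = comps
        cells["state"] = comps
        idx = build_niche_index(cells, radius=50)
        counts, _ = niche_composition(idx, cells, level="compartment")
        d = np.hypot(*(xy[:, None] - xy[None]).transpose(2, 0, 1))
        for i in range(30):
            members = d[i] <= 50
            for c in ["epithelial", "fibroblast", "myeloid"]:
                assert counts.iloc[i][c] == (members & (comps == c)).sum()

    def test_mixed_cells_excluded_from_fractions(self):
        cells = make_cells(np.zeros((4, 2)))
        cells["compartment"] = ["epithelial", "epithelial", "mixed", "mixed"]
        cells["state"] = ["gastric-like"] * 2 + ["mixed"] * 2
        idx = build_niche_index(cells, 60)
        counts, frac = niche_composition(idx, cells, level="compartment")
        assert counts.loc["c0", "mixed"] == 2  # counts keep everything
        np.testing.assert_allclose(frac["epithelial"], 1.0)


class TestOrderNiches:
    def _tissue(self):
        rng = np.random.default_rng(2)
        xy = rng.uniform(0, 300, (200, 2))
        cells = make_cells(xy, state="gastric-like")
        dc = pd.Series(xy[:, 0] / 300.0, index=cells.index)
        return cells, dc

    def test_uniform_dc_gives_that_mean(self):
        cells = make_cells(np.zeros((12, 2)), state="progenitor-like")
        dc = pd.Series(0.7, index=cells.index)
        idx = build_niche_index(cells, 60)
        b = order_niches(idx, dc, states=cells["state"], min_epithelial=10)
        np.testing.assert_allclose(b.niche_dc, 0.7)

    def test_mean_of_mixed_values(self):
        cells = make_cells(np.zeros((10, 2)),
                           state=["gastric-like"] * 5 + ["progenitor-like"] * 5)
        dc = pd.Series([0.2] * 5 + [0.8] * 5, index=cells.index)
        idx = build_niche_index(cells, 60)
        b = order_niches(idx, dc, states=cells["state"], min_epithelial=10)
        np.testing.assert_allclose(b.niche_dc, 0.5)

    def test_below_minimum_unbinned(self):
        cells = make_cells(np.zeros((5, 2)), state="gastric-like")
        dc = pd.Series(0.5, index=cells.index)
        idx = build_niche_index(cells, 60)
        with pytest.raises(ValueError):
            order_niches(idx, dc, states=cells["state"], min_epithelial=10)

    def test_permutation_invariance(self):
        cells, dc = self._tissue()
        idx = build_niche_index(cells, 60)
        b1 = order_niches(idx, dc, states=cells["state"], min_epithelial=3,
                          n_bins=20)
        perm = np.random.default_rng(0).permutation(len(cells))
        cells2 = cells.iloc[perm]
        idx2 = build_niche_index(cells2, 60)
        b2 = order_niches(idx2, dc[cells2.index], states=cells2["state"],
                          min_epithelial=3, n_bins=20)
        np.testing.assert_allclose(b1.niche_dc[perm], b2.niche_dc)
        np.testing.assert_array_equal(b1.bin_id[perm], b2.bin_id)

    def test_recovers_local_truth_on_synthetic_tissue(self, small_tissue):
        cells, _, truth = small_tissue
        epi = cells["state"].isin(["gastric-like", "progenitor-like"])
        idx = build_niche_index(cells, 60)
        b = order_niches(idx, truth.latent, states=cells["state"],
                         min_epithelial=10)
        ok = np.isfinite(b.niche_dc)
        rho = spearmanr(b.niche_dc[ok], truth.local_dc.to_numpy()[ok]).statistic
        assert rho >= 0.9


class TestNicheExpression:
    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        n = 40
        xy = rng.uniform(0, 200, (n, 2))
        cells = make_cells(xy)
        comps = rng.choice(["epithelial", "fibroblast"], n)
        cells["compartment"] = comps
        X = rng.poisson(3, (n, 6)).astype(float)
        idx = build_niche_index(cells, radius=70)
        genes = pd.Index([f"g{i}" for i in range(6)])
        tensor = niche_expression(idx, X, cells["compartment"], genes,
                                  log1p=True)
        d = np.hypot(*(xy[:, None] - xy[None]).transpose(2, 0, 1))
        for c in ["epithelial", "fibroblast"]:
            S = np.array([X[(d[i] <= 70) & (comps == c)].sum(axis=0)
                          for i in range(n)])
            size = S.sum(axis=1)
            mask = size > 0
            med = np.median(size[mask])
            norm = np.log1p(S[mask] / size[mask, None] * med)
            mu, sd = norm.mean(axis=0), norm.std(axis=0)
            sd = np.where(sd > 0, sd, 1.0)
            z = (norm - mu) / sd
            np.testing.assert_allclose(tensor.z[c][mask], z, atol=1e-10)
            np.testing.assert_array_equal(tensor.mask[c], mask)

    def test_z_slices_standardized(self, small_tissue):
        cells, adata, _ = small_tissue
        idx = build_niche_index(cells, 60)
        tensor = niche_expression(idx, adata.X, cells["compartment"],
                                  adata.var_names,
                                  which_compartments=["fibroblast"])
        z, mask = tensor.z["fibroblast"], tensor.mask["fibroblast"]
        mean = z[mask].mean(axis=0)
        sd = z[mask].std(axis=0)
        np.testing.assert_allclose(mean, 0.0, atol=1e-8)
        varying = sd > 0.5  # genes with real variation must have SD 1
        np.testing.assert_allclose(sd[varying], 1.0, atol=1e-6)

    def test_absent_compartment_masked_not_zero(self):
        cells = make_cells([[0, 0], [500, 0]])
        cells["compartment"] = ["epithelial", "fibroblast"]
        idx = build_niche_index(cells, 60)
        genes = pd.Index(["g"])
        tensor = niche_expression(idx, np.array([[5.0], [5.0]]),
                                  cells["compartment"], genes)
        assert not tensor.mask["fibroblast"][0]
        assert np.isnan(tensor.normalized["fibroblast"][0, 0])


class TestGeneTrends:
    def _toy_tensor_binning(self):
        from nichetrace.niche import NicheBinning, NicheExpressionTensor

        n, m = 150, 3
        dcv = np.linspace(0, 1, n)
        z = np.column_stack([
            np.zeros(n),  # flat
            (dcv - dcv.mean()) / dcv.std(),  # linear rise
            -(dcv - dcv.mean()) / dcv.std(),  # linear fall
        ])
        tensor = NicheExpressionTensor(
            z={"epithelial": z}, normalized={"epithelial": z},
            mask={"epithelial": np.ones(n, bool)},
            genes=pd.Index(["flat", "rise", "fall"]),
            compartments=["epithelial"],
        )
        edges = np.linspace(0, 1, 11)
        bin_id = np.clip(np.searchsorted(edges, dcv, "right") - 1, 0, 9)
        binning = NicheBinning(niche_dc=dcv, bin_id=bin_id, bin_edges=edges,
                               n_bins=10)
        return tensor, binning

    def test_flat_gene_is_flat_and_linear_is_monotone(self):
        tensor, binning = self._toy_tensor_binning()
        trends, orders = gene_trends(tensor, binning, landmark="argmax")
        t = trends["epithelial"]
        np.testing.assert_allclose(t[:, 0], 0.0, atol=1e-12)
        assert (np.diff(t[:, 1]) > 0).all()
        assert np.nanargmax(t[:, 1]) == 9  # rises to the last occupied bin

    def test_ordering_by_landmark_with_name_tiebreak(self):
        tensor, binning = self._toy_tensor_binning()
        _, orders = gene_trends(tensor, binning, landmark="argmax")
        assert list(orders["epithelial"]) == ["fall", "flat", "rise"]


class TestCanonicalSets:
    def test_split_follows_median_rule(self):
        from nichetrace.niche import NicheBinning

        n = 100
        dcv = np.linspace(0, 1, n)
        frac = pd.DataFrame({
            "progenitor-like": dcv,
            "gastric-like": 1 - dcv,
        })
        edges = np.linspace(0, 1, 11)
        bin_id = np.clip(np.searchsorted(edges, dcv, "right") - 1, 0, 9)
        binning = NicheBinning(dcv, bin_id, edges, 10)
        sets = canonical_niche_sets(frac, binning)
        # progenitor fraction exceeds gastric above 0.5 -> top 5 bins
        assert sets["progenitor_bins"] == [5, 6, 7, 8, 9]
        assert sets["gastric_bins"] == [0, 1, 2, 3, 4]
        assert sets["progenitor_pct"] == pytest.approx(50.0, abs=2)

    def test_all_gastric_tissue_gives_empty_progenitor_set(self):
        from nichetrace.niche import NicheBinning

        n = 50
        dcv = np.linspace(0, 1, n)
        frac = pd.DataFrame({"progenitor-like": np.zeros(n),
                             "gastric-like": np.ones(n)})
        edges = np.linspace(0, 1, 11)
        bin_id = np.clip(np.searchsorted(edges, dcv, "right") - 1, 0, 9)
        with pytest.warns(UserWarning, match="no bin"):
            sets = canonical_niche_sets(frac, NicheBinning(dcv, bin_id, edges, 10))
        assert len(sets["progenitor_niches"]) == 0


class TestEnrichment:
    def test_niche_fraction_equal_to_dataset_scores_zero(self):
        cells = make_cells(np.zeros((10, 2)),
                           state=["progenitor-like"] * 5 + ["gastric-like"] * 5)
        idx = build_niche_index(cells, 60)
        s = enrichment_score(idx, cells, "progenitor-like")
        np.testing.assert_allclose(s, 0.0, atol=1e-12)

    def test_gate_excludes_boundary(self):
        prog = np.array([2.0, 2.1])
        gast = np.array([-1.0, -1.0])
        sel = select_enriched_anchors(prog, gast)
        assert sel.tolist() == [False, True]

    def test_mean_score_near_zero_under_uniform_labels(self):
        rng = np.random.default_rng(7)
        n = 5000
        xy = rng.uniform(0, 2000, (n, 2))
        cells = make_cells(xy)
        cells["state"] = rng.choice(["progenitor-like", "gastric-like"], n)
        idx = build_niche_index(cells, 60)
        s = enrichment_score(idx, cells, "progenitor-like")
        assert abs(np.nanmean(s)) < 0.05

    def test_absent_state_raises(self):
        cells = make_cells(np.zeros((3, 2)), state="gastric-like")
        idx = build_niche_index(cells, 60)
        with pytest.raises(ValueError, match="absent"):
            enrichment_score(idx, cells, "progenitor-like")


class TestNeighborhoods:
    def _setup(self):
        rng = np.random.default_rng(8)
        xy = rng.uniform(0, 400, (60, 2))
        cells = make_cells(xy)
        cells["state"] = (["progenitor-like"] * 20 + ["gastric-like"] * 20
                          + ["Tnc-myCAF"] * 20)
        idx = build_niche_index(cells, 60)
        return cells, idx

    def test_pure_neighborhood_retained_with_infinite_dominance(self):
        cells, idx = self._setup()
        nbhd = NeighborhoodSet(members={0: np.arange(10),
                                        1: np.array([0, 1, 2, 20, 21])})
        out = annotate_neighborhoods(nbhd, cells, idx)
        assert out.dominance_ratio[0] == np.inf
        assert not out.excluded[0]
        assert out.dominant_state[0] == "progenitor-like"

    def test_dominance_ratio_value(self):
        cells, idx = self._setup()
        members = np.r_[np.arange(15), np.arange(20, 25)]  # 15 prog, 5 gastric
        nbhd = NeighborhoodSet(members={0: members})
        out = annotate_neighborhoods(nbhd, cells, idx)
        assert out.dominance_ratio[0] == pytest.approx(3.0)

    def test_lowest_quantile_mixed_excluded(self):
        cells, idx = self._setup()
        members = {i: np.array([i, i + 1, 20 + i]) for i in range(15)}
        members[15] = np.array([0, 20, 21, 22, 23, 24, 25])  # weakly dominant
        nbhd = annotate_neighborhoods(
            NeighborhoodSet(members=members), cells, idx,
            purity_exclusion_quantile=0.07,
        )
        assert any(nbhd.excluded.values())
        # the flagged one has the smallest dominance ratio
        flagged = [k for k, v in nbhd.excluded.items() if v]
        ratios = {k: v for k, v in nbhd.dominance_ratio.items()
                  if np.isfinite(v)}
        assert min(ratios, key=ratios.get) in flagged

    def test_empty_neighborhood_raises(self):
        cells, idx = self._setup()
        with pytest.raises(ValueError, match="empty"):
            annotate_neighborhoods(
                NeighborhoodSet(members={0: np.array([], int)}), cells, idx
            )

    def test_sampler_shapes(self):
        rng = np.random.default_rng(0)
        latent = rng.normal(0, 1, (100, 5))
        nbhd = sample_neighborhoods(latent, prop=0.1, k=8, seed=1)
        assert len(nbhd.members) == 10
        assert all(len(v) == 8 for v in nbhd.members.values())


class TestConditionTest:
    def test_balanced_neighborhood_null(self):
        cond = np.array(["a", "b"] * 50)
        nbhd = NeighborhoodSet(members={0: np.arange(20)})  # 10 a, 10 b
        out = neighborhood_condition_test(nbhd, cond)
        assert out.loc[0, "p"] == pytest.approx(1.0)
        assert out.loc[0, "lfc"] == pytest.approx(0.0)

    def test_matches_hypergeometric_tail(self):
        # table (20, 0 | 80, 100): p = two-sided Fisher
        cond = np.array(["a"] * 100 + ["b"] * 100)
        members = np.arange(20)  # all condition a
        out = neighborhood_condition_test(
            NeighborhoodSet(members={0: members}), cond
        )
        # brute-force two-sided Fisher: sum of table probabilities <= observed
        rv = hypergeom(200, 100, 20)
        p_obs = rv.pmf(20)
        brute = sum(rv.pmf(k) for k in range(21) if rv.pmf(k) <= p_obs + 1e-12)
        assert out.loc[0, "p"] == pytest.approx(brute, rel=1e-6)

    def test_single_condition_raises(self):
        with pytest.raises(ValueError):
            neighborhood_condition_test(
                NeighborhoodSet(members={0: np.arange(3)}),
                np.array(["a"] * 10),
            )

    def test_type_one_error_controlled_under_permutation(self):
        rng = np.random.default_rng(9)
        n = 2000
        cond = rng.permutation(np.array(["a", "b"]).repeat(n // 2))
        members = {i: rng.choice(n, 30, replace=False) for i in range(200)}
        out = neighborhood_condition_test(NeighborhoodSet(members=members),
                                          cond)
        assert (out["q"] < 0.1).mean() <= 0.1


class TestConditionalDensity:
    def test_columns_sum_to_one(self):
        rng = np.random.default_rng(10)
        x = rng.uniform(0, 1, 2000)
        y = rng.uniform(0, 1, 2000)
        D, _, _ = conditional_density(x, y, 10, 10)
        sums = np.nansum(D, axis=1)
        occupied = ~np.isnan(D).all(axis=1)
        np.testing.assert_allclose(sums[occupied], 1.0)

    def test_deterministic_relation_single_bin_per_column(self):
        x = np.linspace(0.01, 1, 500)
        y = x**2
        D, _, _ = conditional_density(x, y, 8, 8)
        for col in D:
            if not np.isnan(col).all():
                assert (col > 0).sum() <= 2  # edge effects at bin borders

    def test_independent_axes_have_similar_columns(self):
        rng = np.random.default_rng(11)
        x = rng.uniform(0.01, 1, 10000)
        y = rng.uniform(0.01, 1, 10000)
        D, _, _ = conditional_density(x, y, 5, 5)
        cols = D[~np.isnan(D).all(axis=1)]
        tv = 0.5 * np.abs(cols[:, None, :] - cols[None, :, :]).sum(axis=2)
        assert tv.max() < 0.1

    def test_all_zero_vector_raises(self):
        with pytest.raises(ValueError, match="pseudocount"):
            conditional_density(np.zeros(10), np.ones(10), 3, 3)


class TestGroupScoreTest:
    def _tensor(self, scores_a, scores_b):
        """One compartment, one gene; niches carry the given z-scores."""
        from nichetrace.niche import NicheExpressionTensor

        z = np.array(scores_a + scores_b, dtype=float)[:, None]
        return NicheExpressionTensor(
            z={"fibroblast": z}, normalized={"fibroblast": z},
            mask={"fibroblast": np.ones(len(z), bool)},
            genes=pd.Index(["g"]), compartments=["fibroblast"],
        )

    def test_exact_rank_sum_p_for_separated_groups(self):
        # per-replicate scores (1,2,3) vs (4,5,6): two-sided exact p = 0.1
        tensor = self._tensor([1, 2, 3], [4, 5, 6])
        sets = {"progenitor_niches": [3, 4, 5], "gastric_niches": [0, 1, 2]}
        reps = np.array(["r1", "r2", "r3", "r4", "r5", "r6"])
        out = group_score_test(tensor, ["g"], sets, reps)
        assert out.loc["fibroblast", "p"] == pytest.approx(0.1)

    def test_identical_groups_p_near_one(self):
        tensor = self._tensor([1, 2, 3], [1, 2, 3])
        sets = {"progenitor_niches": [3, 4, 5], "gastric_niches": [0, 1, 2]}
        reps = np.array(["r1", "r2", "r3"] * 2)
        out = group_score_test(tensor, ["g"], sets, reps)
        assert out.loc["fibroblast", "p"] == pytest.approx(1.0)

    def test_planted_upregulated_gene_set_detected(self, small_tissue):
        cells, adata, truth = small_tissue
        idx = build_niche_index(cells, 60)
        tensor = niche_expression(idx, adata.X, cells["compartment"],
                                  adata.var_names,
                                  which_compartments=["fibroblast"])
        b = order_niches(idx, truth.latent, states=cells["state"],
                         min_epithelial=10)
        ok = np.flatnonzero(b.bin_id >= 0)
        dc = b.niche_dc[ok]
        hi = ok[dc >= np.quantile(dc, 0.7)]
        lo = ok[dc <= np.quantile(dc, 0.3)]
        sets = {"progenitor_niches": hi, "gastric_niches": lo}
        reps = np.random.default_rng(0).choice(
            [f"m{i}" for i in range(6)], idx.membership.shape[0]
        )
        genes = truth.modules["fibroblast"]["fib_wound"]
        out = group_score_test(tensor, genes, sets, reps)
        assert out.loc["fibroblast", "p"] < 0.05
        a = np.mean(out.loc["fibroblast", "scores_progenitor_niches"])
        g = np.mean(out.loc["fibroblast", "scores_gastric_niches"])
        assert a > g


class TestDissect:
    def test_distance_boundary(self):
        cells = make_cells([[0, 0], [199, 0], [201, 0]])
        cells["compartment"] = ["epithelial", "fibroblast", "fibroblast"]
        cells["state"] = cells["compartment"]
        mask, frac = dissect_parenchyma(cells)
        assert mask.tolist() == [True, True, False]

    def test_lymph_node_size_rule_strictly_greater(self):
        # a tight blob of n lymphoid cells within 30 um links
        def blob(n):
            # grid blob with 5-um spacing close to an epithelial cell, so the
            # 200-um parenchyma rule keeps every blob cell
            pts = [(100 + 5 * (i % 20), 5 * (i // 20)) for i in range(n)]
            cells = make_cells([[147, 30]] + pts)
            cells["compartment"] = ["epithelial"] + ["lymphoid"] * n
            cells["state"] = ["gastric-like"] + ["B-cell"] * n
            return cells

        mask250, _ = dissect_parenchyma(blob(250))
        assert mask250[1:].all()  # exactly 250 cells: retained
        mask251, _ = dissect_parenchyma(blob(251))
        assert not mask251[1:].any()  # 251 cells: excluded

    def test_no_epithelium_raises(self):
        cells = make_cells([[0, 0]], compartment="fibroblast")
        with pytest.raises(ValueError, match="epithelial"):
            dissect_parenchyma(cells)

    def test_matches_planted_lymph_node_truth(self):
        from nichetrace.simdata import SimConfig, generate_tissue

        cfg = SimConfig(seed=13, n_lesions=2, cells_per_lesion=(60, 80),
                        stroma_density=300, fov=(1200, 1200),
                        lesion_centers=[(300.0, 300.0), (400.0, 500.0)],
                        lymph_nodes=[((1000.0, 1000.0), 70.0, 400)])
        cells, _, truth = generate_tissue(cfg)
        mask, _ = dissect_parenchyma(cells)
        in_node = (truth.lymph_node_id >= 0).to_numpy()
        assert not mask[in_node].any()
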