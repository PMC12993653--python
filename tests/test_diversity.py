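"""Diversity statistics against hand computations and brute-force oracles."""

from itertools import permutations

import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix

from conftest import tree_from_newick
from rhizosignal.diversity import (
    alpha_diversity,
    beta_dispersion,
    pcoa,
    permanova,
    time_comparison,
    unweighted_unifrac,
)
from rhizosignal.io import CountTable, RhizosignalError, SampleMetadata


# ---------------------------------------------------------------------------
# alpha diversity
# ---------------------------------------------------------------------------


class TestAlphaDiversity:
    def test_two_equal_counts_give_ln2(self, cherry_tree):
        table = CountTable(["A", "B", "C"], ["s"], np.array([[1], [1], [0]]))
        alpha = alpha_diversity(table, cherry_tree)
        assert alpha.loc["s", "shannon"] == pytest.approx(np.log(2))
        assert alpha.loc["s", "richness"] == 2

    def test_all_taxa_present_pd_is_total_branch_length(self, six_tip_tree):
        taxa = [t.name for t in six_tip_tree.tips()]
        table = CountTable(taxa, ["s"], np.ones((6, 1), dtype=int))
        total = sum(n.length or 0 for n in six_tip_tree.traverse(include_self=False))
        alpha = alpha_diversity(table, six_tip_tree)
        assert alpha.loc["s", "faith_pd"] == pytest.approx(total)

    def test_faith_pd_matches_hand_enumerated_paths(self):
        # ((A:1,B:2):1.5,(C:0.7,D:0.3):0.5) with A and C present:
        # branches A(1) + AB-stem(1.5) + C(0.7) + CD-stem(0.5) = 3.7
        tree = tree_from_newick("((A:1,B:2):1.5,(C:0.7,D:0.3):0.5);")
        table = CountTable(["A", "B", "C", "D"], ["s"], np.array([[3], [0], [1], [0]]))
        alpha = alpha_diversity(table, tree)
        assert alpha.loc["s", "faith_pd"] == pytest.approx(3.7)

    def test_taxon_missing_from_tree_errors(self, cherry_tree):
        table = CountTable(["A", "Z"], ["s"], np.array([[1], [1]]))
        with pytest.raises(RhizosignalError, match="absent"):
            alpha_diversity(table, cherry_tree)


# ---------------------------------------------------------------------------
# unweighted UniFrac vs a per-branch tally oracle
# ---------------------------------------------------------------------------


def unifrac_branch_walk(tree, present_a: set, present_b: set) -> float:
    """Independent oracle: walk every branch, tally shared vs unshared."""
    unique = shared_or = 0.0
    for node in tree.traverse(include_self=False):
        below = {t.name for t in node.tips()} or {node.name}
        in_a = bool(below & present_a)
        in_b = bool(below & present_b)
        length = node.length or 0.0
        if in_a or in_b:
            shared_or += length
            if in_a != in_b:
                unique += length
    return unique / shared_or if shared_or else 0.0


class TestUnweightedUnifrac:
    def test_identical_presence_sets_give_zero(self, six_tip_tree):
        taxa = [t.name for t in six_tip_tree.tips()]
        col = np.array([[1], [0], [2], [0], [1], [0]])
        table = CountTable(taxa, ["x", "y"], np.hstack([col, 5 * col]))
        dm = unweighted_unifrac(table, six_tip_tree)
        assert dm["x", "y"] == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_tips_share_no_branches(self):
        # unit tip branches, zero-length internal stems: nothing is shared
        tree = tree_from_newick("((A:1,B:1):0.0,(C:1,D:1,E:1):0.0);")
        taxa = ["A", "B", "C", "D", "E"]
        counts = np.array([[1, 0], [1, 0], [0, 1], [0, 1], [0, 0]])
        table = CountTable(taxa, ["x", "y"], counts)
        dm = unweighted_unifrac(table, tree)
        assert dm["x", "y"] == pytest.approx(1.0)

    def test_matches_branch_walk_oracle_on_random_fixtures(self, six_tip_tree):
        taxa = [t.name for t in six_tip_tree.tips()]
        rng = np.random.default_rng(8)
        counts = (rng.random((6, 5)) < 0.6).astype(int)
        counts[:, counts.sum(axis=0) == 0] = 1  # no empty samples
        table = CountTable(taxa, [f"s{j}" for j in range(5)], counts)
        dm = unweighted_unifrac(table, six_tip_tree)
        for a in range(5):
            for b in range(a + 1, 5):
                pa = {taxa[i] for i in range(6) if counts[i, a] > 0}
                pb = {taxa[i] for i in range(6) if counts[i, b] > 0}
                oracle = unifrac_branch_walk(six_tip_tree, pa, pb)
                assert dm[f"s{a}", f"s{b}"] == pytest.approx(oracle, abs=1e-10)

    def test_metric_properties_on_random_fixtures(self, six_tip_tree):
        taxa = [t.name for t in six_tip_tree.tips()]
        rng = np.random.default_rng(21)
        counts = (rng.random((6, 6)) < 0.5).astype(int)
        counts[:, counts.sum(axis=0) == 0] = 1
        table = CountTable(taxa, [f"s{j}" for j in range(6)], counts)
        d = unweighted_unifrac(table, six_tip_tree).data
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0)
        for i in range(6):
            for j in range(6):
                for k in range(6):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-12

    def test_empty_sample_errors(self, star_tree):
        taxa = [t.name for t in star_tree.tips()]
        counts = np.zeros((5, 2), dtype=int)
        counts[0, 0] = 1
        table = CountTable(taxa, ["x", "y"], counts)
        with pytest.raises(RhizosignalError, match="no taxa"):
            unweighted_unifrac(table, star_tree)


# ---------------------------------------------------------------------------
# PCoA
# ---------------------------------------------------------------------------


class TestPcoa:
    def test_collinear_points_embed_exactly_on_axis_one(self):
        pts = np.array([0.0, 3.0, 7.0])
        d = np.abs(pts[:, None] - pts[None, :])
        res = pcoa(d, sample_ids=["a", "b", "c"])
        x = res.coordinates[:, 0]
        recon = np.abs(x[:, None] - x[None, :])
        np.testing.assert_allclose(recon, d, atol=1e-8)
        assert np.all(np.abs(res.eigenvalues[1:]) < 1e-8)

    def test_duplicate_samples_coincide(self):
        pts = np.array([[0, 0], [1, 2], [1, 2], [3, 1]], dtype=float)
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        res = pcoa(d)
        np.testing.assert_allclose(res.coordinates[1], res.coordinates[2], atol=1e-8)

    def test_matches_direct_gower_formula(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(8, 3))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        res = pcoa(d)
        # oracle: explicit double-centering and Gram reconstruction
        a = -0.5 * d**2
        J = np.eye(8) - np.ones((8, 8)) / 8
        G = J @ a @ J
        assert res.eigenvalues.sum() == pytest.approx(np.trace(G), abs=1e-8)
        pos = res.eigenvalues > 1e-10
        recon = res.coordinates[:, pos] @ res.coordinates[:, pos].T
        np.testing.assert_allclose(recon, G, atol=1e-8)

    def test_asymmetric_input_rejected(self):
        d = np.array([[0, 1, 2], [1, 0, 1], [99, 1, 0.0]])
        with pytest.raises(RhizosignalError):
            pcoa(d)


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------


def _meta(groups: dict[str, str]) -> SampleMetadata:
    df = pd.DataFrame(
        {
            "treatment": pd.Series(groups),
            "timepoint": "T2",
            "microhabitat": "bulk",
            "replicate": 1,
        }
    )
    return SampleMetadata(df)


def permanova_enumeration_oracle(d: np.ndarray, labels: list[str]):
    """Anderson's pseudo-F from raw distances plus full relabeling null."""
    n = len(labels)

    def pseudo_f(lab):
        lab = np.asarray(lab)
        sst = (d[np.triu_indices(n, 1)] ** 2).sum() / n
        ssw = 0.0
        for g in set(lab):
            idx = np.where(lab == g)[0]
            sub = d[np.ix_(idx, idx)]
            ssw += (sub[np.triu_indices(len(idx), 1)] ** 2).sum() / len(idx)
        ssb = sst - ssw
        a = len(set(lab))
        return (ssb / (a - 1)) / (ssw / (n - a))

    f_obs = pseudo_f(labels)
    labels = np.asarray(labels)
    f_null = [pseudo_f(labels[list(p)]) for p in permutations(range(n))]
    p_exact = np.mean([f >= f_obs - 1e-12 for f in f_null])
    return f_obs, p_exact


class TestPermanova:
    def test_exhaustive_p_matches_full_enumeration_oracle(self):
        rng = np.random.default_rng(12)
        pts = rng.normal(size=(5, 2))
        pts[:2] += 2.0
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        ids = [f"s{i}" for i in range(5)]
        groups = ["ambient", "ambient", "severe", "severe", "severe"]
        dm = DistanceMatrix(d, ids=ids)
        meta = _meta(dict(zip(ids, groups)))
        res = permanova(dm, meta, formula="treatment", exhaustive=True)
        f_oracle, p_oracle = permanova_enumeration_oracle(d, groups)
        assert res.table.loc["treatment", "pseudo_F"] == pytest.approx(f_oracle, abs=1e-10)
        assert res.table.loc["treatment", "p_value"] == pytest.approx(p_oracle, abs=1e-12)

    def test_single_term_decomposition_identity(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(9, 2))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        ids = [f"s{i}" for i in range(9)]
        meta = _meta({s: ("ambient" if i < 4 else "severe") for i, s in enumerate(ids)})
        res = permanova(DistanceMatrix(d, ids=ids), meta, "treatment", n_perm=49, seed=1)
        t = res.table
        assert t.loc["treatment", "sum_sq"] + t.loc["Residual", "sum_sq"] == pytest.approx(
            t.loc["Total", "sum_sq"], abs=1e-8
        )
        assert t.loc["treatment", "r2"] + t.loc["Residual", "r2"] == pytest.approx(1.0)
        assert 0 <= t.loc["treatment", "r2"] <= 1

    def test_r2_small_for_exchangeable_groups(self):
        # labels carry no information: R² for the factor stays near its
        # null expectation df/(n-1) and never approaches 1
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(20, 3))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        ids = [f"s{i}" for i in range(20)]
        meta = _meta({s: ("ambient" if i % 2 else "severe") for i, s in enumerate(ids)})
        res = permanova(DistanceMatrix(d, ids=ids), meta, "treatment", n_perm=99, seed=2)
        assert res.table.loc["treatment", "r2"] < 0.3

    def test_zero_df_term_errors(self, tiny_metadata):
        rng = np.random.default_rng(0)
        ids = tiny_metadata.sample_ids
        pts = rng.normal(size=(len(ids), 2))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        with pytest.raises(RhizosignalError, match="degrees of freedom"):
            # timepoint is constant in this metadata
            permanova(DistanceMatrix(d, ids=ids), tiny_metadata, "timepoint", n_perm=9)


# ---------------------------------------------------------------------------
# beta dispersion
# ---------------------------------------------------------------------------


class TestBetaDispersion:
    def test_translated_copies_have_equal_dispersion(self):
        rng = np.random.default_rng(6)
        cloud = rng.normal(size=(6, 2))
        pts = np.vstack([cloud, cloud + 20.0])  # same spread, far apart
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        ids = [f"s{i}" for i in range(12)]
        groups = pd.Series(["g1"] * 6 + ["g2"] * 6, index=ids)
        res = beta_dispersion(DistanceMatrix(d, ids=ids), groups, n_perm=199, seed=0)
        assert res.f_statistic == pytest.approx(0.0, abs=1e-10)
        assert res.p_value > 0.5

    def test_centroid_distances_match_hand_computation(self):
        # 1-D fixture: group1 {0,1,2} (centroid 1), group2 {10,14} (centroid 12)
        pts = np.array([0.0, 1.0, 2.0, 10.0, 14.0])
        d = np.abs(pts[:, None] - pts[None, :])
        ids = list("abcde")
        groups = pd.Series(["g1", "g1", "g1", "g2", "g2"], index=ids)
        res = beta_dispersion(DistanceMatrix(d, ids=ids), groups, n_perm=99, seed=1)
        np.testing.assert_allclose(
            res.distances.to_numpy(), [1.0, 0.0, 1.0, 2.0, 2.0], atol=1e-8
        )

    def test_identical_points_error(self):
        d = np.zeros((6, 6))
        ids = [f"s{i}" for i in range(6)]
        groups = pd.Series(["a"] * 3 + ["b"] * 3, index=ids)
        with pytest.raises(RhizosignalError):
            beta_dispersion(DistanceMatrix(d, ids=ids), groups, n_perm=9)

    def test_singleton_group_warned_and_excluded(self):
        pts = np.array([0.0, 1.0, 2.0, 10.0, 14.0, 99.0])
        d = np.abs(pts[:, None] - pts[None, :])
        ids = list("abcdef")
        groups = pd.Series(["g1"] * 3 + ["g2"] * 2 + ["g3"], index=ids)
        with pytest.warns(UserWarning, match="single sample"):
            beta_dispersion(DistanceMatrix(d, ids=ids), groups, n_perm=9, seed=0)


# ---------------------------------------------------------------------------
# T1 vs T2 comparisons
# ---------------------------------------------------------------------------


def _time_meta(n1=6, n2=4) -> SampleMetadata:
    rows = []
    for i in range(n1):
        rows.append((f"t1_{i}", "ambient", "T1", "rhizosphere", i + 1))
    for i in range(n2):
        rows.append((f"t2_{i}", "ambient", "T2", "rhizosphere", i + 1))
    df = pd.DataFrame(
        rows, columns=["sample_id", "treatment", "timepoint", "microhabitat", "replicate"]
    ).set_index("sample_id")
    return SampleMetadata(df)


class TestTimeComparison:
    def test_identical_compositions_are_never_significant(self, small_taxonomy):
        meta = _time_meta()
        col = np.array([5, 3, 2])
        counts = np.tile(col[:, None], (1, 10))
        table = CountTable(["zotu1", "zotu2", "zotu3"], meta.sample_ids, counts)
        res = time_comparison(table, meta, small_taxonomy, rank="phylum")
        assert (res["p_value"] > 0.05).all()

    def test_clade_lost_at_t2_ranks_most_significant(self, small_taxonomy):
        meta = _time_meta()
        counts = np.ones((3, 10), dtype=int) * 10
        counts[2, 6:] = 0  # zotu3 (phylum pB) vanishes at T2
        table = CountTable(["zotu1", "zotu2", "zotu3"], meta.sample_ids, counts)
        res = time_comparison(table, meta, small_taxonomy, rank="phylum")
        # compositional closure means the surviving phylum shifts too, so
        # the vanished clade ties for the smallest adjusted p
        assert res.loc["pB", "p_adjusted"] == res["p_adjusted"].min()
        assert res.loc["pB", "p_adjusted"] < 0.05

    def test_row_count_equals_detected_clades(self, small_taxonomy):
        meta = _time_meta()
        counts = np.ones((3, 10), dtype=int)
        table = CountTable(["zotu1", "zotu2", "zotu3"], meta.sample_ids, counts)
        res = time_comparison(table, meta, small_taxonomy, rank="phylum")
        assert len(res) == 2  # phyla pA and pB
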