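"""Response ratios, their permutation null, and clade-wide tests."""

from itertools import permutations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from rhizosignal.io import CountTable, RhizosignalError
from rhizosignal.response import (
    call_directions,
    clade_response_test,
    response_ratio,
    response_ratio_null,
)


class TestResponseRatio:
    @pytest.mark.parametrize(
        "t, a, expected",
        [
            ([10], [10], [0.0]),
            ([5], [0], [1.0]),
            ([0], [5], [-1.0]),
            ([0], [0], [0.0]),
        ],
    )
    def test_extreme_and_equal_counts(self, t, a, expected):
        r, mean = response_ratio(t, a)
        np.testing.assert_allclose(r, expected)
        assert mean == pytest.approx(np.mean(expected))

    def test_hand_computed_pairwise_ratios(self):
        t, a = [4, 0, 6, 2, 8], [2, 2, 2, 2, 2]
        expected = [(4 - 2) / 6, (0 - 2) / 2, (6 - 2) / 8, 0.0, (8 - 2) / 10]
        r, mean = response_ratio(t, a)
        np.testing.assert_allclose(r, expected)
        assert mean == pytest.approx(np.mean(expected))

    def test_unequal_replicates_error_unless_mean_pairing(self):
        with pytest.raises(RhizosignalError, match="unequal"):
            response_ratio([1, 2, 3], [1, 2])
        r, mean = response_ratio([1, 2, 3], [1, 2], pairing="mean")
        assert mean == pytest.approx((6 - 3) / 9)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        t=st.lists(st.integers(0, 100), min_size=3, max_size=6),
        scale=st.integers(1, 20),
    )
    def test_antisymmetry_and_scale_invariance(self, t, scale):
        a = t[::-1]
        r_fwd, m_fwd = response_ratio(t, a)
        r_rev, m_rev = response_ratio(a, t)
        np.testing.assert_allclose(r_fwd, -r_rev, atol=1e-12)
        assert m_fwd == pytest.approx(-m_rev, abs=1e-12)
        r_scaled, _ = response_ratio([x * scale for x in t], [x * scale for x in a])
        np.testing.assert_allclose(r_scaled, r_fwd, atol=1e-12)

    def test_ratios_bounded(self):
        rng = np.random.default_rng(0)
        t = rng.integers(0, 1000, 50)
        a = rng.integers(0, 1000, 50)
        r, mean = response_ratio(t, a)
        assert (np.abs(r) <= 1).all() and abs(mean) <= 1


class TestResponseRatioNull:
    def test_constant_taxon_has_zero_rr_and_p_one(self, tiny_metadata):
        counts = np.array([[7] * 6, [1, 9, 3, 2, 8, 4]])
        table = CountTable(["flat", "vary"], tiny_metadata.sample_ids, counts)
        res = response_ratio_null(
            table, tiny_metadata, ("severe", "ambient"), n_perm=99, seed=0
        )
        assert res.table.loc["flat", "observed_rr"] == 0.0
        assert res.table.loc["flat", "p_value"] == 1.0

    def test_exhaustive_p_matches_independent_enumeration(self, tiny_metadata):
        meta = tiny_metadata
        two_two = [s for s in meta.sample_ids if not s.endswith("3")]
        counts = np.array([[9, 4, 1, 2], [3, 3, 8, 1]])
        table = CountTable(["u", "v"], two_two, counts)
        res = response_ratio_null(
            table, meta, ("severe", "ambient"), exhaustive=True
        )
        # oracle: plain-python enumeration of all 24 column orders
        g1 = sorted(s for s in two_two if s.startswith("severe"))
        g0 = sorted(s for s in two_two if s.startswith("ambient"))
        order = g1 + g0
        X = table.select_samples(order).counts.astype(float)

        def mean_rr(cols):
            out = []
            for ti, ai in zip(cols[:2], cols[2:]):
                tot = X[:, ti] + X[:, ai]
                r = np.where(tot > 0, (X[:, ti] - X[:, ai]) / np.where(tot > 0, tot, 1), 0)
                out.append(r)
            return np.mean(out, axis=0)

        obs = mean_rr(range(4))
        null = np.array([mean_rr(p) for p in permutations(range(4))])
        p_exact = (np.abs(null) >= np.abs(obs)[None, :] - 1e-12).mean(axis=0)
        np.testing.assert_allclose(res.table["p_value"].to_numpy(), p_exact, atol=1e-12)

    def test_same_seed_reproduces_p_vector(self, tiny_metadata):
        rng = np.random.default_rng(1)
        counts = rng.integers(0, 50, (10, 6))
        table = CountTable([f"z{i}" for i in range(10)], tiny_metadata.sample_ids, counts)
        a = response_ratio_null(table, tiny_metadata, ("severe", "ambient"), n_perm=99, seed=7)
        b = response_ratio_null(table, tiny_metadata, ("severe", "ambient"), n_perm=99, seed=7)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_too_few_samples_error(self, tiny_metadata):
        one_each = ["severe1", "ambient1"]
        table = CountTable(["z"], one_each, np.array([[1, 2]]))
        with pytest.raises(RhizosignalError, match="at least 2"):
            response_ratio_null(table, tiny_metadata, ("severe", "ambient"))

    def test_group_swap_negates_observed_rr(self, tiny_metadata):
        rng = np.random.default_rng(2)
        counts = rng.integers(0, 30, (5, 6))
        table = CountTable([f"z{i}" for i in range(5)], tiny_metadata.sample_ids, counts)
        fwd = response_ratio_null(table, tiny_metadata, ("severe", "ambient"), n_perm=9, seed=0)
        rev = response_ratio_null(table, tiny_metadata, ("ambient", "severe"), n_perm=9, seed=0)
        np.testing.assert_allclose(
            fwd.table["observed_rr"], -rev.table["observed_rr"], atol=1e-12
        )


class TestCladeResponseTest:
    def _taxonomy_for(self, assignments: dict[str, str]):
        from rhizosignal.io import RANKS, TaxonomyTable

        rows = {
            t: ["bacteria", phylum, "unassigned", "unassigned", "unassigned", "unassigned"]
            for t, phylum in assignments.items()
        }
        return TaxonomyTable(pd.DataFrame.from_dict(rows, orient="index", columns=list(RANKS)))

    def test_symmetric_ratios_give_t_zero_p_one(self):
        rr = pd.Series([-0.4, -0.2, 0.0, 0.2, 0.4], index=[f"z{i}" for i in range(5)])
        tax = self._taxonomy_for({f"z{i}": "pX" for i in range(5)})
        res = clade_response_test(rr, tax, rank="phylum")
        assert res.loc["pX", "t_statistic"] == pytest.approx(0.0, abs=1e-12)
        assert res.loc["pX", "p_value"] == pytest.approx(1.0)
        assert res.loc["pX", "direction"] == "none"

    def test_t_statistic_matches_textbook_formula(self):
        values = [0.5, 0.6, 0.4, 0.5, 0.5]
        rr = pd.Series(values, index=[f"z{i}" for i in range(5)])
        tax = self._taxonomy_for({f"z{i}": "pY" for i in range(5)})
        res = clade_response_test(rr, tax, rank="phylum")
        mean, sd, n = np.mean(values), np.std(values, ddof=1), len(values)
        t_hand = mean / (sd / np.sqrt(n))
        p_hand = 2 * stats.t.sf(abs(t_hand), n - 1)
        assert res.loc["pY", "t_statistic"] == pytest.approx(t_hand, abs=1e-10)
        assert res.loc["pY", "p_value"] == pytest.approx(p_hand, abs=1e-10)
        assert res.loc["pY", "direction"] == "positive"

    def test_bh_adjustment_matches_hand_step_up(self):
        # craft three 5-member clades whose raw one-sample t p-values are
        # {0.01, 0.02, 0.04}; hand BH step-up gives {0.03, 0.03, 0.04}
        def values_for_p(p_target):
            t_target = stats.t.isf(p_target / 2, df=4)
            # mean 1, sd chosen so t == t_target: t = 1/(sd/sqrt(5))
            sd = np.sqrt(5) / t_target
            base = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
            vals = 1.0 + base * (sd / np.std(base, ddof=1))
            return vals

        rrs, tax_map = [], {}
        for c, p_target in enumerate([0.01, 0.02, 0.04]):
            vals = values_for_p(p_target)
            for i, v in enumerate(vals):
                name = f"c{c}_z{i}"
                rrs.append((name, v))
                tax_map[name] = f"clade{c}"
        rr = pd.Series(dict(rrs))
        res = clade_response_test(rr, self._taxonomy_for(tax_map), rank="phylum")
        raw = res["p_value"].sort_values()
        np.testing.assert_allclose(raw.to_numpy(), [0.01, 0.02, 0.04], atol=1e-10)
        adj = res.loc[raw.index, "p_adjusted"].to_numpy()
        np.testing.assert_allclose(adj, [0.03, 0.03, 0.04], atol=1e-10)

    def test_small_clades_skipped_and_empty_table_warns(self):
        rr = pd.Series([0.1, 0.2], index=["z0", "z1"])
        tax = self._taxonomy_for({"z0": "pA", "z1": "pB"})
        with pytest.warns(UserWarning, match="minimum size"):
            res = clade_response_test(rr, tax, rank="phylum", min_clade_size=5)
        assert len(res) == 0


class TestCallDirections:
    def test_zero_rr_is_neutral_and_categories_partition(self, tiny_metadata):
        # columns: ambient1..3 then severe1..3
        counts = np.array([[5] * 6, [0, 1, 0, 9, 8, 9], [9, 8, 9, 0, 1, 0]])
        table = CountTable(["flat", "up", "down"], tiny_metadata.sample_ids, counts)
        rr = response_ratio_null(table, tiny_metadata, ("severe", "ambient"),
                                 n_perm=199, seed=0)
        taxon_calls, _ = call_directions(rr, significance_filter=False)
        assert taxon_calls["flat"] == "neutral"
        assert taxon_calls["up"] == "positive"
        assert taxon_calls["down"] == "negative"
        assert set(taxon_calls.index) == {"flat", "up", "down"}
        assert taxon_calls.isin(["positive", "negative", "neutral"]).all()

    def test_planted_positive_clade_called_positive(self, synthetic_study):
        study = synthetic_study
        rr = response_ratio_null(
            study["counts"], study["metadata"], ("severe", "ambient"),
            n_perm=199, seed=5,
        )
        clade_tips, delta = study["truth"].responder_clades[0]
        assert delta > 0
        # directional single-seed check: the planted clade's members shift
        # positive relative to the background (detection *rates* are the
        # subject of the multi-run recovery tests in the acceptance suite)
        member_rr = rr.observed.loc[clade_tips]
        background = rr.observed.drop(clade_tips)
        assert member_rr.mean() > 0
        assert member_rr.mean() > background.mean()
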