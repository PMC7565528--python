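import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st_h

from tmeomix.diffexp import (
    DEThresholds,
    hypergeom_enrich,
    shared_de,
    student_t_de,
    top_ranked,
)
from tmeomix.io_formats import ExpressionTable, GeneSetCollection, UsageError

from conftest import make_design, make_table


def brute_force_bh(p: np.ndarray) -> np.ndarray:
    """Step-up BH: q_(i) = min_{j>=i} (m * p_(j) / j), capped at 1."""
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


@pytest.fixture(scope="module")
def de_fixture():
    design = make_design({"EC": 4, "ET": 4})
    rng = np.random.default_rng(11)
    table = make_table(
        rng,
        [f"g{i}" for i in range(30)] + ["planted"],
        design,
        sd=0.3,
        group_means={("planted", "ET"): 13.0},  # +5 over the 8.0 baseline
    )
    return table, design


class TestStudentT:
    def test_identical_groups_null_statistics(self):
        design = make_design({"EC": 3, "ET": 3})
        vals = np.tile([[1.0, 2.0, 3.0, 1.0, 2.0, 3.0]], (2, 1))
        frame = pd.DataFrame(vals, index=["a", "b"], columns=design.sample_ids)
        res = student_t_de(ExpressionTable(frame, "mrna"), design, ("EC", "ET"))
        assert res.table.loc["a", "mean_diff"] == 0
        assert res.table.loc["a", "t"] == 0
        assert res.table.loc["a", "p"] == pytest.approx(1.0)
        assert not res.table.loc["a", "passes"]

    def test_planted_five_log2_shift_passes_default_thresholds(self, de_fixture):
        table, design = de_fixture
        res = student_t_de(table, design, ("EC", "ET"))
        assert res.table.loc["planted", "passes"]
        assert res.table.loc["planted", "direction"] == "up"
        assert list(res.passing().index) == ["planted"]

    def test_t_matches_scipy_equal_variance(self, de_fixture):
        import scipy.stats as st

        table, design = de_fixture
        res = student_t_de(table, design, ("EC", "ET"))
        a = table.data[design.samples_in_group("EC")].to_numpy()
        b = table.data[design.samples_in_group("ET")].to_numpy()
        ref = st.ttest_ind(b, a, axis=1, equal_var=True)
        np.testing.assert_allclose(res.table["t"], ref.statistic, rtol=1e-10)
        np.testing.assert_allclose(res.table["p"], ref.pvalue, rtol=1e-10)

    def test_contrast_antisymmetry(self, de_fixture):
        table, design = de_fixture
        fwd = student_t_de(table, design, ("EC", "ET"))
        rev = student_t_de(table, design, ("ET", "EC"))
        np.testing.assert_allclose(rev.table["mean_diff"], -fwd.table["mean_diff"])
        np.testing.assert_allclose(rev.table["t"], -fwd.table["t"], rtol=1e-10)
        np.testing.assert_allclose(rev.table["p"], fwd.table["p"], rtol=1e-10)

    def test_q_values_match_brute_force_step_up(self, de_fixture):
        table, design = de_fixture
        res = student_t_de(table, design, ("EC", "ET"))
        q = brute_force_bh(res.table["p"].to_numpy())
        np.testing.assert_allclose(res.table["q"], q, rtol=1e-12)

    def test_protein_molecules_with_sparse_groups_are_untested(self):
        design = make_design({"EC": 3, "ET": 3})
        frame = pd.DataFrame(
            [[1.0, 2.0, np.nan, 5.0, 6.0, 7.0], [np.nan, np.nan, 2.0, 5.0, 6.0, 7.0]],
            index=["tested", "sparse"],
            columns=design.sample_ids,
        )
        res = student_t_de(ExpressionTable(frame, "protein"), design, ("EC", "ET"))
        assert res.table.loc["tested", "tested"]
        assert not res.table.loc["sparse", "tested"]
        assert np.isnan(res.table.loc["sparse", "q"])

    def test_unknown_group_is_a_usage_error(self, de_fixture):
        table, design = de_fixture
        with pytest.raises(UsageError):
            student_t_de(table, design, ("EC", "XT"))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st_h.integers(0, 10_000))
    def test_bh_oracle_on_random_p_vectors(self, seed):
        from statsmodels.stats.multitest import multipletests

        p = np.random.default_rng(seed).random(200)
        np.testing.assert_allclose(
            multipletests(p, method="fdr_bh")[1], brute_force_bh(p), rtol=1e-12
        )


class TestTopRanked:
    def _result(self, rows):
        frame = pd.DataFrame(rows).set_index("id")
        frame["tested"] = True
        from tmeomix.diffexp import DEResult

        return DEResult(frame, ("EC", "ET"), "mrna")

    def test_underfull_returns_all_in_p_order(self):
        res = self._result(
            [
                {"id": "a", "p": 0.02, "mean_diff": 5, "direction": "up", "passes": True, "q": 0.02},
                {"id": "b", "p": 0.01, "mean_diff": 5, "direction": "up", "passes": True, "q": 0.01},
                {"id": "c", "p": 0.03, "mean_diff": 5, "direction": "up", "passes": True, "q": 0.03},
            ]
        )
        assert top_ranked(res, "up", 20) == ["b", "a", "c"]

    def test_p_ties_broken_by_larger_absolute_difference(self):
        res = self._result(
            [
                {"id": "small", "p": 0.01, "mean_diff": 4, "direction": "up", "passes": True, "q": 0.01},
                {"id": "big", "p": 0.01, "mean_diff": 6, "direction": "up", "passes": True, "q": 0.01},
            ]
        )
        assert top_ranked(res, "up", 2) == ["big", "small"]

    def test_matches_brute_force_sort_on_random_fixture(self):
        rng = np.random.default_rng(13)
        rows = [
            {
                "id": f"m{i:02d}",
                "p": float(rng.choice([1e-4, 1e-3, 1e-2])),
                "mean_diff": float(rng.normal(0, 6)),
                "passes": bool(rng.random() < 0.7),
                "q": 0.0,
            }
            for i in range(50)
        ]
        for r in rows:
            r["direction"] = "up" if r["mean_diff"] >= 0 else "down"
        res = self._result(rows)
        expected = sorted(
            (r for r in rows if r["passes"] and r["direction"] == "up"),
            key=lambda r: (r["p"], -abs(r["mean_diff"]), r["id"]),
        )
        assert top_ranked(res, "up", 20) == [r["id"] for r in expected][:20]


class TestSharedDE:
    def _results(self, passing_sets, p=1e-4):
        from tmeomix.diffexp import DEResult

        out = {}
        for cell, ids in passing_sets.items():
            universe = sorted(set.union(*map(set, passing_sets.values())) | {"bg"})
            frame = pd.DataFrame(
                {
                    "p": p,
                    "mean_diff": 5.0,
                    "direction": "up",
                    "passes": [i in ids for i in universe],
                    "tested": True,
                    "q": p,
                },
                index=universe,
            )
            out[cell] = DEResult(frame, ("EC", "ET"), "mrna")
        return out

    def test_intersection_semantics(self):
        res = self._results({"E": {"a", "b"}, "I": {"b", "c"}, "K": {"b"}})
        assert list(shared_de(res, "up").index) == ["b"]

    def test_empty_intersection_is_not_an_error(self):
        res = self._results({"E": {"a"}, "I": {"b"}, "K": {"c"}})
        assert shared_de(res, "up").empty

    def test_score_is_minus_log10_of_mean_p(self):
        res = self._results({"E": {"x"}, "I": {"x"}, "K": {"x"}}, p=1e-4)
        assert shared_de(res, "up").loc["x", "score"] == pytest.approx(4.0)

    def test_mixed_layers_rejected(self):
        res = self._results({"E": {"a"}, "I": {"a"}})
        res["I"].layer = "mirna"
        with pytest.raises(UsageError):
            shared_de(res, "up")


def enumerate_hypergeom_p(M, K, N, k_obs):
    """P(X >= k_obs) by exhaustive enumeration of all C(M, N) draws."""
    import itertools

    universe = range(M)
    inset = set(range(K))
    total = hits = 0
    for draw in itertools.combinations(universe, N):
        total += 1
        if len(inset & set(draw)) >= k_obs:
            hits += 1
    return hits / total


class TestHypergeomEnrich:
    def _run(self, M, K, N, k):
        universe = {f"u{i}" for i in range(M)}
        members = {f"u{i}" for i in range(K)}
        query = {f"u{i}" for i in range(K - k, K - k + N)} if k else {
            f"u{i}" for i in range(K, K + N)
        }
        # query has exactly k members inside the set
        assert len(query & members) == k and query <= universe
        coll = GeneSetCollection({"S": members})
        return hypergeom_enrich(query, coll, universe).table.loc["S"]

    def test_full_overlap_small_universe_matches_enumeration(self):
        row = self._run(M=10, K=5, N=5, k=5)
        assert row["p"] == pytest.approx(1 / 252)
        assert row["p"] == pytest.approx(enumerate_hypergeom_p(10, 5, 5, 5))

    def test_universe_four_pair_overlap(self):
        row = self._run(M=4, K=2, N=2, k=2)
        assert row["p"] == pytest.approx(1 / 6)
        assert row["p"] == pytest.approx(enumerate_hypergeom_p(4, 2, 2, 2))

    def test_zero_overlap_gives_certainty(self):
        row = self._run(M=10, K=3, N=4, k=0)
        assert row["p"] == pytest.approx(1.0)

    def test_matches_monte_carlo_within_three_standard_errors(self):
        rng = np.random.default_rng(17)
        M, K, N = 40, 12, 9
        universe = [f"u{i}" for i in range(M)]
        members = set(universe[:K])
        query = set(rng.choice(universe, size=N, replace=False))
        k = len(query & members)
        coll = GeneSetCollection({"S": members})
        p = hypergeom_enrich(query, coll, set(universe)).table.loc["S", "p"]
        draws = 100_000
        hits = 0
        for _ in range(draws):
            sample = rng.choice(M, size=N, replace=False)
            hits += (sample < K).sum() >= k
        mc = hits / draws
        se = np.sqrt(mc * (1 - mc) / draws)
        assert abs(p - mc) <= 3 * max(se, 1e-4)

    def test_query_outside_universe_is_an_error(self):
        coll = GeneSetCollection({"S": {"a"}})
        with pytest.raises(UsageError, match="stranger"):
            hypergeom_enrich({"stranger"}, coll, {"a", "b"})
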