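"""The statistical core: KS statistics, p-values, FDR, and activity calls."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import ks_2samp
from statsmodels.stats.multitest import multipletests

from kinact import (
    DiffKinaseError,
    KinomeFilter,
    benjamini_hochberg,
    classify_from_results,
    differential_activity_from_samples,
    differential_kinase_activity,
    filter_kinome,
    ks_pvalue_asymptotic,
    ks_pvalue_permutation,
    ks_statistics,
    one_sided_pvalues,
    phospho_enrichment_fisher,
    results_to_frame,
)
from conftest import brute_force_exact_p, brute_force_ks


class TestKsStatistics:
    def test_identical_samples_give_zero(self):
        assert ks_statistics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == (0.0, 0.0, 0.0)

    def test_fully_separated_samples(self):
        d, d_plus, d_minus = ks_statistics([3, 4], [1, 2])
        assert (d, d_plus, d_minus) == (1.0, 1.0, 0.0)

    def test_interleaved_samples(self):
        d, d_plus, d_minus = ks_statistics([1, 3], [2, 4])
        assert d == pytest.approx(0.5)
        assert d == max(d_plus, d_minus)

    def test_empty_sample_errors(self):
        with pytest.raises(DiffKinaseError):
            ks_statistics([], [1.0])

    def test_matches_brute_force_and_scipy(self, rng):
        for _ in range(30):
            x = rng.normal(0, 1, rng.integers(2, 30))
            y = rng.normal(0.4, 1.2, rng.integers(2, 30))
            d, d_plus, d_minus = ks_statistics(x, y)
            bd, bdp, bdm = brute_force_ks(x, y)
            assert d == pytest.approx(bd, abs=1e-12)
            assert d_plus == pytest.approx(bdp, abs=1e-12)
            assert d_minus == pytest.approx(bdm, abs=1e-12)
            assert d == pytest.approx(ks_2samp(x, y).statistic, abs=1e-12)

    def test_ties_handled_deterministically(self):
        d, d_plus, d_minus = ks_statistics([1, 1, 2], [1, 2, 2])
        bd, bdp, bdm = brute_force_ks([1, 1, 2], [1, 2, 2])
        assert (d, d_plus, d_minus) == (bd, bdp, bdm)

    @settings(deadline=None, max_examples=50)
    @given(
        x=st.lists(st.integers(-100, 100), min_size=1, max_size=12),
        y=st.lists(st.integers(-100, 100), min_size=1, max_size=12),
        scale=st.floats(0.1, 5),
        offset=st.floats(-10, 10),
    )
    def test_invariance_under_common_monotone_transform(self, x, y, scale, offset):
        """D depends on ranks only: common strictly increasing maps leave it unchanged."""
        base = ks_statistics(x, y)
        mapped = ks_statistics(
            [scale * v + offset for v in x], [scale * v + offset for v in y]
        )
        cubed = ks_statistics([v**3 for v in x], [v**3 for v in y])
        assert base == pytest.approx(mapped, abs=1e-9)
        assert base == pytest.approx(cubed, abs=1e-9)


class TestPValues:
    def test_zero_statistic_gives_p_one(self):
        assert ks_pvalue_asymptotic(0.0, 5, 5) == 1.0

    def test_full_separation_is_highly_significant(self):
        assert ks_pvalue_asymptotic(1.0, 10, 10) < 1e-4

    def test_p_decreases_with_d(self):
        assert ks_pvalue_asymptotic(0.3, 20, 20) > ks_pvalue_asymptotic(0.6, 20, 20)

    def test_invalid_d_errors(self):
        with pytest.raises(DiffKinaseError):
            ks_pvalue_asymptotic(1.5, 5, 5)

    def test_agrees_with_scipy_asymptotic_mode(self, rng):
        x, y = rng.normal(0, 1, 40), rng.normal(0.5, 1, 60)
        d, _, _ = ks_statistics(x, y)
        ours = ks_pvalue_asymptotic(d, 40, 60)
        scipys = ks_2samp(x, y, method="asymp").pvalue
        assert ours == pytest.approx(scipys, rel=0.05, abs=1e-4)

    def test_one_sided_limits_and_value(self):
        p_up, p_down = one_sided_pvalues(0.0, 0.2, 10, 10)
        assert p_up == 1.0
        # ne = 10 when n = m = 20
        p_up, _ = one_sided_pvalues(0.5, 0.0, 20, 20)
        assert p_up == pytest.approx(math.exp(-5.0))

    def test_one_sided_agrees_with_permutation_oracle(self, rng):
        x = rng.normal(0.8, 1, 10)
        y = rng.normal(0.0, 1, 50)
        _, d_plus, d_minus = ks_statistics(x, y)
        p_up, _ = one_sided_pvalues(d_plus, d_minus, 10, 50)
        p_perm = ks_pvalue_permutation(x, y, side="up", n_perm=4000, seed=7)
        assert p_up == pytest.approx(p_perm, abs=0.05)


class TestPermutation:
    def test_exact_enumeration_of_separated_pair(self):
        assert ks_pvalue_permutation([3, 4], [1, 2], side="two") == pytest.approx(2 / 6)

    def test_equal_singletons_give_p_one(self):
        assert ks_pvalue_permutation([1.0], [1.0], side="two") == 1.0

    def test_sampled_mode_is_deterministic_under_seed(self, rng):
        x, y = rng.normal(0, 1, 10), rng.normal(0.5, 1, 10)
        first = ks_pvalue_permutation(x, y, side="two", n_perm=500, seed=3)
        second = ks_pvalue_permutation(x, y, side="two", n_perm=500, seed=3)
        assert first == second

    def test_enumeration_matches_brute_force(self, rng):
        for side in ("two", "up", "down"):
            for _ in range(5):
                x = rng.choice(20, size=rng.integers(2, 5), replace=False).astype(float)
                y = rng.choice(20, size=rng.integers(2, 5), replace=False).astype(float)
                ours = ks_pvalue_permutation(x, y, side=side)
                oracle = brute_force_exact_p(x, y, side=side)
                assert ours == pytest.approx(oracle, abs=1e-12)


class TestBenjaminiHochberg:
    def test_single_p_is_unchanged(self):
        assert benjamini_hochberg([0.04]) == pytest.approx([0.04])

    def test_hand_computed_triple(self):
        np.testing.assert_allclose(benjamini_hochberg([0.01, 0.02, 0.03]), [0.03] * 3)

    def test_hand_computed_pair(self):
        np.testing.assert_allclose(benjamini_hochberg([0.005, 0.5]), [0.01, 0.5])

    def test_q_dominates_p_and_preserves_ranking(self, rng):
        p = rng.uniform(0, 1, 200)
        q = benjamini_hochberg(p)
        assert np.all(q >= p - 1e-15)
        assert np.all(q <= 1.0)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)

    def test_invariant_to_input_order(self, rng):
        p = rng.uniform(0, 1, 50)
        perm = rng.permutation(50)
        q = benjamini_hochberg(p)
        q_perm = benjamini_hochberg(p[perm])
        np.testing.assert_allclose(q_perm, q[perm])

    def test_matches_statsmodels(self, rng):
        p = rng.uniform(0, 1, 100)
        expected = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(benjamini_hochberg(p), expected, atol=1e-12)

    def test_out_of_range_p_errors(self):
        with pytest.raises(DiffKinaseError):
            benjamini_hochberg([0.1, 1.2])


class TestKinomeFilter:
    def test_usable_is_the_intersection(self):
        kinome = KinomeFilter(supported=["A", "B", "C"], expressed=["B", "C", "D"])
        assert kinome.usable == {"B", "C"}

    def test_filter_keeps_only_usable_rows(self):
        predictions = pd.DataFrame(
            {"protein": "P1", "position": 1, "residue": "S",
             "kinase": ["A", "B", "B"], "score": [1.0, 2.0, 0.5]}
        )
        kinome = KinomeFilter(supported=["A", "B"], expressed=["B"])
        out = filter_kinome(predictions, kinome)
        assert set(out["kinase"]) == {"B"}
        assert len(out) == 2

    def test_full_overlap_is_identity(self):
        predictions = pd.DataFrame(
            {"protein": "P1", "position": 1, "residue": "S",
             "kinase": ["A", "B"], "score": [1.0, 2.0]}
        )
        kinome = KinomeFilter(supported=["A", "B"], expressed=["A", "B"])
        pd.testing.assert_frame_equal(filter_kinome(predictions, kinome), predictions)

    def test_empty_usable_set_errors(self):
        kinome = KinomeFilter(supported=["A"], expressed=["B"])
        with pytest.raises(DiffKinaseError, match="empty"):
            filter_kinome(pd.DataFrame({"kinase": ["A"]}), kinome)


class TestDifferentialActivity:
    def test_null_kinases_are_unchanged(self, rng):
        bg = {f"K{i}": rng.normal(0, 1, 400) for i in range(5)}
        reg = {k: v[:40].copy() for k, v in bg.items()}
        results = differential_activity_from_samples(reg, bg)
        assert all(r.call == "unchanged" for r in results)

    def test_shifted_kinases_called_in_the_right_direction(self, rng):
        bg = {"UP": rng.normal(0, 1, 2000), "DOWN": rng.normal(0, 1, 2000),
              "NULL": rng.normal(0, 1, 2000)}
        reg = {"UP": rng.normal(1.5, 1, 30), "DOWN": rng.normal(-1.5, 1, 30),
               "NULL": rng.normal(0, 1, 30)}
        by_kinase = {r.kinase: r for r in differential_activity_from_samples(reg, bg)}
        assert by_kinase["UP"].call == "activated"
        assert by_kinase["UP"].D_plus > by_kinase["UP"].D_minus
        assert by_kinase["DOWN"].call == "inhibited"
        assert by_kinase["NULL"].call == "unchanged"
        for r in by_kinase.values():
            assert r.D == pytest.approx(max(r.D_plus, r.D_minus))
            assert r.q >= r.p_two_sided - 1e-15

    def test_min_sites_gate(self, rng):
        bg = {"A": rng.normal(0, 1, 500), "B": rng.normal(0, 1, 500)}
        reg = {"A": rng.normal(2, 1, 3), "B": rng.normal(2, 1, 30)}
        results = {r.kinase: r for r in differential_activity_from_samples(reg, bg, min_sites=5)}
        assert results["A"].call == "insufficient_data"
        assert math.isnan(results["A"].q)
        assert results["B"].call == "activated"

    def test_no_testable_kinase_errors(self, rng):
        with pytest.raises(DiffKinaseError):
            differential_activity_from_samples(
                {"A": rng.normal(0, 1, 2)}, {"A": rng.normal(0, 1, 100)}, min_sites=5
            )

    def test_table_pipeline_matches_sample_core(self, rng):
        rows_reg, rows_bg = [], []
        for i, kinase in enumerate(["K1", "K2"]):
            for j, score in enumerate(rng.normal(0.5 * i, 1, 20)):
                rows_reg.append(("RP%d" % j, 10, "S", kinase, score))
            for j, score in enumerate(rng.normal(0, 1, 300)):
                rows_bg.append(("BP%d" % j, 10, "S", kinase, score))
        cols = ["protein", "position", "residue", "kinase", "score"]
        reg_df = pd.DataFrame(rows_reg, columns=cols)
        bg_df = pd.DataFrame(rows_bg, columns=cols)
        from_tables = differential_kinase_activity(reg_df, bg_df, min_sites=5)
        from_samples = differential_activity_from_samples(
            {k: g["score"].to_numpy() for k, g in reg_df.groupby("kinase")},
            {k: g["score"].to_numpy() for k, g in bg_df.groupby("kinase")},
        )
        assert results_to_frame(from_tables).equals(results_to_frame(from_samples))

    def test_classify_from_results_reproduces_calls(self, rng):
        bg = {f"K{i}": rng.normal(0, 1, 800) for i in range(6)}
        reg = {f"K{i}": rng.normal(0.9 if i < 2 else 0, 1, 25) for i in range(6)}
        results = differential_activity_from_samples(reg, bg, alpha=0.01)
        frame = results_to_frame(results)
        stripped = frame.drop(columns=["q", "call"])
        reclassified = classify_from_results(stripped, alpha=0.01)
        merged = frame.set_index("kinase").join(
            reclassified.set_index("kinase"), rsuffix="_re"
        )
        assert (merged["call"] == merged["call_re"]).all()
        np.testing.assert_allclose(merged["q"], merged["q_re"])

    def test_results_frame_sorted_by_q(self, rng):
        bg = {f"K{i}": rng.normal(0, 1, 500) for i in range(4)}
        reg = {f"K{i}": rng.normal(0.3 * i, 1, 20) for i in range(4)}
        frame = results_to_frame(differential_activity_from_samples(reg, bg))
        q = frame["q"].to_numpy()
        assert np.all(np.diff(q[~np.isnan(q)]) >= 0)


class TestFisherEnrichment:
    def test_perfect_overlap_is_significant(self):
        universe = [f"K{i}" for i in range(20)]
        half = set(universe[:10])
        _, p = phospho_enrichment_fisher(half, half, universe)
        assert p < 0.05

    def test_three_by_three_diagonal_table(self):
        universe = list("ABCDEF")
        table, p = phospho_enrichment_fisher(set("ABC"), set("ABC"), universe)
        assert table.tolist() == [[3, 0], [0, 3]]
        assert p == pytest.approx(2 / math.comb(6, 3))

    def test_matches_hypergeometric_enumeration(self, rng):
        """Two-sided p equals the sum of table probabilities <= observed."""
        universe = [f"K{i}" for i in range(12)]
        activated = set(rng.choice(universe, 5, replace=False))
        phosph = set(rng.choice(universe, 6, replace=False))
        table, p = phospho_enrichment_fisher(activated, phosph, universe)
        n_act, n_ph, n_tot = 5, 6, 12
        observed = len(activated & phosph)

        def prob(k):
            return (
                math.comb(n_ph, k) * math.comb(n_tot - n_ph, n_act - k)
                / math.comb(n_tot, n_act)
            )
        p_obs = prob(observed)
        expected = sum(
            prob(k) for k in range(max(0, n_act + n_ph - n_tot), min(n_act, n_ph) + 1)
            if prob(k) <= p_obs * (1 + 1e-9)
        )
        assert p == pytest.approx(expected, rel=1e-9)

    def test_empty_universe_errors(self):
        with pytest.raises(DiffKinaseError):
            phospho_enrichment_fisher(set(), set(), set())
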