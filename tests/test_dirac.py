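"""DIRAC core: pair orders, templates, conservation, differential regulation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import astrodirac as ad
from astrodirac.dirac import (
    build_rank_template,
    conservation_index,
    matching_scores,
    pair_order,
    pair_order_matrix,
)
from conftest import toy_labels, toy_matrix
from oracles import (
    brute_conservation_index,
    brute_matching_score,
    brute_pair_bits,
    brute_template,
    random_monotone_map,
)


class TestPairOrder:
    @pytest.mark.parametrize(
        "values, expected",
        [
            ([1, 2, 3], [1, 1, 1]),   # fully ascending
            ([3, 2, 1], [0, 0, 0]),   # fully descending
            ([2, 2, 5], [0, 1, 1]),   # tie -> bit 0
        ],
    )
    def test_examples(self, values, expected):
        assert pair_order(values).astype(int).tolist() == expected

    def test_single_gene_rejected(self):
        with pytest.raises(ValueError):
            pair_order([1.0])


class TestTemplate:
    def test_majority_per_pair(self):
        bits = np.array([[1, 1, 1], [1, 1, 1], [1, 1, 0]]).T  # pairs x samples
        t = build_rank_template(bits)
        assert t.template.astype(int).tolist() == [1, 1, 1]
        assert not t.tie_mask.any()

    def test_identical_samples_zero_tie_mask(self):
        bits = np.tile(np.array([[1], [0], [1]]), (1, 4))
        t = build_rank_template(bits)
        assert t.template.astype(int).tolist() == [1, 0, 1]
        assert not t.tie_mask.any()

    def test_two_opposite_samples_fully_tied(self):
        a = pair_order([1, 2, 3])
        b = pair_order([3, 2, 1])
        t = build_rank_template(np.stack([a, b], axis=1))
        assert not t.template.any()
        assert t.tie_mask.all()


class TestMatchingScore:
    def test_extremes(self):
        t = build_rank_template(pair_order([1, 2, 3])[:, None])
        assert ad.rank_matching_score(pair_order([1, 2, 3]), t) == 1.0
        assert ad.rank_matching_score(pair_order([3, 2, 1]), t) == 0.0

    def test_four_gene_hand_enumerated(self):
        # template from A<B<C<D; sample A=2,B=1,C=3,D=4 disagrees only on (A,B)
        t = build_rank_template(pair_order([1, 2, 3, 4])[:, None])
        score = ad.rank_matching_score(pair_order([2, 1, 3, 4]), t)
        assert score == pytest.approx(5 / 6)

    def test_length_mismatch_rejected(self):
        t = build_rank_template(pair_order([1, 2, 3])[:, None])
        with pytest.raises(ValueError, match="length"):
            ad.rank_matching_score(pair_order([1, 2, 3, 4]), t)


class TestConservationIndex:
    def test_identical_orderings_give_one(self):
        bits = np.tile(pair_order([3, 1, 2])[:, None], (1, 5))
        idx, scores = conservation_index(bits)
        assert idx == 1.0 and (scores == 1.0).all()

    def test_hand_computed_three_sample_value(self):
        bits = np.array([[1, 1, 1], [1, 1, 0], [1, 1, 1]]).T
        idx, _ = conservation_index(bits)
        assert idx == pytest.approx(8 / 9)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_majority_bound_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        m = int(rng.integers(2, 7))
        n = int(rng.integers(1, 9))
        bits = pair_order_matrix(rng.normal(size=(m, n)))
        idx, _ = conservation_index(bits)
        assert idx >= 0.5


class TestBruteForceOracle:
    def test_scores_and_indices_match_pair_enumeration(self):
        """100 random instances (<=6 genes, <=8 samples): exact equality with
        the independent explicit-loop implementation."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            m = int(rng.integers(2, 7))
            n = int(rng.integers(2, 9))
            data = rng.normal(size=(m, n))
            samples = [list(data[:, j]) for j in range(n)]
            bits = pair_order_matrix(data)
            # pair bits
            for j, s in enumerate(samples):
                assert bits[:, j].astype(int).tolist() == brute_pair_bits(s)
            # template + ties
            t = build_rank_template(bits)
            bt, btie = brute_template(samples)
            assert t.template.astype(int).tolist() == bt
            assert t.tie_mask.astype(int).tolist() == btie
            # matching scores and conservation index, exact
            scores = matching_scores(bits, t)
            for j, s in enumerate(samples):
                assert scores[j] == brute_matching_score(s, bt)
            idx, _ = conservation_index(bits)
            assert idx == brute_conservation_index(samples)


class TestRankInvariance:
    def test_outputs_unchanged_under_monotone_per_sample_transforms(self, small_cohort):
        _, nets, matrix, labels, _, _ = small_cohort
        base = ad.conservation_table(matrix, labels, nets).indices
        rng = np.random.default_rng(7)
        for _ in range(20):
            warped = matrix.values.to_numpy().copy()
            for j in range(warped.shape[1]):
                warped[:, j] = random_monotone_map(rng)(warped[:, j])
            wm = ad.ExpressionMatrix(
                pd.DataFrame(warped, index=matrix.gene_ids, columns=matrix.sample_ids)
            )
            pd.testing.assert_frame_equal(ad.conservation_table(wm, labels, nets).indices, base)


class TestGlobalDysregulation:
    def test_unweighted_mean_over_networks(self):
        table = ad.ConservationTable(
            indices=pd.DataFrame({"Normal": [0.9, 1.0]}, index=["n1", "n2"])
        )
        assert ad.global_dysregulation(table, "Normal") == pytest.approx(0.95)

    def test_noiseless_cohort_all_indices_one(self):
        cfg = ad.SimConfig(
            n_genes=100, samples_per_phenotype={p: 4 for p in ad.PHENOTYPES},
            n_networks=5, network_size_range=(5, 8),
            sigma_by_phenotype={p: 0.0 for p in ad.PHENOTYPES}, batch_sigma=0.0, seed=3,
        )
        nets = ad.generate_networks(cfg)
        matrix, labels, _, _ = ad.generate_cohort(cfg, nets)
        table = ad.conservation_table(ad.rank_transform(matrix), labels, nets)
        assert (table.indices == 1.0).all().all()

    def test_sigma_ladder_orders_phenotype_means(self):
        cfg = ad.SimConfig(
            n_genes=400, samples_per_phenotype={p: 12 for p in ad.PHENOTYPES},
            n_networks=40, network_size_range=(5, 25), seed=4,
        )  # default sigma ladder rises with grade
        nets = ad.generate_networks(cfg)
        matrix, labels, _, _ = ad.generate_cohort(cfg, nets)
        table = ad.conservation_table(ad.rank_transform(matrix), labels, nets, merge_gbm=True)
        means = [ad.global_dysregulation(table, p) for p in ("Normal", "G2", "G3", "GBM")]
        assert means[0] > means[1] > means[2] > means[3]


class TestDifferentialRegulation:
    def test_random_split_of_noiseless_population_all_null(self):
        # one noiseless population, labels an arbitrary split -> deltas 0, p 1
        rng = np.random.default_rng(0)
        base = np.sort(rng.normal(size=30))
        values = np.tile(base[:, None], (1, 10))
        matrix = toy_matrix(values)
        labels = toy_labels({f"s{j}": ("G2" if j < 5 else "G3") for j in range(10)})
        nets = ad.GeneSetCollection({"n1": [f"g{i}" for i in range(8)],
                                     "n2": [f"g{i}" for i in range(10, 20)]})
        res = ad.differential_regulation(matrix, labels, nets, "G2", "G3", n_perm=50, seed=1)
        assert (res.table["delta"] == 0).all()
        assert (res.table["p"] == 1.0).all()

    def test_planted_network_attains_top_delta_and_small_p(self):
        sig = {p: 15.0 for p in ad.PHENOTYPES}
        cfg = ad.SimConfig(
            n_genes=800, samples_per_phenotype={p: 25 for p in ad.PHENOTYPES},
            n_networks=15, network_size_range=(8, 25), sigma_by_phenotype=sig,
            planted_dysreg=[("NET_004", "pGBM", 90.0)], seed=5,
        )
        nets = ad.generate_networks(cfg)
        matrix, labels, _, _ = ad.generate_cohort(cfg, nets)
        res = ad.differential_regulation(
            ad.rank_transform(matrix), labels, nets, "G3", "pGBM", n_perm=1000, seed=5
        )
        assert res.table.index[0] == "NET_004"
        assert res.table["p"].iloc[0] < 0.01
        assert res.table["direction"].iloc[0] == "more conserved in G3"

    def test_delta_sign_convention(self):
        # index(A) < index(B) -> negative delta, "more conserved in B"
        table = pd.DataFrame({"index_a": [0.877], "index_b": [0.945]})
        delta = table["index_a"] - table["index_b"]
        assert delta.iloc[0] == pytest.approx(-0.068)
        # exercised through the API on a small planted case above

    def test_invariants_abs_delta_bounded_p_positive(self, small_cohort):
        _, nets, matrix, labels, _, _ = small_cohort
        res = ad.differential_regulation(matrix, labels, nets, "Normal", "sGBM",
                                         n_perm=30, seed=2)
        assert (res.table["abs_delta"] <= 0.5 + 1e-12).all()
        assert ((res.table["p"] > 0) & (res.table["p"] <= 1)).all()

    def test_per_network_null_option(self, small_cohort):
        _, nets, matrix, labels, _, _ = small_cohort
        res = ad.differential_regulation(matrix, labels, nets, "Normal", "sGBM",
                                         n_perm=30, seed=2, per_network_null=True)
        assert res.table["p"].min() >= 1 / 31


class TestCohortStatistics:
    def test_anova_identical_groups(self):
        table = ad.ConservationTable(
            indices=pd.DataFrame({"A": [1.0, 2.0, 3.0], "B": [1.0, 2.0, 3.0]},
                                 index=["n1", "n2", "n3"])
        )
        f, p = ad.anova_conservation(table)
        assert f == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_anova_separation_limit(self):
        rng = np.random.default_rng(1)
        table = ad.ConservationTable(
            indices=pd.DataFrame(
                {"A": rng.normal(0, 1e-4, 10), "B": 1 + rng.normal(0, 1e-4, 10)},
                index=[f"n{i}" for i in range(10)],
            )
        )
        _, p = ad.anova_conservation(table)
        assert p < 1e-12

    def test_anova_hand_computed_two_by_three(self):
        # groups {1,2,3} and {2,4,6}: grand mean 3, SSB = 3*(2-3)^2+3*(4-3)^2 = 6
        # SSW = 2 + 8 = 10; F = (6/1)/(10/4) = 2.4
        table = ad.ConservationTable(
            indices=pd.DataFrame({"A": [1.0, 2.0, 3.0], "B": [2.0, 4.0, 6.0]},
                                 index=["n1", "n2", "n3"])
        )
        f, _ = ad.anova_conservation(table)
        assert f == pytest.approx(2.4)

    def test_anova_degenerate_zero_variance(self):
        table = ad.ConservationTable(
            indices=pd.DataFrame({"A": [1.0, 1.0], "B": [1.0, 1.0]}, index=["n1", "n2"])
        )
        with pytest.raises(ValueError, match="variance"):
            ad.anova_conservation(table)

    def test_paired_t_identical_and_shifted_columns(self):
        idx = [f"n{i}" for i in range(10)]
        vals = np.linspace(0.8, 0.95, 10)
        table = ad.ConservationTable(
            indices=pd.DataFrame({"A": vals, "B": vals, "C": vals + 0.1}, index=idx)
        )
        p = ad.pairwise_t_tests(table)
        assert p.loc["A", "B"] == 1.0  # t = 0
        assert np.isnan(p.loc["A", "C"])  # zero-variance nonzero shift flagged
        assert p.equals(p.T)

    def test_paired_t_matches_textbook_formula(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0.9, 0.02, 12)
        b = a + rng.normal(0.01, 0.02, 12)
        table = ad.ConservationTable(
            indices=pd.DataFrame({"A": a, "B": b}, index=[f"n{i}" for i in range(12)])
        )
        d = a - b
        t = d.mean() / (d.std(ddof=1) / np.sqrt(12))
        from scipy import stats
        expected = 2 * stats.t.sf(abs(t), 11)
        assert ad.pairwise_t_tests(table).loc["A", "B"] == pytest.approx(expected)

    @pytest.mark.parametrize(
        "k, n, expected",
        [
            (5, 5, 1 / 32),
            (10, 12, (66 + 12 + 1) / 4096),  # exact tail sum
            (6, 12, None),  # k = n/2 -> p > 0.5 by symmetry
        ],
    )
    def test_binomial_direction_tail(self, k, n, expected):
        p = ad.binomial_direction_test(n, k)
        if expected is None:
            assert p > 0.5
        else:
            assert p == pytest.approx(expected)

    def test_binomial_empty_rejected(self):
        with pytest.raises(ValueError):
            ad.binomial_direction_test(0, 0)
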