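import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.base import clone

import prmpanel as pp
from prmpanel.gsea import plot_enrichment
from oracles import brute_force_es


@pytest.fixture
def small_counts():
    rng = np.random.default_rng(0)
    counts = pd.DataFrame(
        rng.poisson(50, size=(30, 12)),
        index=[f"BG{i:04d}" for i in range(30)],
        columns=[f"S{i:03d}" for i in range(12)],
    )
    counts.index.name = "protein_id"
    return counts


class TestNormalizeCounts:
    def test_constant_matrix_all_zero(self):
        counts = pd.DataFrame(np.full((4, 5), 7), columns=list("abcde"))
        z = pp.normalize_counts(counts)
        assert (z.to_numpy() == 0).all()

    def test_column_totals_equalized_before_log(self, small_counts):
        from prmpanel.gsea import _scale_columns

        scaled = _scale_columns(small_counts, "median_total")
        totals = scaled.sum(axis=0).to_numpy()
        assert np.allclose(totals, np.median(small_counts.sum(axis=0)))

    def test_rows_standardized(self, small_counts):
        z = pp.normalize_counts(small_counts)
        assert np.abs(z.mean(axis=1)).max() < 1e-9
        sd = z.std(axis=1, ddof=1)
        assert np.abs(sd[sd > 0] - 1).max() < 1e-9

    def test_hand_matrix_matches_spreadsheet_computation(self):
        counts = pd.DataFrame(
            [[10, 0, 4], [2, 8, 6], [30, 12, 20], [0, 4, 2]],
            index=list("ABCD"),
            columns=["s1", "s2", "s3"],
        )
        # independent spreadsheet-style evaluation, written out literally
        totals = np.array([42.0, 24.0, 32.0])
        scale = np.median(totals) / totals  # 32 / totals
        scaled = counts.to_numpy() * scale
        logged = np.log2(scaled + 1.0)
        mu = logged.mean(axis=1, keepdims=True)
        sd = logged.std(axis=1, ddof=1, keepdims=True)
        expected = (logged - mu) / sd
        z = pp.normalize_counts(counts)
        np.testing.assert_allclose(z.to_numpy(), expected, atol=1e-12)

    def test_zero_total_sample_rejected(self, small_counts):
        bad = small_counts.copy()
        bad.iloc[:, 0] = 0
        with pytest.raises(ValueError, match="zero total"):
            pp.normalize_counts(bad)

    def test_minimum_shape_enforced(self):
        with pytest.raises(ValueError, match="at least 2"):
            pp.normalize_counts(pd.DataFrame({"a": [1, 2, 3]}))

    @pytest.mark.parametrize("method", ["total", "quantile"])
    def test_alternative_normalizations_run(self, small_counts, method):
        z = pp.normalize_counts(small_counts, method=method)
        assert np.abs(z.mean(axis=1)).max() < 1e-9

    def test_unknown_method_rejected(self, small_counts):
        with pytest.raises(ValueError, match="unknown normalization"):
            pp.normalize_counts(small_counts, method="rank")

    def test_estimator_wrapper_matches_function(self, small_counts):
        norm = pp.CountZScoreNormalizer()
        z_est = norm.fit_transform(small_counts)
        pd.testing.assert_frame_equal(z_est, pp.normalize_counts(small_counts))
        assert clone(norm).get_params()["method"] == "median_total"


class TestRankByTarget:
    def test_matching_profile_ranks_first(self, small_counts):
        z = pp.normalize_counts(small_counts)
        target = z.loc["BG0005"].to_numpy()
        ranked = pp.rank_by_target(z, target)
        assert ranked.iloc[0]["protein"] == "BG0005"
        assert ranked.iloc[0]["score"] == pytest.approx(1.0)

    def test_sign_flipped_profile_ranks_last(self, small_counts):
        z = pp.normalize_counts(small_counts)
        target = -z.loc["BG0005"].to_numpy()
        ranked = pp.rank_by_target(z, target)
        assert ranked.iloc[-1]["protein"] == "BG0005"
        assert ranked.iloc[-1]["score"] == pytest.approx(-1.0)

    def test_scores_sorted_descending_ties_by_id(self, small_counts):
        z = pp.normalize_counts(small_counts)
        z.loc["BG0001"] = z.loc["BG0000"]  # force an exact score tie
        ranked = pp.rank_by_target(z, z.loc["BG0000"].to_numpy())
        scores = ranked["score"].to_numpy()
        assert (np.diff(scores) <= 1e-12).all()
        tied = ranked[ranked["protein"].isin(["BG0000", "BG0001"])]
        assert list(tied["protein"]) == ["BG0000", "BG0001"]

    def test_zero_variance_target_rejected(self, small_counts):
        z = pp.normalize_counts(small_counts)
        with pytest.raises(ValueError, match="zero variance"):
            pp.rank_by_target(z, np.ones(z.shape[1]))

    def test_series_target_aligned_by_sample(self, small_counts):
        z = pp.normalize_counts(small_counts)
        target = pd.Series(
            z.loc["BG0003"].to_numpy(), index=z.columns
        ).sample(frac=1, random_state=1)  # shuffled index order
        ranked = pp.rank_by_target(z, target)
        assert ranked.iloc[0]["protein"] == "BG0003"

    def test_s2n_ranking_available(self, small_counts):
        z = pp.normalize_counts(small_counts)
        ranked = pp.rank_by_target(z, z.loc["BG0002"].to_numpy(), ranking="s2n")
        assert ranked.iloc[0]["protein"] == "BG0002"


class TestEnrichmentScore:
    def test_two_protein_top_set(self):
        ranked = pd.DataFrame({"protein": ["A", "B"], "score": [2.0, -1.0]})
        assert pp.enrichment_score(ranked, ["A"], weight_p=0).es == pytest.approx(1.0)

    def test_two_protein_bottom_set(self):
        ranked = pd.DataFrame({"protein": ["A", "B"], "score": [2.0, -1.0]})
        assert pp.enrichment_score(ranked, ["B"], weight_p=0).es == pytest.approx(-1.0)

    def test_empty_intersection_not_evaluable(self):
        ranked = pd.DataFrame({"protein": ["A", "B"], "score": [2.0, -1.0]})
        res = pp.enrichment_score(ranked, ["ZZZ"])
        assert np.isnan(res.es)
        assert res.n_members_present == 0

    def test_all_proteins_set_rejected(self):
        ranked = pd.DataFrame({"protein": ["A", "B"], "score": [2.0, -1.0]})
        with pytest.raises(ValueError, match="every ranked protein"):
            pp.enrichment_score(ranked, ["A", "B"])

    def test_matches_bruteforce_oracle_exhaustively(self):
        """ES (p=0 and p=1) equals a position-by-position running-sum oracle
        on every instance with <= 12 proteins and set sizes 1-4."""
        rng = np.random.default_rng(42)
        for n in (2, 3, 5, 8, 12):
            scores = np.sort(rng.normal(0, 2, n))[::-1]
            ids = [f"P{i:02d}" for i in range(n)]
            ranked = pd.DataFrame({"protein": ids, "score": scores})
            for size in range(1, min(4, n - 1) + 1):
                for members in itertools.combinations(ids, size):
                    for p in (0.0, 1.0):
                        es = pp.enrichment_score(ranked, list(members), weight_p=p).es
                        oracle = brute_force_es(ids, scores, members, p)
                        assert es == pytest.approx(oracle, abs=1e-12)

    def test_matches_gseapy_reference(self):
        """Cross-check the weighted ES against the gseapy implementation."""
        gseapy = pytest.importorskip("gseapy")
        scores = np.array([5.0, 4.0, 3.0, 2.0, 1.0, -1.0, -2.0, -3.0, -4.0, -5.0])
        ids = [f"G{i}" for i in range(10)]
        ranked = pd.DataFrame({"protein": ids, "score": scores})
        sets = {"up": ["G0", "G3", "G7"], "down": ["G8", "G9", "G2"]}
        res = gseapy.prerank(
            rnk=pd.DataFrame({"gene": ids, "score": scores}),
            gene_sets=sets,
            permutation_num=10,
            outdir=None,
            seed=1,
            min_size=1,
            max_size=100,
            weight=1.0,
            no_plot=True,
        ).res2d
        for _, row in res.iterrows():
            mine = pp.enrichment_score(ranked, sets[row["Term"]], weight_p=1.0).es
            assert mine == pytest.approx(float(row["ES"]), abs=1e-9)

    @given(
        n=st.integers(min_value=3, max_value=40),
        seed=st.integers(min_value=0, max_value=10_000),
        p=st.sampled_from([0.0, 1.0, 2.0]),
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_es_always_in_unit_interval(self, n, seed, p):
        rng = np.random.default_rng(seed)
        scores = np.sort(rng.normal(size=n))[::-1]
        ids = [f"P{i:03d}" for i in range(n)]
        ranked = pd.DataFrame({"protein": ids, "score": scores})
        size = int(rng.integers(1, n))
        members = list(rng.choice(ids, size=size, replace=False))
        es = pp.enrichment_score(ranked, members, weight_p=p).es
        assert -1.0 - 1e-12 <= es <= 1.0 + 1e-12

    def test_running_sum_profile_ends_near_zero(self):
        rng = np.random.default_rng(3)
        scores = np.sort(rng.normal(size=20))[::-1]
        ranked = pd.DataFrame(
            {"protein": [f"P{i:02d}" for i in range(20)], "score": scores}
        )
        res = pp.enrichment_score(ranked, ["P01", "P07", "P15"], weight_p=0)
        assert res.running_sum[-1] == pytest.approx(0.0, abs=1e-12)


class TestPermutationTest:
    def _fixture(self, effect=0.0, seed=0, n_samples=14):
        cfg = pp.SyntheticConfig(
            n_samples=n_samples,
            gene_set_effect=effect,
            n_background_proteins=120,
            n_gene_sets=4,
            gene_set_size=20,
            seed=seed,
        )
        truth, _ = pp.generate_cohort(cfg)
        counts, gene_sets = pp.generate_spectral_counts(truth, cfg)
        z = pp.normalize_counts(counts)
        target = truth.true_abundance.loc[cfg.gsea_target]
        return z, target, gene_sets

    def test_same_seed_identical_results(self):
        z, target, gene_sets = self._fixture(seed=5)
        r1 = pp.permutation_test(z, target, gene_sets, n_perm=150, seed=9)
        r2 = pp.permutation_test(z, target, gene_sets, n_perm=150, seed=9)
        pd.testing.assert_frame_equal(r1, r2)

    def test_pvalues_never_zero(self):
        z, target, gene_sets = self._fixture(effect=3.0, seed=1)
        res = pp.permutation_test(z, target, gene_sets, n_perm=150, seed=2)
        assert (res["p_perm"] >= 1.0 / 151).all()
        assert (res["p_perm"] <= 1.0).all()

    def test_embedded_signal_set_wins(self):
        z, target, gene_sets = self._fixture(effect=2.0, seed=3, n_samples=20)
        res = pp.permutation_test(z, target, gene_sets, n_perm=200, seed=4)
        best = res.loc[res["nes"].abs().idxmax(), "set"]
        assert best.startswith("RESPONSE")
        signal = res[res["set"].str.startswith("RESPONSE")].iloc[0]
        assert signal["fdr_q"] == res["fdr_q"].min()

    def test_exhaustive_permutations_at_small_n(self):
        rng = np.random.default_rng(0)
        z = pd.DataFrame(
            rng.normal(size=(15, 4)),
            index=[f"P{i:02d}" for i in range(15)],
            columns=list("abcd"),
        )
        sets = {"s": ["P00", "P01", "P02"]}
        with pytest.warns(UserWarning, match="exhaustive"):
            res = pp.permutation_test(z, rng.normal(size=4), sets, n_perm=100, seed=0)
        # 4! = 24 permutations -> p granularity of 1/25
        assert res["p_perm"].iloc[0] >= 1.0 / 25

    def test_too_few_permutations_rejected(self):
        z, target, gene_sets = self._fixture()
        with pytest.raises(ValueError, match="n_perm"):
            pp.permutation_test(z, target, gene_sets, n_perm=50)

    def test_missing_set_flagged_not_evaluable(self):
        z, target, gene_sets = self._fixture()
        gene_sets = dict(gene_sets, GHOST=["NOT_THERE_1", "NOT_THERE_2"])
        res = pp.permutation_test(z, target, gene_sets, n_perm=120, seed=1)
        ghost = res[res["set"] == "GHOST"].iloc[0]
        assert np.isnan(ghost["es"]) and np.isnan(ghost["p_perm"])
        assert ghost["n_members_present"] == 0


class TestTargetSortedGSEAEstimator:
    def test_fit_exposes_results(self):
        cfg = pp.SyntheticConfig(
            n_samples=16, n_background_proteins=100, n_gene_sets=3,
            gene_set_size=15, seed=2,
        )
        truth, _ = pp.generate_cohort(cfg)
        counts, gene_sets = pp.generate_spectral_counts(truth, cfg)
        model = pp.TargetSortedGSEA(gene_sets=gene_sets, n_perm=120, random_state=0)
        model.fit(counts, truth.true_abundance.loc[cfg.gsea_target])
        assert set(model.results_["set"]) == set(gene_sets)
        assert model.ranking_.shape[0] == counts.shape[0]
        assert model.zscores_.shape == counts.shape
        profile = model.score_profile(next(iter(gene_sets)))
        assert profile.n_members_present == 15
        assert clone(model).get_params()["n_perm"] == 120

    def test_gene_sets_required(self, small_counts):
        with pytest.raises(ValueError, match="gene_sets"):
            pp.TargetSortedGSEA().fit(small_counts, np.arange(12.0))

    def test_plot_helper_runs(self, small_counts, tmp_path):
        import matplotlib

        matplotlib.use("Agg")
        z = pp.normalize_counts(small_counts)
        ranked = pp.rank_by_target(z, z.loc["BG0004"].to_numpy())
        ax = plot_enrichment(ranked, ["BG0004", "BG0011", "BG0020"])
        ax.figure.savefig(tmp_path / "es.png")
        assert (tmp_path / "es.png").exists()
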