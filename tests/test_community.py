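import numpy as np
import pandas as pd
import pytest

from darktaxa import community, synthio
from darktaxa.errors import ConfigError, DataError

from oracles import covariance_eig_relative, normal_equations_adjusted_r2, textbook_pearson


def frame(data, traps=None):
    traps = traps or [f"t{i}" for i in range(len(data))]
    return pd.DataFrame(data, index=traps)


class TestBuildMatrix:
    def test_row_normalisation(self):
        counts = frame([{"F1": 5, "F2": 5}])
        mat = community.build_matrix(counts)
        assert mat.loc["t0"].tolist() == [0.5, 0.5]

    def test_single_family_row(self):
        counts = frame([{"F1": 7}])
        assert community.build_matrix(counts).loc["t0", "F1"] == 1.0

    def test_unidentified_excluded_before_normalisation(self):
        counts = frame([{"F1": 3, "unassigned": 7}])
        mat = community.build_matrix(counts)
        assert "unassigned" not in mat.columns
        assert mat.loc["t0", "F1"] == 1.0

    def test_empty_trap_dropped_with_warning(self):
        counts = frame([{"F1": 3, "F2": 1}, {"F1": 0, "F2": 0}])
        with pytest.warns(UserWarning, match="empty"):
            mat = community.build_matrix(counts)
        assert list(mat.index) == ["t0"]

    def test_negative_counts_rejected(self):
        with pytest.raises(DataError):
            community.build_matrix(frame([{"F1": -1}]))

    def test_rows_sum_to_one(self, rng):
        counts = frame(
            [
                {f"F{j}": int(rng.integers(0, 30)) + (1 if j == 0 else 0) for j in range(6)}
                for _ in range(8)
            ]
        )
        mat = community.build_matrix(counts)
        assert np.allclose(mat.sum(axis=1), 1.0, atol=1e-9)

    def test_noise_free_rows_equal_profile(self):
        scenario = synthio.CommunityScenario(
            n_traps=6,
            n_families=4,
            family_profile=(0.4, 0.3, 0.2, 0.1),
            species_mean=10.0,
            species_dispersion=None,
            seed=21,
        )
        truth = synthio.simulate_community(scenario)
        counts = (
            truth.specimens.groupby(["trap", "family"])["species"]
            .nunique()
            .unstack(fill_value=0)
        )
        mat = community.build_matrix(counts)
        for row in mat.itertuples(index=False):
            assert tuple(row) == pytest.approx((0.4, 0.3, 0.2, 0.1))


class TestApplyExclusions:
    def setup_method(self):
        self.mat = frame([{"F1": 0.5, "F2": 0.3, "F3": 0.2}, {"F1": 0.6, "F2": 0.2, "F3": 0.2}])

    def test_ten_specimens_excluded(self):
        out = community.apply_exclusions(
            self.mat,
            specimen_totals={"F1": 10, "F2": 100, "F3": 100},
            samples_present={"F1": 2, "F2": 2, "F3": 2},
        )
        assert list(out.columns) == ["F2", "F3"]

    def test_single_sample_family_excluded(self):
        out = community.apply_exclusions(
            self.mat,
            specimen_totals={"F1": 100, "F2": 100, "F3": 100},
            samples_present={"F1": 2, "F2": 1, "F3": 2},
        )
        assert list(out.columns) == ["F1", "F3"]

    def test_boundary_retained_and_rows_not_renormalised(self):
        out = community.apply_exclusions(
            self.mat,
            specimen_totals={"F1": 11, "F2": 5, "F3": 100},
            samples_present={"F1": 2, "F2": 2, "F3": 2},
        )
        assert list(out.columns) == ["F1", "F3"]
        assert out.loc["t0"].sum() == pytest.approx(0.7)  # original denominator kept

    def test_missing_metadata(self):
        with pytest.raises(DataError):
            community.apply_exclusions(self.mat, {"F1": 5}, {"F1": 1})


class TestRankTopFamilies:
    def test_ordering(self):
        mat = frame([{"A": 0.3, "B": 0.1, "C": 0.6}])
        ranking = community.rank_top_families(mat, n=2)
        assert ranking["family"].tolist() == ["C", "A"]

    def test_n_zero_empty(self):
        mat = frame([{"A": 1.0}])
        assert community.rank_top_families(mat, n=0).empty

    def test_overlong_request_warns(self):
        mat = frame([{"A": 0.5, "B": 0.5}])
        with pytest.warns(UserWarning):
            ranking = community.rank_top_families(mat, n=10)
        assert len(ranking) == 2

    def test_tie_break_by_total_then_name(self):
        mat = frame([{"A": 0.25, "B": 0.25, "C": 0.25, "D": 0.25}])
        ranking = community.rank_top_families(mat, n=4, totals={"A": 1, "B": 9, "C": 9, "D": 2})
        assert ranking["family"].tolist() == ["B", "C", "D", "A"]

    def test_profile_order_recovered_noise_free(self):
        scenario = synthio.CommunityScenario(
            n_traps=5,
            n_families=4,
            family_profile=(0.4, 0.3, 0.2, 0.1),
            species_mean=10.0,
            species_dispersion=None,
            seed=8,
        )
        truth = synthio.simulate_community(scenario)
        counts = (
            truth.specimens.groupby(["trap", "family"])["species"]
            .nunique()
            .unstack(fill_value=0)
        )
        ranking = community.rank_top_families(community.build_matrix(counts), n=4)
        assert ranking["family"].tolist() == [
            "family_01",
            "family_02",
            "family_03",
            "family_04",
        ]


class TestVarianceExplained:
    def test_constant_within_family_gives_one(self):
        mat = frame([{"A": 0.7, "B": 0.3}] * 4)
        assert community.variance_explained_by_taxon(mat) == pytest.approx(1.0)

    def test_matches_normal_equations_oracle(self):
        mat = frame([{"A": 0.7, "B": 0.3}, {"A": 0.55, "B": 0.45}])
        expected = normal_equations_adjusted_r2(
            np.array([0.7, 0.55, 0.3, 0.45]), ["A", "A", "B", "B"]
        )
        assert community.variance_explained_by_taxon(mat) == pytest.approx(expected)

    def test_matches_oracle_on_random_matrix(self, rng):
        raw = rng.dirichlet(np.ones(5), size=9)
        mat = pd.DataFrame(raw, columns=[f"F{i}" for i in range(5)])
        long = mat.stack()
        expected = normal_equations_adjusted_r2(
            long.to_numpy(), [f for _, f in long.index]
        )
        assert community.variance_explained_by_taxon(mat) == pytest.approx(expected)

    def test_shuffled_labels_near_zero(self, rng):
        # permutation null: mean adjusted R^2 within +/-0.05 of 0
        values = []
        for _ in range(100):
            raw = rng.dirichlet(np.ones(4), size=30)
            shuffled = raw.copy()
            for row in shuffled:
                rng.shuffle(row)
            mat = pd.DataFrame(shuffled, columns=list("ABCD"))
            values.append(community.variance_explained_by_taxon(mat))
        assert abs(np.mean(values)) < 0.05

    def test_invariance_to_reordering(self, rng):
        raw = rng.dirichlet(np.ones(4), size=6)
        mat = pd.DataFrame(raw, columns=list("ABCD"))
        shuffled = mat.sample(frac=1, random_state=1)[list("DCAB")]
        assert community.variance_explained_by_taxon(mat) == pytest.approx(
            community.variance_explained_by_taxon(shuffled)
        )

    def test_too_small_rejected(self):
        with pytest.raises(DataError):
            community.variance_explained_by_taxon(frame([{"A": 1.0}]))


class TestPCA:
    def test_relative_eigenvalues_sum_to_one(self, rng):
        mat = pd.DataFrame(rng.random((6, 4)))
        res = community.pca_relative_eigenvalues(mat)
        assert res.relative_eigenvalues.sum() == pytest.approx(1.0)
        assert (np.diff(res.relative_eigenvalues) <= 1e-12).all()
        assert (res.relative_eigenvalues >= -1e-12).all()

    def test_rank_one_matrix(self):
        base = np.array([1.0, 2.0, 3.0])
        mat = pd.DataFrame([base * 1, base * 2, base * 3])
        res = community.pca_relative_eigenvalues(mat)
        assert res.relative_eigenvalues[0] == pytest.approx(1.0)

    def test_constant_matrix_flagged(self):
        mat = pd.DataFrame([[0.5, 0.5]] * 3)
        res = community.pca_relative_eigenvalues(mat)
        assert res.degenerate
        assert np.all(res.relative_eigenvalues == 0)

    def test_matches_dense_eigensolver_oracle(self, rng):
        mat = pd.DataFrame(rng.random((5, 4)))
        res = community.pca_relative_eigenvalues(mat)
        expected = covariance_eig_relative(mat.to_numpy())
        assert np.allclose(res.relative_eigenvalues, expected, atol=1e-10)

    def test_scores_reproduce_centred_data(self, rng):
        mat = pd.DataFrame(rng.random((6, 3)))
        res = community.pca_relative_eigenvalues(mat)
        centred = mat.to_numpy() - mat.to_numpy().mean(axis=0)
        # scores hold the same total variance as the centred data
        assert np.allclose((res.scores**2).sum(), (centred**2).sum())


class TestTurnover:
    def test_all_private(self):
        inc = pd.DataFrame([[1, 0], [0, 1]], columns=["sp1", "sp2"])
        assert community.turnover_single_site(inc) == 1.0

    def test_half(self):
        inc = pd.DataFrame([[1, 1], [1, 0]], columns=["sp1", "sp2"])
        assert community.turnover_single_site(inc) == 0.5

    def test_family_subset(self):
        inc = pd.DataFrame([[1, 1, 1], [0, 1, 0]], columns=["a", "b", "c"])
        frac = community.turnover_single_site(
            inc, families=["X"], family_of={"a": "X", "b": "Y", "c": "X"}
        )
        assert frac == 1.0

    def test_empty_subset_error(self):
        inc = pd.DataFrame([[1]], columns=["a"])
        with pytest.raises(DataError):
            community.turnover_single_site(inc, families=["Z"], family_of={"a": "X"})

    def test_generator_turnover_within_ci(self):
        from scipy import stats

        scenario = synthio.CommunityScenario(
            n_traps=8,
            n_families=3,
            family_profile=(0.5, 0.3, 0.2),
            species_mean=30.0,
            turnover=0.9,
            seed=31,
        )
        truth = synthio.simulate_community(scenario)
        inc = (
            truth.specimens.groupby(["trap", "species"]).size().unstack(fill_value=0) > 0
        )
        frac = community.turnover_single_site(inc)
        n = truth.specimens["species"].nunique()
        lo, hi = stats.binom.interval(0.99, n, 0.9)
        assert lo / n <= frac <= hi / n


class TestCladeAgeCorrelation:
    def test_perfect_linearity(self):
        ages = [10.0, 20.0, 30.0, 40.0]
        props = [0.1, 0.2, 0.3, 0.4]
        r, n, p = community.clade_age_correlation(ages, props)
        assert r == pytest.approx(1.0)
        assert n == 4

    def test_permuted_near_zero(self, rng):
        ages = rng.uniform(10, 300, size=10_000)
        props = rng.permutation(rng.uniform(0, 1, size=10_000))
        r, _, _ = community.clade_age_correlation(ages, props)
        assert abs(r) < 0.05

    def test_three_pair_textbook_value(self):
        ages = [100.0, 150.0, 240.0]
        props = [0.05, 0.22, 0.11]
        r, n, _ = community.clade_age_correlation(ages, props)
        assert r == pytest.approx(textbook_pearson(ages, props))
        assert n == 3

    def test_zero_variance_error(self):
        with pytest.raises(DataError):
            community.clade_age_correlation([10, 10, 10], [0.1, 0.2, 0.3])


class TestMergeAndRerank:
    def test_identity_map_unchanged(self):
        mat = frame([{"A": 0.5, "B": 0.3, "C": 0.2}])
        base = community.rank_top_families(mat, n=3)
        merged = community.merge_and_rerank(mat, {}, n=3)
        pd.testing.assert_frame_equal(base, merged)

    def test_additivity(self):
        mat = frame([{"A": 0.04, "B": 0.03, "C": 0.93}])
        merged = community.merge_and_rerank(mat, {"A": "AB", "B": "AB"}, n=2)
        row = merged.set_index("family")["mean_proportion"]
        assert row["AB"] == pytest.approx(0.07)

    def test_merge_lifts_clade_into_top_n(self):
        mat = frame([{"A": 0.28, "B": 0.27, "C": 0.20, "D": 0.14, "E": 0.11}])
        base = community.rank_top_families(mat, n=3)
        assert "D" not in base["family"].tolist()
        merged = community.merge_and_rerank(mat, {"D": "DE", "E": "DE"}, n=3)
        assert "DE" in merged["family"].tolist()

    def test_unknown_key_rejected(self):
        mat = frame([{"A": 1.0}])
        with pytest.raises(DataError):
            community.merge_and_rerank(mat, {"Z": "ZZ"})

    def test_collision_rejected(self):
        mat = frame([{"A": 0.5, "B": 0.5}])
        with pytest.raises(DataError):
            community.merge_and_rerank(mat, {"A": "B"})
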