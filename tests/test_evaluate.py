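"""Assessment metrics, contribution analysis and the random baseline."""

import numpy as np
import pytest
from scipy.stats import hypergeom

import dockpot as dp
from conftest import bead_structure


class TestTopnSuccess:
    def test_native_at_rank_one(self):
        ranks = np.array([1, 2, 3])
        hits = np.array([True, False, False])
        assert dp.topn_success(ranks, hits, 1)

    def test_near_native_at_rank_eleven(self):
        ranks = np.arange(1, 21)
        hits = ranks == 11
        assert not dp.topn_success(ranks, hits, 10)
        assert dp.topn_success(ranks, hits, 100)


class TestEnrichmentFraction:
    def test_perfectly_ranked_hits_give_one(self):
        ranks = np.arange(1, 101)
        hits = ranks <= 5
        assert dp.enrichment_fraction(ranks, hits, 0.05) == 1.0

    def test_no_hits_in_top_slice_gives_zero(self):
        ranks = np.arange(1, 101)
        hits = ranks > 90
        assert dp.enrichment_fraction(ranks, hits, 0.05) == 0.0

    def test_random_ranking_averages_to_percentile(self):
        """Over 10^4 shuffles the mean captured fraction ~= percentile."""
        rng = np.random.default_rng(9)
        n, m, q, shuffles = 200, 40, 0.05, 10_000
        hits = np.zeros(n, dtype=bool)
        hits[:m] = True
        vals = []
        for _ in range(shuffles):
            ranks = rng.permutation(n) + 1
            vals.append(dp.enrichment_fraction(ranks, hits, q))
        top = int(np.ceil(q * n))
        # captured count is hypergeometric(n, m, top)
        sd = np.sqrt(hypergeom(n, m, top).var()) / m
        assert abs(np.mean(vals) - top / n) < 3 * sd / np.sqrt(shuffles)

    def test_zero_hits_raise(self):
        with pytest.raises(ValueError):
            dp.enrichment_fraction(np.arange(1, 11), np.zeros(10, bool), 0.1)


@pytest.fixture(scope="module")
def grid_and_native(decoy_set, native):
    decoys, _ = decoy_set
    grid = dp.build_feature_grid(decoys[:20], dp.StepForm((0, 4, 6)))
    return grid, native


class TestInsertNative:

    def test_augmented_grid_has_one_more_row(self, grid_and_native):
        grid, native = grid_and_native
        aug = dp.insert_native(grid, native)
        assert aug.n_decoys == grid.n_decoys + 1
        assert aug.native_row == grid.n_decoys

    def test_native_row_equals_direct_featurization(self, grid_and_native):
        grid, native = grid_and_native
        aug = dp.insert_native(grid, native)
        direct = dp.compute_features(native, grid.form)
        assert np.array_equal(aug.matrix[aug.native_row], direct)

    def test_excluding_native_reproduces_original_assessment(
            self, grid_and_native):
        grid, native = grid_and_native
        aug = dp.insert_native(grid, native)
        pv = dp.ParameterVector(form=grid.form,
                                values=np.linspace(-1, 1, 20), n_types=4)
        s_orig = dp.score(grid, pv)
        s_aug = dp.score(aug, pv)
        mask = np.arange(aug.n_decoys) != aug.native_row
        assert np.array_equal(s_aug[mask], s_orig)

    def test_table_mismatch_raises(self, grid_and_native):
        grid, _ = grid_and_native
        other = bead_structure([[0, 0, 0]], [[3.0, 0, 0]], n_types=5)
        with pytest.raises(dp.LayoutError):
            dp.insert_native(grid, other)


class TestContributions:
    def test_zero_parameter_gives_zero_contribution(self):
        assert dp.class_contribution(0.0, 5.0, 3.0) == 0.0

    def test_class_mean_equal_to_total_returns_sigma(self):
        assert dp.class_contribution(-2.5, 4.0, 4.0) == pytest.approx(-2.5)

    def test_three_decoy_fixture_matches_hand_enumeration(self):
        """Two near-native and one incorrect decoy, single feature."""
        features = np.array([3.0, 5.0, 10.0])
        near = np.array([True, True, False])
        sigma = -1.2
        nc_nn = features[near].mean()          # 4.0
        nc_inc = features[~near].mean()        # 10.0
        nc_tot = features.mean()               # 6.0
        assert dp.class_contribution(sigma, nc_nn, nc_tot) \
            == pytest.approx(-1.2 * 4.0 / 6.0)
        rec = dp.discriminating_contribution(sigma, nc_nn, nc_inc, nc_tot)
        assert rec.dp_abs == pytest.approx(-1.2 * 6.0 / 6.0)
        assert rec.dp_signed == pytest.approx(
            (-1.2 * 10.0 / 6.0) - (-1.2 * 4.0 / 6.0))

    def test_equal_class_means_give_zero_dp(self):
        rec = dp.discriminating_contribution(2.0, 3.0, 3.0, 3.0)
        assert rec.dp_abs == 0.0 and rec.dp_signed == 0.0

    def test_false_negative_flag(self):
        """Negative (favourable) parameter but contacts favour incorrect."""
        rec = dp.discriminating_contribution(-1.0, 2.0, 5.0, 3.0)
        assert rec.false_negative and not rec.false_positive

    def test_false_positive_flag(self):
        rec = dp.discriminating_contribution(1.0, 5.0, 2.0, 3.0)
        assert rec.false_positive and not rec.false_negative

    def test_rescaling_features_and_sigma_inversely_is_invariant(self):
        a = dp.discriminating_contribution(2.0, 4.0, 1.0, 2.0)
        b = dp.discriminating_contribution(2.0 / 10, 40.0, 10.0, 20.0)
        assert a.dp_abs == pytest.approx(b.dp_abs * 10)  # dp scales as sigma*1
        # p is invariant when sigma and features rescale inversely
        assert dp.class_contribution(2.0, 4.0, 2.0) == pytest.approx(
            dp.class_contribution(0.2, 40.0, 20.0) * 10)


class TestRandomBaseline:
    def test_same_seed_gives_identical_report(self):
        hits = [np.array([True] + [False] * 49)]
        a = dp.random_baseline([50], hits, n_shuffles=200, seed=3)
        b = dp.random_baseline([50], hits, n_shuffles=200, seed=3)
        assert a.success == b.success
        assert a.enrichment == b.enrichment

    def test_topn_success_matches_hypergeometric(self):
        """m of n hits, top-N draw: P(success) = 1 - C(n-m,N)/C(n,N)."""
        n, m, N, shuffles = 60, 6, 10, 10_000
        hits = [np.concatenate([np.ones(m, bool), np.zeros(n - m, bool)])]
        rep = dp.random_baseline([n], hits, n_shuffles=shuffles, seed=1,
                                 top_n=(N,), percentiles=(0.05,))
        p = 1.0 - hypergeom(n, m, N).pmf(0)
        se = np.sqrt(p * (1 - p) / shuffles)
        assert abs(rep.success[N] - p) < 3 * se

    def test_enrichment_matches_percentile(self):
        n, m, q, shuffles = 100, 20, 0.05, 10_000
        hits = [np.concatenate([np.ones(m, bool), np.zeros(n - m, bool)])]
        rep = dp.random_baseline([n], hits, n_shuffles=shuffles, seed=2,
                                 top_n=(1,), percentiles=(q,))
        top = int(np.ceil(q * n))
        sd = np.sqrt(hypergeom(n, m, top).var()) / m
        assert abs(rep.enrichment[q] - top / n) < 3 * sd / np.sqrt(shuffles)


class TestEvaluatePotential:
    def test_success_fractions_non_decreasing_in_n(self, decoy_set):
        decoys, _ = decoy_set
        grid = dp.build_feature_grid(decoys, dp.StepForm((0, 4, 6)))
        rng = np.random.default_rng(6)
        pv = dp.ParameterVector(form=grid.form, values=rng.normal(size=20),
                                n_types=4)
        hits = [rng.uniform(size=grid.n_decoys) < 0.2]
        rep = dp.evaluate_potential([grid], pv, hits,
                                    top_n=(1, 10, 50), percentiles=(0.01,
                                                                    0.05,
                                                                    0.2))
        vals = [rep.success[n] for n in (1, 10, 50)]
        assert vals == sorted(vals)
        enr = [rep.enrichment[p] for p in (0.01, 0.05, 0.2)]
        assert enr == sorted(enr)
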