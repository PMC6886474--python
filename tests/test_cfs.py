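import logging
from itertools import combinations

import numpy as np
import pytest

from molscreen import ConfigurationError, DataError
from molscreen.cfs import (
    BFConfig,
    GPSOConfig,
    GSConfig,
    MeritEvaluator,
    SSFSConfig,
    best_first_search,
    class_feature_correlation,
    exhaustive_search,
    genetic_search,
    gpso_search,
    merit,
    reduction_rate,
    ssfs_search,
)
from molscreen.synthetic import SyntheticSpec, generate_training_dataset

from conftest import make_table, small_labeled_table
from oracles import merit_literal

logging.disable(logging.WARNING)  # SSFS top_k clamp notices on tiny tables


def instance(seed, **kw):
    base = dict(
        n_active=60, n_inactive=40, n_informative=4, n_redundant=2,
        n_zero_variance=0, n_noise=5, effect_size=1.0, frac_binary=0.4,
        redundancy_noise=0.05, seed=seed,
    )
    base.update(kw)
    return generate_training_dataset(SyntheticSpec(**base)).table


class TestClassFeatureCorrelation:
    def test_column_identical_to_class_gives_one(self):
        y = np.array([0, 1, 0, 1, 1, 0])
        t = make_table(y.reshape(-1, 1).astype(float), y=y)
        assert class_feature_correlation(t, "F00") == pytest.approx(1.0)

    def test_constant_column_gives_zero(self):
        y = np.array([0, 1, 0, 1])
        t = make_table(np.ones((4, 1)), y=y)
        assert class_feature_correlation(t, "F00") == 0.0

    def test_independent_column_small_magnitude(self):
        rng = np.random.default_rng(0)
        n = 10_000
        y = rng.integers(0, 2, n)
        t = make_table(rng.normal(size=(n, 1)), y=y)
        assert class_feature_correlation(t, "F00") < 0.05

    def test_requires_labels(self):
        t = make_table(np.ones((4, 1)))
        with pytest.raises(DataError):
            class_feature_correlation(t, "F00")


class TestMerit:
    def test_singleton_merit_equals_class_correlation(self, labeled_table):
        col = labeled_table.columns[0]
        score = merit(labeled_table, [col])
        assert score.merit == pytest.approx(
            class_feature_correlation(labeled_table, col)
        )
        assert score.mean_inter_corr == 0.0

    def test_duplicated_feature_closed_form(self):
        # k=2, rcf=0.5, rff=1 -> merit = 2*0.5/sqrt(2+2) = 0.5
        rng = np.random.default_rng(5)
        y = np.repeat([0, 1], 100)
        base = rng.normal(size=200)
        # calibrate a column with |corr to class| ~ anything; duplicate it
        x = base + 0.0
        t = make_table(np.column_stack([x, x]), y=y)
        score = merit(t, ["F00", "F01"])
        rcf = class_feature_correlation(t, "F00")
        assert score.mean_inter_corr == pytest.approx(1.0)
        assert score.merit == pytest.approx(2 * rcf / np.sqrt(4))

    @pytest.mark.parametrize("seed", range(3))
    def test_all_subsets_match_literal_transcription(self, seed):
        rng = np.random.default_rng(seed)
        n, d = 60, 8
        y = rng.integers(0, 2, n)
        X = rng.normal(size=(n, d)) + 0.5 * y[:, None] * rng.random(d)
        t = make_table(X, y=y)
        for k in range(1, d + 1):
            for idx in combinations(range(d), k):
                cols = [t.columns[j] for j in idx]
                got = merit(t, cols).merit
                want = merit_literal(X, y.astype(float), idx)
                assert got == pytest.approx(want, abs=1e-10)

    def test_empty_subset_rejected(self, labeled_table):
        with pytest.raises(ConfigurationError):
            merit(labeled_table, [])

    def test_merit_decomposition_identity(self, labeled_table):
        score = merit(labeled_table, labeled_table.columns[:4])
        k, rcf, rff = score.k, score.mean_class_corr, score.mean_inter_corr
        assert score.merit == pytest.approx(
            k * rcf / np.sqrt(k + k * (k - 1) * rff)
        )

    def test_adding_exact_duplicate_never_increases_merit(self):
        rng = np.random.default_rng(7)
        y = rng.integers(0, 2, 80)
        X = rng.normal(size=(80, 4)) + y[:, None]
        X = np.hstack([X, X[:, [0]]])  # F04 duplicates F00
        t = make_table(X, y=y)
        base = merit(t, ["F00", "F01", "F02"]).merit
        extended = merit(t, ["F00", "F01", "F02", "F04"]).merit
        assert extended <= base + 1e-12


class TestReductionRate:
    def test_table4_set01_bf_arithmetic(self):
        # 1,872 candidate features, 37 selected -> 98.02% removed
        assert reduction_rate(1872, 37) == pytest.approx(0.9802, abs=5e-5)

    def test_boundaries(self):
        assert reduction_rate(10, 10) == 0.0
        assert reduction_rate(10, 0) == 1.0

    def test_bounds_enforced(self):
        with pytest.raises(ConfigurationError):
            reduction_rate(0, 0)
        with pytest.raises(ConfigurationError):
            reduction_rate(5, 6)


class TestExhaustive:
    def test_single_column_table(self):
        t = small_labeled_table(d_inf=1, d_noise=0)
        assert exhaustive_search(t).columns == [t.columns[0]]

    def test_refuses_large_tables(self):
        t = small_labeled_table(d_inf=4, d_noise=13)
        with pytest.raises(ConfigurationError, match="guard"):
            exhaustive_search(t)

    @pytest.mark.parametrize("seed", range(20))
    def test_one_informative_among_noise_recovered(self, seed):
        t = instance(
            seed, n_informative=1, n_redundant=0, n_noise=7,
            effect_size=1.5, frac_binary=0.0, n_active=80, n_inactive=60,
        )
        assert exhaustive_search(t).columns == ["INF000"]

    def test_redundant_pair_yields_single_member(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, 100)
        x = rng.normal(size=100) + 1.5 * y
        X = np.column_stack([x, x, rng.normal(size=100)])
        t = make_table(X, y=y)
        winner = exhaustive_search(t)
        assert len(set(winner.columns) & {"F00", "F01"}) == 1


class TestBestFirst:
    def test_beats_every_singleton(self, labeled_table):
        best = best_first_search(labeled_table)
        singles = [
            merit(labeled_table, [c]).merit for c in labeled_table.columns
        ]
        assert best.score.merit >= max(singles) - 1e-12

    def test_matches_exhaustive_on_small_instances(self):
        hits = 0
        for seed in range(20):
            t = instance(seed)
            ex = exhaustive_search(t, max_dim=12)
            bf = best_first_search(t)
            assert bf.score.merit <= ex.score.merit + 1e-12  # oracle dominance
            hits += bf.score.merit >= ex.score.merit - 1e-12
        assert hits >= 18  # >= 90% of instances

    def test_patience_monotonicity(self):
        for seed in (0, 3, 9):
            t = instance(seed)
            m1 = best_first_search(t, BFConfig(patience=1)).score.merit
            m5 = best_first_search(t, BFConfig(patience=5)).score.merit
            assert m5 >= m1 - 1e-12

    def test_score_not_stale(self, labeled_table):
        best = best_first_search(labeled_table)
        assert best.score.merit == pytest.approx(
            merit(labeled_table, best.columns).merit
        )


class TestGenetic:
    def test_deterministic_given_seed(self, labeled_table):
        a = genetic_search(labeled_table, GSConfig(seed=5))
        b = genetic_search(labeled_table, GSConfig(seed=5))
        assert a.columns == b.columns and a.score == b.score

    def test_elitism_never_loses_initial_best(self, labeled_table):
        # replicate the seeded initial population and check the returned
        # merit dominates it (single-elite carryover guarantee)
        config = GSConfig(seed=11, generations=3)
        rng = np.random.default_rng(config.seed)
        d = labeled_table.n_cols
        init_best = -np.inf
        for _ in range(config.population):
            mask = rng.random(d) < 0.5
            if not mask.any():
                mask[rng.integers(d)] = True
            cols = [labeled_table.columns[j] for j in np.flatnonzero(mask)]
            init_best = max(init_best, merit(labeled_table, cols).merit)
        result = genetic_search(labeled_table, config)
        assert result.score.merit >= init_best - 1e-12

    def test_within_five_percent_of_optimum(self):
        ok = 0
        for seed in range(20):
            t = instance(seed)
            ex = exhaustive_search(t, max_dim=12)
            gs = genetic_search(t, GSConfig(seed=seed))
            assert gs.score.merit <= ex.score.merit + 1e-12
            ok += gs.score.merit >= 0.95 * ex.score.merit
        assert ok >= 16  # >= 80% of seeded runs


class TestGPSO:
    def test_weight_validation(self):
        with pytest.raises(ConfigurationError):
            GPSOConfig(w1=0.5, w2=0.5, w3=0.5)

    def test_inertia_only_returns_best_initial_particle(self, labeled_table):
        # w=(1,0,0): positions never change
        config = GPSOConfig(w1=1.0, w2=0.0, w3=0.0, seed=3)
        rng = np.random.default_rng(config.seed)
        d = labeled_table.n_cols
        init_best = -np.inf
        for _ in range(config.particles):
            mask = rng.random(d) < 0.5
            if not mask.any():
                mask[rng.integers(d)] = True
            cols = [labeled_table.columns[j] for j in np.flatnonzero(mask)]
            init_best = max(init_best, merit(labeled_table, cols).merit)
        result = gpso_search(labeled_table, config)
        assert result.score.merit == pytest.approx(init_best)

    def test_social_only_collapses_to_global_best(self, labeled_table):
        # w2=1: every particle inherits the global best wholesale
        result = gpso_search(
            labeled_table, GPSOConfig(w1=0.0, w2=1.0, w3=0.0, seed=3)
        )
        init = gpso_search(
            labeled_table, GPSOConfig(w1=1.0, w2=0.0, w3=0.0, seed=3)
        )
        assert result.score.merit == pytest.approx(init.score.merit)

    def test_deterministic_given_seed(self, labeled_table):
        a = gpso_search(labeled_table, GPSOConfig(seed=2))
        b = gpso_search(labeled_table, GPSOConfig(seed=2))
        assert a.columns == b.columns

    def test_within_five_percent_of_optimum(self):
        ok = 0
        for seed in range(20):
            t = instance(seed)
            ex = exhaustive_search(t, max_dim=12)
            ps = gpso_search(t, GPSOConfig(seed=seed))
            assert ps.score.merit <= ex.score.merit + 1e-12
            ok += ps.score.merit >= 0.95 * ex.score.merit
        assert ok >= 16


class TestSSFS:
    def test_top_k_one_returns_top_ranked_singleton(self, labeled_table):
        result = ssfs_search(labeled_table, SSFSConfig(top_k=1))
        ranked = max(
            labeled_table.columns,
            key=lambda c: class_feature_correlation(labeled_table, c),
        )
        assert result.columns == [ranked]

    def test_recovers_planted_singleton(self):
        wins = 0
        for seed in range(20):
            t = instance(
                seed, n_informative=1, n_redundant=0, n_noise=9,
                effect_size=1.5, frac_binary=0.0, n_active=80, n_inactive=60,
            )
            result = ssfs_search(t, SSFSConfig(seed=seed))
            wins += "INF000" in result.columns and len(result.columns) == 1
        assert wins >= 16

    def test_smaller_or_equal_than_best_first_in_majority(self):
        smaller = 0
        for seed in range(20):
            t = instance(seed)
            bf = best_first_search(t)
            ss = ssfs_search(t, SSFSConfig(seed=seed))
            smaller += len(ss.columns) <= len(bf.columns)
        assert smaller > 10

    def test_deterministic_given_seed(self, labeled_table):
        a = ssfs_search(labeled_table, SSFSConfig(seed=4))
        b = ssfs_search(labeled_table, SSFSConfig(seed=4))
        assert a.columns == b.columns


class TestSubsetInvariants:
    @pytest.mark.parametrize("searcher,cfg", [
        (best_first_search, BFConfig()),
        (genetic_search, GSConfig(seed=1)),
        (gpso_search, GPSOConfig(seed=1)),
        (ssfs_search, SSFSConfig(seed=1)),
    ])
    def test_returned_score_matches_recomputation(self, searcher, cfg):
        t = instance(13)
        result = searcher(t, cfg)
        assert result.score.merit == pytest.approx(
            merit(t, result.columns).merit
        )
        assert len(result.columns) == len(set(result.columns))
        assert set(result.columns) <= set(t.columns)
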