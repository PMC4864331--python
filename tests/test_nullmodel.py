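import numpy as np
import pandas as pd
import pytest

import urbfilter as uf
from urbfilter.nullmodel import (
    NullModel,
    build_pool,
    classify_fates,
    loss_metrics,
    simulate_random_communities,
)


def _tiny_city(urban_counts, peri_counts):
    """One city, one urban and one periurban cell with given species counts."""
    survey = pd.DataFrame(
        [urban_counts, peri_counts],
        index=["u1", "p1"],
        columns=[f"s{j}" for j in range(len(urban_counts))],
    )
    cells = pd.DataFrame(
        {"city": ["a", "a"], "habitat": ["urban", "periurban"], "veg_cover": [0.2, 0.6]},
        index=survey.index,
    )
    return survey, cells


class TestBuildPool:
    def test_pool_is_normalised_periurban_proportions(self):
        survey, cells = _tiny_city([3, 1, 2], [8, 2, 0])
        pool, urban, N = build_pool(survey, cells, "a")
        assert pool.tolist() == [0.8, 0.2, 0.0]
        assert N == 6

    def test_species_absent_from_both_habitats_excluded(self):
        survey, cells = _tiny_city([3, 0, 0], [8, 0, 2])
        pool, urban, N = build_pool(survey, cells, "a")
        assert list(pool.index) == ["s0", "s2"]

    def test_zero_periurban_individuals_error(self):
        survey, cells = _tiny_city([3, 1], [0, 0])
        with pytest.raises(ValueError, match="periurban"):
            build_pool(survey, cells, "a")

    def test_natives_only_pool_excludes_exotics(self):
        survey, cells = _tiny_city([3, 1], [5, 5])
        traits = pd.DataFrame(
            {"diet_guild": ["granivore"] * 2, "habitat_guild": ["open"] * 2,
             "origin": ["exotic", "native"]},
            index=survey.columns,
        )
        pool, _, _ = build_pool(survey, cells, "a", include_exotics=False, traits=traits)
        assert list(pool.index) == ["s1"]


class TestSimulatedCommunities:
    def test_single_species_pool_is_deterministic(self):
        sim = simulate_random_communities([1.0], N=7, n_sims=20, rng=np.random.default_rng(0))
        assert np.all(sim == 7)

    def test_rows_conserve_community_size(self):
        rng = np.random.default_rng(1)
        sim = simulate_random_communities([0.5, 0.3, 0.2], N=40, n_sims=999, rng=rng)
        assert sim.shape == (999, 3)
        assert np.all(sim.sum(axis=1) == 40)

    def test_per_species_means_match_binomial_moments(self):
        p, N, n_sims = np.array([0.6, 0.3, 0.1]), 200, 999
        sim = simulate_random_communities(p, N, n_sims, np.random.default_rng(2))
        se = np.sqrt(N * p * (1 - p) / n_sims)
        assert np.all(np.abs(sim.mean(axis=0) - N * p) <= 3 * se)


class TestClassification:
    def test_mode_zero_is_chance_absent(self):
        sim = np.array([[0], [0], [0], [1], [2]])
        out = classify_fates(sim, pd.Series([0], index=["s0"]), [0.1])
        assert out.loc["s0", "sim_mode"] == 0
        assert out.loc["s0", "fate"] == "chance_absent"

    def test_positive_mode_is_avoider(self):
        sim = np.array([[3], [2], [3], [3], [1]])
        out = classify_fates(sim, pd.Series([0], index=["s0"]), [0.1])
        assert out.loc["s0", "sim_mode"] == 3
        assert out.loc["s0", "fate"] == "avoider"

    def test_presence_dominates_any_mode(self):
        sim = np.array([[3], [3], [0], [0], [0]])
        out = classify_fates(sim, pd.Series([5], index=["s0"]), [0.1])
        assert out.loc["s0", "fate"] == "present"

    def test_mode_tie_break_direction(self):
        sim = np.array([[0], [0], [1], [1]])
        low = classify_fates(sim, pd.Series([0], index=["s0"]), [0.1], "smallest")
        high = classify_fates(sim, pd.Series([0], index=["s0"]), [0.1], "largest")
        assert low.loc["s0", "fate"] == "chance_absent"
        assert high.loc["s0", "fate"] == "avoider"


class TestLossMetrics:
    def _fates(self):
        # 25 recorded species: 20 periurban, 8 of them absent from urban,
        # 4 absentees classified avoider
        pool = [0.05] * 20 + [0.0] * 5
        urban = [1] * 12 + [0] * 8 + [1] * 5
        fate = (
            ["present"] * 12
            + ["avoider"] * 4
            + ["chance_absent"] * 4
            + ["present"] * 5
        )
        return pd.DataFrame(
            {"pool_proportion": pool, "urban_abundance": urban, "fate": fate}
        )

    def test_loss_arithmetic(self):
        fates = self._fates()
        # simulations whose mean richness is 18 of the 20 periurban species
        sim = np.zeros((2, 25), dtype=int)
        sim[0, :17] = 1
        sim[1, :19] = 1
        out = loss_metrics(fates, sim)
        assert out["S_periurban"] == 20
        assert out["observed_loss_pct"] == pytest.approx(40.0)
        assert out["random_loss_pct"] == pytest.approx(10.0)
        assert out["tolerance_richness"] == 25 - 4

    def test_all_absent_periurban_error(self):
        fates = self._fates()
        fates["pool_proportion"] = 0.0
        with pytest.raises(ValueError):
            loss_metrics(fates, np.zeros((2, 25), dtype=int))


def test_random_loss_decreases_with_community_size():
    """Holding the pool fixed, larger urban communities lose fewer species."""
    rng = np.random.default_rng(3)
    pool = np.array([0.5, 0.3, 0.1, 0.06, 0.03, 0.01])
    losses = []
    for N in (20, 100, 500):
        sim = simulate_random_communities(pool, N, 999, np.random.default_rng(9))
        mean_rich = (sim > 0).sum(axis=1).mean()
        losses.append(100 * (len(pool) - mean_rich) / len(pool))
    assert losses[0] > losses[1] > losses[2]


def test_fit_is_deterministic_and_city_independent(small_study):
    survey, cells, traits, _ = small_study
    a = NullModel(n_sims=99, seed=5).fit(survey, cells, traits)
    b = NullModel(n_sims=99, seed=5).fit(survey, cells, traits)
    pd.testing.assert_frame_equal(a.loss_, b.loss_)
    # dropping a city leaves the other city's results untouched
    keep = cells.city == "city1"
    c = NullModel(n_sims=99, seed=5).fit(survey.loc[keep.index[keep]], cells.loc[keep], traits)
    pd.testing.assert_frame_equal(
        a.loss_.loc[["city1"]], c.loss_.loc[["city1"]]
    )


def test_fate_invariants_on_synthetic_data(small_study):
    survey, cells, traits, _ = small_study
    fates = NullModel(n_sims=99, seed=1).fit(survey, cells, traits).fates_
    present = fates.fate == "present"
    assert ((fates.urban_abundance > 0) == present).all()
    absent = fates[~present]
    assert ((absent.sim_mode == 0) == (absent.fate == "chance_absent")).all()
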