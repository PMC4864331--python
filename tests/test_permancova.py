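import subprocess

import numpy as np
import pandas as pd
import pytest
import skbio
from scipy import stats

from urbfilter.distance import bray_curtis, euclidean
from urbfilter.permancova import DesignError, Permancova, permancova


def _meta(index, **cols):
    return pd.DataFrame(cols, index=index)


def _univariate(values):
    idx = [f"c{i}" for i in range(len(values))]
    return euclidean(pd.DataFrame({"y": values}, index=idx)), idx


def test_single_fixed_factor_reduces_to_classical_anova():
    rng = np.random.default_rng(0)
    y = rng.normal(size=24)
    g = np.repeat(["a", "b", "c"], 8)
    D, idx = _univariate(y)
    res = permancova(D, _meta(idx, habitat=g), fixed_factor="habitat", n_perms=99, seed=0)
    expected = stats.f_oneway(y[:8], y[8:16], y[16:]).statistic
    assert res.loc["habitat", "pseudo_F"] == pytest.approx(expected, rel=1e-10)


def test_one_way_bray_curtis_matches_skbio_permanova():
    rng = np.random.default_rng(1)
    X = pd.DataFrame(
        rng.poisson(5, size=(16, 8)).astype(float),
        index=[f"c{i}" for i in range(16)],
    )
    D = bray_curtis(X)
    meta = _meta(X.index, habitat=np.repeat(["u", "p"], 8))
    res = permancova(D, meta, fixed_factor="habitat", n_perms=99, seed=0)
    sk = skbio.stats.distance.permanova(D, meta["habitat"], permutations=99)
    assert res.loc["habitat", "pseudo_F"] == pytest.approx(sk["test statistic"], rel=1e-10)


def test_sequential_ss_matches_vegan_adonis2(tmp_path):
    """Full covariate + random x fixed design against the R vegan oracle."""
    rng = np.random.default_rng(21)
    n = 24
    X = pd.DataFrame(
        rng.poisson(4, size=(n, 6)).astype(float),
        index=[f"c{i}" for i in range(n)],
        columns=[f"s{j}" for j in range(6)],
    )
    meta = _meta(
        X.index,
        city=np.repeat(["t", "v", "o"], 8),
        habitat=np.tile(np.repeat(["u", "p"], 4), 3),
        veg_cover=rng.uniform(0, 1, n),
    )
    res = permancova(
        bray_curtis(X), meta,
        fixed_factor="habitat", random_factor="city", covariate="veg_cover",
        n_perms=9, seed=0,
    )
    X.to_csv(tmp_path / "comm.csv")
    meta.to_csv(tmp_path / "meta.csv")
    r_code = f"""
    suppressMessages(library(vegan))
    comm <- read.csv("{tmp_path}/comm.csv", row.names=1)
    meta <- read.csv("{tmp_path}/meta.csv", row.names=1)
    a <- adonis2(vegdist(comm, "bray") ~ veg_cover + city + habitat + veg_cover:city +
                 veg_cover:habitat + city:habitat + veg_cover:city:habitat,
                 data=meta, by="terms", permutations=2)
    write.csv(as.data.frame(a), "{tmp_path}/adonis.csv")
    """
    subprocess.run(["Rscript", "-e", r_code], check=True, capture_output=True)
    ref = pd.read_csv(tmp_path / "adonis.csv", index_col=0)
    pairs = {
        "veg_cover": "veg_cover",
        "city": "city",
        "habitat": "habitat",
        "veg_cover:city": "veg_cover x city",
        "veg_cover:habitat": "veg_cover x habitat",
        "city:habitat": "city x habitat",
        "veg_cover:city:habitat": "veg_cover x city x habitat",
        "Residual": "Residual",
    }
    for r_name, my_name in pairs.items():
        assert res.loc[my_name, "SS"] == pytest.approx(
            ref.loc[r_name, "SumOfSqs"], abs=1e-8
        )
        assert res.loc[my_name, "df"] == ref.loc[r_name, "Df"]


def test_ss_partition_and_cv_normalisation(small_study):
    survey, cells, traits, _ = small_study
    import urbfilter as uf

    D = bray_curtis(uf.fourth_root(survey))
    est = Permancova(
        fixed_factor="habitat", random_factor="city", covariate="veg_cover",
        n_perms=49, seed=3,
    ).fit(D, cells)
    r = est.results_
    assert r["SS"].sum() == pytest.approx(est.total_ss_, abs=1e-8)
    assert (r["CV_pct"] >= 0).all()
    assert r["CV_pct"].sum() == pytest.approx(100.0, abs=1e-8)
    p = r["p_perm"].dropna()
    assert ((p > 0) & (p <= 1)).all()


def test_fixed_factor_over_interaction_always_reports_monte_carlo(small_study):
    """With 2 cities x 2 habitats, few distinguishable habitat relabellings
    exist, so the habitat term must carry a Monte-Carlo p-value."""
    survey, cells, traits, _ = small_study
    import urbfilter as uf

    D = bray_curtis(uf.fourth_root(survey))
    est = Permancova(
        fixed_factor="habitat", random_factor="city", covariate="veg_cover",
        n_perms=49, seed=0,
    ).fit(D, cells)
    r = est.results_
    assert r.loc["habitat", "denominator"] == "city x habitat"
    assert np.isfinite(r.loc["habitat", "p_MC"])
    assert r.loc["habitat", "unique_perms"] < 1000
    # terms with astronomically many residual permutations report no p_MC
    assert np.isnan(r.loc["veg_cover", "p_MC"])


def test_type_one_error_calibration_under_null():
    """With no effects, permutation p-values are uniform: the alpha=0.05
    rejection rate over 200 replicates stays within binomial 99% bounds."""
    n, reps, alpha = 20, 200, 0.05
    rejections = 0
    for s in range(reps):
        rng = np.random.default_rng(10_000 + s)
        y = rng.normal(size=n)
        g = rng.permutation(np.repeat(["a", "b"], n // 2))
        D, idx = _univariate(y)
        res = permancova(D, _meta(idx, habitat=g), fixed_factor="habitat",
                         n_perms=199, seed=s)
        rejections += res.loc["habitat", "p_perm"] <= alpha
    se = np.sqrt(alpha * (1 - alpha) / reps)
    assert abs(rejections / reps - alpha) <= 2.576 * se + 1e-12


def test_confounded_design_raises_naming_the_term():
    rng = np.random.default_rng(2)
    y = rng.normal(size=12)
    g = np.repeat(["a", "b"], 6)
    D, idx = _univariate(y)
    meta = _meta(idx, habitat=g, city=g)  # city duplicates habitat exactly
    with pytest.raises(DesignError, match="habitat"):
        permancova(D, meta, fixed_factor="habitat", random_factor="city",
                   n_perms=9, seed=0)


def test_denominator_map_override_is_applied():
    rng = np.random.default_rng(3)
    y = rng.normal(size=24)
    meta_cols = dict(
        city=np.repeat(["a", "b", "c"], 8),
        habitat=np.tile(np.repeat(["u", "p"], 4), 3),
    )
    D, idx = _univariate(y)
    est = Permancova(
        fixed_factor="habitat", random_factor="city", n_perms=9, seed=0,
        denominator_map={"habitat": "Residual"},
    ).fit(D, _meta(idx, **meta_cols))
    assert est.results_.loc["habitat", "denominator"] == "Residual"
    assert est.scheme_["denominators"]["habitat"] == "Residual"


def test_fit_is_deterministic_given_seed():
    rng = np.random.default_rng(4)
    y = rng.normal(size=18)
    g = np.repeat(["a", "b", "c"], 6)
    D, idx = _univariate(y)
    r1 = permancova(D, _meta(idx, habitat=g), fixed_factor="habitat", n_perms=199, seed=7)
    r2 = permancova(D, _meta(idx, habitat=g), fixed_factor="habitat", n_perms=199, seed=7)
    pd.testing.assert_frame_equal(r1, r2)


def test_monte_carlo_p_tracks_classical_f_in_univariate_limit():
    """In the Euclidean univariate one-factor limit the chi-square mixture
    collapses to the F distribution, so p_MC approximates the ANOVA p."""
    rng = np.random.default_rng(5)
    y = np.concatenate([rng.normal(0, 1, 5), rng.normal(2.0, 1, 5)])
    g = np.repeat(["a", "b"], 5)
    D, idx = _univariate(y)
    # mc_threshold above 10! forces the Monte-Carlo route for this tiny design
    res = permancova(D, _meta(idx, habitat=g), fixed_factor="habitat",
                     n_perms=999, seed=1, mc_threshold=10 ** 7)
    p_classical = stats.f_oneway(y[:5], y[5:]).pvalue
    assert res.loc["habitat", "p_MC"] == pytest.approx(p_classical, abs=0.02)
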