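"""Queller-Goodnight relatedness, randomization tests, difference model."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nestkin.genotypes import GenotypeTable, LocusPanel
from nestkin.matechoice import (
    MateDifferenceModel,
    mate_choice_analysis,
    qg_relatedness,
    randomization_test,
    relatedness_to_pool,
)
from nestkin.simulate import (
    SimulationConfig,
    _draw_genotype,
    _mendelian_offspring,
    simulate_allele_frequencies,
)

from conftest import draw_table


@pytest.fixture(scope="module")
def study_panel():
    return simulate_allele_frequencies(SimulationConfig(rng_seed=7))


def test_identical_genotypes_have_r_one(study_panel, rng):
    g = _draw_genotype(study_panel, rng)
    assert qg_relatedness(g, g, study_panel.frequencies) == pytest.approx(1.0)


def test_maximally_dissimilar_pair_has_r_minus_one():
    freqs = [{1: 0.25, 2: 0.25, 3: 0.25, 4: 0.25}]
    x = np.array([[1, 2]])
    y = np.array([[3, 4]])
    assert qg_relatedness(x, y, freqs) == pytest.approx(-1.0)


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=25, deadline=None)
def test_r_is_symmetric(seed):
    rng = np.random.default_rng(seed)
    freqs = [
        {a: p for a, p in zip(range(1, 5), v / v.sum())}
        for v in rng.uniform(0.05, 1.0, size=(6, 4))
    ]
    x = rng.integers(1, 5, size=(6, 2))
    y = rng.integers(1, 5, size=(6, 2))
    rxy = qg_relatedness(x, y, freqs)
    ryx = qg_relatedness(y, x, freqs)
    assert rxy == pytest.approx(ryx, abs=1e-12)


def test_missing_loci_are_skipped(study_panel, rng):
    x = _draw_genotype(study_panel, rng)
    y = _draw_genotype(study_panel, rng)
    x_masked = x.copy()
    x_masked[5:] = 0
    r_masked = qg_relatedness(x_masked, y, study_panel.frequencies)
    r_first5 = qg_relatedness(x[:5], y[:5], study_panel.frequencies[:5])
    assert r_masked == pytest.approx(r_first5)


def test_all_uninformative_returns_nan():
    x = np.zeros((3, 2), dtype=int)
    assert np.isnan(qg_relatedness(x, x, [{1: 1.0}] * 3))


def test_unrelated_mean_zero_parent_offspring_half(study_panel, rng):
    n = 4000
    r_un, r_po = np.empty(n), np.empty(n)
    for i in range(n):
        a = _draw_genotype(study_panel, rng)
        b = _draw_genotype(study_panel, rng)
        r_un[i] = qg_relatedness(a, b, study_panel.frequencies)
        o = _mendelian_offspring(a, _draw_genotype(study_panel, rng), rng)
        r_po[i] = qg_relatedness(a, o, study_panel.frequencies)
    assert abs(r_un.mean()) < 3 * r_un.std() / np.sqrt(n)
    assert r_po.mean() == pytest.approx(0.5, abs=0.02)


def test_focal_exclusion_changes_r_only_slightly(study_panel, rng):
    """Removing the focal male from the frequency counts is an O(1/n)
    correction for reference samples of a few hundred."""
    pool = draw_table(study_panel, 200, rng, prefix="m")
    from nestkin.genotypes import allele_frequencies

    panel = allele_frequencies(pool)
    fem = _draw_genotype(study_panel, rng)
    base = relatedness_to_pool(fem, pool, panel)
    corrected = relatedness_to_pool(fem, pool, panel, exclude_focal_counts=True)
    assert np.nanmax(np.abs(base - corrected)) < 0.05


# ---------------------------------------------------------------------------
# randomization tests


def _pool_and_panel(rng, n_males=20, seed=7):
    panel = simulate_allele_frequencies(SimulationConfig(rng_seed=seed))
    pool = draw_table(panel, n_males, rng, prefix="m")
    from nestkin.genotypes import allele_frequencies

    return pool, allele_frequencies(pool)


def test_pool_maximum_has_exact_p_one_over_pool(rng):
    pool, panel = _pool_and_panel(rng)
    fem = _draw_genotype(panel, rng)
    null = relatedness_to_pool(fem, pool, panel)
    focal = pool.ids[int(np.nanargmax(null))]
    res = randomization_test("f", focal, fem, pool, panel, seed=1)
    assert res.exact_p_high == pytest.approx(1 / 20)


def test_monte_carlo_p_within_3_se_of_enumeration(rng):
    pool, panel = _pool_and_panel(rng, n_males=5)
    fem = _draw_genotype(panel, rng)
    res = randomization_test(
        "f", pool.ids[2], fem, pool, panel, n_iter=10_000, seed=3, pool_floor=2
    )
    for p_mc, p_exact in [(res.p_high, res.exact_p_high), (res.p_low, res.exact_p_low)]:
        se = np.sqrt(p_exact * (1 - p_exact) / 10_000)
        assert abs(p_mc - p_exact) <= 3 * se + 1e-9


def test_prior_mates_are_excluded_from_null(rng):
    pool, panel = _pool_and_panel(rng)
    fem = _draw_genotype(panel, rng)
    res = randomization_test(
        "f", pool.ids[0], fem, pool, panel, exclude={pool.ids[1], pool.ids[2]}, seed=2
    )
    assert res.pool_size == 18


def test_small_pool_flagged_underpowered(rng):
    pool, panel = _pool_and_panel(rng, n_males=5)
    fem = _draw_genotype(panel, rng)
    res = randomization_test("f", pool.ids[0], fem, pool, panel, seed=2)
    assert res.flagged == "underpowered" and res.category is None


def test_type_i_error_rate_matches_alpha(rng):
    """Under random mating the inbred category fires at ~alpha."""
    from scipy.stats import binomtest

    pool, panel = _pool_and_panel(rng, n_males=100, seed=11)
    n_pairs = 400
    hits = 0
    for i in range(n_pairs):
        fem = _draw_genotype(panel, rng)
        focal = pool.ids[int(rng.integers(0, 100))]
        res = randomization_test(
            "f", focal, fem, pool, panel, n_iter=2_000, alpha=0.05, seed=100 + i
        )
        hits += res.category == "inbred"
    ci = binomtest(hits, n_pairs).proportion_ci(0.95, method="exact")
    assert ci.low <= 0.05 <= ci.high


# ---------------------------------------------------------------------------
# mate-difference model


def test_zero_differences_give_zero_estimate_and_t():
    tri = pd.DataFrame(
        {
            "female": ["a", "b", "c"],
            "year": [2012] * 3,
            "r_first": [0.1, 0.2, 0.3],
            "r_additional": [[0.1], [0.2], [0.3]],
        }
    )
    res = MateDifferenceModel(tri).fit(seed=0)
    row = res.table.iloc[0]
    assert row["estimate"] == 0.0 and row["t"] == 0.0


def test_sign_convention_less_related_additional_is_positive():
    tri = pd.DataFrame(
        {
            "female": ["a", "b"],
            "year": [2012] * 2,
            "r_first": [0.3, 0.2],
            "r_additional": [[0.0], [-0.1]],
        }
    )
    res = MateDifferenceModel(tri).fit(seed=0)
    assert res.table.iloc[0]["estimate"] == pytest.approx(0.3)


def test_single_triad_year_is_estimate_only():
    tri = pd.DataFrame(
        {"female": ["a"], "year": [2012], "r_first": [0.4], "r_additional": [[0.1]]}
    )
    res = MateDifferenceModel(tri).fit(seed=0)
    row = res.table.iloc[0]
    assert row["estimate"] == pytest.approx(0.3) and np.isnan(row["t"])
    assert row["flag"] is not None


def test_rejection_rate_matches_one_sample_t_power(rng):
    """True mean d = 0.15, sd 0.15, n = 9: empirical rejections at
    alpha = .05 match the noncentral-t power of the one-sample test."""
    from scipy import stats

    n, mu, sd = 9, 0.15, 0.15
    nc = mu / (sd / np.sqrt(n))
    tcrit = stats.t.ppf(0.975, df=n - 1)
    power = 1 - stats.nct.cdf(tcrit, df=n - 1, nc=nc) + stats.nct.cdf(
        -tcrit, df=n - 1, nc=nc
    )
    n_rep = 400
    rej = 0
    for i in range(n_rep):
        d = rng.normal(mu, sd, size=n)
        tri = pd.DataFrame(
            {
                "female": [f"f{j}" for j in range(n)],
                "year": [2012] * n,
                "r_first": d,
                "r_additional": [[0.0]] * n,
            }
        )
        res = MateDifferenceModel(tri).fit(seed=i)
        rej += res.table.iloc[0]["p"] < 0.05
    se = np.sqrt(power * (1 - power) / n_rep)
    assert abs(rej / n_rep - power) < 3.5 * se


def test_duplicate_female_year_triads_rejected():
    tri = pd.DataFrame(
        {
            "female": ["a", "a"],
            "year": [2012, 2012],
            "r_first": [0.1, 0.2],
            "r_additional": [[0.0], [0.0]],
        }
    )
    with pytest.raises(ValueError, match="one triad"):
        MateDifferenceModel(tri)


def test_pipeline_analysis_on_simulated_study(small_study):
    from nestkin.pedigree import reconstruct_pedigree

    _, _, obs = small_study
    res = reconstruct_pedigree(obs.genotypes, obs.nests)
    pairs, table, diff_model = mate_choice_analysis(
        res.females, obs.genotypes, n_iter=500, seed=4
    )
    assert len(pairs) > 0
    categorized = [p for p in pairs if p.category is not None]
    # random mating: the vast majority of pairs are 'unrelated'
    frac = np.mean([p.category == "unrelated" for p in categorized])
    assert frac > 0.8
    if diff_model is not None:
        fit = diff_model.fit(seed=0)
        assert {"year", "n", "estimate"}.issubset(fit.table.columns)
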