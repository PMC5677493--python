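"""Genotype container, I/O, panel statistics and identity matching."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nestkin.genotypes import (
    Genotype,
    GenotypeTable,
    LocusPanel,
    allele_frequencies,
    estimate_error_rates,
    match_identity,
    pid_hw,
    read_genotypes,
    write_genotypes,
)

from conftest import draw_table


# ---------------------------------------------------------------------------
# container and I/O


def test_genotype_allele_pairs_are_order_insensitive():
    a = Genotype("x", ((3, 1), (2, 2)))
    b = Genotype("x", ((1, 3), (2, 2)))
    assert a == b and hash(a) == hash(b)


def test_roundtrip_preserves_genotypes_and_missing(tmp_path, small_panel, rng):
    table = draw_table(small_panel, 500, rng)
    table.alleles[3, 1] = 0  # a missing locus survives the round trip
    table.meta["year"] = 2012
    table.meta["role"] = "fry"
    table.meta["nest_id"] = "N1"
    path = tmp_path / "geno.csv"
    write_genotypes(table, path)
    back = read_genotypes(path)
    assert back == table
    assert back.missing_mask()[3, 1]


def test_empty_file_with_header_gives_empty_collection(tmp_path):
    path = tmp_path / "empty.csv"
    path.write_text("id,L01_1,L01_2\n")
    assert len(read_genotypes(path)) == 0


def test_duplicate_ids_rejected():
    with pytest.raises(ValueError, match="duplicate"):
        GenotypeTable(["a", "a"], ["L01"], np.ones((2, 1, 2), dtype=int))


def test_odd_allele_column_is_a_parse_error(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text("id,L01_1,L01_2,L02_1\na,1,2,3\n")
    with pytest.raises(ValueError, match="L02"):
        read_genotypes(path)


# ---------------------------------------------------------------------------
# allele frequencies


def test_allele_counting():
    # genotypes {AA, AB}: p_A = 3/4
    table = GenotypeTable(["i", "j"], ["L01"], np.array([[[1, 1]], [[1, 2]]]))
    panel = allele_frequencies(table)
    assert panel.frequencies[0] == {1: 0.75, 2: 0.25}


def test_exclusion_of_focal_individuals():
    table = GenotypeTable(["i", "j"], ["L01"], np.array([[[1, 1]], [[1, 2]]]))
    panel = allele_frequencies(table, exclude_ids=["i"])
    assert panel.frequencies[0] == {1: 0.5, 2: 0.5}


def test_missing_excluded_and_all_missing_locus_dropped():
    alleles = np.array([[[1, 2], [0, 0]], [[1, 0], [0, 0]]])
    with pytest.warns(UserWarning, match="dropped"):
        panel = allele_frequencies(GenotypeTable(["i", "j"], ["L01", "L02"], alleles))
    assert panel.loci == ["L01"]
    # the half-missing call at L01 contributes its single scored allele
    assert panel.frequencies[0] == {1: 2 / 3, 2: 1 / 3}


def test_large_sample_frequencies_within_3_se(small_panel, rng):
    table = draw_table(small_panel, 10_000, rng)
    est = allele_frequencies(table)
    for j, freq in enumerate(small_panel.frequencies):
        for allele, p in freq.items():
            se = np.sqrt(p * (1 - p) / (2 * 10_000))
            assert abs(est.frequencies[j][allele] - p) < 3 * se + 1e-12


# ---------------------------------------------------------------------------
# probability of identity


def _enumerate_pid_one_locus(freq: dict[int, float]) -> tuple[float, float]:
    """Brute-force P(ID) by enumerating genotype (pairs of) draws.

    HW case: sum over genotypes of P_HW(g)^2.  Sib case: enumerate both
    parents' genotypes under HWE and the Mendelian offspring distribution,
    then the probability two independent offspring of those parents share
    a genotype.
    """
    alleles = list(freq)

    def hw_prob(g):
        a, b = g
        return freq[a] ** 2 if a == b else 2 * freq[a] * freq[b]

    genotypes = [
        (a, b) for i, a in enumerate(alleles) for b in alleles[i:]
    ]
    pid = sum(hw_prob(g) ** 2 for g in genotypes)

    pid_sib = 0.0
    for mo in genotypes:
        for fa in genotypes:
            p_par = hw_prob(mo) * hw_prob(fa)
            off: dict[tuple[int, int], float] = {}
            for x in mo:
                for y in fa:
                    g = tuple(sorted((x, y)))
                    off[g] = off.get(g, 0.0) + 0.25
            pid_sib += p_par * sum(v**2 for v in off.values())
    return pid, pid_sib


@pytest.mark.parametrize(
    "freq",
    [
        {1: 0.5, 2: 0.5},
        {1: 0.25, 2: 0.25, 3: 0.25, 4: 0.25},
        {1: 0.7, 2: 0.2, 3: 0.1},
    ],
)
def test_pid_formulas_match_enumeration(freq):
    panel = LocusPanel(["L01"], [freq])
    stats = pid_hw(panel)
    exp_hw, exp_sib = _enumerate_pid_one_locus(freq)
    assert stats.pid_hw == pytest.approx(exp_hw, abs=1e-12)
    assert stats.pid_sib == pytest.approx(exp_sib, abs=1e-12)


def test_pid_biallelic_half_half(two_allele_panel):
    stats = pid_hw(two_allele_panel)
    assert stats.pid_hw == pytest.approx(0.375)
    assert stats.pid_sib == pytest.approx(0.59375)


def test_pid_monomorphic_locus_is_one():
    stats = pid_hw(LocusPanel(["L01"], [{1: 1.0}]))
    assert stats.pid_hw == 1.0 and stats.pid_sib == 1.0


def test_pid_multiplicative_over_loci(small_panel):
    stats = pid_hw(small_panel)
    assert stats.pid_hw == pytest.approx(np.prod(stats.pid_hw_locus))
    per_locus = [pid_hw(LocusPanel([l], [f])) for l, f in
                 zip(small_panel.loci, small_panel.frequencies)]
    assert stats.pid_hw == pytest.approx(np.prod([s.pid_hw for s in per_locus]))


def test_pid_sib_dominates_hw_and_products_shrink(small_panel):
    stats = pid_hw(small_panel)
    assert (stats.pid_sib_locus >= stats.pid_hw_locus).all()
    running = np.cumprod(stats.pid_hw_locus)
    assert (np.diff(running) <= 0).all()


def test_pid_unbiased_requires_n_at_least_4(small_panel):
    with pytest.raises(ValueError, match="n < 4"):
        pid_hw(small_panel, n=3)
    stats = pid_hw(small_panel, n=1_000_000)
    # the correction vanishes in large samples
    assert stats.pid_unbiased == pytest.approx(stats.pid_hw, rel=1e-3)


def test_empirical_sharing_rate_matches_pid(two_allele_panel, rng):
    """Two unrelated HW individuals share a genotype at rate P(ID)."""
    panel = LocusPanel(
        ["L01", "L02"], [{1: 0.5, 2: 0.5}, {1: 0.7, 2: 0.2, 3: 0.1}]
    )
    n = 1_000_000
    a = draw_table(panel, n, rng).alleles
    b = draw_table(panel, n, rng).alleles
    same = (np.sort(a, axis=2) == np.sort(b, axis=2)).all(axis=(1, 2))
    pid = pid_hw(panel).pid_hw
    se = np.sqrt(pid * (1 - pid) / n)
    assert abs(same.mean() - pid) < 4 * se


# ---------------------------------------------------------------------------
# error rates


def test_identical_repeats_give_zero_error(small_panel, rng):
    table = draw_table(small_panel, 20, rng)
    pairs = [(table.alleles[i], table.alleles[i]) for i in range(20)]
    df = estimate_error_rates(pairs, small_panel.loci)
    assert (df["error_rate"].dropna() == 0).all()


def test_error_rate_is_mismatch_fraction():
    loci = [f"L{i}" for i in range(1, 6)]
    a = np.ones((5, 2), dtype=int)
    pairs = [(a, a.copy()) for _ in range(10)]
    pairs[0][1][2, 1] = 9  # one allele mismatch at locus 3
    df = estimate_error_rates(pairs, loci)
    assert df.loc["L3", "error_rate"] == pytest.approx(1 / 20)
    assert df.loc["overall", "error_rate"] == pytest.approx(1 / 100)


def test_no_repeat_captures_is_an_error():
    with pytest.raises(ValueError, match="repeat captures"):
        estimate_error_rates([], ["L01"])


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=20, deadline=None)
def test_error_rate_invariant_to_allele_order(seed):
    rng = np.random.default_rng(seed)
    loci = [f"L{i}" for i in range(4)]
    a = rng.integers(1, 6, size=(4, 2))
    b = rng.integers(1, 6, size=(4, 2))
    base = estimate_error_rates([(a, b)], loci)["error_rate"]
    flipped = estimate_error_rates([(a[:, ::-1], b)], loci)["error_rate"]
    pd.testing.assert_series_equal(base, flipped)


def test_error_recovery_from_simulated_repeats(small_panel, rng):
    """Repeat captures scored with e=0.005 recover the rate within its CI."""
    from scipy.stats import binomtest

    from nestkin.simulate import _apply_errors

    e = 0.005
    panel = small_panel
    rates = np.full(panel.n_loci, e)
    pairs = []
    for _ in range(400):
        g = draw_table(panel, 1, rng).alleles[0]
        pairs.append(
            (_apply_errors(g, panel, rates, rng), _apply_errors(g, panel, rates, rng))
        )
    df = estimate_error_rates(pairs, panel.loci)
    k = int(df.loc["overall", "mismatches"])
    n = int(df.loc["overall", "comparisons"])
    ci = binomtest(k, n).proportion_ci(confidence_level=0.95, method="exact")
    # each of the two genotypes carries errors, and a miscall can land on
    # the true allele, so the discordance rate is ~2e(1 - e - hom sharing)
    assert ci.low <= 2 * e


# ---------------------------------------------------------------------------
# identity matching


def test_identical_genotypes_match(small_panel, rng):
    g = draw_table(small_panel, 1, rng).alleles[0]
    res = match_identity(g, g, min_shared_loci=4)
    assert res.is_match and res.mismatch_loci == 0


def test_five_locus_disagreement_is_no_match(rng):
    g = np.tile([1, 2], (20, 1))
    h = g.copy()
    h[:5] = [3, 4]
    res = match_identity(g, h)
    assert res.verdict == "no_match" and res.mismatch_loci == 5


def test_few_shared_loci_is_uninformative():
    g = np.tile([1, 2], (20, 1))
    h = g.copy()
    h[:15] = 0
    assert match_identity(g, h).verdict == "uninformative"


def test_matching_separates_repeats_from_unrelated(rng):
    """With e = 0.0075 per allele, repeat captures merge and unrelated
    pairs never do, over 1,000 trials each."""
    from nestkin.simulate import SimulationConfig, simulate_allele_frequencies, _apply_errors

    cfg = SimulationConfig(rng_seed=5)
    panel = simulate_allele_frequencies(cfg)
    rates = np.full(panel.n_loci, 0.0075)
    true_merges = false_merges = 0
    table = draw_table(panel, 2000, rng)
    for t in range(1000):
        g = table.alleles[2 * t]
        repeat = _apply_errors(g, panel, rates, rng)
        if match_identity(g, repeat).is_match:
            true_merges += 1
        if match_identity(g, table.alleles[2 * t + 1]).is_match:
            false_merges += 1
    assert false_merges == 0
    assert true_merges > 990
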