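"""Paternity checks, maternal sibship partitioning, female merging, QC."""

import itertools

import numpy as np
import pandas as pd
import pytest

from nestkin.pedigree import (
    categorize_assignments,
    check_paternity,
    maternal_constraints,
    merge_females,
    partition_maternal_sibships,
    reconstruct_pedigree,
)
from nestkin.simulate import SimulationConfig, observe, simulate_breeding_seasons


# ---------------------------------------------------------------------------
# brute-force oracle: exhaustive search over set partitions x maternal
# genotypes (independent of the production branch-and-bound)


def _set_partitions(items):
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield part + [[first]]


def brute_force_min_mothers(fry_alleles, father_alleles, alleles_per_locus):
    """Minimum number of mothers by trying every partition and, per group,
    every diploid maternal genotype over the allele space."""
    cons = maternal_constraints(fry_alleles, father_alleles)
    n = len(cons)
    n_loci = fry_alleles.shape[1]
    space = list(range(1, alleles_per_locus + 1))
    pairs = [(a, b) for a in space for b in space if a <= b]

    def group_feasible(members):
        for j in range(n_loci):
            sets = [cons[i][j] for i in members if cons[i][j] is not None]
            if not sets:
                continue
            if not any(all(m1 in s or m2 in s for s in sets) for m1, m2 in pairs):
                return False
        return True

    best = n
    for part in _set_partitions(list(range(n))):
        if len(part) >= best:
            continue
        if all(group_feasible(g) for g in part):
            best = len(part)
    return best


def random_brood(rng, n_fry, n_loci=3, n_alleles=4, n_mothers=None):
    """A brood of fry from one father and 1-3 mothers, all random."""
    def geno():
        return rng.integers(1, n_alleles + 1, size=(n_loci, 2))

    father = geno()
    n_mothers = n_mothers or rng.integers(1, 4)
    mothers = [geno() for _ in range(n_mothers)]
    fry = np.zeros((n_fry, n_loci, 2), dtype=np.int64)
    for i in range(n_fry):
        m = mothers[rng.integers(0, n_mothers)]
        for j in range(n_loci):
            fry[i, j, 0] = father[j, rng.integers(0, 2)]
            fry[i, j, 1] = m[j, rng.integers(0, 2)]
    return father, fry


# ---------------------------------------------------------------------------
# paternity


def test_compatible_fry_has_zero_exclusions(rng):
    father = rng.integers(1, 9, size=(20, 2))
    fry = father.copy()  # carries a paternal allele everywhere
    chk = check_paternity(father, ["f1"], fry[None, :, :])
    assert chk.verdicts == ["compatible"] and chk.exclusions[0] == 0


def test_unrelated_fry_excluded():
    father = np.tile([1, 2], (20, 1))
    fry = np.tile([3, 4], (20, 1))
    chk = check_paternity(father, ["f1"], fry[None, :, :], tolerance=2)
    assert chk.verdicts == ["excluded"] and chk.exclusions[0] == 20


def test_missing_male_routes_brood_to_no_male():
    chk = check_paternity(None, ["f1"], np.ones((1, 3, 2)))
    assert chk.brood_verdict == "no_male"


def test_true_offspring_survive_genotyping_error(rng):
    """With e = 0.005 at least 99% of true offspring stay compatible."""
    cfg = SimulationConfig(
        nests_per_year=60, n_years=1, error_rate_per_locus=0.005,
        p_fry_mixed=0.0, p_male_unsampled=0.0, rng_seed=44,
    )
    pop = simulate_breeding_seasons(cfg)
    obs = observe(pop, cfg)
    fry = obs.genotypes.select(role="fry")
    males = obs.genotypes.select(role="male")
    male_of = {
        str(males.meta.iloc[i]["nest_id"]): males.alleles[i]
        for i in range(len(males))
    }
    n_ok = n_tot = 0
    for nest_id, grp in fry.meta.groupby("nest_id"):
        idx = grp.index.to_numpy()
        chk = check_paternity(
            male_of[str(nest_id)], [fry.ids[i] for i in idx], fry.alleles[idx]
        )
        n_ok += sum(v == "compatible" for v in chk.verdicts)
        n_tot += len(idx)
    assert n_ok / n_tot >= 0.99


# ---------------------------------------------------------------------------
# maternal sibship partitioning


def test_full_sib_brood_resolves_single_mother():
    # parents AB x CD at every locus
    father = np.tile([1, 2], (5, 1))
    fry = np.zeros((6, 5, 2), dtype=np.int64)
    rng = np.random.default_rng(0)
    for i in range(6):
        fry[i, :, 0] = father[:, rng.integers(0, 2, 5)][np.arange(5), np.arange(5)]
    for i in range(6):
        for j in range(5):
            fry[i, j, 0] = [1, 2][rng.integers(0, 2)]
            fry[i, j, 1] = [3, 4][rng.integers(0, 2)]
    part = partition_maternal_sibships([f"f{i}" for i in range(6)], fry, father)
    assert part.n_mothers == 1
    for j in range(5):
        patterns = part.patterns[0][j]
        concrete = {p for p in patterns if 0 not in p}
        assert concrete <= {(3, 4)} and patterns  # resolved up to {C, D}


def test_two_mother_brood_matches_truth(rng):
    cfg = SimulationConfig(
        nests_per_year=1, n_years=1, error_rate_per_locus=0.0, rng_seed=60
    )
    from nestkin.simulate import simulate_allele_frequencies, _draw_genotype, _mendelian_offspring

    panel = simulate_allele_frequencies(cfg)
    father = _draw_genotype(panel, rng)
    mothers = [_draw_genotype(panel, rng) for _ in range(2)]
    fry = np.stack(
        [_mendelian_offspring(father, mothers[i % 2], rng) for i in range(10)]
    )
    part = partition_maternal_sibships(
        [f"f{i}" for i in range(10)], fry, father, tolerance=0
    )
    assert part.n_mothers == 2
    groups = [set(g) for g in part.groups]
    assert {f"f{i}" for i in range(0, 10, 2)} in groups


@pytest.mark.parametrize("trial", range(60))
def test_partition_count_equals_brute_force(trial):
    """Exact minimal-mother counts on random small broods (3 loci)."""
    rng = np.random.default_rng(1000 + trial)
    n_fry = int(rng.integers(2, 7))
    father, fry = random_brood(rng, n_fry)
    part = partition_maternal_sibships(
        [f"f{i}" for i in range(n_fry)], fry, father, tolerance=0
    )
    expected = brute_force_min_mothers(fry, father, 4)
    assert part.n_mothers == expected


def test_partition_groups_are_disjoint_and_cover(rng):
    father, fry = random_brood(rng, 6, n_loci=10, n_alleles=6)
    ids = [f"f{i}" for i in range(6)]
    part = partition_maternal_sibships(ids, fry, father, tolerance=0)
    flat = [f for g in part.groups for f in g]
    assert sorted(flat) == sorted(ids)


def test_node_budget_falls_back_to_greedy():
    rng = np.random.default_rng(2)
    father, fry = random_brood(rng, 12, n_loci=3, n_alleles=8, n_mothers=3)
    with pytest.warns(UserWarning, match="node budget"):
        part = partition_maternal_sibships(
            [f"f{i}" for i in range(12)], fry, father, tolerance=0, node_budget=5
        )
    assert not part.exact
    assert sum(len(g) for g in part.groups) == 12


# ---------------------------------------------------------------------------
# merging females


def _nest_info(rows):
    return pd.DataFrame(
        rows, columns=["nest_id", "year", "male_id", "spawn_day", "shoreline_rank"]
    ).set_index("nest_id")


def test_polyandrous_female_merged_across_nests(rng):
    from nestkin.simulate import simulate_allele_frequencies, _draw_genotype, _mendelian_offspring

    cfg = SimulationConfig(rng_seed=61)
    panel = simulate_allele_frequencies(cfg)
    mother = _draw_genotype(panel, rng)
    parts = []
    for nest_idx in range(2):
        father = _draw_genotype(panel, rng)
        fry = np.stack([_mendelian_offspring(father, mother, rng) for _ in range(9)])
        parts.append(
            partition_maternal_sibships(
                [f"n{nest_idx}f{i}" for i in range(9)],
                fry,
                father,
                nest_id=f"N{nest_idx}",
                tolerance=0,
            )
        )
    info = _nest_info(
        [("N0", 2012, "M0", 3, 1), ("N1", 2012, "M1", 7, 2)]
    )
    females, _ = merge_females(parts, info)
    assert len(females) == 1
    assert females[0].mates(2012) == ["M0", "M1"]
    assert [c["mate_order"] for c in females[0].clutches] == [1, 2]


def test_unrelated_females_stay_separate(rng):
    from nestkin.simulate import simulate_allele_frequencies, _draw_genotype, _mendelian_offspring

    cfg = SimulationConfig(rng_seed=62)
    panel = simulate_allele_frequencies(cfg)
    parts = []
    for nest_idx in range(2):
        father = _draw_genotype(panel, rng)
        mother = _draw_genotype(panel, rng)
        fry = np.stack([_mendelian_offspring(father, mother, rng) for _ in range(9)])
        parts.append(
            partition_maternal_sibships(
                [f"n{nest_idx}f{i}" for i in range(9)],
                fry,
                father,
                nest_id=f"N{nest_idx}",
                tolerance=0,
            )
        )
    info = _nest_info([("N0", 2012, "M0", 3, 1), ("N1", 2012, "M1", 7, 2)])
    females, _ = merge_females(parts, info)
    assert len(females) == 2


def test_false_merge_rate_is_negligible(rng):
    """Reconstructed genotypes of unrelated females collide far less often
    than the panel's sib-level P(ID) would allow (< 1e-3)."""
    from nestkin.simulate import simulate_allele_frequencies, _draw_genotype, _mendelian_offspring

    cfg = SimulationConfig(rng_seed=63)
    panel = simulate_allele_frequencies(cfg)
    n_pairs = 300
    merged = 0
    for t in range(n_pairs):
        parts = []
        for nest_idx in range(2):
            father = _draw_genotype(panel, rng)
            mother = _draw_genotype(panel, rng)
            fry = np.stack(
                [_mendelian_offspring(father, mother, rng) for _ in range(8)]
            )
            parts.append(
                partition_maternal_sibships(
                    [f"t{t}n{nest_idx}f{i}" for i in range(8)],
                    fry,
                    father,
                    nest_id=f"N{nest_idx}",
                    tolerance=0,
                )
            )
        info = _nest_info([("N0", 2012, "M0", 3, 1), ("N1", 2012, "M1", 7, 2)])
        females, _ = merge_females(parts, info)
        merged += len(females) == 1
    assert merged == 0


# ---------------------------------------------------------------------------
# QC categories


def test_fry_label_assignment(small_study):
    _, pop, obs = small_study
    res = reconstruct_pedigree(obs.genotypes, obs.nests)
    labels = res.fry_labels
    # QC labels are total: every sampled fry receives exactly one label
    fry = obs.genotypes.select(role="fry")
    assert sorted(labels["offspring"]) == sorted(fry.ids)
    truth = obs.truth_parentage.set_index("offspring")
    lab = labels.set_index("offspring")["label"]
    mixed_truth = truth[truth["mixed"] == 1].index
    if len(mixed_truth) >= 3:
        # most truly mixed fry are recognized as non-assigned
        frac = (lab.loc[mixed_truth] != "assigned").mean()
        assert frac > 0.5


def test_mixing_rate_recovered_within_ci():
    from scipy.stats import binomtest

    cfg = SimulationConfig(
        nests_per_year=170, n_years=1, p_fry_mixed=0.02, p_male_unsampled=0.0,
        p_nest_fail=0.0, error_rate_per_locus=0.0, rng_seed=71,
    )
    pop = simulate_breeding_seasons(cfg)
    obs = observe(pop, cfg)
    res = reconstruct_pedigree(obs.genotypes, obs.nests)
    n_fry = len(res.fry_labels)
    k_mixed = int((res.fry_labels["label"] == "mixed").sum())
    ci = binomtest(k_mixed, n_fry).proportion_ci(0.95, method="exact")
    assert ci.low <= cfg.p_fry_mixed <= ci.high


def test_pipeline_recovers_truth_pedigree_error_free():
    """Zero-error, zero-mixing data reconstructs parentage exactly."""
    cfg = SimulationConfig(
        nests_per_year=40, n_years=1, error_rate_per_locus=0.0,
        p_fry_mixed=0.0, p_male_unsampled=0.0, p_nest_fail=0.0, rng_seed=80,
    )
    pop = simulate_breeding_seasons(cfg)
    obs = observe(pop, cfg)
    res = reconstruct_pedigree(obs.genotypes, obs.nests)
    truth = obs.truth_parentage.set_index("offspring")
    ped = res.pedigree.set_index("offspring")
    assert set(ped.index) == set(truth.index)
    # fathers match truth exactly
    fathers = ped["father"].str.split("@").str[0]
    assert (fathers == truth.loc[ped.index, "father"]).all()
    # recovered maternal sibships refine or equal the true ones
    joint = pd.DataFrame(
        {"rec": ped["female_id"], "true": truth.loc[ped.index, "mother"]}
    )
    # every reconstructed female maps to exactly one true mother
    assert (joint.groupby("rec")["true"].nunique() == 1).all()
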