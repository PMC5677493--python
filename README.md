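# nestkin

Genetic mating-system analysis for nest-guarding fish from nest-structured
microsatellite data.

## The problem

In smallmouth bass and similar paternal-care species, each brood has a
known candidate father — the guardian male caught at the nest — while
females are never handled and exist in the data only through the alleles
they leave in their offspring. Given per-nest genotypes of guardian males
and a subsample of swim-up fry (~8–12 per nest, 20 microsatellite loci),
`nestkin` reconstructs who mated with whom:

* **paternity confirmation** by allele-sharing exclusion, tolerant of
  genotyping error;
* **maternal sibship partitioning**: each brood's father-compatible fry
  are split into the minimum number of maternal full-sib groups whose
  (unsampled) maternal genotypes can jointly explain every fry's
  non-paternal alleles, with Hardy–Weinberg likelihood as the tie-break;
* **female reconstruction**: maternal genotypes, kept as per-locus
  constraint sets, are matched across nests and seasons to recover
  individual females, their within-season mate order (by nest spawn
  date), and interannual capture histories;
* **mating-system tallies**: monogamy/polygyny/polyandry classes, return
  and skip-spawning counts, interannual mate fidelity, fork-length
  summaries of multi-mating adults;
* **return rates** via a time-dependent Cormack–Jolly–Seber model
  (apparent survival φ_t interpreted as breeding return rate, detection
  p_t estimable or fixed at 1), with profile-likelihood 95% CIs;
* **mate choice**: Queller–Goodnight pairwise relatedness r, per-female
  randomization tests against the year's male pool (10,000 iterations,
  prior mates excluded), inbred/unrelated/outbred categories, and a
  per-year model of d = r(female, first male) − r(female, additional
  male).

A seeded forward simulator (`nestkin.simulate`) generates the whole study
design — multi-year nesting, clutch allocation ordered by spawn
phenology, Mendelian inheritance, per-allele genotyping error, fry mixing
between shoreline-adjacent nests, unsampled males, sex-specific return
with skip-spawning — together with a truth ledger, so every inference
stage is testable without any field data.

## Worked example

```python
from nestkin import (
    SimulationConfig, simulate_study, reconstruct_pedigree,
    tally_mating, CJSModel,
)
from nestkin.matechoice import mate_choice_analysis

cfg = SimulationConfig(nests_per_year=60, n_years=3, rng_seed=42)
pop, obs = simulate_study(cfg)                      # truth + observed tables
res = reconstruct_pedigree(obs.genotypes, obs.nests)

print(tally_mating(res.pedigree, res.females).pooled)
# {'broods_total': 166, 'broods_single_female': 132, 'pct_single_female': 79.5,
#  'multi_mating_males': 34, 'pct_multi_mating_males': 20.5,
#  'females_total': 178, 'multi_mating_females': 22,
#  'pct_multi_mating_females': 12.4}

model = CJSModel.from_dataframe(obs.truth_captures, cfg.years, sex="M")
print(model.fit(fix_p=1.0).summary())
# Cormack-Jolly-Seber return-rate model (sex=M)
# ================================================================
# occasions: [2012, 2013, 2014]   n histories: 128
# log-likelihood: -80.718   converged: True
# detection fixed at p = 1.0
# note: 3 histories right-truncated (skip-season sightings impossible under p=1)
# ----------------------------------------------------------------
# interval             phi      SE            95% CI
# 2012-2013          0.450   0.064    [0.328, 0.576]
# 2013-2014          0.367   0.062    [0.252, 0.492]
# ================================================================
```

`pct_single_female` is the share of assigned broods produced by a single
male–female pair; the remaining nests received clutches from two or three
females. The CJS φ of 0.45 means an estimated 45% of males nesting in
2012 returned to breed in 2013; the bracket is the profile-likelihood 95%
interval. `mate_choice_analysis(res.females, obs.genotypes)` then yields
the pair-level relatedness categories per year and the first-vs-additional
mate difference model for multiple-mating females.

The same stages are available from a shell:

```sh
nestkin simulate --out sim/ --seed 42
nestkin reconstruct sim/genotypes.csv sim/nests.csv --out rec/
nestkin classify rec/
nestkin cjs sim/truth_captures.csv --by-sex --fix-p 1
nestkin matechoice sim/genotypes.csv sim/nests.csv
nestkin panel-stats sim/genotypes.csv
```

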