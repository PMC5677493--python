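# Methods

## Study design being modelled

The package targets the data structure of intensive nesting surveys of
paternal-care fish: every nest along a surveyed shoreline is found and
revisited, its guardian male is caught, tagged, measured and genotyped,
and a subsample of swim-up fry is taken just before dispersal. Mothers
are never captured. Male identity is therefore known across seasons
(physical tags), while female identity exists only as a genotype to be
reconstructed from broods. The analysis year runs female-side on three
fry-sampled seasons and can include an extra males-only first season
(`males_only_first_year`).

## Forward simulator

`simulate_breeding_seasons` draws, per season:

* **males and nests** — returning males plus new recruits fill
  `nests_per_year` nests at shuffled shoreline ranks; spawn day is normal
  around a length-dependent mean (larger males earlier), reflecting the
  spawn phenology that lets first and subsequent mates be ordered.
* **clutch counts** — a male receives a second clutch with probability
  `p_male_poly` and, conditionally, a third with the same probability.
  Propensity rises with fork length through a logistic link
  (`length_poly_slope`, logit units per SD) and is rescaled so the cohort
  mean equals the configured rate exactly; the rate calibration therefore
  survives the size dependence.
* **mothers** — clutch events are processed in spawn-day order. A female
  flagged polyandrous (probability `p_female_poly`, conditional third
  with the same probability) waits in a queue and takes her next clutch
  at the earliest eligible later-spawning male, ties broken by shoreline
  proximity; otherwise a returning female (if any are due) or a new
  female is drawn. This guarantees mate order is consistent with
  phenology and that no interannual pair is forced to re-form.
* **offspring** — clutch sizes are zero-truncated Poisson with mean
  `clutch_size_mean` (the distribution around the mean brood size is not
  dictated by the design, so the simplest count model is used and flagged
  here as an assumption); inheritance is Mendelian at every locus.
* **return** — after each season every breeding adult survives-and-
  returns with probability `phi_male` / `phi_female`; a returner skips
  one season with probability `p_skip`. Capture-history truth records
  actual breeding participation.

`observe` then applies the observation process: whole-brood loss before
sampling (`p_nest_fail`), fry subsampling at `fry_per_nest_sampled`
(8–12; smaller broods are taken whole), per-fry replacement by a fry from
a shoreline-adjacent nest (`p_fry_mixed` — "adjacent" is rank-adjacent,
the operational form of mixing from a neighboring nest), uncaptured
guardian males (`p_male_unsampled`), and per-allele miscalls: with
probability `e_l` an allele call is replaced by a draw from the locus
frequency distribution. The per-locus defaults span 0–0.0075, the range
observed when repeat captures of tagged males are re-scored. Male
genotype rows are emitted per capture (`M0001@2013`) so repeat captures
carry independent errors.

Default parameter values (170 nests/season, 3 seasons, 20 loci with 8
alleles under Dirichlet(1) frequencies, p_male_poly 0.15, p_female_poly
0.09, phi 0.40/0.09, p_skip 0.10, mixing 0.02, unsampled males 0.025,
nest failure 0.03) reproduce the scale and rates of the motivating
surveys. What the simulator does **not** model: spatial home ranges,
predation and seiche-driven brood loss dynamics, null alleles and allelic
dropout, age structure beyond a linear length increment, and linkage
between loci. Passing tests therefore demonstrate correctness of the
inference machinery under a faithful but idealized observation model, not
robustness to every field pathology.

## Paternity and maternal reconstruction

Paternity is exclusion with tolerance: a fry is compatible with its
nest's male when at most `tolerance` (default 2 of 20) jointly scored
loci share no allele. With per-allele error ≤ 0.0075, the chance a true
offspring accrues three or more error-induced exclusions is negligible,
while unrelated fry are excluded at many loci; a Bayesian open-paternity
search is unnecessary because the candidate father is known a priori.

Maternal sibship partitioning works on per-fry, per-locus *maternal
constraint sets*: subtracting one paternal contribution from the fry's
allele pair leaves a forced maternal allele, an ambiguous pair, or no
information. A maternal genotype satisfies a group when, at every locus,
its two alleles hit every member's constraint set; feasibility is checked
over "pair patterns" that may leave one slot unconstrained. The
partitioner finds the **minimum number of mothers** by branch-and-bound
over fry in input order (deterministic), allowing up to `tolerance`
conflicting loci per fry, which are charged to that fry as error loci and
dropped from its constraints. Among minimal partitions the total
Hardy–Weinberg log-likelihood of the implied maternal genotypes breaks
ties — parsimony first, frequency likelihood second, which plays the role
a mean-sibship-size prior plays in likelihood-based sibship software:
discouraging spurious family splits. A node budget (default 1e6) guards
worst cases; beyond it a greedy first-fit partition is returned, flagged
`exact=False`, with a warning. With tolerance 0 the algorithm is exact,
and the test suite verifies equality with exhaustive search over all set
partitions × maternal genotypes on broods of ≤6 fry.

Reconstructed maternal genotypes are kept as per-locus pattern sets, not
point estimates. Two groups merge into one female when their patterns
are compatible at all but at most `match_threshold` (default 2) of at
least `min_shared` (default 10) jointly informative loci — the same
mismatch-tolerance logic used for multilocus identity matching of tagged
males, where the default ≤2-of-20 rule keeps the expected false-merge
probability under a sib-level P(ID) of ~1e-4 well below 1e-3. Merges are
applied best-first; a candidate incompatible with an earlier merge's
consensus is skipped, and exact ties between mutually incompatible
alternatives are left unmerged and logged. Within a year a female's
clutches are ordered by nest spawn date (ties: shoreline rank, then nest
id) to define first/second/third mates; across years merges populate
female capture histories. A nest may hold two maternal groups at
different dates, so a male receiving two clutches at one nest is
representable.

QC labels are truth-free: a fry is *assigned* (compatible with its own
nest's male), *mixed* (only with a rank-adjacent nest's male),
*mis-assigned* (only with some non-adjacent male that year), or
*unknown* (with no sampled male). The spatial adjacency rule is one
operationalization of mixing "from a neighboring nest"; genotyping-error
strays and true strays cannot be distinguished without truth, and the
package does not try. Broods with an uncaptured male are excluded
outright; broods with no own-assigned fry are excluded under their modal
fry category (ties broken mixed > unknown > mis-assigned).

## Panel statistics

Per locus with allele power sums a_k = Σ p_i^k:
P(ID)_HW = 2a₂² − a₄; P(ID)_sib = 0.25 + 0.5a₂ + 0.5a₂² − 0.25a₄;
the unbiased small-sample form is
[n³(2a₂² − a₄) − 2n²(a₃ + 2a₂) + n(9a₂ + 2) − 6] / [(n−1)(n−2)(n−3)],
defined for n ≥ 4. Multilocus values are products over loci. Error rates
from repeat captures score each jointly called locus as the minimum
allele-edit distance between the two calls (0/1/2) over two allele
comparisons, invariant to within-genotype allele order.

## Cormack–Jolly–Seber model

The likelihood is the standard conditional-on-first-release
product-multinomial over the m-array (releases × first recaptures), with
time-dependent φ and p. Estimation is by seeded multi-start L-BFGS-B on
the logit scale; standard errors come from the numerically differentiated
observed information on the probability scale (boundary estimates get no
SE), and 95% confidence intervals are profile-likelihood intervals at the
deviance cutoff 3.84, solved by bracketing with endpoints clamped to 0/1
when the deviance never reaches the cutoff (e.g. φ̂ = 1 gives a
degenerate upper bound). With p free, the terminal φ and p enter the
likelihood only through their product and are flagged as confounded.

Perfect detection and skip-spawning are mutually contradictory: a history
such as `1011` has probability zero under p = 1. The package's default is
therefore to estimate p freely. `fit(fix_p=1.0)` reproduces the
perfect-detection analysis by right-truncating each offending history at
the end of its initial run of sightings — an explicit, counted
approximation (the number of modified histories is reported on the
results object and in `summary()`), not a silent one.

## Relatedness and mate choice

Queller–Goodnight r sums numerators and denominators over loci and both
focal directions before dividing, so r(x,y) = r(y,x), r(x,x) = 1, a
fully dissimilar pair at equifrequent alleles scores −1, and random pairs
average 0. Loci missing in either genotype (including unresolved loci of
reconstructed females) are skipped; an all-uninformative comparison is
NaN and flagged. Reference frequencies come from the year's nesting
males; per-pair exclusion of the focal male's alleles from the counts is
available and changes r by O(1/n).

The randomization null for a pair is the set of r values between that
female and every candidate male of the year (prior mates in the season
excluded; the focal male remains, so the exact upper-tail p of a pool
maximum is 1/pool). Monte-Carlo p-values resample the pool with
replacement (default 10,000 draws, seeded per pair) and are reported
beside the exact enumeration values they converge to. Categories use two
one-tailed tests at α per tail (default 0.05): *inbred* when the
upper-tail p ≤ α, *outbred* for the lower tail — the lower tail is
required for an outbred category to exist at all — and *unrelated*
otherwise; pools below 10 candidates give an "underpowered" flag and no
category. Under random mating the inbred rate is ≈ α by the rank
uniformity of the focal male in his own pool, which the calibration
tests verify.

`MateDifferenceModel` takes one triad per multiple-mating female —
r(female, first male) and one *randomly selected* additional male
(seeded, recorded) to avoid pseudo-replication — and fits the per-year
normal model of d = r_first − r_additional by maximum likelihood, which
for a year-only design equals the one-sample t test of mean d against
zero (positive d: additional males are less related). Years with a
single triad report the estimate without a test.

## Tally conventions

The male-side unit is the assigned brood (nest-year, clutches pooled);
the female-side unit is the reconstructed female-year; pooled fractions
use assigned broods only. Percentages are recomputed from counts with
half-up rounding (as survey tables print them). A "skip" is any season
with no observation between an individual's first and last observations.
Internal consistency (class counts vs totals, offspring sums vs pedigree
rows) is checked and violations are surfaced as flags rather than
propagated. The packaged summary dataset in `nestkin.datasets` is
synthetic: only its class *counts* are calibrated to a published
three-season survey, and where that survey's own table entries disagree
with their printed totals and percentages the self-consistent counts are
used. Clutch-level fry totals in the fixture are solved as a
transportation problem (integral max-flow) so both the male-class and
female-class offspring margins are met exactly.

## Problem sizes and numerical choices

The test suite and acceptance script run the pipeline at the design's
natural scale (≈170 nests × 3 seasons, ~5,000 fry) for recovery checks,
500/200 random small broods for the partition oracle, 100 replicates ×
300 histories for CJS coverage, and a few thousand pairs for relatedness
calibration — sizes chosen so each check has clear statistical power
while the whole suite completes in about a minute. All stochastic
components take explicit seeds; reruns are byte-identical.

## Known limitations

* The partition tolerance heuristic (charging conflicting loci to the
  joining fry) is exact at tolerance 0 but order-dependent at tolerance
  > 0; with realistic error rates this affects well under 1% of fry.
* Female recovery degrades for very small clutches (2–3 sampled fry),
  whose maternal genotypes are mostly unresolved; such females carry
  many wildcard loci and their pair tests may be flagged undefined or
  underpowered.
* The CJS model here is time-dependent only: no covariates, multi-state
  extensions, or model selection across φ/p structures.
* Relatedness supports the Queller–Goodnight estimator only; the
  function signature (genotypes + frequency dicts) is the plug-in point
  for alternatives.
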