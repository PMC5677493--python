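"""Forward simulation of a multi-year nesting population and its observation.

The simulator emulates a snorkel-survey study design for a nest-guarding
fish (smallmouth bass style): every spring, males excavate nests at ordered
shoreline positions and guard a brood alone; females are never handled, so
their identities exist only through the genotypes of the swim-up fry
sampled from each nest (~8-12 per nest).  Males are caught at the nest,
tagged, measured and fin-clipped, so male identity is known across years
while female identity must later be reconstructed genetically.

Two layers are produced:

* the *true* population (`simulate_breeding_seasons`): adults with exact
  genotypes, clutch-by-clutch matings ordered by spawn date, Mendelian
  offspring, and sex-specific annual return with occasional skipped
  seasons;
* the *observed* data (`observe`): per-nest fry subsamples, per-allele
  genotyping errors, unsampled guardian males, low-rate fry mixing between
  shoreline-adjacent nests, and brood loss before sampling.

A truth ledger (parentage, capture histories, mate orders, mixing events)
accompanies the observed tables so that every downstream inference step can
be scored against the generating process.  All randomness flows from a
single seed; identical configurations reproduce identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .genotypes import MISSING, GenotypeTable, LocusPanel

__all__ = [
    "SimulationConfig",
    "Population",
    "Observation",
    "simulate_allele_frequencies",
    "simulate_breeding_seasons",
    "observe",
    "simulate_study",
]


@dataclass
class SimulationConfig:
    """Study-design parameters for the forward simulation.

    Defaults mirror a three-season survey of ~170 nests per season with a
    20-locus microsatellite panel: fry subsamples of 8-12 per nest, mean
    clutch size 11, per-locus genotyping error between 0 and 0.0075, ~15%
    of males receiving a second clutch, ~9% of females spawning in a second
    nest, male annual return near 0.40 versus 0.09 for females, and a 10%
    chance that a returning adult sits out one season before breeding
    again.
    """

    n_loci: int = 20
    alleles_per_locus: int | list[int] = 8
    allele_freq_model: str = "dirichlet"  # 'uniform' | 'dirichlet'
    dirichlet_concentration: float = 1.0
    n_years: int = 3
    start_year: int = 2012
    nests_per_year: int = 170
    fry_per_nest_sampled: tuple[int, int] = (8, 12)
    clutch_size_mean: float = 11.0
    p_male_poly: float = 0.15
    p_female_poly: float = 0.09
    phi_male: float = 0.40
    phi_female: float = 0.09
    p_skip: float = 0.10
    error_rate_per_locus: float | list[float] | None = None
    p_male_unsampled: float = 0.025
    p_fry_mixed: float = 0.02
    p_nest_fail: float = 0.03
    males_only_first_year: bool = False
    length_poly_slope: float = 0.8  # logit units per SD of fork length
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        counts = self.alleles_counts()
        if any(k < 2 for k in counts):
            raise ValueError(
                "alleles_per_locus must be >= 2: monomorphic loci carry no "
                "identity or parentage information"
            )
        lo, hi = self.fry_per_nest_sampled
        if not (1 <= lo <= hi):
            raise ValueError("fry_per_nest_sampled must be a range within [1, ...]")
        if self.clutch_size_mean <= 0:
            raise ValueError("clutch_size_mean must be positive")
        for name in (
            "p_male_poly",
            "p_female_poly",
            "phi_male",
            "phi_female",
            "p_skip",
            "p_male_unsampled",
            "p_fry_mixed",
            "p_nest_fail",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        e = self.error_rates()
        if ((e < 0) | (e > 1)).any():
            raise ValueError("error_rate_per_locus outside [0, 1]")
        if self.n_years < 1:
            raise ValueError("n_years must be >= 1")

    def alleles_counts(self) -> list[int]:
        if isinstance(self.alleles_per_locus, int):
            return [self.alleles_per_locus] * self.n_loci
        if len(self.alleles_per_locus) != self.n_loci:
            raise ValueError("per-locus allele counts must have length n_loci")
        return list(self.alleles_per_locus)

    def error_rates(self) -> np.ndarray:
        if self.error_rate_per_locus is None:
            # span the observed range of repeat-capture error rates
            return np.linspace(0.0, 0.0075, self.n_loci)
        e = np.atleast_1d(np.asarray(self.error_rate_per_locus, dtype=float))
        if e.size == 1:
            return np.full(self.n_loci, float(e[0]))
        if e.size != self.n_loci:
            raise ValueError("error_rate_per_locus must be scalar or length n_loci")
        return e

    @property
    def years(self) -> list[int]:
        return [self.start_year + t for t in range(self.n_years)]

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["fry_per_nest_sampled"] = list(self.fry_per_nest_sampled)
        if isinstance(d["error_rate_per_locus"], np.ndarray):
            d["error_rate_per_locus"] = d["error_rate_per_locus"].tolist()
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if "fry_per_nest_sampled" in d:
            d["fry_per_nest_sampled"] = tuple(d["fry_per_nest_sampled"])
        return cls(**d)


# ---------------------------------------------------------------------------
# population containers


@dataclass
class Adult:
    id: str
    sex: str  # 'M' | 'F'
    alleles: np.ndarray  # (n_loci, 2)
    first_year: int
    length: dict[int, float] = field(default_factory=dict)
    present_years: list[int] = field(default_factory=list)


@dataclass
class Clutch:
    female: str
    day: int
    fry_ids: list[str]


@dataclass
class Nest:
    id: str
    year: int
    male: str
    rank: int
    day: int
    clutches: list[Clutch] = field(default_factory=list)
    failed: bool = False

    @property
    def brood_fry(self) -> list[str]:
        return [f for c in self.clutches for f in c.fry_ids]


@dataclass
class Fry:
    id: str
    father: str
    mother: str
    nest_id: str
    year: int
    alleles: np.ndarray


@dataclass
class Population:
    """True (error-free, fully sampled) state of the simulated population."""

    config: SimulationConfig
    panel: LocusPanel
    adults: dict[str, Adult]
    nests: list[Nest]
    fry: dict[str, Fry]

    def capture_frame(self) -> pd.DataFrame:
        """True presence (breeding participation) per adult and year."""
        years = self.config.years
        rows = []
        for a in self.adults.values():
            hist = {f"y{y}": int(y in a.present_years) for y in years}
            rows.append({"individual": a.id, "sex": a.sex, **hist})
        return pd.DataFrame(rows)

    def matings_frame(self) -> pd.DataFrame:
        """True mate order per female-year, ordered by spawn day."""
        rows = []
        per_female: dict[tuple[str, int], list[tuple[int, int, str, str]]] = {}
        for nest in self.nests:
            for clutch in nest.clutches:
                per_female.setdefault((clutch.female, nest.year), []).append(
                    (clutch.day, nest.rank, nest.male, nest.id)
                )
        for (female, year), events in per_female.items():
            events.sort()
            for order, (day, rank, male, nest_id) in enumerate(events, start=1):
                rows.append(
                    {
                        "female": female,
                        "year": year,
                        "order": order,
                        "male": male,
                        "nest_id": nest_id,
                        "day": day,
                    }
                )
        return pd.DataFrame(rows).sort_values(["year", "female", "order"]).reset_index(
            drop=True
        )


# ---------------------------------------------------------------------------
# allele frequencies


def simulate_allele_frequencies(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> LocusPanel:
    """Draw per-locus allele frequency vectors for the founder population."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.rng_seed).spawn(1)[0])
    loci = [f"L{j + 1:02d}" for j in range(config.n_loci)]
    freqs = []
    for k in config.alleles_counts():
        if config.allele_freq_model == "uniform":
            p = np.full(k, 1.0 / k)
        elif config.allele_freq_model == "dirichlet":
            p = rng.dirichlet(np.full(k, config.dirichlet_concentration))
            # keep every allele usable: floor rare alleles and renormalize
            p = np.maximum(p, 1e-3)
            p = p / p.sum()
        else:
            raise ValueError(f"unknown allele_freq_model: {config.allele_freq_model!r}")
        freqs.append({a + 1: float(x) for a, x in enumerate(p)})
    return LocusPanel(loci, freqs, error_rates=config.error_rates())


def _draw_genotype(panel: LocusPanel, rng: np.random.Generator) -> np.ndarray:
    """One Hardy-Weinberg genotype from the panel frequencies."""
    out = np.empty((panel.n_loci, 2), dtype=np.int64)
    for j, (labels, p) in enumerate(panel.freq_arrays()):
        out[j] = rng.choice(labels, size=2, p=p)
    return out


def _mendelian_offspring(
    father: np.ndarray, mother: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    n = father.shape[0]
    pick_f = rng.integers(0, 2, size=n)
    pick_m = rng.integers(0, 2, size=n)
    out = np.empty((n, 2), dtype=np.int64)
    out[:, 0] = father[np.arange(n), pick_f]
    out[:, 1] = mother[np.arange(n), pick_m]
    return out


def _zt_poisson(mean: float, rng: np.random.Generator) -> int:
    """Zero-truncated Poisson draw (clutches always contain >= 1 egg)."""
    while True:
        k = rng.poisson(mean)
        if k >= 1:
            return int(k)


# ---------------------------------------------------------------------------
# breeding seasons


def _n_extra(p: float, rng: np.random.Generator) -> int:
    """0, 1 or 2 extra matings: a second with probability p, then a third
    conditionally with the same probability."""
    if rng.random() >= p:
        return 0
    return 1 + int(rng.random() < p)


def simulate_breeding_seasons(
    config: SimulationConfig, panel: LocusPanel | None = None
) -> Population:
    """Simulate nesting males, clutch allocation to females, Mendelian
    offspring, and sex-specific interannual return.

    Within a season, clutch events are processed in spawn-date order; a
    polyandrous female's additional clutches therefore always go to males
    spawning on or after her first mate's date, with ties in the candidate
    queue broken by shoreline proximity.  Multi-clutch propensity of males
    rises with fork length through a logistic link whose cohort mean is
    rescaled to the configured rate.
    """
    ss = np.random.SeedSequence(config.rng_seed).spawn(3)
    if panel is None:
        panel = simulate_allele_frequencies(config, np.random.default_rng(ss[0]))
    rng = np.random.default_rng(ss[1])

    adults: dict[str, Adult] = {}
    nests: list[Nest] = []
    all_fry: dict[str, Fry] = {}
    male_counter = female_counter = 0

    # adults scheduled to breed in a given future year
    due: dict[int, list[str]] = {y: [] for y in config.years}

    def schedule_return(adult: Adult, year: int) -> None:
        phi = config.phi_male if adult.sex == "M" else config.phi_female
        if rng.random() >= phi:
            return
        gap = 2 if rng.random() < config.p_skip else 1
        nxt = year + gap
        if nxt in due:
            due[nxt].append(adult.id)

    for year in config.years:
        # --- males and nests -------------------------------------------------
        returning_males = [i for i in due[year] if adults[i].sex == "M"]
        returning_females = [i for i in due[year] if adults[i].sex == "F"]
        n_new_males = max(config.nests_per_year - len(returning_males), 0)
        season_males: list[str] = list(returning_males)
        for _ in range(n_new_males):
            male_counter += 1
            mid = f"M{male_counter:04d}"
            adults[mid] = Adult(mid, "M", _draw_genotype(panel, rng), year)
            adults[mid].length[year] = float(rng.normal(360.0, 40.0))
            season_males.append(mid)
        for mid in returning_males:
            prev = max(adults[mid].length) if adults[mid].length else year - 1
            base = adults[mid].length.get(prev, float(rng.normal(360.0, 40.0)))
            adults[mid].length[year] = base + 15.0 * (year - prev)

        ranks = rng.permutation(len(season_males)) + 1
        lengths = np.array([adults[m].length[year] for m in season_males])
        # larger males tend to spawn earlier
        days = np.clip(
            np.rint(rng.normal(18.0 - 0.05 * (lengths - 360.0), 6.0)), 0, 40
        ).astype(int)

        # multi-clutch propensity: logistic in length, rescaled so the
        # cohort mean equals p_male_poly
        if config.p_male_poly > 0 and len(season_males) > 0:
            z = (lengths - lengths.mean()) / max(lengths.std(), 1e-9)
            logit = np.log(config.p_male_poly / (1 - config.p_male_poly))
            prop = 1.0 / (1.0 + np.exp(-(logit + config.length_poly_slope * z)))
            prop = np.clip(prop * config.p_male_poly / prop.mean(), 0.0, 1.0)
        else:
            prop = np.zeros(len(season_males))

        season_nests: list[Nest] = []
        events: list[tuple[int, int, str]] = []  # (day, rank, nest_idx marker)
        for i, mid in enumerate(season_males):
            nest = Nest(
                id=f"N{year}-{ranks[i]:03d}",
                year=year,
                male=mid,
                rank=int(ranks[i]),
                day=int(days[i]),
            )
            season_nests.append(nest)
            n_clutches = 1 + (_n_extra(float(prop[i]), rng) if config.p_male_poly else 0)
            day = nest.day
            for c in range(n_clutches):
                events.append((day, nest.rank, nest.id))
                day += int(rng.integers(1, 6))
        nest_by_id = {n.id: n for n in season_nests}
        events.sort()

        # --- mothers ---------------------------------------------------------
        rng.shuffle(returning_females)
        fresh_pool = list(returning_females)  # returning females breed first
        # females still owed additional clutches: id -> (first_day, last_rank,
        # remaining, mates-so-far)
        pending: dict[str, list] = {}
        mates_this_year: dict[str, set[str]] = {}

        for day, rank, nest_id in events:
            nest = nest_by_id[nest_id]
            male = nest.male
            # serve a pending polyandrous female if one is eligible
            eligible = [
                f for f, st in pending.items() if male not in st[3]
            ]
            if eligible:
                eligible.sort(key=lambda f: (abs(pending[f][1] - rank), pending[f][0], f))
                fid = eligible[0]
                st = pending[fid]
                st[1] = rank
                st[2] -= 1
                st[3].add(male)
                if st[2] == 0:
                    del pending[fid]
            else:
                if fresh_pool:
                    fid = fresh_pool.pop()
                else:
                    female_counter += 1
                    fid = f"F{female_counter:04d}"
                    adults[fid] = Adult(fid, "F", _draw_genotype(panel, rng), year)
                extra = _n_extra(config.p_female_poly, rng)
                if extra:
                    pending[fid] = [day, rank, extra, {male}]
                mates_this_year.setdefault(fid, set()).add(male)
            if year not in adults[fid].present_years:
                adults[fid].present_years.append(year)

            n_eggs = _zt_poisson(config.clutch_size_mean, rng)
            father_g = adults[male].alleles
            mother_g = adults[fid].alleles
            fry_ids = []
            for k in range(n_eggs):
                fry_id = f"{nest.id}-{len(nest.brood_fry) + k + 1:02d}"
                all_fry[fry_id] = Fry(
                    fry_id, male, fid, nest.id, year,
                    _mendelian_offspring(father_g, mother_g, rng),
                )
                fry_ids.append(fry_id)
            nest.clutches.append(Clutch(fid, day, fry_ids))

        for mid in season_males:
            adults[mid].present_years.append(year)
        nests.extend(season_nests)

        # --- who comes back --------------------------------------------------
        for aid in season_males:
            schedule_return(adults[aid], year)
        for fid in {c.female for n in season_nests for c in n.clutches}:
            schedule_return(adults[fid], year)

    return Population(config, panel, adults, nests, all_fry)


# ---------------------------------------------------------------------------
# observation


@dataclass
class Observation:
    """Observed tables plus the truth ledger of the generating process."""

    genotypes: GenotypeTable
    nests: pd.DataFrame
    truth_parentage: pd.DataFrame
    truth_captures: pd.DataFrame
    truth_matings: pd.DataFrame

    def write(self, outdir) -> None:
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.genotypes.to_frame().to_csv(out / "genotypes.csv", index=False)
        self.nests.to_csv(out / "nests.csv", index=False)
        self.truth_parentage.to_csv(out / "truth_parentage.csv", index=False)
        self.truth_captures.to_csv(out / "truth_captures.csv", index=False)
        self.truth_matings.to_csv(out / "truth_matings.csv", index=False)


def _apply_errors(
    alleles: np.ndarray, panel: LocusPanel, rates: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Per-allele miscall model: with probability e_l an allele call is
    replaced by a random draw from the locus frequency distribution."""
    out = alleles.copy()
    freq = panel.freq_arrays()
    for j in range(panel.n_loci):
        if rates[j] <= 0:
            continue
        labels, p = freq[j]
        for k in range(2):
            if out[j, k] != MISSING and rng.random() < rates[j]:
                out[j, k] = rng.choice(labels, p=p)
    return out


def observe(population: Population, config: SimulationConfig | None = None) -> Observation:
    """Apply the observation process to a simulated population.

    Per nest: the brood may be lost before sampling; otherwise 8-12 fry are
    subsampled, each of which may in truth have drifted in from a
    shoreline-adjacent nest; the guardian male may go uncaptured; all
    emitted allele calls carry the per-locus miscall rates.  Mothers never
    appear in the output genotypes.  Male genotype rows are per capture
    (``<male>@<year>``) so that repeat captures of tagged males carry
    independent errors, as in real scoring.
    """
    if config is None:
        config = population.config
    rng = np.random.default_rng(np.random.SeedSequence(config.rng_seed).spawn(3)[2])
    panel = population.panel
    rates = config.error_rates()

    gen_rows: list[dict] = []
    allele_rows: list[np.ndarray] = []
    nest_rows: list[dict] = []
    parentage_rows: list[dict] = []

    nests_by_year: dict[int, list[Nest]] = {}
    for nest in population.nests:
        nests_by_year.setdefault(nest.year, []).append(nest)

    for year, season in sorted(nests_by_year.items()):
        by_rank = {n.rank: n for n in season}
        failed = {n.id for n in season if rng.random() < config.p_nest_fail}
        male_sampled = {n.id: rng.random() >= config.p_male_unsampled for n in season}
        fry_only_skipped = config.males_only_first_year and year == config.years[0]

        for nest in sorted(season, key=lambda n: n.rank):
            if male_sampled[nest.id]:
                obs_id = f"{nest.male}@{year}"
                gen_rows.append(
                    {"id": obs_id, "year": year, "role": "male", "nest_id": nest.id}
                )
                allele_rows.append(
                    _apply_errors(population.adults[nest.male].alleles, panel, rates, rng)
                )
            nest_rows.append(
                {
                    "nest_id": nest.id,
                    "year": year,
                    "shoreline_rank": nest.rank,
                    "spawn_date": f"{year}-05-{1 + nest.day // 2:02d}"
                    if nest.day < 60
                    else f"{year}-06-01",
                    "spawn_day": nest.day,
                    "male_id": nest.male if male_sampled[nest.id] else "",
                }
            )
            if fry_only_skipped or nest.id in failed:
                continue
            brood = nest.brood_fry
            if not brood:
                continue
            lo, hi = config.fry_per_nest_sampled
            k = min(int(rng.integers(lo, hi + 1)), len(brood))
            sampled = list(rng.choice(brood, size=k, replace=False))
            for idx, fry_id in enumerate(sampled):
                source_nest = nest
                if config.p_fry_mixed > 0 and rng.random() < config.p_fry_mixed:
                    neighbors = [
                        by_rank[r]
                        for r in (nest.rank - 1, nest.rank + 1)
                        if r in by_rank and by_rank[r].brood_fry and by_rank[r].id not in failed
                    ]
                    if neighbors:
                        source_nest = neighbors[rng.integers(0, len(neighbors))]
                        fry_id = str(rng.choice(source_nest.brood_fry))
                fry = population.fry[fry_id]
                obs_id = f"{nest.id}-S{idx + 1:02d}"
                gen_rows.append(
                    {"id": obs_id, "year": year, "role": "fry", "nest_id": nest.id}
                )
                allele_rows.append(_apply_errors(fry.alleles, panel, rates, rng))
                parentage_rows.append(
                    {
                        "offspring": obs_id,
                        "source_fry": fry.id,
                        "father": fry.father,
                        "mother": fry.mother,
                        "true_nest": fry.nest_id,
                        "observed_nest": nest.id,
                        "year": year,
                        "mixed": int(source_nest.id != nest.id),
                    }
                )

    meta = pd.DataFrame(gen_rows)
    table = GenotypeTable(
        meta["id"].tolist(),
        panel.loci,
        np.stack(allele_rows) if allele_rows else np.zeros((0, panel.n_loci, 2), int),
        meta[["year", "role", "nest_id"]],
    )
    return Observation(
        genotypes=table,
        nests=pd.DataFrame(nest_rows),
        truth_parentage=pd.DataFrame(parentage_rows),
        truth_captures=population.capture_frame(),
        truth_matings=population.matings_frame(),
    )


def simulate_study(config: SimulationConfig) -> tuple[Population, Observation]:
    """Convenience wrapper: breeding seasons followed by observation."""
    population = simulate_breeding_seasons(config)
    return population, observe(population, config)
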