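"""Relatedness-based mate choice analysis.

Pairwise genetic relatedness between reconstructed females and nesting
males is estimated with the Queller-Goodnight coefficient r, which weights
allele sharing by population allele frequencies so that r = 0 for random
pairs, ~0.5 for parent-offspring, 1 for identical genotypes, and -1 for a
maximally dissimilar pair.

Whether an observed spawning pair is unusually related is judged against a
per-female randomization null: the distribution of r between that female
and every nesting male of the year (males she had already spawned with
earlier in the season are excluded when testing later mates).  Monte-Carlo
p-values from resampling the pool (default 10,000 draws) are reported
alongside their exact enumeration counterparts; a pair is called *inbred*
when the upper-tail p is at most alpha, *outbred* for the lower tail, and
*unrelated* otherwise.

`MateDifferenceModel` tests whether multiple-mating females choose
additional mates less related than their first: the response is
d = r(female, first male) - r(female, one randomly chosen additional
male), one triad per female, modelled per year by a normal likelihood
(equivalently a one-sample t test of mean d against zero; positive
estimates mean additional males are less related).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import MISSING, GenotypeTable, LocusPanel

__all__ = [
    "qg_relatedness",
    "RelatednessResult",
    "randomization_test",
    "categorize_pairs",
    "MateDifferenceModel",
    "MateDifferenceResults",
]


def qg_relatedness(
    x: np.ndarray, y: np.ndarray, frequencies: list[dict[int, float]]
) -> float:
    """Queller-Goodnight pairwise relatedness.

    For focal genotype x = (a, b) and partner y = (c, d) at one locus,

        num_x = 0.5[I(a=c) + I(a=d)] - p_a + 0.5[I(b=c) + I(b=d)] - p_b
        den_x = 1 + I(a=b) - p_a - p_b

    and symmetrically for y as focal; r sums numerators and denominators
    over loci and both focal directions before dividing, making
    r(x, y) = r(y, x).  Loci missing in either genotype are skipped.
    Returns NaN when every locus is uninformative (zero denominator).
    """
    x = np.asarray(x)
    y = np.asarray(y)
    num = den = 0.0
    for j, freq in enumerate(frequencies):
        a, b = int(x[j, 0]), int(x[j, 1])
        c, d = int(y[j, 0]), int(y[j, 1])
        if MISSING in (a, b, c, d):
            continue
        pa, pb = freq.get(a, 0.0), freq.get(b, 0.0)
        pc, pd_ = freq.get(c, 0.0), freq.get(d, 0.0)
        num += 0.5 * ((a == c) + (a == d)) - pa + 0.5 * ((b == c) + (b == d)) - pb
        den += 1.0 + (a == b) - pa - pb
        num += 0.5 * ((c == a) + (c == b)) - pc + 0.5 * ((d == a) + (d == b)) - pd_
        den += 1.0 + (c == d) - pc - pd_
    if den == 0.0:
        return float("nan")
    return num / den


def relatedness_to_pool(
    female: np.ndarray,
    pool: GenotypeTable | np.ndarray,
    panel: LocusPanel,
    exclude_focal_counts: bool = False,
) -> np.ndarray:
    """r between one female and every male in a pool.

    With ``exclude_focal_counts`` the reference allele frequencies are
    recomputed for each pair with that male's own alleles removed from the
    counts (the small-sample bias correction; an O(1/n) adjustment).
    """
    alleles = pool.alleles if isinstance(pool, GenotypeTable) else np.asarray(pool)
    if not exclude_focal_counts:
        return np.array(
            [qg_relatedness(female, alleles[i], panel.frequencies) for i in range(len(alleles))]
        )
    # count-based frequencies so each male can be subtracted
    counts: list[dict[int, float]] = []
    totals: list[int] = []
    for j in range(panel.n_loci):
        calls = alleles[:, j, :].ravel()
        calls = calls[calls != MISSING]
        labels, cnt = np.unique(calls, return_counts=True)
        counts.append({int(a): int(c) for a, c in zip(labels, cnt)})
        totals.append(int(calls.size))
    out = np.empty(len(alleles))
    for i in range(len(alleles)):
        freqs = []
        for j in range(panel.n_loci):
            c = dict(counts[j])
            tot = totals[j]
            for k in range(2):
                a = int(alleles[i, j, k])
                if a != MISSING:
                    c[a] -= 1
                    tot -= 1
            freqs.append({a: v / tot for a, v in c.items() if v > 0} if tot else {})
        out[i] = qg_relatedness(female, alleles[i], freqs)
    return out


@dataclass
class RelatednessResult:
    """Randomization-test outcome for one female-male pair."""

    female: str
    male: str
    year: int | None
    r: float
    pool_size: int
    p_high: float  # Monte-Carlo proportion of null draws >= r
    p_low: float
    exact_p_high: float  # enumeration over the candidate pool
    exact_p_low: float
    category: str | None  # 'inbred' | 'unrelated' | 'outbred' | None
    flagged: str | None = None


def randomization_test(
    female_id: str,
    male_id: str,
    female_alleles: np.ndarray,
    pool: GenotypeTable,
    panel: LocusPanel,
    exclude: set[str] | None = None,
    n_iter: int = 10_000,
    alpha: float = 0.05,
    seed: int = 0,
    pool_floor: int = 10,
    year: int | None = None,
    null_values: np.ndarray | None = None,
) -> RelatednessResult:
    """Per-female randomization test of pairwise relatedness.

    The null distribution is r between the female and every candidate male
    of the year's pool (``exclude`` removes her earlier mates in the
    season; the focal male remains in the pool, so the exact upper-tail
    p-value of a pool maximum is 1/pool).  Monte-Carlo p-values resample
    the pool with replacement ``n_iter`` times; the exact enumeration
    values they converge to are reported alongside.  A pool smaller than
    ``pool_floor`` yields an 'underpowered' flag and no category.
    """
    exclude = exclude or set()
    keep = [i for i, m in enumerate(pool.ids) if m not in exclude]
    if male_id not in pool.ids or pool.ids.index(male_id) not in keep:
        raise ValueError(f"focal male {male_id} not in the candidate pool")
    if null_values is None:
        null_values = relatedness_to_pool(female_alleles, pool, panel)
    null = np.asarray(null_values)[keep]
    focal_idx = keep.index(pool.ids.index(male_id))
    r_obs = float(null[focal_idx])
    ok = ~np.isnan(null)
    null = null[ok]
    n_pool = int(null.size)
    if np.isnan(r_obs) or n_pool == 0:
        return RelatednessResult(
            female_id, male_id, year, r_obs, n_pool, np.nan, np.nan, np.nan, np.nan,
            None, flagged="undefined: no informative loci",
        )
    exact_hi = float((null >= r_obs).mean())
    exact_lo = float((null <= r_obs).mean())
    rng = np.random.default_rng(seed)
    draws = rng.choice(null, size=n_iter, replace=True)
    p_hi = float((draws >= r_obs).mean())
    p_lo = float((draws <= r_obs).mean())
    if n_pool < pool_floor:
        return RelatednessResult(
            female_id, male_id, year, r_obs, n_pool, p_hi, p_lo, exact_hi, exact_lo,
            None, flagged="underpowered",
        )
    if p_hi <= alpha:
        category = "inbred"
    elif p_lo <= alpha:
        category = "outbred"
    else:
        category = "unrelated"
    return RelatednessResult(
        female_id, male_id, year, r_obs, n_pool, p_hi, p_lo, exact_hi, exact_lo, category
    )


def categorize_pairs(results: list[RelatednessResult]) -> pd.DataFrame:
    """Per-year category counts, fractions and r ranges for spawning pairs."""
    rows = []
    df = pd.DataFrame(
        [
            {"year": res.year, "category": res.category, "r": res.r}
            for res in results
            if res.category is not None
        ]
    )
    if df.empty:
        return pd.DataFrame(
            columns=["year", "category", "pairs", "fraction", "r_min", "r_max"]
        )
    for year, ydf in df.groupby("year"):
        total = len(ydf)
        for cat in ("inbred", "unrelated", "outbred"):
            sel = ydf[ydf["category"] == cat]
            rows.append(
                {
                    "year": year,
                    "category": cat,
                    "pairs": len(sel),
                    "fraction": round(len(sel) / total, 3),
                    "r_min": float(sel["r"].min()) if len(sel) else np.nan,
                    "r_max": float(sel["r"].max()) if len(sel) else np.nan,
                }
            )
    return pd.DataFrame(rows)


class MateDifferenceModel:
    """Per-year model of relatedness differences between first and
    additional mates of multiple-mating females.

    Parameters
    ----------
    triads : DataFrame
        One row per multiple-mating female with columns ``female``,
        ``year``, ``r_first`` and ``r_additional`` (a list when the female
        took more than one additional mate; a single value is accepted).
    """

    def __init__(self, triads: pd.DataFrame):
        required = {"female", "year", "r_first", "r_additional"}
        if not required.issubset(triads.columns):
            raise ValueError(f"triads must have columns {sorted(required)}")
        if triads["female"].duplicated().any() and (
            triads.groupby(["female", "year"]).size() > 1
        ).any():
            raise ValueError("each female-year contributes one triad only")
        self.triads = triads.reset_index(drop=True)

    @classmethod
    def from_females(
        cls, females, male_pools: dict[int, GenotypeTable], panel_by_year: dict[int, LocusPanel]
    ) -> "MateDifferenceModel":
        """Build triads from reconstructed females with >= 2 distinct mates."""
        rows = []
        for fem in females:
            for year in fem.years:
                mates = fem.mates(year)
                distinct = list(dict.fromkeys(mates))
                if len(distinct) < 2:
                    continue
                pool = male_pools[year]
                panel = panel_by_year[year]
                cons = fem.consensus()
                r = {
                    m: qg_relatedness(cons, pool.row(m), panel.frequencies)
                    for m in distinct
                }
                rows.append(
                    {
                        "female": fem.id,
                        "year": year,
                        "r_first": r[distinct[0]],
                        "r_additional": [r[m] for m in distinct[1:]],
                    }
                )
        return cls(pd.DataFrame(rows, columns=["female", "year", "r_first", "r_additional"]))

    def fit(self, seed: int = 0) -> "MateDifferenceResults":
        """Draw one additional male per female (seeded), compute
        d = r_first - r_additional, and fit the per-year normal model."""
        rng = np.random.default_rng(seed)
        rows = []
        for _, row in self.triads.iterrows():
            extra = row["r_additional"]
            if np.isscalar(extra) or isinstance(extra, float):
                chosen = float(extra)
            else:
                extra = list(extra)
                chosen = float(extra[rng.integers(0, len(extra))])
            rows.append(
                {
                    "female": row["female"],
                    "year": row["year"],
                    "d": float(row["r_first"]) - chosen,
                }
            )
        d = pd.DataFrame(rows, columns=["female", "year", "d"])
        per_year = []
        for year, ydf in d.groupby("year"):
            n = len(ydf)
            mean = float(ydf["d"].mean())
            if n >= 2:
                se = float(ydf["d"].std(ddof=1) / np.sqrt(n))
                t = mean / se if se > 0 else 0.0
                p = float(2 * stats.t.sf(abs(t), df=n - 1)) if se > 0 else 1.0
                flag = None
            else:
                se, t, p = np.nan, np.nan, np.nan
                flag = "single triad: estimate only"
            per_year.append(
                {
                    "year": year,
                    "n": n,
                    "estimate": mean,
                    "se": se,
                    "t": t,
                    "p": p,
                    "flag": flag,
                }
            )
        return MateDifferenceResults(self, pd.DataFrame(per_year), d, seed)


@dataclass
class MateDifferenceResults:
    """Per-year estimates of mean r(first) - r(additional)."""

    model: MateDifferenceModel
    table: pd.DataFrame
    differences: pd.DataFrame
    selection_seed: int

    def summary(self) -> str:
        lines = ["Mate relatedness difference (first - additional male)"]
        lines.append("=" * 60)
        lines.append(f"{'year':<8}{'n':>4}{'estimate':>10}{'SE':>8}{'t':>8}{'p':>8}")
        for _, row in self.table.iterrows():
            lines.append(
                f"{row['year']:<8}{row['n']:>4}{row['estimate']:>10.3f}"
                f"{row['se']:>8.3f}{row['t']:>8.3f}{row['p']:>8.3f}"
            )
        lines.append(f"(additional-male selection seed: {self.selection_seed})")
        lines.append("=" * 60)
        return "\n".join(lines)


def mate_choice_analysis(
    females,
    genotypes: GenotypeTable,
    n_iter: int = 10_000,
    alpha: float = 0.05,
    seed: int = 0,
    pool_floor: int = 10,
):
    """Run the full mate-choice analysis over reconstructed females.

    For every female-year and every mate in her spawn-date order, tests the
    pair's relatedness against the year's nesting-male pool (earlier mates
    in the season excluded from the null); first-male pairs feed the
    category table and multiple-mating females feed the difference model.

    Returns ``(pair_results, category_table, diff_model)`` where
    ``diff_model`` is None when no female took two mates.
    """
    results: list[RelatednessResult] = []
    triad_rows = []
    years = sorted({c["year"] for f in females for c in f.clutches})
    pool_by_year: dict[int, GenotypeTable] = {}
    panel_by_year: dict[int, LocusPanel] = {}
    for year in years:
        pool = genotypes.select(role="male", year=year)
        pool_by_year[year] = pool
        from .genotypes import allele_frequencies

        panel_by_year[year] = allele_frequencies(pool)
    pair_idx = 0
    for fem in females:
        for year in fem.years:
            pool = pool_by_year[year]
            panel = panel_by_year[year]

            def pool_id(male: str) -> str | None:
                if male in pool.ids:
                    return male
                cand = f"{male}@{year}"
                return cand if cand in pool.ids else None

            mates = list(dict.fromkeys(fem.mates(year)))
            cons = fem.consensus()
            null_all = relatedness_to_pool(cons, pool, panel)
            r_of: dict[str, float] = {}
            for order, male in enumerate(mates):
                pid = pool_id(male)
                if pid is None:
                    continue
                prior = {pool_id(m) for m in mates[:order]} - {None}
                res = randomization_test(
                    fem.id,
                    pid,
                    cons,
                    pool,
                    panel,
                    exclude=prior,
                    n_iter=n_iter,
                    alpha=alpha,
                    seed=seed + pair_idx,
                    pool_floor=pool_floor,
                    year=year,
                    null_values=None if prior else null_all,
                )
                pair_idx += 1
                r_of[male] = res.r
                if order == 0:
                    results.append(res)
            if len(mates) >= 2 and mates[0] in r_of:
                extras = [r_of[m] for m in mates[1:] if m in r_of]
                if extras:
                    triad_rows.append(
                        {
                            "female": fem.id,
                            "year": year,
                            "r_first": r_of[mates[0]],
                            "r_additional": extras,
                        }
                    )
    table = categorize_pairs(results)
    diff_model = (
        MateDifferenceModel(
            pd.DataFrame(triad_rows, columns=["female", "year", "r_first", "r_additional"])
        )
        if triad_rows
        else None
    )
    return results, table, diff_model
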