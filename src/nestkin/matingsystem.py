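"""Mating-system summaries from a reconstructed pedigree.

Turns per-fry parentage assignments and merged female identities into the
tables a mating-system study reports: per-year counts of nests by number of
contributing females (monogamy vs polygyny), of females by number of mates
(polyandry), interannual return/skip tallies by sex, interannual mate
fidelity, and fork-length summaries of multi-mating individuals.

Counting conventions
--------------------
* The male-side unit is the assigned brood (one nest-year, all clutches
  pooled); the female-side unit is the reconstructed female-year.
* Percentages are recomputed exactly from the counts (count/total*100).
* A "skip" is any season with no observation between the first and last
  seasons an individual was observed.
* Internal consistency (class counts summing to totals, offspring sums
  matching the pedigree) is validated and mismatches are flagged rather
  than silently reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pedigree import ReconstructedFemale

__all__ = [
    "MatingSummary",
    "SizeSummary",
    "tally_mating",
    "tally_returns",
    "mate_fidelity",
    "summarize_sizes",
    "count_skips",
]


def _round_half_up(x: float, digits: int) -> float:
    scale = 10.0**digits
    return np.floor(x * scale + 0.5) / scale


def _pct(count, total, digits: int = 2) -> float:
    # half-up, matching how survey tables conventionally print percentages
    return _round_half_up(100.0 * count / total, digits) if total else 0.0


@dataclass
class MatingSummary:
    """Per-year mating-pattern and return tallies with pooled fractions."""

    male_classes: pd.DataFrame | None = None  # year x (1,2,3 females) broods+offspring
    female_classes: pd.DataFrame | None = None
    returns: pd.DataFrame | None = None
    pooled: dict = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)


def tally_mating(
    pedigree: pd.DataFrame, females: list[ReconstructedFemale]
) -> MatingSummary:
    """Tally broods by females-per-male and females by males-per-female.

    ``pedigree`` must carry one row per assigned fry with columns
    ``offspring, year, nest_id, father, female_id``.  Only assigned broods
    enter the denominators.
    """
    summary = MatingSummary()
    if len(pedigree) == 0:
        cols = ["year", "n_mates", "count", "pct", "offspring", "offspring_pct"]
        summary.male_classes = pd.DataFrame(columns=cols)
        summary.female_classes = pd.DataFrame(columns=cols)
        summary.pooled = {
            "broods_total": 0,
            "broods_single_female": 0,
            "pct_single_female": 0.0,
            "multi_mating_males": 0,
            "pct_multi_mating_males": 0.0,
            "females_total": 0,
            "multi_mating_females": 0,
            "pct_multi_mating_females": 0.0,
        }
        return summary

    male_rows = []
    for year, ydf in pedigree.groupby("year"):
        per_nest = ydf.groupby("nest_id").agg(
            n_females=("female_id", "nunique"), offspring=("offspring", "count")
        )
        total_broods = len(per_nest)
        total_off = per_nest["offspring"].sum()
        for k in (1, 2, 3):
            sel = per_nest[per_nest["n_females"].clip(upper=3) == k]
            male_rows.append(
                {
                    "year": year,
                    "n_mates": k,
                    "count": len(sel),
                    "pct": _pct(len(sel), total_broods),
                    "offspring": int(sel["offspring"].sum()),
                    "offspring_pct": _pct(sel["offspring"].sum(), total_off),
                }
            )
    summary.male_classes = pd.DataFrame(male_rows)

    female_rows = []
    fem_year: list[dict] = []
    for fem in females:
        for year in fem.years:
            n_mates = len({c["male_id"] for c in fem.clutches if c["year"] == year})
            n_off = sum(
                len(c["fry_ids"]) for c in fem.clutches if c["year"] == year
            )
            fem_year.append(
                {"female": fem.id, "year": year, "n_mates": n_mates, "offspring": n_off}
            )
    fem_df = pd.DataFrame(fem_year)
    if len(fem_df):
        for year, ydf in fem_df.groupby("year"):
            total = len(ydf)
            total_off = ydf["offspring"].sum()
            for k in (1, 2, 3):
                sel = ydf[ydf["n_mates"].clip(upper=3) == k]
                female_rows.append(
                    {
                        "year": year,
                        "n_mates": k,
                        "count": len(sel),
                        "pct": _pct(len(sel), total),
                        "offspring": int(sel["offspring"].sum()),
                        "offspring_pct": _pct(sel["offspring"].sum(), total_off),
                    }
                )
    summary.female_classes = pd.DataFrame(female_rows)

    mc, fc = summary.male_classes, summary.female_classes
    broods_total = int(mc["count"].sum())
    single_f = int(mc.loc[mc["n_mates"] == 1, "count"].sum())
    fem_total = int(fc["count"].sum()) if len(fc) else 0
    fem_multi = int(fc.loc[fc["n_mates"] > 1, "count"].sum()) if len(fc) else 0
    summary.pooled = {
        "broods_total": broods_total,
        "broods_single_female": single_f,
        "pct_single_female": _pct(single_f, broods_total, 1)
        if broods_total
        else 0.0,
        "multi_mating_males": broods_total - single_f,
        "pct_multi_mating_males": _pct(broods_total - single_f, broods_total, 1)
        if broods_total
        else 0.0,
        "females_total": fem_total,
        "multi_mating_females": fem_multi,
        "pct_multi_mating_females": _pct(fem_multi, fem_total, 1)
        if fem_total
        else 0.0,
    }

    # internal consistency: offspring sums per class must equal pedigree rows
    if int(mc["offspring"].sum()) != len(pedigree):
        summary.flags.append(
            f"male-class offspring sum {int(mc['offspring'].sum())} != "
            f"{len(pedigree)} pedigree rows"
        )
    if len(fc) and int(fc["offspring"].sum()) != len(pedigree):
        summary.flags.append(
            f"female-class offspring sum {int(fc['offspring'].sum())} != "
            f"{len(pedigree)} pedigree rows"
        )
    return summary


def count_skips(history: np.ndarray) -> int:
    """Number of unobserved seasons between the first and last observation."""
    ones = np.flatnonzero(np.asarray(history, dtype=int))
    if ones.size < 2:
        return 0
    span = np.asarray(history, dtype=int)[ones[0] : ones[-1] + 1]
    return int((span == 0).sum())


def tally_returns(captures: pd.DataFrame, years: list[int]) -> pd.DataFrame:
    """Return/skip tallies by sex, first-observation year and seasons seen.

    ``captures`` has columns ``individual``, ``sex`` and one ``y<year>``
    column per season.  For each (first year, sex, n seasons observed)
    cell, counts individuals and how many of them skipped at least one
    season between observations.
    """
    cols = [f"y{y}" for y in years]
    hist = captures[cols].to_numpy(dtype=int)
    first = np.argmax(hist == 1, axis=1)
    n_obs = hist.sum(axis=1)
    skips = np.array([count_skips(h) for h in hist])
    df = pd.DataFrame(
        {
            "sex": captures["sex"].to_numpy(),
            "first_year": [years[i] for i in first],
            "n_seasons": n_obs,
            "skipped": (skips > 0).astype(int),
        }
    )
    out = (
        df.groupby(["first_year", "sex", "n_seasons"])
        .agg(count=("skipped", "size"), skip=("skipped", "sum"))
        .reset_index()
    )
    return out


def mate_fidelity(
    females: list[ReconstructedFemale],
) -> tuple[int, list[tuple[str, str, list[int]]]]:
    """Male-female pairs that spawned together in more than one year."""
    repeats = []
    for fem in females:
        by_male: dict[str, set[int]] = {}
        for c in fem.clutches:
            # a male's per-capture id is '<male>@<year>'; strip the year so
            # interannual re-pairings are recognized
            male = c["male_id"].split("@")[0]
            by_male.setdefault(male, set()).add(c["year"])
        for male, yrs in by_male.items():
            if len(yrs) >= 2:
                repeats.append((male, fem.id, sorted(yrs)))
    return len(repeats), repeats


@dataclass
class SizeSummary:
    """Fork-length summaries of multi-mating adults, per year."""

    table: pd.DataFrame  # year, group, n, median, minimum


def summarize_sizes(
    pedigree: pd.DataFrame,
    females: list[ReconstructedFemale],
    male_lengths: dict[str, float] | pd.Series,
) -> SizeSummary:
    """Median fork length of multi-mating males and of the first males of
    multi-mating females, per year.

    ``male_lengths`` maps the male id (per-capture ids are reduced to the
    tag id before lookup) to fork length in mm; missing lengths are
    excluded and cells with no data are reported with n=0.
    """
    if isinstance(male_lengths, pd.Series):
        male_lengths = male_lengths.to_dict()

    def length_of(male_id: str) -> float | None:
        return male_lengths.get(male_id, male_lengths.get(male_id.split("@")[0]))

    rows = []
    if len(pedigree):
        for year, ydf in pedigree.groupby("year"):
            per_nest = ydf.groupby("nest_id").agg(
                n_females=("female_id", "nunique"), father=("father", "first")
            )
            multi = per_nest[per_nest["n_females"] >= 2]
            lens = [length_of(m) for m in multi["father"]]
            lens = [x for x in lens if x is not None and not np.isnan(x)]
            rows.append(
                {
                    "year": year,
                    "group": "multi_mating_males",
                    "n": len(lens),
                    "median": float(np.median(lens)) if lens else np.nan,
                    "minimum": float(np.min(lens)) if lens else np.nan,
                }
            )
    years = sorted({c["year"] for f in females for c in f.clutches})
    for year in years:
        firsts = []
        for fem in females:
            mates = fem.mates(year)
            if len(set(mates)) >= 2:
                firsts.append(mates[0])
        lens = [length_of(m) for m in firsts]
        lens = [x for x in lens if x is not None and not np.isnan(x)]
        rows.append(
            {
                "year": year,
                "group": "first_males_of_multi_mating_females",
                "n": len(lens),
                "median": float(np.median(lens)) if lens else np.nan,
                "minimum": float(np.min(lens)) if lens else np.nan,
            }
        )
    return SizeSummary(pd.DataFrame(rows))


def tally_qc(fry_labels: pd.DataFrame, broods: pd.DataFrame) -> pd.DataFrame:
    """Pedigree quality screen tallies, per year.

    Percentages use the year's grand totals (all broods, all fry) as
    denominators.  Rows: assigned broods with their offspring; the mixed /
    unknown / mis-assigned fry *within* assigned broods; and excluded
    broods by reason with their offspring.
    """
    rows = []
    fry_of = fry_labels.groupby("nest_id").size()
    for year in sorted(broods["year"].unique()):
        yb = broods[broods["year"] == year]
        yf = fry_labels[fry_labels["year"] == year]
        grand_broods = len(yb)
        grand_fry = len(yf)
        assigned = yb[yb["verdict"] == "assigned"]
        in_assigned = yf[yf["nest_id"].isin(set(assigned["nest_id"]))]
        own_pair_fry = int((in_assigned["label"] == "assigned").sum())
        rows.append(
            {
                "year": year,
                "row": "assigned",
                "broods": len(assigned),
                "broods_pct": _pct(len(assigned), grand_broods),
                "offspring": own_pair_fry,
                "offspring_pct": _pct(own_pair_fry, grand_fry),
            }
        )
        for label in ("mixed", "unknown", "mis_assigned"):
            n = int((in_assigned["label"] == label).sum())
            rows.append(
                {
                    "year": year,
                    "row": f"fry_{label}",
                    "broods": 0,
                    "broods_pct": np.nan,
                    "offspring": n,
                    "offspring_pct": _pct(n, grand_fry),
                }
            )
        rows.append(
            {
                "year": year,
                "row": "assigned_total",
                "broods": len(assigned),
                "broods_pct": _pct(len(assigned), grand_broods),
                "offspring": len(in_assigned),
                "offspring_pct": _pct(len(in_assigned), grand_fry),
            }
        )
        for reason in ("no_male", "mixed", "unknown", "mis_assigned"):
            sel = yb[yb["verdict"] == f"excluded_{reason}"]
            n_off = int(fry_of.reindex(sel["nest_id"]).fillna(0).sum())
            rows.append(
                {
                    "year": year,
                    "row": f"excluded_{reason}",
                    "broods": len(sel),
                    "broods_pct": _pct(len(sel), grand_broods),
                    "offspring": n_off,
                    "offspring_pct": _pct(n_off, grand_fry),
                }
            )
        rows.append(
            {
                "year": year,
                "row": "grand_total",
                "broods": grand_broods,
                "broods_pct": 100.0,
                "offspring": grand_fry,
                "offspring_pct": 100.0,
            }
        )
    return pd.DataFrame(rows)
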