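"""Packaged synthetic example dataset shaped like a three-season survey.

These builders construct, entirely in code, a pedigree / capture-history /
pair-category dataset whose per-year class counts equal the headline
summaries of a large smallmouth-bass nesting survey (three seasons of
fry-sampled nests plus a fourth males-only season): ~400 assigned broods,
~430 reconstructed female-years, 449 tagged males.  The genotypes behind
those summaries are not shipped — every individual here is synthetic and
only the *counts* are calibrated — so the dataset exercises exactly the
tally arithmetic: class counts, percentages, pooled fractions, return and
skip tallies, and relatedness-category tables.

Where the published summaries are internally inconsistent (one year's
class offspring counts disagreeing with their own percentages and total),
the self-consistent counts implied by the totals are used.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import maximum_flow

from .matechoice import RelatednessResult
from .pedigree import ReconstructedFemale

__all__ = [
    "survey_summary_pedigree",
    "survey_summary_captures",
    "survey_summary_qc",
    "survey_summary_pair_results",
    "MALE_CLASS_COUNTS",
    "FEMALE_CLASS_COUNTS",
]

# broods per nest-class (1, 2, 3 contributing females) and their offspring
MALE_CLASS_COUNTS = {
    2012: {"broods": (128, 20, 5), "offspring": (1364, 219, 51)},
    2013: {"broods": (149, 23, 3), "offspring": (1603, 251, 32)},
    2014: {"broods": (64, 7, 1), "offspring": (720, 89, 10)},
}
# female-years per mate-count class and their offspring
FEMALE_CLASS_COUNTS = {
    2012: {"females": (165, 9, 0), "offspring": (1490, 144, 0)},
    2013: {"females": (176, 14, 0), "offspring": (1630, 256, 0)},
    2014: {"females": (50, 14, 1), "offspring": (515, 277, 27)},
}

# (first year, sex) -> per-seasons-observed (count, of which skipped)
RETURN_COUNTS = {
    (2011, "M"): [(45, 0), (19, 4), (17, 10), (6, 0)],
    (2012, "M"): [(95, 0), (66, 1), (15, 0)],
    (2012, "F"): [(157, 0), (15, 3), (4, 0)],
    (2013, "M"): [(123, 0), (22, 0)],
    (2013, "F"): [(164, 0), (8, 0)],
    (2014, "M"): [(41, 0)],
    (2014, "F"): [(50, 0)],
}

# year -> {category: (pairs, r_min, r_max)}
PAIR_CATEGORY_COUNTS = {
    2012: {
        "inbred": (8, 0.374, 0.672),
        "unrelated": (154, -0.475, 0.372),
        "outbred": (13, -0.501, 0.215),
    },
    2013: {
        "inbred": (12, 0.241, 0.489),
        "unrelated": (170, -0.538, 0.419),
        "outbred": (8, -0.612, -0.294),
    },
    2014: {
        "inbred": (5, 0.197, 0.439),
        "unrelated": (58, -0.417, 0.383),
        "outbred": (2, -0.439, -0.325),
    },
}

# year -> {row: (broods, offspring)}; 'excluded_*' rows are whole broods,
# 'fry_*' rows are fry inside assigned broods
QC_COUNTS = {
    2012: {
        "assigned": (153, 1634),
        "fry_mixed": 28,
        "fry_unknown": 33,
        "fry_mis_assigned": 24,
        "excluded_no_male": (4, 44),
        "excluded_mixed": (5, 59),
        "excluded_unknown": (4, 46),
        "excluded_mis_assigned": (3, 34),
    },
    2013: {
        "assigned": (175, 1886),
        "fry_mixed": 58,
        "fry_unknown": 31,
        "fry_mis_assigned": 30,
        "excluded_no_male": (5, 59),
        "excluded_mixed": (4, 48),
        "excluded_unknown": (4, 44),
        "excluded_mis_assigned": (3, 35),
    },
    2014: {
        "assigned": (72, 819),
        "fry_mixed": 11,
        "fry_unknown": 12,
        "fry_mis_assigned": 7,
        "excluded_no_male": (2, 23),
        "excluded_mixed": (1, 12),
        "excluded_unknown": (2, 24),
        "excluded_mis_assigned": (1, 12),
    },
}


def _clutch_fry_allocation(
    cell_clutches: dict[tuple[int, int], int],
    row_offspring: tuple[int, ...],
    col_offspring: tuple[int, ...],
    row_clutches: tuple[int, ...],
    col_clutches: tuple[int, ...],
) -> dict[tuple[int, int], int]:
    """Integer fry totals per (nest-class, female-class) cell matching both
    class-offspring margins, with every clutch holding at least one fry.

    Solved as a transportation problem on the cells that actually contain
    clutches, via integral max-flow on the surplus above the 1-fry floor.
    """
    rows = [k for k in range(3) if row_clutches[k]]
    cols = [j for j in range(3) if col_clutches[j]]
    R = {k: row_offspring[k] - row_clutches[k] for k in rows}
    C = {j: col_offspring[j] - col_clutches[j] for j in cols}
    if any(v < 0 for v in R.values()) or any(v < 0 for v in C.values()):
        raise ValueError("offspring margins below one fry per clutch")
    # nodes: 0 = source, 1..len(rows) rows, then cols, then sink
    nr, nc = len(rows), len(cols)
    n_nodes = 2 + nr + nc
    src, sink = 0, n_nodes - 1
    cap = np.zeros((n_nodes, n_nodes), dtype=np.int64)
    for a, k in enumerate(rows):
        cap[src, 1 + a] = R[k]
    for b, j in enumerate(cols):
        cap[1 + nr + b, sink] = C[j]
    big = 10**9
    for a, k in enumerate(rows):
        for b, j in enumerate(cols):
            if cell_clutches.get((k, j), 0) > 0:
                cap[1 + a, 1 + nr + b] = big
    res = maximum_flow(csr_matrix(cap), src, sink)
    if res.flow_value != sum(R.values()):
        raise ValueError("fry allocation infeasible on the clutch support")
    flow = res.flow.toarray()
    out = {}
    for a, k in enumerate(rows):
        for b, j in enumerate(cols):
            n_cl = cell_clutches.get((k, j), 0)
            if n_cl:
                out[(k, j)] = n_cl + int(flow[1 + a, 1 + nr + b])
    return out


def survey_summary_pedigree() -> tuple[pd.DataFrame, list[ReconstructedFemale]]:
    """Pedigree rows and reconstructed females realizing the published
    per-year mating-class counts (and class offspring totals) exactly.

    Returns ``(pedigree, females)`` ready for ``tally_mating``.
    """
    ped_rows: list[dict] = []
    females: list[ReconstructedFemale] = []
    fem_counter = 0
    for year in sorted(MALE_CLASS_COUNTS):
        mc = MALE_CLASS_COUNTS[year]
        fc = FEMALE_CLASS_COUNTS[year]
        # nests with their female-slot capacity
        nests: list[dict] = []
        for k, n_k in enumerate(mc["broods"]):
            for i in range(n_k):
                nid = f"N{year}-{len(nests) + 1:03d}"
                nests.append(
                    {"nest_id": nid, "class": k, "capacity": k + 1, "slots": []}
                )
        # female demands, multi-mate females first so they can reach
        # distinct nests
        demands: list[tuple[str, int]] = []
        for j in (2, 1, 0):
            for _ in range(fc["females"][j]):
                fem_counter += 1
                demands.append((f"SF{fem_counter:04d}", j))
        free = [n for n in nests if len(n["slots"]) < n["capacity"]]
        cursor = 0
        assignment: dict[str, list[dict]] = {}
        for fem_id, j in demands:
            chosen: list[dict] = []
            tries = 0
            while len(chosen) < j + 1:
                nest = free[cursor % len(free)]
                cursor += 1
                tries += 1
                if nest in chosen or len(nest["slots"]) >= nest["capacity"]:
                    if tries > 10 * len(free):
                        raise RuntimeError("slot assignment failed")
                    continue
                nest["slots"].append(fem_id)
                chosen.append(nest)
            assignment[fem_id] = chosen
        fem_class = dict(demands)
        cell_clutches: dict[tuple[int, int], int] = {}
        for fem_id, chosen in assignment.items():
            for nest in chosen:
                key = (nest["class"], fem_class[fem_id])
                cell_clutches[key] = cell_clutches.get(key, 0) + 1
        cell_fry = _clutch_fry_allocation(
            cell_clutches,
            mc["offspring"],
            fc["offspring"],
            tuple(
                (k + 1) * n for k, n in enumerate(mc["broods"])
            ),  # clutches per nest class
            tuple((j + 1) * n for j, n in enumerate(fc["females"])),
            # NB: clutches per class, not broods
        )
        # spread each cell's fry over its clutches (>= 1 each)
        remaining = dict(cell_fry)
        clutch_sizes: dict[tuple[str, str], int] = {}
        cell_members: dict[tuple[int, int], list[tuple[str, str]]] = {}
        for fem_id, chosen in assignment.items():
            for nest in chosen:
                key = (nest["class"], fem_class[fem_id])
                cell_members.setdefault(key, []).append((nest["nest_id"], fem_id))
        for key, members in cell_members.items():
            total = remaining[key]
            n_cl = len(members)
            base = total // n_cl
            extra = total - base * n_cl
            for idx, member in enumerate(members):
                clutch_sizes[member] = base + (1 if idx < extra else 0)
        # emit pedigree rows and female objects
        nest_rank = {n["nest_id"]: i + 1 for i, n in enumerate(nests)}
        for fem_id, chosen in assignment.items():
            clutches = []
            for nest in chosen:
                n_fry = clutch_sizes[(nest["nest_id"], fem_id)]
                fry_ids = [
                    f"{nest['nest_id']}-{fem_id}-{i + 1:02d}" for i in range(n_fry)
                ]
                for fry in fry_ids:
                    ped_rows.append(
                        {
                            "offspring": fry,
                            "year": year,
                            "nest_id": nest["nest_id"],
                            "father": f"{nest['nest_id']}-male",
                            "female_id": fem_id,
                            "qc_label": "assigned",
                        }
                    )
                clutches.append(
                    {
                        "year": year,
                        "nest_id": nest["nest_id"],
                        "male_id": f"{nest['nest_id']}-male",
                        "spawn_day": nest_rank[nest["nest_id"]],
                        "rank": nest_rank[nest["nest_id"]],
                        "fry_ids": fry_ids,
                    }
                )
            clutches.sort(key=lambda c: (c["year"], c["spawn_day"]))
            for order, c in enumerate(clutches, start=1):
                c["mate_order"] = order
            females.append(ReconstructedFemale(fem_id, [], clutches))
    return pd.DataFrame(ped_rows), females


def survey_summary_captures() -> tuple[pd.DataFrame, list[int]]:
    """Capture histories realizing the published return/skip tallies.

    Returns ``(captures, years)`` for ``tally_returns`` /  the CJS model.
    """
    years = [2011, 2012, 2013, 2014]
    rows = []
    counter = 0
    for (first, sex), cells in RETURN_COUNTS.items():
        f = years.index(first)
        for n_seasons_idx, (count, skip) in enumerate(cells):
            n_seasons = n_seasons_idx + 1
            for i in range(count):
                h = np.zeros(len(years), dtype=int)
                span = len(years) - f
                if i < skip:
                    # place the observations with one internal gap
                    occ = [f] + list(range(f + 2, f + 2 + n_seasons - 1))
                    if occ[-1] >= len(years):  # fall back: gap in the middle
                        occ = list(range(f, f + n_seasons + 1))
                        occ.remove(f + 1)
                else:
                    occ = list(range(f, f + n_seasons))
                h[occ] = 1
                assert h.sum() == n_seasons and h[f] == 1
                counter += 1
                rows.append(
                    {
                        "individual": f"{sex}{counter:04d}",
                        "sex": sex,
                        **{f"y{y}": int(h[t]) for t, y in enumerate(years)},
                    }
                )
    return pd.DataFrame(rows), years


def survey_summary_qc() -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fry QC labels and brood verdicts realizing the published pedigree
    quality screen (assigned/mixed/unknown/mis-assigned, excluded broods).

    Returns ``(fry_labels, broods)`` shaped like the outputs of
    ``categorize_assignments`` / ``brood_categories``.
    """
    fry_rows, brood_rows = [], []
    for year, counts in QC_COUNTS.items():
        n_assigned, off_assigned = counts["assigned"]
        special = {
            "mixed": counts["fry_mixed"],
            "unknown": counts["fry_unknown"],
            "mis_assigned": counts["fry_mis_assigned"],
        }
        n_special = sum(special.values())
        per_brood = np.full(n_assigned, (off_assigned + n_special) // n_assigned)
        per_brood[: (off_assigned + n_special) - per_brood.sum()] += 1
        labels = (
            ["mixed"] * special["mixed"]
            + ["unknown"] * special["unknown"]
            + ["mis_assigned"] * special["mis_assigned"]
        )
        li = 0
        for b in range(n_assigned):
            nid = f"Q{year}-{b + 1:03d}"
            n_fry = int(per_brood[b])
            for i in range(n_fry):
                if i > 0 and li < len(labels):  # keep >=1 assigned fry per brood
                    label = labels[li]
                    li += 1
                else:
                    label = "assigned"
                fry_rows.append(
                    {
                        "offspring": f"{nid}-{i + 1:02d}",
                        "nest_id": nid,
                        "year": year,
                        "label": label,
                    }
                )
            brood_rows.append(
                {"nest_id": nid, "year": year, "verdict": "assigned", "n_fry": n_fry}
            )
        assert li == len(labels)
        for reason in ("no_male", "mixed", "unknown", "mis_assigned"):
            n_b, n_off = counts[f"excluded_{reason}"]
            per = np.full(n_b, n_off // n_b)
            per[: n_off - per.sum()] += 1
            for b in range(n_b):
                nid = f"Q{year}-X{reason}-{b + 1}"
                label = reason if reason != "no_male" else "unknown"
                for i in range(int(per[b])):
                    fry_rows.append(
                        {
                            "offspring": f"{nid}-{i + 1:02d}",
                            "nest_id": nid,
                            "year": year,
                            "label": label,
                        }
                    )
                brood_rows.append(
                    {
                        "nest_id": nid,
                        "year": year,
                        "verdict": f"excluded_{reason}",
                        "n_fry": int(per[b]),
                    }
                )
    return pd.DataFrame(fry_rows), pd.DataFrame(brood_rows)


def survey_summary_pair_results(seed: int = 0) -> list[RelatednessResult]:
    """Pair-level relatedness results realizing the published per-year
    category counts and r ranges (r values synthetic within each range)."""
    rng = np.random.default_rng(seed)
    results = []
    idx = 0
    for year, cats in PAIR_CATEGORY_COUNTS.items():
        for cat, (n, r_min, r_max) in cats.items():
            for i in range(n):
                idx += 1
                if n == 1:
                    r = r_min
                elif i == 0:
                    r = r_min
                elif i == 1:
                    r = r_max
                else:
                    r = float(rng.uniform(r_min, r_max))
                p_hi = 0.01 if cat == "inbred" else 0.5
                p_lo = 0.01 if cat == "outbred" else 0.5
                results.append(
                    RelatednessResult(
                        female=f"PF{idx:04d}",
                        male=f"PM{idx:04d}",
                        year=year,
                        r=r,
                        pool_size=150,
                        p_high=p_hi,
                        p_low=p_lo,
                        exact_p_high=p_hi,
                        exact_p_low=p_lo,
                        category=cat,
                    )
                )
    return results
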