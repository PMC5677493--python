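"""Pedigree reconstruction for known-father, unsampled-mother broods.

The design of a guardian-male nesting study pins down half the pedigree in
the field: each sampled brood has a known candidate father (the nest's
guardian male), while mothers are never handled.  Reconstruction therefore
reduces to four steps, implemented here without any stochastic search:

1. **Paternity confirmation** — allele-sharing exclusion between each fry
   and its nest's male, tolerating a small number of mismatching loci to
   absorb genotyping error (`check_paternity`).
2. **Maternal sibship partitioning** — split the father-compatible fry of
   a nest into the minimum number of maternal full-sib groups whose
   (unknown) maternal genotypes can jointly explain every fry's
   non-paternal alleles; ties between minimal partitions are broken by the
   Hardy-Weinberg likelihood of the implied maternal genotypes
   (`partition_maternal_sibships`).  The search is exact branch-and-bound
   with a node budget and a greedy fallback.
3. **Female merging** — reconstructed maternal genotypes (kept as per-locus
   constraint sets, not point estimates) are matched across nests and
   years to recover individual females, their within-season mate order by
   spawn date, and their interannual capture histories (`merge_females`).
4. **QC labelling** — every fry is classified as assigned / mixed /
   unknown / mis-assigned from its compatibility with its own, adjacent,
   and non-adjacent nests' males; broods inherit the exclusion categories
   of a field-study quality screen (`categorize_assignments`).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeTable, LocusPanel, allele_frequencies

__all__ = [
    "PaternityCheck",
    "MaternalSibPartition",
    "ReconstructedFemale",
    "PedigreeResult",
    "check_paternity",
    "maternal_constraints",
    "partition_maternal_sibships",
    "merge_females",
    "categorize_assignments",
    "reconstruct_pedigree",
]

WILDCARD = 0  # unconstrained slot in a maternal-pair pattern


# ---------------------------------------------------------------------------
# paternity


def exclusion_counts(
    fry_alleles: np.ndarray, male_alleles: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-fry count of loci sharing no allele with the male.

    ``fry_alleles`` is (n_fry, n_loci, 2); ``male_alleles`` is (n_loci, 2).
    Loci missing in either genotype are not compared.  Returns the
    exclusion counts and the per-fry number of jointly scored loci.
    """
    fry = np.atleast_3d(fry_alleles)
    male = np.asarray(male_alleles)
    fry_ok = (fry != MISSING).all(axis=2)
    male_ok = (male != MISSING).all(axis=1)
    share = (
        (fry[:, :, 0] == male[:, 0])
        | (fry[:, :, 0] == male[:, 1])
        | (fry[:, :, 1] == male[:, 0])
        | (fry[:, :, 1] == male[:, 1])
    )
    scored = fry_ok & male_ok[None, :]
    excl = (~share & scored).sum(axis=1)
    return excl, scored.sum(axis=1)


@dataclass
class PaternityCheck:
    """Exclusion-based paternity verdicts for one brood."""

    nest_id: str
    male_id: str | None
    fry_ids: list[str]
    exclusions: np.ndarray
    scored_loci: np.ndarray
    tolerance: int

    @property
    def verdicts(self) -> list[str]:
        return [
            "compatible" if e <= self.tolerance else "excluded" for e in self.exclusions
        ]

    @property
    def compatible_ids(self) -> list[str]:
        return [f for f, e in zip(self.fry_ids, self.exclusions) if e <= self.tolerance]

    @property
    def brood_verdict(self) -> str:
        if self.male_id is None:
            return "no_male"
        return "confirmed" if self.compatible_ids else "all_excluded"


def check_paternity(
    male_alleles: np.ndarray | None,
    fry_ids: list[str],
    fry_alleles: np.ndarray,
    nest_id: str = "",
    male_id: str | None = None,
    tolerance: int = 2,
) -> PaternityCheck:
    """Confirm the guardian male's paternity of each fry by exclusion.

    A fry is *compatible* when the number of loci at which it shares no
    allele with the male does not exceed ``tolerance`` (default 2 of 20,
    sized so that genotyping error almost never excludes a true offspring
    while unrelated fry are excluded at many loci).
    """
    if male_alleles is None:
        n = len(fry_ids)
        return PaternityCheck(
            nest_id, None, list(fry_ids), np.zeros(n, int), np.zeros(n, int), tolerance
        )
    excl, scored = exclusion_counts(fry_alleles, male_alleles)
    return PaternityCheck(nest_id, male_id, list(fry_ids), excl, scored, tolerance)


# ---------------------------------------------------------------------------
# maternal constraints and sibship partitioning


def maternal_constraints(
    fry_alleles: np.ndarray, father_alleles: np.ndarray | None
) -> list[list[frozenset[int] | None]]:
    """Per fry and locus, the set of alleles the mother may have transmitted.

    Subtracting one paternal contribution from the fry's allele pair leaves
    either a forced maternal allele (singleton set), an ambiguous pair
    (both fry alleles also occur in the father), or no information
    (``None``: locus missing, or paternal mismatch already attributed to
    genotyping error).
    """
    fry = np.atleast_3d(fry_alleles)
    out: list[list[frozenset | None]] = []
    n_loci = fry.shape[1]
    for i in range(fry.shape[0]):
        row: list[frozenset | None] = []
        for j in range(n_loci):
            a, b = int(fry[i, j, 0]), int(fry[i, j, 1])
            if a == MISSING or b == MISSING:
                row.append(None)
                continue
            if father_alleles is None or MISSING in father_alleles[j]:
                row.append(frozenset({a}) if a == b else frozenset({a, b}))
                continue
            fa = set(int(x) for x in father_alleles[j])
            a_in, b_in = a in fa, b in fa
            if a == b:
                row.append(frozenset({a}) if a_in else None)
            elif a_in and b_in:
                row.append(frozenset({a, b}))
            elif a_in:
                row.append(frozenset({b}))
            elif b_in:
                row.append(frozenset({a}))
            else:
                row.append(None)  # paternal mismatch: error locus
        out.append(row)
    return out


def _covering_pairs(sets: list[frozenset[int]]) -> list[tuple[int, int]]:
    """All maternal allele-pair patterns covering every constraint set.

    Patterns use 0 (WILDCARD) for a slot the data do not constrain:
    ``(a, 0)`` means 'one maternal allele is a, the other is anything'.
    Returns an empty list when no diploid genotype can satisfy the sets.
    """
    if not sets:
        return [(WILDCARD, WILDCARD)]
    alleles = sorted(set().union(*sets))
    pairs: list[tuple[int, int]] = []
    # single allele covering everything -> second slot free
    full_cover = [w for w in alleles if all(w in s for s in sets)]
    pairs.extend((w, WILDCARD) for w in full_cover)
    for w1, w2 in itertools.combinations(alleles, 2):
        if w1 in full_cover or w2 in full_cover:
            continue  # subsumed by a wildcard pattern
        if all(w1 in s or w2 in s for s in sets):
            pairs.append((w1, w2))
    return pairs


def _patterns_compatible(p: tuple[int, int], q: tuple[int, int]) -> bool:
    """Can one concrete maternal genotype satisfy both patterns?"""
    pa = {x for x in p if x != WILDCARD}
    qa = {x for x in q if x != WILDCARD}
    if not pa or not qa:
        return True
    if len(pa) == 2 and len(qa) == 2:
        return pa == qa
    if len(pa) == 1 and len(qa) == 1:
        return True  # (a,*) vs (c,*): genotype {a,c} works
    small, big = (pa, qa) if len(pa) == 1 else (qa, pa)
    return next(iter(small)) in big


def pattern_sets_compatible(
    ps: list[tuple[int, int]], qs: list[tuple[int, int]]
) -> bool:
    return any(_patterns_compatible(p, q) for p in ps for q in qs)


@dataclass
class _Group:
    members: list[int]
    # per locus: list of distinct constraint sets accumulated so far
    sets: list[list[frozenset[int]]]
    # per member: loci dropped for that fry (charged genotyping error)
    dropped: dict[int, list[int]]

    def clone(self) -> "_Group":
        return _Group(
            list(self.members),
            [list(s) for s in self.sets],
            {k: list(v) for k, v in self.dropped.items()},
        )


def _try_add(group: _Group, fry_idx: int, cons: list, tolerance: int) -> _Group | None:
    """Add a fry to a group, dropping up to ``tolerance`` conflicting loci
    (charged to the joining fry as genotyping-error loci)."""
    g = group.clone()
    conflicts: list[int] = []
    for j, c in enumerate(cons):
        if c is None or c in g.sets[j]:
            continue
        trial = g.sets[j] + [c]
        if _covering_pairs(trial):
            g.sets[j] = trial
        else:
            conflicts.append(j)
            if len(conflicts) > tolerance:
                return None
    g.members.append(fry_idx)
    if conflicts:
        g.dropped[fry_idx] = conflicts
    return g


@dataclass
class MaternalSibPartition:
    """Minimal maternal full-sib partition of one brood."""

    nest_id: str
    groups: list[list[str]]  # fry ids per maternal group
    patterns: list[list[list[tuple[int, int]]]]  # per group, per locus
    log_likelihoods: list[float]
    exact: bool  # False when the greedy fallback was used
    dropped_loci: dict[str, list[int]] = field(default_factory=dict)

    @property
    def n_mothers(self) -> int:
        return len(self.groups)


def _group_loglik(sets: list[list[frozenset[int]]], panel: LocusPanel | None) -> float:
    """Max Hardy-Weinberg log-likelihood of a maternal genotype satisfying
    the group's constraints; unconstrained loci contribute 0."""
    if panel is None:
        return 0.0
    ll = 0.0
    for j, s in enumerate(sets):
        if not s:
            continue
        freq = panel.frequencies[j]

        def pair_lp(p: tuple[int, int]) -> float:
            a, b = p
            if a == WILDCARD and b == WILDCARD:
                return 0.0
            pa = freq.get(a, 1e-4)
            if b == WILDCARD:
                return float(np.log(pa))  # marginal prob of carrying a (~2p)
            pb = freq.get(b, 1e-4)
            if a == b:
                return float(np.log(pa * pb))
            return float(np.log(2 * pa * pb))

        pairs = _covering_pairs(s)
        ll += max(pair_lp(p) for p in pairs)
    return ll


def partition_maternal_sibships(
    fry_ids: list[str],
    fry_alleles: np.ndarray,
    father_alleles: np.ndarray | None,
    nest_id: str = "",
    tolerance: int = 0,
    panel: LocusPanel | None = None,
    node_budget: int = 1_000_000,
) -> MaternalSibPartition:
    """Partition a brood's father-compatible fry into maternal sib groups.

    Finds the minimum number of mothers whose diploid genotypes can jointly
    explain every fry's maternal allele constraints, allowing up to
    ``tolerance`` error loci per fry; among minimal partitions the one
    maximizing the Hardy-Weinberg likelihood of the implied maternal
    genotypes is returned.  Branch-and-bound over fry in input order
    (deterministic); beyond ``node_budget`` search nodes a greedy first-fit
    partition is returned with a warning and flagged ``exact=False``.
    """
    n = len(fry_ids)
    if n == 0:
        return MaternalSibPartition(nest_id, [], [], [], True)
    cons = maternal_constraints(fry_alleles, father_alleles)

    # greedy first-fit gives the initial upper bound (and the fallback)
    def greedy() -> list[_Group]:
        groups: list[_Group] = []
        n_loci = len(cons[0])
        for i in range(n):
            for g in groups:
                added = _try_add(g, i, cons[i], tolerance)
                if added is not None:
                    g.members = added.members
                    g.sets = added.sets
                    g.dropped = added.dropped
                    break
            else:
                g = _Group([], [[] for _ in range(n_loci)], {})
                added = _try_add(g, i, cons[i], tolerance)
                groups.append(added if added is not None else g)
        return groups

    greedy_groups = greedy()
    best_k = len(greedy_groups)
    best: list[_Group] = greedy_groups
    best_ll = sum(_group_loglik(g.sets, panel) for g in greedy_groups)
    nodes = 0
    exhausted = False

    def search(i: int, groups: list[_Group]) -> None:
        nonlocal nodes, best_k, best, best_ll, exhausted
        if exhausted:
            return
        nodes += 1
        if nodes > node_budget:
            exhausted = True
            return
        if i == n:
            k = len(groups)
            ll = sum(_group_loglik(g.sets, panel) for g in groups)
            if k < best_k or (k == best_k and ll > best_ll):
                best_k, best, best_ll = k, [g.clone() for g in groups], ll
            return
        if len(groups) > best_k:
            return
        for g_idx in range(len(groups)):
            added = _try_add(groups[g_idx], i, cons[i], tolerance)
            if added is not None:
                saved = groups[g_idx]
                groups[g_idx] = added
                search(i + 1, groups)
                groups[g_idx] = saved
        if len(groups) + 1 <= best_k:
            n_loci = len(cons[0])
            g = _Group([], [[] for _ in range(n_loci)], {})
            added = _try_add(g, i, cons[i], tolerance)
            if added is not None:
                groups.append(added)
                search(i + 1, groups)
                groups.pop()

    search(0, [])
    if exhausted:
        warnings.warn(
            f"nest {nest_id}: partition search exceeded node budget "
            f"({node_budget}); using greedy partition"
        )
        best = greedy_groups
    order = sorted(range(len(best)), key=lambda g: best[g].members[0])
    best = [best[g] for g in order]
    dropped = {
        fry_ids[i]: loci for g in best for i, loci in g.dropped.items()
    }
    return MaternalSibPartition(
        nest_id=nest_id,
        groups=[[fry_ids[i] for i in g.members] for g in best],
        patterns=[[_covering_pairs(s) for s in g.sets] for g in best],
        log_likelihoods=[_group_loglik(g.sets, panel) for g in best],
        exact=not exhausted,
        dropped_loci=dropped,
    )


# ---------------------------------------------------------------------------
# merging reconstructed females


@dataclass
class ReconstructedFemale:
    """A female recovered by matching maternal genotypes across nests/years."""

    id: str
    patterns: list[list[tuple[int, int]]]  # per-locus maternal-pair patterns
    clutches: list[dict]  # year, nest_id, male_id, spawn_day, rank, fry_ids, mate_order

    @property
    def years(self) -> list[int]:
        return sorted({c["year"] for c in self.clutches})

    def mates(self, year: int) -> list[str]:
        return [
            c["male_id"]
            for c in sorted(
                (c for c in self.clutches if c["year"] == year),
                key=lambda c: c["mate_order"],
            )
        ]

    def consensus(self) -> np.ndarray:
        """(n_loci, 2) point genotype: first pattern per locus, 0=unresolved."""
        return np.array([p[0] if p else (0, 0) for p in self.patterns], dtype=np.int64)


def _pattern_mismatch(
    a: list[list[tuple[int, int]]], b: list[list[tuple[int, int]]]
) -> tuple[int, int]:
    """(#incompatible loci, #jointly informative loci) for two females."""
    mism = shared = 0
    for pa, pb in zip(a, b):
        info_a = any(x != WILDCARD for p in pa for x in p) if pa else False
        info_b = any(x != WILDCARD for p in pb for x in p) if pb else False
        if not (info_a and info_b):
            continue
        shared += 1
        if not pattern_sets_compatible(pa, pb):
            mism += 1
    return mism, shared


def _merge_pattern_sets(
    a: list[list[tuple[int, int]]],
    b: list[list[tuple[int, int]]],
    a_weight: int,
    b_weight: int,
) -> list[list[tuple[int, int]]]:
    """Per-locus consensus of two females' patterns: the mutually
    compatible subset where one exists, otherwise the better-supported
    side's patterns."""
    out = []
    for pa, pb in zip(a, b):
        joint = [p for p in pa if any(_patterns_compatible(p, q) for q in pb)]
        if joint:
            out.append(joint)
        else:
            out.append(pa if a_weight >= b_weight else pb)
    return out


def merge_females(
    partitions: list[MaternalSibPartition],
    nest_info: pd.DataFrame,
    max_mismatch: int = 2,
    min_shared: int = 10,
) -> tuple[list[ReconstructedFemale], list[str]]:
    """Merge maternal sib groups across nests and years into females.

    Two reconstructed maternal genotypes merge when their per-locus
    constraint patterns are compatible at all but at most ``max_mismatch``
    jointly informative loci (and at least ``min_shared`` loci are jointly
    informative).  Candidate merges are applied best-first (fewest
    mismatches, most shared loci); a candidate whose two sides are already
    incompatible with each other's clusters is skipped, and exact ties
    between conflicting alternatives are left unmerged and logged.

    ``nest_info`` must be indexed by nest_id with columns ``year``,
    ``male_id``, ``spawn_day``, ``shoreline_rank``.

    Returns the females (clutches ordered by spawn date; ties broken by
    shoreline rank then nest id) and a log of skipped ambiguous merges.
    """
    groups: list[dict] = []
    for part in partitions:
        info = nest_info.loc[part.nest_id]
        for g_idx, fry in enumerate(part.groups):
            groups.append(
                {
                    "nest_id": part.nest_id,
                    "year": int(info["year"]),
                    "male_id": str(info["male_id"]),
                    "spawn_day": int(info["spawn_day"]),
                    "rank": int(info["shoreline_rank"]),
                    "fry_ids": list(fry),
                    "patterns": part.patterns[g_idx],
                }
            )
    n = len(groups)
    log: list[str] = []
    if n == 0:
        return [], log

    # vectorized screen on point consensus before the exact pattern check
    cons = np.stack(
        [
            np.array([p[0] if p else (0, 0) for p in g["patterns"]], dtype=np.int64)
            for g in groups
        ]
    )
    wild = cons == WILDCARD
    any_wild = wild.any(axis=2)
    candidates: list[tuple[int, int, int]] = []
    slack = 4  # consensus disagreement an ambiguous locus can introduce
    chunk = 256
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        A = cons[lo:hi]  # (m, L, 2)
        share = np.zeros((hi - lo, n, cons.shape[1]), dtype=bool)
        for i_a in range(2):
            for i_b in range(2):
                share |= A[:, None, :, i_a] == cons[None, :, :, i_b]
        share |= any_wild[lo:hi, None, :] | any_wild[None, :, :]
        mism = (~share).sum(axis=2)
        for i_loc, j in zip(*np.nonzero(mism <= max_mismatch + slack)):
            i = lo + int(i_loc)
            if i < j:
                candidates.append((i, int(j), int(mism[i_loc, j])))

    edges = []
    for i, j, _ in candidates:
        mism, shared = _pattern_mismatch(groups[i]["patterns"], groups[j]["patterns"])
        if shared >= min_shared and mism <= max_mismatch:
            edges.append((mism, -shared, i, j))
    edges.sort()

    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    profiles = {i: groups[i]["patterns"] for i in range(n)}
    weights = {i: len(groups[i]["fry_ids"]) for i in range(n)}

    # exact ties between conflicting alternatives are left unmerged
    blocked: set[tuple[int, int]] = set()
    by_score: dict[tuple[int, int], list[tuple[int, int]]] = {}
    for mism, negsh, i, j in edges:
        by_score.setdefault((mism, negsh), []).append((i, j))
    for score, tier in by_score.items():
        if len(tier) < 2:
            continue
        for (i1, j1), (i2, j2) in itertools.combinations(tier, 2):
            common = {i1, j1} & {i2, j2}
            if len(common) != 1:
                continue
            a = ({i1, j1} - common).pop()
            b = ({i2, j2} - common).pop()
            m_ab, s_ab = _pattern_mismatch(groups[a]["patterns"], groups[b]["patterns"])
            if m_ab > max_mismatch:
                blocked.add((i1, j1))
                blocked.add((i2, j2))
                log.append(
                    f"tied ambiguous merge involving groups {common.pop()}, {a}, {b}: "
                    "left unmerged"
                )

    for mism, negsh, i, j in edges:
        if (i, j) in blocked:
            continue
        ri, rj = find(i), find(j)
        if ri == rj:
            continue
        # a female spawns at most once per nest; same-nest groups never merge
        years_i = {groups[g]["nest_id"] for g in range(n) if find(g) == ri}
        years_j = {groups[g]["nest_id"] for g in range(n) if find(g) == rj}
        if years_i & years_j:
            continue
        m, s = _pattern_mismatch(profiles[ri], profiles[rj])
        if s < min_shared or m > max_mismatch:
            log.append(f"merge {i}-{j} rejected against cluster profiles")
            continue
        merged = _merge_pattern_sets(profiles[ri], profiles[rj], weights[ri], weights[rj])
        parent[rj] = ri
        profiles[ri] = merged
        weights[ri] = weights[ri] + weights[rj]

    clusters: dict[int, list[int]] = {}
    for g in range(n):
        clusters.setdefault(find(g), []).append(g)

    females: list[ReconstructedFemale] = []
    ordered = sorted(
        clusters.items(),
        key=lambda kv: min(
            (groups[g]["year"], groups[g]["spawn_day"], groups[g]["nest_id"])
            for g in kv[1]
        ),
    )
    for f_idx, (root, members) in enumerate(ordered, start=1):
        clutches = []
        for g in members:
            grp = groups[g]
            clutches.append(
                {
                    "year": grp["year"],
                    "nest_id": grp["nest_id"],
                    "male_id": grp["male_id"],
                    "spawn_day": grp["spawn_day"],
                    "rank": grp["rank"],
                    "fry_ids": grp["fry_ids"],
                }
            )
        clutches.sort(key=lambda c: (c["year"], c["spawn_day"], c["rank"], c["nest_id"]))
        order_in_year: dict[int, int] = {}
        for c in clutches:
            order_in_year[c["year"]] = order_in_year.get(c["year"], 0) + 1
            c["mate_order"] = order_in_year[c["year"]]
        females.append(
            ReconstructedFemale(id=f"RF{f_idx:04d}", patterns=profiles[root], clutches=clutches)
        )
    return females, log


# ---------------------------------------------------------------------------
# QC categories


def categorize_assignments(
    fry_table: GenotypeTable,
    male_obs: dict[str, np.ndarray],  # nest_id -> observed male alleles
    nests: pd.DataFrame,
    tolerance: int = 2,
) -> pd.DataFrame:
    """Label every fry by which nest's parents it is compatible with.

    * ``assigned`` — compatible with its own nest's guardian male;
    * ``mixed`` — not its own, but compatible with a shoreline-adjacent
      nest's male (drifted fry);
    * ``mis_assigned`` — compatible only with some non-adjacent sampled
      male in the same year;
    * ``unknown`` — compatible with no sampled male that year.

    Returns a DataFrame (offspring, nest_id, year, label).
    """
    nests = nests.set_index("nest_id") if "nest_id" in nests.columns else nests
    rows = []
    for year in sorted(set(fry_table.meta["year"])):
        sub = fry_table.select(year=year)
        if len(sub) == 0:
            continue
        year_nests = nests[nests["year"] == year]
        rank_of = year_nests["shoreline_rank"].to_dict()
        sampled_nests = [nid for nid in year_nests.index if nid in male_obs]
        if sampled_nests:
            males = np.stack([male_obs[nid] for nid in sampled_nests])
            excl = np.zeros((len(sub), len(sampled_nests)), dtype=int)
            for k in range(len(sampled_nests)):
                excl[:, k], _ = exclusion_counts(sub.alleles, males[k])
            compat = excl <= tolerance
        else:
            compat = np.zeros((len(sub), 0), dtype=bool)
        col = {nid: k for k, nid in enumerate(sampled_nests)}
        for i, fry_id in enumerate(sub.ids):
            own = sub.meta.iloc[i]["nest_id"]
            own_rank = rank_of.get(own)
            if own in col and compat[i, col[own]]:
                label = "assigned"
            else:
                adj = [
                    nid
                    for nid in sampled_nests
                    if nid != own and abs(rank_of[nid] - own_rank) == 1
                ]
                if any(compat[i, col[nid]] for nid in adj):
                    label = "mixed"
                elif any(
                    compat[i, col[nid]] for nid in sampled_nests if nid != own
                ):
                    label = "mis_assigned"
                else:
                    label = "unknown"
            rows.append(
                {"offspring": fry_id, "nest_id": own, "year": year, "label": label}
            )
    return pd.DataFrame(rows)


def brood_categories(fry_labels: pd.DataFrame, nests: pd.DataFrame) -> pd.DataFrame:
    """Brood-level verdicts from fry QC labels.

    A brood with an uncaptured male is excluded outright; a brood with at
    least one own-assigned fry is assigned; a brood whose fry are uniformly
    non-assigned is excluded under its modal fry category (ties broken
    mixed > unknown > mis_assigned).
    """
    nests_idx = nests.set_index("nest_id") if "nest_id" in nests.columns else nests
    rows = []
    for nest_id, grp in fry_labels.groupby("nest_id"):
        male = str(nests_idx.loc[nest_id, "male_id"])
        if male in ("", "nan"):
            verdict = "excluded_no_male"
        elif (grp["label"] == "assigned").any():
            verdict = "assigned"
        else:
            priority = {"mixed": 0, "unknown": 1, "mis_assigned": 2}
            counts = grp["label"].value_counts()
            top = sorted(counts.items(), key=lambda kv: (-kv[1], priority.get(kv[0], 9)))
            verdict = f"excluded_{top[0][0]}"
        rows.append(
            {
                "nest_id": nest_id,
                "year": int(nests_idx.loc[nest_id, "year"]),
                "verdict": verdict,
                "n_fry": len(grp),
            }
        )
    # nests whose male went uncaptured may have no fry rows at all
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# full pipeline


@dataclass
class PedigreeResult:
    """Output of the full reconstruction pipeline."""

    pedigree: pd.DataFrame  # offspring, year, nest_id, father, female_id, qc_label
    females: list[ReconstructedFemale]
    partitions: list[MaternalSibPartition]
    paternity: list[PaternityCheck]
    fry_labels: pd.DataFrame
    broods: pd.DataFrame
    merge_log: list[str]
    report: dict

    def female_captures(self, years: list[int]) -> pd.DataFrame:
        rows = []
        for f in self.females:
            hist = {f"y{y}": int(y in f.years) for y in years}
            rows.append({"individual": f.id, "sex": "F", **hist})
        return pd.DataFrame(rows)


def reconstruct_pedigree(
    genotypes: GenotypeTable,
    nests: pd.DataFrame,
    tolerance: int = 2,
    partition_tolerance: int | None = None,
    match_threshold: int = 2,
    min_shared: int = 10,
    node_budget: int = 1_000_000,
) -> PedigreeResult:
    """Run paternity confirmation, sibship partitioning, female merging and
    QC labelling over a full observed dataset.

    ``genotypes`` holds per-capture male rows (``role='male'``) and fry rows
    (``role='fry'``) with ``year`` and ``nest_id`` metadata; ``nests`` is the
    nest table (nest_id, year, shoreline_rank, spawn_day, male_id).
    """
    if partition_tolerance is None:
        partition_tolerance = tolerance
    nest_idx = nests.set_index("nest_id")
    panel = allele_frequencies(genotypes.select(role="male")) if any(
        genotypes.meta.get("role", pd.Series(dtype=str)) == "male"
    ) else None

    male_obs: dict[str, np.ndarray] = {}
    male_tab = genotypes.select(role="male")
    for i, _ in enumerate(male_tab.ids):
        male_obs[str(male_tab.meta.iloc[i]["nest_id"])] = male_tab.alleles[i]

    fry_tab = genotypes.select(role="fry")
    fry_labels = categorize_assignments(fry_tab, male_obs, nests, tolerance)
    broods = brood_categories(fry_labels, nests)

    paternity: list[PaternityCheck] = []
    partitions: list[MaternalSibPartition] = []
    ped_rows: list[dict] = []
    for nest_id, grp in fry_tab.meta.groupby("nest_id"):
        idx = grp.index.to_numpy()
        ids = [fry_tab.ids[i] for i in idx]
        alleles = fry_tab.alleles[idx]
        male_alleles = male_obs.get(str(nest_id))
        male_id = str(nest_idx.loc[nest_id, "male_id"])
        chk = check_paternity(
            male_alleles, ids, alleles, str(nest_id), male_id or None, tolerance
        )
        paternity.append(chk)
        if male_alleles is None:
            continue
        comp = chk.compatible_ids
        comp_idx = [i for i, f in zip(idx, ids) if f in set(comp)]
        if not comp_idx:
            continue
        part = partition_maternal_sibships(
            [fry_tab.ids[i] for i in comp_idx],
            fry_tab.alleles[comp_idx],
            male_alleles,
            nest_id=str(nest_id),
            tolerance=partition_tolerance,
            panel=panel,
            node_budget=node_budget,
        )
        partitions.append(part)

    females, merge_log = merge_females(
        partitions, nest_idx, max_mismatch=match_threshold, min_shared=min_shared
    )

    label_of = dict(zip(fry_labels["offspring"], fry_labels["label"]))
    for fem in females:
        for c in fem.clutches:
            for fry in c["fry_ids"]:
                ped_rows.append(
                    {
                        "offspring": fry,
                        "year": c["year"],
                        "nest_id": c["nest_id"],
                        "father": c["male_id"],
                        "female_id": fem.id,
                        "qc_label": label_of.get(fry, "assigned"),
                    }
                )
    pedigree = pd.DataFrame(
        ped_rows,
        columns=["offspring", "year", "nest_id", "father", "female_id", "qc_label"],
    )
    report = {
        "n_nests": int(len(nests)),
        "n_fry": int(len(fry_tab)),
        "n_females": len(females),
        "n_partitions_exact": sum(p.exact for p in partitions),
        "fry_label_counts": fry_labels["label"].value_counts().to_dict(),
        "brood_verdict_counts": broods["verdict"].value_counts().to_dict()
        if len(broods)
        else {},
    }
    return PedigreeResult(
        pedigree, females, partitions, paternity, fry_labels, broods, merge_log, report
    )
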