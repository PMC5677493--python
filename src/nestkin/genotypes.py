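"""Genotype data model, I/O and locus-panel statistics.

Genotypes are diploid, unphased, multilocus microsatellite calls.  Alleles
are positive integers (fragment sizes or arbitrary labels); ``0`` encodes a
missing call, and a locus is treated as missing when either of its two
alleles is 0.  The in-memory container is :class:`GenotypeTable`, a thin
wrapper around a ``(n_individuals, n_loci, 2)`` integer array plus a pandas
metadata frame (year, role, nest), which keeps the per-pair arithmetic
(relatedness, identity matching, Mendelian checks) vectorizable.

Panel statistics implemented here:

* allele frequencies (with optional exclusion of focal individuals, the
  bias correction used by pairwise relatedness estimators);
* probability of identity under Hardy-Weinberg, its unbiased small-sample
  correction, and the full-sib variant P(ID)sib — the standard measures of
  a marker panel's power to distinguish individuals;
* per-locus genotyping error rates estimated from repeat captures of
  physically tagged individuals;
* mismatch-tolerant multilocus identity matching used to track individuals
  across breeding seasons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = 0

__all__ = [
    "MISSING",
    "Genotype",
    "GenotypeTable",
    "LocusPanel",
    "PanelStats",
    "MatchResult",
    "read_genotypes",
    "write_genotypes",
    "write_genepop",
    "allele_frequencies",
    "pid_hw",
    "estimate_error_rates",
    "match_identity",
]


@dataclass(frozen=True)
class Genotype:
    """A single individual's multilocus genotype.

    Allele pairs are order-insensitive: equality and hashing canonicalize
    each locus to (min, max).
    """

    id: str
    alleles: tuple[tuple[int, int], ...]

    def __post_init__(self):
        canon = tuple(tuple(sorted(pair)) for pair in self.alleles)
        object.__setattr__(self, "alleles", canon)

    @property
    def n_loci(self) -> int:
        return len(self.alleles)

    def missing_mask(self) -> np.ndarray:
        arr = np.asarray(self.alleles)
        return (arr == MISSING).any(axis=1)


class GenotypeTable:
    """Collection of diploid genotypes with per-individual metadata.

    Parameters
    ----------
    ids : sequence of str
        Unique individual identifiers.
    loci : sequence of str
        Locus names, one per marker.
    alleles : ndarray, shape (n, n_loci, 2)
        Integer allele calls; 0 = missing.
    meta : DataFrame, optional
        Per-individual metadata indexed like ``ids`` (columns such as
        ``year``, ``role``, ``nest_id``).
    """

    META_COLS = ("year", "role", "nest_id")

    def __init__(self, ids, loci, alleles, meta: pd.DataFrame | None = None):
        self.ids = list(map(str, ids))
        if len(set(self.ids)) != len(self.ids):
            dupes = pd.Series(self.ids).value_counts()
            dupes = list(dupes[dupes > 1].index)
            raise ValueError(f"duplicate individual ids: {dupes}")
        self.loci = list(loci)
        alleles = np.asarray(alleles, dtype=np.int64)
        if alleles.shape != (len(self.ids), len(self.loci), 2):
            raise ValueError(
                f"alleles shape {alleles.shape} does not match "
                f"({len(self.ids)}, {len(self.loci)}, 2)"
            )
        self.alleles = alleles
        if meta is None:
            meta = pd.DataFrame(index=range(len(self.ids)))
        self.meta = meta.reset_index(drop=True)
        self._index = {ind: i for i, ind in enumerate(self.ids)}

    def __len__(self) -> int:
        return len(self.ids)

    def __contains__(self, ind: str) -> bool:
        return ind in self._index

    def row(self, ind: str) -> np.ndarray:
        """Allele array (n_loci, 2) for one individual."""
        return self.alleles[self._index[ind]]

    def genotype(self, ind: str) -> Genotype:
        arr = self.row(ind)
        return Genotype(ind, tuple(map(tuple, arr.tolist())))

    def subset(self, ids) -> "GenotypeTable":
        idx = [self._index[i] for i in ids]
        return GenotypeTable(
            [self.ids[i] for i in idx],
            self.loci,
            self.alleles[idx],
            self.meta.iloc[idx],
        )

    def select(self, **conditions) -> "GenotypeTable":
        """Subset on metadata equality, e.g. ``select(role='male', year=2012)``."""
        mask = np.ones(len(self), dtype=bool)
        for col, val in conditions.items():
            mask &= (self.meta[col] == val).to_numpy()
        idx = np.flatnonzero(mask)
        return GenotypeTable(
            [self.ids[i] for i in idx], self.loci, self.alleles[idx], self.meta.iloc[idx]
        )

    def missing_mask(self) -> np.ndarray:
        """(n, n_loci) boolean mask, True where the locus call is missing."""
        return (self.alleles == MISSING).any(axis=2)

    def to_frame(self) -> pd.DataFrame:
        cols = {"id": self.ids}
        for c in self.META_COLS:
            if c in self.meta.columns:
                cols[c] = self.meta[c].to_numpy()
        for j, locus in enumerate(self.loci):
            cols[f"{locus}_1"] = self.alleles[:, j, 0]
            cols[f"{locus}_2"] = self.alleles[:, j, 1]
        return pd.DataFrame(cols)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GenotypeTable":
        allele_cols = [c for c in df.columns if c.endswith("_1") or c.endswith("_2")]
        loci: list[str] = []
        for c in allele_cols:
            name = c[:-2]
            if name not in loci:
                loci.append(name)
        for locus in loci:
            for suffix in ("_1", "_2"):
                if locus + suffix not in df.columns:
                    raise ValueError(
                        f"locus {locus!r} has an odd number of allele columns "
                        f"(missing {locus + suffix!r})"
                    )
        n = len(df)
        alleles = np.zeros((n, len(loci), 2), dtype=np.int64)
        for j, locus in enumerate(loci):
            for k, suffix in enumerate(("_1", "_2")):
                col = df[locus + suffix]
                vals = pd.to_numeric(col, errors="coerce").fillna(MISSING)
                alleles[:, j, k] = vals.astype(np.int64)
        meta_cols = [c for c in cls.META_COLS if c in df.columns]
        meta = df[meta_cols].copy() if meta_cols else None
        return cls(df["id"].astype(str).tolist(), loci, alleles, meta)

    def __eq__(self, other) -> bool:
        if not isinstance(other, GenotypeTable):
            return NotImplemented
        if self.ids != other.ids or self.loci != other.loci:
            return False
        # allele pairs are unordered
        return bool(
            np.array_equal(np.sort(self.alleles, axis=2), np.sort(other.alleles, axis=2))
        )


def read_genotypes(path, dialect: str = "csv") -> GenotypeTable:
    """Read a genotype table.

    The CSV dialect has columns ``id``, optional ``year``/``role``/``nest_id``,
    then two columns per locus named ``<locus>_1`` and ``<locus>_2``.
    Empty cells or ``0`` denote missing allele calls.
    """
    if dialect != "csv":
        raise ValueError(f"unsupported dialect: {dialect!r}")
    df = pd.read_csv(path, dtype={"id": str})
    if "id" not in df.columns:
        raise ValueError(f"{path}: missing required 'id' column")
    bad = df["id"].isna()
    if bad.any():
        line = int(bad.idxmax()) + 2  # header + 1-based
        raise ValueError(f"{path}: malformed row at line {line} (empty id)")
    try:
        return GenotypeTable.from_frame(df)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def write_genotypes(table: GenotypeTable, path, dialect: str = "csv") -> None:
    if dialect != "csv":
        raise ValueError(f"unsupported dialect: {dialect!r}")
    table.to_frame().to_csv(path, index=False)


def write_genepop(table: GenotypeTable, path, title: str = "nestkin export") -> None:
    """Write a GenePop-dialect file (3-digit allele codes, one POP)."""
    with open(path, "w") as fh:
        fh.write(title + "\n")
        for locus in table.loci:
            fh.write(locus + "\n")
        fh.write("POP\n")
        for i, ind in enumerate(table.ids):
            codes = []
            for j in range(len(table.loci)):
                a, b = table.alleles[i, j]
                codes.append(f"{a:03d}{b:03d}")
            fh.write(f"{ind}, " + " ".join(codes) + "\n")


# ---------------------------------------------------------------------------
# panel statistics


@dataclass
class LocusPanel:
    """Per-locus allele frequencies and (optionally) error rates."""

    loci: list[str]
    frequencies: list[dict[int, float]]
    error_rates: np.ndarray | None = None

    def __post_init__(self):
        for locus, freq in zip(self.loci, self.frequencies):
            tot = sum(freq.values())
            if not np.isclose(tot, 1.0, atol=1e-9):
                raise ValueError(f"locus {locus}: frequencies sum to {tot}, not 1")
            if any(p <= 0 for p in freq.values()):
                raise ValueError(f"locus {locus}: non-positive frequency")
        if self.error_rates is not None:
            e = np.asarray(self.error_rates, dtype=float)
            if ((e < 0) | (e > 1)).any():
                raise ValueError("error rates must lie in [0, 1]")
            self.error_rates = e

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def freq_arrays(self) -> list[tuple[np.ndarray, np.ndarray]]:
        """Per locus, (allele labels, frequencies) as aligned arrays."""
        out = []
        for freq in self.frequencies:
            labels = np.array(sorted(freq), dtype=np.int64)
            out.append((labels, np.array([freq[a] for a in labels])))
        return out


def allele_frequencies(
    table: GenotypeTable, exclude_ids=None, min_alleles: int = 1
) -> LocusPanel:
    """Estimate per-locus allele frequencies by gene counting.

    Missing calls are excluded from the denominators.  ``exclude_ids``
    removes focal individuals before counting (the bias correction used
    when the same sample provides both the pair and the reference
    frequencies).  Loci with no non-missing data are dropped with a warning.
    """
    exclude = set(exclude_ids or ())
    keep = [i for i, ind in enumerate(table.ids) if ind not in exclude]
    alleles = table.alleles[keep]
    loci, freqs = [], []
    for j, locus in enumerate(table.loci):
        calls = alleles[:, j, :].ravel()
        calls = calls[calls != MISSING]
        if calls.size < min_alleles:
            warnings.warn(f"locus {locus}: all data missing; dropped from panel")
            continue
        labels, counts = np.unique(calls, return_counts=True)
        total = counts.sum()
        freqs.append({int(a): c / total for a, c in zip(labels, counts)})
        loci.append(locus)
    if not loci:
        raise ValueError("no locus with non-missing data")
    return LocusPanel(loci, freqs)


@dataclass
class PanelStats:
    """Probability-of-identity summary for a marker panel.

    ``pid_hw`` is the Hardy-Weinberg expectation that two unrelated
    individuals share a genotype, ``pid_sib`` the same probability for full
    sibs, and ``pid_unbiased`` the small-sample-corrected estimator (defined
    when the reference sample size ``n`` >= 4 is supplied).  Multilocus
    values are products across independent loci.
    """

    loci: list[str]
    pid_hw_locus: np.ndarray
    pid_sib_locus: np.ndarray
    pid_unbiased_locus: np.ndarray | None
    n: int | None = None

    @property
    def pid_hw(self) -> float:
        return float(np.prod(self.pid_hw_locus))

    @property
    def pid_sib(self) -> float:
        return float(np.prod(self.pid_sib_locus))

    @property
    def pid_unbiased(self) -> float | None:
        if self.pid_unbiased_locus is None:
            return None
        return float(np.prod(self.pid_unbiased_locus))

    def to_frame(self) -> pd.DataFrame:
        data = {"pid_hw": self.pid_hw_locus, "pid_sib": self.pid_sib_locus}
        if self.pid_unbiased_locus is not None:
            data["pid_unbiased"] = self.pid_unbiased_locus
        return pd.DataFrame(data, index=pd.Index(self.loci, name="locus"))


def pid_hw(panel: LocusPanel, n: int | None = None) -> PanelStats:
    """Probability of identity for a locus panel.

    Per locus, with allele frequencies p_i and power sums a_k = sum p_i^k:

    * P(ID)_HW  = 2 a_2^2 - a_4
    * P(ID)_sib = 0.25 + 0.5 a_2 + 0.5 a_2^2 - 0.25 a_4
    * P(ID)_unbiased = [n^3 (2 a_2^2 - a_4) - 2 n^2 (a_3 + 2 a_2)
                        + n (9 a_2 + 2) - 6] / [n (n-1) (n-2) (n-3)]

    the last being the bias-corrected estimator for frequencies counted
    from a sample of n diploid individuals (requires n >= 4).
    """
    hw, sib, unb = [], [], []
    if n is not None and n < 4:
        raise ValueError("unbiased P(ID) correction undefined for n < 4")
    for freq in panel.frequencies:
        p = np.array(list(freq.values()))
        a2, a3, a4 = (p**2).sum(), (p**3).sum(), (p**4).sum()
        hw.append(2 * a2**2 - a4)
        sib.append(0.25 + 0.5 * a2 + 0.5 * a2**2 - 0.25 * a4)
        if n is not None:
            num = n**3 * (2 * a2**2 - a4) - 2 * n**2 * (a3 + 2 * a2) + n * (9 * a2 + 2) - 6
            den = (n - 1) * (n - 2) * (n - 3)
            unb.append(num / den)
    return PanelStats(
        list(panel.loci),
        np.array(hw),
        np.array(sib),
        np.array(unb) if n is not None else None,
        n=n,
    )


# ---------------------------------------------------------------------------
# error rates from repeat captures


def _pair_mismatches(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus minimum allele-edit distance (0/1/2) and a validity mask.

    ``a``, ``b`` are (n_loci, 2) allele arrays.  A locus missing in either
    genotype is excluded (mask False).  Allele order within a genotype is
    irrelevant: the distance is computed on sorted pairs, taking the
    smaller of the two possible allele alignments.
    """
    a = np.sort(a, axis=1)
    b = np.sort(b, axis=1)
    ok = (a != MISSING).all(axis=1) & (b != MISSING).all(axis=1)
    direct = (a != b).sum(axis=1)
    crossed = (a != b[:, ::-1]).sum(axis=1)
    return np.minimum(direct, crossed), ok


def estimate_error_rates(
    repeat_pairs: list[tuple[np.ndarray, np.ndarray]], loci: list[str]
) -> pd.DataFrame:
    """Per-locus genotyping error rates from repeat-capture genotype pairs.

    Each element of ``repeat_pairs`` is a pair of (n_loci, 2) allele arrays
    for the same physical individual genotyped in two different seasons.
    The per-locus rate is (mismatching allele comparisons) / (total allele
    comparisons), i.e. each scored locus contributes two allele
    comparisons; missing loci contribute none.

    Returns a DataFrame indexed by locus with columns ``mismatches``,
    ``comparisons`` and ``error_rate``, plus an ``overall`` row.
    """
    if not repeat_pairs:
        raise ValueError(
            "no repeat captures available; supply per-locus error rates "
            "via configuration instead"
        )
    n_loci = len(loci)
    mism = np.zeros(n_loci, dtype=np.int64)
    comp = np.zeros(n_loci, dtype=np.int64)
    for a, b in repeat_pairs:
        d, ok = _pair_mismatches(np.asarray(a), np.asarray(b))
        mism[ok] += d[ok]
        comp[ok] += 2
    with np.errstate(invalid="ignore"):
        rate = np.where(comp > 0, mism / np.maximum(comp, 1), np.nan)
    df = pd.DataFrame(
        {"mismatches": mism, "comparisons": comp, "error_rate": rate},
        index=pd.Index(loci, name="locus"),
    )
    overall = pd.DataFrame(
        {
            "mismatches": [mism.sum()],
            "comparisons": [comp.sum()],
            "error_rate": [mism.sum() / comp.sum() if comp.sum() else np.nan],
        },
        index=pd.Index(["overall"], name="locus"),
    )
    return pd.concat([df, overall])


# ---------------------------------------------------------------------------
# identity matching


@dataclass
class MatchResult:
    """Outcome of a mismatch-tolerant multilocus identity comparison."""

    verdict: str  # 'match' | 'no_match' | 'uninformative'
    mismatch_loci: int
    shared_loci: int

    @property
    def is_match(self) -> bool:
        return self.verdict == "match"


def match_identity(
    a: np.ndarray,
    b: np.ndarray,
    max_mismatch_loci: int = 2,
    min_shared_loci: int = 10,
) -> MatchResult:
    """Decide whether two multilocus genotypes are the same individual.

    Genotyping error makes exact matching too strict: with per-allele error
    rates up to ~0.0075 a true repeat capture can disagree at a couple of
    loci, while the panel's P(ID)sib makes a chance near-match between
    different individuals vanishingly rare.  The default tolerance of 2
    mismatching loci out of 20 keeps the expected false-merge probability
    well below 1e-3 for panels of that power.

    A comparison with fewer than ``min_shared_loci`` jointly scored loci is
    'uninformative' rather than a yes/no verdict.
    """
    d, ok = _pair_mismatches(np.asarray(a), np.asarray(b))
    shared = int(ok.sum())
    mismatches = int((d[ok] > 0).sum())
    if shared < min_shared_loci:
        return MatchResult("uninformative", mismatches, shared)
    verdict = "match" if mismatches <= max_mismatch_loci else "no_match"
    return MatchResult(verdict, mismatches, shared)
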