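"""Cormack-Jolly-Seber open-population model for annual return rates.

Adults breeding in successive seasons form capture histories (one row per
individual, one column per season).  Conditioning on first release, the
CJS likelihood is a product-multinomial over the m-array — releases per
occasion crossed with occasion of first recapture — with apparent survival
``phi_t`` per interval (interpreted here as the breeding *return rate*)
and detection ``p_t`` per occasion.

The interface follows the statsmodels pattern::

    model = CJSModel(histories)              # or CJSModel.from_dataframe(df)
    res = model.fit()                        # phi and p free
    res = model.fit(fix_p=1.0)               # detection assumed perfect
    print(res.summary())

``fit`` maximizes the likelihood on the logit scale (seeded multi-start
L-BFGS-B), reports standard errors from the observed information, and
profile-likelihood 95% confidence intervals at the deviance cutoff 3.84.

Perfect detection and skipped seasons are mutually contradictory: a
history like ``1011`` has zero probability under ``p = 1``.  By default
``p`` is therefore estimated freely; with ``fix_p=1.0`` each offending
history is right-truncated at the end of its initial run of sightings (the
longest prefix consistent with perfect detection), and the number of
histories so modified is reported on the results object.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = ["CJSModel", "CJSResults", "build_m_array", "cjs_loglik", "simulate_histories"]

_NEG_INF = -1e300
_DEVIANCE_CUTOFF = stats.chi2.ppf(0.95, df=1)  # 3.841...


def _logit(x):
    x = np.clip(x, 1e-12, 1 - 1e-12)
    return np.log(x / (1 - x))


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


def build_m_array(histories: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Reduce capture histories to the CJS sufficient statistic.

    Returns ``(releases, m)`` where ``releases[t]`` counts individuals
    captured (and re-released) at occasion t (t = 0..K-2) and ``m[t, u]``
    counts those among them whose *first* recapture is at occasion u.
    """
    h = np.asarray(histories, dtype=int)
    if h.ndim != 2 or h.shape[1] < 2:
        raise ValueError("histories must be 2-D with at least 2 occasions")
    if (h.sum(axis=1) < 1).any():
        raise ValueError("every capture history must contain at least one capture")
    n, K = h.shape
    releases = h[:, :-1].sum(axis=0)
    m = np.zeros((K - 1, K), dtype=int)
    for t in range(K - 1):
        at_t = h[:, t] == 1
        later = h[at_t, t + 1 :]
        seen = later.argmax(axis=1)
        any_seen = later.any(axis=1)
        for u, cnt in zip(*np.unique(seen[any_seen], return_counts=True)):
            m[t, t + 1 + u] += cnt
    return releases, m


def _cell_probs(phi: np.ndarray, p: np.ndarray, K: int) -> tuple[np.ndarray, np.ndarray]:
    """P(first recapture at u | release at t) and never-seen-again chi_t.

    ``phi`` has length K-1 (interval t -> t+1); ``p`` has length K-1 with
    ``p[u-1]`` the detection probability at occasion u (u = 1..K-1).
    """
    P = np.zeros((K - 1, K))
    for t in range(K - 1):
        surv = 1.0
        for u in range(t + 1, K):
            surv_to_u = surv * phi[u - 1]
            P[t, u] = surv_to_u * p[u - 1]
            surv = surv_to_u * (1.0 - p[u - 1])
    chi = np.ones(K)
    for t in range(K - 2, -1, -1):
        chi[t] = 1.0 - phi[t] * (p[t] + (1.0 - p[t]) * (1.0 - chi[t + 1]))
    return P, chi[:-1]


def cjs_loglik(
    phi: np.ndarray, p: np.ndarray, releases: np.ndarray, m: np.ndarray
) -> float:
    """Conditional-on-first-release product-multinomial log-likelihood.

    Cells with zero expected probability contribute 0 when their count is
    zero and a -inf sentinel otherwise (the fit rejects that region).
    """
    phi = np.asarray(phi, float)
    p = np.asarray(p, float)
    if ((phi < 0) | (phi > 1) | (p < 0) | (p > 1)).any():
        raise ValueError("phi and p must lie in [0, 1]")
    K = m.shape[1]
    P, chi = _cell_probs(phi, p, K)
    ll = 0.0
    never = releases - m.sum(axis=1)
    for t in range(K - 1):
        for u in range(t + 1, K):
            if m[t, u] > 0:
                if P[t, u] <= 0:
                    return _NEG_INF
                ll += m[t, u] * np.log(P[t, u])
        if never[t] > 0:
            if chi[t] <= 0:
                return _NEG_INF
            ll += never[t] * np.log(chi[t])
    return float(ll)


def _loglik_histories(histories: np.ndarray, phi: np.ndarray, p: np.ndarray) -> float:
    """Same likelihood computed individual-by-individual (no m-array)."""
    h = np.asarray(histories, dtype=int)
    K = h.shape[1]
    _, chi = _cell_probs(phi, p, K)
    chi_full = np.append(chi, 1.0)
    ll = 0.0
    for row in h:
        ones = np.flatnonzero(row)
        first, last = ones[0], ones[-1]
        pr = 1.0
        for t in range(first, last):
            pr *= phi[t] * (p[t] if row[t + 1] == 1 else 1.0 - p[t])
        pr *= chi_full[last]
        if pr <= 0:
            return _NEG_INF
        ll += np.log(pr)
    return float(ll)


def _truncate_internal_zeros(h: np.ndarray) -> tuple[np.ndarray, int]:
    """Right-truncate each history at its longest perfect-detection prefix."""
    h = np.asarray(h, dtype=int).copy()
    n_mod = 0
    for i, row in enumerate(h):
        ones = np.flatnonzero(row)
        first, last = ones[0], ones[-1]
        span = row[first : last + 1]
        if (span == 0).any():
            stop = first + int(np.argmin(span))  # first internal zero
            h[i, stop:] = 0
            n_mod += 1
    return h, n_mod


class CJSModel:
    """Time-dependent CJS model built from a capture-history matrix.

    Parameters
    ----------
    histories : array-like, shape (n, K)
        Binary capture histories; every row must contain a capture and
        K >= 2 occasions are required.
    occasions : sequence, optional
        Occasion labels (e.g. years); defaults to 0..K-1.
    sex : str, optional
        Carried through to the results for labelling.
    """

    def __init__(self, histories, occasions=None, sex: str | None = None):
        self.histories = np.asarray(histories, dtype=int)
        self.releases, self.m = build_m_array(self.histories)
        self.K = self.histories.shape[1]
        self.occasions = list(occasions) if occasions is not None else list(range(self.K))
        if len(self.occasions) != self.K:
            raise ValueError("occasion labels must match the number of columns")
        self.sex = sex

    @classmethod
    def from_dataframe(cls, captures: pd.DataFrame, years: list[int], sex=None):
        """Build from a capture table with ``y<year>`` columns (optionally
        filtered to one value of its ``sex`` column)."""
        df = captures
        if sex is not None and "sex" in df.columns:
            df = df[df["sex"] == sex]
        cols = [f"y{y}" for y in years]
        h = df[cols].to_numpy(dtype=int)
        h = h[h.sum(axis=1) >= 1]
        return cls(h, occasions=years, sex=sex)

    def loglike(self, phi, p) -> float:
        return cjs_loglik(phi, p, self.releases, self.m)

    @property
    def m_array(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.m[:, 1:],
            index=pd.Index(self.occasions[:-1], name="release"),
            columns=pd.Index(self.occasions[1:], name="first_recapture"),
        )
        df.insert(0, "released", self.releases)
        return df

    # -- estimation ---------------------------------------------------------

    def fit(
        self,
        fix_p: float | None = None,
        n_restarts: int = 3,
        seed: int = 0,
        profile: bool = True,
    ) -> "CJSResults":
        """Maximum-likelihood fit.

        With ``fix_p`` the detection probability is held at the given value
        (1.0 reproduces the perfect-detection analysis, after right-
        truncating histories with internal zeros); otherwise ``p`` is
        estimated, in which case the terminal ``phi`` and ``p`` are only
        identified through their product and are flagged as confounded.
        """
        K = self.K
        n_phi = K - 1
        histories = self.histories
        n_truncated = 0
        releases, m = self.releases, self.m
        if fix_p is not None and fix_p >= 1.0:
            histories, n_truncated = _truncate_internal_zeros(self.histories)
            if n_truncated:
                warnings.warn(
                    f"{n_truncated} capture histories have unobserved seasons "
                    "between sightings, impossible under p=1; right-truncated "
                    "at the first gap"
                )
            histories = histories[histories.sum(axis=1) >= 1]
            releases, m = build_m_array(histories)

        def unpack(x):
            phi = _expit(x[:n_phi])
            if fix_p is not None:
                p = np.full(n_phi, fix_p)
            else:
                p = _expit(x[n_phi:])
            return phi, p

        def nll(x):
            phi, p = unpack(x)
            ll = cjs_loglik(phi, p, releases, m)
            return -ll if ll > _NEG_INF else 1e12

        n_par = n_phi if fix_p is not None else 2 * n_phi
        rng = np.random.default_rng(seed)
        best = None
        starts = [np.zeros(n_par)]
        starts += [rng.normal(0.0, 1.5, size=n_par) for _ in range(n_restarts - 1)]
        for x0 in starts:
            res = optimize.minimize(nll, x0, method="L-BFGS-B")
            if best is None or res.fun < best.fun:
                best = res
        phi_hat, p_hat = unpack(best.x)
        llf = -best.fun

        # observed information on the probability scale (phi only when p fixed)
        se_phi = np.full(n_phi, np.nan)
        se_p = np.full(n_phi, np.nan)
        try:
            free = (
                np.concatenate([phi_hat, p_hat]) if fix_p is None else phi_hat.copy()
            )

            def nat_nll(v):
                if fix_p is None:
                    phi, p = v[:n_phi], v[n_phi:]
                else:
                    phi, p = v, np.full(n_phi, fix_p)
                if ((phi <= 0) | (phi >= 1) | (p < 0) | (p > 1)).any():
                    return 1e12
                ll = cjs_loglik(phi, p, releases, m)
                return -ll if ll > _NEG_INF else 1e12

            interior = (free > 1e-4) & (free < 1 - 1e-4)
            H = _numerical_hessian(nat_nll, free)
            cov = np.full_like(H, np.nan)
            idx = np.flatnonzero(interior)
            if idx.size:
                sub = H[np.ix_(idx, idx)]
                cov_sub = np.linalg.inv(sub)
                cov[np.ix_(idx, idx)] = cov_sub
            se = np.sqrt(np.clip(np.diag(cov), 0, None))
            se_phi = se[:n_phi]
            if fix_p is None:
                se_p = se[n_phi:]
        except np.linalg.LinAlgError:
            pass

        results = CJSResults(
            model=self,
            phi=phi_hat,
            p=p_hat,
            fix_p=fix_p,
            phi_se=se_phi,
            p_se=se_p,
            llf=llf,
            converged=bool(best.success),
            n_truncated=n_truncated,
            _releases=releases,
            _m=m,
        )
        if profile:
            results.phi_ci = np.array(
                [results._profile_ci_phi(i) for i in range(n_phi)]
            )
        return results


def _numerical_hessian(f, x, eps: float = 1e-5) -> np.ndarray:
    n = len(x)
    H = np.zeros((n, n))
    f0 = f(x)
    for i in range(n):
        for j in range(i, n):
            xpp = x.copy(); xpp[i] += eps; xpp[j] += eps
            xpm = x.copy(); xpm[i] += eps; xpm[j] -= eps
            xmp = x.copy(); xmp[i] -= eps; xmp[j] += eps
            xmm = x.copy(); xmm[i] -= eps; xmm[j] -= eps
            H[i, j] = H[j, i] = (f(xpp) - f(xpm) - f(xmp) + f(xmm)) / (4 * eps * eps)
    return H


@dataclass
class CJSResults:
    """Fitted CJS model: estimates, uncertainty and diagnostics."""

    model: CJSModel
    phi: np.ndarray
    p: np.ndarray
    fix_p: float | None
    phi_se: np.ndarray
    p_se: np.ndarray
    llf: float
    converged: bool
    n_truncated: int
    _releases: np.ndarray
    _m: np.ndarray
    phi_ci: np.ndarray | None = None

    @property
    def terminal_confounded(self) -> bool:
        """With p free, the last interval's phi and p enter only as a
        product and are not separately identified."""
        return self.fix_p is None

    @property
    def terminal_product(self) -> float:
        return float(self.phi[-1] * self.p[-1])

    def _profile_loglik_phi(self, index: int, value: float) -> float:
        """Maximized log-likelihood with phi[index] held at ``value``."""
        n_phi = len(self.phi)
        free_idx = [i for i in range(n_phi) if i != index]

        def unpack(x):
            phi = np.empty(n_phi)
            phi[free_idx] = _expit(x[: len(free_idx)])
            phi[index] = value
            if self.fix_p is not None:
                p = np.full(n_phi, self.fix_p)
            else:
                p = _expit(x[len(free_idx) :])
            return phi, p

        def nll(x):
            phi, p = unpack(x)
            ll = cjs_loglik(phi, p, self._releases, self._m)
            return -ll if ll > _NEG_INF else 1e12

        n_par = len(free_idx) + (0 if self.fix_p is not None else n_phi)
        if n_par == 0:
            phi = np.array([value])
            return cjs_loglik(phi, np.full(1, self.fix_p), self._releases, self._m)
        x0 = np.concatenate(
            [
                _logit(self.phi[free_idx]),
                _logit(self.p) if self.fix_p is None else np.empty(0),
            ]
        )
        res = optimize.minimize(nll, x0, method="L-BFGS-B")
        return -res.fun

    def _profile_ci_phi(self, index: int, alpha: float = 0.05) -> tuple[float, float]:
        """Profile-likelihood CI endpoints at deviance 3.84 (95%)."""
        cutoff = stats.chi2.ppf(1 - alpha, df=1)
        target = self.llf - cutoff / 2.0
        mle = self.phi[index]

        def g(v):
            return self._profile_loglik_phi(index, v) - target

        lo, hi = 0.0, 1.0
        eps = 1e-9
        # lower endpoint
        if g(eps) >= 0:
            lower = 0.0
        else:
            lower = optimize.brentq(g, eps, max(mle, 2 * eps), xtol=1e-6)
        if g(1 - eps) >= 0:
            upper = 1.0
        else:
            upper = optimize.brentq(g, min(mle, 1 - 2 * eps), 1 - eps, xtol=1e-6)
        return float(lower), float(upper)

    def summary(self) -> str:
        occ = self.model.occasions
        lines = []
        title = "Cormack-Jolly-Seber return-rate model"
        if self.model.sex:
            title += f" (sex={self.model.sex})"
        lines.append(title)
        lines.append("=" * 64)
        lines.append(
            f"occasions: {occ}   n histories: {self.model.histories.shape[0]}"
        )
        lines.append(
            f"log-likelihood: {self.llf:.3f}   converged: {self.converged}"
        )
        if self.fix_p is not None:
            lines.append(f"detection fixed at p = {self.fix_p}")
            if self.n_truncated:
                lines.append(
                    f"note: {self.n_truncated} histories right-truncated "
                    "(skip-season sightings impossible under p=1)"
                )
        lines.append("-" * 64)
        lines.append(f"{'interval':<16}{'phi':>8}{'SE':>8}{'95% CI':>18}")
        for i in range(len(self.phi)):
            label = f"{occ[i]}-{occ[i + 1]}"
            ci = (
                f"[{self.phi_ci[i][0]:.3f}, {self.phi_ci[i][1]:.3f}]"
                if self.phi_ci is not None
                else ""
            )
            flag = ""
            if self.terminal_confounded and i == len(self.phi) - 1:
                flag = "  (confounded with p)"
            lines.append(
                f"{label:<16}{self.phi[i]:>8.3f}{self.phi_se[i]:>8.3f}{ci:>18}{flag}"
            )
        if self.fix_p is None:
            lines.append(f"{'occasion':<16}{'p':>8}{'SE':>8}")
            for i in range(len(self.p)):
                lines.append(f"{occ[i + 1]:<16}{self.p[i]:>8.3f}{self.p_se[i]:>8.3f}")
        lines.append("=" * 64)
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        occ = self.model.occasions
        return pd.DataFrame(
            {
                "interval": [f"{occ[i]}-{occ[i + 1]}" for i in range(len(self.phi))],
                "phi": self.phi,
                "se": self.phi_se,
                "ci_low": self.phi_ci[:, 0] if self.phi_ci is not None else np.nan,
                "ci_high": self.phi_ci[:, 1] if self.phi_ci is not None else np.nan,
            }
        )


def simulate_histories(
    n: int,
    phi: np.ndarray,
    p: np.ndarray | float = 1.0,
    rng: np.random.Generator | None = None,
    staggered_entry: bool = True,
) -> np.ndarray:
    """Simulate CJS capture histories for testing and power analysis."""
    rng = rng or np.random.default_rng()
    phi = np.asarray(phi, float)
    K = len(phi) + 1
    p_arr = np.full(K - 1, p, dtype=float) if np.isscalar(p) else np.asarray(p, float)
    h = np.zeros((n, K), dtype=int)
    entry = rng.integers(0, K - 1, size=n) if staggered_entry else np.zeros(n, int)
    for i in range(n):
        t = entry[i]
        h[i, t] = 1
        alive = True
        for u in range(t, K - 1):
            alive = alive and (rng.random() < phi[u])
            if alive and rng.random() < p_arr[u]:
                h[i, u + 1] = 1
    return h[h.sum(axis=1) >= 1]
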