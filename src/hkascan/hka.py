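"""Maximum-likelihood HKA model for detecting locus-specific selection.

The multilocus HKA framework contrasts within-species polymorphism with
between-species divergence.  Under neutrality both are proportional to the
locus mutation parameter θ_i, so with a Poisson approximation

    S_i ~ Poisson(k_i · θ_i · a_{n_i})            (segregating sites)
    D_i ~ Poisson(θ_i · (T + (1 + k_i) / 2))      (divergence to outgroup)

where a_n is the harmonic number Σ 1/i, T the species divergence time in
units of 2N generations, and k_i a per-locus selection parameter scaling the
focal species' coalescent depth: k < 1 signals a sweep (diversity deficit),
k > 1 balancing selection.  The (1 + k)/2 term carries the ancestral
polymorphism contribution to divergence.

The neutral model fixes k_i = 1 everywhere (free: θ_1..θ_m, T); the selection
model frees k at one focal locus.  Twice the log-likelihood difference is
referred to a χ² distribution (2 degrees of freedom by convention in the
study design this package reproduces — see ``lrt_df``).

Fitting exploits the fact that, given (T, k), each θ_i has a closed-form
Poisson MLE, so the likelihood is maximized on a 1-D (neutral) or 2-D
(selection) profile surface in log-parameter space with a moment-based start
plus seeded random restarts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import gammaln
from scipy.stats import chi2

from .diversity import harmonic_number

__all__ = [
    "HkaLocusData",
    "HkaFit",
    "HkaTestResult",
    "MLHKA",
    "MLHKAResults",
    "ConvergenceError",
    "hka_loglik",
    "fit_neutral",
    "fit_selection",
    "lrt_test",
    "hka_test",
    "read_count_table",
    "write_count_table",
    "locus_data_from_frame",
]

THETA_MIN = 1e-8
K_BOUNDS = (1e-4, 100.0)
T_BOUNDS = (1e-3, 1e4)


class ConvergenceError(RuntimeError):
    """Raised when no optimizer restart converged; carries the best fit so far."""

    def __init__(self, message: str, best: "MLHKAResults"):
        super().__init__(message)
        self.best = best


@dataclass(frozen=True)
class HkaLocusData:
    """Observed counts for one locus in one pool's HKA dataset."""

    locus_id: str
    S: int
    D: int
    L: int
    n: int
    role: str = "neutral"  # neutral | candidate
    D_exact: float | None = None

    def __post_init__(self) -> None:
        if self.S < 0 or self.D < 0:
            raise ValueError(f"{self.locus_id}: S and D must be non-negative")
        if self.n < 2:
            raise ValueError(f"{self.locus_id}: n must be >= 2")
        if self.L < 1:
            raise ValueError(f"{self.locus_id}: L must be >= 1")

    @property
    def a_n(self) -> float:
        return harmonic_number(self.n)


def _pois_logpmf(x: np.ndarray, mu: np.ndarray) -> np.ndarray:
    return x * np.log(mu) - mu - gammaln(x + 1.0)


def hka_loglik(
    data: Sequence[HkaLocusData],
    theta: np.ndarray,
    T: float,
    k: np.ndarray,
) -> float:
    """Log-likelihood of the multilocus Poisson HKA model."""
    theta = np.asarray(theta, dtype=float)
    k = np.asarray(k, dtype=float)
    S = np.array([d.S for d in data], dtype=float)
    D = np.array([d.D for d in data], dtype=float)
    a = np.array([d.a_n for d in data], dtype=float)
    mu_S = k * theta * a
    mu_D = theta * (T + (1.0 + k) / 2.0)
    if np.any(mu_S <= 0) or np.any(mu_D <= 0):
        raise ValueError("expected counts must be positive; check theta, T, k")
    return float(_pois_logpmf(S, mu_S).sum() + _pois_logpmf(D, mu_D).sum())


class MLHKA:
    """Maximum-likelihood HKA model for a set of loci.

    Parameters
    ----------
    data
        Per-locus counts (same pool throughout).
    focal
        Locus id whose selection parameter k is freed; ``None`` fits the
        strictly neutral model (all k = 1).
    k_bounds
        Allowed range for the focal k.
    """

    def __init__(
        self,
        data: Sequence[HkaLocusData],
        focal: str | None = None,
        k_bounds: tuple[float, float] = K_BOUNDS,
    ):
        if len(data) < 1:
            raise ValueError("need at least one locus")
        ids = [d.locus_id for d in data]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate locus ids in HKA dataset")
        self.data = list(data)
        self.locus_ids = ids
        self.k_bounds = k_bounds
        if focal is not None:
            if focal not in ids:
                raise ValueError(f"focal locus {focal!r} not in dataset")
            if len(data) < 2:
                raise ValueError("selection model needs at least one non-focal locus")
        self.focal = focal
        self._S = np.array([d.S for d in data], dtype=float)
        self._D = np.array([d.D for d in data], dtype=float)
        self._a = np.array([d.a_n for d in data], dtype=float)
        self._ifocal = ids.index(focal) if focal is not None else None

    # -- profile machinery -------------------------------------------------
    def _kvec(self, k_focal: float) -> np.ndarray:
        k = np.ones(len(self.data))
        if self._ifocal is not None:
            k[self._ifocal] = k_focal
        return k

    def _profile_theta(self, T: float, k: np.ndarray) -> np.ndarray:
        denom = k * self._a + T + (1.0 + k) / 2.0
        return np.maximum((self._S + self._D) / denom, THETA_MIN)

    def _profile_negll(self, x: np.ndarray) -> float:
        T = float(np.exp(x[0]))
        k_focal = float(np.exp(x[1])) if self.focal is not None else 1.0
        k = self._kvec(k_focal)
        theta = self._profile_theta(T, k)
        mu_S = k * theta * self._a
        mu_D = theta * (T + (1.0 + k) / 2.0)
        ll = _pois_logpmf(self._S, mu_S).sum() + _pois_logpmf(self._D, mu_D).sum()
        return -float(ll)

    def _starts(self, n_starts: int, seed: int) -> list[np.ndarray]:
        theta0 = np.maximum(self._S, 0.5) / self._a
        T0 = float(np.clip(self._D.sum() / theta0.sum() - 1.0, 0.05, T_BOUNDS[1] / 10))
        starts = [np.array([np.log(T0)])]
        rng = np.random.default_rng(seed)
        for _ in range(max(n_starts - 1, 0)):
            starts.append(np.array([rng.uniform(np.log(0.1), np.log(100.0))]))
        if self.focal is not None:
            k0_list = [1.0, 0.05]
            out = []
            for i, s in enumerate(starts):
                k0 = k0_list[i % 2] if i > 0 else 1.0
                out.append(np.append(s, np.log(k0)))
            # one start at the observed polymorphism ratio
            kf = self._S[self._ifocal] / max(theta0[self._ifocal] * self._a[self._ifocal], 1e-6)
            kf = float(np.clip(kf if kf > 0 else self.k_bounds[0], *self.k_bounds))
            out[0] = np.array([np.log(T0), np.log(max(kf, self.k_bounds[0]))])
            starts = out
        return starts

    def fit(self, n_starts: int = 8, seed: int = 0) -> "MLHKAResults":
        """Maximize the likelihood; returns an :class:`MLHKAResults`.

        ``seed`` controls the random restart locations only; with a fixed
        seed the fit is deterministic.
        """
        lo = [np.log(T_BOUNDS[0])]
        hi = [np.log(T_BOUNDS[1])]
        if self.focal is not None:
            lo.append(np.log(self.k_bounds[0]))
            hi.append(np.log(self.k_bounds[1]))
        bounds = list(zip(lo, hi))
        best = None
        any_ok = False
        for x0 in self._starts(n_starts, seed):
            res = minimize(
                self._profile_negll, x0, method="L-BFGS-B", bounds=bounds,
                options={"ftol": 1e-12, "gtol": 1e-10, "maxiter": 500},
            )
            if not res.success:
                res2 = minimize(
                    self._profile_negll, res.x, method="Nelder-Mead",
                    options={"fatol": 1e-10, "xatol": 1e-8, "maxiter": 2000},
                )
                if res2.fun <= res.fun:
                    res = res2
            any_ok = any_ok or res.success
            if best is None or res.fun < best.fun:
                best = res
        assert best is not None
        T_hat = float(np.exp(np.clip(best.x[0], *np.log(T_BOUNDS))))
        k_focal = (
            float(np.exp(np.clip(best.x[1], *np.log(self.k_bounds))))
            if self.focal is not None
            else 1.0
        )
        k = self._kvec(k_focal)
        theta = self._profile_theta(T_hat, k)
        lnL = -best.fun
        n_free = len(self.data) + 1 + (1 if self.focal is not None else 0)
        results = MLHKAResults(
            model=self,
            theta=theta,
            T=T_hat,
            k=k,
            lnL=float(lnL),
            n_free=n_free,
            converged=bool(any_ok),
        )
        if not any_ok:
            raise ConvergenceError(
                f"MLHKA fit did not converge after {n_starts} restarts", results
            )
        return results


@dataclass
class MLHKAResults:
    """Fitted ML-HKA parameters with uncertainties and a summary table."""

    model: MLHKA
    theta: np.ndarray
    T: float
    k: np.ndarray
    lnL: float
    n_free: int
    converged: bool
    _bse_cache: dict | None = field(default=None, repr=False)

    @property
    def k_focal(self) -> float:
        if self.model.focal is None:
            return 1.0
        return float(self.k[self.model._ifocal])

    def _full_loglik(self, phi: np.ndarray) -> float:
        m = len(self.model.data)
        theta = np.exp(phi[:m])
        T = float(np.exp(phi[m]))
        k_focal = float(np.exp(phi[m + 1])) if self.model.focal is not None else 1.0
        k = self.model._kvec(k_focal)
        return hka_loglik(self.model.data, theta, T, k)

    def bse(self) -> dict[str, float]:
        """Asymptotic standard errors from the observed information matrix.

        Computed on the log scale and mapped back with the delta method;
        NaN where the information matrix is singular (e.g. k at a bound).
        """
        if self._bse_cache is not None:
            return self._bse_cache
        m = len(self.model.data)
        phi = np.log(np.concatenate([self.theta, [self.T]]))
        if self.model.focal is not None:
            phi = np.append(phi, np.log(max(self.k_focal, THETA_MIN)))
        d = len(phi)
        h = 1e-4
        H = np.zeros((d, d))
        f0 = self._full_loglik(phi)
        for i in range(d):
            for j in range(i, d):
                ei = np.zeros(d); ei[i] = h
                ej = np.zeros(d); ej[j] = h
                fpp = self._full_loglik(phi + ei + ej)
                fpm = self._full_loglik(phi + ei - ej)
                fmp = self._full_loglik(phi - ei + ej)
                fmm = self._full_loglik(phi - ei - ej)
                H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h * h)
        names = [f"theta_{lid}" for lid in self.model.locus_ids] + ["T"]
        if self.model.focal is not None:
            names.append("k_" + self.model.focal)
        values = list(self.theta) + [self.T] + ([self.k_focal] if self.model.focal is not None else [])
        try:
            cov = np.linalg.inv(-H)
            se_log = np.sqrt(np.clip(np.diag(cov), 0, np.inf))
            se = {nm: float(v * s) for nm, v, s in zip(names, values, se_log)}
        except np.linalg.LinAlgError:
            se = {nm: float("nan") for nm in names}
        self._bse_cache = se
        return se

    def summary(self) -> str:
        lines = []
        kind = "selection" if self.model.focal is not None else "neutral"
        lines.append(f"ML-HKA {kind} model")
        lines.append("=" * 58)
        lines.append(f"loci: {len(self.model.data)}   free parameters: {self.n_free}")
        lines.append(f"log-likelihood: {self.lnL:.4f}   converged: {self.converged}")
        se = self.bse()
        lines.append("-" * 58)
        lines.append(f"{'parameter':<20}{'estimate':>12}{'std err':>12}")
        for lid, th in zip(self.model.locus_ids, self.theta):
            lines.append(f"{'theta_' + lid:<20}{th:>12.4f}{se.get('theta_' + lid, float('nan')):>12.4f}")
        lines.append(f"{'T':<20}{self.T:>12.4f}{se.get('T', float('nan')):>12.4f}")
        if self.model.focal is not None:
            nm = "k_" + self.model.focal
            lines.append(f"{nm:<20}{self.k_focal:>12.4f}{se.get(nm, float('nan')):>12.4f}")
        lines.append("=" * 58)
        return "\n".join(lines)


@dataclass(frozen=True)
class HkaTestResult:
    """Likelihood-ratio test of selection at one focal locus."""

    locus_id: str
    pool: str
    lnL0: float
    lnL1: float
    lrt: float
    df: int
    p_value: float
    k_hat: float


def fit_neutral(data: Sequence[HkaLocusData], n_starts: int = 8, seed: int = 0) -> MLHKAResults:
    """Fit the strictly neutral model (all k = 1)."""
    return MLHKA(data).fit(n_starts=n_starts, seed=seed)


def fit_selection(
    data: Sequence[HkaLocusData], focal: str, n_starts: int = 8, seed: int = 0,
    k_bounds: tuple[float, float] = K_BOUNDS,
) -> MLHKAResults:
    """Fit the selection model with k free at the focal locus."""
    return MLHKA(data, focal=focal, k_bounds=k_bounds).fit(n_starts=n_starts, seed=seed)


def lrt_test(
    fit0: MLHKAResults, fit1: MLHKAResults, df: int = 2, pool: str = "", tol: float = 1e-6
) -> HkaTestResult:
    """Likelihood-ratio test of the selection model against the neutral model.

    LRT = max(0, 2·(lnL1 − lnL0)); p is the upper χ²(df) tail.  A selection
    fit falling below the neutral fit by more than ``tol`` draws a warning
    (optimizer noise) before clamping.
    """
    if fit1.model.focal is None:
        raise ValueError("fit1 must be a selection-model fit")
    delta = fit1.lnL - fit0.lnL
    if delta < -tol:
        warnings.warn(
            f"selection lnL below neutral lnL by {-delta:.3g}; clamping LRT to 0",
            RuntimeWarning,
        )
    lrt = max(0.0, 2.0 * delta)
    return HkaTestResult(
        locus_id=fit1.model.focal,
        pool=pool,
        lnL0=fit0.lnL,
        lnL1=fit1.lnL,
        lrt=lrt,
        df=df,
        p_value=float(chi2.sf(lrt, df)),
        k_hat=fit1.k_focal,
    )


def hka_test(
    data: Sequence[HkaLocusData], focal: str, df: int = 2, n_starts: int = 8,
    seed: int = 0, pool: str = "", k_bounds: tuple[float, float] = K_BOUNDS,
) -> HkaTestResult:
    """Convenience wrapper: neutral fit, selection fit, LRT."""
    fit0 = fit_neutral(data, n_starts=n_starts, seed=seed)
    fit1 = fit_selection(data, focal, n_starts=n_starts, seed=seed, k_bounds=k_bounds)
    return lrt_test(fit0, fit1, df=df, pool=pool)


# -- count-table plumbing --------------------------------------------------

_COUNT_COLS = ["locus", "pool", "role", "S", "D", "L", "n"]


def read_count_table(path: str | Path) -> pd.DataFrame:
    """Read a per-locus count table (TSV: locus, pool, role, S, D, L, n)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(_COUNT_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: count table missing columns {sorted(missing)}")
    return df


def write_count_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=[c for c in _COUNT_COLS if c in df.columns])


def locus_data_from_frame(df: pd.DataFrame, pool: str) -> list[HkaLocusData]:
    """Extract one pool's loci from a count table as :class:`HkaLocusData`."""
    sub = df[df["pool"] == pool]
    out = []
    for row in sub.itertuples(index=False):
        out.append(
            HkaLocusData(
                locus_id=str(row.locus), S=int(row.S), D=int(round(row.D)),
                L=int(row.L), n=int(row.n),
                role="neutral" if str(row.role).startswith("neutral") else "candidate",
                D_exact=float(row.D),
            )
        )
    return out
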