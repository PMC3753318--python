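"""Storey q-value false-discovery-rate control.

The q-value of a test is the minimum FDR at which it is called significant.
Storey's procedure sharpens Benjamini–Hochberg by estimating the proportion
π0 of true nulls from the flat right tail of the p-value distribution:
π̂0(λ) = #{p > λ} / (m(1 − λ)) over a grid of λ, smoothed with a cubic fit
and evaluated at the largest λ.  With π0 = 1 the q-values reduce exactly to
Benjamini–Hochberg adjusted p-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["QValueResult", "estimate_pi0", "storey_qvalues", "DEFAULT_LAMBDA_GRID"]

DEFAULT_LAMBDA_GRID = np.round(np.arange(0.05, 0.901, 0.05), 2)

_MIN_M_FOR_SMOOTHER = 10


@dataclass(frozen=True)
class QValueResult:
    p_values: np.ndarray
    q_values: np.ndarray
    pi0: float
    lambda_grid: np.ndarray


def _check_p(p_values) -> np.ndarray:
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-D array")
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return p


def estimate_pi0(p_values, lambda_grid=DEFAULT_LAMBDA_GRID) -> float:
    """Estimate the null proportion π0 from a p-value vector.

    Uses the cubic-smoother estimate evaluated at the largest λ of the grid,
    clamped to (0, 1].  With fewer than 10 p-values the smoother is
    unreliable, so a fixed λ = 0.5 estimator is used instead (with a warning).
    """
    p = _check_p(p_values)
    m = p.size
    lam = np.asarray(lambda_grid, dtype=float)
    if m < _MIN_M_FOR_SMOOTHER:
        warnings.warn(
            f"only {m} p-values: falling back to fixed lambda=0.5 pi0 estimator",
            RuntimeWarning,
        )
        pi0 = (p > 0.5).sum() / (m * 0.5)
        return float(min(max(pi0, 1.0 / m), 1.0))
    pi0_lam = np.array([(p > l).sum() / (m * (1.0 - l)) for l in lam])
    coef = np.polyfit(lam, pi0_lam, 3)
    pi0 = float(np.polyval(coef, lam.max()))
    return float(min(max(pi0, 1e-8), 1.0))


def storey_qvalues(p_values, lambda_grid=DEFAULT_LAMBDA_GRID, pi0: float | None = None) -> QValueResult:
    """Storey q-values: step-up minimum q_(i) = min_{j≥i} π̂0·m·p_(j)/j.

    ``pi0`` may be supplied to bypass estimation (e.g. 1.0 to obtain plain
    Benjamini–Hochberg adjusted p-values).
    """
    p = _check_p(p_values)
    lam = np.asarray(lambda_grid, dtype=float)
    if pi0 is None:
        pi0 = estimate_pi0(p, lam)
    if not (0.0 < pi0 <= 1.0):
        raise ValueError("pi0 must be in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ps = p[order]
    q_sorted = pi0 * m * ps / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return QValueResult(p_values=p, q_values=q, pi0=float(pi0), lambda_grid=lam)
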