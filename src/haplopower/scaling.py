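"""Scaled noncentrality statistics and the 2x2 arcsine closed-form power.

The central quantity is the squared standardized difference between the
risky-category frequency in cases (p1) and in controls (p0), pooled over
both arms:

    N_scaled(p0, p1, N)       = N (p1 - p0)^2 / (2 pbar (1 - pbar))
    N_sc(p0, p1, N_ca, N_co)  = (p1 - p0)^2 / (pbar (1 - pbar) (1/N_ca + 1/N_co))

with pbar = (p0 + p1) / 2. N_sc generalizes N_scaled to unequal arms and
reduces to it exactly when N_ca = N_co = N. For 2x2 tables and large
samples, the observed-table analogue of this statistic is chi-square with
one degree of freedom under the null — it is the score statistic of the
two-proportion comparison.

Because N_sc is symmetric and harmonic in the arm sizes, it has a finite
limit (p1 - p0)^2 N_ca / (pbar (1 - pbar)) as N_co grows with N_ca fixed:
adding controls beyond a point cannot buy more power. Power decays as more
categories are tested; dividing N_sc by N_H**0.37 (N_H = number of
categories) empirically collapses the power-versus-N_sc curves for
different table widths onto a single curve in the useful power regime
(above ~50%); an exponent of 0.5 fits better below 50% power. The 0.37
constant is empirical, so it is exposed as a parameter.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .design import InputError

__all__ = [
    "n_scaled",
    "n_sc",
    "n_sc_corrected",
    "power_arcsine_2x2",
    "HAPLOGROUP_EXPONENT",
]

#: empirical exponent of the category-number correction
HAPLOGROUP_EXPONENT = 0.37


def _check_freqs(p0: float, p1: float) -> None:
    p0 = np.asarray(p0)
    p1 = np.asarray(p1)
    if np.any(p0 <= 0) or np.any(p0 >= 1) or np.any(p1 <= 0) or np.any(p1 >= 1):
        raise InputError("frequencies must lie strictly in (0, 1)")


def n_scaled(p0: float, p1: float, n: float):
    """Scaled squared standardized frequency difference for equal arms.

    ``n`` is the per-arm sample size (total sample size 2n).
    """
    _check_freqs(p0, p1)
    if np.any(np.asarray(n) < 1):
        raise InputError("per-arm size must be >= 1")
    pbar = (np.asarray(p0) + np.asarray(p1)) / 2.0
    return n * (np.asarray(p1) - np.asarray(p0)) ** 2 / (2.0 * pbar * (1.0 - pbar))


def n_sc(p0: float, p1: float, n_cases: float, n_controls: float):
    """Generalization of :func:`n_scaled` to unequal case/control arms.

    Symmetric in the two arm sizes and driven by their harmonic mean;
    reduces exactly to ``n_scaled(p0, p1, N)`` at ``n_cases == n_controls``.
    """
    _check_freqs(p0, p1)
    n_ca = np.asarray(n_cases, dtype=float)
    n_co = np.asarray(n_controls, dtype=float)
    if np.any(n_ca < 1) or np.any(n_co < 1):
        raise InputError("both arm sizes must be >= 1")
    pbar = (np.asarray(p0) + np.asarray(p1)) / 2.0
    return (np.asarray(p1) - np.asarray(p0)) ** 2 / (
        pbar * (1.0 - pbar) * (1.0 / n_ca + 1.0 / n_co)
    )


def n_sc_corrected(
    p0: float,
    p1: float,
    n_cases: float,
    n_controls: float,
    n_haplogroups: int,
    exponent: float = HAPLOGROUP_EXPONENT,
):
    """N_sc divided by ``n_haplogroups ** exponent`` (default exponent 0.37)."""
    if np.any(np.asarray(n_haplogroups) < 2):
        raise InputError("the number of categories must be >= 2")
    return n_sc(p0, p1, n_cases, n_controls) / np.asarray(n_haplogroups) ** exponent


def power_arcsine_2x2(p0: float, p1: float, n: float, alpha: float = 0.05):
    """Closed-form power for a 2x2 design with equal arms of size ``n``.

    Uses the variance-stabilizing transform phi = 2 arcsin(sqrt(p)); with
    Delta = |phi1 - phi0| the two-sided test at level alpha has power

        Phi(Delta sqrt(n/2) - z_{1-alpha/2}) + Phi(-Delta sqrt(n/2) - z_{1-alpha/2})

    Both tails are included so the null (p1 == p0) returns exactly alpha.
    """
    _check_freqs(p0, p1)
    if np.any(np.asarray(n) < 1):
        raise InputError("per-arm size must be >= 1")
    if not 0 < alpha < 1:
        raise InputError(f"alpha={alpha} must lie in (0, 1)")
    phi0 = 2.0 * np.arcsin(np.sqrt(np.asarray(p0, dtype=float)))
    phi1 = 2.0 * np.arcsin(np.sqrt(np.asarray(p1, dtype=float)))
    delta = np.abs(phi1 - phi0)
    shift = delta * np.sqrt(np.asarray(n, dtype=float) / 2.0)
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    return stats.norm.cdf(shift - z) + stats.norm.cdf(-shift - z)
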