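"""Inverse design problems: N_sc* calibration, sample sizes, detectable effects.

The forward Monte-Carlo machinery maps a scenario (spectrum, effect, arm
sizes) to a power value. Design questions run the other way: how many cases
or controls buy a target power beta at level alpha, and what is the smallest
effect a fixed design can detect? These inversions all route through a
single scalar, the corrected noncentrality statistic
``N_sc / N_H**0.37`` (see :mod:`haplopower.scaling`): simulation shows that
power is, to good approximation, a function of this scalar alone, so a
target power translates into a threshold ``n_sc_star(alpha, beta)`` and the
design questions reduce to algebra on N_sc.

The threshold itself is calibrated empirically: Monte-Carlo power is
simulated over a factorial grid of scenarios (table widths, risky
frequencies, effect sizes, arm sizes and ratios), power is regressed on the
corrected N_sc with a local-linear Gaussian-kernel estimator
(leave-one-out cross-validated bandwidth), the fitted curve is made
monotone by rearrangement, and its inverse is read off at each beta.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import isotonic_regression

from .design import EffectSpec, InputError
from .pvalues import asymptotic_pvalues_batch, resampled_pvalues_batch
from .scaling import HAPLOGROUP_EXPONENT, n_sc, n_sc_corrected
from .tables import simulate_batch

__all__ = [
    "CalibrationGrid",
    "CalibrationRangeError",
    "FittedPowerCurve",
    "NscCalibration",
    "SampleSizeResult",
    "MinDetectableEffect",
    "local_linear_smooth",
    "loo_cv_score",
    "fit_power_curve",
    "simulate_power_grid",
    "calibrate_nsc",
    "min_cases_given_ratio",
    "min_controls_given_cases",
    "min_cases_given_controls",
    "min_detectable_effect",
    "load_default_calibration",
]


class CalibrationRangeError(ValueError):
    """Requested power is outside the range the fitted curve attains."""


# --------------------------------------------------------------------------
# Local-linear Gaussian-kernel regression (1-D, closed form)

def local_linear_smooth(
    x: np.ndarray, y: np.ndarray, x_eval: np.ndarray, bandwidth: float
) -> np.ndarray:
    """Local-linear estimate of E[y|x] at ``x_eval`` with a Gaussian kernel.

    Uses the closed-form weighted-moments expression for the 1-D local
    linear estimator; eval points with essentially no kernel mass fall back
    to the nearest-neighbour value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x_eval = np.atleast_1d(np.asarray(x_eval, dtype=float))
    u = x[None, :] - x_eval[:, None]
    w = np.exp(-0.5 * (u / bandwidth) ** 2)
    s0 = w.sum(axis=1)
    s1 = (w * u).sum(axis=1)
    s2 = (w * u * u).sum(axis=1)
    denom = s0 * s2 - s1 * s1
    numer = (w * (s2[:, None] - s1[:, None] * u) * y).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = numer / denom
    bad = ~np.isfinite(out) | (denom <= 0)
    if bad.any():
        nearest = np.abs(u).argmin(axis=1)
        out[bad] = y[nearest[bad]]
    return out


def loo_cv_score(x: np.ndarray, y: np.ndarray, bandwidth: float) -> float:
    """Leave-one-out CV score of the local-linear fit, via the hat diagonal.

    For linear smoothers, the LOO residual is (y_i - yhat_i)/(1 - L_ii)
    where L_ii is the weight the fit at x_i puts on y_i itself.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    u = x[None, :] - x[:, None]
    w = np.exp(-0.5 * (u / bandwidth) ** 2)
    s0 = w.sum(axis=1)
    s1 = (w * u).sum(axis=1)
    s2 = (w * u * u).sum(axis=1)
    denom = s0 * s2 - s1 * s1
    if np.any(denom <= 0) or not np.all(np.isfinite(denom)):
        return np.inf
    yhat = (w * (s2[:, None] - s1[:, None] * u) * y).sum(axis=1) / denom
    l_ii = s2 / denom  # kernel weight at u = 0 is 1
    resid_scale = 1.0 - l_ii
    if np.any(resid_scale <= 1e-10):
        return np.inf
    return float(np.mean(((y - yhat) / resid_scale) ** 2))


@dataclass(frozen=True)
class FittedPowerCurve:
    """Monotone fitted power-versus-n_sc_corrected curve for one alpha."""

    grid: np.ndarray
    fitted: np.ndarray
    bandwidth: float

    def invert(self, beta: float) -> float:
        """Smallest x on the grid where the monotone fit reaches ``beta``."""
        lo, hi = float(self.fitted[0]), float(self.fitted[-1])
        if not lo <= beta <= hi:
            raise CalibrationRangeError(
                f"power {beta} is outside the fitted curve's attainable range "
                f"[{lo:.3f}, {hi:.3f}]"
            )
        idx = int(np.searchsorted(self.fitted, beta))
        if idx == 0:
            return float(self.grid[0])
        x0, x1 = self.grid[idx - 1], self.grid[idx]
        y0, y1 = self.fitted[idx - 1], self.fitted[idx]
        if y1 == y0:
            return float(x1)
        return float(x0 + (beta - y0) * (x1 - x0) / (y1 - y0))

    def __call__(self, x: float | np.ndarray) -> np.ndarray:
        return np.interp(np.asarray(x, dtype=float), self.grid, self.fitted)


#: points beyond this power level are treated as saturated when choosing
#: the regression window
_SATURATION = 0.995
#: widen the window past the last unsaturated point by this factor
_WINDOW_MARGIN = 1.2


def fit_power_curve(
    x: Sequence[float],
    y: Sequence[float],
    bandwidths: Sequence[float] | None = None,
    grid_size: int = 1500,
) -> FittedPowerCurve:
    """Fit power on n_sc_corrected: local-linear + CV bandwidth + monotone.

    The regression is restricted to the informative window: scenario points
    far beyond saturation (power indistinguishable from 1) carry no
    information about the curve's rise, but their sparse, isolated x values
    would force the leave-one-out criterion onto absurdly wide bandwidths.
    The window keeps everything up to ``_WINDOW_MARGIN`` times the largest
    x whose power is still below ``_SATURATION``.

    Bandwidths default to a log-spaced grid from twice the median point
    spacing up to half the window span. The fitted curve is clipped to
    [0, 1] and made non-decreasing by isotonic (PAVA) rearrangement — an
    L2 projection, unbiased where the raw fit merely wiggles — before any
    inversion.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 5:
        raise InputError("need at least 5 scenario points to fit a power curve")
    unsat = y <= _SATURATION
    if unsat.any() and not unsat.all():
        cap = _WINDOW_MARGIN * x[unsat].max()
        keep = x <= cap
        x, y = x[keep], y[keep]
    order = np.argsort(x)
    x, y = x[order], y[order]
    if bandwidths is None:
        span = x[-1] - x[0]
        spacing = max(float(np.median(np.diff(x))), span / x.size, 1e-9)
        hi = max(span / 2.0, 4.0 * spacing)
        bandwidths = np.geomspace(2.0 * spacing, hi, 25)
    scores = [loo_cv_score(x, y, h) for h in bandwidths]
    best = float(np.asarray(bandwidths)[int(np.argmin(scores))])
    grid = np.linspace(x[0], x[-1], grid_size)
    fitted = np.clip(local_linear_smooth(x, y, grid, best), 0.0, 1.0)
    fitted = np.clip(isotonic_regression(fitted).x, 0.0, 1.0)
    return FittedPowerCurve(grid=grid, fitted=fitted, bandwidth=best)


# --------------------------------------------------------------------------
# Simulation grid and calibration

@dataclass(frozen=True)
class CalibrationGrid:
    """Factorial scenario grid for calibrating n_sc_star.

    Defaults span the design space over which the single-curve collapse
    holds: table widths 4-20, common-to-rare risky frequencies, effect
    sizes from +25% to +100%, case arms 100-1000 and control:case ratios
    1-3, with the non-risky frequency mass split uniformly.
    """

    n_haplogroups: tuple[int, ...] = (4, 8, 12, 16, 20)
    risky_freqs: tuple[float, ...] = (0.30, 0.15, 0.05)
    deviations: tuple[float, ...] = (1.0, 0.5, 0.25)
    n_cases: tuple[int, ...] = (100, 250, 500, 750, 1000)
    ratios: tuple[float, ...] = (1.0, 2.0, 3.0)
    n_sim: int = 2_000
    method: str = "asymptotic"
    n_perm: int = 1_000

    def scenarios(self):
        yield from itertools.product(
            self.n_haplogroups,
            self.risky_freqs,
            self.deviations,
            self.n_cases,
            self.ratios,
        )

    def describe(self) -> dict[str, Any]:
        return asdict(self)


def _uniform_rest_freqs(p0: float, k: int) -> np.ndarray:
    """Spectrum with risky frequency first and the rest split uniformly."""
    freqs = np.full(k, (1.0 - p0) / (k - 1))
    freqs[0] = p0
    return freqs


def simulate_power_grid(
    grid: CalibrationGrid,
    alphas: Sequence[float],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Monte-Carlo power for every grid scenario, at every alpha at once.

    Returns one row per scenario with the raw ``n_sc`` value and a
    ``power_<alpha>`` column per significance level (a single batch of
    simulated tables serves all alphas: power is the fraction of p-values
    below each threshold).
    """
    alphas = [float(a) for a in alphas]
    rows = []
    for n_h, p0, delta, n_ca, ratio in grid.scenarios():
        p1 = p0 * (1.0 + delta)
        n_co = int(round(ratio * n_ca))
        q0 = _uniform_rest_freqs(p0, n_h)
        q1 = q0 * ((1.0 - p1) / (1.0 - p0))
        q1[0] = p1
        ctrl, case = simulate_batch(q0, q1, n_co, n_ca, grid.n_sim, rng)
        if grid.method == "asymptotic":
            pvals = asymptotic_pvalues_batch(ctrl, case)
        else:
            pvals = resampled_pvalues_batch(ctrl, case, grid.n_perm, rng, grid.method)
        row = {
            "n_haplogroups": n_h,
            "p0": p0,
            "deviation": delta,
            "p1": p1,
            "n_cases": n_ca,
            "n_controls": n_co,
            "ratio": ratio,
            "n_sc": float(n_sc(p0, p1, n_ca, n_co)),
        }
        for a in alphas:
            row[f"power_{a:g}"] = float((pvals < a).mean())
        rows.append(row)
    return pd.DataFrame(rows)


def collapse_spread(
    scenarios: pd.DataFrame,
    exponent: float,
    power_window: tuple[float, float],
    alpha: float = 0.05,
    bandwidth: float | None = None,
    n_eval: int = 400,
) -> float:
    """Vertical spread of per-N_H power curves at matched corrected N_sc.

    Diagnoses how well dividing N_sc by ``N_H**exponent`` collapses the
    power curves of different table widths onto one curve. Fits one curve
    per N_H group (shared bandwidth: CV on the pooled cloud unless given),
    evaluates all of them on the common support, and returns the maximum
    max-minus-min across groups over the region where the mean fitted power
    lies inside ``power_window``.
    """
    col = f"power_{alpha:g}"
    x_all = scenarios["n_sc"].to_numpy() / scenarios["n_haplogroups"].to_numpy() ** exponent
    y_all = scenarios[col].to_numpy()
    if bandwidth is None:
        bandwidth = fit_power_curve(x_all, y_all).bandwidth
    curves = []
    for _, sub in scenarios.groupby("n_haplogroups"):
        x = sub["n_sc"].to_numpy() / sub["n_haplogroups"].to_numpy() ** exponent
        y = sub[col].to_numpy()
        order = np.argsort(x)
        x, y = x[order], y[order]
        unsat = y <= _SATURATION
        if unsat.any() and not unsat.all():
            keep = x <= _WINDOW_MARGIN * x[unsat].max()
            x, y = x[keep], y[keep]
        curves.append((x, y))
    lo = max(c[0][0] for c in curves)
    hi = min(c[0][-1] for c in curves)
    if hi <= lo:
        raise InputError("per-group supports do not overlap")
    grid = np.linspace(lo, hi, n_eval)
    vals = np.vstack(
        [
            np.clip(
                isotonic_regression(
                    np.clip(local_linear_smooth(x, y, grid, bandwidth), 0, 1)
                ).x,
                0,
                1,
            )
            for x, y in curves
        ]
    )
    mean = vals.mean(axis=0)
    mask = (mean > power_window[0]) & (mean < power_window[1])
    if not mask.any():
        raise InputError(
            f"no evaluation points with mean power in {power_window}"
        )
    return float((vals[:, mask].max(axis=0) - vals[:, mask].min(axis=0)).max())


@dataclass
class NscCalibration:
    """Calibrated (alpha, beta) -> n_sc_star lookup with its fitted curves."""

    table: pd.DataFrame  # columns: alpha, beta, n_sc_star
    curves: dict[float, FittedPowerCurve] = field(default_factory=dict)
    metadata: dict[str, Any] = field(default_factory=dict)

    def n_sc_star(self, alpha: float, beta: float) -> float:
        """Threshold on the corrected N_sc delivering power beta at level alpha."""
        exact = self.table[
            (np.isclose(self.table["alpha"], alpha, atol=1e-12))
            & (np.isclose(self.table["beta"], beta, atol=1e-12))
        ]
        if len(exact):
            return float(exact["n_sc_star"].iloc[0])
        if alpha in self.curves:
            return self.curves[alpha].invert(beta)
        sub = self.table[np.isclose(self.table["alpha"], alpha, atol=1e-12)]
        if len(sub) >= 2:
            sub = sub.sort_values("beta")
            betas = sub["beta"].to_numpy()
            if betas[0] <= beta <= betas[-1]:
                return float(np.interp(beta, betas, sub["n_sc_star"].to_numpy()))
            raise CalibrationRangeError(
                f"beta={beta} outside tabulated range [{betas[0]}, {betas[-1]}] "
                f"for alpha={alpha}"
            )
        raise CalibrationRangeError(
            f"alpha={alpha} not in this calibration "
            f"(available: {sorted(set(self.table['alpha']))})"
        )

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False, float_format="%.10g")
        sidecar = Path(path).with_suffix(".json")
        meta = dict(self.metadata)
        meta["bandwidths"] = {
            f"{a:g}": c.bandwidth for a, c in self.curves.items()
        }
        sidecar.write_text(json.dumps(meta, indent=2, sort_keys=True))

    @classmethod
    def from_csv(cls, path: str | Path) -> "NscCalibration":
        table = pd.read_csv(path)
        missing = {"alpha", "beta", "n_sc_star"} - set(table.columns)
        if missing:
            raise InputError(f"{path}: calibration CSV lacks columns {missing}")
        sidecar = Path(path).with_suffix(".json")
        metadata = json.loads(sidecar.read_text()) if sidecar.exists() else {}
        return cls(table=table, metadata=metadata)


def calibrate_nsc(
    alpha_grid: Sequence[float],
    beta_grid: Sequence[float],
    grid: CalibrationGrid | None = None,
    rng: np.random.Generator | None = None,
    exponent: float = HAPLOGROUP_EXPONENT,
    seed: int | None = None,
) -> NscCalibration:
    """Calibrate n_sc_star(alpha, beta) by simulation + kernel regression.

    For every scenario in ``grid`` the Monte-Carlo power is estimated once;
    per alpha, power is regressed on ``n_sc / N_H**exponent`` and the
    monotone fitted curve inverted at each beta. Betas outside a curve's
    attainable range yield NaN in the table (and raise on direct lookup).
    """
    if grid is None:
        grid = CalibrationGrid()
    if rng is None:
        rng = np.random.default_rng(seed)
    scen = simulate_power_grid(grid, alpha_grid, rng)
    x_all = scen["n_sc"].to_numpy() / scen["n_haplogroups"].to_numpy() ** exponent
    curves: dict[float, FittedPowerCurve] = {}
    records = []
    for a in alpha_grid:
        y = scen[f"power_{a:g}"].to_numpy()
        curve = fit_power_curve(x_all, y)
        curves[float(a)] = curve
        for b in beta_grid:
            try:
                star = curve.invert(float(b))
            except CalibrationRangeError:
                star = np.nan
            records.append({"alpha": float(a), "beta": float(b), "n_sc_star": star})
    table = pd.DataFrame(records)
    meta = {
        "kernel": "gaussian",
        "estimator": "local_linear",
        "bandwidth_selection": "leave-one-out CV over a log-spaced grid",
        "exponent": exponent,
        "grid": grid.describe(),
        "seed": seed,
    }
    return NscCalibration(table=table, curves=curves, metadata=meta)


def load_default_calibration() -> NscCalibration:
    """The calibration shipped with the package (seed recorded in metadata)."""
    data = resources.files("haplopower").joinpath("data")
    with resources.as_file(data.joinpath("default_calibration.csv")) as p:
        return NscCalibration.from_csv(p)


# --------------------------------------------------------------------------
# Sample-size and detectable-effect inversions

@dataclass(frozen=True)
class SampleSizeResult:
    """Outcome of a minimum-sample-size computation."""

    feasible: bool
    n_cases_min: int | None
    n_controls_min: int | None
    ratio: float | None
    achieved_n_sc_corrected: float | None
    n_sc_star: float
    limit_n_sc_corrected: float | None = None
    sup_power: float | None = None

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)


@dataclass(frozen=True)
class MinDetectableEffect:
    """Smallest detectable deviation for a fixed design, with p1 and OR."""

    feasible: bool
    delta_min: float | None
    p1_min: float | None
    or_min: float | None
    n_sc_star: float
    max_n_sc_corrected: float | None = None

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)


def _effect_p1(effect: EffectSpec | float, p0: float) -> float:
    if isinstance(effect, EffectSpec):
        return effect.case_freq(p0)
    # a bare float is taken as a relative deviation delta
    return EffectSpec(risky_index=0, deviation=float(effect)).case_freq(p0)


def min_cases_given_ratio(
    n_sc_star: float,
    ratio: float,
    p0: float,
    effect: EffectSpec | float,
    n_haplogroups: int,
    exponent: float = HAPLOGROUP_EXPONENT,
) -> SampleSizeResult:
    """Minimum cases N (controls = floor(ratio * N)) reaching n_sc_star.

    Returns the smallest integer N with corrected N_sc at (N, floor(r N))
    at or above the threshold; decrementing N by one violates the bound.
    Always feasible: N_sc grows without bound along a fixed-ratio path.
    """
    if ratio <= 0:
        raise InputError("ratio must be positive")
    if n_sc_star <= 0:
        raise InputError("n_sc_star must be positive")
    p1 = _effect_p1(effect, p0)
    if p1 == p0:
        raise InputError("a null effect has no finite sample size")

    def ok(n: int) -> bool:
        n_co = max(1, int(np.floor(ratio * n)))
        val = n_sc_corrected(p0, p1, n, n_co, n_haplogroups, exponent)
        return bool(val >= n_sc_star - 1e-12)

    pbar = (p0 + p1) / 2.0
    warm = (
        n_sc_star
        * n_haplogroups**exponent
        * pbar
        * (1.0 - pbar)
        * (1.0 + 1.0 / ratio)
        / (p1 - p0) ** 2
    )
    n = max(1, int(np.floor(warm)) - 2)
    while not ok(n):
        n += 1
    while n > 1 and ok(n - 1):
        n -= 1
    n_co = max(1, int(np.floor(ratio * n)))
    return SampleSizeResult(
        feasible=True,
        n_cases_min=n,
        n_controls_min=n_co,
        ratio=ratio,
        achieved_n_sc_corrected=float(
            n_sc_corrected(p0, p1, n, n_co, n_haplogroups, exponent)
        ),
        n_sc_star=float(n_sc_star),
    )


def _min_opposite_arm(
    n_sc_star: float,
    n_fixed: int,
    p0: float,
    effect: EffectSpec | float,
    n_haplogroups: int,
    exponent: float,
    calibration: NscCalibration | None,
    alpha: float | None,
) -> tuple[bool, int | None, float | None, float | None, float | None]:
    """Shared solver: N_sc is symmetric in the arms, so both directions
    reduce to solving 1/N_free = (p1-p0)^2 / (star * N_H^e * pbar(1-pbar)) - 1/N_fixed."""
    if n_fixed < 1:
        raise InputError("the fixed arm must have at least one individual")
    if n_sc_star <= 0:
        raise InputError("n_sc_star must be positive")
    p1 = _effect_p1(effect, p0)
    if p1 == p0:
        raise InputError("a null effect has no finite sample size")
    pbar = (p0 + p1) / 2.0
    rhs = (p1 - p0) ** 2 / (
        n_sc_star * n_haplogroups**exponent * pbar * (1.0 - pbar)
    ) - 1.0 / n_fixed
    limit = float(
        (p1 - p0) ** 2 * n_fixed / (pbar * (1.0 - pbar)) / n_haplogroups**exponent
    )
    if rhs <= 0:
        sup_power = None
        if calibration is not None and alpha is not None:
            curve = calibration.curves.get(float(alpha))
            if curve is not None:
                sup_power = float(curve(limit))
        return False, None, None, limit, sup_power

    def ok(n_free: int) -> bool:
        val = n_sc_corrected(p0, p1, n_fixed, n_free, n_haplogroups, exponent)
        return bool(val >= n_sc_star - 1e-12)

    n_free = max(1, int(np.ceil(1.0 / rhs)) - 2)
    while not ok(n_free):
        n_free += 1
    while n_free > 1 and ok(n_free - 1):
        n_free -= 1
    achieved = float(
        n_sc_corrected(p0, p1, n_fixed, n_free, n_haplogroups, exponent)
    )
    return True, n_free, achieved, None, None


def min_controls_given_cases(
    n_sc_star: float,
    n_cases: int,
    p0: float,
    effect: EffectSpec | float,
    n_haplogroups: int,
    exponent: float = HAPLOGROUP_EXPONENT,
    calibration: NscCalibration | None = None,
    alpha: float | None = None,
) -> SampleSizeResult:
    """Minimum controls for fixed cases; may be infeasible (power ceiling).

    Because N_sc is harmonic in the arm sizes, a fixed case arm caps the
    achievable N_sc no matter how many controls are added. When the target
    exceeds that cap the result is marked infeasible and carries the
    limiting corrected N_sc (and, when a calibration with fitted curves is
    supplied, the supremum power it corresponds to).
    """
    feasible, n_free, achieved, limit, sup_power = _min_opposite_arm(
        n_sc_star, n_cases, p0, effect, n_haplogroups, exponent, calibration, alpha
    )
    return SampleSizeResult(
        feasible=feasible,
        n_cases_min=n_cases if feasible else None,
        n_controls_min=n_free,
        ratio=(n_free / n_cases) if feasible else None,
        achieved_n_sc_corrected=achieved,
        n_sc_star=float(n_sc_star),
        limit_n_sc_corrected=limit,
        sup_power=sup_power,
    )


def min_cases_given_controls(
    n_sc_star: float,
    n_controls: int,
    p0: float,
    effect: EffectSpec | float,
    n_haplogroups: int,
    exponent: float = HAPLOGROUP_EXPONENT,
    calibration: NscCalibration | None = None,
    alpha: float | None = None,
) -> SampleSizeResult:
    """Mirror of :func:`min_controls_given_cases` with the control arm fixed."""
    feasible, n_free, achieved, limit, sup_power = _min_opposite_arm(
        n_sc_star, n_controls, p0, effect, n_haplogroups, exponent, calibration, alpha
    )
    return SampleSizeResult(
        feasible=feasible,
        n_cases_min=n_free,
        n_controls_min=n_controls if feasible else None,
        ratio=(n_controls / n_free) if feasible else None,
        achieved_n_sc_corrected=achieved,
        n_sc_star=float(n_sc_star),
        limit_n_sc_corrected=limit,
        sup_power=sup_power,
    )


def min_detectable_effect(
    n_cases: int,
    n_controls: int,
    p0: float,
    n_haplogroups: int,
    n_sc_star: float,
    exponent: float = HAPLOGROUP_EXPONENT,
) -> MinDetectableEffect:
    """Smallest relative deviation delta > 0 detectable by a fixed design.

    Solves n_sc_corrected(p0, p0 (1+delta)) = n_sc_star by bisection
    (Brent's method, relative tolerance 1e-10); the case frequency is capped
    below 1, so a design can be too small for any admissible effect, in
    which case the result is infeasible and reports the maximum corrected
    N_sc reachable as p1 -> 1.
    """
    from scipy.optimize import brentq

    if not 0 < p0 < 1:
        raise InputError(f"p0={p0} must lie strictly in (0, 1)")
    if n_sc_star <= 0:
        raise InputError("n_sc_star must be positive")
    p1_cap = 1.0 - 1e-9
    delta_cap = p1_cap / p0 - 1.0

    def gap(delta: float) -> float:
        p1 = p0 * (1.0 + delta)
        return float(
            n_sc_corrected(p0, p1, n_cases, n_controls, n_haplogroups, exponent)
            - n_sc_star
        )

    if gap(delta_cap) < 0:
        return MinDetectableEffect(
            feasible=False,
            delta_min=None,
            p1_min=None,
            or_min=None,
            n_sc_star=float(n_sc_star),
            max_n_sc_corrected=float(gap(delta_cap) + n_sc_star),
        )
    delta = float(brentq(gap, 1e-15, delta_cap, rtol=1e-10, maxiter=500))
    p1 = p0 * (1.0 + delta)
    from .design import effect_as_or

    return MinDetectableEffect(
        feasible=True,
        delta_min=delta,
        p1_min=p1,
        or_min=float(effect_as_or(p0, p1)),
        n_sc_star=float(n_sc_star),
    )
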