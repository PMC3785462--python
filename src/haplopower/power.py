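"""Monte-Carlo estimation of a-priori and a-posteriori statistical power.

Power is estimated as the fraction of simulated 2xk tables whose p-value
falls strictly below the significance level. Tables are simulated as two
independent multinomial arms: the control arm from the null spectrum, the
case arm from the effect-shifted frequencies. Under the null effect
(delta = 0) the same machinery estimates the type-I error, which should sit
near alpha for a well-calibrated test.

A-posteriori power follows the prospective convention: the observed row
proportions and row totals of a study's table are treated as the true
frequencies and design, and power is then estimated exactly as a priori.
(This is *not* the post-hoc "observed power" transformation of the p-value,
which is widely criticised; here the observed study only supplies the
scenario.)
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Any

import numpy as np

from . import __version__
from .design import (
    CategorySpectrum,
    EffectSpec,
    StudyDesign,
    InputError,
    build_case_frequencies,
)
from .pvalues import asymptotic_pvalues_batch, resampled_pvalues_batch
from .tables import CountTable2xK, simulate_batch

__all__ = ["PowerEstimate", "estimate_power", "posthoc_power", "power_from_freqs"]


@dataclass(frozen=True)
class PowerEstimate:
    """Monte-Carlo power estimate with its binomial standard error."""

    power: float
    mc_se: float
    n_sim: int
    alpha: float
    method: str
    n_perm: int
    n_cases: int
    n_controls: int
    seed: int | None
    settings: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        assert 0.0 <= self.power <= 1.0 and self.mc_se >= 0.0

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["software_version"] = __version__
        return d

    def to_json(self, **kwargs: Any) -> str:
        kwargs.setdefault("indent", 2)
        return json.dumps(self.to_dict(), **kwargs)


def power_from_freqs(
    control_freqs: np.ndarray,
    case_freqs: np.ndarray,
    n_controls: int,
    n_cases: int,
    alpha: float = 0.05,
    method: str = "permutation",
    n_sim: int = 10_000,
    n_perm: int = 1_000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    settings: dict[str, Any] | None = None,
) -> PowerEstimate:
    """Core Monte-Carlo power loop on raw frequency vectors.

    ``estimate_power`` and ``posthoc_power`` are thin wrappers around this;
    calling it with identical arguments and seed reproduces them exactly.
    """
    if not 0 < alpha <= 1:
        raise InputError(f"alpha={alpha} must lie in (0, 1]")
    if rng is None:
        rng = np.random.default_rng(seed)
    ctrl, case = simulate_batch(
        control_freqs, case_freqs, n_controls, n_cases, n_sim, rng
    )
    if method == "asymptotic":
        pvals = asymptotic_pvalues_batch(ctrl, case)
    else:
        pvals = resampled_pvalues_batch(ctrl, case, n_perm, rng, method=method)
    power = float((pvals < alpha).mean())
    mc_se = float(np.sqrt(power * (1.0 - power) / n_sim))
    return PowerEstimate(
        power=power,
        mc_se=mc_se,
        n_sim=n_sim,
        alpha=alpha,
        method=method,
        n_perm=0 if method == "asymptotic" else n_perm,
        n_cases=n_cases,
        n_controls=n_controls,
        seed=seed,
        settings=settings or {},
    )


def estimate_power(
    spectrum: CategorySpectrum,
    effect: EffectSpec,
    design: StudyDesign,
    rng: np.random.Generator | None = None,
) -> PowerEstimate:
    """A-priori power of a 2xk case-control design under a specified effect."""
    case_freqs = build_case_frequencies(spectrum, effect)
    p0 = float(spectrum.freqs[effect.risky_index])
    return power_from_freqs(
        spectrum.freqs,
        case_freqs,
        design.n_controls,
        design.n_cases,
        alpha=design.alpha,
        method=design.method,
        n_sim=design.n_sim,
        n_perm=design.n_perm,
        seed=design.seed,
        rng=rng,
        settings={
            "labels": list(spectrum.labels),
            "risky_index": effect.risky_index,
            "p0": p0,
            "p1": effect.case_freq(p0),
            "kind": "a_priori",
        },
    )


def posthoc_power(
    observed: CountTable2xK,
    alpha: float = 0.05,
    method: str = "permutation",
    n_sim: int = 10_000,
    n_perm: int = 1_000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> PowerEstimate:
    """Prospective power at the scenario defined by an observed table.

    Row proportions become the true arm frequencies and row totals the arm
    sizes. Categories with zero count in both rows carry no frequency
    information and are dropped first.
    """
    counts = observed.counts
    keep = counts.sum(axis=0) > 0
    counts = counts[:, keep]
    n_co, n_ca = int(counts[0].sum()), int(counts[1].sum())
    if n_co < 1 or n_ca < 1:
        raise InputError("both rows of the observed table must have counts")
    return power_from_freqs(
        counts[0] / n_co,
        counts[1] / n_ca,
        n_co,
        n_ca,
        alpha=alpha,
        method=method,
        n_sim=n_sim,
        n_perm=n_perm,
        seed=seed,
        rng=rng,
        settings={
            "kind": "a_posteriori",
            "observed_counts": counts.tolist(),
            "labels": list(np.asarray(observed.labels)[keep]) if observed.labels else None,
        },
    )
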