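"""Study-design data model: category spectra, effect specifications, designs.

A case-control association study over a 2xk table is described by three
pieces: the frequency spectrum of the k marker categories (haplogroups,
haplotypes, mtSNPs ...) in the control population, an effect specification
saying how one "risky" category is enriched in cases, and the study design
proper (arm sizes, significance level, p-value calibration method).

The effect admits three equivalent parameterizations:

* a relative deviation ``delta``: the risky frequency in cases is
  ``p1 = p0 * (1 + delta)``;
* the target case frequency ``p1`` itself;
* the odds ratio ``OR = (p1/(1-p1)) / (p0/(1-p0))``.

Whatever the parameterization, the frequency gained (or lost) by the risky
category is redistributed proportionally over the remaining categories, so no
non-risky category is a priori favoured.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CategorySpectrum",
    "EffectSpec",
    "StudyDesign",
    "InputError",
    "InfeasibleEffectError",
    "load_spectrum",
    "build_case_frequencies",
    "effect_as_or",
    "or_to_p1",
]

#: methods accepted by StudyDesign / the power engine
METHODS = ("asymptotic", "permutation", "fisher_mc")


class InputError(ValueError):
    """Malformed user input (CSV files, frequency vectors, parameters)."""


class InfeasibleEffectError(ValueError):
    """The requested effect would push a case frequency to 1 or beyond."""


@dataclass(frozen=True)
class CategorySpectrum:
    """Labeled frequency vector of the k categories in the control population.

    Frequencies must be strictly positive and are renormalized to sum to one;
    ``from_raw`` additionally warns when the raw values are off by more than
    1e-6 (printed literature frequencies frequently do not sum to 100%).
    """

    labels: tuple[str, ...]
    freqs: np.ndarray

    def __post_init__(self) -> None:
        freqs = np.asarray(self.freqs, dtype=float)
        if len(self.labels) != freqs.shape[0]:
            raise InputError(
                f"{len(self.labels)} labels but {freqs.shape[0]} frequencies"
            )
        if freqs.ndim != 1 or freqs.shape[0] < 2:
            raise InputError("a spectrum needs at least 2 categories")
        if not np.all(np.isfinite(freqs)) or np.any(freqs <= 0):
            bad = int(np.argmin(freqs))
            raise InputError(
                f"non-positive frequency for category {self.labels[bad]!r}: "
                f"{freqs[bad]!r} (zero-frequency categories are not allowed)"
            )
        if abs(freqs.sum() - 1.0) > 1e-9:
            raise InputError(
                f"frequencies sum to {freqs.sum():.6g}, not 1; "
                "use CategorySpectrum.from_raw to renormalize"
            )
        freqs = freqs / freqs.sum()  # exact renormalization at machine precision
        freqs.flags.writeable = False
        object.__setattr__(self, "labels", tuple(str(l) for l in self.labels))
        object.__setattr__(self, "freqs", freqs)

    @classmethod
    def from_raw(
        cls, labels: Sequence[str], freqs: Sequence[float]
    ) -> "CategorySpectrum":
        """Build a spectrum from raw frequencies, renormalizing to sum 1.

        Logs a warning when the raw sum deviates from 1 by more than 1e-6.
        """
        raw = np.asarray(freqs, dtype=float)
        if raw.ndim != 1 or raw.shape[0] < 2:
            raise InputError("a spectrum needs at least 2 categories")
        if not np.all(np.isfinite(raw)) or np.any(raw <= 0):
            bad = int(np.argmin(np.where(np.isfinite(raw), raw, -np.inf)))
            raise InputError(
                f"non-positive or non-numeric frequency for category "
                f"{labels[bad]!r}: {raw[bad]!r}"
            )
        total = raw.sum()
        if abs(total - 1.0) > 1e-6:
            logger.warning(
                "spectrum frequencies sum to %.6g, not 1; renormalizing", total
            )
        return cls(tuple(str(l) for l in labels), raw / total)

    @property
    def k(self) -> int:
        """Number of categories (the table width, N_H for haplogroups)."""
        return len(self.labels)

    def index_of(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise InputError(
                f"unknown category {label!r}; known: {', '.join(self.labels)}"
            ) from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"label": self.labels, "freq": self.freqs})


def load_spectrum(path: str | Path) -> CategorySpectrum:
    """Load a control-population spectrum from a ``label,freq`` CSV.

    The file must have a header line ``label,freq`` and at least two rows.
    Frequencies are renormalized to sum to one; a warning is logged when the
    raw sum deviates from 1 by more than 1e-6.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - normalize to a single error type
        raise InputError(f"cannot parse spectrum CSV {path}: {exc}") from exc
    cols = [c.strip().lower() for c in df.columns]
    if cols[:2] != ["label", "freq"]:
        raise InputError(
            f"{path}: expected header 'label,freq', found {list(df.columns)!r}"
        )
    if len(df) < 2:
        raise InputError(f"{path}: need at least 2 category rows, found {len(df)}")
    freqs = pd.to_numeric(df.iloc[:, 1], errors="coerce")
    if freqs.isna().any():
        row = int(freqs.isna().idxmax())
        raise InputError(
            f"{path}: non-numeric frequency in row {row + 2} "
            f"(label {df.iloc[row, 0]!r})"
        )
    if (freqs <= 0).any():
        row = int((freqs <= 0).idxmax())
        raise InputError(
            f"{path}: non-positive frequency {freqs[row]} in row {row + 2} "
            f"(label {df.iloc[row, 0]!r})"
        )
    return CategorySpectrum.from_raw(df.iloc[:, 0].astype(str).tolist(), freqs.to_numpy())


@dataclass(frozen=True)
class EffectSpec:
    """Which category is risky and how its case frequency deviates.

    Exactly one of ``deviation`` (relative increase delta, so that
    ``p1 = p0 * (1 + delta)``), ``target_case_freq`` (p1 itself) or
    ``odds_ratio`` must be given.
    """

    risky_index: int
    deviation: float | None = None
    target_case_freq: float | None = None
    odds_ratio: float | None = None

    def __post_init__(self) -> None:
        given = [
            v
            for v in (self.deviation, self.target_case_freq, self.odds_ratio)
            if v is not None
        ]
        if len(given) != 1:
            raise InputError(
                "exactly one of deviation, target_case_freq, odds_ratio "
                f"must be given; got {len(given)}"
            )
        if self.risky_index < 0:
            raise InputError("risky_index must be a non-negative category index")
        if self.deviation is not None and self.deviation < 0:
            raise InputError("deviation must be >= 0 (enrichment in cases)")
        if self.target_case_freq is not None and not (0 < self.target_case_freq < 1):
            raise InputError("target_case_freq must lie strictly in (0, 1)")
        if self.odds_ratio is not None and self.odds_ratio <= 0:
            raise InputError("odds_ratio must be positive")

    def case_freq(self, p0: float) -> float:
        """Risky-category frequency in cases, p1, given the control frequency."""
        if not 0 < p0 < 1:
            raise InputError(f"control frequency p0={p0} must lie in (0, 1)")
        if self.deviation is not None:
            p1 = p0 * (1.0 + self.deviation)
            if p1 >= 1.0:
                raise InfeasibleEffectError(
                    f"deviation {self.deviation} gives case frequency "
                    f"p1={p1:.4g} >= 1; maximum admissible deviation for "
                    f"p0={p0:.4g} is {1.0 / p0 - 1.0:.4g}"
                )
            return p1
        if self.target_case_freq is not None:
            return self.target_case_freq
        return or_to_p1(self.odds_ratio, p0)

    def delta(self, p0: float) -> float:
        """Relative deviation delta = p1/p0 - 1 implied for this p0."""
        return self.case_freq(p0) / p0 - 1.0

    def as_or(self, p0: float) -> float:
        """Odds ratio implied for this p0."""
        return effect_as_or(p0, self.case_freq(p0))


@dataclass(frozen=True)
class StudyDesign:
    """Arm sizes, significance level and calibration settings for one run."""

    n_cases: int
    n_controls: int
    alpha: float = 0.05
    method: str = "permutation"
    n_sim: int = 10_000
    n_perm: int = 1_000
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise InputError("both arms need at least one individual")
        if not 0 < self.alpha <= 1:
            raise InputError(f"alpha={self.alpha} must lie in (0, 1]")
        if self.method not in METHODS:
            raise InputError(f"method must be one of {METHODS}, got {self.method!r}")
        if self.n_sim < 1:
            raise InputError("n_sim must be >= 1")
        if self.method != "asymptotic" and self.n_perm < 1:
            raise InputError("n_perm must be >= 1 for resampling methods")

    @property
    def ratio(self) -> float:
        """Control-case ratio r = N_co / N_ca."""
        return self.n_controls / self.n_cases


def build_case_frequencies(
    spectrum: CategorySpectrum, effect: EffectSpec
) -> np.ndarray:
    """Case-arm frequency vector implied by a spectrum and an effect.

    The risky entry becomes ``p1``; every other entry ``q_j`` is scaled by
    ``(1 - p1) / (1 - p0)`` so the deficit is shared proportionally and the
    vector still sums to one.
    """
    if not 0 <= effect.risky_index < spectrum.k:
        raise InputError(
            f"risky_index {effect.risky_index} out of range for k={spectrum.k}"
        )
    p0 = float(spectrum.freqs[effect.risky_index])
    p1 = effect.case_freq(p0)
    out = spectrum.freqs * ((1.0 - p1) / (1.0 - p0))
    out[effect.risky_index] = p1
    return out / out.sum()


def effect_as_or(p0: float, p1: float) -> float:
    """Odds ratio of case frequency ``p1`` against control frequency ``p0``."""
    if not 0 < p0 < 1 or not 0 < p1 < 1:
        raise InputError(f"frequencies must lie strictly in (0, 1); got {p0}, {p1}")
    return (p1 / (1.0 - p1)) / (p0 / (1.0 - p0))


def or_to_p1(odds_ratio: float, p0: float) -> float:
    """Case frequency implied by an odds ratio and the control frequency."""
    if odds_ratio <= 0:
        raise InputError(f"odds_ratio must be positive, got {odds_ratio}")
    if not 0 < p0 < 1:
        raise InputError(f"p0 must lie strictly in (0, 1), got {p0}")
    odds = odds_ratio * p0 / (1.0 - p0)
    return odds / (1.0 + odds)
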