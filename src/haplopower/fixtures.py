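"""Packaged example spectra and synthetic scenario generation.

The ``euro11`` fixture is the classic European 11-haplogroup control
spectrum used throughout the mtDNA power literature. Its printed
percentages famously sum to 110%, and the fixture ships those values
verbatim so the discrepancy stays visible; loading renormalizes (with a
warning) to a proper probability vector.

Synthetic spectra are drawn from a symmetric Dirichlet: a large
concentration gives near-uniform categories, a small one gives the skewed,
one-common-many-rare shape typical of real haplogroup spectra.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .design import CategorySpectrum, InputError

__all__ = ["EURO11_LABELS", "EURO11_RAW_FREQS", "euro11_spectrum",
           "synthetic_spectrum", "make_fixture", "write_spectrum_csv"]

#: the 11 European haplogroup labels of the example spectrum
EURO11_LABELS = ("H", "I", "J", "K", "M", "T", "U", "V", "W", "X", "other")
#: the printed frequencies, verbatim — they sum to 1.10, not 1
EURO11_RAW_FREQS = (0.41, 0.02, 0.11, 0.08, 0.01, 0.13, 0.15, 0.13, 0.02, 0.02, 0.02)

FIXTURES = {"euro11": (EURO11_LABELS, EURO11_RAW_FREQS)}


def euro11_spectrum() -> CategorySpectrum:
    """The renormalized euro11 spectrum (logs the sum-110% warning)."""
    return CategorySpectrum.from_raw(EURO11_LABELS, EURO11_RAW_FREQS)


def synthetic_spectrum(
    k: int,
    concentration: float = 1.0,
    rng: np.random.Generator | None = None,
    uniform: bool = False,
) -> CategorySpectrum:
    """Random (or uniform) k-category spectrum, Dirichlet(concentration)."""
    if k < 2:
        raise InputError("need at least 2 categories")
    labels = tuple(f"cat{i + 1}" for i in range(k))
    if uniform:
        return CategorySpectrum(labels, np.full(k, 1.0 / k))
    if concentration <= 0:
        raise InputError("concentration must be positive")
    if rng is None:
        rng = np.random.default_rng()
    freqs = rng.dirichlet(np.full(k, concentration))
    # Dirichlet draws can underflow to 0 for tiny concentrations
    freqs = np.clip(freqs, 1e-12, None)
    return CategorySpectrum(labels, freqs / freqs.sum())


def write_spectrum_csv(
    path: str | Path, labels, freqs, renormalize: bool = False
) -> Path:
    """Write a ``label,freq`` CSV; by default the raw values go out verbatim."""
    freqs = np.asarray(freqs, dtype=float)
    if renormalize:
        freqs = freqs / freqs.sum()
    path = Path(path)
    pd.DataFrame({"label": labels, "freq": freqs}).to_csv(path, index=False)
    return path


def make_fixture(
    name: str | None = None,
    out: str | Path = "spectrum.csv",
    k: int | None = None,
    concentration: float = 1.0,
    uniform: bool = False,
    rng: np.random.Generator | None = None,
) -> Path:
    """Write a named or synthesized spectrum CSV and return its path.

    Named fixtures ship their literature values verbatim (euro11 therefore
    writes frequencies summing to 1.10 — renormalization happens on load).
    """
    if name is not None:
        if name not in FIXTURES:
            raise InputError(
                f"unknown fixture {name!r}; known: {sorted(FIXTURES)}"
            )
        labels, freqs = FIXTURES[name]
        return write_spectrum_csv(out, labels, freqs)
    if k is None:
        raise InputError("either a fixture name or a category count k is required")
    spec = synthetic_spectrum(k, concentration=concentration, rng=rng, uniform=uniform)
    return write_spectrum_csv(out, spec.labels, spec.freqs)
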