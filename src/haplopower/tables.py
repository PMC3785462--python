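"""2xk contingency tables and their multinomial simulation.

Tables have two rows — row 0 the control arm, row 1 the case arm — and one
column per category. Under both the null and the alternative the two arms are
simulated as independent multinomial draws with the arm size as the number of
trials.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .design import InputError

__all__ = ["CountTable2xK", "simulate_table", "simulate_batch", "load_table"]


@dataclass(frozen=True)
class CountTable2xK:
    """Observed or simulated 2xk counts (row 0 = controls, row 1 = cases)."""

    counts: np.ndarray
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape[0] != 2 or counts.shape[1] < 2:
            raise InputError(f"counts must be a 2xk matrix with k >= 2, got shape {counts.shape}")
        if not np.issubdtype(counts.dtype, np.integer):
            as_int = counts.astype(np.int64)
            if not np.array_equal(as_int, counts):
                raise InputError("counts must be integers")
            counts = as_int
        if np.any(counts < 0):
            raise InputError("counts must be non-negative")
        counts = np.ascontiguousarray(counts, dtype=np.int64)
        counts.flags.writeable = False
        labels = self.labels
        if labels is not None:
            labels = tuple(str(l) for l in labels)
            if len(labels) != counts.shape[1]:
                raise InputError(
                    f"{len(labels)} labels for {counts.shape[1]} columns"
                )
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "labels", labels)

    @property
    def k(self) -> int:
        return self.counts.shape[1]

    @property
    def n_controls(self) -> int:
        return int(self.counts[0].sum())

    @property
    def n_cases(self) -> int:
        return int(self.counts[1].sum())

    def to_csv(self, path: str | Path) -> None:
        labels = self.labels or tuple(f"cat{i}" for i in range(self.k))
        df = pd.DataFrame(self.counts, index=["controls", "cases"], columns=labels)
        df.to_csv(path, index_label="row")

    @classmethod
    def from_csv(cls, path: str | Path) -> "CountTable2xK":
        return load_table(path)


def load_table(path: str | Path) -> CountTable2xK:
    """Read a 2xk counts CSV: a label header, then a controls and a cases row."""
    path = Path(path)
    try:
        df = pd.read_csv(path, index_col=0)
    except Exception as exc:  # noqa: BLE001
        raise InputError(f"cannot parse table CSV {path}: {exc}") from exc
    rows = [str(r).strip().lower() for r in df.index]
    if sorted(rows) != ["cases", "controls"]:
        raise InputError(
            f"{path}: expected exactly a 'controls' and a 'cases' row, got {rows}"
        )
    df = df.iloc[[rows.index("controls"), rows.index("cases")]]
    counts = df.to_numpy()
    try:
        return CountTable2xK(counts, tuple(df.columns))
    except InputError as exc:
        raise InputError(f"{path}: {exc}") from exc


def simulate_table(
    control_freqs: Sequence[float],
    case_freqs: Sequence[float],
    n_controls: int,
    n_cases: int,
    rng: np.random.Generator,
    labels: Sequence[str] | None = None,
) -> CountTable2xK:
    """Draw one table: independent Multinomial(N_co, q0) and Multinomial(N_ca, q1)."""
    q0 = np.asarray(control_freqs, dtype=float)
    q1 = np.asarray(case_freqs, dtype=float)
    if q0.shape != q1.shape or q0.ndim != 1:
        raise InputError(
            f"control and case frequency vectors must have equal length; "
            f"got {q0.shape} and {q1.shape}"
        )
    counts = np.vstack(
        [rng.multinomial(n_controls, q0 / q0.sum()), rng.multinomial(n_cases, q1 / q1.sum())]
    )
    return CountTable2xK(counts, tuple(labels) if labels is not None else None)


def simulate_batch(
    control_freqs: Sequence[float],
    case_freqs: Sequence[float],
    n_controls: int,
    n_cases: int,
    n_sim: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``n_sim`` independent tables, vectorized.

    Returns a pair of ``(n_sim, k)`` integer arrays: control rows and case
    rows. Each pair of rows i is one simulated 2xk table.
    """
    if n_sim < 1:
        raise InputError("n_sim must be >= 1")
    q0 = np.asarray(control_freqs, dtype=float)
    q1 = np.asarray(case_freqs, dtype=float)
    if q0.shape != q1.shape or q0.ndim != 1:
        raise InputError("control and case frequency vectors must have equal length")
    ctrl = rng.multinomial(n_controls, q0 / q0.sum(), size=n_sim)
    case = rng.multinomial(n_cases, q1 / q1.sum(), size=n_sim)
    return ctrl, case
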