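"""Chi-square statistic and p-values for 2xk tables under three calibrations.

The test statistic is the uncorrected Pearson chi-square (no Yates
continuity correction anywhere, including 2x2). Its p-value can be
calibrated three ways:

``asymptotic``
    Upper tail of the chi-square distribution with k'-1 degrees of freedom,
    k' the number of non-empty columns. Reliable when Cochran's rule holds
    (no expected count below 1, at most 20% of expected counts below 5).
``permutation``
    Resampling from the null with both margins fixed: the control row of a
    margin-fixed table is a multivariate-hypergeometric draw of the column
    totals, which is distributionally the same null as classical table
    permutation. p = (1 + #{resampled stat >= observed}) / (B + 1).
``fisher_mc``
    Monte-Carlo Fisher exact test: same margin-fixed sampling, but tables
    are ranked by their null (multivariate hypergeometric) probability;
    p = (1 + #{sampled table no more probable than observed}) / (B + 1).

The ``+1`` in numerator and denominator keeps every p-value strictly
positive and makes the estimator valid (never anti-conservative in
expectation under the null).

All-zero columns carry no information and break the expected-count formula;
they are dropped with a warning and the degrees of freedom adjusted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import gammaln

from .tables import CountTable2xK

logger = logging.getLogger(__name__)

__all__ = [
    "TestResult",
    "DegenerateTableError",
    "chisq_stat",
    "expected_counts",
    "cochran_rule_ok",
    "pvalue_asymptotic",
    "pvalue_permutation",
    "pvalue_fisher_mc",
    "sample_margin_fixed",
]

#: absolute slack when comparing resampled statistics against the observed
#: one, so exact ties survive floating-point round-off
_TIE_EPS = 1e-9


class DegenerateTableError(ValueError):
    """A table with an empty arm (zero row sum) cannot be tested."""


@dataclass(frozen=True)
class TestResult:
    """Outcome of one homogeneity test on a 2xk table."""

    statistic: float
    p_value: float
    method: str
    n_perm: int
    cochran_ok: bool
    df: int

    def __post_init__(self) -> None:
        assert self.statistic >= 0 and 0 < self.p_value <= 1


def _clean(table: CountTable2xK | np.ndarray, warn: bool = True) -> np.ndarray:
    """Validate row sums and drop all-zero columns (with a warning)."""
    counts = table.counts if isinstance(table, CountTable2xK) else np.asarray(table)
    if counts[0].sum() == 0 or counts[1].sum() == 0:
        raise DegenerateTableError("table has an empty arm (zero row sum)")
    keep = counts.sum(axis=0) > 0
    if not keep.all():
        if warn:
            logger.warning(
                "dropping %d all-zero column(s) before testing", int((~keep).sum())
            )
        counts = counts[:, keep]
    if counts.shape[1] < 2:
        raise DegenerateTableError("fewer than 2 non-empty columns")
    return counts


def expected_counts(table: CountTable2xK | np.ndarray) -> np.ndarray:
    """Expected counts under homogeneity (product-of-margins rule)."""
    counts = table.counts if isinstance(table, CountTable2xK) else np.asarray(table)
    rows = counts.sum(axis=1, keepdims=True).astype(float)
    cols = counts.sum(axis=0, keepdims=True).astype(float)
    return rows * cols / counts.sum()


def chisq_stat(table: CountTable2xK | np.ndarray) -> float:
    """Pearson chi-square statistic, all-zero columns dropped, no correction."""
    counts = _clean(table)
    expected = expected_counts(counts)
    return float(((counts - expected) ** 2 / expected).sum())


def cochran_rule_ok(table: CountTable2xK | np.ndarray) -> bool:
    """Cochran's adequacy rule for the asymptotic calibration.

    True iff every expected count is >= 1 and at most 20% of the expected
    counts are below 5 (computed on the table after dropping empty columns).
    """
    counts = _clean(table)
    expected = expected_counts(counts)
    if expected.min() < 1.0:
        return False
    return bool((expected < 5.0).sum() <= 0.2 * expected.size)


def pvalue_asymptotic(table: CountTable2xK | np.ndarray) -> TestResult:
    """Asymptotic chi-square p-value with df = (non-empty columns) - 1."""
    counts = _clean(table)
    stat = chisq_stat(counts)
    df = counts.shape[1] - 1
    p = float(stats.chi2.sf(stat, df))
    return TestResult(stat, max(p, np.finfo(float).tiny), "asymptotic", 0,
                      cochran_rule_ok(counts), df)


def sample_margin_fixed(
    col_totals: np.ndarray, n_controls: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Sample control rows of margin-fixed tables under the exact null.

    Conditional on both margins, the control row is multivariate
    hypergeometric: draw which ``n_controls`` of the N individuals fall in
    each column. Returns an ``(n_perm, k)`` array; the case row of draw i is
    ``col_totals - out[i]``.
    """
    return rng.multivariate_hypergeometric(
        np.asarray(col_totals, dtype=np.int64), int(n_controls), size=n_perm
    )


def _margin_stats(
    ctrl_rows: np.ndarray, col_totals: np.ndarray, n_controls: int, n_cases: int
) -> np.ndarray:
    """Chi-square statistics for margin-fixed tables, vectorized over rows."""
    total = n_controls + n_cases
    e0 = col_totals * (n_controls / total)
    e1 = col_totals * (n_cases / total)
    case_rows = col_totals - ctrl_rows
    return ((ctrl_rows - e0) ** 2 / e0 + (case_rows - e1) ** 2 / e1).sum(axis=1)


def pvalue_permutation(
    table: CountTable2xK | np.ndarray, n_perm: int, rng: np.random.Generator
) -> TestResult:
    """Margin-fixed permutation p-value for the chi-square statistic."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    counts = _clean(table)
    col_totals = counts.sum(axis=0)
    n_co, n_ca = int(counts[0].sum()), int(counts[1].sum())
    observed = float(_margin_stats(counts[:1], col_totals, n_co, n_ca)[0])
    ctrl_rows = sample_margin_fixed(col_totals, n_co, n_perm, rng)
    perm = _margin_stats(ctrl_rows, col_totals, n_co, n_ca)
    exceed = int((perm >= observed - _TIE_EPS).sum())
    p = (1 + exceed) / (n_perm + 1)
    return TestResult(observed, p, "permutation", n_perm, cochran_rule_ok(counts),
                      counts.shape[1] - 1)


def _log_table_prob(ctrl_rows: np.ndarray, col_totals: np.ndarray) -> np.ndarray:
    """Unnormalized log multivariate-hypergeometric probability of tables.

    log P(table | margins) = sum_j log C(c_j, x_j) - log C(N, N_co); the
    constant term is omitted since only the ordering matters.
    """
    x = ctrl_rows
    c = col_totals
    return (
        gammaln(c + 1) - gammaln(x + 1) - gammaln(c - x + 1)
    ).sum(axis=1)


def pvalue_fisher_mc(
    table: CountTable2xK | np.ndarray, n_perm: int, rng: np.random.Generator
) -> TestResult:
    """Monte-Carlo Fisher exact p-value (probability-ordered, two-sided)."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    counts = _clean(table)
    col_totals = counts.sum(axis=0)
    n_co, n_ca = int(counts[0].sum()), int(counts[1].sum())
    obs_logp = float(_log_table_prob(counts[:1], col_totals)[0])
    ctrl_rows = sample_margin_fixed(col_totals, n_co, n_perm, rng)
    samp_logp = _log_table_prob(ctrl_rows, col_totals)
    at_most = int((samp_logp <= obs_logp + _TIE_EPS).sum())
    p = (1 + at_most) / (n_perm + 1)
    stat = chisq_stat(counts)
    return TestResult(stat, p, "fisher_mc", n_perm, cochran_rule_ok(counts),
                      counts.shape[1] - 1)


def asymptotic_pvalues_batch(ctrl: np.ndarray, case: np.ndarray) -> np.ndarray:
    """Asymptotic chi-square p-values for a batch of 2xk tables.

    ``ctrl`` and ``case`` are ``(n_sim, k)`` count arrays (one table per
    row pair). Empty columns are handled per table: their cells contribute
    nothing and the degrees of freedom shrink accordingly. Tables whose
    non-empty width collapses to one column get p = 1.
    """
    ctrl = np.asarray(ctrl, dtype=float)
    case = np.asarray(case, dtype=float)
    col_tot = ctrl + case
    n_co = ctrl.sum(axis=1, keepdims=True)
    n_ca = case.sum(axis=1, keepdims=True)
    total = n_co + n_ca
    e0 = col_tot * n_co / total
    e1 = col_tot * n_ca / total
    occupied = col_tot > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(occupied, (ctrl - e0) ** 2 / e0 + (case - e1) ** 2 / e1, 0.0)
    stat = terms.sum(axis=1)
    df = occupied.sum(axis=1) - 1
    p = np.ones_like(stat)
    ok = df >= 1
    p[ok] = stats.chi2.sf(stat[ok], df[ok])
    return np.maximum(p, np.finfo(float).tiny)


def resampled_pvalues_batch(
    ctrl: np.ndarray,
    case: np.ndarray,
    n_perm: int,
    rng: np.random.Generator,
    method: str = "permutation",
) -> np.ndarray:
    """Permutation or MC-Fisher p-values for a batch of tables.

    Each table receives its own ``n_perm`` margin-fixed draws (no pooling
    across tables, since the margins differ table to table).
    """
    if method not in ("permutation", "fisher_mc"):
        raise ValueError(f"unknown resampling method {method!r}")
    ctrl = np.asarray(ctrl, dtype=np.int64)
    case = np.asarray(case, dtype=np.int64)
    n_dropped = 0
    out = np.empty(ctrl.shape[0])
    for i in range(ctrl.shape[0]):
        counts = _clean(np.vstack([ctrl[i], case[i]]), warn=False)
        n_dropped += ctrl.shape[1] - counts.shape[1]
        col_totals = counts.sum(axis=0)
        n_co, n_ca = int(counts[0].sum()), int(counts[1].sum())
        ctrl_rows = sample_margin_fixed(col_totals, n_co, n_perm, rng)
        if method == "permutation":
            observed = float(_margin_stats(counts[:1], col_totals, n_co, n_ca)[0])
            perm = _margin_stats(ctrl_rows, col_totals, n_co, n_ca)
            hits = int((perm >= observed - _TIE_EPS).sum())
        else:
            obs_logp = float(_log_table_prob(counts[:1], col_totals)[0])
            samp_logp = _log_table_prob(ctrl_rows, col_totals)
            hits = int((samp_logp <= obs_logp + _TIE_EPS).sum())
        out[i] = (1 + hits) / (n_perm + 1)
    if n_dropped:
        logger.info(
            "dropped %d all-zero column(s) across %d resampled tables",
            n_dropped, ctrl.shape[0],
        )
    return out
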