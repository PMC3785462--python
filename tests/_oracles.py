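"""Independent brute-force oracles used by the unit and acceptance tests.

All functions here enumerate the exact null distribution over 2x2 tables
with fixed margins (hypergeometric measure) and never call the package's
Monte-Carlo samplers, so they can serve as ground truth for them.
"""

import numpy as np
from scipy import stats


def _enumerate_2x2(table):
    """All 2x2 tables sharing the margins of ``table``, with probabilities.

    Yields (x, prob) where x is the top-left (control, first-column) count
    and prob its hypergeometric probability.
    """
    table = np.asarray(table)
    n_co, n_ca = table.sum(axis=1)
    c1 = table[:, 0].sum()
    total = n_co + n_ca
    lo = max(0, c1 - n_ca)
    hi = min(c1, n_co)
    xs = np.arange(lo, hi + 1)
    probs = stats.hypergeom.pmf(xs, total, c1, n_co)
    return xs, probs


def _chisq_2x2(x, n_co, n_ca, c1, c2):
    """Pearson statistic of the margin-fixed 2x2 table with top-left x."""
    total = n_co + n_ca
    cells = np.array(
        [x, c1 - x, n_co - x, n_ca - (c1 - x)], dtype=float
    )  # [ctrl1, case1, ctrl2, case2]
    exp = np.array(
        [n_co * c1, n_ca * c1, n_co * c2, n_ca * c2], dtype=float
    ) / total
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(exp > 0, (cells - exp) ** 2 / exp, 0.0)
    return terms.sum()


def exact_permutation_p(table):
    """Exact P(chi-square of a margin-fixed table >= observed)."""
    table = np.asarray(table)
    n_co, n_ca = table.sum(axis=1)
    c1, c2 = table.sum(axis=0)
    xs, probs = _enumerate_2x2(table)
    obs = _chisq_2x2(table[0, 0], n_co, n_ca, c1, c2)
    stats_all = np.array([_chisq_2x2(x, n_co, n_ca, c1, c2) for x in xs])
    return float(min(1.0, probs[stats_all >= obs - 1e-9].sum()))


def exact_fisher_p(table):
    """Exact two-sided Fisher p: total probability of tables no more likely."""
    table = np.asarray(table)
    xs, probs = _enumerate_2x2(table)
    obs_p = probs[xs == table[0, 0]][0]
    return float(min(1.0, probs[probs <= obs_p + 1e-12].sum()))
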