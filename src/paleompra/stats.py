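"""Small shared statistical helpers.

Multiple-testing correction is delegated to statsmodels; the exact binomial
and hypergeometric tails come from scipy. These wrappers exist so that every
stage of the pipeline applies the same conventions (one-sided tails are
``P(X >= k)``, BH is applied over the family the caller assembles).
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "bh_fdr",
    "binomial_tail",
    "binomial_two_sided",
    "hypergeom_tail",
    "fisher_2x2",
]


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone step-up).

    NaNs are passed through unchanged and excluded from the family.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if mask.sum() == 0:
        return out
    out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def binomial_tail(k: int, n: int, p0: float = 0.5) -> float:
    """One-sided upper tail P(X >= k) for X ~ Binomial(n, p0)."""
    if not 0 <= k <= n:
        raise ValueError(f"k={k} outside [0, n={n}]")
    return float(sps.binom.sf(k - 1, n, p0))


def binomial_two_sided(k: int, n: int, p0: float = 0.5) -> float:
    """Two-sided exact binomial p-value (minlike method, as in R's binom.test)."""
    return float(sps.binomtest(k, n, p0).pvalue)


def hypergeom_tail(k: int, population: int, successes: int, draws: int) -> float:
    """Upper tail P(X >= k) drawing ``draws`` from ``population`` with ``successes``."""
    return float(sps.hypergeom.sf(k - 1, population, successes, draws))


def fisher_2x2(table, alternative: str = "two-sided"):
    """Fisher's exact test on a 2x2 table; returns (odds_ratio, p)."""
    odds, p = sps.fisher_exact(np.asarray(table), alternative=alternative)
    return float(odds), float(p)
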