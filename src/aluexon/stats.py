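"""Statistical kernels used throughout the pipeline.

Thin, contract-enforcing wrappers around scipy/statsmodels: a 2x2 Fisher
exact test, Fisher's method for combining independent p-values, the
Benjamini-Hochberg step-up FDR, the Wilcoxon signed-rank test, and the
log2-odds fold-change arithmetic used for splice-site strength comparisons.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

_ALTERNATIVES = {"two_sided": "two-sided", "greater": "greater", "less": "less"}


def fisher_exact_2x2(
    table: Sequence[Sequence[int]], alternative: str = "two_sided"
) -> tuple[float, float]:
    """Exact hypergeometric test on a 2x2 contingency table.

    Rows are groups, columns success/failure. The two-sided p sums the
    probabilities of all tables (at fixed margins) no more likely than the
    observed one. Returns ``(odds_ratio, p)``.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    if (t < 0).any():
        raise ValueError("table entries must be non-negative")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError(f"degenerate table (empty margin): {t.tolist()}")
    if alternative not in _ALTERNATIVES:
        raise ValueError(f"alternative must be one of {sorted(_ALTERNATIVES)}")
    res = sps.fisher_exact(t, alternative=_ALTERNATIVES[alternative])
    return float(res.statistic), float(res.pvalue)


def fisher_method_combine(p_values: Sequence[float]) -> tuple[float, int, float]:
    """Combine independent p-values: chi2 = -2 sum(ln p), df = 2k.

    Returns ``(chi2, df, combined_p)``. p-values must lie in (0, 1];
    underflow handling (p == 0) is the caller's responsibility.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    chi2 = float(-2.0 * np.log(p).sum())
    df = 2 * p.size
    return chi2, df, float(sps.chi2.sf(chi2, df))


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg q-values (step-up with monotonicity), input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.empty(0)
    if (p < 0).any() or (p > 1).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def wilcoxon_signed_rank(
    x: Sequence[float], y: Sequence[float], two_tailed: bool = True
) -> float:
    """Paired Wilcoxon signed-rank p-value.

    Zero differences are dropped. The exact null distribution is used for
    n <= 25 retained pairs; beyond that, the normal approximation with
    continuity correction. All-zero differences give p = 1 with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired vectors must have equal length")
    d = x - y
    d = d[d != 0]
    if d.size == 0:
        warnings.warn("all paired differences are zero; p = 1", stacklevel=2)
        return 1.0
    method = "exact" if d.size <= 25 else "approx"
    alternative = "two-sided" if two_tailed else "greater"
    res = sps.wilcoxon(d, method=method, correction=True, alternative=alternative)
    return float(res.pvalue)


def log2_odds_fold_change(score_before: float, score_after: float) -> float:
    """Fold change implied by a difference of two log2-odds scores."""
    return float(2.0 ** (score_after - score_before))
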