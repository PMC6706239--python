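"""Group-comparison statistics for metabolite tables.

Three tools, matching common practice in comparative metabolomics of two
xenograft groups: the Mann-Whitney rank test, Cohen's d effect size, and the
two-stage linear step-up false-discovery-rate procedure at level q (stage 1
estimates the number of true nulls with a step-up pass at q/(1+q); stage 2
re-runs the step-up with the estimated null count).  A classic Holm
step-down familywise option is included for comparison.  All statistics are
invariant to sample ordering; missing values are dropped pairwise per
feature.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "mann_whitney",
    "cohens_d",
    "two_stage_stepup_fdr",
    "holm_stepdown",
    "compare_groups",
]


def _clean(a) -> np.ndarray:
    a = np.asarray(a, dtype=float).ravel()
    return a[np.isfinite(a)]


def mann_whitney(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney rank test.

    Returns ``(U, p)`` where ``U`` is the statistic of the first sample.
    The p-value is computed by exact enumeration for combined n <= 12
    without ties, and by the tie-corrected normal approximation otherwise.
    """
    a, b = _clean(a), _clean(b)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 observations")
    combined = np.concatenate([a, b])
    no_ties = np.unique(combined).size == combined.size
    method = "exact" if (combined.size <= 12 and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def cohens_d(a, b) -> float:
    """Cohen's d with the pooled (n-1)-denominator standard deviation."""
    a, b = _clean(a), _clean(b)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 observations")
    na, nb = a.size, b.size
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if sp2 == 0:
        raise ZeroDivisionError("pooled standard deviation is zero")
    return float((a.mean() - b.mean()) / np.sqrt(sp2))


def _stepup_count(p_sorted: np.ndarray, level: float) -> int:
    """Largest k with p_(k) <= level * k / m (0 if none)."""
    m = p_sorted.size
    crit = level * np.arange(1, m + 1) / m
    below = np.flatnonzero(p_sorted <= crit)
    return int(below[-1] + 1) if below.size else 0


def two_stage_stepup_fdr(pvals, q: float = 0.05) -> tuple[np.ndarray, float]:
    """Two-stage linear step-up FDR control at level ``q``.

    Stage 1 runs a linear step-up pass at ``q' = q/(1+q)`` and estimates the
    number of true nulls as ``m0 = m - r1``; stage 2 reruns the step-up at
    ``q' * m / m0``.  Returns ``(discovery_flags, p_threshold)`` where the
    threshold is the largest rejected p-value (0.0 if none).
    """
    p = np.asarray(pvals, dtype=float).ravel()
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if not (0 < q < 1):
        raise ValueError("q must lie in (0, 1)")
    m = p.size
    order = np.argsort(p, kind="stable")
    ps = p[order]
    q1 = q / (1.0 + q)
    r1 = _stepup_count(ps, q1)
    if r1 == 0:
        return np.zeros(m, dtype=bool), 0.0
    m0 = m - r1
    if m0 == 0:
        return np.ones(m, dtype=bool), float(ps[-1])
    r2 = _stepup_count(ps, q1 * m / m0)
    if r2 == 0:
        return np.zeros(m, dtype=bool), 0.0
    thr = float(ps[r2 - 1])
    return p <= thr, thr


def holm_stepdown(pvals, alpha: float = 0.05) -> np.ndarray:
    """Holm's step-down familywise-error procedure (comparison option)."""
    p = np.asarray(pvals, dtype=float).ravel()
    m = p.size
    order = np.argsort(p, kind="stable")
    reject = np.zeros(m, dtype=bool)
    for rank, idx in enumerate(order):
        if p[idx] <= alpha / (m - rank):
            reject[idx] = True
        else:
            break
    return reject


def compare_groups(
    table: pd.DataFrame,
    labels,
    q: float = 0.05,
) -> pd.DataFrame:
    """Feature-by-feature two-group comparison of a metabolite table.

    ``table`` is features x samples; ``labels`` assigns each sample column to
    one of exactly two groups.  Each feature gets a Mann-Whitney U and p,
    Cohen's d, and a discovery flag from the two-stage step-up procedure at
    level ``q``.  Missing values are dropped pairwise; features with fewer
    than two finite observations in either group are skipped (flag NaN).
    """
    labels = np.asarray(labels)
    groups = pd.unique(labels)
    if groups.size != 2:
        raise ValueError("labels must define exactly two groups")
    rows = []
    for feat, row in table.iterrows():
        a = _clean(row.values[labels == groups[0]])
        b = _clean(row.values[labels == groups[1]])
        if a.size < 2 or b.size < 2:
            rows.append((feat, np.nan, np.nan, np.nan, False, False))
            continue
        u, pval = mann_whitney(a, b)
        try:
            d = cohens_d(a, b)
        except ZeroDivisionError:
            d = np.nan
        rows.append((feat, u, pval, d, True, False))
    out = pd.DataFrame(
        rows, columns=["feature", "U", "p", "cohens_d", "tested", "significant"]
    ).set_index("feature")
    tested = out["tested"].to_numpy()
    if tested.any():
        flags, thr = two_stage_stepup_fdr(out.loc[tested, "p"].to_numpy(), q=q)
        out.loc[tested, "significant"] = flags
        out.attrs["p_threshold"] = thr
    return out
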