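"""Shared statistical primitives: NaN-aware two-sample t-tests and p-value
adjustment.  Undetected measurements enter these routines as NaN and are
excluded per protein, so group sizes vary row by row."""

from __future__ import annotations

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests


def nan_group_stats(x: np.ndarray):
    """Per-row count, mean and ddof-1 variance ignoring NaN."""
    x = np.asarray(x, dtype=float)
    ok = ~np.isnan(x)
    n = ok.sum(axis=1)
    s = np.where(ok, x, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = s / n
        sq = np.where(ok, (x - mean[:, None]) ** 2, 0.0).sum(axis=1)
        var = sq / np.maximum(n - 1, 1)
    var[n < 2] = np.nan
    return n, mean, var


def ttest_rows(a: np.ndarray, b: np.ndarray, equal_var: bool = True):
    """Row-wise two-sided two-sample t-test with NaN exclusion.

    Pooled-variance (Student) by default, Welch otherwise.  Rows where either
    side has fewer than 2 non-missing values get NaN statistics.  Degenerate
    rows with zero pooled variance get t=0, p=1 when the means agree and
    t=+/-inf, p=0 otherwise (a deterministic separation).
    """
    na, ma, va = nan_group_stats(a)
    nb, mb, vb = nan_group_stats(b)
    diff = ma - mb
    with np.errstate(invalid="ignore", divide="ignore"):
        if equal_var:
            df = (na + nb - 2).astype(float)
            sp2 = ((na - 1) * va + (nb - 1) * vb) / df
            se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
        else:
            se2a = va / na
            se2b = vb / nb
            se = np.sqrt(se2a + se2b)
            df = (se2a + se2b) ** 2 / (se2a**2 / (na - 1) + se2b**2 / (nb - 1))
        t = diff / se
    p = np.full(t.shape, np.nan)
    ok = (na >= 2) & (nb >= 2)
    zero_se = ok & ~(se > 0)
    # zero within-group variance: exact tie -> null result, else infinite t
    t[zero_se & (diff == 0)] = 0.0
    p[zero_se & (diff == 0)] = 1.0
    t[zero_se & (diff > 0)] = np.inf
    t[zero_se & (diff < 0)] = -np.inf
    p[zero_se & (diff != 0)] = 0.0
    reg = ok & (se > 0)
    p[reg] = 2.0 * stats.t.sf(np.abs(t[reg]), df[reg])
    t[~ok] = np.nan
    return t, p, ok


def bonferroni(p: np.ndarray, family_size: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: min(1, p * m) with m defaulting to the number
    of finite p-values in the family."""
    p = np.asarray(p, dtype=float)
    m = family_size if family_size is not None else int(np.isfinite(p).sum())
    return np.minimum(1.0, p * m)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values; NaNs propagate."""
    p = np.asarray(p, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q
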