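"""Shared statistical primitives: variance F-test, one-way ANOVA, simple
linear regression, Pearson correlation with t-based significance.

All p-values are two-tailed except the ANOVA F (upper tail). No significance
threshold is hard-coded; callers compare against their own α. An optional
Benjamini–Hochberg adjustment is provided but applied nowhere by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps


@dataclass
class StatResult:
    statistic: float
    p: float
    df: tuple[float, ...]
    extras: dict = field(default_factory=dict)

    @property
    def undefined(self) -> bool:
        return bool(np.isnan(self.statistic))


def variance_f_test(
    a, b, larger_numerator: bool = False
) -> StatResult:
    """F-test for equality of variances of two samples.

    F = s_a² / s_b² with (n_a−1, n_b−1) degrees of freedom and a two-tailed
    p-value, 2·min(P[F ≤ f], P[F ≥ f]). With ``larger_numerator`` the larger
    sample variance goes on top (F ≥ 1); the two-tailed p is unchanged.
    Swapping the samples maps F to 1/F and leaves p identical.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    dfa, dfb = a.size - 1, b.size - 1
    if larger_numerator and vb > va:
        va, vb, dfa, dfb = vb, va, dfb, dfa
    if vb == 0.0:
        return StatResult(np.nan, np.nan, (dfa, dfb), {"undefined_reason": "zero denominator variance"})
    f = va / vb
    dist = sps.f(dfa, dfb)
    p = 2.0 * min(dist.cdf(f), dist.sf(f))
    return StatResult(float(f), float(min(p, 1.0)), (dfa, dfb))


def one_way_anova(groups) -> StatResult:
    """Classical one-way ANOVA between/within decomposition.

    F = (SSB / (k−1)) / (SSW / (N−k)) with an upper-tail p-value.
    All-identical values make F undefined (0/0) and are flagged as NaN.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(g.size < 2 for g in groups):
        raise ValueError("each group needs at least 2 values")
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    k, n = len(groups), all_vals.size
    ssb = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    dfb, dfw = k - 1, n - k
    if ssw == 0.0 and ssb == 0.0:
        return StatResult(np.nan, np.nan, (dfb, dfw), {"undefined_reason": "all values identical"})
    if ssw == 0.0:
        return StatResult(np.inf, 0.0, (dfb, dfw), {"ssb": ssb, "ssw": ssw})
    f = (ssb / dfb) / (ssw / dfw)
    p = sps.f.sf(f, dfb, dfw)
    return StatResult(float(f), float(p), (dfb, dfw), {"ssb": float(ssb), "ssw": float(ssw)})


def linear_fit(x, y) -> StatResult:
    """Simple least-squares regression y = a·x + b with R² and slope p-value.

    The statistic is the slope; ``extras`` carries intercept, R² and the
    Pearson r whose square it is. Two-tailed p tests slope = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if x.size < 3:
        raise ValueError("need at least 3 paired finite values")
    if np.ptp(x) == 0.0:
        raise ValueError("x is constant; slope undefined")
    res = sps.linregress(x, y)
    return StatResult(
        float(res.slope),
        float(res.pvalue),
        (float(x.size - 2),),
        {
            "intercept": float(res.intercept),
            "r": float(res.rvalue),
            "r_squared": float(res.rvalue**2),
            "stderr": float(res.stderr),
        },
    )


def pearson_r(x, y) -> tuple[float, float, int]:
    """Pearson r with two-tailed p from t = r·sqrt((n−2)/(1−r²)), df = n−2.

    Pairwise-deletes non-finite values. Returns (r, p, n); r is NaN when
    either variable is constant or n < 3.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    n = int(x.size)
    if n < 3:
        return (np.nan, np.nan, n)
    xd = x - x.mean()
    yd = y - y.mean()
    sx = np.sqrt((xd**2).sum())
    sy = np.sqrt((yd**2).sum())
    if sx == 0.0 or sy == 0.0:
        return (np.nan, np.nan, n)
    r = float((xd * yd).sum() / (sx * sy))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return (r, 0.0, n)
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = float(2.0 * sps.t.sf(abs(t), n - 2))
    return (r, p, n)


def pearson_r_permutation(x, y, n_permutations: int = 9999, seed: int = 0) -> tuple[float, float, int]:
    """Permutation two-tailed p for Pearson r (for very small n)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    r, _, n = pearson_r(x, y)
    if np.isnan(r):
        return (r, np.nan, n)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        rp, _, _ = pearson_r(x, rng.permutation(y))
        if abs(rp) >= abs(r) - 1e-12:
            count += 1
    return (r, (count + 1) / (n_permutations + 1), n)


def benjamini_hochberg(pvals) -> np.ndarray:
    """BH step-up adjusted p-values (monotone, capped at 1). NaNs pass through."""
    p = np.asarray(pvals, dtype=float)
    out = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    ps = p[ok]
    m = ps.size
    if m == 0:
        return out
    order = np.argsort(ps)
    ranked = ps[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(ranked, 1.0)
    out[ok] = adj
    return out
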