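"""Screening statistics for signature extraction.

Implemented in-package (rather than calling a per-gene reference routine)
because the randomization and cross-validation studies re-screen thousands of
gene x run combinations; everything here is vectorized across genes.  The
test suite checks each primitive against an independent reference
implementation.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps


def anova_oneway_matrix(X: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One-way ANOVA per row of ``X`` (features x samples) across ``labels``.

    Returns (F, p) arrays.  Uses the sums-of-squares decomposition
    F = (SSB / (k-1)) / (SSW / (N-k)).
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    groups = np.unique(labels)
    k = groups.size
    N = labels.size
    if k < 2:
        raise ValueError("need at least two groups")
    grand = X.mean(axis=1, keepdims=True)
    ssb = np.zeros(X.shape[0])
    ssw = np.zeros(X.shape[0])
    for g in groups:
        sel = labels == g
        n_g = int(sel.sum())
        mu_g = X[:, sel].mean(axis=1, keepdims=True)
        ssb += n_g * (mu_g[:, 0] - grand[:, 0]) ** 2
        ssw += ((X[:, sel] - mu_g) ** 2).sum(axis=1)
    dfb, dfw = k - 1, N - k
    if dfw < 1:
        raise ValueError("not enough samples for within-group variance")
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ssb / dfb) / (ssw / dfw)
    p = sps.f.sf(F, dfb, dfw)
    return F, p


def anova_oneway(*groups) -> tuple[float, float]:
    """One-way ANOVA for explicit groups of observations."""
    sizes = [len(g) for g in groups]
    X = np.concatenate([np.asarray(g, dtype=float) for g in groups])[None, :]
    labels = np.concatenate([np.full(n, i) for i, n in enumerate(sizes)])
    F, p = anova_oneway_matrix(X, labels)
    return float(F[0]), float(p[0])


def tukey_kramer(*groups) -> list[dict]:
    """Tukey-Kramer all-pairs comparisons.

    For groups of unequal size the standard error of the (i, j) contrast is
    sqrt(MSW/2 * (1/n_i + 1/n_j)); the studentized range statistic
    q = |mean_i - mean_j| / SE is referred to the studentized range
    distribution with k groups and N - k error degrees of freedom.
    """
    k = len(groups)
    if k < 2:
        raise ValueError("need at least two groups")
    arrs = [np.asarray(g, dtype=float) for g in groups]
    ns = np.array([a.size for a in arrs])
    N = int(ns.sum())
    means = np.array([a.mean() for a in arrs])
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrs)
    dfw = N - k
    msw = ssw / dfw
    out = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = means[j] - means[i]
            se = np.sqrt(msw / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
            q = abs(diff) / se if se > 0 else np.inf
            p = float(sps.studentized_range.sf(q, k, dfw))
            out.append({"i": i, "j": j, "diff": float(diff), "se": float(se),
                        "q": float(q), "p": p})
    return out


def tukey_contrast_vs_rest(
    X: np.ndarray, labels: np.ndarray, community, mask: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-row Tukey-Kramer-style contrast of one group against the pooled rest.

    The background groups are pooled into a single contrast mean; the error
    variance and degrees of freedom come from the full k-group ANOVA, and the
    q statistic is referred to the studentized range with k groups, keeping
    Tukey's family-wise calibration.  Returns (diff, q, p) per row; with
    ``mask``, p is evaluated only where mask is True (1.0 elsewhere) since
    the studentized-range survival function is numerically expensive.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    groups = np.unique(labels)
    k = groups.size
    sel = labels == community
    n_in = int(sel.sum())
    n_bg = int((~sel).sum())
    if n_in == 0 or n_bg == 0:
        raise ValueError("community and background must both be non-empty")
    mean_in = X[:, sel].mean(axis=1)
    mean_bg = X[:, ~sel].mean(axis=1)
    ssw = np.zeros(X.shape[0])
    for g in groups:
        gsel = labels == g
        mu = X[:, gsel].mean(axis=1, keepdims=True)
        ssw += ((X[:, gsel] - mu) ** 2).sum(axis=1)
    dfw = labels.size - k
    msw = ssw / dfw
    diff = mean_in - mean_bg
    se = np.sqrt(msw / 2.0 * (1.0 / n_in + 1.0 / n_bg))
    with np.errstate(divide="ignore", invalid="ignore"):
        q = np.abs(diff) / se
    q = np.where(se > 0, q, np.inf)
    p = np.ones_like(q)
    eval_mask = np.ones(q.size, dtype=bool) if mask is None else np.asarray(mask, dtype=bool)
    if eval_mask.any():
        with np.errstate(over="ignore", invalid="ignore"):
            p[eval_mask] = sps.studentized_range.sf(q[eval_mask], k, dfw)
    p = np.nan_to_num(p, nan=0.0)  # sf underflow at extreme q means p ~ 0
    return diff, q, np.asarray(p)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (step-up, monotone)."""
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out
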