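"""Independent reference implementations used only as test oracles."""

from __future__ import annotations

import numpy as np


def brute_force_qb(b, labels, gamma=1.0):
    """Barber bipartite modularity by the literal double sum over all
    patient x interaction pairs."""
    m = b.m
    pdeg = b.patient_degrees()
    ideg = b.interaction_degrees()
    total = 0.0
    for p in b.patients:
        for i in b.interactions:
            if labels[p] != labels[i]:
                continue
            a = 1.0 if i in b.adj[p] else 0.0
            total += a - gamma * pdeg[p] * ideg[i] / m
    return total / m


def iter_partitions(items):
    """All set partitions of ``items`` (restricted-growth enumeration)."""
    items = list(items)
    n = len(items)
    if n == 0:
        yield []
        return
    rgs = [0] * n

    def rec(i, maxv):
        if i == n:
            blocks = {}
            for item, g in zip(items, rgs):
                blocks.setdefault(g, []).append(item)
            yield list(blocks.values())
            return
        for v in range(maxv + 2):
            rgs[i] = v
            yield from rec(i + 1, max(maxv, v))

    yield from rec(1, 0)


def exhaustive_best_qb(b, gamma=1.0):
    """Exhaustive maximum of Q_b over all partitions of P u I."""
    nodes = list(b.patients) + list(b.interactions)
    best = -np.inf
    for part in iter_partitions(nodes):
        labels = {n: k for k, block in enumerate(part) for n in block}
        best = max(best, brute_force_qb(b, labels, gamma))
    return best


def logrank_oracle(times, events, groups):
    """Multi-group Mantel-Haenszel log-rank chi-square statistic."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    glev = np.unique(groups)
    k = glev.size
    obs = np.zeros(k)
    exp = np.zeros(k)
    cov = np.zeros((k, k))
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = at_risk.sum()
        d = ((times == t) & (events == 1)).sum()
        if n < 1:
            continue
        ng = np.array([(at_risk & (groups == g)).sum() for g in glev], dtype=float)
        dg = np.array([((times == t) & (events == 1) & (groups == g)).sum() for g in glev], dtype=float)
        obs += dg
        exp += d * ng / n
        if n > 1:
            factor = d * (n - d) / (n - 1)
            for a in range(k):
                for bb in range(k):
                    delta = 1.0 if a == bb else 0.0
                    cov[a, bb] += factor * (delta * ng[a] * n - ng[a] * ng[bb]) / n**2
    u = (obs - exp)[: k - 1]
    v = cov[: k - 1, : k - 1]
    return float(u @ np.linalg.solve(v, u))


def fisher_two_sided_p(table):
    """Two-sided Fisher exact p by hypergeometric enumeration."""
    from math import comb

    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = comb(n, c1)
    p_obs = comb(r1, a) * comb(r2, c1 - a) / denom
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        px = comb(r1, x) * comb(r2, c1 - x) / denom
        if px <= p_obs * (1 + 1e-9):
            total += px
    return total
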