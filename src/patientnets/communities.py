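"""Network-based patient stratification.

Patient-specific models are aggregated into a patient--interaction bipartite
graph B = (P u I, E): patient-node p is linked to interaction-node j iff
patient p's model contains interaction j (interactions leaving an inhibited
source node are excluded so only functionally active regulation contributes).
The degree d(j) of an interaction-node counts the patients sharing it;
rare (d <= t_L) and ubiquitous (d >= t_U) interactions are filtered out as
uninformative.  Communities are then found by greedily maximizing Barber's
bipartite modularity

    Q_b = (1/m) sum_{i in P} sum_{j in I} [A_ij - gamma * k_i k_j / m] delta(c_i, c_j)

with a Louvain scheme (local moves + aggregation passes), where gamma is the
resolution parameter (gamma < 1 favors larger communities).
"""

from __future__ import annotations

import warnings
from collections import namedtuple
from dataclasses import dataclass, field  # noqa: F401

import numpy as np

from .network import PatientNetwork

InteractionKey = namedtuple("InteractionKey", ["source", "sign", "target"])

DEFAULT_T_LOWER = 4
DEFAULT_T_UPPER = 30
DEFAULT_GAMMA_GRID = tuple(np.round(np.arange(0.6, 1.4001, 0.1), 10))


@dataclass
class BipartiteGraph:
    """Patient--interaction bipartite graph with 0/1 adjacency.

    ``adj`` maps each patient id to the set of interaction keys it contains.
    """

    patients: list
    interactions: list
    adj: dict  # patient -> set of InteractionKey

    def __post_init__(self) -> None:
        iset = set(self.interactions)
        for p in self.patients:
            self.adj.setdefault(p, set())
            self.adj[p] &= iset

    @property
    def m(self) -> int:
        return sum(len(s) for s in self.adj.values())

    def patient_degrees(self) -> dict:
        return {p: len(self.adj[p]) for p in self.patients}

    def interaction_degrees(self) -> dict:
        deg = {i: 0 for i in self.interactions}
        for p in self.patients:
            for i in self.adj[p]:
                deg[i] += 1
        return deg


@dataclass
class Partition:
    """Community labels over P u I with the modularities of the split.

    ``history`` records Q_b after each Louvain pass of the winning run
    (non-decreasing by construction).
    """

    labels: dict  # node (patient id or InteractionKey) -> community int
    gamma: float
    Q: float
    Q_b: float
    history: list = field(default_factory=list)


@dataclass
class FilterParams:
    t_lower: int = DEFAULT_T_LOWER
    t_upper: int = DEFAULT_T_UPPER
    bounds: str = "exclusive"

    def __post_init__(self) -> None:
        if self.t_lower >= self.t_upper:
            raise ValueError("t_lower must be < t_upper")
        if self.bounds not in ("exclusive", "inclusive"):
            raise ValueError("bounds must be 'exclusive' or 'inclusive'")


@dataclass
class CommunityResult:
    community: int
    patients: list
    interactions: list
    ambiguity_fraction: float
    flagged: bool = False


# ---------------------------------------------------------------------------
# Aggregation and projection


def aggregate_networks(coll: dict) -> dict:
    """Aggregate patient models into interaction incidence.

    Returns ``incidence``: InteractionKey -> {patient -> target state}.
    A patient contributes an edge only when its source node is active
    (sigma = +1) in that patient's model; edges leaving inhibited nodes are
    not functional drivers and are excluded.  Patients contributing zero
    edges stay in the graph with degree 0 (reported via a warning).
    """
    if not coll:
        raise ValueError("empty network collection")
    incidence: dict = {}
    empty = []
    for patient, net in coll.items():
        n_contrib = 0
        for s, t, sign in net.edges:
            if net.states.get(s, 0) != 1:
                continue
            key = InteractionKey(s, sign, t)
            incidence.setdefault(key, {})[patient] = net.states.get(t, 0)
            n_contrib += 1
        if n_contrib == 0:
            empty.append(patient)
    if empty:
        warnings.warn(f"{len(empty)} patient(s) contributed no active interactions: {empty[:5]}")
    return incidence


def build_bipartite(incidence: dict, patients: list | None = None) -> BipartiteGraph:
    """Project aggregated incidence to the patient--interaction bipartite graph."""
    if not incidence:
        raise ValueError("empty incidence")
    if patients is None:
        patients = sorted({p for pats in incidence.values() for p in pats})
    adj = {p: set() for p in patients}
    for key, pats in incidence.items():
        for p in pats:
            if p in adj:
                adj[p].add(key)
    return BipartiteGraph(list(patients), sorted(incidence), adj)


def filter_interaction_nodes(b: BipartiteGraph, fp: FilterParams) -> BipartiteGraph:
    """Drop interaction-nodes outside the degree band; patients are kept.

    exclusive (default): remove d(j) <= t_L or d(j) >= t_U;
    inclusive: remove d(j) < t_L or d(j) > t_U.
    """
    deg = b.interaction_degrees()
    if fp.bounds == "exclusive":
        keep = [i for i in b.interactions if fp.t_lower < deg[i] < fp.t_upper]
    else:
        keep = [i for i in b.interactions if fp.t_lower <= deg[i] <= fp.t_upper]
    if not keep:
        raise ValueError(
            f"no interaction-nodes left for t_L={fp.t_lower}, t_U={fp.t_upper}; "
            "loosen the thresholds"
        )
    kset = set(keep)
    adj = {p: b.adj[p] & kset for p in b.patients}
    return BipartiteGraph(list(b.patients), keep, adj)


# ---------------------------------------------------------------------------
# Modularity


def bipartite_modularity(b: BipartiteGraph, labels: dict, gamma: float = 1.0) -> float:
    """Barber bipartite modularity Q_b of a labeling (exact evaluation).

    Equivalent to the double sum over patient--interaction pairs; computed via
    the per-community form (1/m) sum_c [W_c - gamma * KP_c * KI_c / m].
    """
    m = b.m
    if m == 0:
        raise ValueError("graph has no edges (m = 0)")
    pdeg = b.patient_degrees()
    ideg = b.interaction_degrees()
    W: dict = {}
    KP: dict = {}
    KI: dict = {}
    for p in b.patients:
        c = labels[p]
        KP[c] = KP.get(c, 0) + pdeg[p]
        for i in b.adj[p]:
            if labels[i] == c:
                W[c] = W.get(c, 0) + 1
    for i in b.interactions:
        c = labels[i]
        KI[c] = KI.get(c, 0) + ideg[i]
    total = 0.0
    for c in set(KP) | set(KI):
        total += W.get(c, 0) - gamma * KP.get(c, 0) * KI.get(c, 0) / m
    return total / m


def standard_modularity(b: BipartiteGraph, labels: dict, gamma: float = 1.0) -> float:
    """Newman modularity Q = (1/2m) sum_ij [A_ij - gamma k_i k_j / 2m] delta,
    treating the bipartite graph as an ordinary undirected graph."""
    m = b.m
    if m == 0:
        raise ValueError("graph has no edges (m = 0)")
    deg = {**b.patient_degrees(), **b.interaction_degrees()}
    within = 0
    for p in b.patients:
        for i in b.adj[p]:
            if labels[p] == labels[i]:
                within += 1  # each undirected edge counted once
    by_comm: dict = {}
    for node, c in labels.items():
        by_comm[c] = by_comm.get(c, 0) + deg.get(node, 0)
    return within / m - gamma * sum(k * k for k in by_comm.values()) / (4.0 * m * m)


# ---------------------------------------------------------------------------
# Louvain on Q_b


def louvain_bipartite(
    b: BipartiteGraph,
    gamma: float = 1.0,
    seed: int = 0,
    n_restarts: int = 5,
) -> Partition:
    """Louvain maximization of Barber bipartite modularity.

    Local moves (best positive gain, ties to the lowest community id, nodes
    visited in seeded order) alternate with aggregation passes until Q_b stops
    improving.  A small number of seeded restarts is run and the best-Q_b
    partition kept; the result is deterministic per seed.
    """
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    if not b.patients or not b.interactions:
        raise ValueError("empty bipartite graph")
    m = b.m
    if m == 0:
        raise ValueError("graph has no edges")
    nodes = list(b.patients) + list(b.interactions)
    idx = {n: k for k, n in enumerate(nodes)}
    n = len(nodes)
    kP = np.zeros(n)
    kI = np.zeros(n)
    pdeg = b.patient_degrees()
    ideg = b.interaction_degrees()
    for p in b.patients:
        kP[idx[p]] = pdeg[p]
    for i in b.interactions:
        kI[idx[i]] = ideg[i]
    neighbors = [dict() for _ in range(n)]
    for p in b.patients:
        for i in b.adj[p]:
            neighbors[idx[p]][idx[i]] = neighbors[idx[p]].get(idx[i], 0) + 1
            neighbors[idx[i]][idx[p]] = neighbors[idx[i]].get(idx[p], 0) + 1

    rng = np.random.default_rng(seed)
    best_labels = None
    best_q = -np.inf
    best_history: list = []
    for _ in range(max(1, n_restarts)):
        labels, history = _louvain_run(neighbors, kP, kI, m, gamma, rng)
        q = _qb_from_arrays(neighbors, kP, kI, labels, m, gamma)
        if q > best_q + 1e-12:
            best_q = q
            best_labels = labels
            best_history = history
    out = {node: int(best_labels[idx[node]]) for node in nodes}
    out = _relabel(out)
    qb = bipartite_modularity(b, out, gamma)
    q_std = standard_modularity(b, out, gamma)
    return Partition(labels=out, gamma=gamma, Q=q_std, Q_b=qb, history=best_history)


def _qb_from_arrays(neighbors, kP, kI, labels, m, gamma) -> float:
    W: dict = {}
    KP: dict = {}
    KI: dict = {}
    for u in range(len(labels)):
        c = labels[u]
        KP[c] = KP.get(c, 0.0) + kP[u]
        KI[c] = KI.get(c, 0.0) + kI[u]
        for v, w in neighbors[u].items():
            if labels[v] == c and kP[u] > 0:  # count patient->interaction once
                W[c] = W.get(c, 0.0) + w
    total = 0.0
    for c in set(KP):
        total += W.get(c, 0.0) - gamma * KP[c] * KI[c] / m
    return total / m


def _louvain_run(neighbors, kP, kI, m, gamma, rng):
    """One Louvain run: returns (label per original node, Q_b per pass)."""
    n0 = len(kP)
    mapping = np.arange(n0)  # original node -> current super-node
    cur_neighbors = [dict(d) for d in neighbors]
    cur_kP = kP.astype(float).copy()
    cur_kI = kI.astype(float).copy()
    cur_self = np.zeros(n0)  # internal patient-interaction weight of super-nodes
    prev_q = -np.inf
    history: list = []
    while True:
        labels = _local_moves(cur_neighbors, cur_kP, cur_kI, cur_self, m, gamma, rng)
        q = _qb_super(cur_neighbors, cur_kP, cur_kI, cur_self, labels, m, gamma)
        if q <= prev_q + 1e-12:
            return labels[mapping], history
        history.append(q)
        prev_q = q
        # aggregate communities into super-nodes
        comms = sorted(set(labels))
        remap = {c: k for k, c in enumerate(comms)}
        new_n = len(comms)
        new_kP = np.zeros(new_n)
        new_kI = np.zeros(new_n)
        new_self = np.zeros(new_n)
        new_neighbors = [dict() for _ in range(new_n)]
        for u in range(len(labels)):
            cu = remap[labels[u]]
            new_kP[cu] += cur_kP[u]
            new_kI[cu] += cur_kI[u]
            new_self[cu] += cur_self[u]
            for v, w in cur_neighbors[u].items():
                cv = remap[labels[v]]
                if cv == cu:
                    if u < v:  # each undirected edge once
                        new_self[cu] += w
                elif cu < cv:  # each undirected edge handled from one endpoint
                    new_neighbors[cu][cv] = new_neighbors[cu].get(cv, 0) + w
                    new_neighbors[cv][cu] = new_neighbors[cv].get(cu, 0) + w
        mapping = np.array([remap[labels[mapping[i]]] for i in range(n0)])
        cur_neighbors, cur_kP, cur_kI, cur_self = new_neighbors, new_kP, new_kI, new_self
        if new_n == 1:
            return mapping, history


def _qb_super(neighbors, kP, kI, self_w, labels, m, gamma) -> float:
    W: dict = {}
    KP: dict = {}
    KI: dict = {}
    for u in range(len(labels)):
        c = labels[u]
        KP[c] = KP.get(c, 0.0) + kP[u]
        KI[c] = KI.get(c, 0.0) + kI[u]
        W[c] = W.get(c, 0.0) + self_w[u]
        for v, w in neighbors[u].items():
            if labels[v] == c and u < v:
                W[c] = W.get(c, 0.0) + w
    return sum(W.get(c, 0.0) - gamma * KP[c] * KI[c] / m for c in KP) / m


def _local_moves(neighbors, kP, kI, self_w, m, gamma, rng) -> np.ndarray:
    n = len(kP)
    labels = np.arange(n)
    KP = kP.astype(float).copy()
    KI = kI.astype(float).copy()
    order = rng.permutation(n)
    improved = True
    while improved:
        improved = False
        for u in order:
            c_old = labels[u]
            # weight from u to each neighboring community
            wc: dict = {}
            for v, w in neighbors[u].items():
                wc[labels[v]] = wc.get(labels[v], 0.0) + w
            KP[c_old] -= kP[u]
            KI[c_old] -= kI[u]
            best_c = c_old
            base = wc.get(c_old, 0.0) - gamma * (kP[u] * KI[c_old] + kI[u] * KP[c_old]) / m
            best_gain = base
            for c in sorted(wc):
                if c == c_old:
                    continue
                gain = wc[c] - gamma * (kP[u] * KI[c] + kI[u] * KP[c]) / m
                if gain > best_gain + 1e-12:
                    best_gain = gain
                    best_c = c
            if best_c == c_old and KP[c_old] == 0 and KI[c_old] == 0:
                # u is alone: on an exact tie prefer joining a neighbor's
                # community over staying isolated
                for c in sorted(wc):
                    if c == c_old:
                        continue
                    gain = wc[c] - gamma * (kP[u] * KI[c] + kI[u] * KP[c]) / m
                    if gain >= base - 1e-12:
                        best_c = c
                        break
            labels[u] = best_c
            KP[best_c] += kP[u]
            KI[best_c] += kI[u]
            if best_c != c_old:
                improved = True
    return labels


def _relabel(labels: dict) -> dict:
    remap: dict = {}
    out = {}
    for node in labels:
        c = labels[node]
        if c not in remap:
            remap[c] = len(remap)
        out[node] = remap[c]
    return out


# ---------------------------------------------------------------------------
# Threshold / resolution selection and community extraction


def select_lower_threshold(
    b: BipartiteGraph,
    candidates: list,
    gamma: float = 1.0,
    q_min: float = 0.3,
    seed: int = 0,
    t_upper: int = DEFAULT_T_UPPER,
    bounds: str = "exclusive",
) -> tuple[int, dict]:
    """Smallest t_L whose filtered graph partitions with Q_b above ``q_min``.

    Runs filter + Louvain per candidate (ascending); falls back to the
    argmax-Q_b candidate with a warning when none clears ``q_min``.
    """
    if not candidates:
        raise ValueError("empty candidate list")
    if sorted(candidates) != list(candidates):
        raise ValueError("candidates must be sorted ascending")
    scores: dict = {}
    for t in candidates:
        try:
            fb = filter_interaction_nodes(b, FilterParams(t, t_upper, bounds))
            part = louvain_bipartite(fb, gamma=gamma, seed=seed)
            scores[t] = part.Q_b
        except ValueError:
            scores[t] = float("-inf")
    for t in candidates:
        if scores[t] > q_min:
            return t, scores
    best = max(candidates, key=lambda t: scores[t])
    warnings.warn(
        f"no candidate t_L reached Q_b > {q_min}; falling back to argmax t_L={best}"
    )
    return best, scores


def select_resolution(
    b: BipartiteGraph,
    grid: tuple = DEFAULT_GAMMA_GRID,
    seed: int = 0,
) -> tuple[float, dict]:
    """Scan a gamma grid and keep the resolution maximizing Q_b at gamma=1
    evaluation of its partition (modularity of the partition itself)."""
    scores = {}
    for g in grid:
        part = louvain_bipartite(b, gamma=float(g), seed=seed)
        scores[float(g)] = bipartite_modularity(b, part.labels, gamma=1.0)
    best = max(scores, key=lambda g: (scores[g], -g))
    return best, scores


def extract_community_subgraphs(
    b: BipartiteGraph,
    part: Partition,
    coll: dict,
) -> list[CommunityResult]:
    """Group patients and interactions per community and measure ambiguity.

    The ambiguity fraction of a community is the share of genes in its
    interaction subgraph observed in both activity states across the member
    patients' models.  Communities with no patients or no interactions are
    retained but flagged.
    """
    missing = [n for n in list(b.patients) + list(b.interactions) if n not in part.labels]
    if missing:
        raise ValueError(f"partition does not cover the graph: {missing[:5]}")
    comms = sorted(set(part.labels.values()))
    results = []
    for c in comms:
        pats = [p for p in b.patients if part.labels[p] == c]
        inters = [i for i in b.interactions if part.labels[i] == c]
        genes = {g for i in inters for g in (i.source, i.target)}
        states: dict = {}
        for p in pats:
            net = coll.get(p)
            if net is None:
                continue
            for g in genes:
                s = net.states.get(g, 0)
                if s != 0:
                    states.setdefault(g, set()).add(s)
        ambiguous = sum(1 for g, ss in states.items() if len(ss) > 1)
        frac = ambiguous / len(genes) if genes else 0.0
        results.append(
            CommunityResult(
                community=c,
                patients=pats,
                interactions=inters,
                ambiguity_fraction=frac,
                flagged=not pats or not inters,
            )
        )
    return results
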