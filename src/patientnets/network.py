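"""Patient-specific mechanistic signaling models.

Each patient's model is a signed, directed graph contextualized from a
prior-knowledge network (PKN) of causal protein-protein interactions: edges
carry activation (+1) or inhibition (-1), nodes carry an activity state
sigma in {+1, -1} (or are absent).  The model must be *sign-consistent*:
every active non-source node is explained by at least one used incoming edge
(u, v) with sigma(u) * sign(u, v) = sigma(v), and the used-edge subgraph is
acyclic.  Contextualization minimizes

    sum_{v measured} |final_score(v)| * 1[sigma(v) != mu(v)]  +  beta * |U|

over state assignments sigma and used-edge sets U, where mu(v) is the
measured activity sign and U the used edges.  An exact enumeration solver
(for <= 15 nodes) serves as the oracle for a seeded multi-start local-search
solver.  Hallmark-phenotype activation is then scored by path proximity:
the mean (or median) of sigma(n) * path_sign over model nodes with an
annotated path to the phenotype, against a node-state-shuffling null.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

EXACT_NODE_LIMIT = 15
DEFAULT_BETA = 0.1


@dataclass(frozen=True)
class CausalEdge:
    """One signed causal interaction; ``direct`` distinguishes binding-level
    regulation from indirect (e.g., transcriptional) regulation."""

    source: str
    target: str
    sign: int
    direct: bool = True
    mechanism: str | None = None
    residue: str | None = None

    def __post_init__(self) -> None:
        if self.sign not in (1, -1):
            raise ValueError("sign must be +1 or -1")
        if self.source == self.target:
            raise ValueError(f"self-loop on {self.source}")


class PKN:
    """Prior-knowledge network: a deduplicated set of causal edges."""

    def __init__(self, edges):
        seen = {}
        for e in edges:
            seen.setdefault((e.source, e.target, e.sign, e.residue), e)
        self.edges: list[CausalEdge] = list(seen.values())

    @property
    def nodes(self) -> set:
        out = set()
        for e in self.edges:
            out.add(e.source)
            out.add(e.target)
        return out

    def __len__(self) -> int:
        return len(self.edges)

    def to_digraph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for e in self.edges:
            g.add_edge(e.source, e.target, sign=e.sign, direct=e.direct,
                       mechanism=e.mechanism, residue=e.residue)
        return g


@dataclass
class PhenotypeActivation:
    phenotype: str
    phenoscore: float
    z_null: float
    p: float
    significant: bool

    @property
    def activation(self) -> int:
        return int(np.sign(self.phenoscore))


@dataclass
class PatientNetwork:
    """A contextualized mechanistic model for one patient."""

    patient: str
    states: dict  # gene -> sigma in {+1, -1}; absent genes carry no state
    edges: list   # used (source, target, sign) triples
    sources: set = field(default_factory=set)
    phenotypes: list = field(default_factory=list)
    objective: float = float("nan")

    @property
    def nodes(self) -> set:
        return set(self.states)


def validate_patient_network(net: PatientNetwork) -> None:
    """Independent walk of the model invariants; raises on violation."""
    for s, t, sign in net.edges:
        if s not in net.states or t not in net.states:
            raise AssertionError(f"edge endpoint missing from node set: {(s, t)}")
        if sign not in (1, -1):
            raise AssertionError("edge sign must be +/-1")
    g = nx.DiGraph()
    g.add_nodes_from(net.states)
    g.add_edges_from((s, t) for s, t, _ in net.edges)
    if not nx.is_directed_acyclic_graph(g):
        raise AssertionError("used-edge subgraph has a cycle")
    for v, sigma in net.states.items():
        if v in net.sources or sigma == 0:
            continue
        ok = any(
            net.states.get(u, 0) * sign == sigma
            for u, t, sign in net.edges
            if t == v
        )
        if not ok:
            raise AssertionError(f"node {v} (sigma={sigma}) has no consistent incoming used edge")


# ---------------------------------------------------------------------------
# PKN preprocessing and naive-network construction


def preprocess_pkn(pkn: PKN, omics_coverage: set | None = None, direct_only: bool = False) -> PKN:
    """Restrict the PKN to measured entities and, optionally, direct edges.

    ``omics_coverage=None`` skips the coverage filter (both endpoints of every
    edge retained); ``direct_only=False`` keeps indirect/transcriptional edges.
    """
    if not len(pkn):
        raise ValueError("empty PKN")
    edges = pkn.edges
    if direct_only:
        edges = [e for e in edges if e.direct]
    if omics_coverage is not None:
        cov = set(omics_coverage)
        edges = [e for e in edges if e.source in cov and e.target in cov]
    if not edges:
        raise ValueError("no PKN edges left after preprocessing")
    return PKN(edges)


def build_naive_network(
    pkn: PKN,
    sources: set,
    targets: set,
    layers: int = 2,
    max_length: tuple = (1, 4),
    connect_all: bool = True,
) -> nx.DiGraph:
    """Union of all source-to-target paths within the per-layer step budgets.

    Layer 1 collects every edge lying on a directed path of length at most
    ``max_length[0]`` from a source to a target; targets reached this way join
    the frontier, and each further layer repeats the search from the enlarged
    frontier with its own budget.  With ``connect_all``, shortest paths (within
    the last layer's budget) among the retained intermediate nodes are added.
    Unreachable targets are recorded on the returned graph
    (``graph.graph['unreachable']``).
    """
    if layers not in (1, 2, 3):
        raise ValueError("layers must be 1, 2 or 3")
    if len(max_length) != layers:
        raise ValueError("max_length must have one entry per layer")
    g = pkn.to_digraph()
    sources = {s for s in sources if s in g}
    targets_all = set(targets)
    out = nx.DiGraph()
    frontier = set(sources)
    reached: set = set()
    for L in max_length:
        found = _paths_within(g, frontier & set(g.nodes), targets_all & set(g.nodes), L, out)
        reached |= found
        frontier |= found
    if connect_all and out.number_of_nodes():
        intermediates = set(out.nodes) - set(sources) - targets_all
        keep = intermediates | reached
        for u in keep:
            if u not in g:
                continue
            lengths, paths = nx.single_source_dijkstra(g, u, cutoff=max_length[-1], weight=None)
            for v in keep:
                if v == u or v not in paths:
                    continue
                path = paths[v]
                for a, b in zip(path, path[1:]):
                    out.add_edge(a, b, **g.edges[a, b])
    unreachable = sorted(targets_all - reached)
    out.graph["unreachable"] = unreachable
    return out


def _paths_within(g: nx.DiGraph, sources: set, targets: set, L: int, out: nx.DiGraph) -> set:
    """Add to ``out`` every edge on a path source->target of length <= L;
    return the set of targets reached."""
    targets = targets & set(g.nodes)
    if not sources or not targets:
        return set()
    dist_s = nx.multi_source_dijkstra_path_length(g, sources, cutoff=L, weight=None)
    rg = g.reverse(copy=False)
    dist_t = nx.multi_source_dijkstra_path_length(rg, targets, cutoff=L, weight=None)
    reached = {t for t in targets if dist_s.get(t, math.inf) <= L}
    for u, v, data in g.edges(data=True):
        du = dist_s.get(u, math.inf)
        dv = dist_t.get(v, math.inf)
        if du + 1 + dv <= L:
            out.add_edge(u, v, **data)
    return reached


# ---------------------------------------------------------------------------
# Sign-consistency optimization


def _roots(graph: nx.DiGraph, mode: str, sources: dict | None) -> dict:
    """Root nodes whose state is free (inverse mode) or fixed (vanilla)."""
    if mode == "vanilla":
        if not sources:
            raise ValueError("vanilla mode requires fixed sources")
        return dict(sources)
    # inverse: a virtual root feeds every in-degree-0 node with both signs,
    # i.e., those nodes may take any state at no explanation cost.
    return {n: None for n in graph.nodes if graph.in_degree(n) == 0}


def _project_and_score(
    order: list,
    in_edges: dict,
    sigma: dict,
    roots: dict,
    activities: dict,
    beta: float,
) -> tuple[float, dict, list]:
    """Force unsupported nodes to 0, then score the assignment.

    Support propagates from active roots: an active non-root node is supported
    once some supported upstream node explains its sign.  One supporting edge
    per supported non-root node forms the (acyclic) used-edge set.
    """
    state = dict(sigma)
    supported = {v for v in roots if state.get(v, 0) != 0}
    used: dict = {}
    changed = True
    while changed:
        changed = False
        for v in order:
            sv = state.get(v, 0)
            if sv == 0 or v in supported:
                continue
            for u, sign in in_edges.get(v, ()):
                if u in supported and state.get(u, 0) * sign == sv:
                    supported.add(v)
                    used[v] = (u, v, sign)
                    changed = True
                    break
    for v in order:
        if state.get(v, 0) != 0 and v not in supported and v not in roots:
            state[v] = 0
    mismatch = sum(
        abs(w) for v, (mu, w) in activities.items() if state.get(v, 0) != mu
    )
    used_edges = [used[v] for v in used if state.get(v, 0) != 0]
    return mismatch + beta * len(used_edges), state, used_edges


def optimize_sign_consistency(
    naive: nx.DiGraph,
    activities: dict,
    mode: str = "inverse",
    edge_penalty: float = DEFAULT_BETA,
    solver: str = "greedy",
    sources: dict | None = None,
    seed: int = 0,
    patient: str = "",
    n_restarts: int = 40,
) -> PatientNetwork:
    """Fit node states to measured activities over the naive network.

    ``activities`` maps gene -> (mu in {+1,-1}, weight = |final_score|).
    ``mode='inverse'`` lets every in-degree-0 node act as an unconstrained
    source; ``mode='vanilla'`` fixes the states of ``sources``.  ``solver``
    is ``'exact'`` (full enumeration, <= 15 nodes) or ``'greedy'`` (seeded
    multi-start local search over single-node state changes).
    """
    if edge_penalty < 0:
        raise ValueError("edge_penalty must be >= 0")
    if mode not in ("inverse", "vanilla"):
        raise ValueError(f"unknown mode {mode!r}")
    if solver not in ("exact", "greedy"):
        raise ValueError(f"unknown solver {solver!r}")
    nodes = sorted(naive.nodes)
    if not activities or not nodes:
        return PatientNetwork(patient, {}, [], set(sources or ()), objective=_null_objective(activities))
    roots = _roots(naive, mode, sources)
    in_edges = {
        v: tuple((u, naive.edges[u, v]["sign"]) for u in naive.predecessors(v))
        for v in nodes
    }
    acts = {g: (mu, w) for g, (mu, w) in activities.items()}
    fixed = {v: s for v, s in roots.items() if s is not None}
    free = [v for v in nodes if v not in fixed]

    if solver == "exact":
        if len(free) > EXACT_NODE_LIMIT:
            raise ValueError(
                f"{len(free)} free nodes exceed the exact-solver limit "
                f"({EXACT_NODE_LIMIT}); use solver='greedy'"
            )
        best = (math.inf, None, None)
        for combo in itertools.product((-1, 0, 1), repeat=len(free)):
            sigma = dict(fixed)
            sigma.update(zip(free, combo))
            obj, state, used = _project_and_score(nodes, in_edges, sigma, roots, acts, edge_penalty)
            if obj < best[0] - 1e-12:
                best = (obj, state, used)
        obj, state, used = best
    else:
        rng = np.random.default_rng(seed)
        starts = [_propagation_start(nodes, in_edges, roots, acts, fixed)]
        starts.append({**fixed, **{v: 0 for v in free}})
        starts.extend(_path_starts(nodes, in_edges, roots, acts, fixed, edge_penalty))
        for _ in range(8):  # tie-break-randomized constructive starts
            starts.extend(_path_starts(nodes, in_edges, roots, acts, fixed, edge_penalty, rng=rng))
        for _ in range(max(0, n_restarts - len(starts))):
            sigma = dict(fixed)
            sigma.update({v: int(rng.integers(-1, 2)) for v in free})
            starts.append(sigma)
        best = (math.inf, None, None, None)
        for sigma in starts:
            obj, state, used, cur = _local_search(
                nodes, free, in_edges, sigma, roots, acts, edge_penalty
            )
            if obj < best[0] - 1e-12:
                best = (obj, state, used, cur)
        # polish the incumbent with coordinated two-node moves (cheap escape
        # from single-flip local optima along chains)
        obj, state, used, cur = best
        obj, state, used = _pair_polish(
            nodes, free, in_edges, cur, roots, acts, edge_penalty, obj, state, used
        )

    states = {v: s for v, s in state.items() if s != 0}
    used = [e for e in used if state.get(e[1], 0) != 0]
    net = PatientNetwork(
        patient=patient,
        states=states,
        edges=sorted(used),
        sources={v for v in roots if v in states},
        objective=obj,
    )
    validate_patient_network(net)
    return net


def _null_objective(activities: dict) -> float:
    return float(sum(abs(w) for _, w in activities.values()))


def _propagation_start(nodes, in_edges, roots, acts, fixed) -> dict:
    """BFS-style start: roots take their measured (or +1) sign, downstream
    nodes take their measured sign when a consistent parent exists."""
    sigma = dict(fixed)
    for v in roots:
        if v not in sigma:
            sigma[v] = acts.get(v, (1, 0.0))[0]
    changed = True
    while changed:
        changed = False
        for v in nodes:
            if v in sigma:
                continue
            for u, sign in in_edges.get(v, ()):
                if sigma.get(u, 0) != 0:
                    implied = sigma[u] * sign
                    want = acts.get(v, (implied, 0.0))[0]
                    sigma[v] = implied if implied == want else implied
                    changed = True
                    break
    for v in nodes:
        sigma.setdefault(v, 0)
    return sigma


def _path_starts(nodes, in_edges, roots, acts, fixed, beta, rng=None) -> list:
    """Constructive starts: route each measured node to a consistent root via
    a min-cost path in the sign-expanded graph (states (node, sign); an edge
    (u, s) -> (v, s * sign(u, v)) per causal edge).  Costs mirror the
    objective: beta per used edge plus the mismatch weight of any measured
    node entered with the wrong sign, so a longer conflict-free route beats a
    short route through a contradicted measurement.  Measured nodes are
    visited in descending and ascending weight order; with ``rng`` the edge
    costs are jittered and the order shuffled to diversify tie-breaking."""
    import heapq

    step = max(beta, 1e-6)
    jitter = (lambda: 1.0 + 0.05 * rng.random()) if rng is not None else (lambda: 1.0)

    def state_cost(g, s):
        mu_w = acts.get(g)
        return mu_w[1] if mu_w is not None and mu_w[0] != s else 0.0

    out_edges: dict = {}
    for v, ins in in_edges.items():
        for u, sign in ins:
            out_edges.setdefault(u, []).append((v, sign))

    def route(sigma, target, mu):
        """Min-cost path to (target, mu) given committed states (free roots);
        nodes committed to the opposite sign are barred."""
        dist: dict = {}
        parent: dict = {}
        heap = []
        for g, s in sigma.items():
            if s:
                dist[(g, s)] = 0.0
                heapq.heappush(heap, (0.0, (g, s)))
        for r, s_fixed in roots.items():
            for s in ((s_fixed,) if s_fixed else (-1, 1)):
                if s and sigma.get(r, 0) == 0:
                    d0 = state_cost(r, s)
                    if d0 < dist.get((r, s), math.inf):
                        dist[(r, s)] = d0
                        heapq.heappush(heap, (d0, (r, s)))
        while heap:
            d, (u, su) = heapq.heappop(heap)
            if d > dist.get((u, su), math.inf):
                continue
            if (u, su) == (target, mu):
                break
            for v, sign in out_edges.get(u, ()):
                sv = su * sign
                if sigma.get(v, 0) == -sv:
                    continue
                cost = d + step * jitter() + state_cost(v, sv)
                if cost < dist.get((v, sv), math.inf):
                    dist[(v, sv)] = cost
                    parent[(v, sv)] = (u, su)
                    heapq.heappush(heap, (cost, (v, sv)))
        if (target, mu) not in dist:
            return None
        path = []
        node = (target, mu)
        while node is not None:
            path.append(node)
            node = parent.get(node)
        return path

    measured = [(v, mu, w) for v, (mu, w) in acts.items() if v in set(nodes)]
    starts = []
    orderings = [True, False] if rng is None else [None, None]
    for reverse in orderings:
        if reverse is None:
            ordering = list(measured)
            rng.shuffle(ordering)
        else:
            ordering = sorted(measured, key=lambda t: t[2], reverse=reverse)
        sigma = dict(fixed)
        for v, mu, _ in ordering:
            if sigma.get(v, 0) == mu:
                continue
            path = route(sigma, v, mu)
            if path is None:
                continue
            for g, s in path:
                sigma[g] = s
        for v in nodes:
            sigma.setdefault(v, 0)
        starts.append(sigma)
    return starts


def _local_search(nodes, free, in_edges, sigma, roots, acts, beta):
    cur = dict(sigma)
    obj, state, used = _project_and_score(nodes, in_edges, cur, roots, acts, beta)
    improved = True
    while improved:
        improved = False
        for v in free:
            for s in (-1, 0, 1):
                if cur.get(v, 0) == s:
                    continue
                cand = dict(cur)
                cand[v] = s
                o2, st2, u2 = _project_and_score(nodes, in_edges, cand, roots, acts, beta)
                if o2 < obj - 1e-12:
                    cur, obj, state, used = cand, o2, st2, u2
                    improved = True
    return obj, state, used, cur


def _pair_polish(nodes, free, in_edges, cur, roots, acts, beta, obj, state, used):
    """Joint two-node moves until no improving pair exists; single-node
    re-descent after each accepted pair."""
    improved = True
    while improved:
        improved = False
        for a_i in range(len(free)):
            for b_i in range(a_i + 1, len(free)):
                va, vb = free[a_i], free[b_i]
                for sa in (-1, 0, 1):
                    for sb in (-1, 0, 1):
                        if cur.get(va, 0) == sa and cur.get(vb, 0) == sb:
                            continue
                        cand = dict(cur)
                        cand[va] = sa
                        cand[vb] = sb
                        o2, st2, u2 = _project_and_score(
                            nodes, in_edges, cand, roots, acts, beta
                        )
                        if o2 < obj - 1e-12:
                            obj, state, used, cur = _local_search(
                                nodes, free, in_edges, cand, roots, acts, beta
                            )
                            improved = True
    return obj, state, used


# ---------------------------------------------------------------------------
# Phenotype activation (path-proximity scoring)


def compute_phenoscores(
    net: PatientNetwork,
    phenopaths: pd.DataFrame,
    max_len: int = 3,
    stat: str = "mean",
    n_random: int = 1000,
    z_thr: float = 1.96,
    p_thr: float = 0.05,
    remove_cascade: bool = False,
    seed: int = 0,
) -> list[PhenotypeActivation]:
    """Score hallmark-phenotype activation from a patient model.

    ``phenopaths`` has columns protein, phenotype, path_sign, path_length.
    For each phenotype the regulators are the model nodes with an annotated
    path of length <= ``max_len``; the phenoscore is the ``stat`` of
    sigma(n) * path_sign.  The null shuffles sigma values across model nodes
    ``n_random`` times; a phenotype is significant when p < ``p_thr`` and
    |z_null| >= ``z_thr``.  ``remove_cascade`` drops a regulator when another
    retained regulator of the same phenotype lies downstream of it in the
    model (its influence is already routed through the cascade).
    """
    if not net.states:
        raise ValueError("network has no nodes")
    if stat not in ("mean", "median"):
        raise ValueError("stat must be 'mean' or 'median'")
    agg = np.mean if stat == "mean" else np.median
    rng = np.random.default_rng(seed)
    g = nx.DiGraph()
    g.add_nodes_from(net.states)
    g.add_edges_from((s, t) for s, t, _ in net.edges)
    node_list = sorted(net.states)
    sigma = np.array([net.states[n] for n in node_list], dtype=float)
    node_idx = {n: i for i, n in enumerate(node_list)}

    results: list[PhenotypeActivation] = []
    pp = phenopaths[phenopaths["path_length"] <= max_len]
    for phenotype, grp in pp.groupby("phenotype", sort=True):
        regs = [(r.protein, int(r.path_sign)) for r in grp.itertuples() if r.protein in net.states]
        if not regs:
            continue
        if remove_cascade and len(regs) > 1:
            reg_nodes = {p for p, _ in regs}
            drop = set()
            for p, _ in regs:
                desc = nx.descendants(g, p)
                if desc & (reg_nodes - {p}):
                    drop.add(p)
            kept = [(p, s) for p, s in regs if p not in drop]
            if kept:
                regs = kept
        idx = np.array([node_idx[p] for p, _ in regs])
        signs = np.array([s for _, s in regs], dtype=float)
        score = float(agg(sigma[idx] * signs))
        null = np.empty(n_random)
        for k in range(n_random):
            shuffled = rng.permutation(sigma)
            null[k] = agg(shuffled[idx] * signs)
        sd = null.std(ddof=1)
        if sd == 0:
            z = 0.0
            p = 1.0
        else:
            z = float((score - null.mean()) / sd)
            p = float((1 + (np.abs(null - null.mean()) >= abs(score - null.mean())).sum()) / (n_random + 1))
        results.append(
            PhenotypeActivation(
                phenotype=phenotype,
                phenoscore=score,
                z_null=z,
                p=p,
                significant=bool(p < p_thr and abs(z) >= z_thr),
            )
        )
    return results
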