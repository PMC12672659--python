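"""Seeded synthetic cohorts with planted structure.

Every pipeline stage is testable offline against cohorts generated here:
a random signed prior-knowledge network; patient-specific models built from
disjoint per-community interaction modules (each member keeps a module edge
with probability 1 - dropout) plus sparse background interactions; z-score-
like expression with each community's signature genes shifted by a planted
effect in its members; and exponential survival times whose hazard is scaled
by a per-community multiplier with independent exponential censoring.  All
generators are deterministic per seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .communities import InteractionKey
from .harmonize import OmicsMatrix
from .network import CausalEdge, PKN, PatientNetwork
from .validation import SurvivalRecord


@dataclass
class GroundTruth:
    """Planted structure of a synthetic cohort."""

    membership: dict           # patient -> community
    modules: dict              # community -> list[InteractionKey] (disjoint)
    signature_genes: dict      # community -> list[str] (disjoint)
    hazard_multipliers: dict   # community -> float
    active_regulators: dict = field(default_factory=dict)  # patient -> list[str]


def generate_pkn(
    n_nodes: int = 150,
    n_edges: int = 600,
    frac_inhibitory: float = 0.3,
    seed: int = 0,
) -> PKN:
    """Random signed, directed PKN without self-loops or duplicates.

    The number of inhibitory edges equals round(frac_inhibitory * n_edges)
    (within one edge of the requested fraction); deterministic per seed.
    """
    if n_edges > n_nodes * (n_nodes - 1):
        raise ValueError("n_edges exceeds the number of ordered node pairs")
    rng = np.random.default_rng(seed)
    nodes = [f"G{i:04d}" for i in range(n_nodes)]
    pairs: set = set()
    while len(pairs) < n_edges:
        need = n_edges - len(pairs)
        u = rng.integers(0, n_nodes, size=2 * need + 8)
        v = rng.integers(0, n_nodes, size=2 * need + 8)
        for a, b in zip(u, v):
            if a != b and (a, b) not in pairs:
                pairs.add((int(a), int(b)))
                if len(pairs) == n_edges:
                    break
    pairs = sorted(pairs)
    n_inh = int(round(frac_inhibitory * n_edges))
    signs = np.ones(n_edges, dtype=int)
    signs[rng.choice(n_edges, size=n_inh, replace=False)] = -1
    edges = [
        CausalEdge(nodes[a], nodes[b], int(s), direct=bool(rng.random() < 0.8))
        for (a, b), s in zip(pairs, signs)
    ]
    return PKN(edges)


def generate_cohort(
    n_patients: int = 40,
    k_communities: int = 4,
    n_genes: int = 300,
    module_size: int = 30,
    sig_size: int = 20,
    effect: float = 2.0,
    noise_sd: float = 1.0,
    dropout: float = 0.05,
    background_prob: float | None = None,
    n_interactions: int = 400,
    seed: int = 0,
) -> tuple[OmicsMatrix, dict, GroundTruth]:
    """Cohort with planted community modules and transcriptomic signatures.

    Returns (expression matrix, patient networks, ground truth).  Patients are
    split evenly over ``k_communities``.  From a pool of ``n_interactions``
    signed interactions, each community owns a disjoint module of
    ``module_size``; a member's network keeps each module edge with
    probability 1 - ``dropout`` and picks up each non-module ("background")
    interaction with probability ``background_prob`` (defaults to ``dropout``,
    one noise knob).  Expression is N(0, noise_sd) z-like values with each
    community's ``sig_size`` signature genes shifted by +``effect`` in its
    members.  Deterministic per seed.
    """
    if k_communities * sig_size > n_genes:
        raise ValueError("k_communities * sig_size must be <= n_genes")
    if k_communities * module_size > n_interactions:
        raise ValueError("k_communities * module_size must be <= n_interactions")
    if background_prob is None:
        background_prob = dropout
    rng = np.random.default_rng(seed)
    patients = [f"P{i:03d}" for i in range(n_patients)]
    membership = {p: i % k_communities for i, p in enumerate(patients)}

    # interaction pool over a generated PKN-like node universe
    n_nodes = max(60, int(math.isqrt(4 * n_interactions)) + 2)
    pkn = generate_pkn(n_nodes=n_nodes, n_edges=n_interactions, frac_inhibitory=0.3,
                       seed=int(rng.integers(0, 2**31 - 1)))
    pool = [InteractionKey(e.source, e.sign, e.target) for e in pkn.edges]
    order = rng.permutation(len(pool))
    modules = {
        c: [pool[i] for i in order[c * module_size:(c + 1) * module_size]]
        for c in range(k_communities)
    }
    module_set = {i for mod in modules.values() for i in mod}
    background = [i for i in pool if i not in module_set]

    networks: dict = {}
    for p in patients:
        c = membership[p]
        keep = [i for i in modules[c] if rng.random() >= dropout]
        extra = [i for i in background if rng.random() < background_prob]
        edges = keep + extra
        states: dict = {}
        for ik in keep:
            states[ik.source] = 1
            states.setdefault(ik.target, 1)
        for ik in extra:
            states.setdefault(ik.source, 1 if rng.random() < 0.7 else -1)
            states.setdefault(ik.target, int(rng.choice((-1, 1))))
        networks[p] = PatientNetwork(
            patient=p,
            states=states,
            edges=sorted((ik.source, ik.target, ik.sign) for ik in edges),
            sources=set(states),
        )

    genes = [f"T{i:04d}" for i in range(n_genes)]
    sig_genes = {
        c: genes[c * sig_size:(c + 1) * sig_size] for c in range(k_communities)
    }
    X = rng.normal(0.0, noise_sd, size=(n_genes, n_patients))
    gene_idx = {g: i for i, g in enumerate(genes)}
    for j, p in enumerate(patients):
        for g in sig_genes[membership[p]]:
            X[gene_idx[g], j] += effect
    expr = OmicsMatrix(
        pd.DataFrame(X, index=genes, columns=patients),
        omic_kind="transcriptomics",
        stage="zscored",
    )
    truth = GroundTruth(
        membership=membership,
        modules=modules,
        signature_genes=sig_genes,
        hazard_multipliers={c: 1.0 for c in range(k_communities)},
        active_regulators={p: sorted({ik.source for ik in modules[membership[p]]}) for p in patients},
    )
    return expr, networks, truth


def generate_survival(
    truth: GroundTruth,
    base_rate: float = 0.01,
    censor_rate: float = 0.005,
    hazard_multipliers: dict | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Exponential survival with per-community hazard multipliers.

    Event time ~ Exp(base_rate * multiplier(community)); censoring time
    ~ Exp(censor_rate); the record keeps the earlier of the two.  Returns a
    frame with columns patient, time, event, group.
    """
    if base_rate <= 0 or censor_rate <= 0:
        raise ValueError("rates must be > 0")
    mult = hazard_multipliers if hazard_multipliers is not None else truth.hazard_multipliers
    rng = np.random.default_rng(seed)
    rows = []
    for p, c in truth.membership.items():
        lam = base_rate * float(mult.get(c, 1.0))
        t_event = rng.exponential(1.0 / lam)
        t_cens = rng.exponential(1.0 / censor_rate)
        t = min(t_event, t_cens)
        rows.append({
            "patient": p, "time": float(t), "event": int(t_event <= t_cens), "group": c,
        })
    return pd.DataFrame(rows)
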