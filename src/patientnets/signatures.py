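"""Community transcriptomic signatures.

Each community's signature is the set (at most ``max_val`` genes) of
transcripts specifically up-regulated in its member patients: per gene a
one-way ANOVA across community labels (BH-adjusted over genes) followed by a
positive, significant Tukey-Kramer contrast of the community against the
pooled background, with mean-expression and effect-size floors.  New patients
are assigned to a signature by preranked enrichment of their z-scored
transcriptome: a weighted Kolmogorov-Smirnov running sum (weight exponent 1)
with a seeded gene-label permutation null, BH-corrected across signatures,
assigning only on positive enrichment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .harmonize import OmicsMatrix
from .stats import anova_oneway_matrix, bh_adjust, tukey_contrast_vs_rest

DEFAULT_PADJ = 0.01
DEFAULT_MAX_GENES = 50


@dataclass
class Signature:
    """Up-regulated gene set of one community, ordered by effect size."""

    community: object
    genes: pd.DataFrame  # columns: gene, F, p, adj_p, mean_in, mean_bg, diff
    flagged: bool = False

    @property
    def gene_list(self) -> list:
        return self.genes["gene"].tolist()

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class EnrichmentAssignment:
    patient: object
    assigned: object  # signature/community id, or None
    table: pd.DataFrame  # per signature: ES, NES, p, adj_p


def extract_signatures(
    expr,
    membership: dict,
    padj_thres: float = DEFAULT_PADJ,
    mean_thr: float = 0.0,
    min_diff: float = 0.0,
    max_val: int = DEFAULT_MAX_GENES,
    tukey_alpha: float = 0.05,
) -> list[Signature]:
    """ANOVA + Tukey screening of community-specific up-regulated genes.

    ``expr`` is a z-scored genes x samples matrix (OmicsMatrix or DataFrame);
    ``membership`` maps patient -> community.  Communities with fewer than two
    members are excluded from testing with a warning.  Genes qualify for a
    community when the BH-adjusted ANOVA p is below ``padj_thres``, the
    community-vs-background Tukey-Kramer contrast is positive and significant
    at ``tukey_alpha``, mean expression in the community exceeds ``mean_thr``
    and the in-minus-background difference exceeds ``min_diff``.  The top
    ``max_val`` genes by difference are kept, ordered descending.
    """
    data = expr.data if isinstance(expr, OmicsMatrix) else expr
    patients = [p for p in data.columns if p in membership]
    counts: dict = {}
    for p in patients:
        counts[membership[p]] = counts.get(membership[p], 0) + 1
    small = {c for c, n in counts.items() if n < 2}
    if small:
        warnings.warn(f"communities with <2 members excluded from testing: {sorted(small)}")
    patients = [p for p in patients if membership[p] not in small]
    comms = sorted(c for c in counts if c not in small)
    if len(comms) < 2:
        raise ValueError("need at least two communities with >= 2 patients")
    X = data[patients].to_numpy(dtype=float)
    labels = np.array([membership[p] for p in patients])
    genes = data.index.to_numpy()

    F, p = anova_oneway_matrix(X, labels)
    adj_p = bh_adjust(p)

    sigs: list[Signature] = []
    for c in comms:
        sel = labels == c
        mean_in = X[:, sel].mean(axis=1)
        mean_bg = X[:, ~sel].mean(axis=1)
        cheap = (adj_p < padj_thres) & (mean_in - mean_bg > min_diff) & (mean_in > mean_thr)
        diff, q, p_tukey = tukey_contrast_vs_rest(X, labels, c, mask=cheap)
        keep = cheap & (p_tukey < tukey_alpha)
        tab = pd.DataFrame(
            {
                "gene": genes[keep],
                "F": F[keep],
                "p": p[keep],
                "adj_p": adj_p[keep],
                "mean_in": mean_in[keep],
                "mean_bg": mean_bg[keep],
                "diff": diff[keep],
            }
        ).sort_values("diff", ascending=False, kind="stable").head(max_val).reset_index(drop=True)
        sigs.append(Signature(community=c, genes=tab, flagged=tab.empty))
    return sigs


def enrichment_score(ranked_genes: np.ndarray, ranked_scores: np.ndarray, gene_set: set) -> float:
    """Weighted KS running-sum enrichment score (weight exponent 1).

    ``ranked_genes``/``ranked_scores`` are sorted by score descending; the ES
    is the extremum of the running sum (hits weighted by |score|, misses by a
    uniform decrement).
    """
    hit = np.fromiter((g in gene_set for g in ranked_genes), dtype=bool, count=len(ranked_genes))
    n_hits = int(hit.sum())
    n = len(ranked_genes)
    if n_hits == 0 or n_hits == n:
        return 0.0
    w = np.abs(ranked_scores) * hit
    wsum = w.sum()
    if wsum == 0:  # all hits have zero score: fall back to unweighted steps
        w = hit.astype(float)
        wsum = w.sum()
    p_hit = np.cumsum(w) / wsum
    p_miss = np.cumsum(~hit) / (n - n_hits)
    dev = p_hit - p_miss
    i = int(np.argmax(np.abs(dev)))
    return float(dev[i])


def assign_by_enrichment(
    ranked: pd.Series,
    sigs: list[Signature],
    n_perm: int = 1000,
    seed: int = 0,
    padj_assign: float = 0.05,
    patient=None,
) -> EnrichmentAssignment:
    """Assign a patient to the most-enriched positive signature.

    ``ranked`` is the patient's gene -> z series (sorted internally by z
    descending).  Per signature the p-value comes from ``n_perm`` seeded
    permutations of gene labels (random same-size gene sets), sign-matched;
    NES is ES over the mean same-sign null magnitude.  BH correction is
    applied across signatures and the patient is assigned to the positively
    enriched signature with the lowest adjusted p below ``padj_assign`` (ties
    broken by larger |NES| then lexicographic id), else to none.
    """
    ranked = ranked.sort_values(ascending=False)
    genes = ranked.index.to_numpy()
    scores = ranked.to_numpy(dtype=float)
    universe = set(genes)
    rng = np.random.default_rng(seed)
    rows = []
    for sig in sigs:
        gset = {g for g in sig.gene_list if g in universe}
        if not gset:
            warnings.warn(f"signature {sig.community} has no genes in the ranked universe")
            continue
        es = enrichment_score(genes, scores, gset)
        size = len(gset)
        null = np.empty(n_perm)
        for k in range(n_perm):
            perm = rng.choice(len(genes), size=size, replace=False)
            null[k] = enrichment_score(genes, scores, set(genes[perm]))
        same = null[null >= 0] if es >= 0 else null[null < 0]
        if same.size == 0:
            p = 1.0 / (n_perm + 1)
            nes = 0.0
        else:
            p = float((1 + (np.abs(same) >= abs(es)).sum()) / (same.size + 1))
            denom = np.abs(same).mean()
            nes = float(es / denom) if denom > 0 else 0.0
        rows.append({"signature": sig.community, "ES": es, "NES": nes, "p": p})
    table = pd.DataFrame(rows)
    if table.empty:
        return EnrichmentAssignment(patient, None, table)
    table["adj_p"] = bh_adjust(table["p"].to_numpy())
    pos = table[(table["ES"] > 0) & (table["adj_p"] < padj_assign)]
    if pos.empty:
        assigned = None
    else:
        pos = pos.assign(_abs_nes=pos["NES"].abs()).sort_values(
            by=["adj_p", "_abs_nes", "signature"], ascending=[True, False, True], kind="stable"
        )
        assigned = pos.iloc[0]["signature"]
    return EnrichmentAssignment(patient, assigned, table)


def write_gmt(sigs: list[Signature], path) -> None:
    """Export signatures as GMT (one community per line)."""
    with open(path, "w") as fh:
        for sig in sigs:
            genes = "\t".join(map(str, sig.gene_list))
            fh.write(f"signature_{sig.community}\tcommunity {sig.community}\t{genes}\n")


def read_gmt(path) -> list[Signature]:
    sigs = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            name = parts[0].replace("signature_", "")
            try:
                name = int(name)
            except ValueError:
                pass
            genes = pd.DataFrame({"gene": parts[2:]})
            for col in ("F", "p", "adj_p", "mean_in", "mean_bg", "diff"):
                genes[col] = np.nan
            sigs.append(Signature(community=name, genes=genes))
    return sigs
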