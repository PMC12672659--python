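"""Robustness of signatures: cross-validation and gene-wise randomization.

Cross-validation stratifies each community into 70/30 train/test splits (50
independent iterations by default), re-derives signatures from the training
patients only, re-assigns the test patients by enrichment, and scores
precision / recall / F1 per community, where a true positive is a test
patient assigned to its original community, a false positive one assigned to
a different community, and a false negative one not enriched in any
signature.  The randomization study shuffles an increasing fraction of genes
independently across samples (preserving each gene's distribution while
destroying the sample-wise structure), re-extracts signatures, and tracks the
overlap with the originals and the prognostic value of the resulting patient
groups (log-rank at a five-year horizon, BH-corrected).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .harmonize import OmicsMatrix
from .signatures import Signature, assign_by_enrichment, extract_signatures
from .stats import bh_adjust
from .validation import km_logrank

DEFAULT_FRACS = (0.05, 0.10, 0.15, 0.25, 0.50, 0.75, 1.00)


def _expr_frame(expr) -> pd.DataFrame:
    return expr.data if isinstance(expr, OmicsMatrix) else expr


def shuffle_gene_wise(expr, frac: float, seed: int):
    """Independently permute ceil(frac * n_genes) rows across samples.

    Each shuffled row remains a permutation of itself (gene-wise distribution
    preserved); which rows are shuffled is a seeded draw.
    """
    if not 0.0 <= frac <= 1.0:
        raise ValueError("frac must be in [0, 1]")
    data = _expr_frame(expr).copy()
    n = math.ceil(frac * data.shape[0])
    if n == 0:
        return OmicsMatrix(data, expr.omic_kind, expr.stage) if isinstance(expr, OmicsMatrix) else data
    rng = np.random.default_rng(seed)
    rows = rng.choice(data.shape[0], size=n, replace=False)
    vals = data.to_numpy()
    for r in rows:
        vals[r] = rng.permutation(vals[r])
    data.loc[:, :] = vals
    if isinstance(expr, OmicsMatrix):
        return OmicsMatrix(data, expr.omic_kind, expr.stage)
    return data


def _assign_all(
    data: pd.DataFrame,
    patients,
    sigs: list[Signature],
    n_perm: int,
    seed: int,
    padj_assign: float = 0.05,
) -> dict:
    out = {}
    for k, p in enumerate(patients):
        ranked = data[p]
        res = assign_by_enrichment(
            ranked, sigs, n_perm=n_perm, seed=seed + 7919 * k, padj_assign=padj_assign, patient=p
        )
        out[p] = res.assigned
    return out


def crossvalidate_communities(
    expr,
    membership: dict,
    train_frac: float = 0.7,
    runs: int = 50,
    seed: int = 0,
    n_perm: int = 200,
    signature_kwargs: dict | None = None,
) -> pd.DataFrame:
    """70/30 stratified cross-validation of community signatures.

    Returns a long frame: one row per (community, run) with TP, FP, FN,
    precision, recall, F1 and gene_recovery_pct (overlap of the training
    signature with the full-data signature).  Communities with fewer than 4
    members are skipped with a warning.
    """
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must be in (0, 1)")
    data = _expr_frame(expr)
    signature_kwargs = signature_kwargs or {}
    by_comm: dict = {}
    for p, c in membership.items():
        if p in data.columns:
            by_comm.setdefault(c, []).append(p)
    skipped = {c for c, ps in by_comm.items() if len(ps) < 4}
    if skipped:
        warnings.warn(f"communities with <4 members skipped: {sorted(skipped)}")
    by_comm = {c: sorted(ps) for c, ps in by_comm.items() if c not in skipped}
    full_sigs = {
        s.community: set(s.gene_list)
        for s in extract_signatures(data, membership, **signature_kwargs)
        if s.community in by_comm
    }
    rng = np.random.default_rng(seed)
    rows = []
    for run in range(runs):
        train, test = [], []
        for c, ps in sorted(by_comm.items(), key=lambda kv: str(kv[0])):
            perm = rng.permutation(len(ps))
            n_train = math.ceil(train_frac * len(ps))
            train += [ps[i] for i in perm[:n_train]]
            test += [ps[i] for i in perm[n_train:]]
        train_membership = {p: membership[p] for p in train}
        try:
            sigs = extract_signatures(data[train], train_membership, **signature_kwargs)
        except ValueError:
            continue
        assignments = _assign_all(data, test, sigs, n_perm, seed + 104729 * run)
        for c, ps in by_comm.items():
            test_c = [p for p in test if membership[p] == c]
            tp = sum(1 for p in test_c if assignments.get(p) == c)
            fn = sum(1 for p in test_c if assignments.get(p) is None)
            fp = len(test_c) - tp - fn
            precision = tp / (tp + fp) if tp + fp else 0.0
            recall = tp / (tp + fn) if tp + fn else 0.0
            f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
            train_sig = next((set(s.gene_list) for s in sigs if s.community == c), set())
            full = full_sigs.get(c, set())
            recovery = 100.0 * len(train_sig & full) / len(full) if full else np.nan
            rows.append({
                "community": c, "run": run, "TP": tp, "FP": fp, "FN": fn,
                "precision": precision, "recall": recall, "F1": f1,
                "gene_recovery_pct": recovery,
            })
    return pd.DataFrame(rows)


def run_randomization_study(
    expr,
    membership: dict,
    survival: pd.DataFrame | None = None,
    fracs=DEFAULT_FRACS,
    runs: int = 50,
    seed: int = 0,
    n_perm: int = 200,
    horizon_months: float = 60.0,
    signature_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Gene-wise randomization study.

    Per (fraction, run): shuffle that fraction of genes, re-extract
    signatures, record the mean percent overlap with the original signatures
    and the number of non-empty signatures; re-assign the cohort's patients
    with the control signatures and, when ``survival`` (patient, time, event)
    is given and at least two groups remain, record the log-rank p at the
    five-year horizon.  Per-fraction p-values are BH-adjusted across runs.
    """
    data = _expr_frame(expr)
    signature_kwargs = signature_kwargs or {}
    originals = {
        s.community: set(s.gene_list) for s in extract_signatures(data, membership, **signature_kwargs)
    }
    patients = [p for p in data.columns if p in membership]
    rows = []
    for fi, frac in enumerate(fracs):
        for run in range(runs):
            sub_seed = seed + 1_000_003 * fi + 613 * run
            shuffled = shuffle_gene_wise(data, frac, sub_seed)
            try:
                sigs = extract_signatures(shuffled, membership, **signature_kwargs)
            except ValueError:
                sigs = []
            overlaps = []
            n_nonempty = 0
            for s in sigs:
                orig = originals.get(s.community, set())
                if len(s):
                    n_nonempty += 1
                if orig:
                    overlaps.append(100.0 * len(set(s.gene_list) & orig) / len(orig))
            overlap = float(np.mean(overlaps)) if overlaps else 0.0
            km_p = np.nan
            if survival is not None and n_nonempty:
                assignments = _assign_all(shuffled, patients, sigs, n_perm, sub_seed)
                df = survival.copy()
                df["group"] = df["patient"].map(assignments)
                df = df.dropna(subset=["group"])
                if df["group"].nunique() >= 2:
                    try:
                        _, _, km_p = km_logrank(df, truncate_months=horizon_months)
                    except ValueError:
                        km_p = np.nan
            rows.append({
                "frac": frac, "run": run, "overlap_pct": overlap,
                "n_signatures_enriching": n_nonempty, "km_p": km_p,
            })
    report = pd.DataFrame(rows)
    report["km_adj_p"] = np.nan
    for frac in report["frac"].unique():
        sel = (report["frac"] == frac) & report["km_p"].notna()
        if sel.any():
            report.loc[sel, "km_adj_p"] = bh_adjust(report.loc[sel, "km_p"].to_numpy())
    return report
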