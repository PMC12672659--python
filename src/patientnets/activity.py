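"""Protein activity inference from omic footprints.

A regulator's activity is estimated from the modulation of its downstream
targets (its regulon) rather than from its own abundance: transcription-factor
activity from target-transcript z-scores (TFEA) and kinase/phosphatase
activity from substrate-phosphosite z-scores (KSEA).  The footprint statistic
here is a signed weighted mean of target z-scores with a seeded permutation
null, optionally corrected with a one-sided hypergeometric enrichment of
modulated targets (combined via Fisher's method).  Proteins carrying directly
regulatory phosphosites get a PhosphoScore: the mean of role-corrected site
z-scores.  Functionally annotated mutations (GOF +1 / LOF -1) override the
inferred scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .harmonize import MODULATION_Z, PhosphoKey

#: minimum regulon sizes ensuring robust footprint estimates
DEFAULT_MIN_SIZE = {"tf": 10, "kinase": 5}
#: magnitude of a mutation-driven activity override (beyond the 1.96 call threshold)
DEFAULT_OVERRIDE_K = 2.0


@dataclass(frozen=True)
class Regulon:
    """A regulator with its signed, weighted targets.

    ``layer`` is ``tf`` (targets are transcripts) or ``kinase`` (targets are
    phosphosites); ``targets`` holds (target key, mode in {+1,-1}, weight >= 0).
    """

    regulator: str
    layer: str
    targets: tuple

    def __post_init__(self) -> None:
        if self.layer not in ("tf", "kinase"):
            raise ValueError(f"layer must be 'tf' or 'kinase', got {self.layer!r}")
        if not self.targets:
            raise ValueError(f"regulon {self.regulator} has no targets")
        for _, mode, weight in self.targets:
            if mode not in (1, -1):
                raise ValueError("target mode must be +1 or -1")
            if not np.isfinite(weight) or weight < 0:
                raise ValueError("target weight must be finite and >= 0")


@dataclass(frozen=True)
class RegulatorySite:
    """A phosphosite with a known effect on its host protein."""

    site: PhosphoKey
    role: int  # +1 activating, -1 inhibiting
    affects: str = "activity"  # "activity" | "stability"

    def __post_init__(self) -> None:
        if self.role not in (1, -1):
            raise ValueError("role must be +1 or -1")
        if self.affects not in ("activity", "stability"):
            raise ValueError(f"affects must be activity/stability, got {self.affects!r}")


@dataclass(frozen=True)
class MutationCall:
    patient: str
    gene: str
    effect: int  # +1 GOF, -1 LOF

    def __post_init__(self) -> None:
        if self.effect not in (1, -1):
            raise ValueError("effect must be +1 (GOF) or -1 (LOF)")


@dataclass(frozen=True)
class FootprintScore:
    regulator: str
    layer: str
    score: float
    p: float
    n_targets: int


def score_footprint(
    regulons: list[Regulon],
    profile: dict[str, float],
    min_size: int = 5,
    n_perm: int = 1000,
    seed: int = 0,
    hypergeom_correct: bool = False,
    z_threshold: float = MODULATION_Z,
) -> list[FootprintScore]:
    """Footprint activity of each regulator on one sample's z-score profile.

    score = sum(mode * weight * z) / sum(weight) over targets present in the
    profile; regulons with fewer than ``min_size`` present targets are skipped.
    The two-sided p-value comes from ``n_perm`` seeded permutations drawing
    target z-values from the full profile; with ``hypergeom_correct`` it is
    combined (Fisher's method) with a one-sided hypergeometric enrichment of
    modulated targets (|z| > 1.96) in the regulon.
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    all_z = np.asarray(list(profile.values()), dtype=float)
    n_modulated = int((np.abs(all_z) > z_threshold).sum())
    results: list[FootprintScore] = []
    for reg in regulons:
        present = [(t, m, w) for t, m, w in reg.targets if t in profile]
        if len(present) < min_size:
            continue
        z = np.array([profile[t] for t, _, _ in present])
        modes = np.array([m for _, m, _ in present], dtype=float)
        weights = np.array([w for _, _, w in present], dtype=float)
        wsum = weights.sum()
        if wsum == 0:
            continue
        score = float((modes * weights * z).sum() / wsum)
        # permutation null: same modes/weights, z drawn from the full profile
        idx = rng.integers(0, all_z.size, size=(n_perm, z.size))
        null = (modes * weights * all_z[idx]).sum(axis=1) / wsum
        p_perm = float((1 + (np.abs(null) >= abs(score)).sum()) / (n_perm + 1))
        if hypergeom_correct:
            k_mod = int((np.abs(z) > z_threshold).sum())
            p_hg = float(stats.hypergeom.sf(k_mod - 1, all_z.size, n_modulated, z.size))
            _, p = stats.combine_pvalues([p_perm, min(max(p_hg, 1e-300), 1.0)], method="fisher")
            p = float(p)
        else:
            p = p_perm
        results.append(FootprintScore(reg.regulator, reg.layer, score, p, len(present)))
    return results


def score_phospho(
    sites: list[tuple[RegulatorySite, float]],
    activity_only: bool = True,
) -> tuple[float, int] | None:
    """PhosphoScore: mean of role * z over a protein's regulatory sites.

    With ``activity_only`` (the default) stability-affecting sites are ignored,
    keeping the estimate comparable with footprint activities.  Returns None
    when no site survives filtering (the protein is skipped, not an error).
    """
    kept = [(s, z) for s, z in sites if not activity_only or s.affects == "activity"]
    if not kept:
        return None
    vals = [s.role * z for s, z in kept]
    return float(np.mean(vals)), len(kept)


def combine_and_override(
    footprint: dict[tuple[str, str], FootprintScore],
    phospho: dict[tuple[str, str], float],
    mutations: list[MutationCall] = (),
    K: float = DEFAULT_OVERRIDE_K,
) -> pd.DataFrame:
    """Merge footprint and PhosphoScore evidence and apply mutation overrides.

    ``footprint`` and ``phospho`` are keyed by (patient, gene).  Proteins with
    both evidence streams get the unweighted mean of the two (method
    ``combined``) and a ``discordant`` flag when the signs differ.  Mutation
    calls overwrite ``final_score`` with effect * K (method ``mutation``) or
    introduce new rows for genes absent from the inference.

    Returns the activity table: one row per (patient, gene) with columns
    patient, gene, mf, final_score, method, p, discordant.
    """
    # conflicting duplicate mutation calls are an input error
    seen: dict[tuple[str, str], int] = {}
    for mc in mutations:
        key = (mc.patient, mc.gene)
        if key in seen and seen[key] != mc.effect:
            raise ValueError(f"conflicting mutation calls for {key}: {seen[key]} vs {mc.effect}")
        seen[key] = mc.effect

    rows: dict[tuple[str, str], dict] = {}
    for (patient, gene), fs in footprint.items():
        mf = "tf" if fs.layer == "tf" else "kin"
        rows[(patient, gene)] = {
            "patient": patient, "gene": gene, "mf": mf,
            "final_score": fs.score, "method": "footprint", "p": fs.p, "discordant": False,
        }
    for (patient, gene), score in phospho.items():
        key = (patient, gene)
        if key in rows:
            prev = rows[key]
            fp_score = prev["final_score"]
            prev.update(
                final_score=(fp_score + score) / 2.0,
                method="combined",
                discordant=bool(np.sign(fp_score) * np.sign(score) < 0),
            )
        else:
            rows[key] = {
                "patient": patient, "gene": gene, "mf": "phos",
                "final_score": score, "method": "phosphoscore", "p": np.nan, "discordant": False,
            }
    for (patient, gene), effect in seen.items():
        key = (patient, gene)
        if key in rows:
            rows[key].update(final_score=effect * K, method="mutation")
        else:
            rows[key] = {
                "patient": patient, "gene": gene, "mf": "other",
                "final_score": effect * K, "method": "mutation", "p": np.nan, "discordant": False,
            }
    table = pd.DataFrame(rows.values())
    if table.empty:
        table = pd.DataFrame(
            columns=["patient", "gene", "mf", "final_score", "method", "p", "discordant"]
        )
    return table.reset_index(drop=True)


def proteomics_correction_weight(z_protein: float, max_abs_z: float) -> float:
    """Down-weight for phosphosites co-modulated with protein abundance.

    Multiplicative weight 1 - |z_prot| / max|z|: a site on a protein whose
    abundance itself moves as strongly as anything in the sample contributes
    nothing, one on a flat protein contributes fully.  An interpretation of
    qualitative guidance; off by default in the scoring functions.
    """
    if max_abs_z <= 0:
        return 1.0
    return max(0.0, 1.0 - abs(z_protein) / max_abs_z)
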