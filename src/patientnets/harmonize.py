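"""Multi-omic matrix harmonization.

Cancer cohorts frequently ship without replicates or matched normal tissue, so
up/down-regulation is estimated per patient with sample-wise z-scores centered
on the median of all analytes measured in that sample.  This module covers the
preprocessing contract shared by the downstream stages: missing-value
filtering, seeded single imputation for (phospho)proteomics, z-scoring, calling
significantly modulated analytes at |z| > 1.96 (two standard deviations, i.e.
outside the 95% interval), and standardization of phosphosite identities with
15-mer sequence windows centered on the phosphorylated residue.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

OMIC_KINDS = ("transcriptomics", "proteomics", "phosphoproteomics")
STAGES = ("raw", "filtered", "imputed", "zscored")

#: z threshold beyond which an analyte is considered significantly modulated
MODULATION_Z = 1.96


@dataclass
class OmicsMatrix:
    """Analytes x samples abundance (or z-score) matrix.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows are analyte keys (gene symbols, or ``gene|accession|residue|position``
        phospho keys), columns are patient/sample identifiers.
    omic_kind : str
        One of ``transcriptomics``, ``proteomics``, ``phosphoproteomics``.
    stage : str
        Processing stage: ``raw`` -> ``filtered`` -> ``imputed`` -> ``zscored``.
    """

    data: pd.DataFrame
    omic_kind: str
    stage: str = "raw"

    def __post_init__(self) -> None:
        if self.omic_kind not in OMIC_KINDS:
            raise ValueError(f"unknown omic_kind {self.omic_kind!r}")
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][:5].tolist()
            raise ValueError(f"duplicate analyte keys: {dup}")
        if self.data.columns.has_duplicates:
            dup = self.data.columns[self.data.columns.duplicated()][:5].tolist()
            raise ValueError(f"duplicate sample ids: {dup}")
        if self.stage in ("imputed", "zscored") and self.data.isna().any().any():
            raise ValueError(f"stage={self.stage} forbids missing entries")

    @property
    def analyte_keys(self) -> list:
        return self.data.index.tolist()

    @property
    def sample_ids(self) -> list:
        return self.data.columns.tolist()

    def copy(self) -> "OmicsMatrix":
        return OmicsMatrix(self.data.copy(), self.omic_kind, self.stage)


@dataclass(frozen=True)
class PhosphoKey:
    """Identity of one phosphosite on one protein.

    ``window`` is the ``2 * flank + 1``-character sequence window centered on
    the phosphorylated residue, padded with ``_`` where the window runs past
    a protein terminus.  ``position`` is 1-based into the protein sequence.
    """

    gene: str
    accession: str
    residue: str
    position: int
    window: str = ""
    multiplicity: int = 1
    peptide: str | None = None

    def __post_init__(self) -> None:
        if self.residue not in ("S", "T", "Y"):
            raise ValueError(f"residue must be S/T/Y, got {self.residue!r}")
        if self.position < 1:
            raise ValueError("position must be >= 1 (1-based)")

    @property
    def key(self) -> str:
        return f"{self.gene}|{self.accession}|{self.residue}|{self.position}"


@dataclass(frozen=True)
class ModulationCall:
    analyte: str
    sample: str
    z: float
    modulated: str  # "up" | "down" | "none"


def filter_missing_analytes(m: OmicsMatrix, max_missing_frac: float = 0.8) -> OmicsMatrix:
    """Drop analytes with a missing fraction strictly above ``max_missing_frac``.

    For transcriptomics the remaining missing entries are set to 0 (the value
    a fully absent transcript would take before z-scoring); (phospho)proteomic
    gaps are left in place for :func:`impute_missing`.
    """
    if not 0.0 <= max_missing_frac <= 1.0:
        raise ValueError(f"max_missing_frac must be in [0, 1], got {max_missing_frac}")
    if m.stage != "raw":
        raise ValueError(f"expected stage=raw, got {m.stage}")
    frac = m.data.isna().mean(axis=1)
    kept = m.data.loc[frac <= max_missing_frac].copy()
    if kept.empty:
        raise ValueError(
            f"no analytes left after removing rows with >{max_missing_frac:.0%} missing"
        )
    if m.omic_kind == "transcriptomics":
        kept = kept.fillna(0.0)
    return OmicsMatrix(kept, m.omic_kind, "filtered")


def impute_missing(m: OmicsMatrix, method: str = "normal_regression", seed: int = 0) -> OmicsMatrix:
    """Seeded single imputation of missing (phospho)proteomic values.

    Three interchangeable engines share one contract: observed entries are
    untouched and the output is identical for identical seeds.

    - ``normal_regression``: draw from a normal model fit to the analyte's
      observed values (mean, sample sd).
    - ``pmm_like``: predictive-mean-matching flavour; each missing cell takes
      the value of a donor drawn from the observed values closest to the
      analyte mean.
    - ``mean``: analyte mean.
    """
    if method not in ("normal_regression", "pmm_like", "mean"):
        raise ValueError(f"unknown imputation method {method!r}")
    if m.stage != "filtered":
        raise ValueError(f"expected stage=filtered, got {m.stage}")
    if m.omic_kind not in ("proteomics", "phosphoproteomics"):
        raise ValueError("imputation applies to (phospho)proteomics only")
    rng = np.random.default_rng(seed)
    out = m.data.copy()
    values = out.to_numpy(dtype=float)
    n_donors = 5
    for i in range(values.shape[0]):
        row = values[i]
        miss = np.isnan(row)
        if not miss.any():
            continue
        obs = row[~miss]
        if obs.size == 0:
            raise ValueError(f"analyte {out.index[i]!r} is entirely missing; cannot impute")
        mu = float(obs.mean())
        if method == "mean":
            row[miss] = mu
        elif method == "normal_regression":
            sd = float(obs.std(ddof=1)) if obs.size > 1 else 0.0
            row[miss] = rng.normal(mu, sd, size=int(miss.sum()))
        else:  # pmm_like
            order = np.argsort(np.abs(obs - mu), kind="stable")
            donors = obs[order[: min(n_donors, obs.size)]]
            row[miss] = rng.choice(donors, size=int(miss.sum()), replace=True)
    out.loc[:, :] = values
    return OmicsMatrix(out, m.omic_kind, "imputed")


def zscore_matrix(m: OmicsMatrix, by: str = "sample", center: str = "median") -> OmicsMatrix:
    """Z-score the matrix along samples (columns) or analytes (rows).

    ``center`` picks the location estimate (median is the robust default);
    the scale is always the sample standard deviation (n-1 denominator).
    """
    if by not in ("sample", "analyte"):
        raise ValueError(f"by must be 'sample' or 'analyte', got {by!r}")
    if center not in ("median", "mean"):
        raise ValueError(f"center must be 'median' or 'mean', got {center!r}")
    axis = 0 if by == "sample" else 1  # pandas axis along which stats collapse
    if m.data.isna().any().any():
        raise ValueError("missing entries present; filter/impute before z-scoring")
    loc = m.data.median(axis=axis) if center == "median" else m.data.mean(axis=axis)
    sd = m.data.std(axis=axis, ddof=1)
    zero = sd[(sd == 0) | sd.isna()]
    if len(zero):
        kind = "sample" if by == "sample" else "analyte"
        raise ValueError(f"zero standard deviation for {kind}(s): {zero.index[:5].tolist()}")
    if by == "sample":
        z = (m.data - loc) / sd
    else:
        z = m.data.sub(loc, axis=0).div(sd, axis=0)
    return OmicsMatrix(z, m.omic_kind, "zscored")


def flag_modulated(m: OmicsMatrix, threshold: float = MODULATION_Z) -> pd.DataFrame:
    """Call each (analyte, sample) up/down/none at ``|z| > threshold`` (strict).

    Returns a long-format frame with columns analyte, sample, z, modulated.
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    if m.stage != "zscored":
        raise ValueError(f"expected stage=zscored, got {m.stage}")
    long = m.data.stack().rename("z").reset_index()
    long.columns = ["analyte", "sample", "z"]
    long["modulated"] = np.where(
        long["z"] > threshold, "up", np.where(long["z"] < -threshold, "down", "none")
    )
    return long


def sequence_window(sequence: str, position: int, flank: int = 7) -> str:
    """Extract the ``2*flank+1``-mer centered on 1-based ``position``, '_'-padded."""
    idx = position - 1
    left = max(0, idx - flank)
    right = min(len(sequence), idx + flank + 1)
    pad_l = "_" * (flank - (idx - left))
    pad_r = "_" * (flank - (right - 1 - idx))
    return pad_l + sequence[left:right] + pad_r


def harmonize_phosphosites(
    table: pd.DataFrame,
    sequences: Mapping[str, str],
    flank: int = 7,
    reanchor_window: int = 5,
) -> tuple[list[PhosphoKey], dict]:
    """Standardize a phosphosite annotation table against protein sequences.

    Expects columns gene, accession, residue, position and optionally peptide,
    multiplicity.  Steps: drop sites with an ambiguous residue (anything other
    than a single S/T/Y); drop sites whose accession has no sequence (reported);
    re-anchor positions whose stated residue mismatches the sequence by
    searching +/- ``reanchor_window`` positions for the same letter (nearest
    match, ties to the left); deduplicate (accession, residue, position) by
    longest peptide then lowest multiplicity; and compute the sequence window.

    Returns the harmonized keys and a report of dropped rows.
    """
    report = {"ambiguous_residue": 0, "missing_sequence": 0, "unanchorable": 0, "deduplicated": 0}
    rows: list[PhosphoKey] = []
    for rec in table.to_dict("records"):
        residue = str(rec.get("residue", "")).strip()
        if residue not in ("S", "T", "Y"):
            report["ambiguous_residue"] += 1
            continue
        accession = str(rec["accession"])
        seq = sequences.get(accession)
        if seq is None:
            report["missing_sequence"] += 1
            continue
        position = int(rec["position"])
        if position < 1 or position > len(seq) or seq[position - 1] != residue:
            position = _reanchor(seq, residue, position, reanchor_window)
            if position is None:
                report["unanchorable"] += 1
                continue
        peptide = rec.get("peptide")
        peptide = None if peptide is None or (isinstance(peptide, float) and np.isnan(peptide)) else str(peptide)
        rows.append(
            PhosphoKey(
                gene=str(rec["gene"]),
                accession=accession,
                residue=residue,
                position=position,
                window=sequence_window(seq, position, flank),
                multiplicity=int(rec.get("multiplicity", 1) or 1),
                peptide=peptide,
            )
        )
    # deduplicate: longest peptide first, then lowest multiplicity
    best: dict[tuple, PhosphoKey] = {}
    for pk in rows:
        key = (pk.accession, pk.residue, pk.position)
        cur = best.get(key)
        if cur is None:
            best[key] = pk
            continue
        report["deduplicated"] += 1
        if _dedup_rank(pk) < _dedup_rank(cur):
            best[key] = pk
    return list(best.values()), report


def _dedup_rank(pk: PhosphoKey) -> tuple:
    pep_len = len(pk.peptide) if pk.peptide else 0
    return (-pep_len, pk.multiplicity)


def _reanchor(seq: str, residue: str, position: int, window: int) -> int | None:
    """Nearest position within +/-window holding ``residue``; ties go left."""
    for off in range(window + 1):
        for cand in (position - off, position + off):
            if 1 <= cand <= len(seq) and seq[cand - 1] == residue:
                return cand
    return None
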