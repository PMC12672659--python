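"""Clinical and compositional validation utilities.

Kaplan-Meier survival with the multi-group log-rank test (via lifelines),
Fisher's exact association between stratifications and covariates, and cosine
similarity of subtype-proportion vectors across cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats as sps


@dataclass(frozen=True)
class SurvivalRecord:
    patient: str
    time: float  # months
    event: int  # 1 = event, 0 = censored
    group: object

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("time must be >= 0")
        if self.event not in (0, 1):
            raise ValueError("event must be 0 or 1")


def _records_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame([r.__dict__ for r in records])
    if (df["time"] < 0).any():
        raise ValueError("negative survival times")
    return df


def km_logrank(records, truncate_months: float | None = None):
    """Kaplan-Meier curves per group and the multi-group log-rank test.

    ``truncate_months`` recodes events after the horizon as censored at the
    horizon (the five-year analyses use 60).  Returns (curves, chi2, p) where
    ``curves`` maps group -> DataFrame(time, survival).
    """
    df = _records_frame(records)
    groups = df["group"].unique()
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g in groups:
        if not len(df[df["group"] == g]):
            raise ValueError(f"group {g} has no records")
    if truncate_months is not None:
        over = df["time"] > truncate_months
        df.loc[over, "event"] = 0
        df.loc[over, "time"] = truncate_months
    curves = {}
    for g in sorted(groups, key=str):
        sub = df[df["group"] == g]
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], sub["event"])
        sf = kmf.survival_function_.reset_index()
        sf.columns = ["time", "survival"]
        curves[g] = sf
    res = multivariate_logrank_test(df["time"], df["group"], df["event"])
    return curves, float(res.test_statistic), float(res.p_value)


def fisher_association(table) -> tuple[float, float]:
    """Two-sided Fisher's exact test on a 2x2 table.

    Returns (odds_ratio, p).  The odds ratio is the sample OR (ad/bc); when a
    zero cell makes it undefined, 0.5 is added to every cell (Haldane
    continuity) -- the caller can detect that case from a zero in the table.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a non-negative 2x2 table")
    if t.sum() == 0 or (t.sum(0) == 0).any() and (t.sum(1) == 0).any():
        raise ValueError("degenerate table margin")
    a, b, c, d = t.ravel()
    if b * c == 0 and a * d == 0:
        orr = np.nan
    elif b * c == 0 or a * d == 0:
        orr = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        orr = (a * d) / (b * c)
    _, p = sps.fisher_exact(t.astype(int), alternative="two-sided")
    return float(orr), float(p)


def cosine_subtype_similarity(v1, v2) -> float:
    """Cosine of the angle between two subtype-proportion vectors (in [0, 1]).

    Direction-only: invariant to cohort size.  1 means identical composition,
    0 means disjoint subtype support.
    """
    a = np.asarray(v1, dtype=float)
    b = np.asarray(v2, dtype=float)
    if a.shape != b.shape:
        raise ValueError("vectors must have the same length")
    if (a < 0).any() or (b < 0).any():
        raise ValueError("proportions must be non-negative")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("zero vector")
    return float(a @ b / (na * nb))
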