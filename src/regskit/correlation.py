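"""Pairwise Pearson correlation of AUC0 across drugs within a disease.

A positive, significant correlation of the dose-response summaries of two
drugs over the same cell-line panel indicates shared resistance mechanisms
(typical for agents with similar mechanisms of action, e.g. alkylators).
Missing values are handled by pairwise-complete deletion because not every
drug was screened on every line; pairs with fewer than three complete pairs
are skipped and reported as such.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["CorrelationResult", "pairwise_correlations", "star_code"]

# significance coding, strictly-less thresholds
_STAR_LEVELS = ((0.001, "***"), (0.01, "**"), (0.05, "*"), (0.1, "."))


def star_code(p: float) -> str:
    """Significance stars: '.' p<0.1, '*' p<0.05, '**' p<0.01, '***' p<0.001."""
    if not 0.0 < p <= 1.0:
        raise ValueError("p must be in (0, 1]")
    for threshold, code in _STAR_LEVELS:
        if p < threshold:
            return code
    return "ns"


@dataclass(frozen=True)
class CorrelationResult:
    drug_a: str
    drug_b: str
    disease: str
    r: float
    p: float
    n: int
    stars: str
    skipped: bool = False
    reason: str = ""


def pairwise_correlations(
    auc: pd.DataFrame,
    disease: pd.Series | None = None,
    diseases=None,
    min_n: int = 3,
) -> pd.DataFrame:
    """All drug-pair Pearson correlations of AUC0 within each disease.

    Parameters
    ----------
    auc
        Cell lines × drugs table of AUC0 values; NaN where a line was not
        screened for a drug.
    disease
        Per-cell-line disease label aligned to ``auc``'s index; omit to treat
        the whole table as one group labelled "all".
    min_n
        Minimum number of complete pairs; pairs below it (or with a
        zero-variance column) are returned flagged ``skipped``.

    Two-sided p-values come from the t distribution with n - 2 df.
    """
    if disease is None:
        disease = pd.Series("all", index=auc.index)
    disease = disease.reindex(auc.index)
    rows = []
    for dz in sorted(disease.dropna().unique()):
        if diseases is not None and dz not in set(diseases):
            continue
        sub = auc.loc[disease == dz]
        for a, b in combinations(auc.columns, 2):
            pair = sub[[a, b]].dropna()
            n = len(pair)
            if n < min_n:
                rows.append(
                    CorrelationResult(a, b, dz, np.nan, np.nan, n, "", True, f"fewer than {min_n} complete pairs")
                )
                continue
            xa = pair[a].to_numpy(float)
            xb = pair[b].to_numpy(float)
            if np.ptp(xa) == 0 or np.ptp(xb) == 0:
                rows.append(
                    CorrelationResult(a, b, dz, np.nan, np.nan, n, "", True, "zero-variance column")
                )
                continue
            res = stats.pearsonr(xa, xb)
            p = float(res.pvalue)
            # identical columns give r = 1 with p = 0.0; keep p in (0, 1]
            p = max(p, np.finfo(float).tiny)
            rows.append(CorrelationResult(a, b, dz, float(res.statistic), p, n, star_code(p)))
    return pd.DataFrame([r.__dict__ for r in rows])
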