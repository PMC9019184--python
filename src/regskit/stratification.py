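"""Cohort stratification: subtype assignment, group tests, survival splits.

Given per-patient resistance probabilities and a molecular-subtype
class-probability matrix (e.g. from a cell-of-origin classifier), this module

* assigns each sample to its highest-probability subtype, relabelling the 15%
  of samples with the lowest classification confidence per cohort as
  unclassified;
* compares resistance probabilities between subtypes with a tie-corrected
  Kruskal-Wallis test (exact permutation reference available at small n);
* trichotomizes a cohort into sensitive / intermediate / resistant tertiles of
  predicted resistance probability and compares their survival with
  Kaplan-Meier curves and a k-group log-rank test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from .signature import tertile_sizes

__all__ = [
    "SubtypeAssignment",
    "TestResult",
    "assign_subtypes",
    "compare_groups",
    "trichotomize",
    "km_logrank",
]


@dataclass(frozen=True)
class SubtypeAssignment:
    sample_id: str
    assigned_class: str
    confidence: float


@dataclass
class TestResult:
    statistic: float
    df: int
    p: float
    group_sizes: dict = field(default_factory=dict)
    method: str = ""
    undefined: bool = False


def assign_subtypes(prob_matrix: pd.DataFrame, unclassified_fraction: float = 0.15) -> pd.DataFrame:
    """Argmax subtype per sample, with the lowest-confidence 15% unclassified.

    ``prob_matrix`` is samples × classes with rows summing to 1 (±1e-6).
    Exactly ``ceil(unclassified_fraction · n)`` samples — those with the
    lowest maximum class probability, ties broken by row order — are
    relabelled ``"unclassified"``.  Returns columns
    ``sample_id, assigned_class, confidence, unclassified``.
    """
    probs = prob_matrix.to_numpy(float)
    if probs.ndim != 2 or probs.shape[0] == 0:
        raise ValueError("probability matrix must be non-empty")
    if np.isnan(probs).any() or (probs < -1e-12).any():
        raise ValueError("malformed probability rows")
    if np.abs(probs.sum(axis=1) - 1.0).max() > 1e-6:
        raise ValueError("probability rows must sum to 1 (±1e-6)")
    n = probs.shape[0]
    conf = probs.max(axis=1)
    assigned = prob_matrix.columns.to_numpy(object)[probs.argmax(axis=1)]
    n_unc = math.ceil(unclassified_fraction * n)
    order = np.argsort(conf, kind="stable")  # stable: ties keep row order
    unclassified = np.zeros(n, dtype=bool)
    unclassified[order[:n_unc]] = True
    out = pd.DataFrame(
        {
            "sample_id": prob_matrix.index.astype(str),
            "assigned_class": np.where(unclassified, "unclassified", assigned),
            "confidence": conf,
            "unclassified": unclassified,
        }
    )
    return out.reset_index(drop=True)


def _kw_statistic(values: np.ndarray, codes: np.ndarray, k: int) -> float:
    """Tie-corrected Kruskal-Wallis H from pre-computed group codes."""
    n = len(values)
    ranks = stats.rankdata(values)
    h = 0.0
    for g in range(k):
        rg = ranks[codes == g]
        h += rg.sum() ** 2 / len(rg)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(values, return_counts=True)
    tie = 1.0 - (counts**3 - counts).sum() / (n**3 - n)
    return h / tie if tie > 0 else 0.0


def compare_groups(values, groups, exact: bool = False) -> TestResult:
    """Kruskal-Wallis comparison of a quantity (e.g. resistance probability)
    between groups.

    Uses the chi-square approximation with tie correction; with ``exact=True``
    (total n <= 10) the p-value is taken from full enumeration of the group
    assignments instead.  All-identical observations give H = 0, p = 1.
    """
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    if len(values) != len(groups):
        raise ValueError("values and groups must align")
    uniq, codes = np.unique(groups, return_inverse=True)
    k = len(uniq)
    sizes = {str(u): int((codes == i).sum()) for i, u in enumerate(uniq)}
    if k < 2:
        raise ValueError("need at least 2 non-empty groups")
    if len(values) < 5:
        raise ValueError("need total n >= 5")
    if np.ptp(values) == 0:
        return TestResult(0.0, k - 1, 1.0, sizes, "kruskal-wallis")
    if exact:
        if len(values) > 10:
            raise ValueError("exact permutation test limited to n <= 10")
        h_obs = _kw_statistic(values, codes, k)
        count = total = 0
        for perm_codes in _group_assignments(len(values), [sizes[str(u)] for u in uniq]):
            total += 1
            if _kw_statistic(values, perm_codes, k) >= h_obs - 1e-12:
                count += 1
        return TestResult(h_obs, k - 1, count / total, sizes, "kruskal-wallis-exact")
    h, p = stats.kruskal(*(values[codes == i] for i in range(k)))
    return TestResult(float(h), k - 1, float(p), sizes, "kruskal-wallis")


def _group_assignments(n: int, sizes: list):
    """Yield every assignment of n items into groups of the given sizes."""
    def rec(remaining: tuple, group: int, codes: np.ndarray):
        if group == len(sizes) - 1:
            codes = codes.copy()
            codes[list(remaining)] = group
            yield codes
            return
        for chosen in combinations(remaining, sizes[group]):
            nxt = codes.copy()
            nxt[list(chosen)] = group
            rest = tuple(i for i in remaining if i not in set(chosen))
            yield from rec(rest, group + 1, nxt)

    yield from rec(tuple(range(n)), 0, np.zeros(n, dtype=np.int64))


def trichotomize(probabilities, sample_ids=None) -> pd.DataFrame:
    """Within-cohort tertile split of predicted resistance probability.

    Lowest third "sensitive", top third "resistant"; group sizes differ by at
    most one and ties are broken by stable sample order.  The cutpoints
    actually used are recorded in the result attributes.
    """
    probs = np.asarray(probabilities, float)
    n = len(probs)
    if n < 3:
        raise ValueError("need n >= 3 to trichotomize")
    if sample_ids is None:
        sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    if np.ptp(probs) == 0:
        warnings.warn("all probabilities equal; tertiles fall back to stable order", stacklevel=2)
    n_sens, n_mid, _ = tertile_sizes(n)
    order = np.argsort(probs, kind="stable")
    group = np.empty(n, dtype=object)
    group[order[:n_sens]] = "sensitive"
    group[order[n_sens : n_sens + n_mid]] = "intermediate"
    group[order[n_sens + n_mid :]] = "resistant"
    out = pd.DataFrame({"sample_id": sample_ids, "resistance_prob": probs, "group": group})
    out.attrs["cutpoints"] = (
        float(probs[order[n_sens - 1]]) if n_sens else float("nan"),
        float(probs[order[n_sens + n_mid - 1]]) if n_mid else float("nan"),
    )
    return out


def km_logrank(surv: pd.DataFrame, group_col: str = "group"):
    """Kaplan-Meier curves per group and a k-group log-rank test.

    ``surv`` needs columns ``time, event`` (event 1 = observed) and a group
    column.  Censored samples contribute risk-set time only.  With zero
    events the test is undefined and flagged.
    """
    for col in ("time", "event", group_col):
        if col not in surv.columns:
            raise ValueError(f"survival table missing column {col!r}")
    if (surv["time"] <= 0).any():
        raise ValueError("survival times must be positive")
    groups = surv[group_col].unique()
    if len(groups) < 2:
        raise ValueError("need >=2 groups for a log-rank test")
    sizes = surv.groupby(group_col, sort=True).size().to_dict()
    curves = {}
    for g, sub in surv.groupby(group_col, sort=True):
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], event_observed=sub["event"], label=str(g))
        sf = kmf.survival_function_
        curves[str(g)] = pd.DataFrame(
            {"time": sf.index.to_numpy(float), "survival": sf.iloc[:, 0].to_numpy(float)}
        )
    if int(surv["event"].sum()) == 0:
        return curves, TestResult(
            float("nan"), len(groups) - 1, float("nan"), sizes, "log-rank", undefined=True
        )
    res = multivariate_logrank_test(surv["time"], surv[group_col], surv["event"])
    return curves, TestResult(
        float(res.test_statistic), len(groups) - 1, float(res.p_value), sizes, "log-rank"
    )
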