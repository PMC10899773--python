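"""Two-condition comparison of charged fractions.

Per group, replicate charged fractions are compared between two
conditions with a two-sided Welch's t-test (unequal variances,
Welch-Satterthwaite degrees of freedom); the family of raw p-values at
one grouping level is corrected with the Benjamini-Hochberg step-up FDR
procedure, and groups are flagged significant at adjusted q <= alpha.
Raw p is reported alongside q so either flagging convention can be
audited. Groups without at least two defined replicate fractions per
condition, or with zero pooled variance, are untestable and excluded
from the BH family rather than imputed.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .quant import ChargingTable

__all__ = ["StatResult", "welch_t", "bh_adjust", "compare_conditions"]


@dataclass(frozen=True)
class StatResult:
    """Welch/BH outcome for one group in a two-condition comparison."""

    group_id: str
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    t: float
    df: float
    p: float
    q: float
    significant: bool
    testable: bool


def welch_t(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float, float]:
    """Two-sided Welch's t-test.

    t = (mean_x - mean_y) / sqrt(s2x/nx + s2y/ny), df by
    Welch-Satterthwaite, p from the t distribution with that df.
    Requires at least two finite values per side and nonzero pooled
    variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("welch_t requires at least two values per group")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("welch_t requires finite values")
    if x.var(ddof=1) + y.var(ddof=1) == 0.0:
        raise ValueError("zero pooled variance: group is untestable")
    res = sps.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.array([])
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def compare_conditions(
    ct: ChargingTable,
    condition_of: Mapping[str, str],
    conditions: Optional[Tuple[str, str]] = None,
    alpha: float = 0.05,
) -> List[StatResult]:
    """Welch + BH comparison of every group between two conditions.

    ``conditions`` selects the (a, b) pair; it may be omitted only when
    the table's samples span exactly two conditions. The BH family is
    the set of testable groups at this grouping level; untestable groups
    are returned with NaN statistics and ``testable=False``.
    """
    present: List[str] = []
    for sid in ct.sample_ids:
        cond = condition_of[sid]
        if cond not in present:
            present.append(cond)
    if conditions is None:
        if len(present) != 2:
            raise ValueError(
                f"{len(present)} conditions present; specify an explicit pair"
            )
        conditions = (present[0], present[1])
    cond_a, cond_b = conditions
    for cond in conditions:
        if cond not in present:
            raise ValueError(f"condition {cond!r} has no samples in the table")

    sids_a = [s for s in ct.sample_ids if condition_of[s] == cond_a]
    sids_b = [s for s in ct.sample_ids if condition_of[s] == cond_b]

    partial: List[dict] = []
    for group in ct.group_ids:
        x = ct.fractions.loc[group, sids_a].dropna().to_numpy(dtype=float)
        y = ct.fractions.loc[group, sids_b].dropna().to_numpy(dtype=float)
        row = {
            "group_id": group,
            "mean_a": float(np.mean(x)) if len(x) else math.nan,
            "sd_a": float(np.std(x, ddof=1)) if len(x) > 1 else math.nan,
            "n_a": len(x),
            "mean_b": float(np.mean(y)) if len(y) else math.nan,
            "sd_b": float(np.std(y, ddof=1)) if len(y) > 1 else math.nan,
            "n_b": len(y),
        }
        testable = len(x) >= 2 and len(y) >= 2 and (
            np.var(x, ddof=1) + np.var(y, ddof=1) > 0.0
        )
        if testable:
            t, df, p = welch_t(x, y)
            row.update(t=t, df=df, p=p, testable=True)
        else:
            row.update(t=math.nan, df=math.nan, p=math.nan, testable=False)
        partial.append(row)

    testable_idx = [i for i, r in enumerate(partial) if r["testable"]]
    qvals = bh_adjust([partial[i]["p"] for i in testable_idx])
    for i, q in zip(testable_idx, qvals):
        partial[i]["q"] = float(q)

    results = []
    for row in partial:
        q = row.get("q", math.nan)
        results.append(
            StatResult(
                group_id=row["group_id"],
                mean_a=row["mean_a"],
                sd_a=row["sd_a"],
                n_a=row["n_a"],
                mean_b=row["mean_b"],
                sd_b=row["sd_b"],
                n_b=row["n_b"],
                t=row["t"],
                df=row["df"],
                p=row["p"],
                q=q,
                significant=bool(row["testable"] and q <= alpha),
                testable=row["testable"],
            )
        )
    return results


def stats_frame(results: Sequence[StatResult]) -> pd.DataFrame:
    """Tidy table of :class:`StatResult` rows."""
    return pd.DataFrame([vars(r) for r in results])
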