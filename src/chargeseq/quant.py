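"""Charge calling, count tables, normalization and charged fractions.

A read whose alignment ends flush with the reference 3' terminus and
whose last three bases read exactly "CCA" is called charged; one ending
one base short with terminal "CC" is uncharged; anything else (internal
3' ends, terminal mismatches) is indeterminate and excluded from the
counts. Raw counts are scaled per sample by a coefficient equal to the
mean classified-read total across samples divided by the sample's own
total, then aggregated to charged fractions at the gene (reference
entry), anticodon-group (isodecoder) or amino-acid level by summing
counts over member entries before dividing.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .align import AlignmentResult
from .reference import TRNAReference

__all__ = [
    "CHARGED",
    "UNCHARGED",
    "INDETERMINATE",
    "ChargeCall",
    "CountTable",
    "ChargingTable",
    "call_charge",
    "tabulate",
    "normalize",
    "fraction_by_group",
    "condition_summary",
]

CHARGED = "charged"
UNCHARGED = "uncharged"
INDETERMINATE = "indeterminate"

LEVELS = ("gene", "anticodon", "amino_acid")


@dataclass(frozen=True)
class ChargeCall:
    read_id: str
    entry_id: str
    state: str  # CHARGED | UNCHARGED | INDETERMINATE


def call_charge(aln: AlignmentResult, insert: str) -> ChargeCall:
    """Classify one aligned insert from its 3' end.

    Charged: ends flush with the reference (end_offset 0) and the
    insert's last three bases are exactly "CCA". Uncharged: ends one
    base short (end_offset 1) with terminal "CC". Everything else is
    indeterminate - a value, not an error.
    """
    state = INDETERMINATE
    if aln.end_offset == 0 and insert.endswith("CCA"):
        state = CHARGED
    elif aln.end_offset == 1 and insert.endswith("CC"):
        state = UNCHARGED
    return ChargeCall(read_id=aln.read_id, entry_id=aln.entry_id, state=state)


@dataclass
class CountTable:
    """Charged/uncharged read counts per (reference entry, sample).

    ``charged`` and ``uncharged`` are DataFrames indexed by entry_id
    with one column per sample (dense; absent combinations are 0).
    ``coefficients`` stores the per-sample normalization factor once
    :func:`normalize` has been applied.
    """

    charged: pd.DataFrame
    uncharged: pd.DataFrame
    normalized: bool = False
    coefficients: Optional[pd.Series] = None

    def __post_init__(self):
        if not self.charged.index.equals(self.uncharged.index) or not (
            self.charged.columns.equals(self.uncharged.columns)
        ):
            raise ValueError("charged/uncharged tables must share index and columns")

    @property
    def sample_ids(self) -> List[str]:
        return list(self.charged.columns)

    def sample_totals(self) -> pd.Series:
        """Classified (charged+uncharged) reads per sample."""
        return self.charged.sum() + self.uncharged.sum()

    def to_long(self) -> pd.DataFrame:
        c = self.charged.stack().rename("charged")
        u = self.uncharged.stack().rename("uncharged")
        out = pd.concat([c, u], axis=1).reset_index()
        out.columns = ["entry_id", "sample_id", "charged", "uncharged"]
        return out


def tabulate(
    calls_by_sample: Mapping[str, Iterable[ChargeCall]],
    entry_ids: Sequence[str],
) -> CountTable:
    """Count charged/uncharged calls into a dense raw table.

    Indeterminate calls are excluded from the counts (callers report
    them in the run log); entries without calls keep explicit zero rows.
    """
    samples = list(calls_by_sample.keys())
    charged = pd.DataFrame(0, index=list(entry_ids), columns=samples, dtype=float)
    uncharged = pd.DataFrame(0, index=list(entry_ids), columns=samples, dtype=float)
    for sid, calls in calls_by_sample.items():
        for call in calls:
            if call.state == CHARGED:
                charged.at[call.entry_id, sid] += 1
            elif call.state == UNCHARGED:
                uncharged.at[call.entry_id, sid] += 1
    return CountTable(charged=charged, uncharged=uncharged, normalized=False)


def normalize(table: CountTable) -> CountTable:
    """Scale each sample by mean(sample totals) / its own total.

    After scaling every sample's classified total equals the grand mean,
    so the grand total is conserved. A sample with zero classified reads
    is an error (its coefficient would be undefined).
    """
    if table.normalized:
        raise ValueError("table is already normalized")
    totals = table.sample_totals()
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(
            f"sample(s) with zero classified reads: {', '.join(zero.index)}"
        )
    coef = totals.mean() / totals
    return CountTable(
        charged=table.charged * coef,
        uncharged=table.uncharged * coef,
        normalized=True,
        coefficients=coef,
    )


@dataclass
class ChargingTable:
    """Charged fraction per group and sample at one grouping level.

    ``fractions`` is indexed by group_id with one column per sample;
    undefined fractions (zero denominator) are NaN and propagate as
    missing, never as 0.
    """

    fractions: pd.DataFrame
    level: str

    @property
    def group_ids(self) -> List[str]:
        return list(self.fractions.index)

    @property
    def sample_ids(self) -> List[str]:
        return list(self.fractions.columns)


def _group_keys(reference: TRNAReference, level: str) -> pd.Series:
    meta = reference.metadata()
    if level == "gene":
        return pd.Series(meta.index, index=meta.index)
    if level == "anticodon":
        return meta["group"]
    if level == "amino_acid":
        return meta["isotype"]
    raise ValueError(f"unknown grouping level {level!r}; use one of {LEVELS}")


def fraction_by_group(
    table: CountTable,
    reference: TRNAReference,
    level: str = "anticodon",
    combine: str = "counts",
) -> ChargingTable:
    """Charged fraction per group: sum counts over member entries, divide.

    ``combine="counts"`` (default) sums charged and uncharged counts
    across the group's entries before dividing, so at the amino-acid
    level isoacceptors are combined by read weight. ``combine="mean"``
    instead averages the per-anticodon fractions - exposed for
    comparison, not the default.
    """
    keys = _group_keys(reference, level)
    missing = [e for e in table.charged.index if e not in keys.index]
    if missing:
        raise ValueError(f"entries absent from reference metadata: {missing}")
    if combine == "counts":
        c = table.charged.groupby(table.charged.index.map(keys)).sum()
        u = table.uncharged.groupby(table.uncharged.index.map(keys)).sum()
        denom = c + u
        with np.errstate(invalid="ignore"):
            frac = c / denom
        frac = frac.where(denom > 0)
    elif combine == "mean":
        anticodon = fraction_by_group(table, reference, "anticodon", "counts")
        meta = reference.metadata()[["group", "isotype"]].drop_duplicates("group")
        key = meta.set_index("group")["isotype"]
        if level != "amino_acid":
            raise ValueError('combine="mean" only applies at the amino_acid level')
        frac = anticodon.fractions.groupby(
            anticodon.fractions.index.map(key)
        ).mean()
    else:
        raise ValueError(f"unknown combine mode {combine!r}")
    frac = frac.sort_index()
    return ChargingTable(fractions=frac, level=level)


def condition_summary(
    ct: ChargingTable, condition_of: Mapping[str, str]
) -> pd.DataFrame:
    """Mean and sample SD (n-1) of replicate fractions per (group, condition).

    Replicates with undefined fractions are excluded; a condition left
    with zero defined replicates yields NaN mean with a warning. n = 1
    yields SD NaN (zero-width, flagged by the ``n`` column).
    """
    rows = []
    conditions: List[str] = []
    for sid in ct.sample_ids:
        cond = condition_of[sid]
        if cond not in conditions:
            conditions.append(cond)
    for group in ct.group_ids:
        for cond in conditions:
            sids = [s for s in ct.sample_ids if condition_of[s] == cond]
            vals = ct.fractions.loc[group, sids].dropna()
            if len(vals) == 0:
                warnings.warn(
                    f"group {group!r} has no defined replicate in condition "
                    f"{cond!r}",
                    stacklevel=2,
                )
                rows.append((group, cond, math.nan, math.nan, 0))
                continue
            mean = float(vals.mean())
            sd = float(vals.std(ddof=1)) if len(vals) > 1 else math.nan
            rows.append((group, cond, mean, sd, len(vals)))
    return pd.DataFrame(rows, columns=["group_id", "condition", "mean", "sd", "n"])
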