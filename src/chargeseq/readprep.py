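"""Demultiplexing and adapter trimming for charging libraries.

Each read pair carries a 5-nt inline sample barcode inside the ligated
3'-adapter; by the library geometry the barcode is read first on R2 (as
its reverse complement), followed by the 5-nt UMI and then the tRNA 3'
end. Pairs whose barcode matches no sample are discarded. Trimming
strips the 26-nt 5'-adapter from R1, removes the 3'-constant arm plus
the 10 nt of UMI+barcode preceding it (falling back to the R1/R2 pair
overlap when the constant arm is not reached), and rejects inserts
shorter than 20 nt, which correspond to empty-adapter ligation products.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from .io import FastqRecord, read_id_stem, revcomp
from .simulate import BARCODE_LEN, FIVEP_ADAPTER, THREEP_CONST, UMI_LEN

__all__ = [
    "SampleSheet",
    "SampleRow",
    "InsertRead",
    "TrimRejection",
    "DemuxResult",
    "demultiplex",
    "trim_insert",
    "prepare_reads",
]

Pair = Tuple[FastqRecord, FastqRecord]


@dataclass(frozen=True)
class SampleRow:
    sample_id: str
    barcode: str
    condition: str
    replicate: int = 1


class SampleSheet:
    """Sample metadata: id, 5-nt inline barcode, condition, replicate index."""

    def __init__(self, rows: Sequence[SampleRow]):
        if not rows:
            raise ValueError("sample sheet is empty")
        ids = [r.sample_id for r in rows]
        if len(set(ids)) != len(ids):
            raise ValueError("sample_ids must be unique")
        barcodes = [r.barcode for r in rows]
        if len(set(barcodes)) != len(barcodes):
            raise ValueError("barcodes must be unique")
        for r in rows:
            if len(r.barcode) != BARCODE_LEN or set(r.barcode) - set("ACGT"):
                raise ValueError(
                    f"{r.sample_id}: barcode {r.barcode!r} must be 5 nt over A/C/G/T"
                )
            if not r.condition:
                raise ValueError(f"{r.sample_id}: condition must be non-empty")
        self.rows: List[SampleRow] = list(rows)

    @property
    def sample_ids(self) -> List[str]:
        return [r.sample_id for r in self.rows]

    @property
    def barcode_of(self) -> Dict[str, str]:
        return {r.sample_id: r.barcode for r in self.rows}

    @property
    def condition_of(self) -> Dict[str, str]:
        return {r.sample_id: r.condition for r in self.rows}

    @property
    def conditions(self) -> List[str]:
        seen: List[str] = []
        for r in self.rows:
            if r.condition not in seen:
                seen.append(r.condition)
        return seen

    def samples_in(self, condition: str) -> List[str]:
        return [r.sample_id for r in self.rows if r.condition == condition]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.rows])

    @classmethod
    def from_tsv(cls, path) -> "SampleSheet":
        df = pd.read_csv(path, sep="\t", dtype=str)
        required = {"sample_id", "barcode", "condition"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"sample sheet missing column(s): {sorted(missing)}")
        rows = [
            SampleRow(
                sample_id=r.sample_id,
                barcode=r.barcode,
                condition=r.condition,
                replicate=int(getattr(r, "replicate", 1) or 1),
            )
            for r in df.itertuples()
        ]
        return cls(rows)


@dataclass(frozen=True)
class InsertRead:
    """A demultiplexed, adapter-free tRNA-derived insert."""

    read_id: str
    sample_id: str
    insert_seq: str
    adapter_in_r1: bool = True
    pair_overlap_used: bool = False


@dataclass(frozen=True)
class TrimRejection:
    read_id: str
    reason: str  # "adapter" | "short" | "no_overlap"


@dataclass
class DemuxResult:
    by_sample: Dict[str, List[Pair]]
    n_input: int
    n_discarded: int

    @property
    def n_assigned(self) -> int:
        return sum(len(v) for v in self.by_sample.values())


def _hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def _max_mm(length: int, rate: float) -> int:
    # guard against float artefacts like 0.1 * 26 = 2.6000000000000005
    return max(0, math.floor(rate * length + 1e-9))


def demultiplex(
    pairs: Iterable[Pair],
    sheet: SampleSheet,
    max_mismatch: int = 0,
) -> DemuxResult:
    """Assign read pairs to samples by the inline barcode.

    The observed barcode is the reverse complement of R2 positions 1-5.
    With ``max_mismatch >= 1`` all sheet barcodes must differ pairwise at
    more than ``2 * max_mismatch`` positions (unique decoding); violation
    is a configuration error raised before any pair is processed. Pairs
    matching no barcode are discarded; assignment is order-stable.
    """
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    if max_mismatch >= 1:
        for a, b in combinations(sheet.rows, 2):
            if _hamming(a.barcode, b.barcode) <= 2 * max_mismatch:
                raise ValueError(
                    f"barcodes {a.barcode} and {b.barcode} are too close for "
                    f"unambiguous decoding at max_mismatch={max_mismatch}"
                )
    lookup = {r.barcode: r.sample_id for r in sheet.rows}
    by_sample: Dict[str, List[Pair]] = {sid: [] for sid in sheet.sample_ids}
    n_input = 0
    n_discarded = 0
    for rec1, rec2 in pairs:
        if read_id_stem(rec1[0]) != read_id_stem(rec2[0]):
            raise ValueError(f"R1/R2 id mismatch: {rec1[0]!r} vs {rec2[0]!r}")
        n_input += 1
        observed = revcomp(rec2[1][:BARCODE_LEN])
        sid = lookup.get(observed)
        if sid is None and max_mismatch >= 1:
            for bc, cand in lookup.items():
                if _hamming(observed, bc) <= max_mismatch:
                    sid = cand
                    break
        if sid is None:
            n_discarded += 1
        else:
            by_sample[sid].append((rec1, rec2))
    return DemuxResult(by_sample=by_sample, n_input=n_input, n_discarded=n_discarded)


def _find_threep(rest: str, min_overlap: int, max_mm_rate: float) -> Optional[int]:
    """Start position of the 3'-constant arm in ``rest``, or None.

    Looks for a full 24-nt occurrence (exact first, then mismatch-
    tolerant, leftmost wins), then for a 3'-terminal partial occurrence
    of length >= ``min_overlap`` (longest wins).
    """
    k = len(THREEP_CONST)
    p = rest.find(THREEP_CONST)
    if p >= 0:
        return p
    if len(rest) >= k:
        allowed = _max_mm(k, max_mm_rate)
        for p in range(len(rest) - k + 1):
            if _hamming(rest[p : p + k], THREEP_CONST) <= allowed:
                return p
    top = min(k - 1, len(rest))
    for length in range(top, min_overlap - 1, -1):
        if _hamming(rest[-length:], THREEP_CONST[:length]) <= _max_mm(
            length, max_mm_rate
        ):
            return len(rest) - length
    return None


def _overlap_insert(
    rest: str, candidate: str, min_overlap: int, max_mm_rate: float
) -> Optional[str]:
    """Delimit the insert by aligning ``candidate`` (revcomp of R2 minus
    barcode/UMI, which ends exactly at the insert 3' end) against the
    adapter-stripped R1. Returns the merged insert or None."""
    M = len(candidate)
    best_score = None
    best_d = None
    for d in range(-M + min_overlap, len(rest) - min_overlap + 1):
        lo, hi = max(0, d), min(len(rest), d + M)
        ov = hi - lo
        if ov < min_overlap:
            continue
        mm = _hamming(rest[lo:hi], candidate[lo - d : hi - d])
        if mm > _max_mm(ov, max_mm_rate):
            continue
        score = ov - 2 * mm
        if best_score is None or score > best_score:
            best_score, best_d = score, d
    if best_d is None:
        return None
    n = best_d + M  # insert length: candidate's end marks the insert 3' end
    if n <= 0:
        return ""
    if len(rest) >= n:
        return rest[:n]
    tail = candidate[len(rest) - best_d : n - best_d]
    return rest + tail


def trim_insert(
    pair: Pair,
    min_len: int = 20,
    min_overlap: int = 10,
    max_mm_rate: float = 0.1,
):
    """Recover the tRNA-derived insert from one read pair.

    Returns an :class:`InsertRead`, or a :class:`TrimRejection` with
    reason ``"adapter"`` (5'-adapter not found), ``"short"`` (insert
    under ``min_len`` after trimming, i.e. an empty-adapter product) or
    ``"no_overlap"`` (3'-constant arm absent and the mates cannot be
    overlapped).
    """
    (rid1, r1, _q1), (_rid2, r2, _q2) = pair
    rid = read_id_stem(rid1)
    ad = len(FIVEP_ADAPTER)
    if len(r1) < ad:
        return TrimRejection(rid, "adapter")
    adapter_found = r1.startswith(FIVEP_ADAPTER) or _hamming(
        r1[:ad], FIVEP_ADAPTER
    ) <= _max_mm(ad, max_mm_rate)
    if not adapter_found:
        return TrimRejection(rid, "adapter")
    rest = r1[ad:]

    p = _find_threep(rest, min_overlap, max_mm_rate)
    if p is not None:
        insert = rest[: p - (UMI_LEN + BARCODE_LEN)] if p >= UMI_LEN + BARCODE_LEN else ""
        if len(insert) < min_len:
            return TrimRejection(rid, "short")
        return InsertRead(rid, "", insert, adapter_in_r1=True, pair_overlap_used=False)

    candidate = revcomp(r2[UMI_LEN + BARCODE_LEN :])
    insert = _overlap_insert(rest, candidate, min_overlap, max_mm_rate)
    if insert is None:
        return TrimRejection(rid, "no_overlap")
    if len(insert) < min_len:
        return TrimRejection(rid, "short")
    return InsertRead(rid, "", insert, adapter_in_r1=True, pair_overlap_used=True)


def prepare_reads(
    pairs: Iterable[Pair],
    sheet: SampleSheet,
    max_mismatch: int = 0,
    min_len: int = 20,
    min_overlap: int = 10,
    max_mm_rate: float = 0.1,
) -> Tuple[Dict[str, List[InsertRead]], Dict]:
    """Demultiplex then trim a paired stream.

    Returns ``(inserts_by_sample, accounting)`` where accounting records
    input/assigned/discarded pair counts and per-sample trim outcomes.
    """
    demux = demultiplex(pairs, sheet, max_mismatch=max_mismatch)
    inserts: Dict[str, List[InsertRead]] = {}
    acct: Dict = {
        "n_input": demux.n_input,
        "n_discarded": demux.n_discarded,
        "per_sample": {},
    }
    for sid in sheet.sample_ids:
        kept: List[InsertRead] = []
        reasons: Dict[str, int] = {}
        for pair in demux.by_sample[sid]:
            res = trim_insert(
                pair, min_len=min_len, min_overlap=min_overlap, max_mm_rate=max_mm_rate
            )
            if isinstance(res, TrimRejection):
                reasons[res.reason] = reasons.get(res.reason, 0) + 1
            else:
                kept.append(
                    InsertRead(
                        res.read_id,
                        sid,
                        res.insert_seq,
                        res.adapter_in_r1,
                        res.pair_overlap_used,
                    )
                )
        inserts[sid] = kept
        acct["per_sample"][sid] = {
            "assigned": len(demux.by_sample[sid]),
            "trimmed": len(kept),
            "rejected": reasons,
        }
    return inserts, acct
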