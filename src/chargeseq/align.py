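"""Ungapped semi-global alignment of inserts to the tRNA reference.

Inserts are short (20-85 nt) substitution-bearing fragments of the
CCA-appended reference entries, so the aligner scores the *full* insert
ungapped at every feasible offset of every entry (sense strand only)
with score = matches - mismatches. The best (entry, offset) wins,
subject to a mismatch ceiling; ties are broken deterministically by
lexicographically smallest entry_id then smallest start, with the tie
count surfaced so ambiguous placements stay auditable. The position of
the read's 3' terminus relative to the reference 3' end (``end_offset``)
is what downstream charge calling consumes: 0 means the read ends flush
with the reference CCA.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .reference import TRNAReference

__all__ = ["AlignmentResult", "align_insert", "align_many", "write_sam"]

_ALLOWED = set("ACGTN")


@dataclass(frozen=True)
class AlignmentResult:
    """Placement of one insert on the CCA-appended reference.

    ``ref_start``/``ref_end`` are 0-based half-open coordinates;
    ``end_offset = len(reference entry) - ref_end`` (0: flush with the
    3' terminus). ``n_tied_best`` counts all (entry, offset) placements
    achieving the best score, the reported one included.
    """

    read_id: str
    entry_id: str
    ref_start: int
    ref_end: int
    end_offset: int
    n_mismatch: int
    n_tied_best: int


def _mismatch_ceiling(length: int, rate: float) -> int:
    return max(0, math.ceil(rate * length - 1e-9))


def align_many(
    inserts: Sequence[str],
    reference: TRNAReference,
    max_mm_rate: float = 0.1,
    read_ids: Optional[Sequence[str]] = None,
) -> List[Optional[AlignmentResult]]:
    """Align a batch of inserts; returns None for unaligned ones.

    Vectorized over inserts of equal length: every feasible offset of
    every entry is scored, exactly as the brute-force definition.
    """
    if read_ids is None:
        read_ids = [f"read{i}" for i in range(len(inserts))]
    if len(read_ids) != len(inserts):
        raise ValueError("read_ids and inserts length mismatch")
    for ins in inserts:
        if not ins or set(ins) - _ALLOWED:
            raise ValueError(
                f"insert contains characters outside A/C/G/T/N: {ins[:40]!r}"
            )

    entries = sorted(reference.entries, key=lambda e: e.entry_id)
    ref_arrays = [np.frombuffer(e.seq.encode(), dtype=np.uint8) for e in entries]

    by_len: dict[int, List[int]] = {}
    for i, ins in enumerate(inserts):
        by_len.setdefault(len(ins), []).append(i)

    results: List[Optional[AlignmentResult]] = [None] * len(inserts)
    for m, idxs in by_len.items():
        B = len(idxs)
        mat = np.frombuffer(
            "".join(inserts[i] for i in idxs).encode(), dtype=np.uint8
        ).reshape(B, m)
        best_mm = np.full(B, m + 1, dtype=np.int32)
        best_entry = np.full(B, -1, dtype=np.int32)
        best_start = np.zeros(B, dtype=np.int32)
        n_tied = np.zeros(B, dtype=np.int32)
        for ei, rarr in enumerate(ref_arrays):
            if len(rarr) < m:
                continue
            windows = sliding_window_view(rarr, m)  # (n_offsets, m)
            mm = (mat[:, None, :] != windows[None, :, :]).sum(
                axis=2, dtype=np.int32
            )  # (B, n_offsets)
            e_best = mm.min(axis=1)
            e_start = mm.argmin(axis=1)  # first == smallest start
            e_ties = (mm == e_best[:, None]).sum(axis=1, dtype=np.int32)
            better = e_best < best_mm
            equal = e_best == best_mm
            # entries scanned in entry_id order, so earlier winners keep ties
            best_entry[better] = ei
            best_start[better] = e_start[better]
            n_tied[better] = e_ties[better]
            best_mm[better] = e_best[better]
            n_tied[equal] += e_ties[equal]
        ceiling = _mismatch_ceiling(m, max_mm_rate)
        for j, i in enumerate(idxs):
            if best_entry[j] < 0 or best_mm[j] > ceiling:
                continue
            entry = entries[best_entry[j]]
            start = int(best_start[j])
            results[i] = AlignmentResult(
                read_id=read_ids[i],
                entry_id=entry.entry_id,
                ref_start=start,
                ref_end=start + m,
                end_offset=len(entry.seq) - (start + m),
                n_mismatch=int(best_mm[j]),
                n_tied_best=int(n_tied[j]),
            )
    return results


def align_insert(
    insert: str,
    reference: TRNAReference,
    max_mm_rate: float = 0.1,
    read_id: str = "read",
) -> Optional[AlignmentResult]:
    """Align a single insert (see :func:`align_many`)."""
    return align_many([insert], reference, max_mm_rate, [read_id])[0]


def write_sam(
    alignments: Sequence[AlignmentResult],
    inserts: Sequence[str],
    reference: TRNAReference,
    path,
) -> None:
    """Export ungapped alignments as a (text) SAM file via pysam."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [
            {"SN": e.entry_id, "LN": len(e.seq)} for e in reference.entries
        ],
    }
    name_to_tid = {e.entry_id: i for i, e in enumerate(reference.entries)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for aln, ins in zip(alignments, inserts):
            if aln is None:
                continue
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = aln.read_id
            seg.query_sequence = ins
            seg.reference_id = name_to_tid[aln.entry_id]
            seg.reference_start = aln.ref_start
            seg.mapping_quality = 255
            seg.cigarstring = f"{len(ins)}M"
            seg.set_tag("NM", aln.n_mismatch)
            seg.set_tag("XT", aln.n_tied_best)
            out.write(seg)
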