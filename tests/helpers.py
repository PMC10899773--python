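"""Independent oracles used by the test suite.

These deliberately re-derive expected results from first principles
(plain loops and textbook formulas) so they share no code path with the
implementation they check.
"""
from __future__ import annotations

import math
from typing import Optional, Tuple


def brute_force_align(
    insert: str, reference, max_mm_rate: float = 0.1
) -> Optional[Tuple[str, int, int, int]]:
    """Exhaustive scan over every entry and offset.

    Returns (entry_id, ref_start, n_mismatch, n_tied_best) for the best
    placement under the same contract as the aligner: score = matches -
    mismatches, ties to the lexicographically smallest entry_id then the
    smallest start; None if the best exceeds ceil(rate * len) mismatches.
    """
    m = len(insert)
    placements = []  # (mm, entry_id, start)
    for entry in sorted(reference.entries, key=lambda e: e.entry_id):
        seq = entry.seq
        for start in range(len(seq) - m + 1):
            mm = sum(1 for a, b in zip(insert, seq[start : start + m]) if a != b)
            placements.append((mm, entry.entry_id, start))
    if not placements:
        return None
    best_mm = min(p[0] for p in placements)
    if best_mm > math.ceil(max_mm_rate * m - 1e-9):
        return None
    tied = [p for p in placements if p[0] == best_mm]
    _, entry_id, start = min(tied, key=lambda p: (p[1], p[2]))
    return entry_id, start, best_mm, len(tied)


def welch_oracle(x, y) -> Tuple[float, float, float]:
    """Welch's t, Welch-Satterthwaite df and two-sided p, by hand."""
    from scipy.stats import t as tdist

    nx, ny = len(x), len(y)
    mx = sum(x) / nx
    my = sum(y) / ny
    vx = sum((v - mx) ** 2 for v in x) / (nx - 1)
    vy = sum((v - my) ** 2 for v in y) / (ny - 1)
    se2 = vx / nx + vy / ny
    t = (mx - my) / math.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2 * tdist.sf(abs(t), df)
    return t, df, p


def bh_oracle(pvals):
    """Benjamini-Hochberg step-up by direct evaluation of the definition."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q = [0.0] * m
    running = math.inf
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * m / rank)
        q[i] = running
    return q
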