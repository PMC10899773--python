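"""Built-in validation benchmarks.

These fix the simulated study conditions used to validate the pipeline
end-to-end against ground truth: a 10-group toy reference (2 genes per
anticodon group, 72-78 nt bodies, >= 20% pairwise divergence), two
conditions of three replicates at 50,000 read pairs per sample,
substitution error rate 0.002, with Pro-AGG charging shifted from 0.85
(control) to 0.45 (treated) and every other group at 0.80 in both
conditions. The same definitions back the test-bench and the
reproducibility script so there is a single source of truth for what
"the benchmark" means.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .quant import ChargingTable
from .readprep import SampleSheet
from .pipeline import PipelineResult, RunParams, run_pipeline, sheet_from_design
from .reference import TRNAReference, build_reference, toy_reference
from .simulate import GroundTruth, SimDesign, SimSample, simulate_fastq
from .stats import compare_conditions

__all__ = [
    "benchmark_reference",
    "benchmark_design",
    "RecoveryOutcome",
    "run_recovery",
    "null_calibration",
]

#: Six well-separated 5-nt inline barcodes (pairwise Hamming distance >= 3).
BENCH_BARCODES = ["ACACA", "CGCGC", "GTGTG", "TATAT", "AGTCG", "CTAGT"]

SHIFTED_GROUP = "Pro-AGG"
NULL_FRACTION = 0.80
SHIFTED_CONTROL = 0.85
SHIFTED_TREATED = 0.45
N_GROUPS = 10
GENES_PER_GROUP = 2
BODY_LEN = 75  # +-3 nt jitter -> 72-78 nt bodies
N_READS = 50_000
ERROR_RATE = 0.002


def benchmark_reference(seed: int = 0) -> TRNAReference:
    """Toy reference under the benchmark conditions."""
    return build_reference(
        toy_reference(N_GROUPS, GENES_PER_GROUP, body_len=BODY_LEN, seed=seed)
    )


def benchmark_design(seed: int = 0, n_reads: int = N_READS) -> SimDesign:
    """2 conditions x 3 replicates with the Pro-AGG charging shift."""
    samples = []
    for ci, cond in enumerate(("control", "treated")):
        for rep in range(3):
            samples.append(
                SimSample(
                    sample_id=f"{cond}_{rep + 1}",
                    barcode=BENCH_BARCODES[ci * 3 + rep],
                    condition=cond,
                    n_reads=n_reads,
                )
            )
    charging = {
        ("control", "default"): NULL_FRACTION,
        ("treated", "default"): NULL_FRACTION,
        ("control", SHIFTED_GROUP): SHIFTED_CONTROL,
        ("treated", SHIFTED_GROUP): SHIFTED_TREATED,
    }
    return SimDesign(
        samples=samples, charging=charging, error_rate=ERROR_RATE, seed=seed
    )


@dataclass
class RecoveryOutcome:
    """Measured pipeline recovery for one benchmark seed.

    ``max_abs_error`` and ``max_error_over_3se`` compare the estimated
    per-(group, sample) fraction with the simulator's emitted ground-truth
    fraction; the 3-sigma band uses the binomial SE of the design fraction
    at the emitted group size.
    """

    seed: int
    max_abs_error: float
    max_error_over_3se: float
    all_within_3se: bool
    shifted_flagged: bool
    null_flagged: List[str]
    demux_assigned_frac: float
    indeterminate_frac: float
    result: Optional[PipelineResult] = None


def _design_fraction(design: SimDesign, condition: str, group: str) -> float:
    return design.charged_fraction(condition, group)


def run_recovery(
    seed: int,
    n_reads: int = N_READS,
    error_rate: float = ERROR_RATE,
    keep_result: bool = False,
) -> RecoveryOutcome:
    """Simulate one benchmark library, run the pipeline, measure recovery."""
    reference = benchmark_reference(seed=0)
    design = benchmark_design(seed=seed, n_reads=n_reads)
    design.error_rate = error_rate
    r1, r2, truth = simulate_fastq(design, reference)
    sheet = sheet_from_design(design)
    result = run_pipeline(reference, sheet, zip(r1, r2))

    est = result.fractions["anticodon"].fractions
    cond_of = sheet.condition_of
    gc = truth.group_counts(reference).set_index(["sample_id", "group"])

    max_abs = 0.0
    max_ratio = 0.0
    for sid in sheet.sample_ids:
        for group in est.index:
            n_c = int(gc.loc[(sid, group), "n_charged"])
            n_u = int(gc.loc[(sid, group), "n_uncharged"])
            n_gs = n_c + n_u
            f_true = n_c / n_gs
            f_design = _design_fraction(design, cond_of[sid], group)
            se = np.sqrt(max(f_design * (1 - f_design), 1e-12) / n_gs)
            err = abs(float(est.loc[group, sid]) - f_true)
            max_abs = max(max_abs, err)
            max_ratio = max(max_ratio, err / (3 * se))

    stats = result.stats["anticodon"]
    shifted = any(r.group_id == SHIFTED_GROUP and r.significant for r in stats)
    nulls = [r.group_id for r in stats if r.significant and r.group_id != SHIFTED_GROUP]

    acct = result.accounting
    n_assigned = acct["n_input"] - acct["n_discarded"]
    n_aligned = sum(s["aligned"] for s in acct["per_sample"].values())
    n_indet = sum(s["indeterminate"] for s in acct["per_sample"].values())

    return RecoveryOutcome(
        seed=seed,
        max_abs_error=max_abs,
        max_error_over_3se=max_ratio,
        all_within_3se=max_ratio <= 1.0,
        shifted_flagged=shifted,
        null_flagged=nulls,
        demux_assigned_frac=n_assigned / acct["n_input"],
        indeterminate_frac=n_indet / max(n_aligned, 1),
        result=result if keep_result else None,
    )


def null_calibration(
    n_families: int = 1000,
    n_groups: int = 20,
    n_reps: int = 3,
    n_reads: int = N_READS,
    fraction: float = NULL_FRACTION,
    seed: int = 0,
) -> pd.DataFrame:
    """Welch/BH behaviour on all-null simulated families.

    Each family holds ``n_groups`` groups whose replicate charged
    fractions in both conditions are iid Binomial(n_reads, fraction) /
    n_reads draws. Returns a tidy frame of (family, group, p, q).
    """
    rng = np.random.default_rng(seed)
    cond_of = {f"a{r}": "A" for r in range(n_reps)}
    cond_of.update({f"b{r}": "B" for r in range(n_reps)})
    sample_ids = list(cond_of.keys())
    rows = []
    for fam in range(n_families):
        draws = rng.binomial(n_reads, fraction, size=(n_groups, 2 * n_reps)) / n_reads
        frac = pd.DataFrame(
            draws, index=[f"G{i}" for i in range(n_groups)], columns=sample_ids
        )
        ct = ChargingTable(fractions=frac, level="anticodon")
        for r in compare_conditions(ct, cond_of, conditions=("A", "B")):
            rows.append((fam, r.group_id, r.p, r.q))
    return pd.DataFrame(rows, columns=["family", "group_id", "p", "q"])
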