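"""End-to-end orchestration: demux -> trim -> align -> call -> tabulate ->
normalize -> fractions -> stats, with per-stage read accounting, TSV/JSON
outputs and convenience figures."""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd
import yaml

from . import __version__
from .align import align_many
from .io import read_fastq_pairs
from .quant import (
    CHARGED,
    INDETERMINATE,
    UNCHARGED,
    ChargingTable,
    CountTable,
    call_charge,
    condition_summary,
    fraction_by_group,
    normalize,
    tabulate,
)
from .readprep import InsertRead, SampleSheet, SampleRow, prepare_reads
from .reference import TRNAReference, build_reference, parse_trna_fasta
from .simulate import SimDesign, SimSample
from .stats import StatResult, compare_conditions, stats_frame

__all__ = [
    "RunParams",
    "RunConfig",
    "PipelineResult",
    "run_pipeline",
    "run_to_dir",
    "load_design",
]


@dataclass
class RunParams:
    """Stage parameters, defaulting to the module-level defaults."""

    max_mismatch: int = 0
    min_len: int = 20
    min_overlap: int = 10
    trim_mm_rate: float = 0.1
    align_mm_rate: float = 0.1
    levels: Tuple[str, ...] = ("anticodon", "amino_acid")
    alpha: float = 0.05

    def validate(self) -> None:
        if self.max_mismatch < 0:
            raise ValueError("max_mismatch must be >= 0")
        if self.min_len < 1:
            raise ValueError("min_len must be >= 1")
        if not 0 <= self.trim_mm_rate <= 0.5 or not 0 <= self.align_mm_rate <= 0.5:
            raise ValueError("mismatch rates must lie in [0, 0.5]")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass
class RunConfig:
    """File-level run configuration consumed by :func:`run_to_dir`."""

    reference_fasta: Path
    sample_sheet: Path
    fastq_r1: Path
    fastq_r2: Path
    outdir: Path
    params: RunParams = field(default_factory=RunParams)
    conditions: Optional[Tuple[str, str]] = None
    make_plots: bool = True
    seed: int = 0

    def validate(self) -> None:
        for p in (self.reference_fasta, self.sample_sheet, self.fastq_r1, self.fastq_r2):
            if not Path(p).exists():
                raise FileNotFoundError(f"input file not found: {p}")
        self.params.validate()


@dataclass
class PipelineResult:
    reference: TRNAReference
    sheet: SampleSheet
    raw_counts: CountTable
    norm_counts: CountTable
    fractions: Dict[str, ChargingTable]
    summaries: Dict[str, pd.DataFrame]
    stats: Dict[str, List[StatResult]]
    accounting: Dict
    inserts: Dict[str, List[InsertRead]]


def run_pipeline(
    reference: TRNAReference,
    sheet: SampleSheet,
    pairs: Iterable,
    params: Optional[RunParams] = None,
    conditions: Optional[Tuple[str, str]] = None,
) -> PipelineResult:
    """Run the full in-memory pipeline on a paired read stream.

    Statistics are computed only when the samples span exactly two
    conditions or an explicit pair is given.
    """
    params = params or RunParams()
    params.validate()

    inserts, acct = prepare_reads(
        pairs,
        sheet,
        max_mismatch=params.max_mismatch,
        min_len=params.min_len,
        min_overlap=params.min_overlap,
        max_mm_rate=params.trim_mm_rate,
    )

    calls_by_sample: Dict[str, list] = {}
    for sid in sheet.sample_ids:
        recs = inserts[sid]
        alns = align_many(
            [r.insert_seq for r in recs],
            reference,
            max_mm_rate=params.align_mm_rate,
            read_ids=[r.read_id for r in recs],
        )
        calls = []
        n_unaligned = 0
        n_state = {CHARGED: 0, UNCHARGED: 0, INDETERMINATE: 0}
        for rec, aln in zip(recs, alns):
            if aln is None:
                n_unaligned += 1
                continue
            call = call_charge(aln, rec.insert_seq)
            n_state[call.state] += 1
            calls.append(call)
        calls_by_sample[sid] = calls
        acct["per_sample"][sid].update(
            aligned=len(calls),
            unaligned=n_unaligned,
            charged=n_state[CHARGED],
            uncharged=n_state[UNCHARGED],
            indeterminate=n_state[INDETERMINATE],
        )

    raw = tabulate(calls_by_sample, reference.entry_ids)
    norm = normalize(raw)

    condition_of = sheet.condition_of
    fractions: Dict[str, ChargingTable] = {}
    summaries: Dict[str, pd.DataFrame] = {}
    stats: Dict[str, List[StatResult]] = {}
    do_stats = conditions is not None or len(sheet.conditions) == 2
    for level in params.levels:
        ct = fraction_by_group(norm, reference, level=level)
        fractions[level] = ct
        summaries[level] = condition_summary(ct, condition_of)
        if do_stats:
            stats[level] = compare_conditions(
                ct, condition_of, conditions=conditions, alpha=params.alpha
            )

    return PipelineResult(
        reference=reference,
        sheet=sheet,
        raw_counts=raw,
        norm_counts=norm,
        fractions=fractions,
        summaries=summaries,
        stats=stats,
        accounting=acct,
        inserts=inserts,
    )


def run_to_dir(config: RunConfig) -> PipelineResult:
    """File-level entry point: read inputs, run, write TSVs/figures/log."""
    config.validate()
    genes = parse_trna_fasta(config.reference_fasta)
    reference = build_reference(genes)
    sheet = SampleSheet.from_tsv(config.sample_sheet)
    pairs = read_fastq_pairs(config.fastq_r1, config.fastq_r2)
    result = run_pipeline(
        reference, sheet, pairs, params=config.params, conditions=config.conditions
    )

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    reference.to_fasta(outdir / "reference.fasta")
    reference.metadata_to_tsv(outdir / "reference.tsv")
    result.raw_counts.to_long().to_csv(
        outdir / "counts_raw.tsv", sep="\t", index=False
    )
    norm_long = result.norm_counts.to_long()
    norm_long.to_csv(outdir / "counts_normalized.tsv", sep="\t", index=False)
    result.norm_counts.coefficients.rename("coefficient").to_csv(
        outdir / "normalization_coefficients.tsv", sep="\t"
    )
    for level, ct in result.fractions.items():
        ct.fractions.to_csv(outdir / f"fractions_{level}.tsv", sep="\t")
        result.summaries[level].to_csv(
            outdir / f"summary_{level}.tsv", sep="\t", index=False
        )
        if level in result.stats:
            stats_frame(result.stats[level]).to_csv(
                outdir / f"stats_{level}.tsv", sep="\t", index=False
            )

    log = {
        "version": __version__,
        "seed": config.seed,
        "params": asdict(config.params),
        "inputs": {
            "reference_fasta": str(config.reference_fasta),
            "sample_sheet": str(config.sample_sheet),
            "fastq_r1": str(config.fastq_r1),
            "fastq_r2": str(config.fastq_r2),
        },
        "reference_entries": len(reference),
        "accounting": result.accounting,
    }
    (outdir / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True))

    if config.make_plots:
        from .plotting import plot_condition_bars, plot_heatmap

        for level, ct in result.fractions.items():
            plot_heatmap(ct, outdir / f"heatmap_{level}.png")
            if level in result.stats:
                plot_condition_bars(
                    result.summaries[level],
                    result.stats[level],
                    outdir / f"barplot_{level}.png",
                )
    return result


def load_design(path, sheet_only: bool = False):
    """Load a plain-text (YAML) simulation design file.

    Layout::

        seed: 1
        error_rate: 0.002
        read_length: 150
        samples:
          - {sample_id: ctrl_1, barcode: ACACA, condition: control, n_reads: 50000}
        charging:
          control: {default: 0.8, Pro-AGG: 0.85}
          treated: {default: 0.8}
        abundance:            # optional, entry_id -> weight
          tRNA-Pro-AGG-1-1: 2.0

    Returns a :class:`~chargeseq.simulate.SimDesign`, or the matching
    :class:`~chargeseq.readprep.SampleSheet` when ``sheet_only``.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "samples" not in raw:
        raise ValueError("design file must define a 'samples' table")
    samples = [
        SimSample(
            sample_id=str(s["sample_id"]),
            barcode=str(s["barcode"]),
            condition=str(s["condition"]),
            n_reads=int(s.get("n_reads", 0)),
        )
        for s in raw["samples"]
    ]
    if sheet_only:
        reps: Dict[str, int] = {}
        rows = []
        for s in samples:
            reps[s.condition] = reps.get(s.condition, 0) + 1
            rows.append(
                SampleRow(s.sample_id, s.barcode, s.condition, reps[s.condition])
            )
        return SampleSheet(rows)
    charging: Dict[Tuple[str, str], float] = {}
    for cond, table in (raw.get("charging") or {}).items():
        if not isinstance(table, dict):
            raise ValueError(f"charging for condition {cond!r} must be a mapping")
        for group, frac in table.items():
            charging[(str(cond), str(group))] = float(frac)
    return SimDesign(
        samples=samples,
        charging=charging,
        abundance=raw.get("abundance"),
        error_rate=float(raw.get("error_rate", 0.0)),
        read_length=int(raw.get("read_length", 150)),
        seed=int(raw.get("seed", 0)),
    )


def sheet_from_design(design: SimDesign) -> SampleSheet:
    """Sample sheet matching a simulation design (replicates numbered per condition)."""
    reps: Dict[str, int] = {}
    rows = []
    for s in design.samples:
        reps[s.condition] = reps.get(s.condition, 0) + 1
        rows.append(SampleRow(s.sample_id, s.barcode, s.condition, reps[s.condition]))
    return SampleSheet(rows)
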