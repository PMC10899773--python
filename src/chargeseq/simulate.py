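"""Synthetic charging-library generator.

The wet-lab assay distinguishes charged from uncharged tRNAs through
periodate chemistry: NaIO4 oxidizes the free 3'-terminal ribose of
uncharged tRNAs (charged ones are protected by the esterified amino
acid), and subsequent beta-elimination removes the oxidized 3'-A, so
after deacylation charged molecules end 3'-CCA and uncharged ones end
3'-CC. A barcoded 3'-adapter (5 random nt acting as a UMI, a 5-nt
sample barcode, and a constant ligation arm) and a 5'-adapter are then
ligated, reverse-transcribed and PCR-amplified into an ~210 nt product
sequenced paired-end.

This module emulates that molecule architecture base-for-base with
per-molecule Bernoulli charging and iid substitution sequencing errors,
and emits the per-molecule ground truth so every downstream stage of the
pipeline can be verified against a known answer.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .io import FastqRecord, revcomp, write_fastq
from .reference import ReferenceEntry, TRNAReference

__all__ = [
    "FIVEP_ADAPTER",
    "THREEP_CONST",
    "FWD_PRIMER",
    "REV_PRIMER",
    "RT_PRIMER",
    "SimSample",
    "SimDesign",
    "GroundTruth",
    "assemble_molecule",
    "amplicon_length",
    "simulate_fastq",
    "simulate_to_files",
]

#: 5'-adapter in DNA form (ligated as RNA; 26 nt). Reads begin here.
FIVEP_ADAPTER = "GTTCAGAGTTCTACAGTCCGACGATC"
#: Constant arm of the ligated 3'-adapter (follows UMI + barcode; 24 nt).
THREEP_CONST = "AGATCGGAAGAGCACACGTCTGAA"
#: Forward PCR primer; its 3'-terminal 21 nt anneal to the 5'-adapter.
FWD_PRIMER = "AATGATACGGCGACCACCGAGATCTACACGTTCAGAGTTCTACAGTCCGA"
#: Reverse PCR primer; its 3'-terminal 24 nt anneal to the 3'-constant arm.
REV_PRIMER = "CAAGCAGAAGACGGCATACGAGATGCCTAAGTGACTGGAGTTCAGACGTGTGCTCTTCCGATCT"
#: Reverse-transcription primer (complementary to the 3'-constant arm).
RT_PRIMER = "AGACGTGTGCTCTTCCGATCT"

_FWD_ANNEAL = 21
_REV_ANNEAL = 24
UMI_LEN = 5
BARCODE_LEN = 5

_BASES = "ACGT"
_BASE_CODES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE_OF = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _CODE_OF[_b] = _i


@dataclass(frozen=True)
class SimSample:
    """One simulated sample: an inline barcode, a condition, a read budget."""

    sample_id: str
    barcode: str
    condition: str
    n_reads: int


@dataclass
class SimDesign:
    """Full specification of a simulated charging library.

    Attributes
    ----------
    samples : list of SimSample
        Barcodes must be unique 5-nt DNA strings.
    charging : dict
        Maps ``(condition, group)`` -> charged fraction in [0, 1], where
        ``group`` is the anticodon-group key ``"<Isotype>-<Anticodon>"``.
        A ``(condition, "default")`` entry supplies the fraction for any
        group not listed explicitly.
    abundance : dict or None
        Optional ``entry_id -> weight``; uniform over entries when None.
    error_rate : float
        Per-base iid substitution probability, applied to R1 and R2
        independently. Must lie in [0, 0.2].
    read_length : int
        Length of each mate; reads are truncated at the molecule end.
    seed : int
        Seed for the single random generator driving the simulation.
    """

    samples: List[SimSample]
    charging: Dict[Tuple[str, str], float]
    abundance: Optional[Dict[str, float]] = None
    error_rate: float = 0.0
    read_length: int = 150
    seed: int = 0

    def __post_init__(self):
        barcodes = [s.barcode for s in self.samples]
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("sample_ids must be unique")
        if len(set(barcodes)) != len(barcodes):
            raise ValueError("barcodes must be unique")
        for b in barcodes:
            if len(b) != BARCODE_LEN or set(b) - set(_BASES):
                raise ValueError(f"barcode {b!r} must be 5 nt over A/C/G/T")
        for s in self.samples:
            if s.n_reads < 0:
                raise ValueError(f"{s.sample_id}: n_reads must be >= 0")
        for key, frac in self.charging.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"charging fraction for {key} outside [0,1]")
        if not 0.0 <= self.error_rate <= 0.2:
            raise ValueError("error_rate must lie in [0, 0.2]")
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")

    @property
    def conditions(self) -> List[str]:
        seen: List[str] = []
        for s in self.samples:
            if s.condition not in seen:
                seen.append(s.condition)
        return seen

    def charged_fraction(self, condition: str, group: str) -> float:
        if (condition, group) in self.charging:
            return self.charging[(condition, group)]
        if (condition, "default") in self.charging:
            return self.charging[(condition, "default")]
        raise KeyError(
            f"no charging fraction for group {group!r} in condition {condition!r}"
        )


@dataclass
class GroundTruth:
    """Per-molecule emission record of a simulation run.

    ``reads`` has one row per read pair with columns ``read_id``,
    ``sample_id``, ``entry_id`` and boolean ``charged``.
    """

    reads: pd.DataFrame

    def counts(self) -> pd.DataFrame:
        """Emitted charged/uncharged molecule counts per (sample, entry)."""
        g = (
            self.reads.groupby(["sample_id", "entry_id"], sort=True)["charged"]
            .agg(n_charged="sum", n_total="count")
            .reset_index()
        )
        g["n_charged"] = g["n_charged"].astype(int)
        g["n_uncharged"] = g["n_total"] - g["n_charged"]
        return g[["sample_id", "entry_id", "n_charged", "n_uncharged"]]

    def group_counts(self, reference: TRNAReference) -> pd.DataFrame:
        """Emitted counts per (sample, anticodon group)."""
        meta = reference.metadata()["group"]
        c = self.counts()
        c["group"] = c["entry_id"].map(meta)
        return (
            c.groupby(["sample_id", "group"], sort=True)[
                ["n_charged", "n_uncharged"]
            ]
            .sum()
            .reset_index()
        )

    def to_tsv(self, path) -> None:
        self.reads.to_csv(path, sep="\t", index=False)


def assemble_molecule(
    entry: ReferenceEntry, charged: bool, barcode: str, umi: str
) -> str:
    """Top strand of the fully ligated insert for one tRNA molecule.

    Layout (5' -> 3'): 5'-adapter, tRNA body ending CCA (charged) or CC
    (uncharged; the oxidized terminal A was removed by beta-elimination),
    5-nt UMI, 5-nt sample barcode, 24-nt constant 3'-adapter arm.
    """
    if not entry.seq.endswith("CCA"):
        raise ValueError(f"{entry.entry_id}: reference entry must end with CCA")
    if len(barcode) != BARCODE_LEN or len(umi) != UMI_LEN:
        raise ValueError("barcode and UMI must both be 5 nt")
    trna = entry.seq if charged else entry.seq[:-1]
    return FIVEP_ADAPTER + trna + umi + barcode + THREEP_CONST


def amplicon_length(entry: ReferenceEntry, charged: bool) -> int:
    """Final PCR product length for one molecule.

    The insert length plus the non-annealing 5' extensions of the two PCR
    primers (the forward primer anneals over its 3' 21 nt to the
    5'-adapter, the reverse over its 3' 24 nt to the 3'-constant arm).
    For a 76-nt mature tRNA this comes to 208 nt, matching the ~210 nt
    band excised from the sizing gel.
    """
    trna_len = len(entry.seq) if charged else len(entry.seq) - 1
    insert = len(FIVEP_ADAPTER) + trna_len + UMI_LEN + BARCODE_LEN + len(THREEP_CONST)
    return insert + (len(FWD_PRIMER) - _FWD_ANNEAL) + (len(REV_PRIMER) - _REV_ANNEAL)


def _apply_errors(
    seqs: List[str], error_rate: float, rng: np.random.Generator
) -> List[str]:
    """Apply iid substitutions; each error replaces a base with a different one."""
    if error_rate <= 0.0:
        return seqs
    lens = np.fromiter((len(s) for s in seqs), dtype=np.int64, count=len(seqs))
    n_err = rng.binomial(lens, error_rate)
    out = list(seqs)
    for i in np.nonzero(n_err)[0]:
        arr = np.frombuffer(out[i].encode(), dtype=np.uint8).copy()
        pos = rng.choice(lens[i], size=n_err[i], replace=False)
        old = _CODE_OF[arr[pos]]
        shift = rng.integers(1, 4, size=n_err[i])
        arr[pos] = _BASE_CODES[(old + shift) % 4]
        out[i] = arr.tobytes().decode()
    return out


def simulate_fastq(
    design: SimDesign, reference: TRNAReference
) -> Tuple[List[FastqRecord], List[FastqRecord], GroundTruth]:
    """Simulate a paired-end charging library.

    For each sample, ``n_reads`` molecules are drawn: the reference entry
    by abundance weight, the charged state Bernoulli with the fraction
    for the sample's condition and the entry's anticodon group, and the
    UMI uniformly. R1 is the first ``read_length`` bases of the insert
    top strand (starting at the 5'-adapter); R2 is the first
    ``read_length`` bases of the bottom strand read inward from the
    barcode-adjacent junction, so it begins with the reverse complement
    of the barcode, then of the UMI, then the tRNA 3' end. Substitution
    errors are applied independently to both mates. Deterministic for a
    given seed.

    Returns ``(r1_records, r2_records, ground_truth)``.
    """
    # fail fast if any (condition, group) lacks a charging fraction
    groups = sorted({e.group for e in reference})
    for cond in design.conditions:
        for grp in groups:
            design.charged_fraction(cond, grp)

    entries = reference.entries
    if design.abundance is None:
        weights = np.full(len(entries), 1.0 / len(entries))
    else:
        w = np.array([design.abundance.get(e.entry_id, 0.0) for e in entries])
        if w.sum() <= 0:
            raise ValueError("abundance weights sum to zero over the reference")
        weights = w / w.sum()

    q = round(-10.0 * math.log10(max(design.error_rate, 1e-4)))
    qchar = chr(q + 33)
    rng = np.random.default_rng(design.seed)
    L = design.read_length

    r1_all: List[FastqRecord] = []
    r2_all: List[FastqRecord] = []
    truth_rows: List[Tuple[str, str, str, bool]] = []

    for sample in design.samples:
        n = sample.n_reads
        frac = np.array(
            [design.charged_fraction(sample.condition, e.group) for e in entries]
        )
        idx = rng.choice(len(entries), size=n, p=weights)
        charged = rng.random(n) < frac[idx]
        umi_codes = rng.integers(0, 4, size=(n, UMI_LEN))
        umis = [
            _BASE_CODES[row].tobytes().decode() for row in umi_codes
        ]
        r1_seqs: List[str] = []
        r2_seqs: List[str] = []
        for i in range(n):
            entry = entries[idx[i]]
            mol = assemble_molecule(entry, bool(charged[i]), sample.barcode, umis[i])
            core = mol[: -len(THREEP_CONST)]  # bottom-strand read starts here
            r1_seqs.append(mol[:L])
            r2_seqs.append(revcomp(core)[:L])
            rid = f"{sample.sample_id}:{i:06d}"
            truth_rows.append((rid, sample.sample_id, entry.entry_id, bool(charged[i])))
        r1_seqs = _apply_errors(r1_seqs, design.error_rate, rng)
        r2_seqs = _apply_errors(r2_seqs, design.error_rate, rng)
        base = len(r1_all)
        for i in range(n):
            rid = truth_rows[base + i][0]
            r1_all.append((rid, r1_seqs[i], qchar * len(r1_seqs[i])))
            r2_all.append((rid, r2_seqs[i], qchar * len(r2_seqs[i])))

    truth = GroundTruth(
        reads=pd.DataFrame(
            truth_rows, columns=["read_id", "sample_id", "entry_id", "charged"]
        )
    )
    return r1_all, r2_all, truth


def simulate_to_files(
    design: SimDesign,
    reference: TRNAReference,
    r1_path,
    r2_path,
    truth_path=None,
) -> GroundTruth:
    """Run :func:`simulate_fastq` and write FASTQ (and optionally truth TSV)."""
    r1, r2, truth = simulate_fastq(design, reference)
    write_fastq(r1, r1_path)
    write_fastq(r2, r2_path)
    if truth_path is not None:
        truth.to_tsv(truth_path)
    return truth
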