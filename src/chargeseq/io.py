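"""FASTA/FASTQ I/O helpers with transparent gzip support."""
from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Iterator, Tuple

from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: (read_id, sequence, quality) triple, Phred+33 quality string.
FastqRecord = Tuple[str, str, str]


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N, case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path) -> Iterator[Tuple[str, str]]:
    with open_text(path) as fh:
        yield from SimpleFastaParser(fh)


def write_fasta(records: Iterable[Tuple[str, str]], path, width: int = 70) -> None:
    with open_text(path, "wt") as fh:
        for header, seq in records:
            fh.write(f">{header}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fastq(path) -> Iterator[FastqRecord]:
    with open_text(path) as fh:
        yield from FastqGeneralIterator(fh)


def write_fastq(records: Iterable[FastqRecord], path) -> None:
    with open_text(path, "wt") as fh:
        for rid, seq, qual in records:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def read_id_stem(read_id: str) -> str:
    """Pairing key for a FASTQ id: first token, trailing /1 or /2 stripped."""
    stem = read_id.split()[0]
    if stem.endswith("/1") or stem.endswith("/2"):
        stem = stem[:-2]
    return stem


def read_fastq_pairs(r1_path, r2_path) -> Iterator[Tuple[FastqRecord, FastqRecord]]:
    """Iterate over an R1/R2 FASTQ file pair in lockstep.

    Raises ValueError if the files hold different numbers of reads or ids
    fail to pair in order.
    """
    _SENTINEL = object()
    it1, it2 = read_fastq(r1_path), read_fastq(r2_path)
    from itertools import zip_longest

    for i, (rec1, rec2) in enumerate(zip_longest(it1, it2, fillvalue=_SENTINEL)):
        if rec1 is _SENTINEL or rec2 is _SENTINEL:
            raise ValueError("R1 and R2 FASTQ files hold different read counts")
        if read_id_stem(rec1[0]) != read_id_stem(rec2[0]):
            raise ValueError(
                f"R1/R2 id mismatch at record {i}: {rec1[0]!r} vs {rec2[0]!r}"
            )
        yield rec1, rec2
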