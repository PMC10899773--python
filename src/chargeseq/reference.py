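"""tRNA gene references for charging analysis.

Mature tRNAs universally end in 3'-CCA, the site of aminoacylation. Reads
from a charging library are aligned against a reference built from a
gtRNAdb-style export of mature tRNA gene sequences: duplicate body
sequences are collapsed to a single entry and "CCA" is appended to each
unique sequence, so a fully charged molecule reads through the whole entry
while an uncharged one stops one base short (3'-CC).

This module parses such FASTA exports, validates gene names of the form
``tRNA-<Isotype>-<Anticodon>-<k>-<m>``, builds the deduplicated
CCA-appended reference, and provides a deterministic toy-reference
generator used throughout the test-bench and benchmark code.
"""
from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from io import StringIO
from pathlib import Path
from typing import Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .io import read_fasta, write_fasta

__all__ = [
    "TRNAGene",
    "ReferenceEntry",
    "TRNAReference",
    "HeaderFormatError",
    "SequenceAlphabetError",
    "parse_trna_fasta",
    "build_reference",
    "toy_reference",
]

#: gtRNAdb-style gene name, tolerant of a species prefix such as
#: ``Homo_sapiens_tRNA-Leu-TAA-1-1``.
_NAME_RE = re.compile(r"(tRNA-([A-Za-z]{2,5})-([ACGTacgt]{3})-(\d+)-(\d+))")
_BODY_RE = re.compile(r"^[ACGT]+$")
_ANTICODON_RE = re.compile(r"^[ACGT]{3}$")


class HeaderFormatError(ValueError):
    """A FASTA header does not carry a parseable tRNA gene name."""

    def __init__(self, headers: Sequence[str]):
        self.headers = list(headers)
        super().__init__(
            "unparseable tRNA FASTA header(s): " + "; ".join(self.headers)
        )


class SequenceAlphabetError(ValueError):
    """A record contains characters outside A/C/G/T/U."""


@dataclass(frozen=True)
class TRNAGene:
    """One mature tRNA gene sequence (no CCA appended).

    Attributes
    ----------
    gene_id : str
        Full gene name, e.g. ``"tRNA-Pro-AGG-1-1"``; unique in one set.
    isotype : str
        Amino-acid token from the name (``"Pro"``; ``"iMet"``/``"SeC"``/
        ``"Und"`` also occur in gtRNAdb exports).
    anticodon : str
        3-nt DNA anticodon from the name.
    body_seq : str
        Uppercase DNA body sequence (U already converted to T).
    """

    gene_id: str
    isotype: str
    anticodon: str
    body_seq: str

    def __post_init__(self):
        if not _ANTICODON_RE.match(self.anticodon):
            raise ValueError(f"{self.gene_id}: bad anticodon {self.anticodon!r}")
        if not _BODY_RE.match(self.body_seq):
            raise SequenceAlphabetError(
                f"{self.gene_id}: body sequence must be non-empty over A/C/G/T"
            )

    @property
    def group(self) -> str:
        """Anticodon-group key, e.g. ``"Pro-AGG"`` (the isodecoder level)."""
        return f"{self.isotype}-{self.anticodon}"


@dataclass(frozen=True)
class ReferenceEntry:
    """One deduplicated, CCA-appended alignment reference entry."""

    entry_id: str
    seq: str  # ends with "CCA"
    member_gene_ids: Tuple[str, ...]
    isotype: str
    anticodon: str

    @property
    def group(self) -> str:
        return f"{self.isotype}-{self.anticodon}"

    @property
    def body(self) -> str:
        return self.seq[:-3]


class TRNAReference:
    """Ordered collection of unique CCA-appended tRNA reference entries."""

    def __init__(self, entries: Sequence[ReferenceEntry]):
        if not entries:
            raise ValueError("reference must contain at least one entry")
        seqs = [e.seq for e in entries]
        if len(set(seqs)) != len(seqs):
            raise ValueError("reference entry sequences must be distinct")
        ids = [e.entry_id for e in entries]
        if len(set(ids)) != len(ids):
            raise ValueError("reference entry_ids must be unique")
        for e in entries:
            if not e.seq.endswith("CCA"):
                raise ValueError(f"{e.entry_id}: entry sequence must end with CCA")
        self.entries: List[ReferenceEntry] = list(entries)
        self._by_id = {e.entry_id: e for e in self.entries}

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def get(self, entry_id: str) -> ReferenceEntry:
        return self._by_id[entry_id]

    @property
    def entry_ids(self) -> List[str]:
        return [e.entry_id for e in self.entries]

    def metadata(self) -> pd.DataFrame:
        """Per-entry metadata table indexed by entry_id."""
        return pd.DataFrame(
            {
                "entry_id": [e.entry_id for e in self.entries],
                "isotype": [e.isotype for e in self.entries],
                "anticodon": [e.anticodon for e in self.entries],
                "group": [e.group for e in self.entries],
                "length": [len(e.seq) for e in self.entries],
                "n_members": [len(e.member_gene_ids) for e in self.entries],
                "member_gene_ids": [
                    ",".join(e.member_gene_ids) for e in self.entries
                ],
            }
        ).set_index("entry_id")

    def genes(self) -> List[TRNAGene]:
        """Reconstruct the member gene list (bodies without the appended CCA)."""
        out = []
        for e in self.entries:
            for gid in e.member_gene_ids:
                out.append(
                    TRNAGene(
                        gene_id=gid,
                        isotype=e.isotype,
                        anticodon=e.anticodon,
                        body_seq=e.body,
                    )
                )
        return out

    def to_fasta(self, path) -> None:
        write_fasta(((e.entry_id, e.seq) for e in self.entries), path)

    def metadata_to_tsv(self, path) -> None:
        self.metadata().to_csv(path, sep="\t")


def _iter_fasta_records(source) -> Iterable[Tuple[str, str]]:
    if isinstance(source, (list, tuple)):
        return source
    if hasattr(source, "read"):
        from Bio.SeqIO.FastaIO import SimpleFastaParser

        return SimpleFastaParser(source)
    if isinstance(source, str) and source.lstrip().startswith(">"):
        from Bio.SeqIO.FastaIO import SimpleFastaParser

        return SimpleFastaParser(StringIO(source))
    return read_fasta(Path(source))


def parse_trna_fasta(source) -> List[TRNAGene]:
    """Parse a gtRNAdb-style mature tRNA FASTA into :class:`TRNAGene` records.

    Parameters
    ----------
    source
        Path to a FASTA file (gzip accepted), raw FASTA text, an open
        file handle, or an iterable of ``(header, sequence)`` pairs.

    Headers must contain a name matching
    ``tRNA-<Isotype>-<Anticodon>-<k>-<m>`` (a leading species prefix is
    tolerated). Sequences are uppercased and U is converted to T.

    Raises
    ------
    HeaderFormatError
        Listing every header that does not match the name pattern.
    SequenceAlphabetError
        If a sequence contains characters outside A/C/G/T/U.
    ValueError
        If the same gene name occurs twice.
    """
    genes: List[TRNAGene] = []
    bad_headers: List[str] = []
    seen = set()
    for header, raw_seq in _iter_fasta_records(source):
        m = _NAME_RE.search(header)
        if not m:
            bad_headers.append(header)
            continue
        seq = raw_seq.upper().replace("U", "T").replace(" ", "")
        if not _BODY_RE.match(seq):
            bad = sorted(set(seq) - set("ACGT"))
            raise SequenceAlphabetError(
                f"{m.group(1)}: non-ACGTU characters in sequence: {bad}"
            )
        gene_id, isotype, anticodon = m.group(1), m.group(2), m.group(3)
        if gene_id in seen:
            raise ValueError(f"duplicate gene name in input: {gene_id}")
        seen.add(gene_id)
        genes.append(
            TRNAGene(
                gene_id=gene_id,
                isotype=isotype,
                anticodon=anticodon.upper(),
                body_seq=seq,
            )
        )
    if bad_headers:
        raise HeaderFormatError(bad_headers)
    return genes


def build_reference(genes: Sequence[TRNAGene]) -> TRNAReference:
    """Collapse duplicate body sequences and append CCA.

    Genes with byte-identical body sequences collapse into one entry whose
    id is the lexicographically smallest member gene_id; the entry sequence
    is ``body + "CCA"``. If collapsed members disagree on isotype or
    anticodon a warning is emitted and the representative's values are
    kept. Entries are ordered by entry_id.
    """
    if not genes:
        raise ValueError("cannot build a reference from an empty gene list")
    ids = [g.gene_id for g in genes]
    if len(set(ids)) != len(ids):
        raise ValueError("gene_ids must be unique")
    by_body: dict[str, List[TRNAGene]] = {}
    for g in genes:
        by_body.setdefault(g.body_seq, []).append(g)
    entries = []
    for body, members in by_body.items():
        members = sorted(members, key=lambda g: g.gene_id)
        rep = members[0]
        if any(
            (g.isotype, g.anticodon) != (rep.isotype, rep.anticodon)
            for g in members[1:]
        ):
            warnings.warn(
                f"duplicate-sequence members of {rep.gene_id} disagree on "
                "isotype/anticodon; keeping the representative's values",
                stacklevel=2,
            )
        entries.append(
            ReferenceEntry(
                entry_id=rep.gene_id,
                seq=body + "CCA",
                member_gene_ids=tuple(g.gene_id for g in members),
                isotype=rep.isotype,
                anticodon=rep.anticodon,
            )
        )
    entries.sort(key=lambda e: e.entry_id)
    return TRNAReference(entries)


#: Real isotype/anticodon pairs used to name toy genes. The first ten have
#: distinct isotypes so amino-acid grouping stays non-trivial but simple.
_TOY_ISOACCEPTORS: List[Tuple[str, str]] = [
    ("Pro", "AGG"),
    ("Leu", "TAA"),
    ("Ala", "AGC"),
    ("Gly", "GCC"),
    ("Glu", "TTC"),
    ("Lys", "CTT"),
    ("Asn", "GTT"),
    ("His", "GTG"),
    ("Phe", "GAA"),
    ("Val", "AAC"),
    ("Arg", "ACG"),
    ("Ser", "AGA"),
    ("Thr", "AGT"),
    ("Ile", "AAT"),
    ("Met", "CAT"),
    ("Trp", "CCA"),
    ("Tyr", "GTA"),
    ("Cys", "GCA"),
    ("Asp", "GTC"),
    ("Gln", "CTG"),
    ("Pro", "CGG"),
    ("Pro", "TGG"),
    ("Leu", "CAA"),
    ("Gly", "TCC"),
    ("iMet", "CAT"),
]

_ACGT = np.frombuffer(b"ACGT", dtype=np.uint8)


def toy_reference(
    n_groups: int,
    genes_per_group: int = 2,
    body_len: int = 75,
    seed: int = 0,
) -> List[TRNAGene]:
    """Deterministic toy tRNA gene set for simulation and testing.

    Generates ``n_groups`` anticodon groups (distinct isotype/anticodon
    pairs with gtRNAdb-style names) of ``genes_per_group`` genes each.
    Body lengths are jittered by up to +-3 nt around ``body_len`` (never
    below 30), and any two bodies differ at >= 20% of their overlapping
    positions so toy alignment is unambiguous.
    """
    if n_groups < 1:
        raise ValueError("n_groups must be >= 1")
    if n_groups > len(_TOY_ISOACCEPTORS):
        raise ValueError(f"n_groups must be <= {len(_TOY_ISOACCEPTORS)}")
    if genes_per_group < 1:
        raise ValueError("genes_per_group must be >= 1")
    if body_len < 30:
        raise ValueError("body_len must be >= 30")
    rng = np.random.default_rng(seed)
    bodies: List[str] = []
    genes: List[TRNAGene] = []
    for gi in range(n_groups):
        isotype, anticodon = _TOY_ISOACCEPTORS[gi]
        for mi in range(genes_per_group):
            length = max(30, body_len + int(rng.integers(-3, 4)))
            for _attempt in range(1000):
                arr = _ACGT[rng.integers(0, 4, size=length)]
                body = arr.tobytes().decode()
                if all(_divergent(body, other) for other in bodies):
                    break
            else:  # pragma: no cover - astronomically unlikely
                raise RuntimeError("could not generate a divergent toy body")
            bodies.append(body)
            genes.append(
                TRNAGene(
                    gene_id=f"tRNA-{isotype}-{anticodon}-{mi + 1}-1",
                    isotype=isotype,
                    anticodon=anticodon,
                    body_seq=body,
                )
            )
    return genes


def _divergent(a: str, b: str, min_frac: float = 0.2) -> bool:
    n = min(len(a), len(b))
    diff = sum(1 for x, y in zip(a[:n], b[:n]) if x != y)
    return diff >= min_frac * n
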