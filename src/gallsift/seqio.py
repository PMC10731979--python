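"""Sequence records and FASTA/FASTQ text I/O.

Every sequence entering the pipeline passes through here: host chromosomes,
simulated reads, assembled contigs and primers.  Sequences are stored
uppercase over the IUPAC nucleotide alphabet; internal coordinates are
0-based half-open throughout the package, and only human-readable reports
convert to 1-based.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Iterable, TextIO

IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

IUPAC_ALPHABET = frozenset(IUPAC_SETS)

_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}
_COMP_TABLE = str.maketrans(
    "".join(_COMPLEMENT) + "".join(_COMPLEMENT).lower(),
    "".join(_COMPLEMENT.values()) + "".join(_COMPLEMENT.values()).lower(),
)

FASTA_WIDTH = 80


class SequenceFormatError(ValueError):
    """Raised for malformed FASTA/FASTQ input or illegal characters."""


@dataclass
class SequenceRecord:
    """A named nucleotide sequence (chromosome, contig, primer template...)."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise SequenceFormatError(f"invalid record id {self.id!r}")
        self.seq = _validate_seq(self.seq, self.id)

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class ReadRecord:
    """One sequencing read; ``sample`` labels its tissue of origin."""

    id: str
    seq: str
    qual: str | None = None
    sample: str = "other"

    def __post_init__(self) -> None:
        self.seq = _validate_seq(self.seq, self.id, alphabet=frozenset("ACGTN"))
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise SequenceFormatError(
                f"length mismatch in read {self.id!r}: "
                f"{len(self.seq)} bases vs {len(self.qual)} quality values"
            )

    def __len__(self) -> int:
        return len(self.seq)


def _validate_seq(seq: str, rec_id: str, alphabet: frozenset[str] = IUPAC_ALPHABET) -> str:
    if not seq:
        raise SequenceFormatError(f"empty sequence in record {rec_id!r}")
    seq = seq.upper()
    for pos, ch in enumerate(seq):
        if ch not in alphabet:
            raise SequenceFormatError(
                f"illegal character {ch!r} at position {pos} in record {rec_id!r}"
            )
    return seq


def _as_text(stream: str | TextIO) -> str:
    return stream if isinstance(stream, str) else stream.read()


def parse_fasta(stream: str | TextIO) -> list[SequenceRecord]:
    """Parse FASTA text into records.

    Sequence lines per header are concatenated and case-folded to uppercase.
    Raises on empty input, duplicate ids and illegal characters.
    """
    text = _as_text(stream)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    header: str | None = None
    chunks: list[str] = []

    def flush() -> None:
        if header is None:
            return
        fields = header.split(maxsplit=1)
        if not fields:
            raise SequenceFormatError("empty FASTA header")
        rec_id = fields[0]
        if rec_id in seen:
            raise SequenceFormatError(f"duplicate id {rec_id}")
        seen.add(rec_id)
        desc = fields[1] if len(fields) > 1 else ""
        records.append(SequenceRecord(rec_id, "".join(chunks), desc))

    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            header = line[1:]
            chunks = []
        else:
            if header is None:
                raise SequenceFormatError("sequence data before first FASTA header")
            chunks.append(line)
    flush()
    if not records:
        raise SequenceFormatError("no records")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | None = None,
                width: int = FASTA_WIDTH) -> str:
    """Format records as multi-line FASTA (80 columns); write to ``path`` if given."""
    out = io.StringIO()
    for rec in records:
        head = f">{rec.id} {rec.description}" if rec.description else f">{rec.id}"
        out.write(head + "\n")
        for i in range(0, len(rec.seq), width):
            out.write(rec.seq[i:i + width] + "\n")
    text = out.getvalue()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def parse_fastq(stream: str | TextIO, sample: str = "other") -> list[ReadRecord]:
    """Parse 4-line FASTQ records (Sanger Phred+33 qualities assumed)."""
    lines = _as_text(stream).splitlines()
    while lines and not lines[-1].strip():
        lines.pop()
    if not lines:
        raise SequenceFormatError("no records")
    if len(lines) % 4 != 0:
        raise SequenceFormatError(
            f"truncated FASTQ record at index {len(lines) // 4}"
        )
    reads: list[ReadRecord] = []
    for i in range(0, len(lines), 4):
        head, seq, plus, qual = (ln.rstrip("\n") for ln in lines[i:i + 4])
        idx = i // 4
        if not head.startswith("@") or not plus.startswith("+"):
            raise SequenceFormatError(f"malformed FASTQ record at index {idx}")
        rec_id = head[1:].split()[0] if head[1:].split() else ""
        if not rec_id:
            raise SequenceFormatError(f"missing read id at record index {idx}")
        if len(seq) != len(qual):
            raise SequenceFormatError(
                f"length mismatch in read {rec_id!r} (record index {idx})"
            )
        reads.append(ReadRecord(rec_id, seq, qual, sample=sample))
    return reads


def write_fastq(reads: Iterable[ReadRecord], path: str | None = None) -> str:
    """Format reads as 4-line FASTQ; reads without qualities get constant 'I'."""
    out = io.StringIO()
    for read in reads:
        qual = read.qual if read.qual is not None else "I" * len(read.seq)
        out.write(f"@{read.id}\n{read.seq}\n+\n{qual}\n")
    text = out.getvalue()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def reverse_complement(seq: str) -> str:
    """IUPAC-aware reverse complement (length-preserving involution)."""
    for pos, ch in enumerate(seq):
        if ch.upper() not in IUPAC_ALPHABET:
            raise SequenceFormatError(f"illegal character {ch!r} at position {pos}")
    return seq.translate(_COMP_TABLE)[::-1]


def iupac_matches(a: str, b: str) -> bool:
    """True iff the base sets encoded by two IUPAC codes intersect."""
    try:
        sa, sb = IUPAC_SETS[a.upper()], IUPAC_SETS[b.upper()]
    except KeyError as exc:
        raise SequenceFormatError(f"illegal IUPAC code {exc.args[0]!r}") from exc
    return bool(sa & sb)
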