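"""FASTA input/output and the shared sequence record model.

The unit of analysis throughout the package is a :class:`TranscriptRecord` —
a putative full-length cDNA (FL-cDNA) or, with a ``source_hint``, a 5'-end
single-pass EST read.  Sequences are uppercase DNA over ``ACGTN``; ``N``
bases count toward length and count as mismatches in alignment, which is the
conservative choice for every identity-threshold rule downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

_VALID_BASES = frozenset("ACGTN")

FASTA_WRAP = 60  # output line width; fixed so round-trips are byte-stable


class FastaParseError(ValueError):
    """Raised on malformed FASTA input; message names the offending line."""


@dataclass(frozen=True)
class TranscriptRecord:
    """One cDNA (or EST read): identifier, uppercase sequence, description."""

    id: str
    seq: str
    description: str = ""
    source_hint: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.seq:
            raise ValueError(f"record {self.id!r}: sequence must be non-empty")

    def __len__(self) -> int:
        return len(self.seq)


# ESTRead is structurally a TranscriptRecord carrying a source_hint.
ESTRead = TranscriptRecord


def read_fasta(path: str | Path) -> list[TranscriptRecord]:
    """Read a FASTA file into an order-preserving list of records.

    Lowercase is normalized to uppercase.  Duplicate ids, empty sequences,
    headerless leading sequence and non-ACGTN characters are rejected with a
    :class:`FastaParseError` naming the line number.
    """
    path = Path(path)
    records: list[TranscriptRecord] = []
    seen: set[str] = set()
    header: str | None = None
    header_line = 0
    chunks: list[str] = []

    def flush(line_no: int) -> None:
        nonlocal header, chunks
        if header is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise FastaParseError(
                f"{path}:{header_line}: record {header.split()[0]!r} has an "
                "empty sequence"
            )
        rid, _, desc = header.partition(" ")
        if rid in seen:
            raise FastaParseError(
                f"{path}:{header_line}: duplicate record id {rid!r}"
            )
        seen.add(rid)
        records.append(TranscriptRecord(rid, seq, desc.strip()))
        header, chunks = None, []

    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush(line_no)
                header = line[1:].strip()
                if not header:
                    raise FastaParseError(f"{path}:{line_no}: empty FASTA header")
                header_line = line_no
            else:
                if header is None:
                    raise FastaParseError(
                        f"{path}:{line_no}: sequence data before first '>' header"
                    )
                seq = line.upper()
                bad = set(seq) - _VALID_BASES
                if bad:
                    raise FastaParseError(
                        f"{path}:{line_no}: invalid characters {sorted(bad)} "
                        "in sequence (expected A/C/G/T/N)"
                    )
                chunks.append(seq)
        flush(line_no=-1)
    return records


def write_fasta(records: Iterable[TranscriptRecord], path: str | Path) -> None:
    """Write records as FASTA, wrapped at 60 columns."""
    with open(path, "w") as fh:
        for rec in records:
            head = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{head}\n")
            for i in range(0, len(rec.seq), FASTA_WRAP):
                fh.write(rec.seq[i : i + FASTA_WRAP] + "\n")


def length_filter(
    reads: Sequence[TranscriptRecord], min_len: int = 100
) -> list[TranscriptRecord]:
    """Keep reads of length >= ``min_len`` (default 100 nt, the minimum
    usable single-pass read length); the number removed is logged."""
    kept = [r for r in reads if len(r.seq) >= min_len]
    removed = len(reads) - len(kept)
    if removed:
        logger.info("length_filter: removed %d/%d reads < %d nt",
                    removed, len(reads), min_len)
    return kept
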