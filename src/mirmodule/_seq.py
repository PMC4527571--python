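"""Shared sequence utilities and small-RNA FASTA/FASTQ I/O.

One canonical alphabet is used throughout: uppercase DNA (``ACGT``), with
RNA ``U`` normalised to ``T`` on input.  Collapsed small-RNA FASTA files
use the conventional ``>tagN_xCOUNT`` header to carry read counts.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_VALID = re.compile(r"^[ACGT]+$")
_COUNT_HEADER = re.compile(r"_x(\d+)$")


def normalize(seq: str) -> str:
    """Uppercase a nucleotide string and map U to T."""
    return seq.upper().replace("U", "T")


def is_valid(seq: str) -> bool:
    """True if *seq* is non-empty and contains only A/C/G/T."""
    return bool(_VALID.match(seq))


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGT string."""
    return seq.translate(_COMPLEMENT)[::-1]


def parse_count_header(header: str) -> int | None:
    """Extract the read count from a collapsed ``>id_xCOUNT`` header.

    Returns ``None`` when the header carries no count suffix.
    """
    m = _COUNT_HEADER.search(header)
    return int(m.group(1)) if m else None


def read_sequences(path: str | Path) -> Iterator[tuple[str, str, int]]:
    """Yield ``(id, sequence, count)`` triples from FASTA or FASTQ.

    The format is sniffed from the first non-blank character (``>`` FASTA,
    ``@`` FASTQ).  For collapsed FASTA headers the embedded count is used;
    otherwise each record counts once.  Sequences are normalised to
    uppercase DNA; validity is the caller's concern.
    """
    path = Path(path)
    with open(path) as handle:
        first = handle.read(1)
        while first.isspace():
            first = handle.read(1)
    fmt = "fastq" if first == "@" else "fasta"
    for rec in SeqIO.parse(str(path), fmt):
        count = parse_count_header(rec.id) or 1
        yield rec.id, normalize(str(rec.seq)), count


def write_collapsed_fasta(
    tags: Iterable[tuple[str, int]], path: str | Path, prefix: str = "tag"
) -> None:
    """Write ``(sequence, count)`` pairs as collapsed ``>prefixN_xCOUNT`` FASTA."""
    with open(path, "w") as out:
        for i, (seq, count) in enumerate(tags, start=1):
            out.write(f">{prefix}{i}_x{count}\n{seq}\n")


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write ``(id, sequence)`` pairs as plain FASTA."""
    with open(path, "w") as out:
        for name, seq in records:
            out.write(f">{name}\n{seq}\n")


def read_fasta_dict(path: str | Path) -> dict[str, str]:
    """Load a FASTA file as ``{id: normalised sequence}``."""
    return {rec.id: normalize(str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")}
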