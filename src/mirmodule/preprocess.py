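"""Read cleaning and tag collapsing for small-RNA libraries.

Raw reads are adapter-trimmed, filtered on N content and insert length,
and collapsed into unique clean tags carrying per-library counts.
Cleaning is deliberately minimal — 3' adapter removal by seed match,
optional 5' adapter removal, N filter, 18-30 nt length window — because
small-RNA inserts shorter than the read length make adapter position the
dominant signal and quality-window trimming adds nothing for collapsed
tags.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from mirmodule._seq import is_valid, normalize, read_sequences, write_collapsed_fasta

MIN_LEN = 18
MAX_LEN = 30
ADAPTER_SEED = 6


@dataclass
class CleanTag:
    """A unique clean small-RNA sequence with per-library read counts."""

    seq: str
    counts: dict[str, int] = field(default_factory=dict)

    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class LibraryStats:
    """Per-library cleaning statistics."""

    library_id: str
    raw_reads: int = 0
    high_quality_reads: int = 0
    clean_reads: int = 0
    unique_tags: int = 0
    length_histogram: dict[int, int] = field(default_factory=dict)
    discarded_invalid: int = 0
    discarded_length: int = 0
    discarded_n: int = 0


def trim_3p_adapter(read: str, adapter: str, seed: int = ADAPTER_SEED) -> str:
    """Remove a 3' adapter located by its longest prefix match.

    The match must start with at least *seed* exact nucleotides of the
    adapter; the leftmost such occurrence wins.  A read without a seed
    match is returned unchanged (insert longer than the read, or adapter
    already removed upstream).
    """
    if not adapter or len(adapter) < seed:
        return read
    probe = adapter[:seed]
    pos = read.find(probe)
    if pos < 0:
        return read
    return read[:pos]


def trim_5p_adapter(read: str, adapter: str) -> str:
    """Remove a 5' adapter when the read starts with its suffix (>= 6 nt)."""
    if not adapter:
        return read
    for k in range(len(adapter), ADAPTER_SEED - 1, -1):
        if read.startswith(adapter[-k:]):
            return read[k:]
    return read


def clean_reads(
    raw: Iterable[tuple[str, str, int]],
    library_id: str,
    adapter_3p: str = "",
    adapter_5p: str = "",
    min_len: int = MIN_LEN,
    max_len: int = MAX_LEN,
    max_n: int = 0,
) -> tuple[dict[str, CleanTag], LibraryStats]:
    """Clean a read stream and collapse survivors into unique tags.

    *raw* yields ``(id, sequence, count)`` triples (see
    :func:`mirmodule._seq.read_sequences`); counts let collapsed input be
    re-cleaned without expansion.  Returns the tag table keyed by
    sequence and the library statistics.  Reads with non-nucleotide
    characters other than N are discarded and counted separately.
    """
    stats = LibraryStats(library_id=library_id)
    adapter_3p = normalize(adapter_3p)
    adapter_5p = normalize(adapter_5p)
    counter: Counter[str] = Counter()
    for _rid, seq, count in raw:
        seq = normalize(seq)
        stats.raw_reads += count
        n_count = seq.count("N")
        if not seq or not is_valid(seq.replace("N", "A") if n_count else seq):
            stats.discarded_invalid += count
            continue
        stats.high_quality_reads += count
        if n_count > max_n:
            stats.discarded_n += count
            continue
        insert = trim_3p_adapter(trim_5p_adapter(seq, adapter_5p), adapter_3p)
        if not min_len <= len(insert) <= max_len:
            stats.discarded_length += count
            continue
        counter[insert] += count
        stats.clean_reads += count
        stats.length_histogram[len(insert)] = (
            stats.length_histogram.get(len(insert), 0) + count
        )
    tags = {
        seq: CleanTag(seq=seq, counts={library_id: n}) for seq, n in counter.items()
    }
    stats.unique_tags = len(tags)
    stats.length_histogram = dict(sorted(stats.length_histogram.items()))
    return tags, stats


def clean_file(
    path: str | Path,
    library_id: str,
    adapter_3p: str = "",
    adapter_5p: str = "",
    **kwargs,
) -> tuple[dict[str, CleanTag], LibraryStats]:
    """Clean one FASTA/FASTQ file (see :func:`clean_reads`)."""
    return clean_reads(
        read_sequences(path), library_id, adapter_3p=adapter_3p, adapter_5p=adapter_5p, **kwargs
    )


def merge_libraries(per_library: Mapping[str, Mapping[str, CleanTag]]) -> dict[str, CleanTag]:
    """Merge per-library tag tables into one table with combined counts."""
    merged: dict[str, CleanTag] = {}
    for lib in sorted(per_library):
        for seq, tag in per_library[lib].items():
            dest = merged.setdefault(seq, CleanTag(seq=seq))
            for lib_id, n in tag.counts.items():
                dest.counts[lib_id] = dest.counts.get(lib_id, 0) + n
    return merged


def length_distribution(
    tags: Mapping[str, CleanTag] | Iterable[CleanTag], library_id: str | None = None
) -> dict[int, float]:
    """Fraction of clean reads per insert length.

    Computed on redundant (total) counts, not unique tags.  When
    *library_id* is given only that library's counts contribute.  An
    empty tag set yields an empty mapping.
    """
    if isinstance(tags, Mapping):
        tags = tags.values()
    hist: Counter[int] = Counter()
    for tag in tags:
        n = tag.counts.get(library_id, 0) if library_id else tag.total()
        if n:
            hist[len(tag.seq)] += n
    total = sum(hist.values())
    if total == 0:
        return {}
    return {length: hist[length] / total for length in sorted(hist)}


def write_tags(
    tags: Mapping[str, CleanTag], path: str | Path, library_id: str | None = None
) -> None:
    """Write a tag table as collapsed FASTA, sorted by descending count then sequence."""
    items = [
        (seq, tag.counts.get(library_id, 0) if library_id else tag.total())
        for seq, tag in tags.items()
    ]
    items = [(s, c) for s, c in items if c > 0]
    items.sort(key=lambda x: (-x[1], x[0]))
    write_collapsed_fasta(items, path)


def read_tags(path: str | Path, library_id: str) -> dict[str, CleanTag]:
    """Load a collapsed FASTA back into a tag table for one library."""
    tags: dict[str, CleanTag] = {}
    for _rid, seq, count in read_sequences(path):
        dest = tags.setdefault(seq, CleanTag(seq=seq, counts={library_id: 0}))
        dest.counts[library_id] = dest.counts.get(library_id, 0) + count
    return tags


def stats_table(stats_list: Iterable[LibraryStats]):
    """Summarise cleaning statistics as a DataFrame (one row per library)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "library_id": s.library_id,
                "raw_reads": s.raw_reads,
                "high_quality_reads": s.high_quality_reads,
                "clean_reads": s.clean_reads,
                "unique_tags": s.unique_tags,
                "discarded_invalid": s.discarded_invalid,
                "discarded_n": s.discarded_n,
                "discarded_length": s.discarded_length,
            }
            for s in stats_list
        ]
    )
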