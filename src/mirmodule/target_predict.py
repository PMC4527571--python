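"""Plant-style miRNA target prediction by complementarity scoring.

Each transcript window is paired in reverse orientation against the
miRNA and charged an expectation penalty: +1 per mismatch, +0.5 per G:U
wobble, +2 per single-nucleotide bulge, with all penalties doubled at
miRNA positions 2-13 (the 5' core that directs cleavage).  Sites with an
expectation at or below the cutoff (default 4.0) and at most two core
mismatches are reported together with the predicted cleavage position,
the transcript base opposite miRNA positions 10-11.  Bulges are limited
to one nucleotide and may not sit at positions 10-11.

Lower expectation means better complementarity; a perfect reverse
complement scores 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from mirmodule._seq import normalize, is_valid, revcomp

DEFAULT_CUTOFF = 4.0
DEFAULT_CORE_MISMATCH_MAX = 2
CORE_RANGE = (2, 13)  # 1-based miRNA positions with doubled penalties
MISMATCH_PENALTY = 1.0
WOBBLE_PENALTY = 0.5
BULGE_PENALTY = 2.0
CLEAVAGE_POSITIONS = (10, 11)

_PAIR = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "T"), ("T", "G")}  # G:U on the DNA alphabet


@dataclass
class TargetSite:
    """One miRNA target site on a transcript."""

    mirna_id: str
    transcript_id: str
    start: int  # 0-based half-open window on the transcript
    end: int
    expectation: float
    cleavage_pos: int  # 0-based transcript coordinate opposite miRNA position 10
    alignment: str  # three-line duplex text


def _mult(pos_1based: int) -> float:
    return 2.0 if CORE_RANGE[0] <= pos_1based <= CORE_RANGE[1] else 1.0


def _base_penalty(mirna_base: str, target_base: str) -> tuple[float, str]:
    """Penalty and bond symbol for one miRNA/target base pair."""
    if (mirna_base, target_base) in _PAIR:
        return 0.0, "|"
    if (mirna_base, target_base) in _WOBBLE:
        return WOBBLE_PENALTY, "o"
    return MISMATCH_PENALTY, " "


def _score_ungapped(mirna: str, window: str) -> tuple[float, int, list[str]]:
    """Expectation, core mismatches, bond symbols; window length == miRNA length."""
    m = len(mirna)
    total = 0.0
    core_mm = 0
    bonds = []
    for i in range(m):
        pos = i + 1
        pen, bond = _base_penalty(mirna[i], window[m - 1 - i])
        total += pen * _mult(pos)
        if pen == MISMATCH_PENALTY and CORE_RANGE[0] <= pos <= CORE_RANGE[1]:
            core_mm += 1
        bonds.append(bond)
    return total, core_mm, bonds


def score_duplex(mirna: str, target_window: str) -> float:
    """Expectation of the duplex between a miRNA and one target window.

    The window length selects the alignment mode: equal to the miRNA it
    is scored ungapped; one base longer, the best single target bulge is
    used; one base shorter, the best single unpaired miRNA base.  Bulges
    are charged +2 (doubled in the core) at the miRNA position where
    they sit and are not allowed at positions 10-11.
    """
    mirna = normalize(mirna)
    window = normalize(target_window)
    if not (is_valid(mirna) and is_valid(window)):
        raise ValueError("sequences must contain only A/C/G/U(T)")
    m, L = len(mirna), len(window)
    if L == m:
        return _score_ungapped(mirna, window)[0]
    if L == m + 1:
        best = float("inf")
        for b in range(1, m + 1):  # bulged target base sits 3' of miRNA position b
            if b in CLEAVAGE_POSITIONS:
                continue
            s = _score_bulged_target(mirna, window, b)
            best = min(best, s)
        return best
    if L == m - 1:
        best = float("inf")
        for b in range(1, m + 1):  # miRNA position b left unpaired
            if b in CLEAVAGE_POSITIONS:
                continue
            s = _score_bulged_mirna(mirna, window, b)
            best = min(best, s)
        return best
    raise ValueError("window length must be within one base of the miRNA length")


def _score_bulged_target(mirna: str, window: str, b: int) -> float:
    """One extra target base opposite the junction at miRNA position *b*."""
    m = len(mirna)
    total = BULGE_PENALTY * _mult(b)
    for i in range(m):
        pos = i + 1
        # positions 5' of the bulge keep the ungapped register relative to
        # the window 3' end; positions from b on shift by the extra base
        j = (m - i) if pos < b else (m - 1 - i)
        pen, _ = _base_penalty(mirna[i], window[j])
        total += pen * _mult(pos)
    return total


def _score_bulged_mirna(mirna: str, window: str, b: int) -> float:
    """miRNA position *b* unpaired against a window one base short."""
    m = len(mirna)
    total = BULGE_PENALTY * _mult(b)
    for i in range(m):
        pos = i + 1
        if pos == b:
            continue
        j = (m - 2 - i) if pos < b else (m - 1 - i)
        pen, _ = _base_penalty(mirna[i], window[j])
        total += pen * _mult(pos)
    return total


def _site_from_window(
    mirna_id: str,
    mirna: str,
    transcript_id: str,
    transcript: str,
    start: int,
    cutoff: float,
    core_mismatch_max: int,
) -> TargetSite | None:
    m = len(mirna)
    window = transcript[start : start + m]
    if len(window) < m:
        return None
    expectation, core_mm, bonds = _score_ungapped(mirna, window)
    if expectation > cutoff or core_mm > core_mismatch_max:
        return None
    # cleavage opposite miRNA position 10 (1-based): window index m - 10
    cleavage = start + m - CLEAVAGE_POSITIONS[0]
    alignment = (
        f"miRNA  3' {mirna[::-1]} 5'\n"
        f"          {''.join(bonds)[::-1]}\n"
        f"target 5' {window} 3'"
    )
    return TargetSite(
        mirna_id=mirna_id,
        transcript_id=transcript_id,
        start=start,
        end=start + m,
        expectation=expectation,
        cleavage_pos=cleavage,
        alignment=alignment,
    )


def scan_transcriptome(
    mirnas: Mapping[str, str],
    transcripts: Mapping[str, str],
    cutoff: float = DEFAULT_CUTOFF,
    core_mismatch_max: int = DEFAULT_CORE_MISMATCH_MAX,
) -> list[TargetSite]:
    """Scan every transcript for target sites of every miRNA.

    Windows are scored ungapped (bulged variants are a refinement of
    :func:`score_duplex` for window-level rescoring; the scanner reports
    contiguous sites, keeping the site set identical to a brute-force
    all-window scorer).  One transcript may host several sites.  The
    result is deterministically ordered by (miRNA id, transcript id,
    window start).
    """
    if not transcripts:
        raise ValueError("transcript set is empty")
    sites: list[TargetSite] = []
    for mid in sorted(mirnas):
        mirna = normalize(mirnas[mid])
        for tid in sorted(transcripts):
            transcript = normalize(transcripts[tid])
            for start in range(0, len(transcript) - len(mirna) + 1):
                site = _site_from_window(
                    mid, mirna, tid, transcript, start, cutoff, core_mismatch_max
                )
                if site is not None:
                    sites.append(site)
    return sites


def plant_site_coordinates(mirna: str, transcript: str) -> list[int]:
    """Starts of exact reverse-complement sites (diagnostic helper)."""
    rc = revcomp(normalize(mirna))
    transcript = normalize(transcript)
    out, pos = [], transcript.find(rc)
    while pos >= 0:
        out.append(pos)
        pos = transcript.find(rc, pos + 1)
    return out


def sites_table(sites: Iterable[TargetSite]):
    import pandas as pd

    cols = ["mirna_id", "transcript_id", "start", "end", "expectation", "cleavage_pos"]
    rows = [{c: getattr(s, c) for c in cols} for s in sites]
    return pd.DataFrame(rows, columns=cols)


def write_alignments(sites: Sequence[TargetSite], path: str | Path) -> None:
    with open(path, "w") as out:
        for s in sites:
            out.write(
                f"# {s.mirna_id} -> {s.transcript_id}:{s.start}-{s.end} "
                f"expectation={s.expectation:g} cleavage={s.cleavage_pos}\n"
            )
            out.write(s.alignment + "\n\n")
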