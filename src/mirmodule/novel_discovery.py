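"""Novel miRNA discovery from unannotated tags.

Tags that match no reference are mapped exactly to the genome, candidate
precursor windows are excised around each locus, folded into a nested
(pseudoknot-free) secondary structure by weighted base-pair maximisation,
and judged against stem-loop (hairpin) criteria: the mature sequence must
sit on one arm of the stem, pair extensively with the opposite arm (the
miRNA* arm), and the precursor must fold well overall.  Candidates that
fail any criterion are pseudo-miRNAs.

Folding is a weighted Nussinov dynamic programme (G:C = 3, A:U = 2,
G:U = 1, minimum loop 3 nt) rather than a thermodynamic free-energy
model; the score density criterion stands in for a minimum-free-energy
cutoff.  All processing is order-independent: tags and loci are handled
in sorted order so identical inputs give identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from mirmodule._seq import is_valid, normalize, revcomp

# pair weights on the DNA alphabet (U already normalised to T)
_PAIR_WEIGHT = {
    ("G", "C"): 3, ("C", "G"): 3,
    ("A", "T"): 2, ("T", "A"): 2,
    ("G", "T"): 1, ("T", "G"): 1,
}
MIN_LOOP = 3

DEFAULT_FLANK_LONG = 160
DEFAULT_FLANK_SHORT = 20
DEFAULT_MAX_HITS = 20
DEFAULT_MIN_DUPLEX_PAIRS = 14
DEFAULT_MIN_SCORE_DENSITY = 0.5
DEFAULT_MAX_STAR_EXCESS = 5
MATURE_LEN_RANGE = (18, 26)
PRECURSOR_LEN_RANGE = (60, 400)


@dataclass(frozen=True, order=True)
class GenomeLocus:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str  # "+" or "-"

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")


@dataclass
class PrecursorCandidate:
    """An excised genomic window with its fold and mature-arm assignment."""

    locus: GenomeLocus
    seq: str
    structure: str
    pair_score: int
    mature_offset: tuple[int, int]  # within seq, 0-based half-open
    star_offset: tuple[int, int] | None = None
    duplex_pairs: int = 0
    arm: str | None = None  # "5p" or "3p"


@dataclass
class HairpinCall:
    """Verdict on one precursor candidate with per-criterion reasons."""

    candidate: PrecursorCandidate
    verdict: str  # "miRNA" or "pseudo-miRNA"
    reasons: list[str] = field(default_factory=list)


def _weight_matrix(seq: str) -> np.ndarray:
    n = len(seq)
    codes = np.frombuffer(seq.encode(), dtype=np.uint8)
    w = np.zeros((n, n), dtype=np.int64)
    for (a, b), wt in _PAIR_WEIGHT.items():
        w[np.ix_(codes == ord(a), codes == ord(b))] = wt
    return w


def fold(seq: str) -> tuple[str, int]:
    """Fold *seq* by maximum-weight nested base pairing.

    Returns the dot-bracket structure and the integer pair score.  The
    traceback is deterministic: when the closing base has several optimal
    partners the 5'-most one is chosen.

    Raises ``ValueError`` for sequences outside 40-400 nt or containing
    characters other than A/C/G/T(U) after normalisation.
    """
    seq = normalize(seq)
    if not 40 <= len(seq) <= 400:
        raise ValueError(f"sequence length {len(seq)} outside [40, 400]")
    if not is_valid(seq):
        raise ValueError("sequence contains non-ACGU characters")
    structure, score = _fold_any(seq)
    return structure, score


def _fold_any(seq: str) -> tuple[str, int]:
    """Fold without length restriction (used by the short-sequence oracle path)."""
    n = len(seq)
    w = _weight_matrix(seq)
    # g[i][j] = best score over the half-open window [i, j)
    g = np.zeros((n + 1, n + 1), dtype=np.int64)
    span = MIN_LOOP + 2  # shortest window that can hold one pair
    for j in range(span, n + 1):
        last = j - 1
        wcol = w[:, last]
        gcol = g[:, last]
        for i in range(j - span, -1, -1):
            # pair (k, j-1) for k in [i, j-1-MIN_LOOP-1]
            ks = np.arange(i, j - span + 1)
            best = g[i, j - 1]
            if ks.size:
                cand = g[i, ks] + wcol[ks] + gcol[ks + 1]
                # terms with weight 0 never beat leaving j-1 unpaired
                best = max(best, int(cand.max()))
            g[i, j] = best
    structure = _traceback(seq, w, g)
    return structure, int(g[0, n])


def _traceback(seq: str, w: np.ndarray, g: np.ndarray) -> str:
    n = len(seq)
    dots = ["."] * n
    stack = [(0, n)]
    while stack:
        i, j = stack.pop()
        if j - i < MIN_LOOP + 2 or g[i, j] == 0:
            continue
        target = g[i, j]
        paired = False
        for k in range(i, j - MIN_LOOP - 1):
            wt = w[k, j - 1]
            if wt and g[i, k] + wt + g[k + 1, j - 1] == target:
                dots[k] = "("
                dots[j - 1] = ")"
                stack.append((i, k))
                stack.append((k + 1, j - 1))
                paired = True
                break
        if not paired:
            stack.append((i, j - 1))
    return "".join(dots)


def pair_table(structure: str) -> list[int]:
    """Partner index per position (-1 if unpaired) from dot-bracket."""
    partners = [-1] * len(structure)
    stack: list[int] = []
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced structure")
            k = stack.pop()
            partners[k] = i
            partners[i] = k
    if stack:
        raise ValueError("unbalanced structure")
    return partners


# ---------------------------------------------------------------------------
# genome mapping and precursor excision


class GenomeIndex:
    """Exact-match index over a genome: seed table on 18-mers plus verification."""

    SEED = 18

    def __init__(self, genome: Mapping[str, str]):
        if not genome or all(len(s) == 0 for s in genome.values()):
            raise ValueError("empty genome")
        self.genome = {c: normalize(s) for c, s in genome.items()}
        self._seeds: dict[str, list[tuple[str, int]]] = {}
        for chrom in sorted(self.genome):
            seq = self.genome[chrom]
            for pos in range(len(seq) - self.SEED + 1):
                self._seeds.setdefault(seq[pos : pos + self.SEED], []).append((chrom, pos))

    def _forward_hits(self, query: str) -> list[tuple[str, int]]:
        hits = []
        for chrom, pos in self._seeds.get(query[: self.SEED], ()):
            if self.genome[chrom][pos : pos + len(query)] == query:
                hits.append((chrom, pos))
        return hits

    def map_tag(self, tag: str) -> list[GenomeLocus]:
        """All exact full-length loci of *tag*, both strands, sorted."""
        tag = normalize(tag)
        loci = [
            GenomeLocus(chrom, pos, pos + len(tag), "+")
            for chrom, pos in self._forward_hits(tag)
        ]
        loci += [
            GenomeLocus(chrom, pos, pos + len(tag), "-")
            for chrom, pos in self._forward_hits(revcomp(tag))
        ]
        return sorted(loci)


def map_to_genome(
    tags: Iterable[str],
    genome: Mapping[str, str],
    max_hits: int = DEFAULT_MAX_HITS,
) -> dict[str, list[GenomeLocus]]:
    """Map tag sequences to exact genomic loci on both strands.

    Tags hitting more than *max_hits* loci are treated as repeats and
    mapped to no locus.  Tags without any hit are omitted from the result.
    """
    index = GenomeIndex(genome)
    mapped: dict[str, list[GenomeLocus]] = {}
    for tag in sorted(set(normalize(t) for t in tags)):
        loci = index.map_tag(tag)
        if 0 < len(loci) <= max_hits:
            mapped[tag] = loci
    return mapped


def excise_precursors(
    locus: GenomeLocus,
    genome: Mapping[str, str],
    flank_long: int = DEFAULT_FLANK_LONG,
    flank_short: int = DEFAULT_FLANK_SHORT,
) -> list[tuple[GenomeLocus, str, tuple[int, int]]]:
    """Excise the two candidate precursor windows around a mature locus.

    One window extends far upstream (mature on the 3' arm), the other far
    downstream (mature on the 5' arm); both are clipped to chromosome
    bounds and strand-resolved.  Returns ``(window locus, window sequence,
    mature offset within the window)`` triples; the offset is in
    strand-resolved (5'->3') coordinates.
    """
    chrom_seq = normalize(genome[locus.chrom])
    n = len(chrom_seq)
    windows = []
    for up, down in ((flank_long, flank_short), (flank_short, flank_long)):
        start = max(0, locus.start - up)
        end = min(n, locus.end + down)
        wseq = chrom_seq[start:end]
        if locus.strand == "+":
            offset = (locus.start - start, locus.end - start)
        else:
            wseq = revcomp(wseq)
            offset = (end - locus.end, end - locus.start)
        windows.append((GenomeLocus(locus.chrom, start, end, locus.strand), wseq, offset))
    return windows


# ---------------------------------------------------------------------------
# hairpin criteria


def call_hairpin(
    window_seq: str,
    mature_offset: tuple[int, int],
    locus: GenomeLocus | None = None,
    fold_result: tuple[str, int] | None = None,
    min_duplex_pairs: int = DEFAULT_MIN_DUPLEX_PAIRS,
    min_score_density: float = DEFAULT_MIN_SCORE_DENSITY,
    max_star_excess: int = DEFAULT_MAX_STAR_EXCESS,
) -> HairpinCall:
    """Judge one precursor window against the hairpin criteria.

    The verdict is ``miRNA`` only when all of the following hold:

    a. the mature sequence is 18-26 nt;
    b. every paired mature base pairs outside the mature interval and all
       partners lie on the same side, i.e. the mature sits on one arm of
       the stem and does not span the terminal loop;
    c. at least *min_duplex_pairs* mature bases are paired to a compact
       opposite arm, the miRNA*: only partners falling within the densest
       window of width mature length + *max_star_excess* count, so pairs
       scattered across several helices of a multibranched fold do not
       masquerade as a duplex;
    d. pair score per nucleotide is at least *min_score_density*;
    e. the precursor is 60-400 nt.
    """
    seq = normalize(window_seq)
    mstart, mend = mature_offset
    if fold_result is None:
        fold_result = fold(seq)
    structure, score = fold_result
    partners = pair_table(structure)

    reasons: list[str] = []
    ok_len = MATURE_LEN_RANGE[0] <= mend - mstart <= MATURE_LEN_RANGE[1]
    reasons.append(f"mature_length:{'pass' if ok_len else 'fail'}")

    mature_partners = [partners[i] for i in range(mstart, mend) if partners[i] >= 0]
    outside = sorted(p for p in mature_partners if p < mstart or p >= mend)
    internal = len(mature_partners) - len(outside)
    on_one_arm = (
        internal == 0
        and len(outside) > 0
        and (all(p < mstart for p in outside) or all(p >= mend for p in outside))
    )
    reasons.append(f"mature_on_one_arm:{'pass' if on_one_arm else 'fail'}")

    # the star arm is the densest compact window of partner positions;
    # partners beyond a large bulge do not count toward the duplex
    duplex = 0
    star_window: list[int] = []
    if on_one_arm:
        width = (mend - mstart) + max_star_excess
        for lo_idx, lo in enumerate(outside):
            inside = [p for p in outside[lo_idx:] if p < lo + width]
            if len(inside) > duplex:
                duplex = len(inside)
                star_window = inside
    ok_duplex = duplex >= min_duplex_pairs
    reasons.append(f"duplex_pairs>={min_duplex_pairs}:{'pass' if ok_duplex else 'fail'}")

    density = score / len(seq)
    ok_density = density >= min_score_density
    reasons.append(f"score_density>={min_score_density}:{'pass' if ok_density else 'fail'}")

    ok_size = PRECURSOR_LEN_RANGE[0] <= len(seq) <= PRECURSOR_LEN_RANGE[1]
    reasons.append(f"precursor_length:{'pass' if ok_size else 'fail'}")

    arm = None
    star: tuple[int, int] | None = None
    if on_one_arm and star_window:
        arm = "5p" if star_window[0] >= mend else "3p"
        star = (star_window[0], star_window[-1] + 1)

    cand = PrecursorCandidate(
        locus=locus or GenomeLocus("window", 0, len(seq), "+"),
        seq=seq,
        structure=structure,
        pair_score=score,
        mature_offset=mature_offset,
        star_offset=star,
        duplex_pairs=duplex,
        arm=arm,
    )
    verdict = "miRNA" if all([ok_len, on_one_arm, ok_duplex, ok_density, ok_size]) else "pseudo-miRNA"
    return HairpinCall(candidate=cand, verdict=verdict, reasons=reasons)


@dataclass
class NovelMirna:
    """A tag promoted to novel miRNA, with its best-scoring precursor."""

    mirna_id: str
    mature_seq: str
    call: HairpinCall
    n_loci: int


def _overlaps(locus: GenomeLocus, regions: Sequence[GenomeLocus]) -> bool:
    return any(
        r.chrom == locus.chrom and r.start < locus.end and locus.start < r.end
        for r in regions
    )


def discover_novel(
    tags: Iterable[str],
    genome: Mapping[str, str],
    exclude: Sequence[GenomeLocus] = (),
    max_hits: int = DEFAULT_MAX_HITS,
    flank_long: int = DEFAULT_FLANK_LONG,
    flank_short: int = DEFAULT_FLANK_SHORT,
    min_duplex_pairs: int = DEFAULT_MIN_DUPLEX_PAIRS,
    min_score_density: float = DEFAULT_MIN_SCORE_DENSITY,
) -> tuple[list[NovelMirna], list[HairpinCall]]:
    """Run the full discovery cascade over unannotated tag sequences.

    Each genomic locus of each tag is excised and evaluated independently;
    a tag becomes a novel miRNA when at least one locus passes all hairpin
    criteria, and its reported precursor is the best-scoring passing
    window.  Windows overlapping *exclude* regions (known-miRNA or
    structural-RNA loci) are skipped before folding.  Returns the novel
    miRNAs (ids assigned in sorted tag order) and every pseudo-miRNA call.
    """
    mapped = map_to_genome(tags, genome, max_hits=max_hits)
    novel: list[NovelMirna] = []
    pseudo: list[HairpinCall] = []
    for tag in sorted(mapped):
        best: HairpinCall | None = None
        tag_pseudo: list[HairpinCall] = []
        for locus in mapped[tag]:
            for wlocus, wseq, moffset in excise_precursors(
                locus, genome, flank_long=flank_long, flank_short=flank_short
            ):
                if _overlaps(wlocus, exclude):
                    continue
                if not PRECURSOR_LEN_RANGE[0] <= len(wseq) <= 400:
                    continue
                call = call_hairpin(
                    wseq,
                    moffset,
                    locus=wlocus,
                    min_duplex_pairs=min_duplex_pairs,
                    min_score_density=min_score_density,
                )
                if call.verdict == "miRNA":
                    if best is None or call.candidate.pair_score > best.candidate.pair_score:
                        best = call
                else:
                    tag_pseudo.append(call)
        if best is not None:
            novel.append(
                NovelMirna(mirna_id="", mature_seq=tag, call=best, n_loci=len(mapped[tag]))
            )
        else:
            pseudo.extend(tag_pseudo)
    for i, nm in enumerate(novel, start=1):
        nm.mirna_id = f"novel_mir_{i}"
    return novel, pseudo


def verify_known_hairpins(
    known: Mapping[str, str],
    genome: Mapping[str, str],
    max_hits: int = DEFAULT_MAX_HITS,
) -> dict[str, str]:
    """Verify hairpin context of known miRNAs against the genome.

    Returns per miRNA id one of ``verified`` (some locus folds into a
    qualifying hairpin), ``pseudo`` (maps but no locus folds), or
    ``not_genome_verified`` (no exact genomic locus; cross-species
    references need not map and are retained downstream regardless).
    """
    seq_to_ids: dict[str, list[str]] = {}
    for mid in sorted(known):
        seq_to_ids.setdefault(normalize(known[mid]), []).append(mid)
    mapped = map_to_genome(seq_to_ids, genome, max_hits=max_hits)
    verdicts: dict[str, str] = {}
    for seq, ids in seq_to_ids.items():
        if seq not in mapped:
            status = "not_genome_verified"
        else:
            status = "pseudo"
            for locus in mapped[seq]:
                for wlocus, wseq, moffset in excise_precursors(locus, genome):
                    if len(wseq) < PRECURSOR_LEN_RANGE[0]:
                        continue
                    if call_hairpin(wseq, moffset, locus=wlocus).verdict == "miRNA":
                        status = "verified"
                        break
                if status == "verified":
                    break
        for mid in ids:
            verdicts[mid] = status
    return verdicts


# ---------------------------------------------------------------------------
# output writers


def write_gff3(novel: Sequence[NovelMirna], path: str | Path) -> None:
    """Write precursor loci as GFF3 (1-based inclusive coordinates)."""
    with open(path, "w") as out:
        out.write("##gff-version 3\n")
        for nm in novel:
            loc = nm.call.candidate.locus
            out.write(
                "\t".join(
                    [
                        loc.chrom,
                        "mirmodule",
                        "miRNA_primary_transcript",
                        str(loc.start + 1),
                        str(loc.end),
                        str(nm.call.candidate.pair_score),
                        loc.strand,
                        ".",
                        f"ID={nm.mirna_id}",
                    ]
                )
                + "\n"
            )


def write_hairpin_fasta(novel: Sequence[NovelMirna], path: str | Path) -> None:
    with open(path, "w") as out:
        for nm in novel:
            out.write(f">{nm.mirna_id}_precursor\n{nm.call.candidate.seq}\n")
            out.write(f">{nm.mirna_id}_mature\n{nm.mature_seq}\n")


def write_structures(novel: Sequence[NovelMirna], path: str | Path) -> None:
    with open(path, "w") as out:
        for nm in novel:
            out.write(f">{nm.mirna_id}\n{nm.call.candidate.seq}\n{nm.call.candidate.structure}\n")
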