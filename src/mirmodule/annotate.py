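"""Tag annotation against miRNA and structural-RNA references.

Clean tags are partitioned into miRNA, rRNA, snRNA, snoRNA, tRNA and
unannotated, in that priority order, so the partition is exact: every tag
lands in exactly one category.  Mature-miRNA matching is gapless with at
most two substitutions and a terminal overhang of up to 2 nt; structural
RNAs are matched by exact substring containment (the references are full
molecules much longer than a tag).  From the quantified hits a
family-representative database is built: one mature sequence per miRNA
family, the most highly expressed member.
"""

from __future__ import annotations

import re
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from mirmodule._seq import normalize
from mirmodule.preprocess import CleanTag

CATEGORY_PRIORITY = ["miRNA", "rRNA", "snRNA", "snoRNA", "tRNA", "unannotated"]
MAX_MISMATCHES = 2
MAX_OVERHANG = 2
_SEED_K = 6

_SPECIES_PREFIX = re.compile(r"^[a-z]{3,4}-")
_ARM_SUFFIX = re.compile(r"[-.](3p|5p)$")
_VARIANT_SUFFIX = re.compile(r"(?<=\d)[a-z]+$")


def parse_family(mirna_id: str) -> str:
    """Derive the miRNA family name from a miRBase-style identifier.

    Strips the species prefix, the -5p/-3p arm suffix and trailing
    variant letters: ``ath-miR166a-5p`` -> ``miR166``.  Identifiers that
    do not follow the convention are returned unchanged (minus prefix and
    arm suffix), so each such id is its own family.
    """
    name = _SPECIES_PREFIX.sub("", mirna_id)
    name = _ARM_SUFFIX.sub("", name)
    return _VARIANT_SUFFIX.sub("", name)


@dataclass
class ReferenceSet:
    """One category of reference sequences.

    ``family_of`` is filled for mature-miRNA references, either from the
    id convention or from a user-supplied override mapping.
    """

    category: str
    records: dict[str, str]
    family_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.records = {rid: normalize(seq) for rid, seq in self.records.items()}
        for rid, seq in self.records.items():
            if not seq:
                raise ValueError(f"empty reference sequence for {rid}")
        if self.category == "miRNA_mature" and not self.family_of:
            self.family_of = {rid: parse_family(rid) for rid in self.records}


@dataclass
class AnnotatedTag:
    """A clean tag with its category assignment."""

    tag: CleanTag
    category: str
    matched_id: str | None = None
    mismatches: int = 0


@dataclass
class FamilyReference:
    """Per-family representative mature sequences (id and sequence)."""

    representatives: dict[str, tuple[str, str]]  # family -> (source id, sequence)

    def sequences(self) -> dict[str, str]:
        """Representative id -> sequence, for downstream counting."""
        return {rid: seq for rid, seq in self.representatives.values()}


def _align_at(tag: str, ref: str, shift: int) -> tuple[int, int] | None:
    """Mismatches and overlap for tag index i aligned to ref index i+shift."""
    lo = max(0, -shift)
    hi = min(len(tag), len(ref) - shift)
    overlap = hi - lo
    if overlap < len(tag) - MAX_OVERHANG:
        return None
    mm = sum(1 for i in range(lo, hi) if tag[i] != ref[i + shift])
    return mm, overlap


class MatureMatcher:
    """Gapless <=2-substitution matcher against a mature-miRNA reference.

    A shared-6-mer inverted index anchors candidate alignment offsets;
    with at most two substitutions and a 2 nt overhang every true hit
    contains an exact run of at least 5-6 nt, so seeding at 6 with an
    additional exhaustive pass for tags shorter than 20 nt keeps the
    matcher equivalent to the brute-force all-offset Hamming scan.
    """

    def __init__(self, mature_db: ReferenceSet):
        if mature_db.category != "miRNA_mature":
            raise ValueError("matcher requires a miRNA_mature reference set")
        self.db = mature_db
        self._index: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for rid, seq in mature_db.records.items():
            for pos in range(len(seq) - _SEED_K + 1):
                self._index[seq[pos : pos + _SEED_K]].append((rid, pos))

    def _candidates(self, tag: str) -> set[tuple[str, int]]:
        cands: set[tuple[str, int]] = set()
        for p in range(len(tag) - _SEED_K + 1):
            for rid, q in self._index.get(tag[p : p + _SEED_K], ()):
                cands.add((rid, q - p))
        if len(tag) < 20:  # seed guarantee weakens; fall back to all offsets
            for rid, seq in self.db.records.items():
                for shift in range(-MAX_OVERHANG, len(seq) - len(tag) + MAX_OVERHANG + 1):
                    cands.add((rid, shift))
        return cands

    def match(self, tag: str) -> tuple[str | None, int]:
        """Best hit for *tag*: minimal mismatches, ties by smallest id."""
        tag = normalize(tag)
        best: tuple[int, str] | None = None
        for rid, shift in self._candidates(tag):
            res = _align_at(tag, self.db.records[rid], shift)
            if res is None:
                continue
            mm, _overlap = res
            if mm <= MAX_MISMATCHES and (best is None or (mm, rid) < best):
                best = (mm, rid)
        if best is None:
            return None, 0
        return best[1], best[0]


def match_known_mirna(tag: CleanTag | str, mature_db: ReferenceSet) -> tuple[str | None, int]:
    """One-shot best-hit matching of a tag against mature references.

    For repeated queries build a :class:`MatureMatcher` once instead.
    """
    seq = tag.seq if isinstance(tag, CleanTag) else tag
    return MatureMatcher(mature_db).match(seq)


def classify_tags(
    tags: Mapping[str, CleanTag],
    references: Sequence[ReferenceSet],
) -> tuple[list[AnnotatedTag], dict[str, dict[str, int]]]:
    """Assign every tag to exactly one category.

    Priority is miRNA > rRNA > snRNA > snoRNA > tRNA; anything left is
    unannotated.  Returns the annotated tags (sorted by sequence) and a
    summary ``{category: {unique, total}}`` including the totals row.
    Omitted reference categories simply receive no assignments.
    """
    matcher: MatureMatcher | None = None
    structural: dict[str, str] = {}
    for ref in references:
        if ref.category == "miRNA_mature":
            matcher = MatureMatcher(ref)
        elif ref.category in ("rRNA", "snRNA", "snoRNA", "tRNA"):
            # one concatenated haystack per category; '#' guards joins
            structural[ref.category] = "#" + "#".join(
                ref.records[rid] for rid in sorted(ref.records)
            ) + "#"

    def _structural_hit(category: str, seq: str) -> str | None:
        hay = structural.get(category)
        if hay and seq in hay:
            return category  # id-level resolution not needed downstream
        return None

    annotated: list[AnnotatedTag] = []
    for seq in sorted(tags):
        tag = tags[seq]
        category, matched, mm = "unannotated", None, 0
        if matcher is not None:
            hit, hit_mm = matcher.match(seq)
            if hit is not None:
                category, matched, mm = "miRNA", hit, hit_mm
        if category == "unannotated":
            for cat in ("rRNA", "snRNA", "snoRNA", "tRNA"):
                if _structural_hit(cat, seq):
                    category, matched = cat, cat
                    break
        annotated.append(AnnotatedTag(tag=tag, category=category, matched_id=matched, mismatches=mm))

    summary: dict[str, dict[str, int]] = {
        cat: {"unique": 0, "total": 0} for cat in CATEGORY_PRIORITY
    }
    for at in annotated:
        summary[at.category]["unique"] += 1
        summary[at.category]["total"] += at.tag.total()
    summary["Total"] = {
        "unique": sum(v["unique"] for k, v in summary.items() if k != "Total"),
        "total": sum(v["total"] for k, v in summary.items() if k != "Total"),
    }
    return annotated, summary


def build_family_reference(
    hits: Iterable[AnnotatedTag], mature_db: ReferenceSet
) -> FamilyReference:
    """Pick the most highly expressed mature sequence per miRNA family.

    Expression of a reference is the summed count of all tags whose best
    hit it is.  Families with zero expression are excluded; ties go to
    the lexicographically smallest reference id.
    """
    expression: dict[str, int] = defaultdict(int)
    for at in hits:
        if at.category == "miRNA" and at.matched_id is not None:
            expression[at.matched_id] += at.tag.total()
    by_family: dict[str, tuple[int, str]] = {}
    for rid in sorted(expression):
        count = expression[rid]
        if count <= 0:
            continue
        family = mature_db.family_of.get(rid, rid)
        incumbent = by_family.get(family)
        # higher count wins; the sorted loop makes ties fall to the smaller id
        if incumbent is None or count > incumbent[0]:
            by_family[family] = (count, rid)
    return FamilyReference(
        representatives={
            fam: (rid, mature_db.records[rid])
            for fam, (_count, rid) in sorted(by_family.items())
        }
    )


def annotation_table(summary: Mapping[str, Mapping[str, int]]):
    """Category summary as a DataFrame with unique/total counts and percentages."""
    import pandas as pd

    from mirmodule.integrate import summarize_percentages

    total_u = summary["Total"]["unique"]
    total_t = summary["Total"]["total"]
    rows = []
    for cat in CATEGORY_PRIORITY + ["Total"]:
        u, t = summary[cat]["unique"], summary[cat]["total"]
        rows.append(
            {
                "category": cat,
                "unique_sRNAs": u,
                "unique_pct": summarize_percentages(u, total_u) if total_u else 0.0,
                "total_sRNAs": t,
                "total_pct": summarize_percentages(t, total_t) if total_t else 0.0,
            }
        )
    return pd.DataFrame(rows)
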