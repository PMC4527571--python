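"""Quantification and differential expression between two libraries.

Counts per miRNA are accumulated with class-specific matching rules:
known miRNAs accrue tags matching the family representative within two
substitutions (best hit only, so read mass is conserved), novel miRNAs
accrue tags whose differences are confined to the terminal 3 nt of each
end with a perfectly matching interior.  Counts are normalised to TPM
(tags per million clean reads), fold change is log2 of the TPM ratio
with a small floor against zeros, and significance comes from the
Audic-Claverie exact test for tag counts in two libraries — the
appropriate test when each condition is one pooled library without
replicates.  Benjamini-Hochberg FDR is applied within each miRNA class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from mirmodule._seq import normalize
from mirmodule.annotate import FamilyReference, MatureMatcher, ReferenceSet
from mirmodule.preprocess import CleanTag

TPM_FLOOR = 0.01
FC_THRESHOLD = 1.0
P_THRESHOLD = 0.05
FDR_THRESHOLD = 0.05
STRICT_P = 0.01
END_WINDOW = 3
MAX_END_DIFFS = 3


@dataclass
class ExpressionRecord:
    """Per-miRNA expression across the two libraries with the DE call."""

    mirna_id: str
    mirna_class: str  # "known" or "novel"
    count_A: int
    count_B: int
    total_A: int
    total_B: int
    tpm_A: float = 0.0
    tpm_B: float = 0.0
    log2fc: float = 0.0
    p_value: float = 1.0
    fdr: float = 1.0
    status: str = "unDE"
    significant: str = "none"  # "p<0.05", "p<0.01" or "none"


def tpm(count: int, total_clean_reads: int) -> float:
    """Tags per million: count / total clean reads x 10^6."""
    if total_clean_reads <= 0:
        raise ValueError("total clean reads must be positive")
    return count / total_clean_reads * 1_000_000


def fold_change(tpm_b: float, tpm_a: float, floor: float = TPM_FLOOR) -> float:
    """log2(TPM_B / TPM_A) with both TPMs floored to avoid singularities."""
    return math.log2(max(tpm_b, floor) / max(tpm_a, floor))


def de_test(count_a: int, count_b: int, total_a: int, total_b: int) -> float:
    """Two-sided Audic-Claverie exact test for two tag counts.

    Conditional on count_a = x, the null distribution of count_b is
    negative binomial with x+1 successes and success probability
    N1/(N1+N2) (equal per-read sampling rates in both libraries); the
    two-sided p-value doubles the smaller tail at the observed count,
    capped at 1.  Computed through scipy's log-space negative binomial,
    so it is overflow-safe at library-scale totals.
    """
    for v in (count_a, count_b):
        if v < 0:
            raise ValueError("counts must be non-negative")
    if total_a <= 0 or total_b <= 0:
        raise ValueError("library totals must be positive")
    dist = sps.nbinom(count_a + 1, total_a / (total_a + total_b))
    lower = dist.cdf(count_b)
    upper = dist.sf(count_b - 1)  # P(Y >= y)
    return min(1.0, 2.0 * min(lower, upper))


def fisher_de_test(count_a: int, count_b: int, total_a: int, total_b: int) -> float:
    """Fisher's exact test on the 2x2 count-vs-rest table (alternative test)."""
    table = [[count_a, total_a - count_a], [count_b, total_b - count_b]]
    return sps.fisher_exact(table, alternative="two-sided")[1]


def ddct(
    ct_target_cond: float,
    ct_ref_cond: float,
    ct_target_ctrl: float,
    ct_ref_ctrl: float,
) -> float:
    """Relative expression by the 2^-ddCt method for paired qPCR thresholds."""
    ddct_value = (ct_target_cond - ct_ref_cond) - (ct_target_ctrl - ct_ref_ctrl)
    return 2.0 ** (-ddct_value)


# ---------------------------------------------------------------------------
# counting


def count_known(
    tags: Mapping[str, CleanTag],
    family_ref: FamilyReference,
    libraries: Sequence[str],
) -> dict[str, dict[str, int]]:
    """Accumulate tag counts onto family representatives (best hit only).

    Matching mirrors annotation: gapless, at most two substitutions,
    terminal overhang up to 2 nt; each tag's count accrues to exactly one
    representative (fewest mismatches, ties by smallest id).  Every
    representative appears in the result even with zero counts.
    """
    ref_set = ReferenceSet(category="miRNA_mature", records=family_ref.sequences())
    matcher = MatureMatcher(ref_set)
    counts = {rid: {lib: 0 for lib in libraries} for rid in sorted(ref_set.records)}
    for seq in sorted(tags):
        rid, _mm = matcher.match(seq)
        if rid is None:
            continue
        for lib in libraries:
            counts[rid][lib] += tags[seq].counts.get(lib, 0)
    return counts


def matches_novel(tag: str, mature: str, end_window: int = END_WINDOW,
                  max_end_diffs: int = MAX_END_DIFFS) -> bool:
    """End-tolerant matching rule for novel miRNA counting.

    The tag matches when, at some gapless offset, the interior of the
    mature (everything beyond *end_window* nt from each end) aligns with
    zero mismatches and the total number of end differences —
    substitutions within the terminal windows plus overhanging bases —
    is at most *max_end_diffs*.
    """
    tag, mature = normalize(tag), normalize(mature)
    m = len(mature)
    for shift in range(-max_end_diffs, len(tag) - m + max_end_diffs + 1):
        # mature index j aligns tag index j + shift
        diffs = 0
        ok = True
        for j in range(m):
            i = j + shift
            inside = 0 <= i < len(tag)
            agree = inside and tag[i] == mature[j]
            if end_window <= j < m - end_window:
                if not agree:
                    ok = False
                    break
            elif not agree:
                diffs += 1
        if not ok:
            continue
        diffs += max(0, -shift) + max(0, len(tag) - (m + shift))
        # overhanging tag bases beyond either mature end also count as
        # end differences; interior already exact
        if diffs <= max_end_diffs:
            return True
    return False


def count_novel(
    tags: Mapping[str, CleanTag],
    novel_matures: Mapping[str, str],
    libraries: Sequence[str],
) -> dict[str, dict[str, int]]:
    """Accumulate tag counts onto novel matures with the end-mismatch rule.

    A tag may satisfy the rule for several novel matures; it accrues to
    the first match in sorted id order (deterministic best-effort — the
    generator keeps matures well separated so overlaps are rare).
    """
    counts = {mid: {lib: 0 for lib in libraries} for mid in sorted(novel_matures)}
    items = sorted(novel_matures.items())
    # cheap prefilter: exact interior 12-mer of each mature
    interior: dict[str, str] = {}
    for mid, mat in items:
        mat = normalize(mat)
        mid_start = max(END_WINDOW, (len(mat) - 12) // 2)
        interior[mid] = mat[mid_start : mid_start + 12]
    for seq in sorted(tags):
        for mid, mat in items:
            if interior[mid] in seq and matches_novel(seq, mat):
                for lib in libraries:
                    counts[mid][lib] += tags[seq].counts.get(lib, 0)
                break
    return counts


# ---------------------------------------------------------------------------
# DE calling


def quantify(
    counts: Mapping[str, Mapping[str, int]],
    totals: Mapping[str, int],
    lib_a: str,
    lib_b: str,
    mirna_class: str,
    floor: float = TPM_FLOOR,
    test: str = "audic-claverie",
) -> list[ExpressionRecord]:
    """Build expression records with TPM, fold change and p-values."""
    test_fn = de_test if test == "audic-claverie" else fisher_de_test
    records = []
    for mid in sorted(counts):
        ca, cb = counts[mid].get(lib_a, 0), counts[mid].get(lib_b, 0)
        rec = ExpressionRecord(
            mirna_id=mid,
            mirna_class=mirna_class,
            count_A=ca,
            count_B=cb,
            total_A=totals[lib_a],
            total_B=totals[lib_b],
        )
        rec.tpm_A = tpm(ca, rec.total_A)
        rec.tpm_B = tpm(cb, rec.total_B)
        rec.log2fc = fold_change(rec.tpm_B, rec.tpm_A, floor=floor)
        rec.p_value = test_fn(ca, cb, rec.total_A, rec.total_B)
        records.append(rec)
    return records


def call_de(
    records: Iterable[ExpressionRecord],
    fc_threshold: float = FC_THRESHOLD,
    p_threshold: float = P_THRESHOLD,
    fdr_threshold: float = FDR_THRESHOLD,
) -> list[ExpressionRecord]:
    """Apply Benjamini-Hochberg FDR and assign DE status per record.

    Differential expression requires |log2FC| > *fc_threshold*, p <
    *p_threshold* and FDR <= *fdr_threshold*; the direction of the fold
    change sets up/down.  Records with p < 0.01 get the strict
    significance tier.  Call separately per miRNA class so the
    correction matches the class-wise accounting.
    """
    records = list(records)
    if not records:
        return []
    fdrs = multipletests([r.p_value for r in records], method="fdr_bh")[1]
    for rec, fdr in zip(records, fdrs):
        rec.fdr = float(fdr)
        de = (
            abs(rec.log2fc) > fc_threshold
            and rec.p_value < p_threshold
            and rec.fdr <= fdr_threshold
        )
        rec.status = ("up" if rec.log2fc > 0 else "down") if de else "unDE"
        if de:
            rec.significant = "p<0.01" if rec.p_value < STRICT_P else "p<0.05"
        else:
            rec.significant = "none"
    return records


def records_table(records: Iterable[ExpressionRecord]) -> pd.DataFrame:
    """Expression records as a DataFrame with fixed column order."""
    cols = [
        "mirna_id", "mirna_class", "count_A", "count_B", "total_A", "total_B",
        "tpm_A", "tpm_B", "log2fc", "p_value", "fdr", "status", "significant",
    ]
    df = pd.DataFrame([vars(r) for r in records])
    if df.empty:
        return pd.DataFrame(columns=cols)
    return df[cols]


def tpm_column(counts: Sequence[int], total: int) -> np.ndarray:
    """Vectorised TPM for a full tag count vector (sums to 10^6 by construction)."""
    if total <= 0:
        raise ValueError("total clean reads must be positive")
    return np.asarray(counts, dtype=float) / total * 1_000_000
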