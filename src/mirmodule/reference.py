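"""Brute-force reference implementations for cross-validation.

Each function here recomputes a result of the main modules by a slower,
structurally different route — exhaustive enumeration, direct tail
summation, all-offset scanning — so the fast implementations can be
checked against an independent code path.  Nothing in the pipeline
itself calls these.
"""

from __future__ import annotations

import math
from typing import Iterator

from mirmodule._seq import normalize
from mirmodule.novel_discovery import MIN_LOOP, _PAIR_WEIGHT


def enumerate_structures(n: int, can_pair) -> Iterator[list[tuple[int, int]]]:
    """Yield every nested pairing of positions 0..n-1 (minimum loop 3).

    ``can_pair(i, j)`` gates admissible pairs.  Exponential; intended for
    n <= ~14.
    """

    def rec(positions: tuple[int, ...]) -> Iterator[list[tuple[int, int]]]:
        if not positions:
            yield []
            return
        first, rest = positions[0], positions[1:]
        # first unpaired
        for pairing in rec(rest):
            yield pairing
        # first paired with any admissible partner; nestedness splits the rest
        for idx, j in enumerate(rest):
            if j - first <= MIN_LOOP or not can_pair(first, j):
                continue
            inner, outer = rest[:idx], rest[idx + 1 :]
            for pin in rec(inner):
                for pout in rec(outer):
                    yield [(first, j)] + pin + pout

    yield from rec(tuple(range(n)))


def exhaustive_fold_score(seq: str) -> int:
    """Maximum weighted pair score over all nested structures (enumeration)."""
    seq = normalize(seq)

    def weight(i: int, j: int) -> int:
        return _PAIR_WEIGHT.get((seq[i], seq[j]), 0)

    best = 0
    for pairing in enumerate_structures(len(seq), lambda i, j: weight(i, j) > 0):
        best = max(best, sum(weight(i, j) for i, j in pairing))
    return best


def nussinov_cubic(seq: str) -> int:
    """Plain O(n^3) base-pair maximisation in the bifurcation formulation.

    Same objective as :func:`mirmodule.novel_discovery.fold` but written
    with the classic four-way recurrence over closed intervals, without
    vectorisation — an independent route to the same optimum.
    """
    seq = normalize(seq)
    n = len(seq)
    if n == 0:
        return 0
    dp = [[0] * n for _ in range(n)]
    for span in range(MIN_LOOP + 1, n):
        for i in range(n - span):
            j = i + span
            best = dp[i + 1][j]  # i unpaired
            w = _PAIR_WEIGHT.get((seq[i], seq[j]), 0)
            if w:
                best = max(best, w + (dp[i + 1][j - 1] if j - i > 1 else 0))
            for k in range(i + MIN_LOOP + 1, j):
                wk = _PAIR_WEIGHT.get((seq[i], seq[k]), 0)
                if wk:
                    inner = dp[i + 1][k - 1] if k - i > 1 else 0
                    best = max(best, wk + inner + dp[k + 1][j])
            dp[i][j] = best
    return dp[0][n - 1]


def ac_pvalue_direct(x: int, y: int, n1: int, n2: int, tail_span: int = 4000) -> float:
    """Audic-Claverie two-sided p-value by direct log-space tail summation.

    p(y'|x) = (n2/n1)^y' (x+y')! / (x! y'! (1 + n2/n1)^(x+y'+1)) summed
    over the tail at or beyond the observed y, doubled and capped at 1.
    Only valid when the distribution mass is contained within
    *tail_span* counts of the mode (small-count regime).
    """
    r = n2 / n1
    log_r = math.log(r)
    log_1r = math.log1p(r)

    def log_p(yy: int) -> float:
        return (
            yy * log_r
            + math.lgamma(x + yy + 1)
            - math.lgamma(x + 1)
            - math.lgamma(yy + 1)
            - (x + yy + 1) * log_1r
        )

    lower = sum(math.exp(log_p(k)) for k in range(0, y + 1))
    upper = sum(math.exp(log_p(k)) for k in range(y, y + tail_span))
    return min(1.0, 2.0 * min(lower, upper))


def hamming_best_hit(
    tag: str,
    references: dict[str, str],
    max_mismatches: int = 2,
    max_overhang: int = 2,
) -> tuple[str | None, int]:
    """All-offset gapless scan over every reference (matcher oracle).

    Tries every shift of the tag against every reference, requires
    overlap >= tag length - *max_overhang* and Hamming distance <=
    *max_mismatches* over the overlap; best hit by (mismatches, id).
    """
    tag = normalize(tag)
    best: tuple[int, str] | None = None
    for rid in sorted(references):
        ref = normalize(references[rid])
        for shift in range(-len(tag), len(ref) + 1):
            lo = max(0, -shift)
            hi = min(len(tag), len(ref) - shift)
            if hi - lo < len(tag) - max_overhang:
                continue
            mm = sum(1 for i in range(lo, hi) if tag[i] != ref[i + shift])
            if mm <= max_mismatches and (best is None or (mm, rid) < best):
                best = (mm, rid)
    return (None, 0) if best is None else (best[1], best[0])


def brute_force_sites(
    mirna: str,
    transcript: str,
    cutoff: float,
    core_mismatch_max: int = 2,
) -> list[tuple[int, float]]:
    """Score every window of a transcript directly (scanner oracle).

    Recomputes the per-position penalty sum from first principles for
    each window and returns ``(start, expectation)`` for windows passing
    the cutoff and the core mismatch limit.
    """
    mirna = normalize(mirna)
    transcript = normalize(transcript)
    m = len(mirna)
    pairs = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
    wobble = {("G", "T"), ("T", "G")}
    out = []
    for start in range(len(transcript) - m + 1):
        window = transcript[start : start + m]
        total = 0.0
        core_mm = 0
        for pos in range(1, m + 1):  # miRNA position, 5'->3'
            mb = mirna[pos - 1]
            tb = window[m - pos]
            if (mb, tb) in pairs:
                pen = 0.0
            elif (mb, tb) in wobble:
                pen = 0.5
            else:
                pen = 1.0
                if 2 <= pos <= 13:
                    core_mm += 1
            total += pen * (2.0 if 2 <= pos <= 13 else 1.0)
        if total <= cutoff and core_mm <= core_mismatch_max:
            out.append((start, total))
    return out
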