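"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written for transparency, not speed: direct tail sums,
exhaustive window scans and literal re-translations, kept deliberately
separate from the library code paths they validate.
"""

from __future__ import annotations

import math


# -- binomial machinery -----------------------------------------------------


def binom_pmf(k: int, n: int, p: float) -> float:
    return math.comb(n, k) * p**k * (1 - p) ** (n - k)


def binom_upper_tail(k: int, n: int, p: float) -> float:
    """P(X >= k) by direct summation."""
    return sum(binom_pmf(i, n, p) for i in range(k, n + 1))


def binom_lower_tail(k: int, n: int, p: float) -> float:
    """P(X <= k) by direct summation."""
    return sum(binom_pmf(i, n, p) for i in range(0, k + 1))


def conditional_two_sided_p(k1: int, k2: int, p0: float) -> float:
    """Two-sided conditional binomial p for counts (control, mutant)."""
    n = k1 + k2
    if n == 0:
        return 1.0
    lower = binom_lower_tail(k2, n, p0)
    upper = binom_upper_tail(k2, n, p0)
    return min(1.0, 2.0 * min(lower, upper))


def bh_by_hand(pvalues: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up computed literally."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adj = [0.0] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, pvalues[i] * m / rank_from_top)
        adj[i] = val
        prev = val
    return adj


# -- expression -------------------------------------------------------------


def median_ratio_factor(k1, k2) -> float:
    """Median of per-gene relative-abundance ratios (crude TMM stand-in)."""
    n1, n2 = sum(k1), sum(k2)
    ratios = sorted(
        (b / n2) / (a / n1) for a, b in zip(k1, k2) if a > 0 and b > 0
    )
    mid = len(ratios) // 2
    if len(ratios) % 2:
        return ratios[mid]
    return 0.5 * (ratios[mid - 1] + ratios[mid])


# -- methylation contexts ---------------------------------------------------

_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


def trinucleotide_contexts(seq: str) -> dict[tuple[int, str], str]:
    """Context of every cytosine on both strands by literal tabulation."""
    out = {}
    L = len(seq)
    for i, base in enumerate(seq):  # i is 0-based
        pos = i + 1
        if base == "C":
            nxt = seq[i + 1] if i + 1 < L else None
            nxt2 = seq[i + 2] if i + 2 < L else None
            if nxt == "G":
                out[(pos, "+")] = "CG"
            elif nxt is None:
                out[(pos, "+")] = "CHH"
            elif nxt2 == "G":
                out[(pos, "+")] = "CHG"
            else:
                out[(pos, "+")] = "CHH"
        if base == "G":  # C on the minus strand
            nxt = _COMP[seq[i - 1]] if i - 1 >= 0 else None
            nxt2 = _COMP[seq[i - 2]] if i - 2 >= 0 else None
            if nxt == "G":
                out[(pos, "-")] = "CG"
            elif nxt is None:
                out[(pos, "-")] = "CHH"
            elif nxt2 == "G":
                out[(pos, "-")] = "CHG"
            else:
                out[(pos, "-")] = "CHH"
    return out


# -- CpG islands ------------------------------------------------------------


def naive_cgi_scan(
    seq: str,
    window: int = 100,
    min_gc: float = 50.0,
    min_oe: float = 0.6,
    min_length: int = 200,
) -> list[tuple[int, int]]:
    """Exhaustive 1-bp-shift window scan; returns 1-based inclusive islands."""
    seq = seq.upper()
    L = len(seq)
    if L < window:
        return []

    def stats(a: int, b: int) -> tuple[float, float]:  # [a, b) 0-based
        sub = seq[a:b]
        n_c, n_g = sub.count("C"), sub.count("G")
        gc = 100.0 * (n_c + n_g) / (b - a)
        # "CG" occurrences cannot overlap, so str.count is the exact tally
        obs = sub.count("CG")
        exp = n_c * n_g / (b - a)
        return gc, (obs / exp if exp > 0 else 0.0)

    good = []
    for s in range(0, L - window + 1):
        gc, oe = stats(s, s + window)
        if gc >= min_gc and oe >= min_oe:
            good.append(s)
    islands = []
    i = 0
    while i < len(good):
        start = good[i]
        end = start + window
        j = i
        while j + 1 < len(good) and good[j + 1] <= end:
            j += 1
            end = max(end, good[j] + window)
        if end - start >= min_length:
            gc, oe = stats(start, end)
            if gc >= min_gc and oe >= min_oe:
                islands.append((start + 1, end))
        i = j + 1
    return islands
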