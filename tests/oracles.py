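"""Independent brute-force oracles used to cross-check the package.

These deliberately re-derive results from first principles (exhaustive
enumeration, closed forms) and share no code path with the implementation
they check.
"""

from __future__ import annotations

import itertools
from math import comb

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(s: str) -> str:
    return "".join(_COMP[b] for b in reversed(s))


def brute_primitive_motifs(k: int) -> set[str]:
    """All k-mers over ACGT whose smallest period is exactly k, found by
    testing every candidate period of every candidate k-mer."""
    out = set()
    for tup in itertools.product("ACGT", repeat=k):
        s = "".join(tup)
        # the smallest period of a tandem run of s is the smallest divisor
        # d of k with s = (s[:d])^(k/d)
        if not any(k % d == 0 and s == s[:d] * (k // d) for d in range(1, k)):
            out.add(s)
    return out


def brute_find_ssrs(seq: str, min_len: int = 18) -> set[tuple[int, int, str]]:
    """Exhaustive maximal-full-period-run search.

    For every period k and every start, extend the longest run of full
    motif copies; keep runs of total length >= min_len with a primitive
    motif that are maximal (one more full copy fits on neither side) and
    not nested inside another kept run.  Returns {(start, end, motif)}.
    """
    s = seq.upper()
    n = len(s)
    found = {}
    for k in range(1, 7):
        for i in range(n - 2 * k + 1):
            motif = s[i : i + k]
            if "N" in motif:
                continue
            if any(
                k % p == 0 and motif == motif[:p] * (k // p) for p in range(1, k)
            ):
                continue  # non-primitive
            reps = 0
            j = i
            while j + k <= n and s[j : j + k] == motif:
                reps += 1
                j += k
            length = reps * k
            if length < min_len:
                continue
            # maximal: no full copy immediately before or after
            before = s[i - k : i]
            after = s[j : j + k]
            if i - k >= 0 and before == motif:
                continue
            if j + k <= n and after == motif:
                continue
            # left-maximality in the partial sense: the single base before
            # the run must not extend the periodic stretch
            if i > 0 and s[i - 1] == s[i - 1 + k]:
                continue
            found[(i, i + length)] = motif
    # drop strictly nested intervals
    keep = set()
    items = list(found.items())
    for (a, b), motif in items:
        nested = any(
            (c <= a and b <= d) and (c, d) != (a, b) for (c, d), _ in items
        )
        if not nested:
            keep.add((a, b, motif))
    return keep


def brute_longest_orf(seq: str, min_aa: int):
    """Enumerate every ATG..stop span in all six frames; return the best
    (length_aa, strand, start, end, frame) under the plus-strand-first,
    leftmost tie rule, or None."""
    stops = {"TAA", "TAG", "TGA"}
    best = None
    for strand, t in (("+", seq), ("-", rc(seq))):
        for i in range(len(t) - 2):
            if t[i : i + 3] != "ATG":
                continue
            j = i + 3
            while j + 3 <= len(t):
                if t[j : j + 3] in stops:
                    aa = (j - i) // 3
                    if aa >= min_aa:
                        cand = (-aa, 0 if strand == "+" else 1, i, strand, j + 3, i % 3)
                        if best is None or cand < best:
                            best = cand
                    break
                j += 3
    if best is None:
        return None
    negaa, _, start, strand, end, frame = best
    return (-negaa, strand, start, end, frame)


def brute_amplicons(
    genome: dict[str, str], fwd: str, rev: str, max_product: int
) -> set[tuple[str, int, int, str]]:
    """Scan all plus-strand matches of each primer and each primer's
    reverse complement; pair them inward-facing within max_product."""
    hits = set()
    for chrom, text in genome.items():
        text = text.upper()
        for orientation, up, down in (("fwd+", fwd, rc(rev)), ("rev+", rev, rc(fwd))):
            ups = [
                i
                for i in range(len(text) - len(up) + 1)
                if text[i : i + len(up)] == up
            ]
            downs = [
                j
                for j in range(len(text) - len(down) + 1)
                if text[j : j + len(down)] == down
            ]
            for i in ups:
                for j in downs:
                    if j >= i + len(up) and j + len(down) - i <= max_product:
                        hits.add((chrom, i, j + len(down), orientation))
    return hits


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P[X >= k] for X ~ Hypergeom(N, K, n), by direct summation."""
    denom = comb(N, n)
    total = 0
    for x in range(k, min(K, n) + 1):
        total += comb(K, x) * comb(N - K, n - x)
    return total / denom


def bh_stepup(pvals: list[float]) -> list[float]:
    """Benjamini-Hochberg adjusted p-values from the step-up definition."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, pvals[i] * m / rank_from_top)
        adj[i] = val
        prev = val
    return adj


def ari_from_contingency(labels_a, labels_b) -> float:
    """Adjusted Rand index computed directly from the contingency table."""
    from collections import Counter

    pairs = Counter(zip(labels_a, labels_b))
    a_counts = Counter(labels_a)
    b_counts = Counter(labels_b)
    n = len(labels_a)
    sum_comb = sum(comb(v, 2) for v in pairs.values())
    sum_a = sum(comb(v, 2) for v in a_counts.values())
    sum_b = sum(comb(v, 2) for v in b_counts.values())
    expected = sum_a * sum_b / comb(n, 2)
    max_index = (sum_a + sum_b) / 2
    if max_index == expected:
        return 1.0 if sum_comb == expected else 0.0
    return (sum_comb - expected) / (max_index - expected)
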