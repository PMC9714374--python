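"""Small shared helpers: DNA string ops and fixed rounding conventions."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

DNA_ALPHABET = frozenset("ACGT")
DNA_ALPHABET_N = frozenset("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def validate_dna(seq: str, allow_n: bool = True) -> str:
    """Uppercase ``seq`` and reject characters outside A/C/G/T(/N)."""
    s = seq.upper()
    allowed = DNA_ALPHABET_N if allow_n else DNA_ALPHABET
    bad = set(s) - allowed
    if bad:
        raise ValueError(f"non-IUPAC characters in sequence: {sorted(bad)!r}")
    return s


def smallest_period(s: str) -> int:
    """Length of the fundamental (smallest) period of ``s``.

    The fundamental period p is the smallest p such that s[i] == s[i-p]
    for all i >= p.  For a primitive motif p == len(s).
    """
    n = len(s)
    for p in range(1, n):
        if n % p == 0 and s[:p] * (n // p) == s:
            return p
    return n


def is_primitive(motif: str) -> bool:
    """True if ``motif`` is not a whole-number power of a shorter string."""
    return smallest_period(motif) == len(motif)


def min_rotation(s: str) -> str:
    """Lexicographically minimal rotation of ``s`` (strand is preserved)."""
    return min(s[i:] + s[:i] for i in range(len(s)))


def round_half_up(x: float, decimals: int) -> float:
    """Decimal half-up rounding, matching how printed tables round.

    Python's builtin round() is banker's rounding; published frequency
    tables round 0.5 up, so summaries use this throughout.
    """
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def gc_percent(seq: str) -> float:
    if not seq:
        return 0.0
    return 100.0 * sum(1 for b in seq if b in "GC") / len(seq)


def max_homopolymer(seq: str) -> int:
    """Length of the longest single-base run in ``seq``."""
    best = run = 0
    prev = ""
    for b in seq:
        run = run + 1 if b == prev else 1
        prev = b
        if run > best:
            best = run
    return best
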