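"""Detection of mono- to hexanucleotide microsatellites (SSRs) in DNA.

An SSR here is a maximal run of full copies of a primitive motif of length
1-6 nt whose total run length reaches a minimum (default 18 nt).  Runs are
labelled by their fundamental period only, so a run of (AT)9 is reported
once as a dinucleotide repeat and never again under ATAT or ATATAT.  A run
of total length >= 20 nt is classed "perfect", 18-19 nt "imperfect" -- a
pure length classification, not a mismatch/interruption classification.

Coordinates are 0-based half-open.  ``N`` never participates in a run.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from ._util import is_primitive, min_rotation, validate_dna

MAX_MOTIF_LEN = 6
DEFAULT_MIN_LEN = 18
DEFAULT_PERFECT_MIN_LEN = 20

TSV_COLUMNS = (
    "seq_id",
    "motif",
    "motif_class",
    "motif_len",
    "repeat_count",
    "start0",
    "end0",
    "length",
    "perfect",
)


@dataclass(frozen=True, order=True)
class SSRRecord:
    """One maximal microsatellite run.

    ``motif`` is phased at the run start (the first motif_len bases of the
    run); ``motif_class`` is the lexicographically minimal rotation of the
    motif on the same strand -- reverse complements are kept distinct, so
    TC and GA remain different classes.
    """

    seq_id: str
    start: int
    motif_len: int
    motif: str
    motif_class: str
    repeat_count: int
    end: int
    length: int
    perfect: bool


def enumerate_primitive_motifs(k: int) -> frozenset[str]:
    """All DNA k-mers whose fundamental period is exactly ``k`` (1 <= k <= 6).

    Sizes follow the standard necklace-style recurrence
    ``4**k - sum over proper divisors d|k of |primitive(d)|``:
    4, 12, 60, 240, 1020, 4020 for k = 1..6.
    """
    if not 1 <= k <= MAX_MOTIF_LEN:
        raise ValueError(f"motif length must be 1..{MAX_MOTIF_LEN}, got {k}")
    return frozenset(
        "".join(p)
        for p in itertools.product("ACGT", repeat=k)
        if is_primitive("".join(p))
    )


def min_repeats_for_threshold(motif_len: int, min_len: int) -> int:
    """Smallest number of full motif copies whose total length >= min_len."""
    if not 1 <= motif_len <= MAX_MOTIF_LEN:
        raise ValueError(f"motif length must be 1..{MAX_MOTIF_LEN}")
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    return math.ceil(min_len / motif_len)


def classify_perfection(
    record: SSRRecord, perfect_min_len: int = DEFAULT_PERFECT_MIN_LEN
) -> SSRRecord:
    """Return the record with its perfect flag set by the length rule."""
    return replace(record, perfect=record.length >= perfect_min_len)


def find_ssrs(
    seq: str,
    seq_id: str = "seq",
    min_len: int = DEFAULT_MIN_LEN,
    perfect_min_len: int = DEFAULT_PERFECT_MIN_LEN,
) -> list[SSRRecord]:
    """Find every maximal SSR run of total length >= ``min_len``.

    For each period k = 1..6 the sequence is scanned for maximal stretches
    satisfying ``s[i] == s[i-k]``; each stretch is trimmed to full motif
    copies (trailing partial periods are excluded).  A stretch is kept only
    when its start motif is primitive, which for runs of >= 2 copies
    guarantees (by Fine and Wilf) that k is the fundamental period.  Runs
    nested inside a longer reported run are dropped; overlapping non-nested
    runs of different periods are both reported.

    Records are sorted by (start, motif_len).
    """
    s = validate_dna(seq)
    n = len(s)
    records: list[SSRRecord] = []
    for k in range(1, MAX_MOTIF_LEN + 1):
        if n < 2 * k:
            continue
        j = k
        while j < n:
            if s[j] != s[j - k] or s[j] == "N":
                j += 1
                continue
            # maximal stretch of period-k agreement starting at j
            run_start = j - k
            while j < n and s[j] == s[j - k] and s[j] != "N":
                j += 1
            # periodic segment is [run_start, j); trim to full copies
            reps = (j - run_start) // k
            length = reps * k
            if length < min_len:
                continue
            motif = s[run_start : run_start + k]
            if "N" in motif or not is_primitive(motif):
                continue
            records.append(
                SSRRecord(
                    seq_id=seq_id,
                    start=run_start,
                    motif_len=k,
                    motif=motif,
                    motif_class=min_rotation(motif),
                    repeat_count=reps,
                    end=run_start + length,
                    length=length,
                    perfect=length >= perfect_min_len,
                )
            )
    return sorted(_drop_nested(records), key=lambda r: (r.start, r.motif_len))


def _drop_nested(records: Sequence[SSRRecord]) -> list[SSRRecord]:
    """Remove records whose interval is strictly inside another record's."""
    kept = []
    for r in records:
        nested = any(
            (o.start <= r.start and r.end <= o.end)
            and (o.start, o.end) != (r.start, r.end)
            for o in records
        )
        if not nested:
            kept.append(r)
    return kept


def find_ssrs_in_records(
    records: Iterable[tuple[str, str]],
    min_len: int = DEFAULT_MIN_LEN,
    perfect_min_len: int = DEFAULT_PERFECT_MIN_LEN,
) -> list[SSRRecord]:
    """Mine every (seq_id, sequence) pair and concatenate the results."""
    out: list[SSRRecord] = []
    for seq_id, seq in records:
        out.extend(find_ssrs(seq, seq_id, min_len, perfect_min_len))
    return out
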