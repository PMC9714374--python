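"""Physical mapping: cDNA anchoring, flank extraction, primer suggestion
and in-silico PCR.

The mapping route mirrors classic EST-SSR marker development: the SSR's
flanking sequence in the cDNA yields a primer pair, and the pair is
located on a genome by finding inward-facing matches of the forward
primer and the reverse complement of the reverse primer within a product
size bound (both orientations searched, since the marker's genomic
strand is unknown a priori).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from ._util import gc_percent, max_homopolymer, revcomp, validate_dna
from .mine import SSRRecord

DEFAULT_SEED_K = 21
DEFAULT_MIN_IDENTITY = 0.95
DEFAULT_FLANK_LEN = 150
DEFAULT_MAX_PRODUCT = 2000


@dataclass(frozen=True)
class Placement:
    """A cDNA located on the genome (0-based half-open, plus-strand
    coordinates; strand is the strand the cDNA matches)."""

    cdna_id: str
    chrom: str
    start: int
    end: int
    strand: str
    matched_fraction: float


@dataclass(frozen=True)
class FlankPair:
    left: str
    right: str
    left_truncated: bool
    right_truncated: bool


@dataclass(frozen=True)
class PrimerParams:
    min_len: int = 18
    max_len: int = 24
    gc_min: float = 40.0
    gc_max: float = 60.0
    max_homopolymer: int = 3


@dataclass(frozen=True)
class PrimerPair:
    name: str
    fwd: str
    rev: str
    source_ssr: Optional[SSRRecord] = None


@dataclass(frozen=True)
class AmpliconHit:
    chrom: str
    start: int
    end: int
    product_len: int
    orientation: str  # "fwd+" = forward primer matched the plus strand


def anchor_cdna(
    genome: Mapping[str, str],
    cdna: str,
    cdna_id: str = "cdna",
    k: int = DEFAULT_SEED_K,
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> list[Placement]:
    """Locate a cDNA on both strands of a genome.

    Exact substring embeddings are found directly (matched_fraction 1).
    Otherwise every shared k-mer seed is extended ungapped over the full
    cDNA length and placements reaching ``min_identity`` are kept.
    """
    if not genome:
        raise ValueError("empty genome")
    q = validate_dna(cdna)
    if len(q) < k:
        raise ValueError(f"cDNA shorter than seed size k={k}")
    placements: dict[tuple, Placement] = {}
    for chrom, cseq in genome.items():
        text = validate_dna(cseq)
        for strand, query in (("+", q), ("-", revcomp(q))):
            # exact fast path
            for pos in _find_all(text, query):
                placements[(chrom, pos, strand)] = Placement(
                    cdna_id, chrom, pos, pos + len(query), strand, 1.0
                )
            # seeded ungapped extension
            for qoff in range(0, len(query) - k + 1, k):
                seed = query[qoff : qoff + k]
                for pos in _find_all(text, seed):
                    gstart = pos - qoff
                    if gstart < 0 or gstart + len(query) > len(text):
                        continue
                    key = (chrom, gstart, strand)
                    if key in placements:
                        continue
                    window = text[gstart : gstart + len(query)]
                    ident = sum(a == b for a, b in zip(window, query)) / len(query)
                    if ident >= min_identity:
                        placements[key] = Placement(
                            cdna_id, chrom, gstart, gstart + len(query), strand, ident
                        )
    return sorted(
        placements.values(), key=lambda p: (p.chrom, p.start, p.strand)
    )


def _find_all(text: str, pattern: str) -> Iterable[int]:
    i = text.find(pattern)
    while i != -1:
        yield i
        i = text.find(pattern, i + 1)


def extract_flanks(
    sequence: str, ssr: SSRRecord, flank_len: int = DEFAULT_FLANK_LEN
) -> FlankPair:
    """SSR-flanking subsequences, truncated (and flagged) at sequence ends."""
    s = validate_dna(sequence)
    if not (0 <= ssr.start <= ssr.end <= len(s)):
        raise ValueError("SSR coordinates outside sequence")
    left = s[max(0, ssr.start - flank_len) : ssr.start]
    right = s[ssr.end : ssr.end + flank_len]
    return FlankPair(
        left=left,
        right=right,
        left_truncated=len(left) < flank_len,
        right_truncated=len(right) < flank_len,
    )


def _primer_ok(window: str, params: PrimerParams) -> bool:
    if set(window) - set("ACGT"):
        return False
    if not params.gc_min <= gc_percent(window) <= params.gc_max:
        return False
    return max_homopolymer(window) <= params.max_homopolymer


def suggest_primers(
    left: str,
    right: str,
    params: PrimerParams = PrimerParams(),
    name: str = "marker",
    source_ssr: Optional[SSRRecord] = None,
) -> Optional[PrimerPair]:
    """Deterministic primer choice: the innermost windows (closest to the
    SSR) on each flank that satisfy the length/GC/homopolymer constraints.

    The forward primer is read directly off the left flank; the reverse
    primer is the reverse complement of a right-flank window (5'->3' on
    the opposite strand, standard PCR convention).  Returns None when a
    flank admits no satisfying window.
    """
    if not left or not right:
        return None
    fwd = _innermost_window(left, params, from_right=True)
    rev_template = _innermost_window(right, params, from_right=False)
    if fwd is None or rev_template is None:
        return None
    return PrimerPair(name=name, fwd=fwd, rev=revcomp(rev_template), source_ssr=source_ssr)


def _innermost_window(
    flank: str, params: PrimerParams, from_right: bool
) -> Optional[str]:
    """Scan outward from the SSR-proximal end of a flank; for each offset
    try the shortest admissible length first."""
    n = len(flank)
    for offset in range(0, n - params.min_len + 1):
        for length in range(params.min_len, params.max_len + 1):
            if offset + length > n:
                break
            if from_right:
                window = flank[n - offset - length : n - offset]
            else:
                window = flank[offset : offset + length]
            if _primer_ok(window, params):
                return window
    return None


def _match_positions(text: str, pattern: str, max_mismatch: int) -> list[int]:
    if max_mismatch == 0:
        return list(_find_all(text, pattern))
    m = len(pattern)
    out = []
    for i in range(len(text) - m + 1):
        mm = 0
        for a, b in zip(text[i : i + m], pattern):
            if a != b:
                mm += 1
                if mm > max_mismatch:
                    break
        if mm <= max_mismatch:
            out.append(i)
    return out


def match_probe_pair(
    genome: Mapping[str, str],
    pair: PrimerPair,
    max_product: int = DEFAULT_MAX_PRODUCT,
    max_mismatch: int = 0,
) -> list[AmpliconHit]:
    """Predict PCR products of a primer pair on a genome.

    A hit is an interval where one primer matches the plus strand and the
    reverse complement of the other matches downstream of it (3' ends
    facing inward, non-overlapping footprints) within ``max_product``.
    Both orientations are reported: ``fwd+`` (forward primer on plus
    strand) and ``rev+``.
    """
    fwd = validate_dna(pair.fwd, allow_n=False)
    rev = validate_dna(pair.rev, allow_n=False)
    hits: list[AmpliconHit] = []
    for chrom, cseq in genome.items():
        text = validate_dna(cseq)
        for orientation, up, down in (
            ("fwd+", fwd, revcomp(rev)),
            ("rev+", rev, revcomp(fwd)),
        ):
            up_pos = _match_positions(text, up, max_mismatch)
            down_pos = _match_positions(text, down, max_mismatch)
            for i in up_pos:
                for j in down_pos:
                    if j < i + len(up):
                        continue
                    product = j + len(down) - i
                    if product <= max_product:
                        hits.append(
                            AmpliconHit(chrom, i, j + len(down), product, orientation)
                        )
    return sorted(hits, key=lambda h: (h.chrom, h.start, h.end, h.orientation))


def write_physical_map(
    hits_by_marker: Mapping[str, Sequence[AmpliconHit]],
) -> tuple[list[str], list[str]]:
    """Render per-marker amplicon hits as BED lines.

    Returns (bed_lines, ambiguous_marker_names).  Markers with several
    genomic hits emit one line per hit with a ``_1``, ``_2`` suffix and
    are listed as ambiguous.  Lines are sorted by (chrom, start).
    """
    rows: list[tuple[str, int, int, str]] = []
    ambiguous: list[str] = []
    for marker, hits in hits_by_marker.items():
        if not hits:
            continue
        if len(hits) == 1:
            h = hits[0]
            rows.append((h.chrom, h.start, h.end, marker))
        else:
            ambiguous.append(marker)
            for i, h in enumerate(sorted(hits, key=lambda h: (h.chrom, h.start)), 1):
                rows.append((h.chrom, h.start, h.end, f"{marker}_{i}"))
    rows.sort(key=lambda r: (r[0], r[1], r[2], r[3]))
    lines = [f"{c}\t{s}\t{e}\t{n}" for c, s, e, n in rows]
    return lines, ambiguous
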