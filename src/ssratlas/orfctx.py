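"""Longest-ORF finding and SSR positional context (5'UTR / CDS / 3'UTR).

A deterministic six-frame scan locates the longest ATG-to-stop open
reading frame in a cDNA; each SSR is then classified by where it starts
relative to that ORF on the ORF's strand.  Trinucleotide repeats inside
the CDS additionally get an in-frame flag, since triplet repeats that
keep the reading frame encode amino-acid homopolymer tracts.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional

from ._util import revcomp, validate_dna
from .mine import SSRRecord

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
DEFAULT_MIN_AA = 30


class Region(str, Enum):
    FIVE_UTR = "5UTR"
    CDS = "CDS"
    THREE_UTR = "3UTR"
    NONCODING = "noncoding"


@dataclass(frozen=True)
class OrfCall:
    """An ATG..stop span; start/end are 0-based half-open on ``strand``
    (i.e. on the reverse complement when strand is '-').  length_aa
    excludes the stop codon."""

    seq_id: str
    start: int
    end: int
    strand: str
    frame: int
    length_aa: int


@dataclass(frozen=True)
class SSRContext:
    ssr: SSRRecord
    region: Region
    in_frame: Optional[bool]
    boundary: bool


def find_longest_orf(
    seq: str, seq_id: str = "seq", min_aa: int = DEFAULT_MIN_AA
) -> Optional[OrfCall]:
    """Longest ORF (ATG through an in-frame stop) across all six frames.

    Ties are broken in favour of the plus strand, then the smallest
    start coordinate.  Returns None when no ORF reaches ``min_aa``
    codons (stop excluded).
    """
    s = validate_dna(seq)
    best: Optional[OrfCall] = None
    for strand in ("+", "-"):
        t = s if strand == "+" else revcomp(s)
        for frame in range(3):
            open_atg: Optional[int] = None
            for i in range(frame, len(t) - 2, 3):
                codon = t[i : i + 3]
                if open_atg is None and codon == "ATG":
                    open_atg = i
                elif open_atg is not None and codon in STOP_CODONS:
                    aa = (i - open_atg) // 3
                    if aa >= min_aa:
                        cand = OrfCall(seq_id, open_atg, i + 3, strand, frame, aa)
                        if best is None or _orf_key(cand) < _orf_key(best):
                            best = cand
                    open_atg = None
    return best


def _orf_key(o: OrfCall) -> tuple:
    # longest first; plus strand beats minus; then leftmost
    return (-o.length_aa, 0 if o.strand == "+" else 1, o.start)


def locate_ssr_in_gene(
    ssr: SSRRecord, orf: Optional[OrfCall], seq_len: Optional[int] = None
) -> SSRContext:
    """Classify an SSR relative to an ORF on the ORF's strand.

    The SSR's start position (on the ORF's strand) decides the region;
    runs spanning a region boundary are flagged.  ``seq_len`` is required
    for minus-strand ORFs to convert coordinates.  With no ORF the region
    is NONCODING.
    """
    if orf is None:
        return SSRContext(ssr, Region.NONCODING, None, False)
    if orf.strand == "-":
        if seq_len is None:
            raise ValueError("seq_len required to project onto a minus-strand ORF")
        lo, hi = seq_len - ssr.end, seq_len - ssr.start
    else:
        lo, hi = ssr.start, ssr.end
    if lo < orf.start:
        region = Region.FIVE_UTR
        boundary = hi > orf.start
    elif lo < orf.end:
        region = Region.CDS
        boundary = hi > orf.end
    else:
        region = Region.THREE_UTR
        boundary = False
    in_frame: Optional[bool] = None
    if region is Region.CDS and ssr.motif_len == 3:
        in_frame = (lo - orf.start) % 3 == 0
    return SSRContext(ssr, region, in_frame, boundary)
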