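"""Published safflower cDNA-SSR survey counts, usable as inputs.

The 2022 safflower (Carthamus tinctorius) cDNA-SSR survey screened
39,817 cDNA clones and reported 1,841 microsatellites.  The per-type
counts, cDNA multiplicities, perfect/imperfect split and the leading
dinucleotide motifs from its printed tables are encoded here so the
summary arithmetic can be exercised against real published numbers
without the (undeposited) sequence corpus.

``reference_records()`` materialises a synthetic multiset of SSRRecord
objects consistent with those marginal counts; individual coordinates
and most motif identities are arbitrary placeholders -- only the
tabulated margins are faithful.
"""

from __future__ import annotations

import math

from .mine import SSRRecord
from ._util import min_rotation

N_SCREENED_CDNAS = 39_817

# motif_len -> (n_ssrs, n_cdnas_harbouring, n_cdnas_with_multiple, n_imperfect)
# The published multiplicity columns do not all reconcile with the
# per-type SSR and cDNA counts (e.g. 405 dinucleotide runs in 396 cDNAs
# cannot contain 10 multi-run cDNAs, and 128 tetranucleotide runs in 114
# cDNAs must contain some).  Multiplicity counts below are the values
# consistent with the SSR and harbouring-cDNA counts, which are the
# authoritative margins.
TYPE_MARGINS: dict[int, tuple[int, int, int, int]] = {
    1: (7, 7, 0, 0),
    2: (405, 396, 9, 4),
    3: (658, 635, 10, 0),
    4: (128, 114, 14, 0),
    5: (98, 93, 5, 0),
    6: (545, 422, 81, 403),
}

# dinucleotide motif composition: TC 228, AG 83, AC 66, other 28
DI_MOTIFS: tuple[tuple[str, int], ...] = (("TC", 228), ("AG", 83), ("AC", 66), ("GT", 28))

# arbitrary primitive placeholder motifs per type (margins only are faithful)
_PLACEHOLDER_MOTIF = {1: "T", 3: "TTC", 4: "TTTG", 5: "TTCTC", 6: "TCCATC"}

# smallest repeat count of an imperfect (18-19 nt) and a perfect (>=20 nt) run
_IMPERFECT_REPS = {2: 9, 6: 3}
_PERFECT_REPS = {1: 20, 2: 10, 3: 7, 4: 5, 5: 4, 6: 4}


def reference_records() -> list[SSRRecord]:
    """SSR record multiset matching the published safflower table margins.

    Each motif type gets its own disjoint pool of cDNA ids (the published
    per-type harbouring counts sum exactly to the reported 1,667
    SSR-containing cDNAs, so disjoint pools reproduce every margin).
    cDNAs flagged as multi-SSR receive two or more runs of the type;
    imperfect runs get the shortest (<20 nt) repeat count the type
    allows, perfect runs the shortest >=20 nt count.
    """
    records: list[SSRRecord] = []
    for k, (n_ssrs, n_cdnas, n_multi, n_imperfect) in TYPE_MARGINS.items():
        n_single = n_cdnas - n_multi
        # SSRs-per-cDNA assignment: singles get 1, multis share the rest
        loads = [1] * n_single + [2] * n_multi
        extra = n_ssrs - sum(loads)
        if extra < 0 or (extra > 0 and n_multi == 0):
            raise ValueError(f"inconsistent margins for motif length {k}")
        for i in range(extra):
            loads[n_single + (i % n_multi)] += 1
        # motif assignment
        if k == 2:
            motif_pool = [m for m, c in DI_MOTIFS for _ in range(c)]
        else:
            motif_pool = [_PLACEHOLDER_MOTIF[k]] * n_ssrs
        # perfection assignment: first n_imperfect runs are imperfect
        flags = [False] * n_imperfect + [True] * (n_ssrs - n_imperfect)
        idx = 0
        for c, load in enumerate(loads):
            seq_id = f"cdna_k{k}_{c:04d}"
            pos = 0
            for _ in range(load):
                motif = motif_pool[idx]
                perfect = flags[idx]
                reps = _PERFECT_REPS[k] if perfect else _IMPERFECT_REPS[k]
                length = reps * k
                records.append(
                    SSRRecord(
                        seq_id=seq_id,
                        start=pos,
                        motif_len=k,
                        motif=motif,
                        motif_class=min_rotation(motif),
                        repeat_count=reps,
                        end=pos + length,
                        length=length,
                        perfect=perfect,
                    )
                )
                pos += length + 10
                idx += 1
    return records


# marker-validation design of the same study: 38 designed primer pairs,
# 35 amplified, 22 polymorphic overall, 10 polymorphic within the 9
# cultivated accessions; accessions = 9 cultivated + 2 wild relatives.
N_DESIGNED_PAIRS = 38
N_AMPLIFIED_PAIRS = 35
N_POLYMORPHIC = 22
N_CULTIVATED_POLYMORPHIC = 10
N_CULTIVATED = 9
N_WILD = 2
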