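"""Descriptive statistics over mined SSR records.

Reproduces the standard cDNA-SSR survey tables: per-type counts and
percentages, motif frequency within each type, repeat-number bins,
per-cDNA multiplicity, perfect/imperfect tallies, and corpus incidence.

Conventions fixed here so printed-table reproductions are bit-stable:

* all percentages use decimal half-up rounding;
* type-level percents are of the grand total (2 decimals), motif-level
  percents are within their type (1 decimal);
* the per-type "% cDNAs" column is harbouring-cDNA count / SSR count of
  that type x 100 (1 decimal), matching how such tables are printed;
* incidence is SSR count / number of screened sequences x 100
  (2 decimals); the denominator is an explicit argument because corpus
  sizes are reported ambiguously more often than not.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from ._util import round_half_up
from .mine import MAX_MOTIF_LEN, SSRRecord

TYPE_NAMES = {
    1: "mono",
    2: "di",
    3: "tri",
    4: "tetra",
    5: "penta",
    6: "hexa",
}

DEFAULT_REPEAT_BINS: tuple[tuple[int, int | None], ...] = (
    (3, 9),
    (10, 15),
    (16, 20),
    (21, None),
)


@dataclass
class SummaryTables:
    type_table: pd.DataFrame
    motif_table: pd.DataFrame
    repeat_bins: pd.DataFrame
    cdna_table: pd.DataFrame
    perfection_table: pd.DataFrame
    incidence: float


def type_frequency_table(records: Sequence[SSRRecord]) -> pd.DataFrame:
    """Counts and grand-total percents per motif length (1..6).

    Empty input yields zero counts with NaN percents rather than a
    division error.
    """
    counts = Counter(r.motif_len for r in records)
    total = sum(counts.values())
    rows = []
    for k in range(1, MAX_MOTIF_LEN + 1):
        c = counts.get(k, 0)
        pct = round_half_up(100.0 * c / total, 2) if total else float("nan")
        rows.append({"motif_len": k, "type": TYPE_NAMES[k], "count": c, "percent": pct})
    df = pd.DataFrame(rows).set_index("motif_len")
    df.attrs["total"] = total
    return df


def motif_frequency_table(
    records: Sequence[SSRRecord], group_by: str = "literal"
) -> pd.DataFrame:
    """Per-motif counts within each motif length, percent of that type.

    ``group_by="literal"`` counts motifs as phased at the run start;
    ``group_by="class"`` merges rotations of the same motif on the same
    strand (TC with CT, never TC with GA).
    """
    if group_by not in ("literal", "class"):
        raise ValueError("group_by must be 'literal' or 'class'")
    key = (lambda r: r.motif) if group_by == "literal" else (lambda r: r.motif_class)
    counts: dict[int, Counter] = defaultdict(Counter)
    for r in records:
        counts[r.motif_len][key(r)] += 1
    rows = []
    for k in sorted(counts):
        type_total = sum(counts[k].values())
        for motif, c in sorted(counts[k].items(), key=lambda kv: (-kv[1], kv[0])):
            rows.append(
                {
                    "motif_len": k,
                    "motif": motif,
                    "count": c,
                    "percent": round_half_up(100.0 * c / type_total, 1),
                }
            )
    return pd.DataFrame(rows, columns=["motif_len", "motif", "count", "percent"])


def repeat_number_distribution(
    records: Sequence[SSRRecord],
    bins: Sequence[tuple[int, int | None]] = DEFAULT_REPEAT_BINS,
) -> pd.DataFrame:
    """Histogram of repeat counts over half-open integer bins.

    Default bins [3,9], [10,15], [16,20], [>=21] partition the counts; an
    upper bound of None means unbounded.  Repeat counts below the first
    bin are a contract violation (they cannot reach the length threshold).
    """
    lo0 = bins[0][0]
    counts = [0] * len(bins)
    for r in records:
        if r.repeat_count < lo0:
            raise ValueError(
                f"repeat count {r.repeat_count} below minimum bin edge {lo0}"
            )
        for i, (lo, hi) in enumerate(bins):
            if r.repeat_count >= lo and (hi is None or r.repeat_count <= hi):
                counts[i] += 1
                break
        else:
            raise ValueError(f"repeat count {r.repeat_count} falls in no bin")
    total = sum(counts)
    rows = []
    for (lo, hi), c in zip(bins, counts):
        label = f"{lo}-{hi}" if hi is not None else f">={lo}"
        pct = round_half_up(100.0 * c / total, 1) if total else float("nan")
        rows.append({"bin": label, "count": c, "percent": pct})
    return pd.DataFrame(rows).set_index("bin")


def cdna_distribution(
    records: Sequence[SSRRecord], n_screened: int
) -> tuple[pd.DataFrame, float]:
    """Per-type cDNA multiplicity table and overall corpus incidence.

    Returns (table, incidence) where incidence = 100 * n_records /
    n_screened rounded to 2 decimals.  The table carries, per motif
    length: SSR count, number of distinct cDNAs harbouring >=1 run of
    that type, that number as a percent of the type's SSR count, and the
    counts of cDNAs with exactly one / more than one run of the type.
    """
    distinct = {r.seq_id for r in records}
    if n_screened < len(distinct):
        raise ValueError(
            f"n_screened={n_screened} below the {len(distinct)} distinct sequence ids"
        )
    per_type_cdna: dict[int, Counter] = defaultdict(Counter)
    for r in records:
        per_type_cdna[r.motif_len][r.seq_id] += 1
    rows = []
    for k in range(1, MAX_MOTIF_LEN + 1):
        c = per_type_cdna.get(k, Counter())
        n_ssrs = sum(c.values())
        n_cdnas = len(c)
        n_multi = sum(1 for v in c.values() if v > 1)
        pct = round_half_up(100.0 * n_cdnas / n_ssrs, 1) if n_ssrs else float("nan")
        rows.append(
            {
                "motif_len": k,
                "type": TYPE_NAMES[k],
                "n_ssrs": n_ssrs,
                "n_cdnas": n_cdnas,
                "pct_cdnas": pct,
                "n_single": n_cdnas - n_multi,
                "n_multi": n_multi,
            }
        )
    df = pd.DataFrame(rows).set_index("motif_len")
    df.attrs["n_distinct_cdnas"] = len(distinct)
    df.attrs["pct_screened_with_ssr"] = (
        round_half_up(100.0 * len(distinct) / n_screened, 2) if n_screened else float("nan")
    )
    incidence = round_half_up(100.0 * len(records) / n_screened, 2)
    return df, incidence


def perfection_table(records: Sequence[SSRRecord]) -> pd.DataFrame:
    """Per-type imperfect/perfect counts with a Sum row."""
    imp = Counter()
    per = Counter()
    for r in records:
        (per if r.perfect else imp)[r.motif_len] += 1
    rows = []
    for k in range(1, MAX_MOTIF_LEN + 1):
        rows.append(
            {
                "type": TYPE_NAMES[k],
                "imperfect": imp.get(k, 0),
                "perfect": per.get(k, 0),
            }
        )
    rows.append(
        {
            "type": "sum",
            "imperfect": sum(imp.values()),
            "perfect": sum(per.values()),
        }
    )
    return pd.DataFrame(rows).set_index("type")


def summarize_all(
    records: Sequence[SSRRecord],
    n_screened: int,
    group_by: str = "literal",
    bins: Sequence[tuple[int, int | None]] = DEFAULT_REPEAT_BINS,
) -> SummaryTables:
    """Compute every summary table in one pass-friendly call."""
    cdna_table, incidence = cdna_distribution(records, n_screened)
    return SummaryTables(
        type_table=type_frequency_table(records),
        motif_table=motif_frequency_table(records, group_by),
        repeat_bins=repeat_number_distribution(records, bins),
        cdna_table=cdna_table,
        perfection_table=perfection_table(records),
        incidence=incidence,
    )
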