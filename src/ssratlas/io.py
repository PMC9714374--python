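"""File I/O: FASTA via Biopython, TSV table readers/writers.

Human-readable SSR tables carry both 0-based half-open coordinates
(BED-compatible) and nothing else exotic; all tables are plain TSV with
header rows.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .mine import SSRRecord, TSV_COLUMNS
from ._util import min_rotation


def read_fasta(path) -> list[tuple[str, str]]:
    """Read a (possibly gzipped) FASTA into (id, sequence) tuples."""
    path = Path(path)
    if path.suffix == ".gz":
        with gzip.open(path, "rt") as fh:
            return [(r.id, str(r.seq).upper()) for r in SeqIO.parse(fh, "fasta")]
    return [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: Iterable[tuple[str, str]], path) -> None:
    """Write records wrapped at 70 columns."""
    seqs = [SeqRecord(Seq(s), id=i, description="") for i, s in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=70)
        writer.write_file(seqs)


def ssrs_to_frame(records: Sequence[SSRRecord]) -> pd.DataFrame:
    rows = [
        {
            "seq_id": r.seq_id,
            "motif": r.motif,
            "motif_class": r.motif_class,
            "motif_len": r.motif_len,
            "repeat_count": r.repeat_count,
            "start0": r.start,
            "end0": r.end,
            "length": r.length,
            "perfect": r.perfect,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=list(TSV_COLUMNS))


def write_ssrs(records: Sequence[SSRRecord], path) -> None:
    ssrs_to_frame(records).to_csv(path, sep="\t", index=False)


def read_ssrs(path) -> list[SSRRecord]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            SSRRecord(
                seq_id=str(row.seq_id),
                start=int(row.start0),
                motif_len=int(row.motif_len),
                motif=str(row.motif),
                motif_class=min_rotation(str(row.motif)),
                repeat_count=int(row.repeat_count),
                end=int(row.end0),
                length=int(row.length),
                perfect=bool(row.perfect),
            )
        )
    return out


def write_table(df: pd.DataFrame, path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index)


def write_lines(lines: Iterable[str], path) -> None:
    with open(path, "w") as fh:
        for line in lines:
            fh.write(line + "\n")
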