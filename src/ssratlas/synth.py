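"""Synthetic cDNA corpora, genomes, genotype tables and annotations with
known planted truth.

The corpus generator emulates a plant cDNA collection carrying
microsatellites: background sequence is i.i.d. uniform with homopolymers
capped and accidental repeat runs rejected, and each planted SSR is a
clean tandem run of a primitive 1-6 nt motif flanked by guard bases that
break its periodicity, so maximal-run coordinates are unambiguous and
the truth table is exact.  Default densities and motif-type weights
follow the published safflower cDNA-SSR survey (about 4.6 SSRs per 100
cDNAs; type mix dominated by tri- and hexanucleotides).

All generators are deterministic under their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._util import revcomp
from .enrich import TermMap
from .markers import GenotypeMatrix
from .mine import enumerate_primitive_motifs, find_ssrs
from .reference import TYPE_MARGINS

BASES = "ACGT"

# per-type SSR mix of the safflower survey (mono..hexa shares of 1,841)
DEFAULT_TYPE_WEIGHTS: tuple[float, ...] = tuple(
    TYPE_MARGINS[k][0] / sum(v[0] for v in TYPE_MARGINS.values()) for k in range(1, 7)
)

# observed repeat numbers ran 3..28; ranges keep every planted run >=18 nt
DEFAULT_REPEAT_RANGES: dict[int, tuple[int, int]] = {
    1: (18, 28),
    2: (9, 28),
    3: (6, 20),
    4: (5, 15),
    5: (4, 12),
    6: (3, 16),
}


class SizingError(ValueError):
    """A sequence is too short to host the SSRs requested for it."""


@dataclass(frozen=True)
class PlantedSSR:
    seq_id: str
    motif: str
    repeat_count: int
    start: int

    @property
    def length(self) -> int:
        return len(self.motif) * self.repeat_count

    @property
    def end(self) -> int:
        return self.start + self.length


@dataclass
class SynthConfig:
    n_sequences: int = 500
    length_range: tuple[int, int] = (300, 1500)
    ssr_density: float = 0.046
    motif_type_weights: tuple[float, ...] = DEFAULT_TYPE_WEIGHTS
    repeat_count_range: dict[int, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_REPEAT_RANGES)
    )
    background_max_homopolymer: int = 8
    min_planting_len: int = 18
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sequences < 0:
            raise ValueError("n_sequences must be >= 0")
        lo, hi = self.length_range
        if not 1 <= lo <= hi:
            raise ValueError("invalid length_range")
        if len(self.motif_type_weights) != 6 or any(
            w < 0 for w in self.motif_type_weights
        ):
            raise ValueError("motif_type_weights must be 6 nonnegative values")
        if sum(self.motif_type_weights) <= 0:
            raise ValueError("motif_type_weights must sum to > 0")
        if self.ssr_density < 0:
            raise ValueError("ssr_density must be >= 0")
        if not 1 <= self.background_max_homopolymer < 18:
            raise ValueError("background_max_homopolymer must be in [1, 18)")
        for k, (rlo, rhi) in self.repeat_count_range.items():
            if rlo < 3 or rlo > rhi:
                raise ValueError(f"bad repeat range for motif length {k}")
            if rlo * k < self.min_planting_len:
                raise ValueError(
                    f"repeat range for motif length {k} cannot reach "
                    f"min_planting_len={self.min_planting_len}"
                )


_MOTIF_CACHE: dict[int, list[str]] = {}


def _motifs(k: int) -> list[str]:
    if k not in _MOTIF_CACHE:
        _MOTIF_CACHE[k] = sorted(enumerate_primitive_motifs(k))
    return _MOTIF_CACHE[k]


def _random_background(rng: np.random.Generator, length: int, max_homo: int) -> str:
    """i.i.d. uniform bases with homopolymers capped at ``max_homo``."""
    out: list[str] = []
    run = 0
    prev = ""
    while len(out) < length:
        b = BASES[rng.integers(4)]
        if b == prev:
            if run >= max_homo:
                continue
            run += 1
        else:
            run = 1
            prev = b
        out.append(b)
    return "".join(out)


def _guard_base(rng: np.random.Generator, *forbidden: str) -> str:
    choices = [b for b in BASES if b not in forbidden]
    return choices[rng.integers(len(choices))]


def _build_sequence(
    rng: np.random.Generator,
    seq_id: str,
    length: int,
    n_ssrs: int,
    config: SynthConfig,
) -> tuple[str, list[PlantedSSR]]:
    """One attempt at a sequence with ``n_ssrs`` planted runs."""
    weights = np.asarray(config.motif_type_weights, dtype=float)
    weights = weights / weights.sum()
    plans: list[tuple[str, int]] = []
    for _ in range(n_ssrs):
        k = int(rng.choice(np.arange(1, 7), p=weights))
        rlo, rhi = config.repeat_count_range[k]
        reps = int(rng.integers(rlo, rhi + 1))
        motif = _motifs(k)[rng.integers(len(_motifs(k)))]
        plans.append((motif, reps))
    ssr_total = sum(len(m) * r for m, r in plans)
    # each run needs >=1 background base on each side for its guards
    min_needed = ssr_total + 2 * n_ssrs
    if min_needed > length:
        raise SizingError(
            f"sequence {seq_id} of length {length} cannot host {n_ssrs} "
            f"SSRs totalling {ssr_total} nt (needs >= {min_needed})"
        )
    # split the background into n_ssrs+1 gaps, inner gaps >= 2 so that
    # neighbouring runs never share a guard base
    n_gaps = n_ssrs + 1
    bg_total = length - ssr_total
    mins = [1] + [2] * (n_gaps - 2) + [1] if n_gaps > 1 else [bg_total]
    if n_ssrs == 0:
        gaps = [bg_total]
    else:
        spare = bg_total - sum(mins)
        if spare < 0:
            raise SizingError(f"sequence {seq_id}: background too small for guards")
        cuts = np.sort(rng.integers(0, spare + 1, size=n_gaps - 1))
        shares = np.diff(np.concatenate(([0], cuts, [spare])))
        gaps = [m + int(s) for m, s in zip(mins, shares)]
    parts: list[str] = []
    truth: list[PlantedSSR] = []
    pos = 0
    for i, (motif, reps) in enumerate(plans):
        bg = _random_background(rng, gaps[i], config.background_max_homopolymer)
        # guard: base immediately before the run must break left extension
        bg = bg[:-1] + _guard_base(rng, motif[-1], bg[-2] if len(bg) > 1 else "")
        parts.append(bg)
        pos += len(bg)
        run = motif * reps
        truth.append(PlantedSSR(seq_id=seq_id, motif=motif, repeat_count=reps, start=pos))
        parts.append(run)
        pos += len(run)
        # right guard becomes the first base of the next background chunk
        parts.append(_guard_base(rng, motif[0]))
        pos += 1
        gaps[i + 1] -= 1
    parts.append(
        _random_background(rng, gaps[-1], config.background_max_homopolymer)
    )
    return "".join(parts), truth


def gen_cdna_corpus(
    config: SynthConfig,
) -> tuple[list[tuple[str, str]], list[PlantedSSR]]:
    """Generate (seq_id, sequence) records plus the planted-SSR truth.

    Every generated sequence is verified with the miner: the set of
    detected maximal runs must equal the planted set exactly (this also
    certifies the background contains no accidental >=18 nt run).
    Sequences failing verification are resampled; the construction makes
    failures rare, so a persistent failure raises.
    """
    rng = np.random.default_rng(config.seed)
    records: list[tuple[str, str]] = []
    truth: list[PlantedSSR] = []
    for i in range(config.n_sequences):
        seq_id = f"cdna{i:05d}"
        length = int(rng.integers(config.length_range[0], config.length_range[1] + 1))
        n_ssrs = int(rng.poisson(config.ssr_density))
        for attempt in range(60):
            try:
                seq, planted = _build_sequence(rng, seq_id, length, n_ssrs, config)
            except SizingError:
                if attempt >= 10:
                    raise
                continue
            mined = {
                (r.start, r.motif, r.repeat_count)
                for r in find_ssrs(seq, seq_id, min_len=config.min_planting_len)
            }
            wanted = {(p.start, p.motif, p.repeat_count) for p in planted}
            if mined == wanted:
                records.append((seq_id, seq))
                truth.extend(planted)
                break
        else:
            raise RuntimeError(f"could not build a clean sequence for {seq_id}")
    return records, truth


def gen_genome(
    corpus: Sequence[tuple[str, str]],
    flank_len: int = 500,
    n_chromosomes: int = 3,
    seed: int = 0,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Embed each cDNA exactly once in a synthetic genome.

    cDNAs are assigned to chromosomes round-robin in input order; each is
    embedded on a random strand, preceded and followed by a random spacer
    of ``flank_len`` nt.  Returns (chromosome records, placement truth)
    where the truth table has columns cdna_id, chrom, start, strand
    (0-based, plus-strand coordinates).
    """
    if not corpus:
        raise ValueError("empty corpus")
    if n_chromosomes < 1:
        raise ValueError("need at least one chromosome")
    rng = np.random.default_rng(seed)
    chrom_parts: list[list[str]] = [[] for _ in range(n_chromosomes)]
    chrom_pos = [0] * n_chromosomes
    rows = []
    for i, (cdna_id, seq) in enumerate(corpus):
        c = i % n_chromosomes
        spacer = _random_background(rng, flank_len, 8) if flank_len else ""
        strand = "+" if rng.random() < 0.5 else "-"
        embedded = seq if strand == "+" else revcomp(seq)
        chrom_parts[c].append(spacer)
        chrom_pos[c] += len(spacer)
        rows.append(
            {
                "cdna_id": cdna_id,
                "chrom": f"chr{c + 1}",
                "start": chrom_pos[c],
                "end": chrom_pos[c] + len(embedded),
                "strand": strand,
            }
        )
        chrom_parts[c].append(embedded)
        chrom_pos[c] += len(embedded)
    genome = []
    for c in range(n_chromosomes):
        tail = _random_background(rng, flank_len, 8) if flank_len else ""
        seq = "".join(chrom_parts[c]) + tail
        if seq:
            genome.append((f"chr{c + 1}", seq))
    return genome, pd.DataFrame(rows)


def gen_genotypes(
    n_markers: int,
    n_group1: int = 9,
    n_group2: int = 2,
    divergence: float = 22 / 35,
    seed: int = 0,
    group1_polymorphic_fraction: float = 0.5,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Genotype table with planted group-diagnostic (polymorphic) markers.

    Exactly ``round(divergence * n_markers)`` markers are diagnostic:
    group 1 carries allele 1 and group 2 allele 2.  Of those, a
    ``group1_polymorphic_fraction`` share additionally segregate within
    group 1 (a random subset of group-1 accessions carries allele 3), so
    markers can show 2-3 alleles as agarose panels typically do.  The
    remaining markers are monomorphic.  Returns (matrix, truth) where the
    truth table flags each marker polymorphic / group1_polymorphic.
    """
    if n_markers < 1:
        raise ValueError("n_markers must be >= 1")
    if not 0 <= divergence <= 1:
        raise ValueError("divergence must be in [0, 1]")
    if n_group1 < 1 or n_group2 < 1:
        raise ValueError("both groups need at least one accession")
    rng = np.random.default_rng(seed)
    n_acc = n_group1 + n_group2
    accessions = [f"cv{i + 1}" for i in range(n_group1)] + [
        f"wild{i + 1}" for i in range(n_group2)
    ]
    groups = pd.Series(
        ["cultivated"] * n_group1 + ["wild"] * n_group2, index=accessions, name="group"
    )
    marker_names = [f"m{j + 1:03d}" for j in range(n_markers)]
    n_div = round(divergence * n_markers)
    div_idx = sorted(rng.choice(n_markers, size=n_div, replace=False).tolist())
    n_g1poly = round(group1_polymorphic_fraction * n_div)
    g1poly_idx = set(
        np.asarray(div_idx)[
            sorted(rng.choice(n_div, size=n_g1poly, replace=False).tolist())
        ].tolist()
        if n_g1poly
        else []
    )
    calls = np.ones((n_acc, n_markers))
    truth_rows = []
    for j in range(n_markers):
        diagnostic = j in div_idx
        g1poly = j in g1poly_idx and n_group1 >= 2
        if diagnostic:
            calls[n_group1:, j] = 2.0
            if g1poly:
                n_alt = int(rng.integers(1, n_group1))  # proper nonempty subset
                alt = rng.choice(n_group1, size=n_alt, replace=False)
                calls[alt, j] = 3.0
        truth_rows.append(
            {
                "marker": marker_names[j],
                "polymorphic": diagnostic,
                "group1_polymorphic": g1poly,
            }
        )
    gm = GenotypeMatrix(
        calls=pd.DataFrame(calls, index=accessions, columns=marker_names),
        groups=groups,
    )
    return gm, pd.DataFrame(truth_rows).set_index("marker")


def gen_annotation(
    n_genes: int,
    n_terms: int,
    enriched_term_size: int,
    selected_overlap: int,
    n_selected: Optional[int] = None,
    seed: int = 0,
) -> tuple[TermMap, frozenset[str], str]:
    """Annotation with one planted enriched term.

    Exactly one term (returned as the third element) overlaps the
    selected gene set by ``selected_overlap`` genes; every other term is
    a uniform random draw of ``enriched_term_size`` genes, so its overlap
    sits at random expectation.  ``n_selected`` defaults to
    ``selected_overlap``.
    """
    if enriched_term_size > n_genes:
        raise ValueError("enriched_term_size exceeds the universe")
    if n_terms < 1:
        raise ValueError("need at least one term")
    n_sel = selected_overlap if n_selected is None else n_selected
    if selected_overlap > min(enriched_term_size, n_sel):
        raise ValueError(
            "selected_overlap exceeds min(enriched_term_size, n_selected)"
        )
    if n_sel > n_genes:
        raise ValueError("n_selected exceeds the universe")
    rng = np.random.default_rng(seed)
    genes = [f"g{i:05d}" for i in range(n_genes)]
    universe = frozenset(genes)
    selected = frozenset(
        genes[i] for i in rng.choice(n_genes, size=n_sel, replace=False)
    )
    sel_list = sorted(selected)
    out_list = sorted(universe - selected)
    planted_in = [
        sel_list[i]
        for i in rng.choice(len(sel_list), size=selected_overlap, replace=False)
    ]
    n_out = enriched_term_size - selected_overlap
    planted_out = (
        [out_list[i] for i in rng.choice(len(out_list), size=n_out, replace=False)]
        if n_out
        else []
    )
    terms: dict[str, frozenset[str]] = {}
    planted_term = "T0000"
    terms[planted_term] = frozenset(planted_in + planted_out)
    for t in range(1, n_terms):
        members = rng.choice(n_genes, size=enriched_term_size, replace=False)
        terms[f"T{t:04d}"] = frozenset(genes[i] for i in members)
    return TermMap(terms=terms, universe=universe), selected, planted_term
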