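"""End-to-end orchestration: mine -> summarize -> orfctx -> mappcr ->
markers -> enrich from a single flat-text config, with a checksum
manifest so reruns are verifiably byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import io, mine, summarize, orfctx, mappcr, markers, enrich, synth

log = logging.getLogger("ssratlas")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class RunConfig:
    cdna_fasta: str = ""
    out_dir: str = "run"
    genome_fasta: Optional[str] = None
    genotypes_csv: Optional[str] = None
    annotation_tsv: Optional[str] = None
    selected_genes: Optional[str] = None  # newline-separated gene ids
    universe_genes: Optional[str] = None  # newline-separated; default: annotated genes
    min_len: int = 18
    perfect_min_len: int = 20
    n_screened: Optional[int] = None
    min_aa: int = 30
    flank_len: int = 150
    max_product: int = 2000
    max_markers: int = 50
    primer_min_len: int = 18
    primer_max_len: int = 24
    primer_gc_min: float = 40.0
    primer_gc_max: float = 60.0
    primer_max_homopolymer: int = 3
    polymorphism_denominator: Optional[int] = None
    alpha: float = 0.05
    seed: int = 1

    def __post_init__(self) -> None:
        if self.min_len < 1 or self.perfect_min_len < 1:
            raise ValueError("length thresholds must be positive")
        if self.perfect_min_len < self.min_len:
            log.warning(
                "perfect_min_len (%d) < min_len (%d): every run will be perfect",
                self.perfect_min_len,
                self.min_len,
            )

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Parse a flat key = value config file ('#' starts a comment)."""
        kwargs = {}
        types = {f.name: f.type for f in cls.__dataclass_fields__.values()}
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"bad config line: {raw!r}")
            key, val = (x.strip() for x in line.split("=", 1))
            if key not in cls.__dataclass_fields__:
                raise ValueError(f"unknown config key: {key}")
            kwargs[key] = _coerce(key, val)
        return cls(**kwargs)


def _coerce(key: str, val: str):
    if val.lower() in ("none", ""):
        return None
    for caster in (int, float):
        try:
            num = caster(val)
        except ValueError:
            continue
        if caster is int and any(
            key.startswith(p) for p in ("primer_gc", "alpha")
        ):
            return float(num)
        return num
    return val


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: RunConfig) -> dict:
    """Run every configured stage; returns the manifest dict.

    Stage outputs land under ``config.out_dir``; any stage failure
    raises StageError naming the stage.  Identical config + inputs
    produce byte-identical outputs and manifest checksums.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    # --- mine -------------------------------------------------------
    try:
        corpus = io.read_fasta(config.cdna_fasta)
        records = mine.find_ssrs_in_records(
            corpus, config.min_len, config.perfect_min_len
        )
        io.write_ssrs(records, out / "ssrs.tsv")
        written.append(out / "ssrs.tsv")
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001 - stage boundary
        raise StageError("mine", str(e)) from e

    # --- summarize --------------------------------------------------
    try:
        n_screened = config.n_screened or len(corpus)
        tables = summarize.summarize_all(records, n_screened)
        io.write_table(tables.type_table, out / "type_table.tsv")
        io.write_table(tables.motif_table, out / "motif_table.tsv", index=False)
        io.write_table(tables.repeat_bins, out / "repeat_bins.tsv")
        io.write_table(tables.cdna_table, out / "cdna_table.tsv")
        io.write_table(tables.perfection_table, out / "perfection_table.tsv")
        (out / "incidence.json").write_text(
            json.dumps(
                {"n_ssrs": len(records), "n_screened": n_screened,
                 "incidence_percent": tables.incidence},
                indent=2,
            )
            + "\n"
        )
        written += [
            out / "type_table.tsv",
            out / "motif_table.tsv",
            out / "repeat_bins.tsv",
            out / "cdna_table.tsv",
            out / "perfection_table.tsv",
            out / "incidence.json",
        ]
    except Exception as e:
        raise StageError("summarize", str(e)) from e

    # --- orfctx -----------------------------------------------------
    try:
        seqs = dict(corpus)
        rows = []
        orfs = {sid: orfctx.find_longest_orf(s, sid, config.min_aa) for sid, s in seqs.items()}
        for r in records:
            ctx = orfctx.locate_ssr_in_gene(r, orfs[r.seq_id], len(seqs[r.seq_id]))
            orf = orfs[r.seq_id]
            rows.append(
                {
                    "seq_id": r.seq_id,
                    "ssr_start0": r.start,
                    "motif": r.motif,
                    "orf_start": orf.start if orf else "",
                    "orf_end": orf.end if orf else "",
                    "strand": orf.strand if orf else "",
                    "frame": orf.frame if orf else "",
                    "region": ctx.region.value,
                    "in_frame": "" if ctx.in_frame is None else ctx.in_frame,
                    "boundary": ctx.boundary,
                }
            )
        pd.DataFrame(rows).to_csv(out / "ssr_context.tsv", sep="\t", index=False)
        written.append(out / "ssr_context.tsv")
    except Exception as e:
        raise StageError("orfctx", str(e)) from e

    # --- mappcr -----------------------------------------------------
    if config.genome_fasta is not None:
        try:
            genome = dict(io.read_fasta(config.genome_fasta))
            if not genome:
                raise ValueError("genome FASTA is empty")
            params = mappcr.PrimerParams(
                min_len=config.primer_min_len,
                max_len=config.primer_max_len,
                gc_min=config.primer_gc_min,
                gc_max=config.primer_gc_max,
                max_homopolymer=config.primer_max_homopolymer,
            )
            prim_rows = []
            hits_by_marker: dict[str, list[mappcr.AmpliconHit]] = {}
            for i, r in enumerate(records[: config.max_markers]):
                name = f"ssr{i + 1:03d}"
                flanks = mappcr.extract_flanks(seqs[r.seq_id], r, config.flank_len)
                pair = mappcr.suggest_primers(
                    flanks.left, flanks.right, params, name=name, source_ssr=r
                )
                if pair is None:
                    continue
                hits = mappcr.match_probe_pair(genome, pair, config.max_product)
                hits_by_marker[name] = hits
                prim_rows.append(
                    {
                        "name": name,
                        "seq_id": r.seq_id,
                        "motif": r.motif,
                        "fwd": pair.fwd,
                        "rev": pair.rev,
                        "n_hits": len(hits),
                        "product_len": hits[0].product_len if len(hits) == 1 else "",
                    }
                )
            pd.DataFrame(prim_rows).to_csv(out / "primers.tsv", sep="\t", index=False)
            bed, ambiguous = mappcr.write_physical_map(hits_by_marker)
            io.write_lines(bed, out / "physical_map.bed")
            if ambiguous:
                log.warning("markers with multiple genomic hits: %s", ambiguous)
            written += [out / "primers.tsv", out / "physical_map.bed"]
        except Exception as e:
            raise StageError("mappcr", str(e)) from e

    # --- markers ----------------------------------------------------
    if config.genotypes_csv is not None:
        try:
            gm = markers.GenotypeMatrix.from_csv(config.genotypes_csv)
            report = markers.score_polymorphism(
                gm, denominator=config.polymorphism_denominator
            )
            io.write_table(report.per_marker, out / "polymorphism.tsv")
            result = markers.bicluster(gm)
            io.write_table(result.ordered_matrix, out / "heatmap_matrix.tsv")
            io.write_table(result.groups_k2.to_frame(), out / "groups_k2.tsv")
            io.write_lines(
                [markers.linkage_to_newick(result.accession_linkage, list(gm.calls.index))]
                if result.accession_linkage.size
                else [],
                out / "accessions.nwk",
            )
            io.write_lines(
                [
                    markers.linkage_to_newick(
                        result.marker_linkage,
                        [m for m in gm.calls.columns if m not in result.dropped_markers],
                    )
                ]
                if result.marker_linkage.size
                else [],
                out / "markers.nwk",
            )
            written += [
                out / "polymorphism.tsv",
                out / "heatmap_matrix.tsv",
                out / "groups_k2.tsv",
                out / "accessions.nwk",
                out / "markers.nwk",
            ]
        except Exception as e:
            raise StageError("markers", str(e)) from e

    # --- enrich -----------------------------------------------------
    if config.annotation_tsv is not None and config.selected_genes is not None:
        try:
            universe = None
            if config.universe_genes is not None:
                universe = [
                    g.strip()
                    for g in Path(config.universe_genes).read_text().splitlines()
                    if g.strip()
                ]
            tm = enrich.TermMap.from_tsv(config.annotation_tsv, universe=universe)
            selected = [
                g.strip()
                for g in Path(config.selected_genes).read_text().splitlines()
                if g.strip()
            ]
            res = enrich.hypergeom_enrichment(selected, tm, alpha=config.alpha)
            res.to_csv(out / "enrichment.tsv", sep="\t", index=False)
            written.append(out / "enrichment.tsv")
        except Exception as e:
            raise StageError("enrich", str(e)) from e

    manifest = {
        "config": asdict(config),
        "n_ssrs": len(records),
        "outputs": {p.name: _sha256(p) for p in sorted(written)},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def make_demo_inputs(out_dir, seed: int = 1, n_sequences: int = 60) -> RunConfig:
    """Generate a self-contained synthetic input set and its RunConfig."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = synth.SynthConfig(
        n_sequences=n_sequences, length_range=(400, 900), ssr_density=1.0, seed=seed
    )
    corpus, _truth = synth.gen_cdna_corpus(cfg)
    io.write_fasta(corpus, out / "cdna.fa")
    genome, placements = synth.gen_genome(corpus, flank_len=300, n_chromosomes=2, seed=seed + 1)
    io.write_fasta(genome, out / "genome.fa")
    placements.to_csv(out / "placements_truth.tsv", sep="\t", index=False)
    gm, truth = synth.gen_genotypes(35, 9, 2, divergence=22 / 35, seed=seed + 2)
    gm.to_csv(out / "genotypes.csv")
    truth.to_csv(out / "genotypes_truth.tsv", sep="\t")
    tm, selected, _term = synth.gen_annotation(
        400, 30, enriched_term_size=25, selected_overlap=15, n_selected=40, seed=seed + 3
    )
    rows = [(g, t) for t, genes in sorted(tm.terms.items()) for g in sorted(genes)]
    pd.DataFrame(rows, columns=["gene_id", "term_id"]).to_csv(
        out / "annotation.tsv", sep="\t", index=False
    )
    (out / "selected.txt").write_text("\n".join(sorted(selected)) + "\n")
    (out / "universe.txt").write_text("\n".join(sorted(tm.universe)) + "\n")
    return RunConfig(
        cdna_fasta=str(out / "cdna.fa"),
        out_dir=str(out / "run"),
        genome_fasta=str(out / "genome.fa"),
        genotypes_csv=str(out / "genotypes.csv"),
        annotation_tsv=str(out / "annotation.tsv"),
        selected_genes=str(out / "selected.txt"),
        universe_genes=str(out / "universe.txt"),
        polymorphism_denominator=35,
        seed=seed,
    )
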