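"""Anchoring, flank extraction, primer suggestion and in-silico PCR."""

import pytest

from ssratlas import mappcr, synth
from ssratlas.mappcr import PrimerPair, PrimerParams
from ssratlas.mine import find_ssrs, find_ssrs_in_records
from ssratlas.synth import SynthConfig

from oracles import rc, brute_amplicons
from conftest import random_dna


@pytest.fixture(scope="module")
def planted_world():
    cfg = SynthConfig(n_sequences=12, length_range=(500, 900), ssr_density=1.2, seed=31)
    corpus, truth = synth.gen_cdna_corpus(cfg)
    genome, placements = synth.gen_genome(corpus, flank_len=250, n_chromosomes=3, seed=32)
    return corpus, truth, dict(genome), placements


class TestAnchor:
    def test_planted_placements_recovered(self, planted_world):
        corpus, _, genome, placements = planted_world
        seqs = dict(corpus)
        for row in placements.itertuples():
            hits = mappcr.anchor_cdna(genome, seqs[row.cdna_id], row.cdna_id)
            assert len(hits) == 1
            h = hits[0]
            assert (h.chrom, h.start, h.strand) == (row.chrom, row.start, row.strand)
            assert h.matched_fraction == 1.0

    def test_absent_cdna_gives_empty(self, planted_world, rng):
        _, _, genome, _ = planted_world
        probe = random_dna(rng, 120)
        assert mappcr.anchor_cdna(genome, probe) == []

    def test_mismatched_embedding_found_by_extension(self, rng):
        cdna = random_dna(rng, 300)
        mutated = cdna[:150] + ("A" if cdna[150] != "A" else "C") + cdna[151:]
        genome = {"chr1": random_dna(rng, 200) + mutated + random_dna(rng, 200)}
        hits = mappcr.anchor_cdna(genome, cdna)
        assert len(hits) == 1
        assert hits[0].start == 200
        assert hits[0].matched_fraction == pytest.approx(299 / 300)

    def test_empty_genome_rejected(self):
        with pytest.raises(ValueError):
            mappcr.anchor_cdna({}, "ACGT" * 10)


class TestFlanks:
    def _ssr_at(self, seq, start):
        recs = [r for r in find_ssrs(seq, "s") if r.start == start]
        assert recs
        return recs[0]

    def test_ssr_at_origin_truncates_left(self):
        seq = "AT" * 10 + random_dna_pad()
        r = self._ssr_at(seq, 0)
        fl = mappcr.extract_flanks(seq, r, flank_len=50)
        assert fl.left == "" and fl.left_truncated
        assert len(fl.right) == 50 and not fl.right_truncated

    def test_centered_ssr_full_flanks(self, rng):
        # explicit guard bases pin the run to [400, 424)
        seq = random_dna(rng, 399) + "A" + "TTTG" * 6 + "A" + random_dna(rng, 399)
        r = self._ssr_at(seq, 400)
        fl = mappcr.extract_flanks(seq, r, flank_len=150)
        assert len(fl.left) == len(fl.right) == 150
        assert not fl.left_truncated and not fl.right_truncated
        assert seq[250:400] == fl.left and seq[r.end : r.end + 150] == fl.right

    def test_flanks_match_genomic_neighbourhood(self, planted_world):
        corpus, truth, genome, placements = planted_world
        seqs = dict(corpus)
        pmap = placements.set_index("cdna_id")
        p = truth[0]
        r = self._ssr_at(seqs[p.seq_id], p.start)
        fl = mappcr.extract_flanks(seqs[p.seq_id], r, 80)
        row = pmap.loc[p.seq_id]
        chrom = genome[row.chrom]
        segment = chrom[row.start : row.end]
        cdna = segment if row.strand == "+" else rc(segment)
        assert cdna == seqs[p.seq_id]
        assert fl.left in cdna and fl.right in cdna


def random_dna_pad():
    import numpy as np

    return random_dna(np.random.default_rng(77), 200)


class TestSuggestPrimers:
    def test_homopolymer_flank_unusable(self):
        assert mappcr.suggest_primers("A" * 100, "ACGT" * 40) is None

    def test_relaxed_constraints_return_innermost_windows(self, rng):
        left, right = random_dna(rng, 60), random_dna(rng, 60)
        params = PrimerParams(gc_min=0, gc_max=100, max_homopolymer=10**9)
        pair = mappcr.suggest_primers(left, right, params)
        assert pair.fwd == left[-18:]
        assert pair.rev == rc(right[:18])

    def test_constraints_respected(self, rng):
        from ssratlas._util import gc_percent, max_homopolymer

        n_found = 0
        for _ in range(30):
            pair = mappcr.suggest_primers(random_dna(rng, 150), random_dna(rng, 150))
            if pair is None:
                continue
            n_found += 1
            for primer in (pair.fwd, pair.rev):
                assert 18 <= len(primer) <= 24
                assert 40 <= gc_percent(primer) <= 60
                assert max_homopolymer(primer) <= 3
        assert n_found > 20


class TestMatchProbePair:
    def test_constructed_amplicon(self, rng):
        fwd = "ACGTACGTGGCATCGATTGC"
        rev = "TGCCAGTTAGGCATCAGTCC"
        insert = random_dna(rng, 100)
        genome = {"chr1": random_dna(rng, 50) + fwd + insert + rc(rev) + random_dna(rng, 50)}
        hits = mappcr.match_probe_pair(genome, PrimerPair("m", fwd, rev))
        assert len(hits) == 1
        h = hits[0]
        assert h.product_len == len(fwd) + 100 + len(rev)
        assert h.start == 50 and h.orientation == "fwd+"

    def test_swapped_orientation_detected(self, rng):
        fwd = "ACGTACGTGGCATCGATTGC"
        rev = "TGCCAGTTAGGCATCAGTCC"
        genome = {"chr1": random_dna(rng, 40) + rev + random_dna(rng, 80) + rc(fwd) + random_dna(rng, 40)}
        hits = mappcr.match_probe_pair(genome, PrimerPair("m", fwd, rev))
        assert len(hits) == 1
        assert hits[0].orientation == "rev+"

    def test_missing_site_gives_empty(self, rng):
        fwd = "ACGTACGTGGCATCGATTGC"
        rev = "TGCCAGTTAGGCATCAGTCC"
        genome = {"chr1": random_dna(rng, 300) + fwd + random_dna(rng, 300)}
        assert mappcr.match_probe_pair(genome, PrimerPair("m", fwd, rev)) == []

    def test_max_product_bound(self, rng):
        fwd = "ACGTACGTGGCATCGATTGC"
        rev = "TGCCAGTTAGGCATCAGTCC"
        genome = {"chr1": fwd + random_dna(rng, 500) + rc(rev)}
        assert mappcr.match_probe_pair(genome, PrimerPair("m", fwd, rev), max_product=400) == []
        assert len(mappcr.match_probe_pair(genome, PrimerPair("m", fwd, rev), max_product=600)) == 1

    def test_oracle_equivalence_random_genomes(self, rng):
        """All inward-facing pairings within the product bound, on random
        genomes with 0-3 planted sites, match a brute-force scan."""
        fwd = "GATTACAGATCCGTAGGCAT"
        rev = "CCATGGTTCAGACGTTAGGA"
        for _ in range(200):
            pieces = [random_dna(rng, int(rng.integers(50, 200)))]
            for _ in range(int(rng.integers(0, 4))):
                site = [fwd, rc(rev), rev, rc(fwd)][int(rng.integers(4))]
                pieces.append(site)
                pieces.append(random_dna(rng, int(rng.integers(20, 150))))
            genome = {"chr1": "".join(pieces)}
            hits = mappcr.match_probe_pair(genome, PrimerPair("m", fwd, rev), max_product=800)
            got = {(h.chrom, h.start, h.end, h.orientation) for h in hits}
            assert got == brute_amplicons(genome, fwd, rev, 800)


class TestRoundTrip:
    def test_flanks_primers_pcr_recover_planted_ssrs(self):
        """For planted SSRs: extract flanks, suggest primers, amplify on
        the synthetic genome; the single amplicon contains the SSR."""
        cfg = SynthConfig(n_sequences=40, length_range=(600, 1000), ssr_density=1.5, seed=55)
        corpus, truth = synth.gen_cdna_corpus(cfg)
        genome, placements = synth.gen_genome(corpus, flank_len=300, n_chromosomes=3, seed=56)
        g = dict(genome)
        seqs = dict(corpus)
        pmap = placements.set_index("cdna_id")
        mined = {
            (r.seq_id, r.start): r for r in find_ssrs_in_records(corpus)
        }
        n_pairs = n_unique = 0
        checked = 0
        for p in truth:
            if checked >= 50:
                break
            checked += 1
            r = mined[(p.seq_id, p.start)]
            fl = mappcr.extract_flanks(seqs[p.seq_id], r, 150)
            pair = mappcr.suggest_primers(fl.left, fl.right, name=p.seq_id)
            if pair is None:
                continue
            n_pairs += 1
            hits = mappcr.match_probe_pair(g, pair)
            assert len(hits) >= 1
            if len(hits) == 1:
                n_unique += 1
                h = hits[0]
                row = pmap.loc[p.seq_id]
                # project the SSR interval onto the genome and check containment
                if row.strand == "+":
                    ssr_g = (row.start + r.start, row.start + r.end)
                else:
                    ssr_g = (row.end - r.end, row.end - r.start)
                assert h.chrom == row.chrom
                assert h.start <= ssr_g[0] and ssr_g[1] <= h.end
        assert n_pairs >= 40
        assert n_unique == n_pairs  # synthetic genome: single-copy markers


class TestPhysicalMap:
    def _hit(self, chrom, start, end):
        return mappcr.AmpliconHit(chrom, start, end, end - start, "fwd+")

    def test_single_hit_bed_line(self):
        lines, amb = mappcr.write_physical_map({"marker1": [self._hit("chr1", 100, 350)]})
        assert lines == ["chr1\t100\t350\tmarker1"]
        assert amb == []

    def test_sorted_by_chrom_then_start(self):
        lines, _ = mappcr.write_physical_map(
            {
                "b": [self._hit("chr1", 500, 700)],
                "a": [self._hit("chr1", 10, 200)],
                "c": [self._hit("chr0", 900, 950)],
            }
        )
        assert lines == [
            "chr0\t900\t950\tc",
            "chr1\t10\t200\ta",
            "chr1\t500\t700\tb",
        ]

    def test_ambiguous_marker_suffixed_and_flagged(self):
        lines, amb = mappcr.write_physical_map(
            {"m": [self._hit("chr2", 5, 50), self._hit("chr1", 5, 50)]}
        )
        assert amb == ["m"]
        assert lines == ["chr1\t5\t50\tm_1", "chr2\t5\t50\tm_2"]
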