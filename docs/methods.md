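# Methods

## SSR model and detection

An SSR is modelled as a maximal tandem run of full copies of a primitive
motif of length k = 1–6 whose total length reaches `min_len` (default
18 nt). Primitivity is divisor-based: a motif is primitive when it is not a
whole-number power of a shorter string, which is exactly the property that
propagates to tandem runs (a run of a non-primitive motif is the same run at
a smaller period). The detector scans, for each k, the positions where
`s[i] == s[i-k]`; each maximal agreement stretch is trimmed to full motif
copies and kept when the start motif is primitive. For runs of at least two
copies, primitivity of the motif guarantees (Fine–Wilf) that k is the
fundamental period of the run, so each run is reported exactly once.

Conventions:

- **Trailing partial periods** are excluded: (TC)₉T is a 9-repeat run.
  Repeat numbers are therefore always integers.
- **Maximality** means the base immediately before the run breaks the
  period and no further full copy fits on either side.
- **Motif phase** is as the run starts (…C·TCTCT… reports CT); the
  minimal-rotation class is stored alongside so summaries can group
  rotations. Reverse complements are *never* merged: TC and GA are distinct
  motifs, matching how published motif tables are printed.
- **Perfect vs imperfect** is a length rule: total length ≥ 20 nt is
  perfect, 18–19 nt imperfect. It is not a mismatch/interruption class;
  approximate repeats are out of scope.
- `N` terminates any run; other non-IUPAC characters are errors.
- Nested runs are suppressed (outer maximal run wins); overlapping
  non-nested runs of different periods are both reported. Adjacent runs of
  different motifs are never merged into compound records.
- Coordinates are 0-based half-open internally and in TSV (`start0/end0`),
  BED-compatible downstream.

## Summary tables

Percentages use decimal half-up rounding so printed-table reproductions are
bit-stable: type shares to 2 decimals of the grand total, motif shares to
1 decimal within their type, per-type cDNA-harbouring percent as
(cDNAs harbouring ≥1 run) / (runs of that type) × 100 — the convention used
in published survey tables. Corpus incidence is (number of runs) /
(number of screened sequences) × 100; the denominator is a required
argument because published corpus sizes are often ambiguous. Repeat-number
bins default to the half-open partition [3,9], [10,15], [16,20], [≥21]
(published bin labels overlap at 15 and 20; a partition is enforced here).

`reference.py` encodes the margins of a published safflower cDNA-SSR survey
(1,841 runs in 1,667 of 39,817 cDNA clones) and materialises a synthetic
record multiset matching them, so the arithmetic can be exercised against
real printed values without the undeposited corpus. Some printed
multiplicity cells are mutually inconsistent (e.g. 405 dinucleotide runs in
396 cDNAs cannot include 10 multi-run cDNAs; 128 tetranucleotide runs in
114 cDNAs must include some); the encoded multiplicities are the values
consistent with the authoritative SSR and cDNA counts. Only coordinates and
placeholder motifs in that multiset are arbitrary — every tabulated margin
is faithful.

## ORF context

Gene structure is approximated by a deterministic six-frame longest-ORF
scan (ATG through the first in-frame stop; `length_aa` includes the
initiator Met and excludes the stop; default minimum 30 codons, a
conventional short-ORF filter). This is a deliberate, documented
substitution for trained gene predictors: it is dependency-free and
sufficient for classifying repeat position on synthetic data, but it will
mis-annotate real cDNAs with non-ATG starts, truncated 5' ends or introns.
Ties go to the plus strand, then the smallest start. Each SSR is classified
5'UTR / CDS / 3'UTR by its start position on the ORF's strand (runs
spanning a boundary keep the upstream label and carry a boundary flag);
trinucleotide runs in the CDS get an in-frame flag when their offset from
the ATG is divisible by 3. Sequences without an ORF are `noncoding`.

## Physical mapping and in-silico PCR

cDNAs are anchored on a genome by exact substring search on both strands,
plus a seed-and-extend path (shared 21-mers, ungapped extension, ≥ 95 %
identity) for inexact embeddings. No gapped aligner is used: synthetic
genomes embed cDNAs exactly, and the identity threshold covers point
differences only.

Primer suggestion is a deterministic stand-in for interactive primer
design: the innermost flank windows (closest to the repeat) of length
18–24 nt with 40–60 % GC and no homopolymer above 3 nt, shortest length
first. It makes no melting-temperature or dimer calculations, and its
output is not expected to equal any published primer list.

In-silico PCR reports every interval where one primer matches the plus
strand and the reverse complement of the other matches downstream with
non-overlapping footprints within `max_product` (default 2,000 nt), in
both orientations, with optional Hamming-mismatch tolerance (default 0,
exact matching). All valid pairings are reported; markers with several
genomic hits are emitted with suffixed names and flagged ambiguous in the
BED physical map.

## Genotypes, polymorphism and clustering

Genotypes are categorical allele codes (agarose band classes), missing
calls allowed. Polymorphism is ≥ 2 distinct non-missing alleles over the
scored subset; rates take an explicit denominator because panel studies
quote rates over designed, amplified or scored pair counts interchangeably
— the caller must say which.

Two-sided clustering mirrors common heatmap-package defaults, since such
figures rarely state their metric: allele calls are one-hot encoded per
marker, accession rows Z-scored (sample SD, constant rows flagged and set
to 0), pairwise distances are NaN-aware Euclidean, linkage is complete;
markers are clustered on per-marker standardised call profiles. Markers
missing in > 50 % of accessions are dropped with a warning (failed lanes
are routine in agarose scoring). The accession tree cut at k = 2 yields the
group call; concordance with truth labels is the adjusted Rand index.
SciPy's linkage is deterministic for a fixed input order, and group
recovery is invariant under input permutation (verified by test).

## Enrichment

Over-representation uses the upper-tail hypergeometric probability with
Benjamini–Hochberg adjustment and a 0.05 adjusted-p cutoff. This is a
transparent replacement for web-service enrichment tools whose custom
multiple-testing procedures and database versions are not reproducible
offline; absolute term lists from such services are out of scope. The
universe defaults to all annotated genes and can be overridden.

## Synthetic data

The corpus generator emulates a plant cDNA collection: per sequence, a
Poisson(`ssr_density`) number of runs is planted (default density 0.046,
matching the surveyed incidence of ≈ 4.6 runs per 100 cDNAs); motif type is
drawn from weights defaulting to the surveyed type mix (tri- and
hexanucleotide dominated); motifs are uniform over the primitive set;
repeat counts are uniform over per-type ranges spanning the surveyed 3–28
with every planted run ≥ 18 nt. Background is i.i.d. uniform with
homopolymers capped (default 8) and each run is flanked by guard bases that
break its periodicity, making truth coordinates unambiguous. Every
generated sequence is verified by the miner — the mined set must equal the
planted set exactly, otherwise the sequence is resampled — which also
certifies the background free of accidental ≥ 18 nt runs. Sequences too
short for their requested runs raise a sizing error.

What the generator does *not* emulate: UTR/CDS composition bias, codon
structure, real motif-frequency gradients within a type, sequencing error
or polymorphism between corpus and genome. Passing planted-truth tests
therefore demonstrates algorithmic correctness, not performance on real,
noisy cDNA collections.

The genome generator embeds each cDNA exactly once, round-robin across
chromosomes, random strand, separated by random spacers of `flank_len` nt.
The genotype generator plants an exact number of group-diagnostic markers
(`round(divergence × n_markers)`); a configurable fraction of those also
segregate within group 1 via a third allele, emulating panels where some
markers are polymorphic only against wild relatives. The annotation
generator plants exactly one term with a specified overlap with the
selected set; all other terms are uniform random draws.

## Problem sizes and numerics

Default verification scales: miner-vs-oracle on 1,000 random 300-nt
sequences, planted recovery over 100 corpora of 3 sequences, in-silico PCR
oracle on 200 random genomes, clustering recovery over 100 panels of
11 accessions × 35 markers — sizes chosen so the whole suite runs in well
under a minute while exercising every code path at the panel sizes the
marker-validation design actually uses. Floating-point checks use 1e-12
tolerances for Z-scoring identities and relative 1e-9 for hypergeometric
closed forms. All randomness flows through `numpy.random.default_rng`
seeds; identical seeds give byte-identical outputs, including FASTA and
manifest checksums.

## Known limitations

- The ORF finder is not a gene predictor; region labels on real cDNAs are
  approximate.
- Primer suggestion ignores thermodynamics; treat suggested pairs as
  candidates for proper design tools.
- Anchoring is ungapped; spliced alignment of cDNA to genomic DNA is out
  of scope.
- The imperfect/perfect split is the length rule only; interrupted repeats
  with internal mismatches are not modelled.
- Enrichment results depend entirely on the supplied annotation; no
  database is bundled.
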