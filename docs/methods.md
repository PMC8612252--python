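# Methods

This note documents what each pipeline stage computes, the assumptions
behind it, the tunable parameters and their defaults, what the synthetic
data emulate (and do not), and the numerical and design choices made where
the method leaves room.

## Coordinates and containers

All genomic coordinates are 1-based inclusive (the GFF3 convention), and
all arithmetic uses that single convention. Contigs are linear: no
wrap-around adjacency is considered, so a gene at a contig edge simply has
a short flank. Genes within a contig are kept strictly sorted by
(start, end); overlapping genes are legal and common (overlapping operon
members). The intergenic distance between consecutive genes is
`downstream.start − upstream.end − 1`, so abutting genes (no shared base)
score 0 and overlaps score negative.

## Rhodopsin screen

A candidate is retained as a heliorhodopsin iff it has exactly 7
transmembrane helices and an `SxxxK` anchor pattern (fixed residue, three
wildcards, fixed residue) in the helix-7 window; `DxxxK` in the same window
yields a type-1 rhodopsin call. The helix-7 window is TM7 extended by ±3
residues: predicted helix boundaries are imprecise, and a hard helix
boundary would make the call hinge on a one-residue segmentation error. The
window size is this package's choice; no value is prescribed by the screen
itself.

Decisions taken where the screen is silent:

* If both motifs match (at different offsets), heliorhodopsin takes
  precedence and the call carries an `ambiguous_motif` reason.
* Membrane orientation is recorded, not enforced: heliorhodopsins have a
  cytoplasmic ("in") N terminus, and we treat that orientation as
  canonical, but an "out" prediction only attaches an
  `orientation_conflict` reason, because TM count and motif are the
  retention criteria.
* Every rejection carries at least one machine-readable reason
  (`tm_count`, `no_motif`).

### Fallback topology predictor

When no topology table is supplied, a deterministic hydropathy
segmentation is used: Kyte–Doolittle values averaged over a centred
19-residue window (true mean over in-range residues, so termini are not
zero-padded), residues with mean ≥ 1.0 marked, marked runs merged across
gaps ≤ 3 residues, and runs ≥ 15 residues reported as helices. The side of
the N terminus follows the positive-inside rule: Lys+Arg are counted in the
two loop-parity classes (the region before TM1 shares the N terminus'
side), and the parity with more K+R is called "in"; ties give "unknown".
Non-standard residues contribute hydropathy 0 with a logged warning.

This fallback is a simple, reproducible segmenter — adequate for the
well-separated helices of the synthetic cohort and for triage, not a
replacement for a dedicated TM predictor on real proteins. On synthetic
proteins its boundaries land within ~3 residues of the planted helices,
which is well inside the ±3 motif window.

## Envelope classification

Distinct marker domains present anywhere in a genome are counted once
(presence/absence, never copy number — the criterion is about distinct
domains). Verdicts: ≥ 10 distinct markers → `diderm`; ≤ 2 →
`monoderm_consistent`; 3–9 → `ambiguous`. The upper edge (10) is the
published conservative criterion; the band edges below it are this
package's choice, anchored by the two published edge cases: a 60%-complete
genome with 2 markers was deemed uninformative, and a complete genome with
5 markers was judged not a classical diderm. Genomes with completeness
< 0.8 or unknown carry a `low_completeness` caveat, since marker absence in
a fragmentary genome is weak evidence. The 27 curated marker identities are
not embedded; a placeholder set of 27 accession slots (`OMM001`–`OMM027`)
ships as the default and a real list can be supplied as a one-accession-
per-line file. Whether the published count was per-genome or per-protein is
not stated; per-genome distinct domains is assumed.

## Contig taxonomy

Contigs < 5,000 bp are excluded (`too_short`). Otherwise the contig is
assigned the unique phylum whose best-hit vote fraction reaches 60%
(inclusive, matching "≥ 60%"). The denominator is **all** predicted genes
on the contig — the literal reading — so genes without any best hit dilute
support; a config switch (`hits_only_denominator`) restricts the
denominator to genes with hits for sensitivity analysis. Because 60% > 50%,
at most one phylum can qualify under the default denominator, making the
assignment structurally unique. Sequence dereplication (95/95 clustering)
is an upstream external step; only an exact-duplicate dropper is provided.

## Gene context

Neighborhoods come in two modes: `by_genes` (up to 10 genes per side, the
enrichment unit) and `by_window` (every gene overlapping anchor ± 10 kb,
the inspection unit). The anchor is never a member, and the neighborhood's
domain multiset counts each member gene once per distinct domain.

Cotranscription candidates require consecutive same-strand genes at
intergenic distance < 10 bp (strict). Overlapping genes qualify (negative
distances are < 10), consistent with overlapping genes occurring inside
putative operons. Chains extend transitively from the anchor while each
consecutive pair qualifies — multi-gene cotranscription units are the
target — and a `direct_neighbors_only` switch restricts chains to the
anchor's immediate neighbors for the stricter pairwise-only reading. One
maximal chain is emitted per anchor, or none if no neighbor qualifies.

## Neighborhood enrichment

Eligibility: an anchor counts only when it has ≥ 10 annotated genes on each
side of its own contig, which guarantees the draw is exactly n = 20. For
each distinct domain present among the 20 neighbors, an upper-tail
hypergeometric probability is computed with population N = all
protein-coding genes of the genome and K = genes carrying the domain
(gene-level presence: a gene with two copies counts once; the anchor's own
domains are excluded from k). `P(X ≥ 0)` is returned as exactly 1.0.
`scipy.stats.hypergeom.sf` supplies the tail; the test suite checks it
against an exact combinatorial-sum oracle (integer arithmetic) for every
valid instance with N ≤ 40 at 10⁻¹² absolute tolerance.

Multiple testing: all (genome × anchor × domain) tests of a run form one
Benjamini–Hochberg family by default (`per_genome_bh` switches to
within-genome families). The adjustment is the standard step-up
`q_(i) = min_{j≥i} p_(j)·m/j`, order-preserving and capped at 1, delegated
to statsmodels and verified against hand-computed vectors.

Selection: a genome is significant for a domain when any of its eligible
loci has q < 0.05, and a domain is selected when significant genomes make
up ≥ 10% of eligible genomes. The published phrase "in at least 10% of
genomes with low probability" admits a weaker reading (present in 10% and
significant somewhere); the stricter reading is the default and the weaker
one is available via `selection_mode="present_frac"`. Genomes with several
anchors contribute via the OR over their loci. The per-phylum rerun repeats
the entire procedure (including BH) within each phylum contributing ≥ 5
eligible genomes; smaller phyla are omitted with a logged note.

## Motif toolkit

Consensus patterns are upper-case residues plus lower-case `x` wildcards;
mismatches are counted on fixed positions only. MORN repeats
(`YEGEWxNGKxHGYG`, span 14) are scanned greedily left-to-right without
overlaps, because tandem copies abut and overlapping hits would
double-count; zinc ribbons (`CxxC` + exactly 17 arbitrary residues +
`CxxC`, span 25) report all matches including overlapping ones, because
cysteine spacings can nest. The 17-residue spacer is exact by default with
a parameter for other spacings, since it is unknown whether the original
matches allowed slack.

Extension extraction requires a 7-TM topology with known N-terminus side.
Terminal regions (ntv before TM1, ctv after TM7) are always reported when
non-empty; inter-TM loops only when strictly longer than 50 aa. Labels
alternate from the N terminus: with N-in, loops after TM1/3/5 are
ECL1/2/3 and after TM2/4/6 are ICL1/2/3; an "out" N terminus swaps every
ECL↔ICL. Clustering extensions into variant families is out of scope; the
regions are exported as FASTA for external profile-profile analysis.

## Synthetic data

The generator emulates the statistical structure the pipeline assumes:
single-contig genomes of 100–400 genes, gene lengths 300–3,000 bp,
junction types drawn per gene pair (25% operonic: same strand, gap 0–9 bp
or, in 20% of cases, an overlap of −20…−1 bp; 10% decoy: strand flip with a
small gap; otherwise random strand with gap 30–300 bp), domains assigned
per gene from a 2% background over 40 accessions, one heliorhodopsin
anchor per genome with ≥ 12 genes per side, enrichment planted by giving
`round(0.40 × 20) = 8` of the 20 neighbors a chosen accession, envelope
complements of 10–27 (diderm) or 0–2 (monoderm) distinct markers, and
best-hit tables in which exactly `⌈concordance × n⌉` genes hit the target
phylum. Gap and length distributions are uniform within these ranges — no
generative model is prescribed anywhere — and the ranges deliberately
straddle every decision threshold (10 bp, 5 kb, 50 aa, 60%, 10 markers).
Planted proteins use Leu/Ile/Val/Phe helices (23 aa) and hydrophilic
loops free of Ser/Asp/Lys, with Lys/Arg enrichment on the cytoplasmic
side, so the planted helix-7 motif is the only anchor-pattern match and
the positive-inside rule is recoverable; the motif-bearing helix draws
from Leu/Ile/Val only to offset the hydropathy cost of its polar residues.

All randomness flows through one numpy Generator keyed by the seed, and
identical seeds produce byte-identical datasets.

What passing tests on these data do **not** show: real proteins have noisy
hydropathy profiles and helices of varying length, real domain backgrounds
are far from independent across genes (operons and cassettes correlate
them), real genomes are multi-contig and incomplete, and real best-hit
tables carry database and taxonomy biases. The synthetic cohort validates
the decision logic and the statistics, not predictor accuracy on natural
sequences.

## Problem sizes and calibration checks

The statistical properties are verified by simulation at sizes chosen to
keep the full suite fast while leaving no ambiguity in the outcome: the
null-calibration check runs 50 replicate 100-genome cohorts with no
planted signal and requires an empty selected set in ≥ 95% of replicates;
the power check runs 50 replicate 20-genome cohorts with the signal
planted in 30% of genomes (8/20 neighborhood occurrence vs 2% background)
and requires selection in ≥ 95% of replicates; recovery of planted operon
chains, rhodopsin classes and envelope labels is required to be exact on
cohorts of 20–30 genomes. The hypergeometric oracle sweep covers every
valid instance with N ≤ 40.

## Known limitations

* The fallback topology predictor underperforms dedicated HMM-based
  predictors on natural sequences; supply a topology table when available.
* The envelope bands between 2 and 10 markers are intentionally
  conservative (`ambiguous`), and low-completeness genomes can only be
  flagged, not rescued.
* BH across one pooled family treats tests from different genomes as
  exchangeable; genomes with unusually many distinct neighborhood domains
  contribute more tests and thus more of the family.
* Enrichment ignores phylogenetic non-independence between genomes; a
  domain enriched in one well-sampled clade can dominate the cross-genome
  selection (the per-phylum rerun mitigates, but does not remove, this).
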