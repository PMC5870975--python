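# Methods

This note documents the statistical and algorithmic choices behind
mitocomp: what each stage computes, the defaults and why, what the
synthetic-data generator does and does not emulate, and the numerical
corner cases.

## Coordinates, strands and gene names

Coordinates are 1-based inclusive on the majority (J) strand, following
GenBank convention; half-open arithmetic is internal only. A feature that
spans the circular origin keeps `start > end` and is flagged
`wraps_origin`. The J strand is defined as the strand stored in the
record; whole-genome composition is computed on it, per-gene quantities
on each gene's sense strand (reverse complement for N-strand genes).
Raw annotation labels are mapped to canonical symbols through the
versioned alias table `data/gene_names.tsv` (e.g. COX1→COI, cytb→CYTB);
serine/leucine tRNA isotypes are resolved by the anticodon qualifier
(GCU→trnS^AGN, UGA→trnS^UCN, UAG→trnL^CUN, UAA→trnL^UUR). Unmapped
labels warn and are kept verbatim rather than failing. The ambiguity
code N is legal in sequences and never enters composition numerators or
denominators.

## Composition and skews

AT-skew = (A−T)/(A+T), GC-skew = (G−C)/(G+C); a zero denominator yields
NaN rather than a silent zero. Values are held at full precision and
rounded only in reports (percentages to 0.1, skews to 0.001 — the
precision at which such tables are conventionally printed). The pooled
PCG partition concatenates sense strands *including* terminators (they
are genomic sequence); the codon-position partitions frame each gene
from its `codon_start` and drop the trailing partial codon, so an
incomplete terminator contributes to the pooled partition but never to a
codon position. Consequence: `3 × |pos_k| ≤ |PCG|`, with equality only
when every gene ends in a complete stop.

## Codon census

Genetic code fixed to invertebrate mitochondrial (table 5): stops
UAA/UAG only, UGA=Trp, AGA/AGG=Ser (an eight-member serine family),
62 sense codons. Census rules, both switchable:

* start codons **are counted** — COI's CGA start is a translated codon,
  and excluding it would make CGA spuriously missing in some genomes;
* terminators (UAA/UAG, or the trailing T/TA of an incomplete stop)
  **are excluded** — the missing-codon question concerns sense usage.

An internal in-frame UAA/UAG triggers a warning (suspect annotation) and
is excluded from the sense count. RSCU for a family with zero total is
reported as 0 and the family flagged undefined, rather than NaN, so
tables stay numeric. Missing codons are ordered by descending family
size, then alphabetically; published tables group them per species in no
algorithmically stable order, so comparisons should be made as sets.

## tRNA profiling

Cloverleaf regions are read from dot-bracket strings: base pairs are
stacked into helices; exactly four helices (acceptor enclosing DHU,
anticodon, TψC arms in 5′→3′ order) constitute a cloverleaf, and three
helices are accepted for the DHU-less trnS^AGN architecture, in which
case the unpaired run between the acceptor and anticodon stems is
labelled the DHU loop. The anticodon is the central triplet of the
anticodon loop. Stem mismatches are pairs outside {AU, UA, GC, CG, GU,
UG} — G·U wobble is valid pairing.

"Percentage of identical nucleotides" has no universal formula; the
default here is the **modal-residue frequency** per aligned column,
gaps excluded from numerator and denominator. A mean pairwise identity
per column is available via `method="pairwise"`; the two differ at small
sample sizes (for two sequences a split column scores 1/2 under the
modal statistic and 0 under the pairwise one). One subtlety of the modal
statistic: duplicating a minority sequence can *lower* a column's
identity (3/6 → 3/7); only adding the column-wise consensus is
guaranteed non-decreasing. Region means project a designated reference
structure (first taxon by default, for determinism) through the
alignment.

## Alignment

The package carries its own aligner so that conservation profiles,
conserved blocks and supermatrices are reproducible without external
software: Needleman–Wunsch with linear gaps (+1/−1/−2 by default) and a
fixed tie-break (diagonal, then up, then left), merged into a multiple
alignment by the center-star heuristic under "once a gap, always a gap"
(center = sequence maximising summed pairwise scores, ties to the lowest
input index). Row-wise the DP is vectorised: with linear gap costs the
in-row dependency reduces to a running maximum of `candidate_j − g·j`.
Local alignment (spacer vs gene) is Smith–Waterman with affine gaps
(open −2, extend −1); identity is matches over aligned columns. Center-
star is a heuristic — it guarantees each row un-gaps to its input and is
deterministic, not that the MSA is score-optimal; progressive or
iterative refinement is out of scope.

## Supermatrices

Dataset codes follow the usual mitogenomic naming: PCG123 (13 PCGs, all
positions), PCG12 (third positions removed), PCG123R/PCG12R (plus the
two rRNAs and the pooled 22 tRNAs). PCGs are aligned codon-aware —
translated under table 5, aligned as amino acids, back-threaded to
nucleotides — which keeps gaps frame-preserving, so every PCG block is a
codon multiple and the PCG12 width is exactly 2/3 of PCG123. Genes are
concatenated alphabetically by canonical name within each class (no
order is conventional; alphabetical is reproducible). Partitions are
(name, strided column ranges): per-gene codon-position charsets
(`start-end\3`, matching the "each codon site of PCGs" partitioning
scheme), one charset per rRNA, one pooled tRNA charset; together they
tile the matrix exactly. Output formats are relaxed PHYLIP and NEXUS
with a `sets` block.

## Non-coding regions

The control region is the annotated A+T-rich feature when present,
otherwise the largest gap (≥ 50 bp) between rrnS and trnM — the position
it occupies in this clade — flagged inferred. Motif scanning is
IUPAC-aware and exact; the ambiguous published rendering "A(T)TTTA" for
CBS-2 is implemented as the alternative set {ATTTA, ATTTTA}. Poly-T/A
runs default to minimum length 5 and the (AT)n microsatellite to n ≥ 3
(no thresholds are conventional; both are configurable) and are reported
as maximal hits only. Scanning can cover both strands; hits are always
reported in forward-strand coordinates. The conserved-block caller
slides a window (default 5 columns) over an alignment and merges
qualifying windows (mean modal identity ≥ 0.9, mean non-gap support
≥ 0.9 by default) into maximal blocks with minimal-IUPAC consensus
strings; it is invariant under taxon reordering.

## Gene order and TDRL

Orders are signed circular permutations, rotation-normalised to an
anchor gene (COI — present and unambiguous in every complete genome).
Order comparison reports maximal differing segments after the rotation
minimising the number of differing positions. TDRL enumeration tries
every circular block up to `max_block` (default 3, the size of the
I-Q-M neighbourhood; enumeration is exponential in block length) and
every loss pattern keeping one copy per duplicated gene, verifying each
candidate by literal replay; strand-differing inputs are rejected since
tandem duplication preserves orientation. For ancestral trnI-trnQ-trnM
versus Ditrysia trnM-trnI-trnQ exactly one event exists at block ≤ 3:
duplicate [I,Q,M], lose the first copies of I and Q and the second copy
of M. Multi-step rearrangement distances (DCJ, inversions) are out of
scope.

## Synthetic-data generator

The generator defines the study conditions for all seeded tests. One
genome is a contiguous circle of 37 genes in the Ditrysia (or ancestral)
reference order plus a control region, with three deliberate non-coding
gaps: the CR between rrnS and trnM, a 20 bp trnS^UCN–ND1 spacer carrying
one planted ATACTAW instance, and a 60 bp trnQ–ND2 spacer built as a
10%-diverged copy of an internal ND2 fragment.

Defaults (chosen once, as the conditions of the cohort this package
targets): A+T 0.80, AT-skew −0.02, GC-skew −0.20 on PCG sense strands;
3,710 PCG codons across realistic per-gene lengths (~11.2 kb);
rrnL 1361 bp and rrnS 780 bp (the biologically consistent large/small
subunit sizes — published summaries of this clade print the two averages
the other way around, which we flag rather than follow); CR 340 bp with
CBS-1+poly-T, CBS-2, (AT)n and CBS-3 planted in the canonical layout;
exclusion set {AGG, CGC, CUG} (three typical G/C-rich absentees);
CGA start for COI, ATT for ND2/ND5, incomplete stops T/T/TA/T for
COI/COII/ND5/ND4 realised by abutting the downstream feature; tRNA
substitution rates 0.05 (J strand) vs 0.15 (N strand) per site for
ortholog sets of 10 taxa.

Protein-coding sequence is drawn codon-by-codon from a multinomial over
allowed sense codons whose weights are products of per-base weights.
Because stops and the exclusion set are removed before renormalisation,
the naive weights would miss the composition targets; the base weights
are therefore calibrated by a root solve so the *restricted* codon
distribution hits A+T content and both skews exactly in expectation
(residual < 1e−8; infeasible targets raise). After sampling, every
allowed sense codon is seeded at least once (replacing a random slot of
the currently most abundant codon), so the realised missing-codon set
equals the exclusion set exactly; at 3,710 codons the seeding perturbs
composition by well under one binomial standard deviation. Start codons
and terminators are placed verbatim and sit outside the calibration;
their net composition effect is a few bases in ~33,000.

What the generator does **not** emulate: position-specific codon
composition (positions are exchangeable under the codon model, so the
third-position A+T excess of real mitogenomes appears only weakly),
phylogenetically correlated evolution (ortholog sets mutate i.i.d. from
one ancestor; no tree), indels in tRNA/rRNA orthologs, rRNA secondary
structure, and length variation between cohort genomes under one
configuration. Passing the seeded tests therefore demonstrates correct
recovery of planted signal under idealised noise, not performance on
real annotation irregularities.

## Problem sizes in tests and the acceptance script

The seeded test suite and `scripts/acceptance.py` run on cohorts of five
full-size genomes (three for supermatrix construction), 200 replicate
ortholog sets for the strand-conservation ordering, and brute-force
oracle comparisons at small n (alignment length ≤ 12, gene orders ≤ 7) —
sizes at which the exhaustive oracles are exact and the whole run stays
in seconds. Parameter recovery is judged on the cohort-pooled estimator
against three of its own binomial standard errors; per-genome,
per-statistic 3σ testing across a cohort is a multiple-comparison trap
(15 simultaneous 3σ checks fail for ~4% of seeds even for a perfectly
calibrated generator, and the generator's calibration was verified
unbiased over 30 genomes).
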