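# Methods

`chemogene` reimplements, as a tested library and CLI, the computational
core of a comparative annotation of insect odorant binding protein (OBP)
and chemosensory protein (CSP) gene families: signature scanning, open
reading frame finding, spliced mRNA-to-genome alignment under the GT–AG
rule, tandem-cluster detection, ungapped motif discovery with arrangement
patterns, and transcript-abundance / qPCR expression arithmetic.  A seeded
synthetic-data module generates every input the pipeline needs, with
planted ground truth, so every stage can be scored end to end without any
external data.

## Coordinates and table conventions

All genomic coordinates are 1-based and fully inclusive; an interval
`(start, stop)` spans `stop − start + 1` bases.  This convention is forced
by the published tables the package bundles: a gene printed at
340085…345920 has a printed genomic size of 5836 bp, which only the fully
inclusive reading reproduces.  Table averages (mean intron size, mean exon
size) are rounded half-away-from-zero to integers; this too is forced by
the printed rows (16384/5 = 3276.8 → 3277; 489/2 = 244.5 → 245).  Open
reading frame lengths exclude the stop codon, so protein length =
`orf_bp / 3` (858 bp → 286 residues).

The two bundled printed tables disagree on one gene (the CSP7 row's
coordinate span equals the printed intron total rather than the printed
genomic size); the package treats the coordinate table as the coordinate
truth and does not attempt to repair the row.

## Cysteine-spacing signatures

The classical OBP signature is six conserved cysteines spaced
C1-X15–39-C2-X3-C3-X21–44-C4-X7–12-C5-X8-C6; the CSP signature is four
cysteines spaced C1-X6–8-C2-X16–21-C3-X2-C4.  `X_k–m` means *exactly k to m
residues strictly between* consecutive conserved cysteines, and an
intervening residue may itself be a cysteine (nothing in the signature
forbids it).  These bounds force a classical OBP match to span 60–112
residues and a CSP match 28–35 residues; both bounds are property-tested.
The scanner enumerates placements by depth-first search over cysteine
positions; `mode="all"` is verified against exhaustive enumeration over
ordered cysteine subsets on random proteins up to 200 residues.

plus-C sub-classification: a classical match is promoted to plus-C when
the residue immediately after C6 is proline and at least one further
cysteine (C6a) occurs within `plusc_window` residues downstream of C6.
The window defaults to 30 residues — the signature's sources state the
proline and the extra cysteine but not C6a's distance, and 30 residues
covers the C-terminal tail lengths seen in the family while excluding
chance cysteines far downstream.  A protein matching both signatures is
labelled OBP (the six-cysteine pattern is the more specific) with an
ambiguity flag.

Signal peptides are accepted as input annotations only; the package does
not predict them.

## Spliced alignment (GT–AG rule)

`spliced_align` reconstructs a gene's exon/intron structure by aligning
its mRNA to a genomic window with a dynamic programme that covers the mRNA
end to end, allows gaps only in the genomic dimension (introns of at least
`min_intron` bases), and scores

* `+match_score` (1) per matching base,
* `−mismatch_penalty` (3) per substitution,
* `−intron_open` (8) per intron,
* `−noncanonical_penalty` (10) extra for an intron not flanked GT…AG.

The recurrence is O(m·n): the intron transition is a running prefix
maximum (with a lag of `min_intron`) over the previous mRNA row, kept
separately for GT-donor positions and for all positions, so canonical and
non-canonical donors are resolved in constant time per cell.  Ties are
broken toward fewer introns (a sub-integer penalty of 1e-4 per intron,
which cannot reorder any non-tied comparison since all score terms are
integers) and then toward the leftmost donor (the prefix maximum keeps the
first position achieving it).  Alignments whose identity falls below
`min_coverage` (0.95) raise an "unmappable" error.  For minus-strand genes
the mRNA is aligned to the reverse complement of the window and exon
coordinates are mapped back to the forward axis, matching the convention
of the published coordinate table.

The default penalties were chosen so that a planted GT–AG structure
dominates any single-exon or shifted-junction alternative: recovery on 50
generated genes with 1–8 introns of 30–4000 bp is exact in all 50 cases
for the seeds exercised in the tests; the only anticipated failures are
junctions where the flanking sequence makes the splice placement
genuinely ambiguous.

## Tandem clusters

A cluster is a maximal chain of same-scaffold genes, ordered by start
coordinate, whose consecutive intergenic gaps (`next.start − prev.stop −
1`) are all at most `cluster_max_gap`, irrespective of strand.  The
default of 50 kb was chosen because the published tandem arrays span at
most ~39 kb; at that threshold the bundled 18-gene table yields exactly
the four published arrays (OBP7/3/8, CSP4/1/6, CSP9/2, CSP5/8).
Overlapping genes are chained with a gap of zero and a warning.  Cluster
detection is verified against a transitive-closure oracle on random
placements.

## Motif discovery and arrangement patterns

Motifs are ungapped position-weight matrices of width 6–10, up to eight
per run, discovered sequentially under a ZOOPS model (each sequence has
zero or one occurrence; background uniform over the 20 amino acids).  For
each rank and width, every admissible length-w subsequence seeds the fit
(deterministically subsampled above 150 seeds); seeds are ranked by one
E-step of the log-likelihood ratio against the background-only model, the
best seed is refined by EM to convergence (tolerance 1e-8, at most 200
iterations), and the objective is asserted non-decreasing at every
iteration.  Occurrences are called where the site posterior reaches
`motif_site_threshold` (0.5) and are masked before the next rank, so
occurrences of rank r never overlap earlier ranks.

Width selection uses the converged log-likelihood ratio penalised by
`0.5 · 19 · w · ln(expected site count)` — a BIC-style charge for the free
PWM parameters.  A raw per-column average cannot separate a fully
conserved core from its own sub-words, and an unpenalised sum rewards
padding the core with background columns; the BIC charge resolves both,
in the same spirit as the significance-penalised objective of the external
discovery tool the study used.  The external tool's E-value itself is not
reimplemented, so published pattern strings are reproduced in structure
(planted-motif recovery, arrangement logic), not motif-for-motif.

A protein's arrangement pattern is the hyphen-joined string of motif
indices ordered by occurrence start (ties broken toward the lower index).
Pattern frequencies split at `min_members` shared proteins ("present in
more than three" proteins = threshold 4).

Percent-identity matrices use Biopython's global aligner with match +1,
mismatch 0, gap open −10, gap extend −0.5; identity is 100 × identical
columns / alignment columns, verified against full enumeration of
alignments on short pairs.  The commercial tool the study used is
unpublished, so these identities are internally comparable but not
comparable to the study's supplementary matrices.

## Abundance and expression arithmetic

* RPKM(A) = 1e6 · C · 1000 / (N · L) with C the gene's uniquely mapped
  reads, N the library's uniquely mapped reads and L the gene length in
  bases.
* N50/N90: sort lengths descending; the smallest length at which the
  cumulative sum first reaches the requested fraction of the total.
* ddCT: technical replicates are averaged to one CT per biological
  replicate; dCT = CT_target − CT_reference; ddCT subtracts the calibrator
  tissue's dCT (paired by biological replicate where the ids align,
  otherwise against the calibrator mean); fold = 2^(−ddCT), reported as
  the per-replicate folds plus mean ± standard error.  The calibrator
  defaults to the decapitated body.
* Dilution validation: the least-squares slope of dCT against log10
  dilution over a fivefold series must satisfy |slope| < 0.1 for the ddCT
  assumption (equal efficiencies) to hold; with target and reference
  efficiencies E_t, E_r the noiseless slope is exactly
  1/log10(E_t) − 1/log10(E_r).
* Standard-curve efficiency: E = 10^(−1/slope) of CT against log10
  template, flagged at E ≥ 1.90 (perfect doubling E = 2).  Per-cycle
  fluorescence-window efficiency estimation is out of scope; the
  standard-curve estimate replaces it.
* Tukey letters: one-way ANOVA context with all-pairs Tukey HSD
  (`scipy.stats.tukey_hsd`).  Letters are the maximal cliques of the
  non-significance graph, lettered from the clique containing the highest
  mean, so two tissues share a letter exactly when Tukey finds no
  difference between them.  (A purely greedy assignment from the highest
  mean can separate a pair the test does not distinguish, which the
  simulation-vs-oracle test catches.)  The replicate structure is treated
  as one-way over tissues with biological replicates as the averaging
  unit; nested variance components are not modelled.

## Synthetic data: what it emulates and what it does not

Generators are pure functions of a spec plus a seed.

* `gen_genome` plants one multi-exon gene per scaffold; every intron
  begins GT and ends AG; exon/intron counts and length distributions are
  configurable, and `obp_like_genome_spec` calibrates them to the
  published OBP family (intron counts drawn from the empirical per-gene
  counts 4,5,6,6,6,6,6,7,8; exons uniform 40–120 bp; introns log-uniform
  30–5600 bp), giving an expected genomic length of ~6.9 kb, within 2% of
  the published family mean over 100 seeds.
* `gen_family` plants cysteine-spacing signatures with gaps drawn
  uniformly inside the pattern bounds (background residues avoid cysteine
  so the planted placement is the signature) and can insert an ungapped
  motif into the C-terminal tail; decoys are global shuffles.
* `gen_counts` draws Poisson counts around expectations proportional to
  abundance × length — the simplest noise model under which RPKM is the
  natural estimator.
* `gen_qpcr` produces CT = base − log_E(template) with additive Gaussian
  noise on the CT scale (default SD 0.15 cycles) and a fivefold dilution
  series; noiseless settings make the ddCT and efficiency round trips
  exact.

What the generators do **not** emulate: sequencing error and read-level
artefacts, assembly fragmentation, paralogy/pseudogenes, repeat content
around splice sites, non-GT–AG minor-spliceosome introns, PCR inhibitors
or melt-curve pathology.  Passing tests therefore demonstrate algorithmic
correctness against planted truth under the stated noise models, not
robustness to every artefact of real sequencing or qPCR data.

## Problem sizes and numerical choices

The test suite and acceptance script run at desk scale by design: 50 genes
for aligner recovery, 150 random proteins per signature for the scanner
oracle, 18-member families for motif recovery, 150 simulated datasets for
the Tukey oracle comparison.  EM uses a pseudocount of 1e-6 (stabilises
logarithms without visibly flattening degenerate point-mass columns) and
log-sum-exp throughout.  Degenerate inputs are defined explicitly: a
single-exon gene has zero intron statistics; an empty occurrence set gives
the empty arrangement pattern; identical qPCR groups share one Tukey
letter, while distinct groups with zero variance are flagged rather than
lettered.

## Known limitations

* The spliced aligner assumes the genomic window contains the whole gene;
  there is no whole-genome seeding/indexing, and trans-splicing is out of
  scope.
* Motif indices are run-relative (rank order); patterns from different
  input sets are not comparable, matching the caveat attached to the
  published figures.
* Homology search, signal-peptide prediction and phylogenetics are out of
  scope; candidate identification rests on the spacing signatures alone.
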