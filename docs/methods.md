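# Methods

## Micro-synteny model

The unit of inference is a focal gene whose immediate neighbours anchor a
conserved block in a target genome. The scanner walks each focal chromosome
in order and, for every gene that does not overlap its −1 or +1 neighbour by
more than 80% (overlap normalized by the focal gene's length; a symmetric
max-of-both variant is available via `denominator="symmetric"`), evaluates
every pairwise combination of −1-neighbour and +1-neighbour homologues drawn
from the orthology map. A combination is a block when both anchors lie on
one target chromosome separated by one or two protein-coding genes and the
anchors do not share an orthology group (apparent paralogues would otherwise
manufacture blocks around tandem arrays). The genes between the anchors are
the "opposite" genes — the predicted homologue location.

Three stringencies differ only in the outer-neighbour condition:

* **relaxed** — no outer condition;
* **standard** — if the −2 (resp. +2) neighbour has homologues on the
  anchor chromosome, at least one must lie within rank distance ≤ 2 of the
  −1 (resp. +1) anchor; a neighbour without homologues never disqualifies;
* **stringent** — the same conditional rule extended to the −3/+3 layer,
  chained to the nearest inner homologue that exists (when the −2 layer has
  no homologue, the −3 layer is checked against the −1 anchor).

Rank distances are direction-agnostic, so micro-inversions pass and are
recorded in `anchor_orientation`. Because each level only adds conditions,
the focal-gene sets nest (stringent ⊆ standard ⊆ relaxed); this is asserted
on simulated pairs. The definition is focal-centric: swapping focal and
target roles need not give mirrored blocks, and no such symmetry is claimed.

Tolerating *absence* of outer homologues (rather than requiring it) is a
deliberate reading of an ambiguous rule; the conditional interpretation is
the one that makes relaxed/standard/stringent a nested family.

## Search cascade and statistics

Micro-synteny genes are searched in four short-circuiting steps: opposite
proteins (all isoforms; a gene's best hit is the minimum E-value over
isoform pairs), the opposite genomic span ±2 kb in six reading frames,
the whole target proteome, and the whole translated genome. The final
genome-wide step always runs at a fixed E ≤ 10⁻⁶ and is excluded from
cutoff optimisation; the other steps share the calibrated cutoff. Outcomes
are monotone in the cutoff by construction (relaxing it can only move a gene
from not-found toward found), and each step's best E-value can be recorded
so curves over a cutoff grid need a single pass of searching.

The built-in engine is Smith–Waterman with affine gaps (BLOSUM62, gap open
11, extend 1) via Biopython's `PairwiseAligner`. Significance uses the
Karlin–Altschul form E = K·m·n·e^(−λS). Because no analytic (λ, K) exists
for gapped alignment, the constants were calibrated by fitting a Gumbel
distribution to optimal local scores of random uniform-composition protein
pairs at three search-space shapes, giving λ = 0.240, K = 0.035; with these
the engine's decoy hit rate matches the Poisson expectation 1 − e^(−E)
within binomial error (asserted in the suite). E-values are comparable
within this engine, which is all the pipeline needs — every reported
quantity is a proportion at a cutoff, not an absolute significance.

Whole-proteome and whole-genome steps seed candidate subjects by exact
k-mer matches (k = 5 for protein–protein, k = 6 on six-frame translations)
before aligning, the same heuristic family BLAST uses; sensitivity loss is
negligible for the similarity levels the cascade must detect (a homologue
pair at 50% identity over 200 residues shares ~6 expected 5-mers on the
diagonal). Searches where weak random-level hits matter — the
reversed-proteome decoy curves read at generous cutoffs up to E = 1 — use
exhaustive alignment instead (automatic below 400 focal genes, the scale
the calibration runs at). Stop codons translate to `*`, which scores −4
against every residue. No low-complexity masking is applied anywhere; the
composition filter is known to create artefacts for exactly the weak-signal
searches this pipeline lives on, so its absence is a feature, not a gap.
An adapter shells out to BLAST+ (`blastp`/`tblastn`, tabular output) when
the binaries are on PATH; the cascade logic is engine-independent and a
concordance test checks hit/no-hit agreement on unambiguous pairs.

## Calibration

False homologies are matches of focal proteins against the
character-reversed target proteome (plus the reversed opposite region for
micro-synteny genes) — reversal preserves length and composition but
biological sequences do not evolve by reversal, so every such match is
spurious. Across the default cutoff grid {10⁻²⁰, 10⁻¹⁵, 10⁻¹⁰, 10⁻⁷, 10⁻⁶,
10⁻⁵, 10⁻⁴, 10⁻³, 10⁻², 10⁻¹, 1} two rules select operating points:

* **phylostratigraphy-optimal** — the largest cutoff whose false-homology
  proportion over the whole focal proteome is strictly below 5%
  (sensitivity-first);
* **MCC-optimal** — sequence-detected micro-synteny homologies are TP,
  undetectable ones FN, reversed matches FP, reversed non-matches TN; the
  cutoff maximizing the Matthews correlation coefficient wins, with ties
  after rounding to three decimals resolved toward the larger cutoff.

The FP/TN denominator is the whole focal proteome (the natural reading of a
proteome-wide decoy proportion); restricting it to micro-synteny genes is
available by passing a filtered `reversed_evalues` map.

## Estimators

For one pair: n focal genes examined, X with no similarity anywhere in the
target (proteome at the pair's cutoff, translated genome at 10⁻⁶), d the
proportion of micro-synteny genes without similarity **computed over the
same search set as X** — i.e. the local ±2 kb translated step is excluded
from d, otherwise d and X/n would measure different detection protocols and
their ratio would be biased. The contribution of divergence beyond
recognition to genes without similarity is d/(X/n), capped at 1 with a
warning (sampling noise can push d above X/n at desk scale). Standard
errors are binomial, √(p(1−p)/count).

The rate fit regresses d on divergence time by OLS with a free intercept
(two-sided slope test); the through-origin slope is reported alongside,
since forcing d(0) = 0 is defensible but not obviously right once anchor
noise exists. Phylostrata are the nested ancestral branches of the focal
lineage; a gene's stratum is the youngest one whose subtree contains every
species it matches (equivalently, the stratum of its farthest match), and
genes matching nothing are focal-specific. The TRG contribution of a
stratum divides the proportion of outside-stratum-block-bearing genes that
are TRGs of the stratum by the overall TRG fraction, capped at 1. The
lineage-specific screen keeps genes with undetectable homologues in ≥ 2
target species that are not exactly a clade of the target tree and with no
match in any more distant target, and reports the parsimony loss branch
(MRCA of the focal species and the undetectable-homologue species);
non-binary nodes flag the candidate ambiguous rather than dropping it.
`rank_effect_size` provides the two-sided Mann–Whitney Z (tie-corrected
normal approximation) and Rosenthal's R = Z/√N for comparing imported
covariates (e.g. dN/dS tables) inside vs outside micro-synteny; computing
dN/dS itself is out of scope.

## Simulator

One ancestral genome (default 1,000 genes over 4 chromosomes, lengths
~N(200, 50) codons, uniform residue composition) is held fixed as the focal
genome; each target derives from it so that several targets at different
divergence times share a coherent focal side. Per target: a per-gene
substitution fraction ~N(mean, sd) truncated to [0, 0.6] is applied with a
flat exchangeability over amino acids (the pipeline needs graded similarity
decay, not a realistic rate matrix); a fraction `f_scrambled` of surviving
genes is residue-shuffled and re-sampled (≤ 100 draws) until the best local
alignment against the ancestral sequence has E > 10⁻³ at the pairwise
search-space size — the strictest space the pipeline will evaluate, so the
planted pairs are undetectable by construction; genes are lost
(`p_loss` = 0.05), tandem-duplicated into the same orthology group
(`p_tandem_dup` = 0.02), born de novo on each side (`p_denovo` = 0.05), and
`n_inversions` = 5 segments (geometric length, mean ~6) flip order and
strand. CDS are uniform-codon back-translations; chromosomes concatenate
Poisson-length random spacers (mean 200 nt) with gene sequences, so GFF,
protein, CDS and genome FASTA round-trip exactly through the readers.

The emitted orthology map contains only detectably related pairs —
scrambled pairs are excluded by construction, mirroring the premise that
orthology databases cannot group homologues with no similarity (an
`include_scrambled_in_orthology` flag exists for stress tests). The ground
truth records per-gene origin classes that partition the focal gene set,
the planted d (scrambled ÷ surviving-context genes) and the planted X/n
(scrambled + lost + de novo focal ÷ all focal genes).

What the simulator does *not* emulate: indels and alignment-length
variation, intron structure, codon-usage and composition bias,
low-complexity sequence, isoform variety (one isoform per simulated gene,
though the data model and searches handle many), and realistic intergenic
content. Passing recovery tests therefore shows the estimators are correct
under the stated generative model, not that real-data hit rates will match;
on real genomes the aligner statistics, masking policy and orthology
quality dominate.

## Validation design and problem sizes

Parameter recovery (planted f ∈ {0, 0.05, 0.2, 0.5}, 1,000-gene genomes,
20 seeds each) runs with target-side insertion processes disabled
(`p_tandem_dup = 0`, `p_denovo_target = 0`, `n_inversions = 0`): an
insertion or inversion boundary landing between the anchors of a lost or de
novo focal gene creates apparent micro-synteny around a non-homologue, a
false-positive class the estimator counts by design — it is an upper bound
on real data. With those processes off, no such configuration can arise,
the micro-synteny sample coincides with the generator's surviving-context
population, and the recovered d can differ from the planted value only
through search-layer misclassification — which is exactly what the coverage
test then measures. (The planted d is conditioned on surviving context
because micro-synteny inclusion depends on neighbour statuses: against an
unconditional rate the estimator's sampling variance exceeds binomial at
high planted rates, a property of the sampling design, not of any
implementation.) With the rearrangement processes on, the same machinery
demonstrates the upper-bound behaviour instead. Losses and focal-side de
novo births stay enabled so the contribution d/(X/n) is a genuine ratio
below one.

The trend experiment uses 600-gene genomes at five time points with planted
d = 0.02·t and substitution level 0.05 + 0.06·t; the null calibration of
the slope test feeds the fitter binomially sampled d values directly (500
replicates), which isolates the estimator from simulation cost. Calibration
curves run at 120–150 genes where the reversed search is exhaustive.
These sizes were chosen as the smallest at which binomial standard errors
are tight enough for the coverage assertions to be informative.

## Numerical and degenerate-input conventions

Hits order by (E-value, −bitscore, subject id); co-optimal alignment spans
break ties toward the lowest query start, then subject start. Chromosome
ends clip flanking regions and terminate neighbour walks without error;
genes on 1–2-gene scaffolds simply never anchor a block. Zero-margin
confusion tables define MCC = 0. A pair with no micro-synteny genes has no
curve and no estimate (flagged, never silently zero). Scrambling rejects
inputs shorter than 10 residues and homopolymer-like sequences that cannot
lose similarity. All statistical tests are two-sided. Every random choice
flows through one integer-seeded NumPy generator, and pipeline outputs are
byte-identical across reruns for a fixed seed.
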