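# Methods

`pansubspec` re-implements, as a tested and reusable library, the
comparative-genomics workflow used to dissect a bacterial species into
its subspecies: gene-family clustering, pan/core-genome profiling,
subspecies-specific core-genome extraction, ANI-based quality
control/deduplication/classification, a core-genome neighbour-joining
phylogeny, codon-usage-based screening for horizontally acquired genes,
and the cohort summary statistics. This note documents the models,
defaults and design choices, and what the synthetic cohorts do and do
not establish about real data.

## Synthetic cohorts

Real inputs for this kind of study are hundreds of annotated assemblies.
The simulator (`pansubspec.simulate`) replaces them with desk-scale
cohorts whose structure is known exactly, so every downstream stage can
be scored against planted truth.

**Family universe.** Gene families come in four tiers: species *core*
(prevalence 1.0), per-subspecies *markers* (default prevalence 0.9),
*shell* (Bernoulli presence with per-family probability drawn from
U(0.3, 0.7)) and *cloud* (U(0.02, 0.15)). Each family has one ancestral
CDS sampled codon-by-codon: amino acids uniform, synonymous codons from
a usage profile. The host profile favours G/C third positions with odds
`alien_bias` (default 4), emulating a high-GC organism; alien genes are
sampled from the mirrored A/T-favouring profile. The mean per-synonymous-
family Kullback-Leibler divergence between the two profiles is 0.82 nats
at the default bias; generation refuses profiles below the configured
minimum separation (0.5 nats).

**Divergence model.** Each subspecies derives a family variant from the
ancestor by independent per-site substitution at half the configured
inter-subspecies rate; each genome derives its gene copy from the
subspecies variant at half the intra-subspecies rate. Expected pairwise
distances therefore match the configured rates (0.015 within, ~0.065
between at the defaults, i.e. within-subspecies nucleotide identity
~98.5 % vs ~93.5 % between — the ordering, not the absolute range, of a
real three-subspecies taxon). Substitutions creating internal stop
codons are reverted. Genomes are a single contig of concatenated CDS
with 50-bp spacers; spacers are themselves inherited DNA (one ancestral
spacer per family slot, mutated down the same subspecies/genome
cascade), so whole-genome identity — and hence ANI — reflects the
configured divergences rather than being diluted by per-genome random
DNA. At the defaults, within-subspecies ANI lands at ~98–99 % and
between-subspecies at ~93.5–94 %, so an ANI cut of 96 % recovers the
three subspecies as single-linkage subgroups. No other intergenic
biology, rearrangements or strand variation is simulated (no downstream
stage is strand-sensitive).

**Aliens.** Two kinds of alien genes are planted. A per-subspecies pool
of alien accessory families is rotated across genomes so that each
genome's alien gene count matches the configured alien fraction
(default 0.2 of its CDS, the order of magnitude reported for
HGT-affected bifidobacterial genomes) while each pool family stays near
50 % in-group prevalence — below the subspecies-core rule. Additionally
one marker family per subspecies is alien, producing foreign
subspecies-core genes like those in the printed core-gene table. The
knobs `n_alien_pool_per_subspecies` and `n_alien_markers_per_subspecies`
are derived from the spec-level fields and rarely need touching.

**Planted complications.** Duplicate genomes are verbatim copies under
new identifiers. Mislabelled strains carry a wrong subspecies label but
true sequences. Quality violators each breach exactly one rule. Because
the classical absolute thresholds (2.2 Mb, 1600 CDS) cannot apply to
~0.1 Mb synthetic genomes, the generator emits a scaled
`ThresholdConfig` derived from the clean genomes (85 % of the minimum
observed size and CDS count; 10 contigs; 30-fold coverage); the rule
*structure* and strict inequalities are identical to the real ones,
which remain the package defaults. Coverage is synthesized metadata
(U(50, 100)), not computed from reads.

**Default cohort size.** 3 subspecies x 10 genomes with ~190 CDS each
(120 core, 6 markers, 40 shell, 90 cloud families, plus alien pools),
4 QC violators, 2 duplicates, 2 mislabels. These sizes keep the full
pipeline at a few CPU-minutes while leaving every recovery task
non-trivial.

**What passing does not show.** Synthetic genes have no paralogy beyond
chance, no domain shuffling, no fragmented assemblies, no GC gradients,
and mutation is uniform i.i.d.; real-data performance of the clustering
identity/coverage cutoffs, the ANI estimator and especially the
codon-usage HGT detector will be worse and should be validated against
external tools.

## Quality control and deduplication

A genome is discarded iff size < 2.2 Mb, CDS count < 1600, contigs
> 100, or (when coverage is known) coverage < 30-fold; all comparisons
are strict, matching the phrasing of the original selection rules, and
every violated rule is reported. Genomes without coverage metadata are
not discarded by the coverage rule but are listed as coverage-unknown.
Duplicates are connected components of the graph with edges where
symmetric ANI > 99.99 (strict); one representative per component is
kept — the largest genome, ties broken by lexicographically smallest
identifier (the original study does not state its choice; this one is
deterministic and reproducible).

## ANI engine

Fragment-based, fastANI-style in contract: the query is cut into
non-overlapping 1000-bp fragments (trailing remainder discarded), each
fragment is seeded into the reference by exact 16-mers sampled every
8 bp, seed hits vote for a diagonal, the winning diagonal (ties to the
leftmost reference position) is scored by ungapped identity over the
fragment, and fragments at >= 80 % identity count as mapped. ANI is the
mean identity of mapped fragments; the symmetric value is the
arithmetic mean of both directions; pairs with mapped fraction < 0.2
are flagged unreliable. Only the forward strand is searched — adequate
for the simulator's same-strand assemblies; real assemblies with
reverse-complemented contigs need a strand-aware ANI tool.
Subgrouping at an ANI cut is single-linkage (connected components of
the >= cut graph).

On planted substitution rates the estimator is unbiased to well within
0.1 percentage points because every mapped fragment is compared at the
true offset; mapping failures only begin to matter above ~15 %
divergence where 16-mer seeds become scarce.

## Gene-family clustering

Candidate pairs must share >= 2 amino-acid 5-mers (exact counting, no
sampling). This replaces the BLAST e-value heuristic of the original
pipeline: e-values are database-size dependent and irreproducible
without BLAST, whereas the binding constraints — >= 50 % identity over
>= 80 % of *both* proteins — are kept exactly. Candidates are aligned
globally (Needleman-Wunsch, BLOSUM62, BLAST-like affine gap cost
11 + L). Identity is matches over aligned columns excluding
terminal-gap columns; coverage of each sequence counts its residues
inside that core region, so fragments fail coverage rather than
deflating identity. Edges passing both rules are weighted by
identity x min(coverage), and clustered with MCL: self-loops set to the
maximum incident weight, column-stochastic normalization, expansion
(matrix squaring) alternating with inflation (elementwise power 2.0 and
renormalization), pruning below 1e-6, convergence when the largest
elementwise change is below 1e-8 (cap 200 iterations, warning on
non-convergence). Clusters are read off attractor rows; overlapping
attractor sets merge; unclaimed nodes follow their strongest column.
MCL runs per connected component (it cannot merge components), keeping
the dense matrices small. Multiple genes of one genome may share a
family; presence/absence later caps them at "present".

## Pan-genome statistics

The presence/absence matrix stores member counts (genomes x families).
Species core = families present in all genomes; truly unique genes
(TUGs) = families present in exactly one genome. Rarefaction draws
random genome orderings (default 100 permutations, seeded) and tracks
pan and core sizes along each prefix; openness is judged by the mean
number of newly added families over the last three steps, the tail
statistic used in the original analysis (no Heaps-law exponent is
fitted, deliberately). The subspecies-specific core of subspecies *s*
contains families at >= 85 % prevalence within *s* and present in at
most `other_prevalence_max` (default 0, strict absence) of each other
subspecies; the 85 % rule is applied to the prevalence fraction
directly (0.85 exactly at the boundary), and prevalence is always
computed on post-QC, post-dedup genomes under type-strain-corrected
labels (below).

## Phylogenomics

The original workflow concatenates core genes, aligns them with a
progressive MSA and builds an NJ tree from the alignment. Here the
distance between two genomes is the alignment-length-weighted mean of
per-core-family pairwise p-distances, each from a global alignment of
one representative member per genome (the longest protein, ties by
gene identifier). This is the one intentional methodological
substitution in the tree stage: it avoids re-implementing progressive
MSA while giving NJ an equivalent input up to MSA quality. NJ is the
canonical algorithm (Q-criterion, two-point branch lengths, final
three-way join); negative branch-length estimates are clamped to zero
with the deficit moved to the sibling edge. On additive matrices the
implementation reproduces path lengths to 1e-9 and the true topology —
its primary oracle. Bootstrap resamples core *families* with
replacement (gene-wise bootstrap; no concatenated alignment exists from
which to resample columns), rebuilds distances from cached per-family
matrices and reports for every internal edge the percentage of
replicate trees containing the same leaf bipartition (default 100
replicates, 1000 supported).

Classification assigns each genome to the subspecies of its highest-ANI
type strain; a genome is flagged misclassified when the assignment
contradicts its declared label, and ambiguous on a tie within 1e-9
(assigned to the lexicographically first subspecies). The pipeline
performs this reassignment *before* any per-subspecies analysis, so a
mislabelled strain cannot leak marker families into another
subspecies's out-group counts — mirroring the original study, which
corrected misclassified strains before the subspecies pan-genomes.

## HGT screen

A full genomic-island HMM (SIGI-HMM/Colombo) is not re-implemented; the
stage contract — a per-gene alien/native call and a per-genome alien
percentage — is preserved by an RSCU-deviation detector, and all
downstream statistics equally accept externally produced call tables in
the same TSV schema. Each gene's RSCU vector over the 59 informative
codons (codons of unobserved amino acids set to 1 by convention) is
compared to the genome's own profile (per-codon mean and SD across
genes, SD floored at 0.1); the score is the mean absolute standardized
deviation. Genes shorter than 100 codons face a threshold scaled by
(1 + 50/len).

The decision threshold defaults to 1.0. Calibration rationale: the
score is self-standardized, so native genes concentrate around the
half-normal mean (~0.8) with small spread regardless of the usage
profiles, while the genome's own alien content inflates the per-codon
SD and caps alien scores near sqrt((1-f)/f) for alien fraction f (2.0
at f = 0.2). A threshold of 1.0 sits ~3 SD above the native mode and
safely below that ceiling; at the default cohort conditions it yields
sensitivity 1.0 at false-positive rate 0.0 with no score overlap. A
higher threshold (e.g. 2.0) is mathematically unreachable by alien
genes at f = 0.2 and would drive sensitivity to zero. The sensitivity
parameter of the original external tool has no public formula and maps
to nothing here; the real-data HGT percentages are therefore ordering
targets only.

## Cohort statistics

`summarize_core_hgt` counts Native/Foreign core genes per subspecies;
percentages are emitted at full precision plus a display rounding
(half-away-from-zero at one decimal; integer-printed prevalences use
nearest integer). The packaged core-gene table reproduces the printed
counts (24/53/5 rows, 2/10/0 foreign); note 10/53 = 18.87 %, which the
source prints as 18.8 % — an irreducible rounding discrepancy, so only
the full-precision value is asserted machine-side. One-way ANOVA is
computed from first principles (between/within sums of squares, F upper
tail) and cross-checked against `scipy.stats.f_oneway` in the tests;
its type-I error is verified by simulation. The defense-vs-HGT relation
is read as the t-test of the Pearson correlation coefficient across
genomes (t = r sqrt((n-2)/(1-r^2))), the only reading compatible with
"negatively correlate ... t-test"; a Welch two-group alternative is
provided. Perfect correlations report p = 0 with a degeneracy flag;
zero-variance inputs report missing.

The defense-annotation fixture shipped with the package is a synthetic
stand-in (the per-strain table of the original study is
supplementary-only): subspecies sizes and complete-CRISPR counts match
the printed numbers exactly, R-M counts match the printed means/SDs at
printed precision, and the per-genome HGT percentages scatter around
the printed subspecies means with a planted negative dependence on R-M
count.

## Numerical and determinism choices

All randomness flows through `numpy.random.default_rng` seeded from
explicit configuration; identical configuration and seed produce
byte-identical FASTA/GFF3/TSV/Newick outputs (fixed orderings, `\n`
line endings). Alignment uses Biopython's `PairwiseAligner` (first
optimal alignment, deterministic). MCL tolerances are fixed (prune
1e-6, converge 1e-8). NJ ties resolve to the first minimum in row-major
order; dedup and representative ties resolve by size then identifier.

## Known limitations

- Forward-strand-only ANI; no reverse-complement seeding.
- Gene-wise (not column-wise) bootstrap differs from alignment
  bootstraps when per-gene alignments are short.
- The RSCU detector's operating point is demonstrated under planted
  profile separation >= 0.5 nats and genes >= 150 codons; amelioration
  of anciently transferred genes, length effects below 100 codons and
  highly biased native genes (e.g. ribosomal proteins) will erode it on
  real genomes.
- The simulator's QC thresholds are rescaled to synthetic genome sizes;
  absolute-threshold behaviour is tested separately at the classical
  values.
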