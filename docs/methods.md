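# Methods

This note documents the models, default parameters and design decisions
behind `sclonetrace`, and what the synthetic-data tests do and do not
establish about real data.

## The synthetic patient

`simulate.simulate_patient` draws one multi-site patient from a
`SimulationConfig`. The design mirrors a multi-region sampling study:
ordered sites labelled `N` (adjacent normal), `PT_R1..PT_Rk` (primary
tumor regions), and `LyM`/`LM`/`OM` (lymph-node, liver, omentum
metastases), each with a declared clone mixture. Tumor clones form a
rooted tree (root = precursor clone); the implicit clone `normal` is
diploid with no somatic mitochondrial mutations.

**Inheritance.** Copy-number events and private mitochondrial sites are
declared per clone but accumulate root-to-leaf: a child carries its
ancestors' events plus its own, with the child's event overriding an
ancestor's on overlap. This is what truncal/private semantics require — a
truncal mutation is present in every descendant clone, and a metastatic
clone carries its source clone's mutations plus extras.

**Expression.** Gene g in cell i has negative-binomial counts with mean
`base_mean[g] · (copy[g]/2) · lib[i] · 2^shift` and variance
`m + dispersion·m²`:

* `base_mean` ~ log-normal(μ = 1.5, σ = 2.4, natural log). σ sets the
  cross-gene structure that cell–cell Pearson correlations read; 2.4
  places good cells' second-max correlations around 0.8–0.9 with ~1300–
  1500 of 2000 genes detected, i.e. the regime of high-precision
  scRNA-seq that the 0.6-correlation filter presumes. Smaller σ produces
  data in which even healthy cells fail the published filter.
* `copy/2` is the dosage term: a single-copy gain (copy 3) scales means
  by 1.5, a loss (copy 1) by 0.5.
* `lib` ~ log-normal(0, 0.2) models library-size variation.
* `dispersion` = 0.2, a shared overdispersion typical of UMI counts.
* Driver-program genes shift by `2^log2_shift` (default 4-fold, 20 genes)
  in program-on cells. Program genes' baseline mean is floored at 5
  counts: a transcriptional program is by definition a set of expressed
  genes, and a fold change on an unexpressed gene is not a simulable
  phenotype. `program_penetrance` (default 1.0) lets only a fraction of a
  mutant clone switch the program on, emulating the situation where part
  of a mutant primary-tumor clone expresses the metastasis-associated
  program.

**Genome.** 22 autosomes + X with hg19-like lengths; genes are spread
proportionally to chromosome length and evenly spaced. Coordinates are
0-based half-open internally; user-facing mitochondrial positions are
1-based on the 16,569-bp circular genome.

**Mitochondrial read-out.** Site depth ~ Poisson(`mean_site_depth`,
default λ = 50), independent of nuclear expression depth (the simplest
model that still produces undeterminable states); alt reads ~
Binomial(depth, h(1−ε) + (1−h)ε) with sequencing error ε = 0.002 at
clone heteroplasmy h. `undetermined_fraction_target`, when set, solves
the Poisson CDF at depth 8 for λ instead — the two parameters are one
knob viewed from two sides.

**Injected QC failures.** `lowq_cell_fraction` (default 0.1) of cells are
spoiled by two mechanisms, exercising both arms of the cell filter:
half keep only 600 random genes (detection falls below 1000), half have
their gene labels permuted (detection is preserved, correlation to every
other cell collapses to ≈ 0).

**Default patient.** 300 cells (N 60, PT_R1 80, PT_R2 80, LyM 40,
LM 40); clones C1 (truncal), C2 and C3 (children of C1); truncal site
13368 homoplasmic in all tumor cells; C2 private 2897 at heteroplasmy
0.5, C3 private 10396 at 1.0 (levels {0, 0.5, 1.0}); CNVs +chr7 truncal,
−chr18 in C2, +chr20 in C3; LyM seeded from C2, LM from C3 — a
distinct-origins patient. Ground truth records per-cell clone labels, QC
flags, per-clone genotypes and copy profiles, and each metastasis's true
source clone (nearest ancestor-or-self of the metastatic clone present
in a primary region).

**What the simulator does not model.** No read-level data (FASTQ/BAM),
no doublets, no mtDNA selection/drift dynamics across divisions
(heteroplasmy is static per clone), no UMI saturation, no ambient RNA,
no correlation between mitochondrial coverage and nuclear library size.
Passing recovery tests therefore shows the pipeline is correct under
its stated assumptions, not that those assumptions hold in any given
real dataset.

## QC and normalization

TPM is per-cell count scaling to 10⁶ — with 3' UMI counting there is no
gene-length term. The cell filter is `genes_detected >= 1000` AND
`second_max_corr > 0.6`, thresholds applied literally (≥ and >). Design
points the published rule leaves open, fixed here and configurable:

* Correlation gene universe: per pair, the union of genes detected in at
  least one of the two cells, on log2(TPM+1).
* "Second maximum" is per cell against all other cells in the same
  matrix (one accidental twin cannot rescue a cell); correlations are
  within the provided matrix (per patient), not across a cohort.
* A zero-variance cell has undefined correlations and fails the
  criterion explicitly (`zero_variance` reason).
* Order of operations: cell filter, then TPM, then gene filter on the
  full-normalization TPM; TPM is not recomputed after gene filtering.
* No mitochondrial-read-fraction filter, deliberately: mitochondrial
  reads are the lineage signal here.

## Mitochondrial genotyping

The depth-9 determinability rule is fixed; the WT/HET/HOM cutoffs
(f ≤ 0.05 / f ≥ 0.95, minimum 2 alt reads) are conventional
heteroplasmy bounds, configurable per call. Depth is ref + alt; at a
multi-allelic site only the most frequent alt is counted (tumor mtDNA
sites are effectively biallelic). Tumor-specificity is judged against
normal epithelium only; with no normal cells the flag is unknown and a
warning is raised, because different developmental origins of a shared
mutation cannot be excluded computationally.

Clone clustering: pairwise distance = fraction of discordant states
among jointly determined informative sites (UNDET ignored; a pair with
no overlap gets distance 1), average linkage, cut at 0.2. The cut sits
between within-clone discordance (≈ classification error, ~0 at λ = 50)
and the smallest between-clone discordance in a three-site design (1/3).
Cells determined at no informative site are `unassigned`. Determinism:
cells are processed in lexicographic id order; clone names are ordered by
size.

## CNV inference

Defaults k = 101 genes, clamp ± 3, reference = normal-epithelial cells —
the conventions of the standard reference-based expression-CNV recipe.
Windows truncate at chromosome ends and never span chromosomes; a
chromosome with fewer than k genes shrinks the window with a warning
(with 2000 simulated genes every chromosome does; the events planted are
chromosome-scale, so this costs nothing). Median-centering is per cell
(the open choice; per-gene centering is the alternative), making
profiles invariant to cell-wide shifts.

Subclone calling: Ward/Euclidean on the windows whose cross-cell
variance exceeds the 0.75 quantile — copy-number structure concentrates
variance in affected windows, and uniform-noise windows only dilute the
silhouette. Cluster count = argmax of mean silhouette over 2..n_max
(ties → fewer clusters); if the best silhouette is below 0.2 the data
are called a single subclone (silhouette is undefined at k = 1, so a
floor is the only way to "reject all splits"; 0.2 is far above the
silhouette of pure-noise splits, ~0.05, and far below that of real
copy-number splits, ≳ 0.25).

WGS windows: fixed 10-Mb grid; per-sample normalization by total, then
per-window scaling by the cross-sample mean, giving the identity that
each window's mean ratio across samples is exactly 1; all-zero windows
are emitted as missing. `simulate_wgs_windows` generates matching bulk
counts (Poisson around length × mixture-averaged copy) for verification.

## Phylogeny and clone integration

Region distances are raw counts of differing loci over sites mutant in
≥ 2 samples, missing values handled pairwise (the cited distance
convention, without a variance correction). Neighbor joining is the
classic Saitou–Nei iteration; tie-breaks take the lexicographically
smallest taxon pair, so equidistant inputs are deterministic; negative
pendant lengths are floored at 0 with the deficit shifted to the sister
branch. On additive distances the reconstruction is exact (topology and
path lengths), which the tests verify against independently simulated
trees and against an independent NJ implementation.

Merged clones are (CNV subclone × mito clone) pairs with ≥ 3 cells
(`min_cells`); smaller pairs fold into the dominant pair with the
nearest consensus genotype, preferring pairs that share the CNV label,
so cell accounting is conserved. Origin inference uses mutation-set
containment: primary clone P qualifies as source of metastatic clone M
unless P is mutant at a site where M is determined wild-type; among
qualifiers the one sharing the most mutant sites wins (HET vs HOM is not
distinguished — heteroplasmic mutations drift toward homoplasmy along a
lineage, so state identity is not evidence). UNDET never contradicts.
No qualifier → `ambiguous`. The consistency score is the adjusted Rand
index between the two labelings on jointly assigned cells; the package
reports both labelings and the score rather than forcing agreement.

## Differential expression and markers

`thresh.test = 1.5` is implemented as a pre-filter on the absolute mean
log2(TPM+1) difference; the test is a two-sided Wilcoxon rank-sum
(asymptotic, tie-corrected — deterministic); BH correction runs over the
tested genes only, so FDR is conditional on the fold pre-filter (the
standard, if debatable, convention of the single-cell toolkits). No
detection-fraction filter is applied. Marker positivity is
log2(TPM+1) > 1 by default, with multi-marker queries requiring all
markers (double-positivity); pairwise region comparisons are Fisher
exact with BH. The pipeline's demonstration readout thresholds the top
differential gene at its cohort mean instead, so "positive" separates
program-level from baseline expression.

## Pipeline

Stages run in fixed order (simulate, qc, mito, cnv, lineage, phenotype)
with dependencies validated before execution. Per-stage seeds are the
first 31 bits of `np.random.SeedSequence(seed).spawn(i+1)[i]`, i the
stage index, so each stage is independently reproducible. The manifest
hashes every output file (SHA-256); reruns with the same config and seed
reproduce identical hashes. Problem sizes throughout (300-cell patients,
2000 genes, 20-seed recovery loops, 50-tree NJ sweeps, 50-seed null
calibrations) are the package's reference conditions: large enough for
the statistics they support, small enough to run interactively.

## Numerical notes and limitations

* Distances and Q-values use strict comparisons with 1e-12 slack for
  tie detection; Newick branch lengths print at full precision (%.17g).
* `wgs_window_ratios` requires a consistent window grid; inconsistent
  grids are an error, not an alignment attempt.
* The silhouette floor (0.2), the clustering cut (0.2) and the
  heteroplasmy cutoffs are scalar conventions, not fitted quantities;
  all are exposed as function parameters.
* Region genotype aggregation calls a region mutant at ≥ 20% determined
  mutant cells — a coarse majority rule appropriate for the clone sizes
  simulated, not for rare subclones.
* The merged-clone fold rule can absorb a genuine rare clone (< 3
  cells) into a neighbor; raising `min_cells` trades resolution for
  stability.
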