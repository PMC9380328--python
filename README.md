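# sclonetrace

Clonal lineage tracing of multi-site tumors from single-cell RNA-seq.

When a colorectal tumor and its lymph-node and liver metastases are
sampled region by region — together with adjacent normal tissue — the
same scRNA-seq data can answer three questions at once: *what does each
cell express*, *which copy-number subclone does it belong to*, and *which
mitochondrial lineage does it descend from*. Mitochondrial mutations are
covered deeply enough by 3' scRNA-seq reads to genotype per cell, and the
mutant-allele fraction (heteroplasmy) marks clones: a truncal homoplasmic
mutation tags all tumor cells, clone-private heteroplasmic mutations tag
lineages within them. `sclonetrace` implements that integrated analysis as
a tested, reusable library, and ships a synthetic-patient simulator with
known clonal ground truth so every step can be validated by parameter
recovery. It is aimed at computational biologists studying tumor clonal
architecture and metastatic seeding, and at method developers who need a
controlled testbed.

## What it computes

**QC and normalization.** A cell is retained iff it detects ≥ 1000 genes
and its second-largest pairwise Pearson correlation to the other cells
exceeds 0.6, computed on log2(TPM+1) over each pair's union of detected
genes. TPM is per-cell scaling of UMI counts to 10⁶ (no gene-length term).
Genes are kept when log2(TPM+1) > 1 in ≥ 4 cells.

**Mitochondrial genotyping.** For a cell-site pair with ref/alt read
counts, depth d = ref + alt and alt fraction f = alt/d:

    d < 9                 -> UNDET  (undeterminable)
    f <= 0.05 or alt < 2  -> WT
    f >= 0.95             -> HOM    (homoplasmic mutant)
    otherwise             -> HET    (heteroplasmic)

Sites mutated in ≥ 2 cells are lineage-informative; a site is
tumor-specific when no determined normal-epithelial cell is mutant at it.
Cells cluster into mitochondrial clones by average linkage on the
fraction of discordant determined states.

**CNV inference.** Per gene, subtract the normal-epithelium reference
mean of log2(TPM+1), clamp to [−3, 3], order genes along the genome,
moving-average over k = 101 genes within chromosomes, and median-center
per cell. Subclones are Ward clusters with a silhouette-chosen count.
Bulk WGS verification divides the genome into 10-Mb windows, normalizes
window counts by sample totals and scales each window by the cross-sample
mean, so diploid windows sit at ratio 1.

**Phylogeny and origins.** Regions are genotyped over mutations shared by
≥ 2 samples; distance = count of differing loci; the unrooted tree is
built by Saitou–Nei neighbor joining (Q(i,j) = (r−2)d(i,j) − R_i − R_j,
standard branch-length formulas, deterministic tie-breaks). Merged clones
are (CNV subclone × mitochondrial clone) pairs; each metastasis is traced
to the primary-tumor clone whose mutation set is a subset of its own
(metastases may gain private mutations).

**Genotype–phenotype.** Two-sided Wilcoxon rank-sum on genes whose mean
log2(TPM+1) difference reaches 1.5, BH-corrected; marker-positive cell
fractions per region compared by Fisher's exact test.

## Worked example

`examples/` holds one short script per capability. Tracing the
mitochondrial clones of the default simulated patient
(`python examples/03_mito_clones.py`):

```
informative sites (>= 2 mutant cells):
       n_mutant_cells  informative  tumor_specific  normal_mutated
pos
2897               66         True            True           False
10396              74         True            True           False
13368             215         True            True           False

mitochondrial clones: {'M1': 75, 'M2': 74, 'M3': 66, 'M4': 55}
per-clone consensus genotype:
pos 2897  10396 13368
M1     WT    WT   HOM
M2     WT   HOM   HOM
M3    HET    WT   HOM
M4     WT    WT    WT

adjusted Rand index vs true clones: 1.000
```

All three planted sites are recovered as tumor-specific informative
sites; site 13368 is homoplasmic in every tumor clone (truncal), while
2897 (heteroplasmy 0.5) and 10396 (1.0) split the tumor into its two
derived lineages; M4 is the normal epithelium. The ARI of 1.0 against the
simulator's truth means the clone assignment is exact. Continuing with
`examples/05_phylogeny_and_origins.py` prints the region NJ tree —
`(LyM:0,PT_R1:0,(N:1,(LM:0,PT_R2:0):1):1);` — in which the lymph-node
metastasis joins primary region 1 and the liver metastasis joins primary
region 2: the two metastases have distinct origins, and the inferred
source clones match the simulated seeding exactly.

A full end-to-end run from one config is
`sclonetrace run --config cfg.json` (or `examples/07_full_pipeline.py`);
every stage output is hashed into a manifest and reruns are byte-stable.

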