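"""Per-cell mitochondrial mutation states and mitochondrial clone calling.

Heteroplasmy — the mutant-allele fraction among a cell's many mtDNA
copies — is read out from scRNA-seq allele counts. A cell-site pair with
read depth below 9 is undeterminable (UNDET); otherwise the alt-allele
fraction f classifies the site as wild-type (f <= 0.05 or fewer than 2 alt
reads), homoplasmic mutant (f >= 0.95) or heteroplasmic (in between). The
WT/HET/HOM cutoffs are conventional and configurable; the depth-9 rule is
the determinability threshold used throughout.

Lineage-informative sites are those mutated in at least two cells; a site
is tumor-specific when no determined normal-epithelial cell is mutated at
it. Cells are grouped into mitochondrial clones by average-linkage
clustering of the pairwise discordance of determined states.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform

from .simulate import site_type

__all__ = ["STATES", "classify_site", "classify_table",
           "build_genotype_matrix", "cluster_mito_clones",
           "MitoGenotypeResult", "MitoCloneLabels", "pairwise_discordance",
           "export_vcf_like"]

STATES = ("WT", "HET", "HOM", "UNDET")

MIN_DEPTH = 9
HET_LOW = 0.05
HET_HIGH = 0.95
MIN_ALT = 2


def classify_site(ref: int, alt: int, *, min_depth: int = MIN_DEPTH,
                  het_low: float = HET_LOW, het_high: float = HET_HIGH,
                  min_alt: int = MIN_ALT) -> str:
    """State of one cell-site pair from its ref/alt read counts.

    Total on all nonnegative (ref, alt); monotone in the alt fraction at
    fixed depth. Raises ``ValueError`` on negative counts.
    """
    if ref < 0 or alt < 0:
        raise ValueError(f"negative allele counts: ref={ref}, alt={alt}")
    depth = ref + alt
    if depth < min_depth:
        return "UNDET"
    f = alt / depth
    if f <= het_low or alt < min_alt:
        return "WT"
    if f >= het_high:
        return "HOM"
    return "HET"


def classify_table(ref: np.ndarray, alt: np.ndarray, *,
                   min_depth: int = MIN_DEPTH, het_low: float = HET_LOW,
                   het_high: float = HET_HIGH,
                   min_alt: int = MIN_ALT) -> np.ndarray:
    """Vectorized :func:`classify_site` over aligned count arrays."""
    ref = np.asarray(ref)
    alt = np.asarray(alt)
    if (ref < 0).any() or (alt < 0).any():
        raise ValueError("negative allele counts in table")
    depth = ref + alt
    with np.errstate(invalid="ignore"):
        f = np.where(depth > 0, alt / np.maximum(depth, 1), 0.0)
    out = np.full(ref.shape, "HET", dtype=object)
    out[(f <= het_low) | (alt < min_alt)] = "WT"
    out[(f >= het_high) & (alt >= min_alt) & (f > het_low)] = "HOM"
    out[depth < min_depth] = "UNDET"
    return out


@dataclass
class MitoGenotypeResult:
    """Cell x site state matrix plus the informative-site annotation."""
    states: pd.DataFrame          # cells x positions, values in STATES
    allele_fraction: pd.DataFrame  # cells x positions, NaN where depth 0
    sites: pd.DataFrame           # per position: n_mutant_cells,
                                  # informative, tumor_specific, normal_mutated

    @property
    def informative_sites(self) -> pd.Index:
        return self.sites.index[self.sites["informative"]]


def build_genotype_matrix(allele_counts: pd.DataFrame,
                          cell_meta: pd.DataFrame,
                          min_cells_mutant: int = 2,
                          **classify_kwargs) -> MitoGenotypeResult:
    """Classify every (cell, site) pair and annotate informative sites.

    ``allele_counts`` is long-form (cell_id, pos, ref_count, alt_count);
    ``cell_meta`` is indexed by cell id with a ``site`` column whose labels
    distinguish normal tissue (N*) from tumor regions. Sites mutated
    (HET/HOM) in at least ``min_cells_mutant`` cells are informative;
    a site is tumor-specific when no determined normal cell is mutant at
    it, and sites mutated in normal cells are flagged separately so
    normal-subclone structure stays visible.
    """
    tbl = allele_counts.copy()
    tbl["state"] = classify_table(tbl["ref_count"].to_numpy(),
                                  tbl["alt_count"].to_numpy(),
                                  **classify_kwargs)
    depth = (tbl["ref_count"] + tbl["alt_count"]).to_numpy()
    with np.errstate(invalid="ignore"):
        tbl["af"] = np.where(depth > 0, tbl["alt_count"] / np.maximum(depth, 1),
                             np.nan)

    states = tbl.pivot(index="cell_id", columns="pos", values="state")
    states = states.fillna("UNDET").sort_index()
    af = tbl.pivot(index="cell_id", columns="pos", values="af").sort_index()

    mutant = states.isin(["HET", "HOM"])
    n_mutant = mutant.sum(axis=0)

    normal_cells = cell_meta.index[
        cell_meta["site"].map(site_type) == "normal"]
    normal_cells = states.index.intersection(normal_cells)
    if len(normal_cells) == 0:
        warnings.warn("no normal cells available; tumor-specificity flags "
                      "set to unknown", stacklevel=2)
        tumor_specific = pd.Series(pd.NA, index=states.columns, dtype=object)
        normal_mutated = pd.Series(pd.NA, index=states.columns, dtype=object)
    else:
        normal_mutated = mutant.loc[normal_cells].any(axis=0)
        tumor_specific = ~normal_mutated

    sites = pd.DataFrame({
        "n_mutant_cells": n_mutant,
        "informative": n_mutant >= min_cells_mutant,
        "tumor_specific": tumor_specific,
        "normal_mutated": normal_mutated,
    })
    sites.index.name = "pos"
    return MitoGenotypeResult(states=states, allele_fraction=af, sites=sites)


@dataclass
class MitoCloneLabels:
    """Cell -> mitochondrial clone assignment with per-clone consensus."""
    labels: pd.Series             # cell -> clone label or "unassigned"
    consensus: pd.DataFrame       # clone x informative position -> state

    @property
    def assigned(self) -> pd.Index:
        return self.labels.index[self.labels != "unassigned"]


def pairwise_discordance(states: pd.DataFrame) -> pd.DataFrame:
    """Fraction of discordant determined states for each cell pair.

    UNDET entries are ignored; a pair with no jointly determined site gets
    distance 1 (maximally uninformative).
    """
    code_map = {"WT": 0.0, "HET": 1.0, "HOM": 2.0, "UNDET": -1.0}
    codes = np.vectorize(code_map.__getitem__, otypes=[float])(
        states.to_numpy())
    det = codes >= 0
    n = codes.shape[0]
    diff = np.zeros((n, n))
    both = np.zeros((n, n))
    for s in range(codes.shape[1]):
        d = det[:, s]
        joint = np.outer(d, d)
        both += joint
        ne = codes[:, s][:, None] != codes[:, s][None, :]
        diff += joint & ne
    with np.errstate(invalid="ignore"):
        dist = np.where(both > 0, diff / np.maximum(both, 1), 1.0)
    np.fill_diagonal(dist, 0.0)
    return pd.DataFrame(dist, index=states.index, columns=states.index)


def cluster_mito_clones(geno: MitoGenotypeResult,
                        cut: float = 0.2,
                        min_determined: int = 1,
                        sites: pd.Index | None = None) -> MitoCloneLabels:
    """Group cells into mitochondrial clones over the informative sites.

    Average-linkage agglomerative clustering of the pairwise discordance
    matrix, cut at ``cut``; cells with fewer than ``min_determined``
    determined informative sites are "unassigned". Deterministic: cells
    are processed in lexicographic id order and clone labels (M1, M2, ...)
    are numbered by descending clone size, ties by smallest member id.
    """
    if sites is None:
        sites = geno.informative_sites
    cells = geno.states.index.sort_values()
    if len(sites) == 0:
        warnings.warn("empty informative site set: all cells unassigned",
                      stacklevel=2)
        labels = pd.Series("unassigned", index=cells, name="mito_clone")
        return MitoCloneLabels(labels=labels,
                               consensus=pd.DataFrame(columns=sites))

    sub = geno.states.loc[cells, sites]
    determined = (sub != "UNDET").sum(axis=1)
    usable = cells[determined >= min_determined]
    labels = pd.Series("unassigned", index=cells, name="mito_clone")

    if len(usable) == 1:
        labels[usable] = "M1"
    elif len(usable) > 1:
        dist = pairwise_discordance(sub.loc[usable])
        Z = average(squareform(dist.to_numpy(), checks=False))
        raw = fcluster(Z, t=cut, criterion="distance")
        order = sorted(
            np.unique(raw),
            key=lambda c: (-(raw == c).sum(), usable[raw == c][0]))
        rename = {c: f"M{i + 1}" for i, c in enumerate(order)}
        labels[usable] = [rename[c] for c in raw]

    consensus = _consensus_genotypes(sub, labels)
    return MitoCloneLabels(labels=labels, consensus=consensus)


def _consensus_genotypes(states: pd.DataFrame,
                         labels: pd.Series) -> pd.DataFrame:
    """Per-clone modal determined state per site (UNDET when no cell in
    the clone is determined there)."""
    rows = {}
    for clone in sorted(set(labels) - {"unassigned"}):
        sub = states.loc[labels.index[labels == clone]]
        cons = {}
        for pos in states.columns:
            counts = sub[pos][sub[pos] != "UNDET"].value_counts()
            cons[pos] = counts.index[0] if len(counts) else "UNDET"
        rows[clone] = cons
    return pd.DataFrame(rows, index=states.columns).T


def export_vcf_like(geno: MitoGenotypeResult,
                    allele_counts: pd.DataFrame) -> str:
    """Minimal VCF-style text export (CHROM=chrM, per-cell AD) of all sites."""
    cells = list(geno.states.index)
    lines = ["##fileformat=VCFv4.2",
             '##FORMAT=<ID=AD,Number=2,Type=Integer,'
             'Description="Ref,Alt read depth">',
             "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
             + "\t".join(cells)]
    ad_map = {(r.cell_id, r.pos): (r.ref_count, r.alt_count)
              for r in allele_counts.itertuples()}
    for pos in geno.states.columns:
        fields = ["chrM", str(int(pos)), ".", "N", "N", ".", "PASS", ".", "AD"]
        for c in cells:
            ref, alt = ad_map.get((c, pos), (0, 0))
            fields.append(f"{ref},{alt}")
        lines.append("\t".join(fields))
    return "\n".join(lines) + "\n"
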