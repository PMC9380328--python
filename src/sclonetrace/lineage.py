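"""Region-level phylogenies and clone integration.

Tumor regions are compared over mutations shared by at least two samples;
the region distance is the raw count of loci at which two regions differ
(sites missing in either member of a pair are skipped). The unrooted tree
is built by the Saitou-Nei neighbor-joining algorithm, re-implemented here
with a deterministic tie-break and non-negative branch lengths (a negative
pendant length is floored at zero and the deficit moved to its sister).

Clone integration crosses the CNV subclone and mitochondrial clone
labelings into merged clones and infers, for each metastatic site, its
source clone in the primary tumor: the primary clone whose mutation set is
contained in the metastatic clone's (metastases may gain private mutations
on top of their source's; a site counts as a contradiction only when the
primary clone is mutant and the metastasis is determined wild-type).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import dendropy
import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .simulate import site_type

__all__ = ["region_distance_matrix", "neighbor_joining", "nj_newick",
           "CloneModel", "integrate_clones_and_infer_origins",
           "aggregate_region_genotypes"]


def region_distance_matrix(rg: pd.DataFrame,
                           min_shared: int = 2) -> pd.DataFrame:
    """Pairwise count-of-differences over shared mutations.

    ``rg`` is samples x sites with values 0 (wild-type), 1 (mutant) or NaN
    (missing). Sites mutant in fewer than ``min_shared`` samples are
    dropped first. Distance(i, j) counts retained sites, non-missing in
    both i and j, at which the two differ. A pair with no jointly
    determined site is an error naming the pair.
    """
    if rg.shape[0] < 3:
        raise ValueError(f"need >= 3 samples, got {rg.shape[0]}")
    keep = (rg == 1).sum(axis=0) >= min_shared
    sub = rg.loc[:, keep]
    M = sub.to_numpy(dtype=float)
    n = M.shape[0]
    D = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        both = ~np.isnan(M[i]) & ~np.isnan(M[j])
        if not both.any():
            raise ValueError(
                "no jointly determined retained site for sample pair "
                f"({rg.index[i]!r}, {rg.index[j]!r})")
        D[i, j] = D[j, i] = float((M[i, both] != M[j, both]).sum())
    return pd.DataFrame(D, index=rg.index, columns=rg.index)


def _check_distance_matrix(D: pd.DataFrame) -> None:
    A = D.to_numpy(dtype=float)
    if A.shape[0] != A.shape[1] or not np.allclose(A, A.T, atol=1e-12):
        raise ValueError("distance matrix must be square and symmetric")
    if (A < 0).any():
        raise ValueError("distance matrix must be nonnegative")
    if not np.allclose(np.diag(A), 0.0, atol=1e-12):
        raise ValueError("distance matrix must have a zero diagonal")
    if A.shape[0] < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")


def nj_newick(D: pd.DataFrame) -> str:
    """Newick string of the unrooted NJ tree for distance matrix ``D``.

    Classic Saitou-Nei iteration: at each step the pair minimizing
    Q(i,j) = (r-2) d(i,j) - R_i - R_j is joined, with pendant lengths
    l_i = d/2 + (R_i - R_j) / (2(r-2)) and l_j = d - l_i, and distances to
    the new node d(u,k) = (d(i,k) + d(j,k) - d(i,j)) / 2. Ties pick the
    lexicographically smallest taxon-name pair; negative pendant lengths
    are floored at zero with the deficit shifted to the sister branch. The
    final three nodes join at an unresolved (trifurcating) center via the
    three-point formulas.
    """
    _check_distance_matrix(D)
    labels = [str(x) for x in D.index]
    mat = D.to_numpy(dtype=float).copy()
    # each active node: (newick subtree, sort key = smallest leaf label)
    nodes = [(lab, lab) for lab in labels]

    def fmt(x: float) -> str:
        return f"{x:.17g}"

    while len(nodes) > 3:
        r = len(nodes)
        R = mat.sum(axis=1)
        best, best_q = None, np.inf
        for i, j in combinations(range(r), 2):
            q = (r - 2) * mat[i, j] - R[i] - R[j]
            key = tuple(sorted((nodes[i][1], nodes[j][1])))
            if q < best_q - 1e-12 or (abs(q - best_q) <= 1e-12
                                      and (best is None or key < best[2])):
                best, best_q = (i, j, key), q
        i, j, _ = best
        d = mat[i, j]
        li = d / 2.0 + (R[i] - R[j]) / (2.0 * (r - 2))
        lj = d - li
        if li < 0:
            li, lj = 0.0, d
        if lj < 0:
            li, lj = d, 0.0
        sub = (f"({nodes[i][0]}:{fmt(li)},{nodes[j][0]}:{fmt(lj)})",
               min(nodes[i][1], nodes[j][1]))
        keep = [k for k in range(r) if k not in (i, j)]
        new_d = 0.5 * (mat[i, keep] + mat[j, keep] - d)
        mat = mat[np.ix_(keep, keep)]
        mat = np.pad(mat, ((0, 1), (0, 1)))
        mat[-1, :-1] = mat[:-1, -1] = np.maximum(new_d, 0.0)
        nodes = [nodes[k] for k in keep] + [sub]

    (a, _), (b, _), (c, _) = nodes
    dab, dac, dbc = mat[0, 1], mat[0, 2], mat[1, 2]
    la = max((dab + dac - dbc) / 2.0, 0.0)
    lb = max((dab + dbc - dac) / 2.0, 0.0)
    lc = max((dac + dbc - dab) / 2.0, 0.0)
    return f"({a}:{fmt(la)},{b}:{fmt(lb)},{c}:{fmt(lc)});"


def neighbor_joining(D: pd.DataFrame) -> dendropy.Tree:
    """Unrooted NJ tree (dendropy ``Tree``) with branch lengths; see
    :func:`nj_newick` for the algorithmic contract."""
    newick = nj_newick(D)
    tree = dendropy.Tree.get(data=newick, schema="newick")
    tree.is_rooted = False
    return tree


def aggregate_region_genotypes(states: pd.DataFrame, cell_meta: pd.DataFrame,
                               min_fraction: float = 0.2) -> pd.DataFrame:
    """Region x site 0/1/NaN genotype matrix from single-cell mito states.

    A region is mutant at a site when at least ``min_fraction`` of its
    determined cells are HET/HOM; missing when no cell is determined.
    """
    rows = {}
    for region, cells in cell_meta.groupby("site").groups.items():
        sub = states.loc[states.index.intersection(cells)]
        det = (sub != "UNDET").sum(axis=0)
        mut = sub.isin(["HET", "HOM"]).sum(axis=0)
        with np.errstate(invalid="ignore"):
            frac = mut / det.replace(0, np.nan)
        rows[region] = (frac >= min_fraction).astype(float).where(det > 0)
    return pd.DataFrame(rows).T


@dataclass
class CloneModel:
    """Merged clone assignments and metastatic-origin inference."""
    cell_labels: pd.Series        # cell -> merged clone label
    clone_table: pd.DataFrame     # per merged clone: n_cells, cnv_subclone,
                                  # mito_clone
    clone_genotypes: pd.DataFrame  # merged clone x site consensus state
    origins: pd.DataFrame         # per metastatic site: source_clone,
                                  # n_shared_sites, shared_sites, status
    consistency_ari: float        # ARI between CNV and mito labelings


def _genotype_distance(a: pd.Series, b: pd.Series) -> float:
    det = (a != "UNDET") & (b != "UNDET")
    if not det.any():
        return 1.0
    return float((a[det] != b[det]).mean())


def _mutant_set(genotype: pd.Series) -> set:
    return set(genotype.index[genotype.isin(["HET", "HOM"])])


def integrate_clones_and_infer_origins(
        mito, cnvl, cell_meta: pd.DataFrame,
        min_cells: int = 3) -> CloneModel:
    """Cross CNV subclones with mitochondrial clones and locate each
    metastasis's source clone in the primary tumor.

    Merged clones are (CNV subclone, mito clone) pairs with at least
    ``min_cells`` cells; smaller pairs are folded into the dominant pair
    with the nearest consensus mitochondrial genotype (preferring pairs
    sharing the CNV subclone), so every cell stays accounted for. The
    consistency score is the adjusted Rand index between the two input
    labelings over their shared assigned cells.
    """
    m_labels, c_labels = mito.labels, cnvl.labels
    common = m_labels.index.intersection(c_labels.index)
    if len(common) == 0:
        raise ValueError("mito and CNV labelings cover disjoint cell sets")

    pairs = pd.DataFrame({
        "cnv": c_labels.loc[common],
        "mito": m_labels.loc[common],
    })
    pair_key = pairs["cnv"] + "|" + pairs["mito"]
    counts = pair_key.value_counts()
    dominant = counts.index[counts >= min_cells]
    if len(dominant) == 0:
        dominant = counts.index[:1]

    # consensus genotype per pair from mito-clone consensus
    def pair_genotype(key: str) -> pd.Series:
        mclone = key.split("|", 1)[1]
        if mclone in mito.consensus.index:
            return mito.consensus.loc[mclone]
        return pd.Series("UNDET", index=mito.consensus.columns)

    fold_to = {}
    for key in counts.index:
        if key in set(dominant):
            fold_to[key] = key
            continue
        g = pair_genotype(key)
        same_cnv = [d for d in dominant
                    if d.split("|", 1)[0] == key.split("|", 1)[0]]
        pool = same_cnv if same_cnv else list(dominant)
        fold_to[key] = min(
            pool, key=lambda d: (_genotype_distance(g, pair_genotype(d)),
                                 -counts[d], d))

    merged = pair_key.map(fold_to)
    rename = {k: f"K{i + 1}" for i, k in enumerate(
        merged.value_counts().index)}
    cell_labels = merged.map(rename)
    cell_labels.name = "merged_clone"

    clone_rows, geno_rows = [], {}
    for key, name in rename.items():
        cnv_s, mito_s = key.split("|", 1)
        cells = cell_labels.index[cell_labels == name]
        clone_rows.append({"merged_clone": name, "n_cells": len(cells),
                           "cnv_subclone": cnv_s, "mito_clone": mito_s})
        geno_rows[name] = pair_genotype(key)
    clone_table = pd.DataFrame(clone_rows).set_index("merged_clone")
    clone_genotypes = pd.DataFrame(geno_rows).T

    # --- metastatic origin inference ---------------------------------
    meta = cell_meta.loc[common]
    stype = meta["site"].map(site_type)
    primary_cells = meta.index[stype == "primary"]
    primary_clones = [
        k for k in clone_table.index
        if (cell_labels.loc[primary_cells] == k).sum() >= min_cells]

    origin_rows = []
    for site in sorted(meta.loc[stype == "metastasis", "site"].unique()):
        site_cells = meta.index[meta["site"] == site]
        met_clone = cell_labels.loc[site_cells].value_counts().index[0]
        met_geno = clone_genotypes.loc[met_clone]
        met_mut = _mutant_set(met_geno)
        candidates = []
        for k in primary_clones:
            g = clone_genotypes.loc[k]
            contradiction = any(
                g[s] in ("HET", "HOM") and met_geno[s] == "WT"
                for s in g.index)
            if not contradiction:
                candidates.append((len(_mutant_set(g) & met_mut), k))
        if candidates:
            n_shared, source = max(candidates, key=lambda t: (t[0], t[1]))
            shared = sorted(_mutant_set(clone_genotypes.loc[source]) & met_mut)
            origin_rows.append({"site": site, "met_clone": met_clone,
                                "source_clone": source,
                                "n_shared_sites": n_shared,
                                "shared_sites": shared, "status": "resolved"})
        else:
            origin_rows.append({"site": site, "met_clone": met_clone,
                                "source_clone": "ambiguous",
                                "n_shared_sites": 0, "shared_sites": [],
                                "status": "ambiguous"})
    origins = pd.DataFrame(
        origin_rows, columns=["site", "met_clone", "source_clone",
                              "n_shared_sites", "shared_sites", "status"])

    both = common[(m_labels.loc[common] != "unassigned")]
    ari = adjusted_rand_score(m_labels.loc[both], c_labels.loc[both]) \
        if len(both) else float("nan")

    return CloneModel(cell_labels=cell_labels, clone_table=clone_table,
                      clone_genotypes=clone_genotypes, origins=origins,
                      consistency_ari=float(ari))
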