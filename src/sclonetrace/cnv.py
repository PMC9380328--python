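"""Copy-number inference from expression, subclone calling, and bulk-WGS
window ratios.

The single-cell procedure follows the standard reference-based recipe:
per gene, subtract the mean log2(TPM+1) of normal-epithelial reference
cells; clamp residuals to [-3, 3]; order genes along the genome and take a
centered moving average of k consecutive genes within each chromosome
(windows never span chromosomes, and shrink at chromosome ends); finally
subtract each cell's median window score so a cell-wide shift cancels.
Subclones are called by Ward clustering of the profiles with the cluster
count chosen by mean silhouette. Bulk WGS verification divides the genome
into 10-Mb windows, normalizes each sample's window counts by its total,
and scales each window by the cross-sample mean, so a diploid genome sits
at ratio 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import AgglomerativeClustering
from sklearn.metrics import silhouette_score

from ._genome import order_genes

__all__ = ["CnvProfileMatrix", "CnvSubcloneLabels", "infer_cnv_profile",
           "call_cnv_subclones", "wgs_window_ratios",
           "expected_profile_from_copies"]

CLAMP = 3.0
DEFAULT_WINDOW_GENES = 101
WGS_WINDOW_SIZE = 10_000_000


@dataclass
class CnvProfileMatrix:
    """Smoothed relative-expression scores: one window per ordered gene."""
    scores: pd.DataFrame    # cells x windows (log2 scale)
    windows: pd.DataFrame   # per window: chrom, start, end, gene_id
    k: int


@dataclass
class CnvSubcloneLabels:
    labels: pd.Series          # cell -> subclone label (S1, S2, ...)
    mean_profiles: pd.DataFrame  # subclone x window mean score
    silhouette: float | None   # of the accepted partition (None for k=1)


def _moving_average_by_chrom(values: np.ndarray, chrom: np.ndarray,
                             k: int) -> np.ndarray:
    """Centered moving average of width k within each chromosome block;
    the window truncates at block ends. ``values`` is cells x genes."""
    out = np.empty_like(values)
    half = k // 2
    warned = False
    for c in pd.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        block = values[:, idx]
        g = block.shape[1]
        if g < k and not warned:
            warnings.warn(
                f"chromosome {c} has {g} genes < window size {k}; "
                "windows shrink to the available genes", stacklevel=3)
            warned = True
        csum = np.cumsum(block, axis=1)
        csum = np.concatenate([np.zeros((block.shape[0], 1)), csum], axis=1)
        lo = np.maximum(np.arange(g) - half, 0)
        hi = np.minimum(np.arange(g) + half + 1, g)
        out[:, idx] = (csum[:, hi] - csum[:, lo]) / (hi - lo)
    return out


def infer_cnv_profile(log_expr: pd.DataFrame, gene_coords: pd.DataFrame,
                      reference_cells, k: int = DEFAULT_WINDOW_GENES,
                      clamp: float = CLAMP) -> CnvProfileMatrix:
    """Per-cell smoothed relative-expression CNV profile.

    Parameters
    ----------
    log_expr
        cells x genes log2(TPM+1).
    gene_coords
        DataFrame indexed by gene id with chrom/start/end; genes missing
        coordinates are dropped (with a logged count).
    reference_cells
        Ids of normal-epithelial cells whose mean defines copy 2.
    """
    reference_cells = pd.Index(reference_cells)
    if len(reference_cells) == 0:
        raise ValueError("reference_cells must be nonempty")
    missing = reference_cells.difference(log_expr.index)
    if len(missing):
        raise ValueError(f"reference cells absent from matrix: "
                         f"{list(missing[:5])}")

    coords = gene_coords.loc[gene_coords.index.intersection(log_expr.columns)]
    coords = coords.dropna(subset=["chrom", "start"])
    n_dropped = log_expr.shape[1] - len(coords)
    if n_dropped:
        warnings.warn(f"dropping {n_dropped} genes without coordinates",
                      stacklevel=2)
    ordered = order_genes(coords)
    X = log_expr[ordered].to_numpy(dtype=float)

    ref_mean = log_expr.loc[reference_cells, ordered].to_numpy().mean(axis=0)
    rel = np.clip(X - ref_mean, -clamp, clamp)

    chrom = coords.loc[ordered, "chrom"].to_numpy()
    smooth = _moving_average_by_chrom(rel, chrom, k)
    smooth = smooth - np.median(smooth, axis=1, keepdims=True)

    windows = coords.loc[ordered, ["chrom", "start", "end"]].copy()
    windows["gene_id"] = ordered
    windows.index = pd.Index([f"W{i:05d}" for i in range(len(ordered))],
                             name="window")
    scores = pd.DataFrame(smooth, index=log_expr.index, columns=windows.index)
    return CnvProfileMatrix(scores=scores, windows=windows, k=k)


def expected_profile_from_copies(copies: pd.Series,
                                 profile: CnvProfileMatrix) -> pd.Series:
    """True copy-number track mapped onto a profile's windows.

    ``copies`` is per-gene integer copy number; the log2(copy/2) track is
    smoothed with the same moving window so it is directly comparable with
    inferred scores.
    """
    ordered = profile.windows["gene_id"]
    track = np.log2(copies.loc[ordered].to_numpy(dtype=float) / 2.0)[None, :]
    chrom = profile.windows["chrom"].to_numpy()
    smooth = _moving_average_by_chrom(track, chrom, profile.k)[0]
    return pd.Series(smooth, index=profile.windows.index)


def call_cnv_subclones(profiles: CnvProfileMatrix, n_max: int = 8,
                       min_silhouette: float = 0.2,
                       var_quantile: float = 0.75) -> CnvSubcloneLabels:
    """Ward/Euclidean hierarchical clustering with the cluster count picked
    by maximum mean silhouette over 2..n_max (ties -> fewest clusters); if
    no split reaches ``min_silhouette`` the data are a single subclone.

    Clustering and silhouette operate on the windows whose cross-cell
    variance exceeds the ``var_quantile`` quantile (copy-number structure
    concentrates variance in the affected windows; uniform-noise windows
    only dilute the separation). Labels S1, S2, ... are ordered by
    descending subclone size (ties by smallest member cell id), so the
    partition is invariant to cell order.
    """
    X = profiles.scores.to_numpy(dtype=float)
    cells = profiles.scores.index
    if X.shape[0] < 2:
        raise ValueError("need at least 2 cells to call subclones")
    if 0.0 < var_quantile < 1.0 and X.shape[1] > 1:
        v = X.var(axis=0)
        keep = v >= np.quantile(v, var_quantile)
        if keep.any():
            X = X[:, keep]

    order = np.argsort(cells.to_numpy())    # lexicographic, deterministic
    Xo = X[order]
    if np.allclose(Xo, Xo[0][None, :]):
        warnings.warn("all CNV profiles identical: single subclone",
                      stacklevel=2)
        best_raw, best_sil = np.zeros(X.shape[0], dtype=int), None
    else:
        best_raw, best_sil, best_k = None, -np.inf, None
        for k in range(2, min(n_max, X.shape[0] - 1) + 1):
            raw = AgglomerativeClustering(n_clusters=k, linkage="ward"
                                          ).fit_predict(Xo)
            sil = silhouette_score(Xo, raw, metric="euclidean")
            if sil > best_sil + 1e-12:     # strict: ties keep smaller k
                best_raw, best_sil, best_k = raw, sil, k
        if best_raw is None or best_sil < min_silhouette:
            best_raw, best_sil = np.zeros(X.shape[0], dtype=int), None

    labels_o = pd.Series(best_raw, index=cells[order])
    uniq = sorted(set(best_raw),
                  key=lambda c: (-(best_raw == c).sum(),
                                 labels_o.index[best_raw == c][0]))
    rename = {c: f"S{i + 1}" for i, c in enumerate(uniq)}
    labels = labels_o.map(rename).reindex(cells)
    labels.name = "cnv_subclone"

    means = profiles.scores.groupby(labels).mean()
    return CnvSubcloneLabels(labels=labels, mean_profiles=means,
                             silhouette=best_sil)


def wgs_window_ratios(counts: pd.DataFrame,
                      window_size: int = WGS_WINDOW_SIZE) -> pd.DataFrame:
    """Cross-sample scaled read-depth ratios on a fixed 10-Mb window grid.

    ``counts`` is long-form (sample, chrom, start, end, count) on a
    consistent window grid across >= 2 samples. Each sample's window count
    is normalized by the sample total, then each window is divided by the
    cross-sample mean of normalized values, so every window's mean ratio
    over samples is exactly 1. Windows with zero counts in all samples get
    a missing ratio.
    """
    samples = counts["sample"].unique()
    if len(samples) < 2:
        raise ValueError("wgs_window_ratios needs >= 2 samples")
    wide = counts.pivot_table(index=["chrom", "start", "end"],
                              columns="sample", values="count", sort=False)
    if wide.isna().any().any():
        raise ValueError("inconsistent window grid across samples")
    norm = wide / wide.sum(axis=0)
    mean = norm.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = norm.div(mean, axis=0)
    ratio[mean == 0] = np.nan

    out = []
    for s in samples:
        t = pd.DataFrame({
            "sample": s,
            "chrom": [i[0] for i in wide.index],
            "start": [i[1] for i in wide.index],
            "end": [i[2] for i in wide.index],
            "count": wide[s].to_numpy(),
            "normalized": norm[s].to_numpy(),
            "ratio": ratio[s].to_numpy(),
        })
        out.append(t)
    return pd.concat(out, ignore_index=True)
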