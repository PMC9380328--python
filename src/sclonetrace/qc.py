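"""Cell and gene quality filters and TPM normalization.

The cell filter keeps a cell only if it (a) detects at least 1000 genes
and (b) has a second-largest pairwise Pearson correlation to the other
cells above 0.6 — a single accidental twin cannot rescue a low-quality
cell. Correlations are computed on log2(TPM+1), for each cell pair over
the union of genes detected in at least one of the two cells. TPM here is
plain per-cell count scaling to one million (3' UMI counting carries no
gene-length term). The gene filter keeps genes with log2(TPM+1) strictly
above 1 in at least four cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = ["QcReport", "tpm_normalize", "log2_tpm", "filter_cells",
           "filter_genes", "pairwise_second_max_corr"]

MIN_GENES = 1000
MIN_SECOND_CORR = 0.6
GENE_FILTER_MIN_CELLS = 4
GENE_FILTER_CUTOFF = 1.0


@dataclass
class QcReport:
    """Per-cell QC metrics and the overall retained fraction."""
    table: pd.DataFrame        # genes_detected, second_max_corr, pass flags, reason
    retained_fraction: float

    @property
    def passed(self) -> pd.Index:
        return self.table.index[self.table["passed"]]


def _dense_counts(adata: ad.AnnData) -> np.ndarray:
    X = adata.X
    return np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X)


def tpm_normalize(adata: ad.AnnData) -> ad.AnnData:
    """Return a copy with layers ``tpm`` and ``log2_tpm`` added.

    Every cell's TPM row sums to 1e6. A cell with zero total counts cannot
    be normalized and raises ``ValueError`` naming the cell.
    """
    counts = _dense_counts(adata).astype(float)
    totals = counts.sum(axis=1)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError("cannot TPM-normalize all-zero cell(s): "
                         + ", ".join(adata.obs_names[zero[:5]]))
    out = adata.copy()
    tpm = counts / totals[:, None] * 1e6
    out.layers["tpm"] = tpm
    out.layers["log2_tpm"] = np.log2(tpm + 1.0)
    return out


def log2_tpm(adata: ad.AnnData) -> pd.DataFrame:
    """log2(TPM+1) as a cells x genes DataFrame (normalizing on the fly
    when the layer is absent)."""
    if "log2_tpm" not in adata.layers:
        adata = tpm_normalize(adata)
    return pd.DataFrame(adata.layers["log2_tpm"], index=adata.obs_names,
                        columns=adata.var_names)


def pairwise_second_max_corr(counts: np.ndarray) -> np.ndarray:
    """Per-cell second-largest Pearson correlation to any other cell.

    For each pair, the correlation is computed on log2(TPM+1) restricted to
    genes detected (count > 0) in at least one of the two cells. A pair
    with zero variance on that gene set contributes correlation -inf
    (a constant cell can never satisfy the correlation criterion).
    """
    n = counts.shape[0]
    if n < 3:
        raise ValueError(f"second-maximum correlation needs >= 3 cells, got {n}")
    totals = counts.sum(axis=1, keepdims=True).astype(float)
    totals[totals == 0] = 1.0
    X = np.log2(counts / totals * 1e6 + 1.0)
    D = (counts > 0)

    second = np.empty(n)
    Xsq = X * X
    for i in range(n):
        M = (D | D[i]).astype(float)            # n x g union masks
        cnt = M.sum(axis=1)
        a = X[i]
        sa = M @ a
        saa = M @ (a * a)
        sb = (M * X).sum(axis=1)
        sbb = (M * Xsq).sum(axis=1)
        sab = (M * X * a).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            cov = sab - sa * sb / cnt
            va = saa - sa * sa / cnt
            vb = sbb - sb * sb / cnt
            r = cov / np.sqrt(va * vb)
        r[~np.isfinite(r)] = -np.inf
        r[i] = -np.inf                           # exclude self
        top2 = np.partition(r, n - 2)[n - 2]
        second[i] = top2
    return second


def filter_cells(adata: ad.AnnData,
                 min_genes: int = MIN_GENES,
                 min_second_corr: float = MIN_SECOND_CORR,
                 ) -> tuple[QcReport, ad.AnnData]:
    """Apply the two-criterion cell filter; return the report and the
    retained submatrix. Deterministic and idempotent."""
    counts = _dense_counts(adata)
    genes_detected = (counts > 0).sum(axis=1)
    second = pairwise_second_max_corr(counts)

    pass_genes = genes_detected >= min_genes
    pass_corr = second > min_second_corr
    passed = pass_genes & pass_corr
    reason = []
    for ok_g, ok_c, s in zip(pass_genes, pass_corr, second):
        parts = []
        if not ok_g:
            parts.append("low_genes")
        if not ok_c:
            parts.append("zero_variance" if np.isneginf(s)
                         else "low_correlation")
        reason.append(";".join(parts) if parts else "ok")
    reason = np.asarray(reason, dtype=object)

    table = pd.DataFrame({
        "genes_detected": genes_detected,
        "second_max_corr": second,
        "pass_genes": pass_genes,
        "pass_corr": pass_corr,
        "passed": passed,
        "reason": reason,
    }, index=adata.obs_names)
    report = QcReport(table=table,
                      retained_fraction=float(passed.mean()))
    return report, adata[passed].copy()


def filter_genes(adata: ad.AnnData,
                 min_cells: int = GENE_FILTER_MIN_CELLS,
                 cutoff: float = GENE_FILTER_CUTOFF) -> pd.Index:
    """Genes with log2(TPM+1) > ``cutoff`` in at least ``min_cells`` cells.

    Operates on the full-normalization TPM of the (QC-passing) matrix; TPM
    is not recomputed after dropping genes.
    """
    lt = log2_tpm(adata)
    keep = (lt.to_numpy() > cutoff).sum(axis=0) >= min_cells
    return adata.var_names[keep]
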