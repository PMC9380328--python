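"""On-disk layout for synthetic datasets: MTX counts plus TSV/JSON tables.

A dataset directory holds exactly six data files — counts.mtx, cells.tsv,
genes.tsv, allele_counts.tsv, driver_genotypes.tsv, ground_truth.json —
plus a manifest.json recording each file's size and SHA-256. The reader
reconstructs a :class:`~sclonetrace.simulate.SyntheticDataset` that is
integer-exact against the written one.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .simulate import GroundTruth, SyntheticDataset

__all__ = ["write_dataset", "read_dataset", "sha256_file"]

DATA_FILES = ("counts.mtx", "cells.tsv", "genes.tsv", "allele_counts.tsv",
              "driver_genotypes.tsv", "ground_truth.json")


def _json_default(o):
    if hasattr(o, "item"):      # numpy scalar
        return o.item()
    raise TypeError(f"not JSON serializable: {type(o)}")


def sha256_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_dataset(ds: SyntheticDataset, out_dir: str | Path) -> dict:
    """Write all tables of ``ds`` under ``out_dir``; return the manifest.

    Raises ``ValueError`` on an empty dataset (nothing is written) and the
    usual ``OSError`` on an unwritable path.
    """
    if ds.adata.n_obs == 0 or ds.adata.n_vars == 0:
        raise ValueError("refusing to write an empty dataset "
                         f"({ds.adata.n_obs} cells x {ds.adata.n_vars} genes)")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    scipy.io.mmwrite(out / "counts.mtx", sp.coo_matrix(ds.adata.X),
                     field="integer")
    ds.adata.obs.to_csv(out / "cells.tsv", sep="\t")
    ds.adata.var.to_csv(out / "genes.tsv", sep="\t")
    ds.allele_counts.to_csv(out / "allele_counts.tsv", sep="\t", index=False)
    ds.driver_genotypes.to_csv(out / "driver_genotypes.tsv", sep="\t",
                               index=False)

    t = ds.truth
    truth_json = {
        "cells": t.cells.reset_index().to_dict(orient="list"),
        "clone_heteroplasmy": {
            "clones": list(t.clone_heteroplasmy.index),
            "positions": [int(p) for p in t.clone_heteroplasmy.columns],
            "values": t.clone_heteroplasmy.to_numpy().tolist(),
        },
        "clone_copy": {
            "clones": list(t.clone_copy.index),
            "genes": list(t.clone_copy.columns),
            "values": t.clone_copy.to_numpy().astype(int).tolist(),
        },
        "metastasis_sources": t.metastasis_sources,
        "clone_tree": t.clone_tree,
    }
    (out / "ground_truth.json").write_text(
        json.dumps(truth_json, default=_json_default))

    manifest = {"files": {}}
    for name in DATA_FILES:
        p = out / name
        manifest["files"][name] = {"bytes": p.stat().st_size,
                                   "sha256": sha256_file(p)}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def read_dataset(in_dir: str | Path) -> SyntheticDataset:
    """Read a dataset directory written by :func:`write_dataset`."""
    d = Path(in_dir)
    X = sp.csr_matrix(scipy.io.mmread(d / "counts.mtx")).astype(np.int64)
    obs = pd.read_csv(d / "cells.tsv", sep="\t", index_col=0)
    obs.index = obs.index.astype(str)
    var = pd.read_csv(d / "genes.tsv", sep="\t", index_col=0,
                      dtype={"chrom": str})
    adata = ad.AnnData(X=X, obs=obs, var=var)
    allele_counts = pd.read_csv(d / "allele_counts.tsv", sep="\t")
    driver = pd.read_csv(d / "driver_genotypes.tsv", sep="\t")

    tj = json.loads((d / "ground_truth.json").read_text())
    cells = pd.DataFrame(tj["cells"]).set_index("cell_id")
    ch = tj["clone_heteroplasmy"]
    clone_h = pd.DataFrame(np.asarray(ch["values"], dtype=float),
                           index=ch["clones"], columns=ch["positions"])
    cc = tj["clone_copy"]
    clone_copy = pd.DataFrame(np.asarray(cc["values"], dtype=int),
                              index=cc["clones"], columns=cc["genes"])
    clone_copy.columns.name = "gene_id"
    from .simulate import heteroplasmy_to_state
    truth = GroundTruth(
        cells=cells,
        clone_heteroplasmy=clone_h,
        clone_mito_genotype=clone_h.map(heteroplasmy_to_state),
        clone_copy=clone_copy,
        metastasis_sources=dict(tj["metastasis_sources"]),
        clone_tree={k: v for k, v in tj["clone_tree"].items()},
    )
    return SyntheticDataset(adata=adata, allele_counts=allele_counts,
                            driver_genotypes=driver, truth=truth)
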