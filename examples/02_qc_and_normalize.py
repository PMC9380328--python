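"""Cell filter, gene filter and TPM normalization.

A cell is kept when it detects >= 1000 genes AND its second-largest
pairwise Pearson correlation (on log2(TPM+1), per-pair union of detected
genes) exceeds 0.6. Genes are kept when log2(TPM+1) > 1 in >= 4 cells.
On the simulated patient the removed set should be exactly the injected
low-quality cells.
"""

import sclonetrace as st

ds = st.simulate_patient(st.default_config(seed=1))
report, retained = st.filter_cells(ds.adata)

print(f"retained {len(retained)} of {ds.adata.n_obs} cells "
      f"({report.retained_fraction:.1%})")
print("failure reasons:",
      dict(report.table.loc[~report.table['passed'], 'reason']
           .value_counts()))
injected = set(ds.truth.cells.index[ds.truth.cells["qc_fail"]])
removed = set(report.table.index[~report.table["passed"]])
print(f"removed set == injected low-quality set: {removed == injected}")

retained = st.tpm_normalize(retained)
print(f"TPM row sums (should all be 1e6): "
      f"{retained.layers['tpm'].sum(axis=1).round(6).min()} .. "
      f"{retained.layers['tpm'].sum(axis=1).round(6).max()}")
genes = st.filter_genes(retained)
print(f"genes passing expression filter: {len(genes)} of {retained.n_vars}")
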