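"""Simulate one multi-site colorectal-cancer-like patient.

Builds the default 300-cell patient (normal tissue, two primary-tumor
regions, lymph-node and liver metastases; three tumor clones) and prints
what was planted: the clone tree, the mitochondrial mutations with their
heteroplasmy, the copy-number events, and the true source clone of each
metastasis.
"""

import sclonetrace as st

cfg = st.default_config(seed=1)
ds = st.simulate_patient(cfg)

print(f"cells x genes: {ds.adata.shape}")
print(f"sites: {dict(ds.adata.obs['site'].value_counts())}")
print(f"clone tree (child -> parent): {cfg.clone_tree}")
print("clone heteroplasmy (mutant mtDNA fraction per site):")
print(ds.truth.clone_heteroplasmy.round(2))
print(f"metastasis source clones (truth): {ds.truth.metastasis_sources}")
print(f"injected QC-failing cells: {int(ds.truth.cells['qc_fail'].sum())}")
# Site 13368 is truncal and homoplasmic (fraction 1.0 in every tumor
# clone); 2897 and 10396 are clone-private, so they mark lineages.
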