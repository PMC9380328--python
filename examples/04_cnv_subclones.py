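"""Expression-inferred CNV profiles, subclones, and WGS verification.

Per gene, the normal-epithelium mean log2(TPM+1) is subtracted, residuals
are clamped to [-3, 3], smoothed along the genome (101-gene windows that
never span chromosomes) and median-centered per cell. Ward clustering
with a silhouette-chosen cluster count calls subclones; simulated bulk
WGS 10-Mb window ratios verify the planted events at the DNA level.
"""

import warnings

import numpy as np

import sclonetrace as st

warnings.simplefilter("ignore")   # small-chromosome window-shrink notices

cfg = st.default_config(seed=1)
ds = st.simulate_patient(cfg)
_, retained = st.filter_cells(ds.adata)
retained = st.tpm_normalize(retained)
log_tpm = st.log2_tpm(retained)
reference = retained.obs_names[retained.obs["site"] == "N"]

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    prof = st.infer_cnv_profile(log_tpm, retained.var, reference)
labels = st.call_cnv_subclones(prof)
print(f"CNV subclones: {dict(labels.labels.value_counts())} "
      f"(silhouette {labels.silhouette:.2f})")

# each subclone's mean profile vs the matched true copy-number track
truth = ds.truth.cells.loc[prof.scores.index]
for clone in ("C1", "C2", "C3"):
    cells = truth.index[truth["clone"] == clone]
    track = st.expected_profile_from_copies(ds.truth.clone_copy.loc[clone],
                                            prof)
    r = np.corrcoef(prof.scores.loc[cells].mean(axis=0), track)[0, 1]
    print(f"clone {clone}: Pearson(inferred profile, true copy track) "
          f"= {r:.2f}")

# bulk WGS verification: the chr7 truncal gain shows up as ratio > 1 in
# tumor samples and < 1 in the normal sample
wgs = st.simulate_wgs_windows(cfg)
ratios = st.wgs_window_ratios(wgs)
chr7 = ratios[ratios["chrom"] == "7"].groupby("sample")["ratio"].mean()
print("\nmean WGS ratio over chr7 windows per sample:")
print(chr7.round(3).to_string())
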