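import warnings

import pytest

import sclonetrace as st


@pytest.fixture(scope="session")
def default_patient():
    """The reference 300-cell patient (seed 1), shared across test modules."""
    cfg = st.default_config(seed=1)
    return cfg, st.simulate_patient(cfg)


@pytest.fixture(scope="session")
def qc_passed(default_patient):
    """QC report plus TPM-normalized retained matrix of the reference patient."""
    _, ds = default_patient
    report, retained = st.filter_cells(ds.adata)
    retained = st.tpm_normalize(retained)
    return report, retained, st.log2_tpm(retained)


@pytest.fixture(scope="session")
def cnv_profiles(default_patient, qc_passed):
    _, ds = default_patient
    _, retained, log_tpm = qc_passed
    reference = retained.obs_names[retained.obs["site"] == "N"]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        profiles = st.infer_cnv_profile(log_tpm, retained.var, reference)
    return profiles


@pytest.fixture(scope="session")
def mito_result(default_patient, qc_passed):
    _, ds = default_patient
    _, retained, _ = qc_passed
    ac = ds.allele_counts[ds.allele_counts["cell_id"].isin(retained.obs_names)]
    geno = st.build_genotype_matrix(ac, retained.obs)
    clones = st.cluster_mito_clones(geno)
    return geno, clones
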