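"""Expression-inferred CNV profiles, subclone calling, WGS window ratios."""

import warnings

import numpy as np
import pandas as pd
import pytest

import sclonetrace as st
from sclonetrace.cnv import CnvProfileMatrix
from sclonetrace.simulate import NORMAL_CLONE


def _toy_matrix(values, chroms=None):
    values = np.asarray(values, dtype=float)
    n, g = values.shape
    chroms = chroms or ["1"] * g
    log_expr = pd.DataFrame(values, index=[f"c{i}" for i in range(n)],
                            columns=[f"g{j}" for j in range(g)])
    coords = pd.DataFrame({"chrom": chroms,
                           "start": np.arange(g) * 100,
                           "end": np.arange(g) * 100 + 50},
                          index=log_expr.columns)
    return log_expr, coords


class TestInferProfile:
    def test_empty_reference_is_an_error(self):
        log_expr, coords = _toy_matrix(np.ones((3, 5)))
        with pytest.raises(ValueError, match="reference"):
            st.infer_cnv_profile(log_expr, coords, [])

    def test_reference_cells_center_near_zero(self, default_patient,
                                              qc_passed, cnv_profiles):
        _, retained, _ = qc_passed
        reference = retained.obs_names[retained.obs["site"] == "N"]
        group_mean = cnv_profiles.scores.loc[reference].mean(axis=0)
        assert group_mean.abs().mean() < 0.05

    def test_clamp_bounds_gene_contributions(self):
        # a +5.2 residual contributes exactly as +3 would
        base = np.zeros((4, 9))
        hi, capped = base.copy(), base.copy()
        hi[0, 4], capped[0, 4] = 5.2, 3.0
        for vals in (hi, capped):
            log_expr, coords = _toy_matrix(vals)
            prof = st.infer_cnv_profile(log_expr, coords,
                                        ["c1", "c2", "c3"], k=3)
            if vals is hi:
                got_hi = prof.scores
            else:
                got_capped = prof.scores
        pd.testing.assert_frame_equal(got_hi, got_capped)

    def test_cell_wide_shift_cancelled_by_median_centering(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(0, 1, size=(5, 40))
        shifted = vals.copy()
        shifted[2] += 7.0
        le1, coords = _toy_matrix(vals)
        le2, _ = _toy_matrix(shifted)
        ref = ["c0", "c1"]
        # clamp wide so the clamp itself doesn't interfere with the shift
        p1 = st.infer_cnv_profile(le1, coords, ref, k=5, clamp=50)
        p2 = st.infer_cnv_profile(le2, coords, ref, k=5, clamp=50)
        assert np.allclose(p1.scores.loc["c2"], p2.scores.loc["c2"])

    def test_windows_never_span_chromosomes(self):
        # step on chromosome boundary stays sharp: genes of chrom 2 are
        # unaffected by chrom 1 values
        vals = np.zeros((3, 10))
        vals[0, :5] = 3.0
        log_expr, coords = _toy_matrix(vals, chroms=["1"] * 5 + ["2"] * 5)
        prof = st.infer_cnv_profile(log_expr, coords, ["c1", "c2"], k=3)
        chrom2 = prof.windows.index[prof.windows["chrom"] == "2"]
        scores = prof.scores.loc["c0"]
        # chrom-2 windows are all at the cell's baseline (equal values)
        assert np.allclose(scores[chrom2], scores[chrom2].iloc[0])

    def test_planted_arm_gain_separates_carriers(self, default_patient,
                                                 cnv_profiles):
        _, ds = default_patient
        truth = ds.truth.cells.loc[cnv_profiles.scores.index]
        arm = cnv_profiles.windows.index[cnv_profiles.windows["chrom"] == "20"]
        carrier = (truth["clone"] == "C3").to_numpy()
        normal = (truth["clone"] == NORMAL_CLONE).to_numpy()
        s_c = cnv_profiles.scores.loc[carrier, arm].mean(axis=1)
        s_n = cnv_profiles.scores.loc[normal, arm].mean(axis=1)
        se = np.sqrt(s_c.var() / len(s_c) + s_n.var() / len(s_n))
        assert s_c.mean() > s_n.mean()
        assert (s_c.mean() - s_n.mean()) / se > 3

    def test_profiles_track_true_copy_number(self, default_patient,
                                             cnv_profiles):
        _, ds = default_patient
        truth = ds.truth.cells.loc[cnv_profiles.scores.index]
        for clone in ("C1", "C2", "C3"):
            cells = truth.index[truth["clone"] == clone]
            mean_prof = cnv_profiles.scores.loc[cells].mean(axis=0)
            track = st.expected_profile_from_copies(
                ds.truth.clone_copy.loc[clone], cnv_profiles)
            r = np.corrcoef(mean_prof, track)[0, 1]
            assert r > 0.5


class TestSubclones:
    def test_two_disjoint_planted_clones_recovered_exactly(self):
        cfg = st.default_config(
            seed=11, sites={"N": 40, "PT_R1": 100},
            site_composition={"N": {NORMAL_CLONE: 1.0},
                              "PT_R1": {"C1": 0.5, "C2": 0.5}},
            clone_tree={"C1": None, "C2": "C1"},
            cnv_events={"C1": [st.CnvEvent("1", 0, 249_000_000, 3)],
                        "C2": [st.CnvEvent("2", 0, 243_000_000, 1)]},
            private_mito_sites={"C2": [st.MitoSite(2897, 1.0)]},
            lowq_cell_fraction=0.0, driver=st.DriverSpec())
        ds = st.simulate_patient(cfg)
        lt = st.log2_tpm(st.tpm_normalize(ds.adata))
        tumor = ds.adata.obs_names[ds.adata.obs["site"] == "PT_R1"]
        ref = ds.adata.obs_names[ds.adata.obs["site"] == "N"]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            prof = st.infer_cnv_profile(lt, ds.adata.var, ref)
        sub = CnvProfileMatrix(scores=prof.scores.loc[tumor],
                               windows=prof.windows, k=prof.k)
        labels = st.call_cnv_subclones(sub)
        truth = ds.truth.cells.loc[tumor, "clone"]
        assert labels.mean_profiles.shape[0] == 2
        grp = labels.labels.groupby(truth).nunique()
        assert (grp == 1).all()            # each true clone -> one label

    def test_all_normal_profiles_stay_single_cluster(self):
        cfg = st.default_config(
            seed=12, sites={"N": 60, "PT_R1": 30},
            site_composition={"N": {NORMAL_CLONE: 1.0},
                              "PT_R1": {NORMAL_CLONE: 1.0}},
            cnv_events={}, private_mito_sites={}, lowq_cell_fraction=0.0)
        ds = st.simulate_patient(cfg)
        lt = st.log2_tpm(st.tpm_normalize(ds.adata))
        ref = ds.adata.obs_names[ds.adata.obs["site"] == "N"]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            prof = st.infer_cnv_profile(lt, ds.adata.var, ref)
        labels = st.call_cnv_subclones(prof)
        assert labels.mean_profiles.shape[0] == 1
        assert labels.silhouette is None

    def test_partition_invariant_to_cell_order(self, cnv_profiles):
        labels = st.call_cnv_subclones(cnv_profiles)
        perm = np.random.default_rng(3).permutation(len(cnv_profiles.scores))
        shuffled = CnvProfileMatrix(
            scores=cnv_profiles.scores.iloc[perm],
            windows=cnv_profiles.windows, k=cnv_profiles.k)
        labels_p = st.call_cnv_subclones(shuffled)
        pd.testing.assert_series_equal(labels_p.labels.sort_index(),
                                       labels.labels.sort_index())

    def test_identical_profiles_single_cluster_with_warning(self):
        prof = CnvProfileMatrix(
            scores=pd.DataFrame(np.ones((5, 8)),
                                index=[f"c{i}" for i in range(5)]),
            windows=pd.DataFrame(), k=1)
        with pytest.warns(UserWarning, match="identical"):
            labels = st.call_cnv_subclones(prof)
        assert (labels.labels == "S1").all()


class TestWgsWindows:
    def _grid(self, counts_by_sample):
        rows = []
        for sample, counts in counts_by_sample.items():
            for w, c in enumerate(counts):
                rows.append((sample, "1", w * 10_000_000,
                             (w + 1) * 10_000_000, c))
        return pd.DataFrame(rows, columns=["sample", "chrom", "start", "end",
                                           "count"])

    def test_identical_uniform_samples_give_unit_ratios(self):
        tbl = self._grid({"A": [100] * 8, "B": [100] * 8})
        out = st.wgs_window_ratios(tbl)
        assert np.allclose(out["ratio"], 1.0)

    def test_doubled_window_matches_hand_computation(self):
        W = 10                        # windows per sample; one doubled in A
        counts = {"A": [200] + [100] * (W - 1), "B": [100] * W}
        out = st.wgs_window_ratios(self._grid(counts))
        a0 = out[(out["sample"] == "A") & (out["start"] == 0)]["ratio"].iloc[0]
        b0 = out[(out["sample"] == "B") & (out["start"] == 0)]["ratio"].iloc[0]
        # by hand: A total = (W+1), B total = W (in units of 100)
        na, nb = 2 / (W + 1), 1 / W
        mean = (na + nb) / 2
        assert a0 == pytest.approx(na / mean)
        assert b0 == pytest.approx(nb / mean)
        assert a0 == pytest.approx(4 * W / (3 * W + 1))   # -> 4/3 as W grows

    def test_cross_sample_mean_ratio_is_one(self):
        rng = np.random.default_rng(5)
        tbl = self._grid({s: rng.integers(50, 500, 12).tolist()
                          for s in "ABCD"})
        out = st.wgs_window_ratios(tbl)
        means = out.groupby("start")["ratio"].mean()
        assert np.allclose(means, 1.0, atol=1e-9)

    def test_zero_window_emitted_missing(self):
        tbl = self._grid({"A": [100, 0, 100], "B": [100, 0, 100]})
        out = st.wgs_window_ratios(tbl)
        assert out[out["start"] == 10_000_000]["ratio"].isna().all()

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError, match="2 samples"):
            st.wgs_window_ratios(self._grid({"A": [1, 2, 3]}))
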