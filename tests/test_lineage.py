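"""Region distances, neighbor joining, clone integration and origins."""

import random

import dendropy
import numpy as np
import pandas as pd
import pytest
from dendropy.calculate import treecompare

import sclonetrace as st
from sclonetrace.mito import MitoCloneLabels
from sclonetrace.cnv import CnvSubcloneLabels
from sclonetrace.simulate import NORMAL_CLONE


def random_tree_and_distances(n_taxa, rng):
    """Random tree with uniform(0.5, 2) branch lengths and its additive
    leaf-to-leaf distance matrix (the independent oracle for NJ)."""
    taxa = [f"T{i}" for i in range(n_taxa)]
    ns = dendropy.TaxonNamespace(taxa)
    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n_taxa,
        taxon_namespace=ns, rng=rng)
    for e in tree.edges():
        if e.length is not None:
            e.length = rng.uniform(0.5, 2.0)
    pdm = tree.phylogenetic_distance_matrix()
    D = pd.DataFrame(0.0, index=taxa, columns=taxa)
    for t1 in ns:
        for t2 in ns:
            D.loc[t1.label, t2.label] = pdm.distance(t1, t2)
    return tree, D


class TestRegionDistance:
    def test_identical_vectors_distance_zero(self):
        rg = pd.DataFrame([[1, 0, 1]] * 3, index=list("abc"))
        D = st.region_distance_matrix(rg, min_shared=2)
        assert (D.to_numpy() == 0).all()

    def test_counting_definition(self):
        rg = pd.DataFrame([[1, 1, 1, 0, 1, 1, 1, 0, 1, 1],
                           [1, 0, 0, 1, 1, 1, 1, 0, 1, 1],
                           [1, 1, 1, 0, 1, 1, 1, 0, 1, 1]],
                          index=list("abc"), dtype=float)
        # keep all sites regardless of sharing to test the raw count
        D = st.region_distance_matrix(rg, min_shared=0)
        assert D.loc["a", "b"] == 3
        assert D.loc["a", "c"] == 0

    def test_matches_brute_force_hamming(self):
        rng = np.random.default_rng(0)
        rg = pd.DataFrame(rng.integers(0, 2, size=(6, 40)).astype(float),
                          index=[f"s{i}" for i in range(6)])
        D = st.region_distance_matrix(rg, min_shared=2)
        keep = [c for c in rg.columns if (rg[c] == 1).sum() >= 2]
        for i in rg.index:
            for j in rg.index:
                brute = (rg.loc[i, keep] != rg.loc[j, keep]).sum()
                assert D.loc[i, j] == brute

    def test_missing_handled_pairwise(self):
        rg = pd.DataFrame([[1, 1, 0], [1, np.nan, 1], [1, 1, 1]],
                          index=list("abc"))
        D = st.region_distance_matrix(rg, min_shared=2)
        # site 1 missing in b: a-b compared on sites 0 and 2 only
        assert D.loc["a", "b"] == 1

    def test_pair_without_joint_sites_is_an_error(self):
        rg = pd.DataFrame([[1, np.nan], [np.nan, 1], [1, 1]],
                          index=list("abc"))
        with pytest.raises(ValueError, match="'a'.*'b'|'b'.*'a'"):
            st.region_distance_matrix(rg, min_shared=1)


class TestNeighborJoining:
    def test_three_taxon_branch_lengths_exact(self):
        D = pd.DataFrame([[0, 3, 4], [3, 0, 5], [4, 5, 0]],
                         index=list("ABC"), columns=list("ABC"), dtype=float)
        assert st.nj_newick(D) == "(A:1,B:2,C:3);"

    def test_recovers_random_additive_trees(self):
        bad, max_err = 0, 0.0
        for s in range(50):
            rng = random.Random(s)
            tree, D = random_tree_and_distances(rng.randint(5, 12), rng)
            rec = dendropy.Tree.get(data=st.nj_newick(D), schema="newick",
                                    taxon_namespace=tree.taxon_namespace)
            tree.is_rooted = rec.is_rooted = False
            tree.update_bipartitions()
            rec.update_bipartitions()
            bad += treecompare.symmetric_difference(tree, rec) != 0
            pdm = rec.phylogenetic_distance_matrix()
            ns = tree.taxon_namespace
            max_err = max(max_err,
                          max(abs(pdm.distance(a, b) - D.loc[a.label, b.label])
                              for a in ns for b in ns))
        assert bad == 0
        assert max_err <= 1e-9

    def test_agrees_with_independent_nj_oracle(self):
        # dendropy's own NJ on the same matrix: identical unrooted topology
        rng = random.Random(99)
        tree, D = random_tree_and_distances(9, rng)
        import io as _io
        csv = "," + ",".join(D.columns) + "\n" + "\n".join(
            f"{i}," + ",".join(str(D.loc[i, j]) for j in D.columns)
            for i in D.index)
        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            src=_io.StringIO(csv), taxon_namespace=tree.taxon_namespace)
        oracle = pdm.nj_tree()
        mine = dendropy.Tree.get(data=st.nj_newick(D), schema="newick",
                                 taxon_namespace=tree.taxon_namespace)
        oracle.is_rooted = mine.is_rooted = False
        oracle.update_bipartitions()
        mine.update_bipartitions()
        assert treecompare.symmetric_difference(oracle, mine) == 0

    def test_equidistant_matrix_deterministic(self):
        D = pd.DataFrame(1.0 - np.eye(4), index=list("ABCD"),
                         columns=list("ABCD"))
        outputs = {st.nj_newick(D) for _ in range(5)}
        assert len(outputs) == 1

    def test_taxon_relabeling_relabels_tree(self):
        rng = random.Random(4)
        _, D = random_tree_and_distances(7, rng)
        perm = list(D.index[::-1])
        D2 = D.loc[perm, perm].rename(index=str.lower, columns=str.lower)
        t1 = dendropy.Tree.get(data=st.nj_newick(D), schema="newick")
        t2 = dendropy.Tree.get(data=st.nj_newick(D2), schema="newick")
        for leaf in t2.leaf_node_iter():
            leaf.taxon.label = leaf.taxon.label.upper()
        ns = dendropy.TaxonNamespace([t.label for t in t1.taxon_namespace])
        a = dendropy.Tree.get(data=t1.as_string(schema="newick"),
                              schema="newick", taxon_namespace=ns)
        b = dendropy.Tree.get(data=t2.as_string(schema="newick"),
                              schema="newick", taxon_namespace=ns)
        a.is_rooted = b.is_rooted = False
        a.update_bipartitions()
        b.update_bipartitions()
        assert treecompare.symmetric_difference(a, b) == 0

    @pytest.mark.parametrize("bad", [
        pd.DataFrame([[0, 1], [1, 0]], dtype=float),                # < 3 taxa
        pd.DataFrame([[0, 1, 2], [9, 0, 1], [2, 1, 0]], dtype=float),  # asym
        pd.DataFrame([[0, -1, 2], [-1, 0, 1], [2, 1, 0]], dtype=float),
    ])
    def test_invalid_matrices_rejected(self, bad):
        bad.index = bad.columns = list("XYZ")[:len(bad)]
        with pytest.raises(ValueError):
            st.nj_newick(bad)


def _labels(d):
    return pd.Series(d, name="label")


class TestIntegration:
    def _mito(self, labels, consensus):
        return MitoCloneLabels(labels=_labels(labels),
                               consensus=consensus)

    def _cnv(self, labels):
        return CnvSubcloneLabels(labels=_labels(labels),
                                 mean_profiles=pd.DataFrame(),
                                 silhouette=None)

    def test_identical_labelings_merge_to_same_partition(self):
        cells = [f"c{i}" for i in range(9)]
        lab = {c: ("A" if i < 5 else "B") for i, c in enumerate(cells)}
        cons = pd.DataFrame({100: ["HOM", "WT"], 200: ["WT", "HOM"]},
                            index=["A", "B"])
        meta = pd.DataFrame({"site": ["PT_R1"] * 9}, index=cells)
        model = st.integrate_clones_and_infer_origins(
            self._mito(lab, cons), self._cnv(lab), meta)
        assert model.consistency_ari == pytest.approx(1.0)
        merged = model.cell_labels
        assert merged.groupby(pd.Series(lab)).nunique().eq(1).all()
        assert merged.nunique() == 2

    def test_disjoint_cell_sets_rejected(self):
        consensus = pd.DataFrame({100: ["HOM"]}, index=["A"])
        mito = self._mito({"a": "A", "b": "A", "c": "A"}, consensus)
        cnvl = self._cnv({"x": "S1", "y": "S1", "z": "S1"})
        meta = pd.DataFrame({"site": ["PT_R1"] * 6},
                            index=list("abcxyz"))
        with pytest.raises(ValueError, match="disjoint"):
            st.integrate_clones_and_infer_origins(mito, cnvl, meta)

    def test_metastasis_with_extra_private_mutation_traces_to_parent(self):
        # liver clone = primary clone plus one private mutation;
        # the parent's mutations are a subset -> source = parent
        cfg = st.default_config(
            seed=21,
            sites={"N": 40, "PT_R1": 80, "LM": 40},
            site_composition={"N": {NORMAL_CLONE: 1.0},
                              "PT_R1": {"C1": 1.0},
                              "LM": {"C2": 1.0}},
            clone_tree={"C1": None, "C2": "C1"},
            private_mito_sites={"C2": [st.MitoSite(10396, 1.0)]},
            cnv_events={"C1": [st.CnvEvent("7", 0, 159_000_000, 3)]},
            lowq_cell_fraction=0.0, driver=st.DriverSpec())
        ds = st.simulate_patient(cfg)
        model = _integrated_model(ds)
        src = model.origins.set_index("site").loc["LM", "source_clone"]
        src_cells = model.cell_labels.index[model.cell_labels == src]
        true_clone = ds.truth.cells.loc[src_cells, "clone"].mode()[0]
        assert true_clone == ds.truth.metastasis_sources["LM"] == "C1"

    def test_two_metastases_from_distinct_primary_clones(self,
                                                         default_patient,
                                                         qc_passed,
                                                         mito_result,
                                                         cnv_profiles):
        # the distinct-origins scenario: LyM seeded from C2, LM from C3
        _, ds = default_patient
        _, retained, _ = qc_passed
        _, clones = mito_result
        cnv_labels = st.call_cnv_subclones(cnv_profiles)
        model = st.integrate_clones_and_infer_origins(
            clones, cnv_labels, retained.obs)
        origins = model.origins.set_index("site")
        mapped = {}
        for site in ("LyM", "LM"):
            src = origins.loc[site, "source_clone"]
            assert src != "ambiguous"
            cells = model.cell_labels.index[model.cell_labels == src]
            mapped[site] = ds.truth.cells.loc[cells, "clone"].mode()[0]
        assert mapped["LyM"] != mapped["LM"]
        assert mapped == ds.truth.metastasis_sources


def _integrated_model(ds):
    report, retained = st.filter_cells(ds.adata)
    retained = st.tpm_normalize(retained)
    lt = st.log2_tpm(retained)
    ac = ds.allele_counts[ds.allele_counts["cell_id"].isin(retained.obs_names)]
    geno = st.build_genotype_matrix(ac, retained.obs)
    clones = st.cluster_mito_clones(geno)
    import warnings
    ref = retained.obs_names[retained.obs["site"] == "N"]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        prof = st.infer_cnv_profile(lt, retained.var, ref)
    cnv_labels = st.call_cnv_subclones(prof)
    return st.integrate_clones_and_infer_origins(clones, cnv_labels,
                                                 retained.obs)
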