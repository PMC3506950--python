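import numpy as np
import pandas as pd
import pytest

from phylofunc.containers import ValidationError
from phylofunc.inference import (
    CladeMapping,
    GeneContentInferrer,
    infer_ko_abundance,
    jaccard,
    map_taxonomy_to_tree,
    per_sample_spearman,
    reconstruct_gene_content,
    reconstruction_weight,
    rollup_gene_sets,
)

from conftest import annotated_tree, make_feature_table


@pytest.mark.parametrize("d, w", [(0.0, 1.0), (1.0, 0.5), (2.0, 0.25)])
def test_reconstruction_weight_halves_per_unit(d, w):
    assert reconstruction_weight(d) == w


def test_reconstruction_weight_rejects_negative():
    with pytest.raises(ValueError):
        reconstruction_weight(-0.5)


class TestReconstruction:
    def test_two_leaf_weighted_average(self, two_leaf_phylogeny):
        # leaves at distances 1 and 2 with vectors (1,0) and (0,1):
        # (0.5*(1,0) + 0.25*(0,1)) / 0.75 = (2/3, 1/3)
        phylo = reconstruct_gene_content(two_leaf_phylogeny)
        root = phylo.node_vectors.loc["root"]
        assert root["K0"] == pytest.approx(2 / 3, abs=1e-12)
        assert root["K1"] == pytest.approx(1 / 3, abs=1e-12)

    def test_leaves_keep_their_own_vectors(self, two_leaf_phylogeny):
        phylo = reconstruct_gene_content(two_leaf_phylogeny)
        assert phylo.node_vectors.loc["A"].tolist() == [1.0, 0.0]
        assert phylo.node_vectors.loc["B"].tolist() == [0.0, 1.0]

    def test_identical_leaves_reconstruct_exactly(self):
        phylo = annotated_tree(
            "((A:0.3,B:1.7)x:1,C:0.4)r;", {k: [2, 1] for k in "ABC"}
        )
        phylo = reconstruct_gene_content(phylo)
        for node in ("x", "r"):
            assert phylo.node_vectors.loc[node].tolist() == [2.0, 1.0]

    def test_single_leaf_subtree_equals_leaf(self):
        phylo = annotated_tree("((A:5)x:1,B:1)r;", {"A": [3, 0], "B": [0, 7]})
        phylo = reconstruct_gene_content(phylo)
        assert phylo.node_vectors.loc["x"].tolist() == [3.0, 0.0]

    def test_zero_branch_lengths_allowed(self):
        phylo = annotated_tree("(A:0,B:0)r;", {"A": [1, 0], "B": [0, 1]})
        phylo = reconstruct_gene_content(phylo)
        assert phylo.node_vectors.loc["r"].tolist() == [0.5, 0.5]

    def test_values_bounded_by_descendant_range(self):
        rng = np.random.default_rng(7)
        from phylofunc.synth import generate_annotated_tree

        for seed in range(10):
            ref = generate_annotated_tree(10, 8, seed=seed)
            phylo = reconstruct_gene_content(ref.phylogeny)
            sets = phylo.descendant_leaf_sets()
            for name, leaves in sets.items():
                lo = phylo.ko_table.loc[sorted(leaves)].min()
                hi = phylo.ko_table.loc[sorted(leaves)].max()
                vec = phylo.node_vectors.loc[name]
                assert (vec >= lo - 1e-12).all() and (vec <= hi + 1e-12).all()

    def test_unannotated_leaves_excluded(self):
        phylo = annotated_tree("(A:1,B:1)r;", {"A": [4], "B": [0]})
        phylo.unannotated = ["B"]
        phylo = reconstruct_gene_content(phylo)
        assert phylo.node_vectors.loc["r"].tolist() == [4.0]


class TestCladeMapping:
    def test_identity_clade_scores_one(self):
        phylo = annotated_tree("((g1:1,g2:1)x:1,g3:1)r;", {g: [1] for g in ("g1", "g2", "g3")})
        mapping = map_taxonomy_to_tree({"genusA": {"g1", "g2"}}, phylo)
        node, j, ties = mapping.assignments["genusA"]
        assert (node, j, ties) == ("x", 1.0, 1)

    def test_partial_overlap_prefers_higher_jaccard(self):
        # clade {g1,g2}: node x has {g1,g2,g3} (J=2/3), leaf g1 has J=1/2
        phylo = annotated_tree(
            "((g1:1,g2:1,g3:1)x:1,g4:1)r;", {g: [1] for g in ("g1", "g2", "g3", "g4")}
        )
        mapping = map_taxonomy_to_tree({"genusA": {"g1", "g2"}}, phylo)
        node, j, _ = mapping.assignments["genusA"]
        assert node == "x"
        assert j == pytest.approx(2 / 3)

    def test_absent_genus_unmapped(self):
        phylo = annotated_tree("(g1:1,g2:1)r;", {"g1": [1], "g2": [1]})
        mapping = map_taxonomy_to_tree({"genusZ": {"g9"}}, phylo)
        assert mapping.unmapped == ["genusZ"]
        assert mapping.assignments == {}

    def test_empty_annotation_unmapped_with_warning(self, caplog):
        phylo = annotated_tree("(g1:1,g2:1)r;", {"g1": [1], "g2": [1]})
        with caplog.at_level("WARNING"):
            mapping = map_taxonomy_to_tree({"genusE": set()}, phylo)
        assert mapping.unmapped == ["genusE"]
        assert "genusE" in caplog.text

    def test_tie_broken_toward_most_specific_clade(self):
        # clade {g1}: leaf g1 (J=1) is preferred over any larger node
        phylo = annotated_tree("((g1:0)x:1,g2:1)r;", {"g1": [1], "g2": [1]})
        mapping = map_taxonomy_to_tree({"c": {"g1"}}, phylo)
        node, j, ties = mapping.assignments["c"]
        assert j == 1.0
        assert node == "g1"  # x has the same descendant set; g1 is a leaf
        assert ties == 2

    def test_matches_exhaustive_search(self):
        from phylofunc.synth import generate_annotated_tree

        for seed in range(5):
            ref = generate_annotated_tree(12, 5, seed=seed, mismatch=0.2)
            mapping = map_taxonomy_to_tree(ref.taxonomy, ref.phylogeny)
            sets = ref.phylogeny.descendant_leaf_sets()
            for clade, genomes in ref.taxonomy.items():
                best = max(jaccard(genomes, s) for s in sets.values())
                if best == 0:
                    assert clade in mapping.unmapped
                else:
                    assert mapping.assignments[clade][1] == pytest.approx(best)


class TestInferAbundance:
    def setup_method(self):
        self.phylo = annotated_tree("(A:1,B:1)r;", {"A": [2, 0], "B": [1, 3]})
        self.mapping = CladeMapping({"pA": ("A", 1.0, 1), "pB": ("B", 1.0, 1)})

    def test_weighted_sum_of_copy_numbers(self):
        taxa = make_feature_table([[0.6, 0.4]], features=["pA", "pB"])
        ko, skipped = infer_ko_abundance(
            taxa, self.mapping, self.phylo, renormalize=False
        )
        assert ko.data.loc["S0", "K0"] == pytest.approx(0.6 * 2 + 0.4 * 1)  # 1.6
        assert ko.data.loc["S0", "K1"] == pytest.approx(1.2)
        assert skipped["S0"] == 0.0

    def test_zero_abundance_contributes_nothing(self):
        taxa = make_feature_table([[0.0, 1.0]], features=["pA", "pB"])
        ko, _ = infer_ko_abundance(taxa, self.mapping, self.phylo, renormalize=False)
        assert ko.data.loc["S0"].tolist() == [1.0, 3.0]

    def test_single_phylotype_identity_mixture(self):
        taxa = make_feature_table([[1.0]], features=["pA"])
        mapping = CladeMapping({"pA": ("A", 1.0, 1)})
        ko, _ = infer_ko_abundance(taxa, mapping, self.phylo, renormalize=False)
        assert ko.data.loc["S0"].tolist() == [2.0, 0.0]

    def test_skipped_mass_reported(self):
        taxa = make_feature_table([[0.7, 0.3]], features=["pA", "unknown"])
        mapping = CladeMapping({"pA": ("A", 1.0, 1)})
        ko, skipped = infer_ko_abundance(taxa, mapping, self.phylo)
        assert skipped["S0"] == pytest.approx(0.3)
        assert ko.data.loc["S0"].sum() == pytest.approx(1.0)  # renormalized

    def test_sample_with_no_mapped_mass_errors(self):
        taxa = make_feature_table([[1.0]], features=["unknown2"])
        with pytest.raises(ValidationError):
            infer_ko_abundance(taxa, CladeMapping({"pA": ("A", 1.0, 1)}),
                               self.phylo)

    def test_renormalized_rows_sum_to_one(self):
        taxa = make_feature_table([[0.5, 0.5], [0.9, 0.1]], features=["pA", "pB"])
        ko, _ = infer_ko_abundance(taxa, self.mapping, self.phylo)
        assert np.allclose(ko.data.sum(axis=1), 1.0)


class TestRollup:
    def make_ko(self):
        return make_feature_table(
            [[0.2, 0.4, 0.4]], features=["K1", "K2", "K3"], feature_kind="gene"
        )

    def test_mean_and_sum_modes(self):
        gs = {"set1": ["K1", "K2"]}
        assert rollup_gene_sets(self.make_ko(), gs).data.loc["S0", "set1"] == \
            pytest.approx(0.3)
        assert rollup_gene_sets(self.make_ko(), gs, how="sum").data.loc["S0", "set1"] == \
            pytest.approx(0.6)

    def test_singleton_set_passes_through(self):
        out = rollup_gene_sets(self.make_ko(), {"solo": ["K3"]})
        assert out.data.loc["S0", "solo"] == pytest.approx(0.4)

    def test_empty_set_dropped_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            out = rollup_gene_sets(self.make_ko(), {"ok": ["K1"], "ghost": ["K9"]})
        assert list(out.data.columns) == ["ok"]
        assert "ghost" in caplog.text


def test_exact_leaf_spearman_is_one():
    from phylofunc.synth import (
        generate_annotated_tree,
        generate_paired_metagenome,
        sample_leaf_communities,
    )

    ref = generate_annotated_tree(20, 30, seed=5)
    taxa = sample_leaf_communities(ref, n_samples=6, seed=5)
    inferred = GeneContentInferrer().fit(ref.phylogeny).transform(taxa)
    truth = generate_paired_metagenome(taxa, ref.phylogeny)
    rho = per_sample_spearman(inferred, truth)
    assert np.allclose(rho, 1.0)
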