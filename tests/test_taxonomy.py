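"""Intergenomic similarity, demarcation, protein clusters and VGCs."""

import numpy as np
import pytest

from immikit.taxonomy import (
    DistanceMatrix,
    cluster_proteins,
    demarcate,
    hierarchical_vgc,
    intergenomic_similarity,
    pc_distance,
    pc_distance_matrix,
    similarity_matrix,
    SimilarityMatrix,
)

from conftest import partition


class TestIntergenomicSimilarity:
    def test_identical_genomes(self):
        seq = "".join(np.random.default_rng(0).choice(list("ACGT"), size=6000))
        sim, fa, fb = intergenomic_similarity(seq, seq)
        assert sim == pytest.approx(100.0)
        assert fa == fb == pytest.approx(1.0)

    def test_unrelated_genomes(self):
        rng = np.random.default_rng(1)
        a = "".join(rng.choice(list("ACGT"), size=3000))
        b = "".join(rng.choice(list("ACGT"), size=3000))
        sim, fa, fb = intergenomic_similarity(a, b)
        assert sim < 2.0 and fa < 0.02 and fb < 0.02

    def test_matches_whole_genome_hamming_oracle(self, small_uniform_family):
        """On an indel-free family with uniform gene content, block similarity
        tracks the whole-genome Hamming identity within 1.5 points."""
        genomes = small_uniform_family.genomes
        t = small_uniform_family.truth
        # same-species pairs: high identity, equal architecture and gene content
        pairs = [
            (a, b)
            for a in genomes
            for b in genomes
            if a.id < b.id and t.species_assignments[a.id] == t.species_assignments[b.id]
        ]
        assert pairs
        for a, b in pairs:
            assert len(a.sequence) == len(b.sequence)
            hamming = 100.0 * sum(x == y for x, y in zip(a.sequence, b.sequence)) / len(a)
            sim, _, _ = intergenomic_similarity(a, b)
            assert sim == pytest.approx(hamming, abs=1.5)


class TestDemarcation:
    def test_all_similar_single_cluster(self):
        m = SimilarityMatrix(["a", "b", "c"], np.full((3, 3), 97.0), np.ones((3, 3)))
        _, _, n_sp, n_gen = demarcate(m)
        assert (n_sp, n_gen) == (1, 1)

    def test_cluster_named_after_smallest_member(self):
        vals = np.array([[100.0, 96.0], [96.0, 100.0]])
        species, genera, _, _ = demarcate(
            SimilarityMatrix(["zeta", "alpha"], vals, np.ones((2, 2)))
        )
        assert species == {"zeta": "alpha", "alpha": "alpha"}

    def test_simulated_family_recovered_exactly(self, family):
        sm = similarity_matrix(family.genomes)
        species, genera, n_sp, n_gen = demarcate(sm)
        t = family.truth
        assert (n_sp, n_gen) == (t.n_species(), t.n_genera())
        assert partition(species) == partition(t.species_assignments)
        assert partition(genera) == partition(t.genus_assignments)

    def test_species_refine_genera(self, family):
        sm = similarity_matrix(family.genomes[:6])
        species, genera, _, _ = demarcate(sm)
        genus_of_species = {}
        for gid in species:
            sp = species[gid]
            assert genus_of_species.setdefault(sp, genera[gid]) == genera[gid]

    def test_threshold_order_enforced(self):
        m = SimilarityMatrix(["a"], np.array([[100.0]]), np.ones((1, 1)))
        with pytest.raises(ValueError):
            demarcate(m, species_threshold=70, genus_threshold=95)


class TestProteinClusters:
    def test_identical_copies_one_pc(self):
        prot = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ" * 3
        pcs = cluster_proteins({f"g{i}": [prot] for i in range(5)})
        assert len(pcs) == 1 and len(pcs[0].members) == 5

    def test_two_divergent_groups_two_pcs(self):
        rng = np.random.default_rng(2)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        p1 = "M" + "".join(rng.choice(aas, size=99))
        p2 = "M" + "".join(rng.choice(aas, size=99))  # unrelated (~5% identity)
        near1 = p1[:50] + "A" + p1[51:]  # ~99% identical to p1
        pcs = cluster_proteins({"a": [p1], "b": [near1], "c": [p2]})
        assert len(pcs) == 2
        sizes = sorted(len(pc.members) for pc in pcs)
        assert sizes == [1, 2]

    def test_simulated_core_families_form_multi_genome_pcs(self, family):
        proteomes = {g.id: [f.protein for f in g.genes] for g in family.genomes}
        pcs = cluster_proteins(proteomes)
        multi = [pc for pc in pcs if len({g for g, _ in pc.members}) > 1]
        assert len(multi) >= family.config.n_core

    def test_each_protein_in_exactly_one_pc(self, family):
        proteomes = {g.id: [f.protein for f in g.genes] for g in family.genomes[:4]}
        pcs = cluster_proteins(proteomes)
        seen = [m for pc in pcs for m in pc.members]
        assert len(seen) == len(set(seen)) == sum(len(v) for v in proteomes.values())


class TestPCDistance:
    def _pcs_from_sets(self, sets: dict[str, set[str]]):
        """Build a PC list from explicit genome -> PC-id sets."""
        from immikit.taxonomy import ProteinCluster

        ids = sorted({pc for s in sets.values() for pc in s})
        return [
            ProteinCluster(pc, tuple(sorted((g, 0) for g in sets if pc in sets[g])))
            for pc in ids
        ]

    def test_hand_computed_dice(self):
        sets = {
            "A": {f"PC{i}" for i in range(10)},
            "B": {f"PC{i}" for i in range(5, 15)},  # 5 shared of 10+10
        }
        pcs = self._pcs_from_sets(sets)
        assert pc_distance("A", "B", pcs) == pytest.approx(0.5)

    def test_identical_and_disjoint(self):
        same = self._pcs_from_sets({"A": {"PC1", "PC2"}, "B": {"PC1", "PC2"}})
        assert pc_distance("A", "B", same) == 0.0
        disjoint = self._pcs_from_sets({"A": {"PC1"}, "B": {"PC2"}})
        assert pc_distance("A", "B", disjoint) == 1.0

    def test_exact_dice_on_enumerated_sets(self):
        """Implementation equals the Dice-complement formula evaluated
        directly on enumerated presence sets, exactly."""
        rng = np.random.default_rng(3)
        universe = [f"PC{i}" for i in range(20)]
        sets = {
            g: {pc for pc in universe if rng.random() < 0.5} | {"PC0"}
            for g in ("A", "B", "C")
        }
        pcs = self._pcs_from_sets(sets)
        for a in sets:
            for b in sets:
                if a >= b:
                    continue
                expected = 1 - 2 * len(sets[a] & sets[b]) / (len(sets[a]) + len(sets[b]))
                assert pc_distance(a, b, pcs) == expected


class TestVGC:
    def test_all_zero_distances_single_vgc(self):
        dm = DistanceMatrix(["a", "b", "c"], np.zeros((3, 3)))
        _, labels = hierarchical_vgc(dm)
        assert set(labels.values()) == {"VGC1"}

    def test_two_planted_families_split_at_cut(self, family, family_b):
        proteomes = {g.id: [f.protein for f in g.genes] for g in family.genomes}
        proteomes.update(
            {f"B_{g.id}": [f.protein for f in g.genes] for g in family_b.genomes}
        )
        pcs = cluster_proteins(proteomes)
        dm = pc_distance_matrix(sorted(proteomes), pcs)
        _, labels = hierarchical_vgc(dm, cut=0.7)
        fam_a_labels = {labels[g.id] for g in family.genomes}
        fam_b_labels = {labels[f"B_{g.id}"] for g in family_b.genomes}
        assert len(fam_a_labels) == len(fam_b_labels) == 1
        assert fam_a_labels != fam_b_labels

    def test_lower_cut_refines_partition(self, family):
        proteomes = {g.id: [f.protein for f in g.genes] for g in family.genomes}
        pcs = cluster_proteins(proteomes)
        dm = pc_distance_matrix([g.id for g in family.genomes], pcs)
        _, coarse = hierarchical_vgc(dm, cut=0.7)
        _, fine = hierarchical_vgc(dm, cut=0.3)
        # every fine cluster sits inside one coarse cluster
        for blk in partition(fine):
            assert len({coarse[g] for g in blk}) == 1

    def test_newick_leaves_match_labels(self, family):
        import io

        from Bio import Phylo

        proteomes = {g.id: [f.protein for f in g.genes] for g in family.genomes[:5]}
        pcs = cluster_proteins(proteomes)
        dm = pc_distance_matrix(sorted(proteomes), pcs)
        newick, _ = hierarchical_vgc(dm)
        tree = Phylo.read(io.StringIO(newick), "newick")
        assert {leaf.name for leaf in tree.get_terminals()} == set(proteomes)
        assert all(c.branch_length >= 0 for c in tree.find_clades() if c.branch_length is not None)

    def test_non_finite_rejected(self):
        dm = DistanceMatrix(["a", "b"], np.array([[0.0, np.nan], [np.nan, 0.0]]))
        with pytest.raises(ValueError):
            hierarchical_vgc(dm)
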