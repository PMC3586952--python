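"""Unit tests for the synthetic-data generators: seed determinism, zero-event
conservation and the planted ground truth they expose."""

import numpy as np
import pytest

from phyloscan import trees
from phyloscan.model import GAP
from phyloscan.simgen import (evolve_alignment, evolve_gene_orders,
                              generate_species_tree, make_phylome_records,
                              randomize_clade_sequences, simulate_gene_trees)


class TestGenerateSpeciesTree:
    def test_two_species_is_the_single_cherry(self):
        tree, groups = generate_species_tree(2, seed=1)
        assert sorted(trees.leaf_labels(tree)) == ["s1", "s2"]
        assert trees.topology_key(tree) == "(s1,s2)"
        assert set(groups.values()) == {"Ingroup"}

    def test_seed_determinism(self):
        a, _ = generate_species_tree(6, seed=7)
        b, _ = generate_species_tree(6, seed=7)
        assert trees.to_newick(a) == trees.to_newick(b)

    def test_yule_reaches_many_topologies_but_at_most_945(self):
        seen = {trees.topology_key(generate_species_tree(6, seed=s)[0])
                for s in range(1000)}
        assert 400 < len(seen) <= 945

    def test_groups_are_monophyletic(self):
        sizes = {"Outgroup": 2, "Microsporidia": 3, "Zygomycotina": 2}
        tree, groups = generate_species_tree(7, sizes, seed=5)
        for group in sizes:
            members = [s for s, g in groups.items() if g == group]
            assert trees.is_monophyletic(tree, members)

    def test_too_few_species_rejected(self):
        with pytest.raises(ValueError):
            generate_species_tree(1)

    def test_branch_lengths_positive(self):
        tree, _ = generate_species_tree(8, seed=3)
        for node in tree.preorder_node_iter():
            if node.parent_node is not None:
                assert node.edge.length >= 0


class TestEvolveGeneOrders:
    def test_zero_rates_reproduce_ancestor_everywhere(self):
        sp, _ = generate_species_tree(4, seed=2)
        genomes, truth = evolve_gene_orders(sp, 25, 0, 0, 0, seed=3)
        orders = {g.genome_id: [(x.family_id, x.ortholog_id, x.strand)
                                for _, x in g.genes()]
                  for g in genomes.values()}
        reference = next(iter(orders.values()))
        assert all(order == reference for order in orders.values())
        # full 1:1 orthology: every token present once per genome
        sets = truth.ortholog_sets()
        assert all(len(v) == len(genomes) for v in sets.values())

    def test_duplication_on_one_branch_stays_in_that_lineage(self):
        tree = trees.parse_newick("(a:1,b:1);")
        for seed in range(40):
            genomes, truth = evolve_gene_orders(tree, 20, 0, 3.0, 0,
                                                seed=seed)
            multi = {gid: any(len(pos) > 1
                              for pos in g.family_positions().values())
                     for gid, g in genomes.items()}
            dup_branches = {e["branch"] for e in truth.events
                            if e["type"] == "segmental_duplication"}
            for gid, has_multi in multi.items():
                if has_multi:
                    assert gid in dup_branches

    def test_zero_genes_rejected(self):
        sp, _ = generate_species_tree(3, seed=1)
        with pytest.raises(ValueError):
            evolve_gene_orders(sp, 0, 0, 0, 0)

    def test_determinism(self):
        sp, _ = generate_species_tree(5, seed=8)
        a, _ = evolve_gene_orders(sp, 30, 0.5, 0.3, 0.3, seed=11)
        b, _ = evolve_gene_orders(sp, 30, 0.5, 0.3, 0.3, seed=11)
        for species in a:
            assert a[species].to_frame().equals(b[species].to_frame())


class TestSimulateGeneTrees:
    def test_no_events_reproduce_species_topology(self):
        sp, _ = generate_species_tree(6, seed=4)
        for gt in simulate_gene_trees(sp, 10, 0, 0, seed=5):
            assert gt.planted_duplications == 0
            key = trees.topology_key(gt).replace("_1", "")
            assert key == trees.topology_key(sp)

    def test_planted_duplication_labels_cover_internal_nodes(self):
        sp, _ = generate_species_tree(5, seed=6)
        for gt in simulate_gene_trees(sp, 20, 0.2, 0.1, seed=7):
            labels = [node.planted_event
                      for node in gt.preorder_internal_node_iter()]
            assert set(labels) <= {"duplication", "speciation"}
            assert labels.count("duplication") == gt.planted_duplications

    def test_leaves_name_their_species(self):
        sp, _ = generate_species_tree(4, seed=9)
        species = set(trees.leaf_labels(sp))
        for gt in simulate_gene_trees(sp, 5, 0.3, 0.2, seed=1):
            for leaf in trees.leaf_labels(gt):
                assert trees.species_of(leaf) in species

    def test_negative_rates_rejected(self):
        sp, _ = generate_species_tree(3, seed=1)
        with pytest.raises(ValueError):
            simulate_gene_trees(sp, 1, -0.1, 0)


class TestEvolveAlignment:
    def test_zero_branch_lengths_copy_the_root_sequence(self):
        tree = trees.parse_newick("((a:0,b:0):0,(c:0,d:0):0);")
        aln, _ = evolve_alignment(tree, 50, seed=3)
        assert (aln.data == aln.data[0]).all()

    def test_seed_determinism_byte_identical(self, tmp_path):
        sp, _ = generate_species_tree(5, seed=1)
        out = []
        for _ in range(2):
            aln, _ = evolve_alignment(sp, 120, gamma_shape=0.5, seed=42)
            path = tmp_path / "a.fasta"
            aln.write_fasta(path)
            out.append(path.read_bytes())
        assert out[0] == out[1]

    def test_slow_category_changes_less_than_fast(self):
        # total tree length 0.1 split over one branch pair
        tree = trees.parse_newick("(a:0.05,b:0.05);")
        aln, truth = evolve_alignment(tree, 10000, gamma_shape=0.5,
                                      n_categories=16, seed=8)
        diff = aln.data[0] != aln.data[1]
        slow = diff[truth.categories == 1].mean()
        fast = diff[truth.categories == 16].mean()
        assert slow < fast

    def test_invalid_parameters_rejected(self):
        tree = trees.parse_newick("(a:1,b:1);")
        with pytest.raises(ValueError):
            evolve_alignment(tree, 0)
        with pytest.raises(ValueError):
            evolve_alignment(tree, 10, gamma_shape=-1)


class TestRandomizeCladeSequences:
    def _alignment(self):
        sp, _ = generate_species_tree(6, seed=12)
        aln, _ = evolve_alignment(sp, 10000, seed=13)
        aln.data[0, :100] = GAP  # inject gaps into a focal row
        return aln

    def test_non_focal_rows_untouched_and_gaps_preserved(self):
        aln = self._alignment()
        out = randomize_clade_sequences(aln, {"s1", "s2"}, seed=1)
        for i, name in enumerate(aln.names):
            if name not in ("s1", "s2"):
                assert (out.data[i] == aln.data[i]).all()
            else:
                assert ((out.data[i] == GAP) == (aln.data[i] == GAP)).all()

    def test_composition_matched_frequencies_close(self):
        aln = self._alignment()
        out = randomize_clade_sequences(aln, {"s3"}, "composition_matched",
                                        seed=2)
        row_old = aln.row("s3")
        row_new = out.row("s3")
        for residue in set(row_old):
            old = (row_old == residue).mean()
            new = (row_new == residue).mean()
            assert abs(old - new) < 0.02

    def test_empty_focal_set_rejected(self):
        aln = self._alignment()
        with pytest.raises(ValueError):
            randomize_clade_sequences(aln, set())


class TestMakePhylomeRecords:
    def _trees(self, n=5):
        sp, _ = generate_species_tree(4, seed=3)
        return simulate_gene_trees(sp, n, 0, 0, seed=4)

    def test_constant_metadata_passes_or_fails_filters(self):
        from phyloscan.treescan import apply_filters
        records = make_phylome_records(self._trees(), 1.0, 0.9, 600, seed=1)
        for record in records:
            assert record.consistency_score == 0.9
            assert record.alignment_length == 600
        short = make_phylome_records(self._trees(), 1.0, 0.9, 400, seed=1)
        assert all(r.alignment_length == 400 for r in short)

    def test_determinism(self):
        def sampler(rng):
            return float(rng.uniform(0.5, 1.0))

        a = make_phylome_records(self._trees(), sampler, sampler, 600, seed=9)
        b = make_phylome_records(self._trees(), sampler, sampler, 600, seed=9)
        assert [r.consistency_score for r in a] == \
               [r.consistency_score for r in b]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            make_phylome_records([], 1.0, 0.9, 600)
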