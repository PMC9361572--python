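import pytest

from ksdater import (
    DupClass,
    GenomeSimSpec,
    PairSimSpec,
    classify_genes,
    compute_kaks,
    simulate_codon_pair,
    simulate_gene_tree,
    simulate_genome,
)


class TestCodonPairSim:
    def test_zero_divergence_gives_identical_sequences(self):
        pair, truth = simulate_codon_pair(PairSimSpec(n_codons=50, target_ks=0.0))
        assert pair.seq_a == pair.seq_b
        assert compute_kaks(pair).ks == 0.0
        assert truth["total_syn_events"] == 0

    def test_same_seed_reproduces_output(self):
        spec = PairSimSpec(n_codons=100, target_ks=0.4, omega=0.3, seed=11)
        p1, t1 = simulate_codon_pair(spec)
        p2, t2 = simulate_codon_pair(spec)
        assert (p1.seq_a, p1.seq_b) == (p2.seq_a, p2.seq_b)
        assert t1 == t2

    def test_different_seeds_differ(self):
        p1, _ = simulate_codon_pair(PairSimSpec(seed=1))
        p2, _ = simulate_codon_pair(PairSimSpec(seed=2))
        assert (p1.seq_a, p1.seq_b) != (p2.seq_a, p2.seq_b)

    def test_truth_event_counts_match_target(self):
        spec = PairSimSpec(n_codons=200, target_ks=0.3, omega=0.2, seed=3)
        _, truth = simulate_codon_pair(spec)
        target = truth["target_syn_events_per_lineage"]
        assert target == round(0.3 / 2 * truth["ancestor_S"])
        for lineage in truth["lineages"]:
            assert lineage["syn_events"] == target

    def test_omega_zero_allows_purely_synonymous_divergence(self):
        pair, truth = simulate_codon_pair(
            PairSimSpec(n_codons=100, target_ks=0.2, omega=0.0, seed=4)
        )
        assert truth["total_nonsyn_events"] == 0
        assert pair.seq_a != pair.seq_b

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            PairSimSpec(n_codons=0)
        with pytest.raises(ValueError):
            PairSimSpec(target_ks=-0.1)
        with pytest.raises(ValueError):
            PairSimSpec(omega=-1)


class TestGenomeSim:
    def test_zero_features_all_singletons(self):
        spec = GenomeSimSpec(
            n_tandem_arrays=0,
            n_proximal_pairs=0,
            n_collinear_blocks=0,
            n_dispersed_pairs=0,
        )
        loci, homologs, collinear, truth = simulate_genome(spec)
        assert len(homologs) == 0 and len(collinear) == 0
        assert all(label == DupClass.SINGLETON for label in truth.values())

    def test_single_tandem_array_plants_two_genes(self):
        spec = GenomeSimSpec(
            n_tandem_arrays=1,
            n_proximal_pairs=0,
            n_collinear_blocks=0,
            n_dispersed_pairs=0,
        )
        _, _, _, truth = simulate_genome(spec)
        tandem = [g for g, label in truth.items() if label == DupClass.TANDEM]
        assert len(tandem) == 2

    def test_same_seed_reproduces_genome(self):
        spec = GenomeSimSpec(seed=17)
        g1 = simulate_genome(spec)
        g2 = simulate_genome(spec)
        assert [(l.gene_id, l.start) for l in g1[0]] == [
            (l.gene_id, l.start) for l in g2[0]
        ]
        assert g1[1].pairs == g2[1].pairs and g1[3] == g2[3]

    def test_capacity_overflow_rejected(self):
        spec = GenomeSimSpec(
            n_chromosomes=2, genes_per_chromosome=4, n_collinear_blocks=5
        )
        with pytest.raises(ValueError, match="capacity"):
            simulate_genome(spec)

    @pytest.mark.parametrize("seed", range(5))
    def test_classifier_recovers_planted_labels(self, seed):
        loci, homologs, collinear, truth = simulate_genome(GenomeSimSpec(seed=seed))
        result = classify_genes(
            list(truth), homologs, collinear, loci, proximal_window=10
        )
        assert result.labels == truth


class TestGeneTreeSim:
    def test_no_events_gives_congruent_tree(self, species_tree_7):
        gt, leaf_map, truth = simulate_gene_tree(species_tree_7, [], seed=0)
        assert truth["duplications"] == 0 and truth["losses"] == 0
        assert len(gt.leaf_nodes()) == 7
        assert sorted(leaf_map.values()) == sorted("ABCDEFG")

    def test_root_duplication_doubles_leaves(self):
        from ksdater import read_newick

        st = read_newick("(A,B);")
        gt, leaf_map, truth = simulate_gene_tree(st, [("A|B", "duplication")], seed=0)
        assert truth["duplications"] == 1
        assert len(gt.leaf_nodes()) == 4
        assert sorted(leaf_map.values()) == ["A", "A", "B", "B"]

    def test_same_seed_reproduces_tree(self, species_tree_7):
        events = [("A|B", "duplication"), ("G", "loss")]
        t1 = simulate_gene_tree(species_tree_7, events, seed=5)
        t2 = simulate_gene_tree(species_tree_7, events, seed=5)
        assert t1[0].as_string(schema="newick") == t2[0].as_string(schema="newick")
        assert t1[1] == t2[1]

    def test_loss_emptying_tree_rejected(self):
        from ksdater import read_newick

        st = read_newick("(A,B);")
        with pytest.raises(ValueError):
            simulate_gene_tree(st, [("A", "loss"), ("B", "loss")], seed=0)

    def test_unknown_branch_rejected(self, species_tree_7):
        with pytest.raises(KeyError):
            simulate_gene_tree(species_tree_7, [("Z", "duplication")], seed=0)

    def test_unknown_event_type_rejected(self, species_tree_7):
        with pytest.raises(ValueError):
            simulate_gene_tree(species_tree_7, [("A", "transfer")], seed=0)
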