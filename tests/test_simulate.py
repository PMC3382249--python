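import json

import numpy as np
import pytest

from spidrevo.reconcile import count_events
from spidrevo.repeats import repeat_identity
from spidrevo.sequences import translate
from spidrevo.simulate import (
    default_aa_weights,
    sim_alignment_indels,
    sim_gene_tree,
    sim_repeat_protein,
    sim_species_tree,
    sim_traits,
    write_truth_sidecar,
)
from spidrevo.trees import write_newick


class TestSpeciesTree:
    def test_two_tips_is_a_cherry(self):
        t = sim_species_tree(2, seed=0)
        assert t.n_leaves() == 2 and len(t.root.children) == 2

    def test_internal_node_count(self):
        t = sim_species_tree(50, seed=1)
        internal = sum(1 for n in t.postorder() if not n.is_leaf())
        assert internal == 49

    def test_ultrametric_positive_lengths(self):
        t = sim_species_tree(10, seed=2)
        depths = set()
        def walk(node, d):
            if node.is_leaf():
                depths.add(round(d, 9))
            for c in node.children:
                walk(c, d + c.length)
        walk(t.root, 0.0)
        assert len(depths) == 1
        assert all(n.length > 0 for n in t.postorder() if n is not t.root)

    def test_mean_depth_matches_yule_expectation(self):
        lam, n = 2.0, 10
        expected = sum(1.0 / (k * lam) for k in range(2, n + 1))
        depths = []
        for seed in range(400):
            t = sim_species_tree(n, birth_rate=lam, seed=seed)
            node = t.root
            d = 0.0
            while node.children:
                node = node.children[0]
                d += node.length
            depths.append(d)
        assert np.mean(depths) == pytest.approx(expected, rel=0.1)

    def test_determinism(self):
        a = write_newick(sim_species_tree(12, seed=9))
        b = write_newick(sim_species_tree(12, seed=9))
        assert a == b


class TestGeneTree:
    def test_no_events_gives_congruent_tree(self):
        sp = sim_species_tree(6, seed=3)
        sim = sim_gene_tree(sp, dup_rate=0.0, loss_rate=0.0, seed=1)
        assert sim.true_counts.duplications == 0
        assert sim.true_counts.losses == 0
        counts, _ = count_events(sim.gene_tree, sp, sim.mapping)
        assert (counts.duplications, counts.losses) == (0, 0)

    def test_mapping_is_total_onto_species(self):
        sp = sim_species_tree(6, seed=3)
        sim = sim_gene_tree(sp, dup_rate=0.5, loss_rate=0.1, seed=2)
        species = set(sp.leaf_labels())
        assert set(sim.mapping) == set(sim.gene_tree.leaf_labels())
        assert set(sim.mapping.values()) <= species

    def test_determinism(self):
        sp = sim_species_tree(6, seed=3)
        a = sim_gene_tree(sp, dup_rate=0.5, loss_rate=0.1, seed=7)
        b = sim_gene_tree(sp, dup_rate=0.5, loss_rate=0.1, seed=7)
        assert write_newick(a.gene_tree) == write_newick(b.gene_tree)
        assert a.true_counts == b.true_counts


class TestRepeatProtein:
    def test_noiseless_copies_identical(self):
        sim = sim_repeat_protein(unit_len=40, n_units=4, sub_rate=0.0, seed=5)
        units = [sim.protein.residues[s:e] for s, e in sim.unit_intervals]
        assert repeat_identity(units) == 100.0
        assert units[0] == sim.ancestral_unit

    def test_dna_translates_to_protein(self):
        sim = sim_repeat_protein(unit_len=30, n_units=3, sub_rate=0.05, seed=6)
        assert translate(sim.dna).residues == sim.protein.residues
        assert "*" not in sim.protein.residues

    def test_unit_composition_tracks_weights(self):
        freq_a = []
        for seed in range(50):
            sim = sim_repeat_protein(unit_len=100, n_units=2, sub_rate=0.0, seed=seed)
            unit = sim.ancestral_unit
            freq_a.append(unit.count("A") / len(unit))
        assert np.mean(freq_a) == pytest.approx(default_aa_weights()["A"], abs=0.02)

    def test_indels_shorten_units(self):
        sim = sim_repeat_protein(unit_len=60, n_units=4, sub_rate=0.0,
                                 indel_rate=0.05, seed=7)
        lengths = [e - s for s, e in sim.unit_intervals]
        assert min(lengths) < 60
        assert translate(sim.dna).residues == sim.protein.residues

    def test_determinism(self):
        a = sim_repeat_protein(seed=11)
        b = sim_repeat_protein(seed=11)
        assert a.dna.residues == b.dna.residues


class TestTraits:
    def test_zero_rate_fixes_tips_at_root_state(self):
        tree = sim_species_tree(6, seed=1)
        traits = sim_traits(tree, "bm_distance", sigma2=0.0, z0=7.5, seed=2)
        assert all(v == 7.5 for v in traits.values())

    def test_two_tip_difference_variance(self):
        from spidrevo.trees import tree_from_newick

        b1, b2, s2 = 0.8, 1.7, 1.4
        tree = tree_from_newick(f"(a:{b1},b:{b2});")
        diffs = [
            sim_traits(tree, "bm_distance", sigma2=s2, seed=seed)["a"]
            - sim_traits(tree, "bm_distance", sigma2=s2, seed=seed)["b"]
            for seed in range(10_000)
        ]
        assert np.var(diffs) == pytest.approx(s2 * (b1 + b2), rel=0.05)

    def test_star_mode_centered_on_root_state(self):
        tree = sim_species_tree(30, seed=4)
        vals = [
            v
            for seed in range(30)
            for v in sim_traits(tree, "star", sigma2=1.0, z0=5.0, seed=seed).values()
        ]
        assert np.mean(vals) == pytest.approx(5.0, abs=0.1)
        assert np.var(vals) == pytest.approx(1.0, rel=0.1)


class TestAlignmentIndels:
    def test_no_events_is_gap_free(self):
        sim = sim_alignment_indels(3, 30, events=[], seed=1)
        assert not any("-" in row for _, row in sim.alignment.rows)
        assert sim.true_matrix.characters == []

    def test_shared_event_plants_one_character(self):
        sim = sim_alignment_indels(3, 30, events=[(["t1", "t2"], 5, 9)], seed=2)
        assert [(c.start, c.end) for c in sim.true_matrix.characters] == [(5, 9)]
        assert sim.true_matrix.as_dict()["t1"][(5, 9)] == "1"
        assert sim.true_matrix.as_dict()["t3"][(5, 9)] == "0"

    def test_nested_events_mark_subsumption(self):
        sim = sim_alignment_indels(
            3, 40, events=[(["t1"], 10, 14), (["t2"], 8, 20)], seed=3
        )
        assert sim.true_matrix.as_dict()["t2"][(10, 14)] == "?"

    def test_contradictory_events_rejected(self):
        with pytest.raises(ValueError, match="contradictory"):
            sim_alignment_indels(3, 40, events=[(["t1"], 5, 10), (["t1"], 9, 15)])

    def test_terminal_events_rejected(self):
        with pytest.raises(ValueError, match="internal"):
            sim_alignment_indels(3, 40, events=[(["t1"], 0, 5)])


class TestSidecars:
    def test_truth_json_round_trip(self, tmp_path):
        sim = sim_repeat_protein(unit_len=20, n_units=3, seed=4)
        p = tmp_path / "truth.json"
        write_truth_sidecar(sim, p)
        data = json.loads(p.read_text())
        assert data["period"] == 20
        assert data["n_units"] == 3
        assert [tuple(iv) for iv in data["unit_intervals"]] == list(sim.unit_intervals)
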