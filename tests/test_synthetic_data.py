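"""Generator invariants: tree shape, Dollo planting, emission, determinism."""

import numpy as np
import pytest

from torcscan import (
    SimConfig,
    assign_trophic_labels,
    dollo_reconstruct,
    emit_proteomes,
    emit_reads,
    generate,
    plant_losses,
    simulate_taxonomy,
)
from torcscan.loss_inference import ABSENT, PRESENT
from torcscan.synthetic_data import (
    build_component_profiles,
    component_reference_msas,
    _species_protein,
)


class TestSimConfig:
    def test_rejects_tiny_trees(self):
        with pytest.raises(ValueError, match="n_tips"):
            SimConfig(n_tips=2)

    def test_rejects_bad_probabilities(self):
        with pytest.raises(ValueError):
            SimConfig(completeness=1.5)
        with pytest.raises(ValueError):
            SimConfig(divergence=-0.1)
        with pytest.raises(ValueError, match="read_length"):
            SimConfig(read_length_aa=3)


class TestSimulateTaxonomy:
    def test_minimal_three_tip_tree(self):
        tree = simulate_taxonomy(SimConfig(n_tips=3, n_clades=1, seed=0))
        assert tree.n_tips == 3
        assert len(set(tree.clade_map.values())) == 1

    def test_seed_determinism(self):
        cfg = SimConfig(n_tips=12, seed=7)
        assert (
            simulate_taxonomy(cfg).to_newick() == simulate_taxonomy(cfg).to_newick()
        )

    def test_structure_and_clade_partition(self):
        cfg = SimConfig(n_tips=50, n_clades=5, seed=3)
        tree = simulate_taxonomy(cfg)
        tips = tree.tip_labels
        assert len(tips) == 50
        assert set(tree.clade_map) == set(tips)  # clades partition the tips
        assert len(set(tree.clade_map.values())) == 5
        reachable = set(tree.subtree_tips(tree.root))
        assert reachable == set(tips)

    @pytest.mark.parametrize("seed", range(5))
    def test_polytomy_present_in_taxonomy_like_trees(self, seed):
        tree = simulate_taxonomy(SimConfig(n_tips=10, n_clades=2, seed=seed))
        assert tree.has_polytomy()


class TestPlantLosses:
    def test_no_loss_limit(self):
        cfg = SimConfig(n_tips=10, seed=1, loss_prob_per_edge=0.0)
        truth = plant_losses(simulate_taxonomy(cfg), cfg)
        assert truth.tip_presence.all().all()
        assert all(not e for e in truth.loss_edges.values())

    def test_certain_loss_limit(self):
        cfg = SimConfig(n_tips=10, seed=1, loss_prob_per_edge=1.0)
        tree = simulate_taxonomy(cfg)
        truth = plant_losses(tree, cfg)
        assert not truth.tip_presence["RAPTOR"].any()
        assert truth.loss_edges["RAPTOR"] == frozenset(tree.children(tree.root))

    def test_irreversibility_no_presence_below_loss(self):
        cfg = SimConfig(n_tips=30, seed=5, loss_prob_per_edge=0.15)
        tree = simulate_taxonomy(cfg)
        truth = plant_losses(tree, cfg)
        for comp, edges in truth.loss_edges.items():
            for edge in edges:
                for tip in tree.subtree_tips(edge):
                    assert not truth.tip_presence.at[tip, comp]

    def test_dollo_recovers_planted_edges(self):
        cfg = SimConfig(n_tips=30, seed=11, loss_prob_per_edge=0.1)
        tree = simulate_taxonomy(cfg)
        truth = plant_losses(tree, cfg)
        for comp in ("RAPTOR", "RICTOR"):
            states = {
                t: PRESENT if truth.tip_presence.at[t, comp] else ABSENT
                for t in tree.tip_labels
            }
            rec = dollo_reconstruct(tree, states)
            assert rec.loss_edges == truth.loss_edges[comp]

    def test_truth_satisfies_cooccurrence_rules(self):
        for seed in range(5):
            cfg = SimConfig(n_tips=25, seed=seed, loss_prob_per_edge=0.2)
            truth = plant_losses(simulate_taxonomy(cfg), cfg)
            tp = truth.tip_presence
            assert (~tp["SIN1"] | tp["RICTOR"]).all()  # SIN1 => RICTOR
            scaffold = tp["RAPTOR"] | tp["RICTOR"]
            assert (~scaffold | tp["TOR"]).all()
            assert (~scaffold | tp["LST8"]).all()


class TestEmitProteomes:
    def test_zero_divergence_yields_exact_consensus(self):
        cfg = SimConfig(n_tips=3, n_clades=1, seed=2, divergence=0.0, n_decoys=3)
        tree = simulate_taxonomy(cfg)
        truth = plant_losses(tree, cfg)
        profiles = build_component_profiles(cfg)
        proteomes = emit_proteomes(truth, profiles, cfg)
        for sp, recs in proteomes.items():
            seqs = {s for _, s in recs}
            for comp in cfg.components:
                if truth.tip_presence.at[sp, comp]:
                    assert profiles[comp].consensus in seqs

    def test_zero_completeness_empties_proteome(self):
        cfg = SimConfig(n_tips=3, n_clades=1, seed=2, completeness=0.0)
        tree = simulate_taxonomy(cfg)
        truth = plant_losses(tree, cfg)
        proteomes = emit_proteomes(truth, build_component_profiles(cfg), cfg)
        assert all(len(v) == 0 for v in proteomes.values())

    def test_determinism(self):
        cfg = SimConfig(n_tips=5, n_clades=1, seed=9, n_decoys=5)
        tree = simulate_taxonomy(cfg)
        truth = plant_losses(tree, cfg)
        profiles = build_component_profiles(cfg)
        assert emit_proteomes(truth, profiles, cfg) == emit_proteomes(
            truth, profiles, cfg
        )

    def test_divergence_lowers_scores_monotonically(self):
        # mean best-domain bits of planted homologs decreases with divergence
        from torcscan import score_sequence

        means = []
        for div in (0.05, 0.3):
            scores = []
            for seed in range(20):
                cfg = SimConfig(
                    n_tips=3, n_clades=1, seed=seed, divergence=div, n_decoys=0
                )
                prof = build_component_profiles(cfg)["LST8"]
                seq = _species_protein("S0001", "LST8", prof, cfg)
                scores.append(score_sequence(prof, seq).best_domain_bits)
            means.append(np.mean(scores))
        assert means[1] < means[0]


class TestEmitReads:
    def test_zero_error_fragments_are_substrings(self):
        cfg = SimConfig(n_tips=3, n_clades=1, seed=4, read_error_rate=0.0)
        tree = simulate_taxonomy(cfg)
        truth = plant_losses(tree, cfg)
        profiles = build_component_profiles(cfg)
        reads = emit_reads(truth, profiles, cfg)
        sp = tree.tip_labels[0]
        proteins = {
            comp: _species_protein(sp, comp, profiles[comp], cfg)
            for comp in cfg.components
            if truth.tip_presence.at[sp, comp]
        }
        n_comp_frags = len(proteins) * cfg.n_reads_per_component
        for i, (fid, frag) in enumerate(reads[sp]):
            if i < n_comp_frags:  # component fragments precede background
                assert any(frag in p for p in proteins.values())

    def test_absent_components_contribute_only_background(self):
        cfg = SimConfig(
            n_tips=3, n_clades=1, seed=4,
            root_state={c: ABSENT for c in ("TOR", "LST8", "RAPTOR", "RICTOR", "SIN1")},
        )
        tree = simulate_taxonomy(cfg)
        truth = plant_losses(tree, cfg)
        reads = emit_reads(truth, build_component_profiles(cfg), cfg)
        assert all(len(v) == cfg.n_background_reads for v in reads.values())


class TestTrophicLabels:
    def test_full_association_labels_all_torc2_lacking_autotroph(self):
        cfg = SimConfig(n_tips=30, seed=6, trophic_assoc=1.0, loss_prob_per_edge=0.3)
        tree = simulate_taxonomy(cfg)
        truth = plant_losses(tree, cfg)
        labels = assign_trophic_labels(truth, cfg)
        lacking = truth.tip_presence.index[~truth.tip_presence["RICTOR"]]
        assert len(lacking) > 0
        assert (labels.loc[lacking, "strategy"] == "autotroph").all()
        retaining = truth.tip_presence.index[truth.tip_presence["RICTOR"]]
        assert not (labels.loc[retaining, "strategy"] == "autotroph").any()

    def test_determinism(self):
        cfg = SimConfig(n_tips=10, seed=8)
        truth = plant_losses(simulate_taxonomy(cfg), cfg)
        a = assign_trophic_labels(truth, cfg)
        b = assign_trophic_labels(truth, cfg)
        assert a.equals(b)


class TestReferenceFamilies:
    def test_msas_deterministic_and_profile_ready(self):
        cfg = SimConfig(seed=3)
        msas = component_reference_msas(cfg)
        assert set(msas) == set(cfg.components)
        assert msas == component_reference_msas(cfg)
        profiles = build_component_profiles(cfg)
        for comp, prof in profiles.items():
            assert prof.length == len(msas[comp][0])


def test_full_dataset_generation_deterministic():
    cfg = SimConfig(n_tips=8, n_clades=2, seed=13, n_decoys=5)
    a, b = generate(cfg), generate(cfg)
    assert a.tree.to_newick() == b.tree.to_newick()
    assert a.proteomes == b.proteomes
    assert a.reads == b.reads
    assert a.trophic.equals(b.trophic)
    assert a.truth.tip_presence.equals(b.truth.tip_presence)
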