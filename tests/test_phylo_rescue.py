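"""Outlier flagging, read-match acceptance gates, short-read rescue."""

import numpy as np
import pandas as pd
import pytest

from torcscan import (
    ReadMatch,
    RescueConfig,
    SimConfig,
    classify_read_match,
    flag_outliers,
    rescue_component,
)
from torcscan.loss_inference import read_tree
from torcscan.phylo_rescue import match_fragment, parse_diamond_tab, run_rescue
from torcscan.synthetic_data import background_fragments, _species_protein


def matrix_for(tree, tier_by_species, component="RICTOR"):
    comps = ("TOR", "LST8", "RAPTOR", "RICTOR", "SIN1")
    rows = {
        sp: {c: (tier_by_species[sp] if c == component else "H") for c in comps}
        for sp in tree.tip_labels
    }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "species"
    return df


class TestFlagOutliers:
    def test_low_completeness_outlier_is_candidate(self):
        tree = read_tree("((A,B),C);")
        matrix = matrix_for(tree, {"A": "ABS", "B": "H", "C": "H"})
        cands = flag_outliers(matrix, tree, {"A": 0.45, "B": 0.9, "C": 0.9})
        assert ("A", "RICTOR") in cands

    def test_clade_wide_absence_not_a_candidate(self):
        tree = read_tree("((A,B),C);")
        matrix = matrix_for(tree, {"A": "ABS", "B": "ABS", "C": "ABS"})
        cands = flag_outliers(matrix, tree, {"A": 0.45, "B": 0.45, "C": 0.45})
        assert cands == []

    def test_high_completeness_absence_trusted(self):
        tree = read_tree("((A,B),C);")
        matrix = matrix_for(tree, {"A": "ABS", "B": "H", "C": "H"})
        cands = flag_outliers(matrix, tree, {"A": 0.95, "B": 0.9, "C": 0.9})
        assert cands == []

    def test_species_missing_from_tree_rejected(self):
        tree = read_tree("((A,B),C);")
        matrix = matrix_for(tree, {"A": "ABS", "B": "H", "C": "H"})
        matrix = matrix.rename(index={"A": "Z"})
        with pytest.raises(ValueError, match="Z"):
            flag_outliers(matrix, tree, {"Z": 0.4})

    def test_uniformly_present_clade_rescues_regardless_of_radius(self):
        # distant low-completeness ABS species inside a present-only clade
        tree = read_tree("(((((A,B),(C,D)),E),F),(G,H));")
        tiers = {sp: "H" for sp in tree.tip_labels}
        tiers["A"] = "ABS"
        matrix = matrix_for(tree, tiers)
        clade_map = {sp: "C1" for sp in "ABCDEF"} | {sp: "C2" for sp in "GH"}
        comp = {sp: 1.0 for sp in tree.tip_labels} | {"A": 0.3}
        cands = flag_outliers(
            matrix, tree, comp, RescueConfig(relative_radius=1), clade_map
        )
        assert ("A", "RICTOR") in cands


class TestClassifyReadMatch:
    def _match(self, **kw):
        base = dict(
            fragment_id="f1",
            component="RICTOR",
            bits=60.0,
            evalue=1e-12,
            align_len=40,
            percent_identity=0.8,
            reference_interval=(10, 50),
            overlaps_domain=True,
        )
        base.update(kw)
        return ReadMatch(**base)

    def test_long_match_passing_all_gates(self):
        ok, reason = classify_read_match(self._match())
        assert ok and reason == "ok"

    def test_short_match_low_identity_rejected(self):
        ok, reason = classify_read_match(self._match(align_len=8, percent_identity=0.65))
        assert not ok
        assert reason == "short_match_identity"

    def test_short_match_high_identity_accepted(self):
        ok, _ = classify_read_match(self._match(align_len=8, percent_identity=0.75))
        assert ok

    def test_no_domain_overlap_rejected(self):
        ok, reason = classify_read_match(self._match(overlaps_domain=False))
        assert not ok
        assert reason == "no_domain_overlap"

    def test_weak_evalue_and_bits_rejected(self):
        assert not classify_read_match(self._match(evalue=1e-8))[0]
        assert not classify_read_match(self._match(bits=50.0))[0]


class TestRescueComponent:
    def _accepted_fragments(self, dataset, species, comp, n):
        cfg = dataset.config
        protein = _species_protein(species, comp, dataset.profiles[comp], cfg)
        rng = np.random.default_rng(0)
        frags = []
        for i in range(n):
            start = int(rng.integers(0, len(protein) - cfg.read_length_aa))
            frags.append((f"r{i}", protein[start : start + cfg.read_length_aa]))
        return frags

    def test_enough_distinct_matches_give_probable(self, small_dataset):
        frags = self._accepted_fragments(small_dataset, "S0001", "RAPTOR", 5)
        call = rescue_component(frags, small_dataset.profiles["RAPTOR"], "S0001")
        assert call.tier == "P"
        assert call.source == "read_rescue"

    def test_single_match_insufficient(self, small_dataset):
        frags = self._accepted_fragments(small_dataset, "S0001", "RAPTOR", 1)
        call = rescue_component(frags, small_dataset.profiles["RAPTOR"], "S0001")
        assert call.tier == "ABS"

    def test_no_fragments_stays_absent_with_flag(self, profiles):
        call = rescue_component([], profiles["RAPTOR"], "S0001")
        assert call.tier == "ABS"
        assert "no_reads" in call.flags

    def test_background_fragments_never_rescue(self, profiles):
        # negative control: 50 seeded replicates of background-only fragments
        prof = profiles["RICTOR"]
        cfg = SimConfig(seed=123)
        false_p = 0
        for rep in range(50):
            frags = background_fragments(50, cfg, seed_tag=f"neg{rep}")
            if rescue_component(frags, prof, "sp").tier == "P":
                false_p += 1
        assert false_p == 0

    def test_rescue_power_at_default_config(self, small_dataset):
        # fragments from a real (diverged) protein recover P nearly always
        prof = small_dataset.profiles["RICTOR"]
        cfg = small_dataset.config
        recovered = 0
        for rep in range(25):
            rng = np.random.default_rng(rep)
            protein = _species_protein("S0002", "RICTOR", prof, cfg)
            frags = []
            for i in range(cfg.n_reads_per_component):
                start = int(rng.integers(0, len(protein) - cfg.read_length_aa))
                frag = protein[start : start + cfg.read_length_aa]
                frags.append((f"r{i}", frag))
            frags += background_fragments(cfg.n_background_reads, cfg, f"pw{rep}")
            if rescue_component(frags, prof, "S0002").tier == "P":
                recovered += 1
        assert recovered >= 23  # >= 90%


class TestRunRescue:
    def test_rescue_only_changes_abs_to_p(self, small_dataset):
        ds = small_dataset
        matrix = ds.truth.tip_presence.replace({True: "H", False: "ABS"})
        # knock one truly-present RAPTOR call down to ABS at low completeness
        present = [s for s in matrix.index if matrix.at[s, "RAPTOR"] == "H"]
        target = present[0]
        matrix.at[target, "RAPTOR"] = "ABS"
        completeness = {s: 1.0 for s in matrix.index} | {target: 0.4}
        updated, report = run_rescue(
            matrix, ds.tree, completeness, ds.reads, ds.profiles,
            clade_map=ds.tree.clade_map,
        )
        changed = (updated != matrix).stack()
        changed = changed[changed]
        for (sp, comp) in changed.index:
            assert matrix.at[sp, comp] == "ABS"
            assert updated.at[sp, comp] == "P"
        if (target, "RAPTOR") in [tuple(x) for x in report[["species", "component"]].values]:
            assert updated.at[target, "RAPTOR"] == "P"


class TestMatchFragment:
    def test_exact_fragment_gets_strong_evalue_and_interval(self, profiles):
        prof = profiles["TOR"]
        frag = prof.consensus[40:70]
        m = match_fragment("f1", frag, prof)
        assert m.bits > 50
        assert m.evalue < 1e-10
        assert m.overlaps_domain
        assert m.reference_interval == (40, 70)
        assert m.percent_identity == pytest.approx(1.0)


def test_parse_diamond_tab(profiles):
    prof = profiles["RAPTOR"]
    text = "r1\tRAPTOR\t85.0\t30\t1e-15\t62.0\t11\t40\n"
    matches = parse_diamond_tab(text.splitlines(), prof)
    assert len(matches) == 1
    m = matches[0]
    assert m.percent_identity == pytest.approx(0.85)
    assert m.reference_interval == (10, 40)
    assert m.overlaps_domain
    with pytest.raises(ValueError, match="line 1"):
        parse_diamond_tab(["bad\trow"], prof)
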