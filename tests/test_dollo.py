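"""Dollo parsimony: tree handling, event inference, lineage summaries, oracle."""

import numpy as np
import pytest

from homeodyn.dollo import (
    EventMap,
    FamilyEvents,
    brute_force_oracle,
    infer_events,
    lineage_summary,
    parse_tree,
    replay_events,
)
from homeodyn.matrix import ABSENT, PRESENT, UNKNOWN, PresenceMatrix
from homeodyn.synthetic import random_binary_tree, simulate_family_evolution


def row_matrix(tree, states):
    """One-family matrix over the tree's leaves."""
    cells = {("fam", sp): st for sp, st in states.items()}
    for leaf in tree.leaf_labels:
        cells.setdefault(("fam", leaf), UNKNOWN)
    return PresenceMatrix(["fam"], tree.leaf_labels, cells)


def random_row(rng, leaves, p_unknown=0.1):
    states = {}
    for leaf in leaves:
        u = rng.random()
        states[leaf] = UNKNOWN if u < p_unknown else (PRESENT if u < 0.55 else ABSENT)
    if all(s != PRESENT for s in states.values()):
        states[leaves[int(rng.integers(len(leaves)))]] = PRESENT
    return states


class TestParseTree:
    def test_packaged_tree_topology(self, tree):
        assert len(tree.leaf_labels) == 11
        anc = tree.mrca({"human", "mouse"})
        under = tree.leaves_under(anc)
        assert {"human", "chimpanzee", "macaque", "mouse", "rat"} == set(under)

    def test_malformed_newick_rejected(self):
        with pytest.raises(ValueError, match="malformed"):
            parse_tree("((A,B)")

    def test_duplicate_leaves_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            parse_tree("(a,(a,b));")

    def test_parse_write_parse_is_stable(self, tree):
        again = parse_tree(tree.newick())
        assert again.newick() == tree.newick()
        assert again.branch_names() == tree.branch_names()

    def test_internal_labels_are_unique_and_deterministic(self, tree):
        labels = [n.label for n in tree.preorder()]
        assert len(labels) == len(set(labels))
        assert parse_tree(tree.newick()).node(tree.root.label) is not None


class TestInferEvents:
    def test_rodent_only_family_gains_on_rodent_stem_without_losses(self, tree):
        m = row_matrix(
            tree,
            {sp: PRESENT if sp in ("mouse", "rat") else ABSENT for sp in tree.leaf_labels},
        )
        ev = infer_events(m, tree)["fam"]
        assert ev.gain == "chimpanzee+mouse>mouse+rat"
        assert ev.losses == frozenset()

    def test_msx3_pattern_gains_at_placental_ancestor_with_three_losses(self, tree):
        present = {"mouse", "rat", "pig", "horse"}
        m = row_matrix(
            tree, {sp: PRESENT if sp in present else ABSENT for sp in tree.leaf_labels}
        )
        ev = infer_events(m, tree)["fam"]
        assert ev.gain.endswith(">chimpanzee+cow")  # branch into the placental MRCA
        assert len(ev.losses) == 3
        lost_clades = [set(tree.leaves_under(tree.branch_child(b))) for b in ev.losses]
        assert {"human", "chimpanzee", "macaque"} in lost_clades
        assert {"cow"} in lost_clades and {"dog"} in lost_clades

    def test_ubiquitous_family_gains_at_root_without_losses(self, tree):
        m = row_matrix(tree, {sp: PRESENT for sp in tree.leaf_labels})
        ev = infer_events(m, tree)["fam"]
        assert ev.gain == tree.branch_name(tree.root)
        assert ev.losses == frozenset()

    def test_all_absent_family_has_no_gain(self, tree):
        m = row_matrix(tree, {sp: ABSENT for sp in tree.leaf_labels})
        ev = infer_events(m, tree)["fam"]
        assert ev.gain is None and ev.losses == frozenset()

    def test_unknown_leaves_never_force_losses(self, tree):
        states = {sp: ABSENT for sp in tree.leaf_labels}
        states.update({"human": PRESENT, "dog": PRESENT, "cow": UNKNOWN, "pig": UNKNOWN})
        ev = infer_events(row_matrix(tree, states), tree)["fam"]
        lost = set()
        for b in ev.losses:
            lost |= tree.leaves_under(tree.branch_child(b))
        assert "cow" not in lost and "pig" not in lost

    def test_matrix_species_must_be_tree_leaves(self, tree):
        m = PresenceMatrix(["f"], ["human", "yeti"], {("f", "human"): PRESENT, ("f", "yeti"): ABSENT})
        with pytest.raises(KeyError, match="yeti"):
            infer_events(m, tree)


class TestLineageSummary:
    def test_table2_headline_counts(self, table2, tree):
        summary = lineage_summary(infer_events(table2, tree), tree, ("human", "mouse"))
        assert summary["human"]["losses"] == ["Msx3"]
        assert summary["human"]["gains"] == ["Leutx"]
        assert summary["mouse"]["losses"] == [
            "Argfx",
            "Dprx",
            "LOC647589",
            "Nanognb",
            "Rax2",
            "Shox",
            "Tprx1",
            "Ventx",
        ]
        assert summary["mouse"]["gains"] == ["Crxos1", "Gm5585", "Gm7235", "Obox"]

    def test_empty_event_map_gives_zero_counts(self, tree):
        summary = lineage_summary(EventMap({}), tree, ("human", "mouse"))
        assert summary["human"] == {"gains": [], "losses": []}

    def test_missing_focal_leaf_rejected(self, tree):
        with pytest.raises(KeyError, match="yeti"):
            lineage_summary(EventMap({}), tree, ("human", "yeti"))

    def test_laurasiatherian_rearrangement_leaves_focal_counts_unchanged(self, table2):
        """The human/mouse tallies do not depend on the internal arrangement
        of the cow/pig/horse/dog subtree."""
        base = "(frog,(chicken,((((human,chimpanzee),macaque),(mouse,rat)),{L})));"
        results = []
        for laur in [
            "((cow,pig),(horse,dog))",
            "((cow,horse),(pig,dog))",
            "(cow,(pig,(horse,dog)))",
            "((cow,dog),(horse,pig))",
        ]:
            t = parse_tree(base.format(L=laur))
            s = lineage_summary(infer_events(table2, t), t, ("human", "mouse"))
            results.append(
                (
                    s["human"]["gains"],
                    s["human"]["losses"],
                    s["mouse"]["gains"],
                    s["mouse"]["losses"],
                )
            )
        assert all(r == results[0] for r in results)


class TestOracle:
    def test_matches_inference_on_random_instances(self):
        rng = np.random.default_rng(99)
        for trial in range(200):
            leaves = [f"s{i}" for i in range(8)]
            tree = parse_tree(random_binary_tree(leaves, seed=int(rng.integers(2**31))))
            states = random_row(rng, leaves)
            m = row_matrix(tree, states)
            inferred = infer_events(m, tree)["fam"]
            min_losses, _ = brute_force_oracle(states, tree)
            assert len(inferred.losses) == min_losses, f"trial {trial}"

    def test_replay_of_inferred_events_matches_known_states(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            leaves = [f"s{i}" for i in range(7)]
            tree = parse_tree(random_binary_tree(leaves, seed=int(rng.integers(2**31))))
            states = random_row(rng, leaves)
            m = row_matrix(tree, states)
            events = infer_events(m, tree)
            replay = replay_events(events, tree)["fam"]
            for leaf, st in states.items():
                if st != UNKNOWN:
                    assert replay[leaf] == st

    def test_all_present_row_needs_no_losses(self, tree):
        states = {sp: PRESENT for sp in tree.leaf_labels}
        assert brute_force_oracle(states, tree)[0] == 0

    def test_large_tree_guard(self):
        tree = parse_tree(random_binary_tree([f"s{i}" for i in range(13)], seed=1))
        with pytest.raises(ValueError, match="12 leaves"):
            brute_force_oracle({f"s{i}": PRESENT for i in range(13)}, tree)

    def test_single_leaf_flips_obey_one_sided_loss_bounds(self):
        """Making a leaf present can drop the minimal loss count by at most 1;
        making a leaf absent can raise it by at most 1 (the reverse directions
        are unbounded: a flip can move the gain deeper in the tree, or split
        an all-absent subtree into several)."""
        rng = np.random.default_rng(55)
        for _ in range(100):
            leaves = [f"s{i}" for i in range(8)]
            tree = parse_tree(random_binary_tree(leaves, seed=int(rng.integers(2**31))))
            states = random_row(rng, leaves, p_unknown=0.0)
            before = infer_events(row_matrix(tree, states), tree)["fam"]
            absent = [l for l in leaves if states[l] == ABSENT]
            present = [l for l in leaves if states[l] == PRESENT]
            if absent:
                flip = absent[int(rng.integers(len(absent)))]
                after = infer_events(
                    row_matrix(tree, dict(states, **{flip: PRESENT})), tree
                )["fam"]
                assert len(after.losses) >= len(before.losses) - 1
            if present:
                flip = present[int(rng.integers(len(present)))]
                after = infer_events(
                    row_matrix(tree, dict(states, **{flip: ABSENT})), tree
                )["fam"]
                assert len(after.losses) <= len(before.losses) + 1


class TestSimulationRecovery:
    def test_inference_explains_simulated_data_with_no_more_losses(self, tree):
        """Dollo inference finds a minimal explanation of simulated histories."""
        for seed in range(30):
            matrix, truth = simulate_family_evolution(
                tree, 10, loss_prob_per_branch=0.2, seed=seed
            )
            events = infer_events(matrix, tree)
            replay = replay_events(events, tree)
            sim_losses = {}
            for fam, _, kind in truth.simulation_events:
                if kind == "loss":
                    sim_losses[fam] = sim_losses.get(fam, 0) + 1
            for fam in matrix.families:
                for leaf in tree.leaf_labels:
                    assert replay[fam][leaf] == matrix.state(fam, leaf)
                if events[fam].gain is not None:
                    assert len(events[fam].losses) <= sim_losses.get(fam, 0)
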