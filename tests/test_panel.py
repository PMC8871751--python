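"""Backbone marker selection and consecutive-genotyping assignment."""

from __future__ import annotations

import pytest

from patrilinekit.fixtures import load_backbone_panel, load_backbone_tree
from patrilinekit.nomenclature import NameRegistry, assign_names
from patrilinekit.panel import (
    BackboneError,
    PanelCallSet,
    assign_sample,
    select_backbone,
)
from patrilinekit.phylogeny import build_tree
from patrilinekit.simulate import SimConfig, simulate

from conftest import make_matrix, random_perfect_matrix


def _named_sim_tree(seed: int, mu: float = 0.4):
    truth = simulate(
        SimConfig(generations=5, founders=3, mu=mu, sites=250, seed=seed)
    )
    tree, _ = build_tree(truth.true_matrix)
    assign_names(tree, NameRegistry(), root_label="R")
    return truth, tree


class TestBackboneFixture:
    def test_fixture_loads_with_named_markers(self):
        tree = load_backbone_tree()
        panel = load_backbone_panel(tree)
        assert panel.stage["rAY"] == "key" and panel.stage["rAX"] == "key"
        assert {panel.stage[m] for m in ("rA", "rW", "fYR")} == {"clade"}
        crown = tree.node_by_label("crown")
        assert set(panel.markers_on_edge(crown.node_id)) == {"rAY", "rAX"}
        ta = tree.node_by_label("Ta")
        assert set(panel.markers_on_edge(ta.node_id)) == {
            "sPZ", "fTY", "fRL", "fXT", "fZK", "fZW",
        }

    def test_ta_star_placement_from_published_marker_states(self):
        """Derived on the Ta branch, ancestral for the Ta-s/Ta-b splits,
        untested below: the sample sits at the internal Ta node, starred."""
        tree = load_backbone_tree()
        panel = load_backbone_panel(tree)
        calls = PanelCallSet(
            sample="x",
            calls={
                "rAY": "D", "rAX": "D", "rW": "D",
                "sPZ": "D", "fTY": "D", "fRL": "D",
                "fXT": "D", "fZK": "D", "fZW": "D",
                "qGB": "A", "qGC": "A", "sPY": "A",
            },
        )
        a = assign_sample(calls, tree, panel)
        assert a.node_label == "Ta*"
        assert not a.resolved
        assert set(a.evidence) >= {"sPZ", "fTY", "fRL", "fXT", "fZK", "fZW"}
        assert a.conflicts == ()

    def test_crown_root_star_when_only_keys_derived(self):
        tree = load_backbone_tree()
        panel = load_backbone_panel(tree)
        calls = PanelCallSet(
            sample="x",
            calls={"rAY": "D", "rAX": "D", "rA": "A", "rW": "A", "fYR": "A"},
        )
        a = assign_sample(calls, tree, panel)
        assert a.node_label == "crown*"
        assert not a.resolved

    def test_derived_markers_on_two_clades_conflict(self):
        tree = load_backbone_tree()
        panel = load_backbone_panel(tree)
        calls = PanelCallSet(
            sample="x",
            calls={"rAY": "D", "rAX": "D", "rA": "D", "rW": "D"},
        )
        a = assign_sample(calls, tree, panel)
        assert a.node_label == "conflict"
        assert not a.resolved
        assert a.conflicts


class TestSelectBackbone:
    def test_focus_path_fully_covered(self):
        tree = load_backbone_tree()
        panel = select_backbone(tree, focus={"Ta-bA"})
        # one marker per edge on ROOT -> crown -> T -> Ta -> Ta-b -> Ta-bA
        assert len(panel.markers) == 5
        labels = {tree.nodes[panel.branch_map[m]].label for m in panel.markers}
        assert labels == {"crown", "T", "Ta", "Ta-b", "Ta-bA"}
        # lexicographically smallest site chosen on multi-site edges
        assert "fRL" in panel.markers and "qGC" in panel.markers

    def test_coarse_node_gets_only_subtending_marker(self):
        tree = load_backbone_tree()
        panel = select_backbone(tree, focus=set(), coarse={"Ta"})
        assert len(panel.markers) == 1
        assert tree.nodes[panel.branch_map[panel.markers[0]]].label == "Ta"

    def test_markerless_focus_edge_rejected(self):
        tree = load_backbone_tree()
        with pytest.raises(BackboneError, match="Ao-aA1a"):
            select_backbone(tree, focus={"Ao-aA1a2a"})

    @pytest.mark.parametrize("seed", range(6))
    def test_path_cover_oracle_on_random_trees(self, seed):
        """Every root->focus path edge carries exactly one panel marker and
        nothing else is selected (checked by independent path enumeration)."""
        import numpy as np

        rng = np.random.default_rng(seed)
        m = random_perfect_matrix(rng, int(rng.integers(5, 12)), 20)
        tree, _ = build_tree(m)
        assign_names(tree, NameRegistry(), root_label="R")
        assert len(tree.nodes) <= 40
        labelled = [n for n in tree.nodes.values() if n.parent is not None]
        focus = {n.label for n in labelled[: len(labelled) // 2]}
        coarse = {n.label for n in labelled[len(labelled) // 2 :][:2]}
        panel = select_backbone(tree, focus=focus, coarse=coarse)
        # independent enumeration of required edges
        required = set()
        for lab in focus:
            nid = tree.node_by_label(lab).node_id
            path = tree.path_to_root(nid)[:-1]
            required.update(path)
        optional = set()
        for lab in coarse:
            nid = tree.node_by_label(lab).node_id
            if tree.nodes[nid].edge_sites:
                optional.add(nid)
        tagged = set(panel.branch_map.values())
        assert required <= tagged
        assert tagged <= required | optional
        # minimality: exactly one marker per tagged edge
        for edge in tagged:
            assert len(panel.markers_on_edge(edge)) == 1
            assert panel.markers_on_edge(edge)[0] == min(
                tree.nodes[edge].edge_sites
            )


class TestAssignmentConsistency:
    @pytest.mark.parametrize("seed", range(4))
    def test_full_panel_matches_sequencing_placement(self, seed):
        truth, tree = _named_sim_tree(seed)
        focus = {
            n.label for n in tree.nodes.values() if n.members and n.parent is not None
        }
        panel = select_backbone(tree, focus=focus)
        placement = {
            m: nid for nid, n in tree.nodes.items() for m in n.members
        }
        for sample in truth.samples:
            row = truth.true_matrix.geno[truth.true_matrix.sample_index(sample)]
            derived = {
                truth.true_matrix.sites[i].site_id
                for i in range(truth.true_matrix.n_sites)
                if row[i] == 1
            }
            calls = PanelCallSet(
                sample=sample,
                calls={m: ("D" if m in derived else "A") for m in panel.markers},
            )
            a = assign_sample(calls, tree, panel)
            assert a.node_id == placement[sample]
            assert a.resolved
            assert not a.node_label.endswith("*")

    def test_withheld_markers_star_the_ancestor_never_a_descendant(self):
        truth, tree = _named_sim_tree(1)
        focus = {
            n.label for n in tree.nodes.values() if n.members and n.parent is not None
        }
        panel = select_backbone(tree, focus=focus)
        # pick a sample sitting below an internal node, withhold everything
        # tested below that node
        target = None
        for nid, n in tree.nodes.items():
            if n.parent is not None and tree.children(nid) and n.members:
                target = nid
                break
        assert target is not None
        below = set(tree.subtree(target)) - {target}
        sample = next(
            m
            for sub in tree.subtree(target)
            for m in tree.nodes[sub].members
        )
        row = truth.true_matrix.geno[truth.true_matrix.sample_index(sample)]
        derived = {
            truth.true_matrix.sites[i].site_id
            for i in range(truth.true_matrix.n_sites)
            if row[i] == 1
        }
        calls = {}
        for m in panel.markers:
            if panel.branch_map[m] in below:
                calls[m] = "U"
            else:
                calls[m] = "D" if m in derived else "A"
        a = assign_sample(PanelCallSet(sample=sample, calls=calls), tree, panel)
        assert a.node_id == target
        assert not a.resolved
        assert a.node_label.endswith("*")

    def test_failed_assays_behave_like_untested(self):
        tree = load_backbone_tree()
        panel = load_backbone_panel(tree)
        base = {"rAY": "D", "rAX": "D", "rA": "A", "rW": "A", "fYR": "A"}
        a_u = assign_sample(PanelCallSet("x", dict(base)), tree, panel)
        failed = dict(base)
        failed.update({m: "F" for m in panel.markers if m not in base})
        a_f = assign_sample(PanelCallSet("x", failed), tree, panel)
        assert (a_u.node_label, a_u.resolved) == (a_f.node_label, a_f.resolved)

    def test_auto_imputed_markers_never_in_evidence(self):
        tree = load_backbone_tree()
        panel = load_backbone_panel(tree)
        calls = PanelCallSet(
            sample="x",
            calls={
                "rAY": "D", "rAX": "D", "rW": "D",
                "sPZ": "D", "fTY": "D", "fRL": "D",
                "fXT": "D", "fZK": "D", "fZW": "D",
                "qGB": "A", "qGC": "D", "sPY": "D", "qDK": "A",
            },
        )
        a = assign_sample(calls, tree, panel)
        assert a.node_label == "Ta-b"
        assert a.resolved
        assert set(a.auto_imputed) <= {"qFE", "rAB", "fWO"}
        assert not set(a.auto_imputed) & set(a.evidence)

    def test_non_panel_calls_rejected(self):
        tree = load_backbone_tree()
        panel = load_backbone_panel(tree)
        with pytest.raises(ValueError, match="zzz"):
            assign_sample(PanelCallSet("x", {"zzz": "D"}), tree, panel)
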