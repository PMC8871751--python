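"""Reduced marker backbones and consecutive-genotyping haplotype assignment.

Sequencing every sample is not needed for lineage tracing: a small panel of
branch-tagging markers (the "backbone") suffices.  Markers are genotyped in
a consecutive fashion — key markers first (does the sample belong to the
recently expanded crown haplogroup at all?), then clade markers (which major
clade?), then haplotype markers inside the clade, with markers informative
only in *other* clades imputed as ancestral.  A sample whose markers run out
before a leaf is reached is placed at the deepest supported internal node
and flagged with an asterisk.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from .phylogeny import HaplotypeTree, TreeNode

__all__ = [
    "MarkerPanel",
    "PanelCallSet",
    "Assignment",
    "BackboneError",
    "select_backbone",
    "assign_sample",
    "CALL_SYMBOLS",
]

#: panel call symbols: Ancestral, Derived, Untested, Failed assay
CALL_SYMBOLS = ("A", "D", "U", "F")

ANCESTRAL, DERIVED, UNTESTED, FAILED = CALL_SYMBOLS


class BackboneError(ValueError):
    """Raised when a required tree edge carries no typable marker."""


@dataclass
class MarkerPanel:
    """Ordered marker subset with clade roles and marker -> edge mapping.

    ``branch_map`` identifies each tagged edge by the node id of its child;
    ``stage`` is ``key`` for edges leaving the root (crown-defining),
    ``clade`` for the first split below, and ``ht`` for everything deeper.
    """

    markers: list[str]
    stage: dict[str, str]
    branch_map: dict[str, int]

    def markers_on_edge(self, child_id: int) -> list[str]:
        return [m for m in self.markers if self.branch_map[m] == child_id]

    def to_frame(self, tree: HaplotypeTree | None = None) -> pd.DataFrame:
        rows = []
        for m in self.markers:
            child = self.branch_map[m]
            edge_key = (
                tree.nodes[child].label
                if tree is not None and tree.nodes[child].label
                else str(child)
            )
            rows.append((m, self.stage[m], edge_key))
        return pd.DataFrame(rows, columns=["site_id", "stage", "edge_key"])

    def write(self, path: str | Path, tree: HaplotypeTree | None = None) -> None:
        self.to_frame(tree).to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path: str | Path, tree: HaplotypeTree) -> "MarkerPanel":
        df = pd.read_csv(path, sep="\t", dtype=str)
        markers, stage, branch_map = [], {}, {}
        by_label = {
            n.label: n.node_id for n in tree.nodes.values() if n.label
        }
        for _, row in df.iterrows():
            m = row["site_id"]
            markers.append(m)
            stage[m] = row["stage"]
            key = row["edge_key"]
            branch_map[m] = by_label[key] if key in by_label else int(key)
        return cls(markers=markers, stage=stage, branch_map=branch_map)


@dataclass
class PanelCallSet:
    """Genotyped panel states for one sample (marker -> A/D/U/F)."""

    sample: str
    calls: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for m, c in self.calls.items():
            if c not in CALL_SYMBOLS:
                raise ValueError(f"bad panel call {c!r} for marker {m!r}")

    def get(self, marker: str) -> str:
        return self.calls.get(marker, UNTESTED)


@dataclass
class Assignment:
    """Placement of a panel-genotyped sample on the backbone tree.

    ``resolved`` is off for asterisk placements at internal nodes (untested
    markers remain below) and for conflicts; ``evidence`` lists the derived
    markers supporting the root path, ``conflicts`` any derived markers off
    that path.
    """

    sample: str
    node_label: str
    node_id: int | None
    resolved: bool
    evidence: tuple[str, ...] = ()
    conflicts: tuple[str, ...] = ()
    auto_imputed: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# backbone selection
# ---------------------------------------------------------------------------

def _resolve(tree: HaplotypeTree, label: str) -> int:
    for nid, node in tree.nodes.items():
        if node.label == label:
            return nid
    raise KeyError(f"label {label!r} not found in tree")


def _stage_of(tree: HaplotypeTree, child_id: int) -> str:
    parent = tree.nodes[child_id].parent
    if parent == tree.root:
        return "key"
    if parent is not None and tree.nodes[parent].parent == tree.root:
        return "clade"
    return "ht"


def select_backbone(
    tree: HaplotypeTree,
    focus: set[str] | list[str],
    coarse: set[str] | list[str] = (),
) -> MarkerPanel:
    """Choose one marker per edge needed for the requested traceability.

    Every edge on every root -> *focus* path gets a marker (those lineages
    stay fully traceable), while each *coarse* node gets a marker only on
    its subtending edge (enough to recognise the cluster, not to resolve
    haplotypes inside it).  Where an edge carries several sites the
    lexicographically smallest site_id is taken; an edge on a focus path
    carrying no sites at all is a hard error naming the edge.
    """
    markers: list[str] = []
    stage: dict[str, str] = {}
    branch_map: dict[str, int] = {}

    def tag_edge(child_id: int, required: bool) -> None:
        node = tree.nodes[child_id]
        if not node.edge_sites:
            if required:
                parent = node.parent
                raise BackboneError(
                    f"edge {parent}->{child_id} "
                    f"({tree.nodes[parent].label or parent} -> "
                    f"{node.label or child_id}) has no available sites"
                )
            return
        m = min(node.edge_sites)
        if m not in branch_map:
            markers.append(m)
            branch_map[m] = child_id
            stage[m] = _stage_of(tree, child_id)

    for label in sorted(focus):
        nid = _resolve(tree, label)
        for step in reversed(tree.path_to_root(nid)[:-1]):  # root-side first
            tag_edge(step, required=True)
    for label in sorted(coarse):
        nid = _resolve(tree, label)
        if nid == tree.root:
            continue
        tag_edge(nid, required=False)
    return MarkerPanel(markers=markers, stage=stage, branch_map=branch_map)


# ---------------------------------------------------------------------------
# sample assignment
# ---------------------------------------------------------------------------

def _clade_nodes(tree: HaplotypeTree, panel: MarkerPanel) -> list[int]:
    """Roots of the major clades: children of edges staged 'clade'."""
    return sorted({panel.branch_map[m] for m in panel.markers if panel.stage[m] == "clade"})


def assign_sample(
    calls: PanelCallSet, tree: HaplotypeTree, panel: MarkerPanel
) -> Assignment:
    """Place a panel-genotyped sample on the backbone tree.

    The assigned node is the deepest node such that every tested marker on
    its root path is derived and every tested marker on edges leaving the
    path is ancestral.  Markers informative only in clades other than the
    sample's are imputed ancestral first (and never count as evidence).
    Failed assays are treated exactly like untested markers.  Derived
    markers on two or more disjoint branches are irreconcilable with a
    single patriline and yield ``node_label="conflict"``.
    """
    unknown = set(calls.calls) - set(panel.markers)
    if unknown:
        raise ValueError(f"calls reference non-panel markers: {sorted(unknown)}")

    state: dict[str, str] = {m: calls.get(m) for m in panel.markers}
    for m, s in state.items():
        if s == FAILED:
            state[m] = UNTESTED

    # auto-impute the ancestral allele for markers private to other clades
    auto_imputed: list[str] = []
    clades = _clade_nodes(tree, panel)
    derived_clades = [
        c
        for c in clades
        if any(state[m] == DERIVED for m in panel.markers_on_edge(c))
    ]
    if len(derived_clades) == 1:
        own = set(tree.subtree(derived_clades[0]))
        for other in clades:
            if other == derived_clades[0]:
                continue
            for nid in tree.subtree(other):
                if nid == other:
                    continue  # the clade edge itself stays tested/untested as is
                for m in panel.markers_on_edge(nid):
                    if state[m] == UNTESTED:
                        state[m] = ANCESTRAL
                        auto_imputed.append(m)

    # walk down from the root along edges supported by derived markers
    cur = tree.root
    path_nodes = [cur]
    while True:
        supported = []
        for child in tree.children(cur):
            ms = panel.markers_on_edge(child)
            tested = [m for m in ms if state[m] in (ANCESTRAL, DERIVED)]
            if tested and all(state[m] == DERIVED for m in tested):
                supported.append(child)
        if len(supported) != 1:
            break
        cur = supported[0]
        path_nodes.append(cur)

    path_edges = set(path_nodes[1:])
    derived_markers = [m for m in panel.markers if state[m] == DERIVED]
    evidence = tuple(
        m
        for m in derived_markers
        if panel.branch_map[m] in path_edges and m not in auto_imputed
    )
    conflicts = tuple(
        m for m in derived_markers if panel.branch_map[m] not in path_edges
    )
    node = tree.nodes[cur]
    label = node.label or f"HT{cur}"
    if conflicts:
        return Assignment(
            sample=calls.sample,
            node_label="conflict",
            node_id=None,
            resolved=False,
            evidence=evidence,
            conflicts=conflicts,
            auto_imputed=tuple(auto_imputed),
        )

    # untested markers below the node leave the placement unresolved
    below_untested = [
        m
        for nid in tree.subtree(cur)
        if nid != cur
        for m in panel.markers_on_edge(nid)
        if state[m] == UNTESTED
    ]
    resolved = not below_untested
    if not resolved:
        label = label + "*"
    return Assignment(
        sample=calls.sample,
        node_label=label,
        node_id=cur,
        resolved=resolved,
        evidence=evidence,
        conflicts=(),
        auto_imputed=tuple(auto_imputed),
    )


def load_panel_calls(path: str | Path) -> list[PanelCallSet]:
    """Read a delimited sample x marker grid of A/D/U/F panel calls."""
    df = pd.read_csv(path, sep="\t", dtype=str, index_col=0)
    out = []
    for sample, row in df.iterrows():
        out.append(
            PanelCallSet(
                sample=str(sample),
                calls={m: str(v) for m, v in row.items() if pd.notna(v)},
            )
        )
    return out


def write_assignments(assignments: list[Assignment], path: str | Path) -> None:
    pd.DataFrame(
        [
            (
                a.sample,
                a.node_label,
                int(a.resolved),
                ",".join(a.conflicts) or ".",
                ",".join(a.evidence) or ".",
            )
            for a in assignments
        ],
        columns=["sample", "node_label", "resolved", "conflicts", "evidence"],
    ).to_csv(path, sep="\t", index=False)
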