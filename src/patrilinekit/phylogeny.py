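"""Perfect-phylogeny reconstruction of the rooted MSY haplotype tree.

Because the MSY never recombines, every polymorphic site mutates exactly once
on the genealogy (infinite-sites premise) and the derived-carrier sets of the
sites form a laminar family: the tree can be reconstructed directly by
nesting carrier sets, with the root fixed at the all-ancestral vector of the
outgroup.  Sites violating this premise (recurrent mutation, genotyping
error) are detected with the four-gamete compatibility test and either
reported as a hard failure or greedily dropped.

Polytomies are kept explicit — a star-like multifurcation is a finding about
the underlying expansion, not a drawing artifact.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

from .matrix import ANCESTRAL, DERIVED, MISSING, HET_ARTIFACT, CallMatrix, MatrixError

__all__ = [
    "TreeNode",
    "HaplotypeTree",
    "ConflictReport",
    "PerfectPhylogenyError",
    "four_gamete_check",
    "build_tree",
    "export_tree",
    "load_tree_table",
]

ROOT_LABEL = "ROOT"


class PerfectPhylogenyError(ValueError):
    """Raised when the matrix admits no perfect phylogeny and on_conflict='fail'."""

    def __init__(self, report: "ConflictReport"):
        self.report = report
        pairs = ", ".join(f"({a},{b})" for a, b in report.conflicting_pairs[:5])
        more = "" if len(report.conflicting_pairs) <= 5 else ", ..."
        super().__init__(f"incompatible site pairs: {pairs}{more}")


@dataclass
class ConflictReport:
    """Site pairs failing compatibility, plus any sites dropped to resolve them."""

    conflicting_pairs: list[tuple[str, str]] = field(default_factory=list)
    resolution: list[str] = field(default_factory=list)

    @property
    def is_clean(self) -> bool:
        return not self.conflicting_pairs


@dataclass
class TreeNode:
    """A haplotype (or inferred internal) node of the rooted tree.

    ``edge_sites`` are the variant ids that mutated on the edge from the
    parent to this node (empty for the root); ``members`` are the samples
    whose full state vector equals this node's vector.
    """

    node_id: int
    parent: int | None
    edge_sites: tuple[str, ...] = ()
    members: tuple[str, ...] = ()
    label: str | None = None


@dataclass
class HaplotypeTree:
    """Rooted haplotype tree with variants on edges and sample frequencies."""

    nodes: dict[int, TreeNode]
    root: int

    def children(self, node_id: int) -> list[int]:
        return sorted(
            n.node_id for n in self.nodes.values() if n.parent == node_id
        )

    @property
    def frequencies(self) -> dict[int, int]:
        return {nid: len(n.members) for nid, n in self.nodes.items()}

    @property
    def n_samples(self) -> int:
        return sum(len(n.members) for n in self.nodes.values())

    def path_to_root(self, node_id: int) -> list[int]:
        """Node ids from ``node_id`` up to and including the root."""
        path = [node_id]
        while self.nodes[path[-1]].parent is not None:
            path.append(self.nodes[path[-1]].parent)
        return path

    def derived_sites(self, node_id: int) -> frozenset[str]:
        """All sites derived at this node (union of edge sites on the root path)."""
        out: set[str] = set()
        for nid in self.path_to_root(node_id):
            out.update(self.nodes[nid].edge_sites)
        return frozenset(out)

    def subtree(self, node_id: int) -> list[int]:
        """Node ids of the subtree rooted at ``node_id`` (preorder)."""
        out, stack = [], [node_id]
        while stack:
            nid = stack.pop()
            out.append(nid)
            stack.extend(reversed(self.children(nid)))
        return out

    def node_by_label(self, label: str) -> TreeNode:
        for n in self.nodes.values():
            if n.label == label:
                return n
        raise KeyError(f"no node labelled {label!r}")

    def edge_signature(self) -> frozenset[tuple[frozenset, frozenset]]:
        """Canonical topology signature: {(samples below edge, sites on edge)}.

        Two trees over the same samples are topologically identical iff their
        signatures match (zero-mutation edges cannot occur by construction).
        """
        sig = set()
        for nid, node in self.nodes.items():
            if node.parent is None:
                continue
            below: set[str] = set()
            for sub in self.subtree(nid):
                below.update(self.nodes[sub].members)
            sig.add((frozenset(below), frozenset(node.edge_sites)))
        return frozenset(sig)


# ---------------------------------------------------------------------------
# compatibility
# ---------------------------------------------------------------------------

def _binary_columns(matrix: CallMatrix, samples_idx: list[int]) -> np.ndarray:
    geno = matrix.geno[samples_idx, :]
    if np.any((geno == MISSING) | (geno == HET_ARTIFACT)):
        raise MatrixError("matrix contains missing calls; impute or drop them first")
    return geno


def four_gamete_check(matrix: CallMatrix) -> ConflictReport:
    """Test every site pair for the four-gamete condition.

    A pair of binary sites is incompatible with a tree iff all four gamete
    combinations (00, 01, 10, 11) occur among the samples.  On data generated
    under the infinite-sites model the report is always empty.
    """
    idx = list(range(matrix.n_samples))
    geno = _binary_columns(matrix, idx)
    report = ConflictReport()
    poly = [i for i in range(matrix.n_sites) if len(np.unique(geno[:, i])) > 1]
    for i, j in itertools.combinations(poly, 2):
        a, b = geno[:, i], geno[:, j]
        gametes = {(int(x), int(y)) for x, y in zip(a, b)}
        if len(gametes) == 4:
            report.conflicting_pairs.append(
                (matrix.sites[i].site_id, matrix.sites[j].site_id)
            )
    return report


def _carrier_sets(
    matrix: CallMatrix, ingroup: list[str]
) -> dict[str, frozenset[str]]:
    idx = [matrix.sample_index(s) for s in ingroup]
    geno = _binary_columns(matrix, idx)
    carriers: dict[str, frozenset[str]] = {}
    order = sorted(
        range(matrix.n_sites),
        key=lambda i: (matrix.sites[i].position, matrix.sites[i].site_id),
    )
    for i in order:
        site = matrix.sites[i]
        if site.site_id in matrix.unpolarized_sites:
            continue  # ancestral state unknown: excluded from tree building
        carr = frozenset(s for s, g in zip(ingroup, geno[:, i]) if g == DERIVED)
        if carr:
            carriers[site.site_id] = carr
    return carriers


def _rooted_conflicts(
    carriers: dict[str, frozenset[str]]
) -> list[tuple[str, str]]:
    # With the root fixed at the all-ancestral vector, two sites are
    # compatible iff their carrier sets nest or are disjoint (the root
    # supplies the 00 gamete even when no sampled ingroup male does).
    out = []
    items = sorted(carriers.items())
    for (sa, ca), (sb, cb) in itertools.combinations(items, 2):
        if ca & cb and not (ca <= cb or cb <= ca):
            out.append((sa, sb))
    return out


def build_tree(
    matrix: CallMatrix, on_conflict: str = "fail"
) -> tuple[HaplotypeTree, ConflictReport]:
    """Build the unique rooted perfect phylogeny of the polarized matrix.

    Sites with identical derived-carrier sets share one edge.  When the
    matrix is incompatible, ``on_conflict="fail"`` raises
    :class:`PerfectPhylogenyError`, while ``"greedy_drop"`` repeatedly
    removes the conflicting site with the fewest derived carriers (ties
    broken by site_id) until the remainder is compatible, recording dropped
    sites in the report.
    """
    if not matrix.polarized:
        raise MatrixError("matrix must be polarized before tree building")
    if on_conflict not in ("fail", "greedy_drop"):
        raise ValueError(f"unknown conflict policy {on_conflict!r}")
    ingroup = matrix.ingroup_samples
    if not ingroup:
        raise MatrixError("no ingroup samples")
    carriers = _carrier_sets(matrix, ingroup)
    report = ConflictReport()
    conflicts = _rooted_conflicts(carriers)
    report.conflicting_pairs = list(conflicts)
    if conflicts and on_conflict == "fail":
        raise PerfectPhylogenyError(report)
    while conflicts:
        involved = sorted(
            {s for pair in conflicts for s in pair},
            key=lambda s: (len(carriers[s]), s),
        )
        victim = involved[0]
        report.resolution.append(victim)
        del carriers[victim]
        conflicts = _rooted_conflicts(carriers)

    # group sites with identical carrier sets onto one edge
    clusters: dict[frozenset[str], list[str]] = {}
    for sid, carr in carriers.items():
        clusters.setdefault(carr, []).append(sid)
    ordered = sorted(clusters.items(), key=lambda kv: (-len(kv[0]), sorted(kv[1])))

    nodes: dict[int, TreeNode] = {0: TreeNode(node_id=0, parent=None, label=None)}
    cluster_node: list[tuple[frozenset[str], int]] = []
    for carr, sids in ordered:
        parent = 0
        parent_size = None
        for other, nid in cluster_node:
            if carr < other and (parent_size is None or len(other) < parent_size):
                parent, parent_size = nid, len(other)
        nid = len(nodes)
        nodes[nid] = TreeNode(
            node_id=nid, parent=parent, edge_sites=tuple(sorted(sids))
        )
        cluster_node.append((carr, nid))

    # members: each sample sits at its deepest containing cluster (the one
    # with the fewest carriers, since containing clusters form a chain)
    deepest: dict[str, int] = {s: 0 for s in ingroup}
    best_size: dict[str, int | None] = {s: None for s in ingroup}
    for carr, nid in cluster_node:
        for s in carr:
            if best_size[s] is None or len(carr) < best_size[s]:
                best_size[s] = len(carr)
                deepest[s] = nid
    members: dict[int, list[str]] = {nid: [] for nid in nodes}
    for s in ingroup:
        members[deepest[s]].append(s)
    for nid, node in nodes.items():
        node.members = tuple(sorted(members[nid], key=ingroup.index))

    tree = HaplotypeTree(nodes=nodes, root=0)
    return tree, report


# ---------------------------------------------------------------------------
# export / import
# ---------------------------------------------------------------------------

def export_tree(tree: HaplotypeTree, fmt: str, path: str | Path) -> None:
    """Write the tree as ``newick``, ``dot``, ``graphml`` or ``table``.

    The table format is lossless (node, parent, edge sites, members); Newick
    carries branch lengths equal to the number of mutations on each edge.
    DOT/GraphML exports draw one node per haplotype with the member count as
    a size attribute, mirroring frequency-proportional network drawings.
    """
    path = Path(path)
    if fmt == "table":
        _export_table(tree, path)
    elif fmt == "newick":
        path.write_text(to_newick(tree) + "\n")
    elif fmt in ("dot", "graphml"):
        g = to_networkx(tree)
        import networkx as nx

        if fmt == "dot":
            lines = ["digraph haplotree {"]
            for n, data in g.nodes(data=True):
                lab = data["label"] or f"HT{n}"
                lines.append(
                    f'  n{n} [label="{lab} (n={data["frequency"]})", '
                    f'width={0.3 + 0.1 * data["frequency"]:.2f}];'
                )
            for a, b, data in g.edges(data=True):
                lines.append(f'  n{a} -> n{b} [label="{data["sites"]}"];')
            lines.append("}")
            path.write_text("\n".join(lines) + "\n")
        else:
            nx.write_graphml(g, path)
    else:
        raise ValueError(f"unsupported export format {fmt!r}")


def _node_name(node: TreeNode) -> str:
    return node.label if node.label else f"HT{node.node_id}"


def to_newick(tree: HaplotypeTree) -> str:
    def render(nid: int) -> str:
        node = tree.nodes[nid]
        kids = tree.children(nid)
        name = _node_name(node) if node.parent is not None or not kids else (
            node.label or ROOT_LABEL
        )
        inner = ""
        if kids:
            inner = "(" + ",".join(render(k) for k in kids) + ")"
        if node.parent is None:
            return f"{inner}{name}"
        return f"{inner}{name}:{len(node.edge_sites)}"

    return render(tree.root) + ";"


def to_networkx(tree: HaplotypeTree):
    import networkx as nx

    g = nx.DiGraph()
    for nid, node in tree.nodes.items():
        g.add_node(
            nid,
            label=node.label or "",
            frequency=len(node.members),
            members=",".join(node.members),
        )
    for nid, node in tree.nodes.items():
        if node.parent is not None:
            g.add_edge(node.parent, nid, sites=",".join(node.edge_sites))
    return g


def _export_table(tree: HaplotypeTree, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("node\tparent\tlabel\tedge_sites\tfrequency\tmembers\n")
        for nid in sorted(tree.nodes):
            node = tree.nodes[nid]
            fh.write(
                "\t".join(
                    [
                        str(nid),
                        "." if node.parent is None else str(node.parent),
                        node.label or ".",
                        ",".join(node.edge_sites) or ".",
                        str(len(node.members)),
                        ",".join(node.members) or ".",
                    ]
                )
                + "\n"
            )


def load_tree_table(path: str | Path) -> HaplotypeTree:
    """Inverse of the ``table`` export (lossless round-trip)."""
    nodes: dict[int, TreeNode] = {}
    root = None
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["node", "parent", "label", "edge_sites", "frequency", "members"]
        if header != expected:
            raise MatrixError(f"unexpected tree-table header in {path}")
        for line in fh:
            node_s, parent_s, label, sites_s, _freq, members_s = line.rstrip(
                "\n"
            ).split("\t")
            nid = int(node_s)
            parent = None if parent_s == "." else int(parent_s)
            if parent is None:
                root = nid
            nodes[nid] = TreeNode(
                node_id=nid,
                parent=parent,
                edge_sites=tuple(sites_s.split(",")) if sites_s != "." else (),
                members=tuple(members_s.split(",")) if members_s != "." else (),
                label=None if label == "." else label,
            )
    if root is None:
        raise MatrixError(f"no root node in {path}")
    return HaplotypeTree(nodes=nodes, root=root)
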