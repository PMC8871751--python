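"""Hierarchical haplotype nomenclature: legacy stems plus one character per level.

Haplotype names grow by exactly one alphanumeric character per tree level,
alternating character class with the parent's last character (after a letter
a digit starting at "1", after a digit a lowercase letter starting at "a"),
the same convention used for human Y-chromosome haplotype names.  Historic
labels ("legacy stems" such as ``Ta``, ``Tb-oB``, ``Ao-a`` or ``Hs``) anchor
subtrees and are treated as opaque prefixes — hyphens are ordinary label
characters owned by the stem, and case is significant.

A trailing ``*`` marks an *asterisk haplotype*: a sample placed at the
internal node named by the rest of the label because the available markers
cannot resolve it onto a leaf.  ``X*`` is therefore ancestry-compatible with
every descendant of ``X``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

from .phylogeny import HaplotypeTree

__all__ = [
    "NameRegistry",
    "NomenclatureError",
    "parse_label",
    "is_ancestor_name",
    "assign_names",
]

_LABEL_RE = re.compile(r"^[A-Za-z0-9][A-Za-z0-9-]*\*?$")

# suffix alphabets, 36 symbols each; >36 children at one node is an error
_AFTER_LETTER = "1234567890abcdefghijklmnopqrstuvwxyz"
_AFTER_DIGIT = "abcdefghijklmnopqrstuvwxyz1234567890"


class NomenclatureError(ValueError):
    """Raised for unparseable labels or exhausted suffix alphabets."""


def parse_label(label: str) -> tuple[str, bool]:
    """Split a haplotype label into (core, starred) after validating it."""
    if not isinstance(label, str) or not _LABEL_RE.match(label):
        raise NomenclatureError(f"unparseable haplotype label {label!r}")
    if label.endswith("*"):
        return label[:-1], True
    return label, False


def is_ancestor_name(a: str, b: str) -> bool:
    """True iff the node named ``a`` is an ancestor of (or equal to) ``b``.

    Works purely on the name grammar: after stripping any asterisk, ``a``
    must be a prefix of ``b`` (names grow monotonically down the tree).
    """
    core_a, _ = parse_label(a)
    core_b, _ = parse_label(b)
    return core_b.startswith(core_a)


@dataclass
class NameRegistry:
    """Anchored legacy stems and the final node -> label assignment.

    ``legacy_stems`` maps tree node ids to fixed historic labels; those
    labels replace the mechanical parent+suffix derivation at the anchored
    node, and naming proceeds normally below them.
    """

    legacy_stems: dict[int, str] = field(default_factory=dict)
    assigned: dict[int, str] = field(default_factory=dict)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("node_key\tlabel\n")
            for nid in sorted(self.assigned):
                fh.write(f"{nid}\t{self.assigned[nid]}\n")

    @classmethod
    def read(cls, path: str | Path) -> "NameRegistry":
        reg = cls()
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header != ["node_key", "label"]:
                raise NomenclatureError(f"unexpected registry header in {path}")
            for line in fh:
                key, label = line.rstrip("\n").split("\t")
                parse_label(label)
                reg.legacy_stems[int(key)] = label
        return reg

    def validate(self) -> None:
        labels = list(self.assigned.values())
        if len(labels) != len(set(labels)):
            dup = sorted({x for x in labels if labels.count(x) > 1})
            raise NomenclatureError(f"duplicate labels {dup}")
        for label in labels:
            parse_label(label)


def _child_sort_key(tree: HaplotypeTree, nid: int) -> tuple:
    # deterministic: by smallest member sample id in the subtree
    samples = sorted(
        m for sub in tree.subtree(nid) for m in tree.nodes[sub].members
    )
    return (samples[0], nid) if samples else (chr(0x10FFFF), nid)


def assign_names(
    tree: HaplotypeTree,
    registry: NameRegistry | None = None,
    root_label: str = "ROOT",
) -> NameRegistry:
    """Name every tree node, writing labels onto the nodes and the registry.

    Anchored nodes take their legacy stem verbatim; every other child gets
    its parent's label plus the next free suffix character (digit after a
    letter, lowercase letter after a digit), children visited in order of
    their smallest member sample id.  Renaming an already-named tree is a
    no-op.  More than 36 unanchored children at one node exhausts the suffix
    alphabet and raises :class:`NomenclatureError`.
    """
    registry = registry if registry is not None else NameRegistry()
    for nid in registry.legacy_stems:
        if nid not in tree.nodes:
            raise NomenclatureError(f"anchor node {nid} not present in tree")

    def label_for_root() -> str:
        if tree.root in registry.assigned:
            return registry.assigned[tree.root]
        if tree.root in registry.legacy_stems:
            return registry.legacy_stems[tree.root]
        return root_label

    registry.assigned.setdefault(tree.root, label_for_root())
    tree.nodes[tree.root].label = registry.assigned[tree.root]

    stack = [tree.root]
    while stack:
        nid = stack.pop()
        parent_label = registry.assigned[nid]
        alphabet = (
            _AFTER_LETTER if parent_label[-1].isalpha() else _AFTER_DIGIT
        )
        used = {
            registry.assigned[c][len(parent_label)]
            for c in tree.children(nid)
            if c in registry.assigned
            and registry.assigned[c].startswith(parent_label)
            and len(registry.assigned[c]) == len(parent_label) + 1
        }
        cursor = 0
        for child in sorted(
            tree.children(nid), key=lambda c: _child_sort_key(tree, c)
        ):
            if child in registry.assigned:
                pass  # idempotent: keep existing label
            elif child in registry.legacy_stems:
                registry.assigned[child] = registry.legacy_stems[child]
            else:
                while cursor < len(alphabet) and alphabet[cursor] in used:
                    cursor += 1
                if cursor >= len(alphabet):
                    raise NomenclatureError(
                        f"suffix alphabet exhausted under {parent_label!r} "
                        f"(>{len(alphabet)} children)"
                    )
                registry.assigned[child] = parent_label + alphabet[cursor]
                used.add(alphabet[cursor])
            tree.nodes[child].label = registry.assigned[child]
            stack.append(child)
    registry.validate()
    return registry
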