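"""Packaged reference fixtures: the crown backbone named in the screening text.

The shipped backbone encodes only the marker-to-branch relations that are
explicitly named for the consecutive genotyping workflow: the crown-defining
key variants (rAY, rAX), the three major-clade tests (rA, rW, fYR — the
clade assignment of each is a configurable convention, not a published
fact), the Ta branch markers, the Ta-s/Ta-b split markers and the four
recently arisen subline variants.  Edges whose defining variants are not
individually named ship without markers; users supply their own tree/panel
files for a fully resolved backbone.
"""

from __future__ import annotations

from importlib import resources

from .panel import MarkerPanel
from .phylogeny import HaplotypeTree, load_tree_table

__all__ = ["load_backbone_tree", "load_backbone_panel"]


def _data_path(name: str):
    return resources.files("patrilinekit.data").joinpath(name)


def load_backbone_tree() -> HaplotypeTree:
    with resources.as_file(_data_path("backbone_tree.tsv")) as p:
        return load_tree_table(p)


def load_backbone_panel(tree: HaplotypeTree | None = None) -> MarkerPanel:
    tree = tree if tree is not None else load_backbone_tree()
    with resources.as_file(_data_path("backbone_panel.tsv")) as p:
        return MarkerPanel.read(p, tree)
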