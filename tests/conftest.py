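"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from patrilinekit.matrix import (
    ANCESTRAL,
    DERIVED,
    MISSING,
    CallMatrix,
    VariantSite,
)
from patrilinekit.phylogeny import HaplotypeTree


def make_matrix(
    geno,
    samples=None,
    site_ids=None,
    outgroup=None,
    polarized=True,
    depth=None,
    qual=None,
):
    """Build a CallMatrix from a plain nested list (rows = samples)."""
    geno = np.asarray(geno, dtype=np.int8)
    n, m = geno.shape
    samples = samples or [f"S{i}" for i in range(n)]
    site_ids = site_ids or [f"v{j}" for j in range(m)]
    sites = [
        VariantSite(site_id=sid, position=j + 1, ancestral_state="reference")
        for j, sid in enumerate(site_ids)
    ]
    return CallMatrix(
        samples=samples,
        sites=sites,
        geno=geno,
        depth=None if depth is None else np.asarray(depth, dtype=np.int32),
        qual=None if qual is None else np.asarray(qual, dtype=np.int32),
        outgroup_ids=frozenset([outgroup]) if outgroup else frozenset(),
        polarized=polarized,
    )


def fitch_score(tree: HaplotypeTree, matrix: CallMatrix) -> int:
    """Independent small-parsimony scorer (Fitch, multifurcations supported).

    Members hang off their node as pendant leaves; the root is constrained
    to the ancestral state.  Returns the minimal total number of state
    changes over all sites.
    """
    total = 0
    for i in range(matrix.n_sites):
        states = {
            s: int(matrix.geno[matrix.sample_index(s), i])
            for s in matrix.ingroup_samples
        }
        changes = 0

        def rec(nid: int) -> set[int]:
            nonlocal changes
            sets = [rec(c) for c in tree.children(nid)]
            sets += [{states[m]} for m in tree.nodes[nid].members]
            if not sets:
                return {0, 1}
            cur = sets[0]
            for s in sets[1:]:
                if cur & s:
                    cur = cur & s
                else:
                    cur = cur | s
                    changes += 1
            return cur

        root_set = rec(tree.root)
        if ANCESTRAL not in root_set:
            changes += 1
        total += changes
    return total


def clade_sets(tree: HaplotypeTree) -> frozenset[frozenset[str]]:
    """Topology signature: sample sets below each non-root edge."""
    out = set()
    for nid in tree.nodes:
        if tree.nodes[nid].parent is None:
            continue
        below = frozenset(
            m for sub in tree.subtree(nid) for m in tree.nodes[sub].members
        )
        out.add(below)
    return frozenset(out)


def random_perfect_matrix(rng, n_ht: int, n_sites: int):
    """Random matrix admitting a perfect phylogeny, grown by sequential mutation.

    Starts from the all-ancestral root vector and repeatedly derives a new
    haplotype from a random existing one by flipping fresh sites — so every
    site mutates exactly once and the matrix is compatible by construction.
    """
    vectors = [tuple([0] * n_sites)]
    free = list(range(n_sites))
    rng.shuffle(free)
    while len(vectors) < n_ht and free:
        parent = list(vectors[rng.integers(0, len(vectors))])
        k = min(int(rng.integers(1, 3)), len(free))
        for _ in range(k):
            parent[free.pop()] = 1
        vectors.append(tuple(parent))
    rows, samples = [], []
    for h, vec in enumerate(vectors):
        for rep in range(int(rng.integers(1, 3))):
            rows.append(list(vec))
            samples.append(f"H{h}_{rep}")
    rows.append([0] * n_sites)
    samples.append("OUT")
    matrix = make_matrix(rows, samples=samples, outgroup="OUT", polarized=True)
    poly = [j for j in range(n_sites) if any(r[j] for r in rows)]
    return matrix.take_sites(poly)


@pytest.fixture
def rng():
    return np.random.default_rng(20220229)
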