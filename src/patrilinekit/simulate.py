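"""Forward simulation of non-recombining haploid (MSY-like) inheritance.

Generates male genealogies in which each father-to-son transmission adds
Poisson-distributed mutations at previously unmutated sites (infinite-sites
model, so the true haplotypes always admit a perfect phylogeny), then layers
on the imperfections real data carry: per-call missingness and heterozygous
artifacts with depth/quality values that violate the default filters, and
recorded-pedigree paternity errors.  Full ground truth (pedigree, tree,
error events) is retained so every pipeline stage can be validated.

Time is counted in transmissions; multiply by ``generation_interval_years``
(default 8, a standard mean sire generation interval for horses) for years.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .matrix import (
    ANCESTRAL,
    DERIVED,
    HET_ARTIFACT,
    MISSING,
    CallMatrix,
    VariantSite,
)
from .phylogeny import HaplotypeTree, TreeNode

__all__ = [
    "SimConfig",
    "SimTruth",
    "SitesExhaustedError",
    "simulate",
    "degrade",
    "perturb_pedigree",
    "tail_male_chain",
]

OUTGROUP_ID = "OUTGROUP"


class SitesExhaustedError(RuntimeError):
    """All sites already mutated; rerun with a larger ``sites``."""


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated genealogy.

    ``offspring_mean`` is the mean of the underlying Poisson law before zero
    truncation; ``popular_sire_factor`` multiplies that mean for one male
    per generation, mimicking the dominance of heavily used sires that
    produces star-like haplotype expansions.  ``founder_mutations`` seeds
    each founder with that many private derived sites, emulating haplogroup
    divergence that predates the recorded pedigree (0 starts every founder
    from the ancestral vector).
    """

    generations: int = 5
    founders: int = 3
    offspring_mean: float = 1.8
    offspring_law: str = "ztpoisson"
    popular_sire_factor: float = 1.0
    founder_mutations: int = 0
    sites: int = 300
    mu: float = 0.3
    missing_rate: float = 0.05
    het_artifact_rate: float = 0.01
    paternity_error_rate: float = 0.0
    generation_interval_years: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("missing_rate", "het_artifact_rate", "paternity_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.generations < 1 or self.founders < 1 or self.sites < 1:
            raise ValueError("generations, founders and sites must be >= 1")


@dataclass
class Male:
    mid: str
    generation: int
    father: str | None
    mutations: frozenset[int]  # cumulative derived site indices


@dataclass
class SimTruth:
    """Ground truth of one simulated genealogy."""

    config: SimConfig
    males: dict[str, Male]
    true_pedigree: dict[str, str]  # son -> true father
    recorded_pedigree: dict[str, str]  # son -> recorded father
    samples: list[str]  # extant-generation males
    site_ids: list[str]  # ids of mutated (polymorphic) sites
    true_matrix: CallMatrix  # error-free polarized calls incl. outgroup
    true_tree: HaplotypeTree
    error_events: list[tuple[str, str, str]] = field(default_factory=list)
    skipped_perturbations: list[str] = field(default_factory=list)


def _site_id(index: int) -> str:
    return f"s{index + 1:05d}"


def simulate(config: SimConfig) -> SimTruth:
    """Run one forward simulation; deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    pool = list(range(config.sites))
    rng.shuffle(pool)  # draw order of fresh sites
    cursor = 0

    def draw_mutations(k: int) -> frozenset[int]:
        nonlocal cursor
        if cursor + k > len(pool):
            raise SitesExhaustedError(
                f"{config.sites} sites exhausted; increase SimConfig.sites"
            )
        out = frozenset(pool[cursor : cursor + k])
        cursor += k
        return out

    def n_offspring(mean: float) -> int:
        if config.offspring_law == "fixed":
            return max(1, int(round(mean)))
        if config.offspring_law != "ztpoisson":
            raise ValueError(f"unknown offspring law {config.offspring_law!r}")
        while True:  # zero-truncated Poisson by rejection
            k = int(rng.poisson(mean))
            if k > 0:
                return k

    males: dict[str, Male] = {}
    pedigree: dict[str, str] = {}
    current: list[str] = []
    for f in range(config.founders):
        mid = f"G0_{f:03d}"
        males[mid] = Male(
            mid=mid,
            generation=0,
            father=None,
            mutations=draw_mutations(config.founder_mutations),
        )
        current.append(mid)

    for gen in range(1, config.generations):
        popular = int(rng.integers(0, len(current)))
        nxt: list[str] = []
        for i, father_id in enumerate(current):
            mean = config.offspring_mean * (
                config.popular_sire_factor if i == popular else 1.0
            )
            for _ in range(n_offspring(mean)):
                sid = f"G{gen}_{len(nxt):03d}"
                muts = males[father_id].mutations | draw_mutations(
                    int(rng.poisson(config.mu))
                )
                males[sid] = Male(
                    mid=sid, generation=gen, father=father_id, mutations=muts
                )
                pedigree[sid] = father_id
                nxt.append(sid)
        current = nxt

    samples = list(current)
    polymorphic = sorted({i for s in samples for i in males[s].mutations})
    site_ids = [_site_id(i) for i in polymorphic]
    col_of = {i: c for c, i in enumerate(polymorphic)}

    all_samples = samples + [OUTGROUP_ID]
    geno = np.zeros((len(all_samples), len(polymorphic)), dtype=np.int8)
    for r, s in enumerate(samples):
        for i in males[s].mutations:
            if i in col_of:
                geno[r, col_of[i]] = DERIVED
    sites = [
        VariantSite(
            site_id=_site_id(i),
            position=i + 1,
            ancestral_state="reference",
        )
        for i in polymorphic
    ]
    true_matrix = CallMatrix(
        samples=all_samples,
        sites=sites,
        geno=geno,
        outgroup_ids=frozenset({OUTGROUP_ID}),
        polarized=True,
    )
    true_tree = _truth_tree(males, pedigree, samples)
    return SimTruth(
        config=config,
        males=males,
        true_pedigree=dict(pedigree),
        recorded_pedigree=dict(pedigree),
        samples=samples,
        site_ids=site_ids,
        true_matrix=true_matrix,
        true_tree=true_tree,
    )


def _truth_tree(
    males: dict[str, Male], pedigree: dict[str, str], samples: list[str]
) -> HaplotypeTree:
    """True haplotype tree built from the mutation history, not the matrix.

    Walks the pedigree restricted to sample ancestors, contracting
    mutation-free transmissions, merging males with identical cumulative
    mutation sets, and pruning branch-free internal males, so the result is
    the genealogy with zero-mutation branches contracted.
    """
    relevant: set[str] = set()
    for s in samples:
        m: str | None = s
        while m is not None:
            relevant.add(m)
            m = pedigree.get(m)
    sample_set = set(samples)
    only_sampled = {i for s in samples for i in males[s].mutations}

    nodes: dict[int, TreeNode] = {0: TreeNode(node_id=0, parent=None)}
    node_of_set: dict[frozenset[int], int] = {frozenset(): 0}
    members: dict[int, list[str]] = {0: []}

    def node_for(mutset: frozenset[int], parent_set: frozenset[int]) -> int:
        if mutset in node_of_set:
            return node_of_set[mutset]
        nid = len(nodes)
        parent = node_of_set[parent_set]
        edge = sorted(mutset - parent_set)
        nodes[nid] = TreeNode(
            node_id=nid,
            parent=parent,
            edge_sites=tuple(_site_id(i) for i in edge),
        )
        node_of_set[mutset] = nid
        members[nid] = []
        return nid

    children: dict[str, list[str]] = {}
    roots: list[str] = []
    for m in sorted(relevant):
        f = pedigree.get(m)
        if f is None:
            roots.append(m)
        else:
            children.setdefault(f, []).append(m)

    def visit(mid: str, parent_set: frozenset[int]) -> None:
        # project onto sites observable among the sampled males
        mutset = frozenset(i for i in males[mid].mutations if i in only_sampled)
        nid = node_for(mutset, parent_set) if mutset != parent_set else node_of_set[parent_set]
        if mid in sample_set:
            members[nid].append(mid)
        for kid in children.get(mid, []):
            visit(kid, mutset)

    for r in roots:
        visit(r, frozenset())

    # prune memberless leaves / unary pass-through nodes left by unsampled branches
    changed = True
    while changed:
        changed = False
        kids: dict[int, list[int]] = {}
        for nid, node in nodes.items():
            if node.parent is not None:
                kids.setdefault(node.parent, []).append(nid)
        for nid in list(nodes):
            if nid == 0:
                continue
            if not members[nid] and not kids.get(nid):
                parent = nodes[nid].parent
                del nodes[nid]
                del members[nid]
                node_of_set = {k: v for k, v in node_of_set.items() if v != nid}
                changed = True
    # merge unary memberless internals into their single child's edge
    changed = True
    while changed:
        changed = False
        kids = {}
        for nid, node in nodes.items():
            if node.parent is not None:
                kids.setdefault(node.parent, []).append(nid)
        for nid in list(nodes):
            if nid == 0 or members.get(nid) or len(kids.get(nid, [])) != 1:
                continue
            (child,) = kids[nid]
            nodes[child] = dataclasses.replace(
                nodes[child],
                parent=nodes[nid].parent,
                edge_sites=tuple(sorted(nodes[nid].edge_sites + nodes[child].edge_sites)),
            )
            del nodes[nid]
            del members[nid]
            changed = True
            break

    for nid, node in nodes.items():
        node.members = tuple(sorted(members.get(nid, [])))
    return HaplotypeTree(nodes=nodes, root=0)


def degrade(truth: SimTruth, config: SimConfig | None = None) -> CallMatrix:
    """Overlay genotyping noise on the true matrix.

    Each ingroup call independently becomes missing (``missing_rate``) or a
    heterozygous artifact (``het_artifact_rate``); those calls get read
    depth/genotype quality below the default filter thresholds while clean
    calls get passing values.  The outgroup is never degraded.  A separate
    stream keyed on the seed keeps ``simulate`` and ``degrade`` individually
    deterministic.
    """
    config = config if config is not None else truth.config
    rng = np.random.default_rng([config.seed, 211])
    out = truth.true_matrix.copy()
    n, m = out.geno.shape
    depth = rng.integers(10, 41, size=(n, m)).astype(np.int32)
    qual = rng.integers(30, 100, size=(n, m)).astype(np.int32)
    u = rng.random((n, m))
    is_out = np.array([s in out.outgroup_ids for s in out.samples])
    missing = (u < config.missing_rate) & ~is_out[:, None]
    het = (
        (u >= config.missing_rate)
        & (u < config.missing_rate + config.het_artifact_rate)
        & ~is_out[:, None]
    )
    out.geno[missing] = MISSING
    out.geno[het] = HET_ARTIFACT
    bad = missing | het
    depth[bad] = rng.integers(0, 3, size=int(bad.sum()))
    qual[bad] = rng.integers(0, 5, size=int(bad.sum()))
    out.depth = depth
    out.qual = qual
    return out


def perturb_pedigree(truth: SimTruth, config: SimConfig | None = None) -> SimTruth:
    """Inject recorded-paternity errors.

    Each recorded father link is independently replaced, with probability
    ``paternity_error_rate``, by a different male of the same generation as
    the true father (the error class behind historic mis-assignments such
    as swapped studbook sires).  Links with no alternative father available
    are skipped and logged.  Returns a new ``SimTruth`` sharing the
    biological ground truth.
    """
    config = config if config is not None else truth.config
    rng = np.random.default_rng([config.seed, 977])
    by_generation: dict[int, list[str]] = {}
    for m in truth.males.values():
        by_generation.setdefault(m.generation, []).append(m.mid)
    recorded = dict(truth.true_pedigree)
    events: list[tuple[str, str, str]] = []
    skipped: list[str] = []
    for son in sorted(truth.true_pedigree):
        if rng.random() >= config.paternity_error_rate:
            continue
        true_father = truth.true_pedigree[son]
        peers = [
            p
            for p in sorted(by_generation[truth.males[true_father].generation])
            if p != true_father
        ]
        if not peers:
            skipped.append(son)
            continue
        fake = peers[int(rng.integers(0, len(peers)))]
        recorded[son] = fake
        events.append((son, true_father, fake))
    return dataclasses.replace(
        truth,
        recorded_pedigree=recorded,
        error_events=events,
        skipped_perturbations=skipped,
    )


def tail_male_chain(
    truth: SimTruth, sample: str, recorded: bool = True
) -> list[str]:
    """Ancestor chain from ``sample``'s father up to its founder."""
    pedigree = truth.recorded_pedigree if recorded else truth.true_pedigree
    chain: list[str] = []
    m = pedigree.get(sample)
    while m is not None:
        chain.append(m)
        m = pedigree.get(m)
    return chain if chain else [sample]
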