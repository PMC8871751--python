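"""Haplogroup assignment, within-group consensus imputation and haplotype collapse.

Samples are first clustered into haplogroups using diagnostic variants, then
missing calls are filled from the allelic state observed in other members of
the same group (the MSY is effectively mutation-free within a tight clade at
most sites), and finally samples with identical state vectors are collapsed
into distinct haplotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping

import numpy as np
import pandas as pd

from .matrix import ANCESTRAL, DERIVED, MISSING, HET_ARTIFACT, CallMatrix, MatrixError

__all__ = [
    "HaplogroupRule",
    "Haplotype",
    "HaplotypeTable",
    "ImputationLog",
    "AmbiguousHaplogroupError",
    "assign_haplogroups",
    "impute_by_group",
    "build_haplotypes",
]

UNASSIGNED = "unassigned"


class AmbiguousHaplogroupError(ValueError):
    """A sample satisfies more than one haplogroup-determining rule."""


@dataclass(frozen=True)
class HaplogroupRule:
    """Diagnostic-variant rule defining one haplogroup.

    A sample matches when it carries the derived state at every site in
    ``required_derived`` and the ancestral state at every site in
    ``required_ancestral``; missing calls act as wildcards, but at least one
    required site must be observed for the match to count.
    """

    hg_name: str
    required_derived: frozenset[str] = frozenset()
    required_ancestral: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.required_derived & self.required_ancestral:
            raise ValueError(
                f"rule {self.hg_name!r}: required_derived and required_ancestral overlap"
            )


def assign_haplogroups(
    matrix: CallMatrix, rules: Iterable[HaplogroupRule]
) -> dict[str, str]:
    """Map each ingroup sample to the unique haplogroup rule it satisfies.

    Samples matching no rule (including all-missing samples) map to
    ``"unassigned"``.  A sample matching two rules raises
    :class:`AmbiguousHaplogroupError` naming the sample and both rules.
    """
    rules = list(rules)
    site_idx: dict[str, int] = {}
    for rule in rules:
        for sid in rule.required_derived | rule.required_ancestral:
            if sid not in site_idx:
                site_idx[sid] = matrix.site_index(sid)
    out: dict[str, str] = {}
    for j, sample in enumerate(matrix.samples):
        if sample in matrix.outgroup_ids:
            continue
        matched: list[str] = []
        for rule in rules:
            observed = 0
            ok = True
            for sid in rule.required_derived:
                call = int(matrix.geno[j, site_idx[sid]])
                if call == DERIVED:
                    observed += 1
                elif call == ANCESTRAL:
                    ok = False
                    break
            if ok:
                for sid in rule.required_ancestral:
                    call = int(matrix.geno[j, site_idx[sid]])
                    if call == ANCESTRAL:
                        observed += 1
                    elif call == DERIVED:
                        ok = False
                        break
            if ok and observed > 0:
                matched.append(rule.hg_name)
        if len(matched) > 1:
            raise AmbiguousHaplogroupError(
                f"sample {sample!r} satisfies rules {matched[0]!r} and {matched[1]!r}"
            )
        out[sample] = matched[0] if matched else UNASSIGNED
    return out


@dataclass
class ImputationLog:
    """One row per filled cell: (sample, site_id, filled_state, group, mode)."""

    entries: list[tuple[str, str, int, str, str]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.entries,
            columns=["sample", "site_id", "filled_state", "group", "mode"],
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def __len__(self) -> int:
        return len(self.entries)


def impute_by_group(
    matrix: CallMatrix,
    groups: Mapping[str, str],
    mode: str = "unanimity",
) -> tuple[CallMatrix, ImputationLog]:
    """Fill missing calls with the within-haplogroup consensus state.

    Under ``"unanimity"`` a missing call is filled only when every non-missing
    group member agrees; under ``"majority"`` a strict majority suffices
    (ties stay missing).  Observed calls are never altered; unassigned
    samples are skipped.  Every filled cell is recorded in the log.
    """
    if mode not in ("unanimity", "majority"):
        raise ValueError(f"unknown imputation mode {mode!r}")
    out = matrix.copy()
    log = ImputationLog()
    members_by_group: dict[str, list[int]] = {}
    for sample, group in groups.items():
        if group == UNASSIGNED or sample not in out.samples:
            continue
        members_by_group.setdefault(group, []).append(out.sample_index(sample))
    for group, members in sorted(members_by_group.items()):
        sub = matrix.geno[members, :]  # consensus from *observed* input calls
        for i in range(out.n_sites):
            col = sub[:, i]
            holes = [m for m, g in zip(members, col) if g == MISSING]
            if not holes:
                continue
            called = col[(col == ANCESTRAL) | (col == DERIVED)]
            if called.size == 0:
                continue  # zero-member consensus leaves the call missing
            n_derived = int((called == DERIVED).sum())
            n_ancestral = called.size - n_derived
            if mode == "unanimity":
                if n_derived and n_ancestral:
                    continue
                fill = DERIVED if n_derived else ANCESTRAL
            else:
                if n_derived == n_ancestral:
                    continue
                fill = DERIVED if n_derived > n_ancestral else ANCESTRAL
            for m in holes:
                out.geno[m, i] = fill
                log.entries.append(
                    (out.samples[m], out.sites[i].site_id, fill, group, mode)
                )
    return out, log


@dataclass
class Haplotype:
    """A distinct MSY state vector shared by one or more samples.

    ``resolved`` is switched off for asterisk haplotypes placed at internal
    nodes during panel genotyping (never for sequencing-derived haplotypes).
    """

    ht_name: str | None
    state_vector: tuple[int, ...]
    members: tuple[str, ...]
    resolved: bool = True


@dataclass
class HaplotypeTable:
    """Distinct haplotypes over a common polarized site list."""

    site_ids: tuple[str, ...]
    haplotypes: list[Haplotype]
    excluded_sites: tuple[str, ...] = ()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (
                    h.ht_name or f"HT{k}",
                    len(h.members),
                    ",".join(h.members),
                    "".join(str(s) for s in h.state_vector),
                )
                for k, h in enumerate(self.haplotypes)
            ],
            columns=["ht_name", "n_members", "members", "state_vector"],
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def build_haplotypes(matrix: CallMatrix) -> HaplotypeTable:
    """Collapse samples with identical state vectors into distinct haplotypes.

    Sites with residual missing (or artifact) calls among ingroup samples are
    excluded from the concatenated vectors and reported in
    ``excluded_sites``; rejecting the matrix outright would discard samples
    instead of sites.  Sites are ordered by position, haplotypes by first
    member appearance, making the output invariant to input sample order up
    to the order of the haplotype list itself.
    """
    ingroup = matrix.ingroup_samples
    if not ingroup:
        raise MatrixError("no ingroup samples")
    idx = [matrix.sample_index(s) for s in ingroup]
    order = sorted(range(matrix.n_sites), key=lambda i: (matrix.sites[i].position, matrix.sites[i].site_id))
    kept, excluded = [], []
    for i in order:
        col = matrix.geno[idx, i]
        if np.any((col == MISSING) | (col == HET_ARTIFACT)):
            excluded.append(matrix.sites[i].site_id)
        else:
            kept.append(i)
    if not kept:
        raise MatrixError("no sites without residual missingness remain")
    by_vector: dict[tuple[int, ...], list[str]] = {}
    for s, j in zip(ingroup, idx):
        vec = tuple(int(g) for g in matrix.geno[j, kept])
        by_vector.setdefault(vec, []).append(s)
    haplotypes = [
        Haplotype(ht_name=None, state_vector=vec, members=tuple(members))
        for vec, members in by_vector.items()
    ]
    haplotypes.sort(key=lambda h: min(ingroup.index(m) for m in h.members))
    return HaplotypeTable(
        site_ids=tuple(matrix.sites[i].site_id for i in kept),
        haplotypes=haplotypes,
        excluded_sites=tuple(excluded),
    )
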