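"""Tail-male-line parsing and sire-line / haplotype congruence analysis.

A *tail-male line* is the chain of paternal ancestors from a sampled male
back to the foundation sire of his line.  Because the MSY travels down
exactly that chain, every member of a correctly recorded sire line must
carry the foundation sire's haplotype or a descendant of it (a *subline
haplotype* arising from a de novo mutation inside the documented
time-frame).  Two mutually non-nested haplotypes inside one recorded line
cannot be explained by mutation and expose a pedigree error — more than one
stallion contributed to the line.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable, Iterable, Sequence

import pandas as pd

from .nomenclature import is_ancestor_name, parse_label

__all__ = [
    "TailMaleLine",
    "LineRecord",
    "LineClassification",
    "CongruenceReport",
    "PanelSummary",
    "parse_tail_male",
    "serialize_tail_male",
    "classify_line",
    "congruence_report",
    "summarize_panel",
    "load_table1",
    "DEFAULT_HG_ROLLUP",
]

CHAIN_SEPARATOR = " > "

#: haplogroup labels regarded as the typical Arabian MSY signature, plus the
#: two tentative clusters observed only in single occidental lines
DEFAULT_HG_ROLLUP: tuple[str, ...] = ("Ao-aA", "Ta", "Ao-aD2")
OTHER_HG_ROLLUP: tuple[str, ...] = ("Tb-oB1*", "T2*")

CONSISTENT = "consistent"
SUBLINE_CONSISTENT = "subline_consistent"
INCONGRUENT = "incongruent"


@dataclass(frozen=True)
class TailMaleLine:
    """Ordered paternal ancestor chain ending at the foundation sire."""

    sample: str
    chain: tuple[str, ...]

    @property
    def foundation_sire(self) -> str:
        return self.chain[-1]


def parse_tail_male(record: str, sample: str | None = None) -> TailMaleLine:
    """Parse a ``" > "``-separated ancestor chain, most recent first.

    ``record`` may optionally carry a leading ``sample<TAB>`` column.
    Consecutive duplicate names are collapsed; an empty record is rejected.
    """
    record = record.rstrip("\n")
    if "\t" in record and sample is None:
        sample, record = record.split("\t", 1)
    names = [n.strip() for n in record.split(">")]
    names = [n for n in names if n]
    if not names:
        raise ValueError("empty tail-male record")
    chain: list[str] = []
    for n in names:
        if not chain or chain[-1] != n:
            chain.append(n)
    return TailMaleLine(sample=sample or chain[0], chain=tuple(chain))


def serialize_tail_male(line: TailMaleLine, with_sample: bool = False) -> str:
    text = CHAIN_SEPARATOR.join(line.chain)
    return f"{line.sample}\t{text}" if with_sample else text


# ---------------------------------------------------------------------------
# Line records (machine-encoded summary-table rows)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LineRecord:
    """One (foundation sire, subline, haplotype) row of the screening panel."""

    foundation_sire: str
    subline: str
    count: int
    breed_or_registry: str
    ht_label: str
    remark: str = ""  # "", "subline-HT", "private HT", "incongruence"

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("LineRecord.count must be >= 1")
        parse_label(self.ht_label)


def load_table1() -> list[LineRecord]:
    """The packaged occidental-Arabian screening panel (145 males, 26 lines)."""
    with resources.files("patrilinekit.data").joinpath("table1.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", dtype=str).fillna("")
    return [
        LineRecord(
            foundation_sire=row["foundation_sire"],
            subline=row["subline"],
            count=int(row["count"]),
            breed_or_registry=row["breed_or_registry"],
            ht_label=row["ht_label"],
            remark=row["remark"],
        )
        for _, row in df.iterrows()
    ]


# ---------------------------------------------------------------------------
# congruence classification
# ---------------------------------------------------------------------------

@dataclass
class LineClassification:
    """Congruence verdict for one foundation-sire line."""

    foundation_sire: str
    classification: str
    distinct_hts: tuple[str, ...]
    groups: tuple[tuple[str, ...], ...]
    candidate_subline_events: tuple[tuple[str, str], ...] = ()


@dataclass
class CongruenceReport:
    lines: dict[str, LineClassification] = field(default_factory=dict)

    @property
    def incongruent_lines(self) -> list[str]:
        return sorted(
            sire
            for sire, c in self.lines.items()
            if c.classification == INCONGRUENT
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (
                    s,
                    c.classification,
                    ",".join(c.distinct_hts),
                    ";".join(",".join(g) for g in c.groups),
                    ";".join(f"{ht}@{sub}" for ht, sub in c.candidate_subline_events) or ".",
                )
                for s, c in sorted(self.lines.items())
            ],
            columns=["foundation_sire", "classification", "haplotypes", "groups", "subline_events"],
        )


def _mutually_nested(
    label: str, group: Sequence[str], nesting: Callable[[str, str], bool]
) -> bool:
    return all(nesting(label, g) or nesting(g, label) for g in group)


def classify_line(
    members: Iterable[tuple[str, str, str]],
    nesting: Callable[[str, str], bool] = is_ancestor_name,
    foundation_sire: str = "",
) -> LineClassification:
    """Classify one line's haplotype pattern from its (sample, ht, subline) members.

    Labels are merged into groups in which every pair is ancestry-compatible
    (an asterisk haplotype ``X*`` is compatible with every descendant of
    ``X``).  One group with one label is *consistent*; one group with
    several labels is *subline-consistent* — the derived labels are reported
    as candidate de novo subline haplotypes tied to the sublines carrying
    them; two or more mutually disjoint groups are *incongruent*: more than
    one stallion contributed to the recorded line.

    The verdict is invariant to member order and to duplicated members.
    """
    members = sorted(set(members))
    if not members:
        raise ValueError("classify_line needs at least one member")
    labels = sorted(
        {ht for _, ht, _ in members}, key=lambda l: (len(parse_label(l)[0]), l)
    )
    groups: list[list[str]] = []
    for label in labels:
        for group in groups:
            if _mutually_nested(label, group, nesting):
                group.append(label)
                break
        else:
            groups.append([label])

    events: list[tuple[str, str]] = []
    for group in groups:
        if len(group) < 2:
            continue
        cores = {l: parse_label(l)[0] for l in group}
        for label in group:
            is_derived = any(
                other != label
                and cores[other] != cores[label]
                and cores[label].startswith(cores[other])
                for other in group
            )
            if is_derived:
                sublines = sorted(
                    {sub for _, ht, sub in members if ht == label}
                )
                for sub in sublines:
                    events.append((label, sub))

    if len(groups) >= 2:
        verdict = INCONGRUENT
    elif len(labels) >= 2:
        verdict = SUBLINE_CONSISTENT
    else:
        verdict = CONSISTENT
    return LineClassification(
        foundation_sire=foundation_sire,
        classification=verdict,
        distinct_hts=tuple(labels),
        groups=tuple(tuple(g) for g in groups),
        candidate_subline_events=tuple(sorted(set(events))),
    )


def _records_to_members(
    records: Sequence[LineRecord],
) -> dict[str, list[tuple[str, str, str]]]:
    by_line: dict[str, list[tuple[str, str, str]]] = {}
    for rec in records:
        mem = by_line.setdefault(rec.foundation_sire, [])
        for k in range(rec.count):
            mem.append(
                (f"{rec.foundation_sire}|{rec.subline}|{k}", rec.ht_label, rec.subline)
            )
    return by_line


def congruence_report(
    records: Sequence[LineRecord],
    nesting: Callable[[str, str], bool] = is_ancestor_name,
) -> CongruenceReport:
    """Run :func:`classify_line` on every foundation line of a record set."""
    report = CongruenceReport()
    for sire, members in _records_to_members(records).items():
        report.lines[sire] = classify_line(
            members, nesting=nesting, foundation_sire=sire
        )
    return report


# ---------------------------------------------------------------------------
# panel summary statistics
# ---------------------------------------------------------------------------

@dataclass
class PanelSummary:
    """Headline counts over a screening-panel record set."""

    total_samples: int
    n_lines: int
    n_lines_multi_sampled: int
    distinct_ht_labels: tuple[str, ...]
    hg_sample_counts: dict[str, int]
    hg_line_counts: dict[str, int]
    samples_in_listed_hgs: int
    subline_ht_labels: tuple[str, ...]
    private_ht_labels: tuple[str, ...]
    incongruent_lines: tuple[str, ...]
    congruence: CongruenceReport

    @property
    def n_distinct_hts(self) -> int:
        return len(self.distinct_ht_labels)

    def count_in(self, hg_label: str, records: Sequence[LineRecord]) -> int:
        """Samples whose haplotype nests under ``hg_label``."""
        return sum(
            r.count for r in records if is_ancestor_name(hg_label, r.ht_label)
        )

    def lines_with_label(
        self, ht_label: str, records: Sequence[LineRecord]
    ) -> int:
        """Foundation lines containing the exact haplotype label."""
        return len({r.foundation_sire for r in records if r.ht_label == ht_label})


def summarize_panel(
    records: Sequence[LineRecord],
    hg_labels: Sequence[str] = DEFAULT_HG_ROLLUP,
    nesting: Callable[[str, str], bool] = is_ancestor_name,
) -> PanelSummary:
    """Compute the headline screening-panel statistics.

    Haplogroup membership is decided purely by name nesting against the
    supplied haplogroup list; *private* haplotype labels are those observed
    in exactly one foundation line; incongruent lines come from
    :func:`classify_line`.
    """
    if not records:
        raise ValueError("empty record set")
    per_line_counts: dict[str, int] = {}
    lines_by_label: dict[str, set[str]] = {}
    for rec in records:
        per_line_counts[rec.foundation_sire] = (
            per_line_counts.get(rec.foundation_sire, 0) + rec.count
        )
        lines_by_label.setdefault(rec.ht_label, set()).add(rec.foundation_sire)

    hg_sample_counts: dict[str, int] = {}
    hg_line_counts: dict[str, int] = {}
    for hg in hg_labels:
        in_hg = [r for r in records if nesting(hg, r.ht_label)]
        hg_sample_counts[hg] = sum(r.count for r in in_hg)
        hg_line_counts[hg] = len({r.foundation_sire for r in in_hg})

    report = congruence_report(records, nesting=nesting)
    return PanelSummary(
        total_samples=sum(r.count for r in records),
        n_lines=len(per_line_counts),
        n_lines_multi_sampled=sum(1 for v in per_line_counts.values() if v > 1),
        distinct_ht_labels=tuple(sorted(lines_by_label)),
        hg_sample_counts=hg_sample_counts,
        hg_line_counts=hg_line_counts,
        samples_in_listed_hgs=sum(
            r.count
            for r in records
            if any(nesting(hg, r.ht_label) for hg in hg_labels)
        ),
        subline_ht_labels=tuple(
            sorted({r.ht_label for r in records if r.remark == "subline-HT"})
        ),
        private_ht_labels=tuple(
            sorted(l for l, lines in lines_by_label.items() if len(lines) == 1)
        ),
        incongruent_lines=tuple(report.incongruent_lines),
        congruence=report,
    )
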