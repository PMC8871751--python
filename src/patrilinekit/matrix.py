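"""Haploid MSY call matrices: loading, quality filtering and outgroup polarization.

The male-specific region of the Y chromosome (MSY) is inherited father-to-son
as a single non-recombining linkage block, so every male is haploid at each
variant site.  This module holds the sample x site call grid together with
per-call read depth and genotype quality, applies the ascertainment filters
used for MSY variant panels, and orients alleles as ancestral vs derived
using an outgroup male (e.g. a Przewalski's Horse).

Call states are coded as small integers:

======================  =====  =========================================
state                   code   meaning
======================  =====  =========================================
``ANCESTRAL``           0      reference allele (raw) / ancestral (polarized)
``DERIVED``             1      alternative allele (raw) / derived (polarized)
``MISSING``             -1     no call
``HET_ARTIFACT``        -2     heterozygous-looking call at a haploid locus
======================  =====  =========================================
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ANCESTRAL",
    "DERIVED",
    "MISSING",
    "HET_ARTIFACT",
    "VariantSite",
    "CallMatrix",
    "FilterConfig",
    "FilterReport",
    "MatrixError",
    "load_call_matrix",
    "write_call_matrix",
    "filter_variants",
    "polarize",
]

ANCESTRAL: int = 0
DERIVED: int = 1
MISSING: int = -1
HET_ARTIFACT: int = -2

#: symbol used for a missing call in the delimited matrix dialect
MISSING_SYMBOL = "."

_GT_CODES = {
    "0": ANCESTRAL,
    "1": DERIVED,
    "0/0": ANCESTRAL,
    "0|0": ANCESTRAL,
    "1/1": DERIVED,
    "1|1": DERIVED,
    "0/1": HET_ARTIFACT,
    "1/0": HET_ARTIFACT,
    "0|1": HET_ARTIFACT,
    "1|0": HET_ARTIFACT,
    ".": MISSING,
    "./.": MISSING,
    ".|.": MISSING,
}


class MatrixError(ValueError):
    """Raised for malformed input matrices or invalid matrix operations."""


@dataclass(frozen=True)
class VariantSite:
    """A single MSY variant site.

    ``ancestral_state`` records which observed allele the outgroup carries:
    ``"reference"``, ``"alternative"`` or ``"unknown"`` (not yet polarized,
    or outgroup call missing).
    """

    site_id: str
    position: int
    var_class: str = "SNV"  # SNV | indel | STR
    ref_allele: str = "A"
    alt_alleles: tuple[str, ...] = ("G",)
    ancestral_state: str = "unknown"


@dataclass
class CallMatrix:
    """Haploid sample x site call grid with optional depth/quality metadata.

    ``geno`` has shape ``(n_samples, n_sites)`` and holds the state codes
    above.  ``depth``/``qual`` are parallel integer arrays or ``None`` when
    the input dialect carries no read-level metadata (such calls are treated
    as passing any depth/quality threshold).
    """

    samples: list[str]
    sites: list[VariantSite]
    geno: np.ndarray
    depth: np.ndarray | None = None
    qual: np.ndarray | None = None
    outgroup_ids: frozenset[str] = frozenset()
    polarized: bool = False
    #: site_ids whose ancestral state could not be determined (outgroup missing)
    unpolarized_sites: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        self.geno = np.asarray(self.geno, dtype=np.int8)
        if self.geno.shape != (len(self.samples), len(self.sites)):
            raise MatrixError(
                f"call grid shape {self.geno.shape} does not match "
                f"{len(self.samples)} samples x {len(self.sites)} sites"
            )
        if not set(self.outgroup_ids) <= set(self.samples):
            raise MatrixError("outgroup_ids must be a subset of samples")

    # -- basic accessors -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def site_ids(self) -> list[str]:
        return [s.site_id for s in self.sites]

    @property
    def ingroup_samples(self) -> list[str]:
        return [s for s in self.samples if s not in self.outgroup_ids]

    def sample_index(self, sample: str) -> int:
        try:
            return self.samples.index(sample)
        except ValueError:
            raise MatrixError(f"unknown sample {sample!r}") from None

    def site_index(self, site_id: str) -> int:
        for i, s in enumerate(self.sites):
            if s.site_id == site_id:
                return i
        raise MatrixError(f"unknown site {site_id!r}")

    def copy(self) -> "CallMatrix":
        return CallMatrix(
            samples=list(self.samples),
            sites=list(self.sites),
            geno=self.geno.copy(),
            depth=None if self.depth is None else self.depth.copy(),
            qual=None if self.qual is None else self.qual.copy(),
            outgroup_ids=self.outgroup_ids,
            polarized=self.polarized,
            unpolarized_sites=self.unpolarized_sites,
        )

    def take_sites(self, keep: Sequence[int]) -> "CallMatrix":
        """Sub-matrix restricted to the site indices in ``keep`` (order kept)."""
        keep = list(keep)
        return CallMatrix(
            samples=list(self.samples),
            sites=[self.sites[i] for i in keep],
            geno=self.geno[:, keep].copy(),
            depth=None if self.depth is None else self.depth[:, keep].copy(),
            qual=None if self.qual is None else self.qual[:, keep].copy(),
            outgroup_ids=self.outgroup_ids,
            polarized=self.polarized,
            unpolarized_sites=self.unpolarized_sites
            & {self.sites[i].site_id for i in keep},
        )

    def to_frame(self) -> pd.DataFrame:
        """Site x sample DataFrame of state codes (sites as rows)."""
        return pd.DataFrame(
            self.geno.T, index=self.site_ids, columns=self.samples
        )


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for the MSY variant ascertainment filters.

    A call is *low quality* when its read depth is below ``min_depth`` or its
    genotype quality below ``min_quality``; a site is dropped when more than
    ``max_low_quality_fraction`` of samples have a low-quality call, or when
    fewer than ``min_call_rate`` of samples have a call at all.
    """

    min_depth: int = 3
    min_quality: int = 5
    max_low_quality_fraction: float = 0.10
    min_call_rate: float = 0.75
    drop_heterozygous_only: bool = True
    drop_multiallelic: bool = True
    drop_reference_errors: bool = True

    def __post_init__(self) -> None:
        for name in ("max_low_quality_fraction", "min_call_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass
class FilterReport:
    """Per-site record of which ascertainment rules removed it."""

    removed: list[tuple[str, tuple[str, ...]]] = field(default_factory=list)
    n_input: int = 0
    n_retained: int = 0

    @property
    def removed_site_ids(self) -> list[str]:
        return [site_id for site_id, _ in self.removed]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s, ",".join(r)) for s, r in self.removed],
            columns=["site_id", "reasons"],
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# loading / writing
# ---------------------------------------------------------------------------

def _decode_gt(text: str) -> int:
    text = text.strip()
    if text in _GT_CODES:
        return _GT_CODES[text]
    return MISSING  # unparseable genotype fields become missing


_META_COLUMNS = {"position", "pos", "ref", "alt", "var_class", "class"}


def load_call_matrix(
    source: str | Path,
    dialect: str = "vcf",
    outgroup_ids: Iterable[str] = (),
) -> CallMatrix:
    """Read a haploid call matrix from a VCF or a tab-delimited site table.

    The ``"matrix"`` dialect expects sites as rows and samples as columns,
    with a ``site_id`` first column, optional ``position``/``ref``/``alt``
    metadata columns and ``.`` for missing calls; such tables carry no
    depth/quality metadata.  The ``"vcf"`` dialect honours the ``DP`` and
    ``GQ`` FORMAT keys and accepts haploid (``0``/``1``) or
    homozygous-diploid (``0/0``/``1/1``) genotypes; ``0/1`` is kept as a
    heterozygous artifact until filtering.
    """
    source = Path(source)
    if dialect == "vcf":
        return _load_vcf(source, outgroup_ids)
    if dialect == "matrix":
        return _load_matrix_table(source, outgroup_ids)
    raise MatrixError(f"unknown dialect {dialect!r}")


def _load_vcf(path: Path, outgroup_ids: Iterable[str]) -> CallMatrix:
    import pysam

    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        if len(samples) != len(set(samples)):
            dup = sorted({s for s in samples if samples.count(s) > 1})
            raise MatrixError(f"duplicate sample ID(s) {dup} in {path}")
        sites: list[VariantSite] = []
        geno_rows: list[list[int]] = []
        depth_rows: list[list[int]] = []
        qual_rows: list[list[int]] = []
        for rec in vcf:
            alts = tuple(a for a in (rec.alts or ()) if a is not None)
            sites.append(
                VariantSite(
                    site_id=rec.id or f"{rec.chrom}_{rec.pos}",
                    position=rec.pos,
                    var_class=_infer_var_class(rec.ref or "", alts),
                    ref_allele=rec.ref or "",
                    alt_alleles=alts,
                )
            )
            g_row, d_row, q_row = [], [], []
            for sample in samples:
                call = rec.samples[sample]
                alleles = call.get("GT", (None,))
                g_row.append(_code_from_gt_tuple(alleles))
                dp = call.get("DP")
                gq = call.get("GQ")
                d_row.append(int(dp) if dp is not None else -1)
                q_row.append(int(gq) if gq is not None else -1)
            geno_rows.append(g_row)
            depth_rows.append(d_row)
            qual_rows.append(q_row)
    if not sites:
        raise MatrixError(f"no variant sites found in {path}")
    geno = np.array(geno_rows, dtype=np.int8).T
    depth = np.array(depth_rows, dtype=np.int32).T
    qual = np.array(qual_rows, dtype=np.int32).T
    # absent DP/GQ (-1 sentinel) is treated as passing any threshold
    return CallMatrix(
        samples=samples,
        sites=sites,
        geno=geno,
        depth=depth,
        qual=qual,
        outgroup_ids=frozenset(outgroup_ids),
    )


def _code_from_gt_tuple(alleles: tuple) -> int:
    alleles = tuple(a for a in alleles if a is not None)
    if not alleles:
        return MISSING
    if all(a == 0 for a in alleles):
        return ANCESTRAL
    if all(a == alleles[0] for a in alleles):
        return DERIVED
    return HET_ARTIFACT


def _infer_var_class(ref: str, alts: tuple[str, ...]) -> str:
    if len(ref) == 1 and all(len(a) == 1 for a in alts):
        return "SNV"
    return "indel"


def _load_matrix_table(path: Path, outgroup_ids: Iterable[str]) -> CallMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if len(header) != len(set(header)):  # pandas would silently mangle these
        dup = sorted({c for c in header if header.count(c) > 1})
        raise MatrixError(f"duplicate sample ID(s) {dup} in {path}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[0] == 0:
        raise MatrixError(f"empty site list in {path}")
    cols = list(df.columns)
    id_col = cols[0]
    meta_cols = [c for c in cols[1:] if c.lower() in _META_COLUMNS]
    sample_cols = [c for c in cols[1:] if c.lower() not in _META_COLUMNS]
    if not sample_cols:
        raise MatrixError(f"no sample columns in {path}")

    def meta(row: pd.Series, *names: str, default: str | None = None) -> str | None:
        for c in meta_cols:
            if c.lower() in names:
                return row[c]
        return default

    sites = []
    for i, (_, row) in enumerate(df.iterrows()):
        pos = meta(row, "position", "pos")
        alt = meta(row, "alt", default="G")
        sites.append(
            VariantSite(
                site_id=str(row[id_col]),
                position=int(pos) if pos is not None else i + 1,
                var_class=str(meta(row, "var_class", "class", default="SNV")),
                ref_allele=str(meta(row, "ref", default="A")),
                alt_alleles=tuple(str(alt).split(",")),
            )
        )
    geno = np.empty((len(sample_cols), len(sites)), dtype=np.int8)
    for j, col in enumerate(sample_cols):
        geno[j] = [
            _decode_gt(v) if isinstance(v, str) else MISSING for v in df[col]
        ]
    return CallMatrix(
        samples=sample_cols,
        sites=sites,
        geno=geno,
        outgroup_ids=frozenset(outgroup_ids),
    )


def write_call_matrix(
    matrix: CallMatrix, path: str | Path, dialect: str = "matrix"
) -> None:
    """Serialize a call matrix to the delimited-table or plain-text VCF dialect."""
    path = Path(path)
    if dialect == "matrix":
        _write_matrix_table(matrix, path)
    elif dialect == "vcf":
        _write_vcf(matrix, path)
    else:
        raise MatrixError(f"unknown dialect {dialect!r}")


_SYMBOLS = {ANCESTRAL: "0", DERIVED: "1", MISSING: ".", HET_ARTIFACT: "0/1"}


def _write_matrix_table(matrix: CallMatrix, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("site_id\tposition\tref\talt\t" + "\t".join(matrix.samples) + "\n")
        for i, site in enumerate(matrix.sites):
            calls = "\t".join(_SYMBOLS[int(g)] for g in matrix.geno[:, i])
            fh.write(
                f"{site.site_id}\t{site.position}\t{site.ref_allele}\t"
                f"{','.join(site.alt_alleles)}\t{calls}\n"
            )


def _write_vcf(matrix: CallMatrix, path: Path) -> None:
    has_meta = matrix.depth is not None and matrix.qual is not None
    max_pos = max((s.position for s in matrix.sites), default=1)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID=chrY,length={max_pos + 1000}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if has_meta:
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
            fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.samples)
            + "\n"
        )
        fmt = "GT:DP:GQ" if has_meta else "GT"
        gt_text = {ANCESTRAL: "0", DERIVED: "1", MISSING: ".", HET_ARTIFACT: "0/1"}
        for i, site in enumerate(matrix.sites):
            fields = []
            for j in range(matrix.n_samples):
                g = gt_text[int(matrix.geno[j, i])]
                if has_meta:
                    dp = int(matrix.depth[j, i])
                    gq = int(matrix.qual[j, i])
                    g = f"{g}:{dp if dp >= 0 else '.'}:{gq if gq >= 0 else '.'}"
                fields.append(g)
            fh.write(
                f"chrY\t{site.position}\t{site.site_id}\t{site.ref_allele}\t"
                f"{','.join(site.alt_alleles) or '.'}\t.\t.\t.\t{fmt}\t"
                + "\t".join(fields)
                + "\n"
            )


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def filter_variants(
    matrix: CallMatrix, config: FilterConfig | None = None
) -> tuple[CallMatrix, FilterReport]:
    """Apply the MSY variant ascertainment filters site by site.

    A site is removed when any of the following rules fires (a removed site
    may list several reasons):

    ``low_quality_fraction``
        more than ``max_low_quality_fraction`` of samples have read depth
        below ``min_depth`` or genotype quality below ``min_quality``;
    ``call_rate``
        fewer than ``min_call_rate`` of samples carry any call;
    ``heterozygous_only``
        every non-missing ingroup call looks heterozygous (impossible at a
        haploid locus, hence an artifact);
    ``multiallelic``
        more than one alternative allele;
    ``reference_error``
        every non-missing ingroup call carries the alternative allele, i.e.
        the reference assembly itself is the singleton.

    Heterozygous-artifact calls at surviving sites are demoted to missing.
    Filtering is contractive and idempotent.
    """
    if config is None:
        config = FilterConfig()
    if matrix.n_sites == 0:
        raise MatrixError("cannot filter an empty matrix")
    ingroup_idx = [
        j for j, s in enumerate(matrix.samples) if s not in matrix.outgroup_ids
    ]
    report = FilterReport(n_input=matrix.n_sites)
    keep: list[int] = []
    for i, site in enumerate(matrix.sites):
        reasons: list[str] = []
        col = matrix.geno[:, i]
        if matrix.depth is not None and matrix.qual is not None:
            bad = (
                ((matrix.depth[:, i] >= 0) & (matrix.depth[:, i] < config.min_depth))
                | ((matrix.qual[:, i] >= 0) & (matrix.qual[:, i] < config.min_quality))
            )
            if bad.mean() > config.max_low_quality_fraction:
                reasons.append("low_quality_fraction")
        called = col != MISSING
        if called.mean() < config.min_call_rate:
            reasons.append("call_rate")
        in_col = col[ingroup_idx]
        in_called = in_col[in_col != MISSING]
        if (
            config.drop_heterozygous_only
            and in_called.size > 0
            and np.all(in_called == HET_ARTIFACT)
        ):
            reasons.append("heterozygous_only")
        if config.drop_multiallelic and len(site.alt_alleles) > 1:
            reasons.append("multiallelic")
        if (
            config.drop_reference_errors
            and in_called.size > 0
            and np.all(in_called == DERIVED)
        ):
            reasons.append("reference_error")
        if reasons:
            report.removed.append((site.site_id, tuple(reasons)))
        else:
            keep.append(i)
    out = matrix.take_sites(keep)
    out.geno[out.geno == HET_ARTIFACT] = MISSING
    report.n_retained = out.n_sites
    return out, report


# ---------------------------------------------------------------------------
# polarization
# ---------------------------------------------------------------------------

def polarize(matrix: CallMatrix, outgroup_id: str) -> CallMatrix:
    """Orient alleles as ancestral vs derived using the outgroup's allele.

    After polarization, code 0 means *ancestral* (the outgroup allele) and 1
    means *derived*.  Sites where the outgroup call is missing keep their raw
    coding, get ``ancestral_state="unknown"`` and are flagged in
    ``unpolarized_sites`` (tree building skips them unless overridden).
    """
    if outgroup_id not in matrix.samples:
        raise MatrixError(f"outgroup sample {outgroup_id!r} not in matrix")
    og = matrix.sample_index(outgroup_id)
    out = matrix.copy()
    flagged = set(out.unpolarized_sites)
    new_sites: list[VariantSite] = []
    for i, site in enumerate(out.sites):
        og_call = int(out.geno[og, i])
        if og_call == ANCESTRAL:
            new_sites.append(dataclasses.replace(site, ancestral_state="reference"))
        elif og_call == DERIVED:
            col = out.geno[:, i]
            zeros = col == ANCESTRAL
            ones = col == DERIVED
            col[zeros] = DERIVED
            col[ones] = ANCESTRAL
            new_sites.append(dataclasses.replace(site, ancestral_state="alternative"))
        else:  # missing or het artifact in the outgroup
            flagged.add(site.site_id)
            new_sites.append(dataclasses.replace(site, ancestral_state="unknown"))
    out.sites = new_sites
    out.polarized = True
    out.unpolarized_sites = frozenset(flagged)
    out.outgroup_ids = out.outgroup_ids | {outgroup_id}
    return out
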