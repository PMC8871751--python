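"""One-shot pipeline orchestration with a reproducibility manifest.

Chains the stage operations — filter, polarize, haplogroup clustering,
consensus imputation, haplotype collapse, perfect-phylogeny tree, naming,
optional panel work and the genealogy summary — writing every artifact plus
a manifest of parameters and output checksums.  The pipeline output is a
pure function of (inputs, config, seed): re-running with identical inputs
reproduces byte-identical artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import genealogy
from .haplotypes import (
    HaplogroupRule,
    assign_haplogroups,
    build_haplotypes,
    impute_by_group,
)
from .matrix import CallMatrix, FilterConfig, filter_variants, load_call_matrix, polarize
from .nomenclature import NameRegistry, assign_names
from .phylogeny import build_tree, export_tree

logger = logging.getLogger("patrilinekit")

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage rejected its input; the message carries the stage error verbatim."""


@dataclass
class RunConfig:
    """Pipeline configuration (see ``RunConfig.from_yaml``)."""

    matrix_path: str | None = None
    matrix_dialect: str = "vcf"
    outgroup: str | None = None
    filter: FilterConfig = field(default_factory=FilterConfig)
    imputation_mode: str = "unanimity"
    conflict_policy: str = "fail"
    haplogroup_rules: list[HaplogroupRule] = field(default_factory=list)
    genealogy_fixture: str | None = None
    hg_rollup: tuple[str, ...] = genealogy.DEFAULT_HG_ROLLUP
    output_dir: str = "patrilinekit_run"
    verbosity: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        filt = FilterConfig(**raw.pop("filter", {}))
        rules = [
            HaplogroupRule(
                hg_name=r["hg_name"],
                required_derived=frozenset(r.get("required_derived", ())),
                required_ancestral=frozenset(r.get("required_ancestral", ())),
            )
            for r in raw.pop("haplogroup_rules", [])
        ]
        cfg = cls(filter=filt, haplogroup_rules=rules, **raw)
        for name in ("matrix_path", "genealogy_fixture"):
            p = getattr(cfg, name)
            if p is not None and not Path(p).exists():
                raise PipelineError(f"{name} {p!r} does not exist")
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns the manifest dict.

    Any stage rejection aborts the run with :class:`PipelineError` carrying
    the stage's message verbatim; the manifest is only written on success.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.verbosity, logging.INFO))
    fh = logging.FileHandler(outdir / "run.log")
    logger.addHandler(fh)
    artifacts: dict[str, str] = {}
    warnings: list[str] = []

    def emit(name: str, writer) -> None:
        path = outdir / name
        writer(path)
        artifacts[name] = _sha256(path)
        logger.info("wrote %s", path)

    try:
        if config.matrix_path is not None:
            matrix = load_call_matrix(
                config.matrix_path, config.matrix_dialect
            )
            filtered, freport = filter_variants(matrix, config.filter)
            emit("filter_report.tsv", freport.write)
            if config.outgroup:
                filtered = polarize(filtered, config.outgroup)
                if filtered.unpolarized_sites:
                    warnings.append(
                        f"{len(filtered.unpolarized_sites)} site(s) with unknown "
                        "ancestral state excluded from tree building"
                    )
            groups = (
                assign_haplogroups(filtered, config.haplogroup_rules)
                if config.haplogroup_rules
                else {s: "all" for s in filtered.ingroup_samples}
            )
            imputed, ilog = impute_by_group(
                filtered, groups, mode=config.imputation_mode
            )
            if config.imputation_mode == "majority" and len(ilog):
                warnings.append(
                    f"majority-mode imputation filled {len(ilog)} cell(s)"
                )
            emit("imputation_log.tsv", ilog.write)
            table = build_haplotypes(imputed)
            emit("haplotypes.tsv", table.write)
            if table.excluded_sites:
                warnings.append(
                    f"{len(table.excluded_sites)} site(s) with residual "
                    "missingness excluded from haplotypes and tree"
                )
            kept = [imputed.site_index(sid) for sid in table.site_ids]
            tree, creport = build_tree(
                imputed.take_sites(kept), on_conflict=config.conflict_policy
            )
            if creport.resolution:
                warnings.append(
                    f"dropped conflicting site(s): {','.join(creport.resolution)}"
                )
            assign_names(tree, NameRegistry())
            emit("tree.tsv", lambda p: export_tree(tree, "table", p))
            emit("tree.nwk", lambda p: export_tree(tree, "newick", p))

        if config.genealogy_fixture is not None:
            records = _load_records(config.genealogy_fixture)
            summary = genealogy.summarize_panel(records, config.hg_rollup)
            emit(
                "congruence.tsv",
                lambda p: summary.congruence.to_frame().to_csv(
                    p, sep="\t", index=False
                ),
            )
            emit(
                "summary.json",
                lambda p: Path(p).write_text(
                    json.dumps(
                        {
                            "total_samples": summary.total_samples,
                            "foundation_lines": summary.n_lines,
                            "lines_multi_sampled": summary.n_lines_multi_sampled,
                            "distinct_haplotypes": summary.n_distinct_hts,
                            "hg_sample_counts": summary.hg_sample_counts,
                            "hg_line_counts": summary.hg_line_counts,
                            "samples_in_listed_hgs": summary.samples_in_listed_hgs,
                            "subline_ht_labels": list(summary.subline_ht_labels),
                            "incongruent_lines": list(summary.incongruent_lines),
                        },
                        indent=2,
                        sort_keys=True,
                    )
                    + "\n"
                ),
            )
    except (ValueError, RuntimeError, OSError) as exc:
        logger.error("stage failure: %s", exc)
        raise PipelineError(str(exc)) from exc
    finally:
        logger.removeHandler(fh)
        fh.close()

    manifest = {
        "parameters": _config_dict(config),
        "artifacts": artifacts,
        "warnings": warnings,
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    for w in warnings:
        logger.warning("%s", w)
    return manifest


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    d["filter"] = dataclasses.asdict(config.filter)
    d["haplogroup_rules"] = [
        {
            "hg_name": r.hg_name,
            "required_derived": sorted(r.required_derived),
            "required_ancestral": sorted(r.required_ancestral),
        }
        for r in config.haplogroup_rules
    ]
    d["hg_rollup"] = list(config.hg_rollup)
    return d


def _load_records(path: str) -> list[genealogy.LineRecord]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    return [
        genealogy.LineRecord(
            foundation_sire=row["foundation_sire"],
            subline=row["subline"],
            count=int(row["count"]),
            breed_or_registry=row.get("breed_or_registry", ""),
            ht_label=row["ht_label"],
            remark=row.get("remark", ""),
        )
        for _, row in df.iterrows()
    ]
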