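"""End-to-end pipeline: read inputs, filter, partition, pair, rank, report.

All outputs are deterministic functions of the inputs: re-running on
identical files produces byte-identical artifacts (there is no randomness
anywhere in the analysis path; only the simulator draws random numbers).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import yaml

from .errors import ConfigurationError
from .filters import (
    ConstraintMetric,
    FilterConfig,
    FilterTrace,
    IndelRule,
    MissingAnnotationPolicy,
    load_gene_constraint,
    run_cascade,
)
from .pedigree import BmdCriteria, BmdMode, Pedigree, load_pedigree, pedigree_report
from .prioritize import GeneEvidence, annotate_and_rank, load_gene_evidence
from .segregation import (
    CandidatePair,
    MissingInAffected,
    MissingInUnaffected,
    Partition,
    PresenceRule,
    SegregationPolicy,
    additive_pairs,
    cell_label,
    partition_by_sharing,
)
from .variants import read_annotated_vcf, write_candidates

log = logging.getLogger("famseg")


@dataclass
class PipelineConfig:
    """Paths plus the three policy objects steering the pipeline."""

    vcf: Path
    pedigree: Path
    out_dir: Path
    gene_constraint: Optional[Path] = None
    gene_evidence: Optional[Path] = None
    proband_id: Optional[str] = None
    filters: FilterConfig = field(default_factory=FilterConfig)
    policy: SegregationPolicy = field(default_factory=SegregationPolicy)
    criteria: BmdCriteria = field(default_factory=BmdCriteria)

    def validate_paths(self) -> None:
        for name in ("vcf", "pedigree", "gene_constraint", "gene_evidence"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ConfigurationError(f"{name} path does not exist: {p}")


def config_from_file(path: str | Path) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a YAML/JSON mapping.

    Recognized keys: vcf, pedigree, out_dir, gene_constraint, gene_evidence,
    proband_id, and nested ``filters`` / ``policy`` / ``criteria`` mappings
    whose entries mirror the corresponding dataclass fields.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: config must be a mapping")
    try:
        filters = _build_filters(raw.pop("filters", {}))
        policy = _build_policy(raw.pop("policy", {}))
        criteria = _build_criteria(raw.pop("criteria", {}))
        cfg = PipelineConfig(
            vcf=Path(raw.pop("vcf")),
            pedigree=Path(raw.pop("pedigree")),
            out_dir=Path(raw.pop("out_dir", ".")),
            gene_constraint=_opt_path(raw.pop("gene_constraint", None)),
            gene_evidence=_opt_path(raw.pop("gene_evidence", None)),
            proband_id=raw.pop("proband_id", None),
            filters=filters,
            policy=policy,
            criteria=criteria,
        )
    except KeyError as exc:
        raise ConfigurationError(f"{path}: missing config key {exc}") from None
    if raw:
        raise ConfigurationError(f"{path}: unknown config keys {sorted(raw)}")
    return cfg


def _opt_path(value: Any) -> Optional[Path]:
    return None if value is None else Path(value)


def _build_filters(raw: dict) -> FilterConfig:
    kwargs: dict[str, Any] = {}
    for key, caster in (
        ("maf_max", float),
        ("cadd_min", float),
        ("exclude_synonymous", bool),
        ("intronic_requires_splice_flag", bool),
        ("constraint_threshold", float),
        ("indel_rule", IndelRule),
        ("constraint_metric", ConstraintMetric),
        ("missing_annotation_policy", MissingAnnotationPolicy),
    ):
        if key in raw:
            kwargs[key] = caster(raw.pop(key))
    if raw:
        raise ConfigurationError(f"unknown filter config keys {sorted(raw)}")
    return FilterConfig(**kwargs)


def _build_policy(raw: dict) -> SegregationPolicy:
    kwargs: dict[str, Any] = {}
    for key, caster in (
        ("presence_rule", PresenceRule),
        ("missing_in_unaffected", MissingInUnaffected),
        ("missing_in_affected", MissingInAffected),
    ):
        if key in raw:
            kwargs[key] = caster(raw.pop(key))
    if raw:
        raise ConfigurationError(f"unknown policy config keys {sorted(raw)}")
    return SegregationPolicy(**kwargs)


def _build_criteria(raw: dict) -> BmdCriteria:
    kwargs: dict[str, Any] = {}
    for key, caster in (
        ("mode", BmdMode),
        ("either_site_threshold", float),
        ("sum_threshold", float),
    ):
        if key in raw:
            kwargs[key] = caster(raw.pop(key))
    if raw:
        raise ConfigurationError(f"unknown criteria config keys {sorted(raw)}")
    return BmdCriteria(**kwargs)


@dataclass
class PipelineResult:
    pedigree: Pedigree
    survivors: list
    trace: FilterTrace
    partition: Partition
    pairs: list[CandidatePair]
    report_rows: list[dict]
    artifacts: dict[str, Path]


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Execute the full cascade and write all report artifacts.

    Artifacts written to ``cfg.out_dir``: ``pedigree_report.tsv``,
    ``survivors.tsv``, ``filter_trace.json``, ``partition.tsv``,
    ``pairs.tsv``, ``candidates.tsv``.
    """
    cfg.validate_paths()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    ped = load_pedigree(cfg.pedigree, proband_id=cfg.proband_id)
    log.info("pedigree: %d members, %d affected", len(ped), len(ped.affected_ids()))
    variants, genotypes = read_annotated_vcf(cfg.vcf)
    log.info("VCF: %d variants x %d samples", len(variants), len(genotypes.sample_ids))

    missing = set(ped.sample_ids) - set(genotypes.sample_ids)
    if missing:
        raise ConfigurationError(
            f"pedigree members absent from VCF samples: {sorted(missing)}"
        )

    gene_constraint = (
        load_gene_constraint(cfg.gene_constraint) if cfg.gene_constraint else {}
    )
    evidence: dict[str, GeneEvidence] = (
        load_gene_evidence(cfg.gene_evidence) if cfg.gene_evidence else {}
    )

    survivors, trace = run_cascade(
        variants, genotypes, ped, cfg.filters, cfg.policy, gene_constraint
    )
    for s in trace.stages:
        log.info("stage %-18s %4d -> %4d", s.stage_name, s.n_in, s.n_out)

    partition = partition_by_sharing(
        [v.variant_id for v in survivors], genotypes, ped, cfg.policy
    )
    pairs = additive_pairs(partition, ped)
    report_rows = annotate_and_rank(survivors, partition, evidence)

    artifacts = {
        "pedigree_report": out / "pedigree_report.tsv",
        "survivors": out / "survivors.tsv",
        "trace": out / "filter_trace.json",
        "partition": out / "partition.tsv",
        "pairs": out / "pairs.tsv",
        "candidates": out / "candidates.tsv",
    }

    _write_pedigree_report(artifacts["pedigree_report"], ped, cfg.criteria)
    _write_survivors(artifacts["survivors"], survivors, partition)
    artifacts["trace"].write_text(json.dumps(trace.to_dict(), indent=2) + "\n")
    _write_partition(artifacts["partition"], partition)
    _write_pairs(artifacts["pairs"], pairs)
    write_candidates(report_rows, artifacts["candidates"], fmt="tsv")

    return PipelineResult(
        pedigree=ped,
        survivors=survivors,
        trace=trace,
        partition=partition,
        pairs=pairs,
        report_rows=report_rows,
        artifacts=artifacts,
    )


def _fmt(value: Any) -> str:
    if value is None:
        return "NA"
    if isinstance(value, float):
        return format(value, "g")
    if hasattr(value, "value"):
        return str(value.value)
    return str(value)


def _write_pedigree_report(path: Path, ped: Pedigree, criteria: BmdCriteria) -> None:
    rows = pedigree_report(ped, criteria)
    cols = ["individual_id", "affected", "z_ls", "z_fn", "sum_z", "bmd_class"]
    lines = ["\t".join(cols)]
    for row in rows:
        lines.append("\t".join(_fmt(row[c]) for c in cols))
    path.write_text("\n".join(lines) + "\n")


def _write_survivors(path: Path, survivors, partition: Partition) -> None:
    cols = [
        "variant_id",
        "gene",
        "chrom",
        "pos",
        "ref",
        "alt",
        "region",
        "consequence",
        "maf",
        "cadd",
        "cosegregation",
    ]
    lines = ["\t".join(cols)]
    for v in survivors:
        lines.append(
            "\t".join(
                _fmt(x)
                for x in (
                    v.variant_id,
                    v.gene,
                    v.chrom,
                    v.pos,
                    v.ref,
                    v.alt,
                    v.region_class,
                    v.consequence_class,
                    v.maf,
                    v.cadd_phred,
                    cell_label(partition.cell_of(v.variant_id)),
                )
            )
        )
    path.write_text("\n".join(lines) + "\n")


def _write_partition(path: Path, partition: Partition) -> None:
    lines = ["cell\tn_variants\tvariant_ids"]
    # sort cells by descending size of the affected subset, then label
    for key in sorted(partition.cells, key=lambda k: (-len(k), cell_label(k))):
        vids = partition.cells[key]
        lines.append(f"{cell_label(key)}\t{len(vids)}\t{','.join(sorted(vids))}")
    path.write_text("\n".join(lines) + "\n")


def _write_pairs(path: Path, pairs: list[CandidatePair]) -> None:
    lines = ["variant_a\tvariant_b\tcarriers_a\tcarriers_b\tcovered\tpattern"]
    for p in pairs:
        lines.append(
            "\t".join(
                (
                    p.variant_a,
                    p.variant_b,
                    cell_label(p.carriers_a),
                    cell_label(p.carriers_b),
                    cell_label(p.covered),
                    p.pattern_label,
                )
            )
        )
    path.write_text("\n".join(lines) + "\n")
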