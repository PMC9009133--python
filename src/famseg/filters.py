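"""The rare-variant annotation filter cascade with a per-stage audit trace.

Stage order (the classic dominant exome screen):

1. ``dominant_presence`` — proband carries, every unaffected member does not;
2. ``region_consequence`` — drop non-coding classes, non-splice intronics
   and synonymous changes;
3. ``frequency`` — drop common variants (population MAF above ``maf_max``);
4. ``pathogenicity`` — SNVs need a CADD phred at or above ``cadd_min``;
   indels need a damaging/deleterious call from the categorical indel
   predictors (either one, or both, per ``indel_rule``);
5. ``constraint`` — drop variants in genes enriched for missense variation
   in a population reference (such genes tolerate/accumulate missense
   changes and are noisy candidate sources).

Stages 2-5 are independent per-variant predicates, so the surviving set is
invariant under their ordering; only the trace counts depend on it.

Missing annotations are governed by ``missing_annotation_policy`` and
default to *keep*: a variant absent from gnomAD or without a CADD entry
must not be silently discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Optional, Sequence

from .errors import ValidationError
from .pedigree import Pedigree
from .segregation import SegregationPolicy, dominant_presence
from .variants import (
    AnnotatedVariant,
    ConsequenceClass,
    GenotypeMatrix,
    ProveanIndel,
    RegionClass,
    SiftIndel,
    VariantClass,
)


class IndelRule(str, Enum):
    EITHER_DAMAGING = "either_damaging"
    BOTH_DAMAGING = "both_damaging"


class ConstraintMetric(str, Enum):
    MISSENSE_OE = "missense_oe"  # observed/expected; enrichment = high value
    MISSENSE_Z = "missense_z"  # Z-score; enrichment = low (negative) value


class MissingAnnotationPolicy(str, Enum):
    KEEP = "keep"
    DROP = "drop"


#: region classes excluded by default (everything outside the coding sequence
#: except intronic, which gets its own splice-flag rule)
DEFAULT_EXCLUDED_REGIONS = frozenset(
    {
        RegionClass.INTERGENIC,
        RegionClass.UTR5,
        RegionClass.UTR3,
        RegionClass.UPSTREAM,
        RegionClass.DOWNSTREAM,
        RegionClass.NCRNA,
        RegionClass.UNKNOWN,
    }
)


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds and policies of the annotation filter cascade."""

    maf_max: float = 0.005
    cadd_min: float = 20.0
    excluded_region_classes: frozenset[RegionClass] = DEFAULT_EXCLUDED_REGIONS
    exclude_synonymous: bool = True
    intronic_requires_splice_flag: bool = True
    indel_rule: IndelRule = IndelRule.EITHER_DAMAGING
    constraint_metric: ConstraintMetric = ConstraintMetric.MISSENSE_OE
    constraint_threshold: float = 1.0
    missing_annotation_policy: MissingAnnotationPolicy = MissingAnnotationPolicy.KEEP

    def __post_init__(self) -> None:
        if not (0.0 < self.maf_max <= 1.0):
            raise ValidationError(f"maf_max must be in (0, 1], got {self.maf_max}")
        if self.cadd_min < 0:
            raise ValidationError(f"cadd_min must be >= 0, got {self.cadd_min}")


@dataclass(frozen=True)
class TraceStage:
    stage_name: str
    n_in: int
    n_out: int
    dropped_variant_ids: tuple[str, ...]


@dataclass
class FilterTrace:
    """Ordered per-stage record of how many variants entered, survived, and
    which ids were dropped."""

    stages: list[TraceStage] = field(default_factory=list)

    def add(self, name: str, ids_in: Sequence[str], ids_out: Sequence[str]) -> None:
        dropped = tuple(v for v in ids_in if v not in set(ids_out))
        stage = TraceStage(name, len(ids_in), len(ids_out), dropped)
        if self.stages and self.stages[-1].n_out != stage.n_in:
            raise ValidationError(
                f"trace discontinuity entering {name!r}: "
                f"{self.stages[-1].n_out} != {stage.n_in}"
            )
        if stage.n_out > stage.n_in:
            raise ValidationError(f"stage {name!r} gained variants")
        self.stages.append(stage)

    def counts(self) -> dict[str, tuple[int, int]]:
        return {s.stage_name: (s.n_in, s.n_out) for s in self.stages}

    def all_dropped(self) -> list[str]:
        return [v for s in self.stages for v in s.dropped_variant_ids]

    def to_dict(self) -> list[dict]:
        return [
            {
                "stage": s.stage_name,
                "n_in": s.n_in,
                "n_out": s.n_out,
                "dropped": list(s.dropped_variant_ids),
            }
            for s in self.stages
        ]


# ---------------------------------------------------------------------------
# Per-variant predicates (total functions: never raise on annotation content)


def region_consequence_filter(v: AnnotatedVariant, cfg: FilterConfig = FilterConfig()) -> bool:
    """Keep coding-relevant variants only."""
    if v.region_class in cfg.excluded_region_classes:
        return False
    if v.region_class is RegionClass.INTRONIC and cfg.intronic_requires_splice_flag:
        if not v.splice_affecting:
            return False
    if cfg.exclude_synonymous and v.consequence_class is ConsequenceClass.SYNONYMOUS:
        return False
    return True


def frequency_filter(v: AnnotatedVariant, cfg: FilterConfig = FilterConfig()) -> bool:
    """Keep rare variants; a variant with no population frequency is kept."""
    if v.maf is None:
        return True
    return v.maf <= cfg.maf_max


def pathogenicity_filter(v: AnnotatedVariant, cfg: FilterConfig = FilterConfig()) -> bool:
    """SNVs pass on CADD phred >= ``cadd_min``; indels on the categorical
    indel predictors per ``indel_rule``.

    Absent scores are resolved by ``missing_annotation_policy`` (default
    keep). For indels with exactly one prediction available, the available
    one decides under ``either_damaging``; under ``both_damaging`` the
    missing one is resolved by the policy.
    """
    keep_missing = cfg.missing_annotation_policy is MissingAnnotationPolicy.KEEP
    if v.variant_class is VariantClass.SNV:
        if v.cadd_phred is None:
            return keep_missing
        return v.cadd_phred >= cfg.cadd_min

    sift_damaging = None if v.sift_indel is None else v.sift_indel is SiftIndel.DAMAGING
    provean_damaging = (
        None if v.provean_indel is None else v.provean_indel is ProveanIndel.DELETERIOUS
    )
    calls = [c for c in (sift_damaging, provean_damaging) if c is not None]
    if not calls:
        return keep_missing
    if cfg.indel_rule is IndelRule.EITHER_DAMAGING:
        return any(calls)
    # both_damaging: a missing predictor defers to the missing policy
    if len(calls) == 1:
        return calls[0] and keep_missing
    return all(calls)


def constraint_filter(
    v: AnnotatedVariant,
    gene_constraint: Mapping[str, float],
    cfg: FilterConfig = FilterConfig(),
) -> bool:
    """Drop variants in missense-enriched genes; unlisted genes are kept."""
    metric = gene_constraint.get(v.gene)
    if metric is None:
        return True
    if cfg.constraint_metric is ConstraintMetric.MISSENSE_OE:
        return metric <= cfg.constraint_threshold
    # missense_z: enrichment shows as a low Z
    return metric >= cfg.constraint_threshold


# ---------------------------------------------------------------------------


def run_cascade(
    variants: Sequence[AnnotatedVariant],
    genotypes: GenotypeMatrix,
    ped: Pedigree,
    cfg: FilterConfig = FilterConfig(),
    policy: SegregationPolicy = SegregationPolicy(),
    gene_constraint: Optional[Mapping[str, float]] = None,
) -> tuple[list[AnnotatedVariant], FilterTrace]:
    """Run the full cascade and return (survivors, per-stage trace)."""
    gene_constraint = gene_constraint or {}
    trace = FilterTrace()
    by_id = {v.variant_id: v for v in variants}
    current = [v.variant_id for v in variants]

    def apply(name: str, pred) -> None:
        nonlocal current
        kept = [vid for vid in current if pred(by_id[vid])]
        trace.add(name, current, kept)
        current = kept

    apply(
        "dominant_presence",
        lambda v: dominant_presence(v.variant_id, genotypes, ped, policy),
    )
    apply("region_consequence", lambda v: region_consequence_filter(v, cfg))
    apply("frequency", lambda v: frequency_filter(v, cfg))
    apply("pathogenicity", lambda v: pathogenicity_filter(v, cfg))
    apply("constraint", lambda v: constraint_filter(v, gene_constraint, cfg))

    return [by_id[vid] for vid in current], trace


def load_gene_constraint(path) -> dict[str, float]:
    """Read a two-column TSV (gene, metric value) into a mapping.

    Lines starting with ``#`` are ignored; duplicate genes are an error.
    """
    from pathlib import Path

    table: dict[str, float] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValidationError(f"{path} line {lineno}: expected 2 columns")
        gene, value = parts
        if gene in table:
            raise ValidationError(f"{path} line {lineno}: duplicate gene {gene!r}")
        table[gene] = float(value)
    return table
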