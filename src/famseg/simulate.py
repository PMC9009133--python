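"""Synthetic pedigree studies: gene-dropped genotypes, planted variants,
and a truth table, written as standard VCF/PED files.

The generator emulates the design of a small dominant-pedigree exome
study — six members, three affected (proband, her mother, one daughter)
and three unaffected — so that every pipeline stage can be exercised and
verified end to end without access to real exome data.

Two kinds of variants are emitted:

* **background** variants: founder genotypes drawn at a population allele
  frequency and transmitted down the pedigree by gene dropping (each child
  receives one uniformly chosen allele from each parent; a married-in
  parent absent from the pedigree contributes a population-frequency
  draw). Annotations are drawn from simple parametric mixtures.
* **planted** variants: carriers set directly (no transmission sampling)
  and annotations constructed so the filter cascade assigns a prescribed
  fate — survive, or die at a named stage. Decoy annotation values sit
  well beyond the thresholds (e.g. MAF at 1.2x the cutoff) so the fate is
  unambiguous under either indel rule.

Every emitted variant gets a truth-table row recording its intended
cascade fate and, for survivors, the affected-carrier cell it must land
in. All randomness flows from a single integer seed; the same spec and
seed produce byte-identical output files.

Synthetic contigs are named ``S1``..``S6`` so coordinates can never be
mistaken for (or accidentally joined against) a real genome build.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from enum import Enum
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pysam

from .errors import SimulationError, ValidationError
from .filters import (
    FilterConfig,
    constraint_filter,
    frequency_filter,
    pathogenicity_filter,
    region_consequence_filter,
)
from .pedigree import FOUNDER, Pedigree, hbm_study_pedigree, write_pedigree
from .segregation import SegregationPolicy
from .variants import (
    AnnotatedVariant,
    ConsequenceClass,
    ProveanIndel,
    RegionClass,
    SiftIndel,
    VariantClass,
)

CONTIGS = tuple(f"S{i}" for i in range(1, 7))
CONTIG_LENGTH = 10_000_000

#: metric value written to the constraint table for missense-enriched genes
ENRICHED_OE = 1.5
#: metric value for explicitly unconstrained genes
NEUTRAL_OE = 0.8


class PlantedFate(str, Enum):
    SURVIVE = "survive"
    DIE_PRESENCE = "die_presence"
    DIE_REGION = "die_region"
    DIE_MAF = "die_maf"
    DIE_CADD = "die_cadd"
    DIE_CONSTRAINT = "die_constraint"


# ---------------------------------------------------------------------------
# Gene dropping


def drop_alleles(
    ped: Pedigree, founder_maf: float, rng: np.random.Generator
) -> dict[str, tuple[int, int]]:
    """One gene-dropping realization: (paternal, maternal) alleles per member.

    Founders draw both alleles Bernoulli(``founder_maf``); a non-founder
    inherits one uniformly chosen allele from each parent. A parent slot
    holding the founder marker (an unsampled married-in spouse) contributes
    a fresh population draw.
    """
    if not (0.0 <= founder_maf <= 1.0):
        raise SimulationError(f"founder_maf must be in [0, 1], got {founder_maf}")

    alleles: dict[str, tuple[int, int]] = {}

    def allele_from(parent_id: str) -> int:
        if parent_id == FOUNDER:
            return int(rng.random() < founder_maf)
        pat, mat = resolve(parent_id)
        return pat if rng.random() < 0.5 else mat

    def resolve(iid: str) -> tuple[int, int]:
        if iid not in alleles:
            ind = ped[iid]
            alleles[iid] = (allele_from(ind.father_id), allele_from(ind.mother_id))
        return alleles[iid]

    for ind in ped.individuals:
        resolve(ind.individual_id)
    return alleles


def simulate_genotypes(
    ped: Pedigree, founder_maf: float, seed: int | np.random.Generator
) -> np.ndarray:
    """Gene-drop one variant; returns dosages aligned to ``ped.sample_ids``."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pairs = drop_alleles(ped, founder_maf, rng)
    return np.array([sum(pairs[iid]) for iid in ped.sample_ids], dtype=np.int8)


# ---------------------------------------------------------------------------
# Planted variants


@dataclass(frozen=True)
class PlantedVariant:
    """A variant with prescribed carriers and a prescribed cascade fate.

    Annotation overrides are optional; anything not overridden is set to a
    value that passes the corresponding filter, so the intended fate is the
    only stage at which the variant can die.
    """

    intended_carriers: frozenset[str]
    intended_fate: PlantedFate
    gene: Optional[str] = None
    is_indel: bool = False
    maf: Optional[float] = None
    cadd_phred: Optional[float] = None
    region_class: Optional[RegionClass] = None
    consequence_class: Optional[ConsequenceClass] = None
    splice_affecting: Optional[bool] = None
    sift_indel: Optional[SiftIndel] = None
    provean_indel: Optional[ProveanIndel] = None


def _default_annotations(pv: PlantedVariant, cfg: FilterConfig) -> dict:
    """Fate-determined annotation values; overrides win where given."""
    ann: dict = {
        "region_class": RegionClass.CODING,
        "consequence_class": (
            ConsequenceClass.FRAMESHIFT if pv.is_indel else ConsequenceClass.MISSENSE
        ),
        "splice_affecting": False,
        "maf": cfg.maf_max * 0.04,  # comfortably rare
        "cadd_phred": cfg.cadd_min + 5.0,
        "sift_indel": SiftIndel.DAMAGING if pv.is_indel else None,
        "provean_indel": ProveanIndel.DELETERIOUS if pv.is_indel else None,
    }
    fate = pv.intended_fate
    if fate is PlantedFate.DIE_REGION:
        # a synonymous coding change dies at the region/consequence stage
        ann["consequence_class"] = ConsequenceClass.SYNONYMOUS
    elif fate is PlantedFate.DIE_MAF:
        ann["maf"] = cfg.maf_max * 1.2
    elif fate is PlantedFate.DIE_CADD:
        if pv.is_indel:
            ann["sift_indel"] = SiftIndel.NEUTRAL
            ann["provean_indel"] = ProveanIndel.NEUTRAL
        else:
            ann["cadd_phred"] = cfg.cadd_min * 0.8
    for key in (
        "maf",
        "cadd_phred",
        "region_class",
        "consequence_class",
        "splice_affecting",
        "sift_indel",
        "provean_indel",
    ):
        override = getattr(pv, key)
        if override is not None:
            ann[key] = override
    return ann


def plant_variant(
    pv: PlantedVariant,
    ped: Pedigree,
    cfg: FilterConfig = FilterConfig(),
    chrom: str = CONTIGS[0],
    pos: int = 1000,
    gene: str = "PLANTED",
    variant_id: str = "",
) -> tuple[AnnotatedVariant, np.ndarray]:
    """Materialize a planted variant: annotations plus a dosage vector with
    dosage 1 exactly at the intended carriers.

    Raises :class:`SimulationError` if the carrier set or the (possibly
    overridden) annotations cannot realize the intended fate.
    """
    unknown = pv.intended_carriers - set(ped.sample_ids)
    if unknown:
        raise SimulationError(f"planted carriers not in pedigree: {sorted(unknown)}")

    affected = ped.affected_ids()
    unaffected = ped.unaffected_ids()
    proband = ped.proband_id
    passes_presence = proband in pv.intended_carriers and not (
        pv.intended_carriers & unaffected
    )
    if pv.intended_fate is PlantedFate.DIE_PRESENCE:
        if passes_presence:
            raise SimulationError(
                "die_presence requires the carrier set to violate dominant "
                "presence (proband absent, or an unaffected carrier)"
            )
    elif not passes_presence:
        raise SimulationError(
            f"fate {pv.intended_fate.value} requires carriers that pass the "
            "dominant presence filter (proband carries, no unaffected does)"
        )

    ann = _default_annotations(pv, cfg)
    if pv.is_indel:
        ref, alt = "AT", "A"
    else:
        ref, alt = "A", "G"
    variant = AnnotatedVariant(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        gene=pv.gene or gene,
        variant_id=variant_id,
        **ann,
    )

    constraint = (
        {variant.gene: ENRICHED_OE}
        if pv.intended_fate is PlantedFate.DIE_CONSTRAINT
        else {}
    )
    realized = _cascade_fate(variant, passes_presence, constraint, cfg)
    if realized is not pv.intended_fate:
        raise SimulationError(
            f"unsatisfiable plant: intended {pv.intended_fate.value} but "
            f"annotations realize {realized.value}"
        )

    dosages = np.array(
        [1 if iid in pv.intended_carriers else 0 for iid in ped.sample_ids],
        dtype=np.int8,
    )
    return variant, dosages


def _cascade_fate(
    v: AnnotatedVariant,
    passes_presence: bool,
    gene_constraint: Mapping[str, float],
    cfg: FilterConfig,
) -> PlantedFate:
    """First stage at which a variant dies, evaluated directly."""
    if not passes_presence:
        return PlantedFate.DIE_PRESENCE
    if not region_consequence_filter(v, cfg):
        return PlantedFate.DIE_REGION
    if not frequency_filter(v, cfg):
        return PlantedFate.DIE_MAF
    if not pathogenicity_filter(v, cfg):
        return PlantedFate.DIE_CADD
    if not constraint_filter(v, gene_constraint, cfg):
        return PlantedFate.DIE_CONSTRAINT
    return PlantedFate.SURVIVE


# ---------------------------------------------------------------------------
# Whole-study generation


@dataclass(frozen=True)
class AnnotationModel:
    """Parametric mixtures for background-variant annotations."""

    indel_fraction: float = 0.10
    region_weights: tuple[tuple[RegionClass, float], ...] = (
        (RegionClass.CODING, 0.50),
        (RegionClass.INTRONIC, 0.30),
        (RegionClass.UTR5, 0.04),
        (RegionClass.UTR3, 0.06),
        (RegionClass.UPSTREAM, 0.03),
        (RegionClass.DOWNSTREAM, 0.03),
        (RegionClass.NCRNA, 0.02),
        (RegionClass.INTERGENIC, 0.02),
    )
    synonymous_fraction: float = 0.35  # among coding SNVs
    splice_flag_prob: float = 0.20  # among intronic variants
    missing_maf_prob: float = 0.05
    missing_cadd_prob: float = 0.05
    cadd_range: tuple[float, float] = (0.0, 40.0)
    enriched_gene_prob: float = 0.05  # background genes marked missense-enriched


@dataclass
class SimulationSpec:
    """Everything needed to generate one synthetic study."""

    pedigree: Pedigree = dc_field(default_factory=hbm_study_pedigree)
    n_background: int = 2000
    planted: list[PlantedVariant] = dc_field(default_factory=list)
    founder_maf_range: tuple[float, float] = (1e-5, 0.5)  # log-uniform
    annotations: AnnotationModel = dc_field(default_factory=AnnotationModel)
    filter_config: FilterConfig = dc_field(default_factory=FilterConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_background < 0:
            raise ValidationError("n_background must be >= 0")
        lo, hi = self.founder_maf_range
        if not (0 < lo <= hi < 1):
            raise ValidationError(f"bad founder_maf_range {self.founder_maf_range}")


@dataclass(frozen=True)
class TruthRecord:
    variant_id: str
    intended_fate: PlantedFate
    intended_cell: Optional[frozenset[str]]  # affected carriers; None unless survive


@dataclass(frozen=True)
class StudyFiles:
    vcf: Path
    pedigree: Path
    truth: Path
    gene_constraint: Path


def generate_study(spec: SimulationSpec, out_dir: str | Path) -> StudyFiles:
    """Generate VCF + extended-PED + truth TSV + gene-constraint TSV.

    Deterministic: the same spec and seed yield byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    ped = spec.pedigree
    cfg = spec.filter_config
    affected = ped.affected_ids()

    records: list[tuple[AnnotatedVariant, np.ndarray, TruthRecord]] = []
    constraint_table: dict[str, float] = {}

    # planted variants first (ids P...), then background (ids B...)
    for i, pv in enumerate(spec.planted):
        vid = f"varP{i + 1:04d}"
        gene = pv.gene or f"PG{i + 1:04d}"
        variant, dosages = plant_variant(
            pv, ped, cfg, gene=gene, variant_id=vid
        )
        if pv.intended_fate is PlantedFate.DIE_CONSTRAINT:
            constraint_table[variant.gene] = ENRICHED_OE
        else:
            constraint_table.setdefault(variant.gene, NEUTRAL_OE)
        cell = (
            frozenset(pv.intended_carriers & affected)
            if pv.intended_fate is PlantedFate.SURVIVE
            else None
        )
        records.append((variant, dosages, TruthRecord(vid, pv.intended_fate, cell)))

    ann_model = spec.annotations
    log_lo, log_hi = (math.log(x) for x in spec.founder_maf_range)
    region_classes = [r for r, _ in ann_model.region_weights]
    region_probs = np.array([w for _, w in ann_model.region_weights])
    region_probs = region_probs / region_probs.sum()

    for i in range(spec.n_background):
        vid = f"varB{i + 1:05d}"
        gene = f"BG{i + 1:05d}"
        founder_maf = math.exp(rng.uniform(log_lo, log_hi))
        dosages = simulate_genotypes(ped, founder_maf, rng)

        is_indel = rng.random() < ann_model.indel_fraction
        region = region_classes[rng.choice(len(region_classes), p=region_probs)]
        splice = bool(region is RegionClass.INTRONIC and rng.random() < ann_model.splice_flag_prob)
        if is_indel:
            csq = (
                ConsequenceClass.FRAMESHIFT
                if rng.random() < 0.7
                else ConsequenceClass.INFRAME_INDEL
            )
        elif region is RegionClass.CODING:
            csq = (
                ConsequenceClass.SYNONYMOUS
                if rng.random() < ann_model.synonymous_fraction
                else ConsequenceClass.MISSENSE
            )
        else:
            csq = ConsequenceClass.OTHER
        maf = None if rng.random() < ann_model.missing_maf_prob else round(founder_maf, 6)
        lo_c, hi_c = ann_model.cadd_range
        cadd = (
            None
            if rng.random() < ann_model.missing_cadd_prob
            else round(float(rng.uniform(lo_c, hi_c)), 2)
        )
        sift = provean = None
        if is_indel:
            sift = SiftIndel.DAMAGING if rng.random() < 0.5 else SiftIndel.NEUTRAL
            provean = (
                ProveanIndel.DELETERIOUS if rng.random() < 0.5 else ProveanIndel.NEUTRAL
            )
        if rng.random() < ann_model.enriched_gene_prob:
            constraint_table[gene] = ENRICHED_OE

        variant = AnnotatedVariant(
            chrom=CONTIGS[0],
            pos=1,
            ref="AT" if is_indel else "A",
            alt="A" if is_indel else "G",
            gene=gene,
            region_class=region,
            consequence_class=csq,
            splice_affecting=splice,
            maf=maf,
            cadd_phred=cadd,
            sift_indel=sift,
            provean_indel=provean,
            variant_id=vid,
        )
        carriers = {s for s, d in zip(ped.sample_ids, dosages) if d > 0}
        passes_presence = ped.proband_id in carriers and not (
            carriers & ped.unaffected_ids()
        )
        fate = _cascade_fate(variant, passes_presence, constraint_table, cfg)
        cell = frozenset(carriers & affected) if fate is PlantedFate.SURVIVE else None
        records.append((variant, dosages, TruthRecord(vid, fate, cell)))

    # scatter variants across synthetic contigs at unique positions
    n = len(records)
    contig_idx = rng.integers(0, len(CONTIGS), size=n)
    positions = _unique_positions(rng, n)
    placed = []
    for (variant, dosages, truth), ci, pos in zip(records, contig_idx, positions):
        placed.append(
            (
                AnnotatedVariant(
                    chrom=CONTIGS[ci],
                    pos=int(pos),
                    ref=variant.ref,
                    alt=variant.alt,
                    gene=variant.gene,
                    region_class=variant.region_class,
                    consequence_class=variant.consequence_class,
                    splice_affecting=variant.splice_affecting,
                    maf=variant.maf,
                    cadd_phred=variant.cadd_phred,
                    sift_indel=variant.sift_indel,
                    provean_indel=variant.provean_indel,
                    variant_id=variant.variant_id,
                ),
                dosages,
                truth,
            )
        )
    placed.sort(key=lambda t: (CONTIGS.index(t[0].chrom), t[0].pos))

    files = StudyFiles(
        vcf=out_dir / "study.vcf",
        pedigree=out_dir / "study.ped",
        truth=out_dir / "truth.tsv",
        gene_constraint=out_dir / "gene_constraint.tsv",
    )
    _write_vcf(files.vcf, ped.sample_ids, placed)
    write_pedigree(ped, files.pedigree)
    _write_truth(files.truth, [t for _, _, t in placed])
    _write_constraint(files.gene_constraint, constraint_table)
    return files


def _unique_positions(rng: np.random.Generator, n: int) -> np.ndarray:
    """Draw n distinct positions in [1, CONTIG_LENGTH] (collisions across
    different contigs are harmless but uniqueness keeps ids unambiguous)."""
    seen: list[int] = []
    have: set[int] = set()
    while len(seen) < n:
        draw = rng.integers(1, CONTIG_LENGTH, size=max(16, n - len(seen)))
        for p in draw:
            p = int(p)
            if p not in have:
                have.add(p)
                seen.append(p)
                if len(seen) == n:
                    break
    return np.array(seen)


def _write_vcf(
    path: Path,
    sample_ids: Sequence[str],
    records: Sequence[tuple[AnnotatedVariant, np.ndarray, TruthRecord]],
) -> None:
    header = pysam.VariantHeader()
    for contig in CONTIGS:
        header.contigs.add(contig, length=CONTIG_LENGTH)
    infos = [
        ("GENE", "1", "String", "Gene symbol"),
        ("REGION", "1", "String", "Region class"),
        ("CSQCLASS", "1", "String", "Consequence class"),
        ("SPLICE", "0", "Flag", "Predicted to affect splicing"),
        ("MAF", "1", "Float", "Population minor allele frequency"),
        ("CADD", "1", "Float", "CADD phred score"),
        ("SIFT_INDEL", "1", "String", "SIFT indel call"),
        ("PROVEAN_INDEL", "1", "String", "PROVEAN indel call"),
    ]
    for ident, number, typ, desc in infos:
        header.add_meta(
            "INFO",
            items=[("ID", ident), ("Number", number), ("Type", typ), ("Description", desc)],
        )
    header.add_meta(
        "FORMAT",
        items=[("ID", "GT"), ("Number", "1"), ("Type", "String"), ("Description", "Genotype")],
    )
    for s in sample_ids:
        header.add_sample(s)

    gt_map = {0: (0, 0), 1: (0, 1), 2: (1, 1)}
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for variant, dosages, _ in records:
            rec = out.new_record(
                contig=variant.chrom,
                start=variant.pos - 1,
                alleles=(variant.ref, variant.alt),
                id=variant.variant_id,
            )
            rec.info["GENE"] = variant.gene
            rec.info["REGION"] = variant.region_class.value
            rec.info["CSQCLASS"] = variant.consequence_class.value
            if variant.splice_affecting:
                rec.info["SPLICE"] = True
            if variant.maf is not None:
                rec.info["MAF"] = variant.maf
            if variant.cadd_phred is not None:
                rec.info["CADD"] = variant.cadd_phred
            if variant.sift_indel is not None:
                rec.info["SIFT_INDEL"] = variant.sift_indel.value
            if variant.provean_indel is not None:
                rec.info["PROVEAN_INDEL"] = variant.provean_indel.value
            for sid, d in zip(sample_ids, dosages):
                rec.samples[sid]["GT"] = gt_map[int(d)]
            out.write(rec)


def _write_truth(path: Path, truths: Sequence[TruthRecord]) -> None:
    lines = ["#variant_id\tintended_fate\tintended_cell"]
    for t in truths:
        cell = ",".join(sorted(t.intended_cell)) if t.intended_cell else "none"
        lines.append(f"{t.variant_id}\t{t.intended_fate.value}\t{cell}")
    path.write_text("\n".join(lines) + "\n")


def load_truth(path: str | Path) -> dict[str, TruthRecord]:
    """Read a truth TSV back into a mapping keyed by variant id."""
    table: dict[str, TruthRecord] = {}
    for raw in Path(path).read_text().splitlines():
        if not raw.strip() or raw.startswith("#"):
            continue
        vid, fate, cell = raw.split("\t")
        table[vid] = TruthRecord(
            variant_id=vid,
            intended_fate=PlantedFate(fate),
            intended_cell=None if cell == "none" else frozenset(cell.split(",")),
        )
    return table


def _write_constraint(path: Path, table: Mapping[str, float]) -> None:
    lines = ["# gene\tmissense_oe"]
    for gene in sorted(table):
        lines.append(f"{gene}\t{table[gene]}")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Ready-made study designs


def study_partition_spec(
    counts: tuple[int, int, int, int] = (4, 11, 9, 14),
    n_decoys_per_stage: int = 5,
    n_background: int = 0,
    seed: int = 0,
) -> SimulationSpec:
    """A study that plants survivors across the four affected-sharing cells
    (all-three / proband+mother / proband+daughter / proband-only) at the
    given counts, plus decoys dying at each annotation stage.

    With the default counts this reproduces the published partition
    structure 38 = 4 + 11 + 9 + 14 as a regression fixture.
    """
    ped = hbm_study_pedigree()
    cells = [
        frozenset({"I.1", "II.5", "III.1"}),
        frozenset({"I.1", "II.5"}),
        frozenset({"II.5", "III.1"}),
        frozenset({"II.5"}),
    ]
    planted: list[PlantedVariant] = []
    for cell, k in zip(cells, counts):
        for _ in range(k):
            planted.append(PlantedVariant(intended_carriers=cell, intended_fate=PlantedFate.SURVIVE))
    decoy_fates = [
        PlantedFate.DIE_PRESENCE,
        PlantedFate.DIE_REGION,
        PlantedFate.DIE_MAF,
        PlantedFate.DIE_CADD,
        PlantedFate.DIE_CONSTRAINT,
    ]
    proband_cell = frozenset({"II.5"})
    presence_violating = frozenset({"II.5", "III.2"})  # unaffected carrier
    for fate in decoy_fates:
        for _ in range(n_decoys_per_stage):
            carriers = presence_violating if fate is PlantedFate.DIE_PRESENCE else proband_cell
            planted.append(PlantedVariant(intended_carriers=carriers, intended_fate=fate))
    return SimulationSpec(
        pedigree=ped, n_background=n_background, planted=planted, seed=seed
    )


def study_additive_pair_spec(seed: int = 0, n_background: int = 0) -> SimulationSpec:
    """Minimal study planting one {proband, mother} survivor and one
    {proband, daughter} survivor — the two-locus additive configuration."""
    return SimulationSpec(
        pedigree=hbm_study_pedigree(),
        n_background=n_background,
        planted=[
            PlantedVariant(
                intended_carriers=frozenset({"I.1", "II.5"}),
                intended_fate=PlantedFate.SURVIVE,
            ),
            PlantedVariant(
                intended_carriers=frozenset({"II.5", "III.1"}),
                intended_fate=PlantedFate.SURVIVE,
            ),
        ],
        seed=seed,
    )
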