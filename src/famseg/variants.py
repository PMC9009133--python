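"""Annotated variant and genotype containers plus VCF/report I/O.

A multi-sample VCF annotated with gene symbol, region class, consequence
class, splice flag, population MAF, CADD phred and categorical indel
predictions is normalized into one :class:`AnnotatedVariant` per alt allele
(multiallelic records are decomposed) and a dense :class:`GenotypeMatrix`
of alt-allele dosages. Coordinates stay 1-based VCF throughout.

Absent annotations stay absent (``None``): a variant with no gnomAD entry
must not be silently given frequency 0 or any other default — downstream
filters decide what missing data means.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Any, Iterator, Mapping, Optional, Sequence

import numpy as np
from cyvcf2 import VCF

from .errors import ConfigurationError, ValidationError, VcfFormatError


class VariantClass(str, Enum):
    SNV = "snv"
    INDEL = "indel"


class RegionClass(str, Enum):
    CODING = "coding"
    INTERGENIC = "intergenic"
    UTR5 = "utr5"
    UTR3 = "utr3"
    UPSTREAM = "upstream"
    DOWNSTREAM = "downstream"
    NCRNA = "ncRNA"
    INTRONIC = "intronic"
    UNKNOWN = "unknown"


class ConsequenceClass(str, Enum):
    MISSENSE = "missense"
    SYNONYMOUS = "synonymous"
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    INFRAME_INDEL = "inframe_indel"
    SPLICE_REGION = "splice_region"
    OTHER = "other"


class SiftIndel(str, Enum):
    DAMAGING = "damaging"
    NEUTRAL = "neutral"


class ProveanIndel(str, Enum):
    DELETERIOUS = "deleterious"
    NEUTRAL = "neutral"


#: missing dosage sentinel in the genotype matrix
MISSING = -1


@dataclass(frozen=True)
class AnnotatedVariant:
    """One normalized alt allele with the annotations the filter cascade consumes."""

    chrom: str
    pos: int  # 1-based, VCF convention
    ref: str
    alt: str
    gene: str
    region_class: RegionClass = RegionClass.UNKNOWN
    consequence_class: ConsequenceClass = ConsequenceClass.OTHER
    splice_affecting: bool = False
    maf: Optional[float] = None
    cadd_phred: Optional[float] = None
    sift_indel: Optional[SiftIndel] = None
    provean_indel: Optional[ProveanIndel] = None
    variant_id: str = ""

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValidationError(f"ref == alt ({self.ref!r}) at {self.chrom}:{self.pos}")
        if self.maf is not None and not (0.0 <= self.maf <= 1.0):
            raise ValidationError(f"MAF {self.maf} outside [0,1] at {self.chrom}:{self.pos}")
        if self.cadd_phred is not None and self.cadd_phred < 0:
            raise ValidationError(f"negative CADD {self.cadd_phred} at {self.chrom}:{self.pos}")
        if not self.variant_id:
            object.__setattr__(
                self, "variant_id", f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"
            )

    @property
    def variant_class(self) -> VariantClass:
        # snv  <=>  both alleles are single bases
        if len(self.ref) == 1 and len(self.alt) == 1:
            return VariantClass.SNV
        return VariantClass.INDEL


@dataclass
class GenotypeMatrix:
    """Alt-allele dosages, one row per sample and one column per variant.

    Values are 0/1/2 or :data:`MISSING` (-1). ``variant_ids`` align with the
    accompanying list of :class:`AnnotatedVariant`.
    """

    sample_ids: list[str]
    variant_ids: list[str]
    dosages: np.ndarray  # int8, shape (n_samples, n_variants)
    _vidx: dict[str, int] = field(init=False, repr=False)
    _sidx: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.shape != (len(self.sample_ids), len(self.variant_ids)):
            raise ValidationError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.variant_ids)} variants"
            )
        if len(set(self.variant_ids)) != len(self.variant_ids):
            raise ValidationError("duplicate variant_ids in genotype matrix")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample_ids in genotype matrix")
        bad = ~np.isin(self.dosages, (0, 1, 2, MISSING))
        if bad.any():
            raise ValidationError("dosages must be 0, 1, 2 or missing (-1)")
        self._vidx = {v: j for j, v in enumerate(self.variant_ids)}
        self._sidx = {s: i for i, s in enumerate(self.sample_ids)}

    def dosage(self, sample_id: str, variant_id: str) -> int:
        return int(self.dosages[self._sidx[sample_id], self._vidx[variant_id]])

    def variant_dosages(self, variant_id: str) -> dict[str, int]:
        if variant_id not in self._vidx:
            raise KeyError(f"unknown variant {variant_id!r}")
        col = self.dosages[:, self._vidx[variant_id]]
        return {s: int(d) for s, d in zip(self.sample_ids, col)}

    def subset_variants(self, variant_ids: Sequence[str]) -> "GenotypeMatrix":
        cols = [self._vidx[v] for v in variant_ids]
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            variant_ids=list(variant_ids),
            dosages=self.dosages[:, cols].copy(),
        )


# ---------------------------------------------------------------------------
# VCF ingestion

#: default mapping from AnnotatedVariant field to VCF INFO key
DEFAULT_ANNOTATION_SPEC: dict[str, str] = {
    "gene": "GENE",
    "region_class": "REGION",
    "consequence_class": "CSQCLASS",
    "splice_affecting": "SPLICE",
    "maf": "MAF",
    "cadd_phred": "CADD",
    "sift_indel": "SIFT_INDEL",
    "provean_indel": "PROVEAN_INDEL",
}

_REQUIRED_SPEC_FIELDS = set(DEFAULT_ANNOTATION_SPEC)


def _info_scalar(value: Any, alt_index: int, n_alt: int) -> Any:
    """Pick the per-alt entry from a possibly tuple-valued INFO field."""
    if isinstance(value, tuple):
        if len(value) == n_alt:
            return value[alt_index]
        return value[0]
    return value


def read_annotated_vcf(
    path: str | Path,
    annotation_spec: Mapping[str, str] = DEFAULT_ANNOTATION_SPEC,
    strict: bool = True,
) -> tuple[list[AnnotatedVariant], GenotypeMatrix]:
    """Read a multi-sample VCF into variants + dosage matrix.

    Multiallelic records are decomposed into one :class:`AnnotatedVariant`
    per alt allele; per-alt dosage is the count of that allele in the GT
    call. Genotypes with any missing allele yield a missing dosage.

    ``annotation_spec`` maps model fields to INFO keys. With ``strict=True``
    a spec key absent from the VCF header raises
    :class:`ConfigurationError`; ``strict=False`` downgrades that to the
    field simply being absent on every variant.
    """
    unknown = set(annotation_spec) - _REQUIRED_SPEC_FIELDS
    if unknown:
        raise ConfigurationError(f"unknown annotation_spec fields: {sorted(unknown)}")

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if not samples:
        raise VcfFormatError(f"{path}: VCF has no samples (GT FORMAT required)")

    present_keys = set()
    for field_name, key in annotation_spec.items():
        try:
            vcf.get_header_type(key)
            present_keys.add(key)
        except KeyError:
            if strict:
                raise ConfigurationError(
                    f"{path}: INFO key {key!r} (for {field_name!r}) missing from VCF header"
                ) from None

    variants: list[AnnotatedVariant] = []
    dosage_cols: list[np.ndarray] = []

    for rec in vcf:
        gts = rec.genotypes  # [[a0, a1, phased], ...]
        if gts is None:
            raise VcfFormatError(f"{path}: record {rec.CHROM}:{rec.POS} lacks GT")
        n_alt = len(rec.ALT)
        for k, alt in enumerate(rec.ALT, start=1):
            fields: dict[str, Any] = {}
            for field_name, key in annotation_spec.items():
                if key not in present_keys:
                    continue
                val = rec.INFO.get(key)
                if field_name == "splice_affecting":
                    fields[field_name] = bool(val) if val is not None else False
                    continue
                if val is None:
                    continue
                val = _info_scalar(val, k - 1, n_alt)
                if val is None or val == ".":
                    continue
                if field_name in ("maf", "cadd_phred"):
                    fields[field_name] = float(val)
                elif field_name == "region_class":
                    fields[field_name] = RegionClass(str(val))
                elif field_name == "consequence_class":
                    fields[field_name] = ConsequenceClass(str(val))
                elif field_name == "sift_indel":
                    fields[field_name] = SiftIndel(str(val))
                elif field_name == "provean_indel":
                    fields[field_name] = ProveanIndel(str(val))
                else:
                    fields[field_name] = str(val)
            variant = AnnotatedVariant(
                chrom=rec.CHROM,
                pos=rec.POS,
                ref=rec.REF,
                alt=alt,
                gene=fields.pop("gene", ""),
                variant_id=rec.ID if rec.ID and n_alt == 1 else "",
                **fields,
            )
            col = np.empty(len(samples), dtype=np.int8)
            for i, gt in enumerate(gts):
                alleles = gt[:-1]  # strip phased flag
                if any(a < 0 for a in alleles):
                    col[i] = MISSING
                else:
                    col[i] = sum(1 for a in alleles if a == k)
            variants.append(variant)
            dosage_cols.append(col)
    vcf.close()

    ids = [v.variant_id for v in variants]
    if len(set(ids)) != len(ids):
        raise ValidationError(f"{path}: duplicate variant identities after decomposition")
    dosages = (
        np.column_stack(dosage_cols)
        if dosage_cols
        else np.zeros((len(samples), 0), dtype=np.int8)
    )
    matrix = GenotypeMatrix(sample_ids=samples, variant_ids=ids, dosages=dosages)
    return variants, matrix


# ---------------------------------------------------------------------------
# Candidate report output

#: column order of the candidate report (mirrors the field's candidate tables)
REPORT_COLUMNS = [
    "gene",
    "variant",
    "rs_number",
    "cosegregation",
    "bmd_gwas",
    "disease",
    "cadd",
    "sift_indel",
    "provean_indel",
    "maf",
    "evidence_score",
]


def write_candidates(
    rows: Sequence[Mapping[str, Any]],
    path: str | Path,
    fmt: str = "tsv",
) -> None:
    """Write the ranked candidate report as TSV (default) or JSON.

    ``rows`` are mappings carrying :data:`REPORT_COLUMNS` keys (missing keys
    are emitted as ``NA``); column order is fixed and deterministic.
    """
    path = Path(path)
    if fmt == "tsv":
        lines = ["\t".join(REPORT_COLUMNS)]
        for row in rows:
            lines.append(
                "\t".join(_format_cell(row.get(col)) for col in REPORT_COLUMNS)
            )
        path.write_text("\n".join(lines) + "\n")
    elif fmt == "json":
        payload = [
            {col: _jsonable(row.get(col)) for col in REPORT_COLUMNS} for row in rows
        ]
        path.write_text(json.dumps(payload, indent=2) + "\n")
    else:
        raise ConfigurationError(f"unknown report format {fmt!r}")


def _format_cell(value: Any) -> str:
    if value is None:
        return "NA"
    if isinstance(value, Enum):
        return value.value
    if isinstance(value, float):
        return format(value, "g")
    return str(value)


def _jsonable(value: Any) -> Any:
    if isinstance(value, Enum):
        return value.value
    return value
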