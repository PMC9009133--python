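"""Gene-level evidence annotation and candidate ranking.

The published screens of this kind prioritize surviving variants by manual
curation of gene function, animal-model phenotypes, human disease
associations and BMD GWAS hits. Here that judgment is formalized as an
explicit, reproducible scoring rule over a user-supplied gene-evidence
table: the evidence score is the *count of positive evidence categories*
(BMD GWAS association; human disease; knockout/animal phenotype; a curated
bone-function note), all weighted equally. Equal weights are a convention
of this package, not an empirical estimate.

Candidates are ranked by (evidence score desc, affected-sharing cell size
desc, CADD phred desc) with the gene name as the final tiebreak, giving a
deterministic total order.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping, Optional, Sequence

from .errors import ParseError, ValidationError
from .segregation import Partition, cell_label
from .variants import AnnotatedVariant

_NEGATIVE = {"", "N", "NA", "."}

EVIDENCE_COLUMNS = ["gene", "bmd_gwas", "disease", "ko_phenotype", "function_note"]


@dataclass(frozen=True)
class GeneEvidence:
    """Curated functional evidence for one gene."""

    gene: str
    bmd_gwas: str = "N"  # "Y" / "N"
    disease: str = "N"  # OMIM-style note, or "N"
    ko_phenotype: str = ""  # animal-model phenotype note
    function_note: str = ""  # bone-relevant function note

    def __post_init__(self) -> None:
        if not self.gene:
            raise ValidationError("GeneEvidence.gene must be non-empty")
        if self.bmd_gwas not in ("Y", "N"):
            raise ValidationError(f"bmd_gwas must be Y or N, got {self.bmd_gwas!r}")

    @property
    def evidence_score(self) -> int:
        """Number of positive evidence categories."""
        return sum(
            (
                self.bmd_gwas == "Y",
                self.disease not in _NEGATIVE,
                self.ko_phenotype not in _NEGATIVE,
                self.function_note not in _NEGATIVE,
            )
        )


def load_gene_evidence(path: str | Path) -> dict[str, GeneEvidence]:
    """Read a gene-evidence TSV into a mapping; duplicate genes are rejected.

    Columns: gene, bmd_gwas (Y/N), disease, ko_phenotype, function_note.
    A header line starting with ``#`` is optional.
    """
    path = Path(path)
    table: dict[str, GeneEvidence] = {}
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != len(EVIDENCE_COLUMNS):
            raise ParseError(
                f"{path.name} line {lineno}: expected {len(EVIDENCE_COLUMNS)} columns, "
                f"got {len(parts)}"
            )
        ev = GeneEvidence(*[p.strip() for p in parts])
        if ev.gene in table:
            raise ValidationError(f"{path.name} line {lineno}: duplicate gene {ev.gene!r}")
        table[ev.gene] = ev
    return table


def bundled_evidence_path() -> Path:
    """Path of the packaged evidence table for the six published candidate
    high-BMD genes (a worked example for the ranking rule)."""
    return Path(__file__).parent / "data" / "hbm_gene_evidence.tsv"


def annotate_and_rank(
    survivors: Sequence[AnnotatedVariant],
    partition: Partition,
    evidence: Mapping[str, GeneEvidence],
    rs_numbers: Optional[Mapping[str, str]] = None,
) -> list[dict[str, Any]]:
    """Join survivors with their sharing cell and gene evidence; rank.

    Genes absent from the evidence table score 0. Returns report rows in
    final rank order, shaped for :func:`famseg.variants.write_candidates`.
    """
    rows: list[tuple[tuple, dict[str, Any]]] = []
    for v in survivors:
        key = partition.cell_of(v.variant_id)
        ev = evidence.get(v.gene)
        score = ev.evidence_score if ev is not None else 0
        row = {
            "gene": v.gene,
            "variant": v.variant_id,
            "rs_number": (rs_numbers or {}).get(v.variant_id),
            "cosegregation": cell_label(key),
            "bmd_gwas": ev.bmd_gwas if ev else "N",
            "disease": ev.disease if ev else "N",
            "cadd": v.cadd_phred,
            "sift_indel": v.sift_indel,
            "provean_indel": v.provean_indel,
            "maf": v.maf,
            "evidence_score": score,
        }
        sort_key = (
            -score,
            -len(key),
            -(v.cadd_phred if v.cadd_phred is not None else float("-inf")),
            v.gene,
            v.variant_id,
        )
        rows.append((sort_key, row))
    rows.sort(key=lambda t: t[0])
    return [row for _, row in rows]
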