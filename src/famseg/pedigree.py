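"""Pedigree model and bone-mineral-density phenotype quantification.

The family is represented as a plain PED-style pedigree extended with two
DXA-derived BMD Z-scores per individual (lumbar spine and femoral neck).
Affection status is an *input* label: high-bone-mass (HBM) classification
from the Z-scores is advisory only and never overwrites the label, because
clinical affection calls in dominant-pedigree studies routinely override
fixed thresholds (e.g. a borderline relative called affected on family
context).

Two operational HBM criteria are supported:

* ``either_site`` — Z >= +2.5 at lumbar spine *or* femoral neck;
* ``sum_z``       — Z_LS + Z_FN strictly greater than 4.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional

from .errors import MissingDataError, ParseError, ValidationError

#: conventional PED marker for an absent (founder) parent
FOUNDER = "0"


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class Affection(str, Enum):
    AFFECTED = "affected"
    UNAFFECTED = "unaffected"
    UNKNOWN = "unknown"


class BmdClass(str, Enum):
    HBM = "hbm"
    NORMAL = "normal"


class BmdMode(str, Enum):
    EITHER_SITE = "either_site"
    SUM_Z = "sum_z"


# PED integer encodings <-> enums
_SEX_CODES = {"1": Sex.MALE, "2": Sex.FEMALE, "0": Sex.UNKNOWN}
_AFF_CODES = {"2": Affection.AFFECTED, "1": Affection.UNAFFECTED, "0": Affection.UNKNOWN}
_SEX_OUT = {Sex.MALE: "1", Sex.FEMALE: "2", Sex.UNKNOWN: "0"}
_AFF_OUT = {Affection.AFFECTED: "2", Affection.UNAFFECTED: "1", Affection.UNKNOWN: "0"}


@dataclass(frozen=True)
class Individual:
    """One pedigree member with optional BMD Z-scores (SD units)."""

    individual_id: str
    family_id: str
    father_id: str = FOUNDER
    mother_id: str = FOUNDER
    sex: Sex = Sex.UNKNOWN
    affected: Affection = Affection.UNKNOWN
    z_ls: Optional[float] = None
    z_fn: Optional[float] = None

    @property
    def is_founder(self) -> bool:
        return self.father_id == FOUNDER and self.mother_id == FOUNDER


@dataclass(frozen=True)
class BmdCriteria:
    """Operational thresholds for the high-bone-mass phenotype."""

    mode: BmdMode = BmdMode.EITHER_SITE
    either_site_threshold: float = 2.5
    sum_threshold: float = 4.0  # strict greater-than

    def __post_init__(self) -> None:
        import math

        if not (math.isfinite(self.either_site_threshold) and math.isfinite(self.sum_threshold)):
            raise ValidationError("BMD thresholds must be finite")


@dataclass
class Pedigree:
    """A validated family: members, parent links, and a proband anchor."""

    individuals: list[Individual]
    proband_id: str
    _index: dict[str, Individual] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._index = {}
        for ind in self.individuals:
            if ind.individual_id in self._index:
                raise ValidationError(
                    f"duplicate individual_id {ind.individual_id!r} in family {ind.family_id!r}"
                )
            self._index[ind.individual_id] = ind
        for ind in self.individuals:
            for pid in (ind.father_id, ind.mother_id):
                if pid != FOUNDER and pid not in self._index:
                    raise ValidationError(
                        f"{ind.individual_id!r} references absent parent {pid!r}"
                    )
        self._check_acyclic()
        if self.proband_id not in self._index:
            raise ValidationError(f"proband {self.proband_id!r} not in pedigree")
        if self.proband.affected is not Affection.AFFECTED:
            raise ValidationError(f"proband {self.proband_id!r} must be labeled affected")

    def _check_acyclic(self) -> None:
        # DFS over the parent graph; a back edge means someone is their own ancestor
        WHITE, GRAY, BLACK = 0, 1, 2
        color = {iid: WHITE for iid in self._index}

        def visit(iid: str) -> None:
            color[iid] = GRAY
            ind = self._index[iid]
            for pid in (ind.father_id, ind.mother_id):
                if pid == FOUNDER:
                    continue
                if color[pid] == GRAY:
                    raise ValidationError(f"pedigree cycle involving {pid!r}")
                if color[pid] == WHITE:
                    visit(pid)
            color[iid] = BLACK

        for iid in self._index:
            if color[iid] == WHITE:
                visit(iid)

    # -- convenience accessors -------------------------------------------------

    def __len__(self) -> int:
        return len(self.individuals)

    def __contains__(self, individual_id: str) -> bool:
        return individual_id in self._index

    def __getitem__(self, individual_id: str) -> Individual:
        try:
            return self._index[individual_id]
        except KeyError:
            raise KeyError(f"no individual {individual_id!r} in pedigree") from None

    @property
    def proband(self) -> Individual:
        return self._index[self.proband_id]

    @property
    def sample_ids(self) -> list[str]:
        return [ind.individual_id for ind in self.individuals]

    def affected_ids(self) -> set[str]:
        return {i.individual_id for i in self.individuals if i.affected is Affection.AFFECTED}

    def unaffected_ids(self) -> set[str]:
        return {i.individual_id for i in self.individuals if i.affected is Affection.UNAFFECTED}


# ---------------------------------------------------------------------------
# Phenotype quantification


def sum_z(ind: Individual) -> float:
    """Sum of lumbar-spine and femoral-neck BMD Z-scores.

    Raises :class:`MissingDataError` if either score is absent — a missing
    DXA measurement must never be silently treated as zero.
    """
    if ind.z_ls is None or ind.z_fn is None:
        raise MissingDataError(
            f"{ind.individual_id}: sum Z-score requires both LS and FN Z-scores"
        )
    return ind.z_ls + ind.z_fn


def classify_bmd(ind: Individual, criteria: BmdCriteria = BmdCriteria()) -> BmdClass:
    """Advisory HBM classification; never modifies the ``affected`` label.

    ``either_site`` mode calls HBM when either Z-score meets the threshold
    (>=); ``sum_z`` mode when the sum strictly exceeds the sum threshold.
    """
    if criteria.mode is BmdMode.EITHER_SITE:
        if ind.z_ls is None and ind.z_fn is None:
            raise MissingDataError(f"{ind.individual_id}: no Z-scores for either-site rule")
        hits = [
            z >= criteria.either_site_threshold
            for z in (ind.z_ls, ind.z_fn)
            if z is not None
        ]
        return BmdClass.HBM if any(hits) else BmdClass.NORMAL
    return BmdClass.HBM if sum_z(ind) > criteria.sum_threshold else BmdClass.NORMAL


# ---------------------------------------------------------------------------
# Extended-PED I/O
#
# Tab-separated columns:
#   family_id individual_id father_id mother_id sex(1/2/0) affected(2/1/0) z_ls z_fn
# "." marks a missing Z-score; an optional header line starts with "#".


def _parse_z(token: str, lineno: int, what: str) -> Optional[float]:
    if token == ".":
        return None
    try:
        return float(token)
    except ValueError:
        raise ParseError(f"line {lineno}: bad {what} value {token!r}") from None


def load_pedigree(path: str | Path, proband_id: Optional[str] = None) -> Pedigree:
    """Read an extended-PED file and return a validated :class:`Pedigree`.

    If ``proband_id`` is not given, the first affected individual is taken
    as proband.
    """
    path = Path(path)
    individuals: list[Individual] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 8:
            raise ParseError(
                f"{path.name} line {lineno}: expected 8 tab-separated fields, got {len(fields)}"
            )
        fam, iid, fid, mid, sex, aff, zls, zfn = fields
        if sex not in _SEX_CODES:
            raise ParseError(f"{path.name} line {lineno}: bad sex code {sex!r}")
        if aff not in _AFF_CODES:
            raise ParseError(f"{path.name} line {lineno}: bad affection code {aff!r}")
        individuals.append(
            Individual(
                individual_id=iid,
                family_id=fam,
                father_id=fid,
                mother_id=mid,
                sex=_SEX_CODES[sex],
                affected=_AFF_CODES[aff],
                z_ls=_parse_z(zls, lineno, "z_ls"),
                z_fn=_parse_z(zfn, lineno, "z_fn"),
            )
        )
    if not individuals:
        raise ParseError(f"{path.name}: no pedigree rows")
    if proband_id is None:
        affected = [i for i in individuals if i.affected is Affection.AFFECTED]
        if not affected:
            raise ValidationError(f"{path.name}: no affected individual to anchor as proband")
        proband_id = affected[0].individual_id
    return Pedigree(individuals=individuals, proband_id=proband_id)


def write_pedigree(ped: Pedigree, path: str | Path) -> None:
    """Write the extended-PED dialect read by :func:`load_pedigree`."""
    path = Path(path)
    lines = ["#family_id\tindividual_id\tfather_id\tmother_id\tsex\taffected\tz_ls\tz_fn"]
    for ind in ped.individuals:
        z1 = "." if ind.z_ls is None else format(ind.z_ls, "g")
        z2 = "." if ind.z_fn is None else format(ind.z_fn, "g")
        lines.append(
            "\t".join(
                [
                    ind.family_id,
                    ind.individual_id,
                    ind.father_id,
                    ind.mother_id,
                    _SEX_OUT[ind.sex],
                    _AFF_OUT[ind.affected],
                    z1,
                    z2,
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n")


def hbm_study_pedigree() -> Pedigree:
    """The six-member study family: a proband, her affected mother and
    daughter, and three unaffected relatives (brother and two daughters).

    Z-scores are the published DXA values; the two married-in fathers were
    not sampled and appear as founder markers.
    """
    F = "FAM1"
    rows = [
        Individual("I.1", F, FOUNDER, FOUNDER, Sex.FEMALE, Affection.AFFECTED, 3.3, 2.2),
        Individual("II.1", F, FOUNDER, "I.1", Sex.MALE, Affection.UNAFFECTED, -0.1, 1.0),
        Individual("II.5", F, FOUNDER, "I.1", Sex.FEMALE, Affection.AFFECTED, 4.6, 2.4),
        Individual("III.1", F, FOUNDER, "II.5", Sex.FEMALE, Affection.AFFECTED, 1.3, 2.2),
        Individual("III.2", F, FOUNDER, "II.5", Sex.FEMALE, Affection.UNAFFECTED, -0.2, 0.7),
        Individual("III.3", F, FOUNDER, "II.5", Sex.FEMALE, Affection.UNAFFECTED, -0.4, -0.4),
    ]
    return Pedigree(individuals=rows, proband_id="II.5")


def pedigree_report(ped: Pedigree, criteria: BmdCriteria = BmdCriteria()) -> list[dict]:
    """Per-individual echo of the pedigree with the advisory BMD class.

    The ``affected`` input label and the advisory ``bmd_class`` column are
    reported side by side so disagreements are visible, not resolved.
    """
    rows = []
    for ind in ped.individuals:
        try:
            sz: Optional[float] = sum_z(ind)
        except MissingDataError:
            sz = None
        try:
            cls: Optional[str] = classify_bmd(ind, criteria).value
        except MissingDataError:
            cls = None
        rows.append(
            {
                "individual_id": ind.individual_id,
                "affected": ind.affected.value,
                "z_ls": ind.z_ls,
                "z_fn": ind.z_fn,
                "sum_z": sz,
                "bmd_class": cls,
            }
        )
    return rows


def copy_with_scores(ind: Individual, z_ls: float, z_fn: float) -> Individual:
    """Convenience for tests and simulations: replace the Z-scores."""
    return replace(ind, z_ls=z_ls, z_fn=z_fn)
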