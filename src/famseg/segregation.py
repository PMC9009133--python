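"""Dominant presence/absence filtering, affected-sharing partition, and
additive two-locus candidate pairs.

The core screen for a dominant trait in a small pedigree: keep variants
carried by the proband and absent (homozygous reference) from every
unaffected relative. Survivors are then partitioned by *which* affected
members carry them — with three affected members (proband included) there
are exactly four possible cells. Cells that individually fail to cover all
affected members can still jointly explain the trait: an *additive pair* is
two variants from distinct non-universal cells whose carrier sets together
cover every affected individual, the classic digenic pattern where the
proband carries both variants and each other affected member carries one.

No cosegregation statistic is computed (no LOD score): with a single small
family the pattern itself, not its probability, is the object of interest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence

from .errors import ValidationError
from .pedigree import Pedigree
from .variants import GenotypeMatrix, MISSING


class PresenceRule(str, Enum):
    ANY_ALT = "any_alt"  # dosage 1 or 2 counts as carrying
    HET_ONLY = "het_only"  # only dosage 1 counts


class MissingInUnaffected(str, Enum):
    TREAT_ABSENT = "treat_absent"
    DISQUALIFY = "disqualify"


class MissingInAffected(str, Enum):
    TREAT_ABSENT = "treat_absent"
    TREAT_PRESENT_UNKNOWN = "treat_present_unknown"


@dataclass(frozen=True)
class SegregationPolicy:
    """How genotype presence and missingness are interpreted.

    Defaults are conservative for a rare dominant model: any non-reference
    dosage counts as carrying, and a missing genotype in an unaffected
    member disqualifies the variant (absence cannot be certified).
    """

    presence_rule: PresenceRule = PresenceRule.ANY_ALT
    missing_in_unaffected: MissingInUnaffected = MissingInUnaffected.DISQUALIFY
    missing_in_affected: MissingInAffected = MissingInAffected.TREAT_ABSENT


@dataclass
class Partition:
    """Map from affected-carrier subset to the surviving variants in it.

    Keys are frozensets of affected individual ids; every key contains the
    proband by construction of the dominant presence filter. Cells are
    disjoint and jointly exhaust ``universe``.
    """

    cells: dict[frozenset[str], list[str]]
    universe: list[str]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for key, vids in self.cells.items():
            overlap = seen & set(vids)
            if overlap:
                raise ValidationError(f"partition cells overlap on {sorted(overlap)}")
            seen.update(vids)
        if seen != set(self.universe):
            raise ValidationError("partition cells do not exhaust the universe")

    def cell_counts(self) -> dict[frozenset[str], int]:
        return {k: len(v) for k, v in self.cells.items()}

    def cell_of(self, variant_id: str) -> frozenset[str]:
        for key, vids in self.cells.items():
            if variant_id in vids:
                return key
        raise KeyError(f"variant {variant_id!r} not in partition")

    def label(self, key: frozenset[str]) -> str:
        return cell_label(key)


def cell_label(key: Iterable[str]) -> str:
    """Serialize an affected-subset key as a sorted, comma-joined id list."""
    return ",".join(sorted(key))


@dataclass(frozen=True)
class CandidatePair:
    """Two variants whose affected carrier sets jointly cover all affected."""

    variant_a: str
    variant_b: str
    carriers_a: frozenset[str]
    carriers_b: frozenset[str]
    covered: frozenset[str]
    pattern_label: str


# ---------------------------------------------------------------------------


def carrier_set(
    variant_id: str,
    genotypes: GenotypeMatrix,
    policy: SegregationPolicy = SegregationPolicy(),
) -> set[str]:
    """Samples carrying ``variant_id`` under the policy's presence rule.

    Missing dosages never place a sample in the carrier set; how missing
    data affects the dominant filter is handled in
    :func:`dominant_presence`, not here.
    """
    dosages = genotypes.variant_dosages(variant_id)
    if policy.presence_rule is PresenceRule.ANY_ALT:
        wanted = (1, 2)
    else:
        wanted = (1,)
    return {s for s, d in dosages.items() if d in wanted}


def dominant_presence(
    variant_id: str,
    genotypes: GenotypeMatrix,
    ped: Pedigree,
    policy: SegregationPolicy = SegregationPolicy(),
) -> bool:
    """True iff the proband carries the variant and no unaffected member does.

    A missing proband genotype fails the filter under the default
    ``missing_in_affected=treat_absent`` policy (presence cannot be
    certified). A missing genotype in an unaffected member fails it under
    ``missing_in_unaffected=disqualify``.
    """
    dosages = genotypes.variant_dosages(variant_id)
    carriers = carrier_set(variant_id, genotypes, policy)

    proband = ped.proband_id
    if dosages[proband] == MISSING:
        if policy.missing_in_affected is MissingInAffected.TREAT_ABSENT:
            return False
        # treat_present_unknown: give the proband the benefit of the doubt
    elif proband not in carriers:
        return False

    for uid in ped.unaffected_ids():
        d = dosages.get(uid, MISSING)
        if d == MISSING:
            if policy.missing_in_unaffected is MissingInUnaffected.DISQUALIFY:
                return False
            continue  # treat_absent
        if uid in carriers:
            return False
    return True


def partition_by_sharing(
    survivors: Sequence[str],
    genotypes: GenotypeMatrix,
    ped: Pedigree,
    policy: SegregationPolicy = SegregationPolicy(),
) -> Partition:
    """Assign each surviving variant to its affected-carrier subset cell.

    ``survivors`` must all have passed :func:`dominant_presence`; a survivor
    whose affected carrier set lacks the proband indicates an upstream bug
    and raises :class:`ValidationError`.
    """
    affected = ped.affected_ids()
    proband = ped.proband_id
    cells: dict[frozenset[str], list[str]] = {}
    for vid in survivors:
        carriers = carrier_set(vid, genotypes, policy)
        if (
            genotypes.variant_dosages(vid)[proband] == MISSING
            and policy.missing_in_affected is MissingInAffected.TREAT_PRESENT_UNKNOWN
        ):
            carriers.add(proband)
        key = frozenset(carriers & affected)
        if proband not in key:
            raise ValidationError(
                f"survivor {vid!r} is not carried by the proband — "
                "inconsistent with the dominant presence filter"
            )
        cells.setdefault(key, []).append(vid)
    return Partition(cells=cells, universe=list(survivors))


def additive_pairs(partition: Partition, ped: Pedigree) -> list[CandidatePair]:
    """All unordered variant pairs from distinct cells that jointly cover the
    affected set while neither cell does alone.

    Output is deterministically sorted by variant id, so it is invariant
    under the input ordering of survivors.
    """
    affected = frozenset(ped.affected_ids())
    # cells that are informative for pairing: miss at least one affected member
    partial = [
        (key, vids) for key, vids in partition.cells.items() if key != affected
    ]
    pairs: list[CandidatePair] = []
    for i in range(len(partial)):
        key_a, vids_a = partial[i]
        for j in range(i + 1, len(partial)):
            key_b, vids_b = partial[j]
            if key_a | key_b != affected:
                continue
            for va in vids_a:
                for vb in vids_b:
                    a, b = sorted((va, vb))
                    ka, kb = (key_a, key_b) if a == va else (key_b, key_a)
                    pairs.append(
                        CandidatePair(
                            variant_a=a,
                            variant_b=b,
                            carriers_a=ka,
                            carriers_b=kb,
                            covered=affected,
                            pattern_label=f"{cell_label(ka)} | {cell_label(kb)}",
                        )
                    )
    pairs.sort(key=lambda p: (p.variant_a, p.variant_b))
    return pairs
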