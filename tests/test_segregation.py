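"""Dominant presence, affected-sharing partition, and additive pairs,
cross-checked against independent brute-force enumeration."""

import itertools

import numpy as np
import pytest

from famseg.errors import ValidationError
from famseg.pedigree import Affection, Individual, Pedigree, Sex
from famseg.segregation import (
    MissingInAffected,
    MissingInUnaffected,
    Partition,
    PresenceRule,
    SegregationPolicy,
    additive_pairs,
    carrier_set,
    cell_label,
    dominant_presence,
    partition_by_sharing,
)
from famseg.variants import MISSING, GenotypeMatrix

POLICY = SegregationPolicy()
SAMPLES = ["I.1", "II.1", "II.5", "III.1", "III.2", "III.3"]


def matrix(columns: dict[str, list[int]], samples=SAMPLES) -> GenotypeMatrix:
    ids = list(columns)
    dosages = np.array([[columns[v][i] for v in ids] for i in range(len(samples))], dtype=np.int8)
    return GenotypeMatrix(samples, ids, dosages)


class TestCarrierSet:
    def test_direct_rule(self, study_pedigree):
        gm = matrix({"v": [0, 0, 1, 1, 0, 0]})
        assert carrier_set("v", gm, POLICY) == {"II.5", "III.1"}

    def test_all_zero(self):
        gm = matrix({"v": [0, 0, 0, 0, 0, 0]})
        assert carrier_set("v", gm, POLICY) == set()

    def test_het_only_excludes_hom_alt(self):
        gm = matrix({"v": [0, 0, 2, 1, 0, 0]})
        het_only = SegregationPolicy(presence_rule=PresenceRule.HET_ONLY)
        assert carrier_set("v", gm, het_only) == {"III.1"}
        assert carrier_set("v", gm, POLICY) == {"II.5", "III.1"}


class TestDominantPresence:
    def test_proband_het_unaffected_ref(self, study_pedigree):
        gm = matrix({"v": [1, 0, 1, 0, 0, 0]})
        assert dominant_presence("v", gm, study_pedigree, POLICY)

    def test_unaffected_carrier_fails(self, study_pedigree):
        # carried by the proband but also by unaffected II.1
        gm = matrix({"v": [0, 1, 1, 0, 0, 0]})
        assert not dominant_presence("v", gm, study_pedigree, POLICY)

    def test_proband_without_variant_fails(self, study_pedigree):
        # the filter is proband-anchored: the mother alone is not enough
        gm = matrix({"v": [1, 0, 0, 0, 0, 0]})
        assert not dominant_presence("v", gm, study_pedigree, POLICY)

    def test_missing_unaffected_genotype_policies(self, study_pedigree):
        gm = matrix({"v": [0, MISSING, 1, 0, 0, 0]})
        assert not dominant_presence("v", gm, study_pedigree, POLICY)  # disqualify
        lenient = SegregationPolicy(
            missing_in_unaffected=MissingInUnaffected.TREAT_ABSENT
        )
        assert dominant_presence("v", gm, study_pedigree, lenient)

    def test_missing_proband_genotype_policies(self, study_pedigree):
        gm = matrix({"v": [0, 0, MISSING, 1, 0, 0]})
        assert not dominant_presence("v", gm, study_pedigree, POLICY)  # treat_absent
        optimistic = SegregationPolicy(
            missing_in_affected=MissingInAffected.TREAT_PRESENT_UNKNOWN
        )
        assert dominant_presence("v", gm, study_pedigree, optimistic)


class TestPartition:
    def test_four_singleton_cells(self, study_pedigree):
        gm = matrix(
            {
                "v_all": [1, 0, 1, 1, 0, 0],
                "v_mother": [1, 0, 1, 0, 0, 0],
                "v_daughter": [0, 0, 1, 1, 0, 0],
                "v_only": [0, 0, 1, 0, 0, 0],
            }
        )
        part = partition_by_sharing(list(gm.variant_ids), gm, study_pedigree, POLICY)
        counts = {tuple(sorted(k)): n for k, n in part.cell_counts().items()}
        assert counts == {
            ("I.1", "II.5", "III.1"): 1,
            ("I.1", "II.5"): 1,
            ("II.5", "III.1"): 1,
            ("II.5",): 1,
        }

    def test_single_cell_when_fully_shared(self, study_pedigree):
        gm = matrix({"a": [1, 0, 1, 1, 0, 0], "b": [1, 0, 1, 1, 0, 0]})
        part = partition_by_sharing(["a", "b"], gm, study_pedigree, POLICY)
        assert set(part.cells) == {frozenset({"I.1", "II.5", "III.1"})}
        assert sorted(part.universe) == ["a", "b"]

    def test_survivor_without_proband_is_internal_error(self, study_pedigree):
        gm = matrix({"v": [1, 0, 0, 0, 0, 0]})
        with pytest.raises(ValidationError, match="proband"):
            partition_by_sharing(["v"], gm, study_pedigree, POLICY)

    def test_cells_disjoint_and_exhaustive_enforced(self):
        with pytest.raises(ValidationError, match="overlap"):
            Partition(cells={frozenset({"p"}): ["v"], frozenset({"p", "a"}): ["v"]}, universe=["v"])
        with pytest.raises(ValidationError, match="exhaust"):
            Partition(cells={frozenset({"p"}): ["v"]}, universe=["v", "w"])


class TestAdditivePairs:
    def test_two_locus_configuration(self, study_pedigree):
        """One {proband, mother} variant plus one {proband, daughter} variant
        covers all three affected members: the classic digenic pattern."""
        gm = matrix({"v1": [1, 0, 1, 0, 0, 0], "v2": [0, 0, 1, 1, 0, 0]})
        part = partition_by_sharing(["v1", "v2"], gm, study_pedigree, POLICY)
        pairs = additive_pairs(part, study_pedigree)
        assert len(pairs) == 1
        (p,) = pairs
        assert {p.variant_a, p.variant_b} == {"v1", "v2"}
        assert p.covered == frozenset({"I.1", "II.5", "III.1"})
        assert p.carriers_a | p.carriers_b == p.covered
        assert p.pattern_label == "I.1,II.5 | II.5,III.1"

    def test_proband_only_cell_cannot_pair(self, study_pedigree):
        gm = matrix({"v1": [0, 0, 1, 0, 0, 0], "v2": [0, 0, 1, 0, 0, 0]})
        part = partition_by_sharing(["v1", "v2"], gm, study_pedigree, POLICY)
        assert additive_pairs(part, study_pedigree) == []

    def test_universal_cell_never_pairs(self, study_pedigree):
        gm = matrix({"v_all": [1, 0, 1, 1, 0, 0], "v_m": [1, 0, 1, 0, 0, 0]})
        part = partition_by_sharing(["v_all", "v_m"], gm, study_pedigree, POLICY)
        assert additive_pairs(part, study_pedigree) == []

    def test_order_invariance(self, study_pedigree):
        cols = {
            "b": [1, 0, 1, 0, 0, 0],
            "a": [0, 0, 1, 1, 0, 0],
            "c": [1, 0, 1, 0, 0, 0],
        }
        gm = matrix(cols)
        for order in itertools.permutations(cols):
            part = partition_by_sharing(list(order), gm, study_pedigree, POLICY)
            pairs = additive_pairs(part, study_pedigree)
            assert [(p.variant_a, p.variant_b) for p in pairs] == [("a", "b"), ("a", "c")]


# ---------------------------------------------------------------------------
# Brute-force oracles


def brute_force_partition(survivors, gm, ped):
    """Naive per-sample recomputation of each variant's affected cell."""
    affected = {i.individual_id for i in ped.individuals if i.affected is Affection.AFFECTED}
    cells = {}
    for vid in survivors:
        carriers = set()
        for s in gm.sample_ids:
            if gm.dosage(s, vid) in (1, 2):
                carriers.add(s)
        cells.setdefault(frozenset(carriers & affected), []).append(vid)
    return cells


def brute_force_pairs(survivors, gm, ped):
    """O(n^2) enumeration over all variant pairs from affected carrier sets."""
    affected = {i.individual_id for i in ped.individuals if i.affected is Affection.AFFECTED}

    def aff_carriers(vid):
        return frozenset(
            s for s in gm.sample_ids if gm.dosage(s, vid) in (1, 2)
        ) & affected

    out = []
    for va, vb in itertools.combinations(sorted(survivors), 2):
        ca, cb = aff_carriers(va), aff_carriers(vb)
        if ca != affected and cb != affected and (ca | cb) == affected:
            out.append((va, vb))
    return sorted(out)


def random_instance(rng, max_samples=8, max_variants=64):
    """A random pedigree-free instance: random affection labels + dosages."""
    n_samples = rng.integers(3, max_samples + 1)
    n_variants = rng.integers(1, max_variants + 1)
    samples = [f"s{i}" for i in range(n_samples)]
    # proband affected; everyone else random
    labels = [Affection.AFFECTED] + [
        Affection.AFFECTED if rng.random() < 0.5 else Affection.UNAFFECTED
        for _ in range(n_samples - 1)
    ]
    ped = Pedigree(
        individuals=[
            Individual(s, "F", sex=Sex.UNKNOWN, affected=lab)
            for s, lab in zip(samples, labels)
        ],
        proband_id="s0",
    )
    dosages = rng.choice([0, 1, 2], size=(n_samples, n_variants), p=[0.7, 0.25, 0.05])
    gm = GenotypeMatrix(samples, [f"v{j}" for j in range(n_variants)], dosages.astype(np.int8))
    return ped, gm


def select_survivors(ped, gm):
    """Brute-force dominant presence: proband carries, no unaffected does."""
    unaffected = {i.individual_id for i in ped.individuals if i.affected is Affection.UNAFFECTED}
    out = []
    for vid in gm.variant_ids:
        if gm.dosage(ped.proband_id, vid) not in (1, 2):
            continue
        if any(gm.dosage(u, vid) in (1, 2) for u in unaffected):
            continue
        out.append(vid)
    return out


@pytest.mark.parametrize("n_instances,seed", [(60, 20240601)])
def test_partition_and_pairs_match_brute_force(n_instances, seed):
    rng = np.random.default_rng(seed)
    for _ in range(n_instances):
        ped, gm = random_instance(rng)
        survivors = select_survivors(ped, gm)
        part = partition_by_sharing(survivors, gm, ped, POLICY)
        assert {k: sorted(v) for k, v in part.cells.items()} == {
            k: sorted(v) for k, v in brute_force_partition(survivors, gm, ped).items()
        }
        got = sorted((p.variant_a, p.variant_b) for p in additive_pairs(part, ped))
        assert got == brute_force_pairs(survivors, gm, ped)
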