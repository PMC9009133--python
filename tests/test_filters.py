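"""The annotation filter cascade: per-stage predicates, ordering, trace."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from famseg.filters import (
    ConstraintMetric,
    FilterConfig,
    IndelRule,
    MissingAnnotationPolicy,
    constraint_filter,
    frequency_filter,
    load_gene_constraint,
    pathogenicity_filter,
    region_consequence_filter,
    run_cascade,
)
from famseg.pedigree import hbm_study_pedigree
from famseg.variants import (
    AnnotatedVariant,
    ConsequenceClass,
    GenotypeMatrix,
    ProveanIndel,
    RegionClass,
    SiftIndel,
)

CFG = FilterConfig()


def snv(**kwargs):
    base = dict(
        chrom="S1",
        pos=kwargs.pop("pos", 100),
        ref="A",
        alt="G",
        gene=kwargs.pop("gene", "GENE1"),
        region_class=RegionClass.CODING,
        consequence_class=ConsequenceClass.MISSENSE,
    )
    base.update(kwargs)
    return AnnotatedVariant(**base)


def indel(**kwargs):
    kwargs.setdefault("ref", "AT")
    kwargs.setdefault("alt", "A")
    return snv(**kwargs)


class TestRegionConsequence:
    @pytest.mark.parametrize(
        "region,csq,splice,keep",
        [
            (RegionClass.CODING, ConsequenceClass.MISSENSE, False, True),
            (RegionClass.CODING, ConsequenceClass.SYNONYMOUS, False, False),
            (RegionClass.INTRONIC, ConsequenceClass.OTHER, True, True),
            (RegionClass.INTRONIC, ConsequenceClass.OTHER, False, False),
            (RegionClass.INTERGENIC, ConsequenceClass.OTHER, False, False),
            (RegionClass.UTR5, ConsequenceClass.OTHER, False, False),
            (RegionClass.UTR3, ConsequenceClass.OTHER, False, False),
            (RegionClass.UPSTREAM, ConsequenceClass.OTHER, False, False),
            (RegionClass.DOWNSTREAM, ConsequenceClass.OTHER, False, False),
            (RegionClass.NCRNA, ConsequenceClass.OTHER, False, False),
            (RegionClass.UNKNOWN, ConsequenceClass.OTHER, False, False),
            (RegionClass.CODING, ConsequenceClass.NONSENSE, False, True),
        ],
    )
    def test_rules(self, region, csq, splice, keep):
        v = snv(region_class=region, consequence_class=csq, splice_affecting=splice)
        assert region_consequence_filter(v, CFG) is keep


class TestFrequency:
    #: published candidate MAFs — all rare enough for the 0.005 cutoff
    CANDIDATE_MAFS = [0.00015, 0.00013, 0.00238, 0.00268, 0.00401]

    @pytest.mark.parametrize("maf", CANDIDATE_MAFS)
    def test_published_candidates_pass(self, maf):
        assert frequency_filter(snv(maf=maf), CFG)

    @pytest.mark.parametrize(
        "maf,keep", [(0.005, True), (0.006, False), (0.5, False), (None, True)]
    )
    def test_threshold_and_missing(self, maf, keep):
        assert frequency_filter(snv(maf=maf), CFG) is keep


class TestPathogenicity:
    #: published candidate CADD scores — all at or above the 20 cutoff
    CANDIDATE_CADD = [23.1, 22.8, 24.4, 26.4, 28.0, 28.1]

    @pytest.mark.parametrize("cadd", CANDIDATE_CADD)
    def test_published_candidates_pass(self, cadd):
        assert pathogenicity_filter(snv(cadd_phred=cadd), CFG)

    @pytest.mark.parametrize("cadd,keep", [(20.0, True), (19.9, False), (0.0, False)])
    def test_snv_threshold(self, cadd, keep):
        assert pathogenicity_filter(snv(cadd_phred=cadd), CFG) is keep

    def test_indel_rule_truth_table(self):
        """Enumerate all four predictor combinations under both indel rules
        and compare to the rule stated in words: either_damaging keeps a
        variant with at least one damaging call; both_damaging needs both."""
        for sift, provean in itertools.product(
            [SiftIndel.DAMAGING, SiftIndel.NEUTRAL],
            [ProveanIndel.DELETERIOUS, ProveanIndel.NEUTRAL],
        ):
            v = indel(sift_indel=sift, provean_indel=provean)
            damaging = [sift is SiftIndel.DAMAGING, provean is ProveanIndel.DELETERIOUS]
            either = FilterConfig(indel_rule=IndelRule.EITHER_DAMAGING)
            both = FilterConfig(indel_rule=IndelRule.BOTH_DAMAGING)
            assert pathogenicity_filter(v, either) is any(damaging)
            assert pathogenicity_filter(v, both) is all(damaging)

    def test_missing_annotation_policy(self):
        keep = FilterConfig(missing_annotation_policy=MissingAnnotationPolicy.KEEP)
        drop = FilterConfig(missing_annotation_policy=MissingAnnotationPolicy.DROP)
        unscored_snv = snv()
        unscored_indel = indel()
        assert pathogenicity_filter(unscored_snv, keep)
        assert not pathogenicity_filter(unscored_snv, drop)
        assert pathogenicity_filter(unscored_indel, keep)
        assert not pathogenicity_filter(unscored_indel, drop)
        # one available predictor decides under either_damaging
        half = indel(sift_indel=SiftIndel.DAMAGING)
        assert pathogenicity_filter(half, keep)
        assert pathogenicity_filter(half, drop)


class TestConstraint:
    TABLE = {"ENRICHED": 1.5, "NEUTRAL": 1.0}

    def test_oe_rule(self):
        cfg = FilterConfig(constraint_threshold=1.2)
        assert not constraint_filter(snv(gene="ENRICHED"), self.TABLE, cfg)
        assert constraint_filter(snv(gene="NEUTRAL"), self.TABLE, cfg)
        assert constraint_filter(snv(gene="UNLISTED"), self.TABLE, cfg)

    def test_z_mode_enrichment_is_low(self):
        cfg = FilterConfig(
            constraint_metric=ConstraintMetric.MISSENSE_Z, constraint_threshold=-2.0
        )
        assert not constraint_filter(snv(gene="G"), {"G": -3.0}, cfg)
        assert constraint_filter(snv(gene="G"), {"G": 1.0}, cfg)

    def test_load_table(self, tmp_path):
        p = tmp_path / "c.tsv"
        p.write_text("# header\nA\t1.5\nB\t0.8\n")
        assert load_gene_constraint(p) == {"A": 1.5, "B": 0.8}
        p.write_text("A\t1.5\nA\t0.8\n")
        with pytest.raises(Exception, match="duplicate"):
            load_gene_constraint(p)


# ---------------------------------------------------------------------------
# Whole-cascade properties

variant_strategy = st.builds(
    snv,
    pos=st.integers(1, 10_000),
    gene=st.sampled_from(["ENRICHED", "NEUTRAL", "UNLISTED", "OTHER"]),
    region_class=st.sampled_from(list(RegionClass)),
    consequence_class=st.sampled_from(list(ConsequenceClass)),
    splice_affecting=st.booleans(),
    maf=st.one_of(st.none(), st.floats(0, 1, allow_nan=False)),
    cadd_phred=st.one_of(st.none(), st.floats(0, 50, allow_nan=False)),
    sift_indel=st.one_of(st.none(), st.sampled_from(list(SiftIndel))),
    provean_indel=st.one_of(st.none(), st.sampled_from(list(ProveanIndel))),
)


@given(st.lists(variant_strategy, max_size=30), st.randoms(use_true_random=False))
def test_annotation_filters_are_order_invariant(variants, rnd):
    """The four annotation predicates are independent per-variant functions:
    any application order selects the same survivor set."""
    table = {"ENRICHED": 1.5, "NEUTRAL": 0.9}
    preds = [
        lambda v: region_consequence_filter(v, CFG),
        lambda v: frequency_filter(v, CFG),
        lambda v: pathogenicity_filter(v, CFG),
        lambda v: constraint_filter(v, table, CFG),
    ]
    reference = [v for v in variants if all(p(v) for p in preds)]
    shuffled = list(preds)
    rnd.shuffle(shuffled)
    survivors = list(variants)
    for p in shuffled:
        survivors = [v for v in survivors if p(v)]
    assert [v.variant_id for v in survivors] == [v.variant_id for v in reference]


@given(
    st.lists(variant_strategy, max_size=30),
    st.floats(0, 50, allow_nan=False),
    st.floats(0.001, 1.0, allow_nan=False),
)
def test_threshold_monotonicity(variants, cadd_min, maf_max):
    """Loosening cadd_min or maf_max never shrinks the survivor set."""
    tight = FilterConfig(cadd_min=cadd_min, maf_max=maf_max)
    loose = FilterConfig(cadd_min=max(cadd_min - 5, 0), maf_max=min(maf_max * 2, 1.0))

    def survivors(cfg):
        return {
            v.variant_id
            for v in variants
            if frequency_filter(v, cfg) and pathogenicity_filter(v, cfg)
        }

    assert survivors(tight) <= survivors(loose)


def _trivial_genotypes(variants, ped):
    """All variants het in the proband only (pass dominant presence)."""
    ids = [v.variant_id for v in variants]
    dosages = np.zeros((len(ped.sample_ids), len(ids)), dtype=np.int8)
    dosages[ped.sample_ids.index(ped.proband_id), :] = 1
    return GenotypeMatrix(ped.sample_ids, ids, dosages)


@given(st.lists(variant_strategy, unique_by=lambda v: v.variant_id, max_size=30))
def test_trace_conservation(variants):
    """Total input = survivors + dropped, and no id is dropped twice."""
    ped = hbm_study_pedigree()
    gm = _trivial_genotypes(variants, ped)
    survivors, trace = run_cascade(
        variants, gm, ped, CFG, gene_constraint={"ENRICHED": 1.5}
    )
    dropped = trace.all_dropped()
    assert len(dropped) == len(set(dropped))
    assert len(variants) - len(survivors) == len(dropped)
    assert trace.stages[0].n_in == len(variants)
    assert trace.stages[-1].n_out == len(survivors)
    for prev, nxt in zip(trace.stages, trace.stages[1:]):
        assert prev.n_out == nxt.n_in


def test_empty_cascade(study_pedigree):
    gm = _trivial_genotypes([], study_pedigree)
    survivors, trace = run_cascade([], gm, study_pedigree, CFG)
    assert survivors == []
    assert all(s.n_in == s.n_out == 0 for s in trace.stages)


def test_neutral_filters_pass_everything_coding(study_pedigree):
    """With thresholds wide open, only the dominant presence stage filters."""
    cfg = FilterConfig(
        maf_max=1.0,
        cadd_min=0.0,
        excluded_region_classes=frozenset(),
        exclude_synonymous=False,
        intronic_requires_splice_flag=False,
        missing_annotation_policy=MissingAnnotationPolicy.KEEP,
    )
    variants = [snv(pos=i, maf=0.4, cadd_phred=1.0) for i in range(1, 21)]
    gm = _trivial_genotypes(variants, study_pedigree)
    survivors, trace = run_cascade(variants, gm, study_pedigree, cfg)
    assert len(survivors) == trace.stages[0].n_out == 20
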