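# Methods

## Phenotype model

Bone mineral density is summarized per individual by two DXA Z-scores
(lumbar spine, femoral neck; SD units relative to an age/sex-matched
reference). Two operational high-bone-mass (HBM) criteria are implemented:

* **either-site**: `Z_LS >= t` or `Z_FN >= t`, default `t = +2.5`
  (inclusive, per the convention "Z ≥ +2.5");
* **sum**: `Z_LS + Z_FN > s`, default `s = 4` (strict, per "greater than
  four").

Affection status is an input column of the pedigree file and is treated as
authoritative. The classifier is advisory: clinical affection calls in
small dominant pedigrees legitimately override fixed thresholds (a
borderline relative with sum Z = 3.5 may be called affected given two
clearly affected relatives), and no formal override rule exists, so the
pipeline reports both and encodes neither judgment. Missing Z-scores raise
an explicit error; they are never imputed as zero.

The pedigree is a standard PED structure extended with the two Z-score
columns; absent parents use the conventional founder marker `0`. Parent
references must resolve and the parent graph must be acyclic; the proband
must be labeled affected.

## Filter cascade

Stage order: dominant presence → region/consequence → frequency →
pathogenicity → gene constraint. The four annotation stages are
independent per-variant predicates, so the surviving *set* does not depend
on their order (property-tested); only the per-stage trace counts do. The
trace records `(n_in, n_out, dropped ids)` per stage and is written as
JSON.

Parameters and defaults:

| parameter | default | rationale |
| --- | --- | --- |
| `maf_max` | 0.005 | rare-variant cutoff for a dominant HBM model |
| `cadd_min` | 20 | CADD phred scale: top ~1% of deleteriousness |
| excluded regions | intergenic, UTR5/3, up/downstream, ncRNA, unknown | coding hypothesis |
| intronic rule | keep only if splice-affecting | splice predictions rescue intronics |
| `exclude_synonymous` | true | protein-altering hypothesis |
| `indel_rule` | `either_damaging` | see below |
| constraint metric | missense o/e, drop if > 1.0 | see below |
| missing annotations | keep | missing data must not silently discard candidates |

**Dominant presence.** A variant passes iff the proband carries it and no
unaffected member does. "Carries" defaults to any non-reference dosage
(`any_alt`); a `het_only` rule is available but not default, since the
screen never distinguishes het from hom-alt and a rare dominant allele is
expected het. A missing genotype in an unaffected member disqualifies the
variant by default (absence cannot be certified); this is configurable for
fully-genotyped data sets. Individuals with unknown phenotype are ignored
by both the presence filter and the sharing partition.

**Indel pathogenicity.** The published filtering language ("SIFT indel …
or PROVEAN indel … neutral were filtered out") is ambiguous between
"drop if either predictor is neutral" and "drop only if both are". Both
readings are implemented; the default keeps an indel if *either* predictor
calls it damaging (`either_damaging`), the permissive reading, because the
cascade's later manual-curation stage is the intended arbiter. Decoy
variants in the simulator are made neutral by *both* predictors so their
fate is identical under either rule.

**Missing scores.** `missing_annotation_policy` governs every absent
pathogenicity annotation (CADD for SNVs, SIFT/PROVEAN for indels) and
defaults to *keep*, consistent with the frequency filter retaining
variants that are absent from the population reference. Under
`both_damaging` with one predictor missing, the available predictor must
be damaging *and* the policy must be `keep`.

**Gene constraint.** "Genes enriched in missense variants" has no
published numeric cutoff; the metric (missense observed/expected, or
missense Z where enrichment shows as a low Z) and its threshold are
configuration, defaulting to o/e > 1.0 = enriched. The constraint table is
a two-column TSV supplied by the user; a small synthetic demonstration
table ships in `famseg/data/` (clearly labeled synthetic — it contains
illustrative, not real, population values). Genes absent from the table
are kept.

## Sharing partition and additive pairs

Each survivor is keyed by (affected carriers) = carrier set ∩ affected
set; by construction of the presence filter every key contains the
proband. Cells are disjoint and exhaustive (asserted at run time). An
additive pair is any two variants from distinct cells, neither cell equal
to the full affected set, whose union of cells *is* the full affected set.
With three affected members this reduces to the single cell combination
{P, A₁} × {P, A₂}, but the implementation handles arbitrary affected
counts; pairs are restricted to two loci (higher-order coverage sets are
out of scope). Output order is deterministic (sorted by variant id), so
the report is invariant under input shuffling. Both the partition and the
pair enumeration are cross-checked against naive brute-force enumeration
on hundreds of random instances in the test suite.

No cosegregation statistic (LOD score, Bayes factor) is attached: a single
six-member family carries no meaningful linkage information, and the
pattern itself is the screening object.

## Evidence ranking

The manual literature-curation step of published screens is formalized as
`evidence_score` = count of positive categories among {BMD GWAS = Y,
disease ≠ N, knockout-phenotype note, function note}, equally weighted —
a stated convention, since no weighting is published. Ranking is
(score desc, sharing-cell size desc, CADD desc, gene name) — a total
order, so reports are byte-identical across reruns. An evidence table for
the six candidate genes of the motivating study (VAV3, ADGRE5, AMOTL1,
CDK5RAP3, GLI1, PLXNB2) ships as a worked fixture.

## Synthetic studies

The generator emulates the study design the pipeline targets: a six-member
family (proband II.5; affected mother I.1 and daughter III.1; unaffected
brother II.1 and daughters III.2, III.3), with the published Z-scores as
pedigree defaults and the two married-in fathers unsampled (founder
marker).

**Background variants** get founder genotypes at a frequency drawn
log-uniformly from [1e-5, 0.5] and are transmitted by gene dropping: each
child inherits one uniformly chosen allele from each parent; an unsampled
parent slot contributes a fresh population-frequency draw. There is no de
novo mutation mode — allele-level Mendelian consistency is property-tested
over >10,000 transmissions. Annotations come from simple parametric
mixtures (50% coding, 30% intronic with a 20% splice flag, 10% indels, 35%
synonymous among coding SNVs, CADD uniform on [0, 40], 5% missing MAF/CADD,
5% of genes marked missense-enriched). The default background count is
2,000 variants — large enough to exercise every cascade stage with
realistic sparsity while keeping a full study generation around a second.

**Planted variants** bypass transmission: dosage 1 exactly at the intended
carriers, because candidate variants are defined by observed carrier
subsets, not transmission probability. Annotations are constructed so the
variant dies exactly at its intended stage (or survives): decoy values sit
beyond thresholds with margin (MAF at 1.2× the cutoff, CADD at 0.8× it),
and indel decoys are neutral by both predictors so the fate is unambiguous
under either indel rule. An unsatisfiable request (e.g. "survive" with an
unaffected carrier, or a survive fate overridden with a common MAF) raises
an error at plant time. Every emitted variant gets a truth-table row
(intended fate, intended cell), and the test suite verifies the pipeline
recovers the truth table exactly, including for gene-dropped background
variants whose fate is computed at generation time.

Output is standard: an uncompressed multi-sample VCFv4.2 (written with
pysam; annotations in INFO keys GENE/REGION/CSQCLASS/SPLICE/MAF/CADD/
SIFT_INDEL/PROVEAN_INDEL), an extended PED, the truth TSV and a
gene-constraint TSV. Synthetic contigs are named `S1`–`S6` so coordinates
cannot collide with any real genome build. All randomness flows from one
integer seed; identical specs and seeds yield byte-identical files.

**What the simulator does not model:** sequencing reads, coverage,
genotyping error, quality scores, linkage disequilibrium between variants,
population structure in the founder frequencies, and real annotation
correlations (e.g. CADD vs. consequence class). Passing tests therefore
demonstrate the *logic* of the pipeline — filtering, partition and pair
algebra, trace bookkeeping, format round-trips — not robustness to the
noise structure of real exomes.

## Numerical and degenerate-input choices

* VCF coordinates stay 1-based throughout; multiallelic records are
  decomposed one alt at a time before any filtering (filters are
  per-allele); per-alt dosage is the allele's count in the GT call, so
  decomposition conserves allele counts.
* Genotypes with any missing allele ("./.", "0/.") are missing dosages.
* Threshold comparisons: MAF ≤ `maf_max` keeps; CADD ≥ `cadd_min` keeps;
  either-site uses ≥, sum-Z uses strict >. Annotation floats survive the
  VCF round trip at float32 precision, far finer than any threshold.
* Empty inputs are valid everywhere: an empty VCF yields an empty
  partition, empty pair list, and header-only reports.
* Ranking ties beyond the documented keys are broken by gene name, then
  variant id; ties cannot persist.

## Known limitations

* The partition/pair machinery assumes a single family; multi-family
  aggregation is out of scope.
* Only the dominant hypothesis is implemented (no recessive or
  compound-heterozygous models), matching the screen it reproduces.
* Annotations are consumed, never computed: no VEP/CADD/SIFT scoring.
* The published 38-variant partition cannot be recomputed from real data
  (the study's exomes are not deposited); it is covered by the seeded
  synthetic regression with planted cell counts 4/11/9/14, which verifies
  the pipeline's behavior, not the original data.

## Test problem sizes

Property tests run hypothesis's default example counts with derandomized
seeds; brute-force equivalence uses 200 random instances of up to 8
samples × 64 variants; Mendelian consistency checks 12,000 transmissions;
the regression fixture uses 63 planted variants. The full suite runs in a
few seconds.
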