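# famseg

Family-based rare-variant discovery for dominant high bone-mineral-density
(HBM) pedigrees: phenotype quantification from DXA Z-scores, a dominant
presence/absence filter with an annotation filter cascade, partitioning of
surviving variants by affected-carrier subsets, and detection of additive
two-locus candidate pairs.

## The problem

Some families segregate unusually dense, fracture-resistant bone in an
apparently Mendelian dominant pattern. Exome sequencing of a handful of
affected and unaffected relatives is the standard discovery design, but a
single small family gives no statistical power — the analysis is set
logic over carrier patterns plus aggressive annotation filtering:

1. **Phenotype.** BMD is measured by DXA at the lumbar spine (LS) and
   femoral neck (FN) and expressed as age/sex-standardized Z-scores. Two
   operational HBM definitions are supported: Z ≥ +2.5 at either site, or
   Z_LS + Z_FN > 4. Affection status remains an input label — the advisory
   classification is reported beside it, never substituted for it, because
   borderline relatives are routinely called affected on family context.
2. **Dominant presence filter.** Keep variants carried by the proband and
   homozygous-reference in every unaffected relative.
3. **Annotation cascade.** Drop variants that are non-coding (UTR,
   up/downstream, ncRNA, intergenic, unknown), intronic without a splice
   prediction, or synonymous; common variants (population MAF > 0.005);
   SNVs with CADD phred < 20 and indels called neutral by the categorical
   SIFT-indel/PROVEAN-indel predictors; and variants in genes enriched for
   missense variation in a population reference.
4. **Affected-sharing partition.** Classify survivors by *which* affected
   members carry them. With three affected members (proband P, plus A₁ and
   A₂) there are exactly four cells: {P,A₁,A₂}, {P,A₁}, {P,A₂}, {P}.
5. **Additive pairs.** Two variants from distinct non-universal cells whose
   carrier sets jointly cover all affected members — the digenic pattern
   where the proband carries both variants and each other affected member
   carries one — are reported as candidate pairs.
6. **Ranking.** Survivors are ranked by a transparent gene-evidence score
   (BMD GWAS association, human disease, knockout phenotype, curated
   function note, equally weighted).

Because real family exomes are rarely deposited, the package includes a
seeded synthetic-study generator: gene-dropped background variants plus
planted variants with prescribed carriers and cascade fates, emitted as
standard VCF/PED files together with a truth table, so every stage is
verifiable end to end.

## Worked example

Generate a synthetic study that plants 38 surviving variants across the
four sharing cells at counts 4/11/9/14, plus five decoys dying at each
cascade stage, then run the pipeline:

```sh
famseg simulate --out-dir demo --seed 7 --design partition --n-background 0
famseg run --vcf demo/study.vcf --pedigree demo/study.ped \
    --gene-constraint demo/gene_constraint.tsv --proband II.5 \
    --out-dir demo/out
```

which prints the per-stage trace and summary:

```
INFO stage dominant_presence    63 ->   58
INFO stage region_consequence   58 ->   53
INFO stage frequency            53 ->   48
INFO stage pathogenicity        48 ->   43
INFO stage constraint           43 ->   38
38 survivors in 4 cells; 99 additive pair(s)
```

63 variants enter; each annotation stage removes its five decoys; 38
survive and partition into the planted 4/11/9/14 structure
(`demo/out/partition.tsv`):

```
cell	n_variants	variant_ids
I.1,II.5,III.1	4	varP0001,...
I.1,II.5	11	varP0005,...
II.5,III.1	9	varP0016,...
```

The 99 pairs are the 11 × 9 cross-products of the {proband, mother} and
{proband, daughter} cells — each such pair covers all three affected
members while neither variant alone does. The advisory phenotype report:

```sh
famseg report --pedigree demo/study.ped --mode sum_z
```

```
individual_id	affected	z_ls	z_fn	sum_z	bmd_class
I.1	affected	3.3	2.2	5.5	hbm
II.5	affected	4.6	2.4	7	hbm
III.1	affected	1.3	2.2	3.5	normal
...
```

Note III.1: sum Z-score 3.5 fails the strict > 4 rule, so the advisory
class is `normal` while the authoritative input label stays `affected` —
the disagreement is surfaced, not resolved.

## Layout

| module | contents |
| --- | --- |
| `famseg.pedigree` | extended-PED I/O, Z-score sums, HBM criteria |
| `famseg.variants` | annotated-VCF ingestion (cyvcf2), dosage matrix, reports |
| `famseg.filters` | the annotation filter cascade + audit trace |
| `famseg.segregation` | dominant presence, sharing partition, additive pairs |
| `famseg.prioritize` | gene-evidence table and candidate ranking |
| `famseg.simulate` | gene dropping, planted variants, study generator (pysam) |
| `famseg.pipeline` / `famseg.cli` | orchestration and the `famseg` command |

See `docs/methods.md` for the model, parameter defaults, and limitations.
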