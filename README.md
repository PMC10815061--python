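# ibdkit

Allele-balance identity-by-descent (IBD) mapping and candidate
prioritization for small sequenced pedigrees, with multi-caller
structural-variant consensus and dual-luciferase reporter statistics.

## The problem

Rare dominant disorders segregating in a single family — for example a
split-hand/foot malformation with long-bone involvement in a
three-generation pedigree — are often mapped from whole-genome sequencing
of a handful of relatives: a few affected members and one unaffected.
Classical linkage machinery is overkill at that scale; what works is to
find the genomic regions every pair of affected relatives inherited in
common, then restrict variant prioritization to those regions.  `ibdkit`
implements that workflow for anyone with a joint-genotyped multi-sample
VCF and a PED file, plus the downstream pieces such a study needs: merging
SV calls from several callers into consensus events, intersecting external
gene-prioritization scores with the IBD regions, and the nonparametric
statistics of a TOPFlash/FOPFlash reporter assay used to validate a
candidate in vitro.

## The statistic

For each biallelic SNV *A* that survives hard filters (per-sample read
depth DP > 14, genotype quality GQ > 30, no Mendelian error in any
genotyped trio, alternate-supporting reads present for every non-reference
call) and for each pair of affected samples (1, 2), the allelic-ratio
difference is

```
ratio_diff_A = | AD_A1 / DP_A1  −  AD_A2 / DP_A2 |
```

with AD the alternate-allele read count.  Two samples sharing a haplotype
IBD (IBD1 or IBD2) can never be opposite homozygotes, so informative sites
(differing genotypes) whose genotypes share no allele **and** whose
ratio_diff is near 1 are per-site evidence against sharing; sites with
identical genotypes are non-informative but fully compatible with sharing.
Runs of compatible sites become per-pair IBD segments; intersecting all
C(k,2) affected pairs' segments yields the shared regions where a dominant
variant must lie.  Candidate genes are then external prioritization scores
(Exomiser-style tables) restricted to those regions with scores below 0.5
discarded; SV candidates are consensus clusters (≥ 50% reciprocal overlap,
breakends within 1000 bp, single linkage) that fit the dominant model and
overlap a phenotype-related gene inside an IBD region.  Reporter
comparisons use an exact Mann–Whitney U test (full enumeration of group
labelings) with effect size r = |Z|/√N.

Because real patient genomes in such studies are usually not shareable,
`ibdkit` ships a first-class generator (`ibdkit.simulate`) that
gene-drops founder haplotypes through a configurable pedigree with Poisson
crossovers and a binomial 30× read model, recording exact truth for every
planted IBD segment, SV and assay effect.

## Worked example

```python
from ibdkit import SimConfig, simulate_bundle, IBDMapping, ReporterAssay

bundle = simulate_bundle(SimConfig(seed=1), "demo")          # 20 Mb, ~13k SNVs, 30x
res = IBDMapping.from_files("demo/family.vcf", "demo/family.ped").fit()
print(res.summary())
```

```
Allele-balance IBD mapping
====================================================
samples: II.8, II.9, II.10, III.3, III.7
sites input / passing filters: 13333 / 12714
thresholds: DP > 14, GQ > 30, alt support required: True
segmentation: max_ratio_diff=0.7, max_discordant_run=0, min_sites=25, min_span_bp=500000
----------------------------------------------------
pair                   segments   span (Mb)
II.8 x II.9                   1       19.99
...
shared regions: 1  (19.99 Mb)
```

At this seed no crossover broke the risk haplotype, so all six affected
pairs share essentially the whole simulated chromosome and the
intersection is a single 19.99 Mb region (the planted truth; the recovery
Jaccard is 0.9997).  The reporter side:

```python
print(ReporterAssay.from_csv("demo/assay.csv")
      .fit(alternative="greater", experiment="exp1").summary())
```

```
Dual-luciferase reporter assay
==============================================
normalizer: renilla_rlu
  variant   n=3  median T/F=3.241  mean-based T/F=3.032
  wt        n=3  median T/F=6.128  mean-based T/F=5.963
----------------------------------------------
Mann-Whitney wt vs variant (greater, exact)
  U = 9.0   Z = 1.964   p = 0.05   r = 0.802
```

All three wild-type TOP/FOP ratios exceed all three variant ratios, the
most extreme of the C(6,3) = 20 labelings, hence the exact one-sided
p = 1/20 = 0.05 and effect size r = (4.5/√5.25)/√6 ≈ 0.80 — the
borderline-significant, large-effect readout typical of a triplicate
luciferase experiment with a modest signaling difference.

The same stages are available from a shell (`ibdkit simulate|ibd|
prioritize|svmerge|assay|run`); `ibdkit run --config run.yaml` executes
the whole pipeline and writes an auditable count funnel.

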