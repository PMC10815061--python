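# Methods

## Scope and model

`ibdkit` maps the regions of a genome that all affected members of a small
pedigree inherited identically by descent, using only a joint-genotyped
multi-sample VCF — no phasing, no population reference, no genotype
likelihood HMM.  The underlying observation model is simple: at a
biallelic SNV, a sample's alternate-allele read fraction AD/DP
concentrates near 0, 0.5 or 1 depending on its genotype.  For a pair of
samples, the absolute difference of these fractions (the allelic-ratio
difference) is therefore near 0 for identical genotypes, near 0.5 for a
het/hom pair, and near 1 only for opposite homozygotes.  Opposite
homozygotes are impossible for a pair sharing at least one haplotype IBD,
so they are the sole per-site evidence of non-sharing; everything else is
compatible with IBD1 or IBD2.

The pipeline has four stages, each usable on its own:

1. **Hard filtering** (`vcfio`): autosomal biallelic SNVs; per sample
   DP > 14 and GQ > 30 (strict inequalities), at least one
   alternate-supporting read for any non-reference call, and no Mendelian
   error in any trio genotyped within the sample set.  Mendelian checks
   are trio-local (child vs available parents); a missing genotype makes
   a site untestable and it is retained, since an error cannot be asserted
   on missing data.
2. **IBD segmentation and intersection** (`ibd`): per affected pair,
   classify each site and emit maximal runs as segments; intersect the
   segment unions of all C(k,2) affected pairs into shared regions.
3. **Prioritization** (`prioritize`, `sv`): restrict externally computed
   gene scores to the shared regions and discard scores below 0.5; merge
   multi-caller SV calls into consensus clusters, keep those consistent
   with dominant inheritance, overlapping a phenotype-related gene and
   lying inside a shared region.
4. **Reporter statistics** (`reporter`): renilla normalization, TOP/FOP
   ratios, exact Mann–Whitney U comparison with Z-based effect size.

## Segmentation rule and its parameters

A site enters the segmenter for a pair only when both genotypes are
present.  It is classified:

* **discordant** when the genotypes share no allele *and* the allelic
  ratio difference exceeds `max_ratio_diff` (default 0.7);
* **compatible** otherwise — concordant informative sites (genotypes
  differ but share an allele) and identical-genotype sites.

The two-condition discordance rule is deliberate.  True opposite
homozygotes at 30× show a ratio difference near 0.96; a genotyping error
that turns a het call into a homozygote leaves read fractions near 0.5,
so its apparent opposite-homozygosity is contradicted by the reads and the
site is not allowed to break a segment.  The threshold 0.7 sits several
binomial standard deviations from both populations at 30× depth.  Because
discordance already requires genotype- and read-level agreement, a single
corroborated discordant site is strong IBD0 evidence and the default
consecutive-discordant tolerance is `max_discordant_run = 0`; the
tolerance exists as a parameter for noisier data.

Identical-genotype sites are non-informative for distinguishing IBD
states (and are excluded from the informative count reported per
segment), but they must contribute to segment *support*: a pair sharing
both haplotypes (IBD2) — common between siblings — has identical
genotypes at every site of the region, and an informative-site support
requirement would make exactly those regions invisible.  `min_sites`
(default 25) therefore counts compatible sites of either kind, and
`min_span_bp` (default 500 kb) suppresses short spurious runs: in a true
IBD0 region roughly 15% of informative sites are corroborated-discordant,
so a run long enough to pass both floors essentially never occurs by
chance.  Segment ends are trimmed to the outermost compatible sites; the
IBD1/IBD2 label of a segment is the minimum shared-allele count over its
informative sites (2, i.e. IBD2, when there are none).

The unaffected member is not used by default; `exclude_unaffected=True`
(CLI `--exclude-unaffected`) additionally subtracts intervals that every
affected member also shares with each unaffected sequenced member, for
the stricter "absent in the healthy relatives" reading.  Both modes are
provided because either is defensible for a dominant model with
incomplete penetrance, where an unaffected relative may carry the risk
haplotype.

## SV consensus

Calls merge when on the same chromosome (and of the same type, unless
relaxed) with reciprocal overlap ≥ 0.5 and both breakend distances
≤ 1000 bp.  Clustering is single linkage — transitive, deterministic, and
the behaviour of the standard SV mergers — rather than clique-based.
Consensus coordinates are per-coordinate medians, robust to one outlier
caller.  Insertions and breakends merge on breakend distance alone, since
interval length is meaningless for them.  Per-caller hard filters are
configuration (required FILTER flag, minimum quality), not code, because
each caller's authors publish their own recommendations; read-depth CNV
callers without genotypes contribute "missing" carrier states, which the
dominant-model filter treats as non-informative.

## Reporter statistics

Each well's firefly signal is divided by its co-transfected Renilla
signal (the transfection-efficiency control; an alternative divisor
column, e.g. a β-galactosidase reading, can be selected).  Per replicate,
the TOP and FOP wells of a construct are paired within experiment and
replicate index into a TOP/FOP ratio; constructs are compared on these
ratios with a Mann–Whitney U test.  For pooled sizes up to 20 the p-value
is exact by full enumeration of all C(n1+n2, n1) labelings (midranks under
ties; with ties this is the corresponding permutation test), otherwise a
tie-corrected normal approximation is used.  The reported Z is always the
normal form **without** continuity correction and the effect size is
r = |Z|/√N: with the correction, complete 3-vs-3 separation would give
r ≈ 0.71 instead of the conventional ≈ 0.80, and 0.80 is what this
configuration is universally reported as.  The package default alternative
is two-sided; the acceptance recomputation uses one-sided "greater"
because a directional hypothesis (variant weaker than wild type) at n = 3
per group is the only configuration whose exact p reaches 0.05 — an
interpretation, recorded here rather than asserted as universal practice.

## The synthetic generator

`simulate_family` gene-drops founder haplotypes: founder alleles are
per-site Bernoulli(`founder_alt_freq` = 0.3), each meiosis places
crossovers as a Poisson process (`1e-8` per bp per meiosis) and chooses a
starting strand at random, and the designated risk haplotype — belonging
to the first founder ancestral to all affected members — is forced into
every affected member by flipping the starting strand when needed.  Depth
is Poisson(30); alternate allelic depth is Binomial(DP, p) with
p ∈ {0.02, 0.5, 0.98}, so homozygous calls carry realistic sequencing
error and the ratio-difference thresholds are meaningfully exercised.  GQ
is the phred-scaled binomial likelihood margin between the called
genotype and the best alternative, capped at 99 — a caricature of a
genotyper, but accurate where it matters, around the GQ > 30 threshold.
Injected genotype errors (rate 0 by default; 0.5% in the stressed
acceptance condition) flip the reported call while the reads keep
reflecting the truth, and receive a GQ drawn in 35–70: a *confident*
miscall, the worst case for downstream filters, drawn from an independent
RNG stream so a noisy run differs from its clean counterpart only in the
flipped calls.  Default scale is one 20 Mb chromosome at one SNV per
1.5 kb (~13,333 sites), which exercises every code path in seconds while
preserving the sharing structure of the emulated five-sample family.

Truth is recorded from the realized crossovers, not re-inferred: per-pair
intervals of shared founder-haplotype ancestry and their all-pair
intersection.  Recovery is scored as the Jaccard index (intersection over
union, in bp) between recovered and planted shared regions; under the
defaults it exceeds 0.99 both error-free and at 0.5% genotype error.

SV call sets place `truth_sv_count` = 10 well-separated DEL/DUP events,
jitter each caller's breakpoints with Normal(0, 100 bp) noise and add
Poisson false positives per caller; the first event follows the dominant
carrier model and sits over the risk locus.  The assay generator draws
log-normal well readings (log-sd 0.1 ≈ 10% CV, typical technical
triplicates) centred so normalized TOP/FOP is 5.0 for wild type and 3.0
for the variant — a modest, reliably rank-separable effect.  In the
acceptance script the "representative experiment" is the one of the three
with the largest rank separation, emulating how a representative panel is
chosen for a figure.

What the generator does **not** emulate: linkage disequilibrium and
demographic allele-frequency structure, alignment and capture artifacts,
multi-nucleotide and indel variation, mosaicism, and reference bias.
Passing recovery tests therefore demonstrates the correctness of the
segmentation and intersection machinery under a faithful read-count
model, not performance on real cohort data.

## Numerical and degenerate-input choices

* Thresholds printed as "> 14" and "> 30" are strict; the score cutoff
  discards "less than 0.5", so exactly 0.5 survives.
* VCF positions stay 1-based at the record level; every derived interval
  (segments, regions, SVs, BED output) is 0-based half-open.  Overlap of
  at least one base counts everywhere.
* Multi-allelic records are skipped (counted) by default; a split mode
  decomposes them per alternate, marking calls that carry a different
  alternate as missing.  `sum(AD) > DP` is flagged, not rejected.
* An all-tied Mann–Whitney comparison has zero rank variance; Z is
  defined as 0 and the exact p is 1.
* Interval maps with empty union define Jaccard = 1 (nothing to recover,
  nothing recovered).

## Known limitations

* The segmenter's resolution is one inter-marker spacing (~1.5 kb at the
  default density); boundary placement inside long runs of homozygosity
  is correspondingly coarse.
* Segments require read-backed AD/DP; data without AD fall back to
  genotype-only discordance, losing the miscall rescue.
* The dominant-model SV filter cannot reject events whose carriers are
  all genotype-less (e.g. CNV-caller-only clusters); they pass through as
  non-informative and must be caught by the annotation filters.
* Exact enumeration is limited to pooled sizes ≤ 20 (C(20,10) ≈ 1.8×10⁵
  labelings); beyond that the tie-corrected normal form is used.
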