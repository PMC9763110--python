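# Methods

This note documents the models, rules and design choices behind the
package, what the synthetic-data generator does and does not emulate, and
the numerical conventions that make results reproducible bit for bit.

## Coordinates and interval arithmetic

All in-memory coordinates are 0-based half-open; PennCNV-dialect call
tables (1-based inclusive) are converted exactly once at the read/write
boundary. Interval set operations (union, intersection, overlap pairing,
coverage fractions) are implemented as vectorised sweeps over int64 arrays
in `cnvburden.intervals`, with intervals of different keys (sample ×
chromosome × type) separated by lifting coordinates into `key·2⁴⁰ + pos`.
Tests check these primitives — and everything built on them — against
per-basepair boolean-mask oracles on toy genomes.

## Consensus calling

- **Conflict rule.** The exclusion of loci called gain by one caller and
  loss by the other requires an overlap criterion; we use >50% *reciprocal*
  overlap (the standard CNV-equivalence notion) and remove both members.
  Bare 1-bp contact would over-exclude.
- **Intersection.** Per sample/chromosome/type, each caller's calls are
  unioned and the two unions intersected into maximal dual-supported runs.
  For callers that emit non-overlapping calls per type (the realistic
  case), every consensus run lies inside one call from each caller.
- **Annealing.** Adjacent same-type calls are merged while
  gap/(merged span) < 0.30, greedily left-to-right, iterated to a fixed
  point. The rule is applied after intersection and to all same-type
  adjacent calls regardless of size; the 30% ratio itself suppresses
  merging of genuinely distinct events. Annealing is idempotent and every
  output gap fraction is ≥ 0.30 (property-tested). The alternative
  ordering (anneal before intersection) is not used.
- **Probe counts** of derived intervals are re-counted from the probe map;
  caller-reported counts are undefined for intersected or merged spans.

## Quality control

- **Quartiles** use linear interpolation between order statistics (numpy
  default, R type 7) — pinned for bit-reproducibility.
- The outlier rule is `value ≥ Q3 + 3·IQR`, computed within cohort, for all
  five metrics (LRR SD, BAF SD, waviness, CNV count, kb burden). With a
  degenerate all-equal metric the IQR is 0 and every sample sits at the
  cutoff, so all fail; callers should treat a zero-IQR cohort as
  pathological rather than expect the rule to save it.
- **Aneuploidy** (>20% of any chromosome covered by the union of a
  sample's consensus calls) is evaluated on the consensus set *before*
  CNV-level filters.
- **Frequency** is computed on the post-consensus, post-sample-QC,
  pre-filter callset, jointly over all analysis subjects (no case/control
  stratification): calls are clustered by ≥50% reciprocal overlap and
  identical type with single linkage, and a call's frequency is the number
  of distinct samples in its cluster over the number of analysis subjects.
  Single-linkage chaining means a dense common locus forms one cluster — the
  behaviour that makes the >1% rarity filter remove common polymorphic loci.
- The five CNV-level criteria are independent OR'd exclusions; each removed
  call records all reasons that apply plus one primary reason (fixed
  order: special region, segdup, frequency, length, probes) so that counts
  partition exactly.
- Genotype-QC outcomes (missingness, heterozygosity, sex concordance,
  relatedness) are consumed as boolean flags; computing them needs genotype
  data that is out of scope.

## Burden encoding

- **NDD span partition.** A call counts toward the NDD stratum if it
  overlaps *any* NDD region of matching type by ≥1 bp, otherwise the
  non-NDD stratum; calls are never split, so NDD + non-NDD spans sum to the
  per-type total by construction.
- **Carrier status** uses the union of a subject's same-type calls over a
  region, so fragmentation cannot mask a carrier. The 100%-coverage rule
  tolerates 1 bp to absorb coordinate-dialect edge effects; the ≥50% rule is
  inclusive at exactly one half.
- **Gene models** are isoform-collapsed (minimum start, maximum end) and
  restricted to protein-coding genes (RefSeq `NM_` accession prefix). A CNV
  maps to every gene it overlaps by ≥1 bp; indicators are computed for all
  calls and for deletion-only and duplication-only strata. Gene-set counts
  are sums of member indicators.

## Association models

- Score phenotypes are rescaled to [0, 1] by the instrument's theoretical
  range; case/control cohorts are fitted by maximum-likelihood logistic
  regression and their log-odds estimates enter the meta-analysis directly
  alongside the 0–1-scale linear estimates, interpreting case status as the
  censored observation of the same latent symptom scale. No additional
  rescaling is applied to logistic betas.
- Covariates: five principal components and the LRR-SD quality metric;
  gene-set (enrichment) models additionally adjust for genome-wide CNV
  count and mean CNV length, so a set term is tested above global burden.
- Degenerate fits are marked inestimable with a reason (zero-variance term,
  rank-deficient design, non-converged logistic, leverage-1 observation for
  HC3) and excluded from meta-analysis rather than imputed — IVW weights
  would be undefined.
- HC3 standard errors come from statsmodels' `cov_type="HC3"`; tests verify
  them against the definitional sandwich
  (XᵀX)⁻¹ Xᵀ diag(eᵢ²/(1−hᵢᵢ)²) X (XᵀX)⁻¹ to 1e-10.
- Ordinal (proportional-odds) fits use raw score levels as ordered
  categories, decile-binned when more than 50 distinct levels exist (bounds
  the threshold-parameter count); cohorts with fewer than 3 levels fall
  back to logistic regression, flagged in the result. Odds ratios are
  meta-analysed on the log-OR scale without rescaling.
- The PRS + CNV variance partition fits covariates-only, +PRS, and
  +PRS+CNV models; PRS is standardised to mean 0 / SD 1 within the
  analysis sample. Each increment's ΔR² gets a large-sample standard error
  from Cohen's formula, SE ≈ √(4R²(1−R²)²(n−k−1)²/((n²−1)(n+3))) with R²
  replaced by the increment and k the larger model's parameter count, and a
  partial-F p-value. In small samples this SE is approximate; the F test is
  the inferential anchor.

## Meta-analysis and FDR

Fixed-effects IVW with normal-theory two-sided p-values (no small-k t
correction); Cochran's Q is available behind a flag but not reported by
default. BH step-up q-values are computed within pinned test families:
the seven genome-wide span terms form one family; NDD-region carrier terms
form one family per overlap rule (regions with at least one carrier); gene
indicators form one family per type stratum, restricted to genes whose
carrier frequency reaches 0.01% (configurable); gene-set counts likewise
per stratum. The family boundaries are a reasoned reconstruction of how
separate q-values are conventionally reported for burden, region, gene and
pathway analyses.

## Synthetic-data generator

The generator emulates the *structure* of a multi-cohort SNP-array CNV
study, not its raw signal: no LRR/BAF intensities, no linkage
disequilibrium, no real genome build. Defaults define the study conditions
used throughout the tests:

- Genome: two chromosomes (30 Mb + 25 Mb), probes every 1 kb; telomeres
  (100 kb), a 1 Mb centromere, one Ig/TCR locus, ~3% segmental
  duplications; 200 genes (10% non-coding, one guaranteed multi-isoform
  gene); six labelled NDD regions per chromosome (alternating del/dup,
  400–550 kb), placed clear of the special tracks.
- True CNVs: background events at 1.6 per subject (log-uniform 30–600 kb,
  55% deletions; median ≈ 130 kb, matching the length regime of array-based
  CNV studies), placed clear of special tracks, segdups and NDD regions and
  ≥1 Mb from same-type events of the same subject so annealing can never
  merge two distinct truths; NDD-region events in 8% of subjects (one
  region drawn uniformly, covered fully with ≤50 kb margins), giving
  per-region carrier frequencies ≈ 0.67%, safely under the 1% rarity
  filter.
- Caller error (a modelling choice; real caller error structure is not
  published): independent boundary jitter (SD 2 kb), 10% fragmentation
  into two pieces with a gap below the annealing threshold, 0.2 false
  calls per subject (uniform over the non-centromeric genome, log-uniform
  10 kb–1 Mb), 1% gain/loss flips. With all error rates zero both
  callsets equal the truth and the pipeline round-trips exactly
  (regression-tested).
- Phenotypes: latent = 0.45 + 0.03·(NDD deletion Mb) + PC effects +
  0.011·PRS + N(0, 0.12), truncated to [0, 1]; truncation keeps the
  instrument rescaling invertible and is negligible at these settings.
  Score cohorts cycle through four theoretical instrument ranges
  (17–85, 0–136, 0–51, 0–88); case/control cohorts dichotomise the latent
  scale at 0.62. An optional per-gene-hit effect on one target gene-set
  supports enrichment experiments.
- All randomness derives from one seed through named `SeedSequence`
  spawns; generation is bit-reproducible.

What passing tests therefore show: the pipeline's interval logic, filters
and statistics are correct and calibrated under a realistic-but-idealised
data-generating process. What they do not show: robustness to real array
artefacts (waves, batch effects, platform-specific caller biases), which
enter here only as abstracted QC metrics.

## Simulation sizes and known limitations

Validation simulations use 5 cohorts × 1000 subjects (recovery; 200
replicates), 3 × 400 (null calibration; 1000 phenotype replicates on a
fixed CNV design — valid under the null because the phenotype is
independent of the design) and 1 × 800 (enrichment; 100 replicates): sizes
chosen so each experiment has clear power while the whole suite runs on a
single CPU in minutes. Known limitations: the enrichment control set shows
mild rejection inflation (~10% at α=5%) in planted-effect runs because
set counts are correlated through shared CNVs beyond what the two global
burden covariates absorb — an inherent property of this enrichment design,
visible only when another set carries a true effect; logistic and linear
betas share a meta-analysis only under the latent-scale interpretation;
and the ΔR² standard error is a large-sample approximation.
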