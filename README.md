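# cnvburden

A reusable, tested implementation of a rare copy-number-variant (CNV) burden
association pipeline of the kind used in large psychiatric-genetics
consortium studies: from two per-sample CNV callsets (as produced by
SNP-array callers such as PennCNV, iPattern or QuantiSNP) through dual-caller
consensus calling, sample- and CNV-level quality control, burden encoding at
four genomic scales, per-cohort regression of a symptom phenotype, and
cross-cohort fixed-effects meta-analysis with FDR control.

Individual-level data from such consortia are protected, so the package
ships a first-class synthetic-study generator with planted effects and full
ground truth. Every stage of the pipeline is validated against independent
brute-force oracles and recovery/calibration simulations.

## The method

**Consensus calling.** Calls from two callers are reduced to loci supported
by both. Opposite-type calls (gain vs. loss) from the two callers with >50%
reciprocal overlap mark unreliable loci and are removed from both callsets;
the survivors are intersected per sample, chromosome and CNV type; adjacent
same-type fragments are *annealed* (re-joined) whenever

    gap / (span of the joined call) < 0.30,

greedily left-to-right to a fixed point. Probe counts of derived intervals
are re-counted from the probe map.

**Quality control.** Within each cohort, samples are excluded when any of
log-R-ratio SD, BAF SD, waviness, CNV count or kilobase burden reaches
Q3 + 3·IQR (linear-interpolation quartiles), when >20% of any chromosome is
copy-number variant (aneuploidy), or when an upstream genotype-QC flag
fails. CNVs are excluded when ≥50% covered by centromere/telomere/Ig/TCR
sequence, >50% covered by segmental duplications, more common than 1%
within the data (single-linkage clusters at ≥50% reciprocal overlap),
shorter than 10 kb, or supported by fewer than 10 probes.

**Burden encoding.** Per subject: genome-wide span in megabases (total, by
type, and partitioned by ≥1 bp overlap with neurodevelopmental-disorder
(NDD) CNV regions of matching type); per-region carrier status under three
overlap rules (>0%, ≥50%, 100% of the region covered by the union of the
subject's matching-type calls); per-gene 0/1 indicators (≥1 bp overlap with
isoform-collapsed protein-coding gene spans); and gene-set hit counts.

**Association and meta-analysis.** Per cohort, the phenotype — an inventory
score rescaled to [0, 1] by its theoretical range, or case/control status —
is regressed on one burden term with five ancestry principal components and
the log-R-ratio SD as covariates (linear or logistic model; gene-set models
additionally adjust for genome-wide CNV count and mean CNV length).
Cohort estimates are combined by fixed-effects inverse-variance weighting,

    beta = Σ wᵢbᵢ / Σ wᵢ,  se = 1/√(Σ wᵢ),  wᵢ = 1/seᵢ²,

and Benjamini–Hochberg q-values are computed within test families
(genome-wide spans; NDD regions per overlap rule; genes and gene-sets per
type stratum). Sensitivity machinery: HC3 heteroskedasticity-consistent
standard errors, proportional-odds ordinal fits yielding odds ratios
(meta-analysed unrescaled on the log-OR scale), and a hierarchical
PRS + CNV variance partition with a large-sample SE for each ΔR² increment.

## Worked example

```python
import cnvburden as cb

cfg = cb.SyntheticConfig(seed=11, n_case_control_cohorts=0)  # 5 cohorts, 5000 subjects
study = cb.simulate_study(cfg)                                # planted effect: 0.03 / Mb
result = cb.run_pipeline(
    study.callsets, study.qc_metrics, study.subjects, study.annotation,
    include_carriers=False, include_genes=False, include_genesets=False,
)
row = result.meta.set_index("term").loc["span_ndd_del_mb"]
print(f"k={row['k']:.0f} beta={row['beta']:.4f} se={row['se']:.4f} p={row['p']:.3f}")
print(result.log)
```

prints

```
k=5 beta=0.0163 se=0.0187 p=0.383
{'input_calls': 9524, 'input_samples': 5000, 'conflict_pairs_removed': 79,
 'consensus_calls': 4035, 'annealed_calls': 3410, 'samples_failed_qc': 121,
 'samples_analyzed': 4879, 'input_cnvs': 3133, 'surviving_cnvs': 2187, ...}
```

The meta-analysed estimate for the NDD-deletion span term (here 0.016 with
SE 0.019, within one standard error of the planted 0.03 — a single study at
this size is noisy; averaged over 200 simulated studies the estimate centres
on 0.03) is the per-megabase effect of NDD deletion burden on the 0–1
phenotype scale, combined over the five cohorts by inverse-variance
weighting. The log records how many calls and samples each QC stage removed.

The same analysis runs from the shell on plain-text fixtures:

```bash
cnvburden simulate --seed 11 --out fixtures/
cnvburden run-all --in fixtures/ --out results/
```

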