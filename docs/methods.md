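# Methods

## Model and procedure

The pipeline treats an eQTM-style question: across samples, does DNA
methylation at a CpG track the expression of the gene it is annotated to,
and does that relationship differ between two clinical groups?

1. **Scale.** Beta values (methylated/total intensity, in [0,1]) are
   reported for interpretability, but every statistic is computed on
   M-values, `M = log2(β/(1−β))`, which are closer to homoscedastic and
   unbounded. Betas are clamped to `[ε, 1−ε]` (ε = 1e-6) before the logit so
   fully (un)methylated probes stay finite; `m_to_beta` inverts the map.
2. **Adjustment.** Both matrices are residualized feature-by-feature on an
   intercept plus user-chosen covariates by OLS; the row mean is added back
   so adjusted values stay on the original scale (adding a constant does not
   change any correlation). This one linear-adjustment contract stands in
   for whatever upstream batch/surrogate-variable machinery produced the
   covariates: anything expressible as a per-sample numeric column (including
   0/1 indicators for categorical factors) can be removed. Collinear columns
   are dropped by a deterministic left-to-right scan (a column is kept iff
   its residual against the already-kept basis exceeds 1e-10 relative norm)
   and reported. A missing matrix entry drops that sample from that
   feature's regression only; a row left with fewer than (covariates + 2)
   complete samples is set entirely missing, with a warning. The two
   matrices may use different covariate lists (e.g. cell-type proportions
   for methylation only); the run log records both.
3. **Correlation.** Pearson r per CpG × gene in three strata (pooled,
   group 1, group 2), samples matched by id and pairwise-complete per
   stratum; r is the dot product of the two unit-norm centered vectors
   (exactly ±1 for collinear input), p is two-sided from the exact t
   transform on n−2 df, and `|r| = 1 ⇒ p = 0`. Fewer than 3 complete pairs
   or a zero-variance vector yields a record with missing r/p and a reason
   string rather than an error, so one degenerate probe cannot abort a gene.
   Group strata are labelled GROUP1/GROUP2 from the sample sheet's two group
   levels in lexical order (overridable via `AnalysisConfig.group_order`),
   never from file row order. No multiple-testing correction is applied to
   the per-CpG table: the reporting convention is raw p < α (default 0.05)
   with the sign filter made explicit.
4. **Discordance.** A CpG is discordant when its two group correlations have
   opposite signs and both magnitudes reach the cutoff (default 0.4,
   `both_exceed`). The laxer `either_exceeds` reading (only the larger
   magnitude must reach the cutoff) is available as a config option; the
   strict rule is the default because it is the more conservative reading of
   a "|r| ≥ 0.4 with opposite signs" criterion. An exactly zero (or
   missing) r is never discordant; missing pairs count toward the gene's
   CpG total and are reported as `n_missing`. The gene statistic is the
   discordant proportion, so genes with different CpG counts are comparable
   (comparison on raw counts is a config option).
5. **Permutation null.** Genes are sampled uniformly from an explicit pool —
   without replacement when the usable pool is at least `n_permutations`
   (default 1000), otherwise with replacement, logged either way. Each
   sampled gene's group correlations are recomputed by the same estimator
   (a vectorized r-only path; p-values are not needed for discordance) and
   `empirical p = #{null proportion ≥ observed}/n` with ties counting. The
   plain k/n estimator is the default; the (k+1)/(n+1) smoothed version is a
   flag. Genes with no expression row or fewer than `min_cpgs` usable probes
   (default 1) are excluded from the pool and counted.

## Synthetic cohorts

`generate_cohort` draws, per gene, a standard-normal expression core `e`
(expression = mean + sd·e + covariate effects) and, per CpG,
`M = logit2(β_mean) + noise_sd·(ρ_g·z + √(1−ρ_g²)·ε) + covariate effects`,
where `z` is `e` standardized within each group and `ρ_g` is the
group-specific target correlation; betas are the inverse logit of M. By
construction the within-group correlation between M and expression is ρ_g
regardless of `noise_sd`, which only sets the M-value spread (default 0.5,
a typical array scale). Defaults mirror the motivating study design: 14 + 10
samples, covariates age ~ N(70, 8) years, sex ~ Bern(0.5), post-mortem
interval ~ N(40, 15) hours, batch ~ Bern(0.5), with zero effect sizes unless
configured. One `SeedSequence` spawns a covariate stream plus one stream per
gene, so a gene's data is invariant to the rest of the gene list.

What the generator does **not** emulate: probe-chemistry (type I/II) noise
differences, non-linear batch effects, count-level RNA-seq sampling noise,
correlated CpGs within a region, or heavy-tailed expression. Passing tests
therefore demonstrate correctness of the estimators and the permutation
machinery under the assumed linear-Gaussian structure, not robustness to
every artefact of real array/RNA-seq data. Correlations are induced on the
M-value scale (where the analysis runs); the corresponding beta-scale
correlations are slightly attenuated by the logit's curvature, which is
documented rather than corrected.

Packaged scenarios: `remodelling_scenario()` (TARGET: 7/10 CpGs flipping
+0.6/−0.6, 3 concordant at +0.6; PROMNEG: 4 promoter CpGs at −0.6 in both
groups, emulating promoter repression; 199 null genes as a permutation
pool) and `null_scenario()` (everything ρ = 0, for calibration).

## Numerical and design choices

- Two-sided p-values throughout (the `cor.test` default).
- Pooling uses adjusted values as-is; group is deliberately **not** a
  residualization covariate, so a group mean offset can legitimately drive a
  pooled correlation. Users wanting group-centered pooling can add a group
  indicator to the covariate list.
- TSV matrices carry 12 significant digits (`%.12g`); round-trips are exact
  to that precision. Missing entries are empty cells, distinct from 0.
- The annotation reader accepts manifest-style composite `Feature-CGI`
  strings, normalizing unicode hyphen variants to ASCII before splitting,
  and manifest CGI tokens (`N_Shore`, `S_Shelf`, `OpenSea`, `Island`) to
  the canonical {island, shore, shelf, opensea}. Mapping from the EPIC
  manifest: `IlmnID → probe_id`, `CHR → chromosome`, `MAPINFO → position`
  (1-based, strand-collapsed, no interval), `UCSC_RefGene_Group → feature`,
  `Relation_to_UCSC_CpG_Island → cgi_relation`. A probe annotated to several
  genes (semicolon list) keeps the first listed gene and warns; multi-gene
  expansion was left out because the reference analyses are single-gene.
- "Promoter" in feature breakdowns aggregates TSS1500 + TSS200.
- The packaged reference table stores p-values exactly as printed
  (scientific-notation strings) and parses them on access; its group strata
  keep their original labels (MSA/CTRL), and `gene_discordance` auto-detects
  the two non-pooled labels so both naming conventions work.
- Pipeline outputs contain no timestamps; config hash + seed determine every
  byte, making reruns diffable.

## Validation studies and problem sizes

`eqtm.validation` audits the pipeline by simulation; the default sizes were
chosen to give stable Monte-Carlo estimates while keeping a laptop-scale
runtime of a few minutes: estimator-vs-oracle on 1000 random instances;
ρ recovery at n = 2000; null rejection rate over 2000 simulations at the
cohort's n = 24; null calibration over 200 replicate analyses of a 200-gene
all-null genome; power over 100 replicates of the remodelling scenario with
200 permutations each.

A note on calibration: with 10 CpGs per gene the discordance proportion
takes only 11 values, so the permutation p is discrete and conservative —
under the null, `empirical p ≤ 0.05` requires at least 2 discordant CpGs in
the target, an event with analytic probability ≈ 0.016 at the cohort's
group sizes (below the nominal 0.05, and below a naive "approximately
uniform" expectation). The test is therefore valid (its true size never
exceeds the nominal level) but conservative at small CpG counts; genes with
more CpGs yield a finer null.

## Known limitations

- Linear adjustment only; no surrogate-variable estimation, empirical-Bayes
  batch correction or count-model normalization (inputs are expected
  pre-normalized; a `log2(x+1)` convenience transform is provided for raw
  counts).
- Exactly two groups per analysis run.
- The permutation pool is an explicit input (or "all annotated genes" in
  the pipeline); no automatic expression-level filtering is applied to it,
  and pool composition can matter.
- Small-cohort correlation estimates are noisy: at n = 14/10 a true ±0.6
  sign-flip CpG clears the 0.4/both-groups rule only ~70% of the time, so
  observed discordance proportions understate the remodelled fraction.
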