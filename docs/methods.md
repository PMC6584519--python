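# Methods

## Scope and data model

`methmed` analyzes three sample-aligned matrices — additive genotypes
(0/1/2, missing allowed), methylation beta values in [0, 1], and log2
expression — plus a feature annotation (SNP/CpG positions, CpG
island-relation and gene-region categories, transcript TSS/TES/strand
and gene symbol; all coordinates 1-based inclusive) and an age/disease
covariate table. Files are feature-major TSVs (matrices), annotation and
covariate TSVs, or VCF for genotype import; the in-memory contract is
samples × features. Array preprocessing and normalization are upstream
of the package: inputs are assumed post-normalization.

## Cis scans

For each pair type (meQTL: SNP→CpG; eQTM: CpG→transcript; eQTL:
SNP→transcript) candidate pairs are enumerated within a cis window
(default 1,000,000 bp, boundary inclusive). Point–point pairs use
|pos_a − pos_b| ≤ w; point–interval pairs use pos ∈ [TSS − w, TES + w],
anchoring the window on the whole transcript interval. Each pair is fit
by OLS of the response on [1, predictor, age, disease]; the predictor's
two-sided t test (df = n − 4) is corrected across all cis tests of the
scan jointly by Benjamini–Hochberg (statsmodels step-up). Significance
means q ≤ 0.05.

Numerical route: when no genotypes are missing, both matrices are
residualized against the covariate block once (QR projection) and
per-pair slopes, SEs and t statistics follow from Frisch–Waugh dot
products — algebraically identical to the per-pair fit but ~100× faster,
which is what makes the Monte-Carlo validation runs (hundreds of
thousands of regressions) affordable. With missing genotypes the engine
falls back to per-pair fits with pairwise-complete deletion (≥ 5
complete observations required; a predictor constant after deletion is
flagged degenerate with p = 1 by convention).

Methylation is analyzed on the raw beta scale by default — the
convention of standard matrix-QTL software — with an opt-in logit
transform; both modes recover planted effects, and the choice is exposed
because neither is canonical in the field.

## Trio assembly and the causal inference test

Candidate trios are the combinatorial closure of the three significant
pair sets (one SNP in k chains yields k trios), restricted to genes with
non-empty official symbols, deduplicated and sorted. The CIT then
evaluates four conditions, each adjusted for age and disease:

* p₁: L coefficient in T ~ L + X;
* p₂: L coefficient in G ~ L + T + X;
* p₃: G coefficient in T ~ G + L + X;
* p₄: permutation equivalence test of L ⟂ T | G.

For p₄ the observed partial F for L in T ~ L + G + X is compared with B
permutation replicates in which the residuals of G ~ L + X are shuffled
and added back to the fitted values (G\* = Ĝ + π(r)), preserving the
L–G association while destroying any mediated path;
p₄ = (1 + #{F\* ≤ F_obs}) / (B + 1), so *small* p₄ is evidence *for*
conditional independence. A plain non-significance check of L in
T ~ L + G would reward low power; the permutation construction makes
condition 4 an equivalence test. B defaults to 1,000 (500 in the
validation runs). The omnibus p is max(p₁…p₄) and the mediation verdict
uses α = 0.05, the manuscript-wide convention. Only the forward
(L→G→T) omnibus is tested; no FDR is applied over CIT p-values. Edge
signs for the network are taken from the covariate-adjusted marginal
slopes of G on L and T on G.

Per-trio permutation seeds derive deterministically from
(batch seed, trio index), so batch results are reproducible and
independent of evaluation order. Degenerate trios (constant L,
zero-variance G or T) return a flagged result with all p = 1.

## Linkage disequilibrium

Two-locus haplotype frequencies are estimated from unphased genotypes by
EM over the double-heterozygote phase ambiguity: frequencies initialize
at linkage-equilibrium products; each iteration splits the (1,1) cell
between coupling and repulsion phase in proportion to pAB·pab vs
pAb·paB; convergence at max frequency change < 1e−8 or 1,000 iterations.
The per-iteration log-likelihood trace is retained and is non-decreasing
(asserted in tests). r² = D²/(pA qA pB qB) and D′ = |D|/D_max (0 when
D = 0) follow from the converged frequencies. Monomorphic input raises
an error — LD is undefined, not zero. Group summaries (min/mean pairwise
r²) are reported for SNP sets feeding a shared methylation site; block
*calling* (Gabriel rules etc.) is out of scope.

The estimator was checked against direct likelihood maximization
(agreement to 7 significant digits). Against phased haplotype-count r²
it differs by intrinsic phase-sampling noise of sd ≈ 0.01 per panel at
n = 500, so accuracy is validated on the mean absolute deviation across
panels (≈ 0.01), not per panel.

## Characterization and network export

Category breakdowns count significant *pairs* (not unique CpGs) per CpG
island-relation or gene-region category, with percents rounded half-up
to 2 decimals (report style) and an aggregate CpG-region roll-up
(island + shores + shelves). Distance profiles use the signed
pos_SNP − pos_CpG convention (negative = SNP upstream in genomic
coordinates) with 50 kb bins over ±1 Mb. QQ data pair descending
observed −log10 p with −log10((i − 0.5)/m). The regulatory network is a
directed tripartite graph (SNP→CpG→mRNA) with edges signed by the
marginal slopes; duplicate edges merge (a sign conflict is flagged, the
first sign kept) and exports are deterministic SIF, GraphML or edge-TSV.

## Synthetic data generator

The generator emulates a small clinical multi-omics cohort:

* **Cohort.** Default n = 43 (a realistic clinical cohort size; the
  validation runs use n = 500, where trio-level Monte-Carlo statistics
  are stable); age ~ Uniform(30, 70) years, disease ~ Bernoulli(0.5).
* **Layout.** SNPs/CpGs/genes placed at distinct 1-based positions on
  uniform chromosomes (default 2 × 50 Mb); each planted trio gets a
  distinct gene, with its SNP and CpG within 400 kb of the gene TSS so
  cis eligibility (±1 Mb) holds by construction. CpG island-relation and
  gene-region categories are drawn from fixed 450K-like frequencies.
* **Genotypes.** Haplotype-copy LD model: within a block (default 5
  position-consecutive SNPs), the first SNP's haplotypes are
  Bernoulli(MAF) with MAF ~ Uniform(0.1, 0.5); each later SNP copies the
  previous haplotype allele with probability 1 − ld_decay (default
  decay 0.3), else re-draws. Two haplotypes sum to a dosage; blocks with
  a realized MAF below half the configured lower bound are regenerated
  whole. This gives direct control of block r² (the LD-module oracle)
  without coalescent machinery; there is no population structure and no
  missingness by default.
* **Methylation.** logit(beta) = α_cpg + β_LG·L + covariates + N(0,
  0.5), α_cpg ~ Uniform(−2, 2); betas clipped strictly inside (0, 1).
* **Expression.** T = μ_gene + β_GT·(centered logit G) + β_LT·L +
  covariates + N(0, 1), μ ~ Uniform(6, 12) (log2 microarray scale).
* **Architectures.** mediation (β_LG, β_GT ≠ 0), common cause (β_LG,
  β_LT ≠ 0), reverse causation (β_LT, β_TG ≠ 0), null. Default
  magnitudes 0.8 (genotype effects) and 1.0 (molecular couplings) —
  chosen for testability at desk scale, since real effect-size
  distributions are study-specific; signs are random per trio.
  Generation respects each architecture's DAG: methylation before
  expression except for reverse-causation CpGs, which are re-drawn from
  the same random stream with their expression term after expression
  exists (two-pass), keeping everything else bit-identical.
* **Covariate effects.** Age 0.01 per year (centered at 50) and disease
  +0.25 on the methylation logit scale; 0.01 and +0.30 on log2
  expression — modest, realistic confounding for the scans to adjust
  away.

What passing tests on these data do **not** show: robustness to cell-type
composition, batch effects, probe artefacts, population stratification,
non-additive genotype effects, or the beta-value heteroscedasticity of
real arrays. They do show that the statistical machinery — window
logic, adjusted regression, FDR, the four-condition CIT, EM LD — behaves
correctly under its own assumptions, with calibrated error rates.

## Validation conditions and numerical choices

Monte-Carlo validation uses n = 500 and B = 500: CIT power on 100
planted mediation trios (observed ≈ 100% called), false-call rates on
200 common-cause (≈ 2–5%), 100 null (≈ 0%) and 100 reverse-causation
trios (strictly below mediation power); FDR control on 20 all-null scans
of ~10,000 cis pairs each (mean significant count ≈ 0); LD accuracy on
100 phased panels. Reverse-causation trios are called more often than
common-cause ones because expression drives methylation on the logit
scale while the CIT regresses raw betas — the residual nonlinearity
leaks a small signal into condition 2; the discrimination ordering is
unaffected. QQ diagnostics exclude the five most extreme order
statistics from the deviation bound, whose −log10 values fluctuate by
~0.5 under the null by construction.

Ties and degenerate cases: BH q-values may tie across ranks; D′ is 0
when D = 0; constant predictors yield p = 1; p-values of exactly 0 in QQ
input are clamped to the smallest positive float with a warning.

## Known limitations

* The CIT conditions use the field-standard conditioning sets; no
  reverse-direction omnibus or FDR over trios is computed.
* Pairwise-complete deletion for missing genotypes can use different
  sample subsets across pairs of one scan.
* The LD module reports pair and group statistics, not haplotype blocks.
* Trans associations are out of scope; QQ tooling accepts externally
  computed p-values but no trans scan is provided.
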