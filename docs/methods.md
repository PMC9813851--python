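# Methods

This note records the statistical model behind each stage, the defaults and
why they were chosen, what the synthetic cohort does and does not emulate,
and the numerical conventions a maintainer should know.

## Coordinates and containers

All genomic coordinates are 1-based inclusive, including the BED-like TSVs
the package writes (each file carries a header comment declaring this; it is
a deliberate deviation from half-open BED). The default genome is the 22
human autosomes scaled to 1/300 of their GRCh37 lengths (~10.3 Mb total), so
chromosome-aware logic — length-proportional region resampling, closest-gene
search, per-chromosome clustering — is exercised at desk scale. Genotypes
are held as a samples × SNPs float matrix of A1-allele dosages {0,1,2} with
NaN for missing; the stored per-SNP `freq` is always the A1 frequency among
non-missing calls and is refreshed whenever calls change.

## Synthetic cohort

`simulate_genotypes` draws per-SNP MAF ~ Uniform(0.05, 0.5) and dosages
Binomial(2, MAF) under Hardy–Weinberg; positions are unique, chromosome
chosen length-proportionally. Relatedness is injected by copying one
member's dosages to its partner at a random 50% of SNPs — a
haplotype-sharing shortcut that puts the realized genomic relationship near
0.5, far above the 0.05 pruning cutoff, without coalescent machinery.
`simulate_structured_genotypes` adds Balding–Nichols subpopulations
(default F_ST = 0.1) for stratification and PCA tests.

`simulate_phenotypes` builds RHI = intercept + age_slope·age +
sex_shift·1[F] + Σ effect·dosage + N(0, noise_sd²), ages Uniform{50..85}
(the cohort design only fixes a lower bound of 50), sex Bernoulli(0.5).
Defaults — intercept 2.8, age slope −0.012/yr, female shift −0.15, noise SD
0.35 — put RHI in the 1.5–2.5 range typical of EndoPAT readings in elderly
cohorts with a mild age decline slightly stronger in women. The cohort's
true RHI distribution is not published, so these are illustrative, not
calibrated.

`degrade_calls` emulates re-genotyping from serum cfDNA after whole-genome
amplification: each call independently goes missing (default 10%) or flips
to a different dosage (default 4.2%). Flips are symmetric although real
array error is allele-biased; the concordance metric is direction-invariant
so this does not matter for what the stage is used for.

`simulate_trait_catalog` places hits in Gaussian clusters (default SD 20 kb)
around uniform centers, with ~20 hits per cluster (`max(1, hits/20)`
centers). Clustering mimics the LD clumping of reported GWAS associations
and is what makes the permutation-null SD of overlap counts exceed its
mean, as seen in real catalog enrichment summaries. An `enrich_frac` of
hits can be planted uniformly inside designated regions.

**What the generator does not emulate:** LD between SNPs (each SNP is
independent), imputation panels, allele-biased genotyping error, realistic
site-frequency spectra or demography, or the X chromosome. Passing tests
therefore validate the estimators and the pipeline plumbing, not robustness
to LD-induced correlation among test statistics.

## Quality control

SNPs are dropped when missingness > 0.20 or recomputed MAF < 0.05, both
boundaries kept (a SNP exactly at either threshold survives); a SNP failing
both is attributed to missingness. Survivors are re-polarized so A1 is
minor. The filter is idempotent.

The GRM uses standardized dosages with pairwise-complete SNP sets (the
common tool convention; the per-pair SNP counts are kept in the output).
Relatedness pruning is greedy: repeatedly drop the sample with the most
over-threshold partners (ties: larger missingness, then lexicographically
larger id), which removes exactly one member of each isolated pair and is
deterministic and order-independent. PCA is the eigendecomposition of the
GRM with coordinates scaled by √eigenvalue (noted in the output).

## Association

Within-stratum OLS adjustment uses the unbiased (n−1) SD for z-scoring; a
stratum with < 3 samples, zero age variance, or (numerically) zero residual
variance raises. The mixed model fits REML once on the null model by a
bounded 1-D optimization of the profiled restricted likelihood over
h² ∈ [0, 1−10⁻⁶] on the GRM eigenbasis (eigenvalues clipped at 0), exact
and fast for cohorts up to a few thousand. If the likelihood is flat —
e.g. a near-identity GRM, where h² is unidentifiable — the fit ties-breaks
to h² = 0 and flags it; with ~100 samples and ~20k SNPs the GRM carries
little spectral spread, so per-cohort h² estimates at that scale are
reported but not meaningful.

Per-SNP testing is generalized least squares with V = Aσ²_g + Iσ²_e fixed
from the null fit (the non-LOCO convention: the candidate's own chromosome
stays in the GRM; recorded in output metadata). Standard errors carry a
per-SNP residual dispersion factor r'V⁻¹r/(n−k), which makes the test
reduce *exactly* to per-SNP OLS when σ²_g = 0. Missing dosages are handled
complete-case per SNP (mean-imputation available by flag in burden
scoring); SNPs with zero dosage variance are emitted with missing p.
Wald p-values use the normal survival function (never 1−CDF), keeping
precision to p ~ 10⁻³⁰⁰. Candidate calling is strict (`p < 5e-5`); the
closest gene is the containing interval, else the nearest same-chromosome
interval edge, ties to the smaller start.

## Burden scoring

The protective allele is A1 iff β̂ > 0 (β̂ = 0 is rejected as undefined).
Burden counts resolve the protective allele against the genotype matrix's
*current* allele coding, so re-polarizing a SNP anywhere upstream cannot
change a count. Missing genotypes contribute round(2·p_protective) — modal
imputation keeping counts integral — with exact (non-integer) expectation
behind a flag. Extreme groups take floor(frac·n) members per side
(a 97-sample cohort at 0.30/0.30 splits 29/29, matching how such cohorts
report the split), with ties included on the extreme side. All group
comparisons use Welch's t-test (unequal variances, Welch–Satterthwaite df):
the safer default where only "t-test" is specified, and the default of
common statistical software. Cohort analyses of this design sometimes carve
a small independent test population out of the top-30% group; since there is
no canonical rule for that split, the CLI exposes a seeded random holdout
(`--holdout-frac`) rather than prescribing one.

## Enrichment

The overlap unit is trait *variants* falling inside ≥1 candidate region,
each variant counted once; `--count-genes` switches to counting regions
containing ≥1 variant. The variant unit is the default because clustered
catalog hits naturally produce a permutation-null SD larger than its mean,
the regime real catalog enrichments show. Null regions are resampled
size-matched, chromosome chosen with probability ∝ (length − size + 1) and
start uniform — i.e. uniform over all valid genomic placements — and may
overlap each other. The normal-approximation two-sided P (2Φ(−|z|)) is the
primary output, with a rank-based empirical permutation P (add-one
smoothed) alongside; for |z| beyond ~2 the normal tail extrapolates past
what the permutation count can resolve, which is documented rather than
asserted. FDR is Benjamini–Hochberg within each permutation repeat; the
stability summary reports the per-trait z range across the independent
repeats.

## Pipeline defaults and problem sizes

The default configuration emulates the study scale: 97 samples, 20,000
simulated SNPs (~19.7k post-QC), one injected related pair (pruned to 96),
19 paired degraded call sets (4.2% flip / 10% missing), mixed-model scan,
0.30/0.30 extreme split, 1000 permutations × 5 repeats. The causal
architecture is sparse and strong — 8 SNPs at 1.2 RHI units per allele —
because with ~100 samples only per-allele effects near one phenotypic SD
are detectable at p < 5×10⁻⁵, which is also the effect-size regime such a
cohort reports. The bundled demo (150 × 6,000, 12 × 0.6 effects, 100
permutations) runs in seconds; the test suite scales replicate counts so
the whole run stays within a few minutes on one core. These sizes are the
package's own choices for a desk-scale analysis.

The pipeline also runs on real cohort exports, outside the test suite:
convert the genotype data to VCF or dosage TSV plus the (id, sex, age, rhi)
sample table, then run `vascgwas qc` and `vascgwas gwas --model mlm` with
the default thresholds.

## Known limitations

- No LD: multiple-testing burden and clumping behavior differ from real
  arrays; candidate SNPs are independent by construction.
- Non-LOCO mixed model: proximal contamination (the tested SNP contributing
  to the GRM) slightly deflates signal at large effect sizes.
- The REML profile is exact but O(n³) per fit via the eigendecomposition;
  fine to n ~ few thousand, not biobank scale.
- Permutation enrichment treats hits as points and regions as exchangeable
  with any same-size genomic span; no assembly gaps or LD-aware matching.
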