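# Small all-synthetic pipeline run (~10 s). Start from these settings and
# scale n_samples / n_snps / n_perm up toward the package defaults for a
# study-scale run.
out_dir: vascgwas_demo
seed: 0

# cohort
n_samples: 150
n_snps: 6000
maf_low: 0.05
maf_high: 0.5
n_related_pairs: 1
n_causal: 12
causal_effect: 0.6
noise_sd: 0.35

# paired degraded calls (serum cfDNA emulation)
cfdna_error_rate: 0.042
cfdna_missing_rate: 0.10
n_cfdna_pairs: 19

# QC / association
geno: 0.20
maf: 0.05
rel_cutoff: 0.05
model: mlm
suggestive: 5.0e-5

# burden + enrichment
top_frac: 0.30
bottom_frac: 0.30
n_genes: 80
n_traits: 4
hits_per_trait: 320
min_hits: 300
n_perm: 100
n_repeats: 2
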