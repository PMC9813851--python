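"""End-to-end pipeline orchestration with a flat YAML config and a manifest.

Stages: simulate (optional) -> qc -> adjust -> gwas -> candidates -> score ->
enrich. Every stage writes its outputs as TSV and appends a manifest entry
(file SHA-256, seed, record counts), so a rerun with the same config and
seed is reproducible file-by-file.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import assoc, enrich, io, qc, score, syndata
from .genome import toy_genome

log = logging.getLogger("vascgwas")


@dataclass
class PipelineConfig:
    """Flat configuration for one pipeline run."""

    out_dir: str = "vascgwas_run"
    seed: int = 0
    # synthetic cohort
    n_samples: int = 97
    n_snps: int = 20_000
    maf_low: float = 0.05
    maf_high: float = 0.5
    n_related_pairs: int = 1
    # sparse, large-effect architecture: with ~100 samples only per-allele
    # effects around one phenotypic SD are detectable at the suggestive
    # threshold, matching the effect magnitudes such a cohort reports
    n_causal: int = 8
    causal_effect: float = 1.2
    age_slope: float = -0.012
    sex_shift: float = -0.15
    intercept: float = 2.8
    noise_sd: float = 0.35
    # paired degraded calls (cfDNA emulation)
    cfdna_error_rate: float = 0.042
    cfdna_missing_rate: float = 0.10
    n_cfdna_pairs: int = 19
    # QC thresholds
    geno: float = 0.20
    maf: float = 0.05
    rel_cutoff: float = 0.05
    pca: int = 20
    # association
    model: str = "mlm"
    suggestive: float = 5e-5
    genomewide: float = 5e-8
    # burden
    top_frac: float = 0.30
    bottom_frac: float = 0.30
    # enrichment
    n_genes: int = 120
    n_traits: int = 8
    hits_per_trait: int = 400
    cluster_sd: float = 20_000.0
    enrich_frac: float = 0.3
    min_hits: int = 300
    n_perm: int = 1000
    n_repeats: int = 5

    def validate(self) -> None:
        if self.model not in ("lm", "mlm"):
            raise ValueError("model must be 'lm' or 'mlm'")
        for name in ("geno", "maf", "maf_low", "maf_high", "top_frac",
                     "bottom_frac", "cfdna_error_rate", "cfdna_missing_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.seed is None:
            raise ValueError("seed is mandatory")

    @classmethod
    def from_yaml(cls, path: str | os.PathLike, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        cfg = cls(**raw)
        cfg.validate()
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage on a fully synthetic cohort; return the manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(config.seed).generate_state(8)
    manifest: dict = {"config": asdict(config), "stages": {}, "counts": {}}

    def record(stage: str, path: Path, **counts) -> None:
        manifest["stages"].setdefault(stage, []).append(
            {"file": path.name, "sha256": _sha256(path)})
        manifest["counts"].update(counts)
        log.info("stage=%s file=%s %s", stage, path.name,
                 " ".join(f"{k}={v}" for k, v in counts.items()))

    genome = toy_genome()

    # --- simulate -----------------------------------------------------------
    G = syndata.simulate_genotypes(
        genome, config.n_samples, config.n_snps, config.maf_low,
        config.maf_high, config.n_related_pairs, seed=int(seeds[0]))
    rng = np.random.default_rng(int(seeds[1]))
    causal_ids = rng.choice(G.snps["id"], size=config.n_causal, replace=False)
    causal = {str(s): config.causal_effect for s in causal_ids}
    samples = syndata.simulate_phenotypes(
        G, causal, config.age_slope, config.sex_shift, config.intercept,
        config.noise_sd, seed=int(seeds[2]))
    genes = syndata.simulate_gene_map(genome, config.n_genes, seed=int(seeds[3]))

    io.write_vcf(G, out / "genotypes.vcf", genome)
    io.write_samples(samples, out / "samples.tsv")
    io.write_regions(genes, out / "genes.tsv")
    record("simulate", out / "genotypes.vcf",
           n_samples=G.n_samples, n_snps_simulated=G.n_snps)
    record("simulate", out / "samples.tsv")
    record("simulate", out / "genes.tsv", n_genes=len(genes))

    # paired degraded calls for the concordance check
    pair_ids = G.sample_ids[:config.n_cfdna_pairs]
    G_pairs = G.subset_samples(pair_ids)
    G_cfdna = syndata.degrade_calls(
        G_pairs, config.cfdna_error_rate, config.cfdna_missing_rate,
        seed=int(seeds[4]))
    overall, _, n_comp = qc.pair_concordance(
        G_pairs, G_cfdna, [(s, s) for s in pair_ids])
    record("concordance", out / "samples.tsv",
           concordance=round(overall, 4), n_calls_compared=n_comp)
    manifest["counts"]["concordance"] = overall

    # --- qc -----------------------------------------------------------------
    G_qc, report = qc.filter_variants(G, config.geno, config.maf)
    grm = qc.compute_grm(G_qc)
    missing = dict(zip(G_qc.sample_ids, np.isnan(G_qc.dosages).mean(axis=1)))
    kept, removed = qc.prune_related(grm, config.rel_cutoff, missing)
    coords, eigvals = qc.grm_pca(grm, min(config.pca, grm.n))
    io.write_grm(grm, out / "grm.tsv")
    report.to_frame().to_csv(out / "qc_report.tsv", sep="\t", index=False)
    coords.to_csv(out / "pca.tsv", sep="\t", index=False)
    record("qc", out / "qc_report.tsv",
           n_snps_in=report.n_snps_in, n_snps_out=report.n_snps_out,
           n_samples_removed_related=len(removed))
    record("qc", out / "grm.tsv")
    record("qc", out / "pca.tsv")

    if removed:
        G_qc = G_qc.subset_samples(kept)
        grm = qc.compute_grm(G_qc)
        samples = samples[samples["id"].isin(kept)].reset_index(drop=True)

    # --- adjust + gwas ------------------------------------------------------
    adj = assoc.adjust_phenotype(samples)
    adj.table.to_csv(out / "phenotype_adjusted.tsv", sep="\t", index=False)
    record("adjust", out / "phenotype_adjusted.tsv")

    if config.model == "mlm":
        fit = assoc.fit_mlm_null(adj, grm)
        records = assoc.assoc_mlm(G_qc, adj, grm, fit)
        manifest["counts"]["h2"] = fit.h2
        manifest["counts"]["mlm_converged"] = fit.converged
    else:
        records = assoc.assoc_linear(G_qc, adj)
    lam = assoc.genomic_lambda(records)
    records.to_csv(out / "assoc.tsv", sep="\t", index=False)
    record("gwas", out / "assoc.tsv", genomic_lambda=round(lam, 4))
    manifest["counts"]["genomic_lambda"] = lam

    candidates = assoc.call_candidates(records, genes,
                                       config.suggestive, config.genomewide)
    candidates.to_csv(out / "candidates.tsv", sep="\t", index=False)
    record("candidates", out / "candidates.tsv",
           n_candidate_snps=len(candidates),
           n_candidate_genes=candidates["closest_gene"].replace("", np.nan).nunique())

    # --- score --------------------------------------------------------------
    if len(candidates):
        pas = score.define_protective_alleles(candidates[candidates["b"] != 0])
        burden = score.burden_scores(G_qc, pas)
        groups = score.split_extremes(adj, config.top_frac, config.bottom_frac)
        merged = burden.merge(groups, on="id")
        dec = merged.loc[merged["group"] == "decelerated", "burden"]
        acc = merged.loc[merged["group"] == "accelerated", "burden"]
        t, dfree, p, means = score.compare_burden(dec.to_numpy(), acc.to_numpy())
        merged.to_csv(out / "burden.tsv", sep="\t", index=False)
        summary = {"t": t, "df": dfree, "p": p,
                   "mean_decelerated": means[0], "mean_accelerated": means[1],
                   "n_decelerated": int(len(dec)), "n_accelerated": int(len(acc))}
        (out / "burden_test.json").write_text(json.dumps(summary, indent=2))
        record("score", out / "burden.tsv", burden_p=p)
        record("score", out / "burden_test.json")
        manifest["counts"]["burden_test"] = summary
        candidate_regions = _candidate_gene_regions(candidates, genes)
    else:
        log.warning("no candidate SNPs below suggestive threshold; "
                    "skipping burden scoring")
        candidate_regions = genes.head(0)

    # --- enrich -------------------------------------------------------------
    if len(candidate_regions):
        catalog = syndata.simulate_trait_catalog(
            genome, config.n_traits, config.hits_per_trait, config.cluster_sd,
            enriched_regions=candidate_regions, enrich_frac=config.enrich_frac,
            seed=int(seeds[5]))
        # planted enrichment goes into trait_00 only
        uniform = syndata.simulate_trait_catalog(
            genome, config.n_traits - 1, config.hits_per_trait,
            config.cluster_sd, seed=int(seeds[6]))
        catalog.traits = {"trait_00": catalog.traits["trait_00"],
                          **{f"bg_{k}": v for k, v in uniform.traits.items()}}
        catalog = enrich.trait_filter(catalog, config.min_hits)
        io.write_catalog(catalog, out / "trait_catalog.tsv")
        rec, stability = enrich.run_enrichment(
            genome, candidate_regions, catalog, config.n_perm,
            config.n_repeats, seed=int(seeds[7]))
        rec.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        stability.to_csv(out / "enrichment_stability.tsv", sep="\t", index=False)
        record("enrich", out / "enrichment.tsv", n_traits_tested=len(catalog.names))
        record("enrich", out / "enrichment_stability.tsv")
        top = rec.loc[rec["repeat"] == 0].sort_values("z", ascending=False)
        if len(top):
            manifest["counts"]["top_trait"] = str(top["trait"].iloc[0])
            manifest["counts"]["top_trait_z"] = float(top["z"].iloc[0])

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def _candidate_gene_regions(candidates, genes):
    """Regions of the genes closest to candidate SNPs (the enrichment input)."""
    names = set(candidates["closest_gene"]) - {""}
    return genes[genes["name"].isin(names)].reset_index(drop=True)


def demo_config(out_dir: str, seed: int = 0) -> PipelineConfig:
    """Small all-synthetic configuration that runs in seconds."""
    return PipelineConfig(
        out_dir=out_dir, seed=seed, n_samples=150, n_snps=6000,
        n_causal=12, causal_effect=0.6, n_perm=100, n_repeats=2,
        n_traits=4, hits_per_trait=320, n_genes=80)
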