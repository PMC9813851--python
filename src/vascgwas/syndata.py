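"""Synthetic cohort generators.

Everything downstream of this module (QC, association, burden scoring,
enrichment) is exercised on cohorts built here: Hardy-Weinberg genotypes over
a uniform MAF spectrum, an age>=50 cohort with sex- and age-dependent RHI plus
sparse causal SNP effects, injected related pairs, paired error/missingness-
degraded genotype calls (emulating serum cfDNA vs whole-blood gDNA), clustered
trait-variant catalogs, and a toy gene map. All generators are deterministic
under a fixed seed.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .genome import Genome, validate_regions
from .types import GenotypeMatrix, validate_samples, TraitCatalog

_BASES = np.array(list("ACGT"))


def _draw_positions(genome: Genome, n: int, rng: np.random.Generator) -> pd.DataFrame:
    """n unique (chr, bp) positions, chromosome chosen length-proportionally."""
    names = genome.names
    lengths = np.array([genome.length_of(c) for c in names], dtype=np.int64)
    probs = lengths / lengths.sum()
    seen: set[tuple[int, int]] = set()
    rows: list[tuple[int, int]] = []
    while len(rows) < n:
        k = n - len(rows)
        chroms = rng.choice(len(names), size=k, p=probs)
        bps = rng.integers(1, lengths[chroms] + 1)
        for c, b in zip(chroms, bps):
            key = (int(c), int(b))
            if key not in seen:
                seen.add(key)
                rows.append(key)
    rows.sort()
    df = pd.DataFrame(rows, columns=["chr_idx", "bp"])
    df["chr"] = [names[i] for i in df["chr_idx"]]
    return df[["chr", "bp"]]


def simulate_genotypes(
    genome: Genome,
    n_samples: int,
    n_snps: int,
    maf_low: float = 0.05,
    maf_high: float = 0.5,
    n_related_pairs: int = 0,
    seed: int = 0,
) -> GenotypeMatrix:
    """HWE genotypes with per-SNP MAF ~ Uniform(maf_low, maf_high).

    Each related pair shares half of one founder's genome: the second member
    of the pair copies the first member's dosage at a random 50% of SNPs,
    which drives the estimated genomic relationship above the 0.05 pruning
    threshold without coalescent machinery.
    """
    if not (0 < maf_low <= maf_high <= 0.5):
        raise ValueError("need 0 < maf_low <= maf_high <= 0.5")
    if 2 * n_related_pairs > n_samples:
        raise ValueError("n_related_pairs * 2 exceeds n_samples")
    rng = np.random.default_rng(seed)

    pos = _draw_positions(genome, n_snps, rng)
    maf = rng.uniform(maf_low, maf_high, size=n_snps)
    dosages = rng.binomial(2, maf, size=(n_samples, n_snps)).astype(float)

    for pair in range(n_related_pairs):
        a, b = 2 * pair, 2 * pair + 1
        shared = rng.random(n_snps) < 0.5
        dosages[b, shared] = dosages[a, shared]

    a2_idx = rng.integers(0, 4, size=n_snps)
    a1_idx = (a2_idx + rng.integers(1, 4, size=n_snps)) % 4
    snps = pos.assign(a1=_BASES[a1_idx], a2=_BASES[a2_idx],
                      freq=dosages.mean(axis=0) / 2.0,
                      sim_maf=maf)  # generating MAF, kept for diagnostics
    snps.insert(0, "id", snps["chr"].astype(str) + ":" + snps["bp"].astype(str))

    sample_ids = [f"S{i:04d}" for i in range(n_samples)]
    return GenotypeMatrix(sample_ids, snps.reset_index(drop=True), dosages)


def simulate_structured_genotypes(
    genome: Genome,
    n_per_pop: tuple[int, ...] = (100, 100),
    n_snps: int = 1000,
    fst: float = 0.1,
    maf_low: float = 0.05,
    maf_high: float = 0.5,
    seed: int = 0,
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Two-or-more subpopulations under the Balding-Nichols model.

    Ancestral frequencies are uniform on [maf_low, maf_high]; each
    subpopulation's frequency is Beta(p(1-F)/F, (1-p)(1-F)/F) around the
    ancestral p with divergence F = ``fst``. Returns the genotype matrix and
    an integer population label per sample — the stock test bed for
    population structure (PCA separation, association inflation).
    """
    if not 0 < fst < 1:
        raise ValueError("fst must be in (0, 1)")
    rng = np.random.default_rng(seed)
    pos = _draw_positions(genome, n_snps, rng)
    p_anc = rng.uniform(maf_low, maf_high, size=n_snps)
    a, b = p_anc * (1 - fst) / fst, (1 - p_anc) * (1 - fst) / fst

    blocks, labels = [], []
    for k, n_k in enumerate(n_per_pop):
        p_pop = np.clip(rng.beta(a, b), 1e-6, 1 - 1e-6)
        blocks.append(rng.binomial(2, p_pop, size=(n_k, n_snps)).astype(float))
        labels.extend([k] * n_k)
    dosages = np.vstack(blocks)

    a2_idx = rng.integers(0, 4, size=n_snps)
    a1_idx = (a2_idx + rng.integers(1, 4, size=n_snps)) % 4
    snps = pos.assign(a1=_BASES[a1_idx], a2=_BASES[a2_idx],
                      freq=dosages.mean(axis=0) / 2.0)
    snps.insert(0, "id", snps["chr"].astype(str) + ":" + snps["bp"].astype(str))
    sample_ids = [f"S{i:04d}" for i in range(dosages.shape[0])]
    G = GenotypeMatrix(sample_ids, snps.reset_index(drop=True), dosages)
    return G, np.asarray(labels)


def simulate_phenotypes(
    G: GenotypeMatrix,
    causal: Mapping[str, float] | None = None,
    age_slope: float = -0.012,
    sex_shift: float = -0.15,
    intercept: float = 2.8,
    noise_sd: float = 0.35,
    seed: int = 0,
) -> pd.DataFrame:
    """Sample table with RHI generated from age, sex and sparse SNP effects.

    rhi = intercept + age_slope*age + sex_shift*1[F] + sum(effect * dosage)
    + N(0, noise_sd^2); ages ~ Uniform{50..85}, sex ~ Bernoulli(0.5). Missing
    causal dosages contribute the SNP's mean dosage. Defaults emulate an
    elderly cohort where endothelial function declines with age, slightly
    faster in women, around a healthy-adult RHI baseline.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    causal = dict(causal or {})
    rng = np.random.default_rng(seed)
    n = G.n_samples

    age = rng.integers(50, 86, size=n).astype(float)
    sex = np.where(rng.random(n) < 0.5, "F", "M")
    rhi = intercept + age_slope * age + sex_shift * (sex == "F")

    if causal:
        ids = list(G.snps["id"])
        index = {s: i for i, s in enumerate(ids)}
        unknown = [s for s in causal if s not in index]
        if unknown:
            raise KeyError(f"causal SNPs not in genotype matrix: {unknown[:5]}")
        cols = np.array([index[s] for s in causal])
        effects = np.array([causal[s] for s in causal])
        dose = G.dosages[:, cols].copy()
        col_mean = np.nanmean(dose, axis=0)
        nan_r, nan_c = np.nonzero(np.isnan(dose))
        dose[nan_r, nan_c] = col_mean[nan_c]
        rhi = rhi + dose @ effects

    rhi = rhi + rng.normal(0.0, noise_sd, size=n)
    samples = pd.DataFrame({"id": G.sample_ids, "sex": sex, "age": age, "rhi": rhi})
    return validate_samples(samples)


def degrade_calls(
    G: GenotypeMatrix,
    error_rate: float,
    missing_rate: float,
    seed: int = 0,
) -> GenotypeMatrix:
    """Error/missingness-degraded copy of a call set.

    Emulates re-genotyping the same individuals from a degraded template
    (serum cfDNA after whole-genome amplification vs whole-blood gDNA): each
    call is independently dropped to missing with ``missing_rate``, otherwise
    flipped to one of the two other dosage values with ``error_rate``.
    Concordance against the original, restricted to doubly non-missing calls,
    converges to 1 - error_rate.
    """
    if not (0 <= error_rate <= 1 and 0 <= missing_rate <= 1):
        raise ValueError("rates must be in [0, 1]")
    rng = np.random.default_rng(seed)
    dosages = G.dosages.copy()
    shape = dosages.shape

    miss = rng.random(shape) < missing_rate
    err = (~miss) & (rng.random(shape) < error_rate) & np.isfinite(dosages)
    # symmetric flip: move to one of the two other valid dosages
    shift = rng.integers(1, 3, size=shape)
    dosages[err] = (dosages[err] + shift[err]) % 3
    dosages[miss] = np.nan

    out = GenotypeMatrix(list(G.sample_ids), G.snps.copy(), dosages)
    out.refresh_freq()
    return out


def simulate_trait_catalog(
    genome: Genome,
    n_traits: int,
    hits_per_trait: int,
    cluster_sd: float = 50_000.0,
    enriched_regions: pd.DataFrame | None = None,
    enrich_frac: float = 0.0,
    seed: int = 0,
) -> TraitCatalog:
    """Clustered trait-variant catalogs (a GWAS-catalog stand-in).

    Hits are Gaussian clusters (SD ``cluster_sd`` bp) around uniformly placed
    centers, mimicking the LD-driven clumping of reported associations that
    makes the permutation-null SD of overlap counts exceed its mean. With
    ``enriched_regions``, a fraction ``enrich_frac`` of each trait's hits is
    instead placed uniformly inside those regions (planted enrichment).
    """
    if hits_per_trait < 1:
        raise ValueError("hits_per_trait must be >= 1")
    if enrich_frac > 0 and (enriched_regions is None or not len(enriched_regions)):
        raise ValueError("enrich_frac > 0 requires non-empty enriched_regions")
    rng = np.random.default_rng(seed)
    lengths = genome.lengths

    if enriched_regions is not None and len(enriched_regions):
        validate_regions(enriched_regions, genome)
        reg_chr = enriched_regions["chr"].astype(str).to_numpy()
        reg_start = enriched_regions["start"].to_numpy(np.int64)
        reg_end = enriched_regions["end"].to_numpy(np.int64)
        reg_len = reg_end - reg_start + 1
        reg_p = reg_len / reg_len.sum()

    traits: dict[str, pd.DataFrame] = {}
    # ~20 hits per cluster keeps the catalog visibly clumped at desk scale
    n_clusters = max(1, hits_per_trait // 20)
    for t in range(n_traits):
        n_enriched = int(round(enrich_frac * hits_per_trait))
        n_background = hits_per_trait - n_enriched

        chroms: list[str] = []
        bps: list[int] = []
        if n_background:
            centers = _draw_positions(genome, n_clusters, rng)
            which = rng.integers(0, n_clusters, size=n_background)
            for ci in which:
                chrom = str(centers["chr"].iloc[ci])
                bp = int(round(rng.normal(centers["bp"].iloc[ci], cluster_sd)))
                bps.append(int(np.clip(bp, 1, lengths[chrom])))
                chroms.append(chrom)
        for _ in range(n_enriched):
            ri = rng.choice(len(reg_len), p=reg_p)
            chroms.append(str(reg_chr[ri]))
            bps.append(int(rng.integers(reg_start[ri], reg_end[ri] + 1)))

        traits[f"trait_{t:02d}"] = pd.DataFrame({"chr": chroms, "bp": bps})
    return TraitCatalog(traits)


def simulate_gene_map(
    genome: Genome,
    n_genes: int,
    min_len: int = 2_000,
    max_len: int = 80_000,
    seed: int = 0,
    max_tries_per_gene: int = 200,
) -> pd.DataFrame:
    """Non-overlapping named gene intervals, uniformly placed on the genome."""
    if min_len < 1 or max_len < min_len:
        raise ValueError("need 1 <= min_len <= max_len")
    shortest = min(genome.lengths.values())
    if max_len >= shortest:
        raise ValueError("max_len must be shorter than the shortest chromosome")
    rng = np.random.default_rng(seed)
    names = genome.names
    lengths = np.array([genome.length_of(c) for c in names], dtype=np.int64)
    probs = lengths / lengths.sum()

    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in names}
    rows = []
    tries = 0
    budget = max_tries_per_gene * n_genes
    while len(rows) < n_genes:
        if tries >= budget:
            raise RuntimeError(
                f"could not place {n_genes} non-overlapping genes "
                f"after {budget} tries")
        tries += 1
        ci = rng.choice(len(names), p=probs)
        chrom = names[ci]
        glen = int(rng.integers(min_len, max_len + 1))
        start = int(rng.integers(1, lengths[ci] - glen + 2))
        end = start + glen - 1
        if any(start <= e and s <= end for s, e in placed[chrom]):
            continue
        placed[chrom].append((start, end))
        rows.append((chrom, start, end))

    df = pd.DataFrame(rows, columns=["chr", "start", "end"])
    df = df.sort_values(["chr", "start"], key=_chrom_sort_key).reset_index(drop=True)
    df["name"] = [f"GENE{i:04d}" for i in range(len(df))]
    return validate_regions(df, genome)


def _chrom_sort_key(col: pd.Series) -> pd.Series:
    if col.name == "chr":
        return col.map(lambda c: (0, int(c)) if str(c).isdigit() else (1, str(c)))
    return col
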