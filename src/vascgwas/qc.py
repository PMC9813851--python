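"""SNP-level quality control, paired-sample concordance, GRM, relatedness
pruning and PCA.

The genomic relationship between samples j and k is estimated as

    A_jk = (1/m) * sum_i (x_ij - 2 p_i)(x_ik - 2 p_i) / (2 p_i (1 - p_i))

over the m SNPs non-missing in both samples (pairwise-complete, the common
tool convention), with p_i the sample A1 frequency and x the A1 dosage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .types import GenotypeMatrix


@dataclass
class QcReport:
    n_snps_in: int
    n_removed_missingness: int
    n_removed_maf: int
    n_snps_out: int
    removed_missingness_ids: list[str] = field(default_factory=list)
    removed_maf_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        assert self.n_snps_out == (
            self.n_snps_in - self.n_removed_missingness - self.n_removed_maf)

    def to_frame(self) -> pd.DataFrame:
        rows = ([("missingness", s) for s in self.removed_missingness_ids]
                + [("maf", s) for s in self.removed_maf_ids])
        return pd.DataFrame(rows, columns=["filter", "snp_id"])


def filter_variants(
    G: GenotypeMatrix,
    max_missing: float = 0.20,
    min_maf: float = 0.05,
) -> tuple[GenotypeMatrix, QcReport]:
    """Drop SNPs with missingness > ``max_missing`` or MAF < ``min_maf``.

    MAF is recomputed from non-missing calls; both boundaries follow the
    filter direction: missingness exactly at the threshold is kept, MAF
    exactly at the threshold is kept. A SNP failing both filters is counted
    once, attributed to missingness. Surviving SNPs are re-polarized so that
    A1 is the minor allele (freq <= 0.5).
    """
    if not (0 <= max_missing <= 1 and 0 <= min_maf <= 1):
        raise ValueError("thresholds must be in [0, 1]")
    miss = G.missing_fraction()
    freq = G.observed_freq()
    with np.errstate(invalid="ignore"):
        maf = np.minimum(freq, 1.0 - freq)

    fail_miss = miss > max_missing
    fail_maf = (~fail_miss) & (np.isnan(maf) | (maf < min_maf))
    keep = ~(fail_miss | fail_maf)

    ids = G.snps["id"].to_numpy()
    report = QcReport(
        n_snps_in=G.n_snps,
        n_removed_missingness=int(fail_miss.sum()),
        n_removed_maf=int(fail_maf.sum()),
        n_snps_out=int(keep.sum()),
        removed_missingness_ids=list(ids[fail_miss]),
        removed_maf_ids=list(ids[fail_maf]),
    )

    out = G.subset_snps(keep)
    # re-polarize so A1 is minor
    f = freq[keep]
    flip = f > 0.5
    if flip.any():
        out.dosages[:, flip] = 2.0 - out.dosages[:, flip]
        snps = out.snps
        a1 = snps["a1"].to_numpy().copy()
        a2 = snps["a2"].to_numpy().copy()
        a1[flip], a2[flip] = a2[flip], a1[flip].copy()
        out.snps = snps.assign(a1=a1, a2=a2)
    out.refresh_freq()
    return out, report


def pair_concordance(
    G1: GenotypeMatrix,
    G2: GenotypeMatrix,
    id_pairs: Sequence[tuple[str, str]],
) -> tuple[float, dict[tuple[str, str], float], int]:
    """Genotype concordance between paired samples of two call sets.

    SNPs are intersected by (chr, bp, allele pair); a SNP typed with opposite
    polarity in the two sets is compared after recoding dosage d -> 2 - d.
    Concordance counts matching dosage calls over calls non-missing in both
    members of a pair; ``overall`` pools all pairs.
    """
    key1 = {(r.chr, r.bp, frozenset((r.a1, r.a2))): i
            for i, r in enumerate(G1.snps.itertuples())}
    idx1, idx2, flip = [], [], []
    for j, r in enumerate(G2.snps.itertuples()):
        k = (r.chr, r.bp, frozenset((r.a1, r.a2)))
        if k in key1:
            i = key1[k]
            idx1.append(i)
            idx2.append(j)
            flip.append(G1.snps["a1"].iat[i] != r.a1)
    if not idx1:
        raise ValueError("no SNPs shared between the two call sets")

    d1 = G1.dosages[:, idx1]
    d2 = G2.dosages[:, idx2]
    d2 = np.where(np.asarray(flip), 2.0 - d2, d2)

    pos1 = {s: i for i, s in enumerate(G1.sample_ids)}
    pos2 = {s: i for i, s in enumerate(G2.sample_ids)}
    per_pair: dict[tuple[str, str], float] = {}
    match_total = 0
    n_total = 0
    for s1, s2 in id_pairs:
        if s1 not in pos1 or s2 not in pos2:
            raise KeyError(f"pair ({s1}, {s2}) not present in both call sets")
        a = d1[pos1[s1]]
        b = d2[pos2[s2]]
        both = np.isfinite(a) & np.isfinite(b)
        n = int(both.sum())
        m = int((a[both] == b[both]).sum())
        per_pair[(s1, s2)] = m / n if n else np.nan
        match_total += m
        n_total += n
    if n_total == 0:
        raise ValueError("no calls non-missing in both members of any pair")
    return match_total / n_total, per_pair, n_total


@dataclass
class Grm:
    """Genetic relationship matrix with per-pair SNP counts."""

    sample_ids: list[str]
    matrix: np.ndarray          # n x n, NaN where no SNPs were shared
    n_snps_used: int            # SNPs entering the estimator (variance > 0)
    pair_counts: np.ndarray | None = None

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        ids = self.sample_ids
        for i in range(self.n):
            for j in range(i + 1):
                m = (self.pair_counts[i, j] if self.pair_counts is not None
                     else self.n_snps_used)
                rows.append((ids[i], ids[j], int(m), self.matrix[i, j]))
        return pd.DataFrame(rows, columns=["id1", "id2", "n_snps", "value"])


def compute_grm(G: GenotypeMatrix) -> Grm:
    """Estimate the GRM from standardized A1 dosages (pairwise-complete)."""
    if G.n_samples < 2:
        raise ValueError("need at least 2 samples")
    p = G.observed_freq()
    usable = np.isfinite(p) & (p > 0) & (p < 1)
    X = G.dosages[:, usable]
    p = p[usable]

    Z = (X - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    obs = np.isfinite(Z)
    Z = np.where(obs, Z, 0.0)
    counts = obs.astype(float) @ obs.T.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        A = (Z @ Z.T) / counts
    A[counts == 0] = np.nan
    return Grm(list(G.sample_ids), A, int(usable.sum()), counts.astype(np.int64))


def prune_related(
    grm: Grm,
    threshold: float = 0.05,
    missingness: Mapping[str, float] | None = None,
) -> tuple[list[str], list[str]]:
    """Greedy pruning until no pair exceeds ``threshold`` relationship.

    Repeatedly removes the sample with the most over-threshold partners
    (ties broken by larger genotype missingness if supplied, then by
    lexicographically larger id), so exactly one member of each isolated
    related pair is dropped and the result is order-independent.
    """
    ids = list(grm.sample_ids)
    A = np.array(grm.matrix, dtype=float)
    np.fill_diagonal(A, 0.0)
    active = dict.fromkeys(range(len(ids)), True)
    removed: list[str] = []

    def over(i: int) -> int:
        return int(sum(1 for j in active if j != i and A[i, j] > threshold))

    while True:
        degrees = {i: over(i) for i in active}
        worst = max(degrees.values(), default=0)
        if worst == 0:
            break
        cand = [i for i, d in degrees.items() if d == worst]
        if missingness is not None and len(cand) > 1:
            top = max(missingness.get(ids[i], 0.0) for i in cand)
            cand = [i for i in cand
                    if missingness.get(ids[i], 0.0) == top]
        drop = max(cand, key=lambda i: ids[i])
        removed.append(ids[drop])
        del active[drop]

    kept = [ids[i] for i in sorted(active)]
    removed.sort()
    return kept, removed


def grm_pca(grm: Grm, k: int = 20) -> tuple[pd.DataFrame, np.ndarray]:
    """Top-k eigenvectors of the GRM, scaled by sqrt(eigenvalue).

    Returns (coordinates, eigenvalues) with eigenvalues non-increasing;
    coordinate columns are PC1..PCk with PC_i = eigvec_i * sqrt(max(eig_i, 0)).
    """
    if k > grm.n:
        raise ValueError("k exceeds the number of samples")
    if not np.isfinite(grm.matrix).all():
        raise ValueError("GRM contains non-finite entries")
    A = (grm.matrix + grm.matrix.T) / 2.0
    vals, vecs = np.linalg.eigh(A)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    coords = vecs[:, :k] * np.sqrt(np.clip(vals[:k], 0.0, None))
    df = pd.DataFrame(coords, columns=[f"PC{i + 1}" for i in range(k)])
    df.insert(0, "id", grm.sample_ids)
    return df, vals[:k]
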