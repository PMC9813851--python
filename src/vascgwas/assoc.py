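"""Phenotype adjustment and genome-wide association.

The phenotype model follows the two-step convention for quantitative vascular
function: RHI is regressed on age within each sex stratum (y = b0 + b1*age + e)
and the residuals are standardized to z-scores per stratum; association then
tests each SNP's A1 dosage against z, either by ordinary least squares (lm)
or by a mixed linear model (mlm) with a polygenic random effect whose
covariance is the GRM, variance components estimated once by REML on the null
model and reused per SNP.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .qc import Grm
from .types import GenotypeMatrix, validate_samples

CHI2_1_MEDIAN = 0.4549364231195724  # median of the 1-df chi-square


@dataclass
class AdjustedPhenotype:
    """Per-sample age-adjusted, sex-stratified standardized phenotype."""

    table: pd.DataFrame                    # id, sex, age, rhi, residual, z
    fits: dict[str, tuple[float, float]]   # sex -> (b0, b1)

    def __post_init__(self) -> None:
        for sex, sub in self.table.groupby("sex"):
            z = sub["z"].to_numpy()
            if abs(z.mean()) > 1e-10 or abs(z.std(ddof=1) - 1) > 1e-10:
                raise ValueError(f"z-scores not standardized in stratum {sex}")

    def z_for(self, ids: list[str]) -> np.ndarray:
        s = self.table.set_index("id")["z"]
        return s.loc[ids].to_numpy(dtype=float)


def adjust_phenotype(samples: pd.DataFrame) -> AdjustedPhenotype:
    """OLS of rhi on age per sex stratum; residuals -> z within stratum.

    Uses the unbiased (n-1) SD for standardization. Raises on strata with
    fewer than 3 samples, no age variance, or zero residual variance.
    """
    validate_samples(samples)
    out = samples.copy().reset_index(drop=True)
    out["residual"] = np.nan
    out["z"] = np.nan
    fits: dict[str, tuple[float, float]] = {}
    for sex, sub in out.groupby("sex"):
        if len(sub) < 3:
            raise ValueError(f"stratum {sex!r} has fewer than 3 samples")
        age = sub["age"].to_numpy(dtype=float)
        rhi = sub["rhi"].to_numpy(dtype=float)
        if np.var(age) == 0:
            raise ValueError(f"stratum {sex!r} has zero age variance")
        b1, b0 = np.polyfit(age, rhi, 1)
        resid = rhi - (b0 + b1 * age)
        sd = resid.std(ddof=1)
        if sd <= 1e-10 * max(1.0, float(np.abs(rhi).max())):
            raise ValueError(f"zero residual variance in stratum {sex!r}")
        out.loc[sub.index, "residual"] = resid
        out.loc[sub.index, "z"] = (resid - resid.mean()) / sd
        fits[str(sex)] = (float(b0), float(b1))
    return AdjustedPhenotype(out, fits)


def wald_p(b: float | np.ndarray, se: float | np.ndarray) -> float | np.ndarray:
    """Two-sided Wald p-value, p = 2*Phi(-|b/se|), via the survival function."""
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("standard error must be positive")
    p = 2.0 * stats.norm.sf(np.abs(np.asarray(b, dtype=float) / se))
    return float(p) if p.ndim == 0 else p


ASSOC_COLUMNS = ["id", "chr", "bp", "a1", "a2", "freq", "b", "se", "p", "model"]


def _align(G: GenotypeMatrix, z: AdjustedPhenotype) -> tuple[GenotypeMatrix, np.ndarray]:
    ids = [s for s in G.sample_ids if s in set(z.table["id"])]
    if not ids:
        raise ValueError("no samples shared between genotypes and phenotype")
    Gs = G if ids == G.sample_ids else G.subset_samples(ids)
    return Gs, z.z_for(ids)


def assoc_linear(
    G: GenotypeMatrix,
    z: AdjustedPhenotype,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-SNP OLS of z on A1 dosage (+ intercept + optional covariates).

    Samples with a missing dosage are dropped per SNP (complete-case). SNPs
    with zero dosage variance are emitted with b/se/p set to NaN.
    """
    Gs, y = _align(G, z)
    X = Gs.dosages
    n_snps = Gs.n_snps

    if covariates is not None:
        C = (covariates.set_index("id").loc[Gs.sample_ids]
             .to_numpy(dtype=float)
             if "id" in covariates.columns else
             covariates.loc[Gs.sample_ids].to_numpy(dtype=float))
        b = np.full(n_snps, np.nan)
        se = np.full(n_snps, np.nan)
        for j in range(n_snps):
            x = X[:, j]
            ok = np.isfinite(x)
            if ok.sum() < C.shape[1] + 3 or np.var(x[ok]) == 0:
                continue
            W = np.column_stack([np.ones(ok.sum()), x[ok], C[ok]])
            coef, *_ = np.linalg.lstsq(W, y[ok], rcond=None)
            resid = y[ok] - W @ coef
            dof = ok.sum() - W.shape[1]
            sigma2 = resid @ resid / dof
            cov = sigma2 * np.linalg.inv(W.T @ W)
            b[j], se[j] = coef[1], np.sqrt(cov[1, 1])
    else:
        # vectorized complete-case simple regression
        ok = np.isfinite(X)
        n = ok.sum(axis=0).astype(float)
        Xz = np.where(ok, X, 0.0)
        yv = y[:, None] * ok
        sx = Xz.sum(axis=0)
        sy = yv.sum(axis=0)
        sxx = (Xz * Xz).sum(axis=0)
        sxy = (Xz * y[:, None]).sum(axis=0)
        syy = (yv * y[:, None]).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            Sxx = sxx - sx * sx / n
            Sxy = sxy - sx * sy / n
            Syy = syy - sy * sy / n
            b = Sxy / Sxx
            rss = Syy - b * Sxy
            dof = n - 2
            se = np.sqrt(np.maximum(rss, 0.0) / dof / Sxx)
        bad = (Sxx <= 0) | (n < 3) | ~np.isfinite(se) | (se <= 0)
        b = np.where(bad, np.nan, b)
        se = np.where(bad, np.nan, se)

    return _records(Gs, b, se, "lm")


def _records(G: GenotypeMatrix, b: np.ndarray, se: np.ndarray, model: str) -> pd.DataFrame:
    p = np.full_like(b, np.nan)
    ok = np.isfinite(b) & np.isfinite(se) & (se > 0)
    p[ok] = 2.0 * stats.norm.sf(np.abs(b[ok] / se[ok]))
    rec = G.snps[["id", "chr", "bp", "a1", "a2", "freq"]].copy()
    rec["b"], rec["se"], rec["p"], rec["model"] = b, se, p, model
    return rec


@dataclass
class MlmFit:
    """REML variance components of the polygenic null model."""

    sigma_g2: float
    sigma_e2: float
    h2: float
    loglik: float
    converged: bool
    # eigendecomposition of the GRM, cached for per-SNP GLS
    eigvals: np.ndarray = field(repr=False, default=None)
    eigvecs: np.ndarray = field(repr=False, default=None)
    sample_ids: list[str] = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if self.sigma_g2 < 0 or self.sigma_e2 < 0:
            raise ValueError("variance components must be non-negative")
        if not (0 <= self.h2 < 1):
            raise ValueError("h2 must be in [0, 1)")


def _reml_neg_loglik(h2: float, lam: np.ndarray, Wt: np.ndarray, yt: np.ndarray) -> float:
    w = 1.0 / (h2 * lam + (1.0 - h2))
    WtW = (Wt * w[:, None]).T @ Wt
    Wty = (Wt * w[:, None]).T @ yt
    alpha = np.linalg.solve(WtW, Wty)
    r = yt - Wt @ alpha
    rss = float(r @ (w * r))
    nc = len(yt) - Wt.shape[1]
    sign, logdet_WtW = np.linalg.slogdet(WtW)
    ll = -0.5 * (nc * np.log(rss / nc)
                 + np.sum(np.log(h2 * lam + (1.0 - h2)))
                 + logdet_WtW)
    return -ll


def fit_mlm_null(
    z: AdjustedPhenotype,
    grm: Grm,
    covariates: pd.DataFrame | None = None,
) -> MlmFit:
    """REML fit of y = Wa + g + e with g ~ N(0, A s2g), e ~ N(0, I s2e).

    The restricted likelihood is profiled over the total variance and
    optimized in one dimension over h2 = s2g/(s2g+s2e) on the eigenbasis of
    the (PSD-clipped) GRM — exact for cohorts up to a few thousand samples.
    """
    ids = [s for s in grm.sample_ids if s in set(z.table["id"])]
    idx = [grm.sample_ids.index(s) for s in ids]
    A = grm.matrix[np.ix_(idx, idx)]
    if not np.isfinite(A).all():
        raise ValueError("GRM contains non-finite entries")
    y = z.z_for(ids)
    n = len(y)

    lam, U = np.linalg.eigh((A + A.T) / 2.0)
    lam = np.clip(lam, 0.0, None)
    yt = U.T @ y
    W = np.ones((n, 1))
    if covariates is not None:
        C = (covariates.set_index("id").loc[ids].to_numpy(dtype=float)
             if "id" in covariates.columns else
             covariates.loc[ids].to_numpy(dtype=float))
        W = np.column_stack([W, C])
    Wt = U.T @ W

    upper = 1.0 - 1e-6
    res = optimize.minimize_scalar(
        _reml_neg_loglik, bounds=(0.0, upper), args=(lam, Wt, yt),
        method="bounded", options={"xatol": 1e-8})
    h2 = float(np.clip(res.x, 0.0, upper))

    # flat-likelihood detection: compare against both boundaries
    ll_opt = -_reml_neg_loglik(h2, lam, Wt, yt)
    ll_0 = -_reml_neg_loglik(1e-12, lam, Wt, yt)
    converged = bool(res.success)
    if ll_opt <= ll_0 + 1e-8:
        h2 = 0.0
        ll_opt = ll_0

    w = 1.0 / (h2 * lam + (1.0 - h2))
    WtW = (Wt * w[:, None]).T @ Wt
    alpha = np.linalg.solve(WtW, (Wt * w[:, None]).T @ yt)
    r = yt - Wt @ alpha
    nc = n - W.shape[1]
    sigma_total = float(r @ (w * r)) / nc
    return MlmFit(
        sigma_g2=h2 * sigma_total,
        sigma_e2=(1.0 - h2) * sigma_total,
        h2=h2,
        loglik=ll_opt,
        converged=converged,
        eigvals=lam,
        eigvecs=U,
        sample_ids=ids,
    )


def assoc_mlm(
    G: GenotypeMatrix,
    z: AdjustedPhenotype,
    grm: Grm,
    fit: MlmFit,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-SNP GLS with V = A*s2g + I*s2e fixed from the null REML fit.

    This is the non-LOCO mixed-model association: the whole-genome GRM and
    the null-model variance components are reused for every SNP. Standard
    errors carry a per-SNP residual dispersion factor r'V^-1 r/(n-k), so the
    test reduces exactly to per-SNP OLS when s2g = 0. SNPs with missing calls
    fall back to a complete-case GLS solve on the V submatrix.
    """
    if fit.sample_ids is None or fit.eigvecs is None:
        raise ValueError("MlmFit must carry its eigendecomposition")
    ids = fit.sample_ids
    Gs = G if G.sample_ids == ids else G.subset_samples(ids)
    y = z.z_for(ids)
    n = len(ids)

    d = fit.sigma_g2 * fit.eigvals + fit.sigma_e2
    if np.any(d <= 0):
        raise np.linalg.LinAlgError("singular phenotypic covariance V")
    U = fit.eigvecs
    w = 1.0 / d
    yt = U.T @ y

    C = None
    if covariates is not None:
        C = (covariates.set_index("id").loc[ids].to_numpy(dtype=float)
             if "id" in covariates.columns else
             covariates.loc[ids].to_numpy(dtype=float))

    X = Gs.dosages
    b = np.full(Gs.n_snps, np.nan)
    se = np.full(Gs.n_snps, np.nan)

    complete = ~np.isnan(X).any(axis=0)
    var_ok = np.nanvar(X, axis=0) > 0

    # fast path: rotate all complete SNPs at once
    cols = np.nonzero(complete & var_ok)[0]
    if cols.size:
        Xt = U.T @ X[:, cols]
        ones_t = U.T @ np.ones(n)
        base = [ones_t] + ([U.T @ C[:, k] for k in range(C.shape[1])] if C is not None else [])
        for pos, j in enumerate(cols):
            Wt = np.column_stack(base + [Xt[:, pos]])
            WtW = (Wt * w[:, None]).T @ Wt
            try:
                cov = np.linalg.inv(WtW)
            except np.linalg.LinAlgError:
                continue
            coef = cov @ ((Wt * w[:, None]).T @ yt)
            r = yt - Wt @ coef
            phi = float(r @ (w * r)) / (n - Wt.shape[1])
            b[j] = coef[-1]
            se[j] = np.sqrt(phi * cov[-1, -1])

    # slow path: complete-case GLS on the V submatrix
    V = (U * d) @ U.T
    for j in np.nonzero(~complete & var_ok)[0]:
        x = X[:, j]
        ok = np.isfinite(x)
        if ok.sum() < 3 or np.var(x[ok]) == 0:
            continue
        Wj = np.column_stack(
            [np.ones(ok.sum())] + ([C[ok]] if C is not None else []) + [x[ok]])
        Vi = np.linalg.inv(V[np.ix_(ok, ok)])
        WtVW = Wj.T @ Vi @ Wj
        cov = np.linalg.inv(WtVW)
        coef = cov @ (Wj.T @ Vi @ y[ok])
        r = y[ok] - Wj @ coef
        phi = float(r @ (Vi @ r)) / (int(ok.sum()) - Wj.shape[1])
        b[j] = coef[-1]
        se[j] = np.sqrt(phi * cov[-1, -1])

    return _records(Gs, b, se, "mlm")


def genomic_lambda(records: pd.DataFrame) -> float:
    """Genomic inflation factor: median Wald chi-square over the null median."""
    ok = records["se"].gt(0) & records["b"].notna()
    if not ok.any():
        raise ValueError("no valid association records")
    chisq = (records.loc[ok, "b"] / records.loc[ok, "se"]) ** 2
    return float(np.median(chisq) / CHI2_1_MEDIAN)


def call_candidates(
    records: pd.DataFrame,
    genes: pd.DataFrame | None,
    suggestive: float = 5e-5,
    genomewide: float = 5e-8,
) -> pd.DataFrame:
    """Select SNPs with p < ``suggestive`` and annotate the closest gene.

    The closest gene is the interval containing the SNP (distance 0), else
    the same-chromosome interval with the smallest distance to its nearer
    end; ties break to the smaller start. SNPs on chromosomes without genes
    are kept with an empty annotation.
    """
    hits = records[records["p"] < suggestive].copy()
    hits["tier"] = np.where(hits["p"] < genomewide, "genomewide", "suggestive")
    hits["closest_gene"] = ""
    hits["gene_distance"] = np.nan
    if genes is None or not len(genes):
        return hits.sort_values("p").reset_index(drop=True)

    by_chr = {str(c): sub.sort_values(["start", "end"]).reset_index(drop=True)
              for c, sub in genes.groupby("chr", sort=False)}
    names, dists = [], []
    for r in hits.itertuples():
        sub = by_chr.get(str(r.chr))
        if sub is None:
            names.append("")
            dists.append(np.nan)
            continue
        start = sub["start"].to_numpy()
        end = sub["end"].to_numpy()
        d = np.where((start <= r.bp) & (r.bp <= end), 0,
                     np.minimum(np.abs(start - r.bp), np.abs(end - r.bp)))
        best = int(np.flatnonzero(d == d.min())[0])  # sorted by start: tie -> smaller start
        names.append(str(sub["name"].iat[best]) if "name" in sub else f"region{best}")
        dists.append(int(d.min()))
    hits["closest_gene"] = names
    hits["gene_distance"] = dists
    return hits.sort_values("p").reset_index(drop=True)
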