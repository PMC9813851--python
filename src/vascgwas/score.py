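"""Protective-allele definition, cumulative burden scores, extreme-group
comparison, and continental allele-frequency differentiation.

A candidate SNP's protective allele is the allele whose dosage increases the
adjusted phenotype: A1 when the per-allele effect b is positive, A2 when it
is negative. The burden score of a subject is the cumulative count of
protective alleles over the scored SNPs (0-2 per SNP); extreme phenotype
groups (decelerated vs accelerated vascular aging) are compared by Welch's
t-test on these counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .assoc import AdjustedPhenotype
from .types import GenotypeMatrix


@dataclass
class ProtectiveAlleleSet:
    """Per-candidate-SNP protective allele with its source effect size."""

    table: pd.DataFrame  # id, chr, bp, a1, a2, protective, b

    def __post_init__(self) -> None:
        t = self.table
        is_a1 = t["protective"] == t["a1"]
        if not ((is_a1 & (t["b"] > 0)) | (~is_a1 & (t["b"] < 0))).all():
            raise ValueError("protective allele inconsistent with effect sign")

    def __len__(self) -> int:
        return len(self.table)


def define_protective_alleles(candidates: pd.DataFrame) -> ProtectiveAlleleSet:
    """b > 0 -> A1 protective; b < 0 -> A2 protective; b = 0 undefined."""
    t = candidates.copy()
    if not np.isfinite(t["b"]).all():
        raise ValueError("candidate records must have finite effect sizes")
    zero = t["b"] == 0
    if zero.any():
        raise ValueError(
            "protective allele undefined (b = 0) for: "
            + ", ".join(t.loc[zero, "id"].astype(str)))
    t["protective"] = np.where(t["b"] > 0, t["a1"], t["a2"])
    cols = ["id", "chr", "bp", "a1", "a2", "protective", "b"]
    return ProtectiveAlleleSet(t[cols].reset_index(drop=True))


def burden_scores(
    G: GenotypeMatrix,
    pas: ProtectiveAlleleSet,
    exact_expectation: bool = False,
) -> pd.DataFrame:
    """Per-sample cumulative protective-allele counts.

    The protective dosage is the A1 dosage when A1 is protective, else
    2 - dosage. A missing genotype contributes round(2 * p_protective)
    (modal imputation, keeping counts integral); with
    ``exact_expectation=True`` it contributes 2 * p_protective unrounded.
    Scored SNPs absent from G are reported in the ``n_skipped`` attribute
    of the result and skipped.
    """
    if not len(pas):
        raise ValueError("empty protective allele set")
    index = {s: i for i, s in enumerate(G.snps["id"])}
    present = pas.table["id"].map(index.__contains__)
    skipped = pas.table.loc[~present, "id"].tolist()
    tab = pas.table.loc[present]
    if not len(tab):
        raise ValueError("no protective-allele SNPs found in genotype matrix")

    cols = np.array([index[s] for s in tab["id"]])
    dose = G.dosages[:, cols].copy()
    # resolve the protective allele against G's current polarity, so the
    # count is invariant to re-polarization of either side
    g_a1 = G.snps["a1"].to_numpy()[cols]
    g_a2 = G.snps["a2"].to_numpy()[cols]
    prot = tab["protective"].to_numpy()
    protective_is_a1 = prot == g_a1
    unmatched = ~protective_is_a1 & (prot != g_a2)
    if unmatched.any():
        raise ValueError(
            "protective allele matches neither allele of: "
            + ", ".join(tab["id"].to_numpy()[unmatched][:5]))
    dose[:, ~protective_is_a1] = 2.0 - dose[:, ~protective_is_a1]

    p_a1 = G.snps["freq"].to_numpy()[cols]
    p_prot = np.where(protective_is_a1, p_a1, 1.0 - p_a1)
    fill = 2.0 * p_prot if exact_expectation else np.round(2.0 * p_prot)
    nan_r, nan_c = np.nonzero(np.isnan(dose))
    dose[nan_r, nan_c] = fill[nan_c]

    out = pd.DataFrame({
        "id": G.sample_ids,
        "burden": dose.sum(axis=1),
        "n_snps_scored": len(tab),
    })
    out.attrs["n_skipped"] = len(skipped)
    out.attrs["skipped_ids"] = skipped
    return out


def split_extremes(
    z: AdjustedPhenotype,
    top_frac: float = 0.30,
    bottom_frac: float = 0.30,
) -> pd.DataFrame:
    """Assign samples to decelerated / accelerated / neither aging groups.

    Each extreme group targets floor(frac * n) members (so a 97-sample
    cohort with 0.30/0.30 splits 29/29): the thresholds are the matching
    order statistics of z, and ties are included on the extreme side.
    Overlapping groups (degenerate z distribution) raise.
    """
    if not (0 < top_frac and 0 < bottom_frac and top_frac + bottom_frac <= 1):
        raise ValueError("fractions must be positive and sum to <= 1")
    t = z.table.copy()
    zs = np.sort(t["z"].to_numpy())
    n = len(zs)
    k_bot = max(1, int(bottom_frac * n))
    k_top = max(1, int(top_frac * n))
    lo = zs[k_bot - 1]
    hi = zs[n - k_top]
    accelerated = t["z"] <= lo
    decelerated = t["z"] >= hi
    if (accelerated & decelerated).any():
        raise ValueError("degenerate quantiles: extreme groups overlap")
    t["group"] = np.select([decelerated, accelerated],
                           ["decelerated", "accelerated"], default="neither")
    for g in ("decelerated", "accelerated"):
        if (t["group"] == g).sum() < 2:
            raise ValueError(f"group {g!r} smaller than 2: test undefined")
    return t[["id", "z", "group"]].reset_index(drop=True)


def compare_burden(
    counts_a: np.ndarray,
    counts_b: np.ndarray,
) -> tuple[float, float, float, tuple[float, float]]:
    """Welch's t-test of burden counts between two groups.

    Returns (t, Welch-Satterthwaite df, two-sided p, (mean_a, mean_b)).
    Two zero-variance groups with equal means give t = 0, p = 1.
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need at least 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return 0.0, float(len(a) + len(b) - 2), 1.0, (a.mean(), b.mean())
        raise ValueError("zero variance in both groups with unequal means")
    res = stats.ttest_ind(a, b, equal_var=False)
    sa, sb = va / len(a), vb / len(b)
    df = (sa + sb) ** 2 / (sa ** 2 / (len(a) - 1) + sb ** 2 / (len(b) - 1))
    return float(res.statistic), float(df), float(res.pvalue), (float(a.mean()), float(b.mean()))


def freq_differentiation(
    table: pd.DataFrame,
    focal_group: str,
) -> tuple[float, float, float, tuple[float, float]]:
    """Welch's t-test of country-level allele frequencies, focal vs rest.

    ``table`` has columns (group, country, freq) for one SNP/allele; the
    focal continental group's country frequencies are tested against the
    pooled remaining countries. Returns (t, df, two-sided p,
    (focal mean, rest mean)).
    """
    for col in ("group", "country", "freq"):
        if col not in table.columns:
            raise ValueError(f"frequency table missing column {col!r}")
    if not table["freq"].between(0, 1).all():
        raise ValueError("frequencies must be in [0, 1]")
    groups = set(table["group"])
    if focal_group not in groups:
        raise ValueError(f"unknown focal group {focal_group!r}; have {sorted(groups)}")
    focal = table.loc[table["group"] == focal_group, "freq"].to_numpy(dtype=float)
    rest = table.loc[table["group"] != focal_group, "freq"].to_numpy(dtype=float)
    if len(focal) < 2 or len(rest) < 2:
        raise ValueError("focal group and complement each need >= 2 countries")
    if focal.var(ddof=1) == 0 and rest.var(ddof=1) == 0 and focal.mean() == rest.mean():
        return 0.0, float(len(focal) + len(rest) - 2), 1.0, (float(focal.mean()), float(rest.mean()))
    res = stats.ttest_ind(focal, rest, equal_var=False)
    sa, sb = focal.var(ddof=1) / len(focal), rest.var(ddof=1) / len(rest)
    df = (sa + sb) ** 2 / (sa ** 2 / (len(focal) - 1) + sb ** 2 / (len(rest) - 1))
    return (float(res.statistic), float(df), float(res.pvalue),
            (float(focal.mean()), float(rest.mean())))
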