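"""Core in-memory containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

SNP_COLUMNS = ("id", "chr", "bp", "a1", "a2", "freq")


class SnpMeta(NamedTuple):
    """Per-SNP metadata; A1 is the effect/counted allele (minor after QC)."""

    chr: str
    bp: int
    a1: str
    a2: str
    freq: float

    @property
    def id(self) -> str:
        return f"{self.chr}:{self.bp}"


def snp_frame(snps: list[SnpMeta]) -> pd.DataFrame:
    df = pd.DataFrame(snps, columns=["chr", "bp", "a1", "a2", "freq"])
    df.insert(0, "id", df["chr"].astype(str) + ":" + df["bp"].astype(str))
    return df


@dataclass
class GenotypeMatrix:
    """samples x SNPs A1-dosage matrix with missingness.

    ``dosages`` is float with values in {0, 1, 2} and NaN for missing calls.
    ``snps`` is a DataFrame with columns id, chr, bp, a1, a2, freq where
    ``freq`` is the A1 frequency among non-missing calls.
    """

    sample_ids: list[str]
    snps: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.sample_ids), len(self.snps)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.snps)} SNPs")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample ids must be unique")
        finite = self.dosages[np.isfinite(self.dosages)]
        if finite.size and not np.isin(finite, (0.0, 1.0, 2.0)).all():
            raise ValueError("dosages must be in {0, 1, 2} or NaN")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def observed_freq(self) -> np.ndarray:
        """A1 frequency among non-missing calls per SNP (NaN if all missing)."""
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN column
            return np.nanmean(self.dosages, axis=0) / 2.0

    def missing_fraction(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=0)

    def refresh_freq(self) -> None:
        self.snps = self.snps.assign(freq=self.observed_freq())

    def subset_samples(self, ids: list[str]) -> "GenotypeMatrix":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [index[s] for s in ids]
        return GenotypeMatrix(list(ids), self.snps.copy(), self.dosages[rows].copy())

    def subset_snps(self, mask: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            list(self.sample_ids),
            self.snps.loc[mask].reset_index(drop=True),
            self.dosages[:, np.asarray(mask)].copy(),
        )


SAMPLE_COLUMNS = ("id", "sex", "age", "rhi")


def validate_samples(samples: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample table (id, sex in {F,M}, age >= 50, rhi > 0)."""
    for col in SAMPLE_COLUMNS:
        if col not in samples.columns:
            raise ValueError(f"sample table missing column {col!r}")
    if samples["id"].duplicated().any():
        raise ValueError("duplicate sample ids")
    if not samples["sex"].isin(["F", "M"]).all():
        raise ValueError("sex must be 'F' or 'M'")
    if (samples["age"] < 50).any():
        raise ValueError("cohort design requires age >= 50")
    return samples


@dataclass
class TraitCatalog:
    """Trait -> sorted array of associated variant positions (chr, bp)."""

    traits: dict[str, pd.DataFrame] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, hits in self.traits.items():
            if not {"chr", "bp"}.issubset(hits.columns):
                raise ValueError(f"trait {name!r} hits need chr/bp columns")
            self.traits[name] = hits.sort_values(["chr", "bp"]).reset_index(drop=True)

    def n_hits(self, trait: str) -> int:
        return len(self.traits[trait])

    @property
    def names(self) -> list[str]:
        return list(self.traits)

    def to_frame(self) -> pd.DataFrame:
        parts = [hits.assign(trait=name) for name, hits in self.traits.items()]
        if not parts:
            return pd.DataFrame(columns=["trait", "chr", "bp"])
        return pd.concat(parts, ignore_index=True)[["trait", "chr", "bp"]]

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TraitCatalog":
        return cls({str(name): sub[["chr", "bp"]].reset_index(drop=True)
                    for name, sub in df.groupby("trait", sort=False)})
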