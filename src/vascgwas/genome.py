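"""Genome coordinate model.

All coordinates in this package are 1-based inclusive. A :class:`Genome` is an
ordered list of autosome names with lengths; region tables (gene maps,
candidate regions, resampled null regions) are pandas DataFrames with columns
``chr``, ``start``, ``end`` and optionally ``name``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

# GRCh37 autosome lengths (bp).
GRCH37_AUTOSOME_LENGTHS: dict[str, int] = {
    "1": 249250621, "2": 243199373, "3": 198022430, "4": 191154276,
    "5": 180915260, "6": 171115067, "7": 159138663, "8": 146364022,
    "9": 141213431, "10": 135534747, "11": 135006516, "12": 133851895,
    "13": 115169878, "14": 107349540, "15": 102531392, "16": 90354753,
    "17": 81195210, "18": 78077248, "19": 59128983, "20": 63025520,
    "21": 48129895, "22": 51304566,
}

REGION_COLUMNS = ("chr", "start", "end")


@dataclass(frozen=True)
class Genome:
    """Ordered autosomes with lengths in bp; positions are 1-based inclusive."""

    chromosomes: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        names = [c[0] for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        if any(length <= 0 for _, length in self.chromosomes):
            raise ValueError("chromosome lengths must be positive")

    @property
    def names(self) -> list[str]:
        return [c[0] for c in self.chromosomes]

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    @property
    def total_length(self) -> int:
        return sum(length for _, length in self.chromosomes)

    def length_of(self, chrom: str) -> int:
        try:
            return self.lengths[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def contains(self, chrom: str, bp: int) -> bool:
        return chrom in self.lengths and 1 <= bp <= self.lengths[chrom]


def toy_genome(scale: int = 300) -> Genome:
    """22 autosomes scaled down from GRCh37 lengths by ``scale``.

    The default 1/300 scaling keeps chromosome-aware logic (length-proportional
    resampling, closest-gene search) exercised at desk scale (~10 Mb genome).
    """
    return Genome(tuple((name, max(1, length // scale))
                        for name, length in GRCH37_AUTOSOME_LENGTHS.items()))


def validate_regions(regions: pd.DataFrame, genome: Genome | None = None) -> pd.DataFrame:
    """Check a region table (1-based inclusive intervals); return it unchanged."""
    for col in REGION_COLUMNS:
        if col not in regions.columns:
            raise ValueError(f"region table missing column {col!r}")
    if len(regions):
        if (regions["start"] > regions["end"]).any():
            raise ValueError("region start > end")
        if (regions["start"] < 1).any():
            raise ValueError("region start < 1 (coordinates are 1-based)")
        if genome is not None:
            lengths = genome.lengths
            for chrom, sub in regions.groupby("chr", sort=False):
                if str(chrom) not in lengths:
                    raise ValueError(f"region on unknown chromosome {chrom!r}")
                if (sub["end"] > lengths[str(chrom)]).any():
                    raise ValueError(f"region beyond end of chromosome {chrom}")
    return regions


def merge_regions(regions: pd.DataFrame) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Merge overlapping/adjacent intervals per chromosome.

    Returns ``{chr: (starts, ends)}`` with sorted, disjoint 1-based inclusive
    intervals — the membership-test form used by overlap counting.
    """
    merged: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, sub in regions.groupby("chr", sort=False):
        starts = sub["start"].to_numpy(dtype=np.int64)
        ends = sub["end"].to_numpy(dtype=np.int64)
        order = np.argsort(starts, kind="stable")
        starts, ends = starts[order], ends[order]
        out_s, out_e = [starts[0]], [ends[0]]
        for s, e in zip(starts[1:], ends[1:]):
            if s <= out_e[-1] + 1:
                out_e[-1] = max(out_e[-1], e)
            else:
                out_s.append(s)
                out_e.append(e)
        merged[str(chrom)] = (np.asarray(out_s), np.asarray(out_e))
    return merged
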