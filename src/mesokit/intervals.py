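"""Genomic intervals, coordinate conventions, and the GRCh37 arm table.

External files use 1-based inclusive coordinates (the convention of SEG files
and of the KRAS/TP53 locus positions used throughout this package); all
internal overlap arithmetic is done on 0-based half-open intervals.  The two
converters below are exact integer maps and are round-trip tested.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import pandas as pd


def normalize_chrom(name: str) -> str:
    """Normalize a chromosome name: accept 'chr12'/'12', return '12'.

    'MT' and 'M' both normalize to 'MT'; X/Y are uppercased.
    """
    s = str(name).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    s = s.upper()
    if s == "M":
        s = "MT"
    if not s:
        raise ValueError("empty chromosome name")
    return s


@dataclass(frozen=True)
class GenomicInterval:
    """A 1-based, inclusive genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")
        if self.start < 1:
            raise ValueError("1-based coordinates must be >= 1")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def to_halfopen(self) -> tuple[int, int]:
        """Return the equivalent 0-based half-open (start, end)."""
        return self.start - 1, self.end

    @classmethod
    def from_halfopen(cls, chrom: str, start0: int, end0: int) -> "GenomicInterval":
        return cls(chrom, start0 + 1, end0)

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        a0, a1 = self.to_halfopen()
        b0, b1 = other.to_halfopen()
        return max(0, min(a1, b1) - max(a0, b0))


# Printed gene loci (GRCh37).
KRAS_LOCUS = GenomicInterval("12", 25_357_180, 25_404_863)
TP53_LOCUS = GenomicInterval("17", 7_570_720, 7_591_868)


@lru_cache(maxsize=1)
def arm_table() -> pd.DataFrame:
    """The bundled GRCh37 chromosome-arm table (chrom, arm, start, end)."""
    with resources.files("mesokit.data").joinpath("grch37_arms.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", dtype={"chrom": str})
    df["chrom"] = df["chrom"].map(normalize_chrom)
    return df


@lru_cache(maxsize=None)
def arm_interval(chrom: str, arm: str) -> GenomicInterval:
    """The interval of one chromosome arm, e.g. ('12', 'p')."""
    chrom = normalize_chrom(chrom)
    df = arm_table()
    row = df[(df["chrom"] == chrom) & (df["arm"] == arm)]
    if row.empty:
        raise KeyError(f"unknown arm {chrom}{arm}")
    r = row.iloc[0]
    return GenomicInterval(chrom, int(r["start"]), int(r["end"]))


def all_arms() -> list[tuple[str, str, GenomicInterval]]:
    """All (chrom, arm, interval) triples of the bundled table."""
    return [
        (r["chrom"], r["arm"], GenomicInterval(r["chrom"], int(r["start"]), int(r["end"])))
        for _, r in arm_table().iterrows()
    ]
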