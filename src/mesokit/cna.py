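"""Copy-number scoring, classification, and KRAS/TP53 patient stratification.

Segment tables (SEG-like: one copy-number value per genomic segment per
sample) are summarized to per-locus and per-arm scores by an
overlap-length-weighted mean, classified against the study's z thresholds
(low ±0.1, high/deep ±0.3, strict inequalities), and combined with mutation
records into per-gene alteration calls.  A patient is then assigned one of
three strata: KRAS alteration alone, combined KRAS/TP53 alteration, or
neither (TP53-only counts as neither).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import (
    KRAS_LOCUS,
    TP53_LOCUS,
    GenomicInterval,
    arm_interval,
    normalize_chrom,
)


class Scale(str, enum.Enum):
    Z = "Z"
    ABSOLUTE_CN = "ABSOLUTE_CN"


class CnaStatus(str, enum.Enum):
    MUTATION = "MUTATION"
    HIGH_GAIN = "HIGH_GAIN"
    DEEP_LOSS = "DEEP_LOSS"
    ARM_GAIN = "ARM_GAIN"
    ARM_LOSS = "ARM_LOSS"
    LOW_GAIN = "LOW_GAIN"
    LOW_LOSS = "LOW_LOSS"
    NONE = "NONE"


class Direction(str, enum.Enum):
    GAIN = "GAIN"
    LOSS = "LOSS"


class Stratum(str, enum.Enum):
    KRAS_ONLY = "KRAS_ONLY"
    KRAS_TP53 = "KRAS_TP53"
    OTHER = "OTHER"


class AbsoluteCnState(str, enum.Enum):
    AMPLIFIED = "AMPLIFIED"
    LOST = "LOST"
    NORMAL = "NORMAL"


@dataclass(frozen=True)
class CnaThresholds:
    """Copy-number z thresholds: low ±0.1 (dotted lines), high/deep ±0.3."""

    low_gain: float = 0.1
    high_gain: float = 0.3
    low_loss: float = -0.1
    deep_loss: float = -0.3

    def __post_init__(self) -> None:
        if not (self.deep_loss < self.low_loss < 0 < self.low_gain < self.high_gain):
            raise ValueError(
                "thresholds must satisfy deep_loss < low_loss < 0 < low_gain < high_gain"
            )


@dataclass
class SegmentProfile:
    """Per-sample genomic segments carrying a copy-number score.

    ``segments`` is a DataFrame with columns chrom, start, end, value
    (1-based inclusive coordinates).  Segments on one chromosome must not
    overlap.
    """

    sample_id: str
    segments: pd.DataFrame
    scale: Scale = Scale.Z

    def __post_init__(self) -> None:
        seg = self.segments.copy()
        required = {"chrom", "start", "end", "value"}
        missing = required - set(seg.columns)
        if missing:
            raise ValueError(f"segment table missing columns: {sorted(missing)}")
        seg["chrom"] = seg["chrom"].map(normalize_chrom)
        if not np.all(np.isfinite(seg["value"].to_numpy(dtype=float))):
            raise ValueError("segment values must be finite")
        if (seg["start"] > seg["end"]).any():
            raise ValueError("segment start > end")
        for chrom, grp in seg.groupby("chrom"):
            g = grp.sort_values("start")
            if (g["start"].to_numpy()[1:] <= g["end"].to_numpy()[:-1]).any():
                raise ValueError(f"overlapping segments on chromosome {chrom}")
        self.segments = seg.sort_values(["chrom", "start"]).reset_index(drop=True)


def _weighted_score(profile: SegmentProfile, region: GenomicInterval) -> float:
    seg = profile.segments
    sub = seg[seg["chrom"] == region.chrom]
    if sub.empty:
        return math.nan
    r0, r1 = region.to_halfopen()
    s0 = sub["start"].to_numpy() - 1
    s1 = sub["end"].to_numpy()
    ov = np.minimum(s1, r1) - np.maximum(s0, r0)
    mask = ov > 0
    if not mask.any():
        return math.nan
    w = ov[mask].astype(float)
    v = sub["value"].to_numpy(dtype=float)[mask]
    return float(np.sum(w * v) / np.sum(w))


def _max_magnitude_score(profile: SegmentProfile, region: GenomicInterval) -> float:
    seg = profile.segments
    sub = seg[seg["chrom"] == region.chrom]
    if sub.empty:
        return math.nan
    r0, r1 = region.to_halfopen()
    ov = np.minimum(sub["end"].to_numpy(), r1) - np.maximum(sub["start"].to_numpy() - 1, r0)
    v = sub["value"].to_numpy(dtype=float)[ov > 0]
    if v.size == 0:
        return math.nan
    return float(v[np.argmax(np.abs(v))])


def locus_score(
    profile: SegmentProfile, locus: GenomicInterval, method: str = "weighted_mean"
) -> float:
    """Overlap-length-weighted mean segment value over a locus.

    Returns NaN (distinct from 0) when no segment overlaps the locus.
    ``method='max_magnitude'`` instead returns the value of the overlapping
    segment with the largest absolute value.
    """
    if profile.scale is not Scale.Z:
        raise ValueError("locus_score requires a z-scale profile")
    if method == "weighted_mean":
        return _weighted_score(profile, locus)
    if method == "max_magnitude":
        return _max_magnitude_score(profile, locus)
    raise ValueError(f"unknown aggregation method {method!r}")


def arm_score(
    profile: SegmentProfile, arm: GenomicInterval, method: str = "weighted_mean"
) -> float:
    """Overlap-length-weighted mean segment value over a chromosome arm."""
    return locus_score(profile, arm, method=method)


def classify_locus(z: float, t: CnaThresholds = CnaThresholds()) -> CnaStatus:
    """Classify a locus z score against the printed decision lines.

    Inequalities are strict at every line (gain is z > 0.3, not >=), and a
    missing (NaN) score classifies as NONE.
    """
    if z is None or (isinstance(z, float) and math.isnan(z)):
        return CnaStatus.NONE
    if not math.isfinite(z):
        raise ValueError("z must be finite or NaN")
    if z > t.high_gain:
        return CnaStatus.HIGH_GAIN
    if z < t.deep_loss:
        return CnaStatus.DEEP_LOSS
    if z > t.low_gain:
        return CnaStatus.LOW_GAIN
    if z < t.low_loss:
        return CnaStatus.LOW_LOSS
    return CnaStatus.NONE


def classify_absolute_cn(
    cn: float, amp_threshold: float = 2.3, loss_threshold: float = 1.7
) -> AbsoluteCnState:
    """Classify an absolute copy number (cell-line arrays): >2.3 amplified, <1.7 lost."""
    if cn < 0:
        raise ValueError("copy number must be >= 0")
    if cn > amp_threshold:
        return AbsoluteCnState.AMPLIFIED
    if cn < loss_threshold:
        return AbsoluteCnState.LOST
    return AbsoluteCnState.NORMAL


@dataclass(frozen=True)
class GeneCnaConfig:
    """Locus, arm, and alteration direction for one gene."""

    locus: GenomicInterval
    arm: tuple[str, str]  # (chrom, 'p'|'q')
    direction: Direction


#: Default gene configuration: KRAS gains at 12p12.1, TP53 losses at 17p13.1.
DEFAULT_GENE_CONFIG: dict[str, GeneCnaConfig] = {
    "KRAS": GeneCnaConfig(KRAS_LOCUS, ("12", "p"), Direction.GAIN),
    "TP53": GeneCnaConfig(TP53_LOCUS, ("17", "p"), Direction.LOSS),
}


@dataclass
class AlterationCall:
    sample_id: str
    gene: str
    status: CnaStatus
    evidence: list[tuple[str, object]] = field(default_factory=list)

    @property
    def altered(self) -> bool:
        return self.status in (
            CnaStatus.MUTATION,
            CnaStatus.HIGH_GAIN,
            CnaStatus.DEEP_LOSS,
            CnaStatus.ARM_GAIN,
            CnaStatus.ARM_LOSS,
        )


def call_gene_alterations(
    mutations: pd.DataFrame,
    profiles: dict[str, SegmentProfile] | list[SegmentProfile],
    gene_config: dict[str, GeneCnaConfig] | None = None,
    thresholds: CnaThresholds = CnaThresholds(),
    locus_method: str = "weighted_mean",
) -> pd.DataFrame:
    """Call each configured gene altered / not altered per sample.

    A gene is altered iff (a) any mutation record for it exists, or (b) its
    locus classifies HIGH_GAIN (GAIN genes) / DEEP_LOSS (LOSS genes), or (c)
    its arm score passes the low line (|z| > low threshold) in the gene's
    direction.  Evidence lists every contributing source; the reported status
    is the strongest one (mutation > locus > arm).

    ``mutations`` is MAF-like with at least Tumor_Sample_Barcode and
    Hugo_Symbol columns.  Samples are the union of profile samples and
    mutated samples.
    """
    if gene_config is None:
        gene_config = DEFAULT_GENE_CONFIG
    for gene, cfg in gene_config.items():
        if not isinstance(cfg, GeneCnaConfig):
            raise ValueError(f"invalid configuration for gene {gene!r}")
    if isinstance(profiles, list):
        profiles = {p.sample_id: p for p in profiles}

    mut_samples: dict[str, set[str]] = {g: set() for g in gene_config}
    if len(mutations):
        for col in ("Tumor_Sample_Barcode", "Hugo_Symbol"):
            if col not in mutations.columns:
                raise ValueError(f"mutation table missing column {col}")
        for gene in gene_config:
            mut_samples[gene] = set(
                mutations.loc[mutations["Hugo_Symbol"] == gene, "Tumor_Sample_Barcode"]
            )

    samples = sorted(set(profiles) | set().union(*mut_samples.values()))
    rows = []
    for sample in samples:
        profile = profiles.get(sample)
        for gene, cfg in gene_config.items():
            evidence: list[tuple[str, object]] = []
            status = CnaStatus.NONE
            if profile is not None:
                lz = locus_score(profile, cfg.locus, method=locus_method)
                az = arm_score(profile, arm_interval(*cfg.arm), method=locus_method)
                lstat = classify_locus(lz, thresholds)
                if cfg.direction is Direction.GAIN and lstat is CnaStatus.HIGH_GAIN:
                    evidence.append(("locus", lz))
                    status = CnaStatus.HIGH_GAIN
                if cfg.direction is Direction.LOSS and lstat is CnaStatus.DEEP_LOSS:
                    evidence.append(("locus", lz))
                    status = CnaStatus.DEEP_LOSS
                if not math.isnan(az):
                    if cfg.direction is Direction.GAIN and az > thresholds.low_gain:
                        evidence.append(("arm", az))
                        if status is CnaStatus.NONE:
                            status = CnaStatus.ARM_GAIN
                    if cfg.direction is Direction.LOSS and az < thresholds.low_loss:
                        evidence.append(("arm", az))
                        if status is CnaStatus.NONE:
                            status = CnaStatus.ARM_LOSS
            if sample in mut_samples[gene]:
                evidence.insert(0, ("mutation", True))
                status = CnaStatus.MUTATION
            rows.append(
                {
                    "sample_id": sample,
                    "gene": gene,
                    "status": status.value,
                    "altered": AlterationCall(sample, gene, status, evidence).altered,
                    "evidence": evidence,
                }
            )
    return pd.DataFrame(rows, columns=["sample_id", "gene", "status", "altered", "evidence"])


def stratify_patients(calls: pd.DataFrame) -> pd.DataFrame:
    """Three-way stratification from KRAS/TP53 alteration calls.

    KRAS and TP53 both altered -> KRAS_TP53; KRAS only -> KRAS_ONLY;
    everything else, including TP53-only, -> OTHER.
    """
    wide = calls.pivot(index="sample_id", columns="gene", values="altered")
    for gene in ("KRAS", "TP53"):
        if gene not in wide.columns:
            raise ValueError(f"alteration calls must cover {gene} for every patient")
    if wide[["KRAS", "TP53"]].isna().any().any():
        bad = wide.index[wide[["KRAS", "TP53"]].isna().any(axis=1)].tolist()
        raise ValueError(f"patients missing KRAS/TP53 calls: {bad}")
    kras = wide["KRAS"].astype(bool)
    tp53 = wide["TP53"].astype(bool)
    stratum = np.where(
        kras & tp53,
        Stratum.KRAS_TP53.value,
        np.where(kras, Stratum.KRAS_ONLY.value, Stratum.OTHER.value),
    )
    return pd.DataFrame(
        {"patient_id": wide.index.to_numpy(), "stratum": stratum}
    ).reset_index(drop=True)
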