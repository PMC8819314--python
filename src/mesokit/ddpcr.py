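"""Droplet digital PCR gating, quantification, and per-patient calling.

Two-channel end-point droplet amplitudes are gated at fixed thresholds
(KRAS wild-type 6,000 / KRAS mutant 10,000 / TP53 5,500 / TERT 7,000
fluorescence units).  Quantification is the ratio of positive droplet
counts:

    KRAS mutant copies % = 100 * n_mut_pos / (n_mut_pos + n_wt_pos)
    TP53 copies %        = 100 * n_tp53_pos / n_tert_pos

TERT serves as a two-copy reference locus, so 100% is diploid TP53.
Double-positive droplets count toward both classes; no Poisson volume
correction is applied (the quantities are ratios of positive droplets, not
concentrations).  A patient is KRAS-altered when any well of any sample
contains even a single mutant-positive droplet, and TP53-altered when any
sample's TP53 % falls outside the configured normal range.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass

import pandas as pd
from scipy import stats


class Assay(str, enum.Enum):
    KRAS_G12_13 = "KRAS_G12_13"
    KRAS_Q61 = "KRAS_Q61"
    TP53_TERT = "TP53_TERT"


KRAS_ASSAYS = (Assay.KRAS_G12_13, Assay.KRAS_Q61)


@dataclass(frozen=True)
class GateConfig:
    """Amplitude gates, in fluorescence units (printed defaults)."""

    wt_gate: float = 6_000.0
    mut_gate: float = 10_000.0
    tp53_gate: float = 5_500.0
    tert_gate: float = 7_000.0

    def __post_init__(self) -> None:
        if min(self.wt_gate, self.mut_gate, self.tp53_gate, self.tert_gate) <= 0:
            raise ValueError("all gates must be positive")


@dataclass
class GatedCounts:
    assay: Assay
    n_accepted: int
    n_ch1_pos: int  # mutant probe (KRAS assays) or TP53
    n_ch2_pos: int  # wild-type probe (KRAS assays) or TERT
    n_double_pos: int
    empty_input: bool = False


@dataclass
class DdpcrResult:
    """Gated counts plus the derived percentage for one sample/assay."""

    sample_id: str
    assay: Assay
    n_accepted: int
    n_mut_pos: int
    n_wt_pos: int
    mutant_pct: float  # NaN when undefined
    ci95: tuple[float, float]  # percent; (NaN, NaN) when undefined
    undefined: bool = False


def gate_droplets(droplets: pd.DataFrame, gates: GateConfig = GateConfig()) -> GatedCounts:
    """Count positive droplets per channel for one well.

    ``droplets`` must carry columns assay, ch1_amplitude, ch2_amplitude with a
    single assay value.  For KRAS assays ch1 is the mutant probe (positive
    above ``mut_gate``) and ch2 the wild-type probe (positive above
    ``wt_gate``); for TP53/TERT ch1 is TP53 (> ``tp53_gate``) and ch2 TERT
    (> ``tert_gate``).  Double-positives are counted in both classes.
    """
    if len(droplets) == 0:
        warnings.warn("empty droplet table: all counts zero", stacklevel=2)
        assay = Assay(droplets["assay"].iloc[0]) if len(droplets) else Assay.KRAS_G12_13
        return GatedCounts(assay, 0, 0, 0, 0, empty_input=True)
    assays = set(droplets["assay"].unique())
    if len(assays) != 1:
        raise ValueError(f"gate_droplets expects a single assay, got {sorted(assays)}")
    assay = Assay(next(iter(assays)))
    ch1 = droplets["ch1_amplitude"].to_numpy(dtype=float)
    ch2 = droplets["ch2_amplitude"].to_numpy(dtype=float)
    if (ch1 < 0).any() or (ch2 < 0).any():
        raise ValueError("amplitudes must be >= 0")
    if assay in KRAS_ASSAYS:
        pos1 = ch1 > gates.mut_gate
        pos2 = ch2 > gates.wt_gate
    else:
        pos1 = ch1 > gates.tp53_gate
        pos2 = ch2 > gates.tert_gate
    return GatedCounts(
        assay=assay,
        n_accepted=len(droplets),
        n_ch1_pos=int(pos1.sum()),
        n_ch2_pos=int(pos2.sum()),
        n_double_pos=int((pos1 & pos2).sum()),
    )


def kras_mutant_pct(n_mut_pos: int, n_wt_pos: int) -> tuple[float, tuple[float, float]]:
    """Mutant copy percentage with its exact (Clopper-Pearson) 95% CI.

    Returns (NaN, (NaN, NaN)) when no positive droplet of either class was
    seen -- an undefined estimate, deliberately distinct from 0%.
    """
    if n_mut_pos < 0 or n_wt_pos < 0:
        raise ValueError("droplet counts must be >= 0")
    n = n_mut_pos + n_wt_pos
    if n == 0:
        return math.nan, (math.nan, math.nan)
    pct = 100.0 * n_mut_pos / n
    lo, hi = _clopper_pearson(n_mut_pos, n)
    return pct, (100.0 * lo, 100.0 * hi)


def _clopper_pearson(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    alpha = 1.0 - conf
    lo = 0.0 if k == 0 else stats.beta.ppf(alpha / 2, k, n - k + 1)
    hi = 1.0 if k == n else stats.beta.ppf(1 - alpha / 2, k + 1, n - k)
    return float(lo), float(hi)


def tp53_pct(n_tp53_pos: int, n_tert_pos: int) -> float:
    """TP53 copies % relative to the TERT reference; NaN when no TERT droplet."""
    if n_tp53_pos < 0 or n_tert_pos < 0:
        raise ValueError("droplet counts must be >= 0")
    if n_tert_pos == 0:
        return math.nan
    return 100.0 * n_tp53_pos / n_tert_pos


def quantify_well(
    droplets: pd.DataFrame, gates: GateConfig = GateConfig(), sample_id: str = ""
) -> DdpcrResult:
    """Gate one well and compute its percentage (mutant % or TP53 %)."""
    counts = gate_droplets(droplets, gates)
    if counts.assay in KRAS_ASSAYS:
        pct, ci = kras_mutant_pct(counts.n_ch1_pos, counts.n_ch2_pos)
    else:
        pct = tp53_pct(counts.n_ch1_pos, counts.n_ch2_pos)
        ci = (math.nan, math.nan)
    return DdpcrResult(
        sample_id=sample_id,
        assay=counts.assay,
        n_accepted=counts.n_accepted,
        n_mut_pos=counts.n_ch1_pos,
        n_wt_pos=counts.n_ch2_pos,
        mutant_pct=pct,
        ci95=ci,
        undefined=math.isnan(pct),
    )


DEFAULT_TP53_NORMAL_RANGE = (80.0, 120.0)


def call_sample(
    results: list[DdpcrResult],
    tp53_normal_range: tuple[float, float] = DEFAULT_TP53_NORMAL_RANGE,
) -> tuple[bool, bool]:
    """Per-patient calls from all of the patient's wells.

    KRAS-altered iff any KRAS-assay well has >= 1 mutant-positive droplet;
    TP53-altered iff any TP53/TERT well's TP53 % lies outside the normal
    range (wells with an undefined percentage are not evidence either way).
    """
    if not results:
        raise ValueError("at least one result per patient is required")
    lo, hi = tp53_normal_range
    kras_altered = any(r.assay in KRAS_ASSAYS and r.n_mut_pos >= 1 for r in results)
    tp53_altered = any(
        r.assay is Assay.TP53_TERT
        and not math.isnan(r.mutant_pct)
        and not (lo <= r.mutant_pct <= hi)
        for r in results
    )
    return kras_altered, tp53_altered
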