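"""Synthetic-data generation with known planted truth.

Every input of the analysis pipeline can be generated here so that each
downstream stage is testable offline against a recorded ground truth:

* cohorts of segment profiles, mutation lists, expression matrices, and
  clinical tables stratified into KRAS-only / KRAS+TP53 / unaltered patients,
* two-channel droplet clouds with a planted mutant fraction (or a planted
  TP53:TERT copy ratio),
* negative-binomial count matrices with planted fold changes, gene lengths,
  and library-size factors.

Default cohort composition follows the reference human cohort: 86 patients,
of whom 10 carry a standalone KRAS alteration and 7 a combined KRAS/TP53
alteration.  All randomness flows through one explicit numpy Generator; the
same seed reproduces every table byte for byte.

Per-arm baseline copy-number noise is Normal(0, sd=0.05) truncated just
inside the low decision lines (|z| < 0.095), so that no unplanted arm can
cross an alteration threshold and the planted stratum labels remain exactly
recoverable.  Planted events sit well outside the high/deep lines.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cna import Stratum
from .ddpcr import Assay, GateConfig
from .intervals import KRAS_LOCUS, TP53_LOCUS, GenomicInterval, all_arms

BASELINE_SD = 0.05
BASELINE_TRUNC = 0.095  # keep baseline strictly inside the +/-0.1 low lines
PLANTED_GAIN_Z = 0.5
PLANTED_LOSS_Z = -0.5
PLANTED_ARM_Z = 0.2

DEFAULT_N_PER_STRATUM = {"OTHER": 69, "KRAS_ONLY": 10, "KRAS_TP53": 7}
#: survival: exponential scale (days) of the unaltered stratum and relative hazards
DEFAULT_SURVIVAL_SCALE = 780.0  # median ~ 540 days for unaltered patients
DEFAULT_HAZARD_MULTIPLIERS = {"OTHER": 1.0, "KRAS_ONLY": 2.0, "KRAS_TP53": 3.0}
CENSOR_AT_DAYS = 1825.0  # administrative censoring at five years

N_SIGNATURE_GENES = 40


@dataclass
class CohortTables:
    mutations: pd.DataFrame
    segments: dict  # sample_id -> SegmentProfile
    expression: pd.DataFrame
    clinical: pd.DataFrame
    truth: pd.DataFrame


def _truncated_baseline(rng: np.random.Generator, size: int) -> np.ndarray:
    a, b = -BASELINE_TRUNC / BASELINE_SD, BASELINE_TRUNC / BASELINE_SD
    return stats.truncnorm.ppf(rng.random(size), a, b, loc=0.0, scale=BASELINE_SD)


def _arm_segments(
    rng: np.random.Generator,
    planted: dict[tuple[str, str], float],
    focal: dict[tuple[str, str], tuple[GenomicInterval, float]],
) -> pd.DataFrame:
    """One segment per arm (baseline or planted), carving out focal events."""
    rows = []
    arms = [(c, a, iv) for c, a, iv in all_arms() if c != "Y"]
    base = _truncated_baseline(rng, len(arms))
    for (chrom, arm, iv), bz in zip(arms, base):
        z = planted.get((chrom, arm), float(bz))
        if (chrom, arm) in focal:
            locus, fz = focal[(chrom, arm)]
            if locus.start > iv.start:
                rows.append((chrom, iv.start, locus.start - 1, z))
            rows.append((chrom, locus.start, locus.end, fz))
            if locus.end < iv.end:
                rows.append((chrom, locus.end + 1, iv.end, z))
        else:
            rows.append((chrom, iv.start, iv.end, z))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


_CLASS_TEMPLATES = {
    "C>A": ("C", "A"),
    "C>G": ("C", "G"),
    "C>T": ("C", "T"),
    "T>A": ("T", "A"),
    "T>C": ("T", "C"),
    "T>G": ("T", "G"),
}
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_CLASS_NAMES = list(_CLASS_TEMPLATES)


def _background_mutations(
    rng: np.random.Generator, sample: str, n: int, ct_weight: float
) -> list[dict]:
    """Random SNV records; OTHER patients get a C>T excess via ct_weight."""
    w = np.ones(6)
    w[_CLASS_NAMES.index("C>T")] = ct_weight
    w /= w.sum()
    rows = []
    for _ in range(n):
        cls = _CLASS_NAMES[rng.choice(6, p=w)]
        ref, alt = _CLASS_TEMPLATES[cls]
        if rng.random() < 0.5:  # record on the purine strand
            ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
        rows.append(
            {
                "Tumor_Sample_Barcode": sample,
                "Hugo_Symbol": f"BG{rng.integers(1, 500):04d}",
                "Reference_Allele": ref,
                "Tumor_Seq_Allele2": alt,
                "Variant_Classification": "Missense_Mutation",
            }
        )
    return rows


def generate_cohort(
    n_per_stratum: dict[str, int] | None = None,
    signature_effect: float = 3.0,
    noise_sd: float = 1.0,
    n_background_genes: int = 160,
    background_mutation_mean: float = 20.0,
    other_ct_weight: float = 5.0,
    seed: int | np.random.Generator = 0,
) -> CohortTables:
    """Generate a full synthetic cohort with planted stratum truth.

    KRAS-only patients carry either a KRAS G12D mutation record or a planted
    focal KRAS-locus gain (z = 0.5); KRAS+TP53 patients additionally carry a
    TP53 mutation or a focal deep loss (z = -0.5); unaltered patients carry
    neither (and a C>T-heavy background mutation spectrum).  Forty signature
    genes have group means ordered OTHER < KRAS_ONLY < KRAS_TP53 in steps of
    ``signature_effect``; survival is exponential with per-stratum hazard
    multipliers.
    """
    from .cna import Scale, SegmentProfile  # local import to avoid cycle at module load

    if n_per_stratum is None:
        n_per_stratum = dict(DEFAULT_N_PER_STRATUM)
    for k, v in n_per_stratum.items():
        if k not in DEFAULT_N_PER_STRATUM:
            raise ValueError(f"unknown stratum {k!r}")
        if int(v) != v or v < 0:
            raise ValueError("stratum sizes must be non-negative integers")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if not np.isfinite(signature_effect):
        raise ValueError("signature_effect must be finite")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    patients: list[tuple[str, str]] = []
    i = 0
    for stratum in ("OTHER", "KRAS_ONLY", "KRAS_TP53"):
        for _ in range(int(n_per_stratum.get(stratum, 0))):
            i += 1
            patients.append((f"MPM{i:03d}", stratum))

    mut_rows: list[dict] = []
    truth_rows: list[dict] = []
    profiles: dict[str, SegmentProfile] = {}
    clin_rows: list[dict] = []
    arm_names = [(c, a) for c, a, _ in all_arms() if c != "Y"]

    for pid, stratum in patients:
        kras_mut = tp53_mut = False
        kras_z = tp53_z = 0.0
        planted: dict[tuple[str, str], float] = {}
        focal: dict[tuple[str, str], tuple[GenomicInterval, float]] = {}
        if stratum in ("KRAS_ONLY", "KRAS_TP53"):
            if rng.random() < 0.5:
                kras_mut = True
            else:
                kras_z = PLANTED_GAIN_Z
                focal[("12", "p")] = (KRAS_LOCUS, PLANTED_GAIN_Z)
        if stratum == "KRAS_TP53":
            if rng.random() < 0.5:
                tp53_mut = True
            else:
                tp53_z = PLANTED_LOSS_Z
                focal[("17", "p")] = (TP53_LOCUS, PLANTED_LOSS_Z)
        # extra whole-arm events feed the instability indices, never 12p/17p
        n_extra = {"OTHER": 0, "KRAS_ONLY": 2, "KRAS_TP53": 4}[stratum]
        if n_extra:
            candidates = [a for a in arm_names if a not in (("12", "p"), ("17", "p"))]
            for j in rng.choice(len(candidates), size=n_extra, replace=False):
                planted[candidates[j]] = PLANTED_ARM_Z * (1 if rng.random() < 0.5 else -1)

        profiles[pid] = SegmentProfile(pid, _arm_segments(rng, planted, focal), Scale.Z)

        if kras_mut:
            mut_rows.append(
                {
                    "Tumor_Sample_Barcode": pid,
                    "Hugo_Symbol": "KRAS",
                    "Reference_Allele": "G",
                    "Tumor_Seq_Allele2": "A",
                    "Variant_Classification": "Missense_Mutation",
                }
            )
        if tp53_mut:
            mut_rows.append(
                {
                    "Tumor_Sample_Barcode": pid,
                    "Hugo_Symbol": "TP53",
                    "Reference_Allele": "G",
                    "Tumor_Seq_Allele2": "A",
                    "Variant_Classification": "Missense_Mutation",
                }
            )
        n_bg = int(rng.poisson(background_mutation_mean))
        ct_w = other_ct_weight if stratum == "OTHER" else 1.0
        mut_rows.extend(_background_mutations(rng, pid, n_bg, ct_w))
        if rng.random() < 0.2:  # occasional indel record, skipped by the spectrum
            mut_rows.append(
                {
                    "Tumor_Sample_Barcode": pid,
                    "Hugo_Symbol": f"BG{rng.integers(1, 500):04d}",
                    "Reference_Allele": "-",
                    "Tumor_Seq_Allele2": "AT",
                    "Variant_Classification": "Frame_Shift_Ins",
                }
            )

        mult = DEFAULT_HAZARD_MULTIPLIERS[stratum]
        t = float(rng.exponential(DEFAULT_SURVIVAL_SCALE / mult))
        t = max(t, 1.0)
        event = t <= CENSOR_AT_DAYS
        hist_p = (
            [0.15, 0.80, 0.05] if stratum == "OTHER" else [0.60, 0.30, 0.10]
        )  # biphasic excess among KRAS-altered patients
        histology = ["biphasic", "epithelioid", "sarcomatoid"][rng.choice(3, p=hist_p)]
        clin_rows.append(
            {
                "patient": pid,
                "time_days": round(min(t, CENSOR_AT_DAYS), 1),
                "event": bool(event),
                "histology": histology,
            }
        )
        truth_rows.append(
            {
                "patient_id": pid,
                "stratum": stratum,
                "planted_kras_z": kras_z,
                "planted_tp53_z": tp53_z,
                "has_kras_mutation": kras_mut,
                "has_tp53_mutation": tp53_mut,
                "survival_scale": DEFAULT_SURVIVAL_SCALE / mult,
                "hazard_multiplier": mult,
            }
        )

    sample_ids = [pid for pid, _ in patients]
    strata = np.array([s for _, s in patients])
    step = {"OTHER": 0.0, "KRAS_ONLY": 1.0, "KRAS_TP53": 2.0}
    shifts = np.array([step[s] for s in strata]) * signature_effect
    sig_genes = [f"SIG{i:02d}" for i in range(1, N_SIGNATURE_GENES + 1)]
    bg_genes = [f"EXP{i:03d}" for i in range(1, n_background_genes + 1)]
    base = 5.0
    expr = np.vstack(
        [
            base + shifts + rng.normal(0.0, noise_sd, size=len(sample_ids))
            for _ in sig_genes
        ]
        + [base + rng.normal(0.0, noise_sd, size=len(sample_ids)) for _ in bg_genes]
    )
    expression = pd.DataFrame(expr, index=sig_genes + bg_genes, columns=sample_ids)

    mutations = pd.DataFrame(
        mut_rows,
        columns=[
            "Tumor_Sample_Barcode",
            "Hugo_Symbol",
            "Reference_Allele",
            "Tumor_Seq_Allele2",
            "Variant_Classification",
        ],
    )
    return CohortTables(
        mutations=mutations,
        segments=profiles,
        expression=expression,
        clinical=pd.DataFrame(clin_rows),
        truth=pd.DataFrame(truth_rows),
    )


# ---------------------------------------------------------------------------
# droplets


@dataclass
class DropletTruth:
    """Planted parameters of one simulated KRAS ddPCR well."""

    mutant_fraction: float
    n_droplets: int
    occupancy: float = 0.7
    cloud_means: dict = field(
        default_factory=lambda: {
            "negative": (2000.0, 2000.0),
            "wt": (2000.0, 9000.0),  # (mutant channel, wild-type channel)
            "mut": (13000.0, 2000.0),
        }
    )
    cloud_sd: float = 300.0
    rain_fraction: float = 0.0
    seed: int = 0


def generate_droplets(
    truth: DropletTruth,
    assay: Assay = Assay.KRAS_G12_13,
    gates: GateConfig = GateConfig(),
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate a two-channel droplet table for a KRAS mutation assay.

    Droplets are a mixture of empty, wild-type-positive, and mutant-positive
    axis-aligned Gaussian clouds; the expected mutant-positive count is
    mutant_fraction * n_droplets * occupancy.  An optional uniform "rain"
    component is off by default.  Warns when a cloud mean sits within one sd
    of its gate (ambiguous gating).
    """
    import warnings

    if not 0.0 <= truth.mutant_fraction <= 1.0:
        raise ValueError("mutant_fraction must lie in [0, 1]")
    if truth.n_droplets < 0 or int(truth.n_droplets) != truth.n_droplets:
        raise ValueError("n_droplets must be a non-negative integer")
    if rng is None:
        rng = np.random.default_rng(truth.seed)
    relevant = {"wt": (gates.wt_gate, 1), "mut": (gates.mut_gate, 0)}
    for cls, (gate, ch) in relevant.items():
        if abs(truth.cloud_means[cls][ch] - gate) < truth.cloud_sd:
            warnings.warn(f"{cls} cloud mean within 1 sd of its gate", stacklevel=2)
    n = int(truth.n_droplets)
    occupied = rng.random(n) < truth.occupancy
    mutant = occupied & (rng.random(n) < truth.mutant_fraction)
    wt = occupied & ~mutant
    means = np.tile(np.array(truth.cloud_means["negative"]), (n, 1))
    means[wt] = truth.cloud_means["wt"]
    means[mutant] = truth.cloud_means["mut"]
    amps = np.clip(rng.normal(means, truth.cloud_sd), 0.0, None)
    if truth.rain_fraction > 0:
        rain = rng.random(n) < truth.rain_fraction
        amps[rain] = rng.uniform(0.0, amps.max(initial=1.0), size=(int(rain.sum()), 2))
    return pd.DataFrame(
        {
            "well": "A01",
            "assay": assay.value,
            "ch1_amplitude": amps[:, 0],
            "ch2_amplitude": amps[:, 1],
            "_class": np.where(mutant, "mut", np.where(wt, "wt", "negative")),
        }
    )


def generate_cnv_droplets(
    tp53_per_tert: float,
    n_droplets: int,
    occupancy: float = 0.7,
    cloud_sd: float = 300.0,
    rng: np.random.Generator | int = 0,
    gates: GateConfig = GateConfig(),
) -> pd.DataFrame:
    """Simulate a TP53/TERT copy-number well with a planted copy ratio.

    Channel positives are independent Bernoulli draws: TERT-positive with
    probability ``occupancy`` and TP53-positive with probability
    ``occupancy * tp53_per_tert`` (ratio 1.0 = diploid = 100%).
    """
    if tp53_per_tert < 0:
        raise ValueError("tp53_per_tert must be >= 0")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    n = int(n_droplets)
    tert = rng.random(n) < occupancy
    tp53 = rng.random(n) < min(1.0, occupancy * tp53_per_tert)
    ch1 = np.clip(rng.normal(np.where(tp53, 8000.0, 2000.0), cloud_sd), 0.0, None)
    ch2 = np.clip(rng.normal(np.where(tert, 9500.0, 2000.0), cloud_sd), 0.0, None)
    return pd.DataFrame(
        {
            "well": "A01",
            "assay": Assay.TP53_TERT.value,
            "ch1_amplitude": ch1,
            "ch2_amplitude": ch2,
        }
    )


# ---------------------------------------------------------------------------
# counts


@dataclass
class CountTruth:
    gene_id: str
    length_bp: int
    baseline_mean: float
    fold_change: float
    dispersion: float
    is_de: bool


def make_count_truth(
    n_genes: int,
    n_de: int = 0,
    fold_change: float = 4.0,
    baseline_mean: float = 100.0,
    dispersion: float = 0.05,
    fraction_short: float = 0.1,
    fraction_zero: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> list[CountTruth]:
    """Build a gene-level truth table for :func:`generate_counts`.

    DE genes alternate up (fc) and down (1/fc); a ``fraction_short`` of
    genes gets a length below 500 bp and a ``fraction_zero`` a baseline of
    exactly zero.  ``is_de`` is fold_change outside [1/2, 2] by construction.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n_de > n_genes:
        raise ValueError("n_de cannot exceed n_genes")
    n_zero = int(round(fraction_zero * n_genes))
    n_short = int(round(fraction_short * n_genes))
    truth = []
    for i in range(n_genes):
        fc = 1.0
        if i < n_de:
            fc = fold_change if i % 2 == 0 else 1.0 / fold_change
        base = 0.0 if i >= n_genes - n_zero else float(
            baseline_mean * rng.uniform(0.5, 2.0)
        )
        length = (
            int(rng.integers(100, 500))
            if n_de <= i < n_de + n_short
            else int(rng.integers(500, 5000))
        )
        truth.append(
            CountTruth(
                gene_id=f"G{i + 1:05d}",
                length_bp=length,
                baseline_mean=base,
                fold_change=fc,
                dispersion=dispersion,
                is_de=not (0.5 <= fc <= 2.0),
            )
        )
    return truth


def generate_counts(
    truth: list[CountTruth],
    n_per_group: int,
    size_factors=(1.0, 1.0),
    seed: int | np.random.Generator = 0,
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Draw a negative-binomial count matrix from a gene truth table.

    Two groups of ``n_per_group`` samples; per-sample mean = baseline *
    fold_change^(group) * size_factor, variance = mu + dispersion * mu^2.
    ``size_factors`` has one entry per group (each group's samples share a
    library-size factor) or one entry per sample (length 2*n_per_group).
    Returns (counts, gene lengths, truth table as a DataFrame).
    """
    if int(n_per_group) != n_per_group or n_per_group < 1:
        raise ValueError("n_per_group must be a positive integer")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sf = np.asarray(size_factors, dtype=float)
    if sf.size == 2:
        sf = np.repeat(sf, n_per_group)
    if sf.size != 2 * n_per_group:
        raise ValueError("size_factors must have one entry per group or per sample")
    if (sf <= 0).any():
        raise ValueError("size factors must be > 0")
    samples = [f"A{i + 1}" for i in range(n_per_group)] + [
        f"B{i + 1}" for i in range(n_per_group)
    ]
    group_is_b = np.array([0] * n_per_group + [1] * n_per_group)
    mat = np.zeros((len(truth), 2 * n_per_group), dtype=np.int64)
    for gi, t in enumerate(truth):
        if t.baseline_mean < 0:
            raise ValueError("baseline means must be >= 0")
        if t.dispersion < 0:
            raise ValueError("dispersions must be >= 0")
        mu = t.baseline_mean * np.power(t.fold_change, group_is_b) * sf
        if t.baseline_mean == 0:
            continue
        if t.dispersion == 0:
            mat[gi] = rng.poisson(mu)
        else:
            r = 1.0 / t.dispersion
            mat[gi] = rng.negative_binomial(r, r / (r + mu))
    counts = pd.DataFrame(mat, index=[t.gene_id for t in truth], columns=samples)
    lengths = pd.Series(
        [t.length_bp for t in truth], index=counts.index, name="length_bp"
    )
    truth_df = pd.DataFrame([t.__dict__ for t in truth]).set_index("gene_id")
    return counts, lengths, truth_df


def truth_strata(truth: pd.DataFrame) -> pd.DataFrame:
    """Planted stratum labels in the stratify_patients output layout."""
    return truth[["patient_id", "stratum"]].copy()


def expected_stratum(row: pd.Series) -> str:
    """The stratum implied by a truth row under the classification rule."""
    kras = bool(row["has_kras_mutation"]) or row["planted_kras_z"] > 0.3
    tp53 = bool(row["has_tp53_mutation"]) or row["planted_tp53_z"] < -0.3
    if kras and tp53:
        return Stratum.KRAS_TP53.value
    if kras:
        return Stratum.KRAS_ONLY.value
    return Stratum.OTHER.value
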