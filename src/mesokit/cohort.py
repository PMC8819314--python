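"""Cohort-level statistics: substitution spectra, co-occurrence tests,
genomic-instability indices, and survival comparison across patient strata.

Survival uses the product-limit (Kaplan-Meier) estimator, the log-rank
(Mantel-Cox) test with the standard hypergeometric variance at tied event
times, and the classical Mantel-Haenszel pooled hazard-ratio estimate
HR = sum_j(d1j n2j / nj) / sum_j(d2j n1j / nj) over the 2x2 risk-set
tables at each distinct event time, with the Greenland-Robins variance for
the 95% CI.  (The Peto approximation exp((O1-E1)/V) is also exposed; it is
biased away from the null for hazard ratios far from 1.)

The instability indices are local reconstructions (the source cohort plots
precomputed indices without formulas): the genome-altered fraction is the
length-weighted fraction of the covered genome with |z| above a threshold,
and the aneuploidy score counts chromosome arms whose length-weighted score
magnitude exceeds the same threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cna import Scale, SegmentProfile, arm_score
from .intervals import all_arms

SUBSTITUTION_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class SpectrumResult:
    counts: pd.DataFrame  # classes x groups
    n_skipped_indels: int
    n_rejected: int
    mean_mutations_per_group: pd.Series


def substitution_spectrum(
    mutations: pd.DataFrame, groups: pd.Series | None = None
) -> SpectrumResult:
    """Six-class mononucleotide substitution spectrum, per group.

    Purine-reference substitutions are collapsed to the pyrimidine strand
    (G>A becomes C>T).  Records whose ref or alt is not a single base
    (indels) are skipped and counted; records with ref == alt are rejected.
    ``groups`` maps sample id -> group label; without it a single 'all'
    group is used.
    """
    ref = mutations.get("Reference_Allele", pd.Series(dtype=str)).astype(str).str.upper()
    alt = mutations.get("Tumor_Seq_Allele2", pd.Series(dtype=str)).astype(str).str.upper()
    if groups is None:
        sample_group = pd.Series("all", index=mutations.index)
        group_labels = ["all"]
    else:
        sample_group = mutations["Tumor_Sample_Barcode"].map(groups)
        group_labels = sorted(pd.Series(groups).unique())

    counts = pd.DataFrame(0, index=list(SUBSTITUTION_CLASSES), columns=group_labels)
    n_skipped = 0
    n_rejected = 0
    per_sample: dict[str, int] = {}
    for i in mutations.index:
        r, a = ref.loc[i], alt.loc[i]
        if len(r) != 1 or len(a) != 1 or r not in "ACGT" or a not in "ACGT" or r == "-" or a == "-":
            n_skipped += 1
            continue
        if r == a:
            n_rejected += 1
            continue
        if r in "AG":  # collapse to pyrimidine reference
            r, a = _COMPLEMENT[r], _COMPLEMENT[a]
        cls = f"{r}>{a}"
        g = sample_group.loc[i]
        if g in counts.columns:
            counts.loc[cls, g] += 1
        sample = mutations.loc[i].get("Tumor_Sample_Barcode", "all")
        per_sample[sample] = per_sample.get(sample, 0) + 1

    if groups is not None:
        g = pd.Series(groups)
        ns = pd.Series(per_sample, dtype=float).reindex(g.index).fillna(0.0)
        mean_per_group = ns.groupby(g).mean()
    else:
        mean_per_group = pd.Series(
            {"all": float(np.mean(list(per_sample.values()))) if per_sample else 0.0}
        )
    return SpectrumResult(counts, n_skipped, n_rejected, mean_per_group)


@dataclass
class CooccurrenceResult:
    n: int
    n_x: int
    n_y: int
    overlap: int
    expected_overlap: float
    p_enrichment: float  # upper-tail hypergeometric P(overlap >= k)
    p_two_sided: float  # point-probability exact two-sided p
    degenerate: bool = False


def cooccurrence_test(x_altered, y_altered) -> CooccurrenceResult:
    """Hypergeometric co-occurrence / mutual-exclusivity test.

    With N samples, K x-altered and n y-altered and overlap k, the
    enrichment p is the upper tail P(X >= k) of Hypergeometric(N, K, n).
    The two-sided p sums all outcome probabilities not exceeding the
    observed point probability.  Degenerate margins (all or none altered on
    either axis) return p = 1 with a flag.
    """
    x = np.asarray(x_altered, dtype=bool)
    y = np.asarray(y_altered, dtype=bool)
    if x.shape != y.shape or x.ndim != 1 or x.size < 1:
        raise ValueError("x and y must be equal-length 1-D vectors, length >= 1")
    n = x.size
    nx, ny = int(x.sum()), int(y.sum())
    k = int((x & y).sum())
    expected = nx * ny / n
    if nx in (0, n) or ny in (0, n):
        return CooccurrenceResult(n, nx, ny, k, expected, 1.0, 1.0, degenerate=True)
    rv = stats.hypergeom(n, nx, ny)
    p_enr = float(rv.sf(k - 1))
    support = np.arange(max(0, nx + ny - n), min(nx, ny) + 1)
    pmf = rv.pmf(support)
    p_two = float(pmf[pmf <= rv.pmf(k) * (1 + 1e-7)].sum())
    return CooccurrenceResult(n, nx, ny, k, expected, p_enr, min(p_two, 1.0))


def _check_records(records: pd.DataFrame) -> pd.DataFrame:
    for col in ("time", "event"):
        if col not in records.columns:
            raise ValueError(f"survival records need a {col!r} column")
    if (records["time"] <= 0).any():
        raise ValueError("survival times must be > 0")
    return records


@dataclass
class KmEstimate:
    times: np.ndarray  # event times (jump points)
    survival: np.ndarray  # S(t) just after each event time
    ci_lower: np.ndarray  # log-log (Greenwood) pointwise 95% band
    ci_upper: np.ndarray
    n_at_risk: np.ndarray
    n_events: np.ndarray
    median: float  # NaN when never reached
    median_ci: tuple[float, float]

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(records: pd.DataFrame) -> KmEstimate:
    """Product-limit survival estimator with median and log-log 95% CI.

    The median is the earliest time with S(t) <= 0.5 (NaN if never
    reached); its CI is where the pointwise confidence band crosses 0.5
    (Brookmeyer-Crowley).
    """
    records = _check_records(records)
    if len(records) == 0:
        raise ValueError("at least one record required")
    t = records["time"].to_numpy(dtype=float)
    e = records["event"].to_numpy(dtype=bool)
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    event_times = np.unique(t[e])
    surv, var_sum = [], []
    s, cum = 1.0, 0.0
    n_at_risk, n_events = [], []
    for ti in event_times:
        n_i = int((t >= ti).sum())
        d_i = int(((t == ti) & e).sum())
        s *= (n_i - d_i) / n_i
        if n_i > d_i:
            cum += d_i / (n_i * (n_i - d_i))
        else:
            cum = math.inf
        surv.append(s)
        var_sum.append(cum)
        n_at_risk.append(n_i)
        n_events.append(d_i)
    surv_a = np.array(surv)
    lo = np.full_like(surv_a, math.nan)
    hi = np.full_like(surv_a, math.nan)
    inner = (surv_a > 0) & (surv_a < 1) & np.isfinite(var_sum)
    if inner.any():
        s_in = surv_a[inner]
        se_loglog = np.sqrt(np.array(var_sum)[inner]) / np.abs(np.log(s_in))
        z = stats.norm.ppf(0.975)
        theta = np.log(-np.log(s_in))
        lo[inner] = np.exp(-np.exp(theta + z * se_loglog))
        hi[inner] = np.exp(-np.exp(theta - z * se_loglog))
    lo[surv_a == 0.0] = 0.0
    hi[surv_a == 1.0] = 1.0

    def _first_below(vals: np.ndarray) -> float:
        ok = np.where(np.nan_to_num(vals, nan=1.0) <= 0.5)[0]
        return float(event_times[ok[0]]) if ok.size else math.nan

    median = _first_below(surv_a)
    median_ci = (_first_below(hi), _first_below(lo))
    return KmEstimate(
        times=event_times,
        survival=surv_a,
        ci_lower=lo,
        ci_upper=hi,
        n_at_risk=np.array(n_at_risk),
        n_events=np.array(n_events),
        median=median,
        median_ci=median_ci,
    )


def _risk_table(records: pd.DataFrame, group_col: str):
    """Per event time: at-risk and event counts per group."""
    records = _check_records(records)
    groups = sorted(records[group_col].unique())
    t = records["time"].to_numpy(dtype=float)
    e = records["event"].to_numpy(dtype=bool)
    g = records[group_col].to_numpy()
    event_times = np.unique(t[e])
    n_g = np.array([[(t[g == gr] >= ti).sum() for gr in groups] for ti in event_times])
    d_g = np.array(
        [[((t[g == gr] == ti) & e[g == gr]).sum() for gr in groups] for ti in event_times]
    )
    return groups, event_times, n_g.astype(float), d_g.astype(float)


@dataclass
class LogrankResult:
    statistic: float
    p: float
    df: int
    observed: np.ndarray
    expected: np.ndarray
    undefined: bool = False


def logrank_test(records: pd.DataFrame, group_col: str = "group") -> LogrankResult:
    """K-sample log-rank (Mantel-Cox) test.

    Standard observed-minus-expected construction over distinct event times
    with the hypergeometric variance-covariance for ties; two-sided p from
    the chi-square distribution with k-1 df.  Zero events -> undefined.
    """
    groups, event_times, n_g, d_g = _risk_table(records, group_col)
    k = len(groups)
    if k < 2:
        raise ValueError("log-rank needs >= 2 groups")
    if event_times.size == 0:
        return LogrankResult(math.nan, math.nan, k - 1, np.zeros(k), np.zeros(k), True)
    n_tot = n_g.sum(axis=1)
    d_tot = d_g.sum(axis=1)
    expected = d_tot[:, None] * n_g / n_tot[:, None]
    O = d_g.sum(axis=0)
    E = expected.sum(axis=0)
    # variance-covariance of (O - E) over the first k-1 groups
    V = np.zeros((k, k))
    for j in range(event_times.size):
        nj, dj = n_tot[j], d_tot[j]
        if nj <= 1:
            continue
        frac = n_g[j] / nj
        c = dj * (nj - dj) / (nj - 1)
        V += c * (np.diag(frac) - np.outer(frac, frac))
    z = (O - E)[:-1]
    Vr = V[:-1, :-1]
    try:
        stat = float(z @ np.linalg.solve(Vr, z))
    except np.linalg.LinAlgError:
        stat = float(z @ np.linalg.pinv(Vr) @ z)
    stat = max(stat, 0.0)
    p = float(stats.chi2.sf(stat, k - 1))
    return LogrankResult(stat, p, k - 1, O, E)


@dataclass
class HazardRatioResult:
    hr: float
    ci95: tuple[float, float]
    hr_peto: float  # exp((O1-E1)/V) approximation, for reference
    o_minus_e: float
    variance: float
    undefined: bool = False


def mantel_haenszel_hr(
    records: pd.DataFrame, group_col: str = "group", groups_order: list | None = None
) -> HazardRatioResult:
    """Mantel-Haenszel hazard-ratio estimate for two groups.

    HR of the first group relative to the second is the classical pooled
    rate ratio sum_j(d1j n2j / nj) / sum_j(d2j n1j / nj) over the 2x2
    risk-set tables at each distinct event time; the 95% CI uses the
    Greenland-Robins variance of its logarithm.  The Peto approximation
    exp((O1-E1)/V) is reported alongside.  Degenerate inputs (no events in
    one group, so the ratio is 0 or infinite) are flagged undefined.
    """
    groups, event_times, n_g, d_g = _risk_table(records, group_col)
    if len(groups) != 2:
        raise ValueError("hazard ratio is defined for exactly two groups")
    if groups_order is not None:
        idx = [groups.index(g) for g in groups_order]
        n_g, d_g = n_g[:, idx], d_g[:, idx]
    if event_times.size == 0 or d_g.sum() == 0:
        return HazardRatioResult(math.nan, (math.nan, math.nan), math.nan, 0.0, 0.0, True)
    n_tot = n_g.sum(axis=1)
    d_tot = d_g.sum(axis=1)
    e1 = d_tot * n_g[:, 0] / n_tot
    v = (
        d_tot
        * (n_g[:, 0] / n_tot)
        * (n_g[:, 1] / n_tot)
        * (n_tot - d_tot)
        / np.maximum(n_tot - 1, 1)
    )
    o_minus_e = float(d_g[:, 0].sum() - e1.sum())
    V = float(v.sum())
    hr_peto = math.exp(o_minus_e / V) if V > 0 else math.nan
    num = float((d_g[:, 0] * n_g[:, 1] / n_tot).sum())
    den = float((d_g[:, 1] * n_g[:, 0] / n_tot).sum())
    if num == 0 or den == 0:
        hr = math.inf if den == 0 and num > 0 else 0.0 if num == 0 and den > 0 else math.nan
        return HazardRatioResult(hr, (math.nan, math.nan), hr_peto, o_minus_e, V, True)
    hr = num / den
    # Greenland-Robins variance of log(HR_MH)
    gr = float(
        ((d_tot * n_g[:, 0] * n_g[:, 1]) / n_tot**2 - d_g[:, 0] * d_g[:, 1] / n_tot).sum()
    )
    se = math.sqrt(gr / (num * den))
    z = 1.959963984540054
    return HazardRatioResult(
        hr, (hr * math.exp(-z * se), hr * math.exp(z * se)), hr_peto, o_minus_e, V
    )


@dataclass
class InstabilityIndex:
    sample_id: str
    genome_altered_fraction: float
    aneuploidy_score: int
    covered_bp: int


def instability_indices(
    profile: SegmentProfile, threshold: float = 0.1, arms=None
) -> InstabilityIndex:
    """Genomic-instability indices from a z-scale segment profile.

    genome_altered_fraction: length-weighted fraction of the covered genome
    with |z| > threshold.  aneuploidy_score: number of arms whose
    length-weighted score magnitude exceeds threshold (arms without any
    overlapping segment do not contribute).  These are documented local
    reconstructions of the plotted cohort indices.
    """
    if profile.scale is not Scale.Z:
        raise ValueError("instability indices require a z-scale profile")
    seg = profile.segments
    if seg.empty:
        return InstabilityIndex(profile.sample_id, math.nan, 0, 0)
    lengths = (seg["end"] - seg["start"] + 1).to_numpy(dtype=float)
    altered = np.abs(seg["value"].to_numpy(dtype=float)) > threshold
    frac = float(lengths[altered].sum() / lengths.sum())
    if arms is None:
        arms = [a for _, _, a in all_arms()]
    score = 0
    for arm in arms:
        z = arm_score(profile, arm)
        if not math.isnan(z) and abs(z) > threshold:
            score += 1
    return InstabilityIndex(profile.sample_id, frac, score, int(lengths.sum()))
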