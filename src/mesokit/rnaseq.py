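"""RNA-seq preprocessing cascade and two-group differential expression.

The cascade mirrors classic count-model practice: (0) remove genes with
zero counts across all samples, (1) median-of-ratios size-factor
normalization, (2) three gene filters with strict cutoffs -- length
< 500 bp, average reads per 100 bp less than the 25th percentile of that
distribution, and mean normalized count below the median of per-gene mean
normalized counts -- and (3) a per-gene negative-binomial exact test with
method-of-moments pooled dispersion, BH correction, and a conjunctive
absolute fold-change cutoff of 2 (pseudo-count 1 in the ratio).

The filter cutoffs are computed from the input distribution by default but
accept precomputed values, so that re-running the filter on its own kept
set with the realized cutoffs removes nothing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def remove_zero_genes(counts: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Drop genes with zero counts over all samples; return (kept, n_removed)."""
    totals = counts.sum(axis=1)
    kept = counts.loc[totals > 0]
    return kept, int((totals == 0).sum())


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios per-sample size factors.

    For each gene with all-positive counts, form the ratio of each sample's
    count to the gene's geometric mean across samples; the sample's factor
    is the median of those ratios.  Requires at least one all-positive gene.
    """
    vals = counts.to_numpy(dtype=float)
    if (vals < 0).any():
        raise ValueError("counts must be non-negative")
    allpos = (vals > 0).all(axis=1)
    if not allpos.any():
        raise ValueError("no gene with positive counts in every sample")
    pos = vals[allpos]
    gm = np.exp(np.mean(np.log(pos), axis=1, keepdims=True))
    factors = np.median(pos / gm, axis=0)
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalize_counts(counts: pd.DataFrame, factors: pd.Series | None = None) -> pd.DataFrame:
    if factors is None:
        factors = size_factors(counts)
    return counts / factors


@dataclass
class FilterReport:
    n_input: int
    n_short: int
    n_low_density: int
    n_below_median: int
    n_total_excluded: int  # union of the three
    cutoff_density: float  # realized 25th percentile, reads per 100 bp
    cutoff_median: float  # realized median normalized count
    min_length: int

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def filter_genes(
    norm_counts: pd.DataFrame,
    gene_lengths: pd.Series,
    min_length: int = 500,
    density_quantile: float = 0.25,
    density_cutoff: float | None = None,
    median_cutoff: float | None = None,
) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the three gene filters; remove the union of their catches.

    (i) length < ``min_length`` bp; (ii) average reads per 100 bp
    (mean over samples of normalized count * 100 / length) less than the
    25th percentile of that distribution; (iii) mean normalized count below
    the median of per-gene means.  All inequalities strict, so genes
    sitting exactly at a cutoff are kept.  Cutoffs default to the input
    distribution but can be supplied.
    """
    missing = norm_counts.index.difference(gene_lengths.index)
    if len(missing):
        raise ValueError(f"missing lengths for {len(missing)} genes, e.g. {list(missing[:3])}")
    lengths = gene_lengths.loc[norm_counts.index].astype(float)
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be > 0")

    mean_norm = norm_counts.mean(axis=1)
    density = mean_norm * 100.0 / lengths
    if density_cutoff is None:
        density_cutoff = float(np.quantile(density, density_quantile))
    if median_cutoff is None:
        median_cutoff = float(np.median(mean_norm))

    short = lengths < min_length
    low_density = density < density_cutoff
    below_median = mean_norm < median_cutoff
    excluded = short | low_density | below_median
    report = FilterReport(
        n_input=len(norm_counts),
        n_short=int(short.sum()),
        n_low_density=int(low_density.sum()),
        n_below_median=int(below_median.sum()),
        n_total_excluded=int(excluded.sum()),
        cutoff_density=density_cutoff,
        cutoff_median=median_cutoff,
        min_length=min_length,
    )
    return norm_counts.loc[~excluded], report


def _pooled_dispersion(norm: np.ndarray, group_idx: list[np.ndarray]) -> np.ndarray:
    """Method-of-moments dispersion per gene, pooled across groups.

    alpha solves var = mu + alpha mu^2 within each group; groups with one
    replicate contribute nothing, and when no group has replicates the
    dispersion is estimated treating all samples as one group (early
    count-model practice for unreplicated designs).  Per-gene estimates at
    few replicates are noisy and anti-conservative when they undershoot, so
    each gene's dispersion is floored at the across-gene median estimate
    (conservative sharing, as in early count-model practice).
    """
    ests, weights = [], []
    for idx in group_idx:
        if idx.size < 2:
            continue
        mu = norm[:, idx].mean(axis=1)
        var = norm[:, idx].var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            a = (var - mu) / np.square(mu)
        ests.append(np.where(mu > 0, a, 0.0))
        weights.append(idx.size - 1)
    if not ests:
        mu = norm.mean(axis=1)
        var = norm.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            a = (var - mu) / np.square(mu)
        pooled = np.where(mu > 0, a, 0.0)
    else:
        w = np.array(weights, dtype=float)
        pooled = np.average(np.vstack(ests), axis=0, weights=w)
    pooled = np.clip(pooled, 1e-8, None)
    floor = float(np.median(pooled))
    return np.maximum(pooled, floor)


def _nb_params(mu: float, alpha: float) -> tuple[float, float]:
    """Convert (mean, dispersion) to scipy's (r, p) with var = mu + alpha mu^2."""
    r = 1.0 / alpha
    return r, r / (r + mu)


def _exact_test(ka: int, kb: int, mu_a: float, mu_b: float, alpha_a: float, alpha_b: float) -> float:
    """Conditional two-sided NB exact p for group sums ka vs kb.

    Enumerates all splits a + b = ka + kb of the observed total and sums the
    joint probabilities not exceeding the observed one.
    """
    K = ka + kb
    a = np.arange(K + 1)
    ra, pa = _nb_params(mu_a, alpha_a)
    rb, pb = _nb_params(mu_b, alpha_b)
    logp = stats.nbinom.logpmf(a, ra, pa) + stats.nbinom.logpmf(K - a, rb, pb)
    logp -= logp.max()
    p = np.exp(logp)
    total = p.sum()
    if total == 0 or not np.isfinite(total):
        return 1.0
    obs = p[ka]
    return float(min(1.0, p[p <= obs * (1 + 1e-8)].sum() / total))


def de_two_group(
    counts: pd.DataFrame,
    groups: pd.Series,
    fc_cutoff: float = 2.0,
    alpha_q: float = 0.05,
    factors: pd.Series | None = None,
) -> pd.DataFrame:
    """Two-group differential expression on a count matrix.

    Normalizes by median-of-ratios size factors (or the supplied ones),
    runs the NB exact test per gene with pooled method-of-moments
    dispersion, BH-corrects, and labels a gene DE iff q <= ``alpha_q`` AND
    the normalized-mean ratio (pseudo-count 1) is >= ``fc_cutoff`` in
    either direction.  Returns a table with columns base_mean, mean_a,
    mean_b, fc, log2fc, p, q, significant, direction.
    """
    groups = groups.loc[counts.columns]
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise ValueError(f"exactly two groups required, got {labels}")
    cols = list(counts.columns)
    idx_a = np.array([i for i, c in enumerate(cols) if groups[c] == labels[0]])
    idx_b = np.array([i for i, c in enumerate(cols) if groups[c] == labels[1]])
    raw = counts.to_numpy(dtype=float)
    if raw[:, idx_a].sum() == 0 or raw[:, idx_b].sum() == 0:
        raise ValueError("a group has zero total counts")
    if factors is None:
        factors = size_factors(counts)
    norm = raw / factors.to_numpy()

    alpha = _pooled_dispersion(norm, [idx_a, idx_b])
    mean_a = norm[:, idx_a].mean(axis=1)
    mean_b = norm[:, idx_b].mean(axis=1)
    base_mean = norm.mean(axis=1)
    # pooled per-sample mean under the null, on the normalized scale
    q0 = norm.mean(axis=1)
    ka = np.rint(norm[:, idx_a].sum(axis=1)).astype(np.int64)
    kb = np.rint(norm[:, idx_b].sum(axis=1)).astype(np.int64)
    na, nb = idx_a.size, idx_b.size

    pvals = np.ones(len(counts))
    for i in range(len(counts)):
        if ka[i] + kb[i] == 0:
            continue
        # group sums: mean n*q, var n*(q + alpha q^2) => dispersion alpha/n
        pvals[i] = _exact_test(
            int(ka[i]), int(kb[i]), na * q0[i], nb * q0[i], alpha[i] / na, alpha[i] / nb
        )
    qvals = multipletests(pvals, method="fdr_bh")[1]
    fc = (mean_b + 1.0) / (mean_a + 1.0)
    log2fc = np.log2(fc)
    passes_fc = (fc >= fc_cutoff) | (fc <= 1.0 / fc_cutoff)
    significant = (qvals <= alpha_q) & passes_fc
    direction = np.where(~significant, "ns", np.where(fc > 1, "up", "down"))
    return pd.DataFrame(
        {
            "base_mean": base_mean,
            "mean_a": mean_a,
            "mean_b": mean_b,
            "fc": fc,
            "log2fc": log2fc,
            "p": pvals,
            "q": qvals,
            "significant": significant,
            "direction": direction,
        },
        index=counts.index,
    )
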