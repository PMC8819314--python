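"""Monotone expression-signature extraction, bi-clustering, and qPCR helpers.

The signature is the set of genes that are significantly different across
the three patient strata (Kruskal-Wallis rank test, Benjamini-Hochberg
corrected across genes) AND whose group medians are strictly monotone
increasing from unaltered through KRAS-only to combined KRAS/TP53 patients.
Rows and columns are bi-clustered with Pearson-correlation distance
(d = 1 - r) and complete linkage.  Relative qPCR abundance is the classic
2^-dCt against a reference transcript.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .cna import Stratum

STRATUM_ORDER = (Stratum.OTHER.value, Stratum.KRAS_ONLY.value, Stratum.KRAS_TP53.value)


@dataclass
class SignatureResult:
    table: pd.DataFrame  # per-gene statistic, p, q, group medians, passes
    genes: list[str]  # the signature (ordering + FDR criteria met)
    alpha_q: float
    test: str = "kruskal-wallis"


def monotone_signature(
    expr: pd.DataFrame, strata: pd.DataFrame, alpha_q: float = 0.05
) -> SignatureResult:
    """Extract genes overexpressed monotonically across the three strata.

    ``expr`` is genes x samples (normalized, e.g. log2(fpkm-uq + 1));
    ``strata`` has columns patient_id, stratum.  A gene enters the signature
    iff BH q <= alpha_q and median(KRAS_TP53) > median(KRAS_ONLY) >
    median(OTHER) strictly.  Requires >= 2 samples per stratum.
    """
    smap = strata.set_index("patient_id")["stratum"]
    common = [s for s in expr.columns if s in smap.index]
    if len(common) < len(expr.columns):
        warnings.warn(
            f"{len(expr.columns) - len(common)} expression samples lack stratum labels",
            stacklevel=2,
        )
    expr = expr[common]
    labels = smap.loc[common]
    group_cols = {g: labels.index[labels == g] for g in STRATUM_ORDER}
    for g, cols in group_cols.items():
        if len(cols) < 2:
            raise ValueError(f"stratum {g} has {len(cols)} samples; >= 2 required")

    mats = {g: expr[cols].to_numpy(dtype=float) for g, cols in group_cols.items()}
    stat = np.full(len(expr), math.nan)
    pval = np.ones(len(expr))
    for i in range(len(expr)):
        samples = [mats[g][i] for g in STRATUM_ORDER]
        pooled = np.concatenate(samples)
        if np.allclose(pooled, pooled[0]):
            stat[i], pval[i] = 0.0, 1.0
            continue
        stat[i], pval[i] = stats.kruskal(*samples)
    q = multipletests(pval, method="fdr_bh")[1]
    med = {g: np.median(mats[g], axis=1) for g in STRATUM_ORDER}
    mono = (med[STRATUM_ORDER[2]] > med[STRATUM_ORDER[1]]) & (
        med[STRATUM_ORDER[1]] > med[STRATUM_ORDER[0]]
    )
    passes = (q <= alpha_q) & mono
    table = pd.DataFrame(
        {
            "gene": expr.index,
            "statistic": stat,
            "p": pval,
            "q": q,
            "median_other": med[STRATUM_ORDER[0]],
            "median_kras_only": med[STRATUM_ORDER[1]],
            "median_kras_tp53": med[STRATUM_ORDER[2]],
            "monotone": mono,
            "in_signature": passes,
        }
    ).set_index("gene")
    return SignatureResult(table, list(table.index[passes]), alpha_q)


def zscore_rows(expr: pd.DataFrame) -> pd.DataFrame:
    """Z-score each row to mean 0, sd 1 (population sd); constant rows dropped."""
    vals = expr.to_numpy(dtype=float)
    sd = vals.std(axis=1)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"dropped {int((~keep).sum())} constant rows", stacklevel=2)
    vals = vals[keep]
    z = (vals - vals.mean(axis=1, keepdims=True)) / vals.std(axis=1, keepdims=True)
    return pd.DataFrame(z, index=expr.index[keep], columns=expr.columns)


@dataclass
class Dendrogram:
    linkage: np.ndarray  # scipy linkage matrix
    labels: list[str]

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    @property
    def leaf_order(self) -> list[str]:
        return [self.labels[i] for i in hierarchy.leaves_list(self.linkage)]

    def cut(self, k: int) -> pd.Series:
        lab = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return pd.Series(lab, index=self.labels, name="cluster")

    def to_newick(self) -> str:
        """Export the merge tree as a Newick string with merge heights."""
        n = len(self.labels)
        nodes: dict[int, tuple[str, float]] = {
            i: (self.labels[i], 0.0) for i in range(n)
        }
        for i, (a, b, h, _) in enumerate(self.linkage):
            na, ha = nodes.pop(int(a))
            nb, hb = nodes.pop(int(b))
            rep = f"({na}:{h - ha:.10g},{nb}:{h - hb:.10g})"
            nodes[n + i] = (rep, float(h))
        (root, _), = nodes.values()
        return root + ";"


def pearson_distance(matrix: np.ndarray) -> np.ndarray:
    """Pairwise 1 - Pearson r between rows; rejects constant rows."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape[0] < 2:
        raise ValueError("need >= 2 items to cluster")
    if (matrix.std(axis=1) == 0).any():
        raise ValueError("constant rows have undefined correlations")
    d = 1.0 - np.corrcoef(matrix)
    np.fill_diagonal(d, 0.0)
    return np.clip((d + d.T) / 2, 0.0, None)


def hclust_pearson_complete(matrix: pd.DataFrame, axis: int = 0) -> Dendrogram:
    """Agglomerative complete-linkage clustering with Pearson distance.

    ``axis=0`` clusters rows (genes), ``axis=1`` columns (samples).
    Ties are broken by input order (scipy's deterministic behavior).
    """
    data = matrix.to_numpy(dtype=float)
    labels = list(matrix.index if axis == 0 else matrix.columns)
    if axis == 1:
        data = data.T
    d = pearson_distance(data)
    link = hierarchy.linkage(squareform(d, checks=False), method="complete")
    return Dendrogram(link, labels)


def cluster_enrichment(labels: pd.Series, altered: pd.Series, target_cluster) -> float:
    """Upper-tail hypergeometric p for altered samples in the target cluster.

    ``labels``: sample -> cluster id; ``altered``: sample -> bool.  Empty
    target cluster is degenerate (p = 1).
    """
    common = labels.index.intersection(altered.index)
    if len(common) != len(labels) or len(common) != len(altered):
        raise ValueError("labels and alteration status must cover the same samples")
    in_cluster = labels.loc[common] == target_cluster
    alt = altered.loc[common].astype(bool)
    n_cluster = int(in_cluster.sum())
    if n_cluster == 0:
        return 1.0
    N, K = len(common), int(alt.sum())
    k = int((in_cluster & alt).sum())
    return float(stats.hypergeom(N, K, n_cluster).sf(k - 1))


def ddct_relative_expression(ct_target: float, ct_reference: float) -> float:
    """Relative transcript abundance 2^-(Ct_target - Ct_reference)."""
    if not (math.isfinite(ct_target) and math.isfinite(ct_reference)):
        raise ValueError("Ct values must be finite")
    return 2.0 ** (-(ct_target - ct_reference))
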