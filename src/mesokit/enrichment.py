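"""Gene-set enrichment: pre-ranked running-sum ES and binomial
overrepresentation with fold-enrichment and BH-FDR.

The pre-ranked enrichment score walks the ranked list; hits increment the
running sum by |score|^p normalized over the in-set scores, misses
decrement by 1/(N - N_hits).  ES is the signed maximum deviation from
zero.  The nominal p is a gene-label permutation p (the only permutation
scheme available for pre-ranked input), sign-conditional as in the
original method.  Overrepresentation compares observed vs expected hits of
a query list in each annotation set against a reference universe with an
upper-tail binomial p.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def _validate_ranked(ranked: pd.Series) -> pd.Series:
    if ranked.index.has_duplicates:
        raise ValueError("ranked list contains duplicate gene symbols")
    if not np.all(np.isfinite(ranked.to_numpy(dtype=float))):
        raise ValueError("ranking scores must be finite")
    return ranked.sort_values(ascending=False, kind="stable")


def _es_from_hits(scores: np.ndarray, hits: np.ndarray, p: float) -> float:
    n = scores.size
    n_hits = int(hits.sum())
    if n_hits == 0 or n_hits == n:
        raise ValueError("gene set must hit a strict subset of the ranked list")
    w = np.abs(scores) ** p
    hit_sum = w[hits].sum()
    if hit_sum == 0:
        # all in-set scores are exactly zero: equal hit weights
        inc = hits / n_hits
    else:
        inc = np.where(hits, w / hit_sum, 0.0)
    dec = np.where(hits, 0.0, 1.0 / (n - n_hits))
    running = np.cumsum(inc - dec)
    return float(running[np.argmax(np.abs(running))])


def preranked_es(ranked: pd.Series, gene_set, weight: float = 1.0) -> float:
    """Pre-ranked enrichment score of one gene set.

    ``ranked`` maps gene symbol -> ranking score (sorted internally,
    descending).  Raises when the set has no overlap with the list.
    """
    ranked = _validate_ranked(ranked)
    members = set(gene_set)
    hits = np.array([g in members for g in ranked.index])
    if not hits.any():
        raise ValueError("gene set has no overlap with the ranked list")
    return _es_from_hits(ranked.to_numpy(dtype=float), hits, weight)


def preranked_p(
    ranked: pd.Series,
    gene_set,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
    weight: float = 1.0,
) -> tuple[float, float]:
    """Nominal permutation p of the pre-ranked ES; returns (ES, p).

    Gene labels are permuted (equivalently, random hit positions of the
    same set size).  The p is sign-conditional: for a positive observed ES
    it is the fraction of positive permutation ES values at least as large,
    and symmetrically for negative.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ranked = _validate_ranked(ranked)
    scores = ranked.to_numpy(dtype=float)
    members = set(gene_set)
    hits = np.array([g in members for g in ranked.index])
    if not hits.any():
        raise ValueError("gene set has no overlap with the ranked list")
    es_obs = _es_from_hits(scores, hits, weight)
    n, k = scores.size, int(hits.sum())
    es_perm = np.empty(n_perm)
    for i in range(n_perm):
        idx = rng.choice(n, size=k, replace=False)
        h = np.zeros(n, dtype=bool)
        h[idx] = True
        es_perm[i] = _es_from_hits(scores, h, weight)
    if es_obs >= 0:
        same_sign = es_perm[es_perm >= 0]
        extreme = (same_sign >= es_obs).sum()
    else:
        same_sign = es_perm[es_perm < 0]
        extreme = (same_sign <= es_obs).sum()
    denom = max(1, same_sign.size)
    return es_obs, float(extreme / denom)


@dataclass
class OverrepresentationResult:
    name: str
    n_set_in_reference: int
    observed: int
    expected: float
    fold_enrichment: float
    p: float
    q: float = math.nan


def overrepresentation(
    query: list[str], sets: dict[str, set[str]], reference: list[str]
) -> pd.DataFrame:
    """Binomial overrepresentation of a query list in annotation sets.

    For each set S with m = |S intersect reference| members, expected hits
    = |query| * m / |reference|, fold-enrichment = observed/expected, p =
    upper-tail Binomial(|query|, m/|reference|); q is BH across sets.
    Requires query to be a subset of the reference.
    """
    ref = set(reference)
    if not ref:
        raise ValueError("reference universe is empty")
    qset = set(query)
    outside = qset - ref
    if outside:
        raise ValueError(f"{len(outside)} query genes outside the reference universe")
    nq, nref = len(qset), len(ref)
    rows = []
    for name, members in sets.items():
        m = len(set(members) & ref)
        obs = len(qset & set(members))
        prob = m / nref
        expected = nq * prob
        fold = obs / expected if expected > 0 else math.nan
        p = float(stats.binom.sf(obs - 1, nq, prob)) if m > 0 else 1.0
        rows.append(
            {
                "name": name,
                "n_set_in_reference": m,
                "observed": obs,
                "expected": expected,
                "fold_enrichment": fold,
                "p": p,
            }
        )
    df = pd.DataFrame(rows).set_index("name")
    df["q"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    return df
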