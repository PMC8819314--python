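import itertools
import math

import numpy as np
import pandas as pd
import pytest

from mesokit import cohort
from mesokit.cohort import (
    cooccurrence_test,
    instability_indices,
    km_estimate,
    logrank_test,
    mantel_haenszel_hr,
    substitution_spectrum,
)
from mesokit.intervals import GenomicInterval

from .conftest import profile_from_rows, random_profile


def _muts(pairs, sample="S1"):
    return pd.DataFrame(
        [
            {
                "Tumor_Sample_Barcode": sample,
                "Hugo_Symbol": "G",
                "Reference_Allele": r,
                "Tumor_Seq_Allele2": a,
                "Variant_Classification": "Missense_Mutation",
            }
            for r, a in pairs
        ]
    )


class TestSpectrum:
    def test_purine_reference_collapses_to_pyrimidine(self):
        res = substitution_spectrum(_muts([("G", "A")]))
        assert res.counts.loc["C>T", "all"] == 1

    def test_strand_equivalent_records_pool(self):
        res = substitution_spectrum(_muts([("C", "A"), ("G", "T"), ("C", "A")]))
        assert res.counts.loc["C>A", "all"] == 3

    def test_empty_input_gives_zero_spectrum(self):
        res = substitution_spectrum(_muts([]))
        assert res.counts["all"].sum() == 0 if "all" in res.counts else res.counts.sum().sum() == 0

    def test_indels_skipped_and_conserved(self):
        res = substitution_spectrum(_muts([("C", "T"), ("-", "AT"), ("TT", "T")]))
        assert res.counts.sum().sum() == 1
        assert res.n_skipped_indels == 2
        # conservation: processed + skipped + rejected = input records
        assert res.counts.sum().sum() + res.n_skipped_indels + res.n_rejected == 3

    def test_ref_equals_alt_rejected(self):
        res = substitution_spectrum(_muts([("C", "C")]))
        assert res.n_rejected == 1 and res.counts.sum().sum() == 0


def hypergeom_tail_oracle(n, nx, ny, k):
    """P(overlap >= k) by exhaustive enumeration of y-subsets (x fixed)."""
    x = set(range(nx))
    hits = 0
    total = 0
    for y in itertools.combinations(range(n), ny):
        total += 1
        hits += len(x & set(y)) >= k
    return hits / total


class TestCooccurrence:
    def test_small_instance_exact_value(self):
        x = [True] * 4 + [False] * 6
        y = [True] * 5 + [False] * 5
        res = cooccurrence_test(x, y)
        assert res.overlap == 4
        assert res.p_enrichment == pytest.approx(5 / 210, abs=1e-12)

    def test_matches_enumeration_oracle_small_n(self):
        rng = np.random.default_rng(4)
        for _ in range(30):
            n = int(rng.integers(4, 13))
            nx = int(rng.integers(1, n))
            ny = int(rng.integers(1, n))
            x = np.zeros(n, bool)
            x[:nx] = True
            y = np.zeros(n, bool)
            y[rng.choice(n, ny, replace=False)] = True
            res = cooccurrence_test(x, y)
            assert res.p_enrichment == pytest.approx(
                hypergeom_tail_oracle(n, nx, ny, res.overlap), abs=1e-12
            )

    def test_expected_overlap_gives_nonsmall_p(self):
        # integer-expectation margins, overlap exactly at expectation (2)
        x = [True] * 5 + [False] * 5
        y = [True, True, False, False, False, True, True, False, False, False]
        res = cooccurrence_test(x, y)
        assert res.overlap == res.expected_overlap == 2
        assert res.p_enrichment >= 0.5

    def test_degenerate_margin(self):
        res = cooccurrence_test([True, False], [False, False])
        assert res.degenerate and res.p_enrichment == 1.0

    def test_null_calibration(self):
        # over >= 500 random null draws the 5%-level rejection rate is <= alpha + 2 SE
        rng = np.random.default_rng(9)
        n, nx, ny = 40, 12, 15
        reject = 0
        n_rep = 600
        for _ in range(n_rep):
            x = np.zeros(n, bool)
            x[rng.choice(n, nx, replace=False)] = True
            y = np.zeros(n, bool)
            y[rng.choice(n, ny, replace=False)] = True
            reject += cooccurrence_test(x, y).p_enrichment <= 0.05
        se = math.sqrt(0.05 * 0.95 / n_rep)
        assert reject / n_rep <= 0.05 + 2 * se


class TestKaplanMeier:
    def test_hand_example_with_censoring(self):
        rec = pd.DataFrame({"time": [1, 2, 3], "event": [True, False, True]})
        km = km_estimate(rec)
        assert km.survival_at(1) == pytest.approx(2 / 3)
        assert km.survival_at(3) == pytest.approx(0.0)

    def test_all_censored_survival_stays_one(self):
        rec = pd.DataFrame({"time": [5, 6, 7], "event": [False] * 3})
        km = km_estimate(rec)
        assert km.times.size == 0 and math.isnan(km.median)

    def test_single_event_median(self):
        rec = pd.DataFrame({"time": [5.0], "event": [True]})
        km = km_estimate(rec)
        assert km.survival_at(5) == 0.0 and km.median == 5.0

    def test_no_censoring_equals_empirical_survival(self, rng):
        t = rng.exponential(100, size=40).round(1) + 1
        rec = pd.DataFrame({"time": t, "event": True})
        km = km_estimate(rec)
        for q in [np.quantile(t, x) for x in (0.2, 0.5, 0.8)]:
            assert km.survival_at(q) == pytest.approx((t > q).mean(), abs=1e-12)

    def test_matches_lifelines(self, rng):
        from lifelines import KaplanMeierFitter

        t = rng.exponential(100, size=60) + 1
        e = rng.random(60) < 0.7
        rec = pd.DataFrame({"time": t, "event": e})
        km = km_estimate(rec)
        kmf = KaplanMeierFitter().fit(t, e)
        for ti in km.times:
            assert km.survival_at(ti) == pytest.approx(
                float(kmf.predict(ti)), abs=1e-9
            )

    def test_nonpositive_times_rejected(self):
        with pytest.raises(ValueError):
            km_estimate(pd.DataFrame({"time": [0.0], "event": [True]}))


class TestLogrankAndHazard:
    def test_identical_groups_stat_zero(self):
        rec = pd.DataFrame(
            {"time": [1, 2, 3] * 2, "event": [True] * 6, "group": ["a"] * 3 + ["b"] * 3}
        )
        res = logrank_test(rec)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_hand_computed_six_record_example(self):
        # group a events at 1,2,3; group b at 10,20,30
        # O_a=3, E_a=0.5+0.4+0.25=1.15, V=0.25+0.24+0.1875=0.6775
        rec = pd.DataFrame(
            {
                "time": [1, 2, 3, 10, 20, 30],
                "event": [True] * 6,
                "group": ["a"] * 3 + ["b"] * 3,
            }
        )
        res = logrank_test(rec)
        assert res.statistic == pytest.approx(1.85**2 / 0.6775, rel=1e-12)
        assert res.p < 0.05
        # fully separated groups: pooled rate ratio degenerates to infinity
        hr = mantel_haenszel_hr(rec, groups_order=["a", "b"])
        assert hr.undefined and math.isinf(hr.hr)
        assert hr.hr_peto == pytest.approx(math.exp(1.85 / 0.6775), rel=1e-12)

    def test_hand_computed_interleaved_hazard_ratio(self):
        # a events at 1, 3; b events at 2, 4
        # numerator  = 1*2/4 + 1*1/2 = 1;  denominator = 1*1/3 + 1*0/1 = 1/3
        rec = pd.DataFrame(
            {"time": [1, 3, 2, 4], "event": True, "group": ["a", "a", "b", "b"]}
        )
        hr = mantel_haenszel_hr(rec, groups_order=["a", "b"])
        assert hr.hr == pytest.approx(3.0, rel=1e-12)
        # Greenland-Robins: sum terms 0.25 + 2/9 + 0.25 + 0 = 0.7222...
        se = math.sqrt((0.25 + 2 / 9 + 0.25) / (1.0 * (1 / 3)))
        assert hr.ci95[0] == pytest.approx(3.0 * math.exp(-1.959963984540054 * se), rel=1e-9)

    def test_matches_lifelines_statistic(self, rng):
        from lifelines.statistics import logrank_test as ll_logrank

        t = np.concatenate([rng.exponential(80, 30), rng.exponential(160, 30)]) + 1
        e = rng.random(60) < 0.8
        g = np.array(["a"] * 30 + ["b"] * 30)
        rec = pd.DataFrame({"time": t, "event": e, "group": g})
        res = logrank_test(rec)
        ll = ll_logrank(t[:30], t[30:], e[:30], e[30:])
        assert res.statistic == pytest.approx(ll.test_statistic, rel=1e-6)
        assert res.p == pytest.approx(ll.p_value, rel=1e-6)

    def test_zero_events_flagged(self):
        rec = pd.DataFrame({"time": [1, 2], "event": [False, False], "group": ["a", "b"]})
        assert logrank_test(rec).undefined

    def test_planted_hazard_ratio_recovered(self):
        rng = np.random.default_rng(17)
        hits = 0
        n_rep = 60
        for _ in range(n_rep):
            t1 = rng.exponential(300.0, 200)
            t2 = rng.exponential(100.0, 200)  # hazard ratio 3 vs group 1
            rec = pd.DataFrame(
                {
                    "time": np.concatenate([t2, t1]),
                    "event": True,
                    "group": ["fast"] * 200 + ["slow"] * 200,
                }
            )
            hr = mantel_haenszel_hr(rec, groups_order=["fast", "slow"])
            hits += 2.4 <= hr.hr <= 3.75
        assert hits / n_rep >= 0.9

    def test_logrank_null_p_uniform_under_permutation(self, small_cohort):
        rec = small_cohort.clinical.rename(columns={"time_days": "time"}).copy()
        rng = np.random.default_rng(23)
        n = len(rec)
        pvals = []
        for _ in range(1000):
            rec["group"] = np.where(rng.permutation(n) < n // 2, "a", "b")
            pvals.append(logrank_test(rec).p)
        from scipy.stats import kstest

        assert kstest(pvals, "uniform").statistic < 0.05


class TestInstability:
    def test_half_genome_altered(self):
        p = profile_from_rows([("1", 1, 1000, 0.5), ("1", 2001, 3000, 0.0)])
        idx = instability_indices(p, arms=[])
        assert idx.genome_altered_fraction == pytest.approx(0.5)

    def test_flat_profile_zero(self):
        p = profile_from_rows([("1", 1, 10_000, 0.0)])
        idx = instability_indices(p, arms=[GenomicInterval("1", 1, 10_000)])
        assert idx.genome_altered_fraction == 0.0 and idx.aneuploidy_score == 0

    def test_matches_per_base_oracle(self, rng):
        prof = random_profile(rng, n_segments=20, hi=50_000)
        idx = instability_indices(prof, arms=[])
        seg = prof.segments
        total = altered = 0
        for _, s in seg.iterrows():
            length = s["end"] - s["start"] + 1
            total += length
            if abs(s["value"]) > 0.1:
                altered += length
        assert idx.genome_altered_fraction == pytest.approx(altered / total, abs=1e-12)

    def test_aneuploidy_counts_altered_arms(self):
        arms = [GenomicInterval("1", 1, 1000), GenomicInterval("1", 2001, 3000)]
        p = profile_from_rows([("1", 1, 1000, 0.3), ("1", 2001, 3000, 0.05)])
        idx = instability_indices(p, arms=arms)
        assert idx.aneuploidy_score == 1
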