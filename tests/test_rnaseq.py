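import math

import numpy as np
import pandas as pd
import pytest

from mesokit import rnaseq, simulate
from mesokit.rnaseq import (
    de_two_group,
    filter_genes,
    normalize_counts,
    remove_zero_genes,
    size_factors,
)


def median_of_ratios_oracle(counts):
    """Direct per-gene re-implementation of the size-factor definition."""
    vals = counts.to_numpy(dtype=float)
    keep = (vals > 0).all(axis=1)
    gm = np.exp(np.mean(np.log(vals[keep]), axis=1))
    return np.median(vals[keep] / gm[:, None], axis=0)


class TestSizeFactors:
    def test_doubled_library_ratio_exact(self):
        c = pd.DataFrame({"s1": [10, 20, 30], "s2": [20, 40, 60]}, index=list("abc"))
        sf = size_factors(c)
        assert sf["s2"] / sf["s1"] == pytest.approx(2.0, abs=1e-14)

    def test_single_sample_factor_one(self):
        c = pd.DataFrame({"s1": [5, 9, 2]}, index=list("abc"))
        assert size_factors(c)["s1"] == pytest.approx(1.0)

    def test_matches_brute_force_oracle(self, rng):
        c = pd.DataFrame(
            rng.integers(1, 500, size=(50, 4)), columns=[f"s{i}" for i in range(4)]
        )
        assert size_factors(c).to_numpy() == pytest.approx(
            median_of_ratios_oracle(c), abs=1e-12
        )

    def test_scale_equivariance(self, rng):
        # factors are defined up to a common constant: scaling one sample by c
        # scales its factor relative to every other sample by c
        c = pd.DataFrame(rng.integers(1, 500, size=(60, 3)), columns=list("xyz"))
        sf1 = size_factors(c)
        c2 = c.copy()
        c2["y"] *= 3
        sf2 = size_factors(c2)
        assert (sf2["y"] / sf2["x"]) / (sf1["y"] / sf1["x"]) == pytest.approx(3.0, rel=1e-9)

    def test_no_allpositive_gene_rejected(self):
        c = pd.DataFrame({"s1": [0, 3], "s2": [5, 0]}, index=["a", "b"])
        with pytest.raises(ValueError):
            size_factors(c)

    def test_recovers_planted_library_ratio(self):
        truth = simulate.make_count_truth(400, baseline_mean=200, seed=3)
        counts, _, _ = simulate.generate_counts(truth, 3, size_factors=(1.0, 2.0), seed=3)
        sf = size_factors(counts)
        ratio = sf[["B1", "B2", "B3"]].mean() / sf[["A1", "A2", "A3"]].mean()
        assert ratio == pytest.approx(2.0, rel=0.05)


class TestZeroRemoval:
    def test_planted_zero_genes_removed_exactly(self):
        truth = simulate.make_count_truth(200, fraction_zero=0.25, seed=1)
        counts, _, _ = simulate.generate_counts(truth, 3, seed=1)
        kept, n_removed = remove_zero_genes(counts)
        assert n_removed == 50
        assert len(kept) == 150


def filter_oracle(norm, lengths, min_length, density_cutoff, median_cutoff):
    """Plain-python re-derivation of the three filter sets."""
    short, low, below = set(), set(), set()
    for g in norm.index:
        mean = norm.loc[g].mean()
        if lengths[g] < min_length:
            short.add(g)
        if mean * 100.0 / lengths[g] < density_cutoff:
            low.add(g)
        if mean < median_cutoff:
            below.add(g)
    return short, low, below


class TestFilters:
    def _toy(self):
        # 8 genes engineered so each filter catches known, disjoint genes
        norm = pd.DataFrame(
            {
                "s1": [100, 100, 100, 100, 100, 100, 2, 3],
                "s2": [100, 100, 100, 100, 100, 100, 2, 3],
            },
            index=[f"g{i}" for i in range(8)],
        )
        lengths = pd.Series(
            [300, 400, 1000, 1000, 1000, 1000, 1000, 1000],
            index=norm.index,
        )
        return norm, lengths

    def test_toy_per_filter_counts(self):
        norm, lengths = self._toy()
        # median of means = 100; density 25th pct computed from the data
        kept, rep = filter_genes(norm, lengths)
        assert rep.n_short == 2  # g0, g1 under 500 bp
        assert rep.n_below_median == 2  # g6, g7 strictly below median 100
        short, low, below = filter_oracle(
            norm, lengths, 500, rep.cutoff_density, rep.cutoff_median
        )
        assert rep.n_low_density == len(low)
        assert rep.n_total_excluded == len(short | low | below)
        assert set(kept.index) == set(norm.index) - (short | low | below)

    def test_values_at_cutoffs_are_kept(self):
        # identical genes: quantile == median == every value; strict "<" keeps all
        norm = pd.DataFrame(np.full((10, 3), 50.0), index=[f"g{i}" for i in range(10)])
        lengths = pd.Series(1000, index=norm.index)
        kept, rep = filter_genes(norm, lengths)
        assert rep.n_low_density == 0 and rep.n_below_median == 0
        assert len(kept) == 10

    def test_union_matches_set_oracle_on_random_fixture(self, rng):
        norm = pd.DataFrame(
            rng.gamma(2.0, 50.0, size=(500, 4)), index=[f"g{i}" for i in range(500)]
        )
        lengths = pd.Series(rng.integers(100, 5000, size=500), index=norm.index)
        kept, rep = filter_genes(norm, lengths)
        short, low, below = filter_oracle(
            norm, lengths, 500, rep.cutoff_density, rep.cutoff_median
        )
        assert rep.n_short == len(short)
        assert rep.n_low_density == len(low)
        assert rep.n_below_median == len(below)
        assert rep.n_total_excluded == len(short | low | below)
        assert rep.n_total_excluded <= rep.n_short + rep.n_low_density + rep.n_below_median

    def test_idempotent_with_realized_cutoffs(self, rng):
        norm = pd.DataFrame(
            rng.gamma(2.0, 50.0, size=(300, 3)), index=[f"g{i}" for i in range(300)]
        )
        lengths = pd.Series(rng.integers(100, 5000, size=300), index=norm.index)
        kept, rep = filter_genes(norm, lengths)
        kept2, rep2 = filter_genes(
            kept,
            lengths,
            density_cutoff=rep.cutoff_density,
            median_cutoff=rep.cutoff_median,
        )
        assert rep2.n_total_excluded == 0
        assert kept2.index.equals(kept.index)

    def test_missing_length_rejected(self):
        norm = pd.DataFrame({"s1": [1.0, 2.0]}, index=["a", "b"])
        with pytest.raises(ValueError):
            filter_genes(norm, pd.Series({"a": 1000}))


class TestDifferentialExpression:
    def _planted(self, seed=5):
        truth = simulate.make_count_truth(
            300, n_de=40, fold_change=4.0, baseline_mean=150.0, seed=seed
        )
        counts, _, tdf = simulate.generate_counts(truth, 3, seed=seed)
        groups = pd.Series(["A"] * 3 + ["B"] * 3, index=counts.columns)
        return counts, groups, tdf

    def test_planted_fold_changes_recovered_with_direction(self):
        counts, groups, tdf = self._planted()
        de = de_two_group(counts, groups)
        planted = tdf.index[tdf["is_de"]]
        assert de.loc[planted, "significant"].mean() >= 0.9
        up = tdf.index[tdf["fold_change"] > 2]
        down = tdf.index[tdf["fold_change"] < 0.5]
        sig_up = de.loc[up][de.loc[up, "significant"]]
        sig_down = de.loc[down][de.loc[down, "significant"]]
        assert (sig_up["direction"] == "up").all()
        assert (sig_down["direction"] == "down").all()

    def test_up_down_partition(self):
        counts, groups, _ = self._planted(seed=8)
        de = de_two_group(counts, groups)
        n_sig = int(de["significant"].sum())
        assert n_sig == (de["direction"] == "up").sum() + (de["direction"] == "down").sum()

    def test_null_false_positive_rate(self):
        # >= 500 null genes: per-gene raw p calibrated at the 5% level
        truth = simulate.make_count_truth(600, n_de=0, baseline_mean=120.0, seed=9)
        counts, _, _ = simulate.generate_counts(truth, 3, seed=9)
        groups = pd.Series(["A"] * 3 + ["B"] * 3, index=counts.columns)
        de = de_two_group(counts, groups)
        se = math.sqrt(0.05 * 0.95 / len(de))
        assert (de["p"] <= 0.05).mean() <= 0.05 + 2 * se
        assert de["significant"].mean() <= 0.05 + 2 * se

    def test_fold_change_cutoff_is_conjunctive(self):
        # a strong but small shift (ratio < 2) must not be called DE
        rng = np.random.default_rng(0)
        base = rng.poisson(10_000, size=(1, 6)).astype(int)
        counts = pd.DataFrame(base, index=["g"], columns=list("abcdef"))
        counts.loc["g", ["d", "e", "f"]] = (counts.loc["g", ["d", "e", "f"]] * 1.5).astype(int)
        filler = pd.DataFrame(
            rng.poisson(100, size=(50, 6)), index=[f"f{i}" for i in range(50)], columns=list("abcdef")
        )
        all_counts = pd.concat([counts, filler])
        groups = pd.Series(["A"] * 3 + ["B"] * 3, index=all_counts.columns)
        de = de_two_group(all_counts, groups, factors=pd.Series(1.0, index=all_counts.columns))
        row = de.loc["g"]
        assert 1.0 < row["fc"] < 2.0
        assert not row["significant"]

    def test_zero_total_group_rejected(self):
        counts = pd.DataFrame({"a": [1, 2], "b": [0, 0]}, index=["g1", "g2"])
        with pytest.raises(ValueError):
            de_two_group(counts, pd.Series({"a": "A", "b": "B"}))


def test_normalized_counts_divide_by_factors():
    c = pd.DataFrame({"s1": [10, 20], "s2": [20, 40]}, index=["a", "b"])
    norm = normalize_counts(c)
    assert norm["s1"].to_numpy() == pytest.approx(norm["s2"].to_numpy())
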