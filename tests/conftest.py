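import numpy as np
import pandas as pd
import pytest

from mesokit import cna, simulate
from mesokit.intervals import GenomicInterval


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture(scope="session")
def small_cohort():
    """A 30-patient balanced synthetic cohort with planted truth (seed 1)."""
    return simulate.generate_cohort(
        {"OTHER": 10, "KRAS_ONLY": 10, "KRAS_TP53": 10}, seed=1
    )


def profile_from_rows(rows, sample="S1"):
    """Build a z-scale segment profile from (chrom, start, end, value) rows."""
    return cna.SegmentProfile(
        sample, pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])
    )


def random_profile(rng, chrom="12", n_segments=5, lo=1, hi=2_000_000):
    """Random non-overlapping segments on one chromosome."""
    cuts = np.sort(rng.choice(np.arange(lo, hi), size=2 * n_segments, replace=False))
    rows = []
    for i in range(n_segments):
        start, end = int(cuts[2 * i]), int(cuts[2 * i + 1])
        rows.append((chrom, start, end, float(rng.normal(0, 0.5))))
    return profile_from_rows(rows)


def per_base_mean(profile, interval: GenomicInterval):
    """Brute-force per-base average of segment values over an interval (oracle)."""
    total = 0.0
    covered = 0
    for _, seg in profile.segments.iterrows():
        if seg["chrom"] != interval.chrom:
            continue
        for pos in range(int(seg["start"]), int(seg["end"]) + 1):
            if interval.start <= pos <= interval.end:
                total += seg["value"]
                covered += 1
    return total / covered if covered else float("nan")
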