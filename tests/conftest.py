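import numpy as np
import pandas as pd
import pytest

import cnvbench as cb


def make_baits(n: int = 50, spacing: int = 200, length: int = 100,
               chroms: tuple[str, ...] = ("1", "2")) -> pd.DataFrame:
    """Small deterministic bait set spread over a toy genome."""
    rows = []
    per = n // len(chroms)
    k = 0
    for c in chroms:
        for i in range(per):
            s = i * spacing
            rows.append((c, s, s + length, f"b{k:04d}"))
            k += 1
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "bait_id"])


def random_intervals(rng, n, chrom_len=10_000, chroms=("1",), max_len=400):
    out = []
    for _ in range(n):
        c = chroms[rng.integers(len(chroms))]
        s = int(rng.integers(0, chrom_len - 1))
        e = s + int(rng.integers(1, max_len))
        out.append(cb.GenomicInterval(c, s, e))
    return out


@pytest.fixture(scope="session")
def small_bundle():
    """Small but fully structured synthetic study used across modules."""
    cfg = cb.SimConfig(
        n_samples=60, n_baits=3000, n_chroms=3, chrom_length=2_500_000,
        n_truth_samples=12, n_truth_del=8, n_truth_dup=10,
        truth_size_range=(20_000, 60_000),
        profiles={
            "hot": cb.CallerProfile(0.8, 1e-3, 40),
            "cold": cb.CallerProfile(0.5, 5e-4, 10),
        },
        seed=11,
    )
    return cb.simulate(cfg)


@pytest.fixture(scope="session")
def default_bundle():
    """The default study conditions: 180 samples, 20,000 baits, four callers."""
    return cb.simulate(cb.SimConfig(seed=1))


@pytest.fixture(scope="session")
def default_truth(default_bundle):
    kept, _ = cb.filter_array_cnvs(
        default_bundle.array_cnvs, cb.TruthFilterConfig(), default_bundle.baits
    )
    return cb.expand_to_truth_exons(kept, default_bundle.baits)
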