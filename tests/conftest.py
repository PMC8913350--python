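import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from cardiolipidomics import LipidSimConfig, generate_peak_table


def brute_force_signed_rank_p(diffs, convention="doubling"):
    """Literal 2^n enumeration oracle for the exact signed-rank p-value.

    Kept deliberately naive and independent of the package implementation:
    every sign vector is enumerated and its positive rank sum accumulated.
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        return float("nan")
    ranks = sps.rankdata(np.abs(d))
    w_obs = float(ranks[d > 0].sum())
    sums = np.array([
        sum(r for bit, r in zip(signs, ranks) if bit)
        for signs in itertools.product((0, 1), repeat=n)
    ])
    eps = 1e-9
    if convention == "doubling":
        lower = np.mean(sums <= w_obs + eps)
        upper = np.mean(sums >= w_obs - eps)
        return min(1.0, 2.0 * min(lower, upper))
    p_obs = np.mean(np.abs(sums - w_obs) <= eps)
    probs = np.array([np.mean(np.abs(sums - s) <= eps) for s in sums])
    return float(np.mean(probs <= p_obs + eps))


@pytest.fixture(scope="session")
def small_peak_table():
    """A modest simulated peak table shared by QC tests (deterministic)."""
    cfg = LipidSimConfig(classes=("AcCa", "PC", "TG"), species_per_class=6,
                         qc_fail_rate=0.15, seed=42)
    return generate_peak_table(cfg)


@pytest.fixture()
def tiny_triplicate():
    """One species, one adduct, triplicates in two genotypes."""
    rows = []
    for g, concs in (("WT", (2.0, 4.0, 6.0)), ("KO", (6.0, 12.0, 18.0))):
        for i, c in enumerate(concs, start=1):
            rows.append(("PC(00)", "PC", "+H", f"{g}{i}", g, i, c, 10.0, 0.95))
    return pd.DataFrame(rows, columns=["species_id", "class", "adduct", "sample_id",
                                       "genotype", "replicate", "concentration",
                                       "snr", "pq"])
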