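import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from epivariant.io import SampleSheet
from epivariant.simulate import SimulationConfig, Spike, simulate_cohort


@pytest.fixture
def small_sheet() -> SampleSheet:
    """4 cases + 8 controls."""
    samples = [f"S{i}" for i in range(1, 5)] + [f"C{i}" for i in range(1, 9)]
    return SampleSheet(
        pd.DataFrame({"sample_id": samples, "group": ["case"] * 4 + ["control"] * 8})
    )


@pytest.fixture
def spiked_bundle():
    """Small seeded cohort with one up and one down spike."""
    cfg = SimulationConfig(
        n_peaks=300,
        seed=11,
        spikes=[Spike(10, 0, "up", 4.0), Spike(200, 3, "down", 0.2)],
    )
    return simulate_cohort(cfg)


def brute_force_outlier_calls(matrix: pd.DataFrame, cases, controls,
                              mapq=None, up_fold=1.5, down_fold=0.5,
                              min_cov=5.0, p_max=0.01, low_cov=2.5,
                              mapq_excl=0.75):
    """Literal re-implementation of the selection clauses, loop by loop.

    Independent of the package's vectorized path: plain-Python means,
    n-1 standard deviations and erfc-based normal tails.
    """
    import math

    calls = set()
    values = {s: matrix[s].tolist() for s in matrix.columns}
    peak_ids = list(matrix.index)
    all_samples = list(matrix.columns)
    for i, pid in enumerate(peak_ids):
        if mapq is not None:
            frac = mapq.get(pid)
            if frac is not None and not (isinstance(frac, float) and math.isnan(frac)) \
                    and frac >= mapq_excl:
                continue
        cohort = [values[s][i] for s in all_samples]
        if sum(cohort) / len(cohort) < low_cov:
            continue
        ctrl = [values[c][i] for c in controls]
        mu = sum(ctrl) / len(ctrl)
        var = sum((x - mu) ** 2 for x in ctrl) / (len(ctrl) - 1)
        sd = math.sqrt(var)
        for s in cases:
            q = values[s][i]
            # upper and lower normal tails via erfc; point mass when sd == 0
            if sd > 0:
                z = (q - mu) / sd
                p_up = 0.5 * math.erfc(z / math.sqrt(2))
                p_dn = 0.5 * math.erfc(-z / math.sqrt(2))
            else:
                p_up = 0.0 if q > mu else 1.0
                p_dn = 0.0 if q < mu else 1.0
            if q >= min_cov and all(q >= up_fold * c for c in ctrl) and p_up < p_max:
                calls.add((pid, s, "up"))
            if all(c >= min_cov for c in ctrl) and all(q <= down_fold * c for c in ctrl) \
                    and p_dn < p_max:
                calls.add((pid, s, "down"))
    return calls
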