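"""Screen a cohort for globally divergent but mutually correlated case pairs.

Two cases that differ from everyone else yet resemble each other suggest
a distinct subgroup (different etiology, treatment effect, or a hidden
confounder) and are best analyzed separately from the remaining cases.
Here two case samples share a strong common signal component, dropping
their correlation with the rest of the cohort while staying mutually
similar; the screen flags exactly that pair.
"""

import numpy as np
import pandas as pd

from epivariant import flag_subgroups, sample_correlation

rng = np.random.default_rng(7)
n_peaks = 3000
baseline = rng.lognormal(3.0, 1.0, n_peaks)

samples = {}
for i in range(6):
    samples[f"S{i + 1}"] = baseline * rng.lognormal(0, 0.15, n_peaks)
for i in range(6):
    samples[f"C{i + 1}"] = baseline * rng.lognormal(0, 0.15, n_peaks)
# S1 and S2 share a systematic deviation from the cohort profile
shared = rng.lognormal(0, 0.45, n_peaks)
for s in ("S1", "S2"):
    samples[s] = samples[s] * shared

matrix = pd.DataFrame(samples)
pcc = sample_correlation(matrix)
pair = pcc.loc["S1", "S2"]
rest = pcc.loc["S1", [c for c in matrix.columns if c not in ("S1", "S2")]].mean()
print(f"PCC(S1, S2) = {pair:.2f}; mean PCC of S1 to the rest = {rest:.2f}")

groups = flag_subgroups(pcc, [f"S{i + 1}" for i in range(6)], delta=0.05)
print("flagged subgroups:", groups["flagged"])
print("main case group:", groups["main"][0])
# The flagged pair should then be run as its own case subset (see the
# case_subsets option of the pipeline config) against the full control panel.
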