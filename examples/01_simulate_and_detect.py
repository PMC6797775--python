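"""Simulate a case-control cohort with spiked-in alterations and call outliers.

Builds a 16-case / 16-control cohort of 2,000 peaks with 10 up-spiked and
10 down-spiked (peak, case) pairs, then runs the outlier caller at the
default thresholds (fold >= 1.5 up / <= 0.5 down vs every control,
coverage >= 5, normal-model p < 0.01) and compares the calls with the
ground truth.
"""

import numpy as np

from epivariant import detect_outliers, random_spikes, simulate_cohort, summarize_recurrence
from epivariant.simulate import SimulationConfig

cfg = SimulationConfig(n_peaks=2000, seed=42)
cfg.spikes = random_spikes(np.random.default_rng(43), cfg.n_peaks, cfg.n_cases,
                           n_up=10, n_down=10, up_fold=4.0, down_fold=0.2)
bundle = simulate_cohort(cfg)

result = detect_outliers(bundle.matrix, bundle.sample_sheet, bundle.mapq_summary)
found = {(c.peak_id, c.sample_id, c.direction) for c in result.calls}
truth = {(r.peak_id, r.sample_id, r.direction) for r in bundle.truth.itertuples()}

print(f"eligible peaks: {int(result.eligibility['eligible'].sum())} / {cfg.n_peaks}")
print(f"calls: {len(found)}  (true spikes: {len(truth)})")
print(f"recovered: {len(found & truth)}, spurious: {len(found - truth)}, "
      f"missed: {len(truth - found)}")

rec = summarize_recurrence(result.calls)
print(f"loci altered in a single case: {rec.singleton_fraction:.0%} "
      "of called (locus, direction) groups")
for call in result.calls[:3]:
    print(f"  e.g. {call.peak_id} {call.direction} in {call.sample_id}: "
          f"fold {call.extreme_fold:.2f} vs worst control, p = {call.nominal_p:.2e}")
# A recovered fraction near 1 with no spurious calls shows the every-control
# fold rule is sensitive to strong spikes yet conservative under 15% noise.
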