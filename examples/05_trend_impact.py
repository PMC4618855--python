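"""How inconsistent observations bias a long-term phenological trend.

Consistent onsets advance at -0.37 days/year; autumn second-bloom reports
(no trend of their own, more frequent in later years) contaminate 8% of the
records.  The example fits the trend with and without them and tests the
slope difference by ANCOVA.
"""

import numpy as np

from phenofence import compare_trends, decadal_rate, simulate_trend_contamination
from phenofence.data_model import Observation
from phenofence.outlier_flag import ConsistencyFlag

years, doys, is_out = simulate_trend_contamination(seed=3)
obs = [
    Observation(f"o{i}", int(y), int(np.clip(round(d), 1, 366)), 42.0, -79.0, 100.0)
    for i, (y, d) in enumerate(zip(years, doys))
]
flags = [
    ConsistencyFlag(f"o{i}", "inconsistent_late" if o else "consistent", 0, 0.0, 0.0)
    for i, o in enumerate(is_out)
]

full, clean, ancova = compare_trends(obs, flags)
print(f"full data : slope {full.slope:+.3f} d/yr  ({decadal_rate(full):+.1f} d/decade), n={full.n}")
print(f"clean data: slope {clean.slope:+.3f} d/yr  ({decadal_rate(clean):+.1f} d/decade), n={clean.n}")
print(
    f"ANCOVA slope difference {ancova.interaction_estimate:+.3f} d/yr, "
    f"p = {ancova.p_interaction:.2e}"
)
# Keeping the contaminated records attenuates the apparent advancement of
# flowering; removing them restores the planted -0.37 d/yr trend, and the
# ANCOVA interaction term confirms the two groups have different slopes.
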