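"""Build the 11-variable context matrix from daily climate series.

Each observation is described by where it was made (latitude, longitude,
elevation) and by the climate accumulated from 1 January to the reported
onset: cumulative max/min/average temperature, day length, precipitation,
solar radiation, snow water equivalent and vapor pressure.
"""

import numpy as np

from phenofence import (
    CONTEXT_COLUMNS,
    SimConfig,
    assemble_context_matrix,
    simulate_dataset,
    standardize,
)

ds = simulate_dataset(SimConfig(n_obs=60, n_clusters=2, seed=5))
X, names = assemble_context_matrix(ds.observations, ds.climate)
print(f"context matrix: {X.shape[0]} observations x {X.shape[1]} variables")
for name, mu, sd in zip(names, X.mean(axis=0), X.std(axis=0)):
    print(f"  {name:>10s}: mean {mu:12.1f}  sd {sd:10.1f}")

Z, means, sds, _ = standardize(X, names)
print("after z-scoring: column sds =", np.round(Z.std(axis=0, ddof=1), 6))
# Raw units span seven orders of magnitude (cumulative day length ~5e6 s vs
# latitude ~42 degrees); z-scoring puts all 11 variables on one scale so the
# Euclidean-distance-based embedding is not dominated by a single column.
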