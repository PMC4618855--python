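"""Embed contextual data to 2-D and cluster it with constrained mixtures.

t-SNE maps the 11-dimensional context to two dimensions; Gaussian mixtures
under the ten classical covariance families (EII ... VVV, the decomposition
Sigma_k = lambda_k D_k A_k D_k') are fitted by EM and compared by BIC.
"""

import numpy as np

from phenofence import SimConfig, assemble_context_matrix, model_select, simulate_dataset, standardize, tsne

ds = simulate_dataset(SimConfig(n_obs=240, n_clusters=3, seed=2))
X, names = assemble_context_matrix(ds.observations, ds.climate)
Z, *_ = standardize(X, names)

emb = tsne(Z, perplexity=25, seed=0)
print(f"t-SNE: KL divergence {emb.kl_initial:.3f} -> {emb.kl_final:.3f}")

sel = model_select(emb.Y, G_range=range(1, 7), seed=0, n_restarts=3)
print("\nBIC per family (best over G):")
print(sel.per_family_best[["family", "G", "bic"]].to_string(index=False))
best = sel.best
print(
    f"\nselected: {best.family.code} "
    f"({best.family.distribution}, {best.family.volume} volume, "
    f"{best.family.shape} shape, {best.family.orientation} orientation), "
    f"G={best.G}, BIC={best.bic:.1f}"
)
# Larger (less negative) BIC is better; the winner balances mixture fit
# against the number of covariance parameters its family needs.
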