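# Methods

## Onset derivation from status series

Status-monitoring records are "Yes"/"No" flowering reports per plant and
calendar year (runs never cross 1 January). An *onset* is the DOY of each
"Yes" that begins a maximal run of "Yes" reports. Its *uncertainty* is the
gap to the nearest preceding "No" at any distance (missing when the series
opens with "Yes"); the same rule applies to every run-initial "Yes", so a
second bloom's uncertainty is measured from the "No" that closed the first
bloom. A plant-year with both "Yes" and "No" on the same day is rejected
loudly rather than guessed at. A plant-year with two or more "Yes" runs is
flagged multiple-onset; by default each onset becomes an independent
observation carrying the flag (`one_per_plant_year=True` keeps only the
first), since either convention is defensible and downstream code treats the
flag as advisory.

## Context features

The 11 variables are latitude, longitude, elevation, and the sums of daily
tmax, tmin, tavg = (tmax+tmin)/2, day length, precipitation, solar radiation,
snow water equivalent and vapor pressure from 1 January to the reported
onset DOY. Sums are plain accumulation over doys 1..onset; a gap in the
daily series is a hard error (no imputation). Climate series are matched by
exact location key — gridding and interpolation are data preparation, out of
scope here. Units: °C·day for temperatures, s for day length, mm for
precipitation, W/m²·day for radiation, kg/m²·day for SWE, Pa·day for vapor
pressure.

Columns are z-scored (sample sd, ddof = 1) before embedding by default. Raw
scales differ by seven orders of magnitude (cumulative day length ~5×10⁶
vs latitude ~42), so a Euclidean embedding of raw values would see only one
or two columns. `standardize=False` gives the literal unscaled variant.
cum_tavg is an exact linear combination of cum_tmax and cum_tmin, so the
matrix has one dependent column; distance-based embedding is unaffected.

## Embedding

Exact (O(n²)) t-SNE to 2-D. Input affinities: per-point Gaussian
conditionals whose bandwidth is found by binary search so the conditional
perplexity 2^H matches the target within 1e-4 (≤ 64 iterations), then
symmetrized p_ij = (p_{j|i}+p_{i|j})/(2n). Squared distances are floored at
1e-12 so duplicate points cannot divide by zero. Output affinities use the
Student-t kernel with one degree of freedom normalized over off-diagonal
pairs. The loss is KL(P‖Q) over pairs with p_ij > 0.

Optimizer: 1000 iterations of gradient descent with momentum 0.5 switching
to 0.8 at iteration 250, early exaggeration ×4 for the first 100 iterations,
learning rate 200 with adaptive per-parameter gains, initialization
Y ~ N(0, 10⁻⁴) from the seed. These are the original-algorithm conventions;
runs are bit-reproducible per seed. `kl_initial` is evaluated with the
un-exaggerated P at the random start, `kl_final` after the exaggeration-free
phase ends; momentum steps are not individually monotone, but the final
divergence is below the initial one across seed sweeps (asserted in tests).

Perplexity selection sweeps 5–50 in steps of 5 and keeps the value whose
embedding lets the downstream mixture resolve the most components, ties
toward the smallest value. The published workflow's additional visual
criterion ("spreads and separates") is not reproducible and is excluded.

## Model-based clustering

Covariances are parameterized as Σ_k = λ_k D_k A_k D_kᵀ and constrained to
the ten standard families (EII, VII, EEI, VEI, EVI, VVI, EEE, EEV, VEV,
VVV). M-steps: closed forms for EII/VII/EEI/VVI/EEE/VVV; eigen-decomposition
of the component scatter matrices for EEV (common Λ = Σ_k Ω_k / n); EVI in
closed form (A_k ∝ diag W_k det-normalized, λ from the normalized traces —
a closed form exists here, so the generic λ/A alternation is unnecessary);
VEI and VEV by 20 fixed-point alternations between λ_k and the common shape
A (no joint closed form). Each alternation increases the M-step objective,
so EM remains monotone (generalized EM); log-likelihood paths are exposed
and asserted non-decreasing in tests.

Initialization: kmeans++ seeding with hard nearest-center assignment
converted to responsibilities; 5 independent restarts, best final
log-likelihood kept. (The R reference implementation initializes by
model-based hierarchical agglomeration; kmeans++ restarts are simpler and
reproducible by seed, and on the fixtures both reach the same optimum — the
test suite cross-checks all ten families against R mclust log-likelihoods
and degrees of freedom on a two-component fixture.) A component whose
weight falls below 1/n is a collapse; the fit restarts from a new seed, up
to 5 extra attempts. Covariance eigenvalues are floored at 1e-6. Convergence:
relative log-likelihood change < 1e-8, max 500 iterations.

Selection maximizes BIC = 2 log L − k log n over families × G (default G
1..50, configurable), ties broken toward fewer parameters, then canonical
family order. Both the full (family, G) BIC table and per-family maxima are
emitted. Clustering uncertainty is 1 − max posterior; points with
uncertainty strictly above 0.5 are "unresolved" and excluded from fence
construction and verdicts.

## Intra-cluster screening

Quartiles are Tukey hinges: medians of the lower/upper halves of the sorted
sample, the overall median included in both halves when n is odd — the
convention behind the classical boxplot, chosen because interpolated
quantiles change who is flagged at small n. Fences sit 1.5·IQR beyond the
hinges; DOYs below/above are inconsistent early/late. Clusters with fewer
than 5 retained members give unresolved verdicts (quartiles of < 5 points
are unstable). Only onset DOY is screened, not the context variables.
Inconsistency rates are reported against both denominators (all
observations, and resolved observations only).

## Impact analysis

OLS of onset DOY on calendar year (uncentered; the slope is invariant to
centering and `intercept_at(year)` rescales for readability), two-sided
t-test on the slope. The "full" fit uses all resolved observations, "clean"
the consistent subset. The ANCOVA DOY ~ year + group + year×group is fitted
on resolved observations with group = inconsistent; the interaction
coefficient equals the difference of the two within-group OLS slopes
(asserted against that algebraic oracle), and its p-value is the
slope-difference test. Slopes ×10 give days per decade. Fits go through
statsmodels.

## Synthetic data generator

The generator emulates the *structure* of a volunteered phenology dataset
with known truth; defaults are the package's study conditions:

- n_obs = 600 observations in n_clusters = 3 context groups, group centers
  ≥ 6 within-group sd apart (rejection-sampled in standardized space; a
  warning reports realized separation if the request is infeasible);
- within-group context drawn from a requested covariance family (default
  VEI) in the 10 free dimensions, cum_tavg derived;
- physical magnitudes (lat ~42°, cumulative day length ~5×10⁶ s, ...) follow
  the scales of North-American spring lilac records;
- onset DOY = cluster mean (spring dates 110–160) + trend slope × (year −
  1980) + N(0, 10 d); trend −0.37 d/yr over 1980–2013;
- 3% of records are planted inconsistencies: reported DOY shifted ±5 within-
  group sd (sign random), mirroring too-early frost-bloom reports and
  too-late autumn blooms;
- daily climate per site is a strictly positive seasonal sinusoid rescaled so
  its cumulative sum at the *reported* onset equals the planted context
  target, plus daily noise contributing ~5% of a within-group sd to the
  cumulative. Planted outliers therefore carry cluster-consistent context
  with a wrong date — the case the intra-cluster date screen must catch, and
  the one that keeps the context clustering well-posed.

What the generator does **not** emulate: spatial autocorrelation and real
topographic/climatic coupling (no DAYMET-like structure), observer behavior
beyond a fixed visit interval, leap days (years are 365 days), heavy-tailed
or skewed onset noise. Passing recovery tests therefore demonstrate the
statistical machinery, not robustness to real-data pathologies.

Covariance draws for family-recovery experiments are made *identifiable*:
variable volumes are log-spaced (ratio ≥ 2 across components), variable
shapes rotate their elongation axis across components with ratio bands ~2–9,
and non-axis orientations are kept away from the coordinate axes and from
each other. A nominally variable factor that lands near a constrained value
by chance would make the more parsimonious family the statistically correct
selection and the experiment ill-posed.

The contaminated-trend fixture plants a −0.37 d/yr consistent trend
(sd 10 d, n = 2000, 1980–2013) and autumn second-bloom records near DOY 250
with no trend of their own, contaminating 8% of records with probability
rising linearly over the study period (emulating the growth of
status-based reporting). An a-priori power calculation (interaction se
≈ 0.09 d/yr against a 0.37 d/yr slope difference, t ≈ 4) sizes the fixture
so the ANCOVA detects the slope difference reliably.

## Problem sizes in the test and acceptance runs

The end-to-end experiments run the pipeline at fixed perplexity 30 with G
∈ 1..6 and 3 EM restarts (the full 5–50 sweep with G up to 50 multiplies
runtime roughly tenfold and, because the sweep maximizes the resolved
cluster count, only increases fragmentation — see limitations). The Tukey
coverage check uses 10⁶ normal draws; EM/affinity oracles run on instances
of n ≤ 600; recovery experiments use 5–10 seeds.

## Known limitations

- **BIC over-segments t-SNE maps of large clusters.** t-SNE equalizes
  density, so a Gaussian context cluster of ~200 points embeds as a
  near-uniform disc, and BIC prefers two mixture components per disc (the
  split's likelihood gain grows ~linearly with per-cluster n while the BIC
  penalty grows logarithmically). This is method behavior, not an
  implementation artifact: sklearn's independent t-SNE followed by this EM,
  and this t-SNE followed by R mclust, over-segment identically. The
  sub-clusters are pure subsets of the true groups, so flag *sensitivity* is
  unaffected, but the adjusted Rand index against planted clusters drops to
  ~0.58 and fences from ~100-point sub-clusters are slightly noisier
  (median precision ~0.78 instead of ~0.83 at the default conditions).
  Below roughly 100 points per cluster the effect vanishes and the pipeline
  recovers planted cluster counts reliably (see the sweep-recovery test and
  example 04).
- A cluster whose true onset distribution is skewed will flag its long tail;
  no skewness-adjusted boxplot is implemented.
- The uncertainty filter threshold (0.5) and fence multiplier (1.5) are the
  published workflow's constants, not tuned values.
- Exact t-SNE is O(n²) time and memory; intended for up to a few thousand
  observations.
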