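# phenofence

Context-aware consistency screening for volunteered phenological
observations, and a toolkit for measuring what inconsistent records do to
long-term phenological trends.

## The problem

Volunteer networks collect flowering-onset dates (a record ID, year, onset
day-of-year, location, and — in status-monitoring programs — a dated series
of "Yes"/"No" reports per plant). These data power climate-change analyses,
but a few percent of records carry implausible dates: transcription errors,
autumn second blooms reported as first flowering, frost-interrupted early
blooms. Simple range checks cannot catch them, because what counts as "too
early" in Georgia is normal in Minnesota: plausibility depends on the
*context* of the observation.

`phenofence` screens each record against other records made under similar
geographic and climatic conditions:

1. **Context features.** Each observation is described by 11 variables — 
   latitude, longitude, elevation, and 8 climatic parameters accumulated from
   1 January to the reported onset DOY (cumulative tmax, tmin, tavg =
   (tmax+tmin)/2, day length, precipitation, solar radiation, snow water
   equivalent, vapor pressure). Columns are z-scored by default.
2. **Embedding.** Exact t-SNE maps the context to 2-D. Per-point Gaussian
   bandwidths are calibrated by binary search to a target perplexity, and the
   map minimizes KL(P‖Q) against a Student-t (1 df) kernel. A perplexity
   sweep (5–50 in steps of 5) can select the value that lets the clustering
   resolve the most groups.
3. **Model-based clustering.** Gaussian mixtures are fitted by EM under the
   ten classical covariance families obtained from the decomposition
   Σ_k = λ_k D_k A_k D_kᵀ (volume λ, shape A with det A = 1, orientation D;
   codes EII, VII, EEI, VEI, EVI, VVI, EEE, EEV, VEV, VVV), and the model
   maximizing BIC = 2 log L − k log n is selected over families × component
   counts. Points whose clustering uncertainty 1 − max posterior exceeds 0.5
   are set aside as unresolved.
4. **Intra-cluster screening.** Within each cluster, onset DOYs beyond the
   Tukey fences [Q1 − 1.5·IQR, Q3 + 1.5·IQR] (quartiles as Tukey hinges) are
   flagged `inconsistent_early` / `inconsistent_late`; under normality about
   0.7% of consistent data lands outside the fences.
5. **Impact analysis.** OLS trends of onset DOY on year with and without the
   flagged records, plus an ANCOVA (DOY ~ year × consistency) whose
   interaction term tests the slope difference.

A synthetic-data module generates observation tables, daily climate series
and ground truth (planted clusters, planted wrong dates, planted trend) so
every stage can be validated end to end.

## Worked example

```bash
python examples/04_flag_inconsistencies.py
```

```
clustering: EEE, G=3
flags: 281 consistent, 19 inconsistent, 0 unresolved (6.3% inconsistency among resolved)
against planted truth: sensitivity 0.90, precision 1.00, cluster ARI 1.00
```

300 synthetic observations in 3 context clusters, 5% of them with onset dates
shifted five standard deviations, are screened by the full workflow: the
mixture recovers the 3 planted clusters exactly (ARI 1.00), and the Tukey
screen catches 90% of the planted wrong dates with no false alarms.

The other examples cover onset derivation from status series
(`01_onsets_from_status.py`), context-feature construction (`02`), embedding
and BIC family selection (`03`), and trend bias from contaminated records
(`05`), which prints:

```
full data : slope +0.058 d/yr  (+0.6 d/decade), n=2000
clean data: slope -0.368 d/yr  (-3.7 d/decade), n=1806
ANCOVA slope difference +0.388 d/yr, p = 1.10e-06
```

— keeping the autumn second-bloom records not only attenuates but reverses
the apparent trend; cleaning restores the planted −0.37 d/yr.

There is also a CLI mirroring the library
(`phenofence simulate|features|embed|cluster|run-all|score|impact`); run
`phenofence --help`.

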