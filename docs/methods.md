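# Methods

## Problem setting

An admission is represented by six vital signs — systolic and
diastolic blood pressure (mmHg), heart rate (bpm), respiratory rate
(breaths/min), peripheral oxygen saturation (%), and temperature (°C)
— observed irregularly over the first H hours of hospitalization
(H = 6 by default, 12 in sensitivity mode). The goal is an
unsupervised partition of encounters into a small number of
physiologic signatures ("physiotypes"), a portable model that assigns
new encounters to those signatures, and a characterization of how the
signatures relate to acuity scores and survival.

## Preprocessing

Raw measurements pass a per-vital plausibility filter (defaults:
HR 20–300 bpm, RR 4–80 /min, SBP 30–300 mmHg, DBP 10–200 mmHg,
SpO2 50–100 %, Temp 30–43 °C; all config-overridable — these encode
"device or transcription artifact", not clinical extremes). An
encounter is excluded when at least two of the six vitals have no
in-window measurement at all; a single fully-missing vital (most often
temperature) is retained and imputed.

Each surviving series is resampled to hourly bins over half-open
intervals [60h, 60(h+1)) minutes, averaging multiple in-bin readings.
Empty bins are forward-filled, then backward-filled (so only a leading
gap is backward-filled); vitals with no in-window observation receive
the training cohort's per-(vital, hour) median trajectory. The
per-hour median (rather than a single per-vital constant) preserves
trajectory shape for fully-missing records. Imputation never alters
the observed-mask; each cell carries a provenance tag
(observed/forward/backward/median).

Features are the H hourly values of each included vital, ordered
vital-major (36 features by default), z-scored with training-cohort
means and SDs. Standardization matters: on raw scales Euclidean
distance would be dominated by the mmHg-magnitude pressures, leaving
temperature and SpO2 voiceless. Validation/test cohorts always reuse
the training standardization and medians; nothing is refit, so the
centroid geometry transfers (the chronological
train/validation/test split follows the develop-early, validate-later
design, ties on admission date broken by encounter id).

## Consensus k-means and model selection

For each k in 2..8, `n_resamples = 100` subsamples of
`subsample_fraction = 0.8` of the cohort (drawn without replacement;
resample r uses seed `base_seed + r`, making every resample
individually replayable) are partitioned by k-means (k-means++
seeding, best of R restarts by within-cluster sum of squares; R = 3
within resamples, 10 for the final full-data partition). The consensus
matrix entry M_k(i, j) is the fraction of resamples containing both i
and j in which they were co-clustered; pairs never co-sampled (a
vanishing event at these settings) score 0 with a warning.

Stability is summarized by the area A(k) under the empirical CDF of
the upper-triangular consensus entries, computed exactly as the sum of
step-height × step-width terms. The delta-area statistic is
Δ(k) = (A(k) − A(k−1))/A(k−1) for k above the smallest candidate
(which keeps its absolute area). The selected k is the **largest k
with Δ(k) strictly above 0.10**; if none qualifies the smallest k is
kept (parsimony; a boundary tie also keeps the smaller k). The
resampling parameters are the consensus method's conventional
defaults and are config-exposed; the 0.10 threshold formalizes the
usual visual "little change beyond this k" judgment.

The final labels come from full-data k-means at the selected k (not
from re-partitioning M itself): the method is consensus *k-means* and
the downstream prediction artifact is a centroid model, which
presumes a k-means partition. Per-cluster stability is reported as the
mean within-cluster pairwise consensus (singletons report 1 with a
warning).

## Physiotype labels and prediction

Cluster centroids (means of member feature vectors, standardized
scale) are ordered by the mean of their de-standardized SBP features
across hours, ascending, and named A, B, C, D. New encounters are
standardized with the stored training statistics and assigned to the
nearest centroid by Euclidean distance; ties break toward the earlier
letter. The model serializes to flat JSON (centroids, feature names,
standardization) so prediction needs no training data.

## Gaussian-mixture validation

A k-component Gaussian mixture with **diagonal** covariances is fitted
by EM (10 random initializations, best log-likelihood kept; variance
floor 1e-6 of each feature's variance; convergence at relative
log-likelihood change < 1e-7). Diagonal covariances are the default
because with 36 features and modest cohort sizes per cluster, full
36 × 36 covariance estimation is unstable (BIC on full-covariance fits
at n = 600 collapses to k = 2 purely through the ~700-parameter-per-
component penalty). The per-iteration log-likelihood trace is retained
and is non-decreasing by construction of EM; fits in which a component
collapses onto fewer than two effective members or onto the variance
floor are flagged degenerate and lose the best-of-n selection to any
proper fit — such collapses are likelihood spikes, not mixture fits.

Mixture adequacy is judged by (i) the adjusted Rand index between the
mixture's hard assignment and the consensus partition and (ii) the
posterior membership probabilities of members (median, per-cluster
median, and the fraction in the marginal 0.45–0.55 band). BIC
(−2 logL + p ln N, p = (k−1) + 2kF) is reported per k; note that BIC
component-count selection is only trustworthy when the mixture is
correctly specified — the generator's AR(1) within-encounter
correlation (and the SpO2 ceiling mass at 100 %) make diagonal
components misspecified, in which case BIC predictably over-selects by
one component or so. The component-count recovery test therefore runs
on directly simulated diagonal-Gaussian data, while adequacy on
realistic cohorts is assessed through posteriors and ARI.

## Acuity scores

SOFA sums six organ subscores (0–4 each): respiratory (PaO2/FiO2),
coagulation (platelets), liver (bilirubin), cardiovascular
(MAP/vasopressors), neurologic (GCS), renal (creatinine; the
urine-output criterion is omitted — urine output is outside the data
model). MEWS scores SBP, HR, RR, temperature and AVPU consciousness.
Both lookup tables are shipped as a YAML data file so institutional
variants can be swapped without code changes. Inputs are worst-in-
window values (worst = maximum awarded points). Missing components
score 0 ("normal") and are tagged — the only policy that never
inflates acuity. A binary vasopressor flag scores the lowest
vasopressor tier (2); dose tiers are supported in the table file.
Threshold flags follow the conventional high-acuity cutoffs:
SOFA > 6 and MEWS ≥ 5.

## Outcomes

Kaplan–Meier curves, log-rank tests and Cox proportional-hazards
models (Efron ties, Wald 95 % CIs) are delegated to lifelines behind
this module's interfaces. The physiotype enters Cox models as three
indicators with physiotype C (the minimally deranged group) as
reference; adjustment covariates (age ≥ 65, sex, comorbidity flags or
index, SOFA band 0–1 / 2–4 / ≥ 5) pass through. Median follow-up uses
the reverse-KM method (censoring indicator inverted); its median is
the first time the curve falls strictly below 0.5 — when the curve
sits exactly at 0.5 over an interval, the right endpoint is reported.
Group comparisons use the chi-square test (no continuity correction),
one-way ANOVA, or Kruskal–Wallis as appropriate; Bonferroni adjustment
is p_adj = min(1, m·p) with family size m = 3 for the
versus-reference physiotype comparisons.

## Synthetic cohort generator

The generator defines the study conditions for every test. Four
templates give per-vital hourly mean trajectories interpolated between
window-start and window-end values:

| | SBP | HR | RR | SpO2 | Temp | picture |
|---|---|---|---|---|---|---|
| A | 96→88 | 78 | 13 | 98 | 36.8→36.1 | persistent hypotension, no HR rise, cooling |
| B | 106→100 | 110→116 | 24→27 | 91→90 | 37.8→38.3 | tachycardia, tachypnea, hypoxemia, fever |
| C | 126→124 | 82→80 | 16 | 97 | 37.0 | minimal derangement |
| D | 186→172 | 86→84 | 18 | 96 | 36.9 | severe hypertension |

A separation multiplier scales each template's deviation from a shared
reference trajectory (0 = no signal, 1 = default). Mixing proportions
default to (0.31, 0.23, 0.31, 0.15) in label order.

Within an encounter, each vital's latent hourly values follow an AR(1)
process around the template means (lag-1 coefficient 0.6, stationary
SDs: SBP 12, DBP 8, HR 9, RR 3, SpO2 1.8, Temp 0.45) — correlated
noise makes forward-fill imputation realistic. The number of raw
measurements per vital-hour is Poisson(1.5) with uniform offsets;
each reading adds white jitter (20 % of the vital's SD). Hours are
dropped per vital with probability 0.10 (temperature: 0.45, the
high-missingness vital). With probability 0.01 a reading is replaced
by an implausible out-of-range value to exercise range filtering.
SpO2 readings saturate at the 100 % ceiling (a censored normal), as
oxygen saturation is a percentage; its expected sample mean therefore
sits slightly below the latent template mean.

Survival is exponential with rate −ln(1 − p3y)/1095 per day, so the
cumulative event probability at three years equals the template's
three-year mortality parameter (0.17, 0.25, 0.16, 0.20 for A–D);
administrative censoring at 1570 days (~4.3 years). Comorbidity flags,
vasopressor use and SOFA inputs are drawn with phenotype-linked
prevalences (B skews toward respiratory/renal dysfunction, A toward
vasopressor use, D toward chronic kidney disease).

**What the generator does not emulate:** real EHR vitals have
documentation artifacts correlated with care intensity, informative
(not random) missingness, non-exponential hazards, inter-vital
correlation beyond what the mean trajectories induce, and label noise
with no ground truth. Passing recovery tests therefore demonstrates
the pipeline's correctness and its behavior under controlled signal
and noise — not that four clusters exist in any particular hospital's
data.

## Numerical choices and problem sizes

- k-means and consensus runs are deterministic under the seed ladder;
  all randomness flows from `numpy.random.default_rng` seeds.
- Feature standardization uses population SDs (ddof = 0); a
  zero-variance feature in fitting mode raises (degenerate input).
- EM variance floor 1e-6 × feature variance; BIC parameter count
  (k−1) + 2kF.
- Reference analyses run at n = 600 encounters (recovery checks at
  n = 400–2000, survival calibration at 10⁴ draws, log-rank
  calibration at 1000 replicates of n = 100) — sizes at which the
  Monte-Carlo error of every asserted quantity is far below its
  tolerance.

## Known limitations

- Consensus final labels come from full-data k-means; hierarchically
  partitioning the consensus matrix itself is a reasonable alternative
  not currently exposed.
- SOFA cardiovascular scoring with a binary vasopressor flag caps that
  subscore at 2 unless dose tiers are supplied.
- The SOM mosaic layout is an interpretation (occupancy-weighted
  codebooks on a square grid); quantization error plateaus above zero
  because the neighborhood radius is floored at 0.5.
- No competing risks, time-varying covariates, or formal
  proportional-hazards diagnostics.
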