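# physiotype

Unsupervised discovery of **acute-illness physiotypes** from vital signs
measured in the first hours of hospital admission.

Early in an admission, clinicians triage with little more than bedside
physiology. Clustering those early vital-sign trajectories reveals a
small number of physiologic signatures — *physiotypes* — that carry
prognostic information beyond conventional acuity scores. This package
implements that analysis as a reusable pipeline for biostatisticians
and clinical-informatics researchers working with EHR vital-sign data:

1. **Preprocessing** — irregular raw measurements of six vitals (SBP,
   DBP, HR, RR, SpO2, temperature) are range-filtered, encounters
   completely missing ≥ 2 vitals are excluded, the rest are resampled
   to hourly bins (in-bin means), imputed by forward/backward fill with
   a training-median fallback, and z-scored into an N × 36 feature
   matrix (6 vitals × 6 hours).
2. **Consensus k-means** — for each k in 2..8, the cohort is repeatedly
   subsampled (100 × 80 %) and partitioned; the consensus matrix entry
   M_k(i,j) is the fraction of co-sampled resamples in which i and j
   were co-clustered. The number of clusters is selected from the
   relative change Δ(k) of the area under the CDF of consensus entries
   ("delta area"); k = 4 on cohorts with four latent signatures.
3. **Labeling and prediction** — clusters are named A–D by ascending
   systolic blood pressure; the portable model (centroids + training
   standardization) assigns new encounters by minimum Euclidean
   distance, so later cohorts are scored without refitting.
4. **Validation and characterization** — a diagonal-covariance Gaussian
   mixture replicates the partition (adjusted Rand index, posterior
   membership probabilities); pairwise standardized mean differences,
   self-organizing-map mosaics and a t-SNE embedding describe the
   phenotypes.
5. **Acuity and outcomes** — SOFA and MEWS scores with the standard
   threshold flags (SOFA > 6, MEWS ≥ 5); Kaplan–Meier curves, log-rank
   tests, reverse-KM follow-up, and Cox proportional-hazards models
   with physiotype C as the reference level and Bonferroni-adjusted
   comparisons.

Because real single-center EHR cohorts cannot be redistributed, the
package ships a **synthetic cohort generator** whose four templates
reproduce the published signatures — A: persistent hypotension without
tachycardia; B: tachycardia, tachypnea and hypoxemia with fever; C:
minimal derangement; D: severe hypertension — together with irregular
sampling, per-vital missingness (temperature highest), AR(1)
measurement noise, implausible outliers, phenotype-linked acuity
inputs, and exponential survival calibrated to per-phenotype
three-year mortality (17 %, 25 %, 16 %, 20 %).

## Worked example

```python
import numpy as np
import physiotype as pt
from physiotype.io import RunConfig
from physiotype.gmm import fit_gmm, membership_quality, compare_partitions

templates = pt.make_default_templates(hours=6, separation=1.0)
cohort = pt.generate_cohort(templates, n=600, seed=1)
series = pt.cohort_to_series(cohort)

cfg = RunConfig(seed=1)
res = pt.preprocess_cohort(series, cfg)          # 600 x 36 features
der = pt.derive_physiotypes(res.features, cfg)   # consensus k-means
print(der.consensus.summary().round(3).to_string(index=False))
```

prints the model-selection table

```
 k  cdf_area  delta_area  selected
 2     0.368       0.368     False
 3     0.557       0.512     False
 4     0.731       0.313      True
 5     0.777       0.063     False
 6     0.815       0.049     False
 7     0.846       0.038     False
 8     0.865       0.021     False
```

— the area under the consensus CDF keeps growing substantially up to
k = 4 (Δ = 0.313) and levels off beyond it (Δ ≤ 0.063), so four
clusters are selected. Continuing,

```python
truth = {e.encounter_id: e.true_label for e in cohort}
tl = np.array([truth[i] for i in res.features.encounter_ids])
print("ARI vs generator truth:", round(compare_partitions(tl, der.letters)[0], 3))
fit = fit_gmm(res.features.X, 4, seed=1)
print("GMM median member posterior:",
      round(membership_quality(fit)["median_posterior"], 3))
```

```
ARI vs generator truth: 0.99
GMM median member posterior: 1.0
```

The consensus partition recovers the latent phenotypes almost exactly
(ARI 0.99), and the Gaussian-mixture cross-check assigns members to
their components with essentially certain posteriors. The fitted
centroid model, de-standardized back to physical units, shows the four
signatures (first/last-hour values; mmHg, bpm, %, °C):

```
physiotype  SBP_h0  SBP_h5  HR_h0  SpO2_h0  Temp_h0
         A    94.6    88.2   78.3     97.6     36.7
         B   105.2   100.0  110.9     90.8     37.9
         C   124.5   123.3   82.1     97.0     37.0
         D   183.6   171.4   84.5     96.0     36.9
```

The same pipeline is available from the shell:

```bash
physiotype simulate   --n 600 --seed 1 --out-dir run/
physiotype preprocess --vitals run/vitals.csv --out-dir run/
physiotype cluster    --features run/features.csv --seed 1 --out-dir run/
physiotype predict    --model run/model.json --vitals new_vitals.csv \
                      --medians run/standardization.json --out run/pred.csv
physiotype score      --encounters run/encounters.csv --out run/acuity.csv
physiotype survive    --encounters run/encounters.csv --labels run/labels.csv --out-dir run/
physiotype report     --features run/features.csv --labels run/labels.csv --out-dir run/
```

Sensitivity analyses (dropping temperature; dropping temperature, DBP
and RR; a 12-hour window) are pure configuration: set
`included_vitals` / `window_hours` in a YAML config passed via
`--config`.

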