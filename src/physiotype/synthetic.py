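"""Synthetic EHR cohort generator with four latent physiotypes.

Real early-admission vital-sign data are irregular, noisy, partially
missing, and (in the cohorts that motivate this package) organized into
four physiologic signatures labeled A-D by ascending systolic blood
pressure:

* **A** — early, persistent hypotension without a compensatory rise in
  heart rate, low respiratory rate, high SpO2, falling temperature
  (the non-inflammatory, post-surgical vasoplegia picture);
* **B** — moderate hypotension with tachycardia, tachypnea, hypoxemia
  and low-grade fever (the inflammatory/septic picture);
* **C** — normotensive with minimal derangement;
* **D** — severely elevated blood pressure (SBP > 160 mmHg throughout)
  with otherwise near-normal physiology (chronic disease exacerbation).

The generator emits encounters whose measurements follow each
template's hourly mean trajectory with AR(1) within-encounter noise,
per-vital dropout (temperature the most often missing), sparse
measurement raster (Poisson counts per hour), occasional implausible
outliers, phenotype-linked comorbidity and acuity-score inputs, and
exponential survival times calibrated to per-phenotype three-year
mortality.  Every downstream stage of the pipeline is testable against
the recorded ``true_label``.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .io import DEFAULT_BOUNDS, VITALS

LABELS = ("A", "B", "C", "D")

#: Default mixing proportions of the four phenotypes (A, B, C, D).
DEFAULT_MIXING = (0.31, 0.23, 0.31, 0.15)

#: Three-year mortality probabilities per phenotype, in label order.
DEFAULT_P3Y = (0.17, 0.25, 0.16, 0.20)
#: Thirty-day mortality probabilities per phenotype, in label order.
DEFAULT_P30 = (0.03, 0.07, 0.03, 0.03)

THREE_YEARS_DAYS = 1095.0
#: Administrative censoring horizon (~4.3 years of follow-up).
DEFAULT_HORIZON_DAYS = 1570.0

#: Within-encounter measurement SD per vital (stationary SD of the
#: AR(1) deviation process).
DEFAULT_NOISE_SD = {
    "SBP": 12.0,
    "DBP": 8.0,
    "HR": 9.0,
    "RR": 3.0,
    "SpO2": 1.8,
    "Temp": 0.45,
}

#: Per-hour probability that a vital goes unmeasured; temperature is
#: the high-missingness vital.
DEFAULT_MISSING_PROB = {
    "SBP": 0.10,
    "DBP": 0.10,
    "HR": 0.10,
    "RR": 0.10,
    "SpO2": 0.10,
    "Temp": 0.45,
}

# (start, end) of each vital's mean trajectory over the window; the
# hourly means interpolate linearly between them.  The reference row is
# the no-signal trajectory shared by all phenotypes when the separation
# multiplier is zero.
_REFERENCE = {
    "SBP": (125.0, 125.0),
    "DBP": (72.0, 72.0),
    "HR": (80.0, 80.0),
    "RR": (16.0, 16.0),
    "SpO2": (97.0, 97.0),
    "Temp": (37.0, 37.0),
}

_TEMPLATE_SHAPES = {
    "A": {
        "SBP": (96.0, 88.0),
        "DBP": (56.0, 52.0),
        "HR": (78.0, 78.0),
        "RR": (13.0, 13.0),
        "SpO2": (98.0, 98.0),
        "Temp": (36.8, 36.1),
    },
    "B": {
        "SBP": (106.0, 100.0),
        "DBP": (62.0, 58.0),
        "HR": (110.0, 116.0),
        "RR": (24.0, 27.0),
        "SpO2": (91.0, 90.0),
        "Temp": (37.8, 38.3),
    },
    "C": {
        "SBP": (126.0, 124.0),
        "DBP": (73.0, 71.0),
        "HR": (82.0, 80.0),
        "RR": (16.0, 16.0),
        "SpO2": (97.0, 97.0),
        "Temp": (37.0, 37.0),
    },
    "D": {
        "SBP": (186.0, 172.0),
        "DBP": (102.0, 96.0),
        "HR": (86.0, 84.0),
        "RR": (18.0, 18.0),
        "SpO2": (96.0, 96.0),
        "Temp": (36.9, 36.9),
    },
}

# Comorbidity prevalences per phenotype (hypertension, cardiovascular
# disease, diabetes, chronic kidney disease), in label order A-D.
_COMORBIDITY_PREV = {
    "hypertension": (0.51, 0.51, 0.52, 0.56),
    "cardiovascular": (0.27, 0.29, 0.29, 0.32),
    "diabetes": (0.23, 0.25, 0.24, 0.27),
    "ckd": (0.14, 0.15, 0.16, 0.20),
}

# Vasopressor-use probability per phenotype (A highest, D lowest).
_VASOPRESSOR_PROB = (0.32, 0.10, 0.16, 0.06)


@dataclasses.dataclass
class PhenotypeTemplate:
    """One latent phenotype's generative parameters."""

    label: str
    hourly_means: dict[str, np.ndarray]  # vital -> length-H array
    noise_sd: dict[str, float]
    ar_coef: float
    missing_prob: dict[str, float]
    p30: float
    p3y: float

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}")
        if not 0 <= self.ar_coef < 1:
            raise ValueError("ar_coef must be in [0, 1)")
        for v, p in self.missing_prob.items():
            if not 0 <= p <= 1:
                raise ValueError(f"missing_prob[{v}] outside [0, 1]")


@dataclasses.dataclass
class SyntheticEncounter:
    """One generated admission: measurements plus downstream inputs."""

    encounter_id: str
    true_label: str
    measurements: list[tuple[str, float, float]]  # (vital, offset_min, value)
    age: float
    sex: str
    comorbidities: dict[str, int]
    sofa_inputs: dict[str, float]
    avpu: str
    admission_date: str
    time_days: float
    event: int


def make_default_templates(
    hours: int = 6,
    separation: float = 1.0,
    ar_coef: float = 0.6,
) -> list[PhenotypeTemplate]:
    """Build the four default phenotype templates.

    ``separation`` scales each template's deviation from the shared
    reference trajectory: 0 collapses all four phenotypes onto one mean
    (no-signal mode), 1 is the default signal strength, larger values
    exaggerate it.  Mortality parameters are fixed per phenotype.
    """
    if separation < 0:
        raise ValueError("separation must be non-negative")
    if hours < 1:
        raise ValueError("hours must be >= 1")
    t = np.linspace(0.0, 1.0, hours)
    templates = []
    for i, label in enumerate(LABELS):
        means = {}
        for vital in VITALS:
            r0, r1 = _REFERENCE[vital]
            s0, s1 = _TEMPLATE_SHAPES[label][vital]
            ref = r0 + (r1 - r0) * t
            shape = s0 + (s1 - s0) * t
            means[vital] = ref + separation * (shape - ref)
        templates.append(
            PhenotypeTemplate(
                label=label,
                hourly_means=means,
                noise_sd=dict(DEFAULT_NOISE_SD),
                ar_coef=ar_coef,
                missing_prob=dict(DEFAULT_MISSING_PROB),
                p30=DEFAULT_P30[i],
                p3y=DEFAULT_P3Y[i],
            )
        )
    return templates


def sample_survival(
    template: PhenotypeTemplate,
    horizon_days: float = DEFAULT_HORIZON_DAYS,
    seed: int | None = None,
    size: int = 1,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Exponential death times calibrated to the template's 3-year mortality.

    The event rate is ``-ln(1 - p3y) / 1095`` per day, so the cumulative
    event probability at day 1095 equals ``p3y`` exactly; times beyond
    ``horizon_days`` are administratively censored.
    """
    if horizon_days < 1:
        raise ValueError("horizon_days must be >= 1 day")
    if rng is None:
        rng = np.random.default_rng(seed)
    p3y = template.p3y
    if p3y == 0:
        return np.full(size, float(horizon_days)), np.zeros(size, dtype=int)
    if not 0 < p3y < 1:
        raise ValueError("p3y must be in [0, 1) for event sampling")
    rate = -np.log1p(-p3y) / THREE_YEARS_DAYS
    raw = rng.exponential(1.0 / rate, size=size)
    event = (raw <= horizon_days).astype(int)
    time = np.minimum(raw, horizon_days)
    return time, event


def _outlier_value(vital: str, rng: np.random.Generator) -> float:
    """A value guaranteed to fall outside the plausibility bounds."""
    low, high = DEFAULT_BOUNDS[vital]
    span = high - low
    margin = 0.05 * span
    if rng.random() < 0.5:
        return float(high + margin + rng.random() * 0.5 * span)
    return float(low - margin - rng.random() * 0.5 * span)


def generate_cohort(
    templates: Sequence[PhenotypeTemplate],
    n: int,
    mixing: Sequence[float] = DEFAULT_MIXING,
    seed: int = 0,
    measurements_per_hour: float = 1.5,
    outlier_prob: float = 0.01,
    horizon_days: float = DEFAULT_HORIZON_DAYS,
) -> list[SyntheticEncounter]:
    """Draw ``n`` encounters from the template mixture.

    Each encounter's latent hourly values follow its template's AR(1)
    process around the hourly means (stationary SD = ``noise_sd``); the
    number of raw measurements in each hour is Poisson-distributed with
    mean ``measurements_per_hour``, offsets uniform within the hour,
    each measurement adding a small white observation jitter.  Hours
    are additionally dropped with the template's per-vital missingness
    probability, and with probability ``outlier_prob`` a measurement is
    replaced by an implausible out-of-range value to exercise range
    filtering.  Fully reproducible under ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    mixing = np.asarray(mixing, dtype=float)
    if len(mixing) != len(templates):
        raise ValueError("mixing length must match number of templates")
    if abs(mixing.sum() - 1.0) > 1e-9:
        raise ValueError(f"mixing must sum to 1, got {mixing.sum()!r}")

    rng = np.random.default_rng(seed)
    H = len(templates[0].hourly_means[VITALS[0]])
    label_idx = rng.choice(len(templates), size=n, p=mixing)

    encounters: list[SyntheticEncounter] = []
    width = len(str(n))
    base_date = pd.Timestamp("2020-01-01")
    for e in range(n):
        tpl = templates[label_idx[e]]
        i = LABELS.index(tpl.label)
        measurements: list[tuple[str, float, float]] = []
        first_hour_vals: dict[str, float] = {}
        for vital in VITALS:
            sd = tpl.noise_sd[vital]
            ar = tpl.ar_coef
            innov_sd = sd * np.sqrt(1.0 - ar**2)
            dev = np.empty(H)
            dev[0] = rng.normal(0.0, sd)
            for h in range(1, H):
                dev[h] = ar * dev[h - 1] + rng.normal(0.0, innov_sd)
            latent = tpl.hourly_means[vital] + dev
            first_hour_vals[vital] = float(latent[0])
            observed_hours = rng.random(H) >= tpl.missing_prob[vital]
            counts = rng.poisson(measurements_per_hour, size=H)
            jitter_sd = 0.2 * sd
            for h in range(H):
                if not observed_hours[h] or counts[h] == 0:
                    continue
                offsets = np.sort(rng.uniform(60.0 * h, 60.0 * (h + 1), counts[h]))
                vals = latent[h] + rng.normal(0.0, jitter_sd, counts[h])
                for off, val in zip(offsets, vals):
                    if rng.random() < outlier_prob:
                        val = _outlier_value(vital, rng)
                    elif vital == "SpO2":
                        # oxygen saturation is a percentage: readings
                        # saturate at the 100% ceiling
                        val = min(val, 100.0)
                    measurements.append((vital, float(np.floor(off)), float(val)))

        age = float(np.clip(rng.normal(54.0, 19.0), 18.0, 100.0))
        sex = "F" if rng.random() < 0.55 else "M"
        comorbidities = {
            k: int(rng.random() < prev[i]) for k, prev in _COMORBIDITY_PREV.items()
        }
        vaso = int(rng.random() < _VASOPRESSOR_PROB[i])
        map_mmHg = (first_hour_vals["SBP"] + 2 * first_hour_vals["DBP"]) / 3.0
        # Acuity inputs: B skews toward respiratory/renal dysfunction,
        # D toward chronic kidney disease; the rest near-normal.
        pf_mean = {"A": 380.0, "B": 290.0, "C": 420.0, "D": 400.0}[tpl.label]
        creat_mu = {"A": 0.0, "B": 0.15, "C": -0.05, "D": 0.20}[tpl.label]
        sofa_inputs = {
            "pao2_fio2": float(max(60.0, rng.normal(pf_mean, 80.0))),
            "platelets": float(max(10.0, rng.lognormal(np.log(215.0), 0.35))),
            "bilirubin": float(min(20.0, rng.lognormal(np.log(0.7), 0.6))),
            "map_mmHg": float(map_mmHg),
            "vasopressor": vaso,
            "gcs": int(np.clip(15 - rng.poisson(0.3), 3, 15)),
            "creatinine": float(min(10.0, rng.lognormal(creat_mu, 0.4))),
        }
        avpu = "Alert" if sofa_inputs["gcs"] >= 13 else "Voice"

        time, event = sample_survival(tpl, horizon_days=horizon_days, size=1, rng=rng)
        encounters.append(
            SyntheticEncounter(
                encounter_id=f"E{e:0{width}d}",
                true_label=tpl.label,
                measurements=measurements,
                age=age,
                sex=sex,
                comorbidities=comorbidities,
                sofa_inputs=sofa_inputs,
                avpu=avpu,
                admission_date=str((base_date + pd.Timedelta(hours=e)).date()),
                time_days=float(time[0]),
                event=int(event[0]),
            )
        )
    return encounters


def cohort_to_series(encounters: Sequence[SyntheticEncounter]):
    """Expose a cohort's measurements as per-(encounter, vital) series."""
    from .io import VitalSeries

    series = []
    for e in encounters:
        by_vital: dict[str, list[tuple[float, float]]] = {}
        for vital, off, val in e.measurements:
            by_vital.setdefault(vital, []).append((off, val))
        for vital in VITALS:
            if vital in by_vital:
                series.append(VitalSeries(e.encounter_id, vital, by_vital[vital]))
    return series


def cohort_to_tables(
    encounters: Sequence[SyntheticEncounter],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flatten encounters to the pipeline's two standard CSV tables."""
    vit_rows = [
        {
            "encounter_id": e.encounter_id,
            "vital": vital,
            "offset_minutes": off,
            "value": round(val, 2),
        }
        for e in encounters
        for vital, off, val in sorted(e.measurements, key=lambda m: (m[0], m[1]))
    ]
    vitals_df = pd.DataFrame(
        vit_rows, columns=["encounter_id", "vital", "offset_minutes", "value"]
    )
    enc_rows = []
    for e in encounters:
        row = {
            "encounter_id": e.encounter_id,
            "true_label": e.true_label,
            "age": round(e.age, 1),
            "sex": e.sex,
            "admission_date": e.admission_date,
            "time_days": round(e.time_days, 2),
            "event": e.event,
            "avpu": e.avpu,
        }
        row.update(e.comorbidities)
        row.update({k: round(v, 3) for k, v in e.sofa_inputs.items()})
        enc_rows.append(row)
    return vitals_df, pd.DataFrame(enc_rows)
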