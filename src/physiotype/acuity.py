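"""SOFA and MEWS acuity scoring from worst-in-window values.

SOFA (Sequential Organ Failure Assessment) sums six organ subscores,
each 0-4: respiratory (PaO2/FiO2), coagulation (platelets), liver
(bilirubin), cardiovascular (MAP / vasopressors), neurologic (GCS) and
renal (creatinine; the urine-output criterion is not used because
urine output is outside the data model).  MEWS (Modified Early Warning
Score) scores bedside systolic pressure, heart rate, respiratory rate,
temperature and AVPU consciousness level.

The numeric lookup tables live in a shipped YAML data file
(``data/score_tables.yaml``) rather than in code, so institutional
variants can be swapped in.  Missing components score 0 ("normal") by
default — the only policy that never inflates acuity — and every
defaulted component is tagged in the result.

Inputs are the *worst* values over the scoring window (24 h by
convention); :func:`worst_in_window` derives them from raw vitals by
maximizing the awarded points over all measurements.
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from typing import Mapping, Sequence

import yaml

SOFA_COMPONENTS = (
    "respiratory",
    "coagulation",
    "liver",
    "cardiovascular",
    "neurologic",
    "renal",
)
MEWS_COMPONENTS = ("sbp", "hr", "rr", "temp", "avpu")

_SOFA_INPUT_KEYS = {
    "respiratory": "pao2_fio2",
    "coagulation": "platelets",
    "liver": "bilirubin",
    "neurologic": "gcs",
    "renal": "creatinine",
}

AVPU_LEVELS = ("Alert", "Voice", "Pain", "Unresponsive")


def load_score_tables() -> dict:
    """Read the shipped SOFA/MEWS lookup tables."""
    text = resources.files("physiotype.data").joinpath("score_tables.yaml").read_text()
    return yaml.safe_load(text)


def _apply_rules(rules: Sequence[Mapping], value: float) -> int:
    """First-match threshold scan: 'lt' upper bounds, 'ge' lower bounds."""
    for rule in rules:
        if "lt" in rule and value < rule["lt"]:
            return int(rule["points"])
        if "ge" in rule and value >= rule["ge"]:
            return int(rule["points"])
        if "lt" not in rule and "ge" not in rule:
            return int(rule["points"])
    raise ValueError("rule list exhausted without a default")


@dataclasses.dataclass
class AcuityResult:
    """Scored acuity for one encounter."""

    sofa_subscores: dict[str, int] | None = None
    sofa_total: int | None = None
    sofa_gt6: bool | None = None
    mews_components: dict[str, int] | None = None
    mews_total: int | None = None
    mews_ge5: bool | None = None
    defaulted: list[str] = dataclasses.field(default_factory=list)


def compute_sofa(
    inputs: Mapping[str, float | int | None],
    tables: dict | None = None,
    missing_policy: str = "normal",
) -> AcuityResult:
    """Score SOFA from worst-in-window values.

    ``inputs`` may provide ``pao2_fio2``, ``platelets``, ``bilirubin``,
    ``map_mmHg``, ``vasopressor`` (0/1 flag) or ``vasopressor_tier``
    ("low"/"medium"/"high"), ``gcs`` and ``creatinine``.  Components
    absent or None are scored per ``missing_policy`` ("normal" = 0,
    tagged in ``defaulted``).
    """
    if missing_policy != "normal":
        raise ValueError(f"unknown missing policy {missing_policy!r}")
    tables = tables or load_score_tables()
    sofa = tables["sofa"]
    present = [
        k
        for k in list(_SOFA_INPUT_KEYS.values()) + ["map_mmHg", "vasopressor"]
        if inputs.get(k) is not None
    ]
    if not present:
        raise ValueError("all SOFA components missing")

    gcs = inputs.get("gcs")
    if gcs is not None and not 3 <= gcs <= 15:
        raise ValueError(f"GCS must be in [3, 15], got {gcs}")

    subscores: dict[str, int] = {}
    defaulted: list[str] = []
    for comp, key in _SOFA_INPUT_KEYS.items():
        value = inputs.get(key)
        if value is None:
            subscores[comp] = 0
            defaulted.append(comp)
        else:
            subscores[comp] = _apply_rules(sofa[comp], float(value))

    # cardiovascular: vasopressor use dominates hypotension
    tier = inputs.get("vasopressor_tier")
    vaso = inputs.get("vasopressor")
    map_mmHg = inputs.get("map_mmHg")
    if tier is not None:
        subscores["cardiovascular"] = int(sofa["cardiovascular"]["vasopressor_tiers"][tier])
    elif vaso:
        subscores["cardiovascular"] = int(
            sofa["cardiovascular"]["vasopressor_tiers"]["low"]
        )
    elif map_mmHg is not None:
        subscores["cardiovascular"] = _apply_rules(
            sofa["cardiovascular"]["map"], float(map_mmHg)
        )
    else:
        subscores["cardiovascular"] = 0
        defaulted.append("cardiovascular")

    total = sum(subscores.values())
    return AcuityResult(
        sofa_subscores=subscores,
        sofa_total=total,
        sofa_gt6=total > 6,
        defaulted=defaulted,
    )


def compute_mews(
    inputs: Mapping[str, float | str | None], tables: dict | None = None
) -> AcuityResult:
    """Score MEWS from worst-in-window bedside values.

    Requires at least one of ``sbp``, ``hr``, ``rr``; ``temp`` and
    ``avpu`` default to normal/Alert when absent (tagged).
    """
    tables = tables or load_score_tables()
    mews = tables["mews"]
    if all(inputs.get(k) is None for k in ("sbp", "hr", "rr")):
        raise ValueError("MEWS requires at least one of sbp, hr, rr")

    components: dict[str, int] = {}
    defaulted: list[str] = []
    for comp in ("sbp", "hr", "rr", "temp"):
        value = inputs.get(comp)
        if value is None:
            components[comp] = 0
            defaulted.append(comp)
        else:
            components[comp] = _apply_rules(mews[comp], float(value))
    avpu = inputs.get("avpu")
    if avpu is None:
        components["avpu"] = 0
        defaulted.append("avpu")
    else:
        if avpu not in AVPU_LEVELS:
            raise ValueError(f"AVPU must be one of {AVPU_LEVELS}, got {avpu!r}")
        components["avpu"] = int(mews["avpu"][avpu])

    total = sum(components.values())
    return AcuityResult(
        mews_components=components,
        mews_total=total,
        mews_ge5=total >= 5,
        defaulted=defaulted,
    )


def worst_in_window(
    samples: Mapping[str, Sequence[float]], tables: dict | None = None
) -> dict[str, float | None]:
    """Pick, per MEWS vital, the measurement awarding the most points.

    "Worst" is defined by maximum severity (awarded points, ties kept
    at the first maximizer), matching the worst-in-window framing of
    admission acuity scoring.
    """
    tables = tables or load_score_tables()
    mews = tables["mews"]
    out: dict[str, float | None] = {}
    for comp in ("sbp", "hr", "rr", "temp"):
        vals = list(samples.get(comp, []))
        if not vals:
            out[comp] = None
            continue
        points = [_apply_rules(mews[comp], float(v)) for v in vals]
        out[comp] = float(vals[points.index(max(points))])
    return out
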