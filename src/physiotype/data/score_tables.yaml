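# Published acuity score lookup tables, encoded as ordered threshold
# rules.  Each rule list is scanned top-down; the first matching rule's
# points apply.  "ge"/"lt" bounds are inclusive-low / exclusive-high.
sofa:
  respiratory:        # PaO2/FiO2 ratio, mmHg
    - {lt: 100, points: 4}
    - {lt: 200, points: 3}
    - {lt: 300, points: 2}
    - {lt: 400, points: 1}
    - {points: 0}
  coagulation:        # platelets, x10^9/L
    - {lt: 20, points: 4}
    - {lt: 50, points: 3}
    - {lt: 100, points: 2}
    - {lt: 150, points: 1}
    - {points: 0}
  liver:              # bilirubin, mg/dL
    - {ge: 12.0, points: 4}
    - {ge: 6.0, points: 3}
    - {ge: 2.0, points: 2}
    - {ge: 1.2, points: 1}
    - {points: 0}
  neurologic:         # Glasgow Coma Scale
    - {lt: 6, points: 4}
    - {lt: 10, points: 3}
    - {lt: 13, points: 2}
    - {lt: 15, points: 1}
    - {points: 0}
  renal:              # creatinine, mg/dL (urine-output criterion not used)
    - {ge: 5.0, points: 4}
    - {ge: 3.5, points: 3}
    - {ge: 2.0, points: 2}
    - {ge: 1.2, points: 1}
    - {points: 0}
  cardiovascular:
    # With only a binary vasopressor flag, any vasopressor scores 2
    # (the lowest vasopressor tier); dose tiers apply when a dose
    # category is supplied.
    vasopressor_tiers:
      low: 2          # dopamine <= 5 or dobutamine (any dose)
      medium: 3       # dopamine > 5 or (nor)epinephrine <= 0.1
      high: 4         # dopamine > 15 or (nor)epinephrine > 0.1
    map:
      - {lt: 70, points: 1}
      - {points: 0}
mews:
  sbp:                # mmHg
    - {lt: 71, points: 3}
    - {lt: 81, points: 2}
    - {lt: 101, points: 1}
    - {lt: 200, points: 0}
    - {points: 2}
  hr:                 # beats/min
    - {lt: 41, points: 2}
    - {lt: 51, points: 1}
    - {lt: 101, points: 0}
    - {lt: 111, points: 1}
    - {lt: 130, points: 2}
    - {points: 3}
  rr:                 # breaths/min
    - {lt: 9, points: 2}
    - {lt: 15, points: 0}
    - {lt: 21, points: 1}
    - {lt: 30, points: 2}
    - {points: 3}
  temp:               # degrees C
    - {lt: 35.0, points: 2}
    - {lt: 38.5, points: 0}
    - {points: 2}
  avpu:
    Alert: 0
    Voice: 1
    Pain: 2
    Unresponsive: 3
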