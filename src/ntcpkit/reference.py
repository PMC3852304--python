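"""Reference coefficient sets and cohort summary statistics.

These constants describe the published prostate-radiotherapy cohort that the
synthetic generator emulates: 57 patients scored for late gastrointestinal
(GI) toxicity (RTOG/EORTC grade 1-2) after 76 Gy external-beam treatment.
The three-variable logistic NTCP model combines the rectal V65 (percent
volume receiving >= 65 Gy), use of antihypertensive/anticoagulant drugs
(AH/AC, protective) and prior acute GI toxicity (consequential late effect);
the one-variable comparator uses V65 alone.  They serve as simulation truth
for the synthetic cohort and as ready-made models for prediction.
"""

from __future__ import annotations

import numpy as np

from .logistic import LogisticNTCPModel

__all__ = [
    "MODEL_THREE_VARIABLE",
    "MODEL_V65_ONLY",
    "N_PATIENTS",
    "N_ACUTE_EVENTS",
    "N_LATE_EVENTS",
    "COVARIATE_PREVALENCES",
    "V65_MIN",
    "V65_MEDIAN",
    "V65_MAX",
]

#: Three-variable late-GI NTCP model: g = b0 + b1*V65 + b2*AHAC + b3*acute.
MODEL_THREE_VARIABLE = LogisticNTCPModel(
    variable_names=["v65", "ahac", "acute_gi"],
    beta0=-1.283,
    betas=np.array([0.028, -1.442, 1.458]),
    standard_errors=np.array([0.017, 0.669, 0.669]),
    pvalues=np.array([0.052, 0.031, 0.029]),
)

#: V65-only late-GI NTCP model.
MODEL_V65_ONLY = LogisticNTCPModel(
    variable_names=["v65"],
    beta0=-1.702,
    betas=np.array([0.033]),
    standard_errors=np.array([0.016]),
    pvalues=np.array([0.036]),
)

#: Cohort size and crude event counts (acute and late G1-2 GI toxicity).
N_PATIENTS = 57
N_ACUTE_EVENTS = 21
N_LATE_EVENTS = 19

#: Binary covariate prevalences in the reference cohort.
COVARIATE_PREVALENCES: dict[str, float] = {
    "age_gt70": 0.667,   # age > 70 years
    "t3": 0.158,         # tumour stage >= T3
    "psa_gt15": 0.386,   # PSA > 15 ng/ml at diagnosis
    "gleason_gt6": 0.403,
    "hormonal": 0.93,    # hormonal therapy
    "surgery": 0.456,    # previous abdominal surgery
    "diabetes": 0.246,
    "smoker": 0.544,
    "ahac": 0.649,       # antihypertensive and/or anticoagulant drugs
    "rt_art": 0.544,     # arc (vs fixed-field conformal) technique
    "acute_gi": 0.368,   # acute G1-2 GI toxicity during/after RT
}

#: Rectal V65 marginal summary in the reference cohort (percent volume).
V65_MIN = 0.4
V65_MEDIAN = 27.0
V65_MAX = 98.2


def event_rate_percent(events: int, n: int) -> float:
    """Crude incidence as a percentage, e.g. (19, 57) -> 33.3."""
    if n <= 0 or events < 0 or events > n:
        raise ValueError("need 0 <= events <= n with n > 0")
    return 100.0 * events / n
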