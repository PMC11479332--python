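"""Published reference values for the four-load-cell posture system.

The original study's participant data is not publicly available, so this
module records the aggregate numbers its reports print: the demographics
table of the 18-person cohort, the sizes of the datasets entering each
classification phase, and the headline F1 scores of the best backend
(LightGBM at a 30% incremental-learning level). These serve as inputs for
bookkeeping identities and for composing the hypothetical end-to-end F1
bounds; they are not recomputable from synthetic data.
"""

from __future__ import annotations

import pandas as pd

#: (participant id, sex, height cm, weight kg) for the analysed cohort
COHORT_ROWS = (
    (1, "F", 170.0, 92.0),
    (2, "M", 172.7, 75.2),
    (3, "M", 181.0, 88.7),
    (4, "M", 181.0, 99.8),
    (5, "F", 157.5, 87.8),
    (6, "F", 157.5, 50.3),
    (7, "M", 175.0, 73.8),
    (8, "M", 165.0, 65.5),
    (10, "M", 198.0, 120.3),
    (11, "F", 161.3, 62.6),
    (12, "F", 165.1, 49.2),
    (13, "F", 175.0, 57.4),
    (14, "F", 175.0, 60.8),
    (15, "F", 170.0, 63.7),
    (17, "M", 188.0, 107.6),
    (18, "M", 179.0, 81.8),
    (19, "M", 185.4, 78.0),
    (20, "M", 183.0, 88.5),
)

#: window counts entering Phase One training
DATASET_SIZES = {
    "primary": 2458,           # instrumented cohort, with angle ground truth
    "supplemental_a": 4910,    # lab cohort, coarse labels only
    "supplemental_b": 13913,   # home cohort, coarse labels only
}

#: Phase One correct predictions forwarded to (or withheld from) Phase Two
PHASE_TWO_SUBSET_SIZES = {"left": 763, "supine": 622, "right": 617}

#: best Phase One macro F1 (LightGBM, incremental level 30%)
PHASE_ONE_BEST_F1 = 0.8343

#: Phase Two mean F1 per (side, bin precision) for the best backend
PHASE_TWO_F1 = {
    ("left", "bins45"): 0.919,
    ("left", "bins30"): 0.830,
    ("left", "bins15"): 0.786,
    ("right", "bins45"): 0.900,
    ("right", "bins30"): 0.812,
    ("right", "bins15"): 0.740,
}


def cohort_table() -> pd.DataFrame:
    """The reference cohort with BMI recomputed from height and weight."""
    df = pd.DataFrame(
        COHORT_ROWS, columns=["participant", "sex", "height_cm", "weight_kg"]
    )
    df["bmi"] = df["weight_kg"] / (df["height_cm"] / 100.0) ** 2
    return df


def mean_bmi() -> float:
    """Cohort mean BMI, recomputed from the printed heights and weights."""
    return float(cohort_table()["bmi"].mean())


def phase_one_total() -> int:
    """Total Phase One training observations across all data sources."""
    return sum(DATASET_SIZES.values())


def phase_two_total() -> int:
    """Total correctly classified Phase One windows (all three classes)."""
    return sum(PHASE_TWO_SUBSET_SIZES.values())
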