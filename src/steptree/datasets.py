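"""Published reference confusion matrices for worked examples.

Counts transcribed from the validation tables of a field study that tracked
GPS-collared cows in an open pasture and a forested range, classifying each
between-fix interval as Foraging, Lying, Standing or Walking (or with the two
stationary classes pooled as Resting). They serve as worked examples for the
percent-correct arithmetic: recomputing the per-class "Correct (%)" and the
"Overall (%)" figures from the raw counts reproduces the published integers.

Each entry maps a descriptive key to ``{"classes": [...], "counts": rows}``
with rows = observed classes, columns = predicted classes, in class order.
"""

from __future__ import annotations

import numpy as np

from .stats import ConfusionMatrix

FOUR_CLASSES = ["Foraging", "Lying", "Standing", "Walking"]
POOLED_CLASSES = ["Foraging", "Resting", "Walking"]

REFERENCE_TABLES: dict[str, dict] = {
    # open pasture, 1 min fixes, four classes
    "open_1min_4class_training": {
        "classes": FOUR_CLASSES,
        "counts": [
            [498, 7, 0, 1],
            [8, 41, 0, 0],
            [12, 10, 4, 0],
            [2, 0, 0, 24],
        ],
    },
    "open_1min_4class_validation": {
        "classes": FOUR_CLASSES,
        "counts": [
            [443, 19, 5, 3],
            [21, 33, 1, 0],
            [26, 12, 4, 0],
            [0, 0, 0, 42],
        ],
    },
    # open pasture, 1 min fixes, Lying+Standing pooled as Resting
    "open_1min_pooled_training": {
        "classes": POOLED_CLASSES,
        "counts": [
            [488, 17, 1],
            [16, 59, 0],
            [2, 0, 24],
        ],
    },
    "open_1min_pooled_validation": {
        "classes": POOLED_CLASSES,
        "counts": [
            [432, 35, 3],
            [36, 61, 0],
            [0, 0, 42],
        ],
    },
    # open pasture, 1 min fixes: mixed intervals scored as dominant behaviour
    "open_1min_mixed_dominant": {
        "classes": FOUR_CLASSES,
        "counts": [
            [831, 16, 3, 18],
            [18, 8, 0, 0],
            [124, 18, 5, 7],
            [172, 5, 0, 126],
        ],
    },
    # open pasture, 12 s fixes, four classes
    "open_12s_4class_training": {
        "classes": FOUR_CLASSES,
        "counts": [
            [197, 0, 0, 0],
            [6, 0, 0, 0],
            [8, 0, 2, 0],
            [5, 0, 0, 31],
        ],
    },
    "open_12s_4class_validation": {
        "classes": FOUR_CLASSES,
        "counts": [
            [189, 0, 0, 8],
            [6, 0, 0, 0],
            [11, 0, 0, 0],
            [8, 0, 0, 28],
        ],
    },
    # forested range, 1 min fixes, pooled Resting
    "forest_1min_pooled_training": {
        "classes": POOLED_CLASSES,
        "counts": [
            [177, 99, 0],
            [73, 499, 0],
            [0, 0, 8],
        ],
    },
    "forest_1min_pooled_validation": {
        "classes": POOLED_CLASSES,
        "counts": [
            [117, 157, 2],
            [54, 244, 0],
            [1, 0, 8],
        ],
    },
}


def reference_confusion(name: str) -> ConfusionMatrix:
    """Build a :class:`ConfusionMatrix` from a reference table by key."""
    entry = REFERENCE_TABLES[name]
    return ConfusionMatrix(list(entry["classes"]), np.array(entry["counts"]))
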