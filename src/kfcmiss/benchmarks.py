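"""Published reference results for the Iris Plant and Thyroid Gland benchmarks.

The original study of the adaptive kernel fuzzy clustering strategies reports,
for each dataset, missing-value percentage (5/10/15/20%) and strategy
(whole-data, partial-distance, optimal completion), a cluster-vs-class
confusion matrix together with the corrected Rand index, F-measure and
overall error rate of the best solution, printed truncated to 4 (Iris) or
3 (Thyroid) decimals.  The matrices and printed index values are transcribed
here verbatim so the metric implementations can be validated against them;
the underlying UCI datasets and random masks are not needed for that check.

``INCONSISTENT_CELLS`` lists the printed summary cells that contradict the
study's own printed confusion matrix (no cluster-to-class assignment or
common F-measure variant reproduces them); every other cell is reproducible
exactly.
"""

from __future__ import annotations

import numpy as np

# confusion matrices: rows = clusters, columns = a-priori classes
IRIS_CONFUSION = {
    ("wds", 5): [[50, 0, 0], [0, 47, 12], [0, 3, 38]],
    ("wds", 10): [[50, 0, 0], [0, 46, 7], [0, 4, 43]],
    ("wds", 15): [[50, 0, 0], [0, 44, 4], [0, 6, 46]],
    ("wds", 20): [[50, 0, 0], [0, 42, 3], [0, 8, 47]],
    ("pds", 5): [[50, 0, 0], [0, 47, 8], [0, 3, 42]],
    ("pds", 10): [[50, 0, 0], [0, 45, 9], [0, 5, 41]],
    ("pds", 15): [[50, 0, 0], [0, 45, 9], [0, 5, 41]],
    ("pds", 20): [[50, 0, 0], [0, 45, 9], [0, 5, 41]],
    ("ocs", 5): [[50, 0, 0], [0, 46, 8], [0, 4, 42]],
    ("ocs", 10): [[50, 0, 0], [0, 45, 6], [0, 5, 44]],
    ("ocs", 15): [[50, 0, 0], [0, 45, 5], [0, 5, 45]],
    ("ocs", 20): [[50, 0, 0], [0, 45, 7], [0, 5, 43]],
}

# printed best-solution indices: (corrected Rand, F-measure, OERC)
IRIS_PRINTED = {
    ("wds", 5): (0.7429, 0.8991, 0.1000),
    ("wds", 10): (0.8016, 0.9266, 0.0733),
    ("wds", 15): (0.8176, 0.9333, 0.0666),
    ("wds", 20): (0.8018, 0.9261, 0.0733),
    ("pds", 5): (0.8018, 0.9261, 0.0733),
    ("pds", 10): (0.7561, 0.9065, 0.0933),
    ("pds", 15): (0.7561, 0.9065, 0.0933),
    ("pds", 20): (0.7561, 0.9065, 0.0933),
    ("ocs", 5): (0.7861, 0.9198, 0.0800),
    ("ocs", 10): (0.8015, 0.9266, 0.0733),
    ("ocs", 15): (0.8175, 0.9333, 0.0666),
    ("ocs", 20): (0.7859, 0.9199, 0.0800),
}

THYROID_CONFUSION = {
    ("wds", 5): [[144, 0, 6], [6, 35, 0], [0, 0, 24]],
    ("wds", 10): [[118, 1, 4], [32, 34, 1], [0, 0, 25]],
    ("wds", 15): [[143, 2, 5], [7, 33, 0], [0, 0, 25]],
    ("wds", 20): [[147, 5, 8], [3, 30, 0], [0, 0, 22]],
    ("pds", 5): [[143, 0, 6], [7, 35, 0], [0, 0, 24]],
    ("pds", 10): [[138, 1, 5], [12, 34, 0], [0, 0, 25]],
    ("pds", 15): [[130, 1, 5], [20, 34, 0], [0, 0, 25]],
    ("pds", 20): [[117, 2, 8], [33, 33, 1], [0, 0, 21]],
    ("ocs", 5): [[141, 0, 6], [9, 35, 0], [0, 0, 24]],
    ("ocs", 10): [[133, 1, 6], [17, 34, 0], [0, 0, 24]],
    ("ocs", 15): [[127, 1, 6], [23, 34, 0], [0, 0, 24]],
    ("ocs", 20): [[115, 2, 7], [35, 33, 1], [0, 0, 22]],
}

THYROID_PRINTED = {
    ("wds", 5): (0.818, 0.943, 0.055),
    ("wds", 10): (0.509, 0.838, 0.176),
    ("wds", 15): (0.787, 0.935, 0.065),
    ("wds", 20): (0.753, 0.923, 0.074),
    ("pds", 5): (0.803, 0.939, 0.060),
    ("pds", 10): (0.734, 0.918, 0.083),
    ("pds", 15): (0.633, 0.885, 0.120),
    ("pds", 20): (0.441, 0.809, 0.204),
    ("ocs", 5): (0.775, 0.930, 0.069),
    ("ocs", 10): (0.656, 0.892, 0.111),
    ("ocs", 15): (0.586, 0.868, 0.139),
    ("ocs", 20): (0.434, 0.807, 0.200),
}

DATASETS = {
    "iris": (IRIS_CONFUSION, IRIS_PRINTED, 4),
    "thyroid": (THYROID_CONFUSION, THYROID_PRINTED, 3),
}

METRIC_INDEX = {"corrected_rand": 0, "f_measure": 1, "oerc": 2}

# printed summary cells that contradict the same study's printed confusion
# matrix: (dataset, strategy, percent, metric) -> value implied by the matrix
INCONSISTENT_CELLS = {
    ("iris", "wds", 20, "f_measure"): 0.9264,
    ("iris", "pds", 5, "f_measure"): 0.9264,
    ("thyroid", "ocs", 20, "oerc"): 0.209,
}


def confusion(dataset: str, strategy: str, percent: int) -> np.ndarray:
    tables, _, _ = DATASETS[dataset]
    return np.asarray(tables[(strategy, percent)], dtype=int)


def printed_value(dataset: str, strategy: str, percent: int, metric: str) -> float:
    _, printed, _ = DATASETS[dataset]
    return printed[(strategy, percent)][METRIC_INDEX[metric]]


def printed_decimals(dataset: str) -> int:
    return DATASETS[dataset][2]
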