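"""Reference confusion-count tables for the optimized fingerprint classifiers.

These are the per-iteration cross-validation confusion counts (TP, TN, FP,
FN) reported for the final eyeblink, eye-movement and myogenic classifiers
on their cued-artifact development corpora, and the validation counts from
the cycling-task evaluation.  They serve as fixed inputs for verifying the
evaluation arithmetic (accuracy, precision, false omission rate,
sensitivity, specificity) — the underlying recordings are not distributed,
but every reported metric is recomputable exactly from these counts.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "CROSS_VALIDATION_COUNTS",
    "VALIDATION_COUNTS",
]

#: per-iteration (TP, TN, FP, FN) of the final classifier, 10 iterations each
CROSS_VALIDATION_COUNTS: dict[str, np.ndarray] = {
    "eyeblink": np.array(
        [
            (8, 322, 0, 0),
            (7, 203, 0, 0),
            (7, 263, 0, 0),
            (7, 353, 0, 0),
            (6, 323, 0, 1),
            (8, 232, 0, 0),
            (6, 354, 0, 0),
            (7, 173, 0, 0),
            (7, 263, 0, 0),
            (7, 233, 0, 0),
        ]
    ),
    "eye-movement": np.array(
        [
            (51, 144, 11, 4),
            (21, 150, 7, 2),
            (38, 132, 7, 3),
            (23, 121, 5, 1),
            (42, 157, 8, 3),
            (52, 167, 8, 13),
            (55, 170, 10, 5),
            (47, 181, 5, 7),
            (57, 188, 8, 17),
            (16, 97, 5, 2),
        ]
    ),
    "myogenic": np.array(
        [
            (79, 184, 3, 4),
            (50, 95, 4, 1),
            (63, 171, 1, 5),
            (89, 144, 3, 4),
            (76, 147, 15, 2),
            (45, 156, 8, 1),
            (80, 154, 5, 1),
            (72, 98, 6, 4),
            (89, 170, 7, 4),
            (79, 154, 4, 3),
        ]
    ),
}

#: validation-study (TP, TN, FP, FN) per artifact classifier
VALIDATION_COUNTS: dict[str, tuple[int, int, int, int]] = {
    "eyeblink": (11, 347, 0, 2),
    "eye-movement": (11, 344, 1, 4),
    "myogenic": (90, 244, 10, 16),
}
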