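"""Published per-subject test-set results of the original 10-subject
PMMCT study (optimal hyperparameters, HEOG + HSUM).

The table records, for each subject, the number of positive (SEM) and
negative test windows, the false-positive and false-negative counts, and
the printed percentage metrics.  It serves as input for metric
recomputation: :func:`semscan.evaluation.report_from_counts` must
reproduce every printed percentage from the four counts alone.

One known inconsistency in the published table: S03's printed precision
(99.26) does not follow from its own counts (283 positives, 5 FP, recall
100 give 283/288 = 98.26), while S03's printed F1 (99.12) does follow
from 98.26.  The table below keeps the printed value;
``DERIVED_S03_PRECISION`` holds the count-consistent one.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["load_reference_results", "DERIVED_S03_PRECISION"]

DERIVED_S03_PRECISION = 98.26

_ROWS = [
    # subject, n_pos, n_neg, FP, FN, precision, recall, accuracy, f1
    ("S01", 397, 2891, 1, 0, 99.75, 100.00, 99.97, 99.87),
    ("S02", 454, 5627, 3, 0, 99.34, 100.00, 99.95, 99.67),
    ("S03", 283, 5252, 5, 0, 99.26, 100.00, 99.91, 99.12),
    ("S04", 728, 6747, 34, 1, 95.53, 99.86, 99.53, 97.65),
    ("S05", 396, 3542, 4, 1, 99.00, 99.75, 99.87, 99.37),
    ("S06", 193, 2756, 1, 2, 99.48, 98.96, 99.90, 99.22),
    ("S07", 208, 3901, 1, 0, 99.52, 100.00, 99.98, 99.76),
    ("S08", 637, 3158, 1, 0, 99.84, 100.00, 99.97, 99.92),
    ("S09", 199, 3739, 0, 2, 100.00, 98.99, 99.95, 99.49),
    ("S10", 373, 4554, 2, 2, 99.46, 99.46, 99.92, 99.46),
]


def load_reference_results() -> pd.DataFrame:
    """Per-subject published counts and metrics as a DataFrame."""
    return pd.DataFrame(
        _ROWS,
        columns=[
            "subject",
            "n_pos",
            "n_neg",
            "FP",
            "FN",
            "precision",
            "recall",
            "accuracy",
            "f1",
        ],
    ).set_index("subject")
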