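"""Published summary tables from the original 11-subject mVEP study.

These numbers are the printed per-subject accuracies (percent) and
information transfer rates (bits/min) for the adaptive-calibration
strategies, and the per-calibration-cycle sample-harvest counts of a
representative subject.  The package uses them as fixed inputs for
cross-checking its evaluation arithmetic (the ITR closed form, column
means, audit-ratio accounting); the underlying raw EEG was never
deposited, so per-subject values cannot be recomputed from data.
"""

from __future__ import annotations

import numpy as np

# Per-subject accuracy (%) for the fusion (SVM+fCM) calibration at
# calibration intervals of 4, 6 and 9 blocks, and the fixed-classifier
# baseline; 11 subjects, threshold 0.75, capacity 250.
FUSION_ACCURACY = {
    4: (86.1, 94.4, 69.4, 94.4, 77.8, 91.7, 94.4, 94.4, 94.4, 83.3, 91.7),
    6: (81.5, 94.4, 72.2, 97.2, 80.6, 88.9, 94.4, 94.4, 94.4, 77.8, 94.4),
    9: (83.3, 91.7, 72.2, 94.4, 77.8, 88.9, 91.7, 91.7, 94.4, 80.6, 94.4),
}
FUSION_ITR = {
    4: (13.4, 17.1, 7.9, 17.1, 10.4, 15.8, 17.1, 17.1, 17.1, 12.4, 15.8),
    6: (11.7, 17.1, 8.7, 18.7, 11.4, 14.6, 17.1, 17.1, 17.1, 10.4, 17.1),
    9: (12.4, 15.8, 8.7, 17.1, 10.4, 14.6, 15.8, 15.8, 17.1, 11.4, 17.1),
}
BASELINE_ACCURACY = (83.3, 91.7, 66.7, 91.7, 75.0, 88.9, 91.7, 88.9, 94.4,
                     77.8, 91.7)
BASELINE_ITR = (12.4, 15.8, 7.2, 15.8, 9.5, 14.6, 15.8, 14.6, 17.1, 10.4,
                15.8)

# Sample-harvest audit of a representative subject (8 calibration cycles,
# interval 4 blocks, threshold 0.75): A = correctly labeled additions,
# B = total additions, per strategy.
AUDIT_COUNTS = {
    "svm_only": {"A": (13, 9, 10, 11, 13, 10, 9, 12),
                 "B": (15, 14, 13, 14, 15, 13, 11, 14)},
    "fcm_only": {"A": (4, 3, 2, 3, 5, 4, 6, 7),
                 "B": (6, 5, 4, 5, 6, 5, 6, 7)},
    "fusion":   {"A": (3, 4, 3, 4, 4, 3, 3, 3),
                 "B": (4, 6, 4, 5, 4, 4, 3, 3)},
}


def column_mean(values) -> float:
    return float(np.mean(values))


def audit_ratio(strategy: str) -> float:
    """Pooled ratio C = sum(A) / sum(B) over the calibration cycles."""
    c = AUDIT_COUNTS[strategy]
    return float(sum(c["A"]) / sum(c["B"]))
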