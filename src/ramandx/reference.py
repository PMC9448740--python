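"""Reported summaries of the reference prostate-cancer cohort.

The cohort behind this package — nine patients receiving high-dose-rate
brachytherapy, twelve pre-treatment biopsies — is not publicly deposited;
what is available are its published summary data: the per-biopsy clinical
roster, the per-biopsy processed-spectrum inventory, the test-set confusion
matrices of the three classification tasks and the leave-one-biopsy-out
Ki67 accuracies.  Those summaries live here as plain data: the synthetic
cohort generator uses the roster and inventory as its study conditions, and
the cohort-level statistics (overall accuracies, threshold counts, PSA
median) are recomputed from these inputs rather than hard-coded.
"""

from __future__ import annotations

import numpy as np

#: per-biopsy clinical roster: (biopsy, patient, age, (gleason primary,
#: secondary), CAPRA group, % pattern 4, post-treatment Ki67 %, baseline PSA)
ROSTER = [
    ("72",  "72", 65, (3, 4), "Medium", 25.0, 1.5, 8.5),
    ("74a", "74", 64, (3, 4), "Medium", 20.0, 0.0, 4.56),
    ("74b", "74", 64, (3, 4), "Medium", 20.0, 5.9, 4.56),
    ("75",  "75", 66, (3, 3), "Low",     0.0, 3.1, 3.34),
    ("76a", "76", 65, (3, 3), "Low",     0.0, 2.7, 1.6),
    ("76b", "76", 65, (3, 3), "Low",     0.0, 5.8, 1.6),
    ("86",  "86", 73, (4, 4), "High",  100.0, 7.9, 16.84),
    ("87",  "87", 64, (3, 4), "Medium",  7.5, 3.2, 6.2),
    ("88a", "88", 59, (3, 3), "Medium",  0.0, 1.3, 9.13),
    ("88b", "88", 59, (4, 3), "Medium", 90.0, 0.8, 9.13),
    ("91",  "91", 62, (3, 3), "Low",     0.0, 2.1, 3.54),
    ("99",  "99", 72, (3, 4), "Medium", 80.0, 5.2, 4.02),
]

#: processed spectra per biopsy (cohort total 3905)
SPECTRUM_INVENTORY = {
    "72": 335, "74a": 337, "74b": 325, "75": 346, "76a": 233, "76b": 328,
    "86": 346, "87": 285, "88a": 303, "88b": 342, "91": 370, "99": 355,
}

#: Gleason-task test-set confusion matrix (rows observed, cols predicted)
GLEASON_TEST_CONFUSION = {
    "classes": ["GS6", "GS7", "GS8"],
    "counts": np.array([
        [123, 47, 4],
        [130, 402, 81],
        [25, 56, 133],
    ]),
}

#: CAPRA-task test-set confusion matrix
CAPRA_TEST_CONFUSION = {
    "classes": ["Low", "Medium", "High"],
    "counts": np.array([
        [32, 17, 8],
        [17, 157, 73],
        [41, 131, 487],
    ]),
}

#: Ki67-task test-set confusion matrix
KI67_TEST_CONFUSION = {
    "classes": ["Low", "High"],
    "counts": np.array([
        [287, 61],
        [84, 514],
    ]),
}

#: leave-one-biopsy-out Ki67 classification accuracy (% spectra correct)
KI67_PER_BIOPSY_ACCURACY = {
    "72": 93.0, "74a": 80.0, "74b": 57.0, "75": 98.0, "76a": 88.0,
    "76b": 91.0, "86": 52.0, "87": 93.0, "88a": 60.0, "88b": 86.0,
    "91": 85.0, "99": 15.0,
}

#: the biopsy with the inverted biochemical signature (HCA outlier)
OUTLIER_BIOPSY = "99"
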