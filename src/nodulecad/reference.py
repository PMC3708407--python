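"""Reference confusion matrices and feature rankings.

These are the published reference values for the hybrid-feature pulmonary
nodule classification approach on its original clinical dataset (86 test
patterns: 48 nodules, 38 non-nodules).  The underlying CT data is private,
so these matrices serve as fixtures: the evaluation module must reproduce
the reported rate metrics and kappa statistics from them exactly.

Matrices are keyed by (method_id, classifier_name) with counts in the
tabulated order (TP, FP, FN, TN).
"""

from __future__ import annotations

from .evaluation import ConfusionMatrix

# (method_id, classifier) -> (TP, FP, FN, TN)
REFERENCE_CONFUSION: dict[tuple[int, str], ConfusionMatrix] = {
    (1, "ann"): ConfusionMatrix(42, 6, 7, 31),
    (1, "rf"): ConfusionMatrix(42, 6, 11, 27),
    (1, "bag-ann"): ConfusionMatrix(48, 0, 33, 5),
    (1, "bag-rf"): ConfusionMatrix(42, 6, 6, 32),
    (1, "ada-ann"): ConfusionMatrix(42, 6, 10, 28),
    (1, "ada-rf"): ConfusionMatrix(40, 8, 13, 25),
    (2, "ann"): ConfusionMatrix(41, 7, 7, 31),
    (2, "rf"): ConfusionMatrix(40, 8, 6, 32),
    (2, "bag-ann"): ConfusionMatrix(48, 0, 34, 4),
    (2, "bag-rf"): ConfusionMatrix(40, 8, 8, 30),
    (2, "ada-ann"): ConfusionMatrix(39, 9, 8, 30),
    (2, "ada-rf"): ConfusionMatrix(40, 8, 9, 29),
    (3, "ann"): ConfusionMatrix(40, 8, 6, 32),
    (3, "rf"): ConfusionMatrix(39, 9, 10, 28),
    (3, "bag-ann"): ConfusionMatrix(19, 29, 6, 32),
    (3, "bag-rf"): ConfusionMatrix(40, 8, 5, 33),
    (3, "ada-ann"): ConfusionMatrix(40, 8, 6, 32),
    (3, "ada-rf"): ConfusionMatrix(41, 7, 7, 31),
    (4, "ann"): ConfusionMatrix(43, 5, 3, 35),
    (4, "rf"): ConfusionMatrix(41, 7, 7, 31),
    (4, "bag-ann"): ConfusionMatrix(29, 19, 10, 28),
    (4, "bag-rf"): ConfusionMatrix(42, 6, 6, 32),
    (4, "ada-ann"): ConfusionMatrix(42, 6, 6, 32),
    (4, "ada-rf"): ConfusionMatrix(41, 7, 10, 28),
}

# Reported mRMR orderings on the original training data (reference only;
# not reproducible without that data).
REFERENCE_METHOD2_RANKING = [
    "stat_moment3", "stat_min", "stat_mean", "stat_std", "stat_max", "stat_var",
]
REFERENCE_METHOD3_SELECTION = [
    "geo_compactness", "geo_aspect_ratio", "geo_area", "geo_solidity",
    "geo_ellipticity",
]
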