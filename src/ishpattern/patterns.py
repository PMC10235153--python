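"""Spatial expression-pattern vocabulary and the noiseless classification rules.

Four categories describe expression along the tonotopic (rostro-medial ->
caudo-lateral) axes of the nucleus magnocellularis:

* ``homogeneous`` — no rostral-caudal difference;
* ``differential`` — a significant rostral-caudal difference;
* ``gradient``   — differential, plus a monotone significant change
  MM -> MC -> ML across the middle plane;
* ``selective``  — differential, plus MM differing from MC while MC equals ML
  (expression restricted to the medial part).

:func:`pattern_from_levels` applies the same decision structure to exact
(noise-free) expression levels, replacing each t-test by an equality check;
it is used to label synthetic ground truth consistently with the classifier.
"""

from __future__ import annotations

__all__ = [
    "CATEGORIES",
    "DIRECTIONS",
    "ML_DIRECTIONS",
    "EXPRESSION_ROIS",
    "pattern_from_levels",
]

CATEGORIES = ("homogeneous", "differential", "gradient", "selective")
DIRECTIONS = ("rostral_high", "caudal_high", "none")
ML_DIRECTIONS = ("medial_high", "lateral_high", "none")

EXPRESSION_ROIS = ("RM", "RL", "MM", "MC", "ML", "CM", "CL")


def _cmp(x: float, y: float, tol: float) -> int:
    """-1, 0 or +1 for x < y, x == y, x > y within absolute tolerance."""
    if abs(x - y) <= tol:
        return 0
    return 1 if x > y else -1


def pattern_from_levels(
    roi_levels: dict[str, float], tol: float = 1e-9
) -> tuple[str, str, str]:
    """Classify exact expression levels by the decision tree's noiseless rules.

    Returns ``(category, direction, medial_lateral_direction)``.  Equality
    within ``tol`` stands in for a non-significant test; any difference larger
    than ``tol`` for a significant one.
    """
    missing = [r for r in EXPRESSION_ROIS if r not in roi_levels]
    if missing:
        raise ValueError(f"roi_levels missing ROIs: {missing}")

    rostral = (roi_levels["RM"] + roi_levels["RL"]) / 2.0
    caudal = (roi_levels["CM"] + roi_levels["CL"]) / 2.0
    step1 = _cmp(rostral, caudal, tol)
    if step1 == 0:
        return "homogeneous", "none", "none"

    direction = "rostral_high" if step1 > 0 else "caudal_high"
    mm_mc = _cmp(roi_levels["MM"], roi_levels["MC"], tol)
    mc_ml = _cmp(roi_levels["MC"], roi_levels["ML"], tol)

    if mm_mc != 0 and mc_ml != 0 and mm_mc == mc_ml:
        ml_dir = "medial_high" if mm_mc > 0 else "lateral_high"
        return "gradient", direction, ml_dir
    if mm_mc != 0 and mc_ml == 0:
        ml_dir = "medial_high" if mm_mc > 0 else "lateral_high"
        return "selective", direction, ml_dir
    return "differential", direction, "none"
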