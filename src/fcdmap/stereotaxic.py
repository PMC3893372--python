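"""Normalized anterior-posterior slide coordinates and case-control matching.

Coronal slides are positioned on a stereotaxic y axis anchored at three
landmarks: frontal pole y = +73 mm, anterior commissure (AC) y = 0,
occipital pole y = -106 mm. Intermediate slides are placed by linear
interpolation of slide *index* within each landmark segment. Case slides
are then matched to the control slide nearest in y.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import LandmarkError

Y_FRONTAL = 73.0
Y_AC = 0.0
Y_OCCIPITAL = -106.0


@dataclass
class SlideSeries:
    """Ordered anterior-to-posterior slides with landmark indices."""

    slides: list[str]
    frontal_pole: int
    anterior_commissure: int
    occipital_pole: int
    spacing_mm: float = 1.2  # nominal physical inter-slide spacing

    def __post_init__(self):
        n = len(self.slides)
        for name, i in (
            ("frontal_pole", self.frontal_pole),
            ("anterior_commissure", self.anterior_commissure),
            ("occipital_pole", self.occipital_pole),
        ):
            if i is None:
                raise LandmarkError(f"landmark {name} is missing")
            if not 0 <= i < n:
                raise LandmarkError(f"landmark {name} index {i} out of range")
        if not self.frontal_pole <= self.anterior_commissure <= self.occipital_pole:
            raise LandmarkError(
                "landmarks out of order: need frontal_pole <= AC <= occipital_pole "
                "in anterior-to-posterior list order"
            )
        if self.frontal_pole == self.occipital_pole:
            raise LandmarkError("frontal and occipital poles coincide")


@dataclass
class SlidePosition:
    slide_id: str
    y: float  # mm in normalized space


def assign_y(series: SlideSeries) -> list[SlidePosition]:
    """Piecewise-linear slide-index -> y interpolation between landmarks.

    Slides anterior of the frontal pole or posterior of the occipital pole
    (if any) continue the local linear segment. A warning is issued when
    the implied physical spacing deviates more than 25% from the nominal
    ``spacing_mm``.
    """
    fp, ac, op = series.frontal_pole, series.anterior_commissure, series.occipital_pole
    idx = np.arange(len(series.slides), dtype=float)

    ys = np.empty(len(idx))
    if ac > fp:
        ys = np.where(
            idx <= ac, Y_FRONTAL + (idx - fp) * (Y_AC - Y_FRONTAL) / (ac - fp), 0.0
        )
    else:
        ys = np.where(idx <= ac, Y_AC, 0.0)
    if op > ac:
        post = Y_AC + (idx - ac) * (Y_OCCIPITAL - Y_AC) / (op - ac)
        ys = np.where(idx > ac, post, ys)
    else:
        ys = np.where(idx > ac, Y_OCCIPITAL, ys)

    for lo_i, hi_i, span in ((fp, ac, Y_FRONTAL - Y_AC), (ac, op, Y_AC - Y_OCCIPITAL)):
        if hi_i > lo_i:
            implied = span / (hi_i - lo_i)
            if abs(implied - series.spacing_mm) > 0.25 * series.spacing_mm:
                warnings.warn(
                    f"implied inter-slide spacing {implied:.2f} mm deviates >25% "
                    f"from nominal {series.spacing_mm} mm"
                )

    return [SlidePosition(sid, float(y)) for sid, y in zip(series.slides, ys)]


def match_slides(
    case: list[SlidePosition],
    control: list[SlidePosition],
    max_dy: float = 1.2,
) -> list[tuple[str, str, float]]:
    """Pair each case slide with the nearest-y control slide.

    Pairs farther apart than ``max_dy`` mm are dropped. Ties in distance go
    to the more anterior (larger-y) control slide, so matching is
    deterministic. Returns (case_id, control_id, dy = y_case - y_control).
    """
    if not case or not control:
        raise ValueError("both slide lists must be nonempty")
    # sort controls by descending y; argmin picks the first (most anterior) tie
    ctrl = sorted(control, key=lambda p: -p.y)
    cy = np.array([p.y for p in ctrl])
    out = []
    for p in case:
        j = int(np.argmin(np.abs(cy - p.y)))
        dy = p.y - cy[j]
        if abs(dy) <= max_dy:
            out.append((p.slide_id, ctrl[j].slide_id, float(dy)))
    return out
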