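"""Regional intensity-per-cell scores and quartile level classification.

A region's score is (mean stained intensity − mean control intensity over
the same ROI) × ROI area ÷ DAPI+ nucleus count.  Scores across a cohort are
cut at the 25/50/75th percentiles into four named levels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ImagePlane, RegionOfInterest

LEVELS = ("low", "moderately low", "moderately high", "high")


@dataclass
class RegionalScore:
    region: str
    mean_intensity_AU: float
    control_mean_AU: float
    area_px: int
    nuclei_count: int
    intensity_per_cell_AU: float
    level: str | None = None


class UncountableROIError(ValueError):
    """ROI without countable nuclei; excluded from per-cell scoring."""


def intensity_per_cell(stained: ImagePlane, control: ImagePlane,
                       roi: RegionOfInterest, nuclei_count: int) -> RegionalScore:
    """Background-corrected total intensity per DAPI+ nucleus in one ROI.

    Negative corrected means are retained, not clipped, so that
    control-dominated regions sort to the bottom of the cohort.
    """
    if stained.pixel_size_um != control.pixel_size_um:
        raise ValueError("stained and control must share pixel size")
    if nuclei_count <= 0:
        raise UncountableROIError(f"ROI {roi.label!r} has no countable nuclei")
    mask = roi.effective_mask
    if not mask.any():
        raise ValueError(f"ROI {roi.label!r} is empty")
    mean_stained = float(stained.data[mask].mean())
    mean_control = float(control.data[mask].mean())
    area = int(mask.sum())
    score = (mean_stained - mean_control) * area / nuclei_count
    return RegionalScore(
        region=roi.label,
        mean_intensity_AU=mean_stained,
        control_mean_AU=mean_control,
        area_px=area,
        nuclei_count=nuclei_count,
        intensity_per_cell_AU=score,
    )


def classify_quartiles(scores: list[RegionalScore]) -> list[RegionalScore]:
    """Assign quartile levels across a cohort of regional scores.

    Percentiles use linear interpolation between order statistics; a value
    exactly at a cut joins the upper level, so the cohort maximum is always
    'high' and the minimum always 'low' (for non-degenerate cohorts).
    """
    if len(scores) < 4:
        raise ValueError("quartile classification requires >= 4 regions")
    values = np.array([s.intensity_per_cell_AU for s in scores])
    p25, p50, p75 = np.percentile(values, [25, 50, 75])
    for s in scores:
        v = s.intensity_per_cell_AU
        if v >= p75:
            s.level = "high"
        elif v >= p50:
            s.level = "moderately high"
        elif v >= p25:
            s.level = "moderately low"
        else:
            s.level = "low"
    return scores
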