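"""Nuclei counting: difference of Gaussians, triangle threshold, watershed.

The counting chain is: DoG filter on the DAPI plane, binarization at a
triangle-algorithm threshold of the DoG histogram, watershed separation of
touching nuclei on the distance transform, and an inclusive particle-size
filter (defaults 10–250 px).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import disk, local_maxima
from skimage.segmentation import watershed

from .core import ImagePlane, RegionOfInterest


@dataclass
class NucleiCountParams:
    sigma_small_px: float = 2.0
    sigma_large_px: float = 6.0
    min_area_px: int = 10
    max_area_px: int = 250
    apply_watershed: bool = True
    n_bins: int = 256
    maxima_merge_px: int = 3

    def __post_init__(self) -> None:
        if not (0 < self.sigma_small_px < self.sigma_large_px):
            raise ValueError("require 0 < sigma_small_px < sigma_large_px")
        if not (0 < self.min_area_px < self.max_area_px):
            raise ValueError("require 0 < min_area_px < max_area_px")

    @classmethod
    def for_nucleus_radius(cls, radius_px: float, **kwargs) -> "NucleiCountParams":
        """Scale the DoG sigmas from an expected nucleus radius in pixels."""
        return cls(sigma_small_px=0.3 * radius_px, sigma_large_px=1.0 * radius_px,
                   **kwargs)


def difference_of_gaussians(plane: ImagePlane, params: NucleiCountParams) -> ImagePlane:
    """blur(σ_small) − blur(σ_large); linear, removes constant offsets."""
    data = plane.data
    if not np.isfinite(data).all():
        raise ValueError("image contains non-finite pixels")
    out = (ndi.gaussian_filter(data, params.sigma_small_px)
           - ndi.gaussian_filter(data, params.sigma_large_px))
    return ImagePlane(out, plane.pixel_size_um, name=f"{plane.name}:dog")


def triangle_threshold(histogram: np.ndarray) -> int:
    """Triangle-algorithm threshold on a histogram of bin counts.

    Returns the index of the bin maximizing the perpendicular distance from
    the histogram curve to the line joining the peak bin to the farthest
    nonempty tail bin.  Ties break to the lowest qualifying bin.
    """
    hist = np.asarray(histogram, dtype=float)
    if hist.ndim != 1:
        raise ValueError("histogram must be 1-D")
    nonempty = np.flatnonzero(hist > 0)
    if nonempty.size < 2:
        raise ValueError("triangle threshold requires >= 2 nonempty bins")
    peak = int(np.argmax(hist))
    # farthest nonempty bin from the peak (the histogram tail)
    tail = int(nonempty[np.argmax(np.abs(nonempty - peak))])
    lo, hi = (peak, tail) if peak < tail else (tail, peak)
    xs = np.arange(lo, hi + 1, dtype=float)
    ys = hist[lo:hi + 1]
    x1, y1 = float(peak), hist[peak]
    x2, y2 = float(tail), hist[tail]
    # perpendicular distance of each (x, y) to the peak–tail chord
    norm = np.hypot(x2 - x1, y2 - y1)
    dist = np.abs((y2 - y1) * xs - (x2 - x1) * ys + x2 * y1 - y2 * x1) / norm
    best = int(xs[np.argmax(dist)])  # argmax returns first (lowest bin) on ties
    return best


def _binarize_triangle(dog: np.ndarray, mask: np.ndarray, n_bins: int) -> np.ndarray:
    vals = dog[mask]
    counts, edges = np.histogram(vals, bins=n_bins)
    idx = triangle_threshold(counts)
    thr = edges[idx + 1]  # upper edge of the threshold bin
    binary = np.zeros(dog.shape, dtype=bool)
    binary[mask] = dog[mask] > thr
    return binary


def _watershed_split(binary: np.ndarray, merge_px: int) -> np.ndarray:
    """Watershed on the distance transform, seeded at regional maxima.

    Nearby maxima (plateaus of discretized blobs) are merged by dilating
    the maxima mask by ``merge_px`` before labelling, so mildly elongated
    blobs are not oversplit.
    """
    distance = ndi.distance_transform_edt(binary)
    maxima = local_maxima(distance) & binary
    if merge_px > 0:
        maxima = ndi.binary_dilation(maxima, structure=disk(merge_px)) & binary
    markers, _ = ndi.label(maxima)
    return watershed(-distance, markers, mask=binary)


def count_nuclei(plane: ImagePlane, roi: RegionOfInterest,
                 params: NucleiCountParams | None = None) -> tuple[int, np.ndarray]:
    """Count nuclei in an ROI; returns (count, label grid of kept particles)."""
    params = params or NucleiCountParams()
    if roi.is_empty():
        raise ValueError(f"ROI {roi.label!r} is empty")
    mask = roi.effective_mask
    dog = difference_of_gaussians(plane, params).data
    if not (dog[mask] > dog[mask].min()).any():
        return 0, np.zeros(plane.shape, dtype=np.int32)
    binary = _binarize_triangle(dog, mask, params.n_bins)
    if not binary.any():
        return 0, np.zeros(plane.shape, dtype=np.int32)
    if params.apply_watershed:
        labels = _watershed_split(binary, params.maxima_merge_px)
    else:
        labels, _ = ndi.label(binary)
    # inclusive particle-size filter
    ids, areas = np.unique(labels[labels > 0], return_counts=True)
    keep = ids[(areas >= params.min_area_px) & (areas <= params.max_area_px)]
    out = np.zeros(labels.shape, dtype=np.int32)
    for new_id, old_id in enumerate(keep, start=1):
        out[labels == old_id] = new_id
    return len(keep), out


def density_warning(count: int, roi: RegionOfInterest,
                    max_density_per_px: float = 0.02) -> bool:
    """Flag ROIs so dense that DAPI-based counting is unreliable."""
    area = roi.area_px
    return area > 0 and count / area > max_density_per_px
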