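"""Synthetic multichannel tissue scenes and cluster-expression matrices.

Scenes contain DAPI-stained elliptical nuclei, per-class marker channels
(somatic / membranous / nuclear / vessel-ring patterns), a target channel
whose per-cell signal sits in a perinuclear soma area (optionally polarized
to one side of the nucleus, Golgi-like), an additive diffuse neuropil level,
a control-image background, and autofluorescent puncta present identically
in all channels.  Every generated artefact is accompanied by ground truth
so parameter recovery can be asserted exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import ImagePlane, ImageStack

MARKER_PATTERNS = ("somatic", "membranous", "nuclear", "vessel_ring")

DAPI = "DAPI"
TARGET = "TARGET"

#: nominal intensity of painted nuclei; twice the default detection
#: threshold so the thresholded contour sits near the true boundary
DAPI_AMPLITUDE = 2.0


class PlacementError(RuntimeError):
    """Raised when a cell class cannot be placed without overlap."""


@dataclass(frozen=True)
class CellClassSpec:
    """One planted cell population.

    ``soma_margin_um`` is how far the soma extends beyond the nucleus; small
    margins emulate cells (microglia-like) whose soma hugs the nucleus so
    that a fixed nucleus expansion overshoots into neighbouring cells.
    """

    name: str
    marker_channel: str
    marker_pattern: str
    true_target_mean: float
    count: int
    soma_margin_um: float = 2.0
    ring_offset_um: float = 0.0

    def __post_init__(self) -> None:
        if self.marker_pattern not in MARKER_PATTERNS:
            raise ValueError(f"unknown marker_pattern {self.marker_pattern!r}")
        if self.true_target_mean < 0:
            raise ValueError("true_target_mean must be >= 0")
        if self.count < 0:
            raise ValueError("count must be >= 0")
        if self.soma_margin_um <= 0:
            raise ValueError("soma_margin_um must be > 0")


@dataclass(frozen=True)
class OverlapSpec:
    """Place a fraction of one class's cells overlapping a host class.

    ``depth_um`` is how far the planted nucleus dips inside the host soma
    boundary; the host class must be listed before the overlapping class so
    the latter's soma wins the contested pixels.
    """

    class_name: str
    host_class: str
    fraction: float
    depth_um: float = 1.0


@dataclass
class TissueSimConfig:
    cell_classes: Sequence[CellClassSpec]
    image_size_px: tuple[int, int] = (512, 512)
    pixel_size_um: float = 0.5
    nucleus_area_um2_range: tuple[float, float] = (20.0, 60.0)
    diffuse_level: float = 0.0
    control_background: float = 0.0
    puncta_count: int = 0
    golgi_polarized: bool = False
    noise_frac: float = 0.02
    seed: int = 0
    overlaps: Sequence[OverlapSpec] = field(default_factory=tuple)
    max_aspect: float = 1.6
    puncta_amplitude: float = 5.0

    def __post_init__(self) -> None:
        lo, hi = self.nucleus_area_um2_range
        if not (0 < lo < hi):
            raise ValueError("nucleus_area_um2_range must satisfy 0 < min < max")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        for val, name in [(self.diffuse_level, "diffuse_level"),
                          (self.control_background, "control_background"),
                          (self.noise_frac, "noise_frac")]:
            if val < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.puncta_count < 0:
            raise ValueError("puncta_count must be >= 0")
        names = [c.name for c in self.cell_classes]
        if len(set(names)) != len(names):
            raise ValueError("cell class names must be unique")

    @property
    def channel_names(self) -> list[str]:
        markers: list[str] = []
        for c in self.cell_classes:
            if c.marker_channel not in markers:
                markers.append(c.marker_channel)
        return [DAPI, *markers, TARGET]


# ---------------------------------------------------------------- geometry

def _ellipse_patch(center_rc: tuple[float, float], semi_r: float, semi_c: float,
                   shape: tuple[int, int]):
    """Boolean ellipse on a local patch; returns (row slice, col slice, patch)."""
    r0, c0 = center_rc
    rmin = max(int(math.floor(r0 - semi_r)) - 1, 0)
    rmax = min(int(math.ceil(r0 + semi_r)) + 2, shape[0])
    cmin = max(int(math.floor(c0 - semi_c)) - 1, 0)
    cmax = min(int(math.ceil(c0 + semi_c)) + 2, shape[1])
    if rmin >= rmax or cmin >= cmax:
        return slice(0, 0), slice(0, 0), np.zeros((0, 0), dtype=bool)
    rr = np.arange(rmin, rmax)[:, None]
    cc = np.arange(cmin, cmax)[None, :]
    patch = ((rr - r0) / semi_r) ** 2 + ((cc - c0) / semi_c) ** 2 <= 1.0
    return slice(rmin, rmax), slice(cmin, cmax), patch


def _directional_radius(semi_r: float, semi_c: float, d_r: float, d_c: float) -> float:
    """Radius of an axis-aligned ellipse along a unit direction."""
    return 1.0 / math.sqrt((d_r / semi_r) ** 2 + (d_c / semi_c) ** 2)


@dataclass
class _Cell:
    cell_id: int
    spec: CellClassSpec
    center_rc: tuple[float, float]        # pixels
    nuc_semi_rc: tuple[float, float]      # pixels
    soma_semi_rc: tuple[float, float]     # pixels
    nucleus_area_um2: float


# ---------------------------------------------------------------- placement

def _place_cells(config: TissueSimConfig, rng: np.random.Generator) -> list[_Cell]:
    h, w = config.image_size_px
    px = config.pixel_size_um
    occupancy = np.zeros((h, w), dtype=bool)   # somas placed so far
    cells: list[_Cell] = []
    by_class: dict[str, list[_Cell]] = {}
    overlap_by_class = {o.class_name: o for o in config.overlaps}
    cell_id = 0
    for spec in config.cell_classes:
        ospec = overlap_by_class.get(spec.name)
        n_overlap = int(round(ospec.fraction * spec.count)) if ospec else 0
        for i in range(spec.count):
            area = rng.uniform(*config.nucleus_area_um2_range)
            aspect = rng.uniform(1.0, config.max_aspect)
            semi_a = math.sqrt(area * aspect / math.pi)      # μm, long axis
            semi_b = semi_a / aspect
            if rng.random() < 0.5:
                semi_a, semi_b = semi_b, semi_a
            nuc_semi = (semi_a / px, semi_b / px)
            margin = spec.soma_margin_um
            soma_semi = ((semi_a + margin) / px, (semi_b + margin) / px)
            want_overlap = ospec is not None and i < n_overlap
            placed = False
            for _ in range(500):
                if want_overlap:
                    hosts = by_class.get(ospec.host_class)
                    if not hosts:
                        raise PlacementError(
                            f"overlap host class {ospec.host_class!r} has no placed cells")
                    host = hosts[rng.integers(len(hosts))]
                    theta = rng.uniform(0, 2 * math.pi)
                    d_r, d_c = math.sin(theta), math.cos(theta)
                    host_r = _directional_radius(*host.soma_semi_rc, d_r, d_c)
                    own_r = _directional_radius(*nuc_semi, -d_r, -d_c)
                    dist = host_r + own_r - ospec.depth_um / px
                    center = (host.center_rc[0] + d_r * dist,
                              host.center_rc[1] + d_c * dist)
                    if not (soma_semi[0] < center[0] < h - soma_semi[0] - 1
                            and soma_semi[1] < center[1] < w - soma_semi[1] - 1):
                        continue
                    # tolerate overlap with the chosen host only
                    sl_r, sl_c, patch = _ellipse_patch(center, *soma_semi, (h, w))
                    hsl_r, hsl_c, hpatch = _ellipse_patch(host.center_rc,
                                                          *host.soma_semi_rc, (h, w))
                    occ = occupancy.copy()
                    occ[hsl_r, hsl_c] &= ~hpatch
                    if occ[sl_r, sl_c][patch].any():
                        continue
                else:
                    center = (rng.uniform(soma_semi[0] + 1, h - soma_semi[0] - 2),
                              rng.uniform(soma_semi[1] + 1, w - soma_semi[1] - 2))
                    sl_r, sl_c, patch = _ellipse_patch(center, soma_semi[0] + 1,
                                                       soma_semi[1] + 1, (h, w))
                    if occupancy[sl_r, sl_c][patch].any():
                        continue
                sl_r, sl_c, patch = _ellipse_patch(center, *soma_semi, (h, w))
                occupancy[sl_r, sl_c] |= patch
                cell = _Cell(cell_id, spec, center, nuc_semi, soma_semi, area)
                cells.append(cell)
                by_class.setdefault(spec.name, []).append(cell)
                cell_id += 1
                placed = True
                break
            if not placed:
                raise PlacementError(
                    f"could not place cell {i} of class {spec.name!r}: scene too dense")
    return cells


# ---------------------------------------------------------------- painting

def _paint_noise(clean: np.ndarray, noise_frac: float, rng: np.random.Generator) -> np.ndarray:
    if noise_frac == 0:
        return clean
    noisy = clean + rng.standard_normal(clean.shape) * (noise_frac * clean)
    return np.clip(noisy, 0.0, None)


def _place_puncta(config: TissueSimConfig, rng: np.random.Generator) -> list[tuple[int, int]]:
    h, w = config.image_size_px
    centers: list[tuple[int, int]] = []
    for _ in range(config.puncta_count):
        for _ in range(500):
            r = int(rng.integers(3, h - 3))
            c = int(rng.integers(3, w - 3))
            if all((r - pr) ** 2 + (c - pc) ** 2 > 36 for pr, pc in centers):
                centers.append((r, c))
                break
        else:
            raise PlacementError("could not place puncta with separation")
    return centers


def _add_puncta(arr: np.ndarray, centers: Sequence[tuple[int, int]], amplitude: float) -> None:
    for r, c in centers:
        sl_r, sl_c, patch = _ellipse_patch((r, c), 1.5, 1.5, arr.shape)
        arr[sl_r, sl_c][patch] += amplitude


def generate_tissue_image(config: TissueSimConfig):
    """Generate a multichannel scene.

    Returns ``(stack, ground_truth, masks)`` where ``ground_truth`` is a
    per-cell table (image-level truth in ``.attrs``) and ``masks`` holds the
    nucleus/soma label grids, per-channel ideal positive masks, and the
    label → class map — the raw material for annotations and oracles.
    """
    rng = np.random.default_rng([config.seed, 0])
    h, w = config.image_size_px
    px = config.pixel_size_um
    cells = _place_cells(config, rng)

    nuclei_lbl = np.zeros((h, w), dtype=np.int32)
    soma_lbl = np.zeros((h, w), dtype=np.int32)
    signal = np.zeros((h, w), dtype=float)
    channel_masks: dict[str, np.ndarray] = {
        c.marker_channel: np.zeros((h, w), dtype=bool) for c in config.cell_classes
    }
    label_class: dict[int, str] = {}

    for cell in cells:
        lbl = cell.cell_id + 1
        label_class[lbl] = cell.spec.name
        sl_r, sl_c, nuc = _ellipse_patch(cell.center_rc, *cell.nuc_semi_rc, (h, w))
        nuclei_lbl[sl_r, sl_c][nuc] = lbl
        sl_r, sl_c, soma = _ellipse_patch(cell.center_rc, *cell.soma_semi_rc, (h, w))
        soma_lbl[sl_r, sl_c][soma] = lbl

        pattern = cell.spec.marker_pattern
        mmask = channel_masks[cell.spec.marker_channel]
        if pattern == "somatic":
            mmask[sl_r, sl_c] |= soma
        elif pattern == "nuclear":
            nsl_r, nsl_c, nuc2 = _ellipse_patch(cell.center_rc, *cell.nuc_semi_rc, (h, w))
            mmask[nsl_r, nsl_c] |= nuc2
        elif pattern == "membranous":
            shrink = 0.8 / px
            isl_r, isl_c, inner = _ellipse_patch(
                cell.center_rc, max(cell.soma_semi_rc[0] - shrink, 0.5),
                max(cell.soma_semi_rc[1] - shrink, 0.5), (h, w))
            ring = np.zeros((h, w), dtype=bool)
            ring[sl_r, sl_c] |= soma
            ring[isl_r, isl_c] &= ~inner
            mmask |= ring
        elif pattern == "vessel_ring":
            lumen_r = 2.5 / px
            r_in = lumen_r + cell.spec.ring_offset_um / px
            r_out = r_in + 1.5 / px
            osl_r, osl_c, outer = _ellipse_patch(cell.center_rc, r_out, r_out, (h, w))
            isl_r, isl_c, inner = _ellipse_patch(cell.center_rc, r_in, r_in, (h, w))
            ring = np.zeros((h, w), dtype=bool)
            ring[osl_r, osl_c] |= outer
            ring[isl_r, isl_c] &= ~inner
            mmask |= ring

        # target signal painted on the soma; later cells win contested pixels
        if cell.spec.true_target_mean > 0:
            if config.golgi_polarized:
                blob = _polarized_blob(cell, config, rng, (h, w))
                region = np.zeros((h, w), dtype=bool)
                region[sl_r, sl_c] = soma
                vals = blob[region]
                mean = vals.mean() if vals.size else 0.0
                if mean > 0:
                    blob *= cell.spec.true_target_mean / mean
                signal[region] = blob[region]
            else:
                signal[sl_r, sl_c][soma] = cell.spec.true_target_mean

    base = config.control_background + config.diffuse_level
    target = base + signal

    dapi = np.zeros((h, w), dtype=float)
    dapi[nuclei_lbl > 0] = DAPI_AMPLITUDE

    marker_arrays = {name: mask.astype(float) for name, mask in channel_masks.items()}

    puncta = _place_puncta(config, rng)
    planes: dict[str, np.ndarray] = {DAPI: dapi, **marker_arrays, TARGET: target}
    for name in planes:
        _add_puncta(planes[name], puncta, config.puncta_amplitude)
    for name in planes:
        planes[name] = _paint_noise(planes[name], config.noise_frac, rng)

    stack = ImageStack({n: planes[n] for n in config.channel_names}, pixel_size_um=px)

    gt = pd.DataFrame(
        {
            "cell_id": [c.cell_id + 1 for c in cells],
            "class_name": [c.spec.name for c in cells],
            "centroid_x_um": [c.center_rc[1] * px for c in cells],
            "centroid_y_um": [c.center_rc[0] * px for c in cells],
            "nucleus_area_um2": [c.nucleus_area_um2 for c in cells],
            "true_target_mean": [c.spec.true_target_mean for c in cells],
        }
    )
    gt.attrs.update(
        diffuse_level=config.diffuse_level,
        control_background=config.control_background,
        seed=config.seed,
        puncta=puncta,
    )
    masks = {
        "nuclei": nuclei_lbl,
        "somas": soma_lbl,
        "channel_masks": channel_masks,
        "label_class": label_class,
    }
    return stack, gt, masks


def _polarized_blob(cell: _Cell, config: TissueSimConfig, rng: np.random.Generator,
                    shape: tuple[int, int]) -> np.ndarray:
    """Gaussian blob (σ 1.5 μm) offset 1–2 μm beyond the nucleus edge."""
    px = config.pixel_size_um
    theta = rng.uniform(0, 2 * math.pi)
    d_r, d_c = math.sin(theta), math.cos(theta)
    nuc_r = _directional_radius(*cell.nuc_semi_rc, d_r, d_c)
    offset = nuc_r + rng.uniform(1.0, 2.0) / px
    b_r = cell.center_rc[0] + d_r * offset
    b_c = cell.center_rc[1] + d_c * offset
    sigma = 1.5 / px
    rr = np.arange(shape[0])[:, None]
    cc = np.arange(shape[1])[None, :]
    return np.exp(-(((rr - b_r) ** 2 + (cc - b_c) ** 2) / (2 * sigma ** 2)))


def generate_control_image(config: TissueSimConfig) -> ImagePlane:
    """Control section: background plus puncta only, same noise model."""
    rng = np.random.default_rng([config.seed, 1])
    h, w = config.image_size_px
    arr = np.full((h, w), float(config.control_background))
    puncta = _place_puncta(config, rng)
    _add_puncta(arr, puncta, config.puncta_amplitude)
    arr = _paint_noise(arr, config.noise_frac, rng)
    return ImagePlane(arr, config.pixel_size_um, name="control")


def annotation_mask_for_channel(masks: Mapping, channel: str, erode_px: int = 3) -> np.ndarray:
    """Two-class training annotation for a marker channel.

    Label 1 samples background (complement eroded to keep away from the
    boundary), label 2 samples the ideal positive area.
    """
    from scipy import ndimage as ndi

    pos = masks["channel_masks"][channel]
    bg = ~ndi.binary_dilation(pos, iterations=erode_px)
    ann = np.zeros(pos.shape, dtype=np.int32)
    ann[bg] = 1
    ann[pos] = 2
    return ann


def annotation_mask_high_low(masks: Mapping, erode_px: int = 3) -> np.ndarray:
    """Two-class annotation for target high/low partitioning (2 = high)."""
    from scipy import ndimage as ndi

    high = masks["somas"] > 0
    low = ~ndi.binary_dilation(high, iterations=erode_px)
    ann = np.zeros(high.shape, dtype=np.int32)
    ann[low] = 1
    ann[high] = 2
    return ann


# ------------------------------------------------------------- expression

@dataclass
class ClusterSimConfig:
    n_clusters_per_class: Mapping[str, int]
    class_mean_expression: Mapping[str, float]
    marker_rulebook: Mapping[str, Sequence[str]]
    noise_sd: float = 0.0
    seed: int = 0
    query_gene: str = "query_gene"
    marker_high: float = 1.0
    marker_low: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for cls in self.class_mean_expression:
            if self.n_clusters_per_class.get(cls, 0) < 1:
                raise ValueError(f"class {cls!r} needs >= 1 cluster")
            if not self.marker_rulebook.get(cls):
                raise ValueError(f"class {cls!r} has no marker genes")
            if self.class_mean_expression[cls] < 0:
                raise ValueError("class mean expression must be >= 0")


def generate_cluster_matrix(config: ClusterSimConfig):
    """Clusters × genes mean-expression table with planted class labels.

    Each cluster expresses its own class's canonical markers at
    ``marker_high``, foreign markers at ``marker_low``, and the query gene
    at the class mean plus Gaussian noise.
    """
    rng = np.random.default_rng([config.seed, 2])
    genes: list[str] = []
    for cls, markers in config.marker_rulebook.items():
        for g in markers:
            if g not in genes:
                genes.append(g)
    if config.query_gene not in genes:
        genes.append(config.query_gene)

    rows, labels, names = [], [], []
    for cls in config.class_mean_expression:
        markers = set(config.marker_rulebook[cls])
        for i in range(config.n_clusters_per_class[cls]):
            row = {g: (config.marker_high if g in markers else config.marker_low)
                   for g in genes}
            row[config.query_gene] = (config.class_mean_expression[cls]
                                      + rng.normal(0.0, config.noise_sd))
            rows.append(row)
            labels.append(cls)
            names.append(f"{cls}_{i}")
    matrix = pd.DataFrame(rows, index=names, columns=genes)
    truth = pd.Series(labels, index=names, name="true_class")
    return matrix, truth
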