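"""Per-cell multiplex quantification on perinuclear discs.

Cells are detected on the DAPI plane (median → Gaussian → opening-by-
reconstruction background subtraction → threshold → shape watershed → area
filter), nuclei are expanded by a fixed physical distance into
non-overlapping "discs", discs are classified per marker by seeded pixel
classifiers evaluated at the disc centroid, disc means on the target
channel are corrected by the per-ROI median of a classified 'low-target'
area, normalized by the per-ROI upper quartile of DAPI+ disc intensities,
filtered by region/marker exclusion rules, and summarized per subject ×
region × marker.

An alternative detection mode segments cells directly from an
intensely-somatic marker channel (IBA1-like) without expansion, avoiding
contamination from overlapping neighbour somas.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.morphology import (disk, local_maxima, reconstruction,
                                remove_small_holes, remove_small_objects)
from skimage.segmentation import expand_labels, watershed
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler

from .core import ImagePlane, RegionOfInterest

FEATURE_NAMES = ("gaussian", "laplacian_of_gaussian", "gradient_magnitude",
                 "hessian_determinant", "weighted_std")

BACKGROUND_CLASS = 1


@dataclass
class DetectionParams:
    """Cell-detection operator chain parameters (physical units)."""

    pixel_resolution_um: float = 0.5
    background_radius_um: float = 8.0
    opening_by_reconstruction: bool = True
    median_radius_um: float = 1.5
    gaussian_sigma_um: float = 1.6
    min_area_um2: float = 10.0
    max_area_um2: float = 100.0
    intensity_threshold: float = 1.0
    split_by_shape: bool = True
    smooth_boundaries: bool = True
    expansion_um: float = 2.0
    maxima_merge_px: int = 5

    def __post_init__(self) -> None:
        for name in ("pixel_resolution_um", "background_radius_um",
                     "median_radius_um", "gaussian_sigma_um", "expansion_um"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0 < self.min_area_um2 < self.max_area_um2):
            raise ValueError("require 0 < min_area_um2 < max_area_um2")


@dataclass
class ClassifierConfig:
    """Feature bank and model spec for a seeded pixel classifier."""

    features: Sequence[str] = ("gaussian", "laplacian_of_gaussian", "gradient_magnitude")
    scales_um: Sequence[float] = (0.5, 1.0, 2.0, 4.0)
    local_normalization_scale_um: float | None = None
    hidden_layer_sizes: Sequence[int] = (16,)
    seed: int = 0
    max_samples_per_class: int = 20000
    min_object_um2: float = 10.0
    min_hole_um2: float = 20.0
    max_iter: int = 300

    def __post_init__(self) -> None:
        if not self.features:
            raise ValueError("at least one feature is required")
        unknown = set(self.features) - set(FEATURE_NAMES)
        if unknown:
            raise ValueError(f"unknown features: {sorted(unknown)}")
        scales = list(self.scales_um)
        if scales != sorted(scales) or len(set(scales)) != len(scales):
            raise ValueError("scales must be strictly increasing")
        if self.local_normalization_scale_um is not None and self.local_normalization_scale_um <= 0:
            raise ValueError("local_normalization_scale_um must be > 0")


@dataclass
class FeatureStack:
    """(n_features, H, W) feature grids plus provenance."""

    data: np.ndarray
    names: list[str]
    pixel_size_um: float


#: wide truncation keeps derivative kernels near-exact on flat regions
_TRUNCATE = 6.0


def _single_feature(img: np.ndarray, feature: str, sigma: float) -> np.ndarray:
    if feature == "gaussian":
        return ndi.gaussian_filter(img, sigma, truncate=_TRUNCATE)
    if feature == "laplacian_of_gaussian":
        return ndi.gaussian_laplace(img, sigma, truncate=_TRUNCATE)
    if feature == "gradient_magnitude":
        return ndi.gaussian_gradient_magnitude(img, sigma, truncate=_TRUNCATE)
    if feature == "hessian_determinant":
        h_rr = ndi.gaussian_filter(img, sigma, order=(2, 0), truncate=_TRUNCATE)
        h_cc = ndi.gaussian_filter(img, sigma, order=(0, 2), truncate=_TRUNCATE)
        h_rc = ndi.gaussian_filter(img, sigma, order=(1, 1), truncate=_TRUNCATE)
        return h_rr * h_cc - h_rc ** 2
    if feature == "weighted_std":
        mean = ndi.gaussian_filter(img, sigma, truncate=_TRUNCATE)
        sq_mean = ndi.gaussian_filter(img ** 2, sigma, truncate=_TRUNCATE)
        return np.sqrt(np.clip(sq_mean - mean ** 2, 0.0, None))
    raise ValueError(f"unknown feature {feature!r}")


def compute_features(plane: ImagePlane, cfg: ClassifierConfig) -> FeatureStack:
    """One grid per (feature, scale), optionally locally normalized first."""
    px = plane.pixel_size_um
    img = plane.data.astype(float)
    max_extent_um = max(plane.shape) * px
    for s in cfg.scales_um:
        if s / px > max(plane.shape):
            raise ValueError(f"scale {s} μm exceeds image extent {max_extent_um} μm")
    if cfg.local_normalization_scale_um is not None:
        img = img - ndi.gaussian_filter(img, cfg.local_normalization_scale_um / px)
    grids, names = [], []
    for feature in cfg.features:
        for s in cfg.scales_um:
            grids.append(_single_feature(img, feature, s / px))
            names.append(f"{feature}@{s}um")
    return FeatureStack(np.stack(grids), names, px)


@dataclass
class PixelClassifier:
    """Seeded feed-forward pixel classifier over a fixed feature bank."""

    scaler: StandardScaler
    model: MLPClassifier
    cfg: ClassifierConfig
    classes: np.ndarray
    training_accuracy: float

    def predict(self, features: FeatureStack) -> np.ndarray:
        flat = features.data.reshape(len(features.names), -1).T
        pred = self.model.predict(self.scaler.transform(flat))
        return pred.reshape(features.data.shape[1:]).astype(np.int32)


def train_pixel_classifier(features: FeatureStack, annotations: np.ndarray,
                           cfg: ClassifierConfig) -> PixelClassifier:
    """Train a seeded classifier on sparse pixel annotations (0 = unlabeled)."""
    ann = np.asarray(annotations)
    if ann.shape != features.data.shape[1:]:
        raise ValueError("annotation shape must match feature grids")
    classes = np.unique(ann[ann > 0])
    if classes.size < 2:
        raise ValueError("annotations must contain >= 2 classes")
    rng = np.random.default_rng(cfg.seed)
    rows, labels = [], []
    flat_feat = features.data.reshape(len(features.names), -1).T
    flat_ann = ann.ravel()
    for c in classes:
        idx = np.flatnonzero(flat_ann == c)
        if idx.size > cfg.max_samples_per_class:
            idx = rng.choice(idx, cfg.max_samples_per_class, replace=False)
        rows.append(flat_feat[idx])
        labels.append(np.full(idx.size, c))
    x = np.concatenate(rows)
    y = np.concatenate(labels)
    scaler = StandardScaler().fit(x)
    model = MLPClassifier(hidden_layer_sizes=tuple(cfg.hidden_layer_sizes),
                          random_state=cfg.seed, max_iter=cfg.max_iter)
    xs = scaler.transform(x)
    model.fit(xs, y)
    acc = float(model.score(xs, y))
    return PixelClassifier(scaler=scaler, model=model, cfg=cfg,
                           classes=classes, training_accuracy=acc)


def cleanup_mask(mask: np.ndarray, min_object_um2: float, min_hole_um2: float,
                 pixel_size_um: float) -> np.ndarray:
    """Remove positive components smaller than ``min_object_um2`` and fill
    holes smaller than ``min_hole_um2`` (both strict)."""
    px_area = pixel_size_um ** 2
    min_obj = int(round(min_object_um2 / px_area))
    min_hole = int(round(min_hole_um2 / px_area))
    mask = np.asarray(mask, dtype=bool)
    if min_obj > 1:
        # removes components with area < min_obj (max_size is inclusive)
        mask = remove_small_objects(mask, max_size=min_obj - 1)
    if min_hole > 1:
        mask = remove_small_holes(mask, max_size=min_hole - 1)
    return mask


def classify_pixels(model: PixelClassifier, features: FeatureStack) -> np.ndarray:
    """Argmax-posterior label grid with min-object / min-hole cleanup.

    Class 1 is background by convention; every other class mask has
    components below ``min_object_um2`` removed and holes below
    ``min_hole_um2`` filled.
    """
    labels = model.predict(features)
    out = np.full(labels.shape, BACKGROUND_CLASS, dtype=np.int32)
    for c in model.classes:
        if c == BACKGROUND_CLASS:
            continue
        mask = cleanup_mask(labels == c, model.cfg.min_object_um2,
                            model.cfg.min_hole_um2, features.pixel_size_um)
        out[mask] = c
    return out


def positive_mask(label_grid: np.ndarray, positive_class: int = 2) -> np.ndarray:
    return label_grid == positive_class


# ---------------------------------------------------------------- detection

def detect_cells(plane: ImagePlane, params: DetectionParams | None = None,
                 within: np.ndarray | None = None) -> np.ndarray:
    """Detect individual cells (nuclei) on an intensity plane.

    Chain: median filter → Gaussian smoothing → background subtraction by
    morphological opening-by-reconstruction → fixed intensity threshold →
    optional shape-based watershed split → inclusive area filter in μm² →
    optional boundary smoothing.  Detection is restricted to ``within``
    when given; an empty ``within`` yields zero detections.
    """
    params = params or DetectionParams()
    px = plane.pixel_size_um
    img = plane.data.astype(float)
    if within is not None and not np.asarray(within, dtype=bool).any():
        return np.zeros(img.shape, dtype=np.int32)

    med_r = max(int(round(params.median_radius_um / px)), 1)
    img = ndi.median_filter(img, footprint=disk(med_r))
    img = ndi.gaussian_filter(img, params.gaussian_sigma_um / px)
    if params.opening_by_reconstruction:
        bg_r = max(int(round(params.background_radius_um / px)), 1)
        seed = ndi.grey_erosion(img, footprint=disk(bg_r))
        background = reconstruction(seed, img, method="dilation")
        img = img - background
    binary = img > params.intensity_threshold
    if within is not None:
        binary &= np.asarray(within, dtype=bool)
    if params.smooth_boundaries and binary.any():
        st = disk(1)
        binary = ndi.binary_opening(ndi.binary_closing(binary, structure=st),
                                    structure=st)
    if not binary.any():
        return np.zeros(binary.shape, dtype=np.int32)
    if params.split_by_shape:
        distance = ndi.distance_transform_edt(binary)
        maxima = local_maxima(distance) & binary
        if params.maxima_merge_px > 0:
            maxima = ndi.binary_dilation(maxima, structure=disk(params.maxima_merge_px)) & binary
        markers, _ = ndi.label(maxima)
        labels = watershed(-distance, markers, mask=binary)
    else:
        labels, _ = ndi.label(binary)
    px_area = px ** 2
    ids, areas = np.unique(labels[labels > 0], return_counts=True)
    areas_um2 = areas * px_area
    keep = ids[(areas_um2 >= params.min_area_um2) & (areas_um2 <= params.max_area_um2)]
    out = np.zeros(labels.shape, dtype=np.int32)
    for new_id, old_id in enumerate(keep, start=1):
        out[labels == old_id] = new_id
    return out


def detect_cells_iba1(iba1_plane: ImagePlane, params: DetectionParams,
                      iba1_mask: np.ndarray) -> np.ndarray:
    """Detect cells from intense somatic staining itself (no DAPI).

    Detection runs within the classified positive-staining mask and the
    resulting label grid is the measurement area — it is not expanded.
    """
    return detect_cells(iba1_plane, params, within=iba1_mask)


def expand_to_discs(nuclei: np.ndarray, expansion_um: float,
                    pixel_size_um: float,
                    roi_mask: np.ndarray | None = None) -> np.ndarray:
    """Expand nucleus labels by a physical distance into disjoint discs.

    Contested pixels go to the nearest nucleus (Voronoi-constrained
    growth); discs are clipped at image and ROI borders.
    """
    if expansion_um < 0:
        raise ValueError("expansion_um must be >= 0")
    discs = expand_labels(nuclei, distance=expansion_um / pixel_size_um)
    if roi_mask is not None:
        discs = np.where(np.asarray(roi_mask, dtype=bool), discs, 0)
        discs[nuclei > 0] = nuclei[nuclei > 0]  # a disc always keeps its nucleus
    return discs


# ---------------------------------------------------------------- records

def measure_discs(target: ImagePlane, discs: np.ndarray, *, subject_id: str = "s1",
                  region: str = "region", source: str = "DAPI") -> pd.DataFrame:
    """Per-disc raw target means, centroids and areas as a records table."""
    ids = np.unique(discs[discs > 0])
    if ids.size == 0:
        return pd.DataFrame(columns=["disc_id", "subject_id", "region", "source",
                                     "centroid_r", "centroid_c", "area_px", "raw_mean"])
    means = ndi.mean(target.data, labels=discs, index=ids)
    centroids = ndi.center_of_mass(np.ones_like(discs), labels=discs, index=ids)
    areas = ndi.sum_labels(np.ones_like(discs), labels=discs, index=ids)
    return pd.DataFrame(
        {
            "disc_id": ids,
            "subject_id": subject_id,
            "region": region,
            "source": source,
            "centroid_r": [c[0] for c in centroids],
            "centroid_c": [c[1] for c in centroids],
            "area_px": areas.astype(int),
            "raw_mean": means,
        }
    )


def classify_discs(records: pd.DataFrame,
                   marker_masks: Mapping[str, np.ndarray]) -> pd.DataFrame:
    """Flag each disc positive for each marker by its centroid pixel.

    Flags are independent per marker; ``marker`` names the single positive
    marker for single-positive discs and is ``None`` otherwise;
    ``n_positive`` counts positive flags.
    """
    out = records.copy()
    rows = np.clip(np.rint(out["centroid_r"]).astype(int), 0, None)
    cols = np.clip(np.rint(out["centroid_c"]).astype(int), 0, None)
    for marker, mask in marker_masks.items():
        mask = np.asarray(mask, dtype=bool)
        if (rows >= mask.shape[0]).any() or (cols >= mask.shape[1]).any():
            raise RuntimeError("disc centroid outside image")
        out[f"pos_{marker}"] = mask[rows, cols]
    flag_cols = [f"pos_{m}" for m in marker_masks]
    out["n_positive"] = out[flag_cols].sum(axis=1).astype(int)
    single = out["n_positive"] == 1
    markers = list(marker_masks)
    marker_of = out[flag_cols].to_numpy().argmax(axis=1)
    out["marker"] = [markers[i] if s else None for i, s in zip(marker_of, single)]
    return out


class UncorrectableROIError(ValueError):
    """Raised when the 'low target' class is empty inside an ROI."""


def diffuse_correction(target: ImagePlane, roi: RegionOfInterest,
                       low_mask: np.ndarray,
                       records: pd.DataFrame) -> tuple[float, pd.DataFrame]:
    """Subtract the ROI's median 'low target' intensity from disc means.

    ``low_mask`` is the classified diffuse/absent-staining area.  Corrected
    means may be negative; they are reported, not clipped.
    """
    mask = roi.effective_mask & np.asarray(low_mask, dtype=bool)
    if not mask.any():
        raise UncorrectableROIError(f"ROI {roi.label!r} has no 'low target' area")
    low_median = float(np.median(target.data[mask]))
    out = records.copy()
    out["corrected_mean"] = out["raw_mean"] - low_median
    return low_median, out


def normalize_upper_quartile(records: pd.DataFrame) -> tuple[float, pd.DataFrame]:
    """Divide corrected means by the ROI's DAPI+ upper-quartile intensity.

    The denominator is the 75th percentile (linear interpolation) of
    corrected means over DAPI-derived discs only; alternative-detection
    discs are normalized by the same DAPI-based denominator.
    """
    dapi = records[records["source"] == "DAPI"]
    if len(dapi) < 4:
        raise ValueError("need >= 4 DAPI-derived discs to normalize")
    q3 = float(np.percentile(dapi["corrected_mean"], 75))
    if q3 <= 0:
        raise ValueError("degenerate ROI: upper quartile <= 0")
    out = records.copy()
    out["normalized"] = out["corrected_mean"] / q3
    return q3, out


def apply_exclusions(records: pd.DataFrame,
                     rules: Mapping[str, Sequence[str]] | None = None,
                     drop_multi_positive: bool = True) -> tuple[pd.DataFrame, dict]:
    """Remove discs matching (region → excluded markers) rules.

    Also removes multi-positive discs from the summary set.  Returns the
    filtered records and removal counts per rule.
    """
    rules = rules or {}
    known = {c[4:] for c in records.columns if c.startswith("pos_")}
    counts: dict[str, int] = {}
    keep = pd.Series(True, index=records.index)
    for region, markers in rules.items():
        for marker in markers:
            if marker not in known:
                raise ValueError(f"exclusion rule names unknown marker {marker!r}")
            hit = (records["region"] == region) & records[f"pos_{marker}"]
            counts[f"{region}:{marker}"] = int(hit.sum())
            keep &= ~hit
    if drop_multi_positive:
        multi = records["n_positive"] > 1
        counts["multi_positive"] = int((multi & keep).sum())
        keep &= ~multi
    return records[keep].copy(), counts


def summarize(records: pd.DataFrame, value: str = "normalized") -> pd.DataFrame:
    """Mean (and SEM) of disc intensities per subject × region × marker.

    Only single-positive discs contribute; empty classes yield no row.
    """
    single = records[records["marker"].notna()]
    if single.empty:
        return pd.DataFrame(columns=["subject_id", "region", "marker",
                                     "mean", "n_discs", "sem"])
    grouped = single.groupby(["subject_id", "region", "marker"], observed=True)[value]
    out = grouped.agg(mean="mean", n_discs="size", sem="sem").reset_index()
    return out


# ---------------------------------------------------------------- driver

@dataclass
class PanelConfig:
    """Channel naming plus per-marker classifier configs for one scene."""

    target_channel: str = "TARGET"
    dapi_channel: str = "DAPI"
    marker_configs: Mapping[str, ClassifierConfig] = field(default_factory=dict)
    highlow_config: ClassifierConfig = field(default_factory=lambda: ClassifierConfig(
        features=("gaussian", "laplacian_of_gaussian", "weighted_std"),
        scales_um=(0.5, 1.0, 2.0, 4.0, 8.0),
        local_normalization_scale_um=32.0,
    ))
    detection: DetectionParams = field(default_factory=DetectionParams)
    iba1_channel: str | None = None
    iba1_detection: DetectionParams | None = None
    exclusion_rules: Mapping[str, Sequence[str]] = field(default_factory=dict)


def run_pipeline(stack, *, panel: PanelConfig,
                 marker_annotations: Mapping[str, np.ndarray],
                 highlow_annotation: np.ndarray,
                 roi: RegionOfInterest | None = None,
                 subject_id: str = "s1", region: str = "region"):
    """End-to-end per-cell quantification of one scene/ROI.

    Returns ``(records, info)`` where ``info`` carries the trained models,
    masks and intermediate label grids for inspection.
    """
    px = stack.pixel_size_um
    roi = roi or RegionOfInterest.full(stack.shape)
    target = stack.plane(panel.target_channel)

    nuclei = detect_cells(stack.plane(panel.dapi_channel), panel.detection,
                          within=roi.effective_mask)
    discs = expand_to_discs(nuclei, panel.detection.expansion_um, px,
                            roi_mask=roi.effective_mask)

    marker_masks: dict[str, np.ndarray] = {}
    models: dict[str, PixelClassifier] = {}
    for marker, ann in marker_annotations.items():
        cfg = panel.marker_configs.get(marker, ClassifierConfig())
        feats = compute_features(stack.plane(marker), cfg)
        model = train_pixel_classifier(feats, ann, cfg)
        marker_masks[marker] = positive_mask(classify_pixels(model, feats))
        models[marker] = model

    records = measure_discs(target, discs, subject_id=subject_id, region=region)
    records = classify_discs(records, marker_masks)

    hl_feats = compute_features(target, panel.highlow_config)
    hl_model = train_pixel_classifier(hl_feats, highlow_annotation, panel.highlow_config)
    hl_labels = classify_pixels(hl_model, hl_feats)
    low_mask = hl_labels == BACKGROUND_CLASS

    if panel.iba1_channel is not None:
        det = panel.iba1_detection or panel.detection
        iba1_labels = detect_cells_iba1(stack.plane(panel.iba1_channel), det,
                                        marker_masks[panel.iba1_channel])
        iba1_records = measure_discs(target, iba1_labels, subject_id=subject_id,
                                     region=region, source="IBA1")
        iba1_records = classify_discs(iba1_records, marker_masks)
        records = pd.concat([records, iba1_records], ignore_index=True)

    low_median, records = diffuse_correction(target, roi, low_mask, records)
    q3, records = normalize_upper_quartile(records)
    all_records = records
    records, removal_counts = apply_exclusions(records, panel.exclusion_rules)

    info = {
        "all_records": all_records,
        "nuclei": nuclei,
        "discs": discs,
        "marker_masks": marker_masks,
        "models": models,
        "highlow_model": hl_model,
        "low_mask": low_mask,
        "low_median": low_median,
        "upper_quartile": q3,
        "removal_counts": removal_counts,
    }
    return records, info
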