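"""Core data containers: image planes/stacks and regions of interest.

Images are plain 2-D float arrays tagged with a physical pixel size in
micrometres; stacks are ordered channel collections sharing one geometry.
ROIs are boolean masks (optionally built from polygons) carrying a region
label and optional exclusion sub-regions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import tifffile
from skimage.draw import polygon as _draw_polygon


@dataclass
class ImagePlane:
    """A single-channel 2-D intensity image with physical pixel size."""

    data: np.ndarray
    pixel_size_um: float = 0.5
    name: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError(f"ImagePlane requires a 2-D array, got {self.data.ndim}-D")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def um_to_px(self, length_um: float) -> float:
        return length_um / self.pixel_size_um

    def px_area_um2(self) -> float:
        return self.pixel_size_um ** 2


class ImageStack:
    """Ordered collection of channels sharing shape and pixel size."""

    def __init__(self, channels: Mapping[str, np.ndarray], pixel_size_um: float = 0.5):
        if not channels:
            raise ValueError("ImageStack requires at least one channel")
        self.pixel_size_um = float(pixel_size_um)
        self._channels: dict[str, np.ndarray] = {}
        shape = None
        for name, arr in channels.items():
            arr = np.asarray(arr, dtype=float)
            if shape is None:
                shape = arr.shape
            elif arr.shape != shape:
                raise ValueError("all channels must share one shape")
            self._channels[name] = arr
        self.shape = shape

    @property
    def channel_names(self) -> list[str]:
        return list(self._channels)

    def __contains__(self, name: str) -> bool:
        return name in self._channels

    def __iter__(self) -> Iterator[str]:
        return iter(self._channels)

    def plane(self, name: str) -> ImagePlane:
        return ImagePlane(self._channels[name], self.pixel_size_um, name=name)

    def array(self, name: str) -> np.ndarray:
        return self._channels[name]

    def write_tiff(self, path: str) -> None:
        """Write channels as a multi-page (OME-)TIFF with channel names.

        Paths ending in ``.ome.tif(f)`` get OME-XML metadata; otherwise
        shaped-metadata JSON is used.
        """
        data = np.stack([self._channels[c] for c in self._channels]).astype(np.float32)
        if path.endswith((".ome.tif", ".ome.tiff")):
            meta = {
                "axes": "CYX",
                "Channel": {"Name": self.channel_names},
                "PhysicalSizeX": self.pixel_size_um,
                "PhysicalSizeXUnit": "µm",
                "PhysicalSizeY": self.pixel_size_um,
                "PhysicalSizeYUnit": "µm",
            }
        else:
            meta = {
                "axes": "CYX",
                "channel_names": self.channel_names,
                "pixel_size_um": self.pixel_size_um,
            }
        tifffile.imwrite(path, data, metadata=meta)

    @classmethod
    def read_tiff(cls, path: str) -> "ImageStack":
        with tifffile.TiffFile(path) as tf:
            data = tf.asarray()
            names, px = None, None
            if tf.ome_metadata:
                ome = tifffile.xml2dict(tf.ome_metadata)
                pixels = ome["OME"]["Image"]["Pixels"]
                channels = pixels.get("Channel", [])
                if isinstance(channels, dict):
                    channels = [channels]
                found = [c.get("Name") for c in channels]
                if found and all(found):
                    names = found
                px = pixels.get("PhysicalSizeX")
            elif tf.shaped_metadata:
                meta = tf.shaped_metadata[0]
                names = meta.get("channel_names")
                px = meta.get("pixel_size_um")
        if data.ndim == 2:
            data = data[None]
        names = names or [f"ch{i}" for i in range(data.shape[0])]
        return cls({n: data[i] for i, n in enumerate(names)},
                   pixel_size_um=float(px or 0.5))


def rasterize_polygon(vertices_um: Sequence[Sequence[float]], shape: tuple[int, int],
                      pixel_size_um: float) -> np.ndarray:
    """Rasterize an (x, y) μm polygon onto a pixel grid as a boolean mask."""
    verts = np.asarray(vertices_um, dtype=float) / pixel_size_um
    rr, cc = _draw_polygon(verts[:, 1], verts[:, 0], shape)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return mask


@dataclass
class RegionOfInterest:
    """A named region given as a boolean mask, minus optional exclusions."""

    label: str
    mask: np.ndarray
    exclusions: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def effective_mask(self) -> np.ndarray:
        out = self.mask.copy()
        for ex in self.exclusions:
            out &= ~np.asarray(ex, dtype=bool)
        return out

    @property
    def area_px(self) -> int:
        return int(self.effective_mask.sum())

    def is_empty(self) -> bool:
        return not self.effective_mask.any()

    @classmethod
    def full(cls, shape: tuple[int, int], label: str = "image") -> "RegionOfInterest":
        return cls(label=label, mask=np.ones(shape, dtype=bool))

    @classmethod
    def from_polygon(cls, label: str, vertices_um: Sequence[Sequence[float]],
                     shape: tuple[int, int], pixel_size_um: float,
                     exclusion_polys: Sequence[Sequence[Sequence[float]]] = ()) -> "RegionOfInterest":
        mask = rasterize_polygon(vertices_um, shape, pixel_size_um)
        exclusions = [rasterize_polygon(p, shape, pixel_size_um) for p in exclusion_polys]
        return cls(label=label, mask=mask, exclusions=exclusions)


def read_rois_geojson(path: str, shape: tuple[int, int], pixel_size_um: float) -> list[RegionOfInterest]:
    """Read polygon ROIs from a GeoJSON FeatureCollection.

    Coordinates are interpreted in micrometres. A feature property
    ``exclusion_of`` marks a polygon as an exclusion sub-region of the
    named ROI rather than an ROI of its own.
    """
    with open(path) as fh:
        gj = json.load(fh)
    rois: dict[str, RegionOfInterest] = {}
    pending_exclusions: list[tuple[str, np.ndarray]] = []
    for feat in gj.get("features", []):
        geom = feat.get("geometry", {})
        if geom.get("type") != "Polygon":
            continue
        ring = geom["coordinates"][0]
        props = feat.get("properties", {})
        mask = rasterize_polygon(ring, shape, pixel_size_um)
        if "exclusion_of" in props:
            pending_exclusions.append((props["exclusion_of"], mask))
        else:
            label = props.get("label", f"roi{len(rois)}")
            rois[label] = RegionOfInterest(label=label, mask=mask)
    for parent, mask in pending_exclusions:
        if parent in rois:
            rois[parent].exclusions.append(mask)
    return list(rois.values())


def write_rois_geojson(path: str, rois_polygons: Mapping[str, Sequence[Sequence[float]]]) -> None:
    """Write labelled μm polygons as a GeoJSON FeatureCollection."""
    features = [
        {
            "type": "Feature",
            "properties": {"label": label},
            "geometry": {"type": "Polygon", "coordinates": [[list(map(float, v)) for v in verts]]},
        }
        for label, verts in rois_polygons.items()
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
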