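"""Stain thresholding, band fraction profiles, and object counting.

Fraction-positive quantification follows the fixed-width band partition of
the implant ROI; vessel-type readouts (CD31, CD31+Podo+) are object counts
per region normalised to area. Threshold methods are configurable per stain
(Otsu default); the threshold value actually used is recorded on the mask
for provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage import filters, measure

from .roi_geometry import BandMap, ROIMask

THRESHOLD_METHODS = ("otsu", "triangle", "fixed")


@dataclass
class BinaryStainMask:
    """Thresholded stain channel aligned to the ROI, with provenance."""

    mask: np.ndarray
    stain: str
    pixel_size_um: float
    method: str = "otsu"
    threshold_value: float = float("nan")

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)


def threshold_channel(
    channel: np.ndarray,
    restrict: ROIMask,
    stain: str = "",
    method: str = "otsu",
    value: float | None = None,
) -> BinaryStainMask:
    """Threshold a stain channel using only ROI pixels to set the cutoff.

    ``method`` is one of ``otsu``, ``triangle`` or ``fixed`` (the latter
    requires ``value``). The mask is positive where intensity exceeds the
    threshold; pixels outside the ROI are always negative.
    """
    img = np.asarray(channel, dtype=float)
    if img.shape != restrict.mask.shape:
        raise ValueError("channel and ROI shapes differ")
    vals = img[restrict.mask]
    if method == "fixed":
        if value is None:
            raise ValueError("fixed thresholding requires a value")
        t = float(value)
    elif method == "otsu":
        if np.ptp(vals) == 0:
            raise ValueError(f"constant intensity in ROI: Otsu undefined for {stain!r}")
        t = float(filters.threshold_otsu(vals))
    elif method == "triangle":
        if np.ptp(vals) == 0:
            raise ValueError(f"constant intensity in ROI: triangle undefined for {stain!r}")
        t = float(filters.threshold_triangle(vals))
    else:
        raise ValueError(f"unknown method {method!r}; expected one of {THRESHOLD_METHODS}")
    mask = (img > t) & restrict.mask
    return BinaryStainMask(mask, stain, restrict.pixel_size_um, method, t)


def fraction_positive(mask: BinaryStainMask | np.ndarray, region: np.ndarray) -> float:
    """Positive pixels within ``region`` divided by region pixel count."""
    m = mask.mask if isinstance(mask, BinaryStainMask) else np.asarray(mask, bool)
    region = np.asarray(region, dtype=bool)
    if m.shape != region.shape:
        raise ValueError("mask and region shapes differ")
    n = int(region.sum())
    if n == 0:
        raise ValueError("empty region")
    return float((m & region).sum()) / n


def band_profile(
    mask: BinaryStainMask, bands: BandMap, meta: dict | None = None
) -> pd.DataFrame:
    """Fraction-positive per concentric band.

    Returns one row per non-empty band with columns ``image_id, group,
    timepoint, mouse_id, replicate, stain, band, mid_depth_um,
    fraction_positive, band_area_um2`` — the record schema consumed by the
    distance-trend mixed model.
    """
    if mask.mask.shape != bands.labels.shape:
        raise ValueError("mask and band map shapes differ")
    meta = meta or {}
    n = bands.n_bands
    area_px = np.bincount(bands.labels.ravel(), minlength=n + 1)[1:]
    pos_px = np.bincount(
        bands.labels.ravel(), weights=mask.mask.ravel().astype(float), minlength=n + 1
    )[1:]
    rows = []
    for k in range(1, n + 1):
        if area_px[k - 1] == 0:
            continue
        rows.append(
            {
                "image_id": meta.get("image_id", ""),
                "group": meta.get("group", ""),
                "timepoint": meta.get("timepoint", 0),
                "mouse_id": meta.get("mouse_id", ""),
                "replicate": meta.get("replicate", 0),
                "stain": mask.stain,
                "band": k,
                "mid_depth_um": bands.mid_depth_um(k),
                "fraction_positive": float(pos_px[k - 1] / area_px[k - 1]),
                "band_area_um2": float(area_px[k - 1]) * bands.pixel_size_um**2,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class ObjectCountRecord:
    """Object count in a region with area-normalised density."""

    image_id: str
    region: str  # inner | outer | whole
    count: int
    area_um2: float
    meta: dict = field(default_factory=dict)

    @property
    def density_per_mm2(self) -> float:
        return self.count / (self.area_um2 / 1e6)

    def to_dict(self) -> dict:
        return {
            "image_id": self.image_id,
            "region": self.region,
            "count": self.count,
            "area_um2": self.area_um2,
            "density_per_mm2": self.density_per_mm2,
            **self.meta,
        }


def _labeled_objects(mask: BinaryStainMask, min_area_um2: float):
    """8-connected components with area >= min_area_um2."""
    labels = measure.label(mask.mask, connectivity=2)
    if labels.max() == 0:
        return labels, []
    px_area = mask.pixel_size_um**2
    props = [
        p for p in measure.regionprops(labels) if p.area * px_area >= min_area_um2
    ]
    return labels, props


def count_objects(
    mask: BinaryStainMask,
    region: np.ndarray,
    min_area_um2: float = 20.0,
    region_name: str = "whole",
    image_id: str = "",
    meta: dict | None = None,
) -> ObjectCountRecord:
    """Count 8-connected objects of at least ``min_area_um2`` whose centroid
    lies in ``region``; density is reported per mm^2 of the region."""
    if min_area_um2 < 0:
        raise ValueError("min_area_um2 must be >= 0")
    region = np.asarray(region, dtype=bool)
    _, props = _labeled_objects(mask, min_area_um2)
    count = 0
    for p in props:
        r, c = (int(round(x)) for x in p.centroid)
        r = min(max(r, 0), region.shape[0] - 1)
        c = min(max(c, 0), region.shape[1] - 1)
        if region[r, c]:
            count += 1
    area_um2 = float(region.sum()) * mask.pixel_size_um**2
    return ObjectCountRecord(image_id, region_name, count, area_um2, meta or {})


def colocalize_objects(
    mask_a: BinaryStainMask,
    mask_b: BinaryStainMask,
    region: np.ndarray,
    min_overlap_fraction: float = 0.25,
    min_area_um2: float = 20.0,
    region_name: str = "whole",
    image_id: str = "",
    meta: dict | None = None,
) -> ObjectCountRecord:
    """Count mask_a objects whose pixel overlap with mask_b covers at least
    ``min_overlap_fraction`` of the object's own area (double-positive
    counting, e.g. CD31+ objects that are also Podoplanin+)."""
    if mask_a.mask.shape != mask_b.mask.shape:
        raise ValueError("masks are not aligned")
    region = np.asarray(region, dtype=bool)
    labels, props = _labeled_objects(mask_a, min_area_um2)
    count = 0
    for p in props:
        obj = labels == p.label
        overlap = float((obj & mask_b.mask).sum()) / float(obj.sum())
        if overlap < min_overlap_fraction:
            continue
        r, c = (int(round(x)) for x in p.centroid)
        r = min(max(r, 0), region.shape[0] - 1)
        c = min(max(c, 0), region.shape[1] - 1)
        if region[r, c]:
            count += 1
    area_um2 = float(region.sum()) * mask_a.pixel_size_um**2
    return ObjectCountRecord(image_id, region_name, count, area_um2, meta or {})
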