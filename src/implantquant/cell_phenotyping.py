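"""Spot-based multi-marker cell phenotyping.

Re-specifies the commercial spots-and-surfaces workflow as an open,
deterministic cascade:

1. detect point signals per channel (Laplacian-of-Gaussian peaks with
   subpixel refinement) — DAPI spots stand in for individual cells;
2. deduplicate DAPI spots greedily by intensity so kept spots are farther
   apart than a minimum separation (default 8 um, the scale used to
   distinguish adjacent nuclei);
3. classify cells by proximity rules: within a strict ``< max_dist`` of a
   marker spot (8 um for CD68/iNOS/Arg1/CD3e/CD4 cascades) or within
   ``<= max_dist`` of a thresholded surface (2 um for the TE-7 fibroblast
   rule). Rules compose by flag intersection, giving the subclass hierarchy
   M1 <= macrophage <= cells and T-helper <= T cell <= cells.

All nearest-neighbour queries agree exactly with an all-pairs brute-force
computation; a KD-tree only accelerates them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial import cKDTree

from .image import MultiplexImage
from .intensity_quant import BinaryStainMask, threshold_channel
from .roi_geometry import ROIMask


@dataclass
class SpotSet:
    """Point detections for one channel, positions in um (image frame)."""

    x: np.ndarray
    y: np.ndarray
    intensity: np.ndarray
    channel: str = ""

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if not (self.x.shape == self.y.shape == self.intensity.shape):
            raise ValueError("x, y, intensity must have equal length")

    def __len__(self) -> int:
        return self.x.size

    @property
    def xy(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])

    def select(self, keep: np.ndarray) -> "SpotSet":
        return SpotSet(self.x[keep], self.y[keep], self.intensity[keep], self.channel)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"x_um": self.x, "y_um": self.y, "channel": self.channel,
             "intensity": self.intensity}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, channel: str | None = None) -> "SpotSet":
        if channel is not None:
            df = df[df["channel"] == channel]
        name = channel if channel is not None else (
            df["channel"].iloc[0] if len(df) else "")
        return cls(df["x_um"].to_numpy(), df["y_um"].to_numpy(),
                   df["intensity"].to_numpy(), name)


@dataclass
class ProximityRule:
    """Distance rule classifying a cell by a marker channel."""

    target: str
    max_dist_um: float
    mode: str = "spot_to_spot"  # or "spot_to_surface"

    def __post_init__(self) -> None:
        if self.max_dist_um < 0:
            raise ValueError("max_dist_um must be >= 0")
        if self.mode not in ("spot_to_spot", "spot_to_surface"):
            raise ValueError(f"unknown mode {self.mode!r}")


def detect_spots(
    channel: np.ndarray,
    pixel_size_um: float,
    sigma_um: float = 3.0,
    min_prominence: float = 0.1,
) -> SpotSet:
    """Detect blob-like signals as Laplacian-of-Gaussian peaks.

    The LoG response is scale-normalised at the nuclear scale ``sigma_um``;
    local maxima above ``min_prominence`` (in response units, roughly the
    blob peak amplitude) are kept and refined to subpixel positions by a
    quadratic fit around each peak. Positions are um coordinates of pixel
    centres, i.e. pixel (r, c) maps to ((c + 0.5) * px, (r + 0.5) * px).
    """
    if sigma_um <= 0 or min_prominence <= 0:
        raise ValueError("sigma_um and min_prominence must be positive")
    img = np.asarray(channel, dtype=float)
    s = sigma_um / pixel_size_um
    # -sigma^2 * LoG gives a positive, amplitude-preserving blob response.
    resp = -(s**2) * ndi.gaussian_laplace(img, s)
    # local maxima over a neighbourhood about one blob radius wide
    size = max(3, int(round(s)) * 2 + 1)
    maxed = ndi.maximum_filter(resp, size=size, mode="nearest")
    # response of an ideal unit-peak Gaussian blob is peak/2, so rescale the
    # prominence cut to blob-amplitude units
    peaks = (resp >= maxed) & (resp > min_prominence / 2)
    rows, cols = np.nonzero(peaks)
    if rows.size == 0:
        return SpotSet(np.empty(0), np.empty(0), np.empty(0), "")
    # subpixel quadratic refinement along each axis
    dr = np.zeros(rows.size)
    dc = np.zeros(rows.size)
    H, W = resp.shape
    for i, (r, c) in enumerate(zip(rows, cols)):
        if 0 < r < H - 1:
            a, b, cc = resp[r - 1, c], resp[r, c], resp[r + 1, c]
            den = a - 2 * b + cc
            if den < 0:
                dr[i] = np.clip(0.5 * (a - cc) / den, -0.5, 0.5)
        if 0 < c < W - 1:
            a, b, cc = resp[r, c - 1], resp[r, c], resp[r, c + 1]
            den = a - 2 * b + cc
            if den < 0:
                dc[i] = np.clip(0.5 * (a - cc) / den, -0.5, 0.5)
    x = (cols + dc + 0.5) * pixel_size_um
    y = (rows + dr + 0.5) * pixel_size_um
    inten = img[rows, cols]
    return SpotSet(x, y, inten, "")


def deduplicate_spots(spots: SpotSet, min_sep_um: float = 8.0) -> SpotSet:
    """Greedy deduplication: visit spots in decreasing intensity (ties broken
    by (x, y) lexicographic order) and keep a spot iff it lies at least
    ``min_sep_um`` from every spot already kept.

    The output is therefore independent of input order, and every pairwise
    distance among kept spots is >= ``min_sep_um``.
    """
    if min_sep_um < 0:
        raise ValueError("min_sep_um must be >= 0")
    n = len(spots)
    if n == 0 or min_sep_um == 0:
        return spots
    order = np.lexsort((spots.y, spots.x, -spots.intensity))
    xy = spots.xy[order]
    kept_idx: list[int] = []
    kept_xy = np.empty((n, 2))
    for i in range(n):
        if kept_idx:
            d2 = np.sum((kept_xy[: len(kept_idx)] - xy[i]) ** 2, axis=1)
            if d2.min() < min_sep_um**2:
                continue
        kept_xy[len(kept_idx)] = xy[i]
        kept_idx.append(i)
    keep = np.sort(order[kept_idx])
    return spots.select(keep)


def nearest_marker_distance(cells: SpotSet, markers: SpotSet) -> np.ndarray:
    """Distance from each cell to its nearest marker spot (inf if none).

    KD-tree accelerated; exact (equals the all-pairs minimum)."""
    if len(markers) == 0:
        return np.full(len(cells), np.inf)
    if len(cells) == 0:
        return np.empty(0)
    tree = cKDTree(markers.xy)
    d, _ = tree.query(cells.xy)
    return np.asarray(d, dtype=float)


def assign_by_proximity(
    cells: SpotSet, markers: SpotSet, max_dist_um: float
) -> np.ndarray:
    """Flag each cell iff its nearest marker spot lies strictly closer than
    ``max_dist_um`` (strict ``<``, so a marker exactly at the cutoff does not
    flag). Compose rules by intersecting the returned boolean flags."""
    if max_dist_um < 0:
        raise ValueError("max_dist_um must be >= 0")
    return nearest_marker_distance(cells, markers) < max_dist_um


def surface_distance(cells: SpotSet, surface_mask: BinaryStainMask) -> np.ndarray:
    """Distance (um) from each cell position to the surface region.

    The surface is the union of positive pixel squares, so the distance is 0
    for a cell anywhere on a positive pixel and equals the Euclidean
    point-to-square distance otherwise. A KD-tree over pixel centres
    prefilters candidates; the reported minimum is exact.
    """
    if len(cells) == 0:
        return np.empty(0)
    if not surface_mask.mask.any():
        return np.full(len(cells), np.inf)
    px = surface_mask.pixel_size_um
    rows, cols = np.nonzero(surface_mask.mask)
    centres = np.column_stack([(cols + 0.5) * px, (rows + 0.5) * px])
    tree = cKDTree(centres)
    d_centre, _ = tree.query(cells.xy)
    out = np.empty(len(cells))
    half = 0.5 * px
    for i, (pt, dc) in enumerate(zip(cells.xy, d_centre)):
        # the true nearest square has centre within dc + half*sqrt(2)
        cand = tree.query_ball_point(pt, dc + half * np.sqrt(2.0) + 1e-9)
        dx = np.maximum(np.abs(centres[cand, 0] - pt[0]) - half, 0.0)
        dy = np.maximum(np.abs(centres[cand, 1] - pt[1]) - half, 0.0)
        out[i] = np.sqrt(dx**2 + dy**2).min()
    return out


def assign_by_surface(
    cells: SpotSet, surface_mask: BinaryStainMask, max_dist_um: float = 2.0
) -> np.ndarray:
    """Flag each cell iff it lies within ``max_dist_um`` (inclusive ``<=``)
    of the surface — the rule used for the TE-7 fibroblast call."""
    if max_dist_um < 0:
        raise ValueError("max_dist_um must be >= 0")
    return surface_distance(cells, surface_mask) <= max_dist_um


def ki67_fraction(cells: SpotSet, ki67: SpotSet, max_dist_um: float = 4.0) -> float:
    """Fraction of cells whose nearest Ki67 spot is within ``max_dist_um``
    (inclusive; the proliferating-cell call requires near overlap)."""
    if len(cells) == 0:
        raise ValueError("no cells to score")
    return float(np.mean(nearest_marker_distance(cells, ki67) <= max_dist_um))


@dataclass
class PhenotypeCounts:
    """Per-image cell population table derived from the rule cascade."""

    image_id: str
    n_cells: int
    n_macrophage: int
    n_m1: int
    n_m2: int
    n_tcell: int
    n_thelper: int
    n_fibroblast: int
    n_ki67: int
    implant_area_mm2: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.n_m1 <= self.n_macrophage <= self.n_cells):
            raise ValueError("require M1 <= macrophage <= cells")
        if not (self.n_m2 <= self.n_macrophage):
            raise ValueError("require M2 <= macrophage")
        if not (self.n_thelper <= self.n_tcell <= self.n_cells):
            raise ValueError("require T-helper <= T cell <= cells")

    def fractions(self) -> dict[str, float]:
        n = max(self.n_cells, 1)
        return {
            "macrophage": self.n_macrophage / n,
            "m1": self.n_m1 / n,
            "m2": self.n_m2 / n,
            "tcell": self.n_tcell / n,
            "thelper": self.n_thelper / n,
            "fibroblast": self.n_fibroblast / n,
            "ki67": self.n_ki67 / n,
        }

    def densities_per_mm2(self) -> dict[str, float]:
        a = self.implant_area_mm2
        return {
            "cells": self.n_cells / a,
            "macrophage": self.n_macrophage / a,
            "m1": self.n_m1 / a,
            "m2": self.n_m2 / a,
            "tcell": self.n_tcell / a,
            "thelper": self.n_thelper / a,
            "fibroblast": self.n_fibroblast / a,
            "ki67": self.n_ki67 / a,
        }

    def to_dict(self) -> dict:
        row = {
            "image_id": self.image_id,
            "n_cells": self.n_cells,
            "n_macrophage": self.n_macrophage,
            "n_m1": self.n_m1,
            "n_m2": self.n_m2,
            "n_tcell": self.n_tcell,
            "n_thelper": self.n_thelper,
            "n_fibroblast": self.n_fibroblast,
            "n_ki67": self.n_ki67,
            "implant_area_mm2": self.implant_area_mm2,
        }
        row.update({f"frac_{k}": v for k, v in self.fractions().items()})
        row.update({f"density_{k}": v for k, v in self.densities_per_mm2().items()})
        row.update(self.meta)
        return row


DEFAULT_RULES: dict = {
    "spot_sep_um": 8.0,
    "marker_dist_um": 8.0,
    "surface_dist_um": 2.0,
    "ki67_dist_um": 4.0,
    "sigma_um": 3.0,
    "min_prominence": 0.3,
    "surface_threshold": "otsu",
}


def phenotype_image(
    image: MultiplexImage, roi: ROIMask, rules: dict | None = None
) -> PhenotypeCounts:
    """Run the full phenotyping cascade on one multiplex image.

    DAPI spots are detected, deduplicated and restricted to the ROI; marker
    channels (CD68, iNOS, Arg1, CD3e, CD4, Ki67) provide proximity flags and
    the TE7 channel provides the surface rule. Missing channels raise
    ``KeyError`` naming the channel. Counts, fractions of total cells and
    densities per implant area are reported together.
    """
    cfg = dict(DEFAULT_RULES)
    if rules:
        cfg.update(rules)
    px = image.pixel_size_um
    for ch in ("DAPI", "CD68", "iNOS", "Arg1", "CD3e", "CD4", "TE7", "Ki67"):
        if ch not in image.channels:
            raise KeyError(f"required channel {ch!r} missing from image")

    def spots(ch: str) -> SpotSet:
        s = detect_spots(image.channel(ch), px, cfg["sigma_um"], cfg["min_prominence"])
        s.channel = ch
        return s

    cells = deduplicate_spots(spots("DAPI"), cfg["spot_sep_um"])
    # keep only cells inside the implant ROI
    rows = np.clip((cells.y / px - 0.5).round().astype(int), 0, roi.mask.shape[0] - 1)
    cols = np.clip((cells.x / px - 0.5).round().astype(int), 0, roi.mask.shape[1] - 1)
    cells = cells.select(roi.mask[rows, cols])

    d = cfg["marker_dist_um"]
    mac = assign_by_proximity(cells, spots("CD68"), d)
    m1 = mac & assign_by_proximity(cells, spots("iNOS"), d)
    m2 = mac & assign_by_proximity(cells, spots("Arg1"), d)
    tc = assign_by_proximity(cells, spots("CD3e"), d)
    th = tc & assign_by_proximity(cells, spots("CD4"), d)
    te7_mask = threshold_channel(
        image.channel("TE7"), roi, stain="TE7", method=cfg["surface_threshold"]
    )
    fib = assign_by_surface(cells, te7_mask, cfg["surface_dist_um"])
    ki = nearest_marker_distance(cells, spots("Ki67")) <= cfg["ki67_dist_um"]

    return PhenotypeCounts(
        image_id=str(image.meta.get("image_id", "")),
        n_cells=len(cells),
        n_macrophage=int(mac.sum()),
        n_m1=int(m1.sum()),
        n_m2=int(m2.sum()),
        n_tcell=int(tc.sum()),
        n_thelper=int(th.sum()),
        n_fibroblast=int(fib.sum()),
        n_ki67=int(ki.sum()),
        implant_area_mm2=roi.area_mm2,
        meta=dict(image.meta),
    )
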