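"""Synthetic implant scenes with known ground truth.

Generates the three data streams the quantification pipeline consumes, each
with complete ground truth so that every downstream stage can be checked by
parameter recovery:

* **Scaffolds** — hard-disk packings of ~70 um hydrogel microparticles, a
  configurable fraction of which carry heparin (the "heparin uisland"
  subpopulation, 10% by default).
* **Cells** — an inhomogeneous point process inside the implant ROI whose
  intensity is linear in depth from the implant edge, emulating the radial
  infiltration gradients seen in sections; each cell gets a phenotype label
  and conditional marker flags. A hard-core minimum spacing (default 9 um,
  about one nuclear diameter in packed tissue) keeps nuclei resolvable.
* **Caliper series** — implant length/width/height trajectories with a
  configured volume decay (default 55% loss by 12 months) and multiplicative
  lognormal noise.

Rendering places a Gaussian blob (sigma 3 um, nuclear scale) per cell into
the DAPI channel and per marker flag into the marker channels, with optional
positional jitter between a cell and its marker signal, plus a uniform
in-ROI fill on DAPI (dim unresolved signal of tightly packed tissue) and
additive Gaussian noise. Everything is bit-reproducible given the config
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import measure

from .image import MultiplexImage
from .roi_geometry import ROIMask

#: marker -> {phenotype class -> P(marker | class)}; missing entries are 0.
DEFAULT_MARKER_PROBS: dict[str, dict[str, float]] = {
    "CD68": {"macrophage": 1.0},
    "iNOS": {"macrophage": 0.5},
    "Arg1": {"macrophage": 0.4},
    "CD3e": {"tcell": 1.0},
    "CD4": {"tcell": 0.6},
    "TE7": {"fibroblast": 1.0},
    "Ki67": {"macrophage": 0.2, "tcell": 0.2, "fibroblast": 0.2,
             "endothelial": 0.2, "other": 0.2},
    "CD31": {"endothelial": 1.0},
    "Podo": {"endothelial": 0.5},
}

DEFAULT_CLASS_FRACTIONS: dict[str, float] = {
    "macrophage": 0.30,
    "tcell": 0.15,
    "fibroblast": 0.20,
    "endothelial": 0.05,
    # remainder (0.30) is the unlabeled "other" class
}

#: (mean, sd) particle diameter in um per formulation
DEFAULT_PARTICLE_SIZE_UM: dict[str, tuple[float, float]] = {
    "heparin": (69.7, 2.25),
    "no_heparin": (68.8, 1.87),
}


@dataclass
class SceneConfig:
    """Parameters of one synthetic implant section."""

    image_size_px: tuple[int, int] = (768, 768)
    pixel_size_um: float = 2.0
    roi_shape: dict = field(
        default_factory=lambda: {"kind": "disk", "radius_um": 600.0}
    )
    formulation: str = "heparin"
    particle_size_um: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_PARTICLE_SIZE_UM)
    )
    heparin_fraction: float = 0.10
    n_particles: int = 100
    cell_density_intercept: float = 1000.0  # cells/mm^2 at the ROI edge
    cell_density_slope: float = -1.0  # cells/mm^2 per um of depth
    min_spacing_um: float = 9.0  # hard-core nuclear spacing
    marker_probs: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_MARKER_PROBS.items()}
    )
    class_fractions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_FRACTIONS)
    )
    marker_offset_sd_um: float = 0.5
    blob_sigma_um: float = 3.0
    background_level: float = 0.1
    signal_level: float = 1.0
    roi_fill_level: float = 0.15  # added inside the ROI on DAPI only
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if not 0 <= self.heparin_fraction <= 1:
            raise ValueError("heparin_fraction must be in [0, 1]")
        for name, (_, sd) in self.particle_size_um.items():
            if sd < 0:
                raise ValueError(f"negative diameter sd for {name!r}")
        total = sum(self.class_fractions.values())
        if any(not 0 <= f <= 1 for f in self.class_fractions.values()) or total > 1 + 1e-9:
            raise ValueError("class_fractions must lie in [0,1] and sum to <= 1")
        for marker, by_class in self.marker_probs.items():
            for cls, p in by_class.items():
                if not 0 <= p <= 1:
                    raise ValueError(f"marker_probs[{marker}][{cls}] outside [0,1]")

    @property
    def markers(self) -> list[str]:
        return list(self.marker_probs)


@dataclass
class ParticleSet:
    """Packed microparticles: centres and diameters in um, heparin flags."""

    centers_um: np.ndarray  # (n, 2) as (x, y)
    diameters_um: np.ndarray
    heparin: np.ndarray  # bool flags

    def __len__(self) -> int:
        return self.diameters_um.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x_um": self.centers_um[:, 0],
                "y_um": self.centers_um[:, 1],
                "diameter_um": self.diameters_um,
                "heparin": self.heparin,
            }
        )


@dataclass
class GroundTruth:
    """True synthetic cell table: positions, depths, labels, marker flags."""

    table: pd.DataFrame  # x_um, y_um, depth_um, phenotype, flag_<marker>...
    roi: ROIMask

    def __len__(self) -> int:
        return len(self.table)

    def positions(self) -> np.ndarray:
        return self.table[["x_um", "y_um"]].to_numpy()

    def flags(self, marker: str) -> np.ndarray:
        return self.table[f"flag_{marker}"].to_numpy(dtype=bool)

    def class_fraction(self, phenotype: str) -> float:
        if len(self.table) == 0:
            return 0.0
        return float((self.table["phenotype"] == phenotype).mean())

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


def make_roi_mask(config: SceneConfig) -> ROIMask:
    """Build the true implant ROI mask for a scene (disk, ellipse or blob)."""
    h, w = config.image_size_px
    px = config.pixel_size_um
    yy, xx = np.mgrid[0:h, 0:w]
    cx, cy = (w / 2) * px, (h / 2) * px
    x_um = (xx + 0.5) * px
    y_um = (yy + 0.5) * px
    shape = config.roi_shape
    kind = shape.get("kind", "disk")
    if kind == "disk":
        r = float(shape["radius_um"])
        mask = (x_um - cx) ** 2 + (y_um - cy) ** 2 <= r**2
    elif kind == "ellipse":
        a = float(shape["semi_axis_x_um"])
        b = float(shape["semi_axis_y_um"])
        mask = ((x_um - cx) / a) ** 2 + ((y_um - cy) / b) ** 2 <= 1.0
    elif kind == "blob":
        # smoothed noise thresholded and masked to a disk envelope, then the
        # largest component hole-filled: an irregular but simply connected ROI
        rng = np.random.default_rng(shape.get("seed", config.seed))
        noise = ndi.gaussian_filter(rng.standard_normal((h, w)),
                                    shape.get("smooth_px", 40))
        r = float(shape.get("radius_um", min(cx, cy) * 0.8))
        envelope = (x_um - cx) ** 2 + (y_um - cy) ** 2 <= r**2
        mask = (noise > np.quantile(noise[envelope], 0.3)) & envelope
        lab = measure.label(mask)
        if lab.max() == 0:
            raise ValueError("blob ROI came out empty; change the blob seed")
        mask = lab == (np.argmax(np.bincount(lab.ravel())[1:]) + 1)
        mask = ndi.binary_fill_holes(mask)
    else:
        raise ValueError(f"unknown roi_shape kind {kind!r}")
    if not mask.any():
        raise ValueError("ROI does not fit in the image")
    return ROIMask(mask, px)


def sample_diameters(
    n: int, mean_um: float, sd_um: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw particle diameters from a normal truncated at > 0 (resampling)."""
    d = rng.normal(mean_um, sd_um, size=n)
    while (bad := d <= 0).any():
        d[bad] = rng.normal(mean_um, sd_um, size=int(bad.sum()))
    return d


def generate_scaffold(
    config: SceneConfig,
    roi: ROIMask | None = None,
    overlap_tol: float = 0.0,
    max_attempts_per_particle: int = 200,
) -> ParticleSet:
    """Pack microparticles into the ROI by random sequential addition.

    Diameters are truncated-normal draws from the configured formulation;
    centres are rejected when the particle would cross the ROI edge or
    overlap an accepted particle by more than ``overlap_tol`` (hard disks by
    default). Exactly ``round(n * heparin_fraction)`` particles are flagged
    as heparin-containing. Raises ``RuntimeError`` naming the achieved count
    when packing stalls.
    """
    rng = np.random.default_rng(config.seed)
    roi = roi or make_roi_mask(config)
    mean, sd = config.particle_size_um[config.formulation]
    n = config.n_particles
    diam = sample_diameters(n, mean, sd, rng)
    depth = roi.depth_map()
    inside_rows, inside_cols = np.nonzero(roi.mask)
    px = roi.pixel_size_um
    centers = np.empty((n, 2))
    placed = 0
    attempts = 0
    budget = max_attempts_per_particle * n
    while placed < n and attempts < budget:
        attempts += 1
        i = rng.integers(inside_rows.size)
        jitter = rng.uniform(0, 1, size=2)
        x = (inside_cols[i] + jitter[0]) * px
        y = (inside_rows[i] + jitter[1]) * px
        r = diam[placed] / 2
        # whole particle inside ROI: depth at centre must exceed its radius
        if depth[inside_rows[i], inside_cols[i]] < r:
            continue
        if placed:
            d = np.hypot(centers[:placed, 0] - x, centers[:placed, 1] - y)
            min_allowed = (diam[:placed] / 2 + r) * (1 - overlap_tol)
            if (d < min_allowed).any():
                continue
        centers[placed] = (x, y)
        placed += 1
    if placed < n:
        density = placed * np.pi * (mean / 2) ** 2 / roi.area_um2
        raise RuntimeError(
            f"packing stalled at {placed}/{n} particles "
            f"(achieved packing density {density:.2f}); enlarge the ROI or "
            f"reduce n_particles"
        )
    n_hep = int(round(n * config.heparin_fraction))
    heparin = np.zeros(n, dtype=bool)
    heparin[rng.choice(n, size=n_hep, replace=False)] = True
    return ParticleSet(centers, diam, heparin)


def generate_cells(config: SceneConfig, roi: ROIMask | None = None) -> GroundTruth:
    """Place synthetic cells by a depth-dependent point process.

    The local intensity (cells/mm^2) is ``intercept + slope * depth_um``;
    a negative intensity anywhere inside the ROI is an error. The total
    count is Poisson with the integrated intensity, positions are drawn
    proportionally to the local intensity, and a hard-core thinning enforces
    ``min_spacing_um`` between kept cells (first-come in draw order).
    Phenotype labels follow ``class_fractions`` (remainder = "other") and
    marker flags are Bernoulli draws from ``marker_probs`` given the label.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    roi = roi or make_roi_mask(config)
    px = roi.pixel_size_um
    depth = roi.depth_map()
    lam = config.cell_density_intercept + config.cell_density_slope * depth
    lam[~roi.mask] = 0.0
    if (lam[roi.mask] < 0).any():
        raise ValueError(
            "cell density goes negative inside the ROI; "
            "check intercept/slope against the maximum depth"
        )
    px_area_mm2 = (px / 1000.0) ** 2
    total = float(lam[roi.mask].sum() * px_area_mm2)
    n = int(rng.poisson(total))
    rows, cols = np.nonzero(roi.mask)
    weights = lam[rows, cols]
    wsum = weights.sum()
    if n > 0 and wsum > 0:
        idx = rng.choice(rows.size, size=n, p=weights / wsum)
        jit = rng.uniform(0, 1, size=(n, 2))
        xs = (cols[idx] + jit[:, 0]) * px
        ys = (rows[idx] + jit[:, 1]) * px
    else:
        idx = np.empty(0, dtype=int)
        xs = np.empty(0)
        ys = np.empty(0)
    # hard-core thinning in draw order
    if config.min_spacing_um > 0 and n > 1:
        keep_mask = np.zeros(n, dtype=bool)
        kept = np.empty((n, 2))
        k = 0
        min2 = config.min_spacing_um**2
        for i in range(n):
            if k:
                d2 = np.sum((kept[:k] - (xs[i], ys[i])) ** 2, axis=1)
                if d2.min() < min2:
                    continue
            kept[k] = (xs[i], ys[i])
            keep_mask[i] = True
            k += 1
        idx, xs, ys = idx[keep_mask], xs[keep_mask], ys[keep_mask]
        n = k
    depths = depth[rows[idx], cols[idx]] if n else np.empty(0)

    classes = list(config.class_fractions)
    probs = np.array([config.class_fractions[c] for c in classes])
    other = 1.0 - probs.sum()
    labels = rng.choice(classes + ["other"], size=n,
                        p=np.append(probs, max(other, 0.0)))
    data = {"x_um": xs, "y_um": ys, "depth_um": depths, "phenotype": labels}
    for marker, by_class in config.marker_probs.items():
        p = np.array([by_class.get(c, 0.0) for c in labels])
        data[f"flag_{marker}"] = rng.uniform(size=n) < p
    return GroundTruth(pd.DataFrame(data), roi)


def _splat(canvas: np.ndarray, xs: np.ndarray, ys: np.ndarray,
           mass: float, px: float) -> None:
    """Add point masses at subpixel positions by bilinear splatting."""
    if xs.size == 0:
        return
    H, W = canvas.shape
    cx = xs / px - 0.5
    cy = ys / px - 0.5
    c0 = np.floor(cx).astype(int)
    r0 = np.floor(cy).astype(int)
    fx = cx - c0
    fy = cy - r0
    for dr, dc, w in (
        (0, 0, (1 - fy) * (1 - fx)),
        (0, 1, (1 - fy) * fx),
        (1, 0, fy * (1 - fx)),
        (1, 1, fy * fx),
    ):
        r = r0 + dr
        c = c0 + dc
        ok = (r >= 0) & (r < H) & (c >= 0) & (c < W)
        np.add.at(canvas, (r[ok], c[ok]), mass * w[ok])


def render_scene(
    truth: GroundTruth,
    config: SceneConfig,
    particles: ParticleSet | None = None,
    meta: dict | None = None,
) -> MultiplexImage:
    """Render the scene as one aligned channel per marker plus DAPI.

    Each cell contributes a 2D Gaussian blob of peak ``signal_level`` at its
    position; marker channels render only flagged cells, jittered by
    ``marker_offset_sd_um``. DAPI additionally receives ``roi_fill_level``
    inside the ROI (unresolved signal of tightly packed tissue). Additive
    Gaussian read noise of sd ``noise_sd`` tops a flat ``background_level``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    h, w = config.image_size_px
    px = config.pixel_size_um
    sigma_px = config.blob_sigma_um / px
    # a splat of this mass, Gaussian-filtered, peaks at signal_level
    mass = config.signal_level * 2 * np.pi * sigma_px**2
    xs = truth.table["x_um"].to_numpy()
    ys = truth.table["y_um"].to_numpy()
    channels: dict[str, np.ndarray] = {}

    def finish(canvas: np.ndarray, fill: np.ndarray | None = None) -> np.ndarray:
        img = ndi.gaussian_filter(canvas, sigma_px)
        img += config.background_level
        if fill is not None:
            img += fill
        img += rng.normal(0, config.noise_sd, size=canvas.shape)
        return img.astype(np.float32)

    dapi = np.zeros((h, w))
    _splat(dapi, xs, ys, mass, px)
    roi_fill = config.roi_fill_level * truth.roi.mask.astype(float)
    channels["DAPI"] = finish(dapi, roi_fill)

    for marker in config.markers:
        canvas = np.zeros((h, w))
        flagged = truth.flags(marker)
        mx = xs[flagged]
        my = ys[flagged]
        if config.marker_offset_sd_um > 0 and mx.size:
            mx = mx + rng.normal(0, config.marker_offset_sd_um, mx.size)
            my = my + rng.normal(0, config.marker_offset_sd_um, my.size)
        _splat(canvas, mx, my, mass, px)
        channels[marker] = finish(canvas)
    base_meta = {"pixel_size_um": px, "seed": config.seed}
    if meta:
        base_meta.update(meta)
    return MultiplexImage(channels, px, base_meta)


def measure_particles(particles: ParticleSet, pixel_size_um: float = 1.0) -> pd.DataFrame:
    """Rasterize particles as disks and size them by connected components.

    Each particle becomes a filled disk on a shared canvas; the objects are
    labelled and reported as equivalent-circle diameters, mirroring an
    automated well-scan sizing macro. If two rasterized particles touch and
    merge, an error names the offending pair.
    """
    n = len(particles)
    if n == 0:
        return pd.DataFrame(columns=["particle", "diameter_um"])
    px = pixel_size_um
    r = particles.diameters_um / 2
    margin = r.max() + 2 * px
    x0 = particles.centers_um[:, 0].min() - margin
    y0 = particles.centers_um[:, 1].min() - margin
    W = int(np.ceil((particles.centers_um[:, 0].max() + margin - x0) / px)) + 1
    H = int(np.ceil((particles.centers_um[:, 1].max() + margin - y0) / px)) + 1
    canvas = np.zeros((H, W), dtype=bool)
    for (cx, cy), ri in zip(particles.centers_um, r):
        c0 = int((cx - x0 - ri) / px) - 1
        r0 = int((cy - y0 - ri) / px) - 1
        c1 = int((cx - x0 + ri) / px) + 2
        r1 = int((cy - y0 + ri) / px) + 2
        yy, xx = np.mgrid[max(r0, 0):min(r1, H), max(c0, 0):min(c1, W)]
        xum = x0 + (xx + 0.5) * px
        yum = y0 + (yy + 0.5) * px
        canvas[max(r0, 0):min(r1, H), max(c0, 0):min(c1, W)] |= (
            (xum - cx) ** 2 + (yum - cy) ** 2 <= ri**2
        )
    labels = measure.label(canvas, connectivity=2)
    n_obj = labels.max()
    if n_obj != n:
        # identify a merged pair for the error message
        cc = ((particles.centers_um[:, 0] - x0) / px - 0.5).round().astype(int)
        rr = ((particles.centers_um[:, 1] - y0) / px - 0.5).round().astype(int)
        owner = labels[np.clip(rr, 0, H - 1), np.clip(cc, 0, W - 1)]
        for lab in range(1, n_obj + 1):
            members = np.nonzero(owner == lab)[0]
            if members.size > 1:
                raise ValueError(
                    f"particles {members[0]} and {members[1]} merged when "
                    f"rasterized; reduce pixel size or spread the particles"
                )
        raise ValueError(
            f"expected {n} rasterized objects, found {n_obj}"
        )
    props = measure.regionprops(labels)
    diam = np.array([p.equivalent_diameter_area for p in props]) * px
    return pd.DataFrame({"particle": np.arange(n_obj), "diameter_um": diam})


def grid_particles(diameters_um: np.ndarray, pitch_um: float | None = None) -> ParticleSet:
    """Lay particles out on a square grid (guaranteed non-overlapping), for
    sizing experiments that need no realistic packing."""
    d = np.asarray(diameters_um, dtype=float)
    n = d.size
    if n == 0:
        return ParticleSet(np.empty((0, 2)), d, np.zeros(0, dtype=bool))
    pitch = pitch_um if pitch_um is not None else d.max() + 10.0
    side = int(np.ceil(np.sqrt(n)))
    ii = np.arange(n)
    centers = np.column_stack([(ii % side + 0.5) * pitch, (ii // side + 0.5) * pitch])
    return ParticleSet(centers, d, np.zeros(n, dtype=bool))


def simulate_band_records(
    slopes: dict[tuple[str, object], float],
    intercepts: dict[tuple[str, object], float] | None = None,
    n_mice_per_group: int = 3,
    n_replicates: int = 3,
    n_bands: int = 10,
    band_width_um: float = 100.0,
    mouse_sd: float = 0.02,
    replicate_sd: float = 0.01,
    residual_sd: float = 0.02,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate band fraction records from the distance-trend model itself.

    ``slopes`` maps (group, timepoint) -> true distance slope (fraction/um);
    the response is intercept + slope * mid_depth + mouse intercept +
    replicate intercept + residual noise. Used for parameter-recovery and
    CI-coverage experiments on the mixed model, independent of the imaging
    stages.
    """
    rng = np.random.default_rng(seed)
    intercepts = intercepts or {}
    groups = sorted({g for g, _ in slopes})
    timepoints = sorted({t for _, t in slopes})
    depths = (np.arange(n_bands) + 0.5) * band_width_um
    rows = []
    for g in groups:
        for m in range(n_mice_per_group):
            mouse_id = f"{g}_m{m}"
            u_mouse = rng.normal(0, mouse_sd)
            for t in timepoints:
                for r in range(n_replicates):
                    image_id = f"{mouse_id}_t{t}_r{r}"
                    u_rep = rng.normal(0, replicate_sd)
                    eps = rng.normal(0, residual_sd, size=n_bands)
                    mu = intercepts.get((g, t), 0.5) + slopes[(g, t)] * depths
                    y = mu + u_mouse + u_rep + eps
                    for b in range(n_bands):
                        rows.append(
                            {
                                "image_id": image_id,
                                "group": g,
                                "timepoint": t,
                                "mouse_id": mouse_id,
                                "replicate": r,
                                "stain": "DAPI",
                                "band": b + 1,
                                "mid_depth_um": depths[b],
                                "fraction_positive": y[b],
                                "band_area_um2": band_width_um**2,
                            }
                        )
    return pd.DataFrame(rows)


@dataclass
class CaliperSeriesConfig:
    """Parameters of a synthetic caliper measurement series."""

    n_implants: int = 6
    group: str = "Hep"
    timepoints: tuple = (0, 1, 3, 6, 12)  # months
    volume_fold_by_time: dict = field(
        default_factory=lambda: {0: 1.0, 1: 0.90, 3: 0.80, 6: 0.65, 12: 0.45}
    )
    height_fold_by_time: dict = field(
        default_factory=lambda: {0: 1.0, 1: 1.00, 3: 0.85, 6: 0.70, 12: 0.55}
    )
    baseline_lwh_mm: tuple = (8.0, 8.0, 3.0)
    baseline_cv: float = 0.05
    noise_cv: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if 0 not in self.timepoints:
            raise ValueError("timepoint 0 (implantation) must be present")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        for t, f in {**self.volume_fold_by_time, **self.height_fold_by_time}.items():
            if f <= 0:
                raise ValueError(f"fold at month {t} must be positive")


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative lognormal noise with mean exactly 1 and the given CV."""
    if cv == 0:
        return np.ones(size)
    s2 = np.log(1 + cv**2)
    return rng.lognormal(-s2 / 2, np.sqrt(s2), size=size)


def generate_caliper_series(config: CaliperSeriesConfig) -> pd.DataFrame:
    """Simulate caliper length/width/height per implant and timepoint.

    Heights follow ``height_fold_by_time``; lateral dimensions share the
    residual fold so the noise-free volume fold matches
    ``volume_fold_by_time`` exactly. Noise is multiplicative lognormal per
    dimension (mean 1, CV ``noise_cv``), reflecting positive, roughly
    proportional caliper error.
    """
    rng = np.random.default_rng(config.seed)
    l0, w0, h0 = config.baseline_lwh_mm
    rows = []
    for i in range(config.n_implants):
        base = np.array([l0, w0, h0]) * _lognormal_factor(rng, config.baseline_cv, 3)
        for t in config.timepoints:
            vf = config.volume_fold_by_time.get(t)
            hf = config.height_fold_by_time.get(t, 1.0)
            if vf is None:
                raise ValueError(f"no volume fold configured for month {t}")
            lateral = np.sqrt(vf / hf)
            dims = base * np.array([lateral, lateral, hf])
            if t != 0:
                dims = dims * _lognormal_factor(rng, config.noise_cv, 3)
            rows.append(
                {
                    "implant_id": f"{config.group}_{i:02d}",
                    "mouse_id": f"{config.group}_m{i:02d}",
                    "group": config.group,
                    "timepoint": t,
                    "length_mm": dims[0],
                    "width_mm": dims[1],
                    "height_mm": dims[2],
                }
            )
    return pd.DataFrame(rows)
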