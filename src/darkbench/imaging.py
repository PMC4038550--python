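"""Synthetic brightfield / fluorescence microscopy fields.

Renders populations of rod-shaped bacteria (spherocylinders) lying on a flat
pad, producing a brightfield image (cells darker than background), a
fluorescence image (cell interior at the cell's ground-truth intensity above
a uniform background), a ground-truth label mask, and per-cell truth records.
The camera model applies Poisson shot noise on the photon-equivalent signal,
a linear gain, an offset and Gaussian read noise, then optional 2x2 binning;
binning averages, so intensity scales are binning-invariant.

Geometry is in floating-point pixel units at pixel centers, 0-based,
row-major (row, col).  A pixel belongs to a cell iff its center lies within
the spherocylinder outline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage

__all__ = [
    "FieldSpec",
    "CameraModel",
    "CellGeometry",
    "FieldImage",
    "place_cells",
    "render_field",
    "write_field",
    "read_image",
]


@dataclass(frozen=True)
class FieldSpec:
    """Geometry and optics of one synthetic field (pre-binning pixels).

    Defaults emulate a 512x512 camera chip at 100x (0.065 um/px) imaging
    B. subtilis-sized rods (2-4 um long, 0.8-1 um wide).
    """

    width_px: int = 512
    height_px: int = 512
    pixel_size_um: float = 0.065
    cell_length_um: tuple[float, float] = (2.0, 4.0)
    cell_width_um: tuple[float, float] = (0.8, 1.0)
    n_cells_target: int = 100
    allow_touching: bool = False
    min_gap_px: int = 6
    psf_sigma_px: float = 2.0
    brightfield_bg_level: float = 1000.0
    brightfield_cell_contrast: float = 0.3
    fluor_bg_level: float = 20.0

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("field dimensions must be positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        for lo, hi in (self.cell_length_um, self.cell_width_um):
            if not 0 < lo <= hi:
                raise ValueError("size ranges must satisfy 0 < min <= max")
        if not 0 < self.brightfield_cell_contrast <= 1:
            raise ValueError("brightfield_cell_contrast must lie in (0, 1]")
        if min(self.brightfield_bg_level, self.fluor_bg_level) < 0:
            raise ValueError("background levels must be >= 0")
        if self.min_gap_px < 0 or self.n_cells_target < 0 or self.psf_sigma_px < 0:
            raise ValueError("min_gap_px, n_cells_target, psf_sigma_px must be >= 0")


@dataclass(frozen=True)
class CameraModel:
    """Linear camera: counts = offset + gain * Poisson(signal) + read noise."""

    offset: float = 100.0
    read_noise_sd: float = 2.0
    gain: float = 10.0
    shot_noise: bool = True
    bit_depth: int = 16
    binning: int = 2

    def __post_init__(self) -> None:
        if min(self.offset, self.read_noise_sd, self.gain) < 0:
            raise ValueError("offset, read_noise_sd and gain must be >= 0")
        if self.binning not in (1, 2):
            raise ValueError("binning must be 1 or 2")

    @property
    def max_count(self) -> int:
        return 2 ** self.bit_depth - 1


@dataclass(frozen=True)
class CellGeometry:
    """A spherocylinder: total length (cap to cap), width, center, angle."""

    center_row: float
    center_col: float
    theta: float            # radians, in [0, pi)
    length_px: float        # total length including caps
    width_px: float

    @property
    def half_axis(self) -> float:
        """Half-length of the central segment (excludes the caps)."""
        return max(0.0, (self.length_px - self.width_px) / 2.0)

    @property
    def endpoints(self) -> tuple[np.ndarray, np.ndarray]:
        d = np.array([np.sin(self.theta), np.cos(self.theta)])  # (drow, dcol)
        c = np.array([self.center_row, self.center_col])
        return c - self.half_axis * d, c + self.half_axis * d


@dataclass
class FieldImage:
    """A rendered field: image pair, ground truth, and provenance."""

    brightfield: np.ndarray
    fluorescence: np.ndarray
    truth_mask: np.ndarray
    cell_truths: pd.DataFrame
    field_spec: FieldSpec
    camera: CameraModel
    seed: int
    saturation_fraction: float = 0.0


def _segment_distances(p1: np.ndarray, p2: np.ndarray,
                       q1: np.ndarray, q2: np.ndarray) -> np.ndarray:
    """Min distances between segment (p1, p2) and each segment (q1[i], q2[i]).

    Vectorized closest-point-between-segments (clamped quadratic), robust to
    degenerate (point-like) segments.
    """
    eps = 1e-12
    d1 = p2 - p1                       # (2,)
    d2 = q2 - q1                       # (m, 2)
    r = p1[None, :] - q1               # (m, 2)
    a = float(np.dot(d1, d1))
    e = np.einsum("ij,ij->i", d2, d2)
    f = np.einsum("ij,ij->i", d2, r)
    c = r @ d1                         # (m,)
    b = d2 @ d1
    denom = a * e - b * b
    s = np.where(denom > eps, np.clip((b * f - c * e) / np.where(denom > eps, denom, 1.0), 0, 1), 0.0)
    t = np.where(e > eps, (b * s + f) / np.where(e > eps, e, 1.0), 0.0)
    # re-clamp s for clamped t
    t_cl = np.clip(t, 0.0, 1.0)
    need = t_cl != t
    if a > eps:
        s = np.where(need, np.clip((b * t_cl - c) / a, 0.0, 1.0), s)
    t = t_cl
    closest_p = p1[None, :] + s[:, None] * d1[None, :]
    closest_q = q1 + t[:, None] * d2
    return np.linalg.norm(closest_p - closest_q, axis=1)


def place_cells(spec: FieldSpec, n: int, seed: int,
                max_attempts_per_cell: int = 200) -> list[CellGeometry]:
    """Place up to ``n`` non-overlapping spherocylinders by rejection sampling.

    Cells are kept fully inside the field (a border margin of half the cell
    length plus the gap) so that downstream border-discard policies do not
    remove them.  If ``allow_touching`` is false, pairwise boundary distance
    is kept >= ``min_gap_px``.  When the field saturates before ``n`` cells
    are placed (total attempt budget ``n * max_attempts_per_cell``), fewer
    cells are returned with a warning.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    px = spec.pixel_size_um
    lo_l, hi_l = (v / px for v in spec.cell_length_um)
    lo_w, hi_w = (v / px for v in spec.cell_width_um)

    placed: list[CellGeometry] = []
    p1s: list[np.ndarray] = []
    p2s: list[np.ndarray] = []
    radii: list[float] = []
    budget = n * max_attempts_per_cell
    while len(placed) < n and budget > 0:
        budget -= 1
        length = rng.uniform(lo_l, hi_l)
        width = rng.uniform(lo_w, hi_w)
        theta = rng.uniform(0.0, np.pi)
        margin = length / 2.0 + spec.min_gap_px + 1.0
        if 2 * margin >= min(spec.height_px, spec.width_px):
            raise ValueError("cells do not fit in the field")
        row = rng.uniform(margin, spec.height_px - margin)
        col = rng.uniform(margin, spec.width_px - margin)
        geom = CellGeometry(row, col, theta, length, width)
        a, b = geom.endpoints
        if placed and not spec.allow_touching:
            d = _segment_distances(a, b, np.asarray(p1s), np.asarray(p2s))
            gaps = d - (width / 2.0 + np.asarray(radii))
            if np.any(gaps < spec.min_gap_px):
                continue
        placed.append(geom)
        p1s.append(a)
        p2s.append(b)
        radii.append(width / 2.0)
    if len(placed) < n:
        warnings.warn(
            f"field saturated: placed {len(placed)} of {n} requested cells",
            stacklevel=2)
    return placed


def _rasterize(geoms: list[CellGeometry], shape: tuple[int, int]) -> np.ndarray:
    """Label image of cell footprints (0 background, k for cell k)."""
    labels = np.zeros(shape, dtype=np.int32)
    for k, g in enumerate(geoms, start=1):
        a, b = g.endpoints
        rad = g.width_px / 2.0
        r0 = max(0, int(np.floor(min(a[0], b[0]) - rad - 1)))
        r1 = min(shape[0], int(np.ceil(max(a[0], b[0]) + rad + 2)))
        c0 = max(0, int(np.floor(min(a[1], b[1]) - rad - 1)))
        c1 = min(shape[1], int(np.ceil(max(a[1], b[1]) + rad + 2)))
        rr, cc = np.mgrid[r0:r1, c0:c1]
        pts = np.stack([rr.ravel(), cc.ravel()], axis=1).astype(float)
        d = b - a
        seg_len2 = float(np.dot(d, d))
        if seg_len2 < 1e-12:
            dist = np.linalg.norm(pts - a, axis=1)
        else:
            t = np.clip((pts - a) @ d / seg_len2, 0.0, 1.0)
            dist = np.linalg.norm(pts - (a + t[:, None] * d), axis=1)
        inside = (dist <= rad).reshape(rr.shape)
        labels[r0:r1, c0:c1][inside] = k
    return labels


def _bin_mean(img: np.ndarray, b: int) -> np.ndarray:
    if b == 1:
        return img
    h, w = img.shape
    return img[: h - h % b, : w - w % b].reshape(h // b, b, w // b, b).mean(axis=(1, 3))


def _bin_labels_majority(labels: np.ndarray, b: int) -> np.ndarray:
    """Majority-rule label binning; ties (including all-distinct) go to 0."""
    if b == 1:
        return labels
    h, w = labels.shape
    blocks = labels[: h - h % b, : w - w % b].reshape(h // b, b, w // b, b)
    vals = blocks.transpose(1, 3, 0, 2).reshape(b * b, h // b, w // b)
    counts = (vals[:, None, :, :] == vals[None, :, :, :]).sum(axis=1)
    best = np.argmax(counts, axis=0)
    maxc = counts.max(axis=0)
    mode = np.take_along_axis(vals, best[None], axis=0)[0]
    tied = ((counts == maxc[None]) & (vals != mode[None])).any(axis=0)
    out = np.where(tied, 0, mode)
    return out.astype(labels.dtype)


def _apply_camera(signal: np.ndarray, camera: CameraModel,
                  rng: np.random.Generator) -> tuple[np.ndarray, float]:
    """Photon-equivalent signal -> binned camera counts + saturation fraction."""
    if camera.shot_noise:
        detected = rng.poisson(np.maximum(signal, 0.0)).astype(float)
    else:
        detected = signal
    counts = camera.offset + camera.gain * detected
    if camera.read_noise_sd > 0:
        counts = counts + rng.normal(0.0, camera.read_noise_sd, size=counts.shape)
    counts = _bin_mean(counts, camera.binning)
    sat = float(np.mean(counts > camera.max_count))
    return np.clip(counts, 0, camera.max_count), sat


def render_field(values: np.ndarray, geoms: list[CellGeometry], spec: FieldSpec,
                 camera: CameraModel, seed: int) -> FieldImage:
    """Render one brightfield/fluorescence pair from per-cell intensities.

    ``values`` holds one ground-truth fluorescence value (AU) per geometry.
    The fluorescence photon-equivalent field is background plus the cell value
    over each footprint, blurred by a Gaussian PSF, then passed through the
    camera.  Brightfield renders cells darker than background by
    ``brightfield_cell_contrast`` through the same blur/noise path.  The truth
    mask is the unblurred footprint, majority-binned.
    """
    values = np.asarray(values, dtype=float)
    if len(values) != len(geoms):
        raise ValueError("need exactly one intensity value per cell geometry")
    shape = (spec.height_px, spec.width_px)
    labels = _rasterize(geoms, shape)

    fl = np.full(shape, spec.fluor_bg_level, dtype=float)
    bf = np.full(shape, spec.brightfield_bg_level, dtype=float)
    if len(geoms):
        inside = labels > 0
        fl[inside] += values[labels[inside] - 1]
        bf[inside] *= 1.0 - spec.brightfield_cell_contrast
    if spec.psf_sigma_px > 0:
        fl = ndimage.gaussian_filter(fl, spec.psf_sigma_px)
        bf = ndimage.gaussian_filter(bf, spec.psf_sigma_px)

    ss = np.random.SeedSequence(seed)
    rng_fl, rng_bf = (np.random.default_rng(child) for child in ss.spawn(2))
    fl_counts, sat_fl = _apply_camera(fl, camera, rng_fl)
    bf_counts, sat_bf = _apply_camera(bf, camera, rng_bf)
    mask = _bin_labels_majority(labels, camera.binning)

    binf = camera.binning
    truths = pd.DataFrame({
        "cell_id": np.arange(1, len(geoms) + 1),
        "centroid_row": [g.center_row / binf for g in geoms],
        "centroid_col": [g.center_col / binf for g in geoms],
        "orientation_rad": [g.theta for g in geoms],
        "length_px": [g.length_px / binf for g in geoms],
        "width_px": [g.width_px / binf for g in geoms],
        "true_mean_au": values,
    })
    return FieldImage(brightfield=bf_counts, fluorescence=fl_counts,
                      truth_mask=mask, cell_truths=truths, field_spec=spec,
                      camera=camera, seed=seed,
                      saturation_fraction=max(sat_fl, sat_bf))


def write_field(img: FieldImage, directory, stem: str = "field0") -> dict[str, str]:
    """Write a field as 16-bit TIFFs plus a cell-truth CSV; returns the paths."""
    import os

    os.makedirs(directory, exist_ok=True)
    paths = {}
    for tag, arr in (("bf", img.brightfield), ("fl", img.fluorescence),
                     ("mask", img.truth_mask)):
        p = os.path.join(directory, f"{stem}_{tag}.tif")
        tifffile.imwrite(p, np.round(arr).astype(np.uint16))
        paths[tag] = p
    p = os.path.join(directory, f"{stem}_truth.csv")
    img.cell_truths.to_csv(p, index=False)
    paths["truth"] = p
    return paths


def read_image(path) -> np.ndarray:
    """Read a single-plane grayscale TIFF as float counts."""
    return tifffile.imread(path).astype(float)
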