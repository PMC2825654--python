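"""Collimated detector scoring and dark-field image formation.

The anti-scatter collimator is modelled as an ideal binary angular gate: a
photon is accepted iff the angle between its direction and the detector
normal (+z) does not exceed ``arctan(1 / aspect_ratio)``, where the aspect
ratio is grid height over cell aperture (H/D).  Escaping photons are
propagated along their straight exit ray to the detector plane and binned
into pixels; images are stored per scattering class (primary /
Rayleigh-only / Compton-involved) as counts per launched photon, so runs of
different photon budgets are directly comparable.

The dark-field image is formed by digital subtraction: either between a low
and a high collimation aspect ratio at the same distance (IL - IH), or
between a short and a long object-detector distance at the same aspect
ratio (near - far).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "CollimatorSpec",
    "DetectorGrid",
    "DetectorChannel",
    "DetectorBank",
    "ScatterImageSet",
    "SCATTER_CLASSES",
    "accept",
    "score",
    "darkfield_subtract",
    "distance_subtract",
    "region_stats",
]

#: Scatter-history classes tallied separately.
SCATTER_CLASSES = ("primary", "rayleigh_only", "compton_involved")


@dataclass(frozen=True)
class CollimatorSpec:
    """Anti-scatter grid characterized by its aspect ratio H/D.

    Two acceptance models are available:

    * ``septa=False`` (default): an ideal binary angular gate -- a photon is
      accepted iff the angle between its direction and the detector normal
      is at most ``arctan(1/aspect_ratio)``, regardless of where it lands.
    * ``septa=True``: explicit grid walls -- square collimator cells of
      height ``H = aspect_ratio * pitch`` sit on the pixel lattice, and a
      photon is accepted iff its straight ray enters and leaves the same
      cell (the ray from the grid top plane to the detector plane crosses
      no septum).  This reproduces the partial septal shadowing of a real
      grid and is the geometry the single-scattering angular limits
      describe, so it is the model to use when comparing Monte Carlo
      against the analytic single-scattering image.
    """

    aspect_ratio: float
    septa: bool = False

    def __post_init__(self) -> None:
        if self.aspect_ratio <= 0:
            raise ValueError("collimator aspect ratio must be > 0")

    @property
    def acceptance_half_angle(self) -> float:
        """Half-angle of the acceptance cone, arctan(1/aspect_ratio), rad."""
        return math.atan(1.0 / self.aspect_ratio)

    def height(self, pitch: float) -> float:
        """Absolute grid height H = aspect_ratio * D for cell aperture D."""
        return self.aspect_ratio * pitch


@dataclass(frozen=True)
class DetectorGrid:
    """Pixel grid in a plane z = plane_z, centred laterally on ``center``."""

    n_u: int
    n_v: int
    pitch: float            # cm
    plane_z: float = 0.0    # cm
    center: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.n_u < 1 or self.n_v < 1:
            raise ValueError("pixel counts must be >= 1")
        if self.pitch <= 0:
            raise ValueError("pixel pitch must be > 0")

    @property
    def u_min(self) -> float:
        return self.center[0] - 0.5 * self.n_u * self.pitch

    @property
    def v_min(self) -> float:
        return self.center[1] - 0.5 * self.n_v * self.pitch

    def pixel_centers(self):
        """(u_centers, v_centers) coordinate arrays in cm."""
        u = self.u_min + (np.arange(self.n_u) + 0.5) * self.pitch
        v = self.v_min + (np.arange(self.n_v) + 0.5) * self.pitch
        return u, v


@dataclass(frozen=True)
class DetectorChannel:
    """One acquisition configuration: a collimator at an object-detector
    distance, e.g. the high-aspect short-distance channel 'IH'."""

    name: str
    collimator: CollimatorSpec
    distance_cm: float

    def __post_init__(self) -> None:
        if self.distance_cm < 0:
            raise ValueError("object-detector distance must be >= 0")


@dataclass
class DetectorBank:
    """A shared pixel grid scored through several channels at once.

    Every escaping photon of a simulation is offered to every channel, so
    channel images share the photon stream (matched seeds by construction)
    and subtraction images are free of independent-stream noise.
    """

    grid: DetectorGrid
    channels: list[DetectorChannel]
    phantom_exit_z: float = 2.5

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("detector bank needs at least one channel")
        names = [c.name for c in self.channels]
        if len(set(names)) != len(names):
            raise ValueError("channel names must be unique")

    def channel_grid(self, channel: DetectorChannel) -> DetectorGrid:
        return replace(self.grid,
                       plane_z=self.phantom_exit_z + channel.distance_cm)


def accept(direction, collimator: CollimatorSpec):
    """Binary collimator gate: angle to +z within the acceptance half-angle."""
    d = np.asarray(direction, dtype=float)
    dz = d[..., 2]
    cos_half = math.cos(collimator.acceptance_half_angle)
    ok = (dz > 0) & (dz >= cos_half - 1e-15)
    return bool(ok) if ok.ndim == 0 else ok


def score(position, direction, grid: DetectorGrid,
          collimator: CollimatorSpec):
    """Map one escaping photon to a pixel index, or None.

    Propagates the straight exit ray from ``position`` to the detector
    plane; returns ``(u, v)`` if the intersection lies on the grid and the
    collimator accepts the photon, else ``None``.
    """
    position = np.asarray(position, dtype=float)
    direction = np.asarray(direction, dtype=float)
    if direction[2] <= 0:
        return None
    t = (grid.plane_z - position[2]) / direction[2]
    x = position[0] + t * direction[0]
    y = position[1] + t * direction[1]
    u = math.floor((x - grid.u_min) / grid.pitch)
    v = math.floor((y - grid.v_min) / grid.pitch)
    if not (0 <= u < grid.n_u and 0 <= v < grid.n_v):
        return None
    if collimator.septa:
        h = collimator.height(grid.pitch)
        xt = x - h * direction[0] / direction[2]
        yt = y - h * direction[1] / direction[2]
        ut = math.floor((xt - grid.u_min) / grid.pitch)
        vt = math.floor((yt - grid.v_min) / grid.pitch)
        if (ut, vt) != (u, v):
            return None
    elif not accept(direction, collimator):
        return None
    return u, v


def score_batch(positions: np.ndarray, directions: np.ndarray,
                class_idx: np.ndarray, grid: DetectorGrid,
                collimator: CollimatorSpec, out: np.ndarray) -> int:
    """Accumulate a batch of escaping photons into per-class count images.

    ``out`` has shape ``(len(SCATTER_CLASSES), n_v, n_u)``; returns the
    number of photons detected.  Pixel bins are half-open.
    """
    dz = directions[:, 2]
    if collimator.septa:
        ok = dz > 0
    else:
        cos_half = math.cos(collimator.acceptance_half_angle)
        ok = (dz > 0) & (dz >= cos_half - 1e-15)
    if not np.any(ok):
        return 0
    p = positions[ok]
    d = directions[ok]
    cls = class_idx[ok]
    t = (grid.plane_z - p[:, 2]) / d[:, 2]
    x = p[:, 0] + t * d[:, 0]
    y = p[:, 1] + t * d[:, 1]
    u = np.floor((x - grid.u_min) / grid.pitch).astype(np.int64)
    v = np.floor((y - grid.v_min) / grid.pitch).astype(np.int64)
    valid = (u >= 0) & (u < grid.n_u) & (v >= 0) & (v < grid.n_v)
    if collimator.septa:
        # photon must enter and leave the same collimator cell
        h = collimator.height(grid.pitch)
        xt = x - h * d[:, 0] / d[:, 2]
        yt = y - h * d[:, 1] / d[:, 2]
        ut = np.floor((xt - grid.u_min) / grid.pitch).astype(np.int64)
        vt = np.floor((yt - grid.v_min) / grid.pitch).astype(np.int64)
        valid &= (u == ut) & (v == vt)
    if not np.any(valid):
        return 0
    flat = (cls[valid].astype(np.int64) * grid.n_v + v[valid]) * grid.n_u + u[valid]
    counts = np.bincount(flat, minlength=out.size)
    out += counts.reshape(out.shape)
    return int(valid.sum())


@dataclass
class ScatterImageSet:
    """Per-channel, per-scatter-class images normalized per launched photon."""

    images: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    n_photons: int = 0
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def class_image(self, channel: str, scatter_class: str) -> np.ndarray:
        return self.images[(channel, scatter_class)]

    def total(self, channel: str) -> np.ndarray:
        """Sum of all scatter-class images of a channel."""
        return sum(self.images[(channel, c)] for c in SCATTER_CLASSES)

    def scattered(self, channel: str) -> np.ndarray:
        """Sum of the scattered-photon classes only (no primary beam)."""
        return (self.images[(channel, "rayleigh_only")]
                + self.images[(channel, "compton_involved")])

    @property
    def channels(self) -> list[str]:
        return sorted({ch for ch, _ in self.images})


def _check_shapes(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValueError(f"image shapes differ: {a.shape} vs {b.shape}")


def darkfield_subtract(image_low: np.ndarray, image_high: np.ndarray) -> np.ndarray:
    """Dark-field estimate IL - IH from two collimation aspect ratios.

    The low-aspect image contains primary beam plus small-angle scattering,
    the high-aspect image essentially only the primary beam; their
    difference isolates the small-angle (mostly Rayleigh) signal.  Negative
    pixels are statistical noise and are retained.
    """
    _check_shapes(image_low, image_high)
    return image_low - image_high


def distance_subtract(image_near: np.ndarray, image_far: np.ndarray) -> np.ndarray:
    """Dark-field estimate from two object-detector distances, near - far.

    With a parallel primary beam the primary image is distance-invariant
    while the scattered flux per pixel dilutes with distance, so the
    difference again isolates small-angle scattering.
    """
    _check_shapes(image_near, image_far)
    return image_near - image_far


def negative_fraction(image: np.ndarray) -> float:
    """Fraction of pixels below zero (noise indicator for difference images)."""
    return float(np.mean(image < 0))


def region_stats(image: np.ndarray, phantom, grid: DetectorGrid,
                 margin_cm: float = 0.5) -> pd.DataFrame:
    """Mean/variance of pixel values over each inclusion's projected shadow.

    Regions are the lateral (parallel-beam) shadows of the phantom's
    inclusions plus a background region: pixels inside the background's
    lateral footprint, at least ``margin_cm`` from its edge and from every
    inclusion shadow.  Raises if any region mask is empty.
    """
    if image.shape != (grid.n_v, grid.n_u):
        raise ValueError(
            f"image shape {image.shape} does not match grid "
            f"({grid.n_v}, {grid.n_u})")
    u, v = grid.pixel_centers()
    uu, vv = np.meshgrid(u, v)

    rows = []
    bg = phantom.background
    bg_mask = ((uu > bg.lo[0] + margin_cm) & (uu < bg.hi[0] - margin_cm)
               & (vv > bg.lo[1] + margin_cm) & (vv < bg.hi[1] - margin_cm))
    masks: list[tuple[str, np.ndarray]] = []
    for inc in phantom.inclusions:
        m = ((uu > inc.lo[0]) & (uu < inc.hi[0])
             & (vv > inc.lo[1]) & (vv < inc.hi[1]))
        masks.append((inc.material.name, m))
        bg_mask &= ~((uu > inc.lo[0] - margin_cm) & (uu < inc.hi[0] + margin_cm)
                     & (vv > inc.lo[1] - margin_cm) & (vv < inc.hi[1] + margin_cm))
    masks.insert(0, (bg.material.name, bg_mask))

    for name, mask in masks:
        if not mask.any():
            raise ValueError(f"region mask for {name!r} selects no pixels")
        vals = image[mask]
        rows.append({"region": name, "n_pixels": int(mask.sum()),
                     "mean": float(vals.mean()), "var": float(vals.var())})
    return pd.DataFrame(rows).set_index("region")
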