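"""Phantom geometry: axis-aligned box regions and exact ray traversal.

The phantom is a background box (e.g. a water slab) containing axis-aligned
box inclusions, each mapped to a :class:`~darkscatter.physics.Material`;
everything outside the background is vacuum.  Rays are intersected with the
boxes by the slab method, yielding an ordered material/length partition of
the chord, which drives both free-path sampling in the Monte Carlo transport
and attenuation line integrals in the analytic single-scattering model.

Coordinates are right-handed with the beam travelling along +z; lengths in cm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .physics import Material, VACUUM

__all__ = [
    "BoxRegion",
    "Phantom",
    "build_table1_phantom",
    "table1_materials",
    "trace_segments",
    "sample_interaction",
    "WATER",
    "CUBE1",
    "CUBE2",
    "CUBE3",
    "CUBE4",
]

# Reference 50 keV coefficients (cm^-1): water and four water-equivalent
# cubes sharing water's absorption but with redistributed Rayleigh/Compton
# scattering shares.
WATER = Material.from_components("water", 0.028, 0.0140, 0.1680)
CUBE1 = Material.from_components("cube1", 0.028, 0.0035, 0.1785)
CUBE2 = Material.from_components("cube2", 0.028, 0.0070, 0.1750)
CUBE3 = Material.from_components("cube3", 0.028, 0.0260, 0.1560)
CUBE4 = Material.from_components("cube4", 0.028, 0.0520, 0.1300)


def table1_materials() -> dict[str, Material]:
    """The five reference materials keyed by name."""
    return {m.name: m for m in (WATER, CUBE1, CUBE2, CUBE3, CUBE4)}


@dataclass(frozen=True)
class BoxRegion:
    """An axis-aligned box with a homogeneous material."""

    lo: tuple[float, float, float]
    hi: tuple[float, float, float]
    material: Material

    def __post_init__(self) -> None:
        lo = np.asarray(self.lo, dtype=float)
        hi = np.asarray(self.hi, dtype=float)
        if lo.shape != (3,) or hi.shape != (3,):
            raise ValueError("lo and hi must be 3-vectors")
        if not np.all(lo < hi):
            raise ValueError(f"box corners must satisfy lo < hi, got {lo} / {hi}")
        object.__setattr__(self, "lo", tuple(float(v) for v in lo))
        object.__setattr__(self, "hi", tuple(float(v) for v in hi))

    def contains(self, point) -> bool:
        p = np.asarray(point, dtype=float)
        return bool(np.all(p >= self.lo) and np.all(p <= self.hi))

    def contains_box(self, other: "BoxRegion") -> bool:
        return bool(np.all(np.asarray(other.lo) >= self.lo)
                    and np.all(np.asarray(other.hi) <= self.hi))

    def overlaps(self, other: "BoxRegion") -> bool:
        lo = np.maximum(self.lo, other.lo)
        hi = np.minimum(self.hi, other.hi)
        return bool(np.all(lo < hi))


@dataclass
class Phantom:
    """Background box plus disjoint box inclusions; exterior is vacuum.

    Point lookup returns exactly one material: inclusions override the
    background, the exterior returns vacuum.
    """

    background: BoxRegion
    inclusions: list[BoxRegion] = field(default_factory=list)

    def __post_init__(self) -> None:
        for inc in self.inclusions:
            if not self.background.contains_box(inc):
                raise ValueError(
                    f"inclusion {inc.material.name!r} is not contained in the "
                    "background box")
        for i, a in enumerate(self.inclusions):
            for b in self.inclusions[i + 1:]:
                if a.overlaps(b):
                    raise ValueError(
                        f"inclusions {a.material.name!r} and "
                        f"{b.material.name!r} overlap")
        self._flat = _FlatGeometry(self)

    @property
    def z_min(self) -> float:
        return self.background.lo[2]

    @property
    def z_max(self) -> float:
        return self.background.hi[2]

    def material_at(self, point) -> Material:
        """Material at a point; inclusions win over background, else vacuum."""
        for inc in self.inclusions:
            if inc.contains(point):
                return inc.material
        if self.background.contains(point):
            return self.background.material
        return VACUUM

    @property
    def materials(self) -> list[Material]:
        """Background material followed by inclusion materials, in order."""
        return [self.background.material] + [b.material for b in self.inclusions]

    @property
    def flat(self) -> "_FlatGeometry":
        """Array-of-boxes view used by the vectorized kernels."""
        return self._flat


class _FlatGeometry:
    """Vectorized slab-method kernels over the phantom's boxes.

    Box 0 is the background; boxes 1..m are the inclusions.  Material index
    -1 denotes vacuum; ``mu_t``/``mu_s``/``beta`` are indexed by box index.
    """

    def __init__(self, phantom: Phantom) -> None:
        boxes = [phantom.background] + list(phantom.inclusions)
        self.lo = np.array([b.lo for b in boxes])          # (m, 3)
        self.hi = np.array([b.hi for b in boxes])
        mats = phantom.materials
        self.mu_t = np.array([m.mu_t for m in mats])
        self.mu_s = np.array([m.mu_s for m in mats])
        self.beta = np.array([m.beta for m in mats])
        self.mu_tot = self.mu_t + self.mu_s
        self.n_inclusions = len(boxes) - 1
        self.n_edges = 2 + 2 * self.n_inclusions           # candidate t values

    def _box_t(self, origins: np.ndarray, dirs: np.ndarray, i: int):
        """Slab-method (t_entry, t_exit) of box ``i`` for each ray."""
        d = np.where(np.abs(dirs) < 1e-300, 1e-300, dirs)
        t_a = (self.lo[i] - origins) / d
        t_b = (self.hi[i] - origins) / d
        t_near = np.minimum(t_a, t_b).max(axis=-1)
        t_far = np.maximum(t_a, t_b).min(axis=-1)
        return t_near, t_far

    def segment_edges(self, origins: np.ndarray, dirs: np.ndarray):
        """Sorted boundary parameters and per-segment material indices.

        Returns ``(edges, seg_mat, hit)``: ``edges`` is ``(n, n_edges)`` of
        sorted ray parameters clipped to the forward chord through the
        background, ``seg_mat`` is ``(n, n_edges - 1)`` of material indices
        (-1 only when the ray misses the background), ``hit`` the mask of
        rays whose forward half-line intersects the background.
        """
        origins = np.atleast_2d(np.asarray(origins, dtype=float))
        dirs = np.atleast_2d(np.asarray(dirs, dtype=float))
        n = origins.shape[0]
        t0, t1 = self._box_t(origins, dirs, 0)
        t0 = np.maximum(t0, 0.0)
        hit = t1 > t0 + 1e-15
        t0 = np.where(hit, t0, 0.0)
        t1 = np.where(hit, t1, 0.0)

        edges = np.empty((n, self.n_edges))
        edges[:, 0] = t0
        edges[:, 1] = t1
        for i in range(1, self.n_inclusions + 1):
            a, b = self._box_t(origins, dirs, i)
            edges[:, 2 * i] = np.clip(a, t0, t1)
            edges[:, 2 * i + 1] = np.clip(np.maximum(b, a), t0, t1)
        edges.sort(axis=1)

        t_mid = 0.5 * (edges[:, :-1] + edges[:, 1:])       # (n, n_edges-1)
        pts = origins[:, None, :] + t_mid[:, :, None] * dirs[:, None, :]
        seg_mat = np.zeros(t_mid.shape, dtype=np.int8)
        for i in range(1, self.n_inclusions + 1):
            inside = np.all((pts >= self.lo[i]) & (pts <= self.hi[i]), axis=-1)
            seg_mat[inside] = i
        seg_mat[~hit] = -1
        return edges, seg_mat, hit

    def sample_interaction(self, xi: np.ndarray, origins: np.ndarray,
                           dirs: np.ndarray):
        """Vectorized free-path sampling across material boundaries.

        For each ray, the target optical depth ``-ln(xi)`` is accumulated
        segment by segment; returns ``(escaped, positions, mat_idx)`` where
        escaped rays carry their original position.
        """
        edges, seg_mat, hit = self.segment_edges(origins, dirs)
        seg_len = np.diff(edges, axis=1)
        mu = np.where(seg_mat >= 0, self.mu_tot[np.maximum(seg_mat, 0)], 0.0)
        depth = mu * seg_len
        cum = np.cumsum(depth, axis=1)
        tau = -np.log(xi)
        total = cum[:, -1]
        escaped = (tau > total) | ~hit

        k = np.argmax(cum >= tau[:, None], axis=1)
        idx = (np.arange(len(k)), k)
        cum_prev = cum[idx] - depth[idx]
        mu_k = mu[idx]
        with np.errstate(divide="ignore", invalid="ignore"):
            s_in = np.where(mu_k > 0, (tau - cum_prev) / mu_k, 0.0)
        t_event = edges[:, :-1][idx] + s_in
        positions = np.where(escaped[:, None],
                             origins,
                             origins + t_event[:, None] * dirs)
        mat_idx = np.where(escaped, -1, seg_mat[idx]).astype(np.int8)
        return escaped, positions, mat_idx


def build_table1_phantom() -> Phantom:
    """The reference water phantom with four scattering-contrast cubes.

    A 10 x 10 x 5 cm^3 water slab spanning [-5, 5] x [-5, 5] x [-2.5, 2.5] cm
    with four 1 cm^3 cubes centred at mid-depth at the quadrant centres
    (+-2.5, +-2.5, 0) cm.  Cubes are numbered in reading order of the
    detector view (x right, y up): cube1 top-left, cube2 top-right,
    cube3 bottom-left, cube4 bottom-right.  All cubes share water's
    absorption; their Rayleigh/Compton split differs.
    """
    bg = BoxRegion((-5.0, -5.0, -2.5), (5.0, 5.0, 2.5), WATER)
    centers = {
        CUBE1: (-2.5, 2.5),
        CUBE2: (2.5, 2.5),
        CUBE3: (-2.5, -2.5),
        CUBE4: (2.5, -2.5),
    }
    inclusions = [
        BoxRegion((cx - 0.5, cy - 0.5, -0.5), (cx + 0.5, cy + 0.5, 0.5), mat)
        for mat, (cx, cy) in centers.items()
    ]
    return Phantom(bg, inclusions)


def trace_segments(phantom: Phantom, origin, direction) -> list[tuple[Material, float]]:
    """Partition a ray's chord through the phantom into material segments.

    Returns an ordered list of ``(material, length_cm)`` pairs whose lengths
    sum to the chord length through the background box; an empty list if the
    forward ray misses the phantom.  Adjacent same-material segments are
    merged and zero-length segments dropped.
    """
    direction = np.asarray(direction, dtype=float)
    norm = float(np.linalg.norm(direction))
    if not math.isclose(norm, 1.0, rel_tol=0, abs_tol=1e-9):
        raise ValueError(f"direction must be unit-norm, |d| = {norm:.3g}")
    edges, seg_mat, hit = phantom.flat.segment_edges(
        np.asarray(origin, dtype=float), direction)
    if not hit[0]:
        return []
    mats = phantom.materials
    out: list[tuple[Material, float]] = []
    for j in range(edges.shape[1] - 1):
        length = float(edges[0, j + 1] - edges[0, j])
        if length <= 1e-12:
            continue
        mat = mats[int(seg_mat[0, j])]
        if out and out[-1][0] is mat:
            out[-1] = (mat, out[-1][1] + length)
        else:
            out.append((mat, length))
    return out


def sample_interaction(rng: np.random.Generator, origin, direction,
                       phantom: Phantom):
    """Sample the next interaction site along a ray.

    Draws ``xi`` uniform on (0, 1] and accumulates optical depth
    ``(mu_t + mu_s) * length`` over the ray's material segments until it
    reaches ``-ln(xi)``.  Returns ``(position, material)`` for an interaction
    or ``(None, None)`` if the photon escapes the phantom.
    """
    xi = 1.0 - rng.random()          # maps [0,1) draws onto (0,1]
    flat = phantom.flat
    escaped, pos, mat_idx = flat.sample_interaction(
        np.array([xi]), np.asarray(origin, dtype=float),
        np.asarray(direction, dtype=float))
    if escaped[0]:
        return None, None
    return pos[0], phantom.materials[int(mat_idx[0])]
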