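"""Analytic single-scattering forward model of the collimated scatter image.

For each detector cell the detected single-scatter intensity is an
attenuated volume integral over the phantom,

    f = (1/2pi) * sum_voxels I0 * w_in * w_out * mu_s * int_phi int_theta p(theta),

where ``w_in``/``w_out`` are Beer-Lambert attenuation factors along the
source->voxel and voxel->cell paths and the double angular integral is the
probability that a photon scattered at the voxel passes the anti-scatter
grid into the cell.  The angular window of a cell at lateral offset ``r``
from the scattering point's beam axis is approximated by

    theta1 = arctan((r - D/2) / (R - H)),   theta2 = arctan((r + D/2) / R),
    phi1   = -arctan(D / (2r)),             phi2   = arctan(D / (2r)),

with ``H`` the grid height, ``D`` the cell aperture and ``R`` the (vertical)
distance from the scattering point to the detector plane.  The acceptance is
precomputed on a (depth, material, lateral-offset) table and reused for
every voxel/cell pair by lateral translation invariance of the grid.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import integrate

from .detection import CollimatorSpec, DetectorGrid
from .phantom import Phantom
from .physics import Material, ScatterPhysics, angular_pdf

__all__ = [
    "AcceptanceGeometry",
    "AcceptanceTable",
    "GeometryError",
    "angular_limits",
    "acceptance_probability",
    "build_acceptance_table",
    "single_scatter_image",
]


class GeometryError(ValueError):
    """Invalid collimator/detector geometry for the angular-limit formulas."""


@dataclass(frozen=True)
class AcceptanceGeometry:
    """Geometry of one (scattering point, detector cell) pair.

    H: grid (collimator) height, cm.  D: detector-cell aperture, cm.
    R: vertical distance from the scattering point to the detector plane, cm.
    r: lateral offset from the scattering point's beam axis to the cell
    centre, cm.
    """

    H: float
    D: float
    R: float
    r: float

    def __post_init__(self) -> None:
        if self.H < 0:
            raise GeometryError("grid height H must be >= 0")
        if self.D <= 0:
            raise GeometryError("cell aperture D must be > 0")
        if self.R <= self.H:
            raise GeometryError(
                f"scattering point must lie above the grid: R={self.R} <= H={self.H}")
        if self.r < 0:
            raise GeometryError("lateral offset r must be >= 0")


def angular_limits(geom: AcceptanceGeometry):
    """Polar and azimuthal acceptance limits ``(theta1, theta2, phi1, phi2)``.

    ``theta1`` is clamped to 0 when the cell overlaps the beam axis
    (r < D/2); in that case the cell also subtends the full azimuth, so
    ``(phi1, phi2) = (-pi, pi)``.
    """
    theta1 = math.atan2(geom.r - geom.D / 2.0, geom.R - geom.H)
    theta1 = max(theta1, 0.0)
    theta2 = math.atan((geom.r + geom.D / 2.0) / geom.R)
    if geom.r < geom.D / 2.0:
        phi2 = math.pi
    else:
        phi2 = math.atan(geom.D / (2.0 * geom.r))
    return theta1, theta2, -phi2, phi2


def acceptance_probability(theta_limits, phi_limits, material: Material,
                           physics: ScatterPhysics) -> float:
    """Probability that a scattered photon lands in the cell's angular window.

    ``(1/2pi) * (phi2 - phi1) * int_theta1^theta2 p(theta) d(theta)`` -- the
    azimuthal integrand is independent of theta, so the double integral
    factorizes.  Clamped to [0, 1]; an empty window (theta1 >= theta2)
    yields 0 with a warning.
    """
    theta1, theta2 = theta_limits
    phi1, phi2 = phi_limits
    if theta1 > theta2:
        warnings.warn("theta1 > theta2: detector cell unreachable under the "
                      "single-scattering approximation; returning 0",
                      stacklevel=2)
        return 0.0
    if theta1 == theta2:
        return 0.0
    integral, _ = integrate.quad(
        lambda t: angular_pdf(t, material, physics.compton, physics.rayleigh,
                              physics.weighting),
        theta1, theta2, limit=200, epsabs=1e-12, epsrel=1e-10)
    val = (phi2 - phi1) / (2.0 * math.pi) * integral
    return float(min(max(val, 0.0), 1.0))


class _MixtureCdf:
    """Dense cumulative integral of the mixture density for fast windows."""

    def __init__(self, material: Material, physics: ScatterPhysics,
                 n_grid: int = 32769):
        self.grid = np.linspace(0.0, math.pi, n_grid)
        pdf = angular_pdf(self.grid, material, physics.compton,
                          physics.rayleigh, physics.weighting)
        self.cdf = np.concatenate(
            [[0.0], integrate.cumulative_trapezoid(pdf, self.grid)])

    def window(self, theta1: float, theta2: float) -> float:
        lo, hi = np.interp([theta1, theta2], self.grid, self.cdf)
        return float(max(hi - lo, 0.0))


@dataclass
class AcceptanceTable:
    """Precomputed per-cell acceptance over (depth, material, cell offset).

    ``values[i, j, k]`` is the probability that a photon scattered at depth
    ``depths[i]`` (z coordinate, cm) in material ``j`` is detected in the
    cell at integer lateral offset ``offsets[k] = (du, dv)`` pixels from the
    cell on the scattering point's beam axis; offset ``(0, 0)`` is that
    on-axis cell.  ``method`` records how the entries were obtained:
    ``"quadrature"`` (factorized angular-limit windows) or ``"mc"``
    (statistically simulated against the collimator geometry).
    """

    depths: np.ndarray
    material_names: list[str]
    offsets: np.ndarray            # (n_off, 2) integer (du, dv)
    values: np.ndarray             # (n_depth, n_mat, n_off)
    collimator: CollimatorSpec
    plane_z: float
    pitch: float
    method: str = "quadrature"

    def __post_init__(self) -> None:
        self.offsets = np.asarray(self.offsets, dtype=int).reshape(-1, 2)
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise ValueError("acceptance probabilities must lie in [0, 1]")
        if self.values.shape[2] != self.offsets.shape[0]:
            raise ValueError("offset axis of values does not match offsets")
        axis = np.flatnonzero((self.offsets == 0).all(axis=1))
        if axis.size != 1:
            raise ValueError("offsets must contain (0, 0) exactly once")
        self._axis_idx = int(axis[0])

    @property
    def on_axis(self) -> np.ndarray:
        """(n_depths, n_materials) acceptance of the cell on the beam axis."""
        return self.values[:, :, self._axis_idx]

    @property
    def shape(self):
        return self.on_axis.shape


def grid_height(collimator: CollimatorSpec, grid: DetectorGrid) -> float:
    """Absolute grid height H = aspect_ratio * D with D the pixel pitch."""
    return collimator.height(grid.pitch)


def _depth_grid(phantom: Phantom, depth_step: float) -> np.ndarray:
    thickness = phantom.z_max - phantom.z_min
    n_depth = int(round(thickness / depth_step))
    if not math.isclose(n_depth * depth_step, thickness, rel_tol=1e-9):
        raise ValueError("phantom thickness must be divisible by depth_step")
    return phantom.z_min + (np.arange(n_depth) + 0.5) * depth_step


def _offset_lattice(k_max: int) -> np.ndarray:
    """Integer (du, dv) offsets with (0, 0) first."""
    offs = [(0, 0)] + [(du, dv)
                       for du in range(-k_max, k_max + 1)
                       for dv in range(-k_max, k_max + 1)
                       if (du, dv) != (0, 0)]
    return np.array(offs, dtype=int)


def _reach_k_max(grid: DetectorGrid, collimator: CollimatorSpec,
                 depths: np.ndarray) -> int:
    """Largest reachable integer cell offset over all depths."""
    r_big = float((grid.plane_z - depths).max())
    if collimator.septa:
        h = collimator.height(grid.pitch)
        if r_big <= h:
            return 0
        r_max = grid.pitch * r_big / h - grid.pitch / 2.0
    else:
        r_max = r_big * math.tan(collimator.acceptance_half_angle) + grid.pitch
    return max(int(math.ceil(r_max / grid.pitch)), 0)


def build_acceptance_table(phantom: Phantom, grid: DetectorGrid,
                           collimator: CollimatorSpec,
                           physics: ScatterPhysics,
                           depth_step: float = 0.02,
                           method: str = "quadrature",
                           n_samples: int = 20_000,
                           seed: int = 0) -> AcceptanceTable:
    """Tabulate the per-cell acceptance for every (depth, material, offset).

    Depths are voxel centres through the phantom thickness at ``depth_step``
    spacing (0.02 cm default); the offset axis covers every geometrically
    reachable cell (for a grid of height H the window of a cell closes at
    lateral offset ``r >= D*R/H - D/2``).

    ``method="quadrature"`` evaluates the factorized angular-limit windows
    (:func:`angular_limits` + the mixture-density integral); this realizes
    the grid-septa acceptance geometry.  ``method="mc"`` estimates each
    entry by drawing ``n_samples`` scattering events per (depth, material)
    -- deflection from the mixture density, azimuth uniform, scattering
    point uniform within the cell footprint -- and propagating them through
    the collimator model actually configured (angular gate or explicit
    septa), which makes the table exactly consistent with the Monte Carlo
    transport's detection rule.  Entries at depths below the septa top
    (R <= H) are zero.
    """
    depths = _depth_grid(phantom, depth_step)
    mats = phantom.materials
    k_max = _reach_k_max(grid, collimator, depths)
    offsets = _offset_lattice(k_max)

    if method == "quadrature":
        values = _quadrature_values(depths, mats, offsets, grid, collimator,
                                    physics)
    elif method == "mc":
        values = _mc_values(depths, mats, offsets, grid, collimator, physics,
                            n_samples, seed)
    else:
        raise ValueError(f"unknown table method {method!r}; "
                         "use 'quadrature' or 'mc'")
    np.clip(values, 0.0, 1.0, out=values)
    return AcceptanceTable(depths=depths,
                           material_names=[m.name for m in mats],
                           offsets=offsets, values=values,
                           collimator=collimator, plane_z=grid.plane_z,
                           pitch=grid.pitch, method=method)


def _quadrature_values(depths, mats, offsets, grid, collimator, physics):
    H = collimator.height(grid.pitch)
    D = grid.pitch
    radii = {round(D * math.hypot(du, dv), 12) for du, dv in offsets}
    radii = sorted(radii)
    r_index = {r: i for i, r in enumerate(radii)}
    cdfs = [_MixtureCdf(m, physics) for m in mats]
    by_radius = np.zeros((depths.size, len(mats), len(radii)))
    for i, z in enumerate(depths):
        R = grid.plane_z - z
        if R <= H:
            continue        # below the septa top: unreachable, acceptance 0
        for r, k in r_index.items():
            t1, t2, p1, p2 = angular_limits(
                AcceptanceGeometry(H=H, D=D, R=float(R), r=float(r)))
            if t1 >= t2:
                continue
            phi_frac = (p2 - p1) / (2.0 * math.pi)
            for j, cdf in enumerate(cdfs):
                by_radius[i, j, k] = phi_frac * cdf.window(t1, t2)
    cols = [r_index[round(D * math.hypot(du, dv), 12)] for du, dv in offsets]
    return by_radius[:, :, cols].copy()


def _mc_values(depths, mats, offsets, grid, collimator, physics,
               n_samples, seed):
    D = grid.pitch
    H = collimator.height(D)
    k_arr = offsets  # (n_off, 2)
    k_max = int(np.abs(k_arr).max()) if k_arr.size else 0
    side = 2 * k_max + 1
    lattice_index = np.full((side, side), -1, dtype=int)
    for idx, (du, dv) in enumerate(k_arr):
        lattice_index[dv + k_max, du + k_max] = idx
    cos_half = math.cos(collimator.acceptance_half_angle)

    rng = np.random.Generator(np.random.Philox(key=[seed & 0x7FFFFFFF, 0xACC]))
    n_depth = depths.size
    values = np.zeros((n_depth, len(mats), k_arr.shape[0]))
    R = (grid.plane_z - depths)[:, None]
    for j, m in enumerate(mats):
        total = n_depth * n_samples
        n_ray = rng.binomial(total, m.beta)
        theta = np.empty(total)
        if n_ray:
            theta[:n_ray] = physics.sample_rayleigh(rng, n_ray)
        if total - n_ray:
            theta[n_ray:] = physics.sample_compton(rng, total - n_ray)
        rng.shuffle(theta)
        theta = theta.reshape(n_depth, n_samples)
        phi = rng.random((n_depth, n_samples)) * (2.0 * math.pi)
        ox = (rng.random((n_depth, n_samples)) - 0.5) * D
        oy = (rng.random((n_depth, n_samples)) - 0.5) * D
        forward = theta < math.pi / 2
        with np.errstate(over="ignore", invalid="ignore"):
            tan_t = np.where(forward, np.tan(np.minimum(theta, 1.55)), np.inf)
        xd = ox + R * tan_t * np.cos(phi)
        yd = oy + R * tan_t * np.sin(phi)
        ud = np.floor((xd + D / 2) / D)
        vd = np.floor((yd + D / 2) / D)
        ok = forward & (np.abs(ud) <= k_max) & (np.abs(vd) <= k_max)
        if collimator.septa:
            xt = ox + (R - H) * tan_t * np.cos(phi)
            yt = oy + (R - H) * tan_t * np.sin(phi)
            ut = np.floor((xt + D / 2) / D)
            vt = np.floor((yt + D / 2) / D)
            ok &= (ud == ut) & (vd == vt) & (R > H)
        else:
            ok &= np.cos(theta) >= cos_half - 1e-15
        for i in range(n_depth):
            sel = ok[i]
            if not sel.any():
                continue
            cols = lattice_index[vd[i, sel].astype(int) + k_max,
                                 ud[i, sel].astype(int) + k_max]
            np.add.at(values[i, j], cols[cols >= 0], 1.0)
    values /= n_samples
    return values


def _material_index_maps(phantom: Phantom, grid: DetectorGrid,
                         depths: np.ndarray):
    """Material index (into phantom.materials; -1 = vacuum) per voxel."""
    u, v = grid.pixel_centers()
    uu, vv = np.meshgrid(u, v)
    flat = phantom.flat
    n_d = depths.size
    mat = np.full((n_d, uu.shape[0], uu.shape[1]), -1, dtype=np.int8)
    for i, z in enumerate(depths):
        in_bg = ((uu >= flat.lo[0, 0]) & (uu <= flat.hi[0, 0])
                 & (vv >= flat.lo[0, 1]) & (vv <= flat.hi[0, 1])
                 & (flat.lo[0, 2] <= z <= flat.hi[0, 2]))
        sl = np.where(in_bg, 0, -1).astype(np.int8)
        for b in range(1, flat.n_inclusions + 1):
            if not flat.lo[b, 2] <= z <= flat.hi[b, 2]:
                continue
            inside = ((uu >= flat.lo[b, 0]) & (uu <= flat.hi[b, 0])
                      & (vv >= flat.lo[b, 1]) & (vv <= flat.hi[b, 1]))
            sl[inside] = b
        mat[i] = sl
    return mat


def single_scatter_image(phantom: Phantom, grid: DetectorGrid,
                         collimator: CollimatorSpec, physics: ScatterPhysics,
                         table: AcceptanceTable, i0: float | None = None,
                         ) -> np.ndarray:
    """Predicted single-scatter image (counts per launched photon).

    The phantom is voxelized on the pixel lateral grid and the table's depth
    grid.  Each voxel contributes ``I0 * w_in * w_out * mu_s * dz *
    acceptance`` to the cells within the reachable offset neighbourhood,
    where the attenuation factors are vertical-path line integrals of
    ``mu_t + mu_s`` with half-voxel self terms.

    ``i0`` is the probability per launched photon of traversing one voxel
    column; defaults to ``pitch^2 / (phantom lateral area)``, matching a
    parallel beam launched uniformly over the phantom.
    """
    if table is None:
        raise ValueError("acceptance table not built; call "
                         "build_acceptance_table first")
    if table.pitch != grid.pitch or table.plane_z != grid.plane_z:
        raise ValueError("acceptance table was built for a different grid")
    depths = table.depths
    dz = float(depths[1] - depths[0]) if depths.size > 1 else \
        (phantom.z_max - phantom.z_min)
    flat = phantom.flat
    if i0 is None:
        bg = phantom.background
        area = (bg.hi[0] - bg.lo[0]) * (bg.hi[1] - bg.lo[1])
        i0 = grid.pitch ** 2 / area

    mat = _material_index_maps(phantom, grid, depths)       # (nd, nv, nu)
    safe = np.maximum(mat, 0)
    mu_tot = np.where(mat >= 0, flat.mu_tot[safe], 0.0)
    mu_s = np.where(mat >= 0, flat.mu_s[safe], 0.0)

    tau = mu_tot * dz
    cum = np.cumsum(tau, axis=0)
    w_in = np.exp(-(cum - 0.5 * tau))                       # entry -> voxel
    w_out = np.exp(-(cum[-1][None] - cum + 0.5 * tau))      # voxel -> exit

    image = np.zeros((grid.n_v, grid.n_u))
    n_v, n_u = image.shape
    for i in range(depths.size):
        src = i0 * w_in[i] * w_out[i] * mu_s[i] * dz        # (nv, nu)
        if not src.any():
            continue
        acc = table.values[i][np.maximum(mat[i], 0)]
        acc = np.where((mat[i] >= 0)[..., None], acc, 0.0)  # (nv, nu, n_off)
        for k, (du, dv) in enumerate(table.offsets):
            a = acc[:, :, k]
            if not a.any():
                continue
            contrib = src * a
            # shifted add: voxel (v,u) feeds cell (v+dv, u+du)
            v0, v1 = max(dv, 0), n_v + min(dv, 0)
            u0, u1 = max(du, 0), n_u + min(du, 0)
            image[v0:v1, u0:u1] += contrib[v0 - dv:v1 - dv, u0 - du:u1 - du]
    return image
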