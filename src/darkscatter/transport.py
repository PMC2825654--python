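"""Monte Carlo photon transport through the phantom.

Each history follows the same life-cycle: launch on the entry face of the
phantom, sample a free path from the piecewise-exponential optical depth
along the current direction, then either escape (hand the photon to the
detector bank), absorb with probability ``mu_t / (mu_t + mu_s)``, or scatter
-- Rayleigh with probability ``beta``, Compton otherwise -- drawing the
deflection from the corresponding normalized angular density and a uniform
azimuth, until the photon leaves the phantom or is absorbed.

The engine processes photons in fixed-size chunks of flat numpy arrays; each
chunk owns a Philox substream keyed by ``(seed, chunk_index)`` so a run is
bit-reproducible for a given configuration.  Photons are classified by
scatter history (primary / Rayleigh-only / Compton-involved) and scored per
class into every channel of the detector bank.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from . import detection
from .phantom import Phantom
from .physics import ScatterPhysics

__all__ = [
    "PhotonState",
    "ScatterClass",
    "SimulationConfig",
    "TallyReport",
    "rotate_direction",
    "run_history",
    "simulate",
]

_CHUNK = 1 << 19  # photons per vectorized chunk; fixed so results do not
                  # depend on how a run is split


class ScatterClass(Enum):
    """Scatter-history class of a detected photon."""

    PRIMARY = "primary"
    RAYLEIGH_ONLY = "rayleigh_only"
    COMPTON_INVOLVED = "compton_involved"

    @staticmethod
    def classify(n_rayleigh: int, n_compton: int) -> "ScatterClass":
        if n_compton > 0:
            return ScatterClass.COMPTON_INVOLVED
        if n_rayleigh > 0:
            return ScatterClass.RAYLEIGH_ONLY
        return ScatterClass.PRIMARY


@dataclass
class PhotonState:
    """Position, direction and scatter history of one photon."""

    position: np.ndarray
    direction: np.ndarray
    n_rayleigh: int = 0
    n_compton: int = 0
    alive: bool = True

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        norm = float(np.linalg.norm(self.direction))
        if not math.isclose(norm, 1.0, rel_tol=0, abs_tol=1e-9):
            raise ValueError("photon direction must be unit-norm")
        if self.n_rayleigh < 0 or self.n_compton < 0:
            raise ValueError("scatter counters must be non-negative")

    @property
    def scatter_class(self) -> ScatterClass:
        return ScatterClass.classify(self.n_rayleigh, self.n_compton)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one Monte Carlo run.

    The source is a parallel beam along +z, launched uniformly over the
    rectangle ``source_extent`` ((x_lo, x_hi), (y_lo, y_hi)) on the
    phantom's entry face; by default the phantom's full lateral extent.
    """

    n_photons: int
    seed: int
    source_extent: tuple[tuple[float, float], tuple[float, float]] | None = None
    energy_kev: float = 50.0
    max_scatter: int = 10_000

    def __post_init__(self) -> None:
        if self.n_photons < 1:
            raise ValueError("n_photons must be >= 1")
        if self.max_scatter < 1:
            raise ValueError("max_scatter must be >= 1")


@dataclass
class TallyReport:
    """Photon bookkeeping of a run; launched = absorbed + escaped always."""

    launched: int = 0
    absorbed: int = 0
    escaped: int = 0
    cap_terminated: int = 0     # histories killed by the scatter-count cap,
                                # counted inside `absorbed`
    escaped_by_class: dict[str, int] = field(default_factory=dict)
    detected: dict[tuple[str, str], int] = field(default_factory=dict)
    seed: int | None = None

    def check_conservation(self) -> None:
        if self.launched != self.absorbed + self.escaped:
            raise AssertionError(
                f"photon conservation violated: launched={self.launched}, "
                f"absorbed={self.absorbed}, escaped={self.escaped}")

    def to_dict(self) -> dict:
        return {
            "launched": self.launched,
            "absorbed": self.absorbed,
            "escaped": self.escaped,
            "cap_terminated": self.cap_terminated,
            "seed": self.seed,
            "escaped_by_class": dict(self.escaped_by_class),
            "detected": {f"{ch}/{cls}": n for (ch, cls), n in
                         sorted(self.detected.items())},
        }


def _local_frame(directions: np.ndarray):
    """Deterministic orthonormal frame (e1, e2) transverse to each direction.

    The reference axis is the global axis with the smallest absolute
    direction component, which is never parallel to the direction.
    """
    d = np.atleast_2d(directions)
    axis_idx = np.argmin(np.abs(d), axis=1)
    axes = np.eye(3)[axis_idx]
    e1 = np.cross(d, axes)
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(d, e1)
    return e1, e2


def rotate_direction(direction, theta, phi):
    """Deflect ``direction`` by polar angle ``theta`` and azimuth ``phi``.

    The azimuth is measured in a deterministic transverse frame built from
    the input direction; the output always makes angle ``theta`` with the
    input and is unit-norm.  Works elementwise on stacked inputs.
    """
    d = np.asarray(direction, dtype=float)
    single = d.ndim == 1
    d2 = np.atleast_2d(d)
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    phi = np.atleast_1d(np.asarray(phi, dtype=float))
    e1, e2 = _local_frame(d2)
    st = np.sin(theta)[:, None]
    out = (np.cos(theta)[:, None] * d2
           + st * (np.cos(phi)[:, None] * e1 + np.sin(phi)[:, None] * e2))
    out /= np.linalg.norm(out, axis=1, keepdims=True)
    return out[0] if single else out


def run_history(rng: np.random.Generator, photon: PhotonState,
                phantom: Phantom, physics: ScatterPhysics,
                max_scatter: int = 10_000):
    """Trace one photon history to absorption or escape.

    Returns ``(exit_state, scatter_class)`` where ``exit_state`` is the
    escaping :class:`PhotonState` or ``None`` if the photon was absorbed
    (including the rare scatter-count safety cap).
    """
    from .phantom import sample_interaction

    pos = photon.position.copy()
    direction = photon.direction.copy()
    n_ray, n_comp = photon.n_rayleigh, photon.n_compton
    for _ in range(max_scatter + 1):
        event_pos, material = sample_interaction(rng, pos, direction, phantom)
        if event_pos is None:
            state = PhotonState(pos, direction, n_ray, n_comp, alive=True)
            return state, ScatterClass.classify(n_ray, n_comp)
        if rng.random() < material.mu_t / material.mu_total:
            return None, ScatterClass.classify(n_ray, n_comp)
        kind, theta, phi = physics_sample(rng, material, physics)
        direction = rotate_direction(direction, theta, phi)
        if kind == "rayleigh":
            n_ray += 1
        else:
            n_comp += 1
        pos = event_pos
    return None, ScatterClass.classify(n_ray, n_comp)   # safety cap hit


def physics_sample(rng, material, physics: ScatterPhysics):
    """One scattering draw delegating to the physics bundle."""
    from .physics import sample_scatter
    return sample_scatter(rng, material, physics.compton, physics.rayleigh,
                          physics.weighting)


def simulate(config: SimulationConfig, phantom: Phantom,
             bank: detection.DetectorBank,
             physics: ScatterPhysics | None = None):
    """Run a full Monte Carlo acquisition.

    Every escaping photon is offered to every channel of the detector bank,
    so all channels share one photon stream.  Returns
    ``(ScatterImageSet, TallyReport)``; images are counts per launched
    photon, keyed by ``(channel_name, scatter_class)``.
    """
    if physics is None:
        physics = ScatterPhysics.calibrated(config.energy_kev)
    flat = phantom.flat
    if config.source_extent is None:
        bg = phantom.background
        (x_lo, x_hi), (y_lo, y_hi) = ((bg.lo[0], bg.hi[0]), (bg.lo[1], bg.hi[1]))
    else:
        (x_lo, x_hi), (y_lo, y_hi) = config.source_extent
    z_entry = phantom.z_min

    n_cls = len(detection.SCATTER_CLASSES)
    grids = {ch.name: bank.channel_grid(ch) for ch in bank.channels}
    counts = {ch.name: np.zeros((n_cls, bank.grid.n_v, bank.grid.n_u),
                                dtype=np.int64) for ch in bank.channels}
    tally = TallyReport(seed=config.seed)
    tally.escaped_by_class = {c: 0 for c in detection.SCATTER_CLASSES}

    n_left = config.n_photons
    chunk_idx = 0
    while n_left > 0:
        n = min(_CHUNK, n_left)
        n_left -= n
        rng = np.random.Generator(np.random.Philox(key=[config.seed & 0x7FFFFFFF,
                                                        chunk_idx]))
        chunk_idx += 1
        _run_chunk(rng, n, (x_lo, x_hi, y_lo, y_hi), z_entry, flat, physics,
                   bank, grids, counts, tally, config.max_scatter)

    tally.launched = config.n_photons
    tally.absorbed = config.n_photons - tally.escaped
    tally.check_conservation()

    images = {}
    for ch in bank.channels:
        for ic, cls in enumerate(detection.SCATTER_CLASSES):
            images[(ch.name, cls)] = counts[ch.name][ic] / config.n_photons
            tally.detected[(ch.name, cls)] = int(counts[ch.name][ic].sum())
    image_set = detection.ScatterImageSet(
        images=images, n_photons=config.n_photons, seed=config.seed,
        meta={"energy_kev": config.energy_kev,
              "channels": [ch.name for ch in bank.channels]})
    return image_set, tally


def _run_chunk(rng, n, extent, z_entry, flat, physics, bank, grids, counts,
               tally, max_scatter):
    x_lo, x_hi, y_lo, y_hi = extent
    pos = np.empty((n, 3))
    pos[:, 0] = rng.random(n) * (x_hi - x_lo) + x_lo
    pos[:, 1] = rng.random(n) * (y_hi - y_lo) + y_lo
    pos[:, 2] = z_entry
    dirs = np.zeros((n, 3))
    dirs[:, 2] = 1.0
    n_ray = np.zeros(n, dtype=np.int32)
    n_comp = np.zeros(n, dtype=np.int32)

    for step in range(max_scatter + 1):
        if pos.shape[0] == 0:
            break
        xi = 1.0 - rng.random(pos.shape[0])
        escaped, event_pos, mat_idx = flat.sample_interaction(xi, pos, dirs)

        if np.any(escaped):
            _score_escaped(pos[escaped], dirs[escaped], n_ray[escaped],
                           n_comp[escaped], bank, grids, counts, tally)
        inter = ~escaped
        if not np.any(inter):
            return
        pos = event_pos[inter]
        dirs = dirs[inter]
        n_ray = n_ray[inter]
        n_comp = n_comp[inter]
        mat = mat_idx[inter].astype(np.intp)

        # absorb vs scatter on the local mu_t/(mu_t+mu_s)
        p_abs = flat.mu_t[mat] / flat.mu_tot[mat]
        absorbed = rng.random(mat.size) < p_abs
        keep = ~absorbed
        if not np.any(keep):
            return
        pos, dirs = pos[keep], dirs[keep]
        n_ray, n_comp, mat = n_ray[keep], n_comp[keep], mat[keep]

        # Rayleigh vs Compton branch on beta, then angle draws
        is_ray = rng.random(mat.size) < flat.beta[mat]
        theta = np.empty(mat.size)
        nr = int(is_ray.sum())
        if nr:
            theta[is_ray] = physics.sample_rayleigh(rng, nr)
        if mat.size - nr:
            theta[~is_ray] = physics.sample_compton(rng, mat.size - nr)
        phi = rng.random(mat.size) * (2.0 * math.pi)
        dirs = rotate_direction(dirs, theta, phi)
        n_ray += is_ray
        n_comp += ~is_ray
    else:
        # photons still alive after the safety cap: terminate as absorbed
        tally.cap_terminated += pos.shape[0]


def _score_escaped(pos, dirs, n_ray, n_comp, bank, grids, counts, tally):
    cls = np.where(n_comp > 0, 2, np.where(n_ray > 0, 1, 0)).astype(np.int8)
    tally.escaped += pos.shape[0]
    names = detection.SCATTER_CLASSES
    binc = np.bincount(cls, minlength=3)
    for i, name in enumerate(names):
        tally.escaped_by_class[name] += int(binc[i])
    for ch in bank.channels:
        detection.score_batch(pos, dirs, cls, grids[ch.name], ch.collimator,
                              counts[ch.name])
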