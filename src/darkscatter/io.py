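"""Configuration files, fixtures and image/tally I/O.

Configs are YAML key-value files; images are written both as 32-bit float
TIFF (interchange) and as a plain-text matrix (diff-ability), with a YAML
metadata sidecar.  The packaged fixtures reproduce the reference simulation
setting: a 10 x 10 x 5 cm^3 water phantom with four scattering-contrast
cubes, imaged at collimation aspect ratios 50 and 10 and object-detector
distances 2.5 and 17.5 cm, on a 600 x 600 detector at 0.02 cm pitch
(``table1_full``) or a desk-scale 60 x 60 detector at 0.2 cm pitch
(``table1_reduced``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .detection import CollimatorSpec, DetectorChannel, DetectorGrid
from .phantom import BoxRegion, Phantom
from .physics import Material

__all__ = [
    "ConfigError",
    "RunConfig",
    "load_config",
    "write_config",
    "load_phantom",
    "write_phantom",
    "write_image",
    "read_image",
    "write_tally",
    "make_fixture",
    "FIXTURE_NAMES",
]

FIXTURE_NAMES = ("table1_full", "table1_reduced")


class ConfigError(ValueError):
    """A configuration file is missing, malformed or fails validation."""


def _require_keys(d: dict, required: set[str], optional: set[str],
                  context: str) -> None:
    missing = required - d.keys()
    if missing:
        raise ConfigError(f"{context}: missing keys {sorted(missing)}")
    unknown = d.keys() - required - optional
    if unknown:
        raise ConfigError(f"{context}: unknown keys {sorted(unknown)}")


# ---------------------------------------------------------------------------
# materials and phantom

def _material_from_dict(name: str, spec: dict) -> Material:
    if not isinstance(spec, dict):
        raise ConfigError(f"material {name!r}: expected a mapping")
    try:
        if {"mu_s_rayleigh", "mu_s_compton"} <= spec.keys():
            _require_keys(spec, {"mu_t", "mu_s_rayleigh", "mu_s_compton"},
                          set(), f"material {name!r}")
            return Material.from_components(name, float(spec["mu_t"]),
                                            float(spec["mu_s_rayleigh"]),
                                            float(spec["mu_s_compton"]))
        _require_keys(spec, {"mu_t", "mu_s", "beta"}, set(),
                      f"material {name!r}")
        return Material(name, float(spec["mu_t"]), float(spec["mu_s"]),
                        float(spec["beta"]))
    except ValueError as exc:          # Material invariant violations
        raise ConfigError(f"material {name!r}: {exc}") from exc


def _material_to_dict(m: Material) -> dict:
    return {"mu_t": m.mu_t, "mu_s_rayleigh": m.mu_s_rayleigh,
            "mu_s_compton": m.mu_s_compton}


def phantom_to_dict(phantom: Phantom) -> dict:
    mats = {m.name: _material_to_dict(m) for m in phantom.materials}
    bg = phantom.background
    return {
        "materials": mats,
        "background": {"lo": list(bg.lo), "hi": list(bg.hi),
                       "material": bg.material.name},
        "inclusions": [{"lo": list(b.lo), "hi": list(b.hi),
                        "material": b.material.name}
                       for b in phantom.inclusions],
    }


def phantom_from_dict(d: dict) -> Phantom:
    _require_keys(d, {"materials", "background"}, {"inclusions"}, "phantom")
    materials = {name: _material_from_dict(name, spec)
                 for name, spec in d["materials"].items()}

    def box(spec: dict, context: str) -> BoxRegion:
        _require_keys(spec, {"lo", "hi", "material"}, set(), context)
        name = spec["material"]
        if name not in materials:
            raise ConfigError(f"{context}: unknown material {name!r}")
        try:
            return BoxRegion(tuple(spec["lo"]), tuple(spec["hi"]),
                             materials[name])
        except ValueError as exc:
            raise ConfigError(f"{context}: {exc}") from exc

    bg = box(d["background"], "phantom background")
    incs = [box(s, f"phantom inclusion {i}")
            for i, s in enumerate(d.get("inclusions") or [])]
    try:
        return Phantom(bg, incs)
    except ValueError as exc:
        raise ConfigError(f"phantom: {exc}") from exc


def load_phantom(path) -> Phantom:
    d = _load_yaml(path, "phantom config")
    return phantom_from_dict(d)


def write_phantom(phantom: Phantom, path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(phantom_to_dict(phantom), sort_keys=False))
    return path


# ---------------------------------------------------------------------------
# run configuration

@dataclass
class RunConfig:
    """Validated parameters of a full acquisition run."""

    phantom_file: str
    detector: DetectorGrid
    channels: list[DetectorChannel]
    n_photons: int
    seed: int
    energy_kev: float = 50.0
    form_factor_l: float = 2.0
    target_mean_angle_deg: float = 4.3
    output_dir: str = "out"
    phantom: Phantom | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.channels:
            raise ConfigError("run config needs at least one collimator channel")
        if self.n_photons < 1:
            raise ConfigError("n_photons must be >= 1")


def _load_yaml(path, context: str) -> dict:
    path = Path(path)
    if not path.is_file():
        raise ConfigError(f"{context}: file not found: {path}")
    d = yaml.safe_load(path.read_text())
    if not isinstance(d, dict):
        raise ConfigError(f"{context}: {path} is empty or not a mapping")
    return d


def load_config(path) -> RunConfig:
    """Load and validate a run config; resolves the phantom file relative to
    the config location and loads it eagerly so errors surface here."""
    path = Path(path)
    d = _load_yaml(path, "run config")
    _require_keys(d, {"phantom", "detector", "channels", "n_photons", "seed"},
                  {"physics", "output_dir"}, "run config")

    det = d["detector"]
    _require_keys(det, {"n_u", "n_v", "pitch_cm"}, {"center"}, "detector")
    grid = DetectorGrid(int(det["n_u"]), int(det["n_v"]),
                        float(det["pitch_cm"]),
                        center=tuple(det.get("center", (0.0, 0.0))))

    channels = []
    for i, ch in enumerate(d["channels"]):
        _require_keys(ch, {"name", "aspect_ratio", "distance_cm"}, {"septa"},
                      f"channel {i}")
        channels.append(DetectorChannel(
            str(ch["name"]),
            CollimatorSpec(float(ch["aspect_ratio"]),
                           septa=bool(ch.get("septa", False))),
            float(ch["distance_cm"])))

    phys = d.get("physics", {})
    _require_keys(phys, set(),
                  {"energy_kev", "form_factor_l", "target_mean_angle_deg"},
                  "physics")

    phantom_file = str(d["phantom"])
    phantom_path = Path(phantom_file)
    if not phantom_path.is_absolute():
        phantom_path = path.parent / phantom_path
    cfg = RunConfig(
        phantom_file=phantom_file,
        detector=grid,
        channels=channels,
        n_photons=int(d["n_photons"]),
        seed=int(d["seed"]),
        energy_kev=float(phys.get("energy_kev", 50.0)),
        form_factor_l=float(phys.get("form_factor_l", 2.0)),
        target_mean_angle_deg=float(phys.get("target_mean_angle_deg", 4.3)),
        output_dir=str(d.get("output_dir", "out")),
    )
    cfg.phantom = load_phantom(phantom_path)
    return cfg


def config_to_dict(cfg: RunConfig) -> dict:
    return {
        "phantom": cfg.phantom_file,
        "detector": {"n_u": cfg.detector.n_u, "n_v": cfg.detector.n_v,
                     "pitch_cm": cfg.detector.pitch,
                     "center": list(cfg.detector.center)},
        "channels": [{"name": ch.name,
                      "aspect_ratio": ch.collimator.aspect_ratio,
                      "septa": ch.collimator.septa,
                      "distance_cm": ch.distance_cm}
                     for ch in cfg.channels],
        "physics": {"energy_kev": cfg.energy_kev,
                    "form_factor_l": cfg.form_factor_l,
                    "target_mean_angle_deg": cfg.target_mean_angle_deg},
        "n_photons": cfg.n_photons,
        "seed": cfg.seed,
        "output_dir": cfg.output_dir,
    }


def write_config(cfg: RunConfig, path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(config_to_dict(cfg), sort_keys=False))
    return path


# ---------------------------------------------------------------------------
# images and tallies

def write_image(image: np.ndarray, path, metadata: dict | None = None) -> Path:
    """Write an image as float32 TIFF + text matrix + YAML metadata sidecar.

    ``path`` may carry any (or no) suffix; the three files share its stem.
    Non-finite pixel values are rejected.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("image must be 2-D")
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite values")
    path = Path(path)
    stem = path.with_suffix("")
    stem.parent.mkdir(parents=True, exist_ok=True)
    data = image.astype(np.float32)
    tifffile.imwrite(stem.with_suffix(".tif"), data)
    np.savetxt(stem.with_suffix(".txt"), data, fmt="%.9e")
    meta = dict(metadata or {})
    meta.setdefault("shape", list(image.shape))
    meta.setdefault("dtype", "float32")
    stem.with_suffix(".yaml").write_text(yaml.safe_dump(meta, sort_keys=False))
    return stem.with_suffix(".tif")


def read_image(path) -> tuple[np.ndarray, dict]:
    """Read back a TIFF written by :func:`write_image` with its metadata."""
    path = Path(path)
    stem = path.with_suffix("")
    data = tifffile.imread(stem.with_suffix(".tif"))
    meta_path = stem.with_suffix(".yaml")
    meta = yaml.safe_load(meta_path.read_text()) if meta_path.is_file() else {}
    return data, meta


def write_tally(tally, path) -> Path:
    """Write a tally report as YAML plus an aligned plain-text summary."""
    path = Path(path)
    stem = path.with_suffix("")
    stem.parent.mkdir(parents=True, exist_ok=True)
    d = tally.to_dict()
    stem.with_suffix(".yaml").write_text(yaml.safe_dump(d, sort_keys=False))
    lines = [f"{'launched':<16}{d['launched']}",
             f"{'absorbed':<16}{d['absorbed']}",
             f"{'escaped':<16}{d['escaped']}",
             f"{'cap_terminated':<16}{d['cap_terminated']}",
             f"{'seed':<16}{d['seed']}"]
    for cls, n in d["escaped_by_class"].items():
        lines.append(f"{'escaped/' + cls:<32}{n}")
    for key, n in d["detected"].items():
        lines.append(f"{'detected/' + key:<32}{n}")
    stem.with_suffix(".txt").write_text("\n".join(lines) + "\n")
    return stem.with_suffix(".yaml")


# ---------------------------------------------------------------------------
# fixtures

def _fixture_channels() -> list[dict]:
    return [
        {"name": "IH", "aspect_ratio": 50.0, "distance_cm": 2.5},
        {"name": "IL", "aspect_ratio": 10.0, "distance_cm": 2.5},
        {"name": "IL_far", "aspect_ratio": 10.0, "distance_cm": 17.5},
        {"name": "IL_septa", "aspect_ratio": 10.0, "distance_cm": 2.5,
         "septa": True},
    ]


def make_fixture(name: str, out_dir) -> dict[str, Path]:
    """Write the phantom + run configs of a packaged reference fixture.

    ``table1_full`` is the full-resolution setting (600 x 600 pixels at
    0.02 cm pitch, 2e10 photons); ``table1_reduced`` is the desk-scale
    variant (60 x 60 pixels at 0.2 cm pitch, 1e7 photons) used by the test
    suite.  Both share the water phantom with four contrast cubes and the
    channel set: aspect 50 and 10 at 2.5 cm, aspect 10 at 17.5 cm, plus an
    explicit-septa aspect-10 channel for single-scattering comparisons.
    """
    if name not in FIXTURE_NAMES:
        raise ConfigError(
            f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}")
    from .phantom import build_table1_phantom

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    phantom_path = write_phantom(build_table1_phantom(),
                                 out_dir / f"{name}_phantom.yaml")
    if name == "table1_full":
        detector = {"n_u": 600, "n_v": 600, "pitch_cm": 0.02}
        n_photons = 20_000_000_000
    else:
        detector = {"n_u": 60, "n_v": 60, "pitch_cm": 0.2}
        n_photons = 10_000_000
    run = {
        "phantom": phantom_path.name,
        "detector": detector,
        "channels": _fixture_channels(),
        "physics": {"energy_kev": 50.0, "form_factor_l": 2.0,
                    "target_mean_angle_deg": 4.3},
        "n_photons": n_photons,
        "seed": 1,
        "output_dir": "out",
    }
    run_path = out_dir / f"{name}_run.yaml"
    run_path.write_text(yaml.safe_dump(run, sort_keys=False))
    return {"phantom": phantom_path, "run": run_path}
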