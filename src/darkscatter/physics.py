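"""Scattering physics: cross-sections, angular densities, samplers, calibration.

Two interaction mechanisms are modelled.  Compton (incoherent) scattering
follows the Klein-Nishina differential cross-section; Rayleigh (coherent)
scattering uses the Thomson cross-section modulated by a squared atomic form
factor approximated analytically as ``F(theta) = c1 * theta**l * exp(-c2*theta)``.
The free decay rate ``c2`` is calibrated so that the mean Rayleigh deflection
matches a target angle (4.3 degrees for 50 keV water by default).

Angular densities are normalized over the polar angle ``theta`` on ``[0, pi]``
with a plain ``d(theta)`` measure by default (``weighting="flat"``), matching
the cross-section bookkeeping used for the Rayleigh-fraction ``beta``.  The
conventional solid-angle measure ``sin(theta) d(theta)`` is available behind
``weighting="solid_angle"`` for sensitivity checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import integrate, optimize

__all__ = [
    "ELECTRON_REST_KEV",
    "ComptonModel",
    "RayleighModel",
    "Material",
    "ScatterPhysics",
    "EnvelopeError",
    "compton_dcs",
    "rayleigh_dcs",
    "angular_pdf",
    "sample_scatter",
    "sample_compton_angles",
    "sample_rayleigh_angles",
    "calibrate_form_factor",
    "beta_from_cross_sections",
]

#: Electron rest energy m_e c^2 in keV, used to form alpha = E_gamma / (m_e c^2).
ELECTRON_REST_KEV = 511.0

_WEIGHTINGS = ("flat", "solid_angle")


class EnvelopeError(RuntimeError):
    """A rejection sampler observed a density value above its envelope."""


@dataclass(frozen=True)
class ComptonModel:
    """Klein-Nishina model for a monoenergetic photon.

    Parameters
    ----------
    photon_energy_kev:
        Photon energy E_gamma in keV (50 keV default, a typical diagnostic
        beam quality).
    r_e:
        Classical electron radius scale factor.  Only normalized densities
        enter the transport, so internal units with ``r_e = 1`` are used.
    """

    photon_energy_kev: float = 50.0
    r_e: float = 1.0

    def __post_init__(self) -> None:
        if self.photon_energy_kev < 0:
            raise ValueError("photon energy must be non-negative")

    @property
    def alpha(self) -> float:
        """Dimensionless energy ratio E_gamma / (m_e c^2)."""
        return self.photon_energy_kev / ELECTRON_REST_KEV


@dataclass(frozen=True)
class RayleighModel:
    """Analytic form-factor model ``F(theta) = c1 * theta**l * exp(-c2*theta)``.

    ``c1`` cancels in every normalized density; it is kept for the
    unnormalized cross-section (used when deriving ``beta`` from
    cross-sections).  ``l >= 0`` shapes the forward suppression; ``c2 > 0``
    sets the angular decay and is normally obtained from
    :func:`calibrate_form_factor`.
    """

    c2: float
    c1: float = 1.0
    l: float = 2.0
    r_e: float = 1.0

    def __post_init__(self) -> None:
        if self.c2 <= 0:
            raise ValueError("form-factor decay rate c2 must be > 0")
        if self.l < 0:
            raise ValueError("form-factor exponent l must be >= 0")


@dataclass(frozen=True)
class Material:
    """X-ray interaction parameters of one tissue/region.

    The transport model is fully specified by three parameters: the
    absorption coefficient ``mu_t`` (photoelectric, cm^-1), the scattering
    coefficient ``mu_s`` (Rayleigh + Compton, cm^-1) and the Rayleigh
    fraction ``beta`` (probability that a scattering event is coherent).
    """

    name: str
    mu_t: float
    mu_s: float
    beta: float

    def __post_init__(self) -> None:
        if self.mu_t < 0:
            raise ValueError(f"material {self.name!r}: mu_t must be >= 0")
        if self.mu_s < 0:
            raise ValueError(f"material {self.name!r}: mu_s must be >= 0")
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError(f"material {self.name!r}: beta must be in [0, 1]")

    @classmethod
    def from_components(cls, name: str, mu_t: float, mu_s_rayleigh: float,
                        mu_s_compton: float) -> "Material":
        """Build from separate Rayleigh/Compton scattering coefficients."""
        mu_s = mu_s_rayleigh + mu_s_compton
        beta = mu_s_rayleigh / mu_s if mu_s > 0 else 0.0
        return cls(name, mu_t, mu_s, beta)

    @property
    def mu_s_rayleigh(self) -> float:
        """Coherent (Rayleigh) part of the scattering coefficient, beta*mu_s."""
        return self.beta * self.mu_s

    @property
    def mu_s_compton(self) -> float:
        """Incoherent (Compton) part, (1-beta)*mu_s."""
        return (1.0 - self.beta) * self.mu_s

    @property
    def mu_total(self) -> float:
        """Total interaction coefficient mu_t + mu_s."""
        return self.mu_t + self.mu_s


#: Convenience null material for the region outside any phantom.
VACUUM = Material("vacuum", 0.0, 0.0, 0.0)


def _check_theta(theta) -> np.ndarray:
    theta = np.asarray(theta, dtype=float)
    if np.any(theta < -1e-12) or np.any(theta > math.pi + 1e-12):
        raise ValueError("polar angle theta must lie in [0, pi]")
    return np.clip(theta, 0.0, math.pi)


def compton_dcs(theta, model: ComptonModel):
    """Klein-Nishina differential cross-section at polar angle ``theta``.

    Returns ``(r_e^2/2) * (1 + cos^2(t) + a^2 (1-cos t)^2 / (1 + a(1-cos t)))
    / (1 + a(1-cos t))^2`` with ``a = alpha``.
    """
    theta = _check_theta(theta)
    a = model.alpha
    c = np.cos(theta)
    k = 1.0 + a * (1.0 - c)
    val = 0.5 * model.r_e ** 2 * (1.0 + c ** 2 + a ** 2 * (1.0 - c) ** 2 / k) / k ** 2
    return val if val.ndim else float(val)


def rayleigh_dcs(theta, model: RayleighModel):
    """Coherent differential cross-section ``(r_e^2/2)(1+cos^2 t) F(t)^2``."""
    theta = _check_theta(theta)
    with np.errstate(divide="ignore"):
        # theta**l at theta=0 with l=0 must give 1, with l>0 gives 0
        f = model.c1 * np.where(
            theta > 0, np.power(np.where(theta > 0, theta, 1.0), model.l),
            1.0 if model.l == 0 else 0.0,
        ) * np.exp(-model.c2 * theta)
    val = 0.5 * model.r_e ** 2 * (1.0 + np.cos(theta) ** 2) * f ** 2
    return val if val.ndim else float(val)


def _weight(theta, weighting: str):
    if weighting == "flat":
        return np.ones_like(np.asarray(theta, dtype=float))
    if weighting == "solid_angle":
        return np.sin(theta)
    raise ValueError(f"unknown weighting {weighting!r}; use one of {_WEIGHTINGS}")


@lru_cache(maxsize=256)
def _compton_norm(model: ComptonModel, weighting: str) -> float:
    val, _ = integrate.quad(
        lambda t: compton_dcs(t, model) * _weight(t, weighting), 0.0, math.pi,
        limit=200, epsabs=1e-13, epsrel=1e-12)
    return val


@lru_cache(maxsize=256)
def _rayleigh_norm(model: RayleighModel, weighting: str) -> float:
    val, _ = integrate.quad(
        lambda t: rayleigh_dcs(t, model) * _weight(t, weighting), 0.0, math.pi,
        limit=200, epsabs=1e-14, epsrel=1e-12)
    return val


def compton_pdf(theta, model: ComptonModel, weighting: str = "flat"):
    """Normalized Compton angular density over theta in [0, pi]."""
    return compton_dcs(theta, model) * _weight(_check_theta(theta), weighting) \
        / _compton_norm(model, weighting)


def rayleigh_pdf(theta, model: RayleighModel, weighting: str = "flat"):
    """Normalized Rayleigh angular density over theta in [0, pi]."""
    return rayleigh_dcs(theta, model) * _weight(_check_theta(theta), weighting) \
        / _rayleigh_norm(model, weighting)


def angular_pdf(theta, material: Material, compton_model: ComptonModel,
                rayleigh_model: RayleighModel, weighting: str = "flat"):
    """Mixture angular density of a scattering event in ``material``.

    ``p(theta) = beta * p_rayleigh(theta) + (1 - beta) * p_compton(theta)``
    with each component individually normalized to one over ``[0, pi]``.
    """
    b = material.beta
    return b * rayleigh_pdf(theta, rayleigh_model, weighting) \
        + (1.0 - b) * compton_pdf(theta, compton_model, weighting)


@lru_cache(maxsize=256)
def _envelope_constant(kind_model, weighting: str) -> float:
    """Max of the normalized density over [0, pi]: coarse grid + refinement."""
    kind, model = kind_model
    pdf = compton_pdf if kind == "compton" else rayleigh_pdf
    grid = np.linspace(0.0, math.pi, 4097)
    vals = pdf(grid, model, weighting)
    i = int(np.argmax(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, grid.size - 1)]
    res = optimize.minimize_scalar(lambda t: -pdf(t, model, weighting),
                                   bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-12})
    peak = max(float(vals[i]), float(-res.fun))
    # tiny head-room so float noise at the peak cannot trip the envelope check
    return peak * (1.0 + 1e-9)


def _rejection_sample(rng: np.random.Generator, pdf, envelope: float,
                      size: int) -> np.ndarray:
    """Draw ``size`` angles from ``pdf`` with a constant envelope on [0, pi]."""
    out = np.empty(size)
    filled = 0
    rate = max(1.0 / (envelope * math.pi), 1e-4)  # expected acceptance rate
    while filled < size:
        need = size - filled
        batch = min(max(int(1.2 * need / rate), 1024), 40_000_000)
        cand = rng.random(batch) * math.pi
        vals = pdf(cand)
        if np.any(vals > envelope):
            raise EnvelopeError(
                "sampled density exceeds the rejection envelope; the envelope "
                "constant is stale for this model")
        acc = cand[rng.random(batch) * envelope < vals]
        take = min(acc.size, need)
        out[filled:filled + take] = acc[:take]
        filled += take
    return out


def sample_compton_angles(rng: np.random.Generator, model: ComptonModel,
                          size: int, weighting: str = "flat") -> np.ndarray:
    """Vectorized draw of Compton polar angles."""
    env = _envelope_constant(("compton", model), weighting)
    return _rejection_sample(rng, lambda t: compton_pdf(t, model, weighting),
                             env, size)


def sample_rayleigh_angles(rng: np.random.Generator, model: RayleighModel,
                           size: int, weighting: str = "flat") -> np.ndarray:
    """Vectorized draw of Rayleigh polar angles."""
    env = _envelope_constant(("rayleigh", model), weighting)
    return _rejection_sample(rng, lambda t: rayleigh_pdf(t, model, weighting),
                             env, size)


def sample_scatter(rng: np.random.Generator, material: Material,
                   compton_model: ComptonModel, rayleigh_model: RayleighModel,
                   weighting: str = "flat"):
    """Draw one scattering event in ``material``.

    Returns ``(event_type, theta, phi)`` where ``event_type`` is
    ``"rayleigh"`` with probability ``beta`` else ``"compton"``, ``theta`` is
    drawn from the matching normalized density and ``phi`` is uniform on
    ``[0, 2*pi)``.
    """
    if rng.random() < material.beta:
        kind = "rayleigh"
        theta = float(sample_rayleigh_angles(rng, rayleigh_model, 1, weighting)[0])
    else:
        kind = "compton"
        theta = float(sample_compton_angles(rng, compton_model, 1, weighting)[0])
    phi = float(rng.random() * 2.0 * math.pi)
    return kind, theta, phi


def rayleigh_mean_angle(model: RayleighModel, weighting: str = "flat") -> float:
    """Mean polar angle of the normalized Rayleigh density, by quadrature."""
    num, _ = integrate.quad(
        lambda t: t * rayleigh_dcs(t, model) * _weight(t, weighting),
        0.0, math.pi, limit=200, epsabs=1e-14, epsrel=1e-12)
    return num / _rayleigh_norm(model, weighting)


def calibrate_form_factor(target_mean_angle: float, l: float = 2.0,
                          weighting: str = "flat",
                          c2_max: float = 1e6) -> RayleighModel:
    """Find the form-factor decay rate ``c2`` matching a mean deflection angle.

    Solves ``mean_angle(c2) = target_mean_angle`` for ``c2`` by bracketed
    root finding; the mean angle is strictly decreasing in ``c2``.  ``c1`` is
    stored as 1 (it cancels in the normalized density).

    Parameters
    ----------
    target_mean_angle:
        Desired mean polar deflection in radians, in ``(0, pi/2)``.
    l:
        Form-factor exponent (default 2: zero forward density with a smooth
        small-angle peak).

    Raises
    ------
    ValueError
        If the target is not bracketed by ``c2`` in ``(0, c2_max]``.
    """
    if not 0.0 < target_mean_angle < math.pi / 2:
        raise ValueError("target mean angle must lie in (0, pi/2) radians")
    if l < 0:
        raise ValueError("form-factor exponent l must be >= 0")

    def mean_minus_target(c2: float) -> float:
        return rayleigh_mean_angle(RayleighModel(c2=c2, l=l), weighting) \
            - target_mean_angle

    c2_lo = 1e-9
    f_lo = mean_minus_target(c2_lo)
    if f_lo < 0:
        raise ValueError(
            f"target {target_mean_angle:.6g} rad exceeds the uncalibrated mean "
            f"angle {f_lo + target_mean_angle:.6g} rad; no c2 > 0 can reach it")
    c2_hi = 1.0
    while mean_minus_target(c2_hi) > 0:
        c2_hi *= 4.0
        if c2_hi > c2_max:
            raise ValueError(
                f"no root bracketed for c2 in (0, {c2_max:g}]; target mean "
                f"angle {target_mean_angle:.6g} rad may be too small for l={l}")
    c2 = optimize.brentq(mean_minus_target, c2_lo, c2_hi,
                         xtol=1e-12, rtol=8.9e-16, maxiter=200)
    model = RayleighModel(c2=float(c2), l=l)
    resid = abs(rayleigh_mean_angle(model, weighting) - target_mean_angle)
    if resid > 1e-6:
        raise RuntimeError(
            f"calibration residual {resid:.3g} rad exceeds 1e-6 rad")
    return model


def beta_from_cross_sections(compton_model: ComptonModel,
                             rayleigh_model: RayleighModel,
                             n_electrons: float,
                             weighting: str = "flat") -> float:
    """Rayleigh fraction from per-atom cross-sections.

    ``beta = sigma_r / (sigma_r + N_e * sigma_c)`` with each cross-section
    obtained by integrating the differential cross-section over ``[0, pi]``
    under the configured angular measure (the common ``2*pi`` factor cancels).

    ``n_electrons`` is the number of free electrons per atom weighting the
    Compton term of the per-atom combined cross-section.
    """
    if n_electrons < 0:
        raise ValueError("n_electrons must be >= 0")
    sigma_r = _rayleigh_norm(rayleigh_model, weighting)
    sigma_c = _compton_norm(compton_model, weighting)
    denom = sigma_r + n_electrons * sigma_c
    if denom == 0.0:
        raise ValueError("both cross-sections vanish; beta undefined")
    return sigma_r / denom


@dataclass(frozen=True)
class ScatterPhysics:
    """Bundle of the scattering models used by the transport engine."""

    compton: ComptonModel
    rayleigh: RayleighModel
    weighting: str = "flat"

    @classmethod
    def calibrated(cls, photon_energy_kev: float = 50.0,
                   target_mean_angle_deg: float = 4.3, l: float = 2.0,
                   weighting: str = "flat") -> "ScatterPhysics":
        """Standard setup: given beam energy, Rayleigh model calibrated to a
        target mean deflection (in degrees)."""
        ray = calibrate_form_factor(math.radians(target_mean_angle_deg), l=l,
                                    weighting=weighting)
        return cls(ComptonModel(photon_energy_kev), ray, weighting)

    def mixture_pdf(self, theta, material: Material):
        return angular_pdf(theta, material, self.compton, self.rayleigh,
                           self.weighting)

    def sample_compton(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return sample_compton_angles(rng, self.compton, size, self.weighting)

    def sample_rayleigh(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return sample_rayleigh_angles(rng, self.rayleigh, size, self.weighting)
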