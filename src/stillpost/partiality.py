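"""Spot-size model, Ewald-offset correction and full-intensity conversion.

A reflection is modeled as a sphere of reciprocal radius ``r_s``; a still
exposure records an infinitely thin slice through it at normal distance
``r_h`` from the Ewald sphere.  The Ewald-offset correction

    Eoc(r_h, r_s) = r_s**2 / (2 r_h**2 + r_s**2)

is a smooth (Lorentzian-derived) approximation of the geometric area ratio
``Eoc_area = 1 - r_h**2/r_s**2``; unlike the area ratio it is differentiable
everywhere, which the least-squares refinement requires.  The on-sphere
(areal) intensity is converted to the full spherical-volume intensity by the
volume correction ``V_c = (4/3) r_s`` (sphere volume over central-disc area).

The observed partial intensity is modeled as

    I_obs ~= G * Eoc * Vc**-1 * I_full,

so the full-intensity estimate is ``I_full = Vc * I_obs / (Eoc * G)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SpotProfile",
    "PredictedReflection",
    "predict_reflections",
    "spot_radius",
    "eoc",
    "eoc_area",
    "d_eoc_d_rh",
    "d_eoc_vcinv_d_rs",
    "volume_correction",
    "full_intensity",
]

# r_s floor keeping Eoc and V_c finite during refinement steps
MIN_SPOT_RADIUS = 1e-9


class InvalidProfileError(ValueError):
    """Raised when a spot profile yields a non-positive spot radius."""


@dataclass
class SpotProfile:
    """Four-parameter rocking-curve model of the reciprocal spot radius.

    gamma0  base radius (1/A), dominated by mosaicity / domain size;
    gamma_e spectral-dispersion and unit-cell-variation term, scales with
            tan(theta);
    gamma_x, gamma_y
            beam-divergence anisotropy along the equatorial / meridional
            detector axes.
    """

    gamma0: float
    gamma_e: float = 0.0
    gamma_x: float = 0.0
    gamma_y: float = 0.0

    def __post_init__(self) -> None:
        if self.gamma0 <= 0:
            raise InvalidProfileError(f"gamma0 must be positive, got {self.gamma0}")
        if min(self.gamma_e, self.gamma_x, self.gamma_y) < 0:
            raise InvalidProfileError("gamma_e, gamma_x, gamma_y must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([self.gamma0, self.gamma_e, self.gamma_x, self.gamma_y])


@dataclass
class PredictedReflection:
    """Derived per-observation geometry (vectorized over one frame)."""

    miller: np.ndarray  # (n, 3) int
    r_h: np.ndarray
    r_s: np.ndarray
    eoc: np.ndarray
    vc: np.ndarray
    theta: np.ndarray
    alpha: np.ndarray
    phi: np.ndarray
    pol: np.ndarray
    xy_calc: np.ndarray  # (n, 2) mm
    d: np.ndarray | None = None  # resolution (A), lambda / (2 sin theta)


def predict_reflections(frame, model) -> PredictedReflection:
    """Full per-observation geometry of ``frame`` under ``model``.

    ``model`` carries cell, orientation, spot profile and wavelength (the
    per-image parameter set); ``frame`` provides the observation table and
    detector metadata.  Unreachable reflections (|x| > 2/lambda) carry NaN
    in every derived column and are dropped by downstream selection.
    """
    from . import geometry
    from .polarization import PolarizationModel, polarization_factor

    geom = geometry.FrameGeometry.from_models(
        model.cell, model.orientation, model.wavelength, frame.distance, frame.beam_center
    )
    x = geometry.reciprocal_position(frame.obs.miller, geom.R, geom.O)
    r_h = geometry.ewald_offset(x, model.wavelength)
    theta, alpha, phi, reachable = geometry.bragg_and_azimuth(x, model.wavelength)
    r_s = spot_radius(theta, alpha, model.profile)
    with np.errstate(invalid="ignore"):
        e = np.where(reachable, r_s * r_s / (2.0 * r_h * r_h + r_s * r_s), np.nan)
        vc = np.where(reachable, (4.0 / 3.0) * r_s, np.nan)
    pol = polarization_factor(theta, phi, PolarizationModel(getattr(model, "fx", 1.0)))
    xy_calc, _ = geometry.predict_spot(x, geom)
    with np.errstate(invalid="ignore", divide="ignore"):
        sin_t = np.sin(theta)
        d = np.where(sin_t > 0, model.wavelength / (2.0 * np.where(sin_t > 0, sin_t, 1.0)), np.inf)
    return PredictedReflection(
        miller=frame.obs.miller,
        r_h=r_h,
        r_s=r_s,
        eoc=e,
        vc=vc,
        theta=theta,
        alpha=alpha,
        phi=phi,
        pol=pol,
        xy_calc=xy_calc,
        d=d,
    )


def spot_radius(theta, alpha, profile: SpotProfile):
    """r_s = gamma0 + gamma_e tan(theta) + sqrt((gy cos a)^2 + (gx sin a)^2)."""
    theta = np.asarray(theta, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    aniso = np.hypot(profile.gamma_y * np.cos(alpha), profile.gamma_x * np.sin(alpha))
    rs = profile.gamma0 + profile.gamma_e * np.tan(theta) + aniso
    return np.maximum(rs, MIN_SPOT_RADIUS)


def eoc(r_h, r_s):
    """Smooth Ewald-offset correction, in (0, 1]; 1 iff r_h = 0."""
    r_h = np.asarray(r_h, dtype=float)
    r_s = np.asarray(r_s, dtype=float)
    if np.any(r_s <= 0):
        raise InvalidProfileError("spot radius must be positive")
    rs2 = r_s * r_s
    return rs2 / (2.0 * r_h * r_h + rs2)


def eoc_area(r_h, r_s):
    """Geometric area-ratio correction, clamped to [0, 1].

    Diagnostic / oracle only: its derivative is undefined at |r_h| = r_s, so
    it never enters refinement.
    """
    r_h = np.asarray(r_h, dtype=float)
    r_s = np.asarray(r_s, dtype=float)
    if np.any(r_s <= 0):
        raise InvalidProfileError("spot radius must be positive")
    return np.clip(1.0 - (r_h * r_h) / (r_s * r_s), 0.0, 1.0)


def d_eoc_d_rh(r_h, r_s):
    """d(Eoc)/d(r_h) = -4 r_h r_s^2 / (2 r_h^2 + r_s^2)^2."""
    r_h = np.asarray(r_h, dtype=float)
    r_s = np.asarray(r_s, dtype=float)
    den = 2.0 * r_h * r_h + r_s * r_s
    return -4.0 * r_h * r_s * r_s / (den * den)


def d_eoc_vcinv_d_rs(r_h, r_s):
    """d(Eoc * Vc^-1)/d(r_s).

    Eoc * Vc^-1 = (3/4) r_s / (2 r_h^2 + r_s^2), hence the derivative is
    (3/4)(2 r_h^2 - r_s^2) / (2 r_h^2 + r_s^2)^2.
    """
    r_h = np.asarray(r_h, dtype=float)
    r_s = np.asarray(r_s, dtype=float)
    den = 2.0 * r_h * r_h + r_s * r_s
    return 0.75 * (2.0 * r_h * r_h - r_s * r_s) / (den * den)


def volume_correction(r_s):
    """V_c = (4/3) r_s: sphere volume over central-disc area."""
    r_s = np.asarray(r_s, dtype=float)
    if np.any(r_s <= 0):
        raise InvalidProfileError("spot radius must be positive")
    return (4.0 / 3.0) * r_s


def full_intensity(
    i_obs,
    sigma_obs,
    eoc_values,
    scale,
    vc,
    delta_scale=0.0,
    delta_eoc=0.0,
):
    """Convert observed partials to full-intensity estimates with errors.

    I_full = Vc * I_obs / (Eoc * G).  The variance combines the measurement
    error with the propagated parameter uncertainties,

        sigma_full^2 = (Vc/(Eoc G))^2 sigma_obs^2
                       + I_full^2 [ (dG/G)^2 + (dEoc/Eoc)^2 ],

    written in this form (rather than purely relative variances) so that
    observations with near-zero or negative measured intensity remain
    well-defined.
    """
    i_obs = np.asarray(i_obs, dtype=float)
    sigma_obs = np.asarray(sigma_obs, dtype=float)
    eoc_values = np.asarray(eoc_values, dtype=float)
    scale = np.asarray(scale, dtype=float)
    vc = np.asarray(vc, dtype=float)
    if np.any(eoc_values <= 0) or np.any(scale <= 0):
        raise ValueError("Eoc and G must be positive for full-intensity conversion")
    factor = vc / (eoc_values * scale)
    i_full = factor * i_obs
    rel2 = np.square(np.asarray(delta_scale, dtype=float) / scale) + np.square(
        np.asarray(delta_eoc, dtype=float) / eoc_values
    )
    var = np.square(factor * sigma_obs) + np.square(i_full) * rel2
    return i_full, np.sqrt(var)
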