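"""Reciprocal-space geometry for still diffraction frames.

Coordinate frame
----------------
Right-handed laboratory frame with the *z*-axis pointing toward the X-ray
source and the *y*-axis vertical.  The incident beam therefore travels along
-z and the incident-beam vector is ``S0 = (0, 0, -1/lambda)`` (|S0| is the
Ewald-sphere radius).  The detector is a plane normal to the beam at the
given crystal-to-detector distance; detector coordinates are in mm with *x*
horizontal and *y* vertical.

A reciprocal-lattice point for Miller index ``h`` sits at ``x = R O h``
where ``O`` is the upper-triangular orthogonalization matrix built from the
reciprocal cell and ``R = Rx(theta_x) Ry(theta_y) Rz(theta_z)`` is the
crystal-orientation matrix (the theta_z rotation is applied first).

All angles are stored internally in radians; constructors and reports use
degrees, which is what users and file formats carry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import gemmi
import numpy as np

__all__ = [
    "UnitCell",
    "CrystalOrientation",
    "FrameGeometry",
    "reciprocal_cell",
    "orthogonalization_matrix",
    "orthogonalization_derivatives",
    "rotation_matrix",
    "rotation_derivatives",
    "reciprocal_position",
    "ewald_offset",
    "predict_spot",
    "bragg_and_azimuth",
]


class DegenerateCellError(ValueError):
    """Raised when the six cell parameters do not define a valid lattice."""


@dataclass(frozen=True)
class UnitCell:
    """Direct-space unit cell: lengths in Angstrom, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float
    beta: float
    gamma: float

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise DegenerateCellError(f"non-positive cell length in {self}")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise DegenerateCellError(f"cell angle {ang} outside (0, 180)")
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        # positive-definiteness of the metric tensor <=> positive squared volume
        vol2 = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
        if vol2 <= 0.0:
            raise DegenerateCellError(f"metric tensor not positive definite for {self}")

    @property
    def parameters(self) -> tuple[float, float, float, float, float, float]:
        return (self.a, self.b, self.c, self.alpha, self.beta, self.gamma)

    def to_gemmi(self) -> gemmi.UnitCell:
        return gemmi.UnitCell(*self.parameters)

    @classmethod
    def from_parameters(cls, params) -> "UnitCell":
        return cls(*(float(p) for p in params))

    def d_spacing(self, hkl) -> np.ndarray:
        """Resolution d(h) in Angstrom for one index or an (n, 3) array."""
        g = self.to_gemmi()
        hkl = np.atleast_2d(np.asarray(hkl, dtype=int))
        return np.array([g.calculate_d([int(h), int(k), int(l)]) for h, k, l in hkl])


@dataclass
class CrystalOrientation:
    """Crystal setting angles theta_x, theta_y, theta_z, stored in radians.

    The rotations are applied in the order theta_z, theta_y, theta_x, i.e.
    the combined matrix is ``R = Rx Ry Rz``.
    """

    theta_x: float = 0.0
    theta_y: float = 0.0
    theta_z: float = 0.0

    @classmethod
    def from_degrees(cls, tx: float, ty: float, tz: float) -> "CrystalOrientation":
        return cls(math.radians(tx), math.radians(ty), math.radians(tz))

    def as_degrees(self) -> tuple[float, float, float]:
        return tuple(math.degrees(t) for t in (self.theta_x, self.theta_y, self.theta_z))


def reciprocal_cell(uc: UnitCell) -> tuple[tuple[float, ...], np.ndarray]:
    """Reciprocal-cell parameters (a*, b*, c*, alpha*, beta*, gamma*) and O.

    Lengths in 1/Angstrom, angles in degrees.  ``O`` is the upper-triangular
    orthogonalization matrix such that ``|O h| = 1/d(h)``.
    """
    r = uc.to_gemmi().reciprocal()
    params = r.parameters
    return params, orthogonalization_matrix(params)


def orthogonalization_matrix(recip_params) -> np.ndarray:
    """Upper-triangular O from reciprocal-cell parameters (degrees for angles).

    First row (a*, b* cos g*, c* cos b*); the remaining entries follow the
    standard Busing-Levy construction, so that h -> O h expresses the
    reciprocal-lattice point in orthonormal lab coordinates (before rotation)
    and |O h| = 1/d(h) for every Miller index.
    """
    as_, bs, cs, al, be, ga = recip_params
    ca, cb, cg = (math.cos(math.radians(x)) for x in (al, be, ga))
    sg = math.sin(math.radians(ga))
    if sg <= 0:
        raise DegenerateCellError("degenerate reciprocal cell (sin gamma* <= 0)")
    w2 = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
    if w2 <= 0:
        raise DegenerateCellError("degenerate reciprocal cell (negative volume term)")
    w = math.sqrt(w2)
    return np.array(
        [
            [as_, bs * cg, cs * cb],
            [0.0, bs * sg, cs * (ca - cb * cg) / sg],
            [0.0, 0.0, cs * w / sg],
        ]
    )


def orthogonalization_derivatives(recip_params) -> np.ndarray:
    """d(O)/d(p) for p in (a*, b*, c*, alpha*, beta*, gamma*), shape (6, 3, 3).

    Angle derivatives are per radian (the refinement works in radians).
    """
    as_, bs, cs, al, be, ga = recip_params
    ra, rb, rg = (math.radians(x) for x in (al, be, ga))
    ca, sa = math.cos(ra), math.sin(ra)
    cb, sb = math.cos(rb), math.sin(rb)
    cg, sg = math.cos(rg), math.sin(rg)
    w2 = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
    w = math.sqrt(w2)

    d = np.zeros((6, 3, 3))
    # a*
    d[0, 0, 0] = 1.0
    # b*
    d[1, 0, 1] = cg
    d[1, 1, 1] = sg
    # c*
    d[2, 0, 2] = cb
    d[2, 1, 2] = (ca - cb * cg) / sg
    d[2, 2, 2] = w / sg
    # alpha*: dca = -sa
    dw_da = sa * (ca - cb * cg) / w
    d[3, 1, 2] = cs * (-sa) / sg
    d[3, 2, 2] = cs * dw_da / sg
    # beta*: dcb = -sb
    dw_db = sb * (cb - ca * cg) / w
    d[4, 0, 2] = cs * (-sb)
    d[4, 1, 2] = cs * sb * cg / sg
    d[4, 2, 2] = cs * dw_db / sg
    # gamma*: dcg = -sg, dsg = cg
    dw_dg = sg * (cg - ca * cb) / w
    d[5, 0, 1] = -bs * sg
    d[5, 1, 1] = bs * cg
    d[5, 1, 2] = cs * ((sg * sg * cb) - (ca - cb * cg) * cg) / (sg * sg)
    d[5, 2, 2] = cs * (dw_dg * sg - w * cg) / (sg * sg)
    return d


def _rx(t: float) -> np.ndarray:
    c, s = math.cos(t), math.sin(t)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]], dtype=float)


def _ry(t: float) -> np.ndarray:
    c, s = math.cos(t), math.sin(t)
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]], dtype=float)


def _rz(t: float) -> np.ndarray:
    c, s = math.cos(t), math.sin(t)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]], dtype=float)


def rotation_matrix(orientation: CrystalOrientation) -> np.ndarray:
    """R = Rx(theta_x) Ry(theta_y) Rz(theta_z); theta_z is applied first."""
    return _rx(orientation.theta_x) @ _ry(orientation.theta_y) @ _rz(orientation.theta_z)


def rotation_derivatives(orientation: CrystalOrientation) -> tuple[np.ndarray, np.ndarray]:
    """(dR/dtheta_x, dR/dtheta_y); theta_z is never refined (zero gradient)."""
    tx, ty, tz = orientation.theta_x, orientation.theta_y, orientation.theta_z
    c, s = math.cos(tx), math.sin(tx)
    drx = np.array([[0, 0, 0], [0, -s, -c], [0, c, -s]], dtype=float)
    c, s = math.cos(ty), math.sin(ty)
    dry = np.array([[-s, 0, c], [0, 0, 0], [-c, 0, -s]], dtype=float)
    return drx @ _ry(ty) @ _rz(tz), _rx(tx) @ dry @ _rz(tz)


@dataclass
class FrameGeometry:
    """Per-frame geometry: wavelength (A), detector distance and beam center
    (mm), orthogonalization matrix O, rotation matrix R."""

    wavelength: float
    distance: float
    beam_center: tuple[float, float]
    O: np.ndarray
    R: np.ndarray

    @classmethod
    def from_models(
        cls,
        cell: UnitCell,
        orientation: CrystalOrientation,
        wavelength: float,
        distance: float,
        beam_center: tuple[float, float] = (0.0, 0.0),
    ) -> "FrameGeometry":
        if wavelength <= 0:
            raise ValueError("wavelength must be positive")
        _, O = reciprocal_cell(cell)
        return cls(wavelength, distance, tuple(beam_center), O, rotation_matrix(orientation))

    @property
    def s0(self) -> np.ndarray:
        return np.array([0.0, 0.0, -1.0 / self.wavelength])


def reciprocal_position(hkl, R: np.ndarray, O: np.ndarray) -> np.ndarray:
    """Lab-frame reciprocal-lattice positions x = R O h, shape (n, 3)."""
    h = np.atleast_2d(np.asarray(hkl, dtype=float))
    return h @ (R @ O).T


def ewald_offset(x: np.ndarray, wavelength: float) -> np.ndarray:
    """Signed Ewald-sphere offset r_h = |x + S0| - 1/lambda (1/A).

    Positive when the reciprocal-lattice point lies outside the Ewald sphere,
    negative inside, zero exactly in reflecting position.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    s = x.copy()
    s[:, 2] -= 1.0 / wavelength
    return np.linalg.norm(s, axis=1) - 1.0 / wavelength


def predict_spot(x: np.ndarray, geom: FrameGeometry) -> tuple[np.ndarray, np.ndarray]:
    """Predicted detector positions (mm) for reciprocal points x.

    The diffracted ray leaves the Ewald-sphere center along S = x + S0 and is
    intersected with the detector plane normal to the beam at the given
    distance.  Returns ``(xy_calc, predictable)``; rays with non-negative
    z-component never reach the detector and are flagged unpredictable
    (their coordinates are NaN).
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    s = x + geom.s0
    predictable = s[:, 2] < 0
    xy = np.full((len(s), 2), np.nan)
    t = np.where(predictable, -geom.distance / np.where(predictable, s[:, 2], -1.0), np.nan)
    xy[:, 0] = t * s[:, 0] + geom.beam_center[0]
    xy[:, 1] = t * s[:, 1] + geom.beam_center[1]
    return xy, predictable


def bragg_and_azimuth(
    x: np.ndarray, wavelength: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Bragg angle theta and the two azimuths (alpha, phi) per reflection.

    ``sin(theta) = lambda |x| / 2``.  ``alpha`` is measured from the vertical
    (meridional) detector axis toward the horizontal (equatorial) axis;
    ``phi`` is the angle between the reflection plane (spanned by x and the
    beam) and the laboratory horizontal.  Both are folded into [0, pi/2]
    because only squared trigonometric functions of them enter the models.
    Returns ``(theta, alpha, phi, reachable)`` where unreachable reflections
    (|x| > 2/lambda) carry NaN angles.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    q = np.linalg.norm(x, axis=1)
    reachable = q <= 2.0 / wavelength
    sin_theta = np.where(reachable, wavelength * q / 2.0, np.nan)
    theta = np.arcsin(sin_theta)
    # azimuth of the detector-plane projection of x
    ax, ay = np.abs(x[:, 0]), np.abs(x[:, 1])
    planar = (ax > 0) | (ay > 0)
    alpha = np.where(planar, np.arctan2(ax, ay), 0.0)  # 0 = meridional (vertical)
    phi = np.where(planar, np.arctan2(ay, ax), 0.0)  # 0 = horizontal reflection plane
    alpha = np.where(reachable, alpha, np.nan)
    phi = np.where(reachable, phi, np.nan)
    return theta, alpha, phi, reachable
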