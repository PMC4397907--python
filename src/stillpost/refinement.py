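"""Per-frame post-refinement by Levenberg-Marquardt least squares.

Each still image carries its own parameter set: linear scale G0 and
B-factor (group ``SF``), crystal orientation theta_x/theta_y (``CO``; the
rotation about the beam, theta_z, has zero gradient on the Ewald offset and
is never refined), the four spot-radius parameters gamma0/gamma_e/gamma_x/
gamma_y (``RR``), and the symmetry-constrained unit cell (``UC``).  Groups
are refined iteratively in "microcycles" against the current reference set
by minimizing the partiality target

    T_pr = sum_i (1/sigma_i^2) (I_obs,i - G Eoc_i Vc_i^-1 I_ref,i)^2,

and, for the geometric groups, a subsequent pass minimizes the spot-position
target T_xy = sum |x_obs - x_calc|^2 on a subset of strong spots.  After all
frames are refined, full intensities are merged into a new reference set and
the "macrocycle" repeats until convergence.

During one LM pass the Bragg angle and spot azimuth of each observation are
held fixed at their values under the current geometry (they are recomputed
between passes); this matches the dependency structure of the analytic
derivatives and keeps the Jacobian exact for the function being minimized.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np
import pandas as pd

from . import geometry, merging, partiality
from .geometry import CrystalOrientation, UnitCell
from .partiality import SpotProfile, predict_reflections
from .polarization import PolarizationModel, apply_polarization, polarization_factor

__all__ = [
    "PARAMETER_GROUPS",
    "FrameScale",
    "FrameModel",
    "ParameterUncertainty",
    "RefinementState",
    "RefinementConfig",
    "CellConstraints",
    "unit_cell_constraints",
    "scale_function",
    "FrameEvaluator",
    "levenberg_marquardt",
    "SingularNormalMatrix",
    "refine_group",
    "residuals_pr",
    "residuals_xy",
    "gradients_pr",
    "run_cycles",
    "RunResult",
    "merge_averaged",
    "merge_mean_scaled",
]

log = logging.getLogger("stillpost")

PARAMETER_GROUPS = ("SF", "CO", "RR", "UC")


@dataclass
class FrameScale:
    """Linear scale G0 and isotropic B-factor (A^2) of one image."""

    g0: float = 1.0
    b: float = 0.0

    def __post_init__(self) -> None:
        if self.g0 <= 0:
            raise ValueError("G0 must be positive")


@dataclass
class FrameModel:
    """All refinable per-image parameters (wavelength is fixed)."""

    scale: FrameScale
    orientation: CrystalOrientation
    profile: SpotProfile
    cell: UnitCell
    wavelength: float
    space_group: str = "P1"

    def copy(self) -> "FrameModel":
        return FrameModel(
            scale=replace(self.scale),
            orientation=replace(self.orientation),
            profile=replace(self.profile),
            cell=self.cell,
            wavelength=self.wavelength,
            space_group=self.space_group,
        )


@dataclass
class ParameterUncertainty:
    """Per-parameter standard errors from the covariance at the optimum."""

    errors: dict[str, float] = field(default_factory=dict)

    def update(self, other: dict[str, float]) -> None:
        self.errors.update(other)

    def get(self, name: str, default: float = 0.0) -> float:
        return self.errors.get(name, default)


@dataclass
class RefinementState:
    """Targets and flags for one refinement pass."""

    t_pr_start: float = math.nan
    t_pr_end: float = math.nan
    t_xy_start: float = math.nan
    t_xy_end: float = math.nan
    n_obs: int = 0
    n_iter: int = 0
    refined: bool = False
    message: str = ""


@dataclass
class RefinementConfig:
    """Protocol settings: group order, cycle counts, LM behaviour, selection."""

    group_order: tuple[str, ...] = ("SF", "CO", "RR", "UC")
    n_microcycles: int = 3
    max_macrocycles: int = 5
    lm_lambda0: float = 1e-3
    lm_max_iter: int = 50
    lm_rel_tol: float = 1e-4
    cc_convergence: float = 1e-3
    tpr_convergence: float = 1e-3
    selection: merging.SelectionCriteria = field(default_factory=merging.SelectionCriteria)
    group_selection: dict[str, merging.SelectionCriteria] | None = None
    strong_min_i_over_sigma: float = 5.0
    gamma_e_init: float = 0.002
    fx: float = 1.0
    target_cell: UnitCell | None = None
    anomalous: bool = False
    outlier_cutoff: float = 3.0
    n_shells: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        bad = set(self.group_order) - set(PARAMETER_GROUPS)
        if bad or len(set(self.group_order)) != len(self.group_order):
            raise ValueError(f"group order must be a permutation of a subset of {PARAMETER_GROUPS}")

    def criteria_for(self, group: str) -> merging.SelectionCriteria:
        if self.group_selection and group in self.group_selection:
            return self.group_selection[group]
        return self.selection


def scale_function(scale: FrameScale, theta, wavelength: float):
    """G = G0 exp(-2 B (sin theta / lambda)^2)."""
    st = np.sin(np.asarray(theta, dtype=float)) / wavelength
    return scale.g0 * np.exp(-2.0 * scale.b * st * st)


# ---------------------------------------------------------------------------
# Unit-cell symmetry constraints
# ---------------------------------------------------------------------------


@dataclass
class CellConstraints:
    """Crystal-system constraint pattern for unit-cell refinement.

    The refinement works on the free reciprocal-cell parameters (lengths in
    1/A, angles in radians); ``expansion`` maps d(free) -> d(full six
    reciprocal parameters) for the gradient chain rule.
    """

    crystal_system: str
    free_names: tuple[str, ...]
    expansion: np.ndarray  # (6, n_free)
    fixed_recip_angles_deg: tuple[float, float, float]

    @property
    def n_free(self) -> int:
        return len(self.free_names)

    def free_from_cell(self, cell: UnitCell) -> np.ndarray:
        rp = cell.to_gemmi().reciprocal().parameters
        full = np.array([rp[0], rp[1], rp[2], *np.radians(rp[3:6])])
        # least-squares pseudo-inverse of the expansion recovers free params
        return np.linalg.lstsq(self.expansion, full - self._offset(), rcond=None)[0]

    def _offset(self) -> np.ndarray:
        off = np.zeros(6)
        off[3:6] = np.radians(self.fixed_recip_angles_deg)
        # zero the offset where an angle is free (expansion row non-zero)
        for k in range(3, 6):
            if self.expansion[k].any():
                off[k] = 0.0
        return off

    def expand(self, free: np.ndarray) -> tuple[float, float, float, float, float, float]:
        """Free vector -> full reciprocal parameters (lengths 1/A, angles deg)."""
        full = self.expansion @ np.asarray(free, dtype=float) + self._offset()
        return (full[0], full[1], full[2], *np.degrees(full[3:6]))

    def direct_cell(self, free: np.ndarray) -> UnitCell:
        rp = self.expand(free)
        return UnitCell.from_parameters(gemmi.UnitCell(*rp).reciprocal().parameters)

    def project(self, params) -> UnitCell:
        """Map any six direct-cell parameters to the nearest constrained cell."""
        a, b, c, al, be, ga = (float(p) for p in params)
        cs = self.crystal_system
        if cs == "triclinic":
            return UnitCell(a, b, c, al, be, ga)
        if cs == "monoclinic":
            return UnitCell(a, b, c, 90.0, be, 90.0)
        if cs == "orthorhombic":
            return UnitCell(a, b, c, 90.0, 90.0, 90.0)
        if cs == "tetragonal":
            ab = 0.5 * (a + b)
            return UnitCell(ab, ab, c, 90.0, 90.0, 90.0)
        if cs in ("trigonal", "hexagonal"):
            ab = 0.5 * (a + b)
            return UnitCell(ab, ab, c, 90.0, 90.0, 120.0)
        if cs == "cubic":
            abc = (a + b + c) / 3.0
            return UnitCell(abc, abc, abc, 90.0, 90.0, 90.0)
        raise ValueError(f"unhandled crystal system {cs!r}")


def unit_cell_constraints(space_group: str) -> CellConstraints:
    """Free-parameter map for a space group's crystal system.

    Triclinic cells have six free parameters, monoclinic four, orthorhombic
    three, tetragonal and trigonal/hexagonal two (a and c), cubic one.
    Trigonal groups are assumed in the hexagonal-axes setting.
    """
    sg = gemmi.find_spacegroup_by_name(space_group)
    if sg is None:
        raise ValueError(f"unknown space group {space_group!r}")
    cs = sg.crystal_system_str()

    def cols(*pairs):
        m = np.zeros((6, len(pairs)))
        for j, rows in enumerate(pairs):
            for r in rows:
                m[r, j] = 1.0
        return m

    if cs == "triclinic":
        return CellConstraints(cs, ("a", "b", "c", "alpha", "beta", "gamma"),
                               np.eye(6), (0.0, 0.0, 0.0))
    if cs == "monoclinic":
        return CellConstraints(cs, ("a", "b", "c", "beta"),
                               cols([0], [1], [2], [4]), (90.0, 0.0, 90.0))
    if cs == "orthorhombic":
        return CellConstraints(cs, ("a", "b", "c"),
                               cols([0], [1], [2]), (90.0, 90.0, 90.0))
    if cs == "tetragonal":
        return CellConstraints(cs, ("a", "c"),
                               cols([0, 1], [2]), (90.0, 90.0, 90.0))
    if cs in ("trigonal", "hexagonal"):
        # hexagonal axes: gamma = 120 deg, hence gamma* = 60 deg
        return CellConstraints(cs, ("a", "c"),
                               cols([0, 1], [2]), (90.0, 90.0, 60.0))
    if cs == "cubic":
        return CellConstraints(cs, ("a",),
                               cols([0, 1, 2]), (90.0, 90.0, 90.0))
    raise ValueError(f"unhandled crystal system {cs!r} for {space_group}")


# ---------------------------------------------------------------------------
# Residuals and analytic Jacobians
# ---------------------------------------------------------------------------


class FrameEvaluator:
    """Residuals and analytic Jacobians of T_pr for one frame and group.

    Built against a reference set; observations absent from the reference
    or failing the selection criteria are skipped (and counted).  The Bragg
    angle, azimuths and the resulting scale/anisotropy weights are frozen at
    construction; geometry that the active group actually moves (rotation,
    cell, spot radius) is recomputed exactly on every evaluation.
    """

    def __init__(
        self,
        frame,
        model: FrameModel,
        reference: merging.ReferenceSet | None = None,
        criteria: merging.SelectionCriteria | None = None,
        anomalous: bool = False,
    ) -> None:
        self.model = model
        self.wavelength = model.wavelength
        pred = predict_reflections(frame, model)
        mask = np.isfinite(pred.eoc)
        if criteria is not None:
            mask &= merging.select_reflections(pred, frame.obs, criteria)
        if reference is not None:
            if frame.reduced is None:
                frame.reduced = merging.reduce_miller(frame.space_group, frame.obs.miller, anomalous)
            i_ref, found = reference.lookup(frame.reduced)
            mask &= found
        else:
            i_ref = np.ones(len(frame.obs))
        self.n_skipped = int((~mask).sum())
        self.h = frame.obs.miller[mask].astype(float)
        self.i_obs = frame.obs.intensity[mask]
        self.sigma = frame.obs.sigma[mask]
        self.i_ref = i_ref[mask]
        self.xy_obs = frame.obs.xy_obs[mask]
        self.n = int(mask.sum())
        # frozen per-observation geometry
        self.theta = pred.theta[mask]
        self.alpha = pred.alpha[mask]
        self.st2 = np.square(np.sin(self.theta) / self.wavelength)
        self.tan_theta = np.tan(self.theta)
        self.cos_alpha = np.cos(self.alpha)
        self.sin_alpha = np.sin(self.alpha)
        # base matrices at the current model
        self.recip_params, self.O0 = geometry.reciprocal_cell(model.cell)
        self.R0 = geometry.rotation_matrix(model.orientation)
        self.rh0 = geometry.ewald_offset(self.h @ (self.R0 @ self.O0).T, self.wavelength)
        self.rs0 = partiality.spot_radius(self.theta, self.alpha, model.profile)
        self.constraints = unit_cell_constraints(model.space_group)

    # -- parameter packing --------------------------------------------------

    def pack(self, group: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(p0, lower, upper) for the group's parameter vector."""
        m = self.model
        inf = math.inf
        if group == "SF":
            return (np.array([m.scale.g0, m.scale.b]),
                    np.array([1e-8, -inf]), np.array([inf, inf]))
        if group == "CO":
            return (np.array([m.orientation.theta_x, m.orientation.theta_y]),
                    np.array([-inf, -inf]), np.array([inf, inf]))
        if group == "RR":
            p = m.profile
            return (np.array([p.gamma0, p.gamma_e, p.gamma_x, p.gamma_y]),
                    np.array([1e-9, 0.0, 0.0, 0.0]), np.full(4, inf))
        if group == "UC":
            p0 = self.constraints.free_from_cell(m.cell)
            # lengths bounded away from zero; angle entries bounded in (0, pi)
            lo = np.full(self.constraints.n_free, -inf)
            hi = np.full(self.constraints.n_free, inf)
            for j, name in enumerate(self.constraints.free_names):
                if name in ("alpha", "beta", "gamma"):
                    lo[j], hi[j] = 1e-3, math.pi - 1e-3
                else:
                    lo[j] = 1e-6
            return p0, lo, hi
        raise ValueError(f"unknown group {group!r}")

    def apply(self, group: str, p: np.ndarray, model: FrameModel | None = None) -> FrameModel:
        """Return a copy of the model with the group's parameters replaced."""
        m = (model or self.model).copy()
        if group == "SF":
            m.scale = FrameScale(g0=float(p[0]), b=float(p[1]))
        elif group == "CO":
            m.orientation = CrystalOrientation(float(p[0]), float(p[1]), m.orientation.theta_z)
        elif group == "RR":
            m.profile = SpotProfile(
                gamma0=max(float(p[0]), partiality.MIN_SPOT_RADIUS),
                gamma_e=max(float(p[1]), 0.0),
                gamma_x=max(float(p[2]), 0.0),
                gamma_y=max(float(p[3]), 0.0),
            )
        elif group == "UC":
            m.cell = self.constraints.direct_cell(p)
        return m

    # -- model pieces -------------------------------------------------------

    def _pieces(self, group: str, p: np.ndarray):
        """(g0, b, rh, rs, extras) under parameter vector p for the group."""
        m = self.model
        g0, b = m.scale.g0, m.scale.b
        rh, rs = self.rh0, self.rs0
        extras: dict = {}
        if group == "SF":
            g0, b = p[0], p[1]
        elif group == "CO":
            orient = CrystalOrientation(p[0], p[1], m.orientation.theta_z)
            R = geometry.rotation_matrix(orient)
            x = self.h @ (R @ self.O0).T
            s = x.copy()
            s[:, 2] -= 1.0 / self.wavelength
            slen = np.linalg.norm(s, axis=1)
            rh = slen - 1.0 / self.wavelength
            extras = {"orient": orient, "s": s, "slen": slen}
        elif group == "RR":
            aniso = np.hypot(p[3] * self.cos_alpha, p[2] * self.sin_alpha)
            rs = np.maximum(p[0] + p[1] * self.tan_theta + aniso,
                            partiality.MIN_SPOT_RADIUS)
            extras = {"aniso": aniso}
        elif group == "UC":
            recip = self.constraints.expand(p)
            O = geometry.orthogonalization_matrix(recip)
            x = self.h @ (self.R0 @ O).T
            s = x.copy()
            s[:, 2] -= 1.0 / self.wavelength
            slen = np.linalg.norm(s, axis=1)
            rh = slen - 1.0 / self.wavelength
            extras = {"recip": recip, "s": s, "slen": slen}
        return g0, b, rh, rs, extras

    def residuals(self, group: str, p: np.ndarray) -> np.ndarray:
        g0, b, rh, rs, _ = self._pieces(group, p)
        G = g0 * np.exp(-2.0 * b * self.st2)
        eoc_vcinv = 0.75 * rs / (2.0 * rh * rh + rs * rs)
        return (self.i_obs - G * eoc_vcinv * self.i_ref) / self.sigma

    def t_pr(self, group: str = "SF", p: np.ndarray | None = None) -> float:
        if p is None:
            p = self.pack(group)[0]
        r = self.residuals(group, p)
        return float(r @ r)

    def jacobian(self, group: str, p: np.ndarray) -> np.ndarray:
        """Analytic d(residual)/d(p), shape (n_obs, n_params)."""
        g0, b, rh, rs, extras = self._pieces(group, p)
        G = g0 * np.exp(-2.0 * b * self.st2)
        den = 2.0 * rh * rh + rs * rs
        eoc_vcinv = 0.75 * rs / den
        if group == "SF":
            model_i = eoc_vcinv * self.i_ref
            d_g0 = -model_i * np.exp(-2.0 * b * self.st2) / self.sigma
            d_b = -G * model_i * (-2.0 * self.st2) / self.sigma
            return np.column_stack([d_g0, d_b])
        pref = -G * self.i_ref / self.sigma  # d(residual)/d(eoc_vcinv)
        if group == "RR":
            d_dr_s = 0.75 * (2.0 * rh * rh - rs * rs) / (den * den)
            aniso = extras["aniso"]
            with np.errstate(invalid="ignore", divide="ignore"):
                d_gy = np.where(aniso > 0, p[3] * self.cos_alpha**2 / aniso,
                                np.abs(self.cos_alpha))
                d_gx = np.where(aniso > 0, p[2] * self.sin_alpha**2 / aniso,
                                np.abs(self.sin_alpha))
            base = pref * d_dr_s
            return np.column_stack([base, base * self.tan_theta, base * d_gx, base * d_gy])
        # CO and UC act through r_h: d(eoc_vcinv)/d(rh) = -3 rs rh / den^2
        d_drh = -3.0 * rs * rh / (den * den)
        s_hat = extras["s"] / extras["slen"][:, None]
        cols = []
        if group == "CO":
            dRx, dRy = geometry.rotation_derivatives(extras["orient"])
            for dR in (dRx, dRy):
                dx = self.h @ (dR @ self.O0).T
                cols.append(pref * d_drh * np.einsum("ij,ij->i", s_hat, dx))
        else:  # UC
            dO_full = geometry.orthogonalization_derivatives(extras["recip"])
            for j in range(self.constraints.n_free):
                dO = np.tensordot(self.constraints.expansion[:, j], dO_full, axes=1)
                dx = self.h @ (self.R0 @ dO).T
                cols.append(pref * d_drh * np.einsum("ij,ij->i", s_hat, dx))
        return np.column_stack(cols)

    def eoc_delta(self, uncertainty: ParameterUncertainty) -> np.ndarray:
        """Propagated Eoc uncertainty per observation.

        Delta_Eoc^2 sums (d Eoc/d p)^2 Delta_p^2 over orientation, spot-
        radius and cell parameters (diagonal covariance approximation).
        """
        rh, rs = self.rh0, self.rs0
        den = 2.0 * rh * rh + rs * rs
        d_eoc_drh = -4.0 * rh * rs * rs / (den * den)
        d_eoc_drs = 4.0 * rh * rh * rs / (den * den)
        var = np.zeros(self.n)
        # orientation
        s = self.h @ (self.R0 @ self.O0).T
        s[:, 2] -= 1.0 / self.wavelength
        s_hat = s / np.linalg.norm(s, axis=1)[:, None]
        dRx, dRy = geometry.rotation_derivatives(self.model.orientation)
        for dR, name in ((dRx, "theta_x"), (dRy, "theta_y")):
            dp = uncertainty.get(name)
            if dp:
                dx = self.h @ (dR @ self.O0).T
                var += np.square(d_eoc_drh * np.einsum("ij,ij->i", s_hat, dx) * dp)
        # spot radius
        aniso = np.hypot(
            self.model.profile.gamma_y * self.cos_alpha,
            self.model.profile.gamma_x * self.sin_alpha,
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            drs = {
                "gamma0": np.ones(self.n),
                "gamma_e": self.tan_theta,
                "gamma_x": np.where(aniso > 0,
                                    self.model.profile.gamma_x * self.sin_alpha**2 / aniso, 0.0),
                "gamma_y": np.where(aniso > 0,
                                    self.model.profile.gamma_y * self.cos_alpha**2 / aniso, 0.0),
            }
        for name, dd in drs.items():
            dp = uncertainty.get(name)
            if dp:
                var += np.square(d_eoc_drs * dd * dp)
        # unit cell (free reciprocal parameters)
        dO_full = geometry.orthogonalization_derivatives(self.recip_params)
        for j, name in enumerate(self.constraints.free_names):
            dp = uncertainty.get(f"cell_{name}")
            if dp:
                dO = np.tensordot(self.constraints.expansion[:, j], dO_full, axes=1)
                dx = self.h @ (self.R0 @ dO).T
                var += np.square(d_eoc_drh * np.einsum("ij,ij->i", s_hat, dx) * dp)
        return np.sqrt(var)


# ---------------------------------------------------------------------------
# Levenberg-Marquardt core
# ---------------------------------------------------------------------------


class SingularNormalMatrix(RuntimeError):
    """Normal matrix could not be solved; the group is skipped."""


@dataclass
class LMResult:
    p: np.ndarray
    cost: float
    cost_start: float
    n_iter: int
    jac: np.ndarray
    residuals: np.ndarray
    converged: bool


def levenberg_marquardt(
    fun,
    jac,
    p0: np.ndarray,
    lower: np.ndarray | None = None,
    upper: np.ndarray | None = None,
    max_iter: int = 50,
    lambda0: float = 1e-3,
    rel_tol: float = 1e-4,
) -> LMResult:
    """Damped least squares with accept/reject steps.

    The damping parameter is multiplied by 10 on a rejected step and divided
    by 10 on acceptance, so the cost never increases.  Steps are projected
    onto the box [lower, upper].  Raises :class:`SingularNormalMatrix` when
    the damped normal equations cannot be solved.
    """
    p = np.asarray(p0, dtype=float).copy()
    r = fun(p)
    cost = float(r @ r)
    cost_start = cost
    lam = lambda0
    J = jac(p)
    n_iter = 0
    converged = False
    for _ in range(max_iter):
        n_iter += 1
        A = J.T @ J
        g = J.T @ r
        diag = np.diag(A).copy()
        scale = np.where(diag > 0, diag, 1.0)
        accepted = False
        for _ in range(12):
            try:
                step = np.linalg.solve(A + lam * np.diag(scale), -g)
            except np.linalg.LinAlgError as exc:
                raise SingularNormalMatrix(str(exc)) from exc
            if not np.all(np.isfinite(step)):
                raise SingularNormalMatrix("non-finite LM step")
            p_new = p + step
            if lower is not None:
                p_new = np.maximum(p_new, lower)
            if upper is not None:
                p_new = np.minimum(p_new, upper)
            r_new = fun(p_new)
            c_new = float(r_new @ r_new)
            if np.isfinite(c_new) and c_new <= cost:
                rel = (cost - c_new) / max(cost, 1e-300)
                p, r, cost = p_new, r_new, c_new
                lam = max(lam / 10.0, 1e-12)
                J = jac(p)
                accepted = True
                if rel < rel_tol:
                    converged = True
                break
            lam *= 10.0
            if lam > 1e12:
                break
        if not accepted or converged:
            converged = converged or not accepted
            break
    return LMResult(p, cost, cost_start, n_iter, J, r, converged)


# ---------------------------------------------------------------------------
# Group refinement and the micro/macrocycle protocol
# ---------------------------------------------------------------------------

_PARAM_NAMES = {
    "SF": ("g0", "b"),
    "CO": ("theta_x", "theta_y"),
    "RR": ("gamma0", "gamma_e", "gamma_x", "gamma_y"),
}


def _uncertainty_from_fit(res: LMResult, names: tuple[str, ...]) -> dict[str, float]:
    dof = max(len(res.residuals) - len(res.p), 1)
    chi2red = res.cost / dof
    try:
        cov = np.linalg.pinv(res.jac.T @ res.jac) * chi2red
        errs = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        errs = np.full(len(res.p), np.inf)
    return dict(zip(names, errs))


def residuals_pr(frame, model: FrameModel, reference: merging.ReferenceSet,
                 criteria: merging.SelectionCriteria | None = None):
    """Weighted T_pr residual vector and value at the current model."""
    ev = FrameEvaluator(frame, model, reference, criteria)
    r = ev.residuals("SF", ev.pack("SF")[0])
    return r, float(r @ r)


def gradients_pr(frame, model: FrameModel, reference: merging.ReferenceSet, group: str,
                 criteria: merging.SelectionCriteria | None = None) -> np.ndarray:
    """Analytic Jacobian of the T_pr residuals for one parameter group."""
    ev = FrameEvaluator(frame, model, reference, criteria)
    return ev.jacobian(group, ev.pack(group)[0])


def residuals_xy(frame, model: FrameModel, strong_mask: np.ndarray | None = None):
    """Spot-position residual vector (mm) and T_xy (mm^2).

    Unpredictable spots (diffracted ray away from the detector) are
    excluded and counted via the mask returned by the geometry module.
    """
    pred = predict_reflections(frame, model)
    ok = np.all(np.isfinite(pred.xy_calc), axis=1)
    if strong_mask is not None:
        ok &= strong_mask
    res = (frame.obs.xy_obs[ok] - pred.xy_calc[ok]).ravel()
    return res, float(res @ res)


def _refine_xy(frame, model: FrameModel, group: str, config: RefinementConfig):
    """LM pass minimizing T_xy over the group's parameters (CO or UC)."""
    strong = frame.obs.intensity / frame.obs.sigma >= config.strong_min_i_over_sigma
    if strong.sum() < 3:
        return model, math.nan, math.nan
    ev = FrameEvaluator(frame, model)  # packing/apply helpers only
    p0, lo, hi = ev.pack(group)
    h = frame.obs.miller[strong].astype(float)
    xy_obs = frame.obs.xy_obs[strong]

    def fun(p):
        m = ev.apply(group, p, model)
        geom = geometry.FrameGeometry.from_models(
            m.cell, m.orientation, m.wavelength, frame.distance, frame.beam_center
        )
        xy, ok = geometry.predict_spot(h @ (geom.R @ geom.O).T, geom)
        res = np.where(ok[:, None], xy_obs - xy, 1e3)
        return res.ravel()

    def jac(p):
        steps = np.where(np.abs(p) > 1e-4, np.abs(p) * 1e-6, 1e-8)
        cols = []
        for j in range(len(p)):
            pp = p.copy(); pp[j] += steps[j]
            pm = p.copy(); pm[j] -= steps[j]
            cols.append((fun(pp) - fun(pm)) / (2 * steps[j]))
        return np.column_stack(cols)

    t0 = float(np.sum(fun(p0) ** 2))
    try:
        res = levenberg_marquardt(fun, jac, p0, lo, hi,
                                  max_iter=config.lm_max_iter,
                                  lambda0=config.lm_lambda0,
                                  rel_tol=config.lm_rel_tol)
    except SingularNormalMatrix:
        return model, t0, t0
    return ev.apply(group, res.p, model), t0, res.cost


def refine_group(
    frame,
    model: FrameModel,
    group: str,
    reference: merging.ReferenceSet,
    config: RefinementConfig | None = None,
) -> tuple[FrameModel, ParameterUncertainty, RefinementState]:
    """Refine one parameter group of one frame against the reference set."""
    config = config or RefinementConfig()
    state = RefinementState()
    ev = FrameEvaluator(frame, model, reference, config.criteria_for(group),
                        anomalous=config.anomalous)
    p0, lo, hi = ev.pack(group)
    state.n_obs = ev.n
    if ev.n < len(p0) + 2:
        state.message = "unrefinable: too few observations overlap the reference"
        return model, ParameterUncertainty(), state
    try:
        res = levenberg_marquardt(
            lambda p: ev.residuals(group, p),
            lambda p: ev.jacobian(group, p),
            p0, lo, hi,
            max_iter=config.lm_max_iter,
            lambda0=config.lm_lambda0,
            rel_tol=config.lm_rel_tol,
        )
    except SingularNormalMatrix as exc:
        state.message = f"singular normal matrix: {exc}"
        return model, ParameterUncertainty(), state
    state.t_pr_start, state.t_pr_end = res.cost_start, res.cost
    state.n_iter = res.n_iter
    state.refined = True
    new_model = ev.apply(group, res.p)
    if group == "UC":
        names = tuple(f"cell_{n}" for n in ev.constraints.free_names)
    else:
        names = _PARAM_NAMES[group]
    unc = ParameterUncertainty(_uncertainty_from_fit(res, names))
    if group in ("CO", "UC"):
        new_model, state.t_xy_start, state.t_xy_end = _refine_xy(frame, new_model, group, config)
    return new_model, unc, state


# ---------------------------------------------------------------------------
# Pipeline: polarization, initial models, macrocycles, processing schemes
# ---------------------------------------------------------------------------


def initial_frame_model(frame, config: RefinementConfig) -> FrameModel:
    """Starting parameters: G0=1, B=0, gamma0 = rms Ewald offset of the
    frame's reflections, gamma_e from config, gamma_x = gamma_y = 0."""
    model = FrameModel(
        scale=FrameScale(1.0, 0.0),
        orientation=replace(frame.orientation),
        profile=SpotProfile(1e-3, config.gamma_e_init, 0.0, 0.0),
        cell=frame.cell,
        wavelength=frame.wavelength,
        space_group=frame.space_group,
    )
    _, O = geometry.reciprocal_cell(frame.cell)
    R = geometry.rotation_matrix(frame.orientation)
    rh = geometry.ewald_offset(frame.obs.miller.astype(float) @ (R @ O).T, frame.wavelength)
    gamma0 = float(np.sqrt(np.mean(np.square(rh))))
    model.profile = SpotProfile(max(gamma0, 1e-5), config.gamma_e_init, 0.0, 0.0)
    return model


def _apply_polarization_to_frames(frames, models, config: RefinementConfig) -> None:
    pol = PolarizationModel(config.fx)
    for frame, model in zip(frames, models):
        if frame.obs.pol_corrected:
            continue
        pred = predict_reflections(frame, model)
        p = polarization_factor(pred.theta, pred.phi, pol)
        p = np.where(np.isfinite(p) & (p > 0), p, 1.0)
        frame.obs.intensity, frame.obs.sigma = apply_polarization(
            frame.obs.intensity, frame.obs.sigma, p
        )
        frame.obs.pol_corrected = True


def _median_cell(frames) -> UnitCell:
    arr = np.array([f.cell.parameters for f in frames])
    med = np.median(arr, axis=0)
    return unit_cell_constraints(frames[0].space_group).project(med)


def _full_intensities(frames, models, uncertainties, config, target_cell):
    """Convert every frame's partials to full intensities for merging."""
    reduced_all, i_all, s_all = [], [], []
    n_frames_used = 0
    for frame, model, unc in zip(frames, models, uncertainties):
        if not merging.cell_within_tolerance(model.cell, target_cell,
                                             config.selection.max_cell_deviation):
            continue
        ev = FrameEvaluator(frame, model, None, config.selection, config.anomalous)
        if ev.n == 0:
            continue
        if frame.reduced is None:
            frame.reduced = merging.reduce_miller(frame.space_group, frame.obs.miller,
                                                  config.anomalous)
        pred = predict_reflections(frame, model)
        mask = np.isfinite(pred.eoc)
        mask &= merging.select_reflections(pred, frame.obs, config.selection)
        G = scale_function(model.scale, pred.theta, model.wavelength)
        dg0, db = unc.get("g0"), unc.get("b")
        st2 = np.square(np.sin(pred.theta[mask]) / model.wavelength)
        Gm = G[mask]
        delta_g = np.sqrt(np.square(Gm / model.scale.g0 * dg0)
                          + np.square(-2.0 * st2 * Gm * db))
        # eoc_delta is evaluated on the finite-Eoc subset, which is exactly
        # the evaluator's default mask
        ev_all = FrameEvaluator(frame, model)
        d_eoc_full = np.zeros(len(frame.obs))
        fin = np.isfinite(pred.eoc)
        if ev_all.n:
            d_eoc_full[fin] = ev_all.eoc_delta(unc)
        i_full, s_full = partiality.full_intensity(
            frame.obs.intensity[mask], frame.obs.sigma[mask],
            pred.eoc[mask], Gm, pred.vc[mask],
            delta_scale=delta_g, delta_eoc=d_eoc_full[mask],
        )
        reduced_all.append(frame.reduced[mask])
        i_all.append(i_full)
        s_all.append(s_full)
        n_frames_used += 1
    if not reduced_all:
        raise ValueError("no frames survive selection for merging")
    return (np.vstack(reduced_all), np.concatenate(i_all), np.concatenate(s_all),
            n_frames_used)


@dataclass
class RunResult:
    models: list[FrameModel]
    uncertainties: list[ParameterUncertainty]
    merged: merging.MergedDataset
    reference: merging.ReferenceSet
    history: pd.DataFrame
    param_summary: pd.DataFrame
    converged: bool
    n_macrocycles: int


def _param_summary(models) -> pd.DataFrame:
    rows = {}
    rows["G0"] = [m.scale.g0 for m in models]
    rows["B"] = [m.scale.b for m in models]
    rows["gamma0"] = [m.profile.gamma0 for m in models]
    rows["gamma_y"] = [m.profile.gamma_y for m in models]
    rows["gamma_x"] = [m.profile.gamma_x for m in models]
    rows["gamma_e"] = [m.profile.gamma_e for m in models]
    for i, name in enumerate(("a", "b", "c", "alpha", "beta", "gamma")):
        rows[f"cell_{name}"] = [m.cell.parameters[i] for m in models]
    return pd.DataFrame(
        {"mean": {k: float(np.mean(v)) for k, v in rows.items()},
         "sd": {k: float(np.std(v)) for k, v in rows.items()}}
    )


def run_cycles(frames, config: RefinementConfig | None = None) -> RunResult:
    """Full post-refinement protocol: microcycles within macrocycles.

    Per macrocycle every frame is refined over the configured group order
    for the configured number of microcycles; full intensities are then
    merged into a new reference set.  The loop ends at convergence
    (|change in CC1/2| and median relative change in T_pr below their
    thresholds) or after ``max_macrocycles``.
    """
    config = config or RefinementConfig()
    if not frames:
        raise ValueError("no frames supplied")
    models = [initial_frame_model(f, config) for f in frames]
    _apply_polarization_to_frames(frames, models, config)
    reference = merging.initial_reference(frames, models, config.selection, config.anomalous)
    target_cell = config.target_cell or _median_cell(frames)
    uncertainties = [ParameterUncertainty() for _ in frames]
    history_rows = []
    prev_cc = None
    prev_tpr = None
    converged = False
    n_macro = 0
    for macro in range(config.max_macrocycles):
        n_macro = macro + 1
        tpr_start, tpr_end, txy_start, txy_end = [], [], [], []
        frame_tpr = np.full(len(frames), np.nan)
        for i, frame in enumerate(frames):
            model = models[i]
            unc = uncertainties[i]
            first_start, last_end = math.nan, math.nan
            for _ in range(config.n_microcycles):
                for group in config.group_order:
                    model, g_unc, st = refine_group(frame, model, group, reference, config)
                    if st.refined:
                        unc.update(g_unc.errors)
                        if math.isnan(first_start):
                            first_start = st.t_pr_start
                        last_end = st.t_pr_end
                        if group in ("CO", "UC") and not math.isnan(st.t_xy_start):
                            txy_start.append(st.t_xy_start)
                            txy_end.append(st.t_xy_end)
            models[i] = model
            tpr_start.append(first_start)
            tpr_end.append(last_end)
            frame_tpr[i] = last_end
        reduced, i_full, s_full, n_used = _full_intensities(
            frames, models, uncertainties, config, target_cell
        )
        merged = merging.merge(reduced, i_full, s_full, frames[0].space_group,
                               target_cell, outlier_cutoff=config.outlier_cutoff)
        cc = merging.cc_half(reduced, i_full, s_full, seed=config.seed)
        history_rows.append({
            "macrocycle": n_macro,
            "mean_t_pr_start": float(np.nanmean(tpr_start)) if tpr_start else math.nan,
            "mean_t_pr_end": float(np.nanmean(tpr_end)) if tpr_end else math.nan,
            "mean_t_xy_start": float(np.nanmean(txy_start)) if txy_start else math.nan,
            "mean_t_xy_end": float(np.nanmean(txy_end)) if txy_end else math.nan,
            "cc_half": cc,
            "n_frames_merged": n_used,
        })
        reference = merging.ReferenceSet.from_merged(merged)
        if prev_cc is not None and np.isfinite(cc) and np.isfinite(prev_cc):
            dcc = abs(cc - prev_cc)
            with np.errstate(invalid="ignore", divide="ignore"):
                rel = np.abs(frame_tpr - prev_tpr) / np.where(frame_tpr > 0, frame_tpr, 1.0)
            med = float(np.nanmedian(rel))
            if dcc < config.cc_convergence and med < config.tpr_convergence:
                converged = True
        prev_cc = cc
        prev_tpr = frame_tpr.copy()
        if converged:
            break
    stats = merging.merging_stats(
        merging.MergedDataset(merged.table, merged.space_group, merged.cell,
                              d_max=config.selection.d_max, d_min=config.selection.d_min),
        n_shells=config.n_shells,
        reduced_obs=reduced, i_obs=i_full, sigma_obs=s_full, seed=config.seed,
    )
    merged.cc_half = prev_cc
    merged.stats = stats
    merged.d_max = config.selection.d_max
    merged.d_min = config.selection.d_min
    return RunResult(
        models=models,
        uncertainties=uncertainties,
        merged=merged,
        reference=reference,
        history=pd.DataFrame(history_rows),
        param_summary=_param_summary(models),
        converged=converged,
        n_macrocycles=n_macro,
    )


def merge_averaged(frames, config: RefinementConfig | None = None) -> merging.MergedDataset:
    """"Averaged merged" scheme: plain per-index average of polarization-
    corrected partials, without Ewald-offset correction or scaling."""
    config = config or RefinementConfig()
    models = [initial_frame_model(f, config) for f in frames]
    _apply_polarization_to_frames(frames, models, config)
    reduced_all, i_all, s_all = [], [], []
    for frame in frames:
        if frame.reduced is None:
            frame.reduced = merging.reduce_miller(frame.space_group, frame.obs.miller,
                                                  config.anomalous)
        reduced_all.append(frame.reduced)
        i_all.append(frame.obs.intensity)
        s_all.append(frame.obs.sigma)
    reduced = np.vstack(reduced_all)
    i_obs = np.concatenate(i_all)
    s_obs = np.concatenate(s_all)
    rows = []
    for hkl, idx in merging._group_slices(reduced):
        mi = float(i_obs[idx].mean())
        ms = float(np.sqrt(np.sum(np.square(s_obs[idx]))) / len(idx))
        rows.append((hkl[0], hkl[1], hkl[2], mi, ms, len(idx), 0))
    table = pd.DataFrame(rows, columns=["h", "k", "l", "I", "sigma", "n_obs", "n_rej"])
    ds = merging.MergedDataset(table, frames[0].space_group, _median_cell(frames),
                               d_max=config.selection.d_max, d_min=config.selection.d_min)
    ds.cc_half = merging.cc_half(reduced, i_obs, s_obs, seed=config.seed)
    return ds


def merge_mean_scaled(frames, config: RefinementConfig | None = None) -> merging.MergedDataset:
    """"Mean-intensity partiality corrected" scheme: mean-intensity scaling
    plus Ewald-offset correction from the starting parameters, then merge."""
    config = config or RefinementConfig()
    models = [initial_frame_model(f, config) for f in frames]
    _apply_polarization_to_frames(frames, models, config)
    ref = merging.initial_reference(frames, models, config.selection, config.anomalous)
    table = pd.DataFrame({
        "h": ref.miller[:, 0], "k": ref.miller[:, 1], "l": ref.miller[:, 2],
        "I": ref.i_ref, "sigma": ref.sigma, "n_obs": ref.n_obs, "n_rej": 0,
    })
    ds = merging.MergedDataset(table, frames[0].space_group, _median_cell(frames),
                               d_max=config.selection.d_max, d_min=config.selection.d_min)
    return ds
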