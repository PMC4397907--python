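"""Synthetic still-frame generator with stored ground truth.

Every pipeline stage is testable against known truth: reference intensities
are drawn from a Wilson-like exponential distribution with an overall
B-factor falloff; crystal orientations are uniform on the rotation group;
per-frame scale, B and spot-radius parameters are drawn from realistic
ranges; each reflection close enough to the Ewald sphere (|r_h| <= k r_s)
is "observed" with intensity

    I_obs = P * G * Eoc * Vc^-1 * I_true + eps,  eps ~ N(0, sigma^2),
    sigma^2 = gain * I + background,

where P is the polarization attenuation of the nearly fully horizontally
polarized beam.  Spot positions come from the same detector projection the
pipeline uses.  Starting models handed to the pipeline are the truth
perturbed by seeded Gaussian errors, emulating indexing/integration
inaccuracies.

Default study conditions: a myoglobin-like hexagonal lysozyme-free cell
(P6, a = b = 90.8, c = 45.6 A) at lambda 1.3 A, truncated to 2.5 A
resolution so that a frame carries a few hundred spots (comparable to the
thermolysin experiment's ~350 per image), and 100 frames per data set.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
from scipy.spatial.transform import Rotation

from . import geometry, merging, partiality
from .frameio import ObservationTable, StillFrame
from .geometry import CrystalOrientation, UnitCell
from .partiality import SpotProfile
from .polarization import PolarizationModel, polarization_factor
from .refinement import FrameModel, FrameScale, unit_cell_constraints

__all__ = [
    "NoiseModel",
    "PerturbationSpec",
    "GroundTruth",
    "DEFAULT_CELL",
    "DEFAULT_SPACE_GROUP",
    "simulate_reference",
    "simulate_frames",
    "perturb_frames",
]

DEFAULT_CELL = UnitCell(90.8, 90.8, 45.6, 90.0, 90.0, 120.0)
DEFAULT_SPACE_GROUP = "P6"
DEFAULT_WAVELENGTH = 1.3
DEFAULT_D_MIN = 2.5
DEFAULT_D_MAX = 20.0


@dataclass
class NoiseModel:
    """Counting-like measurement noise: sigma^2 = gain * I + background."""

    gain: float = 1.0
    background: float = 25.0
    enabled: bool = True
    xy_sd: float = 0.03  # spot-centroid noise (mm)

    def sigma(self, intensity: np.ndarray) -> np.ndarray:
        return np.sqrt(self.gain * np.maximum(intensity, 0.0) + self.background)


@dataclass
class PerturbationSpec:
    """Seeded Gaussian perturbations applied to starting models (truth kept).

    ``orientation_deg`` perturbs theta_x/theta_y (degrees), ``cell_frac``
    the free cell lengths (fractional), ``g0_frac`` the linear scale
    (fractional) and ``gamma_frac`` the spot-radius parameters (fractional).
    """

    orientation_deg: float = 0.05
    cell_frac: float = 0.002
    g0_frac: float = 0.2
    gamma_frac: float = 0.2


@dataclass
class GroundTruth:
    """Everything the simulator knows: regenerate with the same seed and
    every value reproduces bit-identically."""

    cell: UnitCell
    space_group: str
    wavelength: float
    d_min: float
    d_max: float
    miller: np.ndarray  # (m, 3) unique reduced indices
    i_true: np.ndarray  # (m,)
    seed: int
    models: list[FrameModel] = field(default_factory=list)  # true per-frame models
    frame_truth: list[dict] = field(default_factory=list)  # per-obs r_h, r_s, eoc, I_partial
    n_regenerated: int = 0  # empty frames redrawn with a new orientation

    def lookup_true(self, reduced: np.ndarray) -> np.ndarray:
        index = {tuple(hkl): i for i, hkl in enumerate(map(tuple, self.miller))}
        idx = np.array([index.get(tuple(hkl), -1) for hkl in np.asarray(reduced)])
        out = np.full(len(idx), np.nan)
        ok = idx >= 0
        out[ok] = self.i_true[idx[ok]]
        return out


def simulate_reference(
    cell: UnitCell = DEFAULT_CELL,
    space_group: str = DEFAULT_SPACE_GROUP,
    d_min: float = DEFAULT_D_MIN,
    d_max: float = DEFAULT_D_MAX,
    seed: int = 0,
    mean_intensity: float = 1000.0,
    b_wilson: float = 15.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Ground-truth intensities for the unique reflections of a cell.

    Intensities are exponentially distributed (acentric Wilson statistics)
    around a mean that falls off as exp(-2 B_overall (sin theta/lambda)^2).
    """
    rng = np.random.default_rng(seed)
    miller, _ = merging.unique_reflection_set(cell, space_group, d_max, d_min)
    _, O = geometry.reciprocal_cell(cell)
    inv_d = np.linalg.norm(miller.astype(float) @ O.T, axis=1)
    s = inv_d / 2.0  # sin(theta)/lambda
    mean = mean_intensity * np.exp(-2.0 * b_wilson * s * s)
    return miller, rng.exponential(mean)


def _expand_to_sphere(miller: np.ndarray, space_group: str):
    """All symmetry- and Friedel-equivalents of the unique set.

    Returns ``(full_miller, parent_idx)`` where ``parent_idx[j]`` is the row
    of the unique array each equivalent descends from (duplicates removed).
    """
    ops = gemmi.find_spacegroup_by_name(space_group).operations()
    rots = [np.array(op.rot, dtype=float).reshape(3, 3) / op.DEN for op in ops.sym_ops]
    blocks = []
    parents = []
    m = miller.astype(float)
    for rot in rots:
        for sign in (1.0, -1.0):
            blocks.append(np.rint(sign * m @ rot).astype(int))
            parents.append(np.arange(len(miller)))
    full = np.vstack(blocks)
    parent = np.concatenate(parents)
    uniq, first = np.unique(full, axis=0, return_index=True)
    return uniq, parent[first]


def _random_orientation(rng: np.random.Generator) -> CrystalOrientation:
    """Uniform (Haar) random orientation expressed as theta_x/theta_y/theta_z."""
    mat = Rotation.random(random_state=rng).as_matrix()
    tx, ty, tz = Rotation.from_matrix(mat).as_euler("XYZ")
    return CrystalOrientation(float(tx), float(ty), float(tz))


def simulate_frames(
    miller: np.ndarray,
    i_true: np.ndarray,
    n_frames: int = 100,
    cell: UnitCell = DEFAULT_CELL,
    space_group: str = DEFAULT_SPACE_GROUP,
    wavelength: float = DEFAULT_WAVELENGTH,
    d_min: float = DEFAULT_D_MIN,
    d_max: float = DEFAULT_D_MAX,
    noise: NoiseModel | None = None,
    perturbation: PerturbationSpec | None = None,
    seed: int = 0,
    observe_k: float = 3.0,
    fx: float = 1.0,
    distance: float = 150.0,
    beam_center: tuple[float, float] = (96.0, 96.0),
    pixel_size: float = 0.08,
    cell_jitter_frac: float = 0.001,
    min_obs: int = 20,
) -> tuple[list[StillFrame], GroundTruth]:
    """Generate ``n_frames`` still frames plus their stored ground truth.

    Frame headers carry the *perturbed* starting models (what an indexing
    program would hand the pipeline); the returned :class:`GroundTruth`
    keeps the true models for recovery scoring.  Frames with fewer than
    ``min_obs`` reflections in diffracting range are regenerated with a
    fresh orientation (counted in ``GroundTruth.n_regenerated``).
    """
    noise = noise if noise is not None else NoiseModel()
    rng = np.random.default_rng(seed)
    gt = GroundTruth(
        cell=cell, space_group=space_group, wavelength=wavelength,
        d_min=d_min, d_max=d_max, miller=miller, i_true=i_true, seed=seed,
    )
    full_miller, parent = _expand_to_sphere(miller, space_group)
    hf = full_miller.astype(float)
    constraints = unit_cell_constraints(space_group)
    pol = PolarizationModel(fx)
    frames: list[StillFrame] = []
    for fid in range(n_frames):
        for _attempt in range(50):
            orient = _random_orientation(rng)
            g0 = float(rng.lognormal(0.0, 0.3))
            b = float(rng.uniform(0.0, 8.0))
            gamma0 = float(np.clip(rng.normal(1.3e-3, 2e-4), 3e-4, None))
            gamma_e = float(np.clip(rng.normal(2.0e-3, 3e-4), 1e-4, None))
            gamma_x = float(abs(rng.normal(0.0, 8e-5)))
            gamma_y = float(abs(rng.normal(0.0, 8e-5)))
            jitter = 1.0 + cell_jitter_frac * rng.standard_normal()
            true_cell = constraints.project(
                [p * jitter if i < 3 else p for i, p in enumerate(cell.parameters)]
            )
            model = FrameModel(
                scale=FrameScale(g0, b),
                orientation=orient,
                profile=SpotProfile(gamma0, gamma_e, gamma_x, gamma_y),
                cell=true_cell,
                wavelength=wavelength,
                space_group=space_group,
            )
            geom = geometry.FrameGeometry.from_models(
                true_cell, orient, wavelength, distance, beam_center
            )
            x = hf @ (geom.R @ geom.O).T
            r_h = geometry.ewald_offset(x, wavelength)
            theta, alpha, phi, reachable = geometry.bragg_and_azimuth(x, wavelength)
            with np.errstate(invalid="ignore"):
                r_s = partiality.spot_radius(theta, alpha, model.profile)
                sel = reachable & (np.abs(r_h) <= observe_k * r_s)
            xy, predictable = geometry.predict_spot(x, geom)
            sel &= predictable
            if sel.sum() >= min_obs:
                break
            gt.n_regenerated += 1
        idx = np.flatnonzero(sel)
        eoc = partiality.eoc(r_h[idx], r_s[idx])
        vc = partiality.volume_correction(r_s[idx])
        g = g0 * np.exp(-2.0 * b * np.square(np.sin(theta[idx]) / wavelength))
        i_partial = g * eoc / vc * i_true[parent[idx]]
        p_factor = polarization_factor(theta[idx], phi[idx], pol)
        i_recorded = p_factor * i_partial
        sig = noise.sigma(i_recorded)
        i_obs = i_recorded + (rng.normal(0.0, sig) if noise.enabled else 0.0)
        if noise.enabled and noise.xy_sd > 0:
            xy_obs = xy[idx] + rng.normal(0.0, noise.xy_sd, size=(len(idx), 2))
        else:
            xy_obs = xy[idx]
        gt.models.append(model)
        gt.frame_truth.append({
            "miller": full_miller[idx],
            "r_h": r_h[idx],
            "r_s": r_s[idx],
            "eoc": eoc,
            "i_partial": i_partial,
            "xy": xy[idx],
            "pol": p_factor,
        })
        start = model.copy()
        frames.append(StillFrame(
            frame_id=f"sim{fid:05d}",
            wavelength=wavelength,
            cell=start.cell,
            space_group=space_group,
            orientation=start.orientation,
            distance=distance,
            beam_center=beam_center,
            pixel_size=pixel_size,
            obs=ObservationTable(
                miller=full_miller[idx],
                intensity=np.asarray(i_obs, dtype=float),
                sigma=sig,
                xy_obs=xy_obs,
            ),
        ))
    if perturbation is not None:
        starting = perturb_frames(gt.models, perturbation,
                                  seed=int(rng.integers(2**31 - 1)))
        for frame, pert in zip(frames, starting):
            frame.cell = pert.cell
            frame.orientation = pert.orientation
    return frames, gt


def perturb_frames(
    models: list[FrameModel],
    magnitudes: PerturbationSpec,
    seed: int = 0,
) -> list[FrameModel]:
    """Seeded Gaussian perturbations of per-frame models (truth unchanged)."""
    rng = np.random.default_rng(seed)
    out = []
    for model in models:
        m = model.copy()
        sd = math.radians(magnitudes.orientation_deg)
        m.orientation = CrystalOrientation(
            m.orientation.theta_x + rng.normal(0.0, sd),
            m.orientation.theta_y + rng.normal(0.0, sd),
            m.orientation.theta_z,
        )
        if magnitudes.cell_frac > 0:
            constraints = unit_cell_constraints(m.space_group)
            factor = 1.0 + rng.normal(0.0, magnitudes.cell_frac)
            m.cell = constraints.project(
                [p * factor if i < 3 else p for i, p in enumerate(m.cell.parameters)]
            )
        if magnitudes.g0_frac > 0:
            m.scale = FrameScale(
                max(m.scale.g0 * (1.0 + rng.normal(0.0, magnitudes.g0_frac)), 1e-3),
                m.scale.b,
            )
        if magnitudes.gamma_frac > 0:
            p = m.profile
            f = lambda v: max(v * (1.0 + rng.normal(0.0, magnitudes.gamma_frac)), 0.0)
            m.profile = SpotProfile(max(f(p.gamma0), 1e-6), f(p.gamma_e),
                                    f(p.gamma_x), f(p.gamma_y))
        out.append(m)
    return out


def write_ground_truth(gt: GroundTruth, path) -> None:
    """JSON sidecar with the scalar truth per frame (for test harnesses)."""
    payload = {
        "seed": gt.seed,
        "space_group": gt.space_group,
        "cell": list(gt.cell.parameters),
        "wavelength": gt.wavelength,
        "d_min": gt.d_min,
        "d_max": gt.d_max,
        "n_regenerated": gt.n_regenerated,
        "frames": [
            {
                "g0": m.scale.g0,
                "b": m.scale.b,
                "theta_deg": list(m.orientation.as_degrees()),
                "gamma": list(m.profile.as_array()),
                "cell": list(m.cell.parameters),
            }
            for m in gt.models
        ],
        "miller": gt.miller.tolist(),
        "i_true": gt.i_true.tolist(),
    }
    Path(path).write_text(json.dumps(payload))
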