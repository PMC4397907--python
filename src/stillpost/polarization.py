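"""Polarization correction for a (nearly) horizontally polarized beam.

For a reflection at Bragg angle theta whose reflection plane makes angle phi
with the laboratory horizontal, the recorded intensity is attenuated by

    P = fx (sin^2 phi + cos^2 phi cos^2 2theta)
      + fy (cos^2 phi + sin^2 phi cos^2 2theta),

where fx and fy (fx + fy = 1) are the horizontal and vertical polarized
fractions.  XFEL beams are nearly 100% horizontally polarized, so fx
defaults to 1; the correction divides the observation by P once, before
reference generation and refinement.  No Lorentz factor applies to stills.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PolarizationModel", "polarization_factor", "apply_polarization"]


@dataclass(frozen=True)
class PolarizationModel:
    fx: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fx <= 1.0:
            raise ValueError(f"fx must be in [0, 1], got {self.fx}")

    @property
    def fy(self) -> float:
        return 1.0 - self.fx


def polarization_factor(theta, phi, model: PolarizationModel = PolarizationModel()):
    theta = np.asarray(theta, dtype=float)
    phi = np.asarray(phi, dtype=float)
    c2t = np.cos(2.0 * theta) ** 2
    sp2 = np.sin(phi) ** 2
    cp2 = np.cos(phi) ** 2
    return model.fx * (sp2 + cp2 * c2t) + model.fy * (cp2 + sp2 * c2t)


def apply_polarization(i_obs, sigma_obs, p):
    """Divide intensity and sigma by the polarization factor P (> 0)."""
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0):
        raise ValueError("polarization factor must be positive")
    return np.asarray(i_obs, dtype=float) / p, np.asarray(sigma_obs, dtype=float) / p
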