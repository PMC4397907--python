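"""Shared fixtures: small synthetic data sets generated at test time."""

import numpy as np
import pytest

from stillpost import merging, refinement, simulate
from stillpost.geometry import UnitCell


@pytest.fixture(scope="session")
def small_reference():
    """Ground-truth intensities for the default (myoglobin-like) cell."""
    miller, i_true = simulate.simulate_reference(seed=11)
    return miller, i_true


@pytest.fixture(scope="session")
def noiseless_frames(small_reference):
    """Ten noise-free frames with true models, polarization-corrected."""
    miller, i_true = small_reference
    frames, gt = simulate.simulate_frames(
        miller, i_true, n_frames=10,
        noise=simulate.NoiseModel(enabled=False), seed=11,
    )
    cfg = refinement.RefinementConfig()
    models = [refinement.initial_frame_model(f, cfg) for f in frames]
    refinement._apply_polarization_to_frames(frames, models, cfg)
    return frames, gt


@pytest.fixture(scope="session")
def truth_reference(small_reference):
    miller, i_true = small_reference
    return merging.ReferenceSet(
        miller=miller,
        i_ref=i_true,
        sigma=np.ones(len(i_true)),
        n_obs=np.ones(len(i_true), dtype=int),
    )


@pytest.fixture(scope="session")
def noisy_frames(small_reference):
    """Twenty noisy frames with perturbed starting models (pipeline input)."""
    miller, i_true = small_reference
    frames, gt = simulate.simulate_frames(
        miller, i_true, n_frames=20,
        perturbation=simulate.PerturbationSpec(), seed=12,
    )
    return frames, gt


@pytest.fixture
def toy_cell():
    return UnitCell(10.0, 10.0, 10.0, 90.0, 90.0, 90.0)
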