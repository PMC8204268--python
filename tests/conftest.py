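"""Shared fixtures: phantoms, simulated frames, and the count-level run.

The expensive end-to-end bootstrap/registration run is session-scoped so
the count-level and SUVr-propagation tests share one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

from petregu.orchestrate import ExperimentDesign, run_uncertainty_analysis
from petregu.phantom import FRAME_SPECS, make_activity, make_phantom
from petregu.recon import ReconConfig, osem
from petregu.simulate import (
    Sinogram,
    attenuation_factors,
    default_system,
    forward_project,
)


@pytest.fixture(scope="session")
def phantom64():
    """Default-scale phantom: labels, regions, mu-map, T1w."""
    return make_phantom(1)


@pytest.fixture(scope="session")
def system64(phantom64):
    labels = phantom64[0]
    return default_system(labels)


@pytest.fixture(scope="session")
def late_neg_activity(phantom64, system64):
    labels, regions, _, _ = phantom64
    return make_activity(labels, regions, FRAME_SPECS["late_neg"], system64)


@pytest.fixture(scope="session")
def noiseless_ac_recon(phantom64, system64, late_neg_activity):
    """Full-count noiseless AC reconstruction (2 iterations) of late_neg."""
    _, _, mu, _ = phantom64
    af = attenuation_factors(mu, system64)
    trues = Sinogram(af.values * forward_project(late_neg_activity, system64).values)
    pet = osem(trues, system64, ReconConfig(mode="AC", iterations=2), af=af)
    return pet, af, trues


@pytest.fixture(scope="session")
def count_level_run():
    """The count-level experiment: late_neg, AC x 2 iterations, 5% vs 60%
    counts, 20 bootstrap replicates on the default 64-cube phantom."""
    design = ExperimentDesign(
        frames=("late_neg",),
        modes=("AC",),
        iteration_grid=(2,),
        count_levels=(0.05, 0.60),
        n_bootstrap=20,
        voxel_sizes=(2.0,),
        grid_shape=(64, 64, 48),
    )
    matrix, records = run_uncertainty_analysis(design, 1)
    return design, matrix, records


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
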