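import numpy as np
import pytest

from petregu.grid import VoxelGrid
from petregu.simulate import (
    ListModeData,
    SystemModel,
    attenuation_factors,
    bin_events,
    bootstrap_listmode,
    default_system,
    forward_project,
    get_projector,
    load_listmode,
    save_listmode,
    simulate_prompts,
)


def _supersampled_ball(shape, voxel, radius_mm, sub=3, axis2_cylinder=False):
    """Fill fractions of a centred ball (or transaxial cylinder) per voxel."""
    n = shape[0]
    offs = (np.arange(sub) + 0.5) / sub - 0.5
    vals = np.zeros(shape)
    idx = np.indices(shape).astype(float)
    centre = (np.asarray(shape) - 1) / 2.0
    acc = np.zeros(shape)
    for ox in offs:
        for oy in offs:
            for oz in offs:
                x = (idx[0] + ox - centre[0]) * voxel
                y = (idx[1] + oy - centre[1]) * voxel
                z = (idx[2] + oz - centre[2]) * voxel
                r2 = x**2 + y**2 if axis2_cylinder else x**2 + y**2 + z**2
                acc += r2 <= radius_mm**2
    return acc / sub**3


def test_zero_activity_projects_to_zero():
    g = VoxelGrid(np.zeros((16, 16, 4)), (2, 2, 2))
    sys = SystemModel(n_angles=14, n_radial_bins=16, n_slices=4, psf_fwhm_mm=0)
    assert forward_project(g, sys).total() == 0.0


def test_central_ray_equals_sphere_chord_length():
    voxel = 2.0
    shape = (32, 32, 32)
    radius = 20.0  # 40 mm diameter, unit activity
    vals = _supersampled_ball(shape, voxel, radius)
    g = VoxelGrid(vals, (voxel,) * 3)
    sys = SystemModel(n_angles=8, n_radial_bins=32, n_slices=32, psf_fwhm_mm=0)
    sino = forward_project(g, sys, psf=False)
    # most-central radial bin sits 1 mm off-axis on an even grid
    r_off = (np.arange(32) - 15.5) * voxel
    ib = int(np.argmin(np.abs(r_off)))
    chord = 2.0 * np.sqrt(radius**2 - r_off[ib] ** 2)
    central = sino.values[0, ib, 15]
    assert abs(central - chord) / chord < 0.02


def test_forward_projection_linear():
    rng = np.random.default_rng(0)
    sys = SystemModel(n_angles=14, n_radial_bins=16, n_slices=4, psf_fwhm_mm=3.0)
    a = VoxelGrid(rng.random((16, 16, 4)), (2, 2, 2))
    b = VoxelGrid(rng.random((16, 16, 4)), (2, 2, 2))
    ab = VoxelGrid(a.values + b.values, (2, 2, 2))
    lhs = forward_project(ab, sys).values
    rhs = forward_project(a, sys).values + forward_project(b, sys).values
    assert np.allclose(lhs, rhs, atol=1e-9)


def test_projector_adjoint_contract():
    sys = SystemModel(n_angles=14, n_radial_bins=16, n_slices=4, psf_fwhm_mm=3.0)
    g = VoxelGrid(np.zeros((16, 16, 4)), (2, 2, 2))
    proj = get_projector(g, sys)
    rng = np.random.default_rng(1)
    x = rng.random((16, 16, 4))
    y = rng.random(sys.sino_shape)
    lhs = float(np.sum(proj.fwd(x) * y))
    rhs = float(np.sum(x * proj.back(y)))
    assert abs(lhs - rhs) / abs(lhs) < 1e-6


def test_geometry_mismatch_raises():
    g = VoxelGrid(np.zeros((16, 16, 4)), (2, 2, 2))
    sys = SystemModel(n_angles=14, n_radial_bins=32, n_slices=4)
    with pytest.raises(ValueError):
        forward_project(g, sys)


def test_attenuation_unity_for_zero_mu():
    g = VoxelGrid(np.zeros((16, 16, 4)), (2, 2, 2))
    sys = SystemModel(n_angles=14, n_radial_bins=16, n_slices=4)
    af = attenuation_factors(g, sys)
    assert np.allclose(af.values, 1.0, atol=1e-12)


def test_attenuation_cylinder_closed_form():
    # 200 mm diameter water cylinder, mu = 0.0096 /mm: exp(-1.92) on centre
    voxel = 4.0
    shape = (64, 64, 4)
    vals = 0.0096 * _supersampled_ball(shape, voxel, 100.0, axis2_cylinder=True)
    g = VoxelGrid(vals, (voxel,) * 3)
    sys = SystemModel(n_angles=8, n_radial_bins=64, n_slices=4, psf_fwhm_mm=0)
    af = attenuation_factors(g, sys)
    r_off = (np.arange(64) - 31.5) * voxel
    ib = int(np.argmin(np.abs(r_off)))
    chord = 2.0 * np.sqrt(100.0**2 - r_off[ib] ** 2)
    expected = np.exp(-0.0096 * chord)
    assert abs(af.values[0, ib, 1] - expected) / expected < 0.02
    assert af.values.min() > 0 and af.values.max() <= 1.0


def test_attenuation_monotone_in_mu_scale():
    rng = np.random.default_rng(2)
    base = rng.random((16, 16, 4)) * 0.01
    sys = SystemModel(n_angles=14, n_radial_bins=16, n_slices=4)
    af1 = attenuation_factors(VoxelGrid(base, (2, 2, 2)), sys).values
    af2 = attenuation_factors(VoxelGrid(2 * base, (2, 2, 2)), sys).values
    assert np.all(af2 <= af1 + 1e-12)


# ----------------------------------------------------------------------
# list-mode generation
# ----------------------------------------------------------------------
@pytest.fixture(scope="module")
def tiny_frame():
    rng = np.random.default_rng(5)
    act = np.zeros((16, 16, 4))
    act[4:12, 4:12, :] = 1.0 + rng.random((8, 8, 4))
    mu = np.where(act > 0, 0.0096, 0.0)
    sys = SystemModel(n_angles=14, n_radial_bins=16, n_slices=4, psf_fwhm_mm=0)
    return VoxelGrid(act, (2, 2, 2)), VoxelGrid(mu, (2, 2, 2)), sys


def test_prompts_expectation_without_background(tiny_frame):
    act, mu, sys = tiny_frame
    af = attenuation_factors(mu, sys)
    expected = float((af.values * forward_project(act, sys).values).sum())
    totals = []
    for seed in range(100):
        lm, sc, rd = simulate_prompts(act, mu, sys, 0.0, 0.0, seed=seed)
        assert sc.total() == 0 and rd.total() == 0
        totals.append(lm.n_events)
    # mean of 100 Poisson totals within 3 standard errors of expectation
    se = np.sqrt(expected / 100)
    assert abs(np.mean(totals) - expected) < 3 * se


def test_simulate_prompts_deterministic(tiny_frame):
    act, mu, sys = tiny_frame
    lm1, _, _ = simulate_prompts(act, mu, sys, 0.1, 0.1, seed=42)
    lm2, _, _ = simulate_prompts(act, mu, sys, 0.1, 0.1, seed=42)
    assert np.array_equal(lm1.events, lm2.events)


def test_bin_expand_roundtrip_preserves_counts(tiny_frame):
    act, mu, sys = tiny_frame
    lm, _, _ = simulate_prompts(act, mu, sys, 0.2, 0.2, seed=7)
    sino = bin_events(lm, sys)
    assert sino.total() == lm.n_events
    assert np.all(sino.values == np.rint(sino.values))


def test_bootstrap_sizes(tiny_frame):
    act, mu, sys = tiny_frame
    lm, _, _ = simulate_prompts(act, mu, sys, seed=3)
    n = lm.n_events
    assert bootstrap_listmode(lm, 1.0, 0).n_events == n
    b = bootstrap_listmode(lm, 0.30, 1)
    assert b.n_events == int(round(0.30 * n))
    assert b.count_level == 0.30


def test_bootstrap_empty_fails():
    lm = ListModeData(np.empty((0, 3), dtype=np.int32))
    with pytest.raises(ValueError):
        bootstrap_listmode(lm, 0.5, 0)


def test_bootstrap_per_bin_calibration(tiny_frame):
    """Per-bin bootstrap means at level f converge to f x original counts."""
    act, mu, sys = tiny_frame
    lm, _, _ = simulate_prompts(act, mu, sys, seed=9)
    orig = bin_events(lm, sys).values
    f = 0.3
    acc = np.zeros_like(orig)
    n_rep = 200
    for i in range(n_rep):
        acc += bin_events(bootstrap_listmode(lm, f, 1000 + i), sys).values
    mean = acc / n_rep
    hot = orig >= 20
    assert hot.sum() > 50
    # binomial thinning theory: per-draw variance ~ f * orig (rare bins)
    se = np.sqrt(f * orig[hot] / n_rep)
    z = np.abs(mean[hot] - f * orig[hot]) / se
    # family-wise allowance: a perfect bootstrap still puts ~0.3% of bins
    # beyond 3 SE when hundreds of bins are checked at once
    assert np.mean(z < 3.0) >= 0.99
    assert np.all(z < 4.5)
    # and at least grossly unbiased in aggregate
    assert abs(mean[hot].sum() - f * orig[hot].sum()) / (f * orig[hot].sum()) < 0.01


def test_listmode_hdf5_roundtrip(tmp_path, tiny_frame):
    act, mu, sys = tiny_frame
    lm, _, _ = simulate_prompts(act, mu, sys, seed=3, frame_id="late_neg")
    p = tmp_path / "lm.h5"
    save_listmode(lm, p, seed=3)
    back = load_listmode(p)
    assert np.array_equal(back.events, lm.events)
    assert back.source_frame == "late_neg"
    assert back.count_level == 1.0


def test_default_system_matches_grid(phantom64):
    labels = phantom64[0]
    sys = default_system(labels)
    assert sys.n_radial_bins == labels.shape[0]
    assert sys.n_slices == labels.shape[2]
    assert sys.n_angles % 14 == 0
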