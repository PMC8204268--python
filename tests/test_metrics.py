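import numpy as np
import pytest
from scipy import ndimage

from petregu.grid import VoxelGrid
from petregu.metrics import (
    DiceDistribution,
    brown_forsythe,
    cov,
    dice,
    jaccard,
    sd_matrix,
    suvr,
    yang_pvc,
)


# ----------------------------------------------------------------------
# overlap statistics
# ----------------------------------------------------------------------
def _mask(shape, idx):
    m = np.zeros(shape, dtype=bool)
    m.ravel()[list(idx)] = True
    return m


def test_dice_jaccard_worked_cases():
    shape = (4, 4, 4)
    a = _mask(shape, range(10, 14))  # |Sr| = 4
    b = _mask(shape, range(11, 17))  # |Sb| = 6, overlap = 3
    assert dice(a, a) == 1.0
    assert jaccard(a, a) == 1.0
    disjoint = _mask(shape, range(30, 34))
    assert dice(a, disjoint) == 0.0
    assert dice(a, b) == pytest.approx(0.6, abs=0)
    assert jaccard(a, b) == pytest.approx(3 / 7, abs=1e-15)


def test_dice_symmetry_and_empty_error():
    shape = (3, 3, 3)
    a = _mask(shape, [0, 1, 2])
    b = _mask(shape, [2, 3])
    assert dice(a, b) == dice(b, a)
    empty = np.zeros(shape, dtype=bool)
    with pytest.raises(ValueError):
        dice(empty, empty)
    with pytest.raises(ValueError):
        jaccard(empty, empty)


def test_dice_jaccard_functional_identity_random_masks():
    """dice = 2j/(1+j) against a brute-force python-set oracle, 100 pairs."""
    rng = np.random.default_rng(42)
    shape = (8, 8, 8)
    for _ in range(100):
        a_idx = set(rng.choice(512, size=rng.integers(1, 60), replace=False).tolist())
        b_idx = set(rng.choice(512, size=rng.integers(1, 60), replace=False).tolist())
        a, b = _mask(shape, a_idx), _mask(shape, b_idx)
        d, j = dice(a, b), jaccard(a, b)
        # set-arithmetic oracle
        inter = len(a_idx & b_idx)
        assert d == pytest.approx(2 * inter / (len(a_idx) + len(b_idx)), abs=1e-15)
        assert j == pytest.approx(
            inter / len(a_idx | b_idx) if (a_idx | b_idx) else 0.0, abs=1e-15
        )
        assert d == pytest.approx(2 * j / (1 + j), abs=1e-12)


# ----------------------------------------------------------------------
# scalar statistics
# ----------------------------------------------------------------------
def test_cov_worked_cases():
    assert cov([1, 1, 1, 1]) == 0.0
    assert cov([2, 4]) == pytest.approx(np.sqrt(2) / 3, abs=1e-9)
    assert cov([2, 4]) == pytest.approx(0.471405, abs=1e-6)
    x = np.array([1.0, 2.0, 5.0, 9.0])
    assert cov(7 * x) == pytest.approx(cov(x), abs=1e-12)
    with pytest.raises(ValueError):
        cov([1.0, -1.0])
    with pytest.raises(ValueError):
        cov([3.0])


def test_brown_forsythe_identical_groups():
    g = [1.0, 2.0, 3.0, 4.0]
    stat, p = brown_forsythe(g, list(g))
    assert stat == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0, abs=1e-12)


def test_brown_forsythe_shift_invariant():
    rng = np.random.default_rng(0)
    a = rng.normal(0, 1, 40)
    b = rng.normal(0, 2, 40)
    s1, _ = brown_forsythe(a, b)
    s2, _ = brown_forsythe(a + 100.0, b)
    assert s1 == pytest.approx(s2, abs=1e-9)


def test_brown_forsythe_detects_variance_ratio_with_permutation_oracle():
    """1-vs-9 variance ratio, n=50: significant by both the F reference
    distribution and an independent permutation null."""
    rng = np.random.default_rng(7)
    a = rng.normal(0, 1, 50)
    b = rng.normal(0, 3, 50)
    stat, p = brown_forsythe(a, b)
    assert p < 0.01

    def bf_stat(x, y):
        dx = np.abs(x - np.median(x))
        dy = np.abs(y - np.median(y))
        n1, n2 = len(dx), len(dy)
        gm = np.concatenate([dx, dy]).mean()
        num = (n1 * (dx.mean() - gm) ** 2 + n2 * (dy.mean() - gm) ** 2) / 1
        den = (((dx - dx.mean()) ** 2).sum() + ((dy - dy.mean()) ** 2).sum()) / (
            n1 + n2 - 2
        )
        return num / den

    assert bf_stat(a, b) == pytest.approx(stat, rel=1e-9)
    pooled = np.concatenate([a, b])
    perm_rng = np.random.default_rng(99)
    exceed = 0
    n_perm = 999
    for _ in range(n_perm):
        perm = perm_rng.permutation(pooled)
        if bf_stat(perm[:50], perm[50:]) >= stat:
            exceed += 1
    p_perm = (exceed + 1) / (n_perm + 1)
    assert p_perm < 0.01


def test_brown_forsythe_validation():
    with pytest.raises(ValueError):
        brown_forsythe([1.0, 2.0, 3.0])
    with pytest.raises(ValueError):
        brown_forsythe([1.0, 2.0], [1.0, 2.0, 3.0])


# ----------------------------------------------------------------------
# SUVr
# ----------------------------------------------------------------------
@pytest.fixture()
def two_region_grid():
    lab = np.zeros((10, 10, 10), dtype=np.int16)
    lab[:5] = 1
    lab[5:] = 2
    return VoxelGrid(lab, (2, 2, 2))


def test_suvr_uniform_is_one(two_region_grid):
    pet = VoxelGrid(np.full((10, 10, 10), 3.7), (2, 2, 2))
    assert suvr(pet, two_region_grid, 1, 2).suvr == pytest.approx(1.0, abs=1e-12)


def test_suvr_ratio_and_scale_invariance(two_region_grid):
    vals = np.zeros((10, 10, 10))
    vals[:5] = 2.4
    vals[5:] = 1.2
    pet = VoxelGrid(vals, (2, 2, 2))
    r = suvr(pet, two_region_grid, 1, 2)
    assert r.suvr == pytest.approx(2.0, abs=1e-12)
    scaled = VoxelGrid(7 * vals, (2, 2, 2))
    assert suvr(scaled, two_region_grid, 1, 2).suvr == pytest.approx(r.suvr, abs=1e-12)


def test_suvr_empty_roi_raises(two_region_grid):
    pet = VoxelGrid(np.ones((10, 10, 10)), (2, 2, 2))
    with pytest.raises(ValueError):
        suvr(pet, two_region_grid, 99, 2)


# ----------------------------------------------------------------------
# iterative Yang PVC
# ----------------------------------------------------------------------
def _blurred_boxes(fwhm_vox=3.0):
    vals = np.zeros((60, 40, 40))
    lab = np.zeros((60, 40, 40), dtype=np.int16)
    vals[10:30, 10:30, 10:30] = 4.0
    lab[10:30, 10:30, 10:30] = 1
    vals[30:50, 10:30, 10:30] = 1.0
    lab[30:50, 10:30, 10:30] = 2
    blur = ndimage.gaussian_filter(vals, fwhm_vox / (2 * np.sqrt(2 * np.log(2))), mode="constant")
    return VoxelGrid(blur, (1, 1, 1)), VoxelGrid(lab, (1, 1, 1))


def test_pvc_zero_fwhm_is_identity():
    pet, lab = _blurred_boxes()
    out = yang_pvc(pet, lab, psf_fwhm_mm=0.0)
    assert np.array_equal(out.values, pet.values)


def test_pvc_recovers_two_region_means():
    """Two regions (4 and 1) blurred with a known 3-voxel-FWHM kernel:
    regional means recovered within 2% after 5 iterations."""
    pet, lab = _blurred_boxes(3.0)
    cor = yang_pvc(pet, lab, psf_fwhm_mm=3.0, n_iter=5)
    m1 = cor.values[lab.values == 1].mean()
    m2 = cor.values[lab.values == 2].mean()
    assert abs(m1 - 4.0) / 4.0 < 0.02
    assert abs(m2 - 1.0) < 0.02
    assert np.all(cor.values >= 0)


def test_pvc_uniform_image_unchanged_in_interior():
    pet = VoxelGrid(np.full((40, 40, 40), 2.0), (1, 1, 1))
    lab = VoxelGrid(np.ones((40, 40, 40), dtype=np.int16), (1, 1, 1))
    out = yang_pvc(pet, lab, psf_fwhm_mm=4.0)
    assert np.allclose(out.values[10:30, 10:30, 10:30], 2.0, atol=1e-9)


def test_pvc_error_shrinks_over_iterations():
    pet, lab = _blurred_boxes(3.0)
    errs = []
    for k in range(1, 6):
        cor = yang_pvc(pet, lab, psf_fwhm_mm=3.0, n_iter=k, tol=0.0)
        m1 = cor.values[lab.values == 1].mean()
        errs.append(abs(m1 - 4.0))
    assert all(e2 <= e1 + 1e-12 for e1, e2 in zip(errs, errs[1:]))


def test_pvc_empty_region_warns_and_continues():
    pet, lab = _blurred_boxes()
    with pytest.warns(UserWarning, match="empty"):
        out = yang_pvc(pet, lab, psf_fwhm_mm=2.0, region_ids=[0, 1, 2, 77])
    assert out.shape == pet.shape


# ----------------------------------------------------------------------
# SD matrices
# ----------------------------------------------------------------------
def _dist(roi, frame, mode, samples, **kw):
    return DiceDistribution(
        roi_name=roi, frame=frame, mode=mode, samples=np.asarray(samples), **kw
    )


def test_sd_matrix_identical_samples_flag_min():
    rng = np.random.default_rng(1)
    d1 = _dist("A", "late_neg", "AC", [0.9] * 10)  # SD = 0 -> the minimum
    d2 = _dist("A", "late_neg", "QNT", 0.9 + 0.01 * rng.standard_normal(10))
    m = sd_matrix([d1, d2])
    assert m.per_roi.loc[m.per_roi["mode"] == "AC", "sd"].iloc[0] == 0.0
    row = m.averages[m.averages["mode"] == "AC"].iloc[0]
    assert bool(row["is_min"])


def test_sd_matrix_average_is_unweighted_mean():
    rng = np.random.default_rng(2)
    dists = [
        _dist(f"R{i}", "late_neg", "AC", rng.random(8) * 0.1 + 0.85) for i in range(9)
    ]
    m = sd_matrix(dists)
    avg = m.averages["avg_sd"].iloc[0]
    assert avg == pytest.approx(np.mean([d.sd for d in dists]), abs=1e-12)


def test_sd_matrix_flags_stable_under_reordering():
    rng = np.random.default_rng(3)
    dists = []
    for mode, scale in (("NAC", 0.05), ("AC", 0.01), ("QNT", 0.012)):
        for i in range(3):
            samples = np.clip(0.9 + scale * rng.standard_normal(12), 0.0, 1.0)
            dists.append(_dist(f"R{i}", "late_neg", mode, samples))
    m1 = sd_matrix(dists)
    m2 = sd_matrix(list(reversed(dists)))
    assert m1.averages.equals(m2.averages)
    assert m1.per_roi.equals(m2.per_roi)


def test_dice_distribution_sd_uses_n_minus_one():
    d = _dist("A", "late_neg", "AC", [0.8, 0.9])
    assert d.sd == pytest.approx(np.std([0.8, 0.9], ddof=1), abs=1e-15)
    assert d.n == 2
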