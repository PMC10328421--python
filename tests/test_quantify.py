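"""Unit and property tests for the core PVS quantification operations."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import pvsquant as pq
from pvsquant.quantify import (
    GRADE_BINS,
    NeighborhoodSpec,
    cluster_minor_extents_mm,
    detect_pvs_voxels,
    enlargement_flag,
    grade_from_max_count,
    label_clusters_per_slice,
    neighborhood_difference_map,
    summarize_pvs,
)

from conftest import make_mask, make_volume


# --------------------------------------------------------------------------
# independent oracles


def diff_map_oracle(data, mask, include_outside=True):
    """Brute-force per-voxel loop: value = I(v) - mean(in-plane 8-ring)."""
    out = np.zeros_like(data, dtype=float)
    nx, ny, nz = data.shape
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                if not mask[i, j, k]:
                    continue
                vals = []
                for di in (-1, 0, 1):
                    for dj in (-1, 0, 1):
                        if di == 0 and dj == 0:
                            continue
                        a, b = i + di, j + dj
                        if 0 <= a < nx and 0 <= b < ny:
                            if include_outside or mask[a, b, k]:
                                vals.append(data[a, b, k])
                # a voxel with no admissible neighbors has no local contrast
                out[i, j, k] = data[i, j, k] - np.mean(vals) if vals else 0.0
    return out


def flood_fill_counts(mask):
    """Stack-based 8-connected flood fill per slice; returns per-slice counts."""
    nx, ny, nz = mask.shape
    counts = []
    for k in range(nz):
        seen = np.zeros((nx, ny), dtype=bool)
        n = 0
        for i in range(nx):
            for j in range(ny):
                if mask[i, j, k] and not seen[i, j]:
                    n += 1
                    stack = [(i, j)]
                    seen[i, j] = True
                    while stack:
                        a, b = stack.pop()
                        for da in (-1, 0, 1):
                            for db in (-1, 0, 1):
                                x, y = a + da, b + db
                                if (
                                    0 <= x < nx
                                    and 0 <= y < ny
                                    and mask[x, y, k]
                                    and not seen[x, y]
                                ):
                                    seen[x, y] = True
                                    stack.append((x, y))
        counts.append(n)
    return counts


# --------------------------------------------------------------------------
# difference map


def test_constant_volume_gives_zero_difference():
    vol = make_volume(np.full((8, 8, 3), 700.0))
    mask = make_mask(np.ones((8, 8, 3)))
    diff = neighborhood_difference_map(vol, mask)
    assert np.allclose(diff.values[mask.data], 0.0)


def test_single_bright_voxel_closed_form():
    data = np.full((9, 9, 3), 1000.0)
    data[4, 4, 1] = 1300.0
    diff = neighborhood_difference_map(make_volume(data), make_mask(np.ones_like(data)))
    assert diff.values[4, 4, 1] == pytest.approx(300.0)


@pytest.mark.parametrize("include_outside", [True, False])
def test_difference_map_matches_bruteforce(include_outside):
    rng = np.random.default_rng(42)
    for _ in range(5):
        data = rng.uniform(0, 2000, size=(7, 7, 3))
        mask = rng.random((7, 7, 3)) < 0.6
        if not mask.any():
            continue
        spec = NeighborhoodSpec(include_outside_mask=include_outside)
        got = neighborhood_difference_map(make_volume(data), make_mask(mask), spec)
        want = diff_map_oracle(data, mask, include_outside)
        np.testing.assert_allclose(got.values, want, atol=1e-9)


def test_difference_map_zero_outside_mask():
    rng = np.random.default_rng(0)
    data = rng.uniform(0, 100, (6, 6, 2))
    mask = np.zeros((6, 6, 2), bool)
    mask[2:4, 2:4, 0] = True
    diff = neighborhood_difference_map(make_volume(data), make_mask(mask))
    assert np.all(diff.values[~mask] == 0.0)


def test_empty_mask_rejected():
    vol = make_volume(np.ones((4, 4, 2)))
    with pytest.raises(ValueError, match="empty"):
        neighborhood_difference_map(vol, make_mask(np.zeros((4, 4, 2))))


def test_nonfinite_voxels_abort():
    data = np.ones((4, 4, 2))
    data[1, 1, 0] = np.nan
    with pytest.raises(Exception, match="non-finite"):
        neighborhood_difference_map(make_volume(data), make_mask(np.ones((4, 4, 2))))


# --------------------------------------------------------------------------
# thresholding


def test_threshold_is_strict():
    """A local difference of exactly 60 is not a PVS voxel; 60+eps is."""
    data = np.full((9, 9, 1), 1000.0)
    data[2, 2, 0] = 1060.0  # difference exactly 60
    data[6, 6, 0] = 1060.001
    diff = neighborhood_difference_map(make_volume(data), make_mask(np.ones_like(data)))
    pvs = detect_pvs_voxels(diff, 60.0)
    assert not pvs.data[2, 2, 0]
    assert pvs.data[6, 6, 0]


def test_constant_t2_detects_nothing():
    vol = make_volume(np.full((8, 8, 2), 1000.0))
    diff = neighborhood_difference_map(vol, make_mask(np.ones((8, 8, 2))))
    assert detect_pvs_voxels(diff).count() == 0


def test_threshold_monotonicity():
    """Raising the threshold never adds PVS voxels, globally or per slice.

    (Cluster counts are not monotone in general — a rising threshold can
    split one cluster into two — so monotonicity is asserted at the voxel
    level, where it is a theorem.)"""
    rng = np.random.default_rng(7)
    data = rng.uniform(900, 1200, (12, 12, 4))
    diff = neighborhood_difference_map(make_volume(data), make_mask(np.ones_like(data)))
    prev = None
    for thr in (0.0, 20.0, 60.0, 100.0):
        pvs = detect_pvs_voxels(diff, thr)
        per_slice_vox = pvs.data.sum(axis=(0, 1))
        if prev is not None:
            assert pvs.count() <= prev[0]
            assert np.all(per_slice_vox <= prev[1])
        prev = (pvs.count(), per_slice_vox)


def test_nonfinite_threshold_rejected():
    vol = make_volume(np.full((6, 6, 2), 1000.0))
    diff = neighborhood_difference_map(vol, make_mask(np.ones((6, 6, 2))))
    with pytest.raises(ValueError):
        detect_pvs_voxels(diff, float("nan"))


# --------------------------------------------------------------------------
# per-slice clustering


def test_corner_touching_voxels_one_cluster():
    mask = np.zeros((6, 6, 1), bool)
    mask[2, 2, 0] = mask[3, 3, 0] = True  # touch only at a corner
    assert label_clusters_per_slice(make_mask(mask)).counts == [1]


def test_adjacent_slices_are_separate_clusters():
    mask = np.zeros((6, 6, 2), bool)
    mask[2, 2, 0] = mask[2, 2, 1] = True  # same in-plane spot, two slices
    assert label_clusters_per_slice(make_mask(mask)).counts == [1, 1]


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_clustering_matches_flood_fill(seed):
    rng = np.random.default_rng(seed)
    mask = rng.random((10, 10, 3)) < 0.25
    got = label_clusters_per_slice(make_mask(mask)).counts
    assert got == flood_fill_counts(mask)


def test_slice_permutation_equivariance():
    rng = np.random.default_rng(3)
    mask = rng.random((10, 10, 5)) < 0.2
    perm = np.array([3, 0, 4, 1, 2])
    base = label_clusters_per_slice(make_mask(mask)).counts
    permuted = label_clusters_per_slice(make_mask(mask[:, :, perm])).counts
    assert permuted == [base[p] for p in perm]
    assert max(permuted) == max(base)


def test_ambiguous_slice_axis_needs_override():
    iso = pq.BinaryMask(np.ones((4, 4, 4), bool), np.eye(4))
    with pytest.raises(Exception, match="ambiguous"):
        label_clusters_per_slice(iso)
    assert label_clusters_per_slice(iso, slice_axis=2).counts == [1, 1, 1, 1]


# --------------------------------------------------------------------------
# grading


@pytest.mark.parametrize(
    "max_count,grade",
    [(0, 0), (1, 1), (10, 1), (11, 2), (20, 2), (21, 3), (40, 3), (41, 4), (100, 4), (1000, 4)],
)
def test_grade_bin_boundaries(max_count, grade):
    assert grade_from_max_count([0, max_count, 0]) == grade


def test_grade_bins_are_exhaustive_and_monotone():
    grades = [grade_from_max_count([m]) for m in range(0, 200)]
    assert grades[0] == 0
    assert all(b - a >= 0 for a, b in zip(grades, grades[1:]))
    assert set(grades) == {0, 1, 2, 3, 4}


def test_grade_rejects_bad_input():
    with pytest.raises(ValueError):
        grade_from_max_count([])
    with pytest.raises(ValueError):
        grade_from_max_count([-1])


# --------------------------------------------------------------------------
# summary and enlargement


def test_normalized_volume_is_ratio():
    mask = np.zeros((30, 30, 12), bool)
    mask[:, :, :] = False
    wm = np.zeros_like(mask)
    wm[3:28, 3:28, :] = True  # make wm 25*25*12 = 7500... use explicit counts
    pvs = np.zeros_like(mask)
    idx = np.argwhere(wm)[:50]
    pvs[tuple(idx.T)] = True
    res = summarize_pvs(make_mask(pvs), make_mask(wm))
    assert res.wm_voxel_count == int(wm.sum())
    assert res.normalized_volume == pytest.approx(50 / wm.sum())


def test_empty_pvs_grade_zero_flag_false():
    wm = np.zeros((8, 8, 3), bool)
    wm[2:6, 2:6, :] = True
    res = summarize_pvs(make_mask(np.zeros_like(wm)), make_mask(wm))
    assert res.pvs_voxel_count == 0
    assert res.grade == 0
    assert not res.enlargement_flag


def test_empty_wm_mask_rejected():
    with pytest.raises(ValueError, match="empty WM"):
        summarize_pvs(make_mask(np.zeros((4, 4, 2))), make_mask(np.zeros((4, 4, 2))))


def test_enlargement_three_wide_clusters():
    """Three in-plane blobs 8 voxels across at 0.4 mm spacing (3.2 mm) flag
    enlargement; two wide plus many thin ones do not."""
    aff04 = np.diag([0.4, 0.4, 4.4, 1.0])
    wide = np.zeros((40, 40, 3), bool)
    for c, k in ((5, 0), (18, 1), (30, 2)):
        wide[c : c + 8, c : c + 8, k] = True
    cl = label_clusters_per_slice(pq.BinaryMask(wide, aff04))
    ext = cluster_minor_extents_mm(cl)
    assert all(e == pytest.approx(3.2) for e in ext)
    assert enlargement_flag(cl)

    two = np.zeros((40, 40, 3), bool)
    two[2:10, 2:10, 0] = True
    two[20:28, 20:28, 0] = True
    for i in range(5):  # thin 1-voxel clusters
        two[2 + 3 * i, 30, 1] = True
    cl2 = label_clusters_per_slice(pq.BinaryMask(two, aff04))
    assert not enlargement_flag(cl2)


def test_minor_extent_of_elongated_cluster():
    """A 1x10 voxel line at 0.8 mm spacing has a 0.8 mm minor extent."""
    mask = np.zeros((20, 20, 1), bool)
    mask[5, 4:14, 0] = True
    cl = label_clusters_per_slice(make_mask(mask))
    (ext,) = cluster_minor_extents_mm(cl)
    assert ext == pytest.approx(0.8, abs=1e-6)


def test_grade_volume_rank_correlation_on_phantom_batch():
    """Across phantoms with growing tube load, normalized volume and grade
    rise together (positive rank correlation)."""
    from scipy.stats import spearmanr

    vols, grades = [], []
    for i, k in enumerate((1, 8, 20, 40, 60)):
        case = pq.generate_phantom(
            pq.counting_phantom_config(k, grid_dims=(96, 96, 16), seed=100 + i)
        )
        res = summarize_pvs(case.pvs_mask_true, case.wm_mask_true)
        vols.append(res.normalized_volume)
        grades.append(res.grade)
    rho = spearmanr(vols, grades).statistic
    assert rho > 0
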