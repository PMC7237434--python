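"""Rigid pose estimation, gape pitch, hyoid excursion, precision statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hyolingual.io import AnatomicalFrame, DegenerateGeometryError
from hyolingual.rigid import (
    InsufficientMarkerError,
    RigidBodyPose,
    central_velocity,
    estimate_pose,
    estimate_pose_series,
    gape_pitch_angle,
    hyoid_excursion,
    pooled_sd,
    zero_velocity_band,
)
from .conftest import random_rotation


def _cluster(rng, n=8, scale=20.0):
    return rng.normal(scale=scale, size=(n, 3))


def _rot_z(deg):
    r = np.radians(deg)
    c, s = np.cos(r), np.sin(r)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])


def test_estimate_pose_identity(rng):
    ref = _cluster(rng)
    rot, t, rms = estimate_pose(ref, ref)
    np.testing.assert_allclose(rot, np.eye(3), atol=1e-12)
    np.testing.assert_allclose(t, 0.0, atol=1e-12)
    assert rms < 1e-12


def test_estimate_pose_known_transform(rng):
    ref = _cluster(rng)
    rot_true = _rot_z(10.0)
    t_true = np.array([1.0, 2.0, 3.0])
    rot, t, rms = estimate_pose(ref, ref @ rot_true.T + t_true)
    np.testing.assert_allclose(rot, rot_true, atol=1e-9)
    np.testing.assert_allclose(t, t_true, atol=1e-9)
    assert rms < 1e-9
    assert np.isclose(np.linalg.det(rot), 1.0)


def test_estimate_pose_noise_monte_carlo():
    """Translation recovered within 0.05 mm and residual ~ sigma for 8-marker
    clusters with 0.05 mm isotropic noise (1000 replicates, fixed seed)."""
    rng = np.random.default_rng(123)
    ref = _cluster(rng)
    rot_true, t_true = random_rotation(rng), np.array([2.0, -1.0, 0.5])
    sigma = 0.05
    t_err, rms_all = [], []
    for _ in range(1000):
        frame = ref @ rot_true.T + t_true + rng.normal(scale=sigma, size=ref.shape)
        _, t, rms = estimate_pose(ref, frame)
        t_err.append(np.linalg.norm(t - t_true))
        rms_all.append(rms)
    assert np.mean(t_err) < sigma
    assert np.quantile(t_err, 0.95) < 3 * sigma / np.sqrt(8)
    # per-marker Euclidean residual RMS: 3 coordinates per marker, 6 rigid
    # DOF absorbed -> E[rms] = sigma * sqrt(3 * (1 - 6 / (3 n)))
    expected_rms = sigma * np.sqrt(3 * (1 - 6 / 24))
    assert np.isclose(np.mean(rms_all), expected_rms, rtol=0.1)


def test_estimate_pose_equivariance_and_relabeling(rng):
    ref = _cluster(rng)
    rot_true, t_true = random_rotation(rng), rng.normal(size=3)
    frame = ref @ rot_true.T + t_true
    perm = rng.permutation(len(ref))
    rot_p, t_p, _ = estimate_pose(ref[perm], frame[perm])
    np.testing.assert_allclose(rot_p, rot_true, atol=1e-9)
    np.testing.assert_allclose(t_p, t_true, atol=1e-9)


def test_estimate_pose_errors(rng):
    with pytest.raises(InsufficientMarkerError):
        estimate_pose(np.zeros((2, 3)), np.zeros((2, 3)))
    line = np.outer(np.arange(5.0), [1.0, 0, 0])
    with pytest.raises(DegenerateGeometryError):
        estimate_pose(line, line)
    ref = _cluster(rng, n=5)
    cur = ref.copy()
    cur[0] = np.nan  # dropped, still enough markers
    rot, _, _ = estimate_pose(ref, cur)
    np.testing.assert_allclose(rot, np.eye(3), atol=1e-9)


def _pose_from_rotations(rots):
    n = len(rots)
    return RigidBodyPose(np.array(rots), np.zeros((n, 3)), np.zeros(n))


def test_gape_pitch_reference_and_pure_rotation():
    # opening = negative rotation about +Z in the generator convention
    rots = [np.eye(3), _rot_z(-5.0), _rot_z(-2.0)]
    gape = gape_pitch_angle(_pose_from_rotations(rots), reference_frame=0)
    np.testing.assert_allclose(gape, [0.0, 5.0, 2.0], atol=1e-9)
    # default reference: frame of minimum gape
    gape2 = gape_pitch_angle(_pose_from_rotations(rots))
    np.testing.assert_allclose(gape2, [0.0, 5.0, 2.0], atol=1e-9)


def test_gape_pitch_pure_translation_is_zero():
    pose = RigidBodyPose(
        np.tile(np.eye(3), (4, 1, 1)), np.outer(np.arange(4.0), [1, 2, 3]), np.zeros(4)
    )
    np.testing.assert_allclose(gape_pitch_angle(pose), 0.0, atol=1e-12)


def test_gape_pitch_marker_subset_invariance(rng):
    """Pitch is independent of which (noise-free) cluster subset is posed."""
    ref = _cluster(rng, n=8)
    rots = [_rot_z(-g) for g in (0.0, 3.0, 7.5)]
    frames = np.stack([ref @ r.T for r in rots])
    full = gape_pitch_angle(estimate_pose_series(ref, frames), reference_frame=0)
    sub = gape_pitch_angle(
        estimate_pose_series(ref[:4], frames[:, :4]), reference_frame=0
    )
    np.testing.assert_allclose(full, sub, atol=1e-9)
    np.testing.assert_allclose(full, [0.0, 3.0, 7.5], atol=1e-9)


def test_hyoid_excursion():
    frame = AnatomicalFrame(np.zeros(3), np.eye(3))
    pts = np.zeros((5, 3))
    dx, dy = hyoid_excursion(pts, frame)
    np.testing.assert_allclose(dx, 0.0)
    np.testing.assert_allclose(dy, 0.0)
    pts2 = pts.copy()
    pts2[3:] += [4.23, 2.13, 0.0]
    dx, dy = hyoid_excursion(pts2, frame, reference_index=0)
    assert np.isclose(dx[4], 4.23) and np.isclose(dy[4], 2.13)
    # linearity: sinusoidal X trajectory -> sinusoidal protraction, same amplitude
    t = np.linspace(0, 2 * np.pi, 50)
    sin_pts = np.column_stack([3.0 * np.sin(t), np.zeros(50), np.zeros(50)])
    dx, _ = hyoid_excursion(sin_pts, frame, reference_index=0)
    np.testing.assert_allclose(dx, 3.0 * np.sin(t), atol=1e-12)
    with pytest.raises(IndexError):
        hyoid_excursion(pts, frame, reference_index=99)


def test_pooled_sd_values():
    assert np.isclose(pooled_sd([0.06, 0.04, 0.08, 0.05]), 0.0594, atol=5e-5)
    assert pooled_sd([0.0]) == 0.0
    assert np.isclose(pooled_sd([0.3, 0.3, 0.3, 0.3]), 0.3)
    assert np.isclose(pooled_sd([0.7]), 0.7)
    with pytest.raises(ValueError):
        pooled_sd([])


@settings(deadline=None, derandomize=True)
@given(
    sds=st.lists(st.floats(0.0, 10.0), min_size=1, max_size=8),
    bump=st.floats(0.01, 5.0),
    idx=st.integers(0, 7),
)
def test_pooled_sd_monotone(sds, bump, idx):
    idx = idx % len(sds)
    bumped = list(sds)
    bumped[idx] += bump
    assert pooled_sd(bumped) >= pooled_sd(sds)


def test_zero_velocity_band():
    rng = np.random.default_rng(5)
    noise = rng.normal(scale=0.1, size=10_000)
    lo, hi = zero_velocity_band(noise)
    assert np.isclose(hi, 0.2, rtol=0.05) and np.isclose(lo, -hi)
    with pytest.warns(UserWarning):
        assert zero_velocity_band(np.zeros(100)) == (0.0, 0.0)
    lo2, hi2 = zero_velocity_band(3.0 * noise)
    assert np.isclose(hi2, 3.0 * hi)


def test_central_velocity():
    x = np.arange(10.0)
    v = central_velocity(x, frame_rate=200.0)
    np.testing.assert_allclose(v, 200.0)
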