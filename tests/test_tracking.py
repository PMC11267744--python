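"""Tracker mechanics: step/angle/length invariants, thresholds, null walks."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from safmap import OdfField, TrackingParams, streamline_length, track_null, track_odf
from safmap.tracking import seed_points_from_mask
from safmap.volume import make_sphere_directions


def assert_tracker_invariants(tractogram, params, tol=1e-6):
    """Every emitted streamline: exact step, bounded turn angle, length window."""
    assert len(tractogram) > 0
    cosmax = np.cos(np.deg2rad(params.max_angle))
    for s in tractogram.streamlines:
        seg = np.diff(s, axis=0)
        steps = np.linalg.norm(seg, axis=1)
        assert np.all(np.abs(steps - params.step_size) <= tol)
        u = seg / steps[:, None]
        dots = np.einsum("ij,ij->i", u[:-1], u[1:])
        assert np.all(dots >= cosmax - 1e-9)
        length = steps.sum()
        assert params.min_length - tol <= length <= params.max_length + tol


@pytest.fixture(scope="module")
def slab_field():
    """Single-direction delta ODF in a slab (z < 6 mm).

    Only the direction closest to +x (and its antipode) carries amplitude;
    every other direction is zero, so admissible propagation is straight.
    """
    directions = make_sphere_directions(2)
    d_x = np.argmax(directions @ np.array([1.0, 0.0, 0.0]))
    nx, ny, nz = 30, 12, 10
    amps = np.zeros((nx, ny, nz, len(directions)), dtype=np.float32)
    amps[:, :, :6, d_x] = 1.0
    anti = np.argmax(directions @ -directions[d_x])
    amps[:, :, :6, anti] = 1.0
    field = OdfField(amplitudes=amps, directions=directions, affine=np.eye(4))
    return field, directions[d_x]


class TestStreamlineLength:
    def test_two_points_one_mm(self):
        assert streamline_length([[0, 0, 0], [1, 0, 0]]) == pytest.approx(1.0)

    def test_collinear_points_at_fixed_spacing(self):
        pts = np.zeros((51, 3))
        pts[:, 0] = np.arange(51) * 0.2
        assert streamline_length(pts) == pytest.approx(10.0)

    @settings(deadline=None, max_examples=30)
    @given(st.integers(0, 2**31 - 1), st.integers(2, 40))
    def test_matches_pairwise_distance_oracle(self, seed, n):
        pts = np.random.default_rng(seed).uniform(-50, 50, (n, 3))
        oracle = sum(
            float(np.sqrt(((pts[i + 1] - pts[i]) ** 2).sum())) for i in range(n - 1)
        )
        assert streamline_length(pts) == pytest.approx(oracle, abs=1e-9)

    def test_single_point_is_an_error(self):
        with pytest.raises(ValueError):
            streamline_length([[0, 0, 0]])


class TestTrackingParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"step_size": 0.0},
            {"max_angle": 95.0},
            {"min_length": 5.0, "max_length": 4.0},
            {"seeds_per_voxel_axis": 0},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            TrackingParams(**kwargs)

    def test_defaults_follow_analysis_conventions(self):
        p = TrackingParams()
        assert (p.step_size, p.max_angle, p.amplitude_threshold) == (0.2, 30.0, 0.1)
        assert (p.min_length, p.max_length, p.seeds_per_voxel_axis) == (3.0, 120.0, 4)


class TestSeeding:
    def test_k_voxels_give_k_times_64_seed_points(self):
        mask = np.zeros((5, 5, 5), dtype=bool)
        mask[1, 1, 1] = mask[2, 3, 1] = mask[4, 0, 2] = True
        pts = seed_points_from_mask(mask, np.eye(4), 4)
        assert len(pts) == 3 * 64

    def test_empty_mask_is_an_error(self):
        with pytest.raises(ValueError):
            seed_points_from_mask(np.zeros((3, 3, 3), dtype=bool), np.eye(4), 4)


class TestTrackOdf:
    def test_dominant_direction_gives_straight_streamlines(self, slab_field):
        field, d_x = slab_field
        mask = np.zeros(field.grid_shape, dtype=bool)
        mask[14:16, 5:7, 2:4] = True
        params = TrackingParams(rng_seed=1, max_length=40.0)
        tg = track_odf(field, mask, params)
        assert_tracker_invariants(tg, params)
        for s in tg.streamlines:
            ends = s[-1] - s[0]
            cos = abs(ends @ d_x) / np.linalg.norm(ends)
            assert cos > 0.95  # straight along the boosted axis

    def test_subthreshold_field_yields_no_streamlines(self):
        directions = make_sphere_directions(2)
        amps = np.full((8, 8, 8, len(directions)), 0.1, dtype=np.float32)
        field = OdfField(amplitudes=amps, directions=directions, affine=np.eye(4))
        mask = np.zeros((8, 8, 8), dtype=bool)
        mask[4, 4, 4] = True
        tg = track_odf(field, mask, TrackingParams(rng_seed=2))
        assert len(tg) == 0

    def test_reproducible_given_seed(self, slab_field):
        field, _ = slab_field
        mask = np.zeros(field.grid_shape, dtype=bool)
        mask[15, 6, 3] = True
        params = TrackingParams(rng_seed=9, max_length=40.0)
        a = track_odf(field, mask, params)
        b = track_odf(field, mask, params)
        assert len(a) == len(b)
        assert all(np.array_equal(x, y) for x, y in zip(a.streamlines, b.streamlines))


class TestTrackNull:
    @pytest.fixture()
    def slab_mask(self):
        mask = np.zeros((40, 20, 12), dtype=bool)
        mask[2:38, 2:18, 2:8] = True
        return mask

    def test_ten_repeats_returned_and_filtered(self, slab_mask):
        seeds = np.zeros_like(slab_mask)
        seeds[18:22, 9:11, 4:6] = True
        params = TrackingParams(rng_seed=3)
        out = track_null(slab_mask, np.eye(4), seeds, params, repeats=10)
        assert len(out) == 10
        for tg in out:
            assert_tracker_invariants(tg, params)

    def test_repeats_are_independent_but_reproducible(self, slab_mask):
        seeds = np.zeros_like(slab_mask)
        seeds[20, 10, 5] = True
        params = TrackingParams(rng_seed=4)
        a = track_null(slab_mask, np.eye(4), seeds, params, repeats=2)
        b = track_null(slab_mask, np.eye(4), seeds, params, repeats=2)
        for ta, tb in zip(a, b):
            assert all(np.array_equal(x, y) for x, y in zip(ta.streamlines, tb.streamlines))
        assert not all(
            np.array_equal(x, y)
            for x, y in zip(a[0].streamlines[:5], a[1].streamlines[:5])
        )

    def test_left_right_symmetry_of_terminations(self, slab_mask):
        # seeds on the mid-plane of a symmetric slab: endpoint x-excursions
        # must balance at large n
        seeds = np.zeros_like(slab_mask)
        seeds[19:21, 4:16, 3:7] = True
        params = TrackingParams(rng_seed=5)
        tgs = track_null(slab_mask, np.eye(4), seeds, params, repeats=4)
        left = right = 0
        for tg in tgs:
            for s in tg.streamlines:
                for e in (s[0], s[-1]):
                    if e[0] < 19.5:
                        left += 1
                    else:
                        right += 1
        assert left + right > 2000
        assert abs(left - right) / (left + right) < 0.05

    def test_length_bias_favours_nearer_targets(self, slab_mask):
        # endpoints landing within 6 mm of the seed plane vastly outnumber
        # those reaching 12-18 mm away: the length bias the null models
        seeds = np.zeros_like(slab_mask)
        seeds[19:21, 8:12, 3:7] = True
        params = TrackingParams(rng_seed=6)
        tgs = track_null(slab_mask, np.eye(4), seeds, params, repeats=2)
        near = far = 0
        for tg in tgs:
            for s in tg.streamlines:
                for e in (s[0], s[-1]):
                    d = abs(e[0] - 20.0)
                    if d < 6.0:
                        near += 1
                    elif 12.0 <= d < 18.0:
                        far += 1
        assert near > 5 * max(far, 1)

    def test_empty_mask_is_an_error(self, slab_mask):
        with pytest.raises(ValueError):
            track_null(np.zeros_like(slab_mask), np.eye(4), slab_mask, TrackingParams())
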