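"""SNR computation, SNR-gated surface smoothing and sub-area segmentation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from safmap import compute_snr, make_mesh, make_retinotopy, segment_subareas, smooth_phase_map
from safmap.retinotopy import circular_mean_deg
from safmap.synthetic import make_area_labels


def dft_magnitude_oracle(x):
    """Independent one-sided spectrum by direct discrete Fourier summation."""
    n = len(x)
    mags = []
    for k in range(n // 2 + 1):
        re = sum(x[t] * np.cos(2 * np.pi * k * t / n) for t in range(n))
        im = -sum(x[t] * np.sin(2 * np.pi * k * t / n) for t in range(n))
        mags.append(np.hypot(re, im))
    return np.array(mags)


class TestComputeSnr:
    def test_strong_stimulus_response_passes_gate(self):
        t = np.arange(64)
        rng = np.random.default_rng(0)
        x = 10.0 * np.sin(2 * np.pi * 8 * t / 64) + rng.normal(0, 1, 64)
        assert compute_snr(x, 8) >= 5.0

    def test_white_noise_matches_direct_dft_oracle(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 32)
        spec = dft_magnitude_oracle(x)
        noise = np.delete(spec[1:], 8 - 1)  # drop DC and the stimulus bin
        expected = spec[8] / noise.std()
        assert compute_snr(x, 8) == pytest.approx(expected, rel=1e-10)

    def test_stimulus_bin_inclusion_is_configurable(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, 32)
        spec = dft_magnitude_oracle(x)
        expected = spec[5] / spec[1:].std()
        got = compute_snr(x, 5, exclude_stimulus_bin=False)
        assert got == pytest.approx(expected, rel=1e-10)

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 40)
        assert compute_snr(2 * x, 6) == pytest.approx(compute_snr(x, 6))

    def test_constant_series_is_an_error(self):
        with pytest.raises(ValueError):
            compute_snr(np.ones(16), 4)

    def test_bad_frequency_index_rejected(self):
        x = np.random.default_rng(2).normal(0, 1, 16)
        for k in (0, 8, 12):
            with pytest.raises(ValueError):
                compute_snr(x, k)

    def test_vectorised_over_vertices(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, (7, 32))
        out = compute_snr(x, 4)
        assert out.shape == (7,)
        assert out[3] == pytest.approx(compute_snr(x[3], 4))


class TestSmoothPhaseMap:
    def test_constant_map_is_a_fixed_point(self, star_mesh):
        phase = np.full(5, 42.0)
        snr = np.full(5, 9.0)
        out = smooth_phase_map(star_mesh, phase, snr, iterations=4)
        assert np.allclose(out, 42.0, atol=1e-12)

    def test_zero_iterations_is_identity(self, star_mesh):
        phase = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        out = smooth_phase_map(star_mesh, phase, np.full(5, 9.0), iterations=0)
        assert np.array_equal(out, phase)

    def test_star_centre_becomes_neighbourhood_mean(self, star_mesh):
        # centre 10 deg, four leaves 20 deg -> mean{10,20,20,20,20} = 18
        phase = np.array([10.0, 20.0, 20.0, 20.0, 20.0])
        out = smooth_phase_map(star_mesh, phase, np.full(5, 9.0), iterations=1)
        assert out[0] == pytest.approx(18.0)

    def test_circular_mean_wraps(self):
        assert circular_mean_deg(np.array([350.0, 10.0])) == pytest.approx(0.0, abs=1e-9)

    def test_circular_smoothing_averages_across_wrap(self, star_mesh):
        phase = np.array([350.0, 10.0, 10.0, 10.0, 10.0])
        out = smooth_phase_map(
            star_mesh, phase, np.full(5, 9.0), iterations=1, circular=True
        )
        # circular mean of {350, 10 x4}: near 2 deg, never near 180
        assert min(out[0], 360 - out[0]) < 15.0

    def test_unreliable_vertices_do_not_contribute(self, star_mesh):
        phase = np.array([10.0, 20.0, 20.0, 20.0, 1000.0])
        snr = np.array([9.0, 9.0, 9.0, 9.0, 1.0])  # leaf 4 unreliable
        out = smooth_phase_map(star_mesh, phase, snr, iterations=1)
        assert out[0] == pytest.approx(np.mean([10, 20, 20, 20]))
        # the unreliable leaf still receives a smoothed value from its
        # reliable neighbourhood (centre + itself excluded)
        assert out[4] != pytest.approx(1000.0)

    def test_isolated_unreliable_region_keeps_values(self, star_mesh):
        phase = np.array([7.0, 8.0, 9.0, 10.0, 11.0])
        out = smooth_phase_map(star_mesh, phase, np.zeros(5), iterations=3)
        assert np.array_equal(out, phase)

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 2**31 - 1), st.integers(1, 4))
    def test_linear_smoothing_never_expands_the_range(self, seed, iterations):
        mesh = make_mesh(6, 7, 1.0, seed=0)
        rng = np.random.default_rng(seed)
        phase = rng.uniform(0, 100, mesh.n_vertices)
        snr = rng.uniform(0, 10, mesh.n_vertices)
        out = smooth_phase_map(mesh, phase, snr, iterations=iterations)
        assert out.max() <= phase.max() + 1e-9
        assert out.min() >= phase.min() - 1e-9

    def test_noiseless_interior_is_near_fixed_point(self, study):
        # linear gradients are preserved by symmetric interior stencils
        mesh, rmap = study["mesh"], study["rmap"]
        out = smooth_phase_map(mesh, rmap.eccentricity, rmap.snr, iterations=4)
        interior = []
        for v in range(mesh.n_vertices):
            r, c = divmod(v, 45)
            if 4 <= r < 20 and 4 <= c < 41:
                interior.append(v)
        assert np.allclose(out[interior], rmap.eccentricity[interior], atol=1e-9)


class TestSegmentSubareas:
    def test_eccentricity_cuts_match_visual_field_thirds(self, study):
        cuts = study["parc"].eccentricity_cuts["V1"]
        assert cuts[1] == pytest.approx(2.59, abs=0.01)
        assert cuts[2] == pytest.approx(4.30, abs=0.01)

    def test_partition_of_reliable_area_vertices(self, study):
        parc, labels, rmap = study["parc"], study["labels"], study["rmap"]
        for a, verts in enumerate(labels.areas):
            reliable = set(int(v) for v in verts if rmap.snr[v] >= 5)
            got = set()
            for i in range(6 * a, 6 * a + 6):
                s = set(int(v) for v in parc.sub_areas[i])
                assert not (s & got)
                got |= s
            assert got == reliable

    def test_low_snr_vertices_are_omitted(self):
        mesh = make_mesh(12, 18, 0.0, seed=0)
        labels = make_area_labels(mesh)
        rmap = make_retinotopy(mesh, labels, 0.0, 0.3, seed=7)
        parc = segment_subareas(mesh, labels, rmap)
        included = parc.included_vertices()
        assert (rmap.snr[included] >= 5).all()
        assert len(included) == (rmap.snr >= 5).sum()

    def test_uniform_eccentricity_fills_bins_evenly(self):
        mesh = make_mesh(12, 30, 0.0, seed=0)
        labels = make_area_labels(mesh)
        rmap = make_retinotopy(mesh, labels, 0.0, 0.0, seed=0)
        parc = segment_subareas(mesh, labels, rmap)
        for i in range(0, 18, 3):
            sizes = [len(parc.sub_areas[i + b]) for b in range(3)]
            assert max(sizes) - min(sizes) <= np.ceil(30 / 3)  # one column of slack

    def test_single_hemifield_errors_unless_allowed(self, flat_mesh):
        labels = make_area_labels(flat_mesh)
        rmap = make_retinotopy(flat_mesh, labels, 0.0, 0.0, seed=1)
        upper_only = type(rmap)(
            eccentricity=rmap.eccentricity,
            polar_angle=np.full(flat_mesh.n_vertices, 90.0),
            snr=rmap.snr,
        )
        with pytest.raises(ValueError):
            segment_subareas(flat_mesh, labels, upper_only)
        parc = segment_subareas(
            flat_mesh, labels, upper_only, require_both_hemifields=False
        )
        for i in range(18):
            empty_expected = (i % 6) < 3  # dorsal sets empty
            assert (len(parc.sub_areas[i]) == 0) == empty_expected

    def test_too_few_reliable_vertices_errors(self, flat_mesh):
        labels = make_area_labels(flat_mesh)
        rmap = make_retinotopy(flat_mesh, labels, 0.0, 0.0, seed=1)
        starved = type(rmap)(
            eccentricity=rmap.eccentricity,
            polar_angle=rmap.polar_angle,
            snr=np.zeros(flat_mesh.n_vertices),
        )
        with pytest.raises(ValueError):
            segment_subareas(flat_mesh, labels, starved)

    def test_hemifield_convention(self, study):
        # upper visual field (0,180) -> ventral sets (local 4-6)
        parc, rmap = study["parc"], study["rmap"]
        for i, verts in enumerate(parc.sub_areas):
            ang = rmap.polar_angle[verts]
            if (i % 6) >= 3:
                assert ((ang > 0) & (ang < 180)).all()
            else:
                assert (~((ang > 0) & (ang < 180))).all()
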