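"""Synthetic cortex generators: meshes, retinotopy, planted tracts, ODF fields."""

import numpy as np
import pytest

from safmap import (
    make_mesh,
    make_odf_field,
    make_planted_tractogram,
    make_retinotopy,
    segment_subareas,
)
from safmap.retinotopy import SubAreaParcellation
from safmap.synthetic import make_area_labels


class TestMakeMesh:
    def test_flat_sheet_counts_and_planarity(self):
        mesh = make_mesh(4, 4, 0.0, seed=1)
        assert mesh.n_vertices == 16
        assert mesh.n_triangles == 18  # 2 * (4-1)^2
        assert np.allclose(mesh.vertices[:, 2], 0.0)

    def test_degenerate_dimensions_rejected(self):
        with pytest.raises(ValueError):
            make_mesh(3, 10, 0.0, seed=1)

    def test_folded_mesh_is_manifold_with_bounded_degree(self):
        mesh = make_mesh(20, 60, 3.0, seed=7)
        # brute-force edge oracle: rebuild degrees from scratch off triangles
        edges = set()
        for a, b, c in mesh.triangles:
            for u, v in ((a, b), (b, c), (c, a)):
                edges.add((min(u, v), max(u, v)))
        degree = np.zeros(mesh.n_vertices, dtype=int)
        for u, v in edges:
            degree[u] += 1
            degree[v] += 1
        assert degree.min() >= 2 and degree.max() <= 6
        # adjacency property must agree with the oracle
        assert all(
            len(mesh.neighbors[v]) == degree[v] for v in range(mesh.n_vertices)
        )

    def test_determinism(self):
        a = make_mesh(12, 15, 2.0, seed=3, jitter=0.2)
        b = make_mesh(12, 15, 2.0, seed=3, jitter=0.2)
        assert np.array_equal(a.vertices, b.vertices)
        assert np.array_equal(a.triangles, b.triangles)

    def test_fold_ridges_run_orthogonal_to_eccentricity_axis(self):
        mesh = make_mesh(10, 30, 2.0, seed=0)
        z = mesh.vertices[:, 2].reshape(10, 30)
        # height varies along x (columns), is constant along y (rows)
        assert np.allclose(z.std(axis=0), 0.0)
        assert z.std(axis=1).max() > 0.5


class TestAreaLabelsAndRetinotopy:
    def test_labels_disjoint_and_cover(self, study):
        labels, mesh = study["labels"], study["mesh"]
        union = labels.union()
        assert len(union) == mesh.n_vertices
        assert len(np.unique(union)) == mesh.n_vertices

    def test_eccentricity_spans_mapped_range(self, study):
        ecc = study["rmap"].eccentricity
        assert ecc.min() == pytest.approx(0.89)
        assert ecc.max() == pytest.approx(6.0)

    def test_polar_angle_reverses_at_shared_borders(self, study):
        # continuity: neighbouring vertices across an area border carry nearly
        # equal polar angle (the meridian representation), i.e. mirror reversal
        mesh, labels, rmap = study["mesh"], study["labels"], study["rmap"]
        area = labels.area_of_vertex(mesh.n_vertices)
        for v in range(mesh.n_vertices):
            for w in mesh.neighbors[v]:
                if area[v] != area[w]:
                    diff = abs(rmap.polar_angle[v] - rmap.polar_angle[w])
                    assert min(diff, 360 - diff) < 25.0

    def test_low_snr_count_is_exact(self):
        mesh = make_mesh(10, 12, 1.0, seed=2)
        labels = make_area_labels(mesh)
        rmap = make_retinotopy(mesh, labels, 0.0, 0.2, seed=9)
        assert (rmap.snr < 5).sum() == int(np.floor(0.2 * mesh.n_vertices))
        rmap2 = make_retinotopy(mesh, labels, 0.0, 0.2, seed=9)
        assert np.array_equal(rmap.snr, rmap2.snr)

    def test_labels_must_cover_mesh(self, flat_mesh):
        labels = make_area_labels(flat_mesh)
        bigger = make_mesh(12, 10, 0.0, seed=0)
        with pytest.raises(ValueError):
            make_retinotopy(bigger, labels, 0.0, 0.0, seed=1)


class TestPlantedTractogram:
    def test_lengths_and_truth_recorded(self, study):
        tg, truth = make_planted_tractogram(
            study["parc"], study["mesh"], 30, 10, 5, seed=11
        )
        assert len(tg) == 45
        lengths = tg.lengths
        assert lengths.min() >= 3.0 and lengths.max() <= 120.0
        assert len(truth.pairs) == 45
        assert truth.kinds.count("retinotopic") == 30
        assert truth.kinds.count("intra") == 5
        assert truth.retinotopic_fraction == pytest.approx(30 / 45)

    def test_retinotopic_pairs_share_local_number(self, study):
        _, truth = make_planted_tractogram(study["parc"], study["mesh"], 40, 0, 0, seed=2)
        for (i, j), kind in zip(truth.pairs, truth.kinds):
            assert kind == "retinotopic"
            assert i % 6 == j % 6 and i // 6 != j // 6

    def test_intra_pairs_stay_within_one_area(self, study):
        _, truth = make_planted_tractogram(study["parc"], study["mesh"], 0, 0, 12, seed=3)
        for i, j in truth.pairs:
            assert i // 6 == j // 6 and i != j

    def test_empty_subarea_is_an_error(self, study):
        empty = SubAreaParcellation(
            sub_areas=[np.empty(0, dtype=int)] * 18, eccentricity_cuts={}
        )
        with pytest.raises(ValueError):
            make_planted_tractogram(empty, study["mesh"], 1, 0, 0, seed=1)

    def test_determinism(self, study):
        a, _ = make_planted_tractogram(study["parc"], study["mesh"], 20, 5, 5, seed=4)
        b, _ = make_planted_tractogram(study["parc"], study["mesh"], 20, 5, 5, seed=4)
        assert all(np.array_equal(x, y) for x, y in zip(a.streamlines, b.streamlines))


class TestOdfField:
    def test_no_bundles_low_baseline_gives_empty_mask(self, flat_mesh):
        field = make_odf_field(
            flat_mesh, [], 1.0, seed=1, base_amplitude=0.05, ambient_amplitude=0.01
        )
        assert field.amplitudes.max() <= 0.1
        assert not field.wm_mask.any()

    def test_mask_equals_amplitude_threshold_semantics(self, study):
        field = make_odf_field(
            study["mesh"], [(0, 6)], 1.0, seed=1, parcellation=study["parc"]
        )
        maxamp = field.amplitudes.max(axis=3)
        assert np.array_equal(field.wm_mask, maxamp > 0.1)
        assert field.wm_mask.any()

    def test_peak_direction_follows_bundle_tangent(self, flat_mesh):
        # One straight bundle across the flat sheet: in tube voxels the
        # max-amplitude direction must align with the bundle tangent.
        labels = make_area_labels(flat_mesh)
        rmap = make_retinotopy(flat_mesh, labels, 0.0, 0.0, seed=1)
        parc = segment_subareas(flat_mesh, labels, rmap)
        field = make_odf_field(flat_mesh, [(0, 12)], 1.0, seed=1, parcellation=parc)
        boosted = np.argwhere(field.amplitudes.max(axis=3) > 0.5)
        assert len(boosted) > 0
        # mid-arc voxels: tangent is roughly the y axis (V1 and V3 bands are
        # separated along y); check the deepest tube voxels
        mid = boosted[np.argsort(boosted[:, 2])[: max(1, len(boosted) // 3)]]
        for vox in mid:
            amps = field.amplitudes[tuple(vox)]
            peak_dir = field.directions[np.argmax(amps)]
            cos = abs(peak_dir @ np.array([0.0, 1.0, 0.0]))
            angle = np.degrees(np.arccos(np.clip(cos, -1, 1)))
            assert angle < 35.0  # arc curves, but stays broadly along y

    def test_unknown_subarea_rejected(self, study):
        with pytest.raises(ValueError):
            make_odf_field(
                study["mesh"], [(0, 99)], 1.0, seed=1, parcellation=study["parc"]
            )
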