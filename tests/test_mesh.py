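"""Template geometry: construction, smoothing, clustering, label morphology."""

from collections import Counter

import numpy as np
import pytest

from surfdetect.mesh import (
    SurfaceLabel,
    build_parcels,
    build_symmetric_template,
    cluster_centroid,
    connected_components,
    dilate_label,
    fit_point_source_fwhm,
    grow_geodesic_label,
    relative_label_size,
    smooth_field,
)


class TestConstruction:
    @pytest.mark.parametrize("level,expected", [(2, 162), (3, 642), (4, 2562)])
    def test_icosphere_vertex_count(self, level, expected):
        mesh = build_symmetric_template(level, 100.0)
        assert mesh.n_per_hemisphere == expected == 10 * 4**level + 2
        assert (mesh.hemisphere == 0).sum() == (mesh.hemisphere == 1).sum()

    def test_too_coarse_refused(self):
        with pytest.raises(ValueError):
            build_symmetric_template(1, 100.0)

    def test_each_hemisphere_is_closed_manifold(self, mesh_l2):
        edges = np.sort(
            np.vstack([mesh_l2.faces[:, [0, 1]], mesh_l2.faces[:, [1, 2]],
                       mesh_l2.faces[:, [2, 0]]]), axis=1)
        counts = Counter(map(tuple, edges))
        assert set(counts.values()) == {2}

    def test_vertex_areas_sum_to_surface_area(self, mesh_l3):
        tri = mesh_l3.vertices[mesh_l3.faces]
        cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        total = 0.5 * np.linalg.norm(cross, axis=1).sum()
        assert mesh_l3.vertex_area.sum() == pytest.approx(total, rel=1e-6)

    def test_mirror_correspondence(self, mesh_l2):
        v = mesh_l2.n_per_hemisphere
        left = mesh_l2.vertices[:v]
        right = mesh_l2.vertices[mesh_l2.contralateral(np.arange(v))]
        # right hemisphere is the x-mirror of the left, shifted apart
        assert np.allclose(left[:, 1:], right[:, 1:])
        assert np.allclose(left[:, 0] + 110.0, -(right[:, 0] - 110.0))


class TestSmoothing:
    def test_constant_field_unchanged(self, mesh_l3, rng):
        const = np.full(mesh_l3.n_vertices, 3.7)
        out = smooth_field(mesh_l3, const, 8.0)
        assert np.allclose(out, 3.7)

    def test_mass_conservation(self, mesh_l3, rng):
        f = rng.normal(size=mesh_l3.n_vertices)
        out = smooth_field(mesh_l3, f, 15.0)
        assert np.dot(out, mesh_l3.vertex_area) == pytest.approx(
            np.dot(f, mesh_l3.vertex_area), rel=1e-9)

    def test_linearity(self, mesh_l3, rng):
        f = rng.normal(size=mesh_l3.n_vertices)
        g = rng.normal(size=mesh_l3.n_vertices)
        lhs = smooth_field(mesh_l3, 2.5 * f - 1.5 * g, 8.0)
        rhs = 2.5 * smooth_field(mesh_l3, f, 8.0) - 1.5 * smooth_field(mesh_l3, g, 8.0)
        assert np.allclose(lhs, rhs, atol=1e-9)

    @pytest.mark.parametrize("fwhm", [8.0, 32.0])
    def test_point_source_achieves_requested_fwhm(self, mesh_l4, fwhm):
        src = np.zeros(mesh_l4.n_vertices)
        src[17] = 1.0
        resp = smooth_field(mesh_l4, src, fwhm)
        fitted = fit_point_source_fwhm(mesh_l4, resp, 17)
        assert abs(fitted - fwhm) / fwhm < 0.15

    def test_nonfinite_field_refused(self, mesh_l2):
        f = np.zeros(mesh_l2.n_vertices)
        f[0] = np.nan
        with pytest.raises(ValueError):
            smooth_field(mesh_l2, f, 8.0)

    def test_smoothing_never_crosses_midline(self, mesh_l2):
        v = mesh_l2.n_per_hemisphere
        src = np.zeros(mesh_l2.n_vertices)
        src[:v] = 1.0
        out = smooth_field(mesh_l2, src, 32.0)
        assert np.allclose(out[v:], 0.0)
        assert np.allclose(out[:v], 1.0)


class TestComponents:
    def test_empty_mask(self, mesh_l2):
        assert connected_components(mesh_l2, np.zeros(mesh_l2.n_vertices, bool)) == []

    def test_two_disjoint_patches(self, mesh_l2):
        mask = np.zeros(mesh_l2.n_vertices, bool)
        a = grow_geodesic_label(mesh_l2, 0, radius_mm=20.0).vertex_ids
        b = grow_geodesic_label(mesh_l2, mesh_l2.n_per_hemisphere, radius_mm=20.0).vertex_ids
        mask[a] = True
        mask[b] = True
        comps = connected_components(mesh_l2, mask)
        assert len(comps) == 2

    def test_full_mask_gives_one_component_per_hemisphere(self, mesh_l2):
        comps = connected_components(mesh_l2, np.ones(mesh_l2.n_vertices, bool))
        assert len(comps) == 2
        assert sorted(len(c) for c in comps) == [162, 162]

    def test_partition_property(self, mesh_l3, rng):
        mask = rng.random(mesh_l3.n_vertices) > 0.6
        comps = connected_components(mesh_l3, mask)
        allv = np.concatenate(comps) if comps else np.array([], dtype=int)
        assert len(allv) == len(set(allv.tolist()))  # disjoint
        assert set(allv.tolist()) == set(np.flatnonzero(mask).tolist())


class TestCentroid:
    def test_singleton(self, mesh_l2):
        assert cluster_centroid(mesh_l2, np.array([7])) == 7

    def test_symmetric_one_ring(self, mesh_l3):
        # pick an interior degree-6 vertex; its closed 1-ring is symmetric
        # enough that the centroid snaps back to the centre vertex
        v = 100
        ring = np.concatenate([[v], mesh_l3.neighbors(v)])
        assert cluster_centroid(mesh_l3, ring) == v

    def test_matches_brute_force(self, mesh_l2, rng):
        cluster = grow_geodesic_label(mesh_l2, 3, radius_mm=45.0).vertex_ids
        w = mesh_l2.vertex_area[cluster]
        mean = (mesh_l2.vertices[cluster] * w[:, None]).sum(0) / w.sum()
        dists = {int(c): np.linalg.norm(mesh_l2.vertices[c] - mean) for c in cluster}
        best = min(sorted(dists), key=lambda c: (dists[c], c))
        assert cluster_centroid(mesh_l2, cluster) == best

    def test_enumeration_order_invariance(self, mesh_l2, rng):
        cluster = grow_geodesic_label(mesh_l2, 50, radius_mm=35.0).vertex_ids
        shuffled = rng.permutation(cluster)
        assert cluster_centroid(mesh_l2, cluster) == cluster_centroid(mesh_l2, shuffled)

    def test_empty_refused(self, mesh_l2):
        with pytest.raises(ValueError):
            cluster_centroid(mesh_l2, np.array([], dtype=int))


class TestLabels:
    def test_dilate_identity(self, mesh_l2):
        lab = SurfaceLabel(vertex_ids=np.array([5, 6]), phi=0.001)
        out = dilate_label(mesh_l2, lab, 0)
        assert np.array_equal(out.vertex_ids, lab.vertex_ids)

    def test_dilate_singleton_one_ring(self, mesh_l3):
        v = 100  # interior vertex of degree 6
        assert len(mesh_l3.neighbors(v)) == 6
        out = dilate_label(mesh_l3, SurfaceLabel(vertex_ids=np.array([v])), 1)
        assert len(out) == 7

    def test_dilation_monotone_in_phi(self, mesh_l2):
        lab = SurfaceLabel(vertex_ids=np.array([0]))
        phis = [dilate_label(mesh_l2, lab, k).phi for k in range(4)]
        assert all(b >= a for a, b in zip(phis, phis[1:]))

    def test_phi_extremes(self, mesh_l2):
        full = SurfaceLabel(vertex_ids=np.arange(mesh_l2.n_vertices))
        assert relative_label_size(mesh_l2, full) == pytest.approx(1.0)
        assert relative_label_size(mesh_l2, np.array([], dtype=int)) == 0.0

    def test_phi_one_hemisphere_is_half(self, mesh_l2):
        v = mesh_l2.n_per_hemisphere
        left = SurfaceLabel(vertex_ids=np.arange(v))
        assert relative_label_size(mesh_l2, left) == pytest.approx(0.5, rel=1e-9)

    def test_phi_additive_over_disjoint_labels(self, mesh_l3):
        a = grow_geodesic_label(mesh_l3, 0, radius_mm=25.0)
        b = grow_geodesic_label(mesh_l3, mesh_l3.n_per_hemisphere, radius_mm=30.0)
        union = SurfaceLabel(np.concatenate([a.vertex_ids, b.vertex_ids]))
        assert relative_label_size(mesh_l3, union) == pytest.approx(
            a.phi + b.phi, rel=1e-12)

    def test_grow_by_phi_hits_target(self, mesh_l4):
        lab = grow_geodesic_label(mesh_l4, 9, target_phi=0.05)
        assert lab.phi == pytest.approx(0.05, rel=0.05)


class TestParcels:
    def test_partition_and_contiguity(self, mesh_l3):
        parcel = build_parcels(mesh_l3, 8, seed=3)
        assert parcel.min() == 0 and parcel.max() == 15
        assert not np.any(parcel == -1)
        for p in range(16):
            mask = parcel == p
            assert mask.sum() > 0
            assert len(connected_components(mesh_l3, mask)) == 1

    def test_reproducible(self, mesh_l2):
        assert np.array_equal(build_parcels(mesh_l2, 5, seed=9),
                              build_parcels(mesh_l2, 5, seed=9))

    def test_single_parcel_is_whole_hemisphere(self, mesh_l2):
        parcel = build_parcels(mesh_l2, 1, seed=0)
        v = mesh_l2.n_per_hemisphere
        assert np.all(parcel[:v] == 0) and np.all(parcel[v:] == 1)
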