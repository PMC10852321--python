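"""AFROC evaluation: marks, centroid criterion, operating points, AUC."""

import numpy as np
import pytest

from surfdetect.afroc import (
    afroc_curve,
    extract_marks,
    per_lesion_detection_fpf,
    rate_marks,
    threshold_grid,
    trapezoid_auc,
)
from surfdetect.mesh import (
    SurfaceLabel,
    dilate_label,
    grow_geodesic_label,
    smooth_field,
)


def smooth_random_maps(mesh, subject_ids, seed, fwhm=15.0):
    rng = np.random.default_rng(seed)
    out = {}
    for sid in subject_ids:
        f = smooth_field(mesh, rng.standard_normal(mesh.n_vertices), fwhm)
        out[sid] = (f - f.mean()) / f.std()
    return out


class TestThresholdGrid:
    def test_single_threshold_is_median(self, mesh_l2):
        maps = {"a": np.arange(mesh_l2.n_vertices, dtype=float)}
        grid = threshold_grid(maps, 1)
        assert grid[0] == pytest.approx(np.quantile(maps["a"], 0.5, method="nearest"))

    def test_grid_values_drawn_from_pooled_maps(self, mesh_l2):
        maps = smooth_random_maps(mesh_l2, ["a", "b"], 3)
        grid = threshold_grid(maps, 33)
        pooled = np.concatenate([m.ravel() for m in maps.values()])
        assert np.all(np.isin(grid, pooled))
        assert np.all(np.diff(grid) < 0)  # strict -> loose

    def test_constant_maps_refused(self, mesh_l2):
        with pytest.raises(ValueError, match="constant"):
            threshold_grid({"a": np.ones(mesh_l2.n_vertices)}, 8)

    def test_auc_converges_in_grid_density(self, mesh_l2):
        sids = [f"c{i}" for i in range(6)] + ["p0", "p1"]
        maps = smooth_random_maps(mesh_l2, sids, 4)
        labels = {"p0": [grow_geodesic_label(mesh_l2, 10, radius_mm=30.0)],
                  "p1": [grow_geodesic_label(mesh_l2, 200, radius_mm=30.0)]}
        ctrl = [s for s in sids if s.startswith("c")]
        aucs = []
        for n in (512, 4096):
            grid = threshold_grid(maps, n)
            aucs.append(afroc_curve(maps, mesh_l2, labels, ctrl, grid).auc)
        assert abs(aucs[0] - aucs[1]) < 0.01


class TestExtractMarks:
    def test_no_marks_above_map_maximum(self, mesh_l2, rng):
        vals = rng.random(mesh_l2.n_vertices)
        assert extract_marks(vals, mesh_l2, vals.max() + 1.0) == []

    def test_single_patch_single_mark(self, mesh_l2):
        lab = grow_geodesic_label(mesh_l2, 12, radius_mm=25.0)
        vals = np.zeros(mesh_l2.n_vertices)
        vals[lab.vertex_ids] = 1.0
        marks = extract_marks(vals, mesh_l2, 0.5)
        assert len(marks) == 1
        assert marks[0].centroid in set(lab.vertex_ids.tolist())

    def test_two_tailed_catches_both_signs(self, mesh_l2):
        a = grow_geodesic_label(mesh_l2, 12, radius_mm=20.0)
        b = grow_geodesic_label(mesh_l2, mesh_l2.n_per_hemisphere + 40,
                                radius_mm=20.0)
        vals = np.zeros(mesh_l2.n_vertices)
        vals[a.vertex_ids] = 2.0
        vals[b.vertex_ids] = -2.0
        assert len(extract_marks(vals, mesh_l2, 1.0, two_tailed=True)) == 2
        assert len(extract_marks(vals, mesh_l2, 1.0, two_tailed=False)) == 1


class TestCentroidCriterion:
    def test_centroid_inside_counts_cluster_mostly_outside(self, mesh_l3):
        # cluster = disk; label = small patch containing the disk's centre
        cluster = grow_geodesic_label(mesh_l3, 30, radius_mm=35.0)
        vals = np.zeros(mesh_l3.n_vertices)
        vals[cluster.vertex_ids] = 1.0
        marks = {"p": extract_marks(vals, mesh_l3, 0.5, subject_id="p")}
        centroid = marks["p"][0].centroid
        label = SurfaceLabel(vertex_ids=np.array([centroid]), phi=1e-4)
        det, flagged, fp = rate_marks(marks, {"p": [label]}, [], mesh_l3.n_vertices)
        assert det == 1 and flagged == 0 and fp == 0

    def test_overlap_without_centroid_is_no_detection(self, mesh_l3):
        cluster = grow_geodesic_label(mesh_l3, 30, radius_mm=30.0)
        vals = np.zeros(mesh_l3.n_vertices)
        vals[cluster.vertex_ids] = 1.0
        marks = {"p": extract_marks(vals, mesh_l3, 0.5, subject_id="p")}
        centroid = marks["p"][0].centroid
        rim = np.setdiff1d(cluster.vertex_ids, [centroid])[-3:]
        label = SurfaceLabel(vertex_ids=rim, phi=1e-4)
        det, *_ = rate_marks(marks, {"p": [label]}, [], mesh_l3.n_vertices)
        assert det == 0

    def test_patient_false_positives_not_counted(self, mesh_l2):
        off_label = grow_geodesic_label(mesh_l2, 5, radius_mm=20.0)
        vals = np.zeros(mesh_l2.n_vertices)
        vals[off_label.vertex_ids] = 1.0
        marks = {"p": extract_marks(vals, mesh_l2, 0.5, subject_id="p"),
                 "c": []}
        far = SurfaceLabel(vertex_ids=np.array([mesh_l2.n_vertices - 1]))
        det, flagged, fp = rate_marks(marks, {"p": [far]}, ["c"],
                                      mesh_l2.n_vertices)
        assert det == 0 and flagged == 0 and fp == 0


class TestCurve:
    def test_oracle_maps_reach_auc_one(self, mesh_l2):
        lab = grow_geodesic_label(mesh_l2, 8, radius_mm=25.0, kind="lesion-wide")
        maps = {"p": lab.mask(mesh_l2.n_vertices).astype(float)}
        for i in range(5):
            maps[f"c{i}"] = np.zeros(mesh_l2.n_vertices)
        grid = np.array([1.0, 0.5])
        curve = afroc_curve(maps, mesh_l2, {"p": [lab]},
                            [f"c{i}" for i in range(5)], grid)
        assert curve.auc == pytest.approx(1.0)

    def test_all_zero_maps_give_auc_zero(self, mesh_l2):
        maps = {sid: np.zeros(mesh_l2.n_vertices) for sid in ["p", "c0", "c1"]}
        lab = grow_geodesic_label(mesh_l2, 8, radius_mm=20.0)
        curve = afroc_curve(maps, mesh_l2, {"p": [lab]}, ["c0", "c1"],
                            np.array([0.5]))
        assert curve.auc == 0.0

    def test_sweep_is_monotone(self, mesh_l2):
        sids = [f"c{i}" for i in range(8)] + ["p"]
        maps = smooth_random_maps(mesh_l2, sids, 6)
        lab = grow_geodesic_label(mesh_l2, 77, radius_mm=30.0)
        grid = threshold_grid(maps, 64)
        curve = afroc_curve(maps, mesh_l2, {"p": [lab]},
                            sids[:-1], grid)
        fpf, tpf = curve.arrays()
        # FPF is monotone in threshold leniency (a flagged control stays
        # flagged as its clusters grow); TPF need not be, because merging
        # clusters can move a centroid out of the label
        assert np.all(np.diff(fpf) >= 0)
        assert 0.0 <= curve.auc <= 1.0

    def test_needs_labels_and_controls(self, mesh_l2):
        maps = {"p": np.zeros(mesh_l2.n_vertices)}
        with pytest.raises(ValueError):
            afroc_curve(maps, mesh_l2, {}, [], np.array([0.5]))


class TestTrapezoidAuc:
    def test_rectangle(self):
        assert trapezoid_auc(np.array([0.0, 1.0]), np.array([1.0, 1.0])) == \
            pytest.approx(1.0)

    def test_diagonal(self):
        f = np.linspace(0, 1, 11)
        assert trapezoid_auc(f, f) == pytest.approx(0.5)

    def test_non_monotone_fpf_refused(self):
        with pytest.raises(ValueError):
            trapezoid_auc(np.array([0.5, 0.2]), np.array([0.1, 0.2]))


class TestPerLesion:
    def test_oracle_map_has_zero_fpf_detection(self, mesh_l2):
        lab = grow_geodesic_label(mesh_l2, 8, radius_mm=25.0)
        maps = {"p": lab.mask(mesh_l2.n_vertices).astype(float),
                "c0": np.zeros(mesh_l2.n_vertices)}
        fpf, detected = per_lesion_detection_fpf(
            maps, mesh_l2, lab, "p", ["c0"], np.array([1.0, 0.5]))
        assert detected and fpf == 0.0

    def test_never_detected_convention(self, mesh_l2):
        lab = grow_geodesic_label(mesh_l2, 8, radius_mm=20.0)
        maps = {"p": np.zeros(mesh_l2.n_vertices),
                "c0": np.zeros(mesh_l2.n_vertices)}
        fpf, detected = per_lesion_detection_fpf(
            maps, mesh_l2, lab, "p", ["c0"], np.array([0.5]))
        assert not detected and fpf == 1.0

    def test_empty_label_refused(self, mesh_l2):
        lab = SurfaceLabel(vertex_ids=np.array([], dtype=int))
        with pytest.raises(ValueError):
            per_lesion_detection_fpf({}, mesh_l2, lab, "p", [], np.array([0.5]))


def test_wide_labels_are_dilated_strict_labels(mesh_l2):
    strict = grow_geodesic_label(mesh_l2, 44, radius_mm=20.0, kind="lesion-strict")
    wide = dilate_label(mesh_l2, strict, 4)
    assert wide.kind == "lesion-wide"
    assert set(strict.vertex_ids.tolist()) < set(wide.vertex_ids.tolist())
    assert wide.phi > strict.phi
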