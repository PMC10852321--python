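"""Synthetic cohort generator: structure, determinism, effect calibration."""

import numpy as np
import pytest
from scipy import stats

from surfdetect.cohort import (
    INTENSITY_DEPTHS,
    MEASURE_NAMES,
    CohortConfig,
    generate_cohort,
    normalize_intensity,
)


def small_cfg(**kw):
    base = dict(n_controls=8, n_positive=2, n_negative=2, n_lesions=3,
                lesion_radius_mm=(20.0, 30.0), seed=7)
    base.update(kw)
    return CohortConfig(**base)


class TestConfigValidation:
    def test_minimum_controls(self):
        with pytest.raises(ValueError):
            CohortConfig(n_controls=2)

    def test_phi_range(self):
        with pytest.raises(ValueError):
            CohortConfig(hypothesis_phi_range=(0.5, 0.2))

    def test_unknown_measure(self):
        with pytest.raises(ValueError):
            CohortConfig(measures=["thickness", "nope"])

    def test_lesion_radius_exceeding_hemisphere(self, mesh_l2):
        cfg = small_cfg(lesion_radius_mm=(10.0, 400.0))
        with pytest.raises(ValueError, match="hemisphere"):
            generate_cohort(cfg, mesh_l2)


class TestStructure:
    def test_canonical_measure_set(self, small_cohort):
        assert small_cohort.measure_names == MEASURE_NAMES
        assert len(MEASURE_NAMES) == 19

    def test_intensity_depth_names(self, small_cohort):
        intensity = [m for m in small_cohort.measure_names
                     if m.startswith(("t1_", "flair_"))]
        assert len(intensity) == 12
        assert {m.split("_", 1)[1] for m in intensity} == set(INTENSITY_DEPTHS)

    def test_group_label_invariants(self, small_cohort):
        for s in small_cohort.subjects:
            if s.group == "control":
                assert not s.lesion_labels and s.hypothesis_label is None
            elif s.group == "mri_positive":
                assert len(s.lesion_labels) >= 1
                assert s.hypothesis_label is None
            else:
                assert s.hypothesis_label is not None
                assert len(s.hypothesis_label) > 0

    def test_lesions_distributed_round_robin(self, mesh_l2):
        cohort = generate_cohort(
            small_cfg(n_controls=3, n_positive=5, n_negative=0, n_lesions=6),
            mesh_l2)
        counts = sorted(len(p.lesion_labels)
                        for p in cohort.by_group("mri_positive"))
        assert counts == [1, 1, 1, 1, 2]

    def test_all_maps_finite_and_complete(self, small_cohort):
        for s in small_cohort.subjects:
            for m in small_cohort.measure_names:
                vals = s.base_measures[m]
                assert vals.shape == (small_cohort.mesh.n_vertices,)
                assert np.all(np.isfinite(vals))

    def test_hypothesis_phi_within_range(self, mesh_l3):
        cfg = small_cfg(n_controls=3, n_positive=0, n_lesions=0, n_negative=12,
                        hypothesis_phi_range=(0.02, 0.36))
        cohort = generate_cohort(cfg, mesh_l3)
        for s in cohort.by_group("mri_negative"):
            assert 0.02 <= s.hypothesis_label.phi <= 0.36


class TestDeterminism:
    def test_same_seed_bit_identical(self, mesh_l2):
        a = generate_cohort(small_cfg(), mesh_l2)
        b = generate_cohort(small_cfg(), mesh_l2)
        for sa, sb in zip(a.subjects, b.subjects):
            assert sa.covariates == sb.covariates
            for m in a.measure_names:
                assert np.array_equal(sa.base_measures[m], sb.base_measures[m])
            for la, lb in zip(sa.lesion_labels, sb.lesion_labels):
                assert np.array_equal(la.vertex_ids, lb.vertex_ids)

    def test_different_seed_differs(self, mesh_l2):
        a = generate_cohort(small_cfg(seed=1), mesh_l2)
        b = generate_cohort(small_cfg(seed=2), mesh_l2)
        assert not np.array_equal(a.subjects[0].base_measures["thickness"],
                                  b.subjects[0].base_measures["thickness"])


class TestIntensities:
    def test_adjacent_depth_correlation(self, small_cohort):
        s = small_cohort.controls[0]
        maps = [s.base_measures[f"t1_{d}"] for d in INTENSITY_DEPTHS]
        for a, b in zip(maps, maps[1:]):
            assert np.corrcoef(a, b)[0, 1] >= 0.5

    def test_t1_depth_gradient_monotone_direction(self, small_cohort):
        # normalized T1: subcortical white matter maps to ~1, cortex to ~0
        s = small_cohort.controls[0]
        assert s.base_measures["t1_sub1mm"].mean() > s.base_measures["t1_gm50"].mean()
        assert s.base_measures["t1_sub2mm"].mean() > s.base_measures["t1_gm25"].mean()

    def test_zero_noise_maps_are_deterministic_transforms(self, mesh_l2):
        cfg = small_cfg(n_controls=4, n_positive=0, n_negative=0, n_lesions=0,
                        noise_sd=0.0, covariate_effect_sizes=0.0)
        cohort = generate_cohort(cfg, mesh_l2)
        ref = cohort.subjects[0].base_measures
        for s in cohort.subjects[1:]:
            for m in cohort.measure_names:
                assert np.allclose(s.base_measures[m], ref[m])


class TestNormalizeIntensity:
    def test_reference_points(self):
        raw = np.array([1000.0, 1400.0, 1200.0])
        out = normalize_intensity(raw, wm_reference=1400.0, cortex_reference=1000.0)
        assert out == pytest.approx([0.0, 1.0, 0.5])

    def test_equal_references_refused(self):
        with pytest.raises(ValueError):
            normalize_intensity(np.array([1.0]), 5.0, 5.0)


class TestEffectCalibration:
    def test_lesion_effect_recovered_in_control_sd_units(self, mesh_l3):
        cfg = CohortConfig(
            n_controls=150, n_positive=10, n_negative=0, n_lesions=10,
            lesion_radius_mm=(20.0, 26.0),
            lesion_effects={"thickness": 4.0},
            covariate_effect_sizes=0.0,
            measures=["thickness"], seed=11)
        cohort = generate_cohort(cfg, mesh_l3)
        ctrl = cohort.measure_matrix("thickness", cohort.controls)
        ratios = []
        for p in cohort.by_group("mri_positive"):
            for lab in p.lesion_labels:
                diff = (p.base_measures["thickness"][lab.vertex_ids].mean()
                        - ctrl[:, lab.vertex_ids].mean())
                sd = ctrl[:, lab.vertex_ids].std(axis=0, ddof=1).mean()
                ratios.append(diff / sd)
        assert np.mean(ratios) == pytest.approx(4.0, rel=0.10)

    def test_zero_effects_are_exchangeable(self, mesh_l3):
        cfg = CohortConfig(
            n_controls=20, n_positive=10, n_negative=0, n_lesions=10,
            lesion_radius_mm=(20.0, 26.0),
            lesion_effects={}, negative_effect_scale=0.0,
            measures=["thickness", "sulc"], seed=13)
        cohort = generate_cohort(cfg, mesh_l3)
        # vertex values within a subject share an intercept, so compare
        # subject-level summaries, which are exchangeable draws under
        # zero effects
        for m in cfg.measures:
            a = cohort.measure_matrix(m, cohort.controls)
            b = cohort.measure_matrix(m, cohort.patients)
            assert stats.ks_2samp(a.mean(axis=1), b.mean(axis=1)).pvalue > 0.01
            assert stats.ks_2samp(a.std(axis=1), b.std(axis=1)).pvalue > 0.01

    def test_negative_subjects_receive_scaled_effect_in_hypothesis(self, mesh_l3):
        cfg = CohortConfig(
            n_controls=60, n_positive=0, n_negative=8, n_lesions=0,
            lesion_radius_mm=(25.0, 35.0),
            lesion_effects={"thickness": 6.0}, negative_effect_scale=1.0,
            covariate_effect_sizes=0.0, measures=["thickness"], seed=17)
        cohort = generate_cohort(cfg, mesh_l3)
        ctrl = cohort.measure_matrix("thickness", cohort.controls)
        mu, sd = ctrl.mean(axis=0), ctrl.std(axis=0, ddof=1)
        hits = 0
        for s in cohort.by_group("mri_negative"):
            z = (s.base_measures["thickness"] - mu) / sd
            inside = z[s.hypothesis_label.vertex_ids].max()
            if inside > 3.0:  # the implanted sub-patch lies in the hypothesis
                hits += 1
        assert hits >= 6
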