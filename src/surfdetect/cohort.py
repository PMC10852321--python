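"""Synthetic cortical cohorts for the lesion-detection pipeline.

Generates controls, MRI-positive patients (small contiguous lesion patches
with an FCD-like radiological profile: cortical thickening, reduced
white/grey contrast, subcortical T1 hypointensity and FLAIR
hyperintensity) and MRI-negative patients (weak diffuse effects plus a
lobar hypothesis label), all as per-vertex maps on a
:class:`~surfdetect.mesh.TemplateMesh`.

Each of the 19 base surface measures is generated as::

    map = smooth population mean field
        + covariate effects (age, sex, site, ICV analog; linear per vertex)
        + subject-level random intercept
        + spatially correlated vertex noise

T1 and FLAIR intensities are sampled at six cortical depths (75%, 50%,
25% of cortical thickness, white-grey interface, 1 mm and 2 mm
subcortical) from a shared smooth latent per modality, then rescaled per
subject with the median mid-cortical and median 1-mm-subcortical
intensities as references (cortex -> 0, white matter -> 1). The
white/grey contrast measure is a percent-contrast analog derived
deterministically from the raw T1 depth maps, so lesion effects implanted
on the subcortical T1 maps propagate into it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from surfdetect.mesh import (
    SurfaceLabel,
    TemplateMesh,
    build_parcels,
    grow_geodesic_label,
    relative_label_size,
    smooth_field,
)

__all__ = [
    "MEASURE_NAMES",
    "INTENSITY_DEPTHS",
    "CohortConfig",
    "SubjectRecord",
    "Cohort",
    "generate_cohort",
    "sample_intensity_depths",
    "normalize_intensity",
]

INTENSITY_DEPTHS = ["gm75", "gm50", "gm25", "interface", "sub1mm", "sub2mm"]

MORPH_MEASURES = ["sulc", "curv", "area", "volume", "thickness", "aici"]

#: The canonical ordered 19-measure base set (6 morphometry measures,
#: white/grey contrast, and normalized T1/FLAIR intensity at 6 depths each).
MEASURE_NAMES = (
    MORPH_MEASURES
    + ["wg_contrast"]
    + [f"t1_{d}" for d in INTENSITY_DEPTHS]
    + [f"flair_{d}" for d in INTENSITY_DEPTHS]
)

# per-measure (baseline, population pattern amplitude, between-subject SD)
_MORPH_PARAMS = {
    "sulc": (0.0, 3.0, 0.6),
    "curv": (0.0, 0.08, 0.02),
    "area": (0.65, 0.08, 0.07),
    "volume": (1.6, 0.25, 0.18),
    "thickness": (2.5, 0.25, 0.15),
    "aici": (0.15, 0.03, 0.02),
}

# raw intensity depth baselines (arbitrary scanner units); T1 increases
# toward white matter, FLAIR decreases (WM dark on FLAIR)
_T1_BASE = {"gm75": 960.0, "gm50": 1000.0, "gm25": 1100.0,
            "interface": 1250.0, "sub1mm": 1400.0, "sub2mm": 1450.0}
_FLAIR_BASE = {"gm75": 1020.0, "gm50": 1000.0, "gm25": 980.0,
               "interface": 930.0, "sub1mm": 870.0, "sub2mm": 850.0}

# variance decomposition of raw intensities (scanner units)
_INT_POP_SHARED = 30.0   # smooth population pattern shared across depths
_INT_POP_DEPTH = 10.0    # smooth per-depth population pattern
_INT_SUBJ_SHARED = 12.0  # per-subject intercept shared across depths
_INT_SUBJ_DEPTH = 5.0    # per-subject per-depth intercept
_INT_NOISE = 20.0        # per-depth spatially correlated vertex noise
#: total per-depth between-subject SD of a raw intensity map
_INT_SD = float(np.sqrt(_INT_SUBJ_SHARED**2 + _INT_SUBJ_DEPTH**2 + _INT_NOISE**2))

# within-measure split of between-subject SD: intercept vs vertex noise
_FRAC_INTERCEPT = np.sqrt(0.3)
_FRAC_NOISE = np.sqrt(0.7)

# covariate slopes per measure unit: (age /year, sex, site, icv /ml)
_COV_SLOPES = {
    "sulc": (0.0, 0.0, 0.25, 0.0),
    "curv": (0.0, 0.0, 0.005, 0.0),
    "area": (-0.0004, 0.01, 0.01, 0.00008),
    "volume": (-0.002, 0.03, 0.02, 0.00025),
    "thickness": (-0.004, 0.02, 0.02, 0.00012),
    "aici": (0.0, 0.0, 0.004, 0.0),
    "t1": (-0.3, 2.0, 8.0, 0.0),     # applied to all depths of the modality
    "flair": (-0.2, 1.5, 6.0, 0.0),
}
_COV_CENTER = np.array([30.0, 0.5, 0.5, 1500.0])  # age, sex, site, icv


@dataclass
class CohortConfig:
    """Generation parameters; defaults mirror the reference clinical cohort layout
    (94 controls, 5 MRI-positive patients carrying 6 lesions, 27
    MRI-negative patients with lobar hypothesis labels)."""

    n_controls: int = 94
    n_positive: int = 5
    n_negative: int = 27
    n_lesions: int = 6
    lesion_radius_mm: tuple[float, float] = (13.0, 36.0)
    lesion_effects: dict = field(default_factory=lambda: {
        "thickness": 2.0,
        "t1_sub1mm": -2.0,
        "t1_sub2mm": -2.0,
        "flair_sub1mm": 2.0,
        "flair_sub2mm": 2.0,
    })
    negative_effect_scale: float = 0.3
    hypothesis_phi_range: tuple[float, float] = (0.02, 0.36)
    noise_sd: float = 1.0
    spatial_correlation_fwhm_mm: float = 15.0
    covariate_effect_sizes: float = 1.0
    n_parcels_per_hemisphere: int = 8
    measures: list[str] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_controls < 3:
            raise ValueError("n_controls must be >= 3")
        if self.n_lesions < self.n_positive and self.n_positive > 0:
            raise ValueError("n_lesions must be >= n_positive")
        lo, hi = self.lesion_radius_mm
        if not 0 < lo <= hi:
            raise ValueError("invalid lesion_radius_mm range")
        lo, hi = self.hypothesis_phi_range
        if not 0 < lo < hi < 1:
            raise ValueError("hypothesis_phi_range must lie within (0, 1)")
        if not 0 <= self.negative_effect_scale <= 1:
            raise ValueError("negative_effect_scale must be in [0, 1]")
        if self.measures is not None:
            unknown = set(self.measures) - set(MEASURE_NAMES)
            if unknown:
                raise ValueError(f"unknown measures: {sorted(unknown)}")


@dataclass
class SubjectRecord:
    subject_id: str
    group: str  # control | mri_positive | mri_negative
    covariates: dict
    base_measures: dict  # measure name -> (2V,) array
    lesion_labels: list = field(default_factory=list)
    hypothesis_label: SurfaceLabel | None = None


@dataclass
class Cohort:
    mesh: TemplateMesh
    subjects: list
    measure_names: list

    def by_group(self, group: str) -> list:
        return [s for s in self.subjects if s.group == group]

    @property
    def controls(self) -> list:
        return self.by_group("control")

    @property
    def patients(self) -> list:
        return [s for s in self.subjects if s.group != "control"]

    def subject(self, subject_id: str) -> SubjectRecord:
        for s in self.subjects:
            if s.subject_id == subject_id:
                return s
        raise KeyError(subject_id)

    def measure_matrix(self, measure: str, subjects: list | None = None) -> np.ndarray:
        """Stack one measure across subjects into a (n_subjects, 2V) array."""
        subjects = self.subjects if subjects is None else subjects
        return np.stack([s.base_measures[measure] for s in subjects])


def normalize_intensity(
    raw: np.ndarray, wm_reference: float, cortex_reference: float
) -> np.ndarray:
    """Affine intensity rescaling mapping cortex_reference -> 0 and
    wm_reference -> 1 (an nFSI-style two-point normalization)."""
    if wm_reference == cortex_reference:
        raise ValueError("degenerate contrast: wm and cortex references are equal")
    return (np.asarray(raw, dtype=float) - cortex_reference) / (
        wm_reference - cortex_reference
    )


def _unit_smooth(rng: np.random.Generator, mesh: TemplateMesh,
                 fwhm: float, n: int = 1) -> np.ndarray:
    """Smooth unit-variance random fields, (2V, n); single field -> (2V,)."""
    x = rng.standard_normal((mesh.n_vertices, n))
    x = smooth_field(mesh, x, fwhm)
    x = (x - x.mean(axis=0)) / x.std(axis=0)
    return x[:, 0] if n == 1 else x


def _wg_contrast(raw_t1: dict) -> np.ndarray:
    """Percent white/grey contrast from raw T1 at -1 mm and mid-cortex."""
    a, b = raw_t1["sub1mm"], raw_t1["gm50"]
    return 100.0 * (a - b) / (0.5 * (a + b))


class _IntensityPopulation:
    """Frozen population-level structure of one modality's depth maps."""

    def __init__(self, rng: np.random.Generator, mesh: TemplateMesh,
                 baselines: dict, fwhm: float):
        self.baselines = baselines
        self.shared = _unit_smooth(rng, mesh, fwhm)
        self.depth = {d: _unit_smooth(rng, mesh, fwhm) for d in INTENSITY_DEPTHS}

    def mean_map(self, depth: str) -> np.ndarray:
        return (self.baselines[depth]
                + _INT_POP_SHARED * self.shared
                + _INT_POP_DEPTH * self.depth[depth])


def sample_intensity_depths(
    rng: np.random.Generator,
    mesh: TemplateMesh,
    population: _IntensityPopulation,
    covariate_shift: float,
    noise_scale: float,
    corr_fwhm: float,
) -> dict:
    """One subject's raw intensity maps at the six named depths.

    Depth maps share a subject intercept and the population latent, giving
    adjacent-depth correlation well above 0.5, while per-depth intercepts
    and spatially correlated noise keep depths from being redundant. With
    ``noise_scale = 0`` the output is a deterministic transform of the
    population mean fields plus the covariate shift.
    """
    b_shared = noise_scale * _INT_SUBJ_SHARED * rng.standard_normal()
    b_depth = noise_scale * _INT_SUBJ_DEPTH * rng.standard_normal(len(INTENSITY_DEPTHS))
    noise = rng.standard_normal((mesh.n_vertices, len(INTENSITY_DEPTHS)))
    if noise_scale > 0:
        noise = smooth_field(mesh, noise, corr_fwhm)
        noise = (noise - noise.mean(axis=0)) / noise.std(axis=0)
    maps = {}
    for j, d in enumerate(INTENSITY_DEPTHS):
        maps[d] = (population.mean_map(d) + covariate_shift + b_shared
                   + b_depth[j] + noise_scale * _INT_NOISE * noise[:, j])
    return maps


def _draw_covariates(rng: np.random.Generator) -> dict:
    return {
        "age": float(rng.normal(30.0, 8.0)),
        "sex": float(rng.integers(0, 2)),
        "site": float(rng.integers(0, 2)),
        "icv_analog": float(rng.normal(1500.0, 130.0)),
    }


def _cov_shift(slopes: tuple, cov: dict, scale: float) -> float:
    x = np.array([cov["age"], cov["sex"], cov["site"], cov["icv_analog"]])
    return float(scale * np.dot(np.asarray(slopes), x - _COV_CENTER))


def _place_lesion(
    rng: np.random.Generator, mesh: TemplateMesh, radius: float,
    occupied: np.ndarray
) -> SurfaceLabel:
    """Uniformly random geodesic disk, rejecting overlap with prior lesions."""
    for _ in range(200):
        seed_v = int(rng.integers(0, mesh.n_vertices))
        lab = grow_geodesic_label(mesh, seed_v, radius_mm=radius)
        if not occupied[lab.vertex_ids].any():
            return lab
    raise RuntimeError("could not place a non-overlapping lesion")


def generate_cohort(config: CohortConfig, mesh: TemplateMesh) -> Cohort:
    """Generate a fully reproducible synthetic cohort on ``mesh``.

    Lesion effect sizes are expressed in control-SD units of the affected
    measure (between-subject SD of intercept plus vertex noise) with the
    FCD-like sign convention: thickness up, white/grey contrast down
    (inherited from T1), subcortical T1 down, subcortical FLAIR up.
    MRI-negative subjects receive the same profile scaled by
    ``negative_effect_scale`` inside a random sub-patch of one parcel of
    their lobar hypothesis label.
    """
    measures = list(config.measures) if config.measures is not None else list(MEASURE_NAMES)
    need_t1 = any(m.startswith("t1_") or m == "wg_contrast" for m in measures)
    need_flair = any(m.startswith("flair_") for m in measures)
    morph = [m for m in measures if m in _MORPH_PARAMS]
    max_radius = config.lesion_radius_mm[1]
    if max_radius >= np.pi * mesh.radius_mm / 2:
        raise ValueError("lesion radius exceeds hemisphere size")

    ss = np.random.SeedSequence(config.seed)
    rng_pop, rng_cov, rng_subj, rng_les, rng_hyp = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )
    fwhm_pop = 40.0
    fwhm_noise = config.spatial_correlation_fwhm_mm

    # --- population structure ------------------------------------------------
    pop_mean = {}
    pop_mod = {}
    for m in morph:
        base, amp, _sd = _MORPH_PARAMS[m]
        pop_mean[m] = base + amp * _unit_smooth(rng_pop, mesh, fwhm_pop)
        pop_mod[m] = 1.0 + 0.5 * _unit_smooth(rng_pop, mesh, fwhm_pop)
    pop_t1 = _IntensityPopulation(rng_pop, mesh, _T1_BASE, fwhm_pop) if need_t1 else None
    pop_flair = (_IntensityPopulation(rng_pop, mesh, _FLAIR_BASE, fwhm_pop)
                 if need_flair else None)

    parcels = build_parcels(mesh, config.n_parcels_per_hemisphere,
                            seed=int(rng_hyp.integers(2**31)))
    n_parc = config.n_parcels_per_hemisphere

    # --- group layout --------------------------------------------------------
    groups = (["control"] * config.n_controls
              + ["mri_positive"] * config.n_positive
              + ["mri_negative"] * config.n_negative)
    lesions_per_pos = np.zeros(config.n_positive, dtype=int)
    for i in range(config.n_lesions if config.n_positive else 0):
        lesions_per_pos[i % config.n_positive] += 1

    subjects = []
    pos_seen = 0
    for idx, group in enumerate(groups):
        sid = f"{group.split('_')[-1][:4]}{idx:03d}"
        cov = _draw_covariates(rng_cov)

        # lesion / hypothesis geometry first (labels are part of the record)
        lesion_labels: list[SurfaceLabel] = []
        hypothesis = None
        effect_patches: list[tuple[SurfaceLabel, float]] = []
        if group == "mri_positive":
            occupied = np.zeros(mesh.n_vertices, dtype=bool)
            for _ in range(lesions_per_pos[pos_seen]):
                r = float(rng_les.uniform(*config.lesion_radius_mm))
                lab = _place_lesion(rng_les, mesh, r, occupied)
                lab.kind = "lesion-strict"
                lab.subject_id = sid
                occupied[lab.vertex_ids] = True
                lesion_labels.append(lab)
                effect_patches.append((lab, 1.0))
            pos_seen += 1
        elif group == "mri_negative":
            hypothesis = _draw_hypothesis(rng_hyp, mesh, parcels, n_parc,
                                          config.hypothesis_phi_range)
            hypothesis.subject_id = sid
            if config.negative_effect_scale > 0:
                patch = _sub_patch(rng_hyp, mesh, parcels, hypothesis,
                                   config.lesion_radius_mm)
                effect_patches.append((patch, config.negative_effect_scale))

        # --- base measure maps ----------------------------------------------
        base_measures = {}
        n_noise = len(morph)
        noise = rng_subj.standard_normal((mesh.n_vertices, max(n_noise, 1)))
        if config.noise_sd > 0 and n_noise:
            noise = smooth_field(mesh, noise, fwhm_noise)
            noise = (noise - noise.mean(axis=0)) / noise.std(axis=0)
        for j, m in enumerate(morph):
            _base, _amp, sd = _MORPH_PARAMS[m]
            sd = sd * config.noise_sd
            b = _FRAC_INTERCEPT * sd * rng_subj.standard_normal()
            shift = _cov_shift(_COV_SLOPES[m], cov, config.covariate_effect_sizes)
            base_measures[m] = (pop_mean[m] + shift * pop_mod[m] + b
                                + _FRAC_NOISE * sd * noise[:, j])

        raw_t1 = raw_flair = None
        if need_t1:
            raw_t1 = sample_intensity_depths(
                rng_subj, mesh, pop_t1,
                _cov_shift(_COV_SLOPES["t1"], cov, config.covariate_effect_sizes),
                config.noise_sd, fwhm_noise)
        if need_flair:
            raw_flair = sample_intensity_depths(
                rng_subj, mesh, pop_flair,
                _cov_shift(_COV_SLOPES["flair"], cov, config.covariate_effect_sizes),
                config.noise_sd, fwhm_noise)

        # --- implant effects (on primitive maps, before normalization) -------
        for lab, scale in effect_patches:
            ids = lab.vertex_ids
            for meas, eff in config.lesion_effects.items():
                delta = scale * eff * config.noise_sd
                if meas in _MORPH_PARAMS and meas in base_measures:
                    base_measures[meas][ids] += delta * _MORPH_PARAMS[meas][2]
                elif meas.startswith("t1_") and raw_t1 is not None:
                    raw_t1[meas[3:]][ids] += delta * _INT_SD
                elif meas.startswith("flair_") and raw_flair is not None:
                    raw_flair[meas[6:]][ids] += delta * _INT_SD

        # --- derived measures -------------------------------------------------
        if raw_t1 is not None:
            if "wg_contrast" in measures:
                base_measures["wg_contrast"] = _wg_contrast(raw_t1)
            wm_ref = float(np.median(raw_t1["sub1mm"]))
            gm_ref = float(np.median(raw_t1["gm50"]))
            for d in INTENSITY_DEPTHS:
                name = f"t1_{d}"
                if name in measures:
                    base_measures[name] = normalize_intensity(raw_t1[d], wm_ref, gm_ref)
        if raw_flair is not None:
            wm_ref = float(np.median(raw_flair["sub1mm"]))
            gm_ref = float(np.median(raw_flair["gm50"]))
            for d in INTENSITY_DEPTHS:
                name = f"flair_{d}"
                if name in measures:
                    base_measures[name] = normalize_intensity(raw_flair[d], wm_ref, gm_ref)

        subjects.append(SubjectRecord(
            subject_id=sid, group=group, covariates=cov,
            base_measures={m: base_measures[m] for m in measures},
            lesion_labels=lesion_labels, hypothesis_label=hypothesis,
        ))

    return Cohort(mesh=mesh, subjects=subjects, measure_names=measures)


def _draw_hypothesis(
    rng: np.random.Generator, mesh: TemplateMesh, parcels: np.ndarray,
    n_parc: int, phi_range: tuple[float, float]
) -> SurfaceLabel:
    """Union of 1-3 same-hemisphere parcels with phi inside phi_range."""
    for _ in range(100):
        hemi = int(rng.integers(0, 2))
        k = int(rng.integers(1, 4))
        chosen = rng.choice(n_parc, size=min(k, n_parc), replace=False) + hemi * n_parc
        ids = np.flatnonzero(np.isin(parcels, chosen))
        phi = relative_label_size(mesh, ids)
        if phi_range[0] <= phi <= phi_range[1]:
            return SurfaceLabel(vertex_ids=ids, kind="hypothesis", phi=phi)
    raise RuntimeError(
        "could not draw a hypothesis label inside hypothesis_phi_range; "
        "adjust n_parcels_per_hemisphere"
    )


def _sub_patch(
    rng: np.random.Generator, mesh: TemplateMesh, parcels: np.ndarray,
    hypothesis: SurfaceLabel, radius_range: tuple[float, float]
) -> SurfaceLabel:
    """Random geodesic sub-patch inside one parcel of the hypothesis label."""
    member_parcels = np.unique(parcels[hypothesis.vertex_ids])
    parcel_id = int(rng.choice(member_parcels))
    in_parcel = np.flatnonzero(parcels == parcel_id)
    seed_v = int(rng.choice(in_parcel))
    r = float(rng.uniform(*radius_range))
    disk = grow_geodesic_label(mesh, seed_v, radius_mm=r)
    ids = np.intersect1d(disk.vertex_ids, in_parcel)
    return SurfaceLabel(vertex_ids=ids, kind="lesion-strict",
                        phi=relative_label_size(mesh, ids))
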