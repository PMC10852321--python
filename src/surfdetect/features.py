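"""Augmented feature banks for the multivariate classifiers.

Each of the 19 base measures is expanded into four variants — 8 mm
smoothed, 32 mm smoothed, their difference (a Difference-of-Gaussians
spatial band-pass) and the interhemispheric asymmetry of the raw measure
smoothed at 8 mm — giving 76 features. Six named subsets select columns
for the classifiers:

========================  ====================================================
``all``                   all 76 features
``all_noflair``           76 minus the FLAIR-derived ones (52)
``base8``                 the 19 base measures at 8 mm only
``base8_noflair``         base8 without FLAIR (13)
``reduced``               6 well-performing measures x 4 variants (24)
``reduced_noflair``       the 4 non-FLAIR of those x 4 variants (16)
========================  ====================================================

Before classification, features are standardized per subject (each column
by its own across-vertex mean/SD) and then per vertex (across the control
reference); for a control subject the vertex-wise reference excludes that
subject (leave-one-out), so specificity estimates are not
self-contaminated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from surfdetect.cohort import Cohort
from surfdetect.mesh import TemplateMesh, smooth_field

__all__ = [
    "VARIANTS",
    "REDUCED_MEASURES",
    "FeatureBank",
    "FeatureSubsetSpec",
    "augment_features",
    "define_subsets",
    "zscore_features",
]

VARIANTS = ["smooth8", "smooth32", "dog", "asym8"]

#: measures consistently informative in univariate analysis: thickness,
#: white/grey contrast, and T1/FLAIR intensity at -1 mm and mid-cortex
REDUCED_MEASURES = [
    "thickness", "wg_contrast", "t1_sub1mm", "t1_gm50",
    "flair_sub1mm", "flair_gm50",
]


@dataclass
class FeatureBank:
    """Per-subject vertices-x-features matrices plus shared provenance."""

    feature_names: list                 # length F, "<measure>.<variant>"
    provenance: dict                    # name -> (measure, variant)
    data: dict                          # subject_id -> (2V, F) array
    standardized: bool = False

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def matrix(self, subject_id: str, subset: "FeatureSubsetSpec | None" = None
               ) -> np.ndarray:
        x = self.data[subject_id]
        if subset is None:
            return x
        cols = [self.feature_names.index(n) for n in subset.members]
        return x[:, cols]


@dataclass
class FeatureSubsetSpec:
    name: str
    members: list

    def __len__(self) -> int:
        return len(self.members)


def augment_features(cohort: Cohort) -> FeatureBank:
    """Expand base measures into the smoothed/DoG/asymmetry variants.

    Asymmetry is computed on the raw measure (this-hemisphere value minus
    the mirror-corresponding contralateral value) and then smoothed at
    8 mm, matching the stated processing order. Deterministic and
    independent across subjects.
    """
    mesh = cohort.mesh
    measures = cohort.measure_names
    names = [f"{m}.{v}" for m in measures for v in VARIANTS]
    provenance = {f"{m}.{v}": (m, v) for m in measures for v in VARIANTS}
    contra = mesh.contralateral()
    data = {}
    for s in cohort.subjects:
        missing = [m for m in measures if m not in s.base_measures]
        if missing:
            raise ValueError(
                f"subject {s.subject_id} is missing base measures: {missing}"
            )
        raw = np.stack([s.base_measures[m] for m in measures], axis=1)
        s8 = smooth_field(mesh, raw, 8.0)
        s32 = smooth_field(mesh, raw, 32.0)
        asym = smooth_field(mesh, raw - raw[contra], 8.0)
        block = np.empty((mesh.n_vertices, len(names)))
        for j, _m in enumerate(measures):
            block[:, 4 * j + 0] = s8[:, j]
            block[:, 4 * j + 1] = s32[:, j]
            block[:, 4 * j + 2] = s8[:, j] - s32[:, j]
            block[:, 4 * j + 3] = asym[:, j]
        data[s.subject_id] = block
    return FeatureBank(feature_names=names, provenance=provenance, data=data)


def define_subsets(bank: FeatureBank) -> list[FeatureSubsetSpec]:
    """The six canonical feature subsets (with/without FLAIR each)."""
    def pick(measures=None, variants=None, flair=True):
        out = []
        for n in bank.feature_names:
            m, v = bank.provenance[n]
            if measures is not None and m not in measures:
                continue
            if variants is not None and v not in variants:
                continue
            if not flair and m.startswith("flair_"):
                continue
            out.append(n)
        return out

    reduced = [m for m in REDUCED_MEASURES
               if any(bank.provenance[n][0] == m for n in bank.feature_names)]
    return [
        FeatureSubsetSpec("all", pick()),
        FeatureSubsetSpec("all_noflair", pick(flair=False)),
        FeatureSubsetSpec("base8", pick(variants=["smooth8"])),
        FeatureSubsetSpec("base8_noflair", pick(variants=["smooth8"], flair=False)),
        FeatureSubsetSpec("reduced", pick(measures=reduced)),
        FeatureSubsetSpec("reduced_noflair", pick(measures=reduced, flair=False)),
    ]


def _stage1(x: np.ndarray) -> np.ndarray:
    """Per-subject z-scoring: each feature column over all vertices
    (both hemispheres pooled)."""
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    if np.any(sd == 0):
        bad = int(np.argmax(sd == 0))
        raise ValueError(f"zero within-subject SD for feature column {bad}")
    return (x - mu) / sd


@dataclass
class StandardizedFeatures:
    """Output of the two-stage z-scoring.

    ``evaluation[sid]`` is the (2V, F) matrix used when *scoring* subject
    ``sid``: for a control subject the vertex-wise reference excludes that
    subject (leave-one-out), for patients it is the full control set.
    ``training[sid]`` is the matrix contributed when ``sid`` appears in a
    *training* set; it always uses the full-control reference so that one
    pooled training matrix is shared across evaluated subjects.
    """

    feature_names: list
    provenance: dict
    evaluation: dict
    training: dict

    def matrix(self, subject_id: str, subset: FeatureSubsetSpec | None = None,
               role: str = "evaluation") -> np.ndarray:
        x = (self.evaluation if role == "evaluation" else self.training)[subject_id]
        if subset is None:
            return x
        cols = [self.feature_names.index(n) for n in subset.members]
        return x[:, cols]


def zscore_features(bank: FeatureBank, cohort: Cohort) -> StandardizedFeatures:
    """Two-stage standardization: subject first, then vertex.

    Stage 1 centres/scales each feature within each subject across
    vertices (both hemispheres pooled); stage 2 centres/scales each
    (vertex, feature) cell across the control reference. A control
    subject's own evaluation matrix is referenced to the *other* controls
    so its novelty scores are not self-contaminated; training matrices use
    the full-control reference.
    """
    controls = cohort.controls
    if len(controls) < 3:
        raise ValueError("need at least 3 control subjects for z-scoring")
    stage1 = {sid: _stage1(x) for sid, x in bank.data.items()}
    ctrl_ids = [s.subject_id for s in controls]
    stack = np.stack([stage1[c] for c in ctrl_ids])       # (n, 2V, F)
    n = stack.shape[0]
    tot = stack.sum(axis=0)
    tot2 = (stack**2).sum(axis=0)

    def standardize(x, m, v):
        sd = np.sqrt(np.clip(v, 0.0, None))
        sd[sd == 0] = 1.0  # degenerate cells carry no information
        return (x - m) / sd

    m_all = tot / n
    v_all = tot2 / n - m_all**2
    evaluation, training = {}, {}
    for s in cohort.subjects:
        sid = s.subject_id
        training[sid] = standardize(stage1[sid], m_all, v_all)
        if s.group == "control":
            i = ctrl_ids.index(sid)
            m = (tot - stack[i]) / (n - 1)
            v = (tot2 - stack[i] ** 2) / (n - 1) - m**2
            evaluation[sid] = standardize(stage1[sid], m, v)
        else:
            evaluation[sid] = training[sid]
    return StandardizedFeatures(
        feature_names=bank.feature_names,
        provenance=bank.provenance,
        evaluation=evaluation,
        training=training,
    )
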