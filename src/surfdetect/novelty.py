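"""Vertex-wise multivariate scoring: novelty detection and a supervised comparator.

Two unsupervised detectors are trained on control vertices only — the
robust Mahalanobis distance (minimum-covariance-determinant location and
scatter) and the isolation forest (t = 100 trees, subsampling size
psi = 2048) — plus a supervised random-forest comparator trained on
lesional vertices from the MRI-positive subjects against a 1:10 random
subsample of control vertices. Training follows a leave-one-out schedule:
a subject's own vertices never appear in the training set of the model
that scores it. Score maps are smoothed on the template at 4 mm FWHM to
suppress single-vertex false positives.

Score conventions: Mahalanobis distance is a nonnegative real, isolation
forest and random forest scores lie in [0, 1]; higher always means more
lesion-like/anomalous.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.covariance import MinCovDet
from sklearn.ensemble import IsolationForest, RandomForestClassifier

from surfdetect.cohort import Cohort
from surfdetect.features import FeatureSubsetSpec, StandardizedFeatures
from surfdetect.mesh import TemplateMesh, smooth_field

__all__ = [
    "NoveltyModel",
    "ScoreMap",
    "train_mahalanobis",
    "train_isolation_forest",
    "train_rfc",
    "score_subject",
    "training_schedule",
    "score_cohort",
]

#: default cap on pooled training rows; larger matrices are subsampled
#: with a seeded, logged draw
ROW_CAP = 2_000_000


@dataclass
class NoveltyModel:
    method: str                      # MAH | IF | RFC
    subset_name: str
    estimator: object
    feature_names: list
    manifest: dict = field(default_factory=dict)

    def score(self, x: np.ndarray) -> np.ndarray:
        if x.shape[1] != len(self.feature_names):
            raise ValueError(
                f"feature count mismatch: model expects {len(self.feature_names)}, "
                f"got {x.shape[1]}"
            )
        if self.method == "MAH":
            return np.sqrt(np.clip(self.estimator.mahalanobis(x), 0.0, None))
        if self.method == "IF":
            # sklearn's score_samples is the negative of the original
            # isolation-forest anomaly score 2^(-E[h]/c(psi)) in (0, 1]
            return -self.estimator.score_samples(x)
        if self.method == "RFC":
            return self.estimator.predict_proba(x)[:, 1]
        raise ValueError(f"unknown method {self.method}")


@dataclass
class ScoreMap:
    values: np.ndarray
    method: str
    subject_id: str
    subset_name: str = ""
    post_smoothed: bool = False


def _cap_rows(x: np.ndarray, cap: int, rng: np.random.Generator) -> np.ndarray:
    if len(x) <= cap:
        return x
    idx = rng.choice(len(x), size=cap, replace=False)
    warnings.warn(f"training matrix subsampled from {len(x)} to {cap} rows",
                  stacklevel=3)
    return x[idx]


def train_mahalanobis(
    x: np.ndarray,
    robust_fraction: float = 0.75,
    subset_name: str = "",
    feature_names: list | None = None,
    seed: int = 0,
    row_cap: int = ROW_CAP,
) -> NoveltyModel:
    """Robust Mahalanobis novelty model (MCD location/scatter)."""
    x = np.asarray(x, dtype=float)
    rng = np.random.default_rng(seed)
    x = _cap_rows(x, row_cap, rng)
    n, k = x.shape
    if n < 10 * k:
        raise ValueError(f"need >= {10 * k} training rows for {k} features, got {n}")
    est = MinCovDet(support_fraction=robust_fraction,
                    random_state=int(rng.integers(2**31)))
    est.fit(x)
    if np.linalg.matrix_rank(est.covariance_) < k:
        raise ValueError(
            "singular robust scatter matrix; reduce the feature subset"
        )
    feature_names = feature_names or [f"f{i}" for i in range(k)]
    return NoveltyModel("MAH", subset_name, est, feature_names,
                        manifest={"robust_fraction": robust_fraction,
                                  "n_rows": n, "seed": seed})


def train_isolation_forest(
    x: np.ndarray,
    t: int = 100,
    psi: int = 2048,
    seed: int = 0,
    subset_name: str = "",
    feature_names: list | None = None,
    row_cap: int = ROW_CAP,
) -> NoveltyModel:
    """Isolation forest with the standard path-length-normalized score."""
    x = np.asarray(x, dtype=float)
    rng = np.random.default_rng(seed)
    x = _cap_rows(x, row_cap, rng)
    if len(x) < psi:
        warnings.warn(f"psi lowered from {psi} to {len(x)} (training set size)",
                      stacklevel=2)
        psi = len(x)
    est = IsolationForest(n_estimators=t, max_samples=psi,
                          random_state=int(rng.integers(2**31)))
    est.fit(x)
    feature_names = feature_names or [f"f{i}" for i in range(x.shape[1])]
    return NoveltyModel("IF", subset_name, est, feature_names,
                        manifest={"t": t, "psi": psi, "n_rows": len(x),
                                  "seed": seed})


def train_rfc(
    control_x: np.ndarray,
    lesional_x: np.ndarray,
    seed: int = 0,
    subset_name: str = "",
    feature_names: list | None = None,
    row_cap: int = ROW_CAP,
) -> NoveltyModel:
    """Supervised random-forest comparator.

    Hyperparameters: 100 trees, sqrt(k) variables per split, splits down
    to single-observation leaves, Gini criterion. Control vertices are
    randomly subsampled to a 1:10 lesional:control ratio.
    """
    lesional_x = np.asarray(lesional_x, dtype=float)
    if len(lesional_x) == 0:
        raise ValueError("no lesional vertices available for RFC training")
    control_x = np.asarray(control_x, dtype=float)
    rng = np.random.default_rng(seed)
    lesional_x = _cap_rows(lesional_x, row_cap, rng)
    n_ctrl = min(10 * len(lesional_x), len(control_x))
    idx = rng.choice(len(control_x), size=n_ctrl, replace=False)
    x = np.vstack([control_x[idx], lesional_x])
    y = np.concatenate([np.zeros(n_ctrl, dtype=int),
                        np.ones(len(lesional_x), dtype=int)])
    est = RandomForestClassifier(
        n_estimators=100, max_features="sqrt", min_samples_leaf=1,
        criterion="gini", random_state=int(rng.integers(2**31)),
    )
    est.fit(x, y)
    feature_names = feature_names or [f"f{i}" for i in range(x.shape[1])]
    return NoveltyModel("RFC", subset_name, est, feature_names,
                        manifest={"n_lesional": len(lesional_x),
                                  "n_control": n_ctrl,
                                  "ratio": f"1:{n_ctrl / max(len(lesional_x), 1):.0f}",
                                  "seed": seed})


def score_subject(
    model: NoveltyModel, subject_matrix: np.ndarray, mesh: TemplateMesh,
    subject_id: str = "", post_fwhm_mm: float = 4.0
) -> ScoreMap:
    """Vertex-wise scores for one subject, post-smoothed on the template.

    Smoothing is a convex averaging, so isolation-forest and
    random-forest scores stay in [0, 1] and Mahalanobis maps stay
    nonnegative.
    """
    raw = model.score(np.asarray(subject_matrix, dtype=float))
    vals = smooth_field(mesh, raw, post_fwhm_mm) if post_fwhm_mm > 0 else raw
    return ScoreMap(values=vals, method=model.method, subject_id=subject_id,
                    subset_name=model.subset_name, post_smoothed=post_fwhm_mm > 0)


def training_schedule(cohort: Cohort, method: str) -> dict:
    """Per-evaluated-subject training manifests (leave-one-out contract).

    MAH/IF train on control subjects only; RFC additionally uses the
    strict lesion labels of the MRI-positive subjects as lesional vertex
    sources. The evaluated subject never contributes training vertices.
    """
    ctrl_ids = [s.subject_id for s in cohort.controls]
    pos_ids = [s.subject_id for s in cohort.by_group("mri_positive")]
    out = {}
    for s in cohort.subjects:
        sid = s.subject_id
        manifest = {"controls": [c for c in ctrl_ids if c != sid]}
        if method == "RFC":
            manifest["lesional"] = [p for p in pos_ids if p != sid]
        out[sid] = manifest
    return out


def _lesional_rows(cohort: Cohort, std: StandardizedFeatures,
                   subset: FeatureSubsetSpec, subject_ids: list) -> np.ndarray:
    rows = []
    for sid in subject_ids:
        subj = cohort.subject(sid)
        mat = std.matrix(sid, subset, role="training")
        for lab in subj.lesion_labels:  # strict labels feed RFC training
            rows.append(mat[lab.vertex_ids])
    if not rows:
        return np.empty((0, len(subset.members)))
    return np.vstack(rows)


def score_cohort(
    cohort: Cohort,
    std: StandardizedFeatures,
    subset: FeatureSubsetSpec,
    method: str,
    seed: int = 0,
    post_fwhm_mm: float = 4.0,
    row_cap: int = ROW_CAP,
) -> dict:
    """Score every cohort subject under the leave-one-out schedule.

    Fits one shared model for all patients (their vertices are never in
    the control pool) and one leave-one-out model per control subject.
    Returns ``subject_id -> ScoreMap``.
    """
    if method not in ("MAH", "IF", "RFC"):
        raise ValueError(f"unknown method {method}")
    mesh = cohort.mesh
    schedule = training_schedule(cohort, method)
    ctrl_mats = {c.subject_id: std.matrix(c.subject_id, subset, role="training")
                 for c in cohort.controls}
    ss = np.random.SeedSequence(seed)
    seeds = iter(s.generate_state(1)[0] % 2**31 for s in ss.spawn(len(cohort.subjects) + 1))

    def fit(manifest, fit_seed):
        ctrl_x = np.vstack([ctrl_mats[c] for c in manifest["controls"]])
        if method == "MAH":
            return train_mahalanobis(ctrl_x, subset_name=subset.name,
                                     feature_names=subset.members,
                                     seed=fit_seed, row_cap=row_cap)
        if method == "IF":
            return train_isolation_forest(ctrl_x, subset_name=subset.name,
                                          feature_names=subset.members,
                                          seed=fit_seed, row_cap=row_cap)
        les_x = _lesional_rows(cohort, std, subset, manifest["lesional"])
        return train_rfc(ctrl_x, les_x, subset_name=subset.name,
                         feature_names=subset.members, seed=fit_seed,
                         row_cap=row_cap)

    # patients share one model: full control pool (+ all lesional for RFC)
    patient_manifest = {"controls": [c.subject_id for c in cohort.controls],
                        "lesional": [p.subject_id
                                     for p in cohort.by_group("mri_positive")]}
    out = {}
    shared = None
    shared_nonloo = None  # for RFC, MRI-positive subjects still need LOO fits
    for s in cohort.subjects:
        sid = s.subject_id
        fit_seed = int(next(seeds))
        if s.group == "control" or (method == "RFC" and s.group == "mri_positive"):
            model = fit(schedule[sid], fit_seed)
        else:
            if shared is None:
                shared = fit(patient_manifest, fit_seed)
            model = shared
        model.manifest["evaluated"] = sid
        out[sid] = score_subject(model, std.matrix(sid, subset), mesh,
                                 subject_id=sid, post_fwhm_mm=post_fwhm_mm)
    return out
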