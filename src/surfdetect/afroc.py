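"""AFROC (alternative free-response ROC) evaluation of score maps.

Score or z maps are thresholded over a grid, suprathreshold vertices are
clustered into edge-connected components, and each cluster is reduced to
a single mark at its centroid. A ground-truth label counts as detected at
a threshold if at least one mark centroid of its subject lies inside it —
a deliberately stringent criterion that reduces clusters to points and
thereby makes the random-guessing null process simulable. False positives
are tallied in control subjects only (patients may harbour unknown
additional lesions).

Per threshold the cohort yields an operating point:

* TPF — detected labels / total labels,
* FPF — controls with any false-positive cluster / total controls,
* FPR — mean false-positive cluster count per control.

The AFROC curve plots TPF against FPF from the strictest to the loosest
threshold; its area (AUC, in [0, 1]) is the summary statistic. The curve
is closed by prepending (0, 0) and extending horizontally to FPF = 1,
consistent with the closed-form guessing-null AUC phi / (phi + 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from surfdetect.mesh import (
    SurfaceLabel,
    TemplateMesh,
    cluster_centroid,
    connected_components,
)

__all__ = [
    "DetectionMark",
    "OperatingPoint",
    "AFROCCurve",
    "threshold_grid",
    "extract_marks",
    "rate_marks",
    "afroc_curve",
    "per_lesion_detection_fpf",
    "trapezoid_auc",
]


@dataclass
class DetectionMark:
    subject_id: str
    centroid: int
    vertices: np.ndarray
    threshold: float


@dataclass
class OperatingPoint:
    threshold: float
    tpf: float
    fpf: float
    fpr: float


@dataclass
class AFROCCurve:
    points: list                      # strict -> loose
    auc: float
    n_labels: int
    n_controls: int
    label_phis: list = field(default_factory=list)

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        fpf = np.array([p.fpf for p in self.points])
        tpf = np.array([p.tpf for p in self.points])
        return fpf, tpf

    def to_frame(self):
        """Operating points as a DataFrame (threshold, TPF, FPF, FPR)."""
        import pandas as pd

        return pd.DataFrame(
            [{"threshold": p.threshold, "tpf": p.tpf, "fpf": p.fpf,
              "fpr": p.fpr} for p in self.points])


def _stat(values: np.ndarray, two_tailed: bool) -> np.ndarray:
    return np.abs(values) if two_tailed else np.asarray(values)


def threshold_grid(
    maps: dict, n_thresholds: int = 512, two_tailed: bool = False
) -> np.ndarray:
    """Pooled empirical quantiles of the thresholding statistic.

    Half of the grid samples the bulk uniformly in quantile space; the
    other half is packed geometrically into the upper tail down to the
    pooled maximum. The strict operating region — where per-subject
    maxima cross the threshold and FPF moves from 0 to 1 — lives in that
    extreme tail, so uniform quantile spacing alone would leave the
    informative part of the AFROC curve bridged by a single long
    trapezoid segment.

    Returns thresholds sorted from strict (high) to loose (low); each
    value is an actual pooled map value (nearest-quantile), so the sweep
    realises attainable operating points only.
    """
    if not maps:
        raise ValueError("no maps supplied")
    pooled = np.concatenate([_stat(m, two_tailed).ravel() for m in maps.values()])
    if np.ptp(pooled) == 0:
        raise ValueError("all maps are constant; no threshold sweep possible")
    if n_thresholds == 1:
        qs = np.array([0.5])
    else:
        n_tail = n_thresholds // 2
        n_bulk = n_thresholds - n_tail
        bulk = np.linspace(0.0, 0.5, n_bulk, endpoint=False)[1:]
        p_min = 1.0 / pooled.size  # tail mass of the single largest value
        tail = 1.0 - np.geomspace(0.5, p_min, n_tail)
        qs = np.concatenate([bulk, tail])
    grid = np.quantile(pooled, qs, method="nearest")
    return np.unique(grid)[::-1]


def extract_marks(
    values: np.ndarray,
    mesh: TemplateMesh,
    threshold: float,
    two_tailed: bool = False,
    subject_id: str = "",
) -> list[DetectionMark]:
    """Threshold, cluster, and reduce each cluster to its centroid mark."""
    stat = _stat(values, two_tailed)
    mask = stat >= threshold
    return [
        DetectionMark(
            subject_id=subject_id,
            centroid=cluster_centroid(mesh, comp),
            vertices=comp,
            threshold=float(threshold),
        )
        for comp in connected_components(mesh, mask)
    ]


def rate_marks(
    marks_by_subject: dict,
    labels_by_subject: dict,
    control_ids: list,
    n_vertices: int,
    label_masks: dict | None = None,
) -> tuple[int, int, int]:
    """Count detected labels, flagged controls and false-positive clusters.

    A label is detected if any mark centroid of its own subject lies in
    it; false positives count in controls only.
    """
    detected = 0
    for sid, labels in labels_by_subject.items():
        marks = marks_by_subject.get(sid, [])
        cents = np.array([m.centroid for m in marks], dtype=np.intp)
        for li, lab in enumerate(labels):
            if label_masks is not None:
                mask = label_masks[(sid, li)]
            else:
                mask = lab.mask(n_vertices)
            if cents.size and mask[cents].any():
                detected += 1
    flagged = 0
    fp_clusters = 0
    for cid in control_ids:
        k = len(marks_by_subject.get(cid, []))
        fp_clusters += k
        flagged += int(k > 0)
    return detected, flagged, fp_clusters


def trapezoid_auc(fpf: np.ndarray, tpf: np.ndarray) -> float:
    """Area under TPF(FPF) with the curve closure applied.

    Points must run strict -> loose (FPF non-decreasing). The curve is
    closed by prepending (0, 0) and extending horizontally at the final
    TPF to FPF = 1; the area is the trapezoid integral over FPF in [0, 1].
    """
    fpf = np.concatenate([[0.0], np.asarray(fpf, dtype=float), [1.0]])
    tpf = np.concatenate([[0.0], np.asarray(tpf, dtype=float),
                          [np.asarray(tpf)[-1] if len(tpf) else 0.0]])
    if np.any(np.diff(fpf) < -1e-12):
        raise ValueError("FPF must be non-decreasing along the sweep")
    return float(np.trapezoid(tpf, fpf))


def _sweep(maps, mesh, labels_by_subject, control_ids, thresholds, two_tailed):
    n_labels = sum(len(v) for v in labels_by_subject.values())
    n_controls = len(control_ids)
    label_masks = {
        (sid, li): lab.mask(mesh.n_vertices)
        for sid, labs in labels_by_subject.items() for li, lab in enumerate(labs)
    }
    points = []
    for tau in thresholds:  # strict -> loose
        marks = {
            sid: extract_marks(vals, mesh, tau, two_tailed, sid)
            for sid, vals in maps.items()
        }
        det, flagged, fp = rate_marks(marks, labels_by_subject, control_ids,
                                      mesh.n_vertices, label_masks)
        points.append(OperatingPoint(
            threshold=float(tau),
            tpf=det / n_labels if n_labels else 0.0,
            fpf=flagged / n_controls if n_controls else 0.0,
            fpr=fp / n_controls if n_controls else 0.0,
        ))
    return points, n_labels, n_controls


def afroc_curve(
    maps: dict,
    mesh: TemplateMesh,
    labels_by_subject: dict,
    control_ids: list,
    thresholds: np.ndarray,
    two_tailed: bool = False,
) -> AFROCCurve:
    """AFROC curve and AUC for a cohort of score maps.

    ``maps`` maps subject_id to per-vertex values (all patients and
    controls); ``labels_by_subject`` maps each patient to its list of
    evaluation labels (wide lesion labels or hypothesis labels).
    """
    n_labels = sum(len(v) for v in labels_by_subject.values())
    if n_labels == 0 or not control_ids:
        raise ValueError("need at least one label and one control subject")
    points, n_labels, n_controls = _sweep(
        maps, mesh, labels_by_subject, control_ids, thresholds, two_tailed)
    fpf = np.array([p.fpf for p in points])
    tpf = np.array([p.tpf for p in points])
    order = np.argsort(fpf, kind="stable")  # guard: sweep should be monotone
    auc = trapezoid_auc(fpf[order], tpf[order])
    phis = [lab.phi for labs in labels_by_subject.values() for lab in labs]
    return AFROCCurve(points=points, auc=auc, n_labels=n_labels,
                      n_controls=n_controls, label_phis=phis)


def per_lesion_detection_fpf(
    maps: dict,
    mesh: TemplateMesh,
    label: SurfaceLabel,
    subject_id: str,
    control_ids: list,
    thresholds: np.ndarray,
    two_tailed: bool = False,
) -> tuple[float, bool]:
    """Cohort FPF at the strictest threshold that detects one label.

    Returns ``(fpf_detection, detected)``; a never-detected label returns
    FPF 1 with ``detected=False`` by convention.
    """
    if len(label) == 0:
        raise ValueError("label must be non-empty")
    mask = label.mask(mesh.n_vertices)
    for tau in thresholds:  # strict -> loose
        marks = extract_marks(maps[subject_id], mesh, tau, two_tailed, subject_id)
        cents = np.array([m.centroid for m in marks], dtype=np.intp)
        if cents.size and mask[cents].any():
            flagged = sum(
                int(len(extract_marks(maps[c], mesh, tau, two_tailed, c)) > 0)
                for c in control_ids
            )
            return flagged / len(control_ids), True
    return 1.0, False
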