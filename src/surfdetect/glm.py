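"""Vertex-wise single-subject-vs-controls GLM z-maps.

For each base measure (at 8 mm smoothing) an ordinary-least-squares model
with nuisance covariates (age, sex, scanner site, and — for area, volume
and thickness — an intracranial-volume analog) is fitted over the control
group, and the evaluated subject is expressed as a prediction residual::

    z = (y0 - x0' beta) / (s * sqrt(1 + x0' (X'X)^-1 x0))

with ``s`` the residual SD on ``n - p`` degrees of freedom. The variance
inflation term accounts for the uncertainty of the prediction at the
subject's covariates, which makes leave-one-out control z-maps
t-distributed (treated as standard normal at the cohort sizes used; the
difference is negligible above ~30 controls). Controls are evaluated
against all remaining controls (leave-one-out); z > 0 means the measure
lies above the covariate-adjusted control expectation, and maps are used
two-tailed downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from surfdetect.cohort import Cohort, SubjectRecord
from surfdetect.mesh import TemplateMesh, smooth_field

__all__ = ["GLMDesign", "ZMap", "subject_zmap", "cohort_zmaps", "zmap_summary"]

#: measures whose design includes the intracranial-volume analog
ICV_MEASURES = ("area", "volume", "thickness")


@dataclass
class GLMDesign:
    """Covariate layout for the nuisance GLM."""

    covariates: tuple = ("age", "sex", "site", "icv_analog")
    use_icv: tuple = ICV_MEASURES

    def row(self, subject: SubjectRecord, measure: str) -> np.ndarray:
        names = self.names(measure)
        return np.array([1.0] + [subject.covariates[c] for c in names])

    def names(self, measure: str) -> list:
        out = [c for c in self.covariates if c != "icv_analog"]
        if measure in self.use_icv:
            out.append("icv_analog")
        return out


@dataclass
class ZMap:
    values: np.ndarray
    measure: str
    subject_id: str
    two_tailed: bool = True


def _fit_controls(X: np.ndarray, Y: np.ndarray):
    """OLS of Y (n x V) on X (n x p); returns beta, residual SD, XtX^-1."""
    n, p = X.shape
    if n < p + 2:
        raise ValueError(f"need at least {p + 2} controls for a rank-{p} design")
    xtx = X.T @ X
    if np.linalg.matrix_rank(xtx) < p:
        raise ValueError("rank-deficient GLM design on the control set")
    xtx_inv = np.linalg.inv(xtx)
    beta = xtx_inv @ (X.T @ Y)
    resid = Y - X @ beta
    s2 = (resid**2).sum(axis=0) / (n - p)
    return beta, np.sqrt(s2), xtx_inv


def subject_zmap(
    subject: SubjectRecord,
    controls: list,
    measure: str,
    design: GLMDesign,
    mesh: TemplateMesh,
    smoothed: dict | None = None,
) -> ZMap:
    """Two-tailed-usable signed z-map of one subject against controls.

    ``smoothed`` optionally maps subject_id to a pre-smoothed (8 mm)
    measure map to avoid recomputation; otherwise maps are smoothed here.
    The evaluated subject must not be in ``controls``.
    """
    if any(c.subject_id == subject.subject_id for c in controls):
        raise ValueError("evaluated subject must be excluded from its reference set")

    def get_map(s: SubjectRecord) -> np.ndarray:
        if smoothed is not None and s.subject_id in smoothed:
            return smoothed[s.subject_id]
        return smooth_field(mesh, s.base_measures[measure], 8.0)

    X = np.stack([design.row(c, measure) for c in controls])
    Y = np.stack([get_map(c) for c in controls])
    beta, s, xtx_inv = _fit_controls(X, Y)
    x0 = design.row(subject, measure)
    infl = float(np.sqrt(1.0 + x0 @ xtx_inv @ x0))
    num = get_map(subject) - x0 @ beta
    z = np.zeros_like(num)
    ok = s > 0
    if not np.all(ok):
        import warnings

        warnings.warn(
            f"{(~ok).sum()} vertices with zero residual SD; z set to 0 there",
            stacklevel=2,
        )
    z[ok] = num[ok] / (s[ok] * infl)
    return ZMap(values=z, measure=measure, subject_id=subject.subject_id)


def cohort_zmaps(
    cohort: Cohort, measure: str, design: GLMDesign | None = None
) -> dict:
    """Z-maps for every cohort subject (leave-one-out for controls).

    Smooths each subject's measure once and reuses it across the
    leave-one-out fits. Returns ``subject_id -> ZMap``.
    """
    design = design or GLMDesign()
    mesh = cohort.mesh
    controls = cohort.controls
    smoothed = {
        s.subject_id: smooth_field(mesh, s.base_measures[measure], 8.0)
        for s in cohort.subjects
    }
    out = {}
    for s in cohort.subjects:
        ref = [c for c in controls if c.subject_id != s.subject_id]
        out[s.subject_id] = subject_zmap(s, ref, measure, design, mesh, smoothed)
    return out


def zmap_summary(zmaps: dict):
    """Per-subject extreme-value summary of a set of z-maps (a DataFrame
    with min, max, max |z| and the vertex attaining it)."""
    import pandas as pd

    rows = []
    for sid, zm in zmaps.items():
        v = zm.values
        peak = int(np.argmax(np.abs(v)))
        rows.append({"subject_id": sid, "measure": zm.measure,
                     "z_min": float(v.min()), "z_max": float(v.max()),
                     "abs_z_max": float(np.abs(v[peak])),
                     "peak_vertex": peak})
    return pd.DataFrame(rows)
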