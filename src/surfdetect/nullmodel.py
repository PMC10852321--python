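"""Random-guessing null model for AFROC lesion-detection significance.

The null hypothesis for a free-response lesion detector is a guessing
process that places marks uniformly at random on the cortical surface
(equal probability per vertex). For very large cohorts its AFROC curve
has the closed form::

    TPF = 1 - (1 - FPF)**phi        AUC = phi / (phi + 1)

where ``phi`` is the ground-truth label area over the total surface area
(phi = 1 recovers classical ROC guessing: TPF = FPF, AUC = 0.5; as
phi -> 0 the guessing AUC vanishes). For a finite cohort the AUC under
guessing is a distribution that broadens as the cohort shrinks; it is
obtained here by Monte-Carlo simulation, and observed AUCs are converted
to one-sided Monte-Carlo p-values p = (b + 1) / (m + 1) with ties counted
conservatively.

Marks accumulate across the threshold sweep by monotone coupling: each
subject receives N ~ Poisson(lambda_max) marks with independent
activation levels u ~ U(0, 1), and the operating point at leniency
``l`` uses the marks with u <= l — a uniform marking process of rate
``l * lambda_max`` whose expected curve is exactly the closed form above.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from surfdetect.afroc import trapezoid_auc
from surfdetect.mesh import SurfaceLabel, TemplateMesh, grow_geodesic_label

__all__ = [
    "GuessingModel",
    "NullDistribution",
    "closed_form_tpf",
    "closed_form_auc",
    "simulate_guessing_run",
    "null_auc_distribution",
    "mc_p_value",
    "bonferroni_adjust",
    "per_lesion_null_probability",
    "make_phi_labels",
]


def _check_unit(value, name: str) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError(f"{name} must lie in [0, 1]")
    return arr


def closed_form_tpf(fpf, phi):
    """Large-cohort guessing-null TPF at a given FPF: 1 - (1 - FPF)^phi."""
    fpf = _check_unit(fpf, "fpf")
    phi = _check_unit(phi, "phi")
    out = 1.0 - (1.0 - fpf) ** phi
    return float(out) if np.ndim(out) == 0 else out


def closed_form_auc(phi):
    """Large-cohort guessing-null AFROC AUC: phi / (phi + 1)."""
    phi = _check_unit(phi, "phi")
    out = phi / (phi + 1.0)
    return float(out) if np.ndim(out) == 0 else out


@dataclass
class GuessingModel:
    """Closed-form guessing AFROC curve for one relative label size."""

    phi: float

    def __post_init__(self) -> None:
        if not 0 < self.phi <= 1:
            raise ValueError("phi must lie in (0, 1]")

    def tpf(self, fpf):
        return closed_form_tpf(fpf, self.phi)

    @property
    def auc(self) -> float:
        return closed_form_auc(self.phi)


@dataclass
class NullDistribution:
    auc_samples: np.ndarray
    n_labels: int
    n_controls: int
    label_phis: list
    seed: int
    manifest: dict = field(default_factory=dict)

    @property
    def m(self) -> int:
        return len(self.auc_samples)


def _min_u_per_segment(u: np.ndarray, counts: np.ndarray) -> np.ndarray:
    """Minimum of consecutive segments of ``u`` (inf for empty segments)."""
    out = np.full(len(counts), np.inf)
    if u.size == 0:
        return out
    offsets = np.concatenate([[0], np.cumsum(counts)[:-1]])
    nonzero = counts > 0
    mins = np.minimum.reduceat(u, offsets[nonzero])
    out[nonzero] = mins
    return out


def simulate_guessing_run(
    mesh: TemplateMesh,
    labels_by_subject: dict,
    n_controls: int,
    lambda_max: float = 20.0,
    n_levels: int = 256,
    rng: np.random.Generator | None = None,
    _label_masks: dict | None = None,
) -> float:
    """One AFROC AUC sample of the finite-cohort guessing process.

    Every subject (patients and controls) receives ``N ~
    Poisson(lambda_max)`` marks at uniformly random vertices with
    activation levels ``u ~ U(0, 1)``; a label is detected at leniency
    ``l`` if any of its subject's marks with ``u <= l`` falls inside it,
    and a control is flagged if it has any active mark. TPF/FPF follow
    the cohort definitions and the AUC uses the same curve closure as the
    real evaluation.
    """
    if not labels_by_subject or n_controls < 1:
        raise ValueError("need at least one labelled subject and one control")
    rng = np.random.default_rng() if rng is None else rng
    V = mesh.n_vertices
    if _label_masks is None:
        _label_masks = {
            (sid, li): lab.mask(V)
            for sid, labs in labels_by_subject.items()
            for li, lab in enumerate(labs)
        }
    u_det = []
    for sid, labs in labels_by_subject.items():
        n = int(rng.poisson(lambda_max))
        verts = rng.integers(0, V, size=n)
        u = rng.random(n)
        for li in range(len(labs)):
            inside = _label_masks[(sid, li)][verts]
            u_det.append(u[inside].min() if inside.any() else np.inf)
    n_marks = rng.poisson(lambda_max, size=n_controls)
    u_all = rng.random(int(n_marks.sum()))
    u_flag = _min_u_per_segment(u_all, n_marks)

    u_det = np.sort(np.asarray(u_det))
    u_flag = np.sort(u_flag)
    levels = _fpf_uniform_levels(n_levels, lambda_max)
    tpf = np.searchsorted(u_det, levels, side="right") / len(u_det)
    fpf = np.searchsorted(u_flag, levels, side="right") / n_controls
    return trapezoid_auc(fpf, tpf)


def _fpf_uniform_levels(n_levels: int, lambda_max: float) -> np.ndarray:
    """Activation levels spaced so expected FPF is sampled uniformly.

    The expected FPF at level ``l`` is ``1 - exp(-lambda_max * l)``, which
    saturates quickly; uniform levels would waste most of the sweep on
    FPF ~ 1 and leave the strict region coarsely resolved.
    """
    f = np.linspace(0.0, 1.0 - np.exp(-lambda_max), n_levels)
    with np.errstate(divide="ignore"):
        levels = -np.log1p(-f) / lambda_max
    levels[-1] = 1.0
    return levels


def null_auc_distribution(
    mesh: TemplateMesh,
    labels_by_subject: dict,
    n_controls: int,
    m: int,
    seed: int = 0,
    lambda_max: float = 20.0,
    n_levels: int = 256,
) -> NullDistribution:
    """m independent guessing-run AUC samples, reproducible for a seed."""
    if m < 1:
        raise ValueError("m must be >= 1")
    rng = np.random.default_rng(seed)
    masks = {
        (sid, li): lab.mask(mesh.n_vertices)
        for sid, labs in labels_by_subject.items()
        for li, lab in enumerate(labs)
    }
    samples = np.array([
        simulate_guessing_run(mesh, labels_by_subject, n_controls,
                              lambda_max, n_levels, rng, _label_masks=masks)
        for _ in range(m)
    ])
    phis = [lab.phi for labs in labels_by_subject.values() for lab in labs]
    return NullDistribution(
        auc_samples=samples,
        n_labels=len(phis),
        n_controls=n_controls,
        label_phis=phis,
        seed=seed,
        manifest={"lambda_max": lambda_max, "n_levels": n_levels, "m": m},
    )


def mc_p_value(observed_auc: float, null: NullDistribution) -> float:
    """One-sided Monte-Carlo p-value p = (b + 1) / (m + 1).

    ``b`` counts null samples greater than *or equal to* the observed AUC
    (conservative tie handling); with m = 1e5 runs the attainable floor
    is ~1e-5.
    """
    if null.m < 1:
        raise ValueError("empty null distribution")
    b = int(np.sum(null.auc_samples >= observed_auc))
    return (b + 1) / (null.m + 1)


def bonferroni_adjust(p_values, k: int | None = None):
    """Family-wise error control: p -> min(1, k * p)."""
    p = np.asarray(p_values, dtype=float)
    if k is None:
        k = p.size
    if k < p.size:
        raise ValueError("family size k must be >= number of p-values")
    return np.minimum(1.0, k * p)


def per_lesion_null_probability(fpf_detection, phi):
    """Chance probability that a label of relative size phi is detected
    at the threshold where FPF equals fpf_detection: 1 - (1 - FPF)^phi.

    Small values mean the lesion was found at a stricter threshold than
    guessing would achieve; interpretable as a per-lesion p-value.
    """
    return closed_form_tpf(fpf_detection, phi)


def make_phi_labels(
    mesh: TemplateMesh,
    phis,
    seed: int = 0,
    kind: str = "lesion-wide",
) -> dict:
    """Geodesic-disk labels with given relative sizes, one subject each.

    Convenience for building guessing-null cohorts with prescribed phi
    statistics. Returns ``{"les000": [label], ...}``; a phi of 1 yields a
    label covering the whole surface.
    """
    rng = np.random.default_rng(seed)
    out = {}
    for i, phi in enumerate(phis):
        if not 0 < phi <= 1:
            raise ValueError("phi targets must lie in (0, 1]")
        sid = f"les{i:03d}"
        if phi >= 1.0:
            lab = SurfaceLabel(vertex_ids=np.arange(mesh.n_vertices),
                               kind=kind, phi=1.0)
        else:
            seed_v = int(rng.integers(0, mesh.n_vertices))
            lab = grow_geodesic_label(mesh, seed_v, target_phi=phi, kind=kind)
        lab.subject_id = sid
        out[sid] = [lab]
    return out
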