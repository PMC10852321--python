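"""Import/export of templates, labels, per-vertex maps and cohorts.

Formats: PLY for the template mesh (via trimesh), plain-text vertex-index
files for surface labels (one index per line, ``#``-prefixed header with
kind and phi), GIFTI for per-vertex overlays (via nibabel), and a
directory layout for cohorts (per-subject GIFTI maps plus a CSV covariate
manifest and a JSON generation config).
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import trimesh

from surfdetect.cohort import Cohort, SubjectRecord
from surfdetect.mesh import SurfaceLabel, TemplateMesh, _adjacency, _vertex_areas

__all__ = [
    "save_mesh_ply", "load_mesh_ply",
    "save_label", "load_label",
    "save_map_gifti", "load_map_gifti",
    "save_cohort", "load_cohort",
]


def save_mesh_ply(mesh: TemplateMesh, path) -> None:
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    tm.export(str(path))


def load_mesh_ply(path, radius_mm: float = 0.0,
                  subdivision_level: int = 0) -> TemplateMesh:
    """Rebuild a TemplateMesh from PLY; the first half of the vertices is
    taken as the left hemisphere (the layout this package writes)."""
    tm = trimesh.load(str(path), process=False)
    v = np.asarray(tm.vertices, dtype=float)
    f = np.asarray(tm.faces, dtype=np.intp)
    n = len(v) // 2
    hemi = np.concatenate([np.zeros(n, dtype=np.int8), np.ones(len(v) - n, dtype=np.int8)])
    return TemplateMesh(
        vertices=v, faces=f, hemisphere=hemi,
        vertex_area=_vertex_areas(v, f),
        adjacency=_adjacency(len(v), f),
        radius_mm=radius_mm, subdivision_level=subdivision_level,
    )


def save_label(label: SurfaceLabel, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# kind: {label.kind}\n# phi: {label.phi:.8g}\n")
        if label.subject_id:
            fh.write(f"# subject: {label.subject_id}\n")
        for i in label.vertex_ids:
            fh.write(f"{int(i)}\n")


def load_label(path) -> SurfaceLabel:
    kind, phi, subject = "lesion-strict", 0.0, None
    ids = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("#"):
                key, _, val = line[1:].partition(":")
                key = key.strip()
                if key == "kind":
                    kind = val.strip()
                elif key == "phi":
                    phi = float(val)
                elif key == "subject":
                    subject = val.strip()
            elif line:
                ids.append(int(line))
    return SurfaceLabel(vertex_ids=np.array(ids, dtype=np.intp), kind=kind,
                        phi=phi, subject_id=subject)


def save_map_gifti(values: np.ndarray, path) -> None:
    arr = nib.gifti.GiftiDataArray(np.asarray(values, dtype=np.float32),
                                   intent="NIFTI_INTENT_NONE")
    nib.save(nib.gifti.GiftiImage(darrays=[arr]), str(path))


def load_map_gifti(path) -> np.ndarray:
    img = nib.load(str(path))
    return np.asarray(img.darrays[0].data, dtype=float)


def save_cohort(cohort: Cohort, directory, config_dict: dict | None = None) -> None:
    root = Path(directory)
    root.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in cohort.subjects:
        sdir = root / s.subject_id
        sdir.mkdir(exist_ok=True)
        for m in cohort.measure_names:
            save_map_gifti(s.base_measures[m], sdir / f"{m}.shape.gii")
        for i, lab in enumerate(s.lesion_labels):
            save_label(lab, sdir / f"lesion{i}.label.txt")
        if s.hypothesis_label is not None:
            save_label(s.hypothesis_label, sdir / "hypothesis.label.txt")
        rows.append({"subject_id": s.subject_id, "group": s.group,
                     **s.covariates,
                     "n_lesions": len(s.lesion_labels)})
    pd.DataFrame(rows).to_csv(root / "manifest.csv", index=False)
    meta = {"measure_names": cohort.measure_names}
    if config_dict:
        meta["config"] = config_dict
    (root / "cohort.json").write_text(json.dumps(meta, indent=2))


def load_cohort(directory, mesh: TemplateMesh) -> Cohort:
    root = Path(directory)
    meta = json.loads((root / "cohort.json").read_text())
    manifest = pd.read_csv(root / "manifest.csv")
    covariate_cols = [c for c in manifest.columns
                      if c not in ("subject_id", "group", "n_lesions")]
    subjects = []
    for _, row in manifest.iterrows():
        sid = row["subject_id"]
        sdir = root / sid
        measures = {m: load_map_gifti(sdir / f"{m}.shape.gii")
                    for m in meta["measure_names"]}
        lesions = sorted(sdir.glob("lesion*.label.txt"))
        hyp = sdir / "hypothesis.label.txt"
        subjects.append(SubjectRecord(
            subject_id=sid, group=row["group"],
            covariates={c: float(row[c]) for c in covariate_cols},
            base_measures=measures,
            lesion_labels=[load_label(p) for p in lesions],
            hypothesis_label=load_label(hyp) if hyp.exists() else None,
        ))
    return Cohort(mesh=mesh, subjects=subjects,
                  measure_names=meta["measure_names"])
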