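"""End-to-end experiment orchestration and report generation.

``run_experiment`` ties the pipeline together: generate a synthetic
cohort, build and standardize the feature bank, run the requested
detectors (per-measure univariate GLM; Mahalanobis, isolation-forest and
random-forest classifiers on named feature subsets), evaluate every
detector's maps with AFROC methodology against two evaluation cohorts —
MRI-positive patients scored against their wide lesion labels and
MRI-negative patients against their lobar hypothesis labels — and
compare each AUC to a Monte-Carlo guessing-null distribution matched to
that cohort's labels, with Bonferroni control over the condition family.

Everything is reproducible from the config alone; ``write_reports``
emits CSV tables (AUC/p per condition, per-lesion detection
significance), null-distribution samples, and a JSON provenance record.
"""

from __future__ import annotations

import dataclasses
import json
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from surfdetect.afroc import afroc_curve, per_lesion_detection_fpf, threshold_grid
from surfdetect.cohort import CohortConfig, generate_cohort
from surfdetect.features import augment_features, define_subsets, zscore_features
from surfdetect.glm import cohort_zmaps
from surfdetect.mesh import build_symmetric_template, dilate_label
from surfdetect.nullmodel import (
    bonferroni_adjust,
    mc_p_value,
    null_auc_distribution,
    per_lesion_null_probability,
)
from surfdetect.novelty import score_cohort

__all__ = ["ExperimentConfig", "StageError", "run_experiment", "write_reports", "main"]

#: morphological dilation (vertex rounds) turning strict lesion labels
#: into the wide evaluation version
WIDE_DILATION = 4


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


@dataclass
class ExperimentConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    mesh_level: int = 4
    mesh_radius_mm: float = 100.0
    glm_measures: list = field(default_factory=lambda: ["thickness"])
    ml_methods: list = field(default_factory=lambda: ["MAH", "IF", "RFC"])
    subsets: list = field(default_factory=lambda: ["reduced", "reduced_noflair"])
    n_thresholds: int = 512
    m_null: int = 10_000
    k_bonferroni: int | None = None  # default: number of conditions per cohort
    lambda_max: float = 20.0
    n_levels: int = 256
    seed: int = 0
    output_dir: str = "results/experiment"

    @classmethod
    def from_file(cls, path) -> "ExperimentConfig":
        text = Path(path).read_text()
        raw = yaml.safe_load(text)
        if not isinstance(raw, dict):
            raise ValueError("config file must contain a mapping")
        cohort = CohortConfig(**raw.pop("cohort", {}))
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(cohort=cohort, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _eval_cohorts(cohort):
    """The two evaluation cohorts: (name, labels_by_subject, patient ids)."""
    out = []
    pos = cohort.by_group("mri_positive")
    if pos:
        labels = {
            p.subject_id: [dilate_label(cohort.mesh, lab, WIDE_DILATION)
                           for lab in p.lesion_labels]
            for p in pos
        }
        out.append(("mri_positive", labels, [p.subject_id for p in pos]))
    neg = cohort.by_group("mri_negative")
    if neg:
        labels = {n.subject_id: [n.hypothesis_label] for n in neg}
        out.append(("mri_negative", labels, [n.subject_id for n in neg]))
    return out


def run_experiment(config: ExperimentConfig) -> dict:
    """Run the full pipeline; returns the result bundle for write_reports."""
    t_start = time.time()
    log: list = []
    warnings_log: list = []

    def stage(name):
        log.append({"stage": name, "t": round(time.time() - t_start, 2)})

    try:
        stage("mesh")
        mesh = build_symmetric_template(config.mesh_level, config.mesh_radius_mm)
    except Exception as e:  # noqa: BLE001
        raise StageError("mesh", e) from e

    try:
        stage("cohort")
        cohort = generate_cohort(config.cohort, mesh)
    except Exception as e:  # noqa: BLE001
        raise StageError("cohort", e) from e

    control_ids = [c.subject_id for c in cohort.controls]
    eval_cohorts = _eval_cohorts(cohort)
    if not eval_cohorts:
        raise StageError("cohort", ValueError("no patients to evaluate"))

    # detectors -> maps
    conditions = []  # (method, subset_or_measure, maps dict, two_tailed)
    try:
        stage("glm")
        for measure in config.glm_measures:
            zmaps = cohort_zmaps(cohort, measure)
            conditions.append(
                ("GLM", measure, {k: v.values for k, v in zmaps.items()}, True))
    except Exception as e:  # noqa: BLE001
        raise StageError("glm", e) from e

    if config.ml_methods:
        try:
            stage("features")
            bank = augment_features(cohort)
            std = zscore_features(bank, cohort)
            subset_specs = {s.name: s for s in define_subsets(bank)}
        except Exception as e:  # noqa: BLE001
            raise StageError("features", e) from e
        try:
            stage("classifiers")
            ss = np.random.SeedSequence(config.seed).spawn(
                len(config.ml_methods) * len(config.subsets))
            k = 0
            for method in config.ml_methods:
                for subset_name in config.subsets:
                    if subset_name not in subset_specs:
                        raise ValueError(f"unknown feature subset {subset_name}")
                    smaps = score_cohort(
                        cohort, std, subset_specs[subset_name], method,
                        seed=int(ss[k].generate_state(1)[0] % 2**31))
                    k += 1
                    conditions.append(
                        (method, subset_name,
                         {kk: v.values for kk, v in smaps.items()}, False))
        except Exception as e:  # noqa: BLE001
            raise StageError("classifiers", e) from e

    # evaluation + nulls
    try:
        stage("evaluate")
        null_seed = np.random.SeedSequence(config.seed + 1)
        null_seeds = iter(int(s.generate_state(1)[0] % 2**31)
                          for s in null_seed.spawn(len(eval_cohorts)))
        auc_rows, lesion_rows, nulls, curves = [], [], {}, {}
        for cname, labels_by_subject, patient_ids in eval_cohorts:
            nulls[cname] = null_auc_distribution(
                mesh, labels_by_subject, len(control_ids), config.m_null,
                seed=next(null_seeds), lambda_max=config.lambda_max,
                n_levels=config.n_levels)
            for method, cond_name, maps, two_tailed in conditions:
                sub_maps = {sid: maps[sid]
                            for sid in patient_ids + control_ids}
                grid = threshold_grid(sub_maps, config.n_thresholds, two_tailed)
                curve = afroc_curve(sub_maps, mesh, labels_by_subject,
                                    control_ids, grid, two_tailed)
                curves[(cname, method, cond_name)] = curve
                p = mc_p_value(curve.auc, nulls[cname])
                auc_rows.append({
                    "cohort": cname, "method": method, "condition": cond_name,
                    "auc": curve.auc, "p": p,
                    "n_labels": curve.n_labels,
                    "n_controls": curve.n_controls,
                })
                for sid, labs in labels_by_subject.items():
                    for li, lab in enumerate(labs):
                        fpf_det, detected = per_lesion_detection_fpf(
                            sub_maps, mesh, lab, sid, control_ids, grid,
                            two_tailed)
                        if not detected:
                            warnings_log.append(
                                f"{cname}/{method}/{cond_name}: label {li} of "
                                f"{sid} never detected")
                        lesion_rows.append({
                            "cohort": cname, "method": method,
                            "condition": cond_name, "subject_id": sid,
                            "label_index": li, "phi": lab.phi,
                            "fpf_detection": fpf_det, "detected": detected,
                            "p_lesion": per_lesion_null_probability(
                                fpf_det, lab.phi),
                        })
        auc_table = pd.DataFrame(auc_rows)
        for cname in auc_table["cohort"].unique():
            sel = auc_table["cohort"] == cname
            k = config.k_bonferroni or int(sel.sum())
            auc_table.loc[sel, "p_adj"] = bonferroni_adjust(
                auc_table.loc[sel, "p"].to_numpy(), k)
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001
        raise StageError("evaluate", e) from e

    stage("done")
    return {
        "config": config,
        "auc_table": auc_table,
        "lesion_table": pd.DataFrame(lesion_rows),
        "nulls": nulls,
        "curves": curves,
        "warnings": warnings_log,
        "log": log,
        "seed": config.seed,
    }


def write_reports(results: dict, output_dir=None) -> list:
    """Write CSV/JSON reports; returns the list of files written."""
    config: ExperimentConfig = results["config"]
    out = Path(output_dir or config.output_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_test"
        probe.write_text("")
        probe.unlink()
    except OSError as e:
        raise StageError("report", e) from e
    written = []

    def emit(df: pd.DataFrame, name: str):
        path = out / name
        df.to_csv(path, index=False, float_format="%.6g")
        written.append(path)

    emit(results["auc_table"], "auc_table.csv")
    emit(results["lesion_table"], "per_lesion.csv")
    for cname, null in results["nulls"].items():
        emit(pd.DataFrame({"auc": null.auc_samples}), f"null_auc_{cname}.csv")
    for (cname, method, cond), curve in results.get("curves", {}).items():
        emit(curve.to_frame(), f"curve_{cname}_{method}_{cond}.csv")
    provenance = {
        "config": config.to_dict(),
        "seed": results["seed"],
        "warnings": results["warnings"],
        "log": results["log"],
        "null_manifests": {
            c: {"m": n.m, "n_labels": n.n_labels, "n_controls": n.n_controls,
                "label_phis": n.label_phis, "seed": n.seed, **n.manifest}
            for c, n in results["nulls"].items()
        },
    }
    path = out / "provenance.json"
    path.write_text(json.dumps(provenance, indent=2))
    written.append(path)
    return written


def main(argv=None) -> int:
    """Thin command-line entry point: run an experiment from a config file."""
    import argparse

    parser = argparse.ArgumentParser(
        description="Run the surface-based lesion-detection experiment "
                    "described by a YAML/JSON config file.")
    parser.add_argument("config", help="path to an experiment config")
    parser.add_argument("--out", default=None, help="output directory override")
    args = parser.parse_args(argv)
    try:
        config = ExperimentConfig.from_file(args.config)
    except Exception as e:  # noqa: BLE001
        print(f"config error: {e}", file=sys.stderr)
        return 2
    try:
        results = run_experiment(config)
        files = write_reports(results, args.out)
    except StageError as e:
        print(str(e), file=sys.stderr)
        return 3
    for f in files:
        print(f)
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
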