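"""End-to-end orchestration: synthesize -> NLP label -> ROI -> features
-> train/evaluate, with a run manifest for reproducibility.

Each stage writes plain-text artifacts into the run directory; a rerun
with an unchanged configuration reuses cached stage outputs (keyed on a
hash of the configuration) and reproduces identical checksums for the
deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ml
from .features import ensemble_features, extract_all, feature_table
from .nlp import PainLexicon, annotate_directory
from .roi import EN3, EN6, ENSEMBLES, EmptyROIError, build_nested
from .synthetic import CohortSpec, TextureParams, generate_cohort
from .volume import CenterPoint, read_ct, world_xyz_to_zyx

__all__ = ["load_config", "run_end_to_end", "report", "extract_cohort_features",
           "DEFAULT_CONFIG"]

DEFAULT_CONFIG = {
    "cohort": {
        "n_patients": 60,
        "pain_fraction": 0.84,
        "seed": 0,
    },
    "roi": {"sigma_mm": 1.0, "hu_min": 0.0, "ensembles": ["EN3", "EN6"]},
    "features": {"bin_width_hu": 25.0},
    "ml": {"train_fraction": 0.7, "smote_k": 5, "cv_folds": 5, "seed": 0,
           "allow_patient_overlap": False, "cross_validate": False},
}


def load_config(path) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        for k, v in user.items():
            if isinstance(v, dict) and k in cfg:
                cfg[k].update(v)
            else:
                cfg[k] = v
    return cfg


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def extract_cohort_features(volumes_dir, points_csv, sigma_mm: float = 1.0,
                            hu_min: float = 0.0, bin_width_hu: float = 25.0,
                            ensembles=("EN3", "EN6")) -> dict[str, pd.DataFrame]:
    """Nested-ROI feature tables for every lesion of a cohort.

    Per-ROI vectors are computed once for the EN6 diameters and sliced
    into each requested ensemble.  Lesions whose ROI is empty after
    thresholding are skipped with a log entry in the returned tables'
    ``attrs["skipped"]``.
    """
    volumes_dir = Path(volumes_dir)
    points = pd.read_csv(points_csv)
    specs = [ENSEMBLES[e] for e in ensembles]
    diam_needed = EN6.diameters_mm if any(s.name == "EN6" for s in specs) else EN3.diameters_mm
    per_ensemble: dict[str, list] = {s.name: [] for s in specs}
    skipped = []
    for pid, grp in points.groupby("patient_id", sort=True):
        vol = read_ct(volumes_dir / f"{pid}.nrrd")
        vol.patient_id = str(pid)
        for _, row in grp.iterrows():
            cp = CenterPoint(str(pid), str(row["lesion_id"]),
                             world_xyz_to_zyx((row["x_mm"], row["y_mm"], row["z_mm"])))
            try:
                masks = build_nested(vol, cp,
                                     spec=EN6 if len(diam_needed) == 6 else EN3,
                                     sigma_mm=sigma_mm, hu_min=hu_min)
            except EmptyROIError as e:
                skipped.append(str(e))
                continue
            vectors = [extract_all(vol, m, bin_width_hu=bin_width_hu) for m in masks]
            by_diam = dict(zip(diam_needed, vectors))
            for s in specs:
                ens = ensemble_features([by_diam[d] for d in s.diameters_mm], s)
                per_ensemble[s.name].append(ens)
    out = {}
    for name, vecs in per_ensemble.items():
        df = feature_table(vecs)
        df.attrs["skipped"] = skipped
        out[name] = df
    return out


def _labeled_dataset(features: pd.DataFrame, labels: pd.DataFrame) -> ml.LabeledDataset:
    """Join a feature table with note-level VDP labels (one per image)."""
    lab = labels.set_index("patient_id")["vdp"]
    merged = features[features["patient_id"].isin(lab.index)]
    dropped = sorted(set(features["patient_id"]) - set(lab.index))
    y = (lab.loc[merged["patient_id"]].to_numpy() == "pain").astype(int)
    feat_cols = [c for c in merged.columns if c not in ("patient_id", "lesion_id")]
    ds = ml.LabeledDataset(
        X=merged[feat_cols].to_numpy(),
        y=y,
        feature_names=feat_cols,
        patient_ids=merged["patient_id"].to_numpy(),
        image_ids=merged["patient_id"].to_numpy(),
        lesion_ids=merged["lesion_id"].to_numpy(),
    )
    if dropped:
        import warnings
        warnings.warn(f"images without a documented pain label dropped: {dropped}")
    return ds


def run_end_to_end(config_path, out_dir) -> dict:
    """Run every stage and return the manifest (also written to disk).

    Stage order: cohort synthesis, note annotation, ROI + feature
    extraction per ensemble, model training/evaluation.  Completed
    stages are reused when the configuration hash is unchanged.
    """
    cfg = load_config(config_path)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = _config_hash(cfg)
    manifest_path = out / "manifest.json"
    old = {}
    if manifest_path.exists():
        old = json.loads(manifest_path.read_text())
        if old.get("config_hash") != chash:
            old = {}
    manifest = {"config": cfg, "config_hash": chash, "stages": {},
                "checksums": {}, "warnings": []}

    def stage_done(name, artifacts):
        return (old.get("stages", {}).get(name, {}).get("status") == "done"
                and all(Path(a).exists() for a in artifacts))

    def finish(name, t0, artifacts):
        manifest["stages"][name] = {
            "status": "done", "seconds": round(time.time() - t0, 3)}
        for a in artifacts:
            manifest["checksums"][str(Path(a).relative_to(out))] = _sha256(Path(a))

    # ---- stage 1: synthesize ------------------------------------------
    data_dir = out / "data"
    cohort_kwargs = dict(cfg["cohort"])
    tex = cohort_kwargs.pop("texture_params", None)
    if tex:
        cohort_kwargs["texture_params"] = TextureParams(**tex)
    cspec = CohortSpec(**cohort_kwargs)
    artifacts = [data_dir / "points.csv", data_dir / "truth.csv",
                 data_dir / "patients.csv"]
    if not stage_done("synthesize", artifacts):
        t0 = time.time()
        try:
            generate_cohort(cspec, data_dir)
        except Exception as e:
            raise RuntimeError(f"stage synthesize failed: {e}") from e
        finish("synthesize", t0, artifacts)
    else:
        manifest["stages"]["synthesize"] = old["stages"]["synthesize"]
        for a in artifacts:
            manifest["checksums"][str(a.relative_to(out))] = _sha256(a)

    # ---- stage 2: NLP labels ------------------------------------------
    labels_csv = out / "labels.csv"
    if not stage_done("nlp", [labels_csv]):
        t0 = time.time()
        notes_dir = data_dir / "notes"
        if not notes_dir.is_dir():
            raise RuntimeError(f"stage nlp failed: notes directory missing: {notes_dir}")
        labels = annotate_directory(notes_dir, PainLexicon())
        labels.to_csv(labels_csv, index=False)
        finish("nlp", t0, [labels_csv])
    else:
        manifest["stages"]["nlp"] = old["stages"]["nlp"]
        manifest["checksums"]["labels.csv"] = _sha256(labels_csv)

    # ---- stage 3: ROI + features --------------------------------------
    ens_names = list(cfg["roi"]["ensembles"])
    feat_paths = {e: out / f"features_{e}.csv" for e in ens_names}
    if not stage_done("features", list(feat_paths.values())):
        t0 = time.time()
        tables = extract_cohort_features(
            data_dir / "volumes", data_dir / "points.csv",
            sigma_mm=cfg["roi"]["sigma_mm"], hu_min=cfg["roi"]["hu_min"],
            bin_width_hu=cfg["features"]["bin_width_hu"], ensembles=ens_names)
        for e, df in tables.items():
            df.to_csv(feat_paths[e], index=False)
            manifest["warnings"].extend(df.attrs.get("skipped", []))
        finish("features", t0, list(feat_paths.values()))
    else:
        manifest["stages"]["features"] = old["stages"]["features"]
        for e, p in feat_paths.items():
            manifest["checksums"][p.name] = _sha256(p)

    # ---- stage 4: train / evaluate ------------------------------------
    t0 = time.time()
    ml_cfg = dict(cfg["ml"])
    do_cv = ml_cfg.pop("cross_validate", False)
    pcfg = ml.PipelineConfig(**ml_cfg)
    labels = pd.read_csv(labels_csv)
    labels = labels[labels["vdp"].isin(["pain", "no_pain"])]
    results = {}
    for e in ens_names:
        features = pd.read_csv(feat_paths[e])
        ds = _labeled_dataset(features, labels)
        ds = ml.stratified_split(ds, pcfg)
        res = ml.run_experiment(ds, pcfg)
        entry = {
            "n_train": res["n_train"], "n_test": res["n_test"],
            "n_selected": len(res["selected_features"]),
            "models": {name: r["panel"].as_dict()
                       for name, r in res["models"].items()},
        }
        roc_rows = []
        for name, r in res["models"].items():
            for fpr, tpr in r["roc"]:
                roc_rows.append({"ensemble": e, "classifier": name,
                                 "fpr": fpr, "tpr": tpr})
        pd.DataFrame(roc_rows).to_csv(out / f"roc_{e}.csv", index=False)
        if do_cv:
            cv = ml.cross_validate(ds.train(), pcfg)
            entry["cv"] = cv.to_dict(orient="records")
        results[e] = entry
    results_path = out / "results.json"
    results_path.write_text(json.dumps(results, indent=2))
    finish("train", t0, [results_path])

    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest


def report(results_dir) -> str:
    """Human-readable AUC / F1 grid (classifier x ensemble) from results.json."""
    results_path = Path(results_dir) / "results.json"
    if not results_path.exists():
        raise FileNotFoundError(f"no results.json in {results_dir}")
    results = json.loads(results_path.read_text())
    lines = ["Model performance on the held-out test set", ""]
    header = f"{'ensemble':<10}" + "".join(f"{n:>10}" for n in ml.CLASSIFIER_NAMES)
    for metric in ("auc", "f1"):
        lines.append(metric.upper())
        lines.append(header)
        for ens, entry in results.items():
            row = f"{ens:<10}"
            for name in ml.CLASSIFIER_NAMES:
                row += f"{entry['models'][name][metric]:>10.3f}"
            lines.append(row)
        lines.append("")
    text = "\n".join(lines)
    (Path(results_dir) / "report.txt").write_text(text)
    return text
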