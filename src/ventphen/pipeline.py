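"""End-to-end orchestration: simulate → preprocess → fit → validate → report.

``run_pipeline`` executes the stages in order, writes every intermediate
artifact under the output directory, and returns a manifest (config, child
seeds, row counts, file checksums) so a rerun with the same config
reproduces every numeric output bit for bit. One global seed fans out to
per-stage child seeds by fixed offsets, so any stage can be rerun in
isolation.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .mixture import MODEL_1, fit_em
from .outcomes import (
    DISPLAY_THRESHOLD,
    SOFA_SEGMENT_EDGES,
    profile_report,
    sofa_mortality_table,
    survival_curves,
)
from .panel import default_feature_panel, feature_names
from .preprocess import ChainedImputer, apply_scaler, fit_scaler, screen_correlated
from .selection import assign_cohort, psi, sweep_k
from .simulate import (
    CohortSpec,
    features_frame,
    read_cohort_csv,
    simulate_cohort,
    split_cohort,
    write_cohort_csv,
)

log = logging.getLogger("ventphen")

# fixed per-stage seed offsets fanned out from the global seed
STAGE_SEEDS = {"simulate": 0, "split": 1, "impute": 2, "em": 3}


@dataclass
class PipelineConfig:
    outdir: str = "results"
    input_csv: str | None = None      # simulate when absent
    n_patients: int = 5013
    seed: int = 0
    split_ratio: float = 0.8
    mice_cycles: int = 10
    mice_imputations: int = 1
    screen_threshold: float | None = None    # sensitivity switch, off by default
    k_min: int = 2
    k_max: int = 8
    fixed_k: int | None = None
    mode: str = MODEL_1
    n_restarts: int = 10
    tol: float = 1e-6
    max_iter: int = 500
    size_floor: float = 0.04
    posterior_floor: float = 0.7
    sofa_edges: tuple = SOFA_SEGMENT_EDGES
    display_threshold: float = DISPLAY_THRESHOLD

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(doc) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**doc)

    def stage_seed(self, stage: str) -> int:
        return int(self.seed + STAGE_SEEDS[stage])


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages and return the manifest (also written as JSON)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": _jsonable(asdict(config)),
        "version": __version__,
        "stages": {},
        "files": {},
        "warnings": [],
    }
    t0 = time.time()
    panel = default_feature_panel()
    cols = feature_names(panel)

    def stage(name):
        log.info("stage %s", name)
        manifest["stages"][name] = {"t_start": round(time.time() - t0, 3)}
        return manifest["stages"][name]

    # -- cohort -------------------------------------------------------------
    st = stage("cohort")
    if config.input_csv:
        cohort = read_cohort_csv(config.input_csv)
    else:
        cohort = simulate_cohort(
            CohortSpec(config.n_patients, seed=config.stage_seed("simulate")),
            panel)
    st["n_rows"] = len(cohort)

    st = stage("split")
    cohort = split_cohort(cohort, config.split_ratio,
                          seed=config.stage_seed("split"))
    train_mask = cohort["split"] == "train"
    st["n_train"] = int(train_mask.sum())
    st["n_validation"] = int((~train_mask).sum())
    write_cohort_csv(cohort, out / "cohort.csv")

    # -- preprocessing ------------------------------------------------------
    st = stage("impute")
    feats = features_frame(cohort, panel)
    train_ids = cohort.loc[train_mask, "patient_id"]
    val_ids = cohort.loc[~train_mask, "patient_id"]
    imputer = ChainedImputer(n_cycles=config.mice_cycles,
                             n_imputations=config.mice_imputations,
                             seed=config.stage_seed("impute"))
    train_feats = imputer.fit_transform(feats.loc[train_ids])
    val_feats = imputer.transform(feats.loc[val_ids])
    completed = pd.concat([train_feats, val_feats]).loc[feats.index]
    completed.to_csv(out / "features_completed.csv")
    st["n_imputed_cells"] = int(feats.isna().sum().sum())

    if config.screen_threshold is not None:
        st = stage("screen")
        miss = feats.loc[train_ids].isna().sum().to_dict()
        train_feats, report = screen_correlated(
            train_feats, config.screen_threshold, miss)
        val_feats = val_feats[train_feats.columns]
        st["dropped"] = report.dropped
        st["pairs"] = [(d, k, round(r, 4)) for d, k, r in report.pairs]

    st = stage("scale")
    scaler = fit_scaler(train_feats)
    if scaler.floored:
        manifest["warnings"].append(f"variance floor hit: {scaler.floored}")
    train_z = apply_scaler(train_feats, scaler)
    val_z = apply_scaler(val_feats, scaler)
    (out / "scaler.json").write_text(scaler.to_json())
    st["n_features"] = train_z.shape[1]

    # -- model selection and fit -------------------------------------------
    em_seed = config.stage_seed("em")
    if config.fixed_k is None:
        st = stage("select")
        report = sweep_k(train_z, range(config.k_min, config.k_max + 1),
                         mode=config.mode, n_restarts=config.n_restarts,
                         tol=config.tol, max_iter=config.max_iter,
                         seed=em_seed, size_floor=config.size_floor,
                         posterior_floor=config.posterior_floor,
                         keep_models=False)
        report.table.to_csv(out / "selection.csv", index=False)
        chosen_k = report.chosen_k
        st["chosen_K"] = chosen_k
        st["fallback"] = report.fallback
        if report.fallback:
            manifest["warnings"].append("selection fell back to pure BIC")
    else:
        chosen_k = config.fixed_k

    st = stage("fit")
    model = fit_em(train_z, chosen_k, mode=config.mode,
                   n_restarts=config.n_restarts, tol=config.tol,
                   max_iter=config.max_iter, seed=em_seed, scaler=scaler)
    (out / "model.json").write_text(model.to_json())
    st["K"] = chosen_k
    st["loglik"] = model.fit_info["loglik"]
    st["converged"] = model.fit_info["converged"]
    if model.fit_info.get("collapsed_restart"):
        manifest["warnings"].append("winning restart had a collapsed class")

    # -- assignment and stability ------------------------------------------
    st = stage("assign")
    post_train = assign_cohort(model, train_z)
    post_val = assign_cohort(model, val_z)
    post_train.to_frame().to_csv(out / "posterior_train.csv")
    post_val.to_frame().to_csv(out / "posterior_validation.csv")
    st["train_counts"] = post_train.counts().tolist()
    st["validation_counts"] = post_val.counts().tolist()

    st = stage("validate")
    stability = psi(post_train.counts(), post_val.counts(),
                    bin_labels=post_train.class_labels)
    stability.to_frame().to_csv(out / "psi.csv", index=False)
    (out / "psi.json").write_text(json.dumps(
        {"total": stability.total,
         "smoothed_bins": stability.smoothed_bins}, indent=1))
    if stability.smoothed_bins:
        manifest["warnings"].append(
            f"PSI zero-bin smoothing applied: {stability.smoothed_bins}")
    st["psi"] = stability.total

    # -- outcomes -----------------------------------------------------------
    st = stage("outcomes")
    train_cohort = cohort[train_mask].copy()
    train_cohort[cols] = train_feats.to_numpy()   # post-imputation features
    profile = profile_report(train_cohort, post_train, list(train_feats.columns),
                             scaler)
    profile.summary.to_csv(out / "phenotype_summary.csv", index=False)
    profile.feature_table.to_csv(out / "phenotype_profiles.csv", index=False)
    sofa = sofa_mortality_table(train_cohort, post_train,
                                edges=config.sofa_edges,
                                display_threshold=config.display_threshold)
    sofa.table.to_csv(out / "sofa_segments.csv", index=False)
    surv = survival_curves(train_cohort, post_train)
    surv.to_frame().to_csv(out / "survival_curves.csv", index=False)
    surv.day28_mortality.rename_axis("phenotype").to_csv(
        out / "day28_mortality.csv")
    st["day28_mortality"] = {int(k): (None if pd.isna(v) else round(v, 6))
                             for k, v in surv.day28_mortality.items()}

    for p in sorted(out.iterdir()):
        if p.is_file() and p.name != "manifest.json":
            manifest["files"][p.name] = _sha256(p)
    manifest["elapsed_s"] = round(time.time() - t0, 3)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
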