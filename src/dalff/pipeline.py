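"""End-to-end orchestration: data -> preprocessing -> dALFF -> statistics.

`run_pipeline` wires the stages together for each configured window length
and writes all artifacts (NIfTI maps, CSV tables, JSON reports) plus a run
manifest under the output directory.  Every source of randomness derives
from the config seed, so a rerun with the same config is byte-identical at
the CSV/JSON level.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import alff, classify, correlate, inference, states, synthetic
from .preprocess import (
    BoldImage,
    load_bold,
    load_covariates,
    run_preprocessing,
    save_volume,
    validate_covariates,
)

log = logging.getLogger("dalff")

__all__ = ["RunConfig", "run_pipeline", "validate_inputs", "load_config"]


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    mode: str = "synthetic"  # "synthetic" | "nifti"
    input_dir: str | None = None  # for mode="nifti": directory of *_bold.nii + covariates.csv
    output_dir: str = "dalff_out"
    n_discard: int = 10
    detrend_order: int = 1
    smooth_fwhm: float = 6.0
    band: tuple[float, float] = (0.01, 0.08)
    window_lengths: tuple[int, ...] = (30, 50, 80)
    step: int = 1
    standardize_cv: bool = True
    voxel_p: float = 0.05
    cluster_p: float = 0.05
    connectivity: int = 26
    k_states: int | None = None  # None = auto via select_k
    k_range: tuple[int, ...] = (2, 3, 4, 5)
    svm_scheme: str = "loo"
    svm_coarse_grid: bool = True
    run_permutation: bool = False
    n_perm: int = 500
    seed: int = 0
    synthetic: dict = field(default_factory=dict)  # forwarded to SyntheticConfig

    def validate(self) -> None:
        if self.mode not in ("synthetic", "nifti"):
            raise ValueError(f"unknown mode '{self.mode}'")
        if self.mode == "nifti" and not self.input_dir:
            raise ValueError("mode='nifti' requires input_dir")
        for p in (self.voxel_p, self.cluster_p):
            if not (0 < p < 1):
                raise ValueError("thresholds must lie in (0, 1)")
        if self.step < 1:
            raise ValueError("step must be >= 1")


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = RunConfig(**raw)
    for name in ("band", "window_lengths", "k_range"):
        setattr(cfg, name, tuple(getattr(cfg, name)))
    cfg.validate()
    return cfg


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def validate_inputs(subjects: list[synthetic.Subject], covariates: pd.DataFrame) -> dict:
    """Consistency checks across the cohort; reports, never mutates."""
    report: dict = {"errors": [], "warnings": [], "n_subjects": len(subjects)}
    if not subjects:
        report["errors"].append("no subjects")
        return report
    trs = {s.bold.tr for s in subjects}
    if len(trs) > 1:
        report["errors"].append(f"mixed TR across cohort: {sorted(trs)}")
    shapes = {s.bold.data.shape[:3] for s in subjects}
    if len(shapes) > 1:
        report["errors"].append(f"mixed grids across cohort: {sorted(shapes)}")
    if not subjects[0].bold.mask.any():
        report["errors"].append("empty brain mask")
    try:
        validate_covariates(covariates)
    except ValueError as err:
        report["errors"].append(str(err))
        return report
    ids = set(covariates["subject_id"])
    for s in subjects:
        if s.subject_id not in ids:
            report["errors"].append(f"missing covariate row for subject {s.subject_id}")
    counts = covariates["group"].value_counts()
    if len(counts) == 2 and counts.max() != counts.min():
        report["warnings"].append(f"group sizes unbalanced: {counts.to_dict()}")
    return report


def _load_nifti_cohort(input_dir: str) -> tuple[list[synthetic.Subject], pd.DataFrame]:
    root = Path(input_dir)
    covariates = load_covariates(root / "covariates.csv")
    subjects = []
    for _, row in covariates.iterrows():
        path = root / f"{row.subject_id}_bold.nii"
        if not path.exists():
            path = root / f"{row.subject_id}_bold.nii.gz"
        if not path.exists():
            raise FileNotFoundError(f"no BOLD image for subject {row.subject_id} in {root}")
        bold = load_bold(path)
        subjects.append(synthetic.Subject(str(row.subject_id), str(row.group), bold))
    return subjects, covariates


def _stage(name: str, t0: float) -> None:
    log.info("stage=%s elapsed=%.1fs", name, time.time() - t0)


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and return the manifest (also written as JSON)."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "version": _package_version(),
        "artifacts": {},
    }
    t0 = time.time()

    # ---- acquire cohort -------------------------------------------------
    if config.mode == "synthetic":
        syn_kwargs = dict(config.synthetic)
        syn_kwargs.setdefault("seed", config.seed)
        regions = syn_kwargs.pop("effect_regions", None)
        syn_cfg = synthetic.SyntheticConfig(**syn_kwargs)
        if regions is not None:
            syn_cfg.effect_regions = [
                r if isinstance(r, synthetic.EffectRegion) else synthetic.EffectRegion(**r)
                for r in regions
            ]
        syn_cfg.window_lengths = tuple(config.window_lengths)
        subjects, truth = synthetic.generate_cohort(syn_cfg)
        covariates = truth.covariates
        covariates.to_csv(out / "covariates.csv", index=False)
        save_volume(truth.effect_mask, subjects[0].bold.affine, out / "effect_mask.nii")
    else:
        subjects, covariates = _load_nifti_cohort(config.input_dir)
    report = validate_inputs(subjects, covariates)
    if report["errors"]:
        raise ValueError(f"stage=validate failed: {report['errors']}")
    manifest["validation"] = report
    _stage("acquire", t0)

    # ---- preprocess ------------------------------------------------------
    for s in subjects:
        try:
            s.bold = run_preprocessing(
                s.bold,
                n_discard=config.n_discard,
                detrend_order=config.detrend_order,
                smooth_fwhm=config.smooth_fwhm,
            )
        except Exception as err:  # pragma: no cover - error plumbing
            raise RuntimeError(f"stage=preprocess subject={s.subject_id}: {err}") from err
    _stage("preprocess", t0)

    mask = subjects[0].bold.mask
    affine = subjects[0].bold.affine
    voxel_size = tuple(subjects[0].bold.voxel_size)
    scores = covariates["score"].to_numpy(dtype=np.float64)
    patient_rows = covariates["group"].to_numpy() == "patient"

    for w in config.window_lengths:
        wdir = out / f"w{w}"
        wdir.mkdir(exist_ok=True)
        stacks: dict[str, np.ndarray] = {}
        cv_flat = []
        cv_maps: dict[str, np.ndarray] = {}
        for s in subjects:
            stack = alff.compute_windowed_alff(s.bold, w, config.step, config.band)
            stacks[s.subject_id] = stack.matrix
            dmap = alff.compute_dalff_cv(stack)
            cv = dmap.cv
            if config.standardize_cv:
                cv = alff.standardize_map(cv, mask)
            cv_maps[s.subject_id] = cv
            cv_flat.append(cv[mask])
            save_volume(cv.astype(np.float32), affine, wdir / f"{s.subject_id}_dalff_w{w}.nii")
        cv_matrix = np.vstack(cv_flat)
        _stage(f"dalff_w{w}", t0)

        # group statistics
        glm = inference.fit_voxelwise_glm(cv_matrix, covariates)
        table, labels = inference.grf_cluster_correct(
            glm,
            mask,
            affine,
            voxel_size,
            voxel_p=config.voxel_p,
            cluster_p=config.cluster_p,
            connectivity=config.connectivity,
        )
        table.to_csv(wdir / "clusters_grf.csv", index=False)
        save_volume(labels, affine, wdir / "cluster_mask.nii")
        if config.run_permutation:
            perm_table, _ = inference.permutation_cluster_correct(
                cv_matrix,
                covariates,
                mask,
                affine,
                voxel_p=config.voxel_p,
                cluster_p=config.cluster_p,
                n_perm=config.n_perm,
                seed=config.seed,
                connectivity=config.connectivity,
            )
            perm_table.to_csv(wdir / "clusters_permutation.csv", index=False)
        _stage(f"group_w{w}", t0)

        # state dynamics
        if config.k_states is None:
            diag = states.select_k(stacks, config.k_range, seed=config.seed)
            model = diag["models"][diag["chosen_k"]]
        else:
            model = states.cluster_states(stacks, config.k_states, seed=config.seed)
        mtable = states.metrics_table(model, covariates, subjects[0].bold.tr, config.step)
        mtable.to_csv(wdir / "state_metrics.csv", index=False)
        states.compare_group_metrics(mtable).to_csv(wdir / "state_group_comparison.csv", index=False)
        _stage(f"states_w{w}", t0)

        # classification from differential clusters
        svm_report = None
        if len(table):
            ftable = classify.extract_roi_features(cv_maps, labels, covariates, window_length=w)
            ftable.features.to_csv(wdir / "features.csv")
            svm_report = classify.train_evaluate_svm(
                ftable,
                grid=classify.default_grid(coarse=config.svm_coarse_grid),
                scheme=config.svm_scheme,
                seed=config.seed,
            )
            with open(wdir / "svm_report.json", "w") as fh:
                json.dump(svm_report.to_dict(), fh, indent=2, sort_keys=True)
            # clinical correlation in patients, per differential cluster
            patient_ids = covariates.loc[patient_rows, "subject_id"]
            patient_features = ftable.features.loc[patient_ids]
            if len(patient_features) >= 4:
                corr = correlate.correlate_with_clinical(patient_features, scores[patient_rows])
                correlate.report_to_csv(corr, wdir / "clinical_correlation.csv")
        _stage(f"classify_w{w}", t0)

        manifest["artifacts"][f"w{w}"] = {
            "dalff_maps": sorted(p.name for p in wdir.glob("*_dalff_*.nii")),
            "clusters_grf": "clusters_grf.csv",
            "state_metrics": "state_metrics.csv",
            "k_states": model.k,
            "n_clusters": int(len(table)),
            "svm": svm_report.to_dict() if svm_report else None,
        }

    manifest["elapsed_seconds"] = round(time.time() - t0, 1)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest


def _package_version() -> str:
    from importlib.metadata import version, PackageNotFoundError

    try:
        return version("dalff")
    except PackageNotFoundError:  # pragma: no cover
        return "unknown"
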