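"""End-to-end pipeline orchestration and the leave-one-subject-out driver.

``run_pipeline`` executes the full chain on synthetic subjects:

    simulate -> coarse segmentation (U-Net) -> largest-component
    refinement -> voxel classification (PCA + classifier) -> mean
    cortex curve -> signal-to-concentration -> 2CFM fit -> SK-GFR ->
    evaluation metrics

Training artifacts (network, PCA, classifier) are fitted on the
training subjects only and applied to the held-out test subject, so no
test-subject data influence any fitted model (this is audited).  A JSON
manifest recording the configuration hash, seeds and sha256 of every
written artifact makes runs resumable: a stage whose manifest entry
matches the current configuration is skipped and its persisted
artifacts reloaded.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import joblib
import numpy as np

from . import coarse_seg, fine_seg, metrics, pk
from .coarse_seg import TrainConfig, UNetConfig
from .dataio import config_hash
from .errors import ConfigurationError, ProvenanceError
from .fine_seg import ClassifierConfig
from .phantom import PhantomConfig, make_phantom

logger = logging.getLogger(__name__)

__all__ = ["default_pipeline_config", "run_pipeline", "loso_driver"]


def default_pipeline_config() -> dict:
    """A scaled-down phantom pipeline configuration (edit before use)."""
    return {
        "n_training_subjects": 2,
        "phantom": {"shape": [192, 192, 8], "noise_sigma": 0.0, "pk_dispersion": 0.0},
        "unet": {"base_filters": 16, "depth": 4, "dropout": 0.2, "seed": 0},
        "train": {"epochs": 10, "learning_rate": 0.01, "momentum": 0.99,
                  "batch_size": 8, "val_fraction": 0.34, "seed": 0},
        "classifier": {"algorithm": "svm_rbf", "svm_gamma": 0.05, "svm_c": 1.0},
        "pca_components": 20,
        "vertical_offsets": 3,
        "seed": 0,
    }


def _phantom_config(cfg: dict, seed: int) -> PhantomConfig:
    section = dict(cfg.get("phantom", {}))
    if "shape" in section:
        section["shape"] = tuple(section["shape"])
    return PhantomConfig(seed=seed, **section)


def _sha(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _Manifest:
    def __init__(self, out_dir: Path, cfg_hash: str):
        self.path = out_dir / "manifest.json"
        self.cfg_hash = cfg_hash
        if self.path.exists():
            data = json.loads(self.path.read_text())
            self.stages = data.get("stages", {}) if data.get("config_hash") == cfg_hash else {}
        else:
            self.stages = {}

    def done(self, stage: str) -> bool:
        entry = self.stages.get(stage)
        return bool(entry) and all(Path(p).exists() for p in entry.get("artifacts", []))

    def record(self, stage: str, artifacts: list[Path]) -> None:
        self.stages[stage] = {
            "artifacts": [str(p) for p in artifacts],
            "sha256": {p.name: _sha(p) for p in artifacts},
        }
        self.path.write_text(
            json.dumps({"config_hash": self.cfg_hash, "stages": self.stages}, indent=1)
        )


def _train_artifacts(cfg: dict, out_dir: Path, seed: int, manifest: _Manifest):
    """Simulate training subjects and fit U-Net + PCA + classifier on them."""
    rng = np.random.SeedSequence(seed)
    child = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in rng.spawn(8)]
    n_train = int(cfg.get("n_training_subjects", 2))
    model_path = out_dir / "models.joblib"
    if manifest.done("train") and model_path.exists():
        logger.info("train stage up to date; reloading artifacts")
        return joblib.load(model_path)

    subjects = {}
    for i in range(n_train):
        subjects[f"train{i}"] = make_phantom(_phantom_config(cfg, seed=child[i]))

    # coarse segmentation training set
    patch_sets = []
    for name, ph in subjects.items():
        frames = coarse_seg.select_enhancement_frames(ph.series)
        kidney = ph.labels.data > 0
        for f in frames:
            patch_sets.append(
                coarse_seg.extract_patches(
                    ph.series.frame(f), kidney,
                    vertical_offsets=int(cfg.get("vertical_offsets", 3)),
                    seed=child[4] + f, subject=name, frame_index=f,
                )
            )
    patches = coarse_seg.concat_patch_sets(patch_sets)
    unet_cfg = UNetConfig(**cfg.get("unet", {}))
    train_cfg = TrainConfig(**cfg.get("train", {}))
    net, history = coarse_seg.train_unet(patches, unet_cfg, train_cfg)

    # fine segmentation training set (ground-truth labels of training subjects)
    tc_sets = [
        fine_seg.extract_time_courses(ph.series, ph.labels.data > 0, ph.labels, subject=name)
        for name, ph in subjects.items()
    ]
    train_tcs = fine_seg.concat_time_courses(tc_sets)
    pca = fine_seg.fit_pca(train_tcs, k=int(cfg.get("pca_components", 20)))
    features = fine_seg.transform_pca(pca, train_tcs)
    bal_x, bal_y = fine_seg.balance_classes(features, train_tcs.labels, seed=child[5])
    clf_cfg = ClassifierConfig(**cfg.get("classifier", {}), seed=child[6])
    clf = fine_seg.train_classifier(bal_x, bal_y, clf_cfg,
                                    training_subjects=sorted(subjects))

    bundle = {"net": net, "pca": pca, "clf": clf, "history": history,
              "training_subjects": sorted(subjects)}
    joblib.dump(bundle, model_path)
    history_path = out_dir / "training_history.csv"
    history.to_csv(history_path, index=False)
    manifest.record("train", [model_path, history_path])
    return bundle


def run_pipeline(cfg: dict | None = None, out_dir: str | Path = "pipeline_out",
                 seed: int | None = None) -> dict:
    """Run the phantom pipeline end to end; returns the evaluation report."""
    cfg = cfg or default_pipeline_config()
    if seed is not None:
        cfg = {**cfg, "seed": seed}
    if "seed" not in cfg:
        raise ConfigurationError("pipeline configuration is missing required key 'seed'")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg_hash = config_hash(cfg)
    manifest = _Manifest(out_dir, cfg_hash)
    master_seed = int(cfg["seed"])

    bundle = _train_artifacts(cfg, out_dir, master_seed, manifest)
    net, pca, clf = bundle["net"], bundle["pca"], bundle["clf"]

    # held-out test subject
    test_seed = master_seed + 10_000
    test = make_phantom(_phantom_config(cfg, seed=test_seed))
    test_name = "held_out"
    if test_name in clf.training_subjects:
        raise ProvenanceError("held-out subject leaked into the training cohort")

    frames = coarse_seg.select_enhancement_frames(test.series)
    left, right = coarse_seg.predict_mask(net, test.series, frames[1])
    left = coarse_seg.largest_component(left)
    right = coarse_seg.largest_component(right)
    pred_mask = left.data | right.data

    pred_labels = fine_seg.classify_voxels(clf, pca, test.series, pred_mask)

    report = {"seed": master_seed, "config_hash": cfg_hash, "sides": {}}
    truth_mask = test.labels.data > 0
    report["kidney_iou"] = metrics.iou(pred_mask, truth_mask)
    seg_scores = metrics.multiclass_scores(pred_labels, test.labels)
    report["weighted_iou"] = seg_scores.weighted_iou
    report["per_class_iou"] = {str(k): v for k, v in seg_scores.per_class_iou.items()}

    vox_ml = test.series.voxel_volume_ml
    for side, side_mask in (("left", left), ("right", right)):
        side_labels = np.where(side_mask.data, pred_labels.data, 0)
        from .dataio import CompartmentLabelMap

        side_map = CompartmentLabelMap(side_labels)
        curve = pk.mean_cortex_curve(test.series, side_map)
        conc = pk.signal_to_concentration(
            curve, test.series.frame_times, test.series.n_baseline_frames,
            t10_s=test.config.t10_s["cortex"], r1=test.config.r1,
            tr_ms=test.series.tr_ms, flip_angle_deg=test.series.flip_angle_deg,
        )
        fit = pk.fit_2cfm(conc, test.aif, n_baseline=test.series.n_baseline_frames)
        gfr = pk.compute_gfr(fit.params.ktrans_per_min, side_map, vox_ml)
        truth = test.sk_gfr_ml_min[side]
        report["sides"][side] = {
            "ktrans_per_min": fit.params.ktrans_per_min,
            "cortex_volume_ml": gfr.cortex_volume_ml,
            "sk_gfr_ml_min": gfr.gfr_ml_min,
            "true_sk_gfr_ml_min": truth,
            "gfr_error_percent": 100.0 * (gfr.gfr_ml_min - truth) / truth,
        }
    report_path = out_dir / "report.json"
    report_path.write_text(json.dumps(report, indent=1))
    manifest.record("evaluate", [report_path])
    return report


def loso_driver(subject_seeds: list[int], cfg: dict | None = None,
                out_dir: str | Path = "loso_out") -> dict:
    """Leave-one-subject-out over synthetic subjects.

    For every held-out subject, the U-Net, PCA and classifier are
    fitted on the remaining subjects only and evaluated on the held-out
    one; per-subject scores and their mean/SD are returned.
    """
    if len(subject_seeds) < 2:
        raise ConfigurationError("leave-one-subject-out needs at least 2 subjects")
    cfg = cfg or default_pipeline_config()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    subjects = {f"subject{i}": make_phantom(_phantom_config(cfg, seed=s))
                for i, s in enumerate(subject_seeds)}
    rows = []
    for held_out in subjects:
        train_names = [s for s in subjects if s != held_out]
        tc_sets = [
            fine_seg.extract_time_courses(subjects[s].series, subjects[s].labels.data > 0,
                                          subjects[s].labels, subject=s)
            for s in train_names
        ]
        train_tcs = fine_seg.concat_time_courses(tc_sets)
        if held_out in set(np.unique(train_tcs.subjects)):
            raise ProvenanceError(f"held-out subject {held_out} present in training data")
        pca = fine_seg.fit_pca(train_tcs, k=int(cfg.get("pca_components", 20)))
        feats = fine_seg.transform_pca(pca, train_tcs)
        bal_x, bal_y = fine_seg.balance_classes(feats, train_tcs.labels, seed=int(cfg.get("seed", 0)))
        clf = fine_seg.train_classifier(
            bal_x, bal_y, ClassifierConfig(**cfg.get("classifier", {})),
            training_subjects=train_names,
        )
        test = subjects[held_out]
        pred = fine_seg.classify_voxels(clf, pca, test.series, test.labels.data > 0)
        score = metrics.multiclass_scores(pred, test.labels)
        rep = metrics.classification_report(
            test.labels.data[test.labels.data > 0], pred.data[test.labels.data > 0]
        )
        rows.append({
            "subject": held_out,
            "balanced_accuracy": rep.balanced_accuracy,
            "weighted_iou": score.weighted_iou,
            **{f"iou_class{c}": score.per_class_iou.get(c, float("nan")) for c in (1, 2, 3)},
        })
    import pandas as pd

    table = pd.DataFrame(rows)
    summary = {"per_subject": rows,
               "mean": table.drop(columns="subject").mean().to_dict(),
               "sd": table.drop(columns="subject").std(ddof=1).to_dict()}
    (out_dir / "loso_report.json").write_text(json.dumps(summary, indent=1))
    table.to_csv(out_dir / "loso_table.csv", index=False)
    return summary
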