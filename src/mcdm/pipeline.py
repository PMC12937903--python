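"""End-to-end orchestration: simulate -> preprocess -> chaos -> render ->
augment -> split/train -> evaluate.

Each stage writes its artifacts under the configured output directory
and stamps them with the config hash and master seed, so identical
config + seed reproduce byte-identical evaluation reports.  Stages can
also be run individually (see :mod:`mcdm.cli`), reading the artifacts a
previous invocation left on disk.

Two augmentation protocols are supported (``classify.augment_before_split``):

* leakage-safe (default): subjects are split first; the training side is
  the train originals plus their augmented copies, the test side the
  untouched test originals.
* augment-before-split: every source image is expanded first and the
  resulting dataset (augmented copies only, four per source) is then
  split at the subject level — this reproduces the 200-subjects-per-class
  -> 800-images-per-class -> 320-test-images bookkeeping.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np

from . import io as mcdm_io
from .classify import (
    HOGConfig, LBPConfig, evaluate, extract_features, feature_importance,
    predict_batch, subject_split, train_rf,
)
from .config import PipelineConfig
from .phase_space import chaos_report
from .preprocess import FilterSpec, apply_filters, average_channels, segment_cycles
from .phase_space import EmbeddingParams, embed, estimate_delay
from .render import (
    MCDMImage, augment_dataset, load_png, read_manifest, render_mcdm,
    save_png, write_manifest,
)
from .synthetic import MCGRecord, simulate_cohort

__all__ = ["run_pipeline", "STAGES", "render_record", "meta_for"]

logger = logging.getLogger("mcdm")

STAGES = ("simulate", "preprocess", "chaos", "render", "augment", "train", "evaluate")


def meta_for(config: PipelineConfig) -> dict:
    return {"config_hash": config.config_hash, "seed": config.seed}


def _ensure_dir(path: Path) -> Path:
    path.mkdir(parents=True, exist_ok=True)
    return path


def stage_simulate(config: PipelineConfig, out: Path) -> list[MCGRecord]:
    cfg = config.simulate
    records = simulate_cohort(
        cfg.n_healthy, cfg.n_ischemic, seed=config.seed,
        n_cycles=cfg.n_cycles, sampling_rate=cfg.sampling_rate,
        morphology_params=cfg.morphology or None,
    )
    sig_dir = _ensure_dir(out / "signals")
    for record in records:
        mcdm_io.write_record(record, sig_dir / f"{record.subject_id}.csv")
    logger.info("simulate: wrote %d records to %s", len(records), sig_dir)
    return records


def load_records(out: Path) -> list[MCGRecord]:
    sig_dir = out / "signals"
    paths = sorted(sig_dir.glob("*.csv"))
    if not paths:
        raise FileNotFoundError(f"no signal artifacts under {sig_dir}")
    return [mcdm_io.read_record(p) for p in paths]


def stage_preprocess(
    config: PipelineConfig, out: Path, records: Sequence[MCGRecord] | None = None
) -> list[dict]:
    """Average channels, filter, and keep fiducials alongside; returns
    one entry per subject with the representative waveform."""
    if records is None:
        records = load_records(out)
    cfg = config.preprocess
    spec = FilterSpec(band_low=cfg.band_low, band_high=cfg.band_high,
                      notch=cfg.notch, median_window=cfg.median_window)
    avg_dir = _ensure_dir(out / "averaged")
    entries = []
    for record in records:
        averaged = average_channels(record, smooth_window=cfg.smooth_window)
        filtered = apply_filters(averaged, spec)
        path = avg_dir / f"{record.subject_id}.csv"
        mcdm_io.write_series(filtered, path)
        if record.fiducials is not None:
            with open(mcdm_io.fiducial_sidecar_path(path), "w") as fh:
                json.dump(record.fiducials.to_dict(), fh)
        entries.append({
            "subject_id": record.subject_id,
            "class_label": record.class_label,
            "series": filtered,
            "fiducials": record.fiducials,
        })
    logger.info("preprocess: averaged and filtered %d records", len(entries))
    return entries


def stage_chaos(config: PipelineConfig, out: Path, entries: Sequence[dict]) -> list[dict]:
    cfg = config.chaos
    chaos_dir = _ensure_dir(out / "chaos")
    subset = entries if cfg.max_subjects is None else entries[: cfg.max_subjects]
    reports = []
    for entry in subset:
        report = chaos_report(
            entry["series"], max_lag=cfg.max_lag, m_max=cfg.m_max, r0=cfg.r0,
            run_surrogates=cfg.run_surrogates, n_surrogates=cfg.n_surrogates,
            seed=config.seed,
        )
        report["subject_id"] = entry["subject_id"]
        report["_meta"] = meta_for(config)
        path = chaos_dir / f"{entry['subject_id']}.json"
        path.write_text(json.dumps(report, indent=2, sort_keys=True))
        reports.append(report)
    logger.info("chaos: wrote %d reports", len(reports))
    return reports


def render_record(
    series, fiducials, subject_id: str, class_label: str | None,
    image_size: tuple[int, int], cycle_index: int | None = None,
) -> MCDMImage:
    """Render one subject's representative cycle into an image."""
    cycles = segment_cycles(series, fiducials, subject_id=subject_id)
    idx = len(cycles) // 2 if cycle_index is None else cycle_index
    cycle = cycles[idx]
    tau = estimate_delay(
        series, max_lag=max(2, min(len(cycle) - 2, int(series.sampling_rate // 2)))
    )
    tau = min(tau, max(1, len(cycle) // 4))  # keep the projection within the cycle
    traj = embed(cycle.values, EmbeddingParams(tau=tau, m=2))
    return render_mcdm(traj, cycle, image_size=image_size, class_label=class_label)


def stage_render(config: PipelineConfig, out: Path, entries: Sequence[dict]) -> list[MCDMImage]:
    cfg = config.render
    img_dir = _ensure_dir(out / "images")
    images, manifest = [], []
    for entry in entries:
        image = render_record(
            entry["series"], entry["fiducials"], entry["subject_id"],
            entry["class_label"], (cfg.height, cfg.width), cfg.cycle_index,
        )
        path = img_dir / f"{entry['subject_id']}_orig.png"
        save_png(image, path)
        manifest.append({
            "path": str(path.relative_to(out)),
            "subject_id": image.subject_id,
            "class_label": image.class_label,
            "cycle_index": image.cycle_index,
            "transform": image.transform,
            **meta_for(config),
        })
        images.append(image)
    write_manifest(manifest, out / "manifest_originals.jsonl")
    logger.info("render: %d original images", len(images))
    return images


def stage_augment(
    config: PipelineConfig, out: Path, images: Sequence[MCDMImage]
) -> list[MCDMImage]:
    cfg = config.augment
    augmented = augment_dataset(
        images, expansion_factor=cfg.expansion_factor,
        seed=config.seed, families=tuple(cfg.families),
    )
    img_dir = _ensure_dir(out / "images")
    manifest = []
    for k, image in enumerate(augmented):
        path = img_dir / f"{image.subject_id}_aug{k % cfg.expansion_factor}_{image.transform['family']}.png"
        save_png(image, path)
        manifest.append({
            "path": str(path.relative_to(out)),
            "subject_id": image.subject_id,
            "class_label": image.class_label,
            "cycle_index": image.cycle_index,
            "transform": image.transform,
            **meta_for(config),
        })
    write_manifest(manifest, out / "manifest_augmented.jsonl")
    logger.info("augment: %d augmented images", len(augmented))
    return augmented


def _features_for(images: Sequence[MCDMImage], config: PipelineConfig):
    fcfg = config.features
    hog_cfg = HOGConfig(cell=(fcfg.hog_cell, fcfg.hog_cell),
                        block=(fcfg.hog_block, fcfg.hog_block),
                        n_bins=fcfg.hog_bins)
    lbp_cfg = LBPConfig(p=fcfg.lbp_p, r=fcfg.lbp_r)
    return [extract_features(img, hog_cfg, lbp_cfg) for img in images]


def stage_train_evaluate(
    config: PipelineConfig, out: Path, originals: Sequence[MCDMImage]
) -> dict:
    """Split, augment per protocol, train the forest and evaluate."""
    ccfg = config.classify
    manifest = [
        {"subject_id": img.subject_id, "class_label": img.class_label}
        for img in originals
    ]
    if ccfg.augment_before_split:
        dataset = stage_augment(config, out, originals)
        dataset_manifest = [
            {"subject_id": img.subject_id, "class_label": img.class_label}
            for img in dataset
        ]
        split = subject_split(dataset_manifest, ccfg.test_fraction, seed=config.seed)
        train_images = [dataset[i] for i in split.train_indices]
        test_images = [dataset[i] for i in split.test_indices]
    else:
        split = subject_split(manifest, ccfg.test_fraction, seed=config.seed)
        train_originals = [originals[i] for i in split.train_indices]
        augmented = stage_augment(config, out, train_originals)
        train_images = list(train_originals) + augmented
        test_images = [originals[i] for i in split.test_indices]

    train_features = _features_for(train_images, config)
    test_features = _features_for(test_images, config)
    train_labels = [img.class_label for img in train_images]
    test_labels = [img.class_label for img in test_images]

    model = train_rf(train_features, train_labels, grid=ccfg.grid,
                     seed=config.seed, cv=ccfg.cv)
    pred_labels, scores = predict_batch(model, test_features)
    report = evaluate(pred_labels, scores, test_labels)

    layout = (train_features[0].hog_length, train_features[0].lbp_length)
    top = feature_importance(model, layout)[:20]

    import joblib

    joblib.dump(model, out / "model.joblib")
    split_record = {
        "train_subjects": sorted(split.train_subjects),
        "test_subjects": sorted(split.test_subjects),
        "n_train_images": len(train_images),
        "n_test_images": len(test_images),
        "protocol": "augment-before-split" if ccfg.augment_before_split
                    else "augment-after-split",
        "_meta": meta_for(config),
    }
    (out / "split.json").write_text(json.dumps(split_record, indent=2, sort_keys=True))

    result = report.to_dict()
    result["feature_importance_top"] = [
        {"index": i, "domain": d, "importance": v} for i, d, v in top
    ]
    result["_meta"] = meta_for(config)
    (out / "eval_report.json").write_text(
        json.dumps(result, indent=2, sort_keys=True)
    )
    with open(out / "roc.csv", "w") as fh:
        fh.write(f"# config_hash={config.config_hash}\n# seed={config.seed}\n")
        fh.write("fpr,tpr\n")
        for fpr, tpr in report.roc_points:
            fh.write(f"{fpr:.6f},{tpr:.6f}\n")
    logger.info("evaluate: accuracy %.2f%%", report.accuracy)
    return result


def run_pipeline(config: PipelineConfig, stages: Sequence[str] | None = None) -> dict:
    """Run the requested stages in order; returns the final artifacts.

    ``stages`` defaults to the full pipeline.  Later stages load their
    inputs from earlier in-memory results when available, otherwise from
    the artifacts on disk.
    """
    stages = tuple(stages or STAGES)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stage(s) {sorted(unknown)}")
    out = _ensure_dir(Path(config.out_dir))
    (out / "config.json").write_text(
        json.dumps({**config.to_dict(), "config_hash": config.config_hash},
                   indent=2, sort_keys=True)
    )

    results: dict = {}
    records = entries = originals = None
    if "simulate" in stages:
        records = stage_simulate(config, out)
    if "preprocess" in stages or "chaos" in stages or "render" in stages:
        entries = stage_preprocess(config, out, records)
    if "chaos" in stages:
        results["chaos"] = stage_chaos(config, out, entries)
    if "render" in stages or "train" in stages or "evaluate" in stages:
        if entries is None:
            entries = stage_preprocess(config, out, None)
        originals = stage_render(config, out, entries)
    if "train" in stages or "evaluate" in stages:
        results["evaluation"] = stage_train_evaluate(config, out, originals)
    elif "augment" in stages and originals is not None:
        results["augmented"] = len(stage_augment(config, out, originals))
    return results
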