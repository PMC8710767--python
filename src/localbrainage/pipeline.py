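"""End-to-end study pipeline: simulate -> train -> test -> reliability -> groups.

Reproduces the four study-design stages on synthetic phantoms (or, through
the same stage functions, on user-supplied data):

1. train the U-Net on a healthy cohort with an 80/20 participant split;
2. evaluate test-set accuracy (MAE and Pearson r) at global and voxel level;
3. compute voxel-level ICC reliability maps from repeat scans, within- and
   between-scanner;
4. de-bias voxel deltas with the binned calibration and compare groups at
   voxel, ROI and global scope with age-matched (>60 year) controls,
   Bonferroni-corrected.

Every run writes a manifest (config snapshot, seeds, software version,
input checksums, stage timestamps) and JSON-lines logs; stage outputs are
pure functions of (inputs, config, seed).
"""

from __future__ import annotations

import copy
import datetime as _dt
import hashlib
import json
import time
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__, bias, phantom, stats, training, volume_io as vio
from .unet import ArchitectureSpec, build_network, save_checkpoint

__all__ = ["DEFAULT_CONFIG", "load_config", "run_pipeline", "PipelineError"]


DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "phantom": {
        "grid_side": 48,
        "n_healthy": 80,
        "n_calibration": 20,
        "n_test": 10,
        "noise_sd": 0.03,
        "smoothing_fwhm": 2.0,
        "beta_max": 0.008,
        "effect_field_spec": "anterior_step",
    },
    "network": {"base_channels": 2, "seed": 0, "init": "local", "output_scale": 100.0},
    "train": {
        "learning_rate": 0.01,
        "hidden_lr_factor": 0.05,
        "lr_final_factor": 1.0,
        "max_iterations": 250,
        "minibatch": 4,
        "grad_splits": 4,
        "split_fraction": 0.8,
        "eval_every": 65,
        "eval_blocks": 8,
        "plateau_patience": 10,
        "plateau_tol": 1e-3,
        # readout polish: frozen-feature phase with cheap iterations
        "polish_iterations": 700,
        "polish_lr": 0.01,
        "polish_minibatch": 32,
        "polish_lr_final_factor": 0.2,
    },
    "reliability": {
        "n_participants": 8,
        "n_repeats": 2,
        "within_noise_sd": 0.01,
        "between_scanner_shift": 0.03,
    },
    "clinical": {
        "n_controls": 14,
        "n_patients": 14,
        "group": "AD",
        "delta_years": 5.0,
        "effect_roi_labels": None,  # default: an anterior (high-beta) ROI
        "age_range": [55.0, 90.0],
        "min_control_age": 60.0,
    },
}


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name for the manifest."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def _deep_update(base: dict, extra: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in (extra or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_update(out[k], v)
        else:
            out[k] = v
    return out


def load_config(source=None) -> dict:
    """Merge a YAML file / dict over the desk-scale defaults."""
    if source is None:
        extra = {}
    elif isinstance(source, dict):
        extra = source
    else:
        with open(source) as fh:
            extra = yaml.safe_load(fh) or {}
    return _deep_update(DEFAULT_CONFIG, extra)


class _JsonlLogger:
    def __init__(self, path: Path):
        self.path = path
        path.parent.mkdir(parents=True, exist_ok=True)
        self._fh = open(path, "a")

    def log(self, stage: str, event: str, **fields) -> None:
        rec = {"ts": _dt.datetime.now().isoformat(), "stage": stage, "event": event}
        rec.update(fields)
        self._fh.write(json.dumps(rec, default=str) + "\n")
        self._fh.flush()

    def close(self) -> None:
        self._fh.close()


def _checksum(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()


def _global_value(map3d: np.ndarray) -> float:
    """Whole-brain value of a map: mean over finite (in-mask) voxels."""
    m = np.asarray(map3d, dtype=float)
    return float(np.nanmean(m))


def _default_effect_roi(truth: phantom.PhantomTruth) -> int:
    """ROI with the highest mean true atrophy rate (anterior, decodable)."""
    best, best_val = None, -np.inf
    for label in truth.atlas.label_ids():
        sel = truth.atlas.labels == label
        val = truth.beta_map[sel].mean()
        if val > best_val:
            best, best_val = label, val
    return int(best)


def run_pipeline(config=None, out_dir="pipeline_out") -> dict:
    """Execute all four stages; returns the manifest dict.

    Artifacts land in ``{out_dir}/{maps,stats,checkpoints,logs}``; any stage
    failure raises :class:`PipelineError` naming the stage after writing the
    manifest collected so far.
    """
    cfg = load_config(config)
    out = Path(out_dir)
    for sub in ("maps", "stats", "checkpoints", "logs"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    logger = _JsonlLogger(out / "logs" / "pipeline.jsonl")
    manifest: dict[str, Any] = {
        "config": cfg,
        "seed": cfg["seed"],
        "version": __version__,
        "checksums": {"config": _checksum(cfg)},
        "stages": {},
    }
    try:
        manifest.update(_run_stages(cfg, out, logger, manifest))
    except PipelineError:
        raise
    except Exception as exc:  # halt with the stage name, per the contract
        open_stages = [s for s, d in manifest["stages"].items() if "finished" not in d]
        raise PipelineError(open_stages[-1] if open_stages else "setup", str(exc)) from exc
    finally:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        logger.close()
    return manifest


def _run_stages(cfg, out: Path, logger: _JsonlLogger, manifest: dict) -> dict:
    seed = int(cfg["seed"])
    pc = cfg["phantom"]

    def stamp(stage):
        manifest["stages"].setdefault(stage, {})["finished"] = _dt.datetime.now().isoformat()

    def begin(stage):
        manifest["stages"][stage] = {"started": _dt.datetime.now().isoformat()}
        logger.log(stage, "start")

    # ---- stage 1: simulate healthy cohort and train ------------------------
    t0 = time.time()
    begin("train")
    healthy_cfg = phantom.PhantomConfig(
        grid_side=pc["grid_side"],
        n_participants=pc["n_healthy"],
        noise_sd=pc["noise_sd"],
        smoothing_fwhm=pc["smoothing_fwhm"],
        beta_max=pc["beta_max"],
        effect_field_spec=pc["effect_field_spec"],
        seed=seed,
    )
    volumes, records, truth = phantom.generate_cohort(healthy_cfg)
    manifest["checksums"]["healthy_ages"] = _checksum([r.age_years for r in records])
    model_records = records
    train_ids, val_ids = training.split_cohort(
        model_records, cfg["train"]["split_fraction"], seed
    )
    by_id = {r.id: i for i, r in enumerate(records)}
    tr = [by_id[i] for i in train_ids]
    va = [by_id[i] for i in val_ids]
    tcfg = training.TrainConfig(
        learning_rate=cfg["train"]["learning_rate"],
        hidden_lr_factor=cfg["train"].get("hidden_lr_factor", 1.0),
        lr_final_factor=cfg["train"].get("lr_final_factor", 1.0),
        max_iterations=cfg["train"]["max_iterations"],
        minibatch=cfg["train"]["minibatch"],
        grad_splits=cfg["train"]["grad_splits"],
        split_fraction=cfg["train"]["split_fraction"],
        eval_every=cfg["train"]["eval_every"],
        eval_blocks=cfg["train"]["eval_blocks"],
        plateau_patience=cfg["train"]["plateau_patience"],
        plateau_tol=cfg["train"]["plateau_tol"],
        seed=seed,
    )
    mean_train_age = float(np.mean([records[i].age_years for i in tr]))
    net = build_network(
        ArchitectureSpec(base_channels=cfg["network"]["base_channels"]),
        seed=cfg["network"]["seed"],
        output_bias=mean_train_age,
        output_scale=cfg["network"].get("output_scale", 1.0),
        init=cfg["network"].get("init", "he"),
    )
    train_sampler = training.CohortBlockSampler(
        [volumes[i] for i in tr], [records[i] for i in tr], truth.mask
    )
    val_sampler = training.CohortBlockSampler(
        [volumes[i] for i in va], [records[i] for i in va], truth.mask
    )
    net, history = training.train(net, train_sampler, tcfg, val_sampler)
    polish_iters = int(cfg["train"].get("polish_iterations", 0))
    if polish_iters:
        pcfg = training.TrainConfig(
            learning_rate=cfg["train"].get("polish_lr", cfg["train"]["learning_rate"]),
            hidden_lr_factor=0.0,
            lr_final_factor=cfg["train"].get("polish_lr_final_factor", 1.0),
            max_iterations=polish_iters,
            minibatch=cfg["train"].get("polish_minibatch", cfg["train"]["minibatch"]),
            grad_splits=cfg["train"]["grad_splits"],
            eval_every=cfg["train"]["eval_every"],
            eval_blocks=cfg["train"]["eval_blocks"],
            plateau_patience=cfg["train"]["plateau_patience"],
            plateau_tol=cfg["train"]["plateau_tol"],
            seed=seed + 11,
        )
        net, polish_history = training.train(net, train_sampler, pcfg, val_sampler)
        for key in history:
            history[key] = list(history[key]) + list(polish_history[key])
    save_checkpoint(net, out / "checkpoints" / "model.npz")
    pd.DataFrame(
        {
            "iteration": history["iteration"],
            "train_loss": history["train_loss"],
            "alpha_1": [a[0] for a in history["alpha"]],
            "alpha_2": [a[1] for a in history["alpha"]],
        }
    ).to_csv(out / "stats" / "loss_history.csv", index=False)
    logger.log("train", "done", seconds=time.time() - t0, iterations=len(history["iteration"]))
    stamp("train")

    # ---- stage 2: held-out accuracy ---------------------------------------
    t0 = time.time()
    begin("test")
    test_cfg = phantom.PhantomConfig(
        grid_side=pc["grid_side"],
        n_participants=pc["n_test"],
        noise_sd=pc["noise_sd"],
        smoothing_fwhm=pc["smoothing_fwhm"],
        beta_max=pc["beta_max"],
        effect_field_spec=pc["effect_field_spec"],
        seed=seed + 1,
    )
    test_vols, test_recs, _ = phantom.generate_cohort(test_cfg)
    plan = train_sampler.plan
    test_maps = [training.predict_map(net, v, truth.mask, plan) for v in test_vols]
    for m, r in zip(test_maps, test_recs):
        vio.save_map(m, truth.affine, out / "maps" / f"{r.id}_predicted_age.nii.gz")
    ages = np.array([r.age_years for r in test_recs])
    global_pred = np.array([_global_value(m) for m in test_maps])
    stack = np.asarray(test_maps, dtype=float)[:, truth.mask]
    voxel_mae = np.abs(stack - ages[:, None]).mean(axis=0)
    test_metrics = {
        "n_test": len(test_recs),
        "global_mae": float(np.abs(global_pred - ages).mean()),
        "global_r": stats.pearson_r(global_pred, ages),
        "voxel_mae_mean": float(voxel_mae.mean()),
        "voxel_mae_median": float(np.median(voxel_mae)),
    }
    mae_map = np.full(truth.mask.shape, np.nan)
    mae_map[truth.mask] = voxel_mae
    vio.save_map(mae_map, truth.affine, out / "maps" / "voxel_mae.nii.gz")
    pd.DataFrame(
        {"participant_id": [r.id for r in test_recs], "age_years": ages, "global_pred": global_pred}
    ).to_csv(out / "stats" / "test_global.csv", index=False)
    (out / "stats" / "test_metrics.json").write_text(json.dumps(test_metrics, indent=2))
    logger.log("test", "done", seconds=time.time() - t0, **test_metrics)
    stamp("test")

    # ---- stage 3: reliability ---------------------------------------------
    t0 = time.time()
    begin("reliability")
    rc = cfg["reliability"]
    sub = (test_vols[: rc["n_participants"]], test_recs[: rc["n_participants"]], truth)
    icc_medians = {}
    for label, shift in (("within_scanner", 0.0), ("between_scanner", rc["between_scanner_shift"])):
        repeats = phantom.generate_repeat_scans(
            sub,
            n_repeats=rc["n_repeats"],
            within_noise_sd=rc["within_noise_sd"],
            between_scanner_shift=shift,
            smoothing_fwhm=pc["smoothing_fwhm"],
            seed=seed + 2,
        )
        rater_maps = [
            np.asarray([training.predict_map(net, v, truth.mask, plan) for v in rep])
            for rep in repeats
        ]
        icc = stats.icc_map(rater_maps, truth.mask)
        vio.save_map(icc, truth.affine, out / "maps" / f"icc_{label}.nii.gz")
        icc_medians[label] = float(np.nanmedian(icc[truth.mask]))
    (out / "stats" / "reliability.json").write_text(json.dumps(icc_medians, indent=2))
    logger.log("reliability", "done", seconds=time.time() - t0, **icc_medians)
    stamp("reliability")

    # ---- stage 4: de-biased group comparisons -----------------------------
    t0 = time.time()
    begin("groups")
    cc = cfg["clinical"]
    calib_cfg = phantom.PhantomConfig(
        grid_side=pc["grid_side"],
        n_participants=pc["n_calibration"],
        noise_sd=pc["noise_sd"],
        smoothing_fwhm=pc["smoothing_fwhm"],
        beta_max=pc["beta_max"],
        effect_field_spec=pc["effect_field_spec"],
        age_sampling="grid",
        seed=seed + 7,
    )
    calib_vols, calib_recs, _ = phantom.generate_cohort(calib_cfg)
    calib_maps = [
        training.predict_map(net, v, truth.mask, plan) for v in calib_vols
    ]
    calib_ages = [r.age_years for r in calib_recs]
    deltas = [m - a for m, a in zip(calib_maps, calib_ages)]
    calibration = bias.fit_voxel_bins(deltas, calib_ages)
    bias.save_calibration(calibration, out / "checkpoints" / "calibration", truth.affine)

    roi_labels = cc["effect_roi_labels"] or [_default_effect_roi(truth)]
    group = cc["group"]
    clin_cfg = phantom.PhantomConfig(
        grid_side=pc["grid_side"],
        n_participants=cc["n_controls"] + cc["n_patients"],
        age_range=tuple(cc["age_range"]),
        noise_sd=pc["noise_sd"],
        smoothing_fwhm=pc["smoothing_fwhm"],
        beta_max=pc["beta_max"],
        effect_field_spec=pc["effect_field_spec"],
        group_sizes={group: cc["n_patients"]},
        group_effects={
            group: phantom.GroupEffect(tuple(int(l) for l in roi_labels), cc["delta_years"])
        },
        seed=seed + 3,
    )
    clin_vols, clin_recs, clin_truth = phantom.generate_cohort(clin_cfg)
    hc = [
        (v, r)
        for v, r in zip(clin_vols, clin_recs)
        if r.group == "HC"
    ]
    matched_ids = {r.id for r in stats.age_matched_subset([r for _, r in hc], cc["min_control_age"])}
    cohort = [
        (v, r)
        for v, r in zip(clin_vols, clin_recs)
        if r.group != "HC" or r.id in matched_ids
    ]
    adj_by_group: dict[str, list[np.ndarray]] = {}
    recs_by_group: dict[str, list] = {}
    for v, r in cohort:
        pmap = training.predict_map(net, v, truth.mask, plan)
        adj = bias.apply_voxel_debias(pmap - r.age_years, r.age_years, calibration)
        adj[~truth.mask] = np.nan
        adj_by_group.setdefault(r.group, []).append(adj)
        recs_by_group.setdefault(r.group, []).append(r)

    # global scope: per-participant mean adjusted delta
    global_vals = {g: [_global_value(m) for m in maps] for g, maps in adj_by_group.items()}
    global_cmp = stats.compare_groups(global_vals, scope="global")
    # voxel scope: pooled in-mask voxel populations
    voxel_vals = {
        g: np.concatenate([m[truth.mask] for m in maps]) for g, maps in adj_by_group.items()
    }
    voxel_cmp = stats.compare_groups(voxel_vals, scope="voxel")
    # ROI scope: per-participant per-ROI mean adjusted delta
    roi_rows = []
    for g, maps in adj_by_group.items():
        for m, r in zip(maps, recs_by_group[g]):
            df = stats.roi_aggregate(m + r.age_years, truth.atlas, r, clin_cfg.voxel_size_mm)
            df["group"] = g
            roi_rows.append(df)
    roi_df = pd.concat(roi_rows, ignore_index=True)
    n_rois = len(truth.atlas.label_ids())
    roi_cmps = []
    for label, sub_df in roi_df.groupby("roi_label"):
        vals = {g: gdf["brain_pad"].to_numpy() for g, gdf in sub_df.groupby("group")}
        cmp = stats.compare_groups(vals, scope="roi", n_comparisons=n_rois)
        cmp.insert(1, "roi_label", label)
        roi_cmps.append(cmp)
    roi_cmp = pd.concat(roi_cmps, ignore_index=True)

    groups_sorted = sorted(adj_by_group)
    if len(groups_sorted) == 2:
        ga, gb = groups_sorted
        tmaps = stats.welch_t_maps(
            [m for m in adj_by_group[ga]], [m for m in adj_by_group[gb]], truth.mask
        )
        for name in ("t", "d", "p_adj"):
            vio.save_map(
                tmaps[name].astype(np.float32),
                truth.affine,
                out / "maps" / f"welch_{ga}_vs_{gb}_{name}.nii.gz",
            )
    global_cmp.to_csv(out / "stats" / "group_comparison_global.csv", index=False)
    voxel_cmp.to_csv(out / "stats" / "group_comparison_voxel.csv", index=False)
    roi_cmp.to_csv(out / "stats" / "group_comparison_roi.csv", index=False)
    logger.log("groups", "done", seconds=time.time() - t0, effect_roi=roi_labels)
    stamp("groups")

    return {
        "test_metrics": test_metrics,
        "icc_medians": icc_medians,
        "effect_roi_labels": [int(l) for l in roi_labels],
    }
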