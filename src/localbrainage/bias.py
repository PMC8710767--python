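"""Age-bias adjustment of brain-age deltas.

Brain-age models systematically over-predict young and under-predict old
participants ("regression dilution"), so raw deltas (predicted minus
chronological age) correlate with age.  Two removal schemes are provided:

* a global straight-line fit of delta on chronological age (or on predicted
  age), subtracted as ``delta - (slope * covariate + intercept)``; and
* the voxel-level binned calibration: a held-out calibration cohort is
  binned by chronological age ([18, 25) first, then 5-year intervals) and
  the per-bin, per-voxel mean delta is subtracted from new participants'
  delta maps.

Calibration participants must be disjoint from the train/validation/test
sets; the calibration object stores bin edges and per-bin counts for
provenance and serialises as per-bin NIfTI mean-delta volumes plus a JSON
sidecar.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "BinCalibration",
    "GlobalBiasFit",
    "default_bin_edges",
    "bin_index",
    "fit_voxel_bins",
    "apply_voxel_debias",
    "fit_global_linear",
    "apply_global_debias",
    "save_calibration",
    "load_calibration",
]


def default_bin_edges(age_max: float = 90.0) -> np.ndarray:
    """[18, 25) then 5-year intervals up to at least ``age_max``."""
    edges = [18.0, 25.0]
    while edges[-1] < age_max:
        edges.append(edges[-1] + 5.0)
    return np.asarray(edges)


def bin_index(age: float, edges: np.ndarray, clamp: bool = True) -> int:
    """Bin of ``age`` under half-open [lo, hi) bins, last bin closed.

    With ``clamp`` (the default) out-of-range ages fall into the nearest
    boundary bin — refusing would break clinical cohorts older than the
    healthy calibration range.
    """
    edges = np.asarray(edges, dtype=float)
    n_bins = len(edges) - 1
    if age < edges[0] or age > edges[-1]:
        if not clamp:
            raise ValueError(f"age {age} outside calibration range [{edges[0]}, {edges[-1]}]")
        return 0 if age < edges[0] else n_bins - 1
    if age == edges[-1]:  # final bin closed at the calibration maximum
        return n_bins - 1
    return int(np.searchsorted(edges, age, side="right") - 1)


@dataclass
class BinCalibration:
    """Per-voxel, per-age-bin mean brain-age delta."""

    edges: np.ndarray  # (n_bins + 1,)
    mean_delta: dict[int, np.ndarray]  # occupied bin -> 3D map
    counts: dict[int, int]

    def __post_init__(self) -> None:
        if set(self.mean_delta) != set(self.counts):
            raise ValueError("mean_delta and counts must cover the same bins")
        if any(c < 1 for c in self.counts.values()):
            raise ValueError("every stored bin needs count >= 1")

    def nearest_occupied(self, b: int) -> int:
        occupied = sorted(self.mean_delta)
        return min(occupied, key=lambda o: (abs(o - b), o))


@dataclass(frozen=True)
class GlobalBiasFit:
    """Straight-line fit of delta on age (or on predicted age)."""

    slope: float
    intercept: float
    mode: str  # "on_age" | "on_predicted"


def fit_voxel_bins(
    delta_maps: Sequence[np.ndarray],
    ages: Sequence[float],
    edges: np.ndarray | None = None,
) -> BinCalibration:
    """Average calibration delta maps within chronological-age bins.

    ``delta_maps`` are voxelwise deltas of the calibration participants
    (NaN allowed outside the mask, averaged as-is); ``ages`` align with them.
    """
    if len(delta_maps) == 0:
        raise ValueError("empty calibration set")
    if len(delta_maps) != len(ages):
        raise ValueError("delta_maps and ages must align")
    if edges is None:
        edges = default_bin_edges(max(90.0, float(np.max(ages))))
    members: dict[int, list[int]] = {}
    for i, age in enumerate(ages):
        members.setdefault(bin_index(float(age), edges), []).append(i)
    stack = np.asarray(delta_maps, dtype=np.float64)
    mean_delta = {b: stack[idx].mean(axis=0) for b, idx in members.items()}
    counts = {b: len(idx) for b, idx in members.items()}
    return BinCalibration(edges=np.asarray(edges, dtype=float), mean_delta=mean_delta, counts=counts)


def apply_voxel_debias(
    delta_map: np.ndarray,
    age: float,
    calibration: BinCalibration,
    clamp: bool = True,
) -> np.ndarray:
    """Subtract the age bin's per-voxel mean delta from one delta map."""
    b = bin_index(float(age), calibration.edges, clamp=clamp)
    if b not in calibration.mean_delta:
        if not clamp:
            raise ValueError(f"no calibration data for bin {b} (age {age})")
        b = calibration.nearest_occupied(b)
    return np.asarray(delta_map, dtype=np.float64) - calibration.mean_delta[b]


def fit_global_linear(
    deltas: Sequence[float],
    covariate: Sequence[float],
    mode: str = "on_age",
) -> GlobalBiasFit:
    """Least-squares line of global deltas on age or on predicted age."""
    if mode not in ("on_age", "on_predicted"):
        raise ValueError(f"mode must be 'on_age' or 'on_predicted', got {mode!r}")
    deltas = np.asarray(deltas, dtype=float)
    covariate = np.asarray(covariate, dtype=float)
    if deltas.size < 3:
        raise ValueError("need >= 3 points for a global bias fit")
    if np.var(covariate) == 0:
        raise ValueError("zero-variance covariate")
    slope, intercept = np.polyfit(covariate, deltas, deg=1)
    return GlobalBiasFit(slope=float(slope), intercept=float(intercept), mode=mode)


def apply_global_debias(deltas, covariate, fit: GlobalBiasFit) -> np.ndarray:
    """Adjusted delta = delta - (slope * covariate + intercept)."""
    deltas = np.asarray(deltas, dtype=float)
    covariate = np.asarray(covariate, dtype=float)
    return deltas - (fit.slope * covariate + fit.intercept)


# ---------------------------------------------------------------------------
# serialisation


def save_calibration(calibration: BinCalibration, out_dir, affine=None) -> Path:
    from .volume_io import default_affine, save_map

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    affine = default_affine() if affine is None else affine
    for b, vol in calibration.mean_delta.items():
        save_map(vol.astype(np.float32), affine, out_dir / f"bin{b:02d}_mean_delta.nii.gz")
    sidecar = {
        "edges": calibration.edges.tolist(),
        "counts": {str(b): c for b, c in calibration.counts.items()},
    }
    (out_dir / "calibration.json").write_text(json.dumps(sidecar, indent=2))
    return out_dir


def load_calibration(cal_dir) -> BinCalibration:
    from .volume_io import load_map

    cal_dir = Path(cal_dir)
    sidecar = json.loads((cal_dir / "calibration.json").read_text())
    counts = {int(b): int(c) for b, c in sidecar["counts"].items()}
    mean_delta = {
        b: load_map(cal_dir / f"bin{b:02d}_mean_delta.nii.gz")[0].astype(np.float64)
        for b in counts
    }
    return BinCalibration(
        edges=np.asarray(sidecar["edges"], dtype=float),
        mean_delta=mean_delta,
        counts=counts,
    )
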