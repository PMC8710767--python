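"""Cutting overlapping input blocks from whole volumes and stitching back.

The network consumes two-channel 52^3 input blocks and emits the central
12^3 of predictions, so input windows overlap by 40 voxels while the 12^3
output regions tile the mask on a stride-12 lattice.  Output regions overlap
only where the lattice is clipped at the volume boundary; stitching averages
there and leaves every interior voxel predicted exactly once.  Input context
reaching past the volume is zero-padded (preprocessed tissue maps are zero
outside the head, so the padding is distribution-consistent).  Blocks whose
output region contains no in-mask voxel are skipped.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterator, Mapping

import numpy as np

from .volume_io import ParticipantRecord, VolumePair

__all__ = ["BlockSample", "BlockGridPlan", "plan_blocks", "extract", "extract_targets", "stitch"]


@dataclass
class BlockSample:
    """One training/inference sample: 2x52^3 context, 12^3 constant-age target."""

    input_block: np.ndarray  # (in_side, in_side, in_side, 2) float32
    target_age: float
    output_origin: tuple[int, int, int]
    participant_id: str


@dataclass
class BlockGridPlan:
    """Stride-``output_side`` lattice of output origins covering a mask."""

    output_origins: list[tuple[int, int, int]]
    volume_shape: tuple[int, int, int]
    input_side: int = 52
    output_side: int = 12

    @property
    def margin(self) -> int:
        """Input context margin per side."""
        return (self.input_side - self.output_side) // 2

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {
                "output_origins": [list(o) for o in self.output_origins],
                "volume_shape": list(self.volume_shape),
                "input_side": self.input_side,
                "output_side": self.output_side,
            }
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload

    @classmethod
    def from_json(cls, source) -> "BlockGridPlan":
        if not str(source).lstrip().startswith("{"):
            with open(source) as fh:
                source = fh.read()
        d = json.loads(source)
        return cls(
            output_origins=[tuple(o) for o in d["output_origins"]],
            volume_shape=tuple(d["volume_shape"]),
            input_side=d["input_side"],
            output_side=d["output_side"],
        )


def _axis_origins(lo: int, hi: int, dim: int, side: int) -> list[int]:
    """Stride-``side`` origins covering [lo, hi), clipped into the volume."""
    origins = []
    pos = lo
    while pos < hi:
        origins.append(max(0, min(pos, dim - side)))
        pos += side
    return sorted(set(origins))


def plan_blocks(mask: np.ndarray, input_side: int = 52, output_side: int = 12) -> BlockGridPlan:
    """Plan output origins so every in-mask voxel lies in >= 1 output region.

    Origins sit on a stride-``output_side`` lattice anchored at the mask
    bounding box; the final origin per axis is clipped back inside the volume
    (those clipped regions are where stitching averages).  Empty-output
    blocks are dropped.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("mask is empty; nothing to plan")
    if input_side <= output_side or (input_side - output_side) % 2:
        raise ValueError(
            f"input_side {input_side} and output_side {output_side} must leave an even margin"
        )
    if any(d < output_side for d in mask.shape):
        raise ValueError(f"volume shape {mask.shape} smaller than output side {output_side}")

    bbox = [(int(idx.min()), int(idx.max()) + 1) for idx in np.nonzero(mask)]
    per_axis = [
        _axis_origins(lo, hi, dim, output_side)
        for (lo, hi), dim in zip(bbox, mask.shape)
    ]
    s = output_side
    origins = [
        (i, j, k)
        for i in per_axis[0]
        for j in per_axis[1]
        for k in per_axis[2]
        if mask[i : i + s, j : j + s, k : k + s].any()
    ]
    return BlockGridPlan(
        output_origins=origins,
        volume_shape=tuple(mask.shape),
        input_side=input_side,
        output_side=output_side,
    )


def _extract_window(channels: np.ndarray, origin: tuple[int, int, int], side: int) -> np.ndarray:
    """Zero-padded ``side^3`` window of a channels-last volume."""
    out = np.zeros((side, side, side, channels.shape[-1]), dtype=np.float32)
    src, dst = [], []
    for o, dim in zip(origin, channels.shape[:3]):
        lo, hi = max(o, 0), min(o + side, dim)
        if lo >= hi:
            return out
        src.append(slice(lo, hi))
        dst.append(slice(lo - o, hi - o))
    out[tuple(dst)] = channels[tuple(src)]
    return out


def extract(
    volume_pair: VolumePair, plan: BlockGridPlan, record: ParticipantRecord
) -> Iterator[BlockSample]:
    """Stream the planned input blocks of one participant.

    Every target voxel is filled with the participant's chronological age —
    the constant-block ground truth the network regresses toward.
    """
    if volume_pair.shape != plan.volume_shape:
        raise ValueError(
            f"volume shape {volume_pair.shape} does not match plan {plan.volume_shape}"
        )
    channels = volume_pair.as_channels()
    m = plan.margin
    for origin in plan.output_origins:
        in_origin = tuple(o - m for o in origin)
        yield BlockSample(
            input_block=_extract_window(channels, in_origin, plan.input_side),
            target_age=record.age_years,
            output_origin=origin,
            participant_id=record.id,
        )


def extract_targets(plan: BlockGridPlan, record: ParticipantRecord) -> dict:
    """Constant-age target blocks keyed by origin (round-trip oracle helper)."""
    s = plan.output_side
    return {
        origin: np.full((s, s, s), record.age_years, dtype=np.float32)
        for origin in plan.output_origins
    }


def stitch(
    predicted_blocks: Mapping[tuple[int, int, int], np.ndarray],
    plan: BlockGridPlan,
    mask: np.ndarray,
) -> np.ndarray:
    """Assemble predicted 12^3 blocks into a whole-brain map.

    Voxels covered by several (lattice-clipped) output regions get the mean
    of the overlapping predictions; voxels outside the mask are NaN.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.shape != plan.volume_shape:
        raise ValueError(f"mask shape {mask.shape} does not match plan {plan.volume_shape}")
    missing = [o for o in plan.output_origins if o not in predicted_blocks]
    if missing:
        raise KeyError(f"missing predicted blocks for origins: {missing[:5]}")
    s = plan.output_side
    acc = np.zeros(plan.volume_shape, dtype=np.float64)
    cnt = np.zeros(plan.volume_shape, dtype=np.int32)
    for origin in plan.output_origins:
        block = np.asarray(predicted_blocks[origin])
        if block.shape != (s, s, s):
            raise ValueError(f"block at {origin} has shape {block.shape}, expected {(s,) * 3}")
        sl = tuple(slice(o, o + s) for o in origin)
        acc[sl] += block
        cnt[sl] += 1
    out = np.full(plan.volume_shape, np.nan, dtype=np.float32)
    covered = cnt > 0
    out[covered] = (acc[covered] / cnt[covered]).astype(np.float32)
    out[~mask] = np.nan
    return out
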