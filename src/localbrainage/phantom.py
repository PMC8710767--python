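"""Synthetic two-channel brain phantoms with a known, spatially varying age effect.

The generator stands in for preprocessed structural MRI: each participant is a
pair of co-registered grey-matter (GM) and white-matter (WM) volume maps whose
local intensity declines linearly with age at a voxel-specific rate
``beta(v)`` (intensity-units per year).  A superellipsoidal brain mask supplies
a cortex/white-matter analogue (GM = outer shell, WM = core), a block
partition of the mask plays the role of an ROI atlas, and named groups can
receive extra, ROI-confined atrophy expressed in years-equivalent units.

The generating model for one participant of age ``a`` is::

    I(v) = S[ base(v) - beta(v) * (a - age_min) + g(v) + eps(v) ] * mask(v)

where ``S`` is a Gaussian smoothing operator (FWHM in voxels), ``g`` the
group-specific atrophy field and ``eps`` i.i.d. Gaussian noise.  Because ``S``
is linear, the *effective* (post-smoothing, masked) ``base`` and ``beta``
fields are what a per-voxel regression of intensity on age recovers; those
effective fields are what :class:`PhantomTruth` stores.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .volume_io import ParticipantRecord, RoiAtlas, VolumePair, default_affine

__all__ = [
    "PhantomConfig",
    "PhantomTruth",
    "GroupEffect",
    "generate_cohort",
    "generate_repeat_scans",
    "save_cohort",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

#: absolute age at which a phantom shows its base intensity; intensity is
#: base - beta * (age - REFERENCE_AGE) regardless of the cohort's sampled
#: age range, so cohorts with different ranges live on one common scale
REFERENCE_AGE = 18.0

#: Named spatial patterns for the per-voxel atrophy rate field.
EFFECT_FIELDS = ("anterior_step", "anterior_gradient", "uniform", "zero")


@dataclass(frozen=True)
class GroupEffect:
    """Extra atrophy for one clinical group, confined to atlas ROIs.

    ``delta_years`` is expressed in years-equivalent units: affected voxels
    lose an additional ``beta(v) * delta_years`` of intensity, i.e. the group
    looks ``delta_years`` older wherever age is locally decodable.
    """

    roi_labels: tuple[int, ...]
    delta_years: float


@dataclass(frozen=True)
class PhantomConfig:
    """Study conditions for one synthetic cohort."""

    grid_side: int = 48
    n_participants: int = 100
    age_range: tuple[float, float] = (18.0, 90.0)
    effect_field_spec: str = "anterior_step"
    beta_max: float = 0.008  # intensity-units per year at the anterior pole
    noise_sd: float = 0.03
    smoothing_fwhm: float = 2.0  # voxels; ~= 4 mm smoothing at 1.5 mm voxels
    group_effects: Mapping[str, GroupEffect] = field(default_factory=dict)
    group_sizes: Mapping[str, int] = field(default_factory=dict)
    #: "uniform" draws ages randomly; "grid" spaces them evenly over
    #: age_range (deterministic) - the desk-scale stand-in for a large
    #: random calibration cohort, guaranteeing every age bin is populated
    age_sampling: str = "uniform"
    voxel_size_mm: float = 1.5
    atlas_cells: int = 3  # block partition: atlas_cells^3 macro-cells
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_side < 32:
            raise ValueError(f"grid_side must be >= 32, got {self.grid_side}")
        lo, hi = self.age_range
        if not (18.0 <= lo < hi <= 90.0):
            raise ValueError(f"age_range must lie within [18, 90], got {self.age_range}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.age_sampling not in ("uniform", "grid"):
            raise ValueError(f"unknown age_sampling {self.age_sampling!r}")
        if self.effect_field_spec not in EFFECT_FIELDS:
            raise ValueError(
                f"unknown effect_field_spec {self.effect_field_spec!r}; "
                f"choose one of {EFFECT_FIELDS}"
            )
        extra = set(self.group_effects) - set(self.group_sizes) - {"HC"}
        if extra - {g for g in self.group_effects if self.group_sizes.get(g)}:
            # group effects without members are legal (e.g. reused configs);
            # sizes without effects are legal too (null groups).
            pass


@dataclass
class PhantomTruth:
    """Effective (post-smoothing, masked) generating fields of a cohort.

    ``beta_map`` and ``base_map`` refer to the summed GM+WM channel; the
    per-channel fields used to rebuild noise-free signals live in
    ``channel_base`` / ``channel_beta`` (shape ``(2, n, n, n)``).
    """

    beta_map: np.ndarray
    base_map: np.ndarray
    mask: np.ndarray
    atlas: RoiAtlas
    affine: np.ndarray
    channel_base: np.ndarray
    channel_beta: np.ndarray
    group_effect_maps: dict[str, np.ndarray]
    channel_group_effects: dict[str, np.ndarray]
    age_min: float


# ---------------------------------------------------------------------------
# geometry


def _superellipsoid(grid_side: int, semi_axis_frac: float = 0.37, power: float = 4.0):
    n = grid_side
    c = (n - 1) / 2.0
    ax = semi_axis_frac * n
    coords = (np.arange(n) - c) / ax
    X, Y, Z = np.meshgrid(coords, coords, coords, indexing="ij")
    r = (np.abs(X) ** power + np.abs(Y) ** power + np.abs(Z) ** power) ** (1.0 / power)
    return r


def make_mask_and_supports(grid_side: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Brain mask plus disjoint GM (outer shell) and WM (core) supports."""
    r = _superellipsoid(grid_side)
    mask = r <= 1.0
    wm = r <= 0.55
    gm = mask & ~wm
    if not mask.any():
        raise ValueError("degenerate (empty) brain mask")
    return mask, gm, wm


def make_block_atlas(mask: np.ndarray, cells: int = 3) -> RoiAtlas:
    """Partition the mask into up to ``cells**3`` contiguous macro-block ROIs."""
    n = mask.shape[0]
    edges = np.linspace(0, n, cells + 1).astype(int)
    cell_idx = np.zeros(mask.shape, dtype=np.int32)
    digit = np.digitize(np.arange(n), edges[1:-1], right=False)
    cell_idx = (
        digit[:, None, None] * cells * cells + digit[None, :, None] * cells + digit[None, None, :]
    )
    labels = np.zeros(mask.shape, dtype=np.int32)
    names: dict[int, str] = {}
    next_label = 1
    for cell in range(cells**3):
        sel = mask & (cell_idx == cell)
        if sel.any():
            labels[sel] = next_label
            i, j, k = cell // (cells * cells), (cell // cells) % cells, cell % cells
            names[next_label] = f"block_x{i}y{j}z{k}"
            next_label += 1
    return RoiAtlas(labels=labels, names=names)


def _beta_field(spec: str, beta_max: float, mask: np.ndarray) -> np.ndarray:
    """Per-voxel atrophy rate (intensity-units/year), zero outside the mask.

    ``anterior_step`` (the default) is ``beta_max`` across the anterior two
    thirds and zero in the posterior third: a region where age is locally
    decodable at a homogeneous rate, and a control region where it is not.
    ``anterior_gradient`` ramps linearly instead, mimicking a frontal
    accuracy gradient; note that a spatially varying rate makes the voxel
    readout a position-dependent-gain problem, which desk-scale training
    budgets cannot reliably solve.
    """
    n = mask.shape[0]
    y = np.arange(n, dtype=np.float64)
    if spec == "anterior_step":
        # signal over the anterior two thirds, posterior third as control:
        # a majority-signal mask keeps the pooled voxel-MAE objective from
        # being indifferent between the age-decoding solution and a
        # constant prediction
        step = (y > n / 3.0).astype(np.float64)
        beta = beta_max * np.broadcast_to(step[None, :, None], mask.shape).copy()
    elif spec == "anterior_gradient":
        ramp = np.clip((y - n / 2.0) / (n / 2.0 - 1.0), 0.0, 1.0)
        beta = beta_max * np.broadcast_to(ramp[None, :, None], mask.shape).copy()
    elif spec == "uniform":
        beta = np.full(mask.shape, beta_max)
    elif spec == "zero":
        beta = np.zeros(mask.shape)
    else:  # pragma: no cover - guarded by PhantomConfig
        raise ValueError(spec)
    beta[~mask] = 0.0
    return beta


# ---------------------------------------------------------------------------
# cohort generation

_GM_BASE = 0.80
_WM_BASE = 0.70


def _smooth(vol: np.ndarray, fwhm: float) -> np.ndarray:
    if fwhm <= 0:
        return vol
    return gaussian_filter(vol, sigma=fwhm * _FWHM_TO_SIGMA, mode="constant")


def _assign_groups(config: PhantomConfig) -> list[str]:
    groups: list[str] = []
    for g, k in config.group_sizes.items():
        groups.extend([g] * int(k))
    if len(groups) > config.n_participants:
        raise ValueError("group_sizes exceed n_participants")
    groups.extend(["HC"] * (config.n_participants - len(groups)))
    return groups


def build_truth(config: PhantomConfig) -> PhantomTruth:
    """Deterministic geometry and effective fields for ``config`` (no cohort)."""
    mask, gm_sup, wm_sup = make_mask_and_supports(config.grid_side)
    atlas = make_block_atlas(mask, config.atlas_cells)
    beta_raw = _beta_field(config.effect_field_spec, config.beta_max, mask)
    base_raw = np.stack(
        [np.where(gm_sup, _GM_BASE, 0.0), np.where(wm_sup, _WM_BASE, 0.0)]
    )
    beta_ch_raw = np.stack([np.where(gm_sup, beta_raw, 0.0), np.where(wm_sup, beta_raw, 0.0)])

    fw = config.smoothing_fwhm
    channel_base = np.stack([_smooth(b, fw) * mask for b in base_raw])
    channel_beta = np.stack([_smooth(b, fw) * mask for b in beta_ch_raw])

    group_maps: dict[str, np.ndarray] = {}
    group_ch: dict[str, np.ndarray] = {}
    for gname, eff in config.group_effects.items():
        roi = np.isin(atlas.labels, np.asarray(eff.roi_labels))
        g_raw = np.where(roi, -beta_raw * eff.delta_years, 0.0)
        g_ch_raw = np.stack([np.where(gm_sup, g_raw, 0.0), np.where(wm_sup, g_raw, 0.0)])
        group_ch[gname] = np.stack([_smooth(g, fw) * mask for g in g_ch_raw])
        group_maps[gname] = group_ch[gname].sum(axis=0)

    return PhantomTruth(
        beta_map=channel_beta.sum(axis=0),
        base_map=channel_base.sum(axis=0),
        mask=mask,
        atlas=atlas,
        affine=default_affine(config.voxel_size_mm),
        channel_base=channel_base,
        channel_beta=channel_beta,
        group_effect_maps=group_maps,
        channel_group_effects=group_ch,
        age_min=REFERENCE_AGE,
    )


def _noise_free_signal(truth: PhantomTruth, age: float, group: str | None) -> np.ndarray:
    sig = truth.channel_base - truth.channel_beta * (age - truth.age_min)
    if group is not None and group in truth.channel_group_effects:
        sig = sig + truth.channel_group_effects[group]
    return sig


def generate_cohort(
    config: PhantomConfig,
) -> tuple[list[VolumePair], list[ParticipantRecord], PhantomTruth]:
    """Draw a cohort of two-channel phantoms with ages uniform over ``age_range``.

    Returns aligned lists of volumes and participant records plus the
    :class:`PhantomTruth` carrying the effective generating fields.  Fixing
    ``config.seed`` makes the output bit-identical across runs.
    """
    truth = build_truth(config)
    rng = np.random.default_rng(config.seed)
    lo, hi = config.age_range
    if config.age_sampling == "grid":
        ages = lo + (hi - lo) * (np.arange(config.n_participants) + 0.5) / config.n_participants
    else:
        ages = rng.uniform(lo, hi, size=config.n_participants)
    groups = _assign_groups(config)

    mask, gm_sup, wm_sup = make_mask_and_supports(config.grid_side)
    beta_raw = _beta_field(config.effect_field_spec, config.beta_max, mask)
    supports = (gm_sup, wm_sup)
    bases = (_GM_BASE, _WM_BASE)

    volumes: list[VolumePair] = []
    records: list[ParticipantRecord] = []
    fw = config.smoothing_fwhm
    for i, (age, group) in enumerate(zip(ages, groups)):
        channels = []
        for sup, base in zip(supports, bases):
            raw = np.where(sup, base - beta_raw * (age - REFERENCE_AGE), 0.0)
            eff = config.group_effects.get(group)
            if eff is not None:
                roi = np.isin(truth.atlas.labels, np.asarray(eff.roi_labels))
                raw = raw + np.where(sup & roi, -beta_raw * eff.delta_years, 0.0)
            if config.noise_sd > 0:
                raw = raw + rng.normal(0.0, config.noise_sd, size=raw.shape)
            channels.append(np.maximum(_smooth(raw, fw) * mask, 0.0).astype(np.float32))
        volumes.append(VolumePair(gm=channels[0], wm=channels[1], affine=truth.affine))
        records.append(
            ParticipantRecord(
                id=f"sub-{i + 1:04d}", age_years=float(age), site="site-1", group=group
            )
        )
    return volumes, records, truth


def generate_repeat_scans(
    cohort: tuple[Sequence[VolumePair], Sequence[ParticipantRecord], PhantomTruth],
    n_repeats: int,
    within_noise_sd: float,
    between_scanner_shift: float = 0.0,
    smoothing_fwhm: float = 2.0,
    seed: int = 0,
) -> list[list[VolumePair]]:
    """Repeat scans for reliability analyses.

    Each repeat shares a participant's noise-free age signal.  Within-scanner
    repeats differ only by fresh smoothed noise of SD ``within_noise_sd``.
    If ``between_scanner_shift > 0``, every repeat after the first is treated
    as a different scanner and additionally receives a smooth additive site
    field with in-mask RMS amplitude ``between_scanner_shift`` (fixed per
    scanner, shared across participants).
    """
    if n_repeats < 2:
        raise ValueError("n_repeats must be >= 2")
    _, records, truth = cohort
    rng = np.random.default_rng(seed)
    mask = truth.mask

    site_fields = [np.zeros((2,) + mask.shape)]
    for _ in range(1, n_repeats):
        if between_scanner_shift > 0:
            f = np.stack(
                [_smooth(rng.normal(size=mask.shape), 3 * smoothing_fwhm) for _ in range(2)]
            )
            rms = np.sqrt(np.mean(f[:, mask] ** 2))
            f = f / rms * between_scanner_shift
            f *= mask
        else:
            f = np.zeros((2,) + mask.shape)
        site_fields.append(f)

    repeats: list[list[VolumePair]] = []
    for r in range(n_repeats):
        scans: list[VolumePair] = []
        for rec in records:
            sig = _noise_free_signal(truth, rec.age_years, rec.group) + site_fields[r]
            if within_noise_sd > 0:
                noise = rng.normal(0.0, within_noise_sd, size=sig.shape)
                sig = sig + np.stack([_smooth(n, smoothing_fwhm) for n in noise]) * mask
            sig = np.maximum(sig, 0.0).astype(np.float32)
            scans.append(VolumePair(gm=sig[0], wm=sig[1], affine=truth.affine))
        repeats.append(scans)
    return repeats


# ---------------------------------------------------------------------------
# on-disk representation


def save_cohort(out_dir, volumes, records, truth) -> None:
    """Write a cohort as NIfTI volumes + CSV table + mask/atlas/truth maps."""
    import pandas as pd

    from . import volume_io as vio

    out_dir = vio._ensure_dir(out_dir)
    for vol, rec in zip(volumes, records):
        vio.save_map(vol.gm, vol.affine, out_dir / f"{rec.id}_gm.nii.gz")
        vio.save_map(vol.wm, vol.affine, out_dir / f"{rec.id}_wm.nii.gz")
    pd.DataFrame(
        {
            "participant_id": [r.id for r in records],
            "age_years": [r.age_years for r in records],
            "site": [r.site for r in records],
            "group": [r.group for r in records],
        }
    ).to_csv(out_dir / "cohort.csv", index=False)
    vio.save_map(truth.mask.astype(np.uint8), truth.affine, out_dir / "mask.nii.gz")
    vio.save_map(truth.atlas.labels, truth.affine, out_dir / "atlas.nii.gz")
    vio.save_map(truth.beta_map, truth.affine, out_dir / "beta_true.nii.gz")
    vio.save_map(truth.base_map, truth.affine, out_dir / "base_true.nii.gz")
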