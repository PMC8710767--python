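"""Volumes, masks, atlases and cohort tables: reading, writing, validation.

NIfTI-1 is the on-disk volume format (via nibabel); cohort tables are UTF-8
CSV with a header row.  Voxel indices are 0-based everywhere; world
coordinates exist only through the affine.  Out-of-mask voxels in *output*
maps carry NaN, never 0 (0 is a legal brain-PAD value).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "VolumePair",
    "ParticipantRecord",
    "RoiAtlas",
    "GeometryError",
    "CohortJoinError",
    "default_affine",
    "load_map",
    "save_map",
    "load_cohort",
    "read_cohort_table",
]

VALID_GROUPS = {"HC", "sMCI", "pMCI", "AD", "other"}


class GeometryError(ValueError):
    """Shape or affine mismatch between volumes that must be co-registered."""


class CohortJoinError(KeyError):
    """Cohort table rows and volume files could not be joined by id."""


def default_affine(voxel_size_mm: float = 1.5) -> np.ndarray:
    """Diagonal voxel->world affine at isotropic ``voxel_size_mm``."""
    aff = np.diag([voxel_size_mm, voxel_size_mm, voxel_size_mm, 1.0])
    return aff


@dataclass
class VolumePair:
    """Co-registered grey- and white-matter tissue-volume maps."""

    gm: np.ndarray
    wm: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.gm = np.asarray(self.gm)
        self.wm = np.asarray(self.wm)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.gm.shape != self.wm.shape:
            raise GeometryError(
                f"GM shape {self.gm.shape} != WM shape {self.wm.shape}"
            )
        if self.gm.ndim != 3:
            raise GeometryError(f"expected 3D volumes, got {self.gm.ndim}D")
        for name, arr in (("gm", self.gm), ("wm", self.wm)):
            if not np.isfinite(arr).all():
                raise ValueError(f"{name} contains non-finite values")
            if (arr < 0).any():
                raise ValueError(f"{name} contains negative tissue values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.gm.shape

    @property
    def voxel_size(self) -> np.ndarray:
        """Voxel edge lengths (mm) from the affine."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def as_channels(self) -> np.ndarray:
        """Stack GM and WM into a channels-last ``(d, h, w, 2)`` array."""
        return np.stack([self.gm, self.wm], axis=-1).astype(np.float32)


@dataclass(frozen=True)
class ParticipantRecord:
    id: str
    age_years: float
    site: str | None = None
    group: str | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.age_years < 130.0):
            raise ValueError(f"implausible age {self.age_years} for {self.id!r}")
        if self.group is not None and self.group not in VALID_GROUPS:
            raise ValueError(
                f"group {self.group!r} not in {sorted(VALID_GROUPS)} for {self.id!r}"
            )


@dataclass
class RoiAtlas:
    """Integer-labelled ROI atlas; label 0 is background."""

    labels: np.ndarray
    names: Mapping[int, str]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("atlas labels must be integers")
        present = set(np.unique(self.labels).tolist()) - {0}
        missing = set(self.names) - present
        if 0 in self.names:
            raise ValueError("label 0 is reserved for background")
        if missing:
            raise ValueError(f"named labels absent from the map: {sorted(missing)}")

    def label_ids(self) -> list[int]:
        return sorted(set(np.unique(self.labels).tolist()) - {0})


# ---------------------------------------------------------------------------
# NIfTI round trip


def save_map(map3d: np.ndarray, affine: np.ndarray, path) -> Path:
    """Write a 3D map as NIfTI.  NaNs (e.g. out-of-mask sentinels) survive."""
    path = Path(path)
    arr = np.asarray(map3d)
    if np.issubdtype(arr.dtype, np.floating):
        arr = arr.astype(np.float32)
        if np.isinf(arr).any():
            raise ValueError("map contains infinities")
    img = nib.Nifti1Image(arr, np.asarray(affine, dtype=np.float64))
    nib.save(img, path)
    return path


def load_map(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj), np.asarray(img.affine)


def _ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p


# ---------------------------------------------------------------------------
# cohort loading


def read_cohort_table(table_path) -> list[ParticipantRecord]:
    """Parse a cohort CSV (participant_id, age_years[, site, group])."""
    df = pd.read_csv(table_path)
    required = {"participant_id", "age_years"}
    if not required.issubset(df.columns):
        raise ValueError(f"cohort table must have columns {sorted(required)}")
    ids = df["participant_id"].astype(str)
    if ids.duplicated().any():
        dupes = sorted(ids[ids.duplicated()].unique())
        raise ValueError(f"duplicate participant ids: {dupes}")
    records = []
    for _, row in df.iterrows():
        site = row.get("site")
        group = row.get("group")
        records.append(
            ParticipantRecord(
                id=str(row["participant_id"]),
                age_years=float(row["age_years"]),
                site=None if pd.isna(site) else str(site),
                group=None if pd.isna(group) else str(group),
            )
        )
    return records


def load_cohort(
    volume_paths: Mapping[str, tuple],
    table_path,
    mask_path=None,
) -> tuple[list[VolumePair], list[ParticipantRecord], np.ndarray | None]:
    """Load volumes + table, joined by participant id, geometry-validated.

    Parameters
    ----------
    volume_paths:
        Mapping ``participant_id -> (gm_path, wm_path)``.
    table_path:
        Cohort CSV; every listed participant must appear in ``volume_paths``.
    mask_path:
        Optional brain mask that all volumes must match in shape and affine.

    Returns the volumes and records in table order, plus the boolean mask
    (or None).  Raises :class:`GeometryError` naming the offending file on
    any shape/affine mismatch and :class:`CohortJoinError` listing ids that
    could not be joined.
    """
    records = read_cohort_table(table_path)
    missing = [r.id for r in records if r.id not in volume_paths]
    if missing:
        raise CohortJoinError(f"no volumes for participant ids: {missing}")

    ref_shape = None
    ref_affine = None
    mask = None
    if mask_path is not None:
        m, ref_affine = load_map(mask_path)
        mask = m.astype(bool)
        ref_shape = mask.shape

    volumes: list[VolumePair] = []
    for rec in records:
        gm_path, wm_path = volume_paths[rec.id]
        gm, aff_gm = load_map(gm_path)
        wm, aff_wm = load_map(wm_path)
        for path, shape, aff in ((gm_path, gm.shape, aff_gm), (wm_path, wm.shape, aff_wm)):
            if ref_shape is None:
                ref_shape, ref_affine = shape, aff
            if shape != ref_shape:
                raise GeometryError(f"{path}: shape {shape} != expected {ref_shape}")
            if not np.allclose(aff, ref_affine, atol=1e-6):
                raise GeometryError(f"{path}: affine differs from reference")
        volumes.append(VolumePair(gm=gm, wm=wm, affine=aff_gm))
    return volumes, records, mask
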