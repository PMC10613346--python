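"""Label-volume and measurement-table I/O with explicit anatomical conventions.

All downstream geometry is computed in anatomical mm space with axes fixed as

    x = medial-lateral (ML), y = posterior-anterior (PA, +y anterior),
    z = inferior-superior (IS),

i.e. an RAS-like frame. :func:`read_label_volume` reorients any input NIfTI
to this convention; left knees are mirrored across the ML axis on load so the
lateral compartment always sits at +x and a single code path serves both
sides.

A voxel is modelled as a closed axis-aligned box centred on its mm-space
center, so the physical length of an n-voxel run is ``n * spacing``.
"""

from __future__ import annotations

import csv
import io
import os
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import (
    LabelAbsentError,
    MissingCellError,
    NonIntegerDataError,
    SingularAffineError,
    TableFormatError,
    VolumeReadError,
)

#: Default semantic label encoding (remappable via CLI flags).
DEFAULT_LABEL_MAP = {1: "medial_meniscus", 2: "lateral_meniscus", 3: "tibial_plateau"}

MEASUREMENT_COLUMNS = [
    "subject_id",
    "group",
    "tear",
    "dlm_type",
    "a_mm",
    "b_mm",
    "c_mm",
    "d_mm",
    "e_mm",
    "L_mm",
    "M_mm",
    "rmt",
    "pcm",
    "lm_ratio",
]


@dataclass
class LabelVolume:
    """A 3D integer label grid plus its voxel-index -> mm affine.

    Parameters
    ----------
    voxels
        3D array of non-negative integer labels, axes ordered (x, y, z)
        after orientation normalization.
    affine
        Invertible 4x4 voxel-index -> mm map.
    label_map
        ``{label_id: structure_name}`` for every nonzero label present.
    side
        ``"left"`` or ``"right"``; after loading, left knees have already
        been mirrored so this is bookkeeping only.
    """

    voxels: np.ndarray
    affine: np.ndarray
    label_map: dict[int, str] = field(default_factory=lambda: dict(DEFAULT_LABEL_MAP))
    side: str = "right"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.voxels.ndim != 3:
            raise VolumeReadError(f"expected a 3D volume, got ndim={self.voxels.ndim}")
        if not np.issubdtype(self.voxels.dtype, np.integer):
            if not np.allclose(self.voxels, np.round(self.voxels)):
                raise NonIntegerDataError("voxel data are not integer-valued")
            self.voxels = np.round(self.voxels).astype(np.int32)
        if self.voxels.min() < 0:
            raise VolumeReadError("negative labels are not allowed")
        if self.affine.shape != (4, 4):
            raise VolumeReadError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise SingularAffineError("affine is singular")
        if self.side not in ("left", "right"):
            raise VolumeReadError(f"side must be 'left' or 'right', got {self.side!r}")
        present = set(np.unique(self.voxels)) - {0}
        undeclared = present - set(self.label_map)
        if undeclared:
            raise VolumeReadError(f"labels {sorted(undeclared)} present but not in label_map")
        if any(s <= 0 for s in self.spacing):
            raise VolumeReadError("spacing components must be strictly positive")

    @property
    def spacing(self) -> tuple[float, float, float]:
        """Per-axis voxel size in mm (column norms of the affine)."""
        return tuple(np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0)))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def label_id(self, name: str) -> int:
        """Look up a label id by its structure name."""
        for lid, lname in self.label_map.items():
            if lname == name:
                return lid
        raise LabelAbsentError(f"label absent: no label named {name!r} in label_map")

    def voxel_centers_mm(self, label: int) -> np.ndarray:
        """mm coordinates of the centers of all voxels carrying ``label``."""
        idx = np.argwhere(self.voxels == label)
        if idx.size == 0:
            return np.empty((0, 3))
        homog = np.c_[idx, np.ones(len(idx))]
        return (self.affine @ homog.T).T[:, :3]


def _to_canonical(voxels: np.ndarray, affine: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Permute/flip axes so the affine is closest to RAS-like (+x, +y, +z)."""
    ornt = nib.orientations.io_orientation(affine)
    affine = affine @ nib.orientations.inv_ornt_aff(ornt, voxels.shape)
    voxels = nib.orientations.apply_orientation(voxels, ornt)
    return np.ascontiguousarray(voxels), affine


def normalize_orientation(vol: LabelVolume) -> LabelVolume:
    """Reorient to the package's RAS-like convention. Idempotent."""
    voxels, affine = _to_canonical(vol.voxels, vol.affine)
    return LabelVolume(voxels=voxels, affine=affine, label_map=dict(vol.label_map), side=vol.side)


def _mirror_ml(voxels: np.ndarray, affine: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # Reflect world x (x -> -x), then re-canonicalize so index order ascends in x.
    reflect = np.diag([-1.0, 1.0, 1.0, 1.0])
    return _to_canonical(voxels, reflect @ affine)


def read_label_volume(
    path: str | os.PathLike,
    label_map: dict[int, str] | None = None,
    side: str = "right",
    require: tuple[int, ...] = (),
) -> LabelVolume:
    """Read a NIfTI label volume and normalize it to the package convention.

    Parameters
    ----------
    path
        A ``.nii`` or ``.nii.gz`` file with integer-valued data.
    label_map
        Label-id -> structure-name mapping; defaults to
        :data:`DEFAULT_LABEL_MAP`.
    side
        ``"left"`` knees are mirrored across the ML axis so lateral is at +x.
    require
        Label ids that must be present; missing ones raise
        :class:`~meniscometry.errors.LabelAbsentError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume file: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises a zoo of types
        raise VolumeReadError(f"cannot read {path} as NIfTI: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if not np.allclose(data, np.round(data), atol=1e-6):
        raise NonIntegerDataError(f"{path} does not contain integer-valued label data")
    data = np.round(data).astype(np.int32)
    affine = np.asarray(img.affine, dtype=float)
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise SingularAffineError(f"{path} has a singular affine")

    voxels, affine = _to_canonical(data, affine)
    if side == "left":
        voxels, affine = _mirror_ml(voxels, affine)
    vol = LabelVolume(
        voxels=voxels,
        affine=affine,
        label_map=dict(label_map or DEFAULT_LABEL_MAP),
        side=side,
    )
    present = set(np.unique(vol.voxels))
    for lab in require:
        if lab not in present:
            name = vol.label_map.get(lab, "?")
            raise LabelAbsentError(f"label absent: id {lab} ({name}) has no voxels in {path}")
    return vol


def write_label_volume(vol: LabelVolume, path: str | os.PathLike) -> Path:
    """Write a LabelVolume as NIfTI; round-trips voxels and mm geometry exactly."""
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"directory does not exist: {path.parent}")
    img = nib.Nifti1Image(vol.voxels.astype(np.int16), vol.affine)
    img.header.set_data_dtype(np.int16)
    nib.save(img, str(path))
    return path


# ---------------------------------------------------------------------------
# Tabular data
# ---------------------------------------------------------------------------


@dataclass
class RatingTable:
    """Wide-format rater x subject numeric grid (one session)."""

    values: np.ndarray  # (n_raters, n_subjects)
    raters: list[str]
    subjects: list[str]
    session: str = "1"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise TableFormatError("rating grid must be 2D (raters x subjects)")
        if self.values.shape != (len(self.raters), len(self.subjects)):
            raise TableFormatError("rating grid shape does not match rater/subject labels")

    @property
    def n_raters(self) -> int:
        return self.values.shape[0]

    @property
    def n_subjects(self) -> int:
        return self.values.shape[1]


def read_ratings(path: str | os.PathLike, session: str = "1") -> RatingTable:
    """Read a wide-format ratings CSV: header = subject ids, one row per rater.

    Blank cells raise :class:`MissingCellError` listing every offending
    (rater, subject) pair; ragged or non-numeric rows raise
    :class:`TableFormatError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such ratings file: {path}")
    with open(path, newline="", encoding="utf-8") as fh:
        rows = list(csv.reader(fh))
    if len(rows) < 2:
        raise TableFormatError(f"{path}: need a header row and at least one rater row")
    header = rows[0]
    subjects = [c.strip() for c in header[1:]]
    raters: list[str] = []
    missing: list[tuple[str, str]] = []
    grid: list[list[float]] = []
    for i, row in enumerate(rows[1:], start=2):
        if len(row) != len(header):
            raise TableFormatError(f"{path}: ragged row {i}: {len(row)} cells, expected {len(header)}")
        rater = row[0].strip()
        raters.append(rater)
        vals: list[float] = []
        for subject, cell in zip(subjects, row[1:]):
            cell = cell.strip()
            if cell == "":
                missing.append((rater, subject))
                vals.append(np.nan)
                continue
            try:
                vals.append(float(cell))
            except ValueError as exc:
                raise TableFormatError(
                    f"{path}: non-numeric cell {cell!r} at (rater {rater}, subject {subject})"
                ) from exc
        grid.append(vals)
    if missing:
        raise MissingCellError(missing)
    return RatingTable(values=np.array(grid), raters=raters, subjects=subjects, session=session)


def write_ratings(table: RatingTable, path: str | os.PathLike) -> Path:
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["rater", *table.subjects])
        for rater, row in zip(table.raters, table.values):
            writer.writerow([rater, *[repr(float(v)) for v in row]])
    return path


def validate_measurements(df: pd.DataFrame, pcm_tol: float = 1e-9) -> pd.DataFrame:
    """Check a per-knee measurement table: one row per knee, sane indices."""
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"measurement table lacks columns: {missing}")
    if df["subject_id"].duplicated().any():
        dupes = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise TableFormatError(f"duplicate subject ids (one row per knee required): {dupes}")
    numeric = df[["rmt", "pcm", "lm_ratio"]].astype(float)
    if (numeric.to_numpy() < 0).any():
        raise TableFormatError("indices must be non-negative")
    if (numeric["pcm"].to_numpy() > 1 + pcm_tol).any():
        raise TableFormatError("pcm exceeds 1 beyond tolerance")
    return df


def read_measurements(path: str | os.PathLike) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such measurement file: {path}")
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise TableFormatError(f"cannot parse {path}: {exc}") from exc
    return validate_measurements(df)


def write_measurements(df: pd.DataFrame, path: str | os.PathLike) -> Path:
    """Write a per-knee measurement table as CSV (RFC 4180, header, UTF-8)."""
    validate_measurements(df)
    path = Path(path)
    buf = io.StringIO()
    df.to_csv(buf, index=False, lineterminator="\r\n")
    path.write_text(buf.getvalue(), encoding="utf-8", newline="")
    return path
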