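"""Reading and writing of axial images, ROI masks, and result tables.

Images live on a single 2-D pixel grid with physical spacing in mm; masks
must match that grid exactly — no resampling is ever performed. NIfTI-1 is
the on-disk format for images and masks; whitespace-delimited matrix text
and run-length CSV are accepted as plain-text alternatives. Tables are
RFC-4180 CSV with a single ``#`` comment line documenting column order.

Coordinate convention: row-major, 0-based indices throughout.
"""

from __future__ import annotations

import csv
import dataclasses
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .exceptions import (
    AmbiguousVolumeError,
    FormatError,
    GridMismatchError,
    SchemaError,
)

logger = logging.getLogger(__name__)

MUSCLES = ("multifidus", "erector_spinae")
SIDES = ("left", "right")


@dataclass(frozen=True)
class AxialImage:
    """A 2-D axial grayscale image with physical pixel spacing.

    Parameters
    ----------
    intensities
        2-D grid of finite, non-negative intensities in arbitrary scanner
        units (bright fat, dark muscle under the T2-weighted convention).
    pixel_spacing
        ``(row_mm, col_mm)`` physical size of one pixel; both > 0.
    subject_id
        Free-form subject identifier.
    grade_label
        Optional ordinal fatty-infiltration grade (0, 1 or 2).
    """

    intensities: np.ndarray
    pixel_spacing: tuple[float, float] = (1.0, 1.0)
    subject_id: str = ""
    grade_label: int | None = None

    def __post_init__(self):
        arr = np.asarray(self.intensities, dtype=float)
        if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
            raise ValueError(f"intensities must be a 2-D grid, got shape {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise ValueError("intensities must all be finite")
        if arr.min() < 0:
            raise ValueError("intensities must be non-negative")
        object.__setattr__(self, "intensities", arr)
        spacing = (float(self.pixel_spacing[0]), float(self.pixel_spacing[1]))
        if spacing[0] <= 0 or spacing[1] <= 0:
            raise ValueError(f"pixel_spacing must be positive, got {spacing}")
        object.__setattr__(self, "pixel_spacing", spacing)
        if self.grade_label is not None and self.grade_label not in (0, 1, 2):
            raise ValueError(f"grade_label must be 0, 1 or 2, got {self.grade_label}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensities.shape

    @property
    def pixel_area_mm2(self) -> float:
        return self.pixel_spacing[0] * self.pixel_spacing[1]


@dataclass(frozen=True)
class RoiMask:
    """A binary region-of-interest mask with its study labels.

    The mask is the stand-in for one rater's manually traced ROI of one
    muscle on one side, under one ROI-definition method (1 includes the
    epimuscular fat tent, 2 excludes it).
    """

    mask: np.ndarray
    muscle: str = "erector_spinae"
    side: str = "left"
    rater_id: str = "r1"
    method: int = 2
    subject_id: str = ""

    def __post_init__(self):
        arr = np.asarray(self.mask)
        if arr.ndim != 2:
            raise ValueError(f"mask must be 2-D, got shape {arr.shape}")
        object.__setattr__(self, "mask", arr.astype(bool))
        if self.muscle not in MUSCLES:
            raise ValueError(f"muscle must be one of {MUSCLES}, got {self.muscle!r}")
        if self.side not in SIDES:
            raise ValueError(f"side must be one of {SIDES}, got {self.side!r}")
        if self.method not in (1, 2):
            raise ValueError(f"method must be 1 or 2, got {self.method!r}")

    @property
    def n_foreground(self) -> int:
        return int(self.mask.sum())

    @property
    def labels(self) -> dict:
        return {
            "subject": self.subject_id,
            "muscle": self.muscle,
            "side": self.side,
            "rater": self.rater_id,
            "method": self.method,
        }

    def check_grid(self, image: AxialImage) -> None:
        if self.mask.shape != image.shape:
            raise GridMismatchError(
                f"mask shape {self.mask.shape} does not match image shape {image.shape}"
            )


def _load_nifti_2d(path: Path) -> tuple[np.ndarray, tuple[float, float]]:
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types
        raise FormatError(f"cannot read {path} as NIfTI: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim == 3:
        if data.shape[2] != 1:
            raise AmbiguousVolumeError(
                f"{path} holds {data.shape[2]} slices; expected a single axial slice"
            )
        data = data[:, :, 0]
    elif data.ndim != 2:
        raise FormatError(f"{path} has {data.ndim} dimensions; expected 2-D")
    zooms = img.header.get_zooms()[:2]
    return np.asarray(data, dtype=float), (float(zooms[0]), float(zooms[1]))


def read_image(path: str | Path, subject_id: str | None = None) -> AxialImage:
    """Read an axial image from NIfTI (2-D or single-slice 3-D) or matrix text.

    Matrix text carries no spacing; (1.0, 1.0) mm is assumed with a warning
    so that pixel counts and areas coincide.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    sid = subject_id if subject_id is not None else path.stem.split("_")[0]
    if path.suffix in (".nii", ".gz") or path.name.endswith(".nii.gz"):
        data, spacing = _load_nifti_2d(path)
        return AxialImage(data, spacing, subject_id=sid)
    try:
        data = np.loadtxt(str(path), dtype=float, ndmin=2)
    except Exception as exc:
        raise FormatError(f"cannot read {path} as matrix text: {exc}") from exc
    warnings.warn(
        f"{path.name}: matrix text has no pixel spacing; assuming 1 mm isotropic",
        stacklevel=2,
    )
    return AxialImage(data, (1.0, 1.0), subject_id=sid)


def write_image(image: AxialImage, path: str | Path) -> None:
    """Write an image as 2-D NIfTI-1 with its spacing in the header."""
    path = Path(path)
    affine = np.diag([image.pixel_spacing[0], image.pixel_spacing[1], 1.0, 1.0])
    img = nib.Nifti1Image(image.intensities.astype(np.float64), affine)
    img.header.set_zooms(image.pixel_spacing)
    nib.save(img, str(path))


def parse_mask_filename(name: str) -> dict:
    """Infer labels from the ``<subject>_<muscle>_<side>_<rater>_<method>`` convention.

    ``erector_spinae`` contains an underscore, so parsing anchors on the
    known muscle and side vocabularies.
    """
    stem = name
    for suffix in (".nii.gz", ".nii", ".csv", ".txt"):
        if stem.endswith(suffix):
            stem = stem[: -len(suffix)]
            break
    parts = stem.split("_")
    if len(parts) < 5:
        raise FormatError(f"filename {name!r} does not follow the naming convention")
    method = int(parts[-1])
    rater = parts[-2]
    side = parts[-3]
    muscle = "_".join(parts[1:-3])
    return {
        "subject_id": parts[0],
        "muscle": muscle,
        "side": side,
        "rater_id": rater,
        "method": method,
    }


def read_mask(
    path: str | Path,
    grid_shape: tuple[int, int] | None = None,
    labels: Mapping | None = None,
) -> RoiMask:
    """Read a binary ROI mask from NIfTI or run-length CSV.

    Any stored value > 0 is foreground (handles 0/1 and 0/255 dialects).
    Labels come from ``labels`` or, failing that, the filename convention.
    An empty mask is flagged with a warning but returned; quantification
    rejects it later.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if labels is None:
        labels = parse_mask_filename(path.name)
    if path.suffix == ".csv":
        if grid_shape is None:
            raise FormatError("grid_shape is required for run-length CSV masks")
        arr = _read_runlength_csv(path, grid_shape)
    else:
        arr, _ = _load_nifti_2d(path)
    if grid_shape is not None and arr.shape != tuple(grid_shape):
        raise GridMismatchError(
            f"mask shape {arr.shape} does not match expected grid {tuple(grid_shape)}"
        )
    binary = arr > 0
    if not binary.any():
        warnings.warn(f"{path.name}: mask has no foreground pixels", stacklevel=2)
    return RoiMask(binary, **labels)


def write_mask(mask: RoiMask, path: str | Path, pixel_spacing=(1.0, 1.0)) -> None:
    """Write a mask as uint8 NIfTI (1 = foreground)."""
    path = Path(path)
    affine = np.diag([pixel_spacing[0], pixel_spacing[1], 1.0, 1.0])
    img = nib.Nifti1Image(mask.mask.astype(np.uint8), affine)
    nib.save(img, str(path))


def _read_runlength_csv(path: Path, grid_shape: tuple[int, int]) -> np.ndarray:
    """Run-length CSV: header ``row,start,length``; one run of foreground per line."""
    arr = np.zeros(grid_shape, dtype=np.uint8)
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header[:3]] != ["row", "start", "length"]:
            raise FormatError(f"{path}: expected run-length header 'row,start,length'")
        for line in reader:
            if not line:
                continue
            r, s, ln = int(line[0]), int(line[1]), int(line[2])
            if r < 0 or r >= grid_shape[0] or s < 0 or s + ln > grid_shape[1]:
                raise GridMismatchError(
                    f"{path}: run (row={r}, start={s}, length={ln}) exceeds grid {grid_shape}"
                )
            arr[r, s : s + ln] = 1
    return arr


def write_runlength_csv(mask: RoiMask, path: str | Path) -> None:
    """Write a mask as run-length CSV (``row,start,length``)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["row", "start", "length"])
        for r in range(mask.mask.shape[0]):
            row = mask.mask[r]
            # run boundaries from the diff of the padded row
            d = np.diff(np.concatenate(([0], row.astype(np.int8), [0])))
            starts = np.flatnonzero(d == 1)
            ends = np.flatnonzero(d == -1)
            for s, e in zip(starts, ends):
                writer.writerow([r, int(s), int(e - s)])


def write_table(records: Sequence, path: str | Path) -> None:
    """Write homogeneous records (dataclasses or dicts) to CSV.

    The first line is a ``#`` comment naming the column order; floats are
    written at full round-trip precision.
    """
    path = Path(path)
    rows = []
    for rec in records:
        if dataclasses.is_dataclass(rec) and not isinstance(rec, type):
            rows.append(dataclasses.asdict(rec))
        elif isinstance(rec, Mapping):
            rows.append(dict(rec))
        else:
            raise SchemaError(f"unsupported record type {type(rec).__name__}")
    if rows:
        schema = list(rows[0].keys())
        for i, row in enumerate(rows[1:], start=1):
            if list(row.keys()) != schema:
                raise SchemaError(
                    f"record {i} schema {list(row.keys())} differs from {schema}"
                )
    else:
        schema = []
    try:
        with open(path, "w", newline="") as fh:
            fh.write("# columns: " + ",".join(schema) + "\n")
            writer = csv.writer(fh)
            writer.writerow(schema)
            for row in rows:
                writer.writerow([repr(v) if isinstance(v, float) else v for v in row.values()])
    except OSError as exc:
        raise OSError(f"cannot write table to {path}: {exc}") from exc


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a CSV written by :func:`write_table`."""
    return pd.read_csv(path, comment="#")
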