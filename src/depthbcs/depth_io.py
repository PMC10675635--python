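"""Depth-frame and dataset-manifest I/O.

The on-disk dataset layout consumed by the whole pipeline:

* depth frames are 16-bit single-channel grayscale PNGs whose pixel values
  are ranges in millimetres (0 is reserved for no-data / removed pixels);
* the manifest is a CSV with columns ``cow_id,camera,frame_ref,bcs,split``
  (plus an optional ``phase`` column added by the augmentation stage).

Coordinates are row-major, origin top-left, 0-based. The default sensor is
Kinect-v2-like: 424 rows x 512 columns.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "SENSOR_SHAPE",
    "BCS_GRID",
    "CameraView",
    "Split",
    "BCSLabel",
    "DepthFrame",
    "DatasetIndex",
    "FormatError",
    "ValidationError",
    "read_depth_frame",
    "write_depth_frame",
    "load_manifest",
    "save_manifest",
]

#: Default sensor shape (rows, cols) of a Kinect-v2-like time-of-flight camera.
SENSOR_SHAPE = (424, 512)

#: The 8-level BCS grid actually observed in the herd (five-point scale,
#: 0.25 increments, restricted to the occupied range).
BCS_GRID = (1.75, 2.00, 2.25, 2.50, 2.75, 3.00, 3.25, 3.50)

GRID_STEP = 0.25


class FormatError(ValueError):
    """Raised when an on-disk artifact is not in the expected dialect."""


class ValidationError(ValueError):
    """Raised when manifest contents violate the dataset contract."""


class CameraView(enum.Enum):
    """The three camera placements over the crush."""

    ANGLED = "ANGLED"
    REAR = "REAR"
    TOP = "TOP"

    @classmethod
    def parse(cls, token: str) -> "CameraView":
        try:
            return cls[str(token).strip().upper()]
        except KeyError:
            raise ValidationError(f"unknown camera view {token!r}; "
                                  f"expected one of {[v.name for v in cls]}") from None


class Split(enum.Enum):
    TRAIN = "TRAIN"
    TEST = "TEST"
    UNASSIGNED = "UNASSIGNED"


@dataclass(frozen=True, order=True)
class BCSLabel:
    """A body condition score on the 8-level grid 1.75 .. 3.50.

    ``class_index`` is the 0-based position on the grid and is bijective
    with ``score`` via ``class_index = round((score - 1.75) / 0.25)``.
    """

    score: float

    def __post_init__(self) -> None:
        idx = (self.score - BCS_GRID[0]) / GRID_STEP
        if not np.isclose(idx, round(idx)) or not (0 <= round(idx) < len(BCS_GRID)):
            raise ValidationError(
                f"BCS {self.score} is off the grid {BCS_GRID[0]}..{BCS_GRID[-1]} "
                f"in steps of {GRID_STEP}")
        object.__setattr__(self, "score", float(BCS_GRID[round(idx)]))

    @property
    def class_index(self) -> int:
        return round((self.score - BCS_GRID[0]) / GRID_STEP)

    @classmethod
    def from_class_index(cls, index: int) -> "BCSLabel":
        if not 0 <= index < len(BCS_GRID):
            raise ValidationError(f"class index {index} outside 0..{len(BCS_GRID) - 1}")
        return cls(BCS_GRID[index])

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.score:.2f}"


@dataclass
class DepthFrame:
    """A single range image: integer millimetres per pixel, 0 = no-data."""

    values: np.ndarray
    camera: CameraView
    frame_id: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
            raise FormatError(f"depth frame must be a 2-D grid, got shape {arr.shape}")
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise FormatError("depth values must be integer millimetres")
            arr = np.round(arr).astype(np.int64)
        if arr.min() < 0:
            raise FormatError("depth values must be non-negative")
        self.values = arr.astype(np.int64)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class ManifestRecord:
    cow_id: str
    camera: CameraView
    frame_ref: str
    label: BCSLabel
    split: Split = Split.UNASSIGNED
    phase: tuple[int, int] | None = None

    @property
    def key(self) -> tuple:
        return (self.cow_id, self.camera, self.frame_ref) + (
            (self.phase,) if self.phase is not None else ())


@dataclass
class DatasetIndex:
    """Manifest of (cow, camera, frame, label, split) records.

    The unit of labelling and of train/test splitting is the *cow*: every
    record of one cow carries the same label and the same split.
    """

    records: list[ManifestRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seen: set[tuple] = set()
        per_cow_label: dict[str, BCSLabel] = {}
        per_cow_split: dict[str, Split] = {}
        for rec in self.records:
            if rec.key in seen:
                raise ValidationError(f"duplicate manifest key {rec.key}")
            seen.add(rec.key)
            if per_cow_label.setdefault(rec.cow_id, rec.label) != rec.label:
                raise ValidationError(f"cow {rec.cow_id} carries conflicting labels")
            if per_cow_split.setdefault(rec.cow_id, rec.split) != rec.split:
                raise ValidationError(f"cow {rec.cow_id} carries conflicting splits")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def cows(self) -> list[str]:
        out: list[str] = []
        for rec in self.records:
            if rec.cow_id not in out:
                out.append(rec.cow_id)
        return out

    def subset(self, *, split: Split | None = None,
               camera: CameraView | None = None) -> "DatasetIndex":
        recs = [r for r in self.records
                if (split is None or r.split == split)
                and (camera is None or r.camera == camera)]
        return DatasetIndex(recs)

    def with_split(self, assignment: dict[str, Split]) -> "DatasetIndex":
        recs = [replace(r, split=assignment.get(r.cow_id, r.split))
                for r in self.records]
        return DatasetIndex(recs)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        has_phase = any(r.phase is not None for r in self.records)
        for r in self.records:
            row = {
                "cow_id": r.cow_id,
                "camera": r.camera.name,
                "frame_ref": r.frame_ref,
                "bcs": f"{r.label.score:.2f}",
                "split": r.split.name,
            }
            if has_phase:
                row["phase"] = "" if r.phase is None else f"{r.phase[0]}{r.phase[1]}"
            rows.append(row)
        cols = ["cow_id", "camera", "frame_ref", "bcs", "split"] + (
            ["phase"] if has_phase else [])
        return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# Depth frame I/O (16-bit grayscale PNG, value = millimetres)
# ---------------------------------------------------------------------------

def write_depth_frame(frame: DepthFrame, path: str | Path) -> Path:
    """Losslessly encode a depth frame as a 16-bit grayscale PNG."""
    path = Path(path)
    vals = frame.values
    if vals.max(initial=0) > 0xFFFF:
        raise ValueError(f"depth value {vals.max()} mm exceeds the 16-bit range")
    img = Image.fromarray(vals.astype(np.uint16))
    path.parent.mkdir(parents=True, exist_ok=True)
    img.save(path, format="PNG")
    return path


def read_depth_frame(path: str | Path, camera: CameraView) -> DepthFrame:
    """Read a 16-bit single-channel grayscale PNG as a depth frame."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with Image.open(path) as img:
        if img.mode not in ("I;16", "I;16B", "I"):
            raise FormatError(
                f"{path}: expected a 16-bit single-channel grayscale image, "
                f"got mode {img.mode!r}")
        arr = np.asarray(img, dtype=np.int64)
    if arr.ndim != 2:
        raise FormatError(f"{path}: expected a single channel, got shape {arr.shape}")
    return DepthFrame(values=arr, camera=camera, frame_id=path.stem)


# ---------------------------------------------------------------------------
# Manifest I/O (CSV)
# ---------------------------------------------------------------------------

_MANIFEST_COLUMNS = ["cow_id", "camera", "frame_ref", "bcs", "split"]


def save_manifest(index: DatasetIndex, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    index.to_frame().to_csv(path, index=False)
    return path


def load_manifest(path: str | Path) -> DatasetIndex:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: manifest missing columns {missing}")
    records = []
    for _, row in df.iterrows():
        phase = None
        if "phase" in df.columns and row.get("phase", ""):
            tok = str(row["phase"])
            if len(tok) != 2 or tok[0] not in "01" or tok[1] not in "01":
                raise ValidationError(f"{path}: bad phase token {tok!r}")
            phase = (int(tok[0]), int(tok[1]))
        try:
            score = float(row["bcs"])
        except ValueError:
            raise ValidationError(f"{path}: non-numeric bcs {row['bcs']!r}") from None
        records.append(ManifestRecord(
            cow_id=str(row["cow_id"]),
            camera=CameraView.parse(row["camera"]),
            frame_ref=str(row["frame_ref"]),
            label=BCSLabel(score),
            split=Split[str(row["split"]).strip().upper() or "UNASSIGNED"],
            phase=phase,
        ))
    return DatasetIndex(records)


def build_index(records: Iterable[ManifestRecord] | Sequence[ManifestRecord]) -> DatasetIndex:
    return DatasetIndex(list(records))
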