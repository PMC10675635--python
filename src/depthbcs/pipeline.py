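"""Dataset assembly: manifests + frames on disk -> aligned fusion arrays.

Chains the study's dataset rules in order: frame capping, cow-level
split, single-test-frame selection, channel construction, and factor-2
phase sub-sampling. Cameras are aligned per cow by capture order (frame
refs sort in capture order within a cow-camera group), and all cameras of
one sample share the same sub-sampling phase, so the four phase images of
a frame carry one label.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .augment import (PHASES, cow_level_split, limit_frames_per_cow,
                      select_test_frames, subsample_phases)
from .depth_io import CameraView, DatasetIndex, Split, read_depth_frame
from .fusion import FusionDataset
from .preprocess import PreprocessConfig, build_channel_stack

__all__ = ["stage_seed", "PreparedData", "prepare_datasets"]


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed so stages can be re-run independently."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


@dataclass
class PreparedData:
    train: FusionDataset
    test: FusionDataset
    index: DatasetIndex          # capped + split + test-selected records


def _aligned_slots(index: DatasetIndex, cameras: tuple[CameraView, ...],
                   ) -> list[tuple[str, dict[CameraView, str]]]:
    """Per cow, align each camera's records by capture order."""
    per_cow: dict[str, dict[CameraView, list[str]]] = {}
    for rec in index:
        per_cow.setdefault(rec.cow_id, {c: [] for c in cameras})
        per_cow[rec.cow_id].setdefault(rec.camera, []).append(rec.frame_ref)
    slots = []
    for cow in sorted(per_cow):
        groups = per_cow[cow]
        if any(c not in groups or not groups[c] for c in cameras):
            continue   # cow lacks a camera entirely -> dropped with a warning upstream
        for c in cameras:
            groups[c] = sorted(groups[c])
        n = min(len(groups[c]) for c in cameras)
        for i in range(n):
            slots.append((cow, {c: groups[c][i] for c in cameras}))
    return slots


def _build_arrays(index: DatasetIndex, root: Path, pp: PreprocessConfig,
                  cameras: tuple[CameraView, ...]) -> FusionDataset:
    slots = _aligned_slots(index, cameras)
    label_of = {rec.cow_id: rec.label.class_index for rec in index}
    X: dict[CameraView, list[np.ndarray]] = {c: [] for c in cameras}
    y: list[int] = []
    cow_ids: list[str] = []
    for cow, refs in slots:
        stacks = {}
        for cam in cameras:
            frame = read_depth_frame(root / refs[cam], cam)
            stack = build_channel_stack(frame, pp)
            # network input normalization: bring the derivative plane
            # (mm per pixel, within +/- gradient_cap) onto the same unit
            # scale as the depth and binary planes
            planes = stack.planes.copy()
            planes[..., 2] /= pp[cam].gradient_cap
            stacks[cam] = subsample_phases(planes)
        for phase in PHASES:
            for cam in cameras:
                X[cam].append(stacks[cam][phase])
            y.append(label_of[cow])
            cow_ids.append(cow)
    return FusionDataset(
        X={c: np.stack(X[c]).astype(np.float32) if X[c]
           else np.zeros((0, 1, 1, 3), np.float32) for c in cameras},
        y=np.array(y, dtype=np.int64),
        cow_ids=np.array(cow_ids))


def prepare_datasets(index: DatasetIndex, root: str | Path, pp: PreprocessConfig,
                     cap: int = 7, test_fraction: float = 0.3,
                     seed: int = 0, stratify: bool = True) -> PreparedData:
    """Apply the dataset rules and materialize aligned train/test arrays.

    ``cap``: at most this many frames per cow-camera (study cap: 7).
    ``test_fraction``: cow-level test share (study: 0.3). Each test cow
    contributes exactly one frame per camera; augmentation then yields
    four samples per retained frame.
    """
    root = Path(root)
    cameras = tuple(sorted({rec.camera for rec in index}, key=lambda c: c.name))
    capped = limit_frames_per_cow(index, cap, seed=stage_seed(seed, "cap"))
    split = cow_level_split(capped, test_fraction, seed=stage_seed(seed, "split"),
                            stratify=stratify)
    selected = select_test_frames(split, seed=stage_seed(seed, "test-frame"))
    train = _build_arrays(selected.subset(split=Split.TRAIN), root, pp, cameras)
    test = _build_arrays(selected.subset(split=Split.TEST), root, pp, cameras)
    return PreparedData(train=train, test=test, index=selected)
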