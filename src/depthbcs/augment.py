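"""Sub-sampling augmentation and dataset assembly rules.

Three dataset rules from the study protocol, plus the augmentation:

* frames are capped at 7 per cow and camera (passage speed varies, so raw
  frame counts per cow differ wildly);
* the 70/30 train/test split is performed on *cows*, never on frames, so
  no animal leaks across the split;
* each test cow contributes exactly one frame per camera, so a model
  cannot score the same animal several times over;
* every image is factor-2 phase sub-sampled: taking every second pixel
  across and every second pixel down at each of the four (row, column)
  phase offsets yields four half-resolution variants, multiplying sample
  counts by exactly 4.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .depth_io import CameraView, DatasetIndex, ManifestRecord, Split
from .preprocess import ChannelStack, GeometryError

__all__ = [
    "PHASES",
    "SplitError",
    "subsample_phases",
    "interleave_phases",
    "limit_frames_per_cow",
    "cow_level_split",
    "select_test_frames",
    "augment_index",
]

#: The four (row, column) phase offsets of factor-2 sub-sampling.
PHASES = ((0, 0), (0, 1), (1, 0), (1, 1))


class SplitError(ValueError):
    pass


def subsample_phases(image: np.ndarray | ChannelStack) -> dict[tuple[int, int], np.ndarray]:
    """Four half-resolution phase images of ``image`` (2-D plane or H x W x C).

    ``member(p, q)[i, j] = image[2i + p, 2j + q]``. For even H and W the
    four members re-interleave exactly back to the original.
    """
    arr = image.planes if isinstance(image, ChannelStack) else np.asarray(image)
    if arr.shape[0] < 2 or arr.shape[1] < 2:
        raise GeometryError(f"cannot sub-sample degenerate shape {arr.shape}")
    return {(p, q): arr[p::2, q::2].copy() for (p, q) in PHASES}


def interleave_phases(members: dict[tuple[int, int], np.ndarray]) -> np.ndarray:
    """Inverse of :func:`subsample_phases` for even-shaped originals."""
    m00 = members[(0, 0)]
    h, w = m00.shape[0] * 2, m00.shape[1] * 2
    out = np.empty((h, w) + m00.shape[2:], dtype=m00.dtype)
    for (p, q), img in members.items():
        out[p::2, q::2] = img
    return out


def limit_frames_per_cow(index: DatasetIndex, cap: int, seed: int = 0) -> DatasetIndex:
    """Retain at most ``cap`` frames per (cow, camera).

    When more frames exist than the cap, the temporally middle ``cap``
    frames are kept (frame refs sort in capture order); ties cannot occur
    because refs are unique. Deterministic.
    """
    if cap < 1:
        raise SplitError("cap must be >= 1")
    by_group: dict[tuple[str, CameraView], list[ManifestRecord]] = {}
    for rec in index:
        by_group.setdefault((rec.cow_id, rec.camera), []).append(rec)
    kept: list[ManifestRecord] = []
    for key in by_group:
        group = sorted(by_group[key], key=lambda r: r.frame_ref)
        if len(group) > cap:
            start = (len(group) - cap) // 2
            group = group[start:start + cap]
        kept.extend(group)
    order = {rec.key: i for i, rec in enumerate(index)}
    kept.sort(key=lambda r: order[r.key])
    return DatasetIndex(kept)


def cow_level_split(index: DatasetIndex, test_fraction: float, seed: int,
                    stratify: bool = False) -> DatasetIndex:
    """Assign every cow wholly to TRAIN or TEST.

    ``|test cows| = round(test_fraction * n_cows)``; with ``stratify`` the
    draw is per BCS class so each class's test share stays within one cow
    of the global fraction. Deterministic given ``seed``.
    """
    if not 0 < test_fraction < 1:
        raise SplitError("test_fraction must lie in (0, 1)")
    cows = sorted(index.cows())
    if len(cows) < 2:
        raise SplitError("need at least 2 cows to split")
    rng = np.random.default_rng(seed)
    assignment: dict[str, Split] = {}
    if stratify:
        label_of = {rec.cow_id: rec.label.class_index for rec in index}
        for cls in sorted({label_of[c] for c in cows}):
            members = [c for c in cows if label_of[c] == cls]
            n_test = int(round(test_fraction * len(members)))
            test = set(rng.choice(members, size=n_test, replace=False)) if n_test else set()
            for c in members:
                assignment[c] = Split.TEST if c in test else Split.TRAIN
    else:
        n_test = int(round(test_fraction * len(cows)))
        test = set(rng.choice(cows, size=n_test, replace=False)) if n_test else set()
        for c in cows:
            assignment[c] = Split.TEST if c in test else Split.TRAIN
    return index.with_split(assignment)


def select_test_frames(index: DatasetIndex, seed: int = 0) -> DatasetIndex:
    """Retain exactly one frame per (test cow, camera); train records pass through.

    The retained frame is a seeded uniform draw per cow-camera group, so
    repeated runs with one seed select the same frame.
    """
    rng = np.random.default_rng(seed)
    by_group: dict[tuple[str, CameraView], list[ManifestRecord]] = {}
    test_recs = [r for r in index if r.split == Split.TEST]
    for rec in test_recs:
        by_group.setdefault((rec.cow_id, rec.camera), []).append(rec)
    keep_keys = set()
    for key in sorted(by_group, key=lambda k: (k[0], k[1].name)):
        group = sorted(by_group[key], key=lambda r: r.frame_ref)
        keep_keys.add(group[int(rng.integers(len(group)))].key)
    kept = [r for r in index
            if r.split != Split.TEST or r.key in keep_keys]
    return DatasetIndex(kept)


def augment_index(index: DatasetIndex) -> DatasetIndex:
    """Expand each record into its four phase records (x4 sample count)."""
    recs = []
    for rec in index:
        if rec.phase is not None:
            raise SplitError("index is already augmented")
        for phase in PHASES:
            recs.append(replace(rec, phase=phase))
    return DatasetIndex(recs)
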