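"""Depth-frame preprocessing and CNN channel construction.

Per camera the pipeline is: distance-limit (zero every pixel further than a
threshold, suppressing background) -> crop to a fixed camera-specific window
-> build three input planes:

* depth, normalized to [0, 1] by the camera's distance threshold;
* binary silhouette (1 = closer than the binarize threshold);
* left-to-right first derivative in mm per pixel step, with large edge
  spikes removed by a cap.

0 mm is the no-data sentinel throughout: such pixels binarize to 0 even
though they compare "closer" than any threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .depth_io import CameraView, DepthFrame

__all__ = [
    "CropWindow",
    "CameraPreprocess",
    "PreprocessConfig",
    "ChannelStack",
    "GeometryError",
    "distance_limit",
    "crop",
    "binarize",
    "derivative",
    "build_channel_stack",
]


class GeometryError(ValueError):
    """A window or shape constraint is violated."""


@dataclass(frozen=True)
class CropWindow:
    top: int
    left: int
    height: int
    width: int

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1 or self.top < 0 or self.left < 0:
            raise GeometryError(f"invalid crop window {self}")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height, self.width)


@dataclass(frozen=True)
class CameraPreprocess:
    """Per-camera preprocessing parameters (all distances in mm)."""

    distance_threshold: float
    crop_window: CropWindow
    binarize_threshold: float
    gradient_cap: float
    depth_norm: float | None = None     # default: distance_threshold

    def __post_init__(self) -> None:
        if self.distance_threshold <= 0 or self.binarize_threshold <= 0:
            raise GeometryError("thresholds must be positive")
        if self.gradient_cap <= 0:
            raise GeometryError("gradient_cap must be positive")

    @property
    def norm(self) -> float:
        return self.depth_norm if self.depth_norm is not None else self.distance_threshold


@dataclass
class PreprocessConfig:
    per_camera: dict[CameraView, CameraPreprocess] = field(default_factory=dict)

    def __getitem__(self, camera: CameraView) -> CameraPreprocess:
        return self.per_camera[camera]


@dataclass
class ChannelStack:
    """3-plane CNN input: (depth in [0,1], binary {0,1}, capped derivative)."""

    planes: np.ndarray          # H x W x 3, float32
    camera: CameraView

    def __post_init__(self) -> None:
        arr = np.asarray(self.planes, dtype=np.float32)
        if arr.ndim != 3 or arr.shape[2] != 3:
            raise GeometryError(f"channel stack must be HxWx3, got {arr.shape}")
        self.planes = arr

    @property
    def shape(self) -> tuple[int, int]:
        return self.planes.shape[:2]  # type: ignore[return-value]

    @property
    def depth(self) -> np.ndarray:
        return self.planes[..., 0]

    @property
    def binary(self) -> np.ndarray:
        return self.planes[..., 1]

    @property
    def deriv(self) -> np.ndarray:
        return self.planes[..., 2]


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def distance_limit(frame: DepthFrame, threshold: float) -> DepthFrame:
    """Zero every pixel further than ``threshold`` mm. Idempotent."""
    if threshold <= 0:
        raise GeometryError("threshold must be positive")
    vals = np.where(frame.values > threshold, 0, frame.values)
    return DepthFrame(values=vals, camera=frame.camera, frame_id=frame.frame_id)


def crop(frame: DepthFrame, window: CropWindow) -> DepthFrame:
    rows, cols = frame.shape
    if window.top + window.height > rows or window.left + window.width > cols:
        raise GeometryError(f"crop {window} exceeds frame shape {frame.shape}")
    vals = frame.values[window.top:window.top + window.height,
                        window.left:window.left + window.width]
    return DepthFrame(values=vals.copy(), camera=frame.camera, frame_id=frame.frame_id)


def binarize(frame: DepthFrame, threshold: float) -> np.ndarray:
    """Silhouette plane: 1 where 0 < value < threshold, else 0.

    Pixels at exactly the threshold count as "further away" (-> 0), and the
    0 mm no-data sentinel maps to 0, not 1.
    """
    if threshold <= 0:
        raise GeometryError("threshold must be positive")
    vals = frame.values
    return ((vals > 0) & (vals < threshold)).astype(np.float32)


def derivative(frame: DepthFrame, gradient_cap: float) -> np.ndarray:
    """Left-to-right first difference in mm per pixel, edge spikes zeroed.

    The first column is 0-padded to preserve shape; any gradient whose
    magnitude exceeds ``gradient_cap`` is set to 0 (object-edge artifact).
    """
    if gradient_cap <= 0:
        raise GeometryError("gradient_cap must be positive")
    if frame.shape[1] < 2:
        raise GeometryError("derivative needs frame width >= 2")
    vals = frame.values.astype(np.float32)
    g = np.zeros_like(vals)
    g[:, 1:] = vals[:, 1:] - vals[:, :-1]
    g[np.abs(g) > gradient_cap] = 0.0
    return g


def build_channel_stack(frame: DepthFrame, config: PreprocessConfig | CameraPreprocess,
                        ) -> ChannelStack:
    """distance_limit -> crop -> stack (normalized depth, binary, derivative)."""
    cam_cfg = config[frame.camera] if isinstance(config, PreprocessConfig) else config
    limited = distance_limit(frame, cam_cfg.distance_threshold)
    cropped = crop(limited, cam_cfg.crop_window)
    depth_plane = (cropped.values / cam_cfg.norm).astype(np.float32)
    binary_plane = binarize(cropped, cam_cfg.binarize_threshold)
    deriv_plane = derivative(cropped, cam_cfg.gradient_cap)
    planes = np.stack([depth_plane, binary_plane, deriv_plane], axis=-1)
    return ChannelStack(planes=planes, camera=frame.camera)
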