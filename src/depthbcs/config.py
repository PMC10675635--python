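"""Config serialization and provenance records for the CLI.

A run is reproducible from (config, seed); every output directory gets a
``provenance.json`` with the config dict, its hash and the seed used.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import yaml

from .depth_io import CameraView
from .preprocess import CameraPreprocess, CropWindow, PreprocessConfig
from .synthetic import BackgroundGeometry, SceneConfig

__all__ = [
    "scene_to_dict", "scene_from_dict", "preprocess_to_dict",
    "preprocess_from_dict", "load_yaml_config", "write_provenance",
    "config_hash",
]


def scene_to_dict(config: SceneConfig) -> dict:
    return {
        "sensor_shape": list(config.sensor_shape),
        "noise_sd": config.noise_sd,
        "frames_per_cow": list(config.frames_per_cow),
        "class_probs": [float(p) for p in config.class_probs],
        "mm_per_px": config.mm_per_px,
        "background": {
            "bar_range_mm": config.background.bar_range_mm,
            "bar_bands": [list(b) for b in config.background.bar_bands],
        },
    }


def scene_from_dict(d: dict) -> SceneConfig:
    bg = d.get("background", {})
    kwargs = dict(
        sensor_shape=tuple(d.get("sensor_shape", (424, 512))),
        noise_sd=float(d.get("noise_sd", 5.0)),
        frames_per_cow=tuple(d.get("frames_per_cow", (3, 7))),
        mm_per_px=d.get("mm_per_px"),
        background=BackgroundGeometry(
            bar_range_mm=float(bg.get("bar_range_mm", 1150.0)),
            bar_bands=tuple(tuple(b) for b in bg.get("bar_bands",
                                                     ((0.05, 0.10), (0.90, 0.95)))),
        ),
    )
    if "class_probs" in d:
        kwargs["class_probs"] = np.asarray(d["class_probs"], dtype=float)
    return SceneConfig(**kwargs)


def preprocess_to_dict(pp: PreprocessConfig) -> dict:
    out = {}
    for cam, cfg in pp.per_camera.items():
        out[cam.name.lower()] = {
            "distance_threshold": cfg.distance_threshold,
            "crop_window": [cfg.crop_window.top, cfg.crop_window.left,
                            cfg.crop_window.height, cfg.crop_window.width],
            "binarize_threshold": cfg.binarize_threshold,
            "gradient_cap": cfg.gradient_cap,
            "depth_norm": cfg.depth_norm,
        }
    return out


def preprocess_from_dict(d: dict) -> PreprocessConfig:
    per_camera = {}
    for cam_name, cfg in d.items():
        t, l, h, w = cfg["crop_window"]
        per_camera[CameraView.parse(cam_name)] = CameraPreprocess(
            distance_threshold=float(cfg["distance_threshold"]),
            crop_window=CropWindow(top=int(t), left=int(l), height=int(h), width=int(w)),
            binarize_threshold=float(cfg["binarize_threshold"]),
            gradient_cap=float(cfg["gradient_cap"]),
            depth_norm=cfg.get("depth_norm"),
        )
    return PreprocessConfig(per_camera=per_camera)


def load_yaml_config(path: str | Path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return data


def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_provenance(out_dir: str | Path, stage: str, config: dict, seed: int) -> Path:
    record = {"stage": stage, "seed": seed, "config": config,
              "config_hash": config_hash(config)}
    path = Path(out_dir) / "provenance.json"
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(record, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path
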