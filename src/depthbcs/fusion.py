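"""Per-camera CNN backbones and early/mid/late multi-camera fusion.

The three fusion strategies combine the cameras at different depths:

* EARLY — the 3-channel stacks of all selected cameras are resampled to a
  common shape and concatenated into one 3·|cameras|-channel input for a
  single CNN (nine channels for the full rig);
* MID — each camera feeds its own convolutional trunk; the flattened
  features are concatenated and classified by one shared dense head;
* LATE — each camera has a complete independent classifier and the final
  prediction is the equal-weight average of the per-camera probability
  vectors (an ensemble; with one member it reduces to that member).

Training minimizes class-weighted cross-entropy (cost-sensitive learning:
weights inversely proportional to per-class training counts) with Adam.

The modelling surface follows the statsmodels convention: build a
:class:`FusionClassifier` from data, call :meth:`~FusionClassifier.fit`,
and work with the returned :class:`FusionResults`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import zoom

from ._nn import Adam, Conv2D, Dense, Flatten, MaxPool2, ReLU, Sequential, softmax, \
    weighted_cross_entropy
from .depth_io import BCS_GRID, CameraView

__all__ = [
    "FusionKind", "BackboneConfig", "TrainConfig", "ModelStats",
    "PredictionRecord", "FusionDataset", "FusionModel", "FusionClassifier",
    "FusionResults", "class_weights", "build_model", "train",
    "ensemble_average", "model_stats", "predict_proba", "build_backbone",
    "fuse_probabilities", "resize_stack",
]


class FusionKind(enum.Enum):
    EARLY = "EARLY"
    MID = "MID"
    LATE = "LATE"


@dataclass(frozen=True)
class BackboneConfig:
    """Generic small CNN: 3 x [conv3x3 -> maxpool2] then dense layers."""

    conv_filters: tuple[int, ...] = (16, 32, 64)
    kernel: int = 3
    dense: tuple[int, ...] = (64,)
    n_classes: int = len(BCS_GRID)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2 or any(f < 1 for f in self.conv_filters + self.dense):
            raise ValueError("backbone dimensions must be positive")


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.001
    epochs: int = 30
    batch_size: int = 16
    class_weighting: bool = True
    checkpoint_window: tuple[int, int] = (5, 30)   # 1-based epoch band
    n_restarts: int = 2    # initializations per component; best val loss kept
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.batch_size < 1 or self.epochs < 1:
            raise ValueError("invalid training configuration")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")


@dataclass(frozen=True)
class ModelStats:
    n_params: int
    flops: int          # 2 x multiply-adds for one forward pass


@dataclass
class PredictionRecord:
    cow_id: str
    per_camera: dict[CameraView, np.ndarray]
    fused: np.ndarray
    predicted_class: int
    true_class: int


@dataclass
class FusionDataset:
    """Aligned multi-camera samples: one row = one (cow, frame, phase)."""

    X: dict[CameraView, np.ndarray]     # camera -> (N, H, W, 3) float32
    y: np.ndarray                       # (N,) class indices
    cow_ids: np.ndarray                 # (N,) strings

    def __post_init__(self) -> None:
        n = len(self.y)
        for cam, arr in self.X.items():
            if arr.shape[0] != n:
                raise ValueError(f"{cam.name}: {arr.shape[0]} samples, expected {n}")
        self.y = np.asarray(self.y, dtype=np.int64)
        self.cow_ids = np.asarray(self.cow_ids)

    @property
    def cameras(self) -> tuple[CameraView, ...]:
        return tuple(sorted(self.X, key=lambda c: c.name))

    def __len__(self) -> int:
        return len(self.y)

    def take(self, idx: np.ndarray) -> "FusionDataset":
        return FusionDataset({c: a[idx] for c, a in self.X.items()},
                             self.y[idx], self.cow_ids[idx])

    def class_counts(self, n_classes: int = len(BCS_GRID)) -> np.ndarray:
        return np.bincount(self.y, minlength=n_classes)


# ---------------------------------------------------------------------------
# Cost-sensitive class weights
# ---------------------------------------------------------------------------

def class_weights(train_counts: Sequence[int] | np.ndarray) -> np.ndarray:
    """Inverse-frequency weights, normalized so that sum_c w_c n_c = sum_c n_c.

    Each populated class then contributes equal total weight to the loss
    (w_c * n_c is constant); empty classes get weight 0.
    """
    counts = np.asarray(train_counts, dtype=np.float64)
    if counts.ndim != 1 or (counts < 0).any():
        raise ValueError("counts must be a 1-D non-negative vector")
    if counts.sum() == 0:
        raise ValueError("at least one class must have samples")
    nz = counts > 0
    w = np.zeros_like(counts)
    w[nz] = counts.sum() / (nz.sum() * counts[nz])
    return w


def ensemble_average(prob_vectors: Iterable[np.ndarray],
                     weights: Sequence[float] | None = None,
                     ) -> tuple[np.ndarray, int]:
    """Element-wise (weighted) mean of probability vectors and its argmax.

    Equal weights by default; ties break to the lowest class index.
    """
    vecs = [np.asarray(v, dtype=np.float64) for v in prob_vectors]
    if not vecs:
        raise ValueError("need at least one probability vector")
    shape = vecs[0].shape
    if any(v.shape != shape for v in vecs) or vecs[0].ndim != 1:
        raise ValueError("probability vectors must be 1-D and of equal length")
    if weights is None:
        fused = np.mean(vecs, axis=0)
    else:
        w = np.asarray(weights, dtype=np.float64)
        if len(w) != len(vecs):
            raise ValueError("one weight per vector required")
        fused = np.tensordot(w / w.sum(), np.stack(vecs), axes=1)
    return fused, int(np.argmax(fused))


def fuse_probabilities(prob_matrices: Sequence[np.ndarray],
                       weights: Sequence[float] | None = None) -> np.ndarray:
    """Row-wise ensemble average over (N, K) probability matrices."""
    mats = [np.asarray(m, dtype=np.float64) for m in prob_matrices]
    if weights is None:
        return np.mean(mats, axis=0)
    w = np.asarray(weights, dtype=np.float64)
    return np.tensordot(w / w.sum(), np.stack(mats), axes=1)


# ---------------------------------------------------------------------------
# Network construction
# ---------------------------------------------------------------------------

def _conv_trunk(in_ch: int, config: BackboneConfig,
                rng: np.random.Generator) -> Sequential:
    layers: list = []
    ch = in_ch
    for f in config.conv_filters:
        layers += [Conv2D(ch, f, config.kernel, rng=rng), ReLU(), MaxPool2()]
        ch = f
    layers.append(Flatten())
    return Sequential(layers)


def _trunk_out_dim(input_shape: tuple[int, int, int], config: BackboneConfig) -> int:
    h, w, _ = input_shape
    for _f in config.conv_filters:
        h, w = h // 2, w // 2
    if h < 1 or w < 1:
        raise ValueError(f"input {input_shape} too small for "
                         f"{len(config.conv_filters)} pooling stages")
    return h * w * config.conv_filters[-1]


def _dense_head(n_in: int, config: BackboneConfig,
                rng: np.random.Generator) -> Sequential:
    layers: list = []
    for d in config.dense:
        layers += [Dense(n_in, d, rng=rng), ReLU()]
        n_in = d
    layers.append(Dense(n_in, config.n_classes, rng=rng))
    return Sequential(layers)


def build_backbone(input_shape: tuple[int, int, int],
                   config: BackboneConfig,
                   rng: np.random.Generator | None = None) -> Sequential:
    """Full single-camera classifier for a (H, W, C) input."""
    rng = rng or np.random.default_rng(config.seed)
    trunk = _conv_trunk(input_shape[2], config, rng)
    head = _dense_head(_trunk_out_dim(input_shape, config), config, rng)
    return Sequential(trunk.layers + head.layers)


class MidNetwork:
    """Per-camera conv trunks, concatenated features, shared dense head."""

    def __init__(self, input_shapes: list[tuple[int, int, int]],
                 config: BackboneConfig, rng: np.random.Generator):
        self.trunks = [_conv_trunk(s[2], config, rng) for s in input_shapes]
        self.feat_dims = [_trunk_out_dim(s, config) for s in input_shapes]
        self.head = _dense_head(sum(self.feat_dims), config, rng)
        self.input_shapes = input_shapes

    def forward(self, xs: list[np.ndarray]) -> np.ndarray:
        feats = [t.forward(x) for t, x in zip(self.trunks, xs)]
        return self.head.forward(np.concatenate(feats, axis=1))

    def backward(self, dout: np.ndarray) -> None:
        dfeat = self.head.backward(dout)
        offset = 0
        for t, dim in zip(self.trunks, self.feat_dims):
            t.backward(dfeat[:, offset:offset + dim])
            offset += dim

    def params_grads(self):
        out = []
        for t in self.trunks:
            out.extend(t.params_grads())
        out.extend(self.head.params_grads())
        return out

    def n_params(self) -> int:
        return sum(p.size for p, _ in self.params_grads())

    def flops(self) -> int:
        total = 0
        shape_after = None
        for t, s in zip(self.trunks, self.input_shapes):
            total += t.flops(s)
        total += self.head.flops((sum(self.feat_dims),))
        return total

    def get_weights(self):
        return [p.copy() for p, _ in self.params_grads()]

    def set_weights(self, weights):
        for (p, _), w in zip(self.params_grads(), weights):
            p[...] = w


def resize_stack(arr: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Bilinear resample of (N, H, W, C) images to (N, *shape, C)."""
    if arr.shape[1:3] == tuple(shape):
        return arr
    zh = shape[0] / arr.shape[1]
    zw = shape[1] / arr.shape[2]
    return zoom(arr, (1, zh, zw, 1), order=1).astype(np.float32)


@dataclass
class FusionModel:
    """A built (possibly untrained) fusion assembly."""

    kind: FusionKind
    cameras: tuple[CameraView, ...]
    config: BackboneConfig
    input_shapes: dict[CameraView, tuple[int, int, int]]
    networks: dict[CameraView, Sequential] | None = None   # LATE
    network: Sequential | MidNetwork | None = None         # EARLY / MID
    shared_shape: tuple[int, int] | None = None            # EARLY resample target

    def early_input(self, X: dict[CameraView, np.ndarray]) -> np.ndarray:
        assert self.kind is FusionKind.EARLY and self.shared_shape is not None
        planes = [resize_stack(X[cam], self.shared_shape) for cam in self.cameras]
        return np.concatenate(planes, axis=3)

    def mid_input(self, X: dict[CameraView, np.ndarray]) -> list[np.ndarray]:
        return [X[cam] for cam in self.cameras]


def build_model(kind: FusionKind, cameras: Sequence[CameraView],
                input_shapes: dict[CameraView, tuple[int, int, int]],
                config: BackboneConfig | None = None) -> FusionModel:
    """Assemble a fusion model for the given camera subset.

    EARLY resamples every camera stack to the smallest selected crop before
    channel concatenation (per-camera crops differ; stacking needs
    congruent shapes and downsampling to the smallest preserves all crops'
    content at matched scale).
    """
    cameras = tuple(sorted(set(cameras), key=lambda c: c.name))
    if not cameras:
        raise ValueError("camera set must be non-empty")
    config = config or BackboneConfig()
    rng = np.random.default_rng(config.seed)
    model = FusionModel(kind=kind, cameras=cameras, config=config,
                        input_shapes={c: tuple(input_shapes[c]) for c in cameras})
    if kind is FusionKind.EARLY:
        shared = min((input_shapes[c][:2] for c in cameras),
                     key=lambda s: s[0] * s[1])
        n_ch = 3 * len(cameras)
        model.shared_shape = shared
        model.network = build_backbone((shared[0], shared[1], n_ch), config, rng)
    elif kind is FusionKind.MID:
        model.network = MidNetwork([input_shapes[c] for c in cameras], config, rng)
    else:
        model.networks = {c: build_backbone(input_shapes[c], config,
                                            np.random.default_rng(config.seed + i))
                          for i, c in enumerate(cameras)}
    return model


def model_stats(model: FusionModel) -> ModelStats:
    """Trainable parameter count and FLOPs (2 x multiply-adds per sample)."""
    if model.kind is FusionKind.LATE:
        assert model.networks is not None
        n = sum(net.n_params() for net in model.networks.values())
        f = sum(net.flops(model.input_shapes[c])
                for c, net in model.networks.items())
        return ModelStats(n_params=n, flops=f)
    if model.kind is FusionKind.MID:
        assert isinstance(model.network, MidNetwork)
        return ModelStats(n_params=model.network.n_params(), flops=model.network.flops())
    assert isinstance(model.network, Sequential) and model.shared_shape is not None
    shape = (model.shared_shape[0], model.shared_shape[1], 3 * len(model.cameras))
    return ModelStats(n_params=model.network.n_params(), flops=model.network.flops(shape))


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _iterate_batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start:start + batch_size]


def _fit_network(net, get_batch, n_train, val_logits_fn, config: TrainConfig,
                 weights: np.ndarray | None, y: np.ndarray, y_val: np.ndarray,
                 ) -> pd.DataFrame:
    """Generic epoch loop with best-epoch checkpointing.

    ``get_batch(idx)`` returns the network input for sample indices;
    ``val_logits_fn()`` evaluates validation logits with current weights.
    The checkpoint kept is the lowest validation loss within the
    configured epoch window (overfitting sets in quickly on small herds),
    or the overall best if training is shorter than the window.
    """
    rng = np.random.default_rng(config.seed)
    opt = Adam(net.params_grads(), lr=config.learning_rate)
    history = []
    best = (np.inf, None, -1)
    lo, hi = config.checkpoint_window
    for epoch in range(1, config.epochs + 1):
        losses = []
        for idx in _iterate_batches(n_train, config.batch_size, rng):
            logits = net.forward(get_batch(idx))
            loss, dlogits = weighted_cross_entropy(logits, y[idx], weights)
            net.backward(dlogits)
            opt.step()
            losses.append(loss)
        val_logits = val_logits_fn()
        val_loss, _ = weighted_cross_entropy(val_logits, y_val, weights)
        history.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                        "val_loss": val_loss})
        in_window = lo <= epoch <= hi
        if (in_window or config.epochs < lo) and val_loss < best[0]:
            best = (val_loss, net.get_weights(), epoch)
    if best[1] is not None:
        net.set_weights(best[1])
    hist = pd.DataFrame(history)
    hist.attrs["best_epoch"] = best[2]
    return hist


def _fit_with_restarts(net, get_batch, n_train, val_logits_fn,
                       config: TrainConfig, weights, y, y_val) -> pd.DataFrame:
    """Train from ``n_restarts`` initializations; keep the lowest-val-loss run.

    A small CNN on a small herd occasionally draws an initialization that
    never generalizes; its checkpoint validation loss flags this reliably,
    so restart selection on that loss is part of the training procedure.
    """
    from ._nn import reinitialize

    best: tuple[float, list | None, pd.DataFrame | None] = (np.inf, None, None)
    for r in range(config.n_restarts):
        run_cfg = config if r == 0 else replace_config(config,
                                                       seed=config.seed + 101 * r)
        if r > 0:
            reinitialize(net, np.random.default_rng(run_cfg.seed))
        hist = _fit_network(net, get_batch, n_train, val_logits_fn, run_cfg,
                            weights, y, y_val)
        epoch = hist.attrs["best_epoch"]
        val = float(hist["val_loss"].iloc[epoch - 1]) if epoch >= 1 \
            else float(hist["val_loss"].iloc[-1])
        if val < best[0]:
            best = (val, net.get_weights(), hist)
    assert best[1] is not None
    net.set_weights(best[1])
    hist = best[2]
    hist.attrs["restart_val_loss"] = best[0]
    return hist


def replace_config(config: TrainConfig, **kwargs) -> TrainConfig:
    return TrainConfig(**{**config.__dict__, **kwargs})


def _predict_in_batches(forward, n: int, batch=256):
    outs = [forward(np.arange(s, min(s + batch, n))) for s in range(0, n, batch)]
    return np.concatenate(outs, axis=0)


def train(model: FusionModel, train_set: FusionDataset,
          validation_set: FusionDataset, config: TrainConfig | None = None,
          ) -> dict[str, pd.DataFrame]:
    """Train a fusion model in place; returns per-component history tables.

    Cost-sensitive learning: when ``config.class_weighting`` the loss
    weights are inverse-frequency over the training class counts.
    """
    config = config or TrainConfig()
    if len(train_set) == 0:
        raise ValueError("empty training set")
    weights = class_weights(train_set.class_counts(model.config.n_classes)) \
        if config.class_weighting else None
    if weights is not None:
        nz = train_set.class_counts(model.config.n_classes) > 0
        # guard: a class absent from training cannot carry loss weight
        weights = np.where(nz, weights, 0.0)
    histories: dict[str, pd.DataFrame] = {}
    y, y_val = train_set.y, validation_set.y

    if model.kind is FusionKind.LATE:
        assert model.networks is not None
        for i, (cam, net) in enumerate(sorted(model.networks.items(),
                                              key=lambda kv: kv[0].name)):
            X, Xv = train_set.X[cam], validation_set.X[cam]
            cam_cfg = replace_config(config, seed=config.seed + i)
            histories[cam.name] = _fit_with_restarts(
                net, lambda idx, X=X: X[idx], len(train_set),
                lambda net=net, Xv=Xv: _predict_in_batches(
                    lambda idx: net.forward(Xv[idx]), len(Xv)),
                cam_cfg, weights, y, y_val)
    elif model.kind is FusionKind.EARLY:
        assert model.network is not None
        Xe = model.early_input(train_set.X)
        Xv = model.early_input(validation_set.X)
        histories["early"] = _fit_with_restarts(
            model.network, lambda idx: Xe[idx], len(train_set),
            lambda: _predict_in_batches(
                lambda idx: model.network.forward(Xv[idx]), len(Xv)),
            config, weights, y, y_val)
    else:
        assert isinstance(model.network, MidNetwork)
        Xs = model.mid_input(train_set.X)
        Xvs = model.mid_input(validation_set.X)
        histories["mid"] = _fit_with_restarts(
            model.network, lambda idx: [x[idx] for x in Xs], len(train_set),
            lambda: _predict_in_batches(
                lambda idx: model.network.forward([x[idx] for x in Xvs]),
                len(validation_set)),
            config, weights, y, y_val)
    return histories


def predict_proba(model: FusionModel, data: FusionDataset,
                  cameras: Sequence[CameraView] | None = None,
                  ) -> tuple[np.ndarray, dict[CameraView, np.ndarray]]:
    """(fused (N, K) probabilities, per-camera probabilities).

    For LATE a camera subset may be fused post hoc; EARLY and MID are fixed
    to the cameras they were built with.
    """
    n = len(data)
    if model.kind is FusionKind.LATE:
        assert model.networks is not None
        cams = tuple(sorted(cameras or model.cameras, key=lambda c: c.name))
        missing = set(cams) - set(model.cameras)
        if missing:
            raise ValueError(f"model has no member for {sorted(c.name for c in missing)}")
        per_cam = {}
        for cam in cams:
            net = model.networks[cam]
            X = data.X[cam]
            logits = _predict_in_batches(lambda idx: net.forward(X[idx]), n)
            per_cam[cam] = softmax(logits)
        fused = fuse_probabilities([per_cam[c] for c in cams])
        return fused, per_cam
    if cameras is not None and tuple(sorted(cameras, key=lambda c: c.name)) != model.cameras:
        raise ValueError(f"{model.kind.name} fusion is fixed to its camera set")
    if model.kind is FusionKind.EARLY:
        Xe = model.early_input(data.X)
        logits = _predict_in_batches(lambda idx: model.network.forward(Xe[idx]), n)
    else:
        Xs = model.mid_input(data.X)
        logits = _predict_in_batches(
            lambda idx: model.network.forward([x[idx] for x in Xs]), n)
    p = softmax(logits)
    return p, {cam: p for cam in model.cameras}


# ---------------------------------------------------------------------------
# statsmodels-style modelling surface
# ---------------------------------------------------------------------------

class FusionClassifier:
    """Multi-camera BCS classifier built from aligned channel-stack arrays.

    Parameters
    ----------
    train_set, validation_set
        Aligned :class:`FusionDataset` objects. If ``validation_set`` is
        omitted, a cow-level 15% slice of the training cows is held out.
    kind
        Fusion strategy (default LATE, the study's best performer).
    """

    def __init__(self, train_set: FusionDataset,
                 validation_set: FusionDataset | None = None,
                 kind: FusionKind = FusionKind.LATE,
                 cameras: Sequence[CameraView] | None = None,
                 backbone: BackboneConfig | None = None):
        self.kind = kind
        self.backbone = backbone or BackboneConfig()
        cams = tuple(sorted(cameras or train_set.cameras, key=lambda c: c.name))
        if validation_set is None:
            train_set, validation_set = self._holdout(train_set, self.backbone.seed)
        self.train_set, self.validation_set = train_set, validation_set
        shapes = {c: train_set.X[c].shape[1:] for c in cams}
        self.model = build_model(kind, cams, shapes, self.backbone)

    @staticmethod
    def _holdout(data: FusionDataset, seed: int,
                 fraction: float = 0.15) -> tuple[FusionDataset, FusionDataset]:
        cows = np.array(sorted(set(data.cow_ids.tolist())))
        rng = np.random.default_rng(seed)
        n_val = max(1, int(round(fraction * len(cows))))
        val_cows = set(rng.choice(cows, size=n_val, replace=False).tolist())
        mask = np.array([c in val_cows for c in data.cow_ids])
        return data.take(np.where(~mask)[0]), data.take(np.where(mask)[0])

    def fit(self, config: TrainConfig | None = None) -> "FusionResults":
        config = config or TrainConfig()
        histories = train(self.model, self.train_set, self.validation_set, config)
        return FusionResults(self, config, histories)


class FusionResults:
    """Fitted fusion model: predictions, histories, metrics, summary."""

    def __init__(self, classifier: FusionClassifier, config: TrainConfig,
                 histories: dict[str, pd.DataFrame]):
        self.classifier = classifier
        self.model = classifier.model
        self.train_config = config
        self.histories = histories
        counts = classifier.train_set.class_counts(classifier.backbone.n_classes)
        self.class_weights_ = class_weights(counts) if config.class_weighting else None

    def predict_proba(self, data: FusionDataset,
                      cameras: Sequence[CameraView] | None = None) -> np.ndarray:
        fused, _ = predict_proba(self.model, data, cameras)
        return fused

    def predict(self, data: FusionDataset,
                cameras: Sequence[CameraView] | None = None) -> np.ndarray:
        return np.argmax(self.predict_proba(data, cameras), axis=1)

    def prediction_records(self, data: FusionDataset,
                           cameras: Sequence[CameraView] | None = None,
                           ) -> list[PredictionRecord]:
        fused, per_cam = predict_proba(self.model, data, cameras)
        recs = []
        for i in range(len(data)):
            recs.append(PredictionRecord(
                cow_id=str(data.cow_ids[i]),
                per_camera={c: per_cam[c][i] for c in per_cam},
                fused=fused[i],
                predicted_class=int(np.argmax(fused[i])),
                true_class=int(data.y[i])))
        return recs

    def evaluate(self, data: FusionDataset,
                 cameras: Sequence[CameraView] | None = None):
        from .evaluate import evaluate_predictions
        return evaluate_predictions(data.y, self.predict(data, cameras))

    def stats(self) -> ModelStats:
        return model_stats(self.model)

    def summary(self) -> str:
        st = self.stats()
        lines = [
            f"{self.model.kind.name} fusion over "
            f"{', '.join(c.name for c in self.model.cameras)}",
            f"  backbone: conv {self.classifier.backbone.conv_filters}, "
            f"dense {self.classifier.backbone.dense}, "
            f"{self.classifier.backbone.n_classes} classes",
            f"  trainable parameters: {st.n_params:,}   FLOPs: {st.flops:,}",
            f"  train samples: {len(self.classifier.train_set)}   "
            f"validation samples: {len(self.classifier.validation_set)}",
        ]
        if self.class_weights_ is not None:
            w = ", ".join(f"{x:.2f}" for x in self.class_weights_)
            lines.append(f"  class weights: [{w}]")
        for name, hist in self.histories.items():
            best = hist.attrs.get("best_epoch", -1)
            row = hist.iloc[best - 1] if best >= 1 else hist.iloc[-1]
            lines.append(f"  {name}: best epoch {best} "
                         f"(train loss {row['train_loss']:.3f}, "
                         f"val loss {row['val_loss']:.3f})")
        return "\n".join(lines)
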