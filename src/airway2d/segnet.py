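"""U-Net airway segmenters: configuration, augmentation, training, inference.

Two variants are exposed: a shallow network with 2 convolutions per block
(``unet18``) and a deep one with 4 (``unet36``), over a fixed 4-level
encoder-decoder topology with skip connections.  Training uses per-pixel
cross entropy and Adam.  ``UNetSegmenter`` wraps the whole recipe as a
scikit-learn style estimator (``fit`` / ``predict`` / ``score``) so it
composes with sklearn tooling; the module-level functions are thin wrappers
used by the command-line interface.

The reference training recipe is learning rate 1e-4, batch size 8, Adam,
200 epochs at 400x400 input; the ``desk`` preset scales the problem to what
a single CPU handles in minutes (96x96 phantoms, 64x64 input, 3 levels,
8 base channels) without changing any code path.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from skimage import transform as sktransform
from sklearn.base import BaseEstimator

from ._nn import Adam, UNet, softmax_cross_entropy
from .imgio import LabelMap, NATIVE_HEIGHT_PX, PIXEL_SPACING_MM
from .phantom import PhantomSample

__all__ = [
    "NetConfig", "TrainConfig", "AugmentSpec", "build_model", "augment_pair",
    "train", "predict", "UNetSegmenter", "save_model", "load_model",
    "desk_net_config", "desk_train_config", "reference_augmentation",
]

VARIANT_CONVS = {"unet18": 2, "unet36": 4}


@dataclass(frozen=True)
class NetConfig:
    """Architecture parameters of the U-Net family."""

    variant: str = "unet18"
    base_channels: int = 32
    depth_levels: int = 4
    num_classes: int = 4
    input_size_px: int = 400

    def __post_init__(self) -> None:
        if self.variant not in VARIANT_CONVS:
            raise ValueError(f"variant must be one of {sorted(VARIANT_CONVS)}")
        if self.base_channels < 1 or self.depth_levels < 1:
            raise ValueError("base_channels and depth_levels must be >= 1")
        if self.input_size_px % 2**self.depth_levels:
            raise ValueError(
                f"input_size_px={self.input_size_px} must be divisible by "
                f"2**depth_levels={2**self.depth_levels}")

    @property
    def convs_per_block(self) -> int:
        return VARIANT_CONVS[self.variant]


@dataclass(frozen=True)
class AugmentSpec:
    """Geometric augmentation ranges; the default is the identity."""

    resize_range: tuple[float, float] = (1.0, 1.0)
    crop_fraction: float = 1.0
    hflip_prob: float = 0.0
    rotation_max_deg: float = 0.0

    def __post_init__(self) -> None:
        lo, hi = self.resize_range
        if not (0 < lo <= hi):
            raise ValueError("resize_range must satisfy 0 < lo <= hi")
        if not (0 < self.crop_fraction <= 1):
            raise ValueError("crop_fraction must be in (0, 1]")
        if not (0 <= self.hflip_prob <= 1):
            raise ValueError("hflip_prob must be in [0, 1]")
        if self.rotation_max_deg < 0:
            raise ValueError("rotation_max_deg must be >= 0")

    @property
    def is_identity(self) -> bool:
        return (self.resize_range == (1.0, 1.0) and self.crop_fraction == 1.0
                and self.hflip_prob == 0.0 and self.rotation_max_deg == 0.0)


def reference_augmentation() -> AugmentSpec:
    """Resize/crop/flip/rotate ranges of the reference training recipe."""
    return AugmentSpec(resize_range=(0.9, 1.1), crop_fraction=0.9,
                       hflip_prob=0.5, rotation_max_deg=10.0)


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation parameters (Adam throughout)."""

    learning_rate: float = 1e-4
    batch_size: int = 8
    epochs: int = 200
    seed: int = 0
    augmentation: AugmentSpec = field(default_factory=AugmentSpec)
    class_weighting: bool = False
    validation_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be >= 1")
        if not (0 <= self.validation_fraction < 1):
            raise ValueError("validation_fraction must be in [0, 1)")


def desk_net_config(variant: str = "unet18") -> NetConfig:
    return NetConfig(variant=variant, base_channels=8, depth_levels=3,
                     input_size_px=64)


def desk_train_config(epochs: int = 40, seed: int = 0) -> TrainConfig:
    return TrainConfig(learning_rate=1e-3, batch_size=8, epochs=epochs,
                       seed=seed)


def build_model(cfg: NetConfig, seed: int = 0) -> UNet:
    """Instantiate an untrained network for the given architecture.

    The network takes two input channels: the grayscale image and a
    normalised row-coordinate plane.  The airway segment boundaries are
    row-level conventions (nasal turbinate, hard palate, soft-palate
    margin); the coordinate channel gives convolutions, which are
    translation-equivariant, direct access to vertical position.
    """
    return UNet(in_channels=2, num_classes=cfg.num_classes,
                base_channels=cfg.base_channels,
                depth_levels=cfg.depth_levels,
                convs_per_block=cfg.convs_per_block, seed=seed)


def _with_coords(imgs: np.ndarray) -> np.ndarray:
    """Stack a [0,1] row-coordinate channel onto (N, H, W) images."""
    n, h, w = imgs.shape
    rows = np.linspace(0.0, 1.0, h, dtype=np.float32)
    coord = np.broadcast_to(rows[:, None], (h, w))
    coord = np.broadcast_to(coord, (n, h, w))
    return np.stack([imgs.astype(np.float32), coord.astype(np.float32)],
                    axis=1)


# ---------------------------------------------------------------------------
# Augmentation


def augment_pair(image: np.ndarray, labels: np.ndarray, spec: AugmentSpec,
                 seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Apply one randomly drawn geometric transform to an image/label pair.

    The same transform is applied to both; label resampling is always
    nearest-neighbour so values stay in {0,1,2,3}.  Deterministic per seed;
    the identity spec returns the inputs unchanged.
    """
    image = np.asarray(image)
    labels = np.asarray(labels)
    if image.shape != labels.shape:
        raise ValueError("image and labels must share shape")
    if spec.is_identity:
        return image, labels
    rng = np.random.default_rng(seed)
    h, w = image.shape
    angle = rng.uniform(-spec.rotation_max_deg, spec.rotation_max_deg)
    scale = rng.uniform(*spec.resize_range)
    flip = rng.random() < spec.hflip_prob
    # crop window (relative size crop_fraction) at a random offset
    ch = max(1, int(round(h * spec.crop_fraction)))
    cw = max(1, int(round(w * spec.crop_fraction)))
    oy = int(rng.integers(0, h - ch + 1))
    ox = int(rng.integers(0, w - cw + 1))

    img, lab = image.astype(np.float64), labels
    if angle != 0.0:
        img = sktransform.rotate(img, angle, order=1, mode="edge")
        lab = sktransform.rotate(lab.astype(np.float64), angle, order=0,
                                 mode="constant", cval=0).astype(labels.dtype)
    if scale != 1.0:
        nh, nw = max(1, int(round(h * scale))), max(1, int(round(w * scale)))
        img = sktransform.resize(img, (nh, nw), order=1, mode="edge",
                                 anti_aliasing=scale < 1)
        lab = sktransform.resize(lab.astype(np.float64), (nh, nw), order=0,
                                 mode="edge", anti_aliasing=False
                                 ).astype(labels.dtype)
        # centre-crop or edge-pad back to the original size
        img = _fit_to(img, h, w, fill=float(np.median(img)))
        lab = _fit_to(lab, h, w, fill=0)
    if spec.crop_fraction < 1.0:
        img = sktransform.resize(img[oy:oy + ch, ox:ox + cw], (h, w),
                                 order=1, mode="edge", anti_aliasing=False)
        lab = sktransform.resize(
            lab[oy:oy + ch, ox:ox + cw].astype(np.float64), (h, w), order=0,
            mode="edge", anti_aliasing=False).astype(labels.dtype)
    if flip:
        img, lab = img[:, ::-1], lab[:, ::-1]
    return np.ascontiguousarray(img), np.ascontiguousarray(lab)


def _fit_to(arr: np.ndarray, h: int, w: int, fill) -> np.ndarray:
    ah, aw = arr.shape
    if ah >= h:
        top = (ah - h) // 2
        arr = arr[top:top + h]
    if aw >= w:
        left = (aw - w) // 2
        arr = arr[:, left:left + w]
    ph, pw = h - arr.shape[0], w - arr.shape[1]
    if ph > 0 or pw > 0:
        arr = np.pad(arr, ((ph // 2, ph - ph // 2), (pw // 2, pw - pw // 2)),
                     constant_values=fill)
    return arr


# ---------------------------------------------------------------------------
# Training / inference


def _coerce_pairs(samples) -> list[tuple[np.ndarray, np.ndarray]]:
    pairs = []
    for s in samples:
        if isinstance(s, PhantomSample):
            pairs.append((s.image, s.labels.grid))
        else:
            img, lab = s
            lab = lab.grid if isinstance(lab, LabelMap) else np.asarray(lab)
            pairs.append((np.asarray(img, dtype=np.float64), lab))
    return pairs


def _resize_pair(img: np.ndarray, lab: np.ndarray,
                 size: int) -> tuple[np.ndarray, np.ndarray]:
    if img.shape == (size, size):
        return img, lab
    img_r = sktransform.resize(img, (size, size), order=1, mode="edge",
                               anti_aliasing=img.shape[0] > size)
    lab_r = sktransform.resize(lab.astype(np.float64), (size, size), order=0,
                               mode="edge", anti_aliasing=False)
    return img_r, lab_r.astype(np.int64)


def train(model: UNet, samples, tcfg: TrainConfig,
          input_size: int | None = None) -> tuple[UNet, list[float]]:
    """Train ``model`` in place; returns it with the per-epoch loss trace.

    Inputs are resized to ``input_size`` (default: inferred square size of
    the first sample) with nearest-neighbour label resampling.  Each epoch
    shuffles the sample order; augmentation (if configured) draws one
    transform per sample per epoch.  Fixed seeds make the trace
    reproducible on a given machine.
    """
    pairs = _coerce_pairs(samples)
    if not pairs:
        raise ValueError("training requires at least one sample")
    size = input_size if input_size is not None else pairs[0][0].shape[0]
    L = model.config["depth_levels"]
    if size % 2**L:
        raise ValueError(f"input size {size} not divisible by {2**L}")
    pairs = [_resize_pair(i, l, size) for i, l in pairs]
    all_labels = np.unique(np.concatenate([l.ravel() for _, l in pairs]))
    if len(all_labels) < 2:
        raise ValueError(
            f"degenerate training labels (single class {all_labels})")

    weights = None
    if tcfg.class_weighting:
        freq = np.bincount(
            np.concatenate([l.ravel() for _, l in pairs]),
            minlength=model.config["num_classes"]).astype(np.float64)
        freq = np.maximum(freq, 1)
        weights = freq.sum() / (len(freq) * freq)

    rng = np.random.default_rng(tcfg.seed)
    opt = Adam(model.params(), lr=tcfg.learning_rate)
    n = len(pairs)
    trace: list[float] = []
    for epoch in range(tcfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, tcfg.batch_size):
            idx = order[start:start + tcfg.batch_size]
            imgs, labs = [], []
            for i in idx:
                img, lab = pairs[i]
                if not tcfg.augmentation.is_identity:
                    img, lab = augment_pair(
                        img, lab, tcfg.augmentation,
                        seed=int(rng.integers(0, 2**31 - 1)))
                imgs.append(img)
                labs.append(lab)
            x = _with_coords(np.stack(imgs))
            y = np.stack(labs).astype(np.int64)
            logits = model.forward(x, train=True)
            loss, grad = softmax_cross_entropy(logits, y,
                                               class_weights=weights)
            model.zero_grad()
            model.backward(grad)
            opt.step()
            losses.append(loss)
        trace.append(float(np.mean(losses)))
    return model, trace


def predict(model: UNet, image: np.ndarray, input_size: int | None = None,
            native_shape: tuple[int, int] | None = None,
            pixel_spacing_mm: float = PIXEL_SPACING_MM,
            native_height_px: int | None = None) -> LabelMap:
    """Segment one grayscale image.

    The image is resized to the network input size, scores are computed in
    eval mode (batch-norm running statistics), and the per-pixel argmax is
    resized back to the native shape by nearest-neighbour.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError("image must be 2D grayscale")
    native = native_shape if native_shape is not None else image.shape
    L = model.config["depth_levels"]
    size = input_size if input_size is not None else image.shape[0]
    if size % 2**L:
        raise ValueError(f"input size {size} not divisible by {2**L}")
    img_r, _ = _resize_pair(image, np.zeros_like(image, dtype=np.int64), size)
    logits = model.forward(_with_coords(img_r[None]), train=False)
    pred = np.argmax(logits[0], axis=0)
    if pred.shape != tuple(native):
        pred = sktransform.resize(pred.astype(np.float64), native, order=0,
                                  mode="edge", anti_aliasing=False
                                  ).astype(np.int64)
    if native_height_px is None:
        native_height_px = native[0]
    return LabelMap(pred, pixel_spacing_mm=pixel_spacing_mm,
                    native_height_px=native_height_px)


# ---------------------------------------------------------------------------
# Persistence

FORMAT_VERSION = 1


def save_model(model: UNet, path: str | Path,
               net_config: NetConfig | None = None,
               input_size: int | None = None) -> None:
    """Save weights + architecture to a versioned ``.npz`` checkpoint."""
    meta = dict(format_version=FORMAT_VERSION, config=model.config,
                input_size=input_size,
                net_config=asdict(net_config) if net_config else None)
    np.savez_compressed(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **model.state_dict())


def load_model(path: str | Path) -> tuple[UNet, dict]:
    """Load a checkpoint; returns the model and its metadata."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        if meta.get("format_version") != FORMAT_VERSION:
            raise ValueError("unsupported checkpoint format version")
        model = UNet(**meta["config"])
        model.load_state_dict({k: data[k] for k in data.files
                               if k != "__meta__"})
    return model, meta


# ---------------------------------------------------------------------------
# Estimator


class UNetSegmenter(BaseEstimator):
    """Scikit-learn style estimator around the U-Net training recipe.

    Parameters mirror :class:`NetConfig` and :class:`TrainConfig`.  ``fit``
    accepts a sequence of 2D grayscale images and label grids (or
    :class:`~airway2d.phantom.PhantomSample` objects via ``fit_samples``);
    ``predict`` returns a label grid per image.

    Attributes (after fit)
    ----------------------
    model_ : UNet
        The trained network.
    loss_trace_ : list of float
        Mean training cross entropy per epoch.
    classes_ : ndarray
        The label values the network emits, ``[0, 1, 2, 3]``.
    """

    def __init__(self, variant: str = "unet18", base_channels: int = 32,
                 depth_levels: int = 4, input_size_px: int = 400,
                 learning_rate: float = 1e-4, batch_size: int = 8,
                 epochs: int = 200, seed: int = 0,
                 augmentation: AugmentSpec | None = None,
                 class_weighting: bool = False):
        self.variant = variant
        self.base_channels = base_channels
        self.depth_levels = depth_levels
        self.input_size_px = input_size_px
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.seed = seed
        self.augmentation = augmentation
        self.class_weighting = class_weighting

    @classmethod
    def desk(cls, variant: str = "unet18", epochs: int = 40,
             seed: int = 0) -> "UNetSegmenter":
        """CPU-scale preset: 64x64 input, 3 levels, 8 base channels."""
        net = desk_net_config(variant)
        tr = desk_train_config(epochs=epochs, seed=seed)
        return cls(variant=variant, base_channels=net.base_channels,
                   depth_levels=net.depth_levels,
                   input_size_px=net.input_size_px,
                   learning_rate=tr.learning_rate, batch_size=tr.batch_size,
                   epochs=epochs, seed=seed)

    def _net_config(self) -> NetConfig:
        return NetConfig(variant=self.variant,
                         base_channels=self.base_channels,
                         depth_levels=self.depth_levels,
                         input_size_px=self.input_size_px)

    def _train_config(self) -> TrainConfig:
        aug = self.augmentation if self.augmentation is not None \
            else AugmentSpec()
        return TrainConfig(learning_rate=self.learning_rate,
                           batch_size=self.batch_size, epochs=self.epochs,
                           seed=self.seed, augmentation=aug,
                           class_weighting=self.class_weighting)

    def fit(self, X: Sequence[np.ndarray], y: Sequence) -> "UNetSegmenter":
        if len(X) != len(y):
            raise ValueError("X and y must have equal length")
        return self.fit_samples(list(zip(X, y)))

    def fit_samples(self, samples) -> "UNetSegmenter":
        cfg = self._net_config()
        self.model_ = build_model(cfg, seed=self.seed)
        self.model_, self.loss_trace_ = train(
            self.model_, samples, self._train_config(),
            input_size=cfg.input_size_px)
        self.classes_ = np.arange(cfg.num_classes)
        return self

    def predict(self, X: Sequence[np.ndarray]) -> list[np.ndarray]:
        if not hasattr(self, "model_"):
            raise RuntimeError("estimator is not fitted")
        return [predict(self.model_, img,
                        input_size=self.input_size_px).grid for img in X]

    def predict_labelmaps(self, X: Sequence[np.ndarray],
                          pixel_spacing_mm: float = PIXEL_SPACING_MM,
                          native_height_px: int | None = None
                          ) -> list[LabelMap]:
        if not hasattr(self, "model_"):
            raise RuntimeError("estimator is not fitted")
        return [predict(self.model_, img, input_size=self.input_size_px,
                        pixel_spacing_mm=pixel_spacing_mm,
                        native_height_px=native_height_px) for img in X]

    def score(self, X: Sequence[np.ndarray], y: Sequence) -> float:
        """Mean macro IoU over the airway classes."""
        from .segmetrics import macro_iou
        preds = self.predict(X)
        ys = [t.grid if isinstance(t, LabelMap) else np.asarray(t) for t in y]
        return float(np.mean([macro_iou(p, t) for p, t in zip(preds, ys)]))
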