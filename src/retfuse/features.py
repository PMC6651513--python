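"""Feature CNN, modality recognition, overlays and 16-D feature fusion.

A 14-layer convolutional network (input with zero-center normalization,
three 9x9 convolution blocks with batch normalization and ReLU, two 2x2
max pools, one 50% dropout, and a final fully connected layer emitting
eight features) is trained with a detachable 2-class softmax head on
healthy/ME labels; at inference the head is dropped and the eight
activations of the fully connected layer are the modality's feature
descriptor. Eight OCT features and eight fundus features concatenate
into the 16-D vector the ensemble classifies. The same architecture,
trained on modality labels, recognizes whether a scan is OCT or fundus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.transform import resize

from . import nn
from .oct_analysis import FindingMasks, LayerBoundarySet
from .scan_io import DatasetManifest, RetinalScan, read_scan


def softmax(x) -> np.ndarray:
    """Shift-stable softmax; output is nonnegative and sums to one."""
    return nn.softmax(x)


@dataclass
class CNNConfig:
    """Architecture description of the 14-layer feature CNN.

    The default geometry is a 227 x 227 x 3 input, 9 x 9 kernels with
    channel widths (8, 16, 32) and an 8-unit fully connected output.
    ``input_size`` is parametric so the same layer pattern can run at
    reduced resolution.
    """

    input_size: int = 227
    in_channels: int = 3
    kernel: int = 9
    channels: tuple[int, int, int] = (8, 16, 32)
    n_features: int = 8
    dropout: float = 0.5

    def layer_descriptions(self) -> list[str]:
        c1, c2, c3 = self.channels
        s = self.input_size
        k = self.kernel
        return [
            f"Input {s}x{s}x{self.in_channels} with zero-center normalization",
            f"Convolution {c1} {k}x{k}x{self.in_channels}, stride 1, padding same",
            f"Batch normalization ({c1} channels)",
            "ReLU",
            "Max pooling 2x2, stride 2",
            f"Convolution {c2} {k}x{k}x{c1}, stride 1, padding same",
            f"Batch normalization ({c2} channels)",
            "ReLU",
            f"Dropout {self.dropout:.0%}",
            "Max pooling 2x2, stride 2",
            f"Convolution {c3} {k}x{k}x{c2}, stride 1, padding same",
            f"Batch normalization ({c3} channels)",
            "ReLU",
            f"Fully connected -> {self.n_features} features",
        ]


@dataclass
class FeatureVector:
    """The fused 16-D descriptor: f1..f8 OCT, f9..f16 fundus."""

    values: np.ndarray
    label: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size != 16:
            raise ValueError("a fused feature vector has exactly 16 entries")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")


@dataclass
class TrainingLog:
    """Per-iteration accuracy and cross-entropy loss, validation every 100 iters."""

    rows: list[tuple[int, float, float, bool]] = field(default_factory=list)

    def record(self, iteration: int, accuracy: float, loss: float, is_validation: bool) -> None:
        if loss < -1e-9:
            raise ValueError("cross-entropy loss must be nonnegative")
        self.rows.append((iteration, accuracy, loss, is_validation))

    @property
    def final_training_accuracy(self) -> float:
        train_rows = [r for r in self.rows if not r[3]]
        return train_rows[-1][1] if train_rows else float("nan")

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            self.rows, columns=["iteration", "accuracy", "loss", "is_validation"]
        ).to_csv(path, index=False)


class _ZeroCenter(nn.Layer):
    """Input normalization: subtract the training-set mean intensity."""

    def __init__(self) -> None:
        super().__init__()
        self.mean = np.float32(0.5)

    def forward(self, x, train, rng):
        return x - self.mean

    def backward(self, dout):
        return dout


class FeatureCNN:
    """The 14-layer feature network plus a detachable classification head."""

    def __init__(self, config: CNNConfig, n_classes: int = 2, seed: int = 0) -> None:
        if n_classes < 2:
            raise ValueError("the classification head needs at least two classes")
        if config.kernel % 2 == 0 or config.kernel < 1:
            raise ValueError("kernel size must be odd and positive")
        if len(config.channels) != 3:
            raise ValueError("the architecture uses exactly three convolution blocks")
        self.config = config
        self.n_classes = n_classes
        c1, c2, c3 = config.channels
        layers: list[nn.Layer] = [
            _ZeroCenter(),
            nn.Conv2D(c1, config.kernel),
            nn.BatchNorm(),
            nn.ReLU(),
            nn.MaxPool2(),
            nn.Conv2D(c2, config.kernel),
            nn.BatchNorm(),
            nn.ReLU(),
            nn.Dropout(config.dropout),
            nn.MaxPool2(),
            nn.Conv2D(c3, config.kernel),
            nn.BatchNorm(),
            nn.ReLU(),
            nn.Flatten(),
            nn.Dense(config.n_features),   # the Table layer emitting the 8 features
            nn.Dense(n_classes),           # detachable training head
        ]
        s = config.input_size
        self.net = nn.Sequential(layers, (s, s, config.in_channels), seed=seed)
        self.feature_layer_index = 14
        self.class_names: list[str] | None = None
        self.trained = False

    @property
    def n_layers(self) -> int:
        """Architecture depth as described (flatten is plumbing, head detachable)."""
        return 14

    def conv_parameter_counts(self) -> list[int]:
        return [l.n_parameters for l in self.net.layers if isinstance(l, nn.Conv2D)]

    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 3:
            x = x[None]
        expected = self.net.input_shape
        if x.shape[1:] != expected:
            raise ValueError(f"expected input of shape {expected}, got {x.shape[1:]}")
        return x

    def features(self, x: np.ndarray) -> np.ndarray:
        """Eight-feature descriptor per input; deterministic (dropout off)."""
        out = self._check_input(x)
        for layer in self.net.layers[: self.feature_layer_index + 1]:
            out = layer.forward(out, False, self.net.rng)
        return np.asarray(out, dtype=float)

    def logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.net.forward(self._check_input(x), train=train)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.logits(x, train=False))


def build_feature_cnn(config: CNNConfig | None = None, n_classes: int = 2,
                      seed: int = 0) -> FeatureCNN:
    """Construct the untrained 14-layer feature CNN with a softmax head."""
    return FeatureCNN(config or CNNConfig(), n_classes=n_classes, seed=seed)


def fit_cnn(
    model: FeatureCNN,
    x: np.ndarray,
    y: np.ndarray,
    class_names: list[str],
    epochs: int = 30,
    lr: float = 0.001,
    momentum: float = 0.9,
    batch_size: int = 16,
    seed: int = 0,
    x_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
) -> TrainingLog:
    """SGD training of the CNN on in-memory arrays (NHWC in [0, 1]).

    Minimizes softmax cross-entropy; the log records accuracy and loss at
    every iteration and a validation point every 100 iterations when a
    validation set is supplied. Fully seeded: shuffling and dropout come
    from one generator derived from ``seed``.
    """
    x = np.asarray(x, dtype=np.float32)
    y = np.asarray(y, dtype=int)
    if np.unique(y).size < 2:
        raise ValueError("training data must contain at least two classes")
    model.class_names = list(class_names)
    zero_center = model.net.layers[0]
    zero_center.mean = np.float32(x.mean())
    rng = np.random.default_rng(seed)
    model.net.rng = rng  # dropout shares the training generator
    opt = nn.SGD(model.net, lr=lr, momentum=momentum)
    log = TrainingLog()
    n = x.shape[0]
    iteration = 0
    for _ in range(epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            xb, yb = x[idx], y[idx]
            logits = model.net.forward(xb, train=True)
            probs = softmax(logits)
            loss = nn.cross_entropy(probs, yb)
            acc = float((probs.argmax(axis=1) == yb).mean())
            dlogits = probs.copy()
            dlogits[np.arange(len(yb)), yb] -= 1.0
            model.net.backward((dlogits / len(yb)).astype(np.float32))
            opt.step()
            iteration += 1
            log.record(iteration, acc, loss, False)
            if x_val is not None and iteration % 100 == 0:
                model.net.recalibrate_batchnorm(x, batch_size)
                vprobs = model.predict_proba(x_val)
                vloss = nn.cross_entropy(vprobs, np.asarray(y_val, int))
                vacc = float((vprobs.argmax(axis=1) == y_val).mean())
                log.record(iteration, vacc, vloss, True)
    # inference-time batch-norm statistics from clean full-data passes
    model.net.recalibrate_batchnorm(x, batch_size)
    model.trained = True
    return log


def prepare_input(image: np.ndarray | RetinalScan, size: int) -> np.ndarray:
    """Resize to the network input (bilinear) and replicate gray to 3 channels."""
    arr = image.pixels if isinstance(image, RetinalScan) else np.asarray(image, float)
    if arr.ndim == 2:
        arr = np.repeat(arr[:, :, None], 3, axis=2)
    out = resize(arr, (size, size), order=1, anti_aliasing=False, preserve_range=True)
    return np.clip(out, 0.0, 1.0).astype(np.float32)


def train_cnn(
    model: FeatureCNN,
    manifest: DatasetManifest,
    root: str | Path = ".",
    label_field: str = "label",
    epochs: int = 30,
    lr: float = 0.001,
    momentum: float = 0.9,
    batch_size: int = 16,
    seed: int = 0,
) -> TrainingLog:
    """Train from a manifest on disk: loads, resizes and fits.

    ``label_field`` selects the supervision signal: ``label`` (healthy/me,
    the feature CNN) or ``modality`` (oct/fundus, the recognition CNN).
    """
    root = Path(root)
    size = model.config.input_size

    def load_split(split: str) -> tuple[np.ndarray, np.ndarray, list[str]]:
        recs = manifest.subset(split=split).records
        targets = sorted({getattr(r, label_field) for r in recs})
        xs = [prepare_input(read_scan(root / r.path), size) for r in recs]
        ys = [targets.index(getattr(r, label_field)) for r in recs]
        return (np.stack(xs) if xs else np.empty((0, size, size, 3), np.float32),
                np.asarray(ys, int), targets)

    x, y, classes = load_split("train")
    if len(classes) < 2:
        raise ValueError("training split must contain at least two classes")
    xv, yv, _ = load_split("validation")
    return fit_cnn(
        model, x, y, classes, epochs=epochs, lr=lr, momentum=momentum,
        batch_size=batch_size, seed=seed,
        x_val=xv if len(xv) else None, y_val=yv if len(yv) else None,
    )


def recognize_modality(model: FeatureCNN, scan: RetinalScan) -> tuple[str, float]:
    """Classify a scan as oct or fundus and tag it; returns (modality, prob)."""
    if not model.trained or model.class_names is None:
        raise RuntimeError("modality model has not been trained")
    x = prepare_input(scan, model.config.input_size)
    probs = model.predict_proba(x)[0]
    i = int(np.argmax(probs))
    modality = model.class_names[i]
    scan.modality = modality
    return modality, float(probs[i])


# fixed, arbitrary overlay color coding (R, G, B); chosen so each finding
# class perturbs a distinct channel combination of the grayscale base
OVERLAY_COLORS = {
    "fluid": (1.0, 0.0, 0.0),
    "vessels": (0.0, 0.3, 1.0),
    "exudates": (1.0, 1.0, 0.0),
    "boundaries": (0.0, 0.0, 1.0),
}


def overlay_findings(
    scan: RetinalScan,
    masks: FindingMasks | None = None,
    layers: LayerBoundarySet | None = None,
) -> np.ndarray:
    """Burn finding masks and boundary curves into a 3-channel copy.

    The original scan is untouched; empty masks reproduce the scan
    replicated to three channels, and the operation is idempotent for
    identical inputs (colors are assigned, not blended).
    """
    base = scan.pixels
    if base.ndim == 2:
        out = np.repeat(base[:, :, None], 3, axis=2).copy()
    else:
        out = base.copy()
    shape = out.shape[:2]

    def paint(mask: np.ndarray | None, color: tuple[float, float, float]) -> None:
        if mask is None:
            return
        mask = np.asarray(mask, bool)
        if mask.shape != shape:
            raise ValueError("mask shape does not match the scan")
        out[mask] = color

    if masks is not None:
        paint(masks.fluid, OVERLAY_COLORS["fluid"])
        paint(masks.exudates, OVERLAY_COLORS["exudates"])
        paint(masks.vessels, OVERLAY_COLORS["vessels"])
    if layers is not None:
        if layers.ilm.size != shape[1]:
            raise ValueError("boundary curves do not match the scan width")
        for b in layers.boundaries:
            cols = np.flatnonzero(np.isfinite(b))
            rows = np.clip(b[cols].round().astype(int), 0, shape[0] - 1)
            out[rows, cols] = OVERLAY_COLORS["boundaries"]
    return out


def fuse_features(oct_features: np.ndarray, fundus_features: np.ndarray,
                  label: str | None = None) -> FeatureVector:
    """Concatenate eight OCT features (f1..f8) and eight fundus features (f9..f16)."""
    a = np.asarray(oct_features, dtype=float).ravel()
    b = np.asarray(fundus_features, dtype=float).ravel()
    if a.size != 8 or b.size != 8:
        raise ValueError("feature fusion expects two 8-vectors")
    return FeatureVector(values=np.concatenate([a, b]), label=label)
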