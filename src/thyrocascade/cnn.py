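"""The second-stage classifier: a residual backbone with a compact head.

The network is a convolutional backbone (ResNet-18/34/50, or the small
``tiny_test`` stack for fast CPU runs) whose classification top is replaced
by: global average pooling over the last feature maps -> batch
normalization over the k pooled features -> dropout -> a 2-unit dense
output with softmax. The head adds k x 4 batch-norm parameters and
2 x (k + 1) output parameters on top of the backbone's #param.

Backbone accounting convention: convolutions carry bias terms and every
batch-norm layer contributes four per-channel terms (scale, shift, running
mean, running variance). Under this convention the ResNet-50 backbone
counts 23,587,712 parameters.

Training minimizes 2-class cross-entropy with Adam; the learning rate
decays geometrically each epoch from the initial to the end rate. Inputs
are resampled to 224 x 224, replicated to three channels and scaled to
[0, 1].
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.transform import resize

from .dataio import BENIGN, MALIGN, GrayImage
from .nn import (Adam, BatchNorm1D, BatchNorm2D, Conv2D, Dense, Dropout,
                 GlobalAvgPool2D, MaxPool2D, Param, ReLU, Residual,
                 Sequential, softmax, softmax_cross_entropy)

__all__ = [
    "BACKBONES", "NetworkSpec", "TrainConfig", "TrainedModel",
    "build_backbone", "build_classifier", "count_parameters",
    "train_classifier", "predict", "preprocess",
]

BACKBONES = ("resnet18", "resnet34", "resnet50", "tiny_test")

#: (m, n, k) of the last convolution output at 224 x 224 input.
FEATURE_SHAPES = {
    "resnet18": (7, 7, 512),
    "resnet34": (7, 7, 512),
    "resnet50": (7, 7, 2048),
    "tiny_test": (7, 7, 32),
}

INPUT_SIDE = 224


@dataclass
class NetworkSpec:
    backbone_kind: str
    feature_shape: tuple[int, int, int]
    dropout_rate: float
    n_classes: int = 2
    param_count: int = 0       # total #param incl. running statistics


@dataclass
class TrainConfig:
    initial_lr: float = 1e-4
    end_lr: float = 1e-5
    n_epochs: int = 10
    batch_size: int = 4
    seed: int = 0

    def lr_schedule(self) -> np.ndarray:
        """Geometric per-epoch decay from initial_lr to end_lr inclusive."""
        if self.n_epochs == 1:
            return np.array([self.initial_lr])
        factor = (self.end_lr / self.initial_lr) ** (1.0 / (self.n_epochs - 1))
        return self.initial_lr * factor ** np.arange(self.n_epochs)


@dataclass
class TrainedModel:
    spec: NetworkSpec
    network: Sequential = field(repr=False)
    history: list[dict] = field(default_factory=list)

    def save(self, model_dir: str | Path) -> None:
        model_dir = Path(model_dir)
        model_dir.mkdir(parents=True, exist_ok=True)
        arrays = {p.name: p.value for p in self.network.params()}
        np.savez(model_dir / "weights.npz", **arrays)
        meta = {
            "backbone_kind": self.spec.backbone_kind,
            "dropout_rate": self.spec.dropout_rate,
            "param_count": self.spec.param_count,
            "history": self.history,
        }
        (model_dir / "spec.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, model_dir: str | Path) -> "TrainedModel":
        model_dir = Path(model_dir)
        meta = json.loads((model_dir / "spec.json").read_text())
        spec, net = build_classifier(meta["backbone_kind"],
                                     dropout_rate=meta["dropout_rate"])
        with np.load(model_dir / "weights.npz") as data:
            for p in net.params():
                p.value = data[p.name].astype(np.float32)
        return cls(spec=spec, network=net, history=meta.get("history", []))


def _bottleneck(cin, f, stride, downsample, rng, name):
    """ResNet-50 style 1x1 -> 3x3 -> 1x1 block with 4f output channels."""
    cout = 4 * f
    main = Sequential(
        Conv2D(cin, f, 1, stride=stride, rng=rng, name=f"{name}.c1"),
        BatchNorm2D(f, name=f"{name}.bn1"), ReLU(),
        Conv2D(f, f, 3, pad=1, rng=rng, name=f"{name}.c2"),
        BatchNorm2D(f, name=f"{name}.bn2"), ReLU(),
        Conv2D(f, cout, 1, rng=rng, name=f"{name}.c3"),
        BatchNorm2D(cout, name=f"{name}.bn3"),
    )
    shortcut = None
    if downsample:
        shortcut = Sequential(
            Conv2D(cin, cout, 1, stride=stride, rng=rng, name=f"{name}.sc"),
            BatchNorm2D(cout, name=f"{name}.scbn"),
        )
    return Residual(main, shortcut)


def _basic_block(cin, f, stride, downsample, rng, name):
    """ResNet-18/34 style 3x3 -> 3x3 block."""
    main = Sequential(
        Conv2D(cin, f, 3, stride=stride, pad=1, rng=rng, name=f"{name}.c1"),
        BatchNorm2D(f, name=f"{name}.bn1"), ReLU(),
        Conv2D(f, f, 3, pad=1, rng=rng, name=f"{name}.c2"),
        BatchNorm2D(f, name=f"{name}.bn2"),
    )
    shortcut = None
    if downsample:
        shortcut = Sequential(
            Conv2D(cin, f, 1, stride=stride, rng=rng, name=f"{name}.sc"),
            BatchNorm2D(f, name=f"{name}.scbn"),
        )
    return Residual(main, shortcut)


def _resnet(layers, block, expansion, rng):
    stem = [
        Conv2D(3, 64, 7, stride=2, pad=3, rng=rng, name="stem.conv"),
        BatchNorm2D(64, name="stem.bn"), ReLU(),
        MaxPool2D(3, stride=2, pad=1),
    ]
    blocks = []
    cin = 64
    for s, (f, n_blocks) in enumerate(zip((64, 128, 256, 512), layers)):
        for b in range(n_blocks):
            stride = 2 if (s > 0 and b == 0) else 1
            downsample = b == 0 and (stride != 1 or cin != f * expansion)
            blk = block(cin, f, stride, downsample, rng, f"s{s}b{b}")
            blocks.append(blk)
            cin = f * expansion
    return Sequential(*stem, *blocks)


def _tiny_test(rng):
    """Four small conv blocks ending at 32 channels / 7 x 7; CPU-friendly."""
    chans = [(3, 8), (8, 16), (16, 24), (24, 32)]
    layers = []
    for i, (cin, cout) in enumerate(chans):
        stride = 2 if i == 0 else 1
        layers += [
            Conv2D(cin, cout, 3, stride=stride, pad=1, rng=rng,
                   name=f"t{i}.conv"),
            BatchNorm2D(cout, name=f"t{i}.bn"), ReLU(),
            MaxPool2D(2),
        ]
    return Sequential(*layers)


def build_backbone(backbone_kind: str,
                   rng: np.random.Generator | None = None) -> Sequential:
    """Build an initialized convolutional backbone (no classification top)."""
    rng = rng or np.random.default_rng(0)
    if backbone_kind == "resnet50":
        return _resnet((3, 4, 6, 3), _bottleneck, 4, rng)
    if backbone_kind == "resnet34":
        return _resnet((3, 4, 6, 3), _basic_block, 1, rng)
    if backbone_kind == "resnet18":
        return _resnet((2, 2, 2, 2), _basic_block, 1, rng)
    if backbone_kind == "tiny_test":
        return _tiny_test(rng)
    raise ValueError(f"unknown backbone {backbone_kind!r}; "
                     f"expected one of {BACKBONES}")


def build_classifier(backbone_kind: str, dropout_rate: float = 0.5,
                     seed: int = 0,
                     weights_file: str | Path | None = None
                     ) -> tuple[NetworkSpec, Sequential]:
    """Backbone -> GAP -> batch norm -> dropout -> 2-unit dense output.

    Weights are randomly initialized; ``weights_file`` (an .npz of named
    arrays matching the network's parameter names) is an optional hook for
    externally obtained weights.
    """
    rng = np.random.default_rng(seed)
    backbone = build_backbone(backbone_kind, rng)
    m, n, k = FEATURE_SHAPES[backbone_kind]
    head_out = Dense(k, 2, rng=rng, name="head.out")
    # zero-init the output layer (standard for transfer-style heads): initial
    # predictions are uniform and the small-learning-rate schedule still
    # orients the decision immediately.
    head_out.w.value[:] = 0.0
    net = Sequential(
        backbone,
        GlobalAvgPool2D(),
        BatchNorm1D(k, name="head.bn"),
        Dropout(dropout_rate, rng=np.random.default_rng(rng.integers(2**31))),
        head_out,
    )
    if weights_file is not None:
        with np.load(weights_file) as data:
            for p in net.params():
                if p.name in data:
                    p.value = data[p.name].astype(np.float32)
    spec = NetworkSpec(
        backbone_kind=backbone_kind,
        feature_shape=(m, n, k),
        dropout_rate=dropout_rate,
        param_count=count_parameters(net, include_nontrainable=True),
    )
    return spec, net


def count_parameters(network, include_nontrainable: bool = True) -> int:
    """Total element count over the network's parameter tensors."""
    return sum(p.size for p in network.params()
               if include_nontrainable or p.trainable)


def head_parameter_count(k: int) -> int:
    """Head parameters for a k-feature backbone: k*4 batch norm + 2*(k+1) dense."""
    return k * 4 + 2 * (k + 1)


def preprocess(image: GrayImage) -> np.ndarray:
    """Resample to 224 x 224, replicate to 3 channels, scale to [0, 1]."""
    px = resize(image.pixels, (INPUT_SIDE, INPUT_SIDE), order=1, mode="edge",
                anti_aliasing=False, preserve_range=True) / 255.0
    return np.repeat(px[None, :, :], 3, axis=0).astype(np.float32)


_LABEL_TO_INT = {BENIGN: 0, MALIGN: 1}
_INT_TO_LABEL = {0: BENIGN, 1: MALIGN}


def train_classifier(network: Sequential, dataset, config: TrainConfig,
                     spec: NetworkSpec | None = None) -> TrainedModel:
    """Train on (GrayImage, label) pairs; reproducible given config.seed.

    The learning rate follows the geometric per-epoch schedule; history
    records per-epoch mean loss and training accuracy.
    """
    images, labels = zip(*dataset)
    y = np.array([_LABEL_TO_INT[lab] for lab in labels])
    if len(np.unique(y)) < 2:
        raise ValueError("training requires at least one sample per class")
    x = np.stack([preprocess(img) for img in images])
    rng = np.random.default_rng(config.seed)
    # re-seed dropout so runs are reproducible independent of build order
    for layer in network.layers:
        if isinstance(layer, Dropout):
            layer.rng = np.random.default_rng(rng.integers(2**31))
    opt = Adam(network.params(), lr=config.initial_lr)
    schedule = config.lr_schedule()
    history = []
    n = len(y)
    for epoch in range(config.n_epochs):
        opt.lr = float(schedule[epoch])
        order = rng.permutation(n)
        losses, correct = [], 0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            logits = network.forward(x[idx], training=True)
            loss, dlogits = softmax_cross_entropy(logits, y[idx])
            network.backward(dlogits)
            opt.step()
            losses.append(loss)
            correct += int((logits.argmax(axis=1) == y[idx]).sum())
        history.append({
            "epoch": epoch + 1,
            "lr": float(schedule[epoch]),
            "loss": float(np.mean(losses)),
            "accuracy": correct / n,
        })
    if spec is None:
        m_, n_, k = FEATURE_SHAPES.get("tiny_test", (7, 7, 32))
        spec = NetworkSpec("tiny_test", (m_, n_, k), 0.5,
                           param_count=count_parameters(network))
    return TrainedModel(spec=spec, network=network, history=history)


def predict(model: TrainedModel, image: GrayImage) -> tuple[str, float]:
    """Predict (label, probability of malign); dropout inactive.

    Probability exactly 0.5 is called malign (the documented tie rule).
    """
    x = preprocess(image)[None]
    logits = model.network.forward(x, training=False)
    p_malign = float(softmax(logits)[0, 1])
    label = MALIGN if p_malign >= 0.5 else BENIGN
    return label, p_malign
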