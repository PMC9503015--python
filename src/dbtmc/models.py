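"""CNN-a and the four reference architectures, built from scratch.

CNN-a is an AlexNet-derived classifier for whole DBT slices with two
modifications: every channel-wise local-response-normalization (LRN)
layer is replaced by batch normalization, and one additional 3x3
max-pooling layer (stride 2, padding 0) sits between the two adjacent
grouped convolutions (conv4 and conv5).  At the full-scale 512-px
input, that extra pool restores the stock 6x6 pre-classifier map.

The references — AlexNet, GoogLeNet, ResNet18, SqueezeNet — are always
randomly initialized (trained from scratch, never pretrained), accept
single-channel 8-bit-derived input and emit two class scores.  All
builds are deterministic per seed.

Fully connected input sizes are derived from the actual feature-map
shape at the configured input size, so the nets work at desk scale
(e.g. 144 px) as well as full scale (512 px).  Channel widths the
architecture diagrams leave unstated keep their stock values.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from dbtmc import nn
from dbtmc.exceptions import ShapeError

ARCHITECTURES = ("cnn_a", "alexnet", "googlenet", "resnet18", "squeezenet")


@dataclass(frozen=True)
class ArchitectureSpec:
    """Name, geometry and serialized layer list of a built network."""

    name: str
    input_size: int
    n_classes: int
    layer_list: tuple[dict, ...]

    def save(self, path: str | Path) -> None:
        """Human-readable one-layer-per-line dump, for diffing."""
        lines = [f"# {self.name} input={self.input_size} classes={self.n_classes}"]
        for d in self.layer_list:
            kind = d["kind"]
            rest = " ".join(f"{k}={v}" for k, v in d.items() if k != "kind")
            lines.append(f"{kind} {rest}".rstrip())
        Path(path).write_text("\n".join(lines) + "\n")


class LocalResponseNorm(nn.Module):
    """Channel-wise LRN: x / (k + alpha/n * sum_win x^2)^beta."""

    def __init__(self, size=5, alpha=1e-4, beta=0.75, k=1.0, name="lrn"):
        self.size, self.alpha, self.beta, self.k, self.name = size, alpha, beta, k, name

    def _window_sum(self, arr):
        pad = self.size // 2
        n, c, h, w = arr.shape
        padded = np.pad(arr, ((0, 0), (pad, pad), (0, 0), (0, 0)))
        cs = np.concatenate(
            [np.zeros((n, 1, h, w), dtype=arr.dtype), np.cumsum(padded, axis=1)], axis=1
        )
        return cs[:, self.size :] - cs[:, :-self.size]

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        s = self._window_sum(x.data**2)
        d = self.k + (self.alpha / self.size) * s
        dmb = d ** (-self.beta)
        out = x.data * dmb

        def bw(grad):
            if not x.requires_grad:
                return
            t = self._window_sum(grad * x.data * d ** (-self.beta - 1))
            dx = grad * dmb - (2 * self.alpha * self.beta / self.size) * x.data * t
            x._accumulate(dx)

        return nn.Tensor(out, (x,), bw)

    def describe(self):
        return {"kind": "lrn", "name": self.name, "size": self.size}


def _probe_flat_dim(features: nn.Sequential, input_size: int) -> int:
    """Flattened feature size for a 1-channel input of the given size."""
    features.set_training(False)
    probe = nn.Tensor(np.zeros((1, 1, input_size, input_size), dtype=np.float32))
    out = features(probe)
    features.set_training(True)
    return int(np.prod(out.data.shape[1:]))


class _SequentialNet(nn.Module):
    """features -> classifier network with a serialized layer list."""

    def __init__(self, features: nn.Sequential, classifier: nn.Sequential):
        self.features = features
        self.classifier = classifier

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        return self.classifier(self.features(x))

    def layer_list(self) -> tuple[dict, ...]:
        return tuple(self.features.describe_layers() + self.classifier.describe_layers())


def _alexnet_features(rng, use_batchnorm: bool, extra_pool: bool) -> nn.Sequential:
    def norm(c, name):
        return nn.BatchNorm2d(c, name=name) if use_batchnorm else LocalResponseNorm(name=name)

    layers = [
        nn.Conv2d(1, 96, 11, stride=4, rng=rng, name="conv1"),
        nn.ReLU(),
        norm(96, "norm1"),
        nn.MaxPool2d(3, 2, name="pool1"),
        nn.Conv2d(96, 256, 5, padding=2, groups=2, rng=rng, name="conv2"),
        nn.ReLU(),
        norm(256, "norm2"),
        nn.MaxPool2d(3, 2, name="pool2"),
        nn.Conv2d(256, 384, 3, padding=1, rng=rng, name="conv3"),
        nn.ReLU(),
        nn.Conv2d(384, 384, 3, padding=1, groups=2, rng=rng, name="conv4"),
        nn.ReLU(),
    ]
    if extra_pool:
        layers.append(nn.MaxPool2d(3, 2, name="pool_new"))
    layers += [
        nn.Conv2d(384, 256, 3, padding=1, groups=2, rng=rng, name="conv5"),
        nn.ReLU(),
        nn.MaxPool2d(3, 2, name="pool5"),
        nn.Flatten(),
    ]
    return nn.Sequential(*layers)


def _alexnet_classifier(rng, flat_dim: int, n_classes: int) -> nn.Sequential:
    return nn.Sequential(
        nn.Dropout(0.5, rng=rng, name="drop6"),
        nn.Linear(flat_dim, 4096, rng=rng, name="fc6"),
        nn.ReLU(),
        nn.Dropout(0.5, rng=rng, name="drop7"),
        nn.Linear(4096, 4096, rng=rng, name="fc7"),
        nn.ReLU(),
        nn.Linear(4096, n_classes, rng=rng, name="fc8"),
    )


def build_cnn_a(
    input_size: int, n_classes: int = 2, seed: int = 0
) -> tuple[_SequentialNet, ArchitectureSpec]:
    """Build CNN-a at the given input size.

    Raises :class:`ShapeError` naming the offending layer when the
    input is too small for the pool chain (minimum 131 px with the
    extra pool).
    """
    rng = np.random.default_rng(seed)
    features = _alexnet_features(rng, use_batchnorm=True, extra_pool=True)
    flat = _probe_flat_dim(features, input_size)  # raises ShapeError if too small
    model = _SequentialNet(features, _alexnet_classifier(rng, flat, n_classes))
    spec = ArchitectureSpec("cnn_a", input_size, n_classes, model.layer_list())
    return model, spec


def _build_alexnet(input_size, n_classes, rng):
    features = _alexnet_features(rng, use_batchnorm=False, extra_pool=False)
    flat = _probe_flat_dim(features, input_size)
    return _SequentialNet(features, _alexnet_classifier(rng, flat, n_classes))


# -- GoogLeNet (Inception v1, batchnorm variant) ----------------------------

class _ConvBNReLU(nn.Module):
    def __init__(self, cin, cout, kernel, stride=1, padding=0, rng=None, name="conv"):
        self.conv = nn.Conv2d(cin, cout, kernel, stride, padding, rng=rng, name=name)
        self.bn = nn.BatchNorm2d(cout, name=name + "_bn")

    def __call__(self, x):
        return nn.relu(self.bn(self.conv(x)))


class _Inception(nn.Module):
    def __init__(self, cin, c1, c3r, c3, c5r, c5, pp, rng, name):
        self.b1 = _ConvBNReLU(cin, c1, 1, rng=rng, name=name + "_1x1")
        self.b2a = _ConvBNReLU(cin, c3r, 1, rng=rng, name=name + "_3x3r")
        self.b2b = _ConvBNReLU(c3r, c3, 3, padding=1, rng=rng, name=name + "_3x3")
        self.b3a = _ConvBNReLU(cin, c5r, 1, rng=rng, name=name + "_5x5r")
        self.b3b = _ConvBNReLU(c5r, c5, 5, padding=2, rng=rng, name=name + "_5x5")
        self.b4 = _ConvBNReLU(cin, pp, 1, rng=rng, name=name + "_poolproj")
        self.out_channels = c1 + c3 + c5 + pp

    def __call__(self, x):
        pooled = nn.max_pool2d(_pad_tensor(x, 1), 3, 1)
        return nn.concat(
            [self.b1(x), self.b2b(self.b2a(x)), self.b3b(self.b3a(x)), self.b4(pooled)]
        )


def _pad_tensor(x: nn.Tensor, p: int) -> nn.Tensor:
    data = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p)), constant_values=-np.inf)
    # -inf padding keeps max-pool semantics; gradient never flows to padding
    data = np.where(np.isfinite(data), data, np.float32(-1e30)).astype(x.data.dtype)

    def bw(grad):
        if x.requires_grad:
            x._accumulate(grad[:, :, p:-p, p:-p])

    return nn.Tensor(data, (x,), bw)


class _GoogLeNet(nn.Module):
    def __init__(self, input_size, n_classes, rng):
        self.stem = nn.Sequential(
            _ConvBNReLU(1, 64, 7, stride=2, padding=3, rng=rng, name="conv1"),
            nn.MaxPool2d(3, 2, name="pool1"),
            _ConvBNReLU(64, 64, 1, rng=rng, name="conv2"),
            _ConvBNReLU(64, 192, 3, padding=1, rng=rng, name="conv3"),
            nn.MaxPool2d(3, 2, name="pool2"),
        )
        self.inc3a = _Inception(192, 64, 96, 128, 16, 32, 32, rng, "inc3a")
        self.inc3b = _Inception(256, 128, 128, 192, 32, 96, 64, rng, "inc3b")
        self.pool3 = nn.MaxPool2d(3, 2, name="pool3")
        self.inc4a = _Inception(480, 192, 96, 208, 16, 48, 64, rng, "inc4a")
        self.inc4b = _Inception(512, 160, 112, 224, 24, 64, 64, rng, "inc4b")
        self.inc4c = _Inception(512, 128, 128, 256, 24, 64, 64, rng, "inc4c")
        self.inc4d = _Inception(512, 112, 144, 288, 32, 64, 64, rng, "inc4d")
        self.inc4e = _Inception(528, 256, 160, 320, 32, 128, 128, rng, "inc4e")
        self.pool4 = nn.MaxPool2d(3, 2, name="pool4")
        self.inc5a = _Inception(832, 256, 160, 320, 32, 128, 128, rng, "inc5a")
        self.inc5b = _Inception(832, 384, 192, 384, 48, 128, 128, rng, "inc5b")
        self.drop = nn.Dropout(0.4, rng=rng, name="drop")
        self.fc = nn.Linear(1024, n_classes, rng=rng, name="fc")

    def __call__(self, x):
        x = self.stem(x)
        x = self.pool3(self.inc3b(self.inc3a(x)))
        x = self.inc4e(self.inc4d(self.inc4c(self.inc4b(self.inc4a(x)))))
        x = self.inc5b(self.inc5a(self.pool4(x)))
        x = nn.global_avg_pool(x)
        return self.fc(self.drop(x))


# -- ResNet18 ---------------------------------------------------------------

class _BasicBlock(nn.Module):
    def __init__(self, cin, cout, stride, rng, name):
        self.conv1 = nn.Conv2d(cin, cout, 3, stride, 1, rng=rng, name=name + "_conv1")
        self.bn1 = nn.BatchNorm2d(cout, name=name + "_bn1")
        self.conv2 = nn.Conv2d(cout, cout, 3, 1, 1, rng=rng, name=name + "_conv2")
        self.bn2 = nn.BatchNorm2d(cout, name=name + "_bn2")
        self.down = None
        if stride != 1 or cin != cout:
            self.down = nn.Conv2d(cin, cout, 1, stride, 0, rng=rng, name=name + "_down")
            self.down_bn = nn.BatchNorm2d(cout, name=name + "_downbn")

    def __call__(self, x):
        identity = x if self.down is None else self.down_bn(self.down(x))
        out = self.bn2(self.conv2(nn.relu(self.bn1(self.conv1(x)))))
        return nn.relu(nn.add(out, identity))


class _ResNet18(nn.Module):
    def __init__(self, input_size, n_classes, rng):
        self.stem = nn.Sequential(
            nn.Conv2d(1, 64, 7, 2, 3, rng=rng, name="conv1"),
            nn.BatchNorm2d(64, name="bn1"),
            nn.ReLU(),
        )
        self.blocks = [
            _BasicBlock(64, 64, 1, rng, "l1b1"), _BasicBlock(64, 64, 1, rng, "l1b2"),
            _BasicBlock(64, 128, 2, rng, "l2b1"), _BasicBlock(128, 128, 1, rng, "l2b2"),
            _BasicBlock(128, 256, 2, rng, "l3b1"), _BasicBlock(256, 256, 1, rng, "l3b2"),
            _BasicBlock(256, 512, 2, rng, "l4b1"), _BasicBlock(512, 512, 1, rng, "l4b2"),
        ]
        self.fc = nn.Linear(512, n_classes, rng=rng, name="fc")

    def __call__(self, x):
        x = nn.max_pool2d(_pad_tensor(self.stem(x), 1), 3, 2, name="maxpool")
        for b in self.blocks:
            x = b(x)
        return self.fc(nn.global_avg_pool(x))


# -- SqueezeNet 1.1 ---------------------------------------------------------

class _Fire(nn.Module):
    def __init__(self, cin, squeeze, e1, e3, rng, name):
        self.s = nn.Conv2d(cin, squeeze, 1, rng=rng, name=name + "_squeeze")
        self.e1 = nn.Conv2d(squeeze, e1, 1, rng=rng, name=name + "_e1")
        self.e3 = nn.Conv2d(squeeze, e3, 3, padding=1, rng=rng, name=name + "_e3")

    def __call__(self, x):
        s = nn.relu(self.s(x))
        return nn.concat([nn.relu(self.e1(s)), nn.relu(self.e3(s))])


class _SqueezeNet(nn.Module):
    def __init__(self, input_size, n_classes, rng):
        self.conv1 = nn.Conv2d(1, 64, 3, 2, rng=rng, name="conv1")
        self.pool1 = nn.MaxPool2d(3, 2, name="pool1")
        self.f2 = _Fire(64, 16, 64, 64, rng, "fire2")
        self.f3 = _Fire(128, 16, 64, 64, rng, "fire3")
        self.pool2 = nn.MaxPool2d(3, 2, name="pool2")
        self.f4 = _Fire(128, 32, 128, 128, rng, "fire4")
        self.f5 = _Fire(256, 32, 128, 128, rng, "fire5")
        self.pool3 = nn.MaxPool2d(3, 2, name="pool3")
        self.f6 = _Fire(256, 48, 192, 192, rng, "fire6")
        self.f7 = _Fire(384, 48, 192, 192, rng, "fire7")
        self.f8 = _Fire(384, 64, 256, 256, rng, "fire8")
        self.f9 = _Fire(512, 64, 256, 256, rng, "fire9")
        self.drop = nn.Dropout(0.5, rng=rng, name="drop")
        self.conv_final = nn.Conv2d(512, n_classes, 1, rng=rng, name="conv_final")

    def __call__(self, x):
        x = self.pool1(nn.relu(self.conv1(x)))
        x = self.pool2(self.f3(self.f2(x)))
        x = self.pool3(self.f5(self.f4(x)))
        x = self.f9(self.f8(self.f7(self.f6(x))))
        x = nn.relu(self.conv_final(self.drop(x)))
        return nn.global_avg_pool(x)


def build_reference(name: str, input_size: int, n_classes: int = 2, seed: int = 0):
    """Randomly initialized reference architecture (never pretrained)."""
    rng = np.random.default_rng(seed)
    if name == "alexnet":
        return _build_alexnet(input_size, n_classes, rng)
    if name == "googlenet":
        return _GoogLeNet(input_size, n_classes, rng)
    if name == "resnet18":
        return _ResNet18(input_size, n_classes, rng)
    if name == "squeezenet":
        return _SqueezeNet(input_size, n_classes, rng)
    raise ValueError(f"unknown architecture {name!r}; choose from {ARCHITECTURES[1:]}")


def build(name: str, input_size: int, n_classes: int = 2, seed: int = 0):
    """Build any supported architecture by name (model only)."""
    if name == "cnn_a":
        return build_cnn_a(input_size, n_classes, seed)[0]
    return build_reference(name, input_size, n_classes, seed)


def parameter_count(model: nn.Module) -> int:
    return int(sum(p.data.size for p in model.parameters()))


def stock_alexnet_layer_list(input_size: int = 512, n_classes: int = 2) -> tuple[dict, ...]:
    """Layer list of the unmodified AlexNet topology, for diffing."""
    rng = np.random.default_rng(0)
    features = _alexnet_features(rng, use_batchnorm=False, extra_pool=False)
    flat = _probe_flat_dim(features, input_size)
    net = _SequentialNet(features, _alexnet_classifier(rng, flat, n_classes))
    return net.layer_list()
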