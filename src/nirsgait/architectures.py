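"""Layer-exact parameter accounting for the image-classifier backbones.

The classification study fine-tunes ImageNet-pretrained backbones after
replacing the 1000-way classifier with a 3-way head. For cost/efficiency
bookkeeping (parameter counts, float32 storage) the architectures are
reproduced here as exact layer tables: every convolution, batch-norm,
squeeze-excite and linear layer of each backbone is enumerated with its
parameter count, the head can be swapped for an ``n_classes``-way one, and
totals follow the closed form

    params(adapted) = params(backbone) - params(old head) + params(new head).

The builders reproduce the published 1000-class totals exactly (e.g.
ResNet-18 11,689,512; VGG-13 133,047,848; EfficientNet-B0 5,288,548;
ViT-B/16 86,567,656). These are accounting models, not trainable networks;
the trainable model in this package is :class:`nirsgait.nn.ToyCNN`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .nn import ToyCNN


@dataclass(frozen=True)
class Layer:
    name: str
    params: int
    buffers: int = 0  # non-trainable state (batch-norm running statistics)


@dataclass
class ArchitectureModel:
    """A backbone as an ordered layer table with a replaceable head."""

    name: str
    layers: list = field(default_factory=list)
    head_in_features: int = 0
    n_classes: int = 1000
    pretrained: bool = False

    @property
    def n_params(self) -> int:
        return sum(l.params for l in self.layers)

    @property
    def n_buffers(self) -> int:
        return sum(l.buffers for l in self.layers)

    @property
    def head(self) -> Layer:
        return self.layers[-1]

    def with_head(self, n_classes: int) -> "ArchitectureModel":
        """Swap the final classifier for an ``n_classes``-way linear layer."""
        if n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        new_head = Layer(
            f"head({self.head_in_features}->{n_classes})",
            self.head_in_features * n_classes + n_classes,
        )
        return ArchitectureModel(
            name=self.name,
            layers=self.layers[:-1] + [new_head],
            head_in_features=self.head_in_features,
            n_classes=n_classes,
            pretrained=self.pretrained,
        )


class _Builder:
    def __init__(self):
        self.layers: list[Layer] = []

    def conv(self, name, cin, cout, k, bias=False, groups=1):
        self.layers.append(Layer(name, cout * (cin // groups) * k * k + (cout if bias else 0)))

    def bn(self, name, c):
        self.layers.append(Layer(name, 2 * c, buffers=2 * c))

    def linear(self, name, cin, cout, bias=True):
        self.layers.append(Layer(name, cin * cout + (cout if bias else 0)))

    def raw(self, name, n):
        self.layers.append(Layer(name, n))


# ---------------------------------------------------------------------------
# channel rounding used by the mobile/efficient families


def make_divisible(v: float, divisor: int = 8, round_limit: float = 0.9) -> int:
    new_v = max(divisor, int(v + divisor / 2) // divisor * divisor)
    if new_v < round_limit * v:
        new_v += divisor
    return new_v


def round_channels(channels: float, multiplier: float = 1.0, divisor: int = 8) -> int:
    if not multiplier:
        return int(channels)
    return make_divisible(channels * multiplier, divisor)


# ---------------------------------------------------------------------------
# families


def _resnet(name, layers_per_stage, block="basic"):
    b = _Builder()
    b.conv("stem.conv", 3, 64, 7)
    b.bn("stem.bn", 64)
    cin = 64
    widths = (64, 128, 256, 512)
    for i, (w, n) in enumerate(zip(widths, layers_per_stage)):
        for j in range(n):
            tag = f"layer{i + 1}.{j}"
            strided = i > 0 and j == 0
            if block == "basic":
                b.conv(f"{tag}.conv1", cin, w, 3); b.bn(f"{tag}.bn1", w)
                b.conv(f"{tag}.conv2", w, w, 3); b.bn(f"{tag}.bn2", w)
                cout = w
            else:
                b.conv(f"{tag}.conv1", cin, w, 1); b.bn(f"{tag}.bn1", w)
                b.conv(f"{tag}.conv2", w, w, 3); b.bn(f"{tag}.bn2", w)
                b.conv(f"{tag}.conv3", w, w * 4, 1); b.bn(f"{tag}.bn3", w * 4)
                cout = w * 4
            if cin != cout or strided:
                b.conv(f"{tag}.downsample.conv", cin, cout, 1)
                b.bn(f"{tag}.downsample.bn", cout)
            cin = cout
    b.linear("fc", cin, 1000)
    return ArchitectureModel(name, b.layers, head_in_features=cin)


_VGG_CFGS = {
    "vgg13": (64, 64, "M", 128, 128, "M", 256, 256, "M", 512, 512, "M", 512, 512, "M"),
    "vgg16": (64, 64, "M", 128, 128, "M", 256, 256, 256, "M", 512, 512, 512, "M",
              512, 512, 512, "M"),
}


def _vgg(name):
    b = _Builder()
    cin, k = 3, 0
    for v in _VGG_CFGS[name]:
        if v == "M":
            continue
        b.conv(f"features.conv{k}", cin, v, 3, bias=True)
        cin, k = v, k + 1
    b.linear("classifier.fc1", 512 * 7 * 7, 4096)
    b.linear("classifier.fc2", 4096, 4096)
    b.linear("classifier.fc3", 4096, 1000)
    return ArchitectureModel(name, b.layers, head_in_features=4096)


# (kind, repeats, kernel, stride, expansion, out_channels, se_ratio)
_EFFNET_B0_BLOCKS = (
    ("ds", 1, 3, 1, 1, 16, 0.25),
    ("ir", 2, 3, 2, 6, 24, 0.25),
    ("ir", 2, 5, 2, 6, 40, 0.25),
    ("ir", 3, 3, 2, 6, 80, 0.25),
    ("ir", 3, 5, 1, 6, 112, 0.25),
    ("ir", 4, 5, 2, 6, 192, 0.25),
    ("ir", 1, 3, 1, 6, 320, 0.25),
)
_MBV2_BLOCKS = (
    ("ds", 1, 3, 1, 1, 16, 0.0),
    ("ir", 2, 3, 2, 6, 24, 0.0),
    ("ir", 3, 3, 2, 6, 32, 0.0),
    ("ir", 4, 3, 2, 6, 64, 0.0),
    ("ir", 3, 3, 1, 6, 96, 0.0),
    ("ir", 3, 3, 2, 6, 160, 0.0),
    ("ir", 1, 3, 1, 6, 320, 0.0),
)


def _effnet(name, blocks, width=1.0, depth=1.0, depth_round=False, stem=32,
            fix_stem=False, num_features=1280):
    b = _Builder()
    stem_ch = stem if fix_stem else round_channels(stem, width)
    b.conv("stem.conv", 3, stem_ch, 3)
    b.bn("stem.bn", stem_ch)
    cin = stem_ch
    for si, (kind, r, k, s, e, c, se) in enumerate(blocks):
        cout = round_channels(c, width)
        r = max(1, round(r * depth)) if depth_round else int(math.ceil(r * depth))
        for j in range(r):
            tag = f"blocks.{si}.{j}"
            if kind == "ds":
                b.conv(f"{tag}.dw", cin, cin, k, groups=cin); b.bn(f"{tag}.dw_bn", cin)
                if se > 0:
                    rd = max(1, int(cin * se))
                    b.conv(f"{tag}.se.reduce", cin, rd, 1, bias=True)
                    b.conv(f"{tag}.se.expand", rd, cin, 1, bias=True)
                b.conv(f"{tag}.pw", cin, cout, 1); b.bn(f"{tag}.pw_bn", cout)
            else:
                mid = cin * e
                b.conv(f"{tag}.pw_exp", cin, mid, 1); b.bn(f"{tag}.exp_bn", mid)
                b.conv(f"{tag}.dw", mid, mid, k, groups=mid); b.bn(f"{tag}.dw_bn", mid)
                if se > 0:
                    rd = max(1, int(cin * se))  # squeeze ratio on block input width
                    b.conv(f"{tag}.se.reduce", mid, rd, 1, bias=True)
                    b.conv(f"{tag}.se.expand", rd, mid, 1, bias=True)
                b.conv(f"{tag}.pw_proj", mid, cout, 1); b.bn(f"{tag}.proj_bn", cout)
            cin = cout
    b.conv("head.conv", cin, num_features, 1)
    b.bn("head.bn", num_features)
    b.linear("classifier", num_features, 1000)
    return ArchitectureModel(name, b.layers, head_in_features=num_features)


def _vit(name, embed, depth, patch=16, img=224):
    b = _Builder()
    b.raw("pos_embed", embed * ((img // patch) ** 2 + 1))
    b.raw("cls_token", embed)
    b.conv("patch_embed", 3, embed, patch, bias=True)
    for i in range(depth):
        b.raw(f"blocks.{i}.norm1", 2 * embed)
        b.linear(f"blocks.{i}.attn.qkv", embed, 3 * embed)
        b.linear(f"blocks.{i}.attn.proj", embed, embed)
        b.raw(f"blocks.{i}.norm2", 2 * embed)
        b.linear(f"blocks.{i}.mlp.fc1", embed, 4 * embed)
        b.linear(f"blocks.{i}.mlp.fc2", 4 * embed, embed)
    b.raw("norm", 2 * embed)
    b.linear("head", embed, 1000)
    return ArchitectureModel(name, b.layers, head_in_features=embed)


_REGISTRY = {
    "resnet18": lambda: _resnet("resnet18", (2, 2, 2, 2), "basic"),
    "resnet26": lambda: _resnet("resnet26", (2, 2, 2, 2), "bottleneck"),
    "vgg13": lambda: _vgg("vgg13"),
    "vgg16": lambda: _vgg("vgg16"),
    "efficientnet_b0": lambda: _effnet("efficientnet_b0", _EFFNET_B0_BLOCKS),
    # TinyNet-E: EfficientNet-B0 block table at width 0.51 / depth 0.6
    # (rounded repeats), unscaled 32-channel stem, 1280 head features.
    "tinynet_e": lambda: _effnet(
        "tinynet_e", _EFFNET_B0_BLOCKS, width=0.51, depth=0.6, depth_round=True,
        fix_stem=True,
    ),
    "mobilenetv2_050": lambda: _effnet("mobilenetv2_050", _MBV2_BLOCKS, width=0.5),
    "vit_base": lambda: _vit("vit_base", 768, 12),
    "vit_tiny": lambda: _vit("vit_tiny", 192, 12),
}

ARCHITECTURES = tuple(_REGISTRY) + ("toy_cnn",)


def build_backbone(architecture: str) -> ArchitectureModel:
    """The named backbone with its original 1000-class head."""
    key = architecture.lower().replace("-", "_")
    if key not in _REGISTRY:
        raise ValueError(f"unknown architecture {architecture!r}; choose from {ARCHITECTURES}")
    return _REGISTRY[key]()


def adapt_head(
    architecture: str,
    n_classes: int = 3,
    pretrained: bool = False,
    covariate_fusion: bool = False,
    seed: int = 0,
):
    """Build a model with its classifier adapted to ``n_classes`` outputs.

    ``toy_cnn`` returns the trainable numpy model; the zoo names return
    layer-accounting models with the 1000-way head replaced. Pretrained
    weights are not bundled with this package, so ``pretrained=True`` falls
    back to fresh initialization with a warning and the model is marked
    accordingly.
    """
    key = architecture.lower().replace("-", "_")
    if pretrained:
        warnings.warn(
            f"no pretrained weights available for {architecture}; "
            "falling back to fresh initialization",
            stacklevel=2,
        )
        pretrained = False
    if key == "toy_cnn":
        return ToyCNN(n_classes=n_classes, covariate_fusion=covariate_fusion, seed=seed)
    model = build_backbone(key).with_head(n_classes)
    if covariate_fusion:
        # widen the head input by the two fused covariates
        widened = Layer(
            f"head({model.head_in_features}+2->{n_classes})",
            (model.head_in_features + 2) * n_classes + n_classes,
        )
        model.layers = model.layers[:-1] + [widened]
    model.pretrained = pretrained
    return model


def count_params(model) -> tuple[int, float]:
    """(trainable parameter count, float32 storage in MiB, 4 bytes each)."""
    if isinstance(model, ToyCNN):
        n = model.n_params()
    elif isinstance(model, ArchitectureModel):
        n = model.n_params
    elif hasattr(model, "n_params"):
        n = int(model.n_params() if callable(model.n_params) else model.n_params)
    else:
        raise TypeError(f"cannot count parameters of {type(model)!r}")
    return n, n * 4 / 2**20
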