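"""Baseline classifier architectures, described as named-parameter
registries for exact size accounting.

The two baselines are the published ImageNet architectures with the final
fully-connected layer replaced by a 2-way (NORMAL vs AMD) softmax head:

* ResNet-50 — 7×7 stem convolution, four bottleneck stages of (3, 4, 6, 3)
  blocks with expansion 4 and batch normalization, global average pooling,
  dense head.  23.5 M trainable parameters with the 2-class head.
* ViT-Base/16 — 16×16 patch embedding of a 3-channel 224×224 input,
  embed dim 768, 12 pre-norm blocks with 12 heads and 4× MLPs, learned
  class token and position embeddings, dense head.  85.8 M parameters.

Only construction and parameter accounting are provided here; these
reference networks are not trained in this package.
"""

from __future__ import annotations

import numpy as np

__all__ = ["BaselineModel", "build_baseline"]


class BaselineModel:
    """An architecture as an ordered mapping of parameter names to shapes."""

    def __init__(self, name: str, shapes: dict[str, tuple[int, ...]]):
        self.name = name
        self.param_shapes = dict(shapes)

    def named_parameter_shapes(self):
        return self.param_shapes.items()

    def n_parameters(self) -> int:
        return int(sum(int(np.prod(s)) for s in self.param_shapes.values()))


def _resnet50_shapes(n_classes: int) -> dict[str, tuple[int, ...]]:
    shapes: dict[str, tuple[int, ...]] = {}

    def conv(name, c_in, c_out, k):
        shapes[f"{name}.weight"] = (c_out, c_in, k, k)

    def bn(name, c):
        shapes[f"{name}.weight"] = (c,)
        shapes[f"{name}.bias"] = (c,)

    conv("conv1", 3, 64, 7)
    bn("bn1", 64)
    inplanes = 64
    for stage, (planes, blocks) in enumerate(
            zip((64, 128, 256, 512), (3, 4, 6, 3)), start=1):
        for b in range(blocks):
            prefix = f"layer{stage}.{b}"
            conv(f"{prefix}.conv1", inplanes, planes, 1)
            bn(f"{prefix}.bn1", planes)
            conv(f"{prefix}.conv2", planes, planes, 3)
            bn(f"{prefix}.bn2", planes)
            conv(f"{prefix}.conv3", planes, planes * 4, 1)
            bn(f"{prefix}.bn3", planes * 4)
            if b == 0:          # projection shortcut on the first block
                conv(f"{prefix}.downsample.0", inplanes, planes * 4, 1)
                bn(f"{prefix}.downsample.1", planes * 4)
            inplanes = planes * 4
    shapes["fc.weight"] = (n_classes, 2048)
    shapes["fc.bias"] = (n_classes,)
    return shapes


def _vit_base_shapes(n_classes: int) -> dict[str, tuple[int, ...]]:
    dim, depth, mlp, patches = 768, 12, 3072, (224 // 16) ** 2
    shapes: dict[str, tuple[int, ...]] = {
        "patch_embed.weight": (dim, 3, 16, 16),
        "patch_embed.bias": (dim,),
        "cls_token": (1, 1, dim),
        "pos_embed": (1, patches + 1, dim),
    }
    for i in range(depth):
        p = f"blocks.{i}"
        shapes[f"{p}.norm1.weight"] = (dim,)
        shapes[f"{p}.norm1.bias"] = (dim,)
        shapes[f"{p}.attn.qkv.weight"] = (3 * dim, dim)
        shapes[f"{p}.attn.qkv.bias"] = (3 * dim,)
        shapes[f"{p}.attn.proj.weight"] = (dim, dim)
        shapes[f"{p}.attn.proj.bias"] = (dim,)
        shapes[f"{p}.norm2.weight"] = (dim,)
        shapes[f"{p}.norm2.bias"] = (dim,)
        shapes[f"{p}.mlp.fc1.weight"] = (mlp, dim)
        shapes[f"{p}.mlp.fc1.bias"] = (mlp,)
        shapes[f"{p}.mlp.fc2.weight"] = (dim, mlp)
        shapes[f"{p}.mlp.fc2.bias"] = (dim,)
    shapes["norm.weight"] = (dim,)
    shapes["norm.bias"] = (dim,)
    shapes["head.weight"] = (n_classes, dim)
    shapes["head.bias"] = (n_classes,)
    return shapes


def build_baseline(name: str, n_classes: int = 2) -> BaselineModel:
    """Construct a baseline architecture registry by name."""
    if name == "resnet50":
        return BaselineModel(name, _resnet50_shapes(n_classes))
    if name == "vit_base":
        return BaselineModel(name, _vit_base_shapes(n_classes))
    raise ValueError(f"unknown baseline {name!r}; have resnet50, vit_base")
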