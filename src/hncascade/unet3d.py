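"""Residual 3D encoder-decoder used identically by both cascade stages.

The encoder has one stage per entry of ``stage_widths``; the first stage
keeps resolution, every later stage halves each spatial dimension with a
stride-2 3x3x3 convolution inside a residual unit (two convolutions, batch
normalization + PReLU, with a 1x1x1 projection on the shortcut whenever the
shape changes). The decoder mirrors it with kernel-2 stride-2 transposed
convolutions, concatenating the same-resolution encoder features, and a
final 1x1x1 convolution maps to the three class scores (background, GTVp,
GTVn). Spatial dimensions must be divisible by ``2**(stages-1)``.

The default widths (16, 32, 64, 128, 256) are the full-scale recipe; the
miniature profile (e.g. (4, 8, 16)) is a first-class configuration that
trains on a CPU in minutes and is what the test suite exercises.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import nn
from .volume_io import LabelVolume, Volume3D


@dataclass
class NetworkSpec:
    in_channels: int = 2
    out_channels: int = 3
    stage_widths: tuple[int, ...] = (16, 32, 64, 128, 256)
    prelu_init: float = 0.25

    def __post_init__(self) -> None:
        self.stage_widths = tuple(int(w) for w in self.stage_widths)
        if self.in_channels not in (1, 2, 3):
            raise ValueError("in_channels must be 1, 2 or 3")
        if self.out_channels != 3:
            raise ValueError("out_channels is fixed at 3 (background, GTVp, GTVn)")
        if len(self.stage_widths) < 2 or any(w <= 0 for w in self.stage_widths):
            raise ValueError("stage_widths must be >=2 positive integers")

    @property
    def downsample_factor(self) -> int:
        return 2 ** (len(self.stage_widths) - 1)

    def to_dict(self) -> dict:
        return {"in_channels": self.in_channels, "out_channels": self.out_channels,
                "stage_widths": list(self.stage_widths), "prelu_init": self.prelu_init}

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkSpec":
        return cls(in_channels=d["in_channels"], out_channels=d.get("out_channels", 3),
                   stage_widths=tuple(d["stage_widths"]),
                   prelu_init=d.get("prelu_init", 0.25))


class ResidualUnit(nn.Module):
    """conv-BN-PReLU x2 with an additive shortcut (projected when needed)."""

    def __init__(self, c_in: int, c_out: int, stride: int,
                 rng: np.random.Generator, prelu_init: float):
        super().__init__()
        self.conv1 = nn.Conv3d(c_in, c_out, 3, stride=stride, padding=1, rng=rng)
        self.bn1 = nn.BatchNorm3d(c_out)
        self.act1 = nn.PReLU(c_out, prelu_init)
        self.conv2 = nn.Conv3d(c_out, c_out, 3, stride=1, padding=1, rng=rng)
        self.bn2 = nn.BatchNorm3d(c_out)
        self.act2 = nn.PReLU(c_out, prelu_init)
        if stride != 1 or c_in != c_out:
            self.proj: Optional[nn.Conv3d] = nn.Conv3d(c_in, c_out, 1, stride=stride, rng=rng)
        else:
            self.proj = None

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        y = self.act1(self.bn1(self.conv1(x)))
        y = self.bn2(self.conv2(y))
        res = self.proj(x) if self.proj is not None else x
        return self.act2(y + res)


class ResUNet3D(nn.Module):
    def __init__(self, spec: NetworkSpec, rng: np.random.Generator):
        super().__init__()
        self.spec = spec
        w = spec.stage_widths
        self.encoders = [ResidualUnit(spec.in_channels, w[0], 1, rng, spec.prelu_init)]
        for i in range(1, len(w)):
            self.encoders.append(ResidualUnit(w[i - 1], w[i], 2, rng, spec.prelu_init))
        self.ups = []
        self.decoders = []
        for i in range(len(w) - 1, 0, -1):
            self.ups.append(nn.ConvTranspose3d2x(w[i], w[i - 1], rng=rng))
            self.decoders.append(ResidualUnit(2 * w[i - 1], w[i - 1], 1, rng, spec.prelu_init))
        self.head = nn.Conv3d(w[0], spec.out_channels, 1, rng=rng)

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        spatial = x.shape[2:]
        f = self.spec.downsample_factor
        if any(s % f for s in spatial):
            raise ValueError(
                f"spatial dims {tuple(spatial)} must be divisible by the "
                f"downsampling factor {f}"
            )
        if x.shape[1] != self.spec.in_channels:
            raise ValueError(f"expected {self.spec.in_channels} input channels, got {x.shape[1]}")
        skips = []
        h = x
        for enc in self.encoders:
            h = enc(h)
            skips.append(h)
        for up, dec, skip in zip(self.ups, self.decoders, reversed(skips[:-1])):
            h = dec(nn.concat([up(h), skip], axis=1))
        return self.head(h)


def build_network(spec: NetworkSpec, seed: int = 0) -> ResUNet3D:
    """Build the network with seeded fan-in weight initialization."""
    return ResUNet3D(spec, np.random.default_rng(seed))


def predict_scores(net: ResUNet3D, channels: np.ndarray) -> np.ndarray:
    """Forward a (C, X, Y, Z) input in eval mode; returns (3, X, Y, Z) scores."""
    was_training = net.training
    net.eval()
    out = net(nn.Tensor(channels[None])).data[0]
    if was_training:
        net.train()
    return out


def predict_labels(net: ResUNet3D, channels: np.ndarray,
                   like: Optional[Volume3D] = None) -> np.ndarray | LabelVolume:
    """Per-voxel argmax over the 3 class-score channels.

    Ties break toward the lowest class index (argmax convention). If ``like``
    is given, the labels are wrapped in a LabelVolume on that geometry.
    """
    scores = predict_scores(net, channels)
    labels = np.argmax(scores, axis=0).astype(np.int16)
    if like is not None:
        return LabelVolume(labels, like.spacing, like.origin)
    return labels


def save_checkpoint(path: str | Path, net: ResUNet3D, extra: Optional[dict] = None) -> Path:
    """Store weights + NetworkSpec (+ metadata such as the config hash)."""
    path = Path(path)
    meta = {"network_spec": net.spec.to_dict(), **(extra or {})}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **net.state_dict())
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def load_checkpoint(path: str | Path) -> tuple[ResUNet3D, dict]:
    with np.load(Path(path)) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        state = {k: z[k] for k in z.files if k != "__meta__"}
    net = build_network(NetworkSpec.from_dict(meta["network_spec"]))
    net.load_state_dict(state)
    net.eval()
    return net, meta
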