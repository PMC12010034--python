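"""Experiment configuration: one YAML schema for the whole pipeline."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

from .cascade import CropSpec, InputRecipe
from .metrics import SurfaceSpec
from .postprocessing import PostprocessSpec
from .preprocessing import DilationSpec, GridSpec, NormalizationSpec
from .training import AugmentationSpec, TrainConfig
from .unet3d import NetworkSpec


@dataclass
class CascadeConfig:
    """Everything that defines one experiment."""

    recipe: InputRecipe = InputRecipe.PREMASK_MID
    grid: GridSpec = field(default_factory=GridSpec)
    crop: CropSpec = field(default_factory=CropSpec)
    dilation: DilationSpec = field(default_factory=DilationSpec)
    normalization: NormalizationSpec = field(default_factory=NormalizationSpec)
    network: NetworkSpec = field(default_factory=NetworkSpec)
    train: TrainConfig = field(default_factory=TrainConfig)
    postprocess: PostprocessSpec = field(default_factory=PostprocessSpec)
    surface: SurfaceSpec = field(default_factory=SurfaceSpec)
    seed: int = 0

    def __post_init__(self):
        self.recipe = InputRecipe(self.recipe)
        self.validate()

    def validate(self) -> None:
        f = self.network.downsample_factor
        if any(c % f for c in self.crop.crop_shape):
            raise ValueError(
                f"crop shape {self.crop.crop_shape} not divisible by the "
                f"network downsampling factor {f}")
        if any(g % f for g in self.grid.target_shape):
            raise ValueError(
                f"grid shape {self.grid.target_shape} not divisible by the "
                f"network downsampling factor {f}")
        if any(c > g for c, g in zip(self.crop.crop_shape, self.grid.target_shape)):
            raise ValueError("crop shape exceeds grid shape")

    # ---- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["recipe"] = self.recipe.value
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CascadeConfig":
        d = dict(d)
        kwargs = {}
        sub = {"grid": GridSpec, "crop": CropSpec, "dilation": DilationSpec,
               "normalization": NormalizationSpec, "network": NetworkSpec,
               "postprocess": PostprocessSpec, "surface": SurfaceSpec}
        for key, typ in sub.items():
            if key in d:
                v = d.pop(key)
                kwargs[key] = typ(**{k: tuple(x) if isinstance(x, list) else x
                                     for k, x in v.items()})
        if "train" in d:
            t = dict(d.pop("train"))
            if "augmentation" in t and isinstance(t["augmentation"], dict):
                t["augmentation"] = AugmentationSpec(
                    **{k: tuple(v) if isinstance(v, list) else v
                       for k, v in t["augmentation"].items()})
            kwargs["train"] = TrainConfig(
                **{k: tuple(v) if isinstance(v, list) and k == "split" else v
                   for k, v in t.items()})
        if "recipe" in d:
            kwargs["recipe"] = InputRecipe(d.pop("recipe"))
        if "seed" in d:
            kwargs["seed"] = int(d.pop("seed"))
        if d:
            raise ValueError(f"unknown config keys: {sorted(d)}")
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(json.loads(json.dumps(self.to_dict())),
                                       sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CascadeConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]

    def with_recipe(self, recipe: InputRecipe | str) -> "CascadeConfig":
        return replace(self, recipe=InputRecipe(recipe))


def mini_config(recipe: InputRecipe | str = InputRecipe.PREMASK_MID,
                epochs: int = 40, seed: int = 0) -> CascadeConfig:
    """Desk-scale profile: 48x48x32 grid at (1,1,2) mm, widths (4,8,16),
    40x40x28 crop, one full learning-rate cycle (ramp up, anneal down).
    Trains on a CPU in a few minutes."""
    return CascadeConfig(
        recipe=InputRecipe(recipe),
        grid=GridSpec((48, 48, 32), (1.0, 1.0, 2.0)),
        crop=CropSpec((40, 40, 28)),
        dilation=DilationSpec((6, 6, 3)),
        network=NetworkSpec(in_channels=InputRecipe(recipe).channels,
                            stage_widths=(4, 8, 16)),
        train=TrainConfig(epochs=epochs, seed=seed, augment=False,
                          val_interval=2, lr_cycle_epochs=epochs,
                          learning_rate=5e-3,
                          split=(0.8, 0.13, 0.07)),
        postprocess=PostprocessSpec(min_component_voxels=4),
        seed=seed,
    )


def paper_scale_config(recipe: InputRecipe | str = InputRecipe.PREMASK_MID,
                       seed: int = 0) -> CascadeConfig:
    """Full-scale profile: 336x336x160 grid at (0.5,0.5,2) mm, widths
    16..256, 256x256x96 crop, 200 epochs. Needs GPU-scale compute."""
    return CascadeConfig(
        recipe=InputRecipe(recipe),
        network=NetworkSpec(in_channels=InputRecipe(recipe).channels),
        train=TrainConfig(),
        seed=seed,
    )
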