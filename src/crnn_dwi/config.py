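"""Validated experiment configuration (YAML-backed).

A single :class:`ExperimentConfig` drives the whole chain
simulate -> undersample -> train -> reconstruct -> fit -> evaluate.
The resolved configuration is serialized alongside every output directory so
any run can be reproduced from its artifacts alone.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

__all__ = [
    "SchemeConfig",
    "PhantomConfig",
    "MaskConfig",
    "NetConfig",
    "TrainingConfig",
    "ExperimentConfig",
    "load_config",
    "save_config",
]


class SchemeConfig(BaseModel):
    """Acquisition scheme: ascending b-values (first 0) and unit directions."""

    bvalues: list[float] = Field(
        default=[0, 50, 100, 200, 400, 600, 800, 1000, 1500, 2000, 2500, 3000, 3500, 4000]
    )
    directions: list[tuple[float, float, float]] = Field(
        default=[(1, 0, 0), (0, 1, 0), (0, 0, 1)]
    )

    @field_validator("bvalues")
    @classmethod
    def _ascending_from_zero(cls, v: list[float]) -> list[float]:
        if not v or v[0] != 0 or any(b2 <= b1 for b1, b2 in zip(v, v[1:])):
            raise ValueError("bvalues must be strictly ascending and start at 0")
        return v

    def build(self):
        from .scheme import BValueScheme

        return BValueScheme(bvalues=tuple(self.bvalues), directions=tuple(self.directions))


class PhantomConfig(BaseModel):
    n_subjects: int = Field(default=10, ge=3)
    slices_per_subject: int = Field(default=25, ge=1)
    height: int = Field(default=256, ge=32)
    width: int = Field(default=256, ge=32)
    n_regions: int = Field(default=3, ge=1)
    noise_sigma: float = Field(default=0.01, ge=0)
    aniso_spread: float = Field(default=0.0, ge=0)


class MaskConfig(BaseModel):
    R: float = Field(default=4.0, ge=1.0)
    n_center: int = Field(default=24, ge=0)
    decay_power: float = Field(default=3.0, ge=0)


class NetConfig(BaseModel):
    n_iterations: int = Field(default=5, ge=1)
    n_hidden: int = Field(default=64, ge=1)
    kernel_size: int = Field(default=3, ge=1)
    share_across_iterations: bool = True

    @field_validator("kernel_size")
    @classmethod
    def _odd(cls, v: int) -> int:
        if v % 2 != 1:
            raise ValueError("kernel_size must be odd")
        return v

    def build(self, seed: int):
        from .network import NetworkConfig

        return NetworkConfig(
            n_iterations=self.n_iterations,
            n_hidden=self.n_hidden,
            kernel_size=self.kernel_size,
            share_across_iterations=self.share_across_iterations,
            seed=seed,
        )


class TrainingConfig(BaseModel):
    epochs: int = Field(default=20, ge=0)
    lr: float = Field(default=1e-3, gt=0)
    batch_size: int = Field(default=8, ge=1)

    def build(self, seed: int):
        from .network import TrainConfig

        return TrainConfig(
            epochs=self.epochs, lr=self.lr, batch_size=self.batch_size, seed=seed
        )


class ExperimentConfig(BaseModel):
    """Top-level experiment description; every stage seeds from ``seed``."""

    scheme: SchemeConfig = SchemeConfig()
    phantom: PhantomConfig = PhantomConfig()
    mask: MaskConfig = MaskConfig()
    network: NetConfig = NetConfig()
    training: TrainingConfig = TrainingConfig()
    seed: int = 0
    output_dir: str = "crnn_dwi_output"

    @model_validator(mode="after")
    def _mask_fits_geometry(self) -> "ExperimentConfig":
        import numpy as np

        n_keep = int(np.floor(self.phantom.height / self.mask.R + 0.5))
        if n_keep < self.mask.n_center:
            raise ValueError(
                f"round(height/R)={n_keep} lines cannot contain the "
                f"{self.mask.n_center}-line center block"
            )
        return self

    @classmethod
    def small_scale(cls, seed: int = 0, R: float = 4.0) -> "ExperimentConfig":
        """The package's default desk-scale experiment.

        64 x 64 phantoms, 6 subjects x 4 slices, a 6-b-value ladder with
        3 directions, a 6-line fully sampled center block (the full-scale
        24-line block scaled by 64/256), and a deliberately small network.
        """
        return cls(
            scheme=SchemeConfig(bvalues=[0, 500, 1000, 2000, 3000, 4000]),
            phantom=PhantomConfig(
                n_subjects=6, slices_per_subject=4, height=64, width=64,
                n_regions=3, noise_sigma=0.01,
            ),
            mask=MaskConfig(R=R, n_center=6),
            network=NetConfig(n_iterations=3, n_hidden=8, kernel_size=3),
            training=TrainingConfig(epochs=20, lr=1e-3, batch_size=8),
            seed=seed,
        )


def load_config(path: str | Path, **overrides) -> ExperimentConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    raw.update(overrides)
    return ExperimentConfig.model_validate(raw)


def save_config(config: ExperimentConfig, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(yaml.safe_dump(config.model_dump(), sort_keys=False))
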