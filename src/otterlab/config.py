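"""Run configuration: a validated YAML schema tying the pipeline together.

Unknown keys are rejected (typos should fail loudly, not silently fall
back to defaults), and every run writes its fully resolved configuration
next to its outputs so results are reproducible from the output directory
alone.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .datasets import AcquisitionConfig, ClassificationSpec, RegressionSpec
from .physics import MaterialProps, OpticalPair
from .benchmark import SplitSpec, CLASSIFIER_NAMES, REGRESSOR_NAMES

__all__ = ["RunConfig", "load_config", "resolve_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class AcquisitionSection(_Strict):
    n_points: int = 512
    t_max_over_tau: float = 20.0
    noise_sd: float = 0.01
    baseline: float = 0.0

    def build(self, seed: int) -> AcquisitionConfig:
        return AcquisitionConfig(seed=seed, **self.model_dump())


class OpticalSection(_Strict):
    beta_w: float = 2.5e5
    beta_d: float = 5.0e4

    def build(self) -> OpticalPair:
        return OpticalPair(**self.model_dump())


class MaterialSection(_Strict):
    D: float = 1e-7

    def build(self) -> MaterialProps:
        return MaterialProps(**self.model_dump())


class RegressionSection(_Strict):
    n_signals: int = 97
    hydration_range: tuple[float, float] = (0.2, 0.9)
    amplitude_range: tuple[float, float] = (0.9, 1.1)
    mode: str = "homogeneous"
    gradient_range: tuple[float, float] = (-1.5e3, 1.5e3)

    def build(self, optical: OpticalPair, material: MaterialProps) -> RegressionSpec:
        return RegressionSpec(optical=optical, material=material, **self.model_dump())


class ClassificationSection(_Strict):
    n_classes: int = 4
    per_class: int = 5
    tau_rel_sd: float = 0.02
    a_rel_sd: float = 0.02

    def build(self, material: MaterialProps, seed: int) -> ClassificationSpec:
        return ClassificationSpec(material=material, seed=seed, **self.model_dump())


class SplitSection(_Strict):
    train_fraction: float = 0.75
    stratify: bool = True

    def build(self, seed: int, stratify: bool | None = None) -> SplitSpec:
        return SplitSpec(
            train_fraction=self.train_fraction,
            seed=seed,
            stratify=self.stratify if stratify is None else stratify,
        )


class ProfileSection(_Strict):
    n_slices: int = 10
    depth_prefactor: float = 1.0
    floor_frac: float = 0.02


class ModelsSection(_Strict):
    regressors: list[str] = Field(default_factory=lambda: list(REGRESSOR_NAMES))
    classifiers: list[str] = Field(default_factory=lambda: list(CLASSIFIER_NAMES))
    scale_features: bool = True
    overrides: dict = Field(default_factory=dict)


class RunConfig(_Strict):
    """Top-level configuration; every field has a sensible default, so an
    empty file is a valid config."""

    seed: int = 0
    out_dir: str = "otterlab-out"
    acquisition: AcquisitionSection = AcquisitionSection()
    optical: OpticalSection = OpticalSection()
    material: MaterialSection = MaterialSection()
    regression: RegressionSection = RegressionSection()
    classification: ClassificationSection = ClassificationSection()
    split: SplitSection = SplitSection()
    profile: ProfileSection = ProfileSection()
    models: ModelsSection = ModelsSection()


def load_config(path=None, **updates) -> RunConfig:
    """Load (or default-construct) a RunConfig, applying flat overrides."""
    data = {}
    if path is not None:
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
    data.update({k: v for k, v in updates.items() if v is not None})
    return RunConfig(**data)


def resolve_config(cfg: RunConfig, out_dir: Path) -> None:
    """Write the fully resolved config and package version into out_dir."""
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = cfg.model_dump(mode="json")
    # the file sits inside out_dir already; embedding the path would make
    # otherwise-identical runs differ byte-for-byte
    payload.pop("out_dir", None)
    payload["package_version"] = __version__
    with (out_dir / "resolved_config.yaml").open("w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)
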