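"""Schema-validated pipeline configuration (YAML-backed, unknown keys rejected).

Every run materializes its fully resolved configuration plus seeds into a
run record, which is enough to reproduce the run bit-for-bit in
single-threaded mode.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PreprocessSection(_Strict):
    clamp: tuple[float, float] = (-1000.0, 800.0)
    sigma_mm: float = 0.75
    inplane: tuple[int, int] = (256, 256)
    depth: int | str = "keep"
    mode: str = "clamped_hu"


class AugmentSection(_Strict):
    enabled: bool = True
    scale: tuple[float, float] = (0.9, 1.1)
    rotate_deg: tuple[float, float] = (-10.0, 10.0)
    flip_lr: bool = True
    prob: float = 0.5
    seed: int = 0


class SegSection(_Strict):
    base_width: int = 16
    depth: int = 3
    chaspp_root_rate: int = 2
    chaspp_branch_rates: tuple[int, int, int] = (1, 2, 3)
    dropout: float = 0.3
    residual_blocks: bool = True
    plane: str = "sagittal"
    seed: int = 0


class RecogSection(_Strict):
    stem_width: int = 12
    stages: list[tuple[int, int, int, int]] = Field(
        default_factory=lambda: [(1, 8, 1, 1), (6, 12, 2, 2), (6, 16, 3, 2)])
    fused_channels: int = 32
    skip_channels: tuple[int, int] = (8, 8)
    decoder_widths: tuple[int, int, int, int] = (32, 16, 8, 8)
    dropout: float = 0.3
    out_classes: int = 25
    residual_blocks: bool = True
    seed: int = 0


class TrainSection(_Strict):
    epochs: int = 150
    lr: float = 0.001
    batch_size: int = 8
    split_fraction: float = 0.8
    seed: int = 0


class PathsSection(_Strict):
    data_dir: str = "data"
    out_dir: str = "runs"


class PipelineConfig(_Strict):
    preprocess: PreprocessSection = Field(default_factory=PreprocessSection)
    augment: AugmentSection = Field(default_factory=AugmentSection)
    seg: SegSection = Field(default_factory=SegSection)
    recog: RecogSection = Field(default_factory=RecogSection)
    train: TrainSection = Field(default_factory=TrainSection)
    paths: PathsSection = Field(default_factory=PathsSection)


def load_config(path=None) -> PipelineConfig:
    if path is None:
        return PipelineConfig()
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig(**raw)


def write_run_record(cfg: PipelineConfig, out_dir, extra: dict | None = None):
    """Resolved config + seeds + package version, for reproducibility."""
    from . import __version__
    rec = {"config": json.loads(cfg.model_dump_json()),
           "package_version": __version__}
    rec.update(extra or {})
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "run_record.json", "w") as fh:
        json.dump(rec, fh, indent=2)
    return rec


def preprocess_config(cfg: PipelineConfig):
    from .preprocess import NormalizationMode, PreprocessConfig
    p = cfg.preprocess
    return PreprocessConfig(clamp_lo=p.clamp[0], clamp_hi=p.clamp[1],
                            smooth_sigma=p.sigma_mm,
                            target_inplane=tuple(p.inplane),
                            target_depth=p.depth,
                            mode=NormalizationMode(p.mode))


def seg_config(cfg: PipelineConfig):
    from .chaspprau import SegModelConfig
    s = cfg.seg
    return SegModelConfig(base_width=s.base_width, depth=s.depth,
                          chaspp_root_rate=s.chaspp_root_rate,
                          chaspp_branch_rates=tuple(s.chaspp_branch_rates),
                          dropout=s.dropout,
                          residual_blocks=s.residual_blocks, seed=s.seed)


def recog_config(cfg: PipelineConfig):
    from .blocks import BottleneckSpec
    from .mru3d import RecogModelConfig
    r = cfg.recog
    return RecogModelConfig(
        stem_width=r.stem_width,
        stages=tuple(BottleneckSpec(*s) for s in r.stages),
        fused_channels=r.fused_channels,
        skip_channels=tuple(r.skip_channels),
        decoder_widths=tuple(r.decoder_widths),
        dropout=r.dropout, out_classes=r.out_classes,
        residual_blocks=r.residual_blocks, seed=r.seed)


def train_config(cfg: PipelineConfig, epochs: int | None = None,
                 seed: int | None = None):
    from .train_eval import TrainConfig
    t = cfg.train
    return TrainConfig(epochs=epochs if epochs is not None else t.epochs,
                       lr=t.lr, batch_size=t.batch_size,
                       seed=seed if seed is not None else t.seed,
                       split_fraction=t.split_fraction)


def augment_spec(cfg: PipelineConfig):
    from .augment import AugmentationSpec
    a = cfg.augment
    if not a.enabled:
        return None
    return AugmentationSpec(scale_range=tuple(a.scale),
                            rotation_range_deg=tuple(a.rotate_deg),
                            flip_lr=a.flip_lr, p_scale=a.prob,
                            p_rotate=a.prob, p_flip=a.prob)
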