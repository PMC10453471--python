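"""High-level orchestration of the two-stage cascade.

Thin glue shared by the CLI, the examples and the acceptance harness:
loading phantom datasets, building slice/volume training items, training
each stage, checkpointing, and running the preprocess -> segment ->
recognize cascade on a volume.
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np

from . import nn
from .augment import AugmentationSpec, random_augment
from .chaspprau import (CHASPPRAUNet, SegModelConfig, build_seg_model,
                        segment_volume)
from .mru3d import MRUNet3D, RecogModelConfig, build_recog_model, recognize
from .nifti_io import LabelMap, Volume, read_labelmap, read_volume
from .preprocess import PreprocessConfig, preprocess_pipeline
from .train_eval import TrainConfig, train


# -- dataset handling ------------------------------------------------------

def load_manifest(data_dir) -> list[dict]:
    path = Path(data_dir) / "manifest.csv"
    with open(path, newline="") as fh:
        return list(csv.DictReader(fh))


def load_samples(data_dir) -> list[tuple[str, Volume, LabelMap]]:
    out = []
    for row in load_manifest(data_dir):
        out.append((row["sample_id"], read_volume(row["image_path"]),
                    read_labelmap(row["label_path"])))
    return out


def preprocess_samples(samples, cfg: PreprocessConfig):
    return [(sid, *preprocess_pipeline(v, m, cfg)) for sid, v, m in samples]


def seg_slice_items(v: Volume, m: LabelMap, plane: str = "sagittal",
                    bg_stride: int = 4) -> list[tuple[np.ndarray, np.ndarray]]:
    """(1, H, W) image / (H, W) binary-target pairs from one volume.

    Every slice containing spine plus every `bg_stride`-th empty slice, so
    background-only slices stay represented without dominating.
    """
    from .chaspprau import PLANE_AXIS
    axis = PLANE_AXIS[plane]
    img = np.moveaxis(v.data, axis, 0).astype(np.float32)
    lab = np.moveaxis(m.data > 0, axis, 0)
    items = []
    n_bg = 0
    for i in range(img.shape[0]):
        if lab[i].any():
            items.append((img[i][None], lab[i].astype(np.int64)))
        else:
            if n_bg % bg_stride == 0:
                items.append((img[i][None], lab[i].astype(np.int64)))
            n_bg += 1
    return items


def recog_volume_item(v: Volume, m: LabelMap,
                      mask: LabelMap | None = None
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Two-channel (CT, spine mask) input and integer target for stage 2."""
    spine = (m.data > 0) if mask is None else (mask.data > 0)
    x = np.stack([v.data, spine]).astype(np.float32)
    return x, m.data.astype(np.int64)


# -- checkpoints -----------------------------------------------------------

def save_checkpoint(model: nn.Module, cfg, path) -> None:
    """Single-file serialized weights plus a config echo."""
    cfg_json = json.dumps(asdict(cfg) if not isinstance(cfg, dict) else cfg,
                          default=lambda o: list(o) if isinstance(o, tuple) else str(o))
    np.savez(path, __config__=cfg_json, **model.state_dict())


def load_checkpoint(path, kind: str):
    """kind: 'seg' or 'recog'.  Returns a model in eval mode."""
    with np.load(path, allow_pickle=False) as z:
        cfg_dict = json.loads(str(z["__config__"]))
        state = {k: z[k] for k in z.files if k != "__config__"}
    if kind == "seg":
        model = build_seg_model(SegModelConfig(**cfg_dict))
    else:
        from .blocks import BottleneckSpec
        cfg_dict["stages"] = tuple(
            BottleneckSpec(**s) if isinstance(s, dict) else BottleneckSpec(*s)
            for s in cfg_dict["stages"])
        for key in ("skip_channels", "decoder_widths"):
            cfg_dict[key] = tuple(cfg_dict[key])
        model = build_recog_model(RecogModelConfig(**cfg_dict))
    model.load_state_dict(state)
    return model.eval()


# -- stage training --------------------------------------------------------

def _seg_forward(model, xs):
    return model(nn.Tensor(xs))


def _seg_predict(model):
    def predict(x):
        with nn.no_grad():
            logits = model(nn.Tensor(x[None] if x.ndim == 3 else x))
        return logits.data[0].argmax(axis=0)
    return predict


def train_stage1(pre_samples, seg_cfg: SegModelConfig, tcfg: TrainConfig,
                 plane: str = "sagittal",
                 augment_spec: AugmentationSpec | None = None,
                 val_fraction_of_train: float = 0.2, log=None):
    """Train the slice-wise spine segmenter on preprocessed samples."""
    items = []
    for _sid, v, m in pre_samples:
        items.extend(seg_slice_items(v, m, plane))
    n_val = max(1, int(round(len(items) * val_fraction_of_train)))
    rng = np.random.default_rng(tcfg.seed)
    order = rng.permutation(len(items))
    val_items = [items[i] for i in order[:n_val]]
    train_items = [items[i] for i in order[n_val:]]
    model = build_seg_model(seg_cfg)
    augment_fn = None
    if augment_spec is not None:
        def augment_fn(x, t, arng):
            xi, ti = random_augment(x[0], t.astype(np.int16), augment_spec, arng)
            return xi[None].astype(np.float32), ti.astype(np.int64)
    from .train_eval import binary_dice_score
    history, best = train(model, train_items, val_items, tcfg,
                          forward=_seg_forward, predict=_seg_predict(model),
                          augment_fn=augment_fn, score=binary_dice_score,
                          log=log)
    model.load_state_dict(best["state"])
    return model.eval(), history, best


def train_stage2(pre_samples, recog_cfg: RecogModelConfig, tcfg: TrainConfig,
                 masks: dict[str, LabelMap] | None = None, log=None):
    """Train the 3D recognizer; `masks` maps sample_id to stage-1 output
    (defaults to the ground-truth spine mask: the oracle-cascade setting)."""
    items = [recog_volume_item(v, m, masks.get(sid) if masks else None)
             for sid, v, m in pre_samples]
    n_val = max(1, len(items) // 5)
    rng = np.random.default_rng(tcfg.seed)
    order = rng.permutation(len(items))
    val_items = [items[i] for i in order[:n_val]]
    train_items = [items[i] for i in order[n_val:]]
    model = build_recog_model(recog_cfg)

    def forward(mdl, xs):
        return mdl(xs[0])

    def predict(x):
        with nn.no_grad():
            logits = model(x)
        lab = logits.data[0].argmax(axis=0)
        lab[x[1] <= 0] = 0
        return lab

    tcfg_1 = TrainConfig(**{**tcfg.__dict__, "batch_size": 1})
    history, best = train(model, train_items, val_items, tcfg_1,
                          forward=forward, predict=predict, log=log)
    model.load_state_dict(best["state"])
    return model.eval(), history, best


# -- the two-step cascade --------------------------------------------------

def predict_cascade(seg_model: CHASPPRAUNet, recog_model: MRUNet3D,
                    v: Volume, pre_cfg: PreprocessConfig,
                    plane: str = "sagittal"
                    ) -> tuple[LabelMap, LabelMap]:
    """preprocess -> slice-wise spine segmentation -> 3D vertebra recognition.

    Returns (binary spine mask, multi-class vertebra labels) on the working
    grid; the vertebra map is zero wherever the spine mask is zero.
    """
    vp, _ = preprocess_pipeline(v, None, pre_cfg)
    spine = segment_volume(seg_model, vp, plane=plane)
    verts = recognize(recog_model, vp, spine)
    return spine, verts
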