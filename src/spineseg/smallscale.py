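"""The reference small-scale experiment: the full two-stage pipeline on
synthetic phantoms, sized to finish on a single CPU core in minutes.

25 default-spec phantoms are generated from one master seed, preprocessed
to a 32x48x48 working grid with unit-range normalization, and split 80/20
into 20 training and 5 held-out phantoms.  Stage 1 (reduced width/depth)
trains on sagittal slices; stage 2 trains on ground-truth spine masks (the
oracle-cascade setting) and is evaluated both that way and through the
real cascade with stage-1 masks.  Every random choice derives from the
single seed, so repeating a run reproduces its metric tables exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import metrics, pipeline
from .chaspprau import SegModelConfig, segment_volume
from .mru3d import RecogModelConfig, recognize
from .nifti_io import LabelMap
from .phantom import PhantomSpec, generate_phantom
from .preprocess import NormalizationMode, PreprocessConfig
from .train_eval import TrainConfig, split_dataset


@dataclass
class SmallScaleSpec:
    n_phantoms: int = 25
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    working_grid: tuple[int, int, int] = (32, 48, 48)   # (z, y, x)
    seg_epochs: int = 10
    recog_epochs: int = 12
    recog_lr: float = 0.01   # epoch budget ~10x below the full schedule
    seed: int = 42


def make_phantom_set(spec: SmallScaleSpec):
    """n seeded phantoms as (id, volume, labels) triples."""
    out = []
    for i, ss in enumerate(np.random.SeedSequence(spec.seed).spawn(
            spec.n_phantoms)):
        rng = np.random.default_rng(int(ss.generate_state(1)[0] % 2 ** 31))
        s = generate_phantom(spec.phantom, rng)
        out.append((f"p{i:02d}", s.volume, s.labels))
    return out


def run_small_scale(spec: SmallScaleSpec | None = None, log=None) -> dict:
    """Train both stages and evaluate on the held-out phantoms.

    Returns a dict with per-sample metric tables and summary means; all
    dice/IoU/precision/recall values are fractions in [0, 1].
    """
    spec = spec or SmallScaleSpec()
    tz, ty, tx = spec.working_grid
    pre = PreprocessConfig(target_inplane=(ty, tx), target_depth=tz,
                           mode=NormalizationMode.UNIT_RANGE)
    samples = make_phantom_set(spec)
    pre_samples = pipeline.preprocess_samples(samples, pre)
    train_s, test_s = split_dataset(pre_samples, 0.8, seed=spec.seed)

    seg_model, seg_hist, seg_best = pipeline.train_stage1(
        train_s, SegModelConfig(base_width=8, depth=2, seed=spec.seed + 1),
        TrainConfig(epochs=spec.seg_epochs, batch_size=8, seed=spec.seed + 1),
        log=log)
    recog_model, recog_hist, recog_best = pipeline.train_stage2(
        train_s,
        RecogModelConfig(out_classes=spec.phantom.n_vertebrae + 1,
                         seed=spec.seed + 2),
        TrainConfig(epochs=spec.recog_epochs, batch_size=1,
                    lr=spec.recog_lr, seed=spec.seed + 2),
        log=log)

    seg_rows, recog_rows, oracle_rows = [], [], []
    for sid, v, m in test_s:
        spine = segment_volume(seg_model, v)
        seg_rows.append({"scan_id": sid,
                         **metrics.binary_report(spine.data > 0,
                                                 m.data > 0)})
        verts = recognize(recog_model, v, spine)
        recog_rows.append({"scan_id": sid,
                           **metrics.macro_report(verts.data, m.data)["macro"]})
        gt_mask = LabelMap((m.data > 0).astype(np.int16), m.affine)
        verts_gt = recognize(recog_model, v, gt_mask)
        oracle_rows.append({
            "scan_id": sid,
            **metrics.macro_report(verts_gt.data, m.data)["macro"]})

    def mean_of(rows, key="dice"):
        return float(np.mean([r[key] for r in rows]))

    return {
        "n_train": len(train_s),
        "n_test": len(test_s),
        "seg_history": [r.__dict__ for r in seg_hist],
        "recog_history": [r.__dict__ for r in recog_hist],
        "seg_rows": seg_rows,
        "recog_rows": recog_rows,
        "recog_oracle_rows": oracle_rows,
        "spine_dice": mean_of(seg_rows),
        "recog_macro_dice": mean_of(recog_rows),
        "recog_macro_dice_gt_masks": mean_of(oracle_rows),
    }
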