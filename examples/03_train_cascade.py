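"""Train the two-stage cascade on phantoms and score held-out volumes.

Runs the package's reference small-scale experiment: 25 phantoms
preprocessed to a 32x48x48 grid, split 20 train / 5 test; stage 1 (CHASPP
residual-attention U-Net, reduced width) learns binary spine-vs-background
segmentation from sagittal slices, stage 2 (3D multi-view mobile residual
U-Net) learns per-vertebra labels from the CT plus the spine mask.  Takes
roughly ten minutes on one CPU core.

Expected output (seed 1): held-out spine dice ~0.92 and vertebra macro
dice ~0.73 through the full cascade.
"""

from spineseg.smallscale import SmallScaleSpec, run_small_scale

run = run_small_scale(SmallScaleSpec(seed=1), log=print)

print(f"\ntrain/test phantoms: {run['n_train']}/{run['n_test']}")
print("held-out results:")
for row in run["seg_rows"]:
    print(f"  {row['scan_id']}: spine dice {row['dice']:.3f}")
print(f"mean spine dice:            {run['spine_dice']:.3f}")
print(f"mean vertebra macro dice:   {run['recog_macro_dice']:.3f} "
      "(cascade: stage-2 masked by stage-1 output)")
print(f"mean macro dice, oracle mask: {run['recog_macro_dice_gt_masks']:.3f} "
      "(stage-2 fed the ground-truth spine mask)")
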