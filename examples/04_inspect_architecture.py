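"""Inspect the two networks: structure, parameter budgets, attention maps.

Prints the trainable-parameter counts of the reference configurations and
compares them with published comparator models, then shows that the
attention gates produce per-pixel weights strictly inside (0, 1).
"""

import numpy as np

from spineseg import (RecogModelConfig, SegModelConfig, build_recog_model,
                      build_seg_model, count_parameters, segment_slice)
from spineseg.blocks import CHASPP, AttentionGate
from spineseg.nn import Tensor

seg = build_seg_model(SegModelConfig())
recog = build_recog_model(RecogModelConfig())
n_seg, n_recog = count_parameters(seg), count_parameters(recog)

print("trainable parameters")
print(f"  stage 1 (spine segmentation):   {n_seg:>12,}")
print(f"  stage 2 (vertebra recognition): {n_recog:>12,}")
print(f"  two-stage total:                {n_seg + n_recog:>12,}")
print("published comparators: U-Net 1,941,105; 3D U-Net 19,069,955; "
      "two-stage reference total 1,245,155")

n_chaspp = sum(isinstance(m, CHASPP) for m in seg.modules())
n_gates = sum(isinstance(m, AttentionGate) for m in seg.modules())
print(f"stage 1 structure: {n_chaspp} CHASPP modules, "
      f"{n_gates} attention gates (depth {seg.cfg.depth})")

# attention weights on a random slice are strictly inside (0, 1)
rng = np.random.default_rng(0)
seg.eval()
gate = seg.gates[0]
skip = Tensor(0.1 * rng.normal(size=(1, 64, 8, 8)).astype(np.float32))
state = Tensor(0.1 * rng.normal(size=(1, 128, 8, 8)).astype(np.float32))
alpha = gate.attention(skip, state).data
print(f"attention weights: min {alpha.min():.4f}, max {alpha.max():.4f} "
      "(logistic scores: always strictly between 0 and 1)")

probs = segment_slice(seg, rng.normal(size=(256, 256)).astype(np.float32))
print(f"slice probabilities: shape {probs.shape}, per-pixel sum "
      f"{probs.sum(axis=0).min():.6f}..{probs.sum(axis=0).max():.6f}")
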