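"""Train the tiny preset briefly on synthetic pairs and segment held-out images.

A short demonstration run (a few minutes on one CPU): 60 training pairs,
T=100 diffusion steps, 600 optimisation steps, ensemble of 3.  Longer runs
(1200 steps on 200 pairs) reach mean Dice around 0.99.
"""

import numpy as np

from spinediff import SynthConfig, make_dataset
from spinediff.config import RunConfig
from spinediff.metrics import evaluate_pairs
from spinediff.trainer import fit, predict

splits = make_dataset(70, (6 / 7, 0.0, 1 / 7), SynthConfig(), seed=3)
cfg = RunConfig(T=100, preset="tiny", lr=1e-3, max_iters=600,
                val_interval=100, ensemble=3, seed=0, augment=False)
model, sched, log = fit(splits["train"], cfg, val_pairs=None)
print(f"trained {log[-1]['step']} steps; "
      f"final 50-step mean loss {np.mean([r['loss'] for r in log[-50:]]):.3f}")

preds, truths = [], []
for p in splits["test"][:4]:
    preds.append(predict(p.image, model, sched, cfg,
                         rng=np.random.default_rng(9)))
    truths.append(p.mask)
rows, summary = evaluate_pairs(preds, truths)
print(f"held-out Dice {summary['dice_mean']:.3f} +/- {summary['dice_sd']:.3f}, "
      f"IoU {summary['iou_mean']:.3f}")
# Dice is the overlap 2|X n Y|/(|X|+|Y|) between predicted and true masks;
# even this short run should land well above the ~0.2 of a trivial guess.
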