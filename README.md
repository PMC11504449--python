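# spinediff

Conditional-diffusion segmentation of spinal 2-D images.

Sagittal spine images are hard to segment: vertebra boundaries blur, the
repeated bodies look alike, and background tissue can match foreground
intensity.  `spinediff` treats the binary vertebra mask as the object of a
conditional denoising diffusion process instead of a direct pixel
classification.  A conditional U-Net first produces a prior mask
`f(b) ∈ [0,1]^{H×W}` from the image `b`; this prior shifts the forward
corruption of the ground-truth mask `x0`,

```
x_t = √ᾱ_t · x0 + √(1−ᾱ_t) · f(b) + √(1−ᾱ_t) · ε,    ε ~ N(0, I),
```

and conditions the diffusion U-Net `Φ_θ(x_t, t, f(b))`, which is trained to
predict `ε` under the hybrid objective `L = ‖ε − ε̂‖² + BCE(x0, x̂0)`.
Segmentation runs the learned reverse chain from pure noise,

```
x_{t−1} = (x_t − (1−α_t)/√(1−ᾱ_t) · ε̂) / √α_t + σ_t z,
```

averages several independently sampled masks, and thresholds at 0.5.
Two bespoke operators refine the features: a **multi-scale fusion module**
(MSFM: 3/5/7 convolution branches fused by a per-channel softmax over learned
logits, `a_n + b_n + c_n = 1`) and a **noise semantic adapter** (NSA: paired
fine-grain and dilated depthwise convolutions with sigmoid attention gating
and residual multiplication) in the denoiser's encoder.  Both are ablation
switches.  Quality is measured by Dice `2|X∩Y|/(|X|+|Y|)` and IoU
`TP/(TP+FP+FN)` with mean ± sd reporting.

Everything runs on CPU NumPy: the networks, including a small reverse-mode
autodiff engine, live in `spinediff/nn`.  A synthetic generator produces
vertebra-column image/mask pairs that emulate the hard cases (blurred
boundaries, background–foreground similarity, shape deformation, high aspect
ratio), so the whole pipeline is testable without any dataset download.

## Worked example

```bash
spinediff generate-data --n 40 --seed 35 --out data/
spinediff train --data data/ --out run/ --t-steps 100 --max-iters 800 --lr 1e-3
spinediff sample --checkpoint run/checkpoint.npz --data data/ --out preds/ --ensemble 3 --seed 1
spinediff evaluate --pred preds/ --data data/ --out metrics.csv
```

The same flow from Python (see `examples/` for narrative scripts):

```python
import numpy as np
from spinediff import SynthConfig, make_dataset
from spinediff.config import RunConfig
from spinediff.metrics import evaluate_pairs
from spinediff.trainer import fit, predict

splits = make_dataset(250, (0.8, 0.1, 0.1), SynthConfig(), seed=7)
cfg = RunConfig(T=100, preset="tiny", lr=1e-3, max_iters=1200, ensemble=3,
                augment=False)
model, sched, log = fit(splits["train"], cfg, val_pairs=splits["val"])
preds = [predict(p.image, model, sched, cfg, rng=np.random.default_rng(k))
         for k, p in enumerate(splits["test"][:6])]
rows, s = evaluate_pairs(preds, [p.mask for p in splits["test"][:6]])
print(f"dice {s['dice_mean']:.3f} +/- {s['dice_sd']:.3f}")
```

A run of exactly this snippet printed:

```
dice 0.993 +/- 0.002
```

meaning the ensemble-averaged sampled masks overlap the ground truth at
~99% Dice after 1200 single-image training steps on one CPU — scaled-down
conditions on synthetic columns, which is enough to show the diffusion
segmenter learns and samples correctly, not that it reaches clinical
accuracy on real data.

## Layout

```
src/spinediff/      schedule, diffusion, msfm, nsa, networks, metrics,
                    synthetic, trainer, config, io, cli, nn (autodiff)
tests/              pytest suite (unit, property and acceptance tests)
examples/           short narrative scripts, one per capability
docs/methods.md     model, assumptions, parameters, limitations
```
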