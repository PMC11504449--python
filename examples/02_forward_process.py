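"""Visualise the prior-shifted forward corruption of a mask.

Shows how the marginal mean interpolates from the clean mask toward the
prior as t grows, and checks the empirical moments of x_t against the
closed form.
"""

import numpy as np

from spinediff import SynthConfig, generate_pair, make_schedule, q_sample

sched = make_schedule(100)
img, mask = generate_pair(SynthConfig(seed=1))
x0 = mask.astype(np.float64)
prior = np.clip(x0 + 0.1, 0, 1)  # stand-in prior before any training

rng = np.random.default_rng(0)
for t in (1, 25, 50, 100):
    ab = sched.alpha_bar_t(t)
    draws = np.stack([q_sample(x0, prior, sched, t,
                               rng.standard_normal(x0.shape))
                      for _ in range(200)])
    print(f"t={t:3d}  abar={ab:.4f}  mean(x_t)={draws.mean():.4f}  "
          f"closed-form mean={np.sqrt(ab)*x0.mean() + np.sqrt(1-ab)*prior.mean():.4f}  "
          f"var={draws.var(axis=0).mean():.4f} (expected {1-ab:.4f})")
# As t grows, abar decays toward 0: the signal term shrinks and the noisy
# label drifts toward prior + unit-variance Gaussian noise.
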