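"""Prior-shifted diffusion: forward noising, reverse sampling and the hybrid loss.

The forward process corrupts a binary mask ``x0`` toward Gaussian noise while
shifting the mean by the conditional network's prior mask ``f(b)``:

    x_t = sqrt(abar_t) * x0 + sqrt(1 - abar_t) * f(b) + sqrt(1 - abar_t) * eps

The denoiser ``Phi_theta(x_t, t, cond)`` predicts ``eps``; reverse sampling
iterates

    x_{t-1} = (x_t - (1 - a_t)/sqrt(1 - abar_t) * eps_hat) / sqrt(a_t)
              + sigma_t * z,          z = 0 at t = 1,

from pure noise ``x_T ~ N(0, I)`` down to a clean mask.  Training minimises
the noise-prediction MSE plus a binary cross-entropy term on the implied
clean mask, with unit weights.

All elementwise formulas below accept either plain ``float64`` NumPy arrays
(used by the closed-form unit oracles) or :class:`~spinediff.nn.Tensor`
graphs (used during training, where gradients must flow through ``f(b)``).
"""

from __future__ import annotations

import numpy as np

from .nn import Tensor
from .nn.tensor import no_grad
from .schedule import NoiseSchedule, posterior_variance

__all__ = [
    "q_sample", "posterior_mean", "reverse_step", "loss_simple", "loss_bce",
    "loss_total", "predict_x0", "train_step", "sample", "sample_ensemble",
    "ensemble_average",
]

BCE_EPS = 1e-6  # clamp width keeping log() finite on saturated predictions


def _check_shapes(*grids) -> None:
    shapes = {np.shape(g.data if isinstance(g, Tensor) else g) for g in grids}
    if len(shapes) > 1:
        raise ValueError(f"shape mismatch among inputs: {sorted(shapes)}")


def _mean(x):
    return x.mean() if isinstance(x, Tensor) else float(np.mean(x))


# --------------------------------------------------------------- forward chain
def q_sample(x0, prior, s: NoiseSchedule, t: int, eps):
    """Draw x_t from the prior-shifted forward marginal (noise ``eps`` supplied)."""
    _check_shapes(x0, prior, eps)
    ab = s.alpha_bar_t(t)
    return np.sqrt(ab) * x0 + np.sqrt(1.0 - ab) * prior + np.sqrt(1.0 - ab) * eps


def posterior_mean(x0, xt, prior, s: NoiseSchedule, t: int):
    """Mean of the forward posterior q(x_{t-1} | x_t, x0, f(b))."""
    _check_shapes(x0, xt, prior)
    a = s.alpha_t(t)
    ab = s.alpha_bar_t(t)
    ab_prev = s.alpha_bar_t(t - 1)
    c0 = np.sqrt(ab_prev) * (1.0 - a) / (1.0 - ab)
    ct = np.sqrt(a) * (1.0 - ab_prev) / (1.0 - ab)
    return c0 * x0 + ct * xt + np.sqrt(1.0 - ab) * prior


def reverse_step(xt, eps_hat, s: NoiseSchedule, t: int, z):
    """One reverse-denoising update x_t -> x_{t-1}.

    ``z`` must be the zero grid at t = 1 (the last step is deterministic).
    """
    _check_shapes(xt, eps_hat, z)
    a = s.alpha_t(t)
    ab = s.alpha_bar_t(t)
    zarr = z.data if isinstance(z, Tensor) else np.asarray(z)
    if t == 1 and np.any(zarr != 0):
        raise ValueError("reverse step at t=1 is deterministic: z must be 0")
    sigma = np.sqrt(posterior_variance(s, t))
    return (xt - (1.0 - a) / np.sqrt(1.0 - ab) * eps_hat) / np.sqrt(a) + sigma * z


def predict_x0(xt, eps_hat, prior, s: NoiseSchedule, t: int):
    """Invert the forward marginal to the implied clean mask estimate."""
    ab = s.alpha_bar_t(t)
    return (xt - np.sqrt(1.0 - ab) * prior - np.sqrt(1.0 - ab) * eps_hat) / np.sqrt(ab)


# --------------------------------------------------------------------- losses
def loss_simple(eps, eps_hat):
    """Noise-prediction MSE, averaged over pixels."""
    _check_shapes(eps, eps_hat)
    return _mean((eps - eps_hat) ** 2)


def loss_bce(target, pred):
    """Binary cross-entropy of probability grid ``pred`` against binary ``target``.

    Predictions are hard-clamped into [BCE_EPS, 1 - BCE_EPS] first.
    """
    _check_shapes(target, pred)
    lo, hi = BCE_EPS, 1.0 - BCE_EPS
    if isinstance(pred, Tensor) or isinstance(target, Tensor):
        p = pred.clamp(lo, hi) if isinstance(pred, Tensor) else np.clip(pred, lo, hi)
        if isinstance(p, np.ndarray):
            p = Tensor(p)
        return -_mean(target * p.log() + (1.0 - target) * (1.0 - p).log())
    p = np.clip(pred, lo, hi)
    return -float(np.mean(target * np.log(p) + (1.0 - target) * np.log(1.0 - p)))


def loss_total(eps, eps_hat, target, pred):
    """Hybrid objective: noise MSE + mask BCE, unit weights."""
    return loss_simple(eps, eps_hat) + loss_bce(target, pred)


# ------------------------------------------------------------------- training
def train_step(image: np.ndarray, x0: np.ndarray, model, s: NoiseSchedule,
               opt, rng: np.random.Generator) -> dict[str, float]:
    """One optimisation step on a single image/mask pair (batch size 1).

    Samples ``t`` uniformly from {1..T}, draws ``eps``, forms ``x_t`` with the
    prior shift, and descends the hybrid loss.  The conditional network is
    trained jointly: gradients reach it both through the ``f(b)`` shift inside
    ``x_t`` and through an explicit BCE supervision of the prior itself.

    Returns the component losses as floats; raises ``FloatingPointError`` if
    the total is non-finite.
    """
    t = int(rng.integers(1, s.T + 1))
    eps = rng.standard_normal(x0.shape).astype(np.float32)

    cond, f_b = model.condition(image)
    fb_grid = f_b.reshape(x0.shape)
    xt = q_sample(x0, fb_grid, s, t, eps)
    eps_hat = model.denoise(xt, t, cond, f_b)
    x0_hat = predict_x0(xt, eps_hat, fb_grid, s, t)

    l_simple = loss_simple(Tensor(eps), eps_hat)
    l_bce = loss_bce(x0, x0_hat)
    loss = l_simple + l_bce
    l_prior = loss_bce(x0, fb_grid)  # joint discriminative supervision of f(b)
    objective = loss + l_prior

    total = float(loss.data)
    if not np.isfinite(float(objective.data)):
        raise FloatingPointError(f"non-finite training loss at t={t}")

    opt.zero_grad()
    objective.backward()
    opt.step()
    return {"loss": total, "loss_simple": float(l_simple.data),
            "loss_bce": float(l_bce.data), "loss_prior": float(l_prior.data),
            "t": t}


# ------------------------------------------------------------------- sampling
def sample(image: np.ndarray, model, s: NoiseSchedule,
           rng: np.random.Generator) -> np.ndarray:
    """Generate one predicted mask by running the full reverse chain.

    Starts from x_T ~ N(0, I) and applies ``reverse_step`` down to t = 1,
    conditioning every denoiser call on the (fixed) image features and prior;
    the final grid is clipped to [0, 1].
    """
    model.eval()  # freeze running statistics so sampling never mutates the model
    try:
        return _sample_inner(image, model, s, rng)
    finally:
        model.train()


def _sample_inner(image, model, s, rng):
    with no_grad():
        cond, f_b = model.condition(image)
        return _reverse_chain(image.shape[-2:], model, s, rng, cond, f_b)


def sample_ensemble(image: np.ndarray, model, s: NoiseSchedule,
                    rng: np.random.Generator, k: int) -> list[np.ndarray]:
    """Run ``k`` independent reverse chains off one generator stream.

    The conditional features are computed once and shared; chain draws are
    consumed sequentially, so ``k = 1`` is bit-identical to a single
    :func:`sample` call from the same generator state.
    """
    if k < 1:
        raise ValueError("ensemble size must be >= 1")
    model.eval()
    try:
        with no_grad():
            cond, f_b = model.condition(image)
            return [_reverse_chain(image.shape[-2:], model, s, rng, cond, f_b)
                    for _ in range(k)]
    finally:
        model.train()


def _reverse_chain(shape, model, s, rng, cond, f_b) -> np.ndarray:
    x = rng.standard_normal(shape).astype(np.float32)
    for t in range(s.T, 0, -1):
        eps_hat = model.denoise(x, t, cond, f_b).data.reshape(x.shape)
        z = (rng.standard_normal(x.shape).astype(np.float32) if t > 1
             else np.zeros_like(x))
        x = reverse_step(x, eps_hat, s, t, z)
    return np.clip(x, 0.0, 1.0)


def ensemble_average(masks: list[np.ndarray]) -> np.ndarray:
    """Elementwise mean of several predicted probability grids."""
    if len(masks) == 0:
        raise ValueError("ensemble_average needs at least one mask")
    _check_shapes(*masks)
    return np.mean(np.stack(masks), axis=0)
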