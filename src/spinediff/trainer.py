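"""Training and inference orchestration.

``fit`` runs the single-sample (batch size 1) training loop with dynamic
augmentation, periodic validation and early stopping once the validation
loss stops decreasing; ``predict`` runs ensemble-averaged reverse sampling
and returns the probability map.
"""

from __future__ import annotations

import numpy as np

from .config import RunConfig
from .diffusion import ensemble_average, sample, sample_ensemble, train_step
from .metrics import binarize
from .networks import build_model
from .nn import Adam, Tensor
from .nn.tensor import no_grad
from .schedule import make_schedule
from .synthetic import AugmentConfig, SamplePair, augment
from . import diffusion

__all__ = ["fit", "predict", "validation_loss"]


def validation_loss(model, sched, pairs, seed: int = 0, n_draws: int = 2) -> float:
    """Deterministic validation objective: hybrid loss at fixed (t, eps) draws.

    The same seed is used on every call so successive values are comparable.
    """
    model.eval()
    rng = np.random.default_rng(seed)
    total = 0.0
    with no_grad():
        for p in pairs:
            x0 = p.mask.astype(np.float32)
            cond, f_b = model.condition(p.image)
            fb_grid = f_b.reshape(x0.shape)
            for _ in range(n_draws):
                t = int(rng.integers(1, sched.T + 1))
                eps = rng.standard_normal(x0.shape).astype(np.float32)
                xt = diffusion.q_sample(x0, fb_grid, sched, t, eps)
                eps_hat = model.denoise(xt, t, cond, f_b)
                x0_hat = diffusion.predict_x0(xt, eps_hat, fb_grid, sched, t)
                total += float(diffusion.loss_total(
                    eps, eps_hat.data, x0, np.asarray(x0_hat.data)))
    model.train()
    return total / (len(pairs) * n_draws)


def fit(train_pairs: list[SamplePair], cfg: RunConfig,
        val_pairs: list[SamplePair] | None = None,
        model=None, log: list | None = None, ema_decay: float = 0.999):
    """Train a model on image/mask pairs; returns (model, sched, log_rows).

    Early-stops when the validation loss has not improved for
    ``cfg.patience`` consecutive evaluations, or at ``cfg.max_iters``.

    An exponential moving average of the weights (decay ``ema_decay`` with
    the usual warm-up ramp) is maintained throughout and loaded into the
    model when training finishes: single-sample optimisation leaves the raw
    weights jittering around the optimum, and the averaged weights give a
    markedly steadier denoiser.  Pass ``ema_decay=0`` to disable.
    """
    sched = make_schedule(cfg.T, cfg.beta_start, cfg.beta_end)
    if model is None:
        model = build_model(cfg.seed, preset=cfg.preset, use_msfm=cfg.msfm,
                            use_nsa=cfg.nsa, nsa_kernel=cfg.nsa_kernel)
    opt = Adam(model.parameters(), lr=cfg.lr)
    rng = np.random.default_rng(cfg.seed + 1)
    aug_rng = np.random.default_rng(cfg.aug_seed)
    aug_cfg = AugmentConfig(seed=cfg.aug_seed)
    log = [] if log is None else log
    params = model.parameters()
    ema = [p.data.copy() for p in params] if ema_decay > 0 else None

    best = np.inf
    stale = 0
    step = 0
    while step < cfg.max_iters:
        p = train_pairs[int(rng.integers(len(train_pairs)))]
        img, msk = p.image, p.mask
        if cfg.augment:
            img, msk = augment(img, msk, aug_cfg, aug_rng)
        out = train_step(img, msk.astype(np.float32), model, sched, opt, rng)
        step += 1
        if ema is not None:
            d = min(ema_decay, (1.0 + step) / (10.0 + step))
            for p_, e in zip(params, ema):
                e += (1.0 - d) * (p_.data - e)
        if step % cfg.val_interval == 0 or step == cfg.max_iters:
            vloss = (validation_loss(model, sched, val_pairs, seed=cfg.seed)
                     if val_pairs else np.nan)
            log.append({"step": step, **{k: v for k, v in out.items() if k != "t"},
                        "val_loss": vloss})
            if val_pairs:
                if vloss < best - 1e-4:
                    best = vloss
                    stale = 0
                else:
                    stale += 1
                    if stale >= cfg.patience:
                        break
        else:
            log.append({"step": step, **{k: v for k, v in out.items() if k != "t"},
                        "val_loss": np.nan})
    if ema is not None:
        for p_, e in zip(params, ema):
            p_.data[...] = e
    return model, sched, log


def predict(image: np.ndarray, model, sched, cfg: RunConfig,
            rng: np.random.Generator | None = None,
            return_prob: bool = False):
    """Ensemble-averaged prediction for one image.

    Draws ``cfg.ensemble`` independent reverse chains, averages them and
    binarises at ``cfg.threshold`` (probability map returned on request).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    masks = sample_ensemble(image, model, sched, rng, cfg.ensemble)
    prob = ensemble_average(masks)
    if return_prob:
        return prob
    return binarize(prob, cfg.threshold)
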