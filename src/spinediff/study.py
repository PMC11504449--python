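"""Scaled-down end-to-end study on synthetic vertebra columns.

One CPU-sized experiment exercising the whole pipeline: generate paired
data, train the full model (MSFM+NSA) and the three ablation configurations
under an identical protocol, score ensemble-averaged predictions on held-out
images, and measure the ensemble-variance property.  Shared by the
acceptance tests and ``scripts/acceptance.py``.

Problem sizes (see docs/methods.md): 200 training pairs at the generator's
default 160x64 canvas, T = 100 steps, tiny preset, lr 1e-3, batch 1, early
stopping on a validation-loss plateau within a 1200-step cap, ensemble of 3,
20 held-out evaluation images for the full model.
"""

from __future__ import annotations

import numpy as np

from .config import RunConfig
from .diffusion import ensemble_average, sample_ensemble
from .metrics import binarize, confusion_counts, dice, iou, summarize
from .synthetic import SynthConfig, make_dataset
from .trainer import fit

__all__ = ["run_scaled_study", "train_variant", "score_pairs"]

STUDY_ITERS = 1200
STUDY_T = 100
STUDY_LR = 1e-3
STUDY_ENSEMBLE = 3


def train_variant(train_pairs, val_pairs, *, msfm: bool, nsa: bool,
                  seed: int, max_iters: int = STUDY_ITERS):
    """Train one configuration under the common scaled protocol."""
    cfg = RunConfig(T=STUDY_T, preset="tiny", msfm=msfm, nsa=nsa, lr=STUDY_LR,
                    max_iters=max_iters, val_interval=150, patience=3,
                    augment=False, ensemble=STUDY_ENSEMBLE, seed=seed)
    model, sched, log = fit(train_pairs, cfg, val_pairs=val_pairs)
    return model, sched, cfg, log


def score_pairs(model, sched, pairs, n_ensemble: int = STUDY_ENSEMBLE,
                seed0: int = 100):
    """Per-image Dice/IoU of ensemble-averaged sampled masks."""
    dices, ious = [], []
    for k, p in enumerate(pairs):
        masks = sample_ensemble(p.image, model, sched,
                                np.random.default_rng(seed0 + 37 * k),
                                n_ensemble)
        pred = binarize(ensemble_average(masks))
        dices.append(dice(pred, p.mask))
        ious.append(iou(confusion_counts(pred, p.mask)))
    return dices, ious


def ensemble_variance_ratio(model, sched, pairs, n_seeds: int = 5,
                            n_ensemble: int = 5, seed0: int = 500):
    """Across-seed variance of per-image Dice: ensemble vs single-sample.

    Returns (var_ensemble, var_single), each averaged over images.
    """
    var_e, var_s = [], []
    for k, p in enumerate(pairs):
        d_ens, d_one = [], []
        for s in range(n_seeds):
            rng = np.random.default_rng(seed0 + 1000 * s + k)
            chains = sample_ensemble(p.image, model, sched, rng, n_ensemble)
            d_ens.append(dice(binarize(ensemble_average(chains)), p.mask))
            d_one.append(dice(binarize(chains[0]), p.mask))
        var_e.append(np.var(d_ens, ddof=1))
        var_s.append(np.var(d_one, ddof=1))
    return float(np.mean(var_e)), float(np.mean(var_s))


def run_scaled_study(seed: int = 1, *, n_pairs: int = 250,
                     n_eval_full: int = 20, n_eval_ablation: int = 6,
                     with_ablations: bool = True,
                     with_ensemble_property: bool = True) -> dict:
    """Run the full scaled study; returns a flat dict of measured quantities."""
    splits = make_dataset(n_pairs, (0.8, 0.1, 0.1), SynthConfig(),
                          seed=seed + 6)
    train, val, test = splits["train"], splits["val"], splits["test"]
    val6 = val[:6]

    full_model, full_sched, _, full_log = train_variant(
        train, val6, msfm=True, nsa=True, seed=seed + 2)
    d_full, i_full = score_pairs(full_model, full_sched, test[:n_eval_full],
                                 seed0=100 + seed)
    d_mean, d_sd = summarize(d_full)
    i_mean, i_sd = summarize(i_full)

    losses = [r["loss"] for r in full_log]
    out = {
        "dice_mean": d_mean, "dice_sd": d_sd,
        "iou_mean": i_mean, "iou_sd": i_sd,
        "full_steps": full_log[-1]["step"],
        "loss_first100_mean": float(np.mean(losses[:100])),
        "loss_last100_mean": float(np.mean(losses[-100:])),
        "n_eval": n_eval_full,
        "per_image_dice": d_full,
        "_full": (full_model, full_sched),
        "_test": test,
    }

    if with_ablations:
        # direction check under the study's ensemble-of-3 protocol on a
        # 6-image subset (identical data, training and evaluation seeds for
        # every configuration)
        sub = test[:n_eval_ablation]
        for name, um, un in (("base", False, False), ("msfm", True, False),
                             ("nsa", False, True)):
            m, s, _, lg = train_variant(train, val6, msfm=um, nsa=un,
                                        seed=seed + 2)
            d, _ = score_pairs(m, s, sub, seed0=100 + seed)
            out[f"dice_{name}"] = float(np.mean(d))
            out[f"{name}_steps"] = lg[-1]["step"]
        # same per-image chain seeds, so the full model's subset scores are
        # the first entries of its 20-image evaluation
        out["dice_full_sub"] = float(np.mean(d_full[:n_eval_ablation]))

    if with_ensemble_property:
        var_e, var_s = ensemble_variance_ratio(full_model, full_sched,
                                               test[:2], seed0=500 + seed)
        out["ensemble_dice_variance"] = var_e
        out["single_dice_variance"] = var_s

    return out
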