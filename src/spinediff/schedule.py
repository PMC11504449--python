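"""Diffusion noise schedule: per-step retention coefficients and derived terms.

The forward corruption at step ``t`` keeps a fraction ``alpha_t = 1 - beta_t``
of the signal; ``alpha_bar_t`` is the running product controlling the total
corruption after ``t`` steps.  The posterior variance
``sigma_t^2 = (1 - alpha_bar_{t-1}) * (1 - alpha_t) / (1 - alpha_bar_t)``
(with ``alpha_bar_0 := 1``) is the variance of the reverse-step noise.

Steps are indexed 1..T throughout, matching the chain x_1..x_T.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["NoiseSchedule", "make_schedule", "schedule_from_betas",
           "posterior_variance"]


@dataclass(frozen=True)
class NoiseSchedule:
    """Linear-beta noise schedule over ``T`` diffusion steps.

    Attributes
    ----------
    T : int
        Number of diffusion steps.
    beta : ndarray, shape (T,)
        Per-step noise rates, linearly spaced in (0, 1).
    alpha : ndarray, shape (T,)
        Retention coefficients ``1 - beta``.
    alpha_bar : ndarray, shape (T,)
        Cumulative products of ``alpha``.
    sigma2 : ndarray, shape (T,)
        Posterior variances; ``sigma2[0]`` (step t=1) is exactly 0.
    """

    T: int
    beta: np.ndarray
    alpha: np.ndarray = field(repr=False, default=None)
    alpha_bar: np.ndarray = field(repr=False, default=None)
    sigma2: np.ndarray = field(repr=False, default=None)

    def alpha_t(self, t: int) -> float:
        self._check(t)
        return float(self.alpha[t - 1])

    def alpha_bar_t(self, t: int) -> float:
        """``alpha_bar`` at step t, with the convention alpha_bar_0 = 1."""
        if t == 0:
            return 1.0
        self._check(t)
        return float(self.alpha_bar[t - 1])

    def _check(self, t: int) -> None:
        if not 1 <= t <= self.T:
            raise ValueError(f"step index t={t} outside [1, {self.T}]")


def make_schedule(T: int, beta_start: float = 1e-4,
                  beta_end: float = 0.02) -> NoiseSchedule:
    """Build a linear-beta schedule with ``T`` steps.

    Raises ``ValueError`` for non-positive ``T`` or beta endpoints outside
    (0, 1) or ``beta_start > beta_end``.
    """
    if not (isinstance(T, (int, np.integer)) and T >= 1):
        raise ValueError(f"T must be a positive integer, got {T!r}")
    if not (0.0 < beta_start <= beta_end < 1.0):
        raise ValueError(
            f"need 0 < beta_start <= beta_end < 1, got ({beta_start}, {beta_end})")
    beta = np.linspace(beta_start, beta_end, T, dtype=np.float64)
    return schedule_from_betas(beta)


def schedule_from_betas(betas) -> NoiseSchedule:
    """Build a schedule from an explicit per-step beta sequence."""
    beta = np.asarray(betas, dtype=np.float64)
    if beta.ndim != 1 or beta.size < 1:
        raise ValueError("betas must be a non-empty 1-D sequence")
    if np.any(beta <= 0.0) or np.any(beta >= 1.0):
        raise ValueError("all betas must lie in (0, 1)")
    alpha = 1.0 - beta
    alpha_bar = np.cumprod(alpha)
    prev = np.concatenate([[1.0], alpha_bar[:-1]])
    sigma2 = (1.0 - prev) * (1.0 - alpha) / (1.0 - alpha_bar)
    sched = NoiseSchedule(T=int(beta.size), beta=beta)
    object.__setattr__(sched, "alpha", alpha)
    object.__setattr__(sched, "alpha_bar", alpha_bar)
    object.__setattr__(sched, "sigma2", sigma2)
    return sched


def posterior_variance(s: NoiseSchedule, t: int) -> float:
    """sigma_t^2 of the forward posterior q(x_{t-1} | x_t, x_0); 0 at t=1."""
    s._check(t)
    return float(s.sigma2[t - 1])
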