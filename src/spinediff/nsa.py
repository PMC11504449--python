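"""Noise semantic adapter (NSA).

A dual-granularity encoder block for the diffusion U-Net: a fine-grain branch
(3x3 or 5x5 convolution) and a wide-context spatial branch (depthwise 7x7
convolution with dilation 3 followed by a pointwise channel-halving
projection) each map the C-channel input to C/2 channels.  Their elementwise
product is reduced to channelwise average and maximum maps, concatenated,
projected back to C channels and squashed by a sigmoid into a gating field T.
The gated combination

    V_bar = F * T_F + S * T_S          (T split into two C/2 halves)
    V     = [V_bar, V_bar] * X         (residual multiplication with the input)

keeps the output the same shape as the input, vanishes wherever the input
vanishes, and lets the block emphasise vertebra-like detail while suppressing
background response.  All products are elementwise (Hadamard).
"""

from __future__ import annotations

import numpy as np

from .nn import Conv2d, Module, Tensor, concat

__all__ = ["NSA", "nsa_combine", "attention_gate_core", "select_fine_kernel"]


def select_fine_kernel(foreground_fraction: float, threshold: float = 0.2) -> int:
    """Heuristic fine-branch kernel choice from the prior mask.

    Inside-vertebra detail (high foreground share) favours the 3x3 kernel;
    background-dominated fields (share below ``threshold``) favour the
    coarser 5x5.  This is an interpretation of the qualitative
    kernel-selection rule; the chosen value feeds ``NSA(kernel_choice=...)``.
    """
    if not 0.0 <= foreground_fraction <= 1.0:
        raise ValueError("foreground fraction must lie in [0, 1]")
    return 5 if foreground_fraction < threshold else 3


def nsa_combine(f, s, t_f, t_s, x):
    """Gated combination V = [F*T_F + S*T_S, tiled to C] * X (elementwise).

    ``f``, ``s``, ``t_f``, ``t_s`` have C/2 channels; ``x`` has C.  The C/2
    combination is tiled along the channel axis to match ``x``.
    """
    vbar = f * t_f + s * t_s
    if isinstance(vbar, Tensor) or isinstance(x, Tensor):
        vbar = vbar if isinstance(vbar, Tensor) else Tensor(vbar)
        tiled = concat([vbar, vbar], axis=-3)
        return tiled * x
    return np.concatenate([vbar, vbar], axis=-3) * x


def attention_gate_core(p_avg, p_max, proj, bias=None):
    """Projection + sigmoid on the concatenated average/maximum maps.

    Exposed separately so the closed-form gate tests (identity projection,
    zero bias => T = 0.5 at zero input) can drive it directly.
    """
    pre = p_avg * proj[0] + p_max * proj[1]
    if bias is not None:
        pre = pre + bias
    if isinstance(pre, Tensor):
        return pre.sigmoid()
    return 1.0 / (1.0 + np.exp(-np.asarray(pre, dtype=np.float64)))


class NSA(Module):
    """Dual-granularity convolutional adapter with sigmoid attention gating.

    Parameters
    ----------
    channels : int
        Input channel count C; must be even (both branches emit C/2).
    rng : numpy Generator
        Weight initialisation source.
    kernel_choice : {3, 5}
        Fine-branch kernel: 3 for intra-vertebra detail, 5 for coarse
        background context.
    """

    def __init__(self, channels: int, rng: np.random.Generator, kernel_choice: int = 3):
        super().__init__()
        if channels % 2:
            raise ValueError(f"NSA needs an even channel count, got {channels}")
        if kernel_choice not in (3, 5):
            raise ValueError(f"fine-branch kernel must be 3 or 5, got {kernel_choice}")
        self.channels = channels
        self.kernel_choice = kernel_choice
        half = channels // 2
        # branch convolutions are bias-free so zero input gives zero F and S
        self.fine = Conv2d(channels, half, kernel_choice, rng, bias=False)
        # depthwise 7x7 dilation 3: effective extent 1 + 6*3 = 19, padding 9
        self.spatial_dw = Conv2d(channels, channels, 7, rng, padding=9,
                                 dilation=3, groups=channels, bias=False)
        self.spatial_proj = Conv2d(channels, half, 1, rng, bias=False)
        self.gate = Conv2d(2, channels, 7, rng)

    # ----------------------------------------------------------- branch ops
    def fine_branch(self, x: Tensor) -> Tensor:
        return self.fine(x)

    def spatial_branch(self, x: Tensor) -> Tensor:
        return self.spatial_proj(self.spatial_dw(x))

    def attention_gate(self, f: Tensor, s: Tensor) -> Tensor:
        """Sigmoid gating field T in (0,1), C channels."""
        if f.shape != s.shape:
            raise ValueError(f"branch shape mismatch: {f.shape} vs {s.shape}")
        p = f * s
        p_avg = p.mean(axis=-3, keepdims=True)
        p_max = p.max(axis=-3, keepdims=True)
        return self.gate(concat([p_avg, p_max], axis=-3)).sigmoid()

    def forward(self, x: Tensor) -> Tensor:
        f = self.fine_branch(x)
        s = self.spatial_branch(x)
        t = self.attention_gate(f, s)
        half = self.channels // 2
        t_f = t[:, :half]
        t_s = t[:, half:]
        return nsa_combine(f, s, t_f, t_s, x)
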