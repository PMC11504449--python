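"""Multi-scale fusion module (MSFM).

Three parallel same-padded convolution branches with 3x3, 5x5 and 7x7 kernels
look at the raw image at different receptive fields.  Their element-sum is
globally average-pooled to a channel descriptor, compressed through a fully
connected ELU layer (with running-statistics normalisation), and three learned
logit matrices turn the compressed code into a per-channel softmax over the
branches:

    a_n = exp(A_n z) / (exp(A_n z) + exp(B_n z) + exp(C_n z)),   a_n+b_n+c_n = 1.

The output is the per-channel convex combination a*A~ + b*B~ + c*C~, so each
channel adaptively selects its receptive field.  The refined map feeds the
conditional U-Net and is also concatenated with the noisy mask at the
diffusion U-Net input.
"""

from __future__ import annotations

import numpy as np

from .nn import Conv2d, Linear, Module, RunningNorm, Tensor, concat

__all__ = ["MSFM", "fuse_sum", "global_pool", "compress", "soft_attention",
           "weighted_merge"]


def _is_t(*xs) -> bool:
    return any(isinstance(x, Tensor) for x in xs)


def fuse_sum(a, b, c):
    """Element-sum of the three branch outputs."""
    for pair in ((a, b), (a, c)):
        sa = (pair[0].data if isinstance(pair[0], Tensor) else np.asarray(pair[0])).shape
        sb = (pair[1].data if isinstance(pair[1], Tensor) else np.asarray(pair[1])).shape
        if sa != sb:
            raise ValueError(f"branch shape mismatch: {sa} vs {sb}")
    return a + b + c


def global_pool(x):
    """Global average pooling over the spatial dims (last two axes)."""
    shape = (x.data if isinstance(x, Tensor) else np.asarray(x)).shape
    if len(shape) < 2 or shape[-1] * shape[-2] == 0:
        raise ValueError("global_pool needs a non-empty H x W grid")
    return x.mean(axis=(-2, -1))


def compress(s, W):
    """Pure compression step z = ELU(W s) (normalisation handled by the module).

    ``s`` is a length-C channel descriptor (or a batch of them), ``W`` a d x C
    matrix.
    """
    if _is_t(s, W):
        s = s if isinstance(s, Tensor) else Tensor(s)
        W = W if isinstance(W, Tensor) else Tensor(W)
        return (s @ W.transpose(1, 0)).elu()
    z = np.asarray(s) @ np.asarray(W).T
    return np.where(z > 0, z, np.expm1(z))


def soft_attention(z, A, B, C):
    """Per-channel three-way softmax over the branch logits A z, B z, C z.

    ``z``: length-d (or batch x d); ``A, B, C``: C x d logit matrices.  The
    result is invariant to adding a constant to all three logits (guarded by
    max-subtraction).  Returns arrays/tensors of shape (..., C) summing to 1
    across the three outputs.
    """
    tensor_mode = _is_t(z, A, B, C)
    if tensor_mode:
        z = z if isinstance(z, Tensor) else Tensor(z)
        mats = [m if isinstance(m, Tensor) else Tensor(m) for m in (A, B, C)]
        logits = [z @ m.transpose(1, 0) for m in mats]
        m = np.maximum(np.maximum(logits[0].data, logits[1].data), logits[2].data)
        exps = [(l - m).exp() for l in logits]
        denom = exps[0] + exps[1] + exps[2]
        return tuple(e / denom for e in exps)
    z = np.asarray(z, dtype=np.float64)
    logits = [z @ np.asarray(m, dtype=np.float64).T for m in (A, B, C)]
    m = np.maximum(np.maximum(logits[0], logits[1]), logits[2])
    exps = [np.exp(l - m) for l in logits]
    denom = exps[0] + exps[1] + exps[2]
    return tuple(e / denom for e in exps)


def weighted_merge(a_map, b_map, c_map, weights):
    """Per-channel convex combination of the three branch grids.

    ``weights`` is a triple (a, b, c) of per-channel vectors broadcastable
    against the branch grids' channel axis (axis -3 for NCHW grids).
    """
    wa, wb, wc = weights

    def expand(w, ref):
        shape = (ref.data if isinstance(ref, Tensor) else np.asarray(ref)).shape
        w_arr = w.data if isinstance(w, Tensor) else np.asarray(w)
        if w_arr.ndim >= len(shape):
            return w
        new_shape = w_arr.shape + (1,) * (len(shape) - w_arr.ndim)
        return w.reshape(new_shape) if isinstance(w, Tensor) else w_arr.reshape(new_shape)

    return (expand(wa, a_map) * a_map + expand(wb, b_map) * b_map
            + expand(wc, c_map) * c_map)


class MSFM(Module):
    """Selective-kernel fusion over 3/5/7 receptive fields.

    Parameters
    ----------
    channels : int
        Channel count C of the input grid (preserved by all branches).
    d : int, optional
        Compression width; default ``max(C // 4, 4)``.
    rng : numpy Generator
        Source for weight initialisation.
    """

    def __init__(self, channels: int, rng: np.random.Generator, d: int | None = None):
        super().__init__()
        self.channels = channels
        self.d = d if d is not None else max(channels // 4, 4)
        # branch kernels are bias-free: the shared bias would cancel in the
        # softmax selection and break zero-propagation.  Near-identity init
        # (centre delta + damped random taps) so the module starts as a mild
        # perturbation of its input and the downstream encoder trains from a
        # faithful image rather than a randomly filtered one.
        self.conv3 = Conv2d(channels, channels, 3, rng, bias=False)
        self.conv5 = Conv2d(channels, channels, 5, rng, bias=False)
        self.conv7 = Conv2d(channels, channels, 7, rng, bias=False)
        for conv in (self.conv3, self.conv5, self.conv7):
            k = conv.weight.data.shape[-1]
            conv.weight.data *= 0.25
            for c in range(channels):
                conv.weight.data[c, c, k // 2, k // 2] += 1.0
        self.fc = Linear(channels, self.d, rng)
        self.norm = RunningNorm(self.d)
        scale = 1.0 / np.sqrt(self.d)
        self.logit_a = Tensor(rng.normal(0, scale, (channels, self.d)).astype(np.float32),
                              requires_grad=True)
        self.logit_b = Tensor(rng.normal(0, scale, (channels, self.d)).astype(np.float32),
                              requires_grad=True)
        self.logit_c = Tensor(rng.normal(0, scale, (channels, self.d)).astype(np.float32),
                              requires_grad=True)

    def branch_transform(self, x: Tensor) -> tuple[Tensor, Tensor, Tensor]:
        return self.conv3(x), self.conv5(x), self.conv7(x)

    def compress(self, s: Tensor) -> Tensor:
        return self.norm(self.fc(s).elu())

    def forward(self, x: Tensor) -> Tensor:
        a_map, b_map, c_map = self.branch_transform(x)
        fused = fuse_sum(a_map, b_map, c_map)
        s = global_pool(fused)                       # (N, C)
        z = self.compress(s)                         # (N, d)
        wa, wb, wc = soft_attention(z, self.logit_a, self.logit_b, self.logit_c)
        return weighted_merge(a_map, b_map, c_map, (wa, wb, wc))
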