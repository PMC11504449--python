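"""Network assembly: conditional U-Net (prior generator) and diffusion U-Net.

The conditional U-Net maps the (MSFM-refined) image to a prior probability
mask f(b) in [0,1].  The diffusion U-Net receives the noisy mask x_t
concatenated channelwise with the refined image features and the prior, plus
a sinusoidal timestep embedding injected into every residual block, and
predicts the noise component of x_t.  NSA blocks sit at each encoder level of
the diffusion U-Net; both NSA and MSFM can be switched off, which reduces the
system to a plain conditional DDPM segmenter.
"""

from __future__ import annotations

import numpy as np

from .msfm import MSFM
from .nn import (Adam, Conv2d, GroupNorm, Linear, Module, Tensor, avg_pool2d,
                 concat, sinusoidal_embedding, upsample_nearest2x)
from .nsa import NSA

__all__ = ["ResBlock", "UNet", "DiffusionSegmenter", "PRESETS", "build_model"]

PRESETS = {
    "tiny": {"widths": (8, 16), "emb_dim": 32},
    "full": {"widths": (64, 128, 256, 512), "emb_dim": 128},
}


class ResBlock(Module):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator,
                 emb_dim: int | None = None):
        super().__init__()
        self.n1 = GroupNorm(cin)
        self.c1 = Conv2d(cin, cout, 3, rng)
        self.n2 = GroupNorm(cout)
        self.c2 = Conv2d(cout, cout, 3, rng)
        # zero-init the closing conv so every block starts as its skip path;
        # residual branches then grow from zero, which removes most of the
        # initialisation-to-initialisation spread in convergence speed
        self.c2.weight.data[...] = 0.0
        self.c2.bias.data[...] = 0.0
        self.skip = Conv2d(cin, cout, 1, rng) if cin != cout else None
        self.emb_proj = Linear(emb_dim, cout, rng) if emb_dim else None

    def forward(self, x: Tensor, emb: Tensor | None = None) -> Tensor:
        h = self.c1(self.n1(x).silu())
        h = self.c2(self.n2(h).silu())
        if self.emb_proj is not None and emb is not None:
            # per-channel bias at the block output: stays effective even
            # while the zero-initialised closing conv is still growing
            b = self.emb_proj(emb)
            h = h + b.reshape(1, b.shape[-1], 1, 1)
        return h + (self.skip(x) if self.skip is not None else x)


class UNet(Module):
    """Encoder-decoder with skip connections; spatial size preserved by
    pad-and-crop so inputs need not be divisible by 2^depth.

    ``with_nsa=True`` inserts an NSA block after each encoder level's residual
    block; ``nsa_enabled`` toggles them at run time (identity when off).
    """

    def __init__(self, cin: int, cout: int, rng: np.random.Generator,
                 widths=(8, 16), emb_dim: int | None = None,
                 with_nsa: bool = False, nsa_kernel: int = 3,
                 final: str | None = None):
        super().__init__()
        self.widths = tuple(widths)
        self.depth = len(widths) - 1
        self.emb_dim = emb_dim
        self.final = final
        self.nsa_enabled = with_nsa
        if emb_dim:
            self.time_fc1 = Linear(emb_dim, emb_dim * 2, rng)
            self.time_fc2 = Linear(emb_dim * 2, emb_dim, rng)
        self.stem = Conv2d(cin, widths[0], 3, rng)
        enc, nsas = [], []
        for i, w in enumerate(widths):
            prev = widths[0] if i == 0 else widths[i - 1]
            enc.append(ResBlock(prev, w, rng, emb_dim))
            if with_nsa:
                nsas.append(NSA(w, rng, kernel_choice=nsa_kernel))
        self.enc = enc
        self.nsas = nsas if with_nsa else []
        self.mid = ResBlock(widths[-1], widths[-1], rng, emb_dim)
        dec = []
        for i in range(self.depth - 1, -1, -1):
            dec.append(ResBlock(widths[i + 1] + widths[i], widths[i], rng, emb_dim))
        self.dec = dec
        self.out_norm = GroupNorm(widths[0])
        self.head = Conv2d(widths[0], cout, 3, rng)

    def _time_embedding(self, t: int) -> Tensor:
        emb = Tensor(sinusoidal_embedding(t, self.emb_dim)[None])
        return self.time_fc2(self.time_fc1(emb).silu())

    def forward(self, x: Tensor, t: int | None = None) -> Tensor:
        n, c, h, w = x.shape
        mult = 2 ** self.depth
        ph, pw = (-h) % mult, (-w) % mult
        if ph or pw:
            pad = np.zeros((n, c, h + ph, w + pw), dtype=np.float32)
            xt = Tensor(pad, parents=(x,))
            xt.data[:, :, :h, :w] = x.data

            def bwd(g, src=x):
                src._accum(g[:, :, :h, :w])
            xt._backward = bwd
            x = xt
        emb = self._time_embedding(t) if (self.emb_dim and t is not None) else None
        hcur = self.stem(x)
        skips = []
        for i, block in enumerate(self.enc):
            if i > 0:
                hcur = avg_pool2d(hcur, 2)
            hcur = block(hcur, emb)
            if self.nsas and self.nsa_enabled:
                hcur = self.nsas[i](hcur)
            skips.append(hcur)
        hcur = self.mid(hcur, emb)
        for i, block in enumerate(self.dec):
            hcur = upsample_nearest2x(hcur)
            hcur = block(concat([hcur, skips[self.depth - 1 - i]], axis=1), emb)
        y = self.head(self.out_norm(hcur).silu())
        if ph or pw:
            y = y[:, :, :h, :w]
        if self.final == "sigmoid":
            y = y.sigmoid()
        return y


class DiffusionSegmenter(Module):
    """Full system: MSFM front end, conditional U-Net, NSA-equipped denoiser.

    ``use_msfm`` / ``use_nsa`` are ablation switches; with both off the model
    is a plain conditional DDPM (raw image conditioning, vanilla encoder).
    """

    def __init__(self, rng: np.random.Generator, preset: str = "tiny",
                 use_msfm: bool = True, use_nsa: bool = True,
                 nsa_kernel: int = 3):
        super().__init__()
        arch = PRESETS[preset]
        self.preset = preset
        self.use_msfm = use_msfm
        self.msfm = MSFM(1, rng)
        self.cond_unet = UNet(1, 1, rng, widths=arch["widths"], final="sigmoid")
        self.diff_unet = UNet(3, 1, rng, widths=arch["widths"],
                              emb_dim=arch["emb_dim"], with_nsa=True,
                              nsa_kernel=nsa_kernel)
        self.diff_unet.nsa_enabled = use_nsa

    @property
    def use_nsa(self) -> bool:
        return self.diff_unet.nsa_enabled

    @use_nsa.setter
    def use_nsa(self, value: bool) -> None:
        self.diff_unet.nsa_enabled = bool(value)

    # ------------------------------------------------------------- interface
    def _as_nchw(self, grid) -> Tensor:
        g = grid if isinstance(grid, Tensor) else Tensor(np.asarray(grid, dtype=np.float32))
        if g.ndim == 2:
            g = g.reshape(1, 1, *g.shape)
        return g

    def image_features(self, image) -> Tensor:
        """MSFM-refined image features (the raw image when MSFM is off)."""
        x = self._as_nchw(image)
        return self.msfm(x) if self.use_msfm else x

    def conditional_forward(self, image) -> Tensor:
        """Prior mask f(b) in [0,1], same H x W as the image."""
        return self.cond_unet(self.image_features(image))

    def condition(self, image) -> tuple[Tensor, Tensor]:
        """(refined image features, prior mask) for one image."""
        feats = self.image_features(image)
        return feats, self.cond_unet(feats)

    def denoise(self, xt, t: int, image_features: Tensor, prior: Tensor) -> Tensor:
        """Noise prediction eps_hat(x_t, t | features, prior), shape H x W."""
        x = self._as_nchw(xt)
        h, w = x.shape[-2:]
        inp = concat([x, image_features, prior], axis=1)
        return self.diff_unet(inp, t).reshape(h, w)


def build_model(seed: int, preset: str = "tiny", use_msfm: bool = True,
                use_nsa: bool = True, nsa_kernel: int = 3) -> DiffusionSegmenter:
    rng = np.random.default_rng(seed)
    return DiffusionSegmenter(rng, preset=preset, use_msfm=use_msfm,
                              use_nsa=use_nsa, nsa_kernel=nsa_kernel)
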