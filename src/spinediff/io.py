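"""Dataset and checkpoint I/O.

Images and masks are single-channel 8-bit PNG (masks use {0, 255}, no
palette) so pairs round-trip bit-exactly once quantised; a manifest CSV
records id, split, per-item seed and generator mode.  Checkpoints are NumPy
``.npz`` archives of the named parameters plus a JSON sidecar with the
schedule, config snapshot and seeds.  An optional NIfTI reader extracts
normalised sagittal slices from real volumes.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np
from PIL import Image

from .config import RunConfig
from .schedule import NoiseSchedule, make_schedule
from .synthetic import SamplePair

__all__ = ["save_image", "load_image", "save_mask", "load_mask",
           "write_dataset", "read_dataset", "save_checkpoint",
           "load_checkpoint", "read_nifti_slices"]


# ------------------------------------------------------------------ PNG pairs
def save_image(path, image: np.ndarray) -> None:
    """Write a [0,1] float image as 8-bit grayscale PNG."""
    arr = np.clip(np.asarray(image), 0.0, 1.0)
    Image.fromarray(np.round(arr * 255.0).astype(np.uint8), mode="L").save(path)


def load_image(path) -> np.ndarray:
    """Read an 8-bit grayscale PNG back to [0,1] float32."""
    arr = np.asarray(Image.open(path).convert("L"), dtype=np.float32)
    return arr / 255.0


def save_mask(path, mask: np.ndarray) -> None:
    arr = (np.asarray(mask) > 0).astype(np.uint8) * 255
    Image.fromarray(arr, mode="L").save(path)


def load_mask(path) -> np.ndarray:
    arr = np.asarray(Image.open(path).convert("L"))
    return (arr > 127).astype(np.uint8)


def write_dataset(root, splits: dict[str, list[SamplePair]]) -> Path:
    """Write image/mask PNG pairs plus ``manifest.csv``; returns the root."""
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    manifest = root / "manifest.csv"
    with manifest.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "split", "seed", "mode"])
        for split, pairs in splits.items():
            d = root / split
            d.mkdir(exist_ok=True)
            for p in pairs:
                save_image(d / f"{p.id}_img.png", p.image)
                save_mask(d / f"{p.id}_mask.png", p.mask)
                w.writerow([p.id, split, p.seed, p.mode])
    return root


def read_dataset(root) -> dict[str, list[SamplePair]]:
    root = Path(root)
    splits: dict[str, list[SamplePair]] = {}
    with (root / "manifest.csv").open() as fh:
        for row in csv.DictReader(fh):
            d = root / row["split"]
            pair = SamplePair(
                id=row["id"],
                image=load_image(d / f"{row['id']}_img.png"),
                mask=load_mask(d / f"{row['id']}_mask.png"),
                seed=int(row["seed"]), mode=row["mode"], split=row["split"])
            splits.setdefault(row["split"], []).append(pair)
    return splits


# ----------------------------------------------------------------- checkpoint
def save_checkpoint(path, model, sched: NoiseSchedule, cfg: RunConfig,
                    extra: dict | None = None) -> None:
    path = Path(path)
    state = model.state_dict()
    np.savez(path, **state)
    meta = {
        "T": sched.T,
        "beta_start": float(sched.beta[0]),
        "beta_end": float(sched.beta[-1]),
        "config": cfg.to_dict(),
        "preset": model.preset,
        "use_msfm": model.use_msfm,
        "use_nsa": model.use_nsa,
    }
    if extra:
        meta.update(extra)
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_checkpoint(path):
    """Returns (model, schedule, config, meta)."""
    from .networks import build_model  # deferred: avoids import cycle

    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    cfg = RunConfig.from_dict(meta["config"])
    sched = make_schedule(meta["T"], meta["beta_start"], meta["beta_end"])
    model = build_model(seed=cfg.seed, preset=meta["preset"],
                        use_msfm=meta["use_msfm"], use_nsa=meta["use_nsa"],
                        nsa_kernel=cfg.nsa_kernel)
    with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as z:
        model.load_state_dict({k: z[k] for k in z.files})
    return model, sched, cfg, meta


# --------------------------------------------------------------- NIfTI (read)
def read_nifti_slices(path, axis: int = 0, normalize: bool = True):
    """Extract 2-D sagittal slices from a NIfTI volume (read-only helper).

    Yields float32 H x W arrays scaled to [0,1] per slice when ``normalize``.
    """
    import nibabel as nib

    vol = np.asanyarray(nib.load(str(path)).dataobj).astype(np.float32)
    for i in range(vol.shape[axis]):
        sl = np.take(vol, i, axis=axis)
        if normalize:
            lo, hi = float(sl.min()), float(sl.max())
            sl = (sl - lo) / (hi - lo) if hi > lo else np.zeros_like(sl)
        yield sl
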