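"""Synthetic fundus generator: seedable branching vessel trees on a circular
field of view with exact paired ground-truth masks.

The generator emulates the geometry and photometry that matter for vessel
segmentation — a dark-rimmed circular FOV, a tortuous width-tapering vessel
tree darker than the retinal background, smooth background texture, and
sensor noise — without attempting photorealism (no optic disc, fovea, or
lesions).  It exists so every pipeline stage is testable without the real
DRIVE / CHASE-DB1 / STARE images.

Vessels are grown by a stack-based recursive walk: each walker advances a
fixed step, perturbs its heading by a Gaussian (tortuosity), occasionally
spawns a branch, and both daughters taper by ``width_decay``; width also
tapers gradually along the vessel run, so every vessel has finite length
(as real vessels thin toward the periphery).  Strokes are rendered
anti-aliased on a 2x supersampled grid and re-binarized at 0.5 for the
mask.  Defaults are tuned to the vessel-density regime of real fundus
photographs (roughly a tenth of the field of view).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .config import SyntheticParams
from .data import SampleRecord, save_manifest, write_pair

_SUPERSAMPLE = 2
_MAX_WALKERS = 4000
_STEP_TAPER = 0.985  # per-step width decay along a vessel run
_MIN_WIDTH = 0.7     # pixels; a walker dies when thinner than this


def _grow_tree(params: SyntheticParams, rng: np.random.Generator) -> np.ndarray:
    """Render the vessel tree; returns a binary (H, W) uint8 mask."""
    s = _SUPERSAMPLE
    h, w = params.height * s, params.width * s
    canvas = np.zeros((h, w), dtype=np.float32)
    cy, cx = h / 2, w / 2
    fov_r = (min(params.height, params.width) / 2 - params.fov_margin) * s

    # roots leave a disc-like entry zone offset from center, heading outward
    disc_angle = rng.uniform(0, 2 * np.pi)
    disc = np.array([cy + 0.55 * fov_r * np.sin(disc_angle),
                     cx + 0.55 * fov_r * np.cos(disc_angle)])
    walkers = []
    for _ in range(params.n_roots):
        ang = rng.uniform(0, 2 * np.pi)
        walkers.append({
            "pos": disc + rng.normal(0, 2 * s, 2),
            "heading": ang,
            "width": params.width_root * rng.uniform(0.7, 1.0),
        })

    step = 1.5 * s
    yy, xx = np.ogrid[:h, :w]
    spawned = len(walkers)
    while walkers:
        wk = walkers.pop()
        pos, heading, width = wk["pos"], wk["heading"], wk["width"]
        while width >= _MIN_WIDTH:
            heading += rng.normal(0, params.tortuosity)
            pos = pos + step * np.array([np.sin(heading), np.cos(heading)])
            width *= _STEP_TAPER
            if (pos[0] - cy) ** 2 + (pos[1] - cx) ** 2 > fov_r ** 2:
                break
            r = max(width * s / 2, 0.5 * s)
            y0, y1 = int(max(pos[0] - r - 1, 0)), int(min(pos[0] + r + 2, h))
            x0, x1 = int(max(pos[1] - r - 1, 0)), int(min(pos[1] + r + 2, w))
            patch = ((yy[y0:y1] - pos[0]) ** 2
                     + (xx[:, x0:x1] - pos[1]) ** 2) <= r * r
            canvas[y0:y1, x0:x1][patch] = 1.0
            if (rng.random() < params.branch_prob
                    and spawned < _MAX_WALKERS and width > 1.2):
                width *= params.width_decay
                split = rng.uniform(0.3, 0.9)
                walkers.append({"pos": pos.copy(), "heading": heading + split,
                                "width": width})
                heading -= split * rng.uniform(0.3, 1.0)
                spawned += 1

    # anti-alias by box-averaging the supersampled canvas, re-binarize at 0.5
    hh, ww = params.height, params.width
    down = canvas.reshape(hh, s, ww, s).mean(axis=(1, 3))
    return (down >= 0.5).astype(np.uint8)


def fov_mask(params: SyntheticParams) -> np.ndarray:
    """Binary mask of the circular field of view."""
    h, w = params.height, params.width
    yy, xx = np.ogrid[:h, :w]
    r = min(h, w) / 2 - params.fov_margin
    return (((yy - h / 2) ** 2 + (xx - w / 2) ** 2) <= r * r).astype(np.uint8)


def generate_sample(params: SyntheticParams) -> tuple[np.ndarray, np.ndarray]:
    """One synthetic fundus image (H, W, 3) float in [0, 1] and its exact
    binary vessel mask (H, W) uint8. Deterministic given ``params.seed``."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    h, w = params.height, params.width
    fov = fov_mask(params).astype(bool)
    mask = _grow_tree(params, rng)
    mask[~fov] = 0

    # smooth textured background, vessels darker by vessel_contrast
    texture = gaussian_filter(rng.standard_normal((h, w)), sigma=h / 10)
    texture = 0.08 * texture / max(np.abs(texture).max(), 1e-9)
    intensity = 0.62 + texture
    soft_vessels = gaussian_filter(mask.astype(np.float32), sigma=0.6)
    intensity = intensity - params.vessel_contrast * soft_vessels
    intensity += rng.normal(0, params.background_noise_sd, (h, w))
    intensity = np.clip(intensity, 0, 1)
    intensity[~fov] = np.clip(
        rng.normal(0.02, 0.01, (~fov).sum()), 0, 1)

    # fundus-like reddish color balance
    image = np.stack([intensity, intensity * 0.55, intensity * 0.30], axis=-1)
    return image.astype(np.float32), mask


def generate_dataset(params: SyntheticParams, n_images: int,
                     out_dir: str | Path) -> list[SampleRecord]:
    """Write ``n_images`` PNG pairs plus a manifest CSV; per-image seeds are
    ``params.seed + index``. Returns the loaded records."""
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as e:
        raise IOError(f"cannot create output directory {out_dir}: {e}") from e
    records = []
    for i in range(n_images):
        p = SyntheticParams(**{**params.__dict__, "seed": params.seed + i})
        image, mask = generate_sample(p)
        rec = SampleRecord(id=f"synth{i:03d}", image=image, mask=mask)
        records.append(write_pair(rec, out_dir))
    save_manifest(records, out_dir / "manifest.csv")
    return records
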