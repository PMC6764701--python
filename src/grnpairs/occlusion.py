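"""Occlusion sensitivity mapping.

Slides a constant-fill occluding patch across the concatenated input pair
and records, at every position, the decrease of the link probability
relative to the unoccluded baseline.  Regions whose occlusion depresses the
output are where the classifier looks; zero means no impact, and negative
values (occlusion *raising* the probability) are kept in the stored map but
clipped at zero for rendering.

The occluder covers the full concatenated (2H x W) input, so both the TF
half (top) and the target half (bottom) are probed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .model import concat_pair, normalize, score_arrays

__all__ = ["OcclusionConfig", "OcclusionMap", "occlusion_map", "render_overlay"]


@dataclass(frozen=True)
class OcclusionConfig:
    kernel_height: int = 32
    kernel_width: int = 32
    stride: int = 16
    fill_value: float = 232.0  # corpus background intensity, not black
    upsample_to_input: bool = True

    def validate(self, input_h: int, input_w: int) -> None:
        if self.kernel_height < 1 or self.kernel_width < 1 or self.stride < 1:
            raise ValueError("kernel dims and stride must be >= 1")
        if self.kernel_height > input_h or self.kernel_width > input_w:
            raise ValueError(
                f"occlusion kernel {self.kernel_height}x{self.kernel_width} "
                f"exceeds input {input_h}x{input_w}")


@dataclass
class OcclusionMap:
    values: np.ndarray       # (grid_h, grid_w) baseline - occluded score
    baseline_score: float
    config: OcclusionConfig
    input_shape: tuple[int, int]

    def grid_position(self, gy: int, gx: int) -> tuple[int, int]:
        """Top-left input pixel covered by grid cell (gy, gx)."""
        return gy * self.config.stride, gx * self.config.stride

    def argmax_box(self) -> tuple[int, int, int, int]:
        """(row0, col0, row1, col1) input box of the strongest position."""
        gy, gx = np.unravel_index(int(self.values.argmax()), self.values.shape)
        r0, c0 = self.grid_position(gy, gx)
        return (r0, c0, r0 + self.config.kernel_height,
                c0 + self.config.kernel_width)

    def save(self, path_prefix) -> None:
        prefix = Path(path_prefix)
        np.save(str(prefix) + ".npy", self.values)
        sidecar = {
            "baseline_score": self.baseline_score,
            "input_shape": list(self.input_shape),
            "config": {
                "kernel_height": self.config.kernel_height,
                "kernel_width": self.config.kernel_width,
                "stride": self.config.stride,
                "fill_value": self.config.fill_value,
            },
        }
        Path(str(prefix) + ".json").write_text(json.dumps(sidecar, indent=1))


def occlusion_map(net, instance, image_sets,
                  cfg: OcclusionConfig | None = None,
                  batch_size: int = 64) -> OcclusionMap:
    """Occlusion map of one image-pair instance (model in eval mode).

    The grid has ``floor((dim - kernel)/stride) + 1`` positions per axis;
    each value is baseline minus occluded probability.
    """
    cfg = cfg or OcclusionConfig()
    g, o, p = instance.tf_image
    tf_img = image_sets[g].image(o, p)
    g2, o2, q = instance.target_image
    tg_img = image_sets[g2].image(o2, q)
    concat = concat_pair(tf_img, tg_img)
    H, W = concat.shape
    cfg.validate(H, W)

    mcfg = net.meta["config"]
    base = float(score_arrays(net, normalize(concat, mcfg)[None])[0])

    gh = (H - cfg.kernel_height) // cfg.stride + 1
    gw = (W - cfg.kernel_width) // cfg.stride + 1
    variants = np.empty((gh * gw,) + normalize(concat, mcfg).shape,
                        dtype=np.float32)
    fill = np.uint8(np.clip(round(cfg.fill_value), 0, 255))
    k = 0
    for gy in range(gh):
        for gx in range(gw):
            occ = concat.copy()
            r0, c0 = gy * cfg.stride, gx * cfg.stride
            occ[r0:r0 + cfg.kernel_height, c0:c0 + cfg.kernel_width] = fill
            variants[k] = normalize(occ, mcfg)
            k += 1
    scores = score_arrays(net, variants, batch_size)
    values = (base - scores).reshape(gh, gw)
    return OcclusionMap(values=values, baseline_score=base, config=cfg,
                        input_shape=(H, W))


def _upsample_nearest(grid: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    H, W = shape
    gy = np.minimum((np.arange(H) * grid.shape[0]) // H, grid.shape[0] - 1)
    gx = np.minimum((np.arange(W) * grid.shape[1]) // W, grid.shape[1] - 1)
    return grid[np.ix_(gy, gx)]


def render_overlay(omap: OcclusionMap, instance, image_sets,
                   out_path=None, alpha: float = 0.45) -> np.ndarray:
    """Alpha-blend the (clipped, normalized) occlusion map over the input.

    Decreases render as a red wash on the grayscale pair; an all-equal map
    renders as a uniform overlay.  Deterministic: identical inputs yield a
    byte-identical PNG.  Returns the RGB array.
    """
    g, o, p = instance.tf_image
    tf_img = image_sets[g].image(o, p)
    g2, o2, q = instance.target_image
    tg_img = image_sets[g2].image(o2, q)
    concat = concat_pair(tf_img, tg_img)
    if concat.shape != omap.input_shape:
        raise ValueError(f"instance shape {concat.shape} does not match the "
                         f"map's input shape {omap.input_shape}")

    vals = np.clip(omap.values, 0.0, None)
    vmax = vals.max()
    if vmax <= 0:
        heat = np.zeros_like(vals)
    else:
        heat = vals / vmax
    if omap.config.upsample_to_input:
        heat = _upsample_nearest(heat, concat.shape)
    rgb = np.repeat(concat[:, :, None], 3, axis=2).astype(np.float64)
    overlay = np.zeros_like(rgb)
    overlay[:, :, 0] = 255.0 * heat
    blended = (1 - alpha * heat[:, :, None]) * rgb + alpha * heat[:, :, None] * overlay
    out = np.clip(np.rint(blended), 0, 255).astype(np.uint8)
    if out_path is not None:
        Image.fromarray(out, mode="RGB").save(out_path, format="PNG")
    return out
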