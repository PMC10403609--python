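"""Rasterize ΔF/F traces into fixed-size grayscale waveform images.

The y-axis is a *global fixed* ΔF/F range shared by every image (no
per-trace autoscaling): the wide spread of dynamic ranges across cells
is part of the signal the composite method is designed to tame, so it
must survive rasterization.  Plots are bare polylines — no axes, ticks
or labels — to avoid classifier-exploitable decorations.

Rasters are deterministic; JPEG (the interchange format) is applied
only at the I/O boundary, so nothing downstream depends on codec noise.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
from PIL import Image
from scipy.ndimage import grey_dilation
from skimage.draw import line as draw_line

from .core import CalciumTrace, ParameterError, UNITS_DFF

__all__ = ["RenderConfig", "WaveformImage", "render_waveform", "save_jpeg", "write_manifest"]


@dataclass(frozen=True)
class RenderConfig:
    """Rasterization settings shared by a dataset of waveform images."""

    canvas_px: tuple[int, int] = (224, 224)  # (height, width)
    y_range_dff: tuple[float, float] = (-0.5, 4.0)
    line_width_px: int = 1
    background: int = 0
    foreground: int = 255
    axes_drawn: bool = False
    jpeg_quality: int = 90
    clip_warn_fraction: float = 0.01

    def validate(self) -> None:
        h, w = self.canvas_px
        if h < 32 or w < 32:
            raise ParameterError("canvas_px: must be at least (32, 32)")
        lo, hi = self.y_range_dff
        if not lo < hi:
            raise ParameterError("y_range_dff: lower bound must be < upper bound")
        if self.line_width_px < 1:
            raise ParameterError("line_width_px: must be >= 1")
        if not (0 <= self.background <= 255 and 0 <= self.foreground <= 255):
            raise ParameterError("background/foreground: must be 8-bit levels")
        if self.background == self.foreground:
            raise ParameterError("background/foreground: must differ")

    def hash(self) -> str:
        return hashlib.sha1(repr(self).encode()).hexdigest()[:12]


@dataclass
class WaveformImage:
    """A rasterized single-trace plot with its dataset labels."""

    pixels: np.ndarray  # uint8, (H, W)
    roi_id: str
    group: str = "unknown"
    substance: str | None = None
    dose: str | None = None
    lot: str | None = None
    config_hash: str = ""
    clip_fraction: float = 0.0
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.dtype != np.uint8:
            raise ParameterError("pixels: expected a 2-D uint8 raster")


def render_waveform(trace: CalciumTrace, cfg: RenderConfig | None = None) -> WaveformImage:
    """Rasterize one ΔF/F trace.

    Time maps linearly onto the full canvas width; ΔF/F maps through the
    global fixed ``y_range_dff`` (values outside are clipped and the
    clipped fraction recorded; > ``clip_warn_fraction`` emits a warning).
    """
    cfg = cfg or RenderConfig()
    cfg.validate()
    if trace.units != UNITS_DFF:
        raise ParameterError("trace: render_waveform expects ΔF/F units")
    H, W = cfg.canvas_px
    lo, hi = cfg.y_range_dff
    v = trace.values
    clip_fraction = float(np.mean((v < lo) | (v > hi)))
    if clip_fraction > cfg.clip_warn_fraction:
        warnings.warn(
            f"{trace.roi_id}: {clip_fraction:.1%} of samples clipped by "
            f"y_range_dff={cfg.y_range_dff}",
            stacklevel=2,
        )
    v = np.clip(v, lo, hi)
    n = v.size
    cols = np.round(np.linspace(0, W - 1, n)).astype(int)
    rows = (H - 1) - np.round((v - lo) / (hi - lo) * (H - 1)).astype(int)

    canvas = np.full((H, W), cfg.background, dtype=np.uint8)
    if cfg.axes_drawn and lo < 0 < hi:
        zero_row = (H - 1) - int(round((0.0 - lo) / (hi - lo) * (H - 1)))
        mid = (int(cfg.background) + int(cfg.foreground)) // 2
        canvas[zero_row, :] = mid
    for i in range(n - 1):
        rr, cc = draw_line(rows[i], cols[i], rows[i + 1], cols[i + 1])
        canvas[rr, cc] = cfg.foreground
    if cfg.line_width_px > 1:
        w = cfg.line_width_px
        if cfg.foreground > cfg.background:
            canvas = grey_dilation(canvas, size=(w, w))
        else:
            canvas = 255 - grey_dilation(255 - canvas, size=(w, w))

    return WaveformImage(
        pixels=canvas,
        roi_id=trace.roi_id,
        group=trace.group,
        substance=trace.substance,
        dose=trace.dose,
        lot=trace.lot,
        config_hash=cfg.hash(),
        clip_fraction=clip_fraction,
    )


def save_jpeg(image: "WaveformImage | Any", path: str | Path, quality: int = 90) -> None:
    """Write a raster (waveform or composite) as a grayscale JPEG file."""
    Image.fromarray(image.pixels, mode="L").save(str(path), quality=quality)


def write_manifest(
    images: Sequence[WaveformImage], filenames: Sequence[str], path: str | Path
) -> pd.DataFrame:
    """Dataset manifest joining image files back to their trace labels."""
    if len(images) != len(filenames):
        raise ParameterError("filenames: must align one-to-one with images")
    df = pd.DataFrame(
        {
            "filename": list(filenames),
            "roi_id": [im.roi_id for im in images],
            "group": [im.group for im in images],
            "substance": [im.substance for im in images],
            "dose": [im.dose for im in images],
            "lot": [im.lot for im in images],
            "config_hash": [im.config_hash for im in images],
            "clip_fraction": [im.clip_fraction for im in images],
        }
    )
    df.to_csv(path, index=False)
    return df
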