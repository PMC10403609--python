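"""Shared containers and the package error taxonomy.

The two containers defined here travel between every stage of the
pipeline: :class:`CalciumTrace` is a single region's fluorescence time
series (raw fluorescence counts or normalised ΔF/F), and
:class:`FluorescenceMovie` is a T×H×W grayscale time-lapse stack with
its spatial and temporal calibration attached.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = [
    "CaWaveError",
    "ParameterError",
    "LayoutError",
    "SegmentationError",
    "AlignmentError",
    "InsufficientPoolError",
    "LabelError",
    "DimensionError",
    "StratificationError",
    "TrainingError",
    "CalciumTrace",
    "FluorescenceMovie",
]


class CaWaveError(Exception):
    """Base class for every error raised by this package."""


class ParameterError(CaWaveError, ValueError):
    """An invalid parameter value; the message names the offending field."""


class LayoutError(CaWaveError, ValueError):
    """Simulated cells placed outside the frame or overlapping."""


class SegmentationError(CaWaveError, ValueError):
    """A degenerate ROI (e.g. zero member pixels)."""


class AlignmentError(CaWaveError, ValueError):
    """Paired sequences whose identifiers do not line up."""


class InsufficientPoolError(CaWaveError, ValueError):
    """Too few waveform images to draw a composite from."""


class LabelError(CaWaveError, ValueError):
    """Mixed or unknown group labels where a single group is required."""


class DimensionError(CaWaveError, ValueError):
    """Heterogeneous raster dimensions."""


class StratificationError(CaWaveError, ValueError):
    """A class too small to stratify at the requested fractions."""


class TrainingError(CaWaveError, ValueError):
    """Training input that cannot yield a binary classifier."""


#: unit flags for CalciumTrace.values
UNITS_RAW = "raw-F"
UNITS_DFF = "dff"


@dataclass
class CalciumTrace:
    """One ROI's fluorescence time series with calibration and labels.

    ``values`` holds raw fluorescence F(t) (``units='raw-F'``) or
    normalised ΔF/F = (F - F0)/F0 (``units='dff'``).  Group labels follow
    the two-arm study design: ``negative`` (no / low-dose treatment),
    ``positive`` (neuronally effective treatment) or ``unknown``.
    """

    values: np.ndarray
    frame_interval_s: float
    units: str = UNITS_RAW
    roi_id: str = "roi-0000"
    group: str = "unknown"
    substance: str | None = None
    dose: str | None = None
    lot: str | None = None
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 2:
            raise ParameterError("values: a trace needs at least 2 samples")
        if not self.frame_interval_s > 0:
            raise ParameterError("frame_interval_s: must be > 0")
        if self.units not in (UNITS_RAW, UNITS_DFF):
            raise ParameterError(f"units: unknown flag {self.units!r}")
        if self.group not in ("negative", "positive", "unknown"):
            raise ParameterError(f"group: unknown label {self.group!r}")

    @property
    def n_samples(self) -> int:
        return int(self.values.size)

    @property
    def duration_s(self) -> float:
        """Nominal recorded duration (one interval per sample)."""
        return self.n_samples * self.frame_interval_s

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.frame_interval_s


@dataclass
class FluorescenceMovie:
    """A grayscale time-lapse stack, frames × height × width.

    ``pixel_size_um`` is the physical edge length of one pixel and
    ``frame_interval_s`` the time between consecutive frames.
    """

    data: np.ndarray
    pixel_size_um: float = 1.0
    frame_interval_s: float = 1.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or self.data.size == 0:
            raise ParameterError("data: movie must be a non-empty (T, H, W) stack")
        if not self.pixel_size_um > 0:
            raise ParameterError("pixel_size_um: must be > 0")
        if not self.frame_interval_s > 0:
            raise ParameterError("frame_interval_s: must be > 0")

    @property
    def n_frames(self) -> int:
        return int(self.data.shape[0])

    @property
    def frame_shape(self) -> tuple[int, int]:
        return int(self.data.shape[1]), int(self.data.shape[2])
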