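import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cawave.core import CalciumTrace, UNITS_DFF
from cawave.render import RenderConfig, WaveformImage

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def noise_trace(seed: int, sigma: float = 0.05, n: int = 300, f0: float = 1000.0) -> CalciumTrace:
    """Pure Gaussian-noise raw-F trace."""
    rng = np.random.default_rng(seed)
    return CalciumTrace(values=f0 * (1 + rng.normal(0, sigma, n)), frame_interval_s=1.0)


def flat_image(level: int, size: int = 48, roi_id: str = "x", group: str = "negative") -> WaveformImage:
    return WaveformImage(
        pixels=np.full((size, size), level, dtype=np.uint8), roi_id=roi_id, group=group
    )


@pytest.fixture
def render_cfg() -> RenderConfig:
    return RenderConfig(canvas_px=(96, 96))


@pytest.fixture
def dff_trace() -> CalciumTrace:
    rng = np.random.default_rng(0)
    v = np.clip(rng.normal(0.0, 0.05, 300), -0.4, None)
    return CalciumTrace(values=v, frame_interval_s=1.0, units=UNITS_DFF, roi_id="t0")


def waveform_pool(n: int, group: str = "negative", size: int = 48, seed: int = 0) -> list[WaveformImage]:
    """Distinct random-content waveform images for compositor/learning tests."""
    rng = np.random.default_rng(seed)
    return [
        WaveformImage(
            pixels=rng.integers(0, 256, (size, size), dtype=np.uint8),
            roi_id=f"{group[:3]}-{i:04d}",
            group=group,
        )
        for i in range(n)
    ]
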