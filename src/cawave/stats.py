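"""Classical waveform statistics.

The two parameters a human analyst would reach for — per-trace spike
frequency and dynamic range — plus the unpaired (equal-variance)
Student's t test used to compare them between treatment groups, and
responder-fraction / frequency-reduction summaries of antagonist-type
experiments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .core import CalciumTrace, ParameterError, UNITS_DFF
from .extract import SpikeTrain, detect_spikes, estimate_noise, to_dff

__all__ = [
    "ALPHA",
    "TTestResult",
    "ResponderComparison",
    "spike_frequency",
    "dynamic_range",
    "unpaired_t_test",
    "responder_stats",
    "group_parameter_comparison",
]

#: two-sided significance level
ALPHA = 0.05


@dataclass(frozen=True)
class TTestResult:
    t_statistic: float
    degrees_of_freedom: int
    p_value: float

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA

    def to_dict(self) -> dict:
        return {
            "t_statistic": self.t_statistic,
            "degrees_of_freedom": self.degrees_of_freedom,
            "p_value": self.p_value,
            "significant": self.significant,
        }


@dataclass(frozen=True)
class ResponderComparison:
    """Responder fractions, mean frequencies, and their percent reductions
    between a reference condition (a) and a treated condition (b)."""

    responder_fraction_a: float
    responder_fraction_b: float
    mean_frequency_hz_a: float
    mean_frequency_hz_b: float
    responder_reduction_pct: float | None  # None when undefined (a = 0)
    frequency_reduction_pct: float | None


def spike_frequency(spikes: SpikeTrain, duration_s: float) -> float:
    """Events per second: spike count / recording duration."""
    if not duration_s > 0:
        raise ParameterError("duration_s: must be > 0")
    return spikes.n_spikes / duration_s


def dynamic_range(trace: CalciumTrace) -> float:
    """max − min of the ΔF/F trace (the conventional per-trace range)."""
    if trace.units != UNITS_DFF:
        raise ParameterError("trace: dynamic_range expects ΔF/F units")
    return float(np.ptp(trace.values))


def unpaired_t_test(x: Sequence[float], y: Sequence[float]) -> TTestResult:
    """Classical equal-variance two-sample Student's t test, two-sided."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ParameterError("x/y: both samples need n >= 2")
    if np.ptp(x) == 0 and np.ptp(y) == 0 and x[0] == y[0]:
        # identical constants: zero pooled variance but a well-defined null
        return TTestResult(t_statistic=0.0, degrees_of_freedom=int(x.size + y.size - 2), p_value=1.0)
    sp2 = (
        (x.size - 1) * x.var(ddof=1) + (y.size - 1) * y.var(ddof=1)
    ) / (x.size + y.size - 2)
    if sp2 == 0:
        raise ParameterError("samples: zero pooled variance; t test undefined")
    res = sps.ttest_ind(x, y, equal_var=True)
    return TTestResult(
        t_statistic=float(res.statistic),
        degrees_of_freedom=int(x.size + y.size - 2),
        p_value=float(res.pvalue),
    )


def responder_stats(
    condition_a: Sequence[SpikeTrain],
    condition_b: Sequence[SpikeTrain],
    duration_s: float = 300.0,
    min_spikes: int = 1,
) -> ResponderComparison:
    """Responder fractions and mean spike frequencies of two conditions,
    with percent reductions 100·(1 − b/a); reductions whose reference is
    zero are flagged as undefined (None)."""
    if len(condition_a) == 0 or len(condition_b) == 0:
        raise ParameterError("condition_a/condition_b: must be non-empty")
    frac_a = sum(s.n_spikes >= min_spikes for s in condition_a) / len(condition_a)
    frac_b = sum(s.n_spikes >= min_spikes for s in condition_b) / len(condition_b)
    freq_a = float(np.mean([spike_frequency(s, duration_s) for s in condition_a]))
    freq_b = float(np.mean([spike_frequency(s, duration_s) for s in condition_b]))
    red_frac = None if frac_a == 0 else 100.0 * (1.0 - frac_b / frac_a)
    red_freq = None if freq_a == 0 else 100.0 * (1.0 - freq_b / freq_a)
    return ResponderComparison(
        responder_fraction_a=frac_a,
        responder_fraction_b=frac_b,
        mean_frequency_hz_a=freq_a,
        mean_frequency_hz_b=freq_b,
        responder_reduction_pct=red_frac,
        frequency_reduction_pct=red_freq,
    )


def group_parameter_comparison(
    traces: Sequence[CalciumTrace],
    detections: Sequence[SpikeTrain] | None = None,
    k_sigma: float = 4.0,
) -> dict[str, TTestResult]:
    """Between-group t tests on the two classical waveform parameters.

    Splits traces by their ``negative``/``positive`` group label,
    computes per-trace spike frequency (from the supplied or freshly run
    detections) and ΔF/F dynamic range, and runs the unpaired Student's
    t test on each.
    """
    groups = {"negative": [], "positive": []}
    for i, tr in enumerate(traces):
        if tr.group not in groups:
            raise ParameterError(f"trace {tr.roi_id}: group must be negative/positive")
        groups[tr.group].append(i)
    if min(len(v) for v in groups.values()) < 2:
        raise ParameterError("each group needs at least 2 traces")

    freqs = np.empty(len(traces))
    dranges = np.empty(len(traces))
    for i, tr in enumerate(traces):
        noise = estimate_noise(tr)
        det = detections[i] if detections is not None else detect_spikes(tr, noise, k_sigma=k_sigma)
        freqs[i] = spike_frequency(det, tr.duration_s)
        dranges[i] = dynamic_range(tr if tr.units == UNITS_DFF else to_dff(tr, noise))
    neg, pos = groups["negative"], groups["positive"]
    return {
        "spike_frequency": unpaired_t_test(freqs[neg], freqs[pos]),
        "dynamic_range": unpaired_t_test(dranges[neg], dranges[pos]),
    }
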