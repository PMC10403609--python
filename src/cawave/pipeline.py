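"""End-to-end benchmark experiments.

``run_experiment`` wires the full computational arm together:
simulate a two-group benchmark → normalise to ΔF/F → rasterize →
(optionally composite) → stratified 90/10 split → train → evaluate.
Three training regimes are supported:

* ``single``     — one waveform image per training example;
* ``composite``  — nine-waveform composite images, one composite per
                   pool waveform (waveforms recur across composites);
* ``composite_matched`` — the equal-waveform-count control: composites
                   drawn without any cross-composite reuse, so the arm
                   consumes the same number of *distinct waveforms* as
                   the single arm while yielding 1/9 as many images.

Every stage draws from seeds derived from one root seed, so a report is
a deterministic function of (benchmark, config, seed).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any

import numpy as np

from .composite import TILES_PER_COMPOSITE, build_composites
from .core import CalciumTrace, ParameterError
from .extract import estimate_noise, to_dff
from .learn import (
    ClassifierModel,
    SegregationResult,
    evaluate,
    segregate_unseen,
    split_dataset,
    train_classifier,
)
from .render import RenderConfig, WaveformImage, render_waveform
from .simulate import BenchmarkSpec, TraceParams, make_benchmark, simulate_trace
from .stats import dynamic_range, group_parameter_comparison

__all__ = ["ExperimentConfig", "MODES", "run_experiment", "holdout_segregation", "report_json"]

MODES = ("single", "composite", "composite_matched")


@dataclass(frozen=True)
class ExperimentConfig:
    """Knobs of one benchmark experiment (rendering + learning)."""

    render: RenderConfig = field(
        default_factory=lambda: RenderConfig(canvas_px=(96, 96))
    )
    split_fractions: tuple[float, float] = (0.90, 0.10)
    classifier: dict[str, Any] = field(default_factory=dict)
    weak_signal_tercile: bool = False  # restrict pool to lowest dynamic-range third
    include_stats: bool = True
    k_sigma: float = 4.0


def _dff_images(
    traces: list[CalciumTrace], cfg: ExperimentConfig
) -> tuple[list[WaveformImage], list[CalciumTrace]]:
    dff_traces = []
    for tr in traces:
        noise = estimate_noise(tr)
        dff_traces.append(to_dff(tr, noise))
    # per-image clip warnings are aggregated into the report instead of
    # being emitted once per trace
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        images = [render_waveform(tr, cfg.render) for tr in dff_traces]
    return images, dff_traces


def _weak_tercile(
    images: list[WaveformImage], dff_traces: list[CalciumTrace]
) -> list[WaveformImage]:
    """Lowest dynamic-range third of each group (the weak-signal control)."""
    keep: list[WaveformImage] = []
    for grp in ("negative", "positive"):
        idx = [i for i, im in enumerate(images) if im.group == grp]
        dr = np.array([dynamic_range(dff_traces[i]) for i in idx])
        cut = np.quantile(dr, 1.0 / 3.0)
        keep.extend(images[i] for i, d in zip(idx, dr) if d <= cut)
    return keep


def run_experiment(
    benchmark: BenchmarkSpec,
    mode: str = "composite",
    config: ExperimentConfig | None = None,
    seed: int = 0,
) -> dict[str, Any]:
    """Run one full simulate→render→(composite)→split→train→evaluate pass.

    Returns a JSON-serialisable report with the evaluation metrics, the
    classical-statistics comparison (when enabled) and the problem sizes
    used.  Deterministic given (benchmark, mode, config, seed).
    """
    if mode not in MODES:
        raise ParameterError(f"mode: expected one of {MODES}, got {mode!r}")
    cfg = config or ExperimentConfig()
    ss = np.random.SeedSequence([seed, benchmark.seed])
    bench_seed, split_seed, comp_seed, train_seed = (
        int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(4)
    )

    traces = make_benchmark(replace(benchmark, seed=bench_seed))
    images, dff_traces = _dff_images(traces, cfg)
    pool = _weak_tercile(images, dff_traces) if cfg.weak_signal_tercile else images

    split = split_dataset(pool, fractions=cfg.split_fractions, seed=split_seed)
    trainval = [pool[i] for i in split.indices("trainval")]
    test = [pool[i] for i in split.indices("test")]

    if mode == "single":
        train_set, test_set = trainval, test
        n_waveforms_train = len(trainval)
    else:
        reuse = mode == "composite"
        train_set, test_set = [], []
        rng = np.random.default_rng(comp_seed)
        for grp in ("negative", "positive"):
            tv = [im for im in trainval if im.group == grp]
            te = [im for im in test if im.group == grp]
            n_out = len(tv) if reuse else len(tv) // TILES_PER_COMPOSITE
            train_set.extend(
                build_composites(tv, grp, n_out, int(rng.integers(2**31)), reuse_across=reuse)
            )
            # test composites always sample with cross-composite reuse so
            # both composite arms are scored on the same kind of input
            test_set.extend(
                build_composites(te, grp, max(1, len(te)), int(rng.integers(2**31)))
            )
        n_waveforms_train = (
            len(trainval) if reuse
            else sum(len(c.member_ids) for c in train_set)
        )

    model = train_classifier(train_set, config=cfg.classifier, seed=train_seed)
    report_eval = evaluate(model, test_set)

    report: dict[str, Any] = {
        "mode": mode,
        "seed": seed,
        "benchmark_seed": benchmark.seed,
        "effect_knob": benchmark.positive_params.effect_knob,
        "n_traces_per_group": benchmark.n_traces_per_group,
        "n_waveforms_train": n_waveforms_train,
        "n_train_images": len(train_set),
        "n_test_images": len(test_set),
        "mean_clip_fraction": float(np.mean([im.clip_fraction for im in images])),
        "evaluation": report_eval.to_dict(),
    }
    if cfg.include_stats:
        comparison = group_parameter_comparison(traces, k_sigma=cfg.k_sigma)
        report["classical_stats"] = {
            name: res.to_dict() for name, res in comparison.items()
        }
    return report


def holdout_segregation(
    model: ClassifierModel,
    params: TraceParams,
    substance: str,
    n_traces: int,
    seed: int,
    render_config: RenderConfig | None = None,
) -> SegregationResult:
    """Challenge a trained model with a noneducated substance.

    Simulates ``n_traces`` fresh waveforms under ``params`` (e.g. the
    positive-group parameters standing in for a held-out neuroactive
    substance), renders them as single waveform images and reports the
    fraction voted into the positive group.
    """
    rcfg = render_config or RenderConfig(canvas_px=(96, 96))
    children = np.random.SeedSequence(seed).spawn(n_traces)
    images = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        for i, child in enumerate(children):
            tr = simulate_trace(params, child)
            tr.roi_id = f"holdout-{i:04d}"
            tr.substance = substance
            noise = estimate_noise(tr)
            images.append(render_waveform(to_dff(tr, noise), rcfg))
    return segregate_unseen(model, images, substance)


def report_json(report: dict[str, Any], path: str | Path | None = None) -> str:
    """Canonical (sorted, fixed-format) JSON for byte-stable reports."""
    text = json.dumps(report, indent=1, sort_keys=True)
    if path is not None:
        Path(path).write_text(text)
    return text
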