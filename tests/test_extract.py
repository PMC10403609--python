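"""Extraction pipeline: preprocessing, hexagonal tiling, traces, noise, spikes."""

import math

import numpy as np
import pytest

from cawave.core import (
    AlignmentError,
    CalciumTrace,
    FluorescenceMovie,
    ParameterError,
    SegmentationError,
)
from cawave.extract import (
    detect_spikes,
    estimate_noise,
    extract_traces,
    hex_tiling,
    hexagon_vertices,
    preprocess_movie,
    select_spiking_rois,
    to_dff,
)
from cawave.simulate import MovieSpec, TraceParams, simulate_movie, simulate_trace, _spark_template

from conftest import noise_trace


def brute_force_hex_labels(H, W, pixel_size_um, diameter_um):
    """Independent point-in-hexagon membership oracle.

    Reconstructs the same flat-top lattice and tests each pixel against
    each hexagon's three half-plane pairs; a pixel on a shared boundary
    goes to the first containing hexagon in (row, col) center order —
    including dropped border hexagons, whose pixels stay unassigned.
    """
    R = diameter_um / pixel_size_um / 2
    dx, dy = 1.5 * R, math.sqrt(3) * R
    n_cols, n_rows = int(math.ceil(W / dx)) + 2, int(math.ceil(H / dy)) + 2
    centers = []
    for j in range(-1, n_cols):
        cx = R + j * dx
        y0 = R * math.sqrt(3) / 2 + (dy / 2 if j % 2 else 0)
        for i in range(-1, n_rows):
            centers.append((y0 + i * dy, cx))

    def inside(cy, cx, py, px, eps=1e-9):
        dyv, dxv = abs(py - cy), abs(px - cx)
        return dyv <= math.sqrt(3) / 2 * R + eps and math.sqrt(3) * dxv + dyv <= math.sqrt(3) * R + eps

    kept = []
    for ci, (cy, cx) in enumerate(centers):
        v = hexagon_vertices((cy, cx), R)
        if (
            v[:, 0].min() >= -1e-9 and v[:, 0].max() <= H - 1 + 1e-9
            and v[:, 1].min() >= -1e-9 and v[:, 1].max() <= W - 1 + 1e-9
        ):
            kept.append(ci)
    roi_of = {ci: r for r, ci in enumerate(sorted(kept, key=lambda i: centers[i]))}
    order = sorted(range(len(centers)), key=lambda i: centers[i])
    lab = np.full((H, W), -1, int)
    for py in range(H):
        for px in range(W):
            for ci in order:
                if inside(*centers[ci], py, px):
                    lab[py, px] = roi_of.get(ci, -1)
                    break
    return lab


class TestPreprocess:
    def test_identity_configuration(self):
        movie, _ = simulate_movie(MovieSpec(height_px=24, width_px=24, n_cells=1, cell_radius_um=5), 0)
        out = preprocess_movie(movie, contrast_percentiles=(0, 100), smooth_sigma_px=0)
        assert np.allclose(out.data, movie.data)

    def test_constant_movie_stays_constant(self):
        movie = FluorescenceMovie(data=np.full((5, 16, 16), 7.0))
        out = preprocess_movie(movie, contrast_percentiles=(1, 99), smooth_sigma_px=1)
        assert np.allclose(out.data, 7.0)

    def test_smoothing_reduces_temporal_variance_of_iid_noise(self):
        rng = np.random.default_rng(0)
        movie = FluorescenceMovie(data=rng.normal(100, 5, (50, 32, 32)))
        out = preprocess_movie(movie, contrast_percentiles=(0, 100), smooth_sigma_px=1)
        var_in = movie.data.var(axis=0).mean()
        var_out = out.data.var(axis=0).mean()
        assert var_out < var_in

    def test_bad_percentiles_rejected(self):
        movie = FluorescenceMovie(data=np.zeros((2, 8, 8)))
        with pytest.raises(ParameterError):
            preprocess_movie(movie, contrast_percentiles=(50, 10))


class TestHexTiling:
    @pytest.mark.parametrize(
        "shape,pixel_size,diameter",
        [
            ((64, 64), 1.0, 20.0),
            ((128, 128), 1.0, 20.0),
            ((50, 80), 0.5, 20.0),
            ((40, 40), 2.0, 20.0),
            ((128, 96), 1.3, 17.0),
        ],
    )
    def test_matches_brute_force_oracle(self, shape, pixel_size, diameter):
        rois = hex_tiling(shape, pixel_size, diameter)
        oracle = brute_force_hex_labels(*shape, pixel_size, diameter)
        assert np.array_equal(rois.label_image(), oracle)

    def test_partition_no_pixel_in_two_rois(self):
        rois = hex_tiling((128, 128), 1.0, 20.0)
        total = sum(r.n_pixels for r in rois.rois)
        assert total == int((rois.label_image() >= 0).sum())

    def test_degenerate_frame_yields_empty_set(self):
        assert len(hex_tiling((10, 10), 1.0, 20.0)) == 0

    def test_unit_conversion_across_distance(self):
        """20 μm at 0.5 μm/px spans 40 px across corners."""
        rois = hex_tiling((200, 200), 0.5, 20.0)
        v = hexagon_vertices(rois.rois[0].center_px, 20.0 / 0.5 / 2)
        assert np.isclose(v[:, 1].max() - v[:, 1].min(), 40.0)

    def test_too_small_hexagon_is_resolution_error(self):
        with pytest.raises(ParameterError, match="diameter"):
            hex_tiling((64, 64), 10.0, 20.0)


class TestExtractTraces:
    def test_constant_movie_gives_constant_traces(self):
        movie = FluorescenceMovie(data=np.full((10, 64, 64), 42.0))
        rois = hex_tiling((64, 64), 1.0, 20.0)
        traces = extract_traces(movie, rois)
        assert len(traces) == len(rois)
        for tr in traces:
            assert tr.n_samples == 10
            assert np.allclose(tr.values, 42.0)

    def test_only_rois_over_flashing_cell_are_modulated(self):
        spec = MovieSpec(
            height_px=96, width_px=96, n_cells=1, centers_px=((48.0, 48.0),),
            background_noise=0.0,
            trace_params=TraceParams(noise_sigma=0, wave_rate_hz=0, cell_scale_sigma=0),
        )
        movie, truth = simulate_movie(spec, seed=1)
        rois = hex_tiling((96, 96), 1.0, 20.0)
        traces = extract_traces(movie, rois)
        r_cell = spec.cell_radius_um
        for tr in traces:
            cy, cx = tr.metadata["center_px"]
            far = math.hypot(cy - 48, cx - 48) > r_cell + 10 + 1
            if far:
                assert np.ptp(tr.values) == 0
        assert any(np.ptp(tr.values) > 0 for tr in traces)

    def test_frame_shape_mismatch_rejected(self):
        movie = FluorescenceMovie(data=np.zeros((3, 32, 32)))
        rois = hex_tiling((64, 64), 1.0, 20.0)
        with pytest.raises(SegmentationError):
            extract_traces(movie, rois)


class TestEstimateNoise:
    def test_pure_gaussian_sigma_within_15_percent(self):
        errs = []
        for s in range(100):
            tr = noise_trace(s, sigma=0.05)
            nz = estimate_noise(tr)
            errs.append(abs(nz.sigma / nz.f0 - 0.05) / 0.05)
        assert np.median(errs) < 0.15

    def test_constant_trace(self):
        tr = CalciumTrace(values=np.full(100, 5.0), frame_interval_s=1.0)
        nz = estimate_noise(tr)
        assert nz.sigma == 0.0 and nz.f0 == 5.0

    def test_sigma_robust_to_sparse_large_spikes(self):
        """σ̂ stays within 20% of the spike-free σ with five 10σ events."""
        tt = np.arange(300.0)
        errs = []
        for s in range(100):
            tr = noise_trace(s, sigma=0.05)
            v = tr.values.copy()
            for t0 in (30, 80, 130, 200, 260):
                v += 1000 * 0.5 * _spark_template(tt - t0, 1.0, 4.0)
            nz = estimate_noise(CalciumTrace(values=v, frame_interval_s=1.0))
            errs.append(abs(nz.sigma - 50.0) / 50.0)
        assert np.median(errs) < 0.20

    def test_short_trace_rejected(self):
        with pytest.raises(ParameterError):
            estimate_noise(CalciumTrace(values=np.zeros(10), frame_interval_s=1.0))


class TestDetectSpikes:
    def test_flat_trace_zero_spikes(self):
        tr = CalciumTrace(values=np.full(100, 3.0), frame_interval_s=1.0)
        det = detect_spikes(tr, estimate_noise(tr))
        assert det.n_spikes == 0

    def test_injected_10sigma_spikes_recovered_exactly(self):
        tt = np.arange(300.0)
        times = (30, 80, 130, 200, 260)
        for s in range(20):
            tr = noise_trace(s, sigma=0.05)
            v = tr.values.copy()
            for t0 in times:
                v += 1000 * 0.5 * _spark_template(tt - t0, 1.0, 4.0)
            trace = CalciumTrace(values=v, frame_interval_s=1.0)
            det = detect_spikes(trace, estimate_noise(trace))
            assert det.n_spikes == len(times)
            # template peaks ~2 s after onset and is flat within the noise
            # over +/-2 samples, so the detected argmax jitters slightly
            assert np.all(np.abs(det.spike_times_s - (np.array(times) + 2)) <= 2)

    def test_subthreshold_excursions_ignored(self):
        """1σ wiggles never cross a 4σ threshold."""
        rng = np.random.default_rng(0)
        v = 1000 * (1 + 0.05 * np.sin(np.arange(300) / 5))
        tr = CalciumTrace(values=v + rng.normal(0, 1e-3, 300), frame_interval_s=1.0)
        nz = estimate_noise(tr)
        det = detect_spikes(tr, type(nz)(f0=nz.f0, sigma=50.0), k_sigma=4)
        assert det.n_spikes == 0

    def test_zero_sigma_nonconstant_guard(self):
        tr = CalciumTrace(values=np.linspace(1, 2, 100), frame_interval_s=1.0)
        from cawave.extract import NoiseEstimate

        with pytest.raises(ParameterError, match="sigma"):
            detect_spikes(tr, NoiseEstimate(f0=1.0, sigma=0.0))

    def test_false_positives_on_pure_noise(self):
        total = 0
        for s in range(200):
            tr = noise_trace(1000 + s, sigma=0.05)
            total += detect_spikes(tr, estimate_noise(tr), k_sigma=4).n_spikes
        assert total / 200 <= 0.05

    def test_rate_recovery_in_resolvable_regime(self):
        """At a low event rate (rare overlaps) detected counts recover the
        Poisson rate within 2 standard errors."""
        p = TraceParams(spark_rate_hz=0.01, wave_rate_hz=0.0)
        counts = []
        for s in range(100):
            tr = simulate_trace(p, s)
            counts.append(detect_spikes(tr, estimate_noise(tr)).n_spikes)
        expected = p.spark_rate_hz * p.duration_s
        se = np.std(counts) / np.sqrt(len(counts))
        assert abs(np.mean(counts) - expected) <= 2 * se

    def test_detected_counts_match_resolvable_ground_truth_clusters(self):
        """On the default benchmark the detector recovers one spike per
        cluster of ground-truth events closer than the refractory window."""
        p = TraceParams()
        diffs = []
        # events are unresolvable when closer than the refractory window
        # (3 s) plus roughly one decay constant of peak-tail interaction,
        # so ground-truth events are clustered at a 6 s linkage
        for s in range(100):
            tr = simulate_trace(p, s)
            times = tr.metadata["ground_truth"]["spark_times_s"]
            n_clusters = 1 + int(np.sum(np.diff(times) >= 6.0)) if times.size else 0
            det = detect_spikes(tr, estimate_noise(tr))
            diffs.append(det.n_spikes - n_clusters)
        assert abs(np.mean(diffs)) < 0.5


class TestSelection:
    def test_select_spiking_rois(self):
        p_active = TraceParams(spark_rate_hz=0.03, noise_sigma=0.02, cell_scale_sigma=0)
        p_silent = TraceParams(spark_rate_hz=0.0, wave_rate_hz=0.0, noise_sigma=0.02)
        traces, dets = [], []
        for i in range(10):
            tr = simulate_trace(p_active if i < 3 else p_silent, 100 + i)
            tr.roi_id = f"roi-{i:04d}"
            traces.append(tr)
            dets.append(detect_spikes(tr, estimate_noise(tr)))
        kept = select_spiking_rois(traces, dets, min_spikes=1)
        assert {tr.roi_id for tr, _ in kept} == {f"roi-{i:04d}" for i in range(3)}
        assert len(select_spiking_rois(traces, dets, min_spikes=0)) == 10

    def test_misaligned_inputs_rejected(self):
        with pytest.raises(AlignmentError):
            select_spiking_rois([noise_trace(0)], [])


class TestEndToEnd:
    def test_movie_to_spikes_recovers_isolated_cell_events(self):
        """simulate → preprocess → tile → extract → detect recovers the
        resolvable ground-truth events of an isolated cell."""
        tp = TraceParams(
            spark_rate_hz=0.0167, wave_rate_hz=0, noise_sigma=0.02,
            cell_scale_sigma=0, spark_amp_sigma=0.1, spark_amp_mu=np.log(2.0),
        )
        spec = MovieSpec(
            height_px=96, width_px=96, n_cells=1, centers_px=((48.0, 48.0),),
            trace_params=tp,
        )
        movie, truth = simulate_movie(spec, seed=5)
        times = truth[0].metadata["ground_truth"]["spark_times_s"]
        n_resolvable = 1 + int(np.sum(np.diff(times) >= 4.0))
        pre = preprocess_movie(movie)
        rois = hex_tiling(movie.frame_shape, 1.0, 20.0)
        traces = extract_traces(pre, rois)
        best = max(
            (detect_spikes(tr, estimate_noise(tr)).n_spikes for tr in traces),
        )
        assert best == n_resolvable
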