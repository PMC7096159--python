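"""SMFS analysis chain: conversion, zeroing, denoising, contour-length
transform, event detection, fingerprint certification, rupture extraction."""

import numpy as np
import pytest

from pullgeom import synthetic_data as sd, trace_analysis as ta
from pullgeom.rupture_stats import BellEvansParams
from pullgeom.wlc import wlc_extension

KBT = 4.141947


def _trace(time, ext, force, **meta):
    return ta.ForceExtensionTrace(time=time, extension=ext, force=force, metadata=meta)


class TestConvertRaw:
    def test_zero_deflection_zero_force(self):
        n = 100
        tr = ta.convert_raw(np.zeros(n), np.linspace(0, 1, n), 50.0, 10.0, 0.15)
        assert np.all(tr.force == 0)
        assert np.allclose(tr.extension, 10.0 * np.linspace(0, 1, n))

    def test_rigid_contact_gives_zero_extension(self):
        # deflection consumes the whole piezo travel: x = ps*z - invols*d = 0
        n = 50
        z = np.linspace(0, 1, n)
        invols, ps = 50.0, 10.0
        d = ps * z / invols
        tr = ta.convert_raw(d, z, invols, ps, 0.15)
        assert np.allclose(tr.extension, 0.0, atol=1e-12)

    def test_round_trip_through_inverted_formulas(self):
        rng = np.random.default_rng(0)
        force = rng.uniform(0, 500, 200)
        ext = rng.uniform(0, 100, 200)
        invols, ps, kc = 47.3, 12.1, 0.15
        d = force / (kc * invols * 1000.0)
        z = (ext + invols * d) / ps
        tr = ta.convert_raw(d, z, invols, ps, kc)
        assert np.allclose(tr.force, force, rtol=1e-9)
        assert np.allclose(tr.extension, ext, rtol=1e-9, atol=1e-9)

    def test_mismatched_channels_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            ta.convert_raw(np.zeros(5), np.zeros(6), 50.0, 10.0, 0.15)


class TestZeroPoints:
    def test_injected_force_offset_recovered(self, tether, subunit_params):
        proto = sd.AcquisitionProtocol(seed=21)
        trace = sd.simulate_trace(tether, subunit_params["D"], proto)
        shifted = trace.replace(force=trace.force + 5.0)
        off, _, corrected = ta.determine_zero_points(shifted)
        noise_se = proto.force_noise_sd / np.sqrt(0.1 * trace.n_samples)
        assert off == pytest.approx(5.0, abs=5 * noise_se + 0.3)

    def test_already_zeroed_noiseless_trace(self, tether, subunit_params):
        proto = sd.AcquisitionProtocol(seed=2, force_noise_sd=0.0)
        trace = sd.simulate_trace(tether, subunit_params["D"], proto)
        f_off, d_off, _ = ta.determine_zero_points(trace)
        assert f_off == 0.0
        assert d_off == pytest.approx(0.0, abs=1e-12)

    def test_all_contact_trace_flagged(self):
        n = 1000
        tr = _trace(np.arange(n) / 1e4, np.linspace(0, 10, n), np.full(n, 300.0))
        with pytest.raises(ta.BaselineError):
            ta.determine_zero_points(tr)


class TestDenoise:
    def test_window_one_is_identity(self):
        n = 200
        rng = np.random.default_rng(1)
        tr = _trace(np.arange(n) / 1e4, np.zeros(n), rng.normal(size=n))
        assert np.array_equal(ta.denoise(tr, 1).force, tr.force)

    def test_constant_trace_unchanged(self):
        n = 100
        tr = _trace(np.arange(n) / 1e4, np.zeros(n), np.full(n, 7.0))
        assert np.allclose(ta.denoise(tr, 11).force, 7.0)

    def test_white_noise_sd_reduced_by_sqrt_window(self):
        n, w, sigma = 10_000, 9, 5.0
        rng = np.random.default_rng(2)
        tr = _trace(np.arange(n) / 1e4, np.zeros(n), rng.normal(0, sigma, n))
        out_sd = ta.denoise(tr, w).force[w:-w].std()
        assert out_sd == pytest.approx(sigma / np.sqrt(w), rel=0.2)

    @pytest.mark.parametrize("window", [0, 2, -3])
    def test_even_or_nonpositive_window_rejected(self, window):
        tr = _trace(np.arange(10) / 1e4, np.zeros(10), np.zeros(10))
        with pytest.raises(ValueError):
            ta.denoise(tr, window)


class TestContourLengthTransform:
    def test_pure_wlc_recovers_contour_length(self):
        F = np.linspace(12, 300, 500)
        ext = wlc_extension(F, 60.0, 0.38, KBT)
        tr = _trace(np.arange(500) / 1e4, ext, F)
        Lc = ta.contour_length_transform(tr, Lp=0.38, kBT=KBT)
        assert np.allclose(Lc, 60.0, rtol=1e-6)

    def test_low_force_points_masked(self):
        F = np.array([2.0, 5.0, 50.0])
        ext = wlc_extension(F, 60.0, 0.38, KBT)
        tr = _trace(np.arange(3) / 1e4, ext, F)
        Lc = ta.contour_length_transform(tr, min_force=10.0)
        assert np.isnan(Lc[0]) and np.isnan(Lc[1]) and np.isfinite(Lc[2])

    def test_two_plateau_trace_gives_bimodal_series(self):
        F = np.concatenate([np.linspace(15, 80, 300), np.linspace(15, 80, 300)])
        ext = np.concatenate(
            [wlc_extension(F[:300], 60.0, 0.38, KBT), wlc_extension(F[300:], 75.0, 0.38, KBT)]
        )
        tr = _trace(np.arange(600) / 1e4, ext, F)
        Lc = ta.contour_length_transform(tr)
        hist, edges = np.histogram(Lc[np.isfinite(Lc)], bins=np.arange(50, 90, 1.0))
        top_two = np.sort(edges[np.argsort(hist)[-2:]])
        assert top_two[0] == pytest.approx(60.0, abs=1.0)
        assert top_two[1] == pytest.approx(75.0, abs=1.0)


class TestEventDetection:
    def test_monotone_ramp_has_no_events(self):
        F = np.linspace(0, 400, 1000)
        ext = wlc_extension(np.clip(F, 1e-6, None), 60.0, 0.38, KBT)
        tr = _trace(np.arange(1000) / 1e4, ext, F)
        Lc = ta.contour_length_transform(tr)
        assert ta.detect_unfolding_events(tr, Lc) == []

    def test_programmed_unfoldings_recovered_within_1_nm(self, tether, subunit_params):
        proto = sd.AcquisitionProtocol(seed=3, force_noise_sd=0.0)
        trace = sd.simulate_trace(tether, subunit_params["D"], proto)
        assert trace.metadata["n_unfolding_events"] == 2
        Lc = ta.contour_length_transform(trace)
        events = ta.detect_unfolding_events(trace, Lc)
        deltas = [e.delta_Lc for e in events if np.isfinite(e.delta_Lc)]
        assert len(deltas) == 2
        assert deltas[0] == pytest.approx(15.0, abs=1.0)
        assert deltas[1] == pytest.approx(16.0, abs=1.0)

    def test_peaks_below_threshold_ignored(self):
        # a 20 pN bump followed by a 200 pN rupture
        F = np.concatenate(
            [np.linspace(0, 20, 200), np.linspace(20, 5, 50), np.linspace(5, 200, 400), np.zeros(100)]
        )
        n = F.size
        tr = _trace(np.arange(n) / 1e4, np.linspace(0, 50, n), F)
        Lc = np.full(n, np.nan)
        events = ta.detect_unfolding_events(tr, Lc, min_peak_force=30.0)
        assert [e.index for e in events] == [649]


class TestFingerprint:
    @staticmethod
    def _events(deltas, rupture=True):
        evs = []
        Lc = 30.0
        for i, d in enumerate(deltas):
            evs.append(ta.UnfoldingEvent(100 * (i + 1), 50.0, Lc, Lc + d))
            Lc += d
        if rupture:
            evs.append(ta.UnfoldingEvent(1000, 400.0, Lc, float("nan")))
        return evs

    def test_matching_increments_accepted(self):
        assert ta.classify_fingerprint(self._events([15.0, 16.0]), (15, 16), 2.0)

    def test_single_increment_rejected(self):
        assert not ta.classify_fingerprint(self._events([15.0]), (15, 16), 2.0)

    def test_order_matters(self):
        assert not ta.classify_fingerprint(self._events([20.0, 15.0]), (15, 20), 2.0)

    def test_extra_spurious_increment_tolerated(self):
        assert ta.classify_fingerprint(self._events([15.0, 9.0, 16.0]), (15, 16), 2.0)

    def test_labeled_synthetic_set_precision_recall(self, tether, subunit_params):
        from pullgeom import cli_io

        cfg = sd.VariantConfig.default("1SA", fingerprint_attach_rate=0.5)
        traces = sd.generate_variant_dataset(cfg, 120, sd.AcquisitionProtocol(seed=17))
        stage = cli_io.TraceStageConfig()
        tp = fp = fn = 0
        for tr in traces:
            label = tr.metadata["specific"]
            ev = cli_io.analyze_trace(tr, stage) if tr.force.max() > 50 else None
            pred = ev is not None and ev.fingerprint_valid
            tp += pred and label
            fp += pred and not label
            fn += (not pred) and label
        precision = tp / max(tp + fp, 1)
        recall = tp / max(tp + fn, 1)
        assert precision >= 0.95
        assert recall >= 0.95


class TestExtractRupture:
    def test_noiseless_linear_ramp_exact(self):
        n = 500
        t = np.arange(n) / 1e4
        F = np.concatenate([1e4 * t[:400], np.zeros(100)])
        tr = _trace(t, np.linspace(0, 50, n), F)
        ev = ta.UnfoldingEvent(399, F[399], 30.0, float("nan"))
        rup = ta.extract_rupture(tr, [ev])
        assert rup.rupture_force == pytest.approx(1e4 * t[399])
        assert rup.loading_rate == pytest.approx(1e4, rel=1e-9)

    def test_loading_rate_within_10pct_on_noisy_strong_bond(
        self, strong_bond_traces, stage_config
    ):
        from pullgeom import cli_io

        errs = []
        for tr in strong_bond_traces:
            if not tr.metadata["ruptured"]:
                continue
            ev = cli_io.analyze_trace(tr, stage_config)
            if ev is None:
                continue
            truth = tr.metadata["true_loading_rate_pN_s"]
            errs.append(abs(ev.loading_rate - truth) / truth)
        assert len(errs) >= 15
        assert np.median(errs) < 0.10

    def test_trace_without_detachment_flagged(self):
        n = 500
        t = np.arange(n) / 1e4
        F = 1e4 * t  # never returns to baseline
        tr = _trace(t, np.linspace(0, 50, n), F)
        ev = ta.UnfoldingEvent(n - 1, F[-1], 30.0, float("nan"))
        with pytest.raises(ValueError, match="detachment"):
            ta.extract_rupture(tr, [ev])


class TestFilter:
    def test_threshold_contract(self):
        n = 100
        low = _trace(np.arange(n) / 1e4, np.zeros(n), np.full(n, 49.0))
        high = _trace(np.arange(n) / 1e4, np.zeros(n), np.full(n, 51.0))
        kept = ta.filter_traces([low, high], 50.0)
        assert kept == [high]

    def test_zero_threshold_keeps_everything(self):
        n = 10
        traces = [_trace(np.arange(n) / 1e4, np.zeros(n), np.full(n, v)) for v in (1.0, 5.0)]
        assert ta.filter_traces(traces, 0.0) == traces

    def test_background_set_kept_fraction_matches_mimic_rate(self):
        cfg = sd.VariantConfig.default("0SA", nonspecific_rate=0.1)
        traces = sd.generate_variant_dataset(cfg, 300, sd.AcquisitionProtocol(seed=5))
        kept = ta.filter_traces(traces, 50.0)
        # binomial n=300, p=0.1: mean 30, sd 5.2
        assert 10 <= len(kept) <= 50


def test_pipeline_determinism(tether, subunit_params, stage_config):
    """Same trace set and config produce an identical rupture table."""
    from pullgeom import cli_io

    traces = [
        sd.simulate_trace(tether, subunit_params["B"], sd.AcquisitionProtocol(seed=s))
        for s in range(5)
    ]
    rows1 = [cli_io.analyze_trace(t, stage_config) for t in traces]
    rows2 = [cli_io.analyze_trace(t, stage_config) for t in traces]
    for a, b in zip(rows1, rows2):
        assert (a is None) == (b is None)
        if a is not None:
            assert a.rupture_force == b.rupture_force
            assert a.loading_rate == b.loading_rate
            assert a.fingerprint_valid == b.fingerprint_valid
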