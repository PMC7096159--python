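"""Generators: WLC mechanics, Bell-Evans sampling, trace and trajectory synthesis."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import kstest

from pullgeom import synthetic_data as sd
from pullgeom.rupture_stats import BellEvansParams, modal_force
from pullgeom.wlc import wlc_contour_length, wlc_extension, wlc_force

KBT = 4.14


class TestWlc:
    def test_zero_extension_gives_zero_force(self):
        assert wlc_force(0.0, 60.0, 0.4, KBT) == 0.0

    def test_half_extension_closed_form(self):
        # s=1/2: bracket is 1/(4*(1/2)^2) - 1/4 + 1/2 = 5/4; prefactor 4.14/0.4
        assert wlc_force(30.0, 60.0, 0.4, KBT) == pytest.approx(12.9375, abs=1e-12)

    def test_extension_at_contour_length_raises(self):
        with pytest.raises(ValueError):
            wlc_force(60.0, 60.0, 0.4, KBT)

    @pytest.mark.parametrize("bad", [{"Lc": -1.0}, {"Lp": 0.0}, {"kBT": -2.0}])
    def test_nonpositive_parameters_raise(self, bad):
        kw = {"Lc": 60.0, "Lp": 0.4, "kBT": KBT}
        kw.update(bad)
        with pytest.raises(ValueError):
            wlc_force(10.0, **kw)

    @given(
        ext=st.floats(0.01, 0.95),
        Lc=st.floats(5.0, 200.0),
        Lp=st.floats(0.1, 2.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_force_strictly_increasing_in_extension(self, ext, Lc, Lp):
        x = ext * Lc
        f1 = wlc_force(x, Lc, Lp, KBT)
        f2 = wlc_force(min(x * 1.01, 0.999 * Lc), Lc, Lp, KBT)
        assert f2 > f1 >= 0

    def test_extension_inverts_force(self):
        for F in [1.0, 10.0, 120.0]:
            x = wlc_extension(F, 60.0, 0.4, KBT)
            assert wlc_force(x, 60.0, 0.4, KBT) == pytest.approx(F, rel=1e-9)

    def test_contour_length_inverts_forward_model(self):
        x = wlc_extension(35.0, 73.0, 0.38, KBT)
        assert wlc_contour_length(x, 35.0, 0.38, KBT) == pytest.approx(73.0, rel=1e-9)


class TestRuptureSampler:
    @staticmethod
    def _cdf(p, r):
        def cdf(F):
            a = p.k0 * p.kBT / (p.x_dagger * r)
            return 1.0 - np.exp(-a * np.expm1(np.asarray(F) * p.x_dagger / p.kBT))

        return cdf

    def test_matches_analytic_cdf_for_random_parameter_sets(self):
        rng = np.random.default_rng(101)
        for _ in range(5):
            p = BellEvansParams(
                k0=10 ** rng.uniform(-6, -1), x_dagger=rng.uniform(0.1, 1.0)
            )
            r = 10 ** rng.uniform(3, 5)
            F = sd.sample_rupture_forces_constant_rate(p, r, 2000, seed=int(rng.integers(2**31)))
            assert kstest(F, self._cdf(p, r)).statistic < 0.05

    def test_modal_force_increases_with_loading_rate(self):
        p = BellEvansParams(k0=1e-4, x_dagger=0.3)
        rates = np.geomspace(1e3, 1e4, 6)  # 10x span
        modes = []
        for i, r in enumerate(rates):
            F = sd.sample_rupture_forces_constant_rate(p, r, 4000, seed=i)
            hist, edges = np.histogram(F, bins=40)
            modes.append(edges[np.argmax(hist)])
        assert np.all(np.diff(modes) > 0)

    def test_reproducible_under_fixed_seed(self):
        p = BellEvansParams(k0=1e-3, x_dagger=0.5)
        a = sd.sample_rupture_forces_constant_rate(p, 1e4, 100, seed=5)
        b = sd.sample_rupture_forces_constant_rate(p, 1e4, 100, seed=5)
        assert np.array_equal(a, b)

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValueError):
            sd.sample_rupture_forces_constant_rate(
                BellEvansParams(k0=1.0, x_dagger=0.5), 0.0, 10
            )


class TestSimulateTrace:
    def test_no_events_gives_monotone_wlc_ramp(self, tether):
        quiet = sd.TetherModel(
            unfolding_steps=(
                sd.UnfoldingStep(delta_Lc=15.0, k0=1e-30, x_dagger=0.01),
            ),
        )
        bond = BellEvansParams(k0=1e-30, x_dagger=0.01)
        proto = sd.AcquisitionProtocol(force_noise_sd=0.0, retract_distance=40.0, seed=0)
        trace = sd.simulate_trace(quiet, bond, proto)
        assert trace.metadata["events"] == []
        assert np.all(np.diff(trace.force) >= 0)

    def test_fast_unfolding_steps_complete_below_50_pN(self):
        eager = sd.TetherModel(
            unfolding_steps=(
                sd.UnfoldingStep(delta_Lc=15.0, k0=500.0, x_dagger=0.5),
                sd.UnfoldingStep(delta_Lc=16.0, k0=500.0, x_dagger=0.5),
            ),
        )
        bond = BellEvansParams(k0=1e-30, x_dagger=0.01)
        proto = sd.AcquisitionProtocol(force_noise_sd=0.0, retract_distance=60.0, seed=1)
        trace = sd.simulate_trace(eager, bond, proto)
        unfolds = [e for e in trace.metadata["events"] if e["type"] == "unfold"]
        assert len(unfolds) == 2
        assert all(e["force_pN"] < 50.0 for e in unfolds)

    def test_event_log_bitwise_reproducible(self, tether, subunit_params):
        proto = sd.AcquisitionProtocol(seed=9)
        t1 = sd.simulate_trace(tether, subunit_params["D"], proto)
        t2 = sd.simulate_trace(tether, subunit_params["D"], proto)
        assert t1.metadata["events"] == t2.metadata["events"]
        assert np.array_equal(t1.force, t2.force)

    def test_noiseless_extension_solves_force_balance(self, tether, subunit_params):
        proto = sd.AcquisitionProtocol(force_noise_sd=0.0, seed=3)
        trace = sd.simulate_trace(tether, subunit_params["D"], proto)
        rup = trace.metadata["events"][-1]["index"]
        # before any event: single 30 nm segment; extension must invert the WLC
        first = trace.metadata["events"][0]["index"]
        sl = slice(10, first)
        expected = wlc_extension(trace.force[sl], 30.0, 0.38, tether.temperature_kBT)
        assert np.allclose(trace.extension[sl], expected, rtol=1e-9, atol=1e-9)
        # detached tail rides the piezo ramp at zero force
        assert np.all(trace.force[rup + 1 :] == 0.0)


class TestVariantDataset:
    def test_0SA_is_all_background(self):
        cfg = sd.VariantConfig.default("0SA")
        traces = sd.generate_variant_dataset(cfg, 50, sd.AcquisitionProtocol(seed=0))
        assert all(t.metadata["subunit"] == "background" for t in traces)
        assert all(not t.metadata["specific"] for t in traces)

    def test_0SA_mimic_rate_matches_configuration(self):
        cfg = sd.VariantConfig.default("0SA", nonspecific_rate=0.05)
        traces = sd.generate_variant_dataset(cfg, 400, sd.AcquisitionProtocol(seed=1))
        mimics = sum(bool(t.metadata["events"]) for t in traces)
        # binomial n=400, p=0.05: mean 20, sd 4.4
        assert 5 <= mimics <= 35

    def test_1SA_specific_traces_use_subunit_D(self):
        cfg = sd.VariantConfig.default("1SA", fingerprint_attach_rate=0.5)
        traces = sd.generate_variant_dataset(cfg, 60, sd.AcquisitionProtocol(seed=2))
        specific = [t for t in traces if t.metadata["specific"]]
        assert specific and all(t.metadata["subunit"] == "D" for t in specific)

    def test_4SA_subunit_frequencies_multinomial(self):
        cfg = sd.VariantConfig.default("4SA", fingerprint_attach_rate=1.0)
        traces = sd.generate_variant_dataset(cfg, 2000, sd.AcquisitionProtocol(seed=3))
        counts = {s: 0 for s in "ABCD"}
        for t in traces:
            counts[t.metadata["subunit"]] += 1
        n, p = 2000, 0.25
        sd3 = 3 * np.sqrt(n * p * (1 - p))
        for s in "ABCD":
            assert abs(counts[s] - n * p) < sd3

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            sd.VariantConfig(
                variant_label="1SA",
                subunit_params={"D": BellEvansParams(k0=1e-4, x_dagger=0.2)},
                subunit_weights={"D": 0.7},
            )

    def test_inaccessible_subunit_weight_rejected(self):
        with pytest.raises(ValueError, match="exposes"):
            sd.VariantConfig(
                variant_label="1SA",
                subunit_params={"D": BellEvansParams(k0=1e-4, x_dagger=0.2)},
                subunit_weights={"A": 1.0},
            )


class TestCorrelatedTrajectory:
    def test_identity_target_gives_independent_nodes(self):
        spec = sd.CorrelationSpec(n_nodes=4, target_correlation=np.eye(4))
        traj = sd.generate_correlated_trajectory(spec, 10_000, seed=4)
        disp = traj.coordinates - traj.coordinates.mean(axis=0)
        flat = disp.transpose(0, 2, 1).reshape(-1, 4)
        C = np.corrcoef(flat.T)
        off = C[~np.eye(4, dtype=bool)]
        assert np.abs(off).max() < 0.05

    def test_programmed_pair_correlation_recovered(self):
        C = np.eye(3)
        C[0, 1] = C[1, 0] = 0.9
        spec = sd.CorrelationSpec(n_nodes=3, target_correlation=C)
        traj = sd.generate_correlated_trajectory(spec, 10_000, seed=5)
        disp = traj.coordinates - traj.coordinates.mean(axis=0)
        c01 = np.corrcoef(
            disp[:, 0, :].ravel(), disp[:, 1, :].ravel()
        )[0, 1]
        assert c01 == pytest.approx(0.9, abs=0.05)

    def test_single_frame_rejected(self):
        spec = sd.CorrelationSpec(n_nodes=3, target_correlation=np.eye(3))
        with pytest.raises(ValueError, match="fewer than 2 frames"):
            sd.generate_correlated_trajectory(spec, 1, seed=0)

    def test_non_psd_target_rejected(self):
        C = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
        with pytest.raises(ValueError, match="positive semidefinite"):
            sd.CorrelationSpec(n_nodes=3, target_correlation=C)


class TestToyPull:
    def test_zero_velocity_no_load_no_events(self):
        model = sd.ToyPullModel(pull_velocity=0.0)
        traj, force = sd.generate_smd_pull_trajectory(model, 2000, seed=6)
        assert traj.metadata["loop_open_frame"] is None
        assert traj.metadata["rupture_frame"] is None
        # force fluctuates about zero on the thermal scale sqrt(kBT*k_s)
        # (~54 pN) without any systematic ramp toward the event thresholds
        assert (force > 0).any() and (force < 0).any()
        assert abs(np.mean(force)) < 2 * 54.0
        assert np.abs(force).max() < model.loop_open_force

    def test_infinite_loop_threshold_keeps_distance_stationary(self):
        model = sd.ToyPullModel(loop_open_force=np.inf, detach_force=np.inf)
        traj, _ = sd.generate_smd_pull_trajectory(model, 1000, seed=7)
        li, lj = model.loop_nodes
        d = np.linalg.norm(
            traj.coordinates[:, li, :] - traj.coordinates[:, lj, :], axis=1
        )
        first, second = d[:500].mean(), d[500:].mean()
        assert abs(second - first) < 0.5  # Å; no programmed step

    def test_loop_opening_precedes_rupture(self, toy_pull):
        traj, _ = toy_pull
        md = traj.metadata
        assert md["loop_open_frame"] is not None and md["rupture_frame"] is not None
        assert md["loop_open_frame"] < md["rupture_frame"]

    def test_bitwise_reproducible(self):
        model = sd.ToyPullModel()
        t1, f1 = sd.generate_smd_pull_trajectory(model, 300, seed=8)
        t2, f2 = sd.generate_smd_pull_trajectory(model, 300, seed=8)
        assert np.array_equal(t1.coordinates, t2.coordinates)
        assert np.array_equal(f1, f2)
        assert t1.metadata["loop_open_frame"] == t2.metadata["loop_open_frame"]


def test_modal_force_helper_round_trip():
    p = BellEvansParams.from_modal_force(440.0, 0.19, 5e4)
    assert modal_force(p, 5e4) == pytest.approx(440.0, rel=1e-12)
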