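"""Wilson-Cowan dynamics: transfer function, fixed points, integration."""

import numpy as np
import pytest

import netstim as ns
from netstim.dynamics import sigmoid_ceiling


class TestSigmoid:
    def test_zero_at_origin(self):
        for a, th in [(1.3, 4.0), (2.0, 3.7), (0.5, 1.0)]:
            assert ns.sigmoid_transfer(0.0, a, th) == pytest.approx(0.0, abs=1e-15)

    def test_value_at_threshold(self):
        # 0.5 - 1/(1 + e^{1.3*4})
        expected = 0.5 - 1.0 / (1.0 + np.exp(5.2))
        assert ns.sigmoid_transfer(4.0, 1.3, 4.0) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.49451, abs=5e-6)

    def test_asymptote(self):
        expected = 1.0 - 1.0 / (1.0 + np.exp(5.2))
        assert ns.sigmoid_transfer(1e3, 1.3, 4.0) == pytest.approx(expected, rel=1e-12)
        assert sigmoid_ceiling(1.3, 4.0) == pytest.approx(expected, rel=1e-12)

    def test_monotone_increasing(self):
        x = np.linspace(-10, 10, 201)
        y = ns.sigmoid_transfer(x, 1.3, 4.0)
        assert np.all(np.diff(y) > 0)

    def test_invalid_slope(self):
        with pytest.raises(ValueError, match="slope"):
            ns.sigmoid_transfer(0.0, -1.0, 4.0)


class TestFixedPoints:
    """The three drive regimes of an uncoupled oscillator."""

    def test_no_drive_low_fixed_point(self, params_deterministic):
        fps = ns.find_fixed_points(params_deterministic, P=0.0)
        stable = [f for f in fps if f.stable]
        assert stable
        assert min(f.E for f in stable) < 0.05

    def test_moderate_drive_no_stable_attractor(self, params_deterministic):
        fps = ns.find_fixed_points(params_deterministic, P=1.25)
        assert all(not f.stable for f in fps)

    def test_high_drive_high_fixed_point(self, params_deterministic):
        low = min(
            f.E for f in ns.find_fixed_points(params_deterministic, P=0.0) if f.stable
        )
        high_fps = [
            f for f in ns.find_fixed_points(params_deterministic, P=2.5) if f.stable
        ]
        assert high_fps
        assert max(f.E for f in high_fps) > low

    def test_fixed_points_are_roots_of_the_flow(self, params_deterministic):
        from netstim.dynamics import _uncoupled_rhs

        for P in (0.0, 1.25, 2.5):
            for f in ns.find_fixed_points(params_deterministic, P=P):
                fE, fI = _uncoupled_rhs(f.E, f.I, params_deterministic, P)
                assert abs(fE) < 1e-9 and abs(fI) < 1e-9


class TestSimulation:
    def test_relaxes_to_low_fixed_point(self, params_deterministic):
        fps = [f for f in ns.find_fixed_points(params_deterministic, P=0.0) if f.stable]
        target = min(fps, key=lambda f: f.E)
        res = ns.simulate_single(params_deterministic, P=0.0, duration=2000.0)
        assert abs(res.E[0, -1] - target.E) < 1e-6
        assert abs(res.I[0, -1] - target.I) < 1e-6

    def test_sustained_oscillation_at_moderate_drive(self, params_deterministic):
        res = ns.simulate_single(params_deterministic, P=1.25, duration=4000.0)
        # peak-to-peak amplitude must not decay over the last second
        last = res.E[0, -10000:]
        prev = res.E[0, -20000:-10000]
        assert np.ptp(last) > 0.05
        assert np.ptp(last) > 0.9 * np.ptp(prev)

    def test_disconnected_nodes_match_single_simulation(self, params_deterministic):
        single = ns.simulate_single(params_deterministic, P=0.7, duration=500.0)
        A = np.zeros((2, 2))
        d = np.full((2, 2), 3.0)
        np.fill_diagonal(d, 0.0)
        proto = ns.StimulusProtocol(baseline=0.7)
        pair = ns.simulate_network(
            A, d, params_deterministic.with_(c5=0.0), proto, 500.0
        )
        for k in range(2):
            assert np.array_equal(pair.E[k], single.E[0])

    def test_bitwise_deterministic_with_noise(self, small_connectome):
        net, regions = small_connectome
        delays = ns.compute_delays(regions.coords)
        p = ns.WCParams(c5=1.0)
        proto = ns.StimulusProtocol(target_region=3, onset=100.0, offset=200.0)
        a = ns.simulate_network(net, delays, p, proto, 300.0, seed=11)
        b = ns.simulate_network(net, delays, p, proto, 300.0, seed=11)
        assert np.array_equal(a.E, b.E) and np.array_equal(a.I, b.I)
        c = ns.simulate_network(net, delays, p, proto, 300.0, seed=12)
        assert not np.array_equal(c.E, a.E)

    def test_step_halving_changes_endpoint_little(self, params_deterministic):
        r1 = ns.simulate_single(params_deterministic, P=0.0, duration=800.0, dt=0.1)
        r2 = ns.simulate_single(params_deterministic, P=0.0, duration=800.0, dt=0.05)
        assert abs(r1.E[0, -1] - r2.E[0, -1]) < 1e-3

    def test_permutation_equivariance(self, small_connectome, params_deterministic):
        net, regions = small_connectome
        delays = ns.compute_delays(regions.coords)
        perm = np.random.default_rng(0).permutation(net.n_regions)
        p = params_deterministic.with_(c5=0.8)
        proto = ns.StimulusProtocol(target_region=5, onset=50.0, offset=150.0)
        base = ns.simulate_network(net.weights, delays.tau_d, p, proto, 200.0)
        proto_p = ns.StimulusProtocol(
            target_region=int(np.flatnonzero(perm == 5)[0]), onset=50.0, offset=150.0
        )
        permuted = ns.simulate_network(
            net.weights[np.ix_(perm, perm)],
            delays.tau_d[np.ix_(perm, perm)],
            p,
            proto_p,
            200.0,
        )
        assert np.allclose(permuted.E, base.E[perm], atol=1e-12)

    def test_every_node_reaches_same_low_fixed_point(self, params_deterministic):
        for n in (2, 5):
            A = np.zeros((n, n))
            d = np.full((n, n), 2.0)
            np.fill_diagonal(d, 0.0)
            res = ns.simulate_network(
                A, d, params_deterministic.with_(c5=0.0),
                ns.StimulusProtocol(), 1500.0,
            )
            assert np.ptp(res.E[:, -1]) < 1e-12
            assert np.all(res.E[:, -1] < 1e-4)

    def test_mean_rate_nondecreasing_in_coupling_before_transition(
        self, small_connectome, params_deterministic
    ):
        net, regions = small_connectome
        delays = ns.compute_delays(regions.coords)
        means = []
        for c5 in (0.0, 0.3, 0.6):
            res = ns.simulate_network(
                net, delays, params_deterministic.with_(c5=c5),
                ns.StimulusProtocol(baseline=0.4), 600.0,
            )
            means.append(res.E[:, -2000:].mean())
        assert means[0] <= means[1] + 1e-9 <= means[2] + 2e-9

    def test_coarse_dt_rejected(self, params_deterministic):
        with pytest.raises(ValueError, match="tau/10"):
            ns.simulate_single(params_deterministic, P=0.0, duration=10.0, dt=1.0)

    def test_dt_exceeding_min_delay_rejected(self, small_connectome):
        net, regions = small_connectome
        delays = ns.compute_delays(regions.coords, velocity=1000.0)  # tiny delays
        with pytest.raises(ValueError, match="delay"):
            ns.simulate_network(
                net, delays, ns.WCParams(), ns.StimulusProtocol(), 10.0, dt=0.1
            )

    def test_invalid_protocol_rejected(self):
        with pytest.raises(ValueError, match="onset"):
            ns.StimulusProtocol(target_region=0, onset=100.0, offset=50.0)


class TestFrequencyEstimation:
    def test_pure_sinusoid(self):
        t = np.arange(0, 3000.0, 0.1)
        x = 0.1 * np.sin(2 * np.pi * 20.0 * t / 1000.0)
        est = ns.estimate_dominant_frequency(x, 0.1, discard=500.0)
        assert est.oscillatory
        assert est.frequency_hz == pytest.approx(20.0, abs=0.5)
        assert est.consistent

    def test_constant_trace_flagged_non_oscillatory(self):
        est = ns.estimate_dominant_frequency(np.full(30000, 0.2), 0.1)
        assert est.frequency_hz == 0.0
        assert not est.oscillatory

    def test_limit_cycle_in_beta_band(self, params_deterministic):
        """The uncoupled oscillator at P=1.25 oscillates in the 15-30 Hz band,
        with spectral and inter-peak estimates in agreement."""
        res = ns.simulate_single(params_deterministic, P=1.25, duration=4000.0)
        est = ns.estimate_dominant_frequency(res.E[0], 0.1, discard=1000.0)
        assert est.oscillatory and est.consistent
        assert 15.0 < est.frequency_hz < 30.0
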