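"""Transition sweep, ICC reproducibility, stimulation campaign, aggregation."""

import numpy as np
import pytest

import netstim as ns
from netstim.connectome import StructuralNetwork
from netstim.experiments import (
    find_transition_point,
    icc,
    stimulation_campaign,
    system_aggregate,
    system_aggregate_arrays,
)

COARSE_GRID = np.round(np.arange(0.6, 2.01, 0.2), 10)


@pytest.fixture(scope="module")
def uniform_net():
    """Small single-system network with a collective transition."""
    net, rs = ns.generate_connectome(
        n_regions=20, n_systems=1, seed=3, density_profile=np.array([[0.35]])
    )
    return net, rs, ns.compute_delays(rs.coords)


def anova_mean_squares_oracle(x):
    """Textbook two-way ANOVA mean squares via explicit loops."""
    I, J = x.shape
    gm = x.sum() / (I * J)
    rms = sms = ems = 0.0
    for i in range(I):
        rms += J * (x[i].sum() / J - gm) ** 2
    for j in range(J):
        sms += I * (x[:, j].sum() / I - gm) ** 2
    for i in range(I):
        for j in range(J):
            ems += (x[i, j] - x[i].sum() / J - x[:, j].sum() / I + gm) ** 2
    return rms / (I - 1), sms / (J - 1), ems / ((I - 1) * (J - 1))


class TestICC:
    def test_mean_squares_match_explicit_oracle(self, rng):
        x = rng.standard_normal((6, 4))
        rep = icc(x)
        rms, sms, ems = anova_mean_squares_oracle(x)
        assert rep.subject_ms == pytest.approx(rms, abs=1e-10)
        assert rep.scan_ms == pytest.approx(sms, abs=1e-10)
        assert rep.error_ms == pytest.approx(ems, abs=1e-10)
        denom = 4 * sms + 6 * rms + (24 - 6 - 4) * ems
        assert rep.icc_between == pytest.approx(4 * (sms - ems) / denom, abs=1e-12)
        assert rep.icc_within == pytest.approx(6 * (rms - ems) / denom, abs=1e-12)

    def test_mean_squares_match_statsmodels(self, rng):
        import pandas as pd
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        x = rng.standard_normal((5, 3))
        I, J = x.shape
        df = pd.DataFrame(
            {
                "y": x.ravel(),
                "subject": np.repeat(np.arange(I), J).astype(str),
                "scan": np.tile(np.arange(J), I).astype(str),
            }
        )
        tab = sm.stats.anova_lm(ols("y ~ C(subject) + C(scan)", data=df).fit(), typ=2)
        ms = tab["sum_sq"] / tab["df"]
        rep = icc(x)
        assert rep.subject_ms == pytest.approx(ms["C(subject)"], rel=1e-10)
        assert rep.scan_ms == pytest.approx(ms["C(scan)"], rel=1e-10)
        assert rep.error_ms == pytest.approx(ms["Residual"], rel=1e-10)

    def test_identical_scans_distinct_subjects(self):
        """Perfect within-subject reproducibility: ICC_W = 1, no within variance."""
        x = np.repeat(np.array([[1.0], [2.0], [5.0], [9.0]]), 3, axis=1)
        rep = icc(x)
        assert rep.icc_within == pytest.approx(1.0)
        assert rep.var_within == 0.0
        assert rep.icc_between == pytest.approx(0.0)
        assert rep.var_between > 0

    def test_constant_table_flagged_degenerate(self):
        with pytest.warns(UserWarning, match="undefined"):
            rep = icc(np.full((4, 3), 2.5))
        assert rep.degenerate
        assert np.isnan(rep.icc_between) and np.isnan(rep.icc_within)
        assert rep.var_between == 0.0 and rep.var_within == 0.0

    def test_recovers_generating_intraclass_correlation(self):
        """Monte-Carlo parameter recovery on the random-effects model.

        Subjects drawn with between-SD 0.12 and within-SD 0.04 (I=8, J=3)
        have a generating intraclass correlation of 0.9; over 200 replicates
        the within-subject ICC recovers it to +-0.15.
        """
        gen = np.random.default_rng(2024)
        sd_b, sd_w, I, J = 0.12, 0.04, 8, 3
        truth = sd_b**2 / (sd_b**2 + sd_w**2)
        estimates = []
        for _ in range(200):
            subj = gen.normal(1.25, sd_b, size=(I, 1))
            x = subj + gen.normal(0.0, sd_w, size=(I, J))
            estimates.append(icc(x).icc_within)
        assert abs(np.mean(estimates) - truth) < 0.15

    def test_unbalanced_or_tiny_tables_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            icc(np.zeros((1, 3)))
        bad = np.ones((3, 3))
        bad[0, 0] = np.nan
        with pytest.raises(ValueError, match="balanced"):
            icc(bad)


class TestTransition:
    def test_negligible_coupling_finds_no_transition(self, uniform_net):
        net, rs, delays = uniform_net
        weak = StructuralNetwork(weights=net.weights * 1e-6, regions=rs)
        with pytest.warns(UserWarning, match="no oscillatory transition"):
            scan = find_transition_point(weak, delays, ns.WCParams(), seed=9)
        assert not scan.found
        assert scan.c5_transition is None and scan.c5_operating is None

    def test_deterministic_per_seed(self, uniform_net):
        net, rs, delays = uniform_net
        kw = dict(
            c5_grid=COARSE_GRID, seed=9, sim_seconds=0.5, stabilize_seconds=0.5
        )
        a = find_transition_point(net, delays, ns.WCParams(), **kw)
        b = find_transition_point(net, delays, ns.WCParams(), **kw)
        assert a.c5_transition == b.c5_transition
        assert np.array_equal(a.mean_rate, b.mean_rate)

    def test_operating_point_immediately_precedes_transition(self, uniform_net):
        net, rs, delays = uniform_net
        scan = find_transition_point(
            net, delays, ns.WCParams(), c5_grid=COARSE_GRID, seed=9,
            sim_seconds=0.5, stabilize_seconds=0.5,
        )
        assert scan.found
        g = scan.transition_index
        assert scan.c5_transition == COARSE_GRID[g]
        assert scan.c5_operating == COARSE_GRID[g - 1]

    def test_transition_shifts_earlier_with_stronger_weights(self, uniform_net):
        """Scaling all weights up cannot delay the oscillatory transition."""
        net, rs, delays = uniform_net
        points = []
        for s in (0.8, 1.0, 1.3):
            scaled = StructuralNetwork(weights=net.weights * s, regions=rs)
            scan = find_transition_point(
                scaled, delays, ns.WCParams(), c5_grid=COARSE_GRID, seed=9,
                sim_seconds=0.5, stabilize_seconds=0.5,
            )
            assert scan.found
            points.append(scan.c5_transition)
        assert points[0] >= points[1] >= points[2]

    def test_invalid_grid_rejected(self, uniform_net):
        net, rs, delays = uniform_net
        with pytest.raises(ValueError, match="increasing"):
            find_transition_point(
                net, delays, ns.WCParams(), c5_grid=np.array([1.5, 1.0]), seed=0
            )


@pytest.fixture(scope="module")
def tiny_campaign_setup():
    net, rs = ns.generate_connectome(
        n_regions=10, n_systems=1, seed=5, density_profile=np.array([[0.4]])
    )
    return net, rs, ns.compute_delays(rs.coords)


class TestCampaign:
    def test_null_stimulation_stays_at_noise_floor(self, tiny_campaign_setup):
        net, rs, delays = tiny_campaign_setup
        res = stimulation_campaign(
            net, delays, ns.WCParams(), 1.0, seed=3, stim_amplitude=0.0
        )
        assert len(res.outcomes) == net.n_regions
        for o in res.outcomes:
            assert o.functional_effect < 0.15

    def test_pipeline_permutation_equivariance(self, tiny_campaign_setup):
        """Stimulation statistics are equivariant under region relabeling.

        Noise-free dynamics with an oscillatory baseline drive, so both
        windows carry variance and the whole pipeline (simulation -> FC ->
        effect statistics) is deterministic.
        """
        net, rs, delays = tiny_campaign_setup
        params = ns.WCParams(sigma=0.0, c5=0.2)
        perm = np.random.default_rng(8).permutation(net.n_regions)

        def outcomes(weights, tau_d, target):
            proto = ns.StimulusProtocol(
                target_region=target, amplitude=0.9, onset=2000.0, offset=3000.0,
                baseline=1.25,
            )
            res = ns.simulate_network(weights, tau_d, params, proto, 3000.0)
            before = ns.functional_connectivity(res.window(1000.0, 2000.0), 0.1)
            during = ns.functional_connectivity(res.window(2000.0, 3000.0), 0.1)
            return (
                ns.functional_effect(before, during),
                ns.structural_effect(weights, before, during),
                ns.fractional_activation(before, during),
            )

        target = 4
        base = outcomes(net.weights, delays.tau_d, target)
        permuted = outcomes(
            net.weights[np.ix_(perm, perm)],
            delays.tau_d[np.ix_(perm, perm)],
            int(np.flatnonzero(perm == target)[0]),
        )
        assert permuted == pytest.approx(base, abs=1e-10)

    def test_campaign_deterministic(self, tiny_campaign_setup):
        net, rs, delays = tiny_campaign_setup
        a = stimulation_campaign(
            net, delays, ns.WCParams(), 1.0, seed=4, regions_to_stimulate=[0, 3]
        )
        b = stimulation_campaign(
            net, delays, ns.WCParams(), 1.0, seed=4, regions_to_stimulate=[0, 3]
        )
        assert a.outcomes[1].functional_effect == b.outcomes[1].functional_effect
        assert np.array_equal(a.outcomes[0].fc_during.fc, b.outcomes[0].fc_during.fc)


class TestSystemAggregate:
    def test_complete_graph_density_one(self):
        net, rs = ns.generate_connectome(
            n_regions=8, n_systems=2, seed=0, density_profile=np.ones((2, 2))
        )
        _, density = system_aggregate_arrays(
            net, rs, np.arange(8), np.zeros(8), np.zeros(8)
        )
        assert np.allclose(density.to_numpy(), 1.0)

    def test_disconnected_systems_zero_between_density(self):
        rs = ns.RegionSet(
            labels=[f"r{i}" for i in range(4)],
            coords=np.arange(12.0).reshape(4, 3),
            volumes=np.ones(4),
            systems=["a", "a", "b", "b"],
        )
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 1.0
        w[2, 3] = w[3, 2] = 2.0
        net = StructuralNetwork(weights=w, regions=rs)
        _, density = system_aggregate_arrays(
            net, rs, np.arange(4), np.zeros(4), np.zeros(4)
        )
        assert density.loc["a", "b"] == 0.0
        assert density.loc["a", "a"] == 1.0

    def test_summary_mean_and_sem(self):
        rs = ns.RegionSet(
            labels=["r0", "r1", "r2", "r3"],
            coords=np.arange(12.0).reshape(4, 3),
            volumes=np.ones(4),
            systems=["a", "a", "a", "a"],
        )
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 1.0
        net = StructuralNetwork(weights=w, regions=rs)
        fe = np.array([1.0, 2.0, 3.0, 4.0])
        summary, _ = system_aggregate_arrays(net, rs, np.arange(4), fe, fe * 0.1)
        assert summary.loc["a", "functional_effect_mean"] == pytest.approx(2.5)
        assert summary.loc["a", "functional_effect_sem"] == pytest.approx(
            np.std(fe, ddof=1) / 2.0
        )

    def test_singleton_system_flagged(self):
        rs = ns.RegionSet(
            labels=["r0", "r1", "r2"],
            coords=np.arange(9.0).reshape(3, 3),
            volumes=np.ones(3),
            systems=["a", "a", "b"],
        )
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.0
        net = StructuralNetwork(weights=w, regions=rs)
        with pytest.warns(UserWarning, match="single"):
            summary, _ = system_aggregate_arrays(
                net, rs, np.arange(3), np.ones(3), np.ones(3)
            )
        assert np.isnan(summary.loc["b", "functional_effect_sem"])

    def test_wrapper_uses_campaign_network(self, tiny_campaign_setup):
        net, rs, delays = tiny_campaign_setup
        res = stimulation_campaign(
            net, delays, ns.WCParams(), 1.0, seed=3, regions_to_stimulate=range(4)
        )
        summary, density = system_aggregate(res, rs)
        assert np.allclose(density.to_numpy(), res.density_table.to_numpy())
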