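"""Network construction, stimulus protocols, simulation engine properties."""

import numpy as np
import pytest

from corticowave.dynamics import fi_rate
from corticowave.network import (
    NetworkConfig,
    build_network,
    make_dc_stimulus,
    make_random_step_stimulus,
    phase_lag,
    simulate,
    source_phase_lags,
)


class TestBuildNetwork:
    def test_default_node_count(self, default_network):
        # 3 areas x 5 laminar nodes + two input-layer pairs
        assert default_network.n_nodes == 19
        assert sum(k == "ig" for k in default_network.node_kinds) == 3

    def test_pulvinar_adds_relay_nodes(self):
        net = build_network(NetworkConfig(pulvinar_enabled=True))
        assert net.n_nodes == 21
        tbl = net.connection_table()
        for a in (1, 2):
            assert (tbl.target == f"Pul{a}").sum() == 1
            assert (tbl.source == f"Pul{a}").sum() == 1

    def test_two_hemispheres_double_without_crossing(self):
        net1 = build_network(NetworkConfig())
        net2 = build_network(NetworkConfig(hemispheres=2))
        assert net2.n_nodes == 2 * net1.n_nodes
        assert net2.n_connections == 2 * net1.n_connections
        tbl = net2.connection_table()
        for _, row in tbl.iterrows():
            assert row.source[:2] == row.target[:2]  # same L./R. stream

    def test_table_wiring(self, default_network):
        tbl = default_network.connection_table().set_index(["source", "target"])
        assert tbl.loc[("Cx1.L4IN", "Cx1.L4X"), "weight"] == -1.2
        assert tbl.loc[("Cx1.L4IN", "Cx1.L4X"), "class"] == "slow_inh"
        assert tbl.loc[("Cx1.SGX", "Cx2.L4X"), "weight"] == 2.0
        assert tbl.loc[("Cx1.SGX", "Cx2.L4X"), "delay"] == pytest.approx(0.012)
        assert tbl.loc[("Cx2.IGIB", "Cx1.SGIN"), "weight"] == 1.5
        assert tbl.loc[("Cx2.IGIB", "Cx1.IGIB"), "class"] == "slow_exc"
        assert tbl.loc[("Cx1.IGIB", "Cx1.IGIB"), "class"] == "ig_self_exc"

    def test_rejects_tiny_hierarchy(self):
        with pytest.raises(ValueError):
            NetworkConfig(n_areas=1)


class TestStimulusProtocols:
    def test_dc_step_window(self):
        stim = make_dc_stimulus(1.2, 1.0, 2.0)
        wf = stim.waveform(3000)
        assert np.all(wf[:1000] == 0.0)
        assert np.all(wf[1000:2000] == 1.2)
        assert np.all(wf[2000:] == 0.0)

    def test_zero_amplitude_is_rest(self):
        assert np.all(make_dc_stimulus(0.0, 0.0, 3.0).waveform(3000) == 0.0)

    def test_random_step_structure(self):
        stim = make_random_step_stimulus(1.5, 10.0, seed=0)
        wf = stim.waveform(10000)
        assert set(np.unique(wf)) <= {0.0, 1.5}
        # constant within 100 ms blocks
        blocks = wf.reshape(-1, 100)
        assert np.all(blocks.max(axis=1) == blocks.min(axis=1))

    def test_random_step_autocorrelation_vanishes_beyond_block(self):
        wf = make_random_step_stimulus(1.0, 200.0, seed=1).waveform(200_000)
        x = wf - wf.mean()
        ac = np.correlate(x[:-150], x[150:], mode="valid")[0] / (
            len(x) * x.var()
        )
        assert abs(ac) < 0.05


class TestSimulation:
    def test_seed_determinism_bitwise(self, default_network):
        t1 = simulate(default_network, None, 1.5, seed=9, batch=2)
        t2 = simulate(default_network, None, 1.5, seed=9, batch=2)
        assert np.array_equal(t1.rates, t2.rates)

    def test_impulse_delay_correctness(self):
        # a current impulse at Cx1.SGX must first perturb Cx2.L4X exactly
        # one inter-areal delay (12 ms) later
        cfg = NetworkConfig(sigma_ou=0.0, ilpr_noise_max=0.0, ig_passive_relay=True)
        net = build_network(cfg)
        base = simulate(net, None, 2.0, seed=0)
        imp = np.zeros(2000)
        imp[1000] = 0.5
        pert = simulate(net, None, 2.0, seed=0,
                        external_currents={"Cx1.SGX": imp})
        l4x2 = net.index["Cx2.L4X"]
        diff = np.abs(pert.rates[0, :, l4x2] - base.rates[0, :, l4x2])
        first = int(np.flatnonzero(diff > 1e-12)[0])
        assert first == 1000 + 12

    def test_pulvinar_zero_weight_is_bitwise_noop(self):
        cortex = build_network(NetworkConfig())
        with_pul = build_network(NetworkConfig(pulvinar_enabled=True, w_pul_l4x=0.0))
        t1 = simulate(cortex, None, 1.5, seed=3)
        t2 = simulate(with_pul, None, 1.5, seed=3)
        cols = [with_pul.index[n] for n in cortex.node_names]
        assert np.array_equal(t1.rates, t2.rates[:, :, cols])

    def test_rates_bounded_at_rest(self, rest_traces):
        assert np.all(rest_traces.rates >= 0.0)
        assert np.all(rest_traces.rates < 1e4)

    def test_rest_state_layout(self, rest_traces):
        # pacemakers oscillate, supragranular nodes largely silent at rest
        for a in (1, 2, 3):
            ig = rest_traces.node(f"Cx{a}.IGIB")[:, 1000:]
            sg = rest_traces.node(f"Cx{a}.SGX")[:, 1000:]
            assert ig.mean() > 5.0
            assert ig.std() > 1.0
            assert sg.mean() < 2.0

    def test_passive_relay_without_pacemakers_settles(self):
        # replacing the pacemakers by rate nodes and removing all noise
        # leaves a fixed point consistent with the FI-curve equilibrium
        cfg = NetworkConfig(sigma_ou=0.0, ilpr_noise_max=0.0, ig_passive_relay=True)
        net = build_network(cfg)
        tr = simulate(net, None, 4.0, seed=0)
        late = tr.rates[0, -200:, :]
        assert np.all(late.std(axis=0) < 1e-6)
        # isolated-at-rest nodes (e.g. ILSt.X) sit at the base-current rate
        # minus their recurrent slow inhibition, solved self-consistently
        ilst = late[-1, net.index["ILSt.X"]]
        assert 0.0 <= ilst <= fi_rate(0.33)

    def test_hdf5_round_trip(self, rest_traces, tmp_path):
        path = str(tmp_path / "traces.h5")
        rest_traces.save(path)
        from corticowave.network import SimulationTraces

        loaded = SimulationTraces.load(path)
        assert loaded.node_names == rest_traces.node_names
        np.testing.assert_allclose(loaded.rates, rest_traces.rates, rtol=1e-6)
        assert loaded.config.n_areas == 3


class TestSourcePhaseLags:
    def test_duplicated_trace_has_zero_lag(self):
        t = np.arange(5000) / 1000.0
        x = np.sin(2 * np.pi * 10 * t) + 0.01 * np.random.default_rng(0).standard_normal(5000)
        assert abs(phase_lag(x, x)) < 1e-12

    def test_imposed_lag_recovered(self):
        t = np.arange(6000) / 1000.0
        lag = 0.7  # rad
        x1 = np.sin(2 * np.pi * 10 * t + lag)
        x2 = np.sin(2 * np.pi * 10 * t)
        est = phase_lag(x1, x2)
        assert est == pytest.approx(lag, abs=0.05)

    def test_rest_is_backward_gradient(self, rest_traces):
        lags = source_phase_lags(rest_traces)
        # higher areas lead at rest: lower-minus-higher phase is negative
        assert lags["IGIB"] < -0.5

    def test_stimulation_reverses_gradient(self, default_network):
        from corticowave.network import make_dc_stimulus

        tr = simulate(default_network, make_dc_stimulus(1.6, 1.0, 6.0), 6.0,
                      seed=5, batch=2)
        i0 = 2000
        sub = tr.rates[:, i0:, :]
        stim_traces = type(tr)(sub, tr.node_names, tr.stimulus[i0:], tr.dt,
                               tr.config, tr.seed)
        lags = source_phase_lags(stim_traces, burn_in=0.0)
        assert lags["SGX"] > 0.5  # lower areas lead under stimulation
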