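"""Channel kinetics, density tables, active simulation and CV estimators."""

import numpy as np
import pytest

from periaxon.cable_core import SolverConfig, Stimulus, axon_record_sites, discretize
from periaxon.channels import (DEFAULT_DENSITIES, ChannelDensityTable,
                               ChannelModel, GateSpec, build_active_model,
                               conduction_velocity, default_channels,
                               load_channels_yaml, onset_time_d3v,
                               onset_time_dvdt_threshold, sensitivity_sweep,
                               simulate_ap)

from conftest import soma_step


def test_gate_steady_state_and_tau():
    g = GateSpec(power=3, v_half=-38.0, k=6.0, tau_base=0.03, tau_amp=0.2,
                 tau_vhalf=-38.0, tau_width=14.0)
    assert g.inf(np.array([-38.0]))[0] == pytest.approx(0.5)
    assert g.inf(np.array([40.0]))[0] > 0.99
    # q speeds kinetics up: tau shrinks
    assert g.tau(np.array([-38.0]), q=2.0)[0] == pytest.approx(
        g.tau(np.array([-38.0]), q=1.0)[0] / 2.0)


def test_q10_rate_scale():
    m = default_channels()["Nav"]
    assert m.rate_scale(m.t_ref_C) == pytest.approx(1.0)
    assert m.rate_scale(m.t_ref_C + 10.0) == pytest.approx(m.q10)


def test_gate_advance_relaxes_to_steady_state():
    m = default_channels()["Kv1"]
    V = np.array([-20.0])
    s = m.init_state(np.array([-75.0]))
    s = m.advance(s, V, dt_ms=1e3, q=1.0)   # >> tau: fully relaxed
    np.testing.assert_allclose(s, m.init_state(V), atol=1e-12)


def test_channels_yaml_round_trip(tmp_path):
    p = tmp_path / "chan.yaml"
    p.write_text(
        "channels:\n"
        "  - name: NavX\n"
        "    erev_mV: 55.0\n"
        "    q10: 3.0\n"
        "    gates:\n"
        "      - {power: 3, v_half: -38.0, k: 6.0, tau_base: 0.03,\n"
        "         tau_amp: 0.2, tau_vhalf: -38.0, tau_width: 14.0}\n"
    )
    chans = load_channels_yaml(p)
    assert chans["NavX"].erev_mV == 55.0
    assert chans["NavX"].q10 == 3.0
    assert chans["NavX"].gates[0].power == 3


def test_density_table_validation():
    with pytest.raises(ValueError):
        ChannelDensityTable({"myelin": {"Nav": 1.0}})
    with pytest.raises(ValueError):
        ChannelDensityTable({"node": {"Nav": -5.0}})
    t = ChannelDensityTable()
    t2 = t.scaled("internode", "Nav", 0.5)
    assert t2.densities["internode"]["Nav"] == pytest.approx(
        DEFAULT_DENSITIES["internode"]["Nav"] * 0.5)
    assert t.densities["internode"]["Nav"] == DEFAULT_DENSITIES["internode"]["Nav"]


def active_tiny_model(tiny_cell, dt_ms=0.01, t_stop_ms=6.0):
    cfg = SolverConfig(dt_ms=dt_ms, t_stop_ms=t_stop_ms, d_lambda=0.1,
                       method="backward_euler")
    graph = discretize(tiny_cell.morph, tiny_cell.params, cfg, mode="DC")
    cfg.record = axon_record_sites(graph)
    return build_active_model(graph), cfg


def test_active_model_gbar_layout(tiny_cell):
    model, _ = active_tiny_model(tiny_cell)
    g = model.graph
    node = g.kind == "node"
    internode = g.kind == "internode"
    na_per_area = model.gbar_uS["Nav"] / (100.0 * g.area_cm2)
    assert np.all(na_per_area[node] > na_per_area[internode].max())
    assert na_per_area[node].max() == pytest.approx(
        DEFAULT_DENSITIES["node"]["Nav"])


def test_simulate_ap_evokes_spike(tiny_cell):
    model, cfg = active_tiny_model(tiny_cell)
    ts = simulate_ap(model, soma_step(amp_pA=1200.0, onset_ms=0.5, dur_ms=1.0), cfg)
    assert ts.meta["ap_detected"]
    assert not ts.meta["regenerative_spiking"]
    # nodal V_m overshoots 0 mV; every gating trajectory stayed in [0, 1]
    node_idx = [i for i, s in enumerate(ts.sites)
                if s["kind"] == "node" and s["potential"] == "V_m"]
    assert max(ts.data[i, 0].max() for i in node_idx) > 0.0


def _gauss_pulse(t0_ms, dt_ms=0.01, t_stop_ms=6.0, sigma_ms=0.2):
    t = np.arange(0.0, t_stop_ms, dt_ms)
    return -75.0 + 100.0 * np.exp(-((t - t0_ms) ** 2) / (2 * sigma_ms**2))


@pytest.mark.parametrize("mode", ["model_d3v", "upstroke_peak"])
def test_conduction_velocity_two_site_closed_form(mode):
    traces = np.stack([_gauss_pulse(2.0), _gauss_pulse(3.0)])
    cv, ordered = conduction_velocity(traces, 0.01, [0.0, 1000.0], mode=mode)
    assert ordered
    assert cv == pytest.approx(1.0, rel=1e-3)   # 1000 um / 1 ms = 1 m/s


def test_conduction_velocity_regression_and_order_flag():
    traces = np.stack([_gauss_pulse(2.0), _gauss_pulse(2.5), _gauss_pulse(3.0)])
    cv, ordered = conduction_velocity(traces, 0.01, [0.0, 500.0, 1000.0],
                                      mode="upstroke_peak")
    assert ordered and cv == pytest.approx(1.0, rel=1e-3)
    cv2, ordered2 = conduction_velocity(traces[::-1], 0.01, [0.0, 500.0, 1000.0],
                                        mode="upstroke_peak")
    assert not ordered2 and cv2 < 0


def test_onset_estimators_on_synthetic_upstroke():
    dt = 0.02
    t = np.arange(0.0, 6.0, dt)
    tr = -75.0 + 100.0 / (1.0 + np.exp(-(t - 2.0) / 0.1))  # sigmoid upstroke
    # both estimators place the onset in the concave foot, before the
    # max-slope midpoint of the rise
    t_d3 = onset_time_d3v(tr, dt)
    t_thr = onset_time_dvdt_threshold(tr, dt, noise_sd_mV=0.0,
                                      pre_samples=None)
    assert 1.0 < t_d3 < 2.0
    assert 1.0 < t_thr < 2.0


def test_conduction_velocity_input_validation():
    tr = _gauss_pulse(2.0)
    with pytest.raises(ValueError):
        conduction_velocity(tr[None, :], 0.01, [0.0])
    with pytest.raises(ValueError):
        conduction_velocity(np.stack([tr, tr]), 0.01, [100.0, 50.0])
    with pytest.raises(ValueError):
        conduction_velocity(np.stack([tr, tr]), 0.01, [0.0, 100.0],
                            mode="no_such_mode")


def test_sensitivity_sweep_validation(tiny_cell):
    model, cfg = active_tiny_model(tiny_cell)
    with pytest.raises(ValueError):
        sensitivity_sweep(model, "not_a_parameter", [1.0],
                          soma_step(), cfg)


def test_sensitivity_sweep_internodal_gna_flat(tiny_cell):
    model, cfg = active_tiny_model(tiny_cell)
    df = sensitivity_sweep(model, "internodal_gNa", [0.25, 1.0],
                           soma_step(amp_pA=1200.0), cfg)
    assert list(df["value"]) == [0.25, 1.0]
    assert df["ap_detected"].all()
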