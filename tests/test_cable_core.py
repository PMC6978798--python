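"""Solver-level checks: exact oracles, conservation, layer nesting, clamps."""

import numpy as np
import pytest
import scipy.linalg

from periaxon.cable_core import (PipetteModel, RecordSite, SolverConfig,
                                 Stimulus, StimulusProtocol, ap_clamp,
                                 attach_pipette, axon_record_sites, discretize,
                                 pipette_outer_area, pipette_wall_capacitance,
                                 simulate_passive, three_potentials,
                                 to_single_cable)

from conftest import small_two_layer_graph, soma_step


def expm_trajectory(G, M, b, stims, x0, dt, nsteps):
    """Reference solution of M dx/dt = -G x + b + s(t) by matrix exponential.

    ``stims`` is a list of (comp, amp_nA, onset_ms, dur_ms); the drive is
    piecewise constant so each step propagates exactly with the segment's
    exponential.
    """
    Gd, Md = G.toarray(), M.toarray()
    A = -np.linalg.solve(Md, Gd)
    E = scipy.linalg.expm(A * dt)
    out = np.empty((nsteps + 1, len(x0)))
    out[0] = x = np.asarray(x0, dtype=float)
    for k in range(nsteps):
        t_mid = (k + 0.5) * dt
        s = np.zeros(len(x0))
        for comp, amp, on, dur in stims:
            if on < t_mid < on + dur:
                s[comp] += amp
        x_ss = np.linalg.solve(Gd, b + s)
        x = x_ss + E @ (x - x_ss)
        out[k + 1] = x
    return out


def test_crank_nicolson_matches_matrix_exponential(tiny_cell):
    rec = [RecordSite("soma", 0, 0.5, ("V_m",))]
    graph, cfg = small_two_layer_graph(tiny_cell, dt_ms=0.001, t_stop_ms=2.0,
                                       record=rec)
    assert graph.n <= 20
    cfg.method = "crank_nicolson"
    stim = soma_step(amp_pA=500.0, onset_ms=0.25, dur_ms=1.0)
    ts = simulate_passive(graph, StimulusProtocol(stimuli=[stim]), cfg)

    G, M, b = graph.assemble(e_rest=cfg.e_rest_mV)
    x0 = np.linalg.solve(G.toarray(), b)   # exact rest, same start as the solver
    comp = graph.comp_at(0, 0.5)
    nsteps = int(round(cfg.t_stop_ms / cfg.dt_ms))
    ref = expm_trajectory(G, M, b, [(comp, 0.5, 0.25, 1.0)], x0,
                          cfg.dt_ms, nsteps)
    ref_vm = ref[:, comp]  # soma has no periaxonal layer: state is V_m
    dev_mV = np.abs(ts.data[0, 0] - ref_vm).max()
    assert dev_mV < 1e-3   # < 1 uV


def test_charge_balance_residual(tiny_cell):
    rec = [RecordSite("soma", 0, 0.5, ("V_m",))]
    for method in ("backward_euler", "crank_nicolson"):
        graph, cfg = small_two_layer_graph(tiny_cell, dt_ms=0.005,
                                           t_stop_ms=3.0, record=rec)
        cfg.method = method
        cfg.check_balance = True
        ts = simulate_passive(graph, StimulusProtocol(stimuli=[soma_step()]), cfg)
        assert ts.meta["max_charge_residual"] < 1e-9


def test_eigen_route_matches_stepping(tiny_cell):
    rec = [RecordSite("soma", 0, 0.5, ("V_m",)),
           RecordSite("end", max(s.id for s in tiny_cell.morph.sections
                                 if s.kind == "unmyelinated_end"), 0.5, ("V_m",))]
    graph, cfg = small_two_layer_graph(tiny_cell, dt_ms=0.001, t_stop_ms=3.0,
                                       record=rec)
    proto = StimulusProtocol(stimuli=[soma_step()])
    cfg.method = "eigen"
    a = simulate_passive(graph, proto, cfg)
    cfg.method = "crank_nicolson"
    b = simulate_passive(graph, proto, cfg)
    assert np.abs(a.data - b.data).max() < 2e-3


def test_double_cable_nests_single_cable(tiny_cell):
    # sealing the periaxonal layer and removing its grounds degenerates the
    # two-layer circuit to the series single-layer one
    rec = [RecordSite("soma", 0, 0.5, ("V_m",))]
    sealed = tiny_cell.params.replace(r_pa=3.18e16, r_pn=3.18e16)
    graph, cfg = small_two_layer_graph(tiny_cell, dt_ms=0.005, t_stop_ms=5.0,
                                       record=rec)
    cfg.ground_myelin_ends = False
    proto = StimulusProtocol(stimuli=[soma_step()])
    dc = simulate_passive(graph, proto, cfg, params=sealed)
    sc = simulate_passive(to_single_cable(graph), proto, cfg, params=sealed)
    span = sc.data.max() - sc.data.min()
    assert np.abs(dc.data - sc.data).max() / span < 0.005


def test_three_potentials_identity(tiny_cell):
    graph, _ = small_two_layer_graph(tiny_cell)
    state = np.random.default_rng(0).normal(size=graph.n)
    pots = three_potentials(graph, state)
    np.testing.assert_allclose(pots["V_m"] + pots["V_my"], pots["V_mym"],
                               rtol=0, atol=1e-12)


def test_ap_clamp_rejects_myelinated_site(tiny_cell):
    graph, cfg = small_two_layer_graph(tiny_cell, dt_ms=0.01, t_stop_ms=2.0)
    internode = int(graph.sec_id[graph.kind == "internode"][0])
    wave = np.full(50, -75.0)
    with pytest.raises(ValueError):
        ap_clamp(graph, internode, wave, cfg, waveform_dt_ms=0.01)


def test_ap_clamp_drives_node_exactly(tiny_cell):
    graph, cfg = small_two_layer_graph(tiny_cell, dt_ms=0.01, t_stop_ms=2.0)
    node = int(graph.sec_id[graph.kind == "node"][0])
    t = np.arange(0, 2.0, 0.01)
    wave = -75.0 + 90.0 * np.exp(-((t - 0.8) ** 2) / (2 * 0.12**2))
    ts = ap_clamp(graph, node, wave, cfg, waveform_dt_ms=0.01)
    clamped = [i for i, s in enumerate(ts.sites)
               if s["section"] == node and s["potential"] == "V_mym"]
    assert clamped
    dev = np.abs(ts.data[clamped[0], 0, : len(wave)] - wave).max()
    assert dev < 1e-9


def test_axon_record_sites_cover_every_axon_compartment(tiny_cell):
    graph, _ = small_two_layer_graph(tiny_cell)
    sites = axon_record_sites(graph)
    axon_secs = {s.id for s in tiny_cell.morph.axon_path()}
    n_axon_comps = int(np.isin(graph.sec_id, list(axon_secs)).sum())
    assert len(sites) == n_axon_comps


def test_attach_pipette_adds_sections_and_preserves_response(tiny_cell):
    rec = [RecordSite("soma", 0, 0.5, ("V_m",))]
    graph, cfg = small_two_layer_graph(tiny_cell, dt_ms=0.005, t_stop_ms=3.0,
                                       record=rec)
    pip = PipetteModel(n_sections=20, bridge_balance_MOhm=15.0)
    g2 = attach_pipette(graph, 0, 0.5, pip)
    assert g2.n > graph.n
    proto = StimulusProtocol(stimuli=[soma_step()])
    a = simulate_passive(graph, proto, cfg)
    b = simulate_passive(g2, proto, cfg)
    # a realistic pipette perturbs the somatic transient only slightly
    rel = np.abs(a.data - b.data).max() / (a.data.max() - a.data.min())
    assert rel < 0.2


def test_pipette_wall_geometry_monotonicity():
    c1 = pipette_wall_capacitance(0.1, 0.5e-4, 1.0e-4)
    c2 = pipette_wall_capacitance(0.2, 0.5e-4, 1.0e-4)
    assert 0 < c1 < c2
    a1 = pipette_outer_area(1.0e-4, 265e-4, 0.2)
    assert a1 > 0


def test_solver_config_validation():
    with pytest.raises(ValueError):
        SolverConfig(dt_ms=0.0)
    with pytest.raises(ValueError):
        SolverConfig(d_lambda=0.0)
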