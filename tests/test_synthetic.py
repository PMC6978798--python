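"""Synthetic world: generator laws, recording emulation, EM and dye data."""

import numpy as np
import pytest

from periaxon.cable_core import (RecordSite, SolverConfig, Stimulus,
                                 StimulusProtocol, discretize, simulate_passive)
from periaxon.morphology import validate
from periaxon.saltation import calibrate_vsd
from periaxon.synthetic import (SynthConfig, make_em_samples,
                                make_l5_morphology, make_recording_set,
                                make_vsd_traces)
from periaxon.ultrastructure import periaxonal_axial_resistance


def test_config_validation():
    with pytest.raises(ValueError):
        SynthConfig(n_internodes=0)
    with pytest.raises(ValueError):
        SynthConfig(n_internodes=7)
    with pytest.raises(ValueError):
        SynthConfig(g_ratio=1.2)
    with pytest.raises(ValueError):
        SynthConfig(artifact_prob=1.5)


def test_internode_lengths_first_two_halved():
    cfg = SynthConfig(seed=0)
    L = cfg.internode_lengths()
    np.testing.assert_allclose(L, [55.0, 55.0, 110.0, 110.0, 110.0, 110.0])


def test_ground_truth_laws(synth_cfg):
    p = synth_cfg.ground_truth_params()
    # 10.5 lamellae per um of core diameter at d = 1.1 -> 12 membranes pairs
    assert p.R_my == pytest.approx(2 * 12 * synth_cfg.R_mm)
    assert p.C_my == pytest.approx(synth_cfg.C_mm / 24.0)
    assert p.r_pa == pytest.approx(
        periaxonal_axial_resistance(synth_cfg.R_pa_ohm_cm,
                                    synth_cfg.axon_diam_um,
                                    synth_cfg.delta_pa_nm), rel=1e-12)
    assert p.r_pn > p.r_pa        # narrower, more resistive paranodal gap


def test_generated_cell_is_valid(synth_cell, synth_cfg):
    assert validate(synth_cell.morph) == []
    assert len(synth_cell.node_positions_um) == synth_cfg.n_internodes
    kinds = {s.kind for s in synth_cell.morph.axon_path()}
    assert {"node", "paranode", "internode", "unmyelinated_end"} <= kinds
    assert all(g.n_my == 12 for g in synth_cell.internode_geometry)


def test_recordings_shape_and_meta(recordings, synth_cfg):
    n_trials = synth_cfg.n_trials_per_level * len(synth_cfg.levels_pA)
    n_samp = int(round(synth_cfg.t_stop_ms * synth_cfg.sampling_rate_hz / 1000.0)) + 1
    assert recordings.data.shape == (2, n_trials, n_samp)
    assert recordings.meta["ground_truth"]["R_i"] == synth_cfg.R_i
    assert recordings.sites[0]["injecting"]
    assert not recordings.sites[1]["injecting"]
    # every configured level appears equally often
    lv, counts = np.unique(recordings.trial_level_pA, return_counts=True)
    assert set(lv) == set(synth_cfg.levels_pA)
    assert (counts == synth_cfg.n_trials_per_level).all()


def test_recordings_noise_level(recordings, synth_cfg):
    # pre-pulse variability across trials = filter-shaped noise + baseline jitter
    pre = int(0.8 * synth_cfg.pulse_onset_ms / recordings.dt_ms)
    sd = recordings.data[0, :, :pre].std(axis=0).mean()
    expect = np.hypot(synth_cfg.noise_sd_mV, synth_cfg.baseline_jitter_mV)
    assert sd == pytest.approx(expect, rel=0.25)


def test_recordings_are_seed_reproducible(synth_cell, synth_cfg):
    tiny = SynthConfig(seed=11, n_internodes=1, n_trials_per_level=2,
                       levels_pA=(-400.0, 400.0), t_stop_ms=30.0)
    cell = make_l5_morphology(tiny)
    a = make_recording_set(cell.morph, cell.params, tiny)
    b = make_recording_set(cell.morph, cell.params, tiny)
    np.testing.assert_array_equal(a.data, b.data)


def test_em_samples_match_reported_statistics(synth_cfg):
    df = make_em_samples(synth_cfg, n=195)
    assert len(df) == 195
    lo, hi = synth_cfg.delta_pa_range_nm
    assert df["delta_pa_nm"].between(lo, hi).all()
    assert df["delta_pa_nm"].mean() == pytest.approx(synth_cfg.delta_pa_nm, abs=0.6)
    assert (df["D_um"] > df["d_um"]).all()
    assert (df["n_my"] >= 1).all()


def test_vsd_round_trip_recovers_voltage(tiny_cell, tiny_cfg):
    cfg = SolverConfig(dt_ms=0.02, method="eigen", t_stop_ms=20.0,
                       record=[RecordSite("soma", 0, 0.5, ("V_m",)),
                               RecordSite("node", 6, 0.5, ("V_m",))])
    graph = discretize(tiny_cell.morph, tiny_cell.params, cfg)
    proto = StimulusProtocol(stimuli=[Stimulus(0, 0.5, -400.0, 2.0, 4.0)])
    sim = simulate_passive(graph, proto, cfg)
    F, cals = make_vsd_traces(tiny_cell.morph, sim, tiny_cfg)
    for i, cal in enumerate(cals):
        back = calibrate_vsd(F.data[i, 0], cal)
        true = sim.data[i, 0]
        # hidden gain and offset cancel; residual is the 1%-of-range shot noise
        resid = np.abs(back - (true - true[0] + cal.v_rest_mV)).max()
        assert resid < 0.1 * np.ptp(true)
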