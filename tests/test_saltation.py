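"""Latency analysis, saltation statistics and fluorescence calibration."""

import math

import numpy as np
import pandas as pd
import pytest

from periaxon.saltation import (LatencyProfile, VSDCalibration, ap_features,
                                calibrate_vsd, onset_latency,
                                saltation_advancement, spatial_profile)
from periaxon.traces import TraceSet


def _sigmoid(t, t0, width=0.1, amp=100.0, base=-75.0):
    return base + amp / (1.0 + np.exp(-(t - t0) / width))


def test_onset_latency_closed_form():
    dt = 0.01
    t = np.arange(0.0, 4.0, dt)
    # linear ramp from 0 mV to 10 mV between 1 and 2 ms: the half-peak
    # crossing is exactly at 1.5 ms
    tr = np.interp(t, [0.0, 1.0, 2.0, 4.0], [0.0, 0.0, 10.0, 10.0])
    assert onset_latency(tr, dt, fraction=0.5) == pytest.approx(1.5, abs=1e-9)
    assert onset_latency(tr, dt, fraction=0.2) == pytest.approx(1.2, abs=1e-9)
    assert onset_latency(tr, dt, fraction=0.5, t0_ms=2.0) == pytest.approx(3.5)


def test_onset_latency_validation():
    tr = np.zeros(100)
    with pytest.raises(ValueError):
        onset_latency(tr, 0.01)                 # no deflection
    with pytest.raises(ValueError):
        onset_latency(tr + 1.0, 0.01, fraction=1.5)


def test_ap_features():
    dt = 0.01
    t = np.arange(0.0, 6.0, dt)
    tr = _sigmoid(t, 2.0)
    peak, dvdt, onset = ap_features(tr, dt)
    assert peak == pytest.approx(100.0, rel=1e-3)
    # max slope of a logistic of amplitude A and width w is A/(4w)
    assert dvdt == pytest.approx(100.0 / 0.4, rel=1e-3)
    assert onset == pytest.approx(2.0, abs=0.02)


def _profile_traceset(latencies_ms, kinds, dt=0.01, t_stop=8.0):
    t = np.arange(0.0, t_stop, dt)
    data = np.stack([_sigmoid(t, lat)[None, :] for lat in latencies_ms])
    sites = [{"name": f"s{i}", "potential": "V_m", "kind": k,
              "path_distance_um": 10.0 * i, "section": 100 + i}
             for i, k in enumerate(kinds)]
    return TraceSet(data, dt, sites, None, {}, {})


def test_spatial_profile_orders_and_flags_internode_maxima():
    lats = [1.0, 1.6, 1.3, 1.8, 1.5]
    kinds = ["node", "internode", "node", "internode", "node"]
    prof = spatial_profile(_profile_traceset(lats, kinds))
    got = prof.table["latency_ms"].to_numpy()
    np.testing.assert_allclose(got, lats, atol=0.02)
    # each single-site internode is its own latency maximum
    assert prof.table["internode_latency_max"].sum() == 2


def test_latency_profile_interpolation_and_range():
    df = pd.DataFrame({"position_um": [0.0, 10.0, 20.0],
                       "latency_ms": [1.0, 2.0, 3.0],
                       "peak_mV": [100.0] * 3,
                       "max_dvdt_V_per_s": [250.0] * 3,
                       "kind": ["node", "internode", "node"]})
    prof = LatencyProfile(df)
    assert prof.latency_at(5.0) == pytest.approx(1.5)
    with pytest.raises(ValueError):
        prof.latency_at(25.0)
    with pytest.raises(ValueError):
        LatencyProfile(df.iloc[::-1].reset_index(drop=True))


def test_saltation_advancement_sign():
    # the node (center) leads its flanks: positive advancement
    df = pd.DataFrame({"position_um": [95.0, 100.0, 105.0],
                       "latency_ms": [1.4, 1.0, 1.5],
                       "peak_mV": [100.0] * 3,
                       "max_dvdt_V_per_s": [250.0] * 3,
                       "kind": ["internode", "node", "internode"]})
    adv = saltation_advancement(LatencyProfile(df), 100.0, offset_um=5.0)
    assert adv == pytest.approx(0.45)
    # a smoothly increasing latency profile gives ~zero advancement
    df2 = df.assign(latency_ms=[1.0, 1.1, 1.2])
    assert abs(saltation_advancement(LatencyProfile(df2), 100.0, 5.0)) < 1e-9


def test_vsd_attenuation_factor_at_one_length_constant():
    cal = VSDCalibration(v_step_soma_mV=1.0, dF_cal=1.0, x_mm=1.18, k_mm=1.18)
    assert cal.mV_per_dF == math.exp(-1.0)      # exactly e^-1 at x = k


def test_vsd_calibration_validation():
    with pytest.raises(ValueError):
        VSDCalibration(1.0, 1.0, 0.5, k_mm=0.0)
    with pytest.raises(ValueError):
        VSDCalibration(1.0, 0.0, 0.5)


def test_calibrate_vsd_round_trip_exact():
    t = np.arange(0.0, 6.0, 0.01)
    V = _sigmoid(t, 2.0, amp=40.0)
    gain, offset, x_mm, k_mm, v_step = 1.7, 120.0, 0.6, 1.18, -20.0
    F = gain * V + offset
    cal = VSDCalibration(v_step, gain * v_step * math.exp(-x_mm / k_mm),
                         x_mm, k_mm, v_rest_mV=V[0])
    back = calibrate_vsd(F, cal)
    np.testing.assert_allclose(back, V, atol=1e-9)
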