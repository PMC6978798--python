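"""Closed-form ultrastructure algebra: worked values and round trips."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from periaxon.ultrastructure import (CableParams, MyelinGeometry,
                                     SubmyelinGeometry, core_axial_resistance,
                                     g_ratio, lamellae_from_sheath,
                                     membrane_props_from_sheath,
                                     periaxonal_axial_resistance,
                                     periaxonal_resistivity, periaxonal_width,
                                     resolving_distance, sheath_from_lamellae,
                                     sheath_thickness)

FINITE = dict(allow_nan=False, allow_infinity=False)


def test_periaxonal_resistivity_worked_value():
    # annulus relation with r_pa = 125 GOhm/cm, delta = 12.3 nm, d = 1.1 um
    assert periaxonal_resistivity(125e9, 1.1, 12.3) == pytest.approx(53.7, abs=0.05)


def test_core_axial_resistance_cylinder():
    # 4*R_i/(pi d^2): R_i = 100 Ohm cm, d = 1.1 um
    expect = 4 * 100 / (math.pi * (1.1e-4) ** 2)
    assert core_axial_resistance(100.0, 1.1) == pytest.approx(expect, rel=1e-12)


def test_lamellae_from_sheath_series_capacitors():
    # C_my = C_m/(2 n) -> n = C_m/(2 C_my); C_my = 0.05 C_m gives 10
    assert lamellae_from_sheath(1.0, 0.05) == pytest.approx(10.0)


def test_sheath_resistance_scales_with_membrane_count():
    R_my, C_my = sheath_from_lamellae(R_mm=20.0, C_mm=1.0, n_my=10)
    assert R_my == pytest.approx(20 * 20.0)      # 2*n*R_mm
    assert C_my == pytest.approx(1.0 / 20.0)     # C_mm/(2n)


def test_resolving_distance_rayleigh():
    rd = resolving_distance(550.0, 1.4, 0.9)
    assert rd == pytest.approx(1.22 * 550 / 2.3, rel=1e-12)
    assert round(rd / 100) * 100 == 300


def test_sheath_thickness_dielectric_relation():
    # delta_my = delta_m * C_m / C_my
    assert sheath_thickness(1.0, 0.05, delta_m=8.0) == pytest.approx(160.0)


def test_g_ratio():
    assert g_ratio(1.1, 1.1 / 0.698) == pytest.approx(0.698)
    with pytest.raises(ValueError):
        g_ratio(2.0, 1.0)   # inner exceeding outer diameter


@settings(deadline=None, max_examples=50, derandomize=True)
@given(r_pa=st.floats(1e9, 1e14, **FINITE), d=st.floats(0.3, 3.0, **FINITE),
       delta=st.floats(1.0, 300.0, **FINITE))
def test_periaxonal_round_trip_width(r_pa, d, delta):
    R = periaxonal_resistivity(r_pa, d, delta)
    assert periaxonal_width(r_pa, d, R) == pytest.approx(delta, rel=1e-9)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(R=st.floats(1.0, 5000.0, **FINITE), d=st.floats(0.3, 3.0, **FINITE),
       delta=st.floats(1.0, 300.0, **FINITE))
def test_periaxonal_round_trip_resistance(R, d, delta):
    r = periaxonal_axial_resistance(R, d, delta)
    assert periaxonal_resistivity(r, d, delta) == pytest.approx(R, rel=1e-9)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(R_mm=st.floats(0.5, 200.0, **FINITE), C_mm=st.floats(0.2, 3.0, **FINITE),
       n=st.integers(1, 60))
def test_sheath_membrane_round_trip(R_mm, C_mm, n):
    R_my, C_my = sheath_from_lamellae(R_mm, C_mm, n)
    back = membrane_props_from_sheath(R_my, C_my, n)
    assert back[0] == pytest.approx(R_mm, rel=1e-9)
    assert back[1] == pytest.approx(C_mm, rel=1e-9)


def test_submyelin_geometry_rejects_subnanometer_widths():
    with pytest.raises(ValueError):
        SubmyelinGeometry(delta_pa=0.5)
    with pytest.raises(ValueError):
        SubmyelinGeometry(delta_pn=0.2)


def test_cable_params_validation_and_replace():
    p = CableParams()
    q = p.replace(R_i=150.0)
    assert q.R_i == 150.0 and p.R_i == 100.0
    with pytest.raises(ValueError):
        CableParams(R_i=-1.0)


def test_myelin_geometry_sanity(synth_cell):
    for g in synth_cell.internode_geometry:
        assert isinstance(g, MyelinGeometry)
        assert g.n_my >= 1
        assert g.D > g.d
        assert 0 < g.g < 1
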