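"""Shared fixtures: small cells and cached synthetic recordings.

Session-scoped fixtures cache the expensive artifacts (morphology build,
recording generation) so the suite stays within a desk-scale budget.
"""

from __future__ import annotations

import numpy as np
import pytest

from periaxon.cable_core import SolverConfig, Stimulus, discretize
from periaxon.fitting import preprocess_trials
from periaxon.synthetic import SynthConfig, make_l5_morphology, make_recording_set


@pytest.fixture(scope="session")
def synth_cfg() -> SynthConfig:
    return SynthConfig(seed=0, noise_sd_mV=0.08)


@pytest.fixture(scope="session")
def synth_cell(synth_cfg):
    return make_l5_morphology(synth_cfg)


@pytest.fixture(scope="session")
def tiny_cfg() -> SynthConfig:
    """One-internode cell: cheap graphs for solver-level tests."""
    return SynthConfig(seed=3, n_internodes=1, noise_sd_mV=0.08)


@pytest.fixture(scope="session")
def tiny_cell(tiny_cfg):
    return make_l5_morphology(tiny_cfg)


@pytest.fixture(scope="session")
def recordings(synth_cfg, synth_cell):
    return make_recording_set(synth_cell.morph, synth_cell.params, synth_cfg)


@pytest.fixture(scope="session")
def fit_target(recordings):
    return preprocess_trials(recordings)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def small_two_layer_graph(cell, d_lambda=1.0, dt_ms=0.001, t_stop_ms=3.0,
                          record=(), mode="DC"):
    """Coarse discretization of the one-internode cell (few compartments)."""
    cfg = SolverConfig(dt_ms=dt_ms, t_stop_ms=t_stop_ms, d_lambda=d_lambda,
                       tau_min_ms=8.0, record=list(record))
    return discretize(cell.morph, cell.params, cfg, mode=mode), cfg


def soma_step(amp_pA=500.0, onset_ms=0.5, dur_ms=1.0, section=0):
    return Stimulus(section=section, arc=0.5, amplitude_pA=amp_pA,
                    onset_ms=onset_ms, duration_ms=dur_ms)
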