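"""Bounds, preprocessing, objective and the evolutionary fit machinery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from periaxon.fitting import (CIRCUIT_MODES, FitProblem, OptBudget,
                              ParameterBounds, ParamSpec, fit_window,
                              noise_floor, objective, optimize,
                              perturb_morphology, preprocess_trials)
from periaxon.synthetic import SynthConfig, make_l5_morphology, make_recording_set

FINITE = dict(allow_nan=False, allow_infinity=False)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(x=st.floats(1e-6, 1e12, **FINITE),
       transform=st.sampled_from(["log", "linear"]))
def test_param_spec_unit_round_trip(x, transform):
    s = ParamSpec(1e-7, 1e13, transform=transform)
    assert s.from_unit(s.to_unit(x)) == pytest.approx(x, rel=1e-9)


def test_param_spec_validation():
    with pytest.raises(ValueError):
        ParamSpec(2.0, 1.0)
    with pytest.raises(ValueError):
        ParamSpec(-1.0, 1.0)
    with pytest.raises(ValueError):
        ParamSpec(1.0, 2.0, transform="exp")


def test_bounds_per_unit_lookup():
    b = ParameterBounds()
    assert b["R_my@3"] is b["R_my"]
    assert b.contains("C_my", 1.0 / 24.0)
    assert not b.contains("R_i", 1e6)


def test_noise_floor(rng):
    tr = rng.normal(0.0, 0.1, size=5000)
    assert noise_floor(tr, 5000) == pytest.approx(0.01, rel=0.1)
    with pytest.raises(ValueError):
        noise_floor(tr, 5)


def test_fit_window_roles():
    assert fit_window(2.0, 2.0, 100.0) == (4.5, 100.0)
    assert fit_window(2.0, 2.0, 100.0, "recording_only") == (2.0, 100.0)
    with pytest.raises(ValueError):
        fit_window(2.0, 2.0, 100.0, "imaging")
    with pytest.raises(ValueError):
        fit_window(2.0, 2.0, 4.2)


def test_objective_closed_form():
    model = np.array([[0.0, 1.0, 2.0], [0.0, 0.0, 0.0]])
    target = np.zeros_like(model)
    val = objective(model, target, [(0, 3), (0, 3)])
    assert val == pytest.approx(((0 + 1 + 4) / 3 + 0.0) / 2)
    val_w = objective(model, target, [(0, 3), (0, 3)], weights=[1.0, 0.0])
    assert val_w == pytest.approx(5.0 / 3)
    with pytest.raises(ValueError):
        objective(model, target[:, :2], [(0, 2), (0, 2)])
    with pytest.raises(ValueError):
        objective(model, target, [(0, 9), (0, 3)])


def noisy_recordings(artifact_prob=0.25):
    cfg = SynthConfig(seed=7, n_internodes=1, n_trials_per_level=6,
                      levels_pA=(-400.0, 400.0), t_stop_ms=40.0,
                      noise_sd_mV=0.08, artifact_prob=artifact_prob)
    cell = make_l5_morphology(cfg)
    return make_recording_set(cell.morph, cell.params, cfg), cell, cfg


def test_preprocess_rejects_artifact_trials_and_averages():
    raw, _, cfg = noisy_recordings(artifact_prob=0.35)
    pre = preprocess_trials(raw)
    n_art = sum(raw.meta["artifact_trials"])
    assert n_art > 0                      # the generator did inject artifacts
    n_rej = sum(pre.meta["rejected_per_level"].values())
    assert n_rej >= 1
    assert pre.data.shape == (2, 2, raw.n_samples)
    assert list(pre.trial_level_pA) == [-400.0, 400.0]
    # averaging suppresses the noise below the single-trial level
    floors = pre.meta["noise_floor_mV2"]
    assert all(f < cfg.noise_sd_mV**2 for f in floors)


def test_preprocess_baselines_to_zero():
    raw, _, _ = noisy_recordings(artifact_prob=0.0)
    pre = preprocess_trials(raw)
    onset_i = int(round(raw.protocol["pulse_onset_ms"] / raw.dt_ms))
    base = pre.data[:, :, :onset_i].mean(axis=2)
    assert np.abs(base).max() < 0.05


def test_fit_problem_free_parameters(tiny_cell, fit_target):
    raw, cell, _ = noisy_recordings(artifact_prob=0.0)
    target = preprocess_trials(raw)
    expected = {
        "SC_expected": 3, "SC": 5, "SC_split_rm": 7, "DC": 7, "DC_no_rpn": 6,
    }
    for mode, n in expected.items():
        p = FitProblem(cell.morph, target, mode=mode)
        names = p.free_parameters()
        assert len(names) == n
        assert names[:3] == ["R_i", "R_m", "C_m"]
    with pytest.raises(ValueError):
        FitProblem(cell.morph, target, mode="triple_cable")
    with pytest.raises(ValueError):
        FitProblem(cell.morph, raw)       # not preprocessed


def test_params_from_vector_sc_expected_ties():
    raw, cell, _ = noisy_recordings(artifact_prob=0.0)
    target = preprocess_trials(raw)
    p = FitProblem(cell.morph, target, mode="SC_expected")
    prm = p.params_from_vector(["R_i", "R_m", "C_m"], np.array([120.0, 10.0, 1.0]))
    assert prm.R_my == pytest.approx(20.0 * 10.0)
    assert prm.C_my == pytest.approx(0.05 * 1.0)


def test_optimize_smoke_returns_in_bound_solutions():
    raw, cell, _ = noisy_recordings(artifact_prob=0.0)
    target = preprocess_trials(raw)
    p = FitProblem(cell.morph, target, mode="SC_expected")
    budget = OptBudget(population=8, generations=4, n_runs=2, refine_maxiter=0)
    sols = optimize(p, budget, seed=0)
    assert len(sols) == 2
    assert sols[0].mse <= sols[1].mse
    for s in sols:
        assert s.exit_reason in ("max_iter", "noise_floor", "converged")
        for name, val in s.values.items():
            assert p.bounds.contains(name, val)
    # same seed, same result
    sols2 = optimize(p, budget, seed=0)
    assert sols2[0].mse == sols[0].mse
    assert sols2[0].values == sols[0].values


def test_perturb_morphology_touches_only_myelinated_sections(synth_cell):
    out = perturb_morphology(synth_cell.morph, rd_nm=300.0, seed=5)
    changed = 0
    for a, b in zip(synth_cell.morph.sections, out.sections):
        da = np.array([d for _, d in a.diam_profile])
        db = np.array([d for _, d in b.diam_profile])
        if a.kind in ("internode", "paranode"):
            changed += int(np.any(da != db))
        else:
            np.testing.assert_array_equal(da, db)
    assert changed > 0
    assert out.metadata["perturbation"]["rd_nm"] == 300.0
    # deterministic in the seed
    out2 = perturb_morphology(synth_cell.morph, rd_nm=300.0, seed=5)
    for a, b in zip(out.sections, out2.sections):
        assert a.diam_profile == b.diam_profile
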