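"""Seeded generators for every input the pipeline needs.

A stylized layer-5-like cell (soma, equivalent dendrite cylinders, AIS and a
myelinated axon with 1-6 internodes) is built from explicit geometric laws:
internode length scales linearly with axon core diameter (first two
internodes halved), lamellae count follows 10.5 per um of core diameter, and
the g-ratio fixes the outer diameter.  Electrode-like trial sets add
Gaussian noise shaped by a 4-pole low-pass emulating a 10 kHz Bessel
filter, per-trial baseline jitter and occasional artifact trials.  All
randomness flows from one :class:`numpy.random.Generator` (PCG64) seeded in
the config, so every artifact is exactly reproducible.

The dendritic load is an equivalent-cylinder stylization, not a
reconstruction; somatic transients are therefore only qualitatively
cortical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import bessel, sosfilt
from scipy.stats import truncnorm

from .cable_core import (
    CompartmentGraph,
    RecordSite,
    SolverConfig,
    Stimulus,
    StimulusProtocol,
    discretize,
    simulate_passive,
)
from .morphology import Morphology, Section, annotate_axon_domains
from .saltation import VSDCalibration
from .traces import TraceSet
from .ultrastructure import CableParams, MyelinGeometry, SubmyelinGeometry

__all__ = ["SynthConfig", "SynthCell", "make_l5_morphology",
           "make_recording_set", "make_vsd_traces", "make_em_samples"]


@dataclass
class SynthConfig:
    """Knobs of the synthetic world; defaults follow the measured laws."""

    seed: int = 0
    n_internodes: int = 6
    axon_diam_um: float = 1.1
    internode_per_diam: float = 100.0    # L = 100 um per um of core diameter
    first_internodes_halved: int = 2
    g_ratio: float = 0.698
    lamellae_per_um: float = 10.5
    node_len_um: float = 1.0
    paranode_len_um: float = 2.3
    end_len_um: float = 10.0             # unmyelinated cut end / bleb
    # soma / dendrite stylization (equivalent cylinders)
    soma_len_um: float = 20.0
    soma_diam_um: float = 20.0
    apical_len_um: float = 400.0
    apical_diam_um: float = 2.5
    basal_len_um: float = 200.0
    basal_diam_um: float = 2.0
    ais_len_um: float = 45.0
    ais_diam_um: float = 1.2
    # ground-truth electrical laws
    R_i: float = 100.0                   # Ohm*cm
    R_m: float = 20.0                    # kOhm*cm^2
    C_m: float = 1.0                     # uF/cm^2
    R_mm: float = 10.0                   # per-membrane myelin resistance, kOhm*cm^2
    C_mm: float = 1.0                    # per-membrane myelin capacitance, uF/cm^2
    delta_pa_nm: float = 12.3
    delta_pa_sd_nm: float = 2.7          # SD back-computed from SEM 0.192, n = 195
    delta_pa_range_nm: tuple[float, float] = (8.5, 17.1)
    delta_pn_nm: float = 7.4
    R_pa_ohm_cm: float = 53.7
    R_pn_ohm_cm: float = 550.0
    # recording emulation
    noise_sd_mV: float = 0.15
    baseline_jitter_mV: float = 0.1
    n_trials_per_level: int = 30
    levels_pA: tuple[float, ...] = (-600, -500, -400, -300, 300, 400, 500, 600)
    pulse_onset_ms: float = 2.0
    pulse_dur_ms: float = 2.0
    # brief step, long sweep: the slow relaxations (tau_m = R_m*C_m ~ 20 ms,
    # tau_my = R_my*C_my ~ 10 ms) must fit inside the record for the myelin
    # parameters to be identifiable from the transients
    t_stop_ms: float = 100.0
    sampling_rate_hz: float = 50_000.0
    bessel_cutoff_hz: float = 10_000.0
    artifact_prob: float = 0.0

    def __post_init__(self) -> None:
        if not 1 <= self.n_internodes <= 6:
            raise ValueError("n_internodes must lie in 1..6")
        if not 0 < self.g_ratio < 1:
            raise ValueError("g_ratio must lie in (0, 1)")
        for name in ("axon_diam_um", "internode_per_diam", "lamellae_per_um",
                     "sampling_rate_hz"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.artifact_prob <= 1:
            raise ValueError("artifact_prob must lie in [0, 1]")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def internode_lengths(self) -> list[float]:
        L = self.internode_per_diam * self.axon_diam_um
        out = []
        for i in range(self.n_internodes):
            out.append(L / 2 if i < self.first_internodes_halved else L)
        return out

    def ground_truth_params(self) -> CableParams:
        """Cable parameters implied by the generator's ultrastructural laws."""
        n_my = round(self.lamellae_per_um * self.axon_diam_um)
        R_my = 2.0 * n_my * self.R_mm
        C_my = self.C_mm / (2.0 * n_my)
        d_cm = self.axon_diam_um * 1e-4
        dpa = self.delta_pa_nm * 1e-7
        dpn = self.delta_pn_nm * 1e-7
        r_pa = self.R_pa_ohm_cm / (math.pi * dpa * (d_cm + dpa))
        r_pn = self.R_pn_ohm_cm / (math.pi * dpn * (d_cm + dpn))
        return CableParams(R_i=self.R_i, R_m=self.R_m, C_m=self.C_m,
                           R_my=R_my, C_my=C_my, r_pa=r_pa, r_pn=r_pn)


@dataclass
class SynthCell:
    """A generated cell: morphology plus its ground truth."""

    morph: Morphology
    params: CableParams
    internode_geometry: list[MyelinGeometry]
    submyelin: SubmyelinGeometry
    node_positions_um: list[float] = field(default_factory=list)
    axon_start_section: int | None = None


def make_l5_morphology(cfg: SynthConfig) -> SynthCell:
    """Build the stylized cell and its per-internode ground truth.

    Layout along the axon (path distance from the AIS end): a heminode flush
    at the start, then alternating paranode/internode/paranode/node spans,
    a terminal paranode where myelin ends, and an unmyelinated cut end.
    """
    secs = [
        Section(0, "soma", None, cfg.soma_len_um,
                [(0.0, cfg.soma_diam_um), (1.0, cfg.soma_diam_um)]),
        Section(1, "dendrite", 0, cfg.apical_len_um,
                [(0.0, cfg.apical_diam_um), (1.0, cfg.apical_diam_um)]),
        Section(2, "dendrite", 0, cfg.basal_len_um,
                [(0.0, cfg.basal_diam_um), (1.0, cfg.basal_diam_um)]),
        Section(3, "ais", 0, cfg.ais_len_um,
                [(0.0, cfg.ais_diam_um), (1.0, cfg.axon_diam_um)]),
    ]
    spans = cfg.internode_lengths()
    node_positions = [cfg.node_len_um / 2.0]
    for L in spans[:-1]:
        node_positions.append(node_positions[-1] + cfg.node_len_um + L)
    myelin_end = node_positions[-1] + cfg.node_len_um / 2.0 + spans[-1]
    total = myelin_end + cfg.end_len_um
    secs.append(Section(4, "axon", 3, total,
                        [(0.0, cfg.axon_diam_um), (1.0, cfg.axon_diam_um)]))
    morph = Morphology(secs, {"generator": "make_l5_morphology", "seed": cfg.seed})
    morph = annotate_axon_domains(
        morph, node_positions, paranode_len=cfg.paranode_len_um,
        node_len=cfg.node_len_um, myelin_end=myelin_end,
    )

    d = cfg.axon_diam_um
    D = d / cfg.g_ratio
    n_my = round(cfg.lamellae_per_um * d)
    geoms = [
        MyelinGeometry(n_my=n_my, delta_my=(D - d) / 2.0 * 1e3, d=d, D=D)
        for _ in spans
    ]
    sub = SubmyelinGeometry(cfg.delta_pa_nm, cfg.delta_pn_nm,
                            cfg.R_pa_ohm_cm, cfg.R_pn_ohm_cm)
    return SynthCell(morph, cfg.ground_truth_params(), geoms, sub,
                     node_positions_um=node_positions, axon_start_section=4)


# ---------------------------------------------------------------------------
# electrode-like trials
# ---------------------------------------------------------------------------

def _end_section(morph: Morphology) -> int:
    path = morph.axon_path()
    ends = [s for s in path if s.kind == "unmyelinated_end"]
    return (ends[-1] if ends else path[-1]).id


def make_recording_set(morph: Morphology, true_params: CableParams,
                       cfg: SynthConfig,
                       record: list[RecordSite] | None = None,
                       inject_section: int | None = None) -> TraceSet:
    """Noisy multi-trial current-step recordings at the soma and axon end.

    Each injection level is forward-simulated once (clean), then per trial:
    Gaussian noise shaped by the emulated Bessel filter, a baseline offset
    jitter, and (with probability ``artifact_prob``) a square artifact large
    and long enough to be caught by trial rejection.  ``meta`` records the
    ground truth and seed for recovery scoring.
    """
    rng = cfg.rng()
    dt = 1000.0 / cfg.sampling_rate_hz
    soma = morph.root().id
    if inject_section is None:
        inject_section = soma
    if record is None:
        record = [
            RecordSite("soma", soma, 0.5, ("V_m",)),
            RecordSite("axon_end", _end_section(morph), 0.5, ("V_m",)),
        ]
    sol = SolverConfig(dt_ms=dt, method="eigen", t_stop_ms=cfg.t_stop_ms,
                       record=record)
    graph = discretize(morph, true_params, sol)

    clean = []
    for lev in cfg.levels_pA:
        proto = StimulusProtocol(stimuli=[Stimulus(
            inject_section, 0.5, lev, cfg.pulse_onset_ms, cfg.pulse_dur_ms)])
        ts = simulate_passive(graph, proto, sol)
        clean.append(ts.data[:, 0, :])
    clean = np.stack(clean)                       # (levels, sites, samples)
    n_sites, n_samp = clean.shape[1], clean.shape[2]

    sos = bessel(4, cfg.bessel_cutoff_hz, fs=cfg.sampling_rate_hz, output="sos")
    n_trials = cfg.n_trials_per_level * len(cfg.levels_pA)
    data = np.empty((n_sites, n_trials, n_samp))
    levels = np.empty(n_trials)
    artifact_flags = []
    k = 0
    for li, lev in enumerate(cfg.levels_pA):
        for _ in range(cfg.n_trials_per_level):
            noise = rng.normal(0.0, cfg.noise_sd_mV, size=(n_sites, n_samp))
            if cfg.noise_sd_mV > 0:
                noise = sosfilt(sos, noise, axis=-1)
                # restore the configured SD after the low-pass
                sd = noise.std(axis=-1, keepdims=True)
                noise *= cfg.noise_sd_mV / np.where(sd > 0, sd, 1.0)
            trial = clean[li] + noise
            trial += rng.normal(0.0, cfg.baseline_jitter_mV, size=(n_sites, 1))
            is_artifact = rng.random() < cfg.artifact_prob
            if is_artifact:
                w = max(int(0.08 * n_samp), int(0.3 / dt) + 1)
                start = rng.integers(0, n_samp - w)
                trial[:, start:start + w] += 10.0 * max(cfg.noise_sd_mV, 0.05)
            artifact_flags.append(bool(is_artifact))
            data[:, k, :] = trial
            levels[k] = lev
            k += 1

    sites = []
    for r in record:
        c = graph.comp_at(r.section, r.arc)
        sites.append({
            "name": r.name, "section": r.section, "arc": r.arc,
            "path_distance_um": float(morph.path_distance(r.section, r.arc)),
            "potential": "V_m", "kind": str(graph.kind[c]),
            "injecting": bool(r.section == inject_section),
        })
    protocol = {
        "pulse_onset_ms": cfg.pulse_onset_ms, "pulse_dur_ms": cfg.pulse_dur_ms,
        "levels_pA": list(cfg.levels_pA), "sampling_rate_hz": cfg.sampling_rate_hz,
        "inject_section": inject_section,
        "bessel_cutoff_hz": cfg.bessel_cutoff_hz,
    }
    meta = {
        "seed": cfg.seed, "rng": "numpy.random.Generator(PCG64)",
        "noise_sd_mV": cfg.noise_sd_mV,
        "artifact_trials": artifact_flags,
        "ground_truth": true_params.as_dict(),
    }
    return TraceSet(data, dt, sites, levels, protocol, meta)


# ---------------------------------------------------------------------------
# fluorescence
# ---------------------------------------------------------------------------

def make_vsd_traces(morph: Morphology, sim_output: TraceSet, cfg: SynthConfig,
                    v_step_soma_mV: float = -20.0, k_mm: float = 1.18
                    ) -> tuple[TraceSet, list[VSDCalibration]]:
    """Dye-like fluorescence from simulated voltage plus a calibration step.

    ``F = gain*V + offset + noise`` with an unknown per-site gain; the paired
    calibration is the fluorescence deflection a known somatic
    hyperpolarizing step would produce at each site after steady-state
    attenuation by ``exp(-x/k)``.
    """
    rng = cfg.rng()
    data = np.empty_like(sim_output.data)
    cals = []
    for i, s in enumerate(sim_output.sites):
        gain = rng.uniform(0.5, 2.0)
        offset = rng.uniform(50.0, 150.0)
        V = sim_output.data[i]
        noise = rng.normal(0.0, 0.01 * abs(gain) * max(np.ptp(V), 1.0), size=V.shape)
        data[i] = gain * V + offset + noise
        x_mm = s.get("path_distance_um", 0.0) * 1e-3
        dF_cal = gain * v_step_soma_mV * math.exp(-x_mm / k_mm)
        cals.append(VSDCalibration(v_step_soma_mV, dF_cal, x_mm, k_mm))
    sites = [dict(s, potential="F") for s in sim_output.sites]
    ts = TraceSet(data, sim_output.dt_ms, sites, sim_output.trial_level_pA,
                  dict(sim_output.protocol),
                  {"seed": cfg.seed, "kind": "vsd"}, sim_output.t0_ms)
    return ts, cals


# ---------------------------------------------------------------------------
# EM-like measurement samples
# ---------------------------------------------------------------------------

def make_em_samples(cfg: SynthConfig, n: int = 195) -> pd.DataFrame:
    """Table of (delta_pa nm, d um, D um, n_my) mimicking EM measurements.

    The periaxonal width is a truncated normal matching the reported mean
    and range; diameters follow the g-ratio law with multiplicative scatter;
    lamellae counts follow the linear lamellae-per-um law with rounding.
    """
    rng = cfg.rng()
    lo, hi = cfg.delta_pa_range_nm
    a = (lo - cfg.delta_pa_nm) / cfg.delta_pa_sd_nm
    b = (hi - cfg.delta_pa_nm) / cfg.delta_pa_sd_nm
    delta_pa = truncnorm.rvs(a, b, loc=cfg.delta_pa_nm, scale=cfg.delta_pa_sd_nm,
                             size=n, random_state=rng)
    d = cfg.axon_diam_um * rng.lognormal(0.0, 0.25, size=n)
    D = d / cfg.g_ratio * rng.normal(1.0, 0.03, size=n)
    n_my = np.maximum(1, np.rint(
        cfg.lamellae_per_um * d + rng.normal(0.0, 1.0, size=n))).astype(int)
    return pd.DataFrame({
        "delta_pa_nm": delta_pa, "d_um": d, "D_um": D, "n_my": n_my,
    })
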