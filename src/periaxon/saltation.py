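"""Analysis of propagation: onset latencies, spatial profiles, temporal
saltation statistics, and voltage calibration of dye fluorescence.

The double cable predicts *temporal saltation*: during the passive spread of
a nodal action potential, the transaxonal potential under the myelin can
reach its half-maximum later near the middle of an internode than at the
next node downstream, while the transfiber potential advances smoothly.
These functions quantify that signature on simulated or recorded trace
sets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .traces import TraceSet

__all__ = [
    "LatencyProfile",
    "VSDCalibration",
    "onset_latency",
    "ap_features",
    "spatial_profile",
    "saltation_advancement",
    "calibrate_vsd",
]


@dataclass
class VSDCalibration:
    """Calibration of dye fluorescence to membrane potential.

    A somatic voltage step of known amplitude produces a fluorescence step
    ``dF_cal`` at the imaged site; the step amplitude reaching the site at
    path distance ``x_mm`` is attenuated by ``exp(-x/k)`` with attenuation
    length ``k_mm``.
    """

    v_step_soma_mV: float
    dF_cal: float
    x_mm: float
    k_mm: float = 1.18
    v_rest_mV: float = -75.0

    def __post_init__(self) -> None:
        if self.k_mm <= 0:
            raise ValueError("attenuation length k must be positive")
        if self.dF_cal == 0:
            raise ValueError("calibration fluorescence step dF_cal must be nonzero")

    @property
    def mV_per_dF(self) -> float:
        return self.v_step_soma_mV * math.exp(-self.x_mm / self.k_mm) / self.dF_cal


@dataclass
class LatencyProfile:
    """Per-position onset statistics along the axon."""

    table: pd.DataFrame        # columns: position_um, latency_ms, peak_mV,
    #                            max_dvdt_V_per_s, kind
    potential: str = "V_m"

    def __post_init__(self) -> None:
        pos = self.table["position_um"].to_numpy()
        if np.any(np.diff(pos) <= 0):
            raise ValueError("positions must be strictly increasing")

    def latency_at(self, position_um: float) -> float:
        """Latency linearly interpolated between profile positions."""
        pos = self.table["position_um"].to_numpy()
        lat = self.table["latency_ms"].to_numpy()
        if not pos[0] - 1e-9 <= position_um <= pos[-1] + 1e-9:
            raise ValueError(
                f"position {position_um} um outside the profile "
                f"[{pos[0]}, {pos[-1]}] um")
        return float(np.interp(position_um, pos, lat))


def onset_latency(trace: np.ndarray, dt_ms: float, fraction: float = 0.5,
                  t0_ms: float = 0.0) -> float:
    """Delay to ``fraction`` of the peak deflection above baseline.

    Baseline is the first sample; the first upward crossing of
    ``baseline + fraction*(peak - baseline)`` is located and linearly
    interpolated between samples.  Raises if the trace never crosses.
    """
    trace = np.asarray(trace, dtype=float)
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    base = trace[0]
    peak = trace.max()
    if peak <= base:
        raise ValueError("trace has no positive-going deflection")
    thr = base + fraction * (peak - base)
    above = trace >= thr
    idx = np.flatnonzero(above)
    i = int(idx[0])
    if i == 0:
        return t0_ms
    f = (thr - trace[i - 1]) / (trace[i] - trace[i - 1])
    return t0_ms + (i - 1 + f) * dt_ms


def ap_features(trace: np.ndarray, dt_ms: float,
                fraction: float = 0.5) -> tuple[float, float, float]:
    """(peak deflection mV, max dV/dt V/s, onset latency ms) of one trace.

    The rate of rise uses central differences (mV/ms == V/s).  A trace with
    no deflection raises through :func:`onset_latency`.
    """
    trace = np.asarray(trace, dtype=float)
    onset = onset_latency(trace, dt_ms, fraction)
    peak = float(trace.max() - trace[0])
    dvdt = float(np.gradient(trace, dt_ms).max())
    return peak, dvdt, onset


def spatial_profile(traces: TraceSet, potential: str = "V_m",
                    fraction: float = 0.5,
                    noise_threshold_mV: float = 0.0) -> LatencyProfile:
    """Onset latency, peak and max rate of rise versus axonal position.

    Uses all sites of the trace set carrying the requested potential
    (trial-averaged if multiple trials); positions are path distances.
    Sites whose peak deflection does not exceed ``noise_threshold_mV`` get
    ``NaN`` latency.  Per-internode latency maxima are flagged in the
    ``internode_latency_max`` column.
    """
    rows = []
    mean = traces.data.mean(axis=1)
    for i, s in enumerate(traces.sites):
        if s.get("potential", "V_m") != potential:
            continue
        tr = mean[i]
        pos = s.get("path_distance_um")
        kind = s.get("kind", "")
        peak = float(tr.max() - tr[0])
        if peak > noise_threshold_mV:
            lat = onset_latency(tr, traces.dt_ms, fraction, traces.t0_ms)
            dvdt = float(np.gradient(tr, traces.dt_ms).max())
        else:
            lat, dvdt = np.nan, np.nan
        rows.append({"position_um": pos, "latency_ms": lat, "peak_mV": peak,
                     "max_dvdt_V_per_s": dvdt, "kind": kind,
                     "section": s.get("section")})
    if len(rows) < 3:
        raise ValueError("spatial profile needs at least 3 positions")
    df = pd.DataFrame(rows).sort_values("position_um").reset_index(drop=True)
    if df["position_um"].duplicated().any():
        df = df.drop_duplicates("position_um").reset_index(drop=True)

    # flag the latency maximum within each internode section
    df["internode_latency_max"] = False
    for sec, grp in df[df["kind"] == "internode"].groupby("section"):
        if grp["latency_ms"].notna().any():
            df.loc[grp["latency_ms"].idxmax(), "internode_latency_max"] = True
    return LatencyProfile(df, potential)


def saltation_advancement(profile: LatencyProfile, node_pos_um: float,
                          offset_um: float = 5.0) -> float:
    """Nodal latency advancement over the flanking internodal axolemma (ms).

    ``mean(latency(node - offset), latency(node + offset)) - latency(node)``;
    positive means the node leads its surroundings (temporal saltation).
    Raises if the profile does not cover ``node_pos +/- offset``.
    """
    lat_n = profile.latency_at(node_pos_um)
    lat_l = profile.latency_at(node_pos_um - offset_um)
    lat_r = profile.latency_at(node_pos_um + offset_um)
    return 0.5 * (lat_l + lat_r) - lat_n


def calibrate_vsd(F_trace: np.ndarray, cal: VSDCalibration) -> np.ndarray:
    """Convert a fluorescence trace to membrane potential (mV).

    ``V(dF) = dF * (V_step_soma * exp(-x/k)) / dF_cal`` with the baseline
    (first sample) mapped to the resting potential.  Gain cancels because it
    multiplies both the trace and the calibration step.
    """
    F = np.asarray(F_trace, dtype=float)
    return cal.v_rest_mV + (F - F[0]) * cal.mV_per_dF
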