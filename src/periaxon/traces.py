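"""Multi-site, multi-trial voltage/fluorescence recordings with protocol metadata."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

__all__ = ["TraceSet"]


@dataclass
class TraceSet:
    """Recordings as a dense array of shape (n_sites, n_trials, n_samples).

    Attributes
    ----------
    data : ndarray (sites, trials, samples)
        mV for voltage, arbitrary units for fluorescence.
    dt_ms : float
        Sample period (1/rate); time axis is ``t0_ms + i*dt_ms``.
    sites : list of dict
        Per-site metadata; conventional keys: ``name``, ``section``, ``arc``,
        ``path_distance_um``, ``potential`` (one of ``V_m``/``V_my``/``V_mym``/``F``).
    trial_level_pA : ndarray or None
        Injected current level per trial, if the set spans several levels.
    protocol : dict
        Stimulus description (``pulse_onset_ms``, ``pulse_dur_ms``,
        ``amplitude_pA`` or list of levels, sampling rate, ...).
    meta : dict
        Free-form provenance (seed, ground truth for recovery scoring, ...).
    """

    data: np.ndarray
    dt_ms: float
    sites: list[dict]
    trial_level_pA: np.ndarray | None = None
    protocol: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)
    t0_ms: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim == 2:  # (sites, samples) -> single trial
            self.data = self.data[:, None, :]
        if self.data.ndim != 3:
            raise ValueError("TraceSet data must have shape (sites, trials, samples)")
        if len(self.sites) != self.data.shape[0]:
            raise ValueError("site metadata length does not match data")
        if self.trial_level_pA is not None:
            self.trial_level_pA = np.asarray(self.trial_level_pA, dtype=float)
            if self.trial_level_pA.shape[0] != self.data.shape[1]:
                raise ValueError("trial_level_pA length does not match trial count")

    @property
    def n_sites(self) -> int:
        return self.data.shape[0]

    @property
    def n_trials(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def time_ms(self) -> np.ndarray:
        return self.t0_ms + np.arange(self.n_samples) * self.dt_ms

    def site_index(self, name: str) -> int:
        for i, s in enumerate(self.sites):
            if s.get("name") == name:
                return i
        raise KeyError(f"no site named {name!r}")

    def get(self, name: str, trial: int | None = None) -> np.ndarray:
        i = self.site_index(name)
        if trial is None:
            return self.data[i]
        return self.data[i, trial]

    def levels(self) -> np.ndarray:
        if self.trial_level_pA is None:
            return np.array([])
        return np.unique(self.trial_level_pA)

    def select_level(self, level_pA: float) -> "TraceSet":
        if self.trial_level_pA is None:
            raise ValueError("trace set has no per-trial levels")
        mask = np.isclose(self.trial_level_pA, level_pA)
        if not mask.any():
            raise ValueError(f"no trials at level {level_pA} pA")
        return TraceSet(
            self.data[:, mask, :], self.dt_ms, list(self.sites),
            self.trial_level_pA[mask], dict(self.protocol), dict(self.meta),
            self.t0_ms,
        )

    def mean_over_trials(self) -> "TraceSet":
        return TraceSet(
            self.data.mean(axis=1, keepdims=True), self.dt_ms, list(self.sites),
            None, dict(self.protocol), dict(self.meta), self.t0_ms,
        )

    # -- I/O ---------------------------------------------------------------

    def to_hdf5(self, path: str | Path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data)
            f.attrs["dt_ms"] = self.dt_ms
            f.attrs["t0_ms"] = self.t0_ms
            f.attrs["sites"] = json.dumps(self.sites)
            f.attrs["protocol"] = json.dumps(self.protocol, default=float)
            f.attrs["meta"] = json.dumps(self.meta, default=float)
            if self.trial_level_pA is not None:
                f.create_dataset("trial_level_pA", data=self.trial_level_pA)

    @classmethod
    def from_hdf5(cls, path: str | Path) -> "TraceSet":
        with h5py.File(path, "r") as f:
            levels = f["trial_level_pA"][()] if "trial_level_pA" in f else None
            return cls(
                data=f["data"][()],
                dt_ms=float(f.attrs["dt_ms"]),
                sites=json.loads(f.attrs["sites"]),
                trial_level_pA=levels,
                protocol=json.loads(f.attrs["protocol"]),
                meta=json.loads(f.attrs["meta"]),
                t0_ms=float(f.attrs.get("t0_ms", 0.0)),
            )

    def to_csv(self, path: str | Path) -> None:
        """Wide CSV: time plus one column per (site, trial)."""
        cols = {"time_ms": self.time_ms}
        for i, s in enumerate(self.sites):
            name = s.get("name", f"site{i}")
            for j in range(self.n_trials):
                key = name if self.n_trials == 1 else f"{name}__trial{j}"
                cols[key] = self.data[i, j]
        pd.DataFrame(cols).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, dt_ms: float | None = None) -> "TraceSet":
        df = pd.read_csv(path)
        t = df["time_ms"].to_numpy()
        if dt_ms is None:
            dt_ms = float(t[1] - t[0])
        names: dict[str, list[np.ndarray]] = {}
        for col in df.columns:
            if col == "time_ms":
                continue
            base = col.split("__trial")[0]
            names.setdefault(base, []).append(df[col].to_numpy())
        data = np.stack([np.stack(v) for v in names.values()])
        sites = [{"name": k} for k in names]
        return cls(data, dt_ms, sites, t0_ms=float(t[0]))
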