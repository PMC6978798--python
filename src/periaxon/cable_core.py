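"""Discretization and implicit integration of the double-cable circuit.

The myelinated axon is modelled with two electrical layers.  The axon core
is a conventional cable (axial resistance from ``R_i``).  Under every
myelinated compartment a second unknown represents the periaxonal space:
the axolemma (``R_m``, ``C_m``) connects core to periaxonal layer, the
myelin sheath (``R_my``, ``C_my``) connects the periaxonal layer to ground,
and the periaxonal layer is itself longitudinally conductive (``r_pa``
inside internodes, ``r_pn`` inside paranodes) and grounded where the myelin
ends at the outer edge of each paranode.  Unmyelinated membrane (soma,
dendrites, AIS, nodes) is a single layer from core to ground.

State variables are the absolute core potential and the absolute periaxonal
potential per compartment; the three reported potentials are derived views:
transaxonal ``V_m = core - periaxonal``, transmyelin ``V_my = periaxonal``,
transfiber ``V_mym = core`` (so ``V_mym = V_m + V_my`` holds identically).

The conductance matrix ``G`` and capacitance matrix ``M`` are symmetric;
``M`` is positive definite.  Two integration routes are provided:

* implicit time stepping (backward Euler, default, or Crank-Nicolson),
  which also supports Dirichlet voltage clamps and the active extension;
* an exact linear-time-invariant route via the generalized symmetric
  eigendecomposition ``G v = w M v`` for piecewise-constant current
  stimuli, used where many passive evaluations are needed (fitting).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import scipy.linalg
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .morphology import Morphology
from .traces import TraceSet
from .ultrastructure import CableParams

__all__ = [
    "SolverConfig",
    "RecordSite",
    "Stimulus",
    "VoltageClampStim",
    "StimulusProtocol",
    "PipetteModel",
    "CompartmentGraph",
    "discretize",
    "simulate_passive",
    "ap_clamp",
    "axon_record_sites",
    "attach_pipette",
    "three_potentials",
    "to_single_cable",
    "pipette_wall_capacitance",
    "pipette_outer_area",
]

_UM_TO_CM = 1e-4

#: vacuum permittivity in uF/cm
EPS0_UF_PER_CM = 8.854e-8


@dataclass
class RecordSite:
    name: str
    section: int
    arc: float = 0.5
    potentials: tuple[str, ...] = ("V_m",)


@dataclass
class Stimulus:
    """Rectangular current step injected into a core compartment."""

    section: int
    arc: float
    amplitude_pA: float
    onset_ms: float
    duration_ms: float


@dataclass
class VoltageClampStim:
    """Dirichlet clamp of a core compartment to a sampled waveform."""

    section: int
    arc: float
    waveform_mV: np.ndarray
    waveform_dt_ms: float
    onset_ms: float = 0.0


@dataclass
class StimulusProtocol:
    stimuli: list[Stimulus] = field(default_factory=list)
    clamps: list[VoltageClampStim] = field(default_factory=list)
    sampling_rate_hz: float | None = None


@dataclass
class SolverConfig:
    dt_ms: float = 0.01
    method: str = "backward_euler"      # backward_euler | crank_nicolson | eigen
    d_lambda: float = 0.1
    tau_min_ms: float = 1.0
    t_stop_ms: float = 20.0
    e_rest_mV: float = -75.0
    record: list[RecordSite] = field(default_factory=list)
    ground_myelin_ends: bool = True     # hard ground at outer paranodal edges
    check_balance: bool = False

    def __post_init__(self) -> None:
        if self.dt_ms <= 0:
            raise ValueError("dt must be positive")
        if not (0 < self.d_lambda <= 1):
            raise ValueError("d_lambda must lie in (0, 1]")


@dataclass
class PipetteModel:
    """Tapering glass pipette tip modelled as an explicit cable.

    The wall is a passive membrane with fixed specific resistance and a
    specific capacitance from the fitted ``C_pip`` (or the geometric
    estimate of :func:`pipette_wall_capacitance`).  The axial resistance
    profile follows the taper and is rescaled so its series total equals
    the amplifier's bridge balance.
    """

    n_sections: int = 200
    section_len_um: float = 10.0
    tip_diam_um: float = 1.0
    back_diam_um: float = 530.0
    wall_R_GOhm_cm2: float = 50.0
    wall_C_uF_cm2: float = 1.29e-4      # uncompensated geometric reference
    bridge_balance_MOhm: float = 15.0

    def __post_init__(self) -> None:
        if self.bridge_balance_MOhm < 0:
            raise ValueError("bridge balance cannot be negative")
        if self.tip_diam_um <= 0 or self.back_diam_um < self.tip_diam_um:
            raise ValueError("pipette taper must be positive and monotone")


def pipette_wall_capacitance(
    L_cm: float,
    r_inner_cm: float,
    r_outer_cm: float,
    alpha_deg: float = 90.0,
    K_pip: float = 4.7,
) -> float:
    """Total wall capacitance (uF) of a conical pipette front end.

    ``C = 2*pi*L*K*eps0*sin(a) / ln((2*r_outer + L*cot(a)) / (2*r_inner + L*cot(a)))``;
    at ``a = 90 deg`` this reduces to the coaxial-cylinder form
    ``2*pi*L*K*eps0 / ln(r_outer/r_inner)``.
    """
    a = math.radians(alpha_deg)
    num = 2.0 * math.pi * L_cm * K_pip * EPS0_UF_PER_CM * math.sin(a)
    cot = math.cos(a) / math.sin(a)
    den = math.log((2 * r_outer_cm + L_cm * cot) / (2 * r_inner_cm + L_cm * cot))
    return num / den


def pipette_outer_area(r_outer_front_cm: float, r_outer_back_cm: float, L_cm: float) -> float:
    """Outer lateral surface area (cm^2) of the truncated-cone pipette tip."""
    dr = r_outer_back_cm - r_outer_front_cm
    return math.pi * (r_outer_back_cm + r_outer_front_cm) * math.sqrt(dr**2 + L_cm**2)


# ---------------------------------------------------------------------------
# compartment graph
# ---------------------------------------------------------------------------

_SINGLE_LAYER = ("soma", "dendrite", "ais", "axon", "node", "collateral",
                 "unmyelinated_end")


class CompartmentGraph:
    """Discretized electrical network (geometry + topology; matrices on demand)."""

    def __init__(self, morph: Morphology, params: CableParams, cfg: SolverConfig,
                 mode: str = "DC") -> None:
        self.morph = morph
        self.params = params
        self.cfg = cfg
        if mode not in ("DC", "SC", "DC_no_rpn"):
            raise ValueError(f"unknown circuit mode {mode!r}")
        self.mode = mode
        self._build(morph, params, cfg)

    # -- construction -------------------------------------------------------

    def _nseg(self, sec, params: CableParams, cfg: SolverConfig) -> int:
        if sec.kind == "pipette":
            return 1
        d = sec.mean_diameter()
        f_hz = 1000.0 / (2.0 * math.pi * cfg.tau_min_ms)
        lam_um = 1e5 * math.sqrt(d / (4.0 * math.pi * f_hz * params.R_i * params.C_m))
        n = int((sec.length_um / (cfg.d_lambda * lam_um) + 0.9) / 2.0) * 2 + 1
        return max(1, n)

    def _build(self, morph: Morphology, params: CableParams, cfg: SolverConfig) -> None:
        kinds: list[str] = []
        sec_ids: list[int] = []
        arcs: list[float] = []
        lens_cm: list[float] = []
        diams_cm: list[float] = []
        first_comp: dict[int, int] = {}
        last_comp: dict[int, int] = {}

        order = self._topo_order(morph)
        for sec in order:
            if any(d <= 0 for _, d in sec.diam_profile):
                raise ValueError(f"section {sec.id} has a zero/negative diameter")
            n = self._nseg(sec, params, cfg)
            edges = np.linspace(0.0, 1.0, n + 1)
            for k in range(n):
                c = 0.5 * (edges[k] + edges[k + 1])
                kinds.append(sec.kind)
                sec_ids.append(sec.id)
                arcs.append(c)
                lens_cm.append(sec.length_um / n * _UM_TO_CM)
                diams_cm.append(float(sec.diameter_at(c)) * _UM_TO_CM)
                if k == 0:
                    first_comp[sec.id] = len(kinds) - 1
            last_comp[sec.id] = len(kinds) - 1

        self.kind = np.array(kinds)
        self.sec_id = np.array(sec_ids)
        self.arc = np.array(arcs)
        self.len_cm = np.array(lens_cm)
        self.diam_cm = np.array(diams_cm)
        self.n_core = len(kinds)
        self.area_cm2 = np.pi * self.diam_cm * self.len_cm
        self.myel = np.isin(self.kind, ("paranode", "internode"))
        self._first_comp = first_comp
        self._last_comp = last_comp

        # core axial edges: (i, j); half geometric factor f with R_half = R_i * f
        core_edges: list[tuple[int, int]] = []
        half_fac = 4.0 * (self.len_cm / 2.0) / (np.pi * self.diam_cm**2)
        for sec in order:
            f0, l0 = first_comp[sec.id], last_comp[sec.id]
            for i in range(f0, l0):
                core_edges.append((i, i + 1))
            if sec.parent_id is not None and sec.parent_id in last_comp:
                core_edges.append((last_comp[sec.parent_id], f0))
        self.core_edges = np.array(core_edges, dtype=int).reshape(-1, 2)
        self.core_half_fac = half_fac

        # periaxonal unknowns and edges (DC only; SC keeps none)
        self.pa_index = np.full(self.n_core, -1, dtype=int)
        if self.mode != "SC":
            self.pa_index[self.myel] = self.n_core + np.arange(int(self.myel.sum()))
        self.n_pa = int((self.pa_index >= 0).sum())
        self.n = self.n_core + self.n_pa

        pa_edges: list[tuple[int, int]] = []      # core-comp indices i, j (both myel)
        pa_ground: list[int] = []                 # myel comp grounded at its outer face
        if self.mode != "SC":
            adjacency = self.core_edges
            for i, j in adjacency:
                mi, mj = self.myel[i], self.myel[j]
                if mi and mj:
                    pa_edges.append((i, j))
                elif mi and not mj:
                    pa_ground.append(i)
                elif mj and not mi:
                    pa_ground.append(j)
            # myelinated compartments at tree leaves / section chain ends
            deg = np.zeros(self.n_core, dtype=int)
            for i, j in adjacency:
                deg[i] += 1
                deg[j] += 1
            for i in np.flatnonzero(self.myel & (deg < 2)):
                pa_ground.append(int(i))
        self.pa_edges = np.array(pa_edges, dtype=int).reshape(-1, 2)
        self.pa_ground = np.array(sorted(set(pa_ground)), dtype=int)

        # internode-unit ordinal per myelinated compartment (for per-internode
        # overrides): each maximal run of myelinated sections along the tree is
        # one sheath unit.
        self.unit = np.full(self.n_core, -1, dtype=int)
        unit_of_sec: dict[int, int] = {}
        counter = 0
        for sec in order:
            if sec.kind in ("paranode", "internode"):
                par = sec.parent_id
                if par is not None and par in unit_of_sec:
                    unit_of_sec[sec.id] = unit_of_sec[par]
                else:
                    unit_of_sec[sec.id] = counter
                    counter += 1
        for sid, u in unit_of_sec.items():
            mask = self.sec_id == sid
            self.unit[mask] = u
        self.n_units = counter

        # pipette wall properties per compartment (set by attach_pipette)
        self.pip_wall_R_kohm_cm2 = np.full(self.n_core, np.nan)
        self.pip_wall_C_uF_cm2 = np.full(self.n_core, np.nan)
        self.pip_axial_R_ohm_half = np.full(self.n_core, np.nan)

    @staticmethod
    def _topo_order(morph: Morphology):
        root = morph.root()
        order = []
        stack = [root]
        while stack:
            sec = stack.pop()
            order.append(sec)
            stack.extend(reversed(morph.children(sec.id)))
        return order

    # -- lookups -------------------------------------------------------------

    def comp_at(self, section: int, arc: float) -> int:
        mask = self.sec_id == section
        if not mask.any():
            raise KeyError(f"no compartments for section {section}")
        idx = np.flatnonzero(mask)
        return int(idx[np.argmin(np.abs(self.arc[idx] - arc))])

    def with_params(self, params: CableParams) -> "CompartmentGraph":
        import copy
        g = copy.copy(self)
        g.params = params
        return g

    # -- matrix assembly -----------------------------------------------------

    def _per_comp_params(self, params: CableParams):
        ov = params.overrides or {}
        R_m = np.full(self.n_core, params.R_m)
        C_m = np.full(self.n_core, params.C_m)
        if "R_m_node" in ov:
            R_m[np.isin(self.kind, ("node", "unmyelinated_end"))] = ov["R_m_node"]
        if "R_m_internode" in ov:
            R_m[self.myel] = ov["R_m_internode"]
        R_my = np.full(self.n_core, params.R_my)
        C_my = np.full(self.n_core, params.C_my)
        for key, arr in (("R_my_unit", R_my), ("C_my_unit", C_my)):
            if key in ov:
                for u, val in ov[key].items():
                    arr[self.unit == int(u)] = val
        return R_m, C_m, R_my, C_my

    def assemble(self, params: CableParams | None = None,
                 channel_g: Sequence[tuple[np.ndarray, float]] = (),
                 e_rest: float | None = None):
        """Assemble (G, M, b) in uS / nF / nA with potentials in mV.

        ``channel_g`` is a sequence of (per-core-compartment conductance uS,
        reversal mV) pairs inserted on the axolemma layer.
        """
        if params is None:
            params = self.params
        if e_rest is None:
            e_rest = self.cfg.e_rest_mV
        n = self.n
        R_m, C_m, R_my, C_my = self._per_comp_params(params)

        rows: list[np.ndarray] = []
        cols: list[np.ndarray] = []
        gv: list[np.ndarray] = []
        mrows: list[np.ndarray] = []
        mcols: list[np.ndarray] = []
        mv: list[np.ndarray] = []
        b = np.zeros(n)

        def add_g(i, j, g):
            rows.append(i); cols.append(j); gv.append(g)

        def add_m(i, j, c):
            mrows.append(i); mcols.append(j); mv.append(c)

        idx = np.arange(self.n_core)
        pip = self.kind == "pipette"

        # membrane conductance/capacitance per core compartment
        g_mem = 1000.0 * self.area_cm2 / R_m            # uS
        c_mem = 1000.0 * self.area_cm2 * C_m            # nF
        if pip.any():
            g_mem[pip] = 1000.0 * self.area_cm2[pip] / self.pip_wall_R_kohm_cm2[pip]
            c_mem[pip] = 1000.0 * self.area_cm2[pip] * self.pip_wall_C_uF_cm2[pip]

        if self.mode == "SC":
            # series-combine axolemma and myelin on myelinated compartments
            g_my = 1000.0 * self.area_cm2 / R_my
            c_my = 1000.0 * self.area_cm2 * C_my
            m = self.myel
            g_comb = np.where(m, g_mem * g_my / (g_mem + g_my), g_mem)
            c_comb = np.where(m, c_mem * c_my / (c_mem + c_my), c_mem)
            add_g(idx, idx, g_comb)
            b[: self.n_core] += g_comb * e_rest
            add_m(idx, idx, c_comb)
        else:
            single = ~self.myel
            i_s = idx[single]
            add_g(i_s, i_s, g_mem[single])
            b[i_s] += g_mem[single] * e_rest
            add_m(i_s, i_s, c_mem[single])

            i_m = idx[self.myel]
            p_m = self.pa_index[i_m]
            gm = g_mem[self.myel]
            cm = c_mem[self.myel]
            # axolemma between core and periaxonal, battery e_rest
            add_g(i_m, i_m, gm); add_g(p_m, p_m, gm)
            add_g(i_m, p_m, -gm); add_g(p_m, i_m, -gm)
            b[i_m] += gm * e_rest
            b[p_m] -= gm * e_rest
            add_m(i_m, i_m, cm); add_m(p_m, p_m, cm)
            add_m(i_m, p_m, -cm); add_m(p_m, i_m, -cm)
            # myelin between periaxonal and ground, no battery
            g_my = 1000.0 * self.area_cm2[self.myel] / R_my[self.myel]
            c_my = 1000.0 * self.area_cm2[self.myel] * C_my[self.myel]
            add_g(p_m, p_m, g_my)
            add_m(p_m, p_m, c_my)

        # core axial conductances
        if len(self.core_edges):
            i, j = self.core_edges[:, 0], self.core_edges[:, 1]
            Rh = params.R_i * self.core_half_fac
            if pip.any():
                Rh = np.where(pip, self.pip_axial_R_ohm_half, Rh)
            g = 1e6 / (Rh[i] + Rh[j])
            add_g(i, i, g); add_g(j, j, g)
            add_g(i, j, -g); add_g(j, i, -g)

        # periaxonal axial conductances and paranodal grounds
        if self.mode != "SC":
            r_pn = params.r_pa if self.mode == "DC_no_rpn" else params.r_pn
            r_layer = np.where(self.kind == "paranode", r_pn, params.r_pa)
            half_R = r_layer * self.len_cm / 2.0
            if len(self.pa_edges):
                i, j = self.pa_edges[:, 0], self.pa_edges[:, 1]
                g = 1e6 / (half_R[i] + half_R[j])
                pi, pj = self.pa_index[i], self.pa_index[j]
                add_g(pi, pi, g); add_g(pj, pj, g)
                add_g(pi, pj, -g); add_g(pj, pi, -g)
            if self.cfg.ground_myelin_ends and len(self.pa_ground):
                i = self.pa_ground
                g = 1e6 / half_R[i]
                pi = self.pa_index[i]
                add_g(pi, pi, g)

        G = sp.csr_matrix(
            (np.concatenate(gv), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n, n),
        )
        M = sp.csr_matrix(
            (np.concatenate(mv), (np.concatenate(mrows), np.concatenate(mcols))),
            shape=(n, n),
        )

        # voltage-gated channels on the axolemma layer only
        for g_arr, e_ch in channel_g:
            g_arr = np.asarray(g_arr, dtype=float)
            nz = np.flatnonzero(g_arr)
            if nz.size == 0:
                continue
            i = nz
            p = self.pa_index[i]
            has_pa = p >= 0
            data = []
            r2 = []
            c2 = []
            r2.extend(i); c2.extend(i); data.extend(g_arr[i])
            if has_pa.any():
                im, pm = i[has_pa], p[has_pa]
                r2.extend(pm); c2.extend(pm); data.extend(g_arr[im])
                r2.extend(im); c2.extend(pm); data.extend(-g_arr[im])
                r2.extend(pm); c2.extend(im); data.extend(-g_arr[im])
                b[pm] -= g_arr[im] * e_ch
            b[i] += g_arr[i] * e_ch
            G = G + sp.csr_matrix((data, (r2, c2)), shape=(n, n))

        return G, M, b


def discretize(morph: Morphology, params: CableParams, cfg: SolverConfig,
               mode: str = "DC") -> CompartmentGraph:
    """Discretize a morphology with the d_lambda rule and build the network.

    Per section the compartment count is the smallest odd integer covering
    ``length / (d_lambda * lambda_f)`` where ``lambda_f`` is the AC length
    constant at ``f_m = 1/(2*pi*tau_min)``.
    """
    return CompartmentGraph(morph, params, cfg, mode=mode)


def to_single_cable(graph: CompartmentGraph) -> CompartmentGraph:
    """Degenerate the double cable to a single cable: the periaxonal layer is
    removed and axolemma + myelin combine in series per compartment."""
    return CompartmentGraph(graph.morph, graph.params, graph.cfg, mode="SC")


# ---------------------------------------------------------------------------
# pipette
# ---------------------------------------------------------------------------

def attach_pipette(graph: CompartmentGraph, section: int, arc: float,
                   pip: PipetteModel) -> CompartmentGraph:
    """Attach an explicitly modelled pipette cable at a recording site.

    The pipette is appended to the morphology as ``pipette`` sections and the
    graph is rebuilt; its axial profile is rescaled so the series total
    equals the bridge balance, the wall resistance is fixed and the wall
    capacitance comes from the model's ``wall_C_uF_cm2``.  Returns a new
    graph; record/stimulate at the last pipette section to emulate the
    electrode.
    """
    kind = graph.kind[graph.comp_at(section, arc)]
    if kind not in ("soma", "dendrite", "ais", "node"):
        raise ValueError(f"pipettes attach to somatic/dendritic/AIS/nodal sites, not {kind!r}")

    from .morphology import Section

    morph = graph.morph.copy()
    nid = morph.next_id()
    parent = section
    diams = np.linspace(pip.tip_diam_um, pip.back_diam_um, pip.n_sections + 1)
    pip_ids = []
    for k in range(pip.n_sections):
        morph.sections.append(Section(
            nid, "pipette", parent, pip.section_len_um,
            [(0.0, float(diams[k])), (1.0, float(diams[k + 1]))],
        ))
        pip_ids.append(nid)
        parent = nid
        nid += 1
    morph._index = {s.id: s for s in morph.sections}

    g = CompartmentGraph(morph, graph.params, graph.cfg, mode=graph.mode)
    mask = np.isin(g.sec_id, pip_ids)
    g.pip_wall_R_kohm_cm2[mask] = pip.wall_R_GOhm_cm2 * 1e6   # GOhm -> kOhm
    g.pip_wall_C_uF_cm2[mask] = pip.wall_C_uF_cm2
    # tapered axial profile rescaled to the bridge balance
    base_half = 4.0 * (g.len_cm[mask] / 2.0) / (np.pi * g.diam_cm[mask] ** 2)
    total = 2.0 * base_half.sum()
    target = pip.bridge_balance_MOhm * 1e6   # Ohm
    scale = target / total if total > 0 else 0.0
    g.pip_axial_R_ohm_half[mask] = np.maximum(base_half * scale, 1e-9)
    g.pipette_sections = pip_ids
    return g


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------

def _stim_vector(graph: CompartmentGraph, stimuli: Sequence[Stimulus]):
    """Per-stimulus (compartment index, nA amplitude, onset, offset)."""
    out = []
    for s in stimuli:
        c = graph.comp_at(s.section, s.arc)
        out.append((c, s.amplitude_pA * 1e-3, s.onset_ms, s.onset_ms + s.duration_ms))
    return out


def _record_indices(graph: CompartmentGraph, cfg: SolverConfig):
    sites = []
    for r in cfg.record:
        c = graph.comp_at(r.section, r.arc)
        for pot in r.potentials:
            sites.append((r.name, c, pot))
    return sites


def _extract(graph: CompartmentGraph, X: np.ndarray, comp: int, pot: str) -> np.ndarray:
    """X has shape (n_unknowns, n_samples)."""
    e = X[comp]
    p_idx = graph.pa_index[comp]
    p = X[p_idx] if p_idx >= 0 else np.zeros_like(e)
    if pot == "V_m":
        return e - p
    if pot == "V_my":
        return p
    if pot == "V_mym":
        return e
    raise ValueError(f"unknown potential {pot!r}")


def three_potentials(graph: CompartmentGraph, state: np.ndarray) -> dict[str, np.ndarray]:
    """Derive (V_m, V_my, V_mym) per core compartment from a state vector."""
    e = state[: graph.n_core]
    p = np.zeros(graph.n_core)
    m = graph.pa_index >= 0
    p[m] = state[graph.pa_index[m]]
    return {"V_m": e - p, "V_my": p, "V_mym": e}


def _rest_state(G, b) -> np.ndarray:
    return spla.spsolve(G.tocsc(), b)


def simulate_passive(graph: CompartmentGraph, protocol: StimulusProtocol,
                     cfg: SolverConfig | None = None,
                     params: CableParams | None = None) -> TraceSet:
    """Integrate the passive network and return recorded traces.

    Initial condition is the uniform resting state (core at ``e_rest``,
    periaxonal layer at 0).  With ``cfg.method == "eigen"`` and only current
    stimuli, the solution is evaluated exactly per piecewise-constant
    stimulus segment; otherwise implicit time stepping is used.
    """
    if cfg is None:
        cfg = graph.cfg
    if not cfg.record:
        raise ValueError("no record sites configured")
    if cfg.method == "eigen":
        if protocol.clamps:
            raise ValueError("the eigen route supports current stimuli only")
        return _simulate_eigen(graph, protocol, cfg, params)
    return _simulate_stepping(graph, protocol, cfg, params)


def _make_traceset(graph, cfg, X, protocol) -> TraceSet:
    sites = _record_indices(graph, cfg)
    data = np.stack([_extract(graph, X, c, pot) for (_, c, pot) in sites])
    meta_sites = []
    for name, c, pot in sites:
        meta_sites.append({
            "name": f"{name}:{pot}" if pot != "V_m" else name,
            "record_name": name,
            "potential": pot,
            "section": int(graph.sec_id[c]),
            "arc": float(graph.arc[c]),
            "path_distance_um": float(
                graph.morph.path_distance(int(graph.sec_id[c]), float(graph.arc[c]))
            ),
            "kind": str(graph.kind[c]),
        })
    prot = {
        "stimuli": [
            {"section": s.section, "arc": s.arc, "amplitude_pA": s.amplitude_pA,
             "onset_ms": s.onset_ms, "duration_ms": s.duration_ms}
            for s in protocol.stimuli
        ],
        "n_clamps": len(protocol.clamps),
        "t_stop_ms": cfg.t_stop_ms,
    }
    return TraceSet(data[:, None, :], cfg.dt_ms, meta_sites, None, prot, {})


def _simulate_stepping(graph, protocol, cfg, params=None) -> TraceSet:
    G, M, b0 = graph.assemble(params=params, e_rest=cfg.e_rest_mV)
    n = graph.n
    nsteps = int(round(cfg.t_stop_ms / cfg.dt_ms))
    dt = cfg.dt_ms

    stims = _stim_vector(graph, protocol.stimuli)
    clamp_comps = []
    clamp_waves = []
    for cl in protocol.clamps:
        c = graph.comp_at(cl.section, cl.arc)
        if graph.kind[c] in ("internode", "paranode"):
            raise ValueError("voltage clamps attach to nodal/unmyelinated sites only")
        tq = np.arange(nsteps + 1) * dt - cl.onset_ms
        wt = np.arange(len(cl.waveform_mV)) * cl.waveform_dt_ms
        wave = np.interp(tq, wt, cl.waveform_mV,
                         left=cl.waveform_mV[0], right=cl.waveform_mV[-1])
        clamp_comps.append(c)
        clamp_waves.append(wave)

    cn = cfg.method == "crank_nicolson"
    if cn:
        A = (M / dt + 0.5 * G).tolil()
        B = (M / dt - 0.5 * G).tocsr()
    else:
        A = (M / dt + G).tolil()
        B = (M / dt).tocsr()
    for c in clamp_comps:
        A.rows[c] = [c]
        A.data[c] = [1.0]
    lu = spla.splu(A.tocsc())

    x = _rest_state(G, b0)
    for c, w in zip(clamp_comps, clamp_waves):
        x[c] = w[0]
    X = np.empty((n, nsteps + 1))
    X[:, 0] = x
    max_resid = 0.0

    def b_interval(k):
        # drive treated as constant over each step; evaluated at the midpoint
        t = (k + 0.5) * dt
        b = b0.copy()
        for c, amp, t0, t1 in stims:
            if t0 < t < t1:
                b[c] += amp
        return b

    Gcsr = G.tocsr()
    for k in range(nsteps):
        bk = b_interval(k)
        rhs = B @ x + bk
        for c, w in zip(clamp_comps, clamp_waves):
            rhs[c] = w[k + 1]
        x_new = lu.solve(rhs)
        if cfg.check_balance:
            # Kirchhoff residual of the implicit update at unclamped rows
            if cn:
                res = (M / dt) @ (x_new - x) + 0.5 * Gcsr @ (x_new + x) - bk
            else:
                res = (M / dt) @ (x_new - x) + Gcsr @ x_new - bk
            for c in clamp_comps:
                res[c] = 0.0
            scale = max(np.abs(Gcsr @ x_new).max(), 1e-30)
            max_resid = max(max_resid, np.abs(res).max() / scale)
        x = x_new
        X[:, k + 1] = x

    ts = _make_traceset(graph, cfg, X, protocol)
    if cfg.check_balance:
        ts.meta["max_charge_residual"] = float(max_resid)
    return ts


def _simulate_eigen(graph, protocol, cfg, params=None) -> TraceSet:
    G, M, b0 = graph.assemble(params=params, e_rest=cfg.e_rest_mV)
    Gd = G.toarray()
    Md = M.toarray()
    w, V = scipy.linalg.eigh(Gd, Md)
    w = np.maximum(w, 1e-300)

    stims = _stim_vector(graph, protocol.stimuli)
    breaks = sorted({0.0, cfg.t_stop_ms} |
                    {t for (_, _, t0, t1) in stims for t in (t0, t1)
                     if 0.0 < t < cfg.t_stop_ms})
    nsteps = int(round(cfg.t_stop_ms / cfg.dt_ms))
    tgrid = np.arange(nsteps + 1) * cfg.dt_ms

    x0 = _rest_state(G, b0)
    y = V.T @ (Md @ x0)
    X = np.empty((graph.n, nsteps + 1))
    for t_a, t_b in zip(breaks, breaks[1:] + [cfg.t_stop_ms]):
        if t_b <= t_a:
            continue
        b = b0.copy()
        for c, amp, t0, t1 in stims:
            if t0 - 1e-9 <= t_a < t1 - 1e-9:
                b[c] += amp
        beta = V.T @ b
        yss = beta / w
        sel = (tgrid >= t_a - 1e-9) & (tgrid <= t_b + 1e-9)
        tt = tgrid[sel] - t_a
        Y = yss[:, None] + (y - yss)[:, None] * np.exp(-w[:, None] * tt[None, :])
        X[:, sel] = V @ Y
        y = yss + (y - yss) * np.exp(-w * (t_b - t_a))
    return _make_traceset(graph, cfg, X, protocol)


def ap_clamp(graph: CompartmentGraph, node_section: int, waveform_mV: np.ndarray,
             cfg: SolverConfig, waveform_dt_ms: float | None = None,
             onset_ms: float = 0.0) -> TraceSet:
    """Drive a nodal compartment with a voltage-command waveform and record
    the passive downstream spread of all three potentials along the axon.

    The clamp is a Dirichlet (row-substitution) condition: the core
    potential at the node follows the waveform exactly.  Rejects clamp
    sites inside myelinated domains.
    """
    c = graph.comp_at(node_section, 0.5)
    if graph.kind[c] in ("internode", "paranode"):
        raise ValueError("AP clamp sites must be nodal/unmyelinated, not inside an internode")
    if waveform_dt_ms is None:
        waveform_dt_ms = cfg.dt_ms
    if waveform_dt_ms > cfg.dt_ms + 1e-12:
        raise ValueError("clamp waveform must be sampled at least at the solver rate")
    if not cfg.record:
        cfg = replace(cfg, record=axon_record_sites(graph))
    protocol = StimulusProtocol(clamps=[VoltageClampStim(
        node_section, 0.5, np.asarray(waveform_mV, dtype=float),
        waveform_dt_ms, onset_ms)])
    return _simulate_stepping(graph, protocol, cfg)


def axon_record_sites(graph: CompartmentGraph,
                      potentials: tuple[str, ...] = ("V_m", "V_my", "V_mym")) -> list[RecordSite]:
    """One record site per compartment along the primary axon."""
    path_ids = [s.id for s in graph.morph.axon_path()]
    sites = []
    k = 0
    for sid in path_ids:
        for i in np.flatnonzero(graph.sec_id == sid):
            sites.append(RecordSite(
                name=f"ax{k:03d}", section=int(sid), arc=float(graph.arc[i]),
                potentials=potentials))
            k += 1
    return sites
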