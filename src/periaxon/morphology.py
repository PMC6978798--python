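"""Labeled section trees for neurons with myelinated axons.

A morphology is a tree of cylindrical/tapering ``Section`` objects rooted at
the soma.  Axonal sections carry domain labels (node of Ranvier, paranode,
internode, unmyelinated end, collateral) that determine which electrical
stencil the solver applies: myelinated domains (paranode, internode) get the
two-layer double-cable stencil, everything else is a single membrane.

Positions are path distances in micrometres measured from the root's
proximal end; diameters are piecewise-linear profiles along each section.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

__all__ = [
    "Section",
    "Morphology",
    "KINDS",
    "annotate_axon_domains",
    "read_morphology",
    "write_morphology",
    "read_swc",
    "validate",
    "DEFAULT_PARANODE_LEN_UM",
    "DEFAULT_NODE_LEN_UM",
]

KINDS = frozenset({
    "soma", "dendrite", "ais", "axon", "node", "paranode", "internode",
    "collateral", "unmyelinated_end", "pipette",
})

MYELINATED_KINDS = frozenset({"paranode", "internode"})

#: Paranode length (um) from longitudinal EM of CNS paranodes.
DEFAULT_PARANODE_LEN_UM = 2.3
#: Node of Ranvier length (um); typical CNS value, configurable everywhere.
DEFAULT_NODE_LEN_UM = 1.0


@dataclass
class Section:
    """One unbranched cable piece with a tapering diameter profile.

    ``diam_profile`` is an ordered list of ``(arc_fraction, diameter_um)``
    pairs with arc fractions in [0, 1]; diameters interpolate linearly in
    between.
    """

    id: int
    kind: str
    parent_id: int | None
    length_um: float
    diam_profile: list[tuple[float, float]]

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown section kind {self.kind!r}")
        self.diam_profile = [(float(a), float(d)) for a, d in self.diam_profile]

    @property
    def myelinated(self) -> bool:
        return self.kind in MYELINATED_KINDS

    def diameter_at(self, arc: float | np.ndarray):
        """Diameter (um) at arc fraction(s) in [0, 1], linearly interpolated."""
        xs = np.array([a for a, _ in self.diam_profile])
        ds = np.array([d for _, d in self.diam_profile])
        return np.interp(arc, xs, ds)

    def mean_diameter(self) -> float:
        xs = np.array([a for a, _ in self.diam_profile])
        ds = np.array([d for _, d in self.diam_profile])
        if len(xs) == 1:
            return float(ds[0])
        return float(np.trapezoid(ds, xs) / (xs[-1] - xs[0]))


@dataclass
class Morphology:
    """A tree of sections rooted at a single soma."""

    sections: list[Section]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._index = {s.id: s for s in self.sections}

    def section(self, sid: int) -> Section:
        return self._index[sid]

    def children(self, sid: int) -> list[Section]:
        return [s for s in self.sections if s.parent_id == sid]

    def root(self) -> Section:
        roots = [s for s in self.sections if s.parent_id is None]
        if len(roots) != 1:
            raise ValueError(f"morphology must have exactly one root, found {len(roots)}")
        return roots[0]

    def next_id(self) -> int:
        return max((s.id for s in self.sections), default=-1) + 1

    def section_start_distance(self, sid: int) -> float:
        """Path distance (um) from the root's proximal end to a section start."""
        dist = 0.0
        sec = self.section(sid)
        seen = set()
        while sec.parent_id is not None:
            if sec.id in seen:
                raise ValueError("cycle in parent references")
            seen.add(sec.id)
            sec = self.section(sec.parent_id)
            dist += sec.length_um
        return dist

    def path_distance(self, sid: int, arc: float = 0.5) -> float:
        """Path distance (um) from root to the point at ``arc`` within a section."""
        return self.section_start_distance(sid) + arc * self.section(sid).length_um

    def axon_path(self) -> list[Section]:
        """Ordered sections of the primary axon (AIS outward, collaterals excluded)."""
        axon_kinds = {"ais", "axon", "node", "paranode", "internode", "unmyelinated_end"}
        path: list[Section] = []
        # start at the first axonal child of the soma (or of a dendrite stub)
        frontier = [self.root()]
        start = None
        while frontier:
            sec = frontier.pop()
            for ch in self.children(sec.id):
                if ch.kind in axon_kinds:
                    start = ch
                    frontier = []
                    break
                frontier.append(ch)
        if start is None:
            return []
        sec = start
        while sec is not None:
            path.append(sec)
            nxt = [c for c in self.children(sec.id) if c.kind in axon_kinds]
            sec = nxt[0] if nxt else None
        return path

    def copy(self) -> "Morphology":
        secs = [Section(s.id, s.kind, s.parent_id, s.length_um, list(s.diam_profile))
                for s in self.sections]
        return Morphology(secs, dict(self.metadata))


# ---------------------------------------------------------------------------
# domain annotation
# ---------------------------------------------------------------------------

def annotate_axon_domains(
    morph: Morphology,
    node_positions: Sequence[float],
    paranode_len: float = DEFAULT_PARANODE_LEN_UM,
    node_len: float = DEFAULT_NODE_LEN_UM,
    myelin_end: float | None = None,
) -> Morphology:
    """Split the plain axon of ``morph`` into node/paranode/internode domains.

    ``node_positions`` are node centres as path distances (um) from the start
    of the axon chain (the contiguous run of sections with kind ``axon``).
    Each node gets flanking paranodes of ``paranode_len``; the gaps in
    between become internodes.  A node whose proximal edge coincides with the
    axon start (centre <= node_len/2) is placed flush at the start without a
    proximal paranode (a heminode at the end of the AIS).  If ``myelin_end``
    is given, myelin stops there: a terminal paranode is placed just before
    it and the remainder becomes an ``unmyelinated_end``.

    Total axon path length is conserved exactly; overlapping domains raise
    ``ValueError`` naming the offending positions.
    """
    positions = [float(p) for p in node_positions]
    if sorted(positions) != positions:
        raise ValueError(f"node positions must be strictly increasing: {positions}")
    for a, b in zip(positions, positions[1:]):
        if b - a < 2 * paranode_len + node_len:
            raise ValueError(
                f"domains overlap: nodes at {a} and {b} um are closer than "
                f"2*paranode_len + node_len = {2 * paranode_len + node_len} um"
            )

    out = morph.copy()
    chain = [s for s in out.axon_path() if s.kind == "axon"]
    if not chain:
        raise ValueError("morphology has no plain 'axon' sections to annotate")
    total_len = sum(s.length_um for s in chain)

    # global diameter profile over the chain, arc measured in um from chain start
    arcs: list[float] = []
    diams: list[float] = []
    offset = 0.0
    for s in chain:
        for a, d in s.diam_profile:
            arcs.append(offset + a * s.length_um)
            diams.append(d)
        offset += s.length_um
    arcs_arr = np.array(arcs)
    diams_arr = np.array(diams)

    def diam_at(x: float) -> float:
        return float(np.interp(x, arcs_arr, diams_arr))

    # breakpoints: list of (start, end, kind)
    pieces: list[tuple[float, float, str]] = []
    cursor = 0.0
    for p in positions:
        n0, n1 = p - node_len / 2.0, p + node_len / 2.0
        if p <= node_len / 2.0 + 1e-9:
            n0, n1 = 0.0, node_len      # heminode flush at the axon start
        if n0 < -1e-9:
            raise ValueError(f"node at {p} um extends before the axon start")
        left_pn = n0 - paranode_len
        if left_pn > cursor + 1e-9:
            pieces.append((cursor, left_pn, "internode"))
            pieces.append((left_pn, n0, "paranode"))
        elif abs(n0 - cursor) <= 1e-9 or left_pn <= cursor + 1e-9:
            # node flush at the current cursor: heminode, no proximal paranode
            if n0 < cursor - 1e-9:
                raise ValueError(f"domains overlap at node position {p} um")
            n0 = cursor
            n1 = n0 + node_len
        pieces.append((n0, n1, "node"))
        cursor = n1 + paranode_len
        if cursor > total_len + 1e-9:
            raise ValueError(f"node at {p} um leaves no room for its distal paranode")
        pieces.append((n1, cursor, "paranode"))

    end_of_myelin = total_len if myelin_end is None else float(myelin_end)
    if end_of_myelin > total_len + 1e-9:
        raise ValueError("myelin_end beyond the axon length")
    if myelin_end is None:
        if cursor < total_len - 1e-9:
            pieces.append((cursor, total_len, "internode"))
    else:
        pn_start = end_of_myelin - paranode_len
        if pn_start < cursor - 1e-9:
            raise ValueError("myelin_end overlaps the last node's paranode")
        if pn_start > cursor + 1e-9:
            pieces.append((cursor, pn_start, "internode"))
        pieces.append((pn_start, end_of_myelin, "paranode"))
        if end_of_myelin < total_len - 1e-9:
            pieces.append((end_of_myelin, total_len, "unmyelinated_end"))

    # drop zero-length pieces, sanity check continuity
    pieces = [(a, b, k) for a, b, k in pieces if b - a > 1e-9]
    for (a0, b0, _), (a1, b1, _) in zip(pieces, pieces[1:]):
        if abs(a1 - b0) > 1e-9:
            raise ValueError("internal error: non-contiguous domain pieces")
    if abs(pieces[-1][1] - total_len) > 1e-9 or abs(pieces[0][0]) > 1e-9:
        raise ValueError("internal error: domain pieces do not span the axon")

    # rebuild: remove old chain, attach new pieces
    chain_ids = {s.id for s in chain}
    parent_of_chain = chain[0].parent_id
    tail_children = [s for s in out.sections if s.parent_id == chain[-1].id]
    out.sections = [s for s in out.sections if s.id not in chain_ids]
    nid = max((s.id for s in out.sections), default=-1) + 1
    prev = parent_of_chain
    for a, b, kind in pieces:
        prof = [(0.0, diam_at(a))]
        interior = [(x - a) / (b - a) for x in arcs if a < x < b]
        prof += [(f, diam_at(a + f * (b - a))) for f in interior]
        prof.append((1.0, diam_at(b)))
        out.sections.append(Section(nid, kind, prev, b - a, prof))
        prev = nid
        nid += 1
    for s in tail_children:
        s.parent_id = prev
    out._index = {s.id: s for s in out.sections}
    out.metadata.setdefault("annotation", {})
    out.metadata["annotation"].update(
        {"paranode_len_um": paranode_len, "node_len_um": node_len}
    )
    return out


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate(morph: Morphology, paranode_len: float | None = None) -> list[str]:
    """Return a list of invariant violations (empty list == valid).

    Checks: unique ids, a single soma root, an acyclic parent tree, positive
    lengths and diameters, paranode lengths matching the configured value,
    and internodes never directly abutting soma or dendrite.
    """
    v: list[str] = []
    ids = [s.id for s in morph.sections]
    if len(ids) != len(set(ids)):
        v.append("section ids are not unique")
    idset = set(ids)
    roots = [s for s in morph.sections if s.parent_id is None]
    if len(roots) != 1:
        v.append(f"expected exactly one root section, found {len(roots)}")
    elif roots[0].kind != "soma":
        v.append(f"root section kind is {roots[0].kind!r}, expected 'soma'")

    for s in morph.sections:
        if s.parent_id is not None and s.parent_id not in idset:
            v.append(f"section {s.id} references missing parent {s.parent_id}")
        if not s.length_um > 0:
            v.append(f"section {s.id} has non-positive length {s.length_um}")
        if any(d <= 0 for _, d in s.diam_profile):
            v.append(f"section {s.id} has a non-positive diameter")
        fracs = [a for a, _ in s.diam_profile]
        if fracs != sorted(fracs) or not fracs or fracs[0] < 0 or fracs[-1] > 1:
            v.append(f"section {s.id} has an invalid diameter profile")

    # cycles
    for s in morph.sections:
        seen = set()
        cur: Section | None = s
        while cur is not None and cur.parent_id is not None:
            if cur.id in seen:
                v.append(f"cycle in parent references at section {s.id}")
                break
            seen.add(cur.id)
            cur = morph._index.get(cur.parent_id)

    pl = paranode_len
    if pl is None:
        pl = morph.metadata.get("annotation", {}).get(
            "paranode_len_um", DEFAULT_PARANODE_LEN_UM
        )
    for s in morph.sections:
        if s.kind == "paranode" and abs(s.length_um - pl) > 1e-6:
            v.append(
                f"paranode {s.id} length {s.length_um} um != configured {pl} um"
            )
        if s.kind == "internode":
            neighbours = []
            if s.parent_id in idset:
                neighbours.append(morph._index[s.parent_id].kind)
            neighbours += [c.kind for c in morph.children(s.id)]
            for k in neighbours:
                if k in ("soma", "dendrite"):
                    v.append(f"internode {s.id} directly adjacent to {k} without a paranode")
    return v


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

_FORMAT_KEY = "periaxon_morphology"
_FORMAT_VERSION = 1


def _to_payload(morph: Morphology) -> dict:
    return {
        _FORMAT_KEY: _FORMAT_VERSION,
        "metadata": morph.metadata,
        "sections": [
            {
                "id": s.id,
                "kind": s.kind,
                "parent": s.parent_id,
                "length_um": s.length_um,
                "diam": [[a, d] for a, d in s.diam_profile],
            }
            for s in morph.sections
        ],
    }


def _from_payload(payload: dict, source: str) -> Morphology:
    if _FORMAT_KEY not in payload:
        raise ValueError(f"{source}: not a periaxon morphology file")
    secs = []
    for rec in payload["sections"]:
        secs.append(
            Section(
                id=int(rec["id"]),
                kind=str(rec["kind"]),
                parent_id=None if rec["parent"] is None else int(rec["parent"]),
                length_um=float(rec["length_um"]),
                diam_profile=[(float(a), float(d)) for a, d in rec["diam"]],
            )
        )
    morph = Morphology(secs, dict(payload.get("metadata") or {}))
    # fail fast on cyclic parents
    for s in morph.sections:
        morph.section_start_distance(s.id)
    return morph


def write_morphology(morph: Morphology, path: str | Path) -> None:
    """Write a morphology as YAML (or JSON for ``.json`` paths); lossless."""
    path = Path(path)
    payload = _to_payload(morph)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(payload, indent=1))
    else:
        path.write_text(yaml.safe_dump(payload, sort_keys=False))


def read_morphology(path: str | Path) -> Morphology:
    """Read a morphology written by :func:`write_morphology`, or an SWC file."""
    path = Path(path)
    if path.suffix.lower() == ".swc":
        return read_swc(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        payload = json.loads(text)
    else:
        payload = yaml.safe_load(text)
    if not isinstance(payload, dict):
        raise ValueError(f"{path}: malformed morphology file")
    return _from_payload(payload, str(path))


_SWC_KIND = {1: "soma", 2: "axon", 3: "dendrite", 4: "dendrite"}


def read_swc(path: str | Path) -> Morphology:
    """Import a standard 7-column SWC file as an unannotated morphology.

    Unbranched runs of points with the same type are merged into single
    sections with piecewise-linear diameter profiles; myelin annotation is
    deferred to :func:`annotate_axon_domains`.  A single-point soma becomes a
    cylinder of length and diameter ``2*radius``.
    """
    path = Path(path)
    points: dict[int, tuple[int, float, float, float, float, int]] = {}
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 7:
            raise ValueError(f"{path}:{lineno}: expected 7 columns, got {len(parts)}")
        try:
            pid = int(parts[0]); ptype = int(parts[1])
            x, y, z, r = (float(q) for q in parts[2:6])
            parent = int(parts[6])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: malformed SWC record: {exc}") from exc
        if pid in points:
            raise ValueError(f"{path}:{lineno}: duplicate point id {pid}")
        points[pid] = (ptype, x, y, z, r, parent)

    if not points:
        raise ValueError(f"{path}: empty SWC file")

    # cycle detection on the point graph
    for pid in points:
        seen = set()
        cur = pid
        while cur != -1:
            if cur in seen:
                raise ValueError(f"{path}: cyclic parent reference at point {pid}")
            seen.add(cur)
            if cur not in points:
                if cur == pid:
                    break
                raise ValueError(f"{path}: point references missing parent {cur}")
            cur = points[cur][5]

    children: dict[int, list[int]] = {}
    for pid, rec in points.items():
        children.setdefault(rec[5], []).append(pid)

    def dist(a: int, b: int) -> float:
        _, xa, ya, za, _, _ = points[a]
        _, xb, yb, zb, _, _ = points[b]
        return math.dist((xa, ya, za), (xb, yb, zb))

    sections: list[Section] = []
    sec_of_point: dict[int, int] = {}
    next_sid = 0

    roots = children.get(-1, [])
    if len(roots) != 1:
        raise ValueError(f"{path}: expected one SWC root, found {len(roots)}")
    root = roots[0]
    rtype, _, _, _, rr, _ = points[root]
    kind = _SWC_KIND.get(rtype, "dendrite")
    soma_pts = [root]
    # absorb contiguous soma points into the root section
    frontier = [p for p in children.get(root, []) if points[p][0] == 1] if rtype == 1 else []
    while frontier:
        p = frontier.pop()
        soma_pts.append(p)
        frontier.extend(q for q in children.get(p, []) if points[q][0] == 1)
    soma_len = sum(dist(points[p][5], p) for p in soma_pts if points[p][5] in points)
    if soma_len <= 0:
        soma_len = 2 * rr
    sections.append(Section(next_sid, kind if rtype == 1 else kind,
                            None, soma_len, [(0.0, 2 * rr), (1.0, 2 * rr)]))
    for p in soma_pts:
        sec_of_point[p] = next_sid
    next_sid += 1

    # walk out of the soma, building one section per unbranched same-type run
    stack = [(p, sec_of_point[points[p][5]] if points[p][5] in sec_of_point else 0)
             for sp in soma_pts for p in children.get(sp, []) if p not in sec_of_point]
    while stack:
        start, parent_sid = stack.pop()
        run = [start]
        cur = start
        while True:
            ch = children.get(cur, [])
            if len(ch) == 1 and points[ch[0]][0] == points[cur][0]:
                cur = ch[0]
                run.append(cur)
            else:
                break
        ptype = points[start][0]
        seg_pts = [points[start][5]] + run if points[start][5] in points else run
        arc = [0.0]
        for a, b in zip(seg_pts, seg_pts[1:]):
            arc.append(arc[-1] + dist(a, b))
        total = arc[-1] if arc[-1] > 0 else 2 * points[start][4]
        prof = [(x / total, 2 * points[p][4]) for x, p in zip(arc, seg_pts)]
        if len(prof) == 1:
            prof = [(0.0, prof[0][1]), (1.0, prof[0][1])]
        sections.append(Section(next_sid, _SWC_KIND.get(ptype, "dendrite"),
                                parent_sid, total, prof))
        for p in run:
            sec_of_point[p] = next_sid
        sid = next_sid
        next_sid += 1
        for nxt in children.get(run[-1], []):
            stack.append((nxt, sid))

    return Morphology(sections, {"source": str(path), "format": "swc"})
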