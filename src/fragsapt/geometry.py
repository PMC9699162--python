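"""Macrocycle conformer descriptors and geometric hydrogen-bond detection.

Each methylene linker of a calixarene-type macroring carries a pair of
dihedral angles (φ, χ) through the atoms C1–C2–C3–C4–C5, where C2, C3, C4
run along the macroring (attachment carbon, bridge CH2, next attachment
carbon) and C1/C5 are the hydroxyl-bearing ring carbons.  The *sign
pattern* of the ordered (φ, χ) pairs — read counterclockwise as seen from
the macrocycle's top side, the side holding the majority of the phenolic
oxygens — distinguishes the pinched-cone (pc), 1,2,3-alternate (al) and
winged-cone (wc) conformers:

    pc:  (±∓±±∓±)      al:  (∓∓±±∓∓)      wc:  (∓=∓±=±)

with ± meaning (φ>0, χ<0), ∓ the reverse, and = both angles of one pair
sharing a sign.  Matching is performed up to cyclic rotation of the ring
numbering and a global sign flip (enantiomers).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .chemgraph import MoleculeGraph, dihedral_angle, AROMATIC

__all__ = [
    "ConformerDescriptor",
    "HBond",
    "HBondParams",
    "conformer_descriptors",
    "classify_conformer",
    "detect_hbonds",
    "hbond_topology",
    "VDW_RADII",
]

VDW_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "P": 1.80, "S": 1.80, "Cl": 1.75, "Br": 1.85, "I": 1.98,
    "B": 1.92, "Si": 2.10,
}

CONFORMER_TEMPLATES = {
    "pc": "PMPPMP",
    "al": "MMPPMM",
    "wc": "M=MP=P",
}
_FLIP = {"P": "M", "M": "P", "N": "B", "B": "N"}


@dataclass
class ConformerDescriptor:
    pairs: list[tuple[float, float]]
    sign_pattern: str
    label: str = "other"

    @property
    def n_linkers(self) -> int:
        return len(self.pairs)


def _pair_symbol(phi: float, chi: float) -> str:
    if phi > 0 and chi < 0:
        return "P"  # ±
    if phi < 0 and chi > 0:
        return "M"  # ∓
    if phi < 0 and chi < 0:
        return "N"  # = (canonical, both negative)
    return "B"      # = (both positive, enantiomeric)


def conformer_descriptors(
    mol: MoleculeGraph,
    macroring: Mapping,
    top_normal: Sequence[float] | None = None,
) -> ConformerDescriptor:
    """Compute the ordered (φ, χ) pairs of a macrocycle.

    ``macroring`` is the ring annotation: ``{"rings": [...], "linkers":
    [...]}`` listing, in macroring order, each ring's attachment carbons
    (``c_in``, ``c_out``), hydroxyl carbon (``c_oh``) and phenolic oxygen
    (``oxygen``), and each linker's bridge carbon.  The top side is the
    side of the macrocycle mean plane holding more phenolic oxygens; a tie
    must be broken with an explicit ``top_normal``.
    """
    rings = macroring["rings"]
    linkers = macroring["linkers"]
    if len(rings) < 3 or len(rings) != len(linkers):
        raise ValueError("not a macrocycle: need n rings alternating with n linkers")
    pos = {a.index: a.coords for a in mol.atoms}
    anchor_ids = [r["c_in"] for r in rings] + [r["c_out"] for r in rings] + [
        l["carbon"] for l in linkers
    ]
    anchors = np.array([pos[i] for i in anchor_ids])
    centroid = anchors.mean(axis=0)
    # mean-plane normal from the smallest principal direction
    _, _, vt = np.linalg.svd(anchors - centroid)
    normal = vt[2]

    if top_normal is not None:
        normal = np.asarray(top_normal, float)
        normal = normal / np.linalg.norm(normal)
    else:
        side = 0
        for r in rings:
            ox = r.get("oxygen")
            if ox is not None:
                side += np.sign(float(np.dot(pos[ox] - centroid, normal)))
        if side == 0:
            warnings.warn(
                "phenolic oxygens are split evenly between the two faces; "
                "supply top_normal explicitly", stacklevel=2
            )
        elif side < 0:
            normal = -normal

    # counterclockwise ordering of rings as seen from the top
    ring_centers = np.array(
        [(pos[r["c_in"]] + pos[r["c_out"]]) / 2.0 for r in rings]
    )
    area = 0.0
    for k in range(len(rings)):
        a = ring_centers[k] - centroid
        b = ring_centers[(k + 1) % len(rings)] - centroid
        area += float(np.dot(np.cross(a, b), normal))
    order = list(range(len(rings)))
    if area < 0:  # stored clockwise from the top: reverse traversal
        order = order[::-1]
        rings = [rings[i] for i in order]
        linkers = [linkers[(i - 1) % len(linkers)] for i in order]
        rings = [
            {**r, "c_in": r["c_out"], "c_out": r["c_in"]} for r in rings
        ]

    pairs = []
    n = len(rings)
    for k in range(n):
        r1, r2 = rings[k], rings[(k + 1) % n]
        c3 = linkers[k]["carbon"]
        phi = dihedral_angle(pos[r1["c_oh"]], pos[r1["c_out"]], pos[c3], pos[r2["c_in"]])
        chi = dihedral_angle(pos[r1["c_out"]], pos[c3], pos[r2["c_in"]], pos[r2["c_oh"]])
        pairs.append((phi, chi))
    pattern = "".join(_pair_symbol(*p) for p in pairs)
    desc = ConformerDescriptor(pairs, pattern)
    if n == 6:
        desc.label = classify_conformer(desc)
    return desc


def _pattern_matches(seq: str, template: str) -> bool:
    def sym_ok(s: str, t: str) -> bool:
        if t == "=":
            return s in "NB"
        return s == t

    flipped = "".join(_FLIP[c] for c in seq)
    for cand in (seq, flipped):
        for r in range(len(cand)):
            rot = cand[r:] + cand[:r]
            if all(sym_ok(a, b) for a, b in zip(rot, template)):
                return True
    return False


def classify_conformer(d: ConformerDescriptor) -> str:
    """pc / al / wc label from the sign pattern, matched up to cyclic
    rotation and global sign flip; anything else is "other"."""
    if d.n_linkers != 6:
        raise ValueError(
            f"conformer templates are defined for 6-ring macrocycles, got {d.n_linkers}"
        )
    for label, template in CONFORMER_TEMPLATES.items():
        if _pattern_matches(d.sign_pattern, template):
            return label
    return "other"


# ---------------------------------------------------------------------------
# hydrogen bonds
# ---------------------------------------------------------------------------

@dataclass
class HBondParams:
    cutoff: float = 2.5          # Å, H...acceptor-atom
    cutoff_pi: float = 3.0       # Å, H...ring-centroid
    angle_min: float = 120.0     # degrees, D-H...A
    vdw_shrink: float = 0.2      # Å below the vdW-radius sum
    donors: tuple[str, ...] = ("O", "N", "S")
    acceptors: tuple[str, ...] = ("O", "N", "S")
    pi_acceptors: bool = True


@dataclass(frozen=True)
class HBond:
    donor: int
    hydrogen: int
    acceptor: int | tuple[str, int]  # atom index or ("ring", k)
    distance: float
    angle: float
    kind: str  # "classic" | "pi-acceptor"


def _aromatic_systems(mol: MoleculeGraph) -> list[list[int]]:
    """Connected components of the aromatic-bond subgraph."""
    adj: dict[int, set[int]] = {}
    for b in mol.bonds:
        if b.order == AROMATIC:
            adj.setdefault(b.i, set()).add(b.j)
            adj.setdefault(b.j, set()).add(b.i)
    comps, todo = [], set(adj)
    while todo:
        stack = [todo.pop()]
        comp = set(stack)
        while stack:
            for nb in adj[stack.pop()]:
                if nb not in comp:
                    comp.add(nb)
                    stack.append(nb)
        todo -= comp
        comps.append(sorted(comp))
    return comps


def detect_hbonds(
    mol: MoleculeGraph, params: HBondParams | None = None
) -> list[HBond]:
    """Geometric hydrogen-bond detection.

    A classic bond D–H⋯A is emitted when the H⋯A distance is below
    min(cutoff, vdW(H)+vdW(A)−shrink) and the D–H⋯A angle is at least
    ``angle_min``.  With ``pi_acceptors``, aromatic-ring centroids act as
    additional acceptors under the (looser) ``cutoff_pi``.
    """
    p = params or HBondParams()
    if not mol.has_coordinates:
        raise ValueError("hydrogen-bond detection requires coordinates")
    pos = {a.index: a.coords for a in mol.atoms}
    donors = []
    for a in mol.atoms:
        if a.element in p.donors:
            for nb in mol.neighbors(a.index):
                if mol.atoms[nb].is_hydrogen:
                    donors.append((a.index, nb))
    if any(a.element in p.donors for a in mol.atoms) and not donors:
        raise ValueError("no donor hydrogens found; are hydrogens missing?")
    acceptors = [a.index for a in mol.atoms if a.element in p.acceptors]
    rings = _aromatic_systems(mol) if p.pi_acceptors else []

    out: list[HBond] = []
    for d, h in donors:
        for a in acceptors:
            if a in (d, h) or a in mol.neighbors(h):
                continue
            dist = float(np.linalg.norm(pos[h] - pos[a]))
            lim = min(p.cutoff,
                      VDW_RADII["H"] + VDW_RADII[mol.atoms[a].element] - p.vdw_shrink)
            if dist > lim:
                continue
            ang = _angle(pos[d], pos[h], pos[a])
            if ang >= p.angle_min:
                out.append(HBond(d, h, a, dist, ang, "classic"))
        for k, ring in enumerate(rings):
            if d in ring:
                continue
            cen = np.mean([pos[i] for i in ring], axis=0)
            dist = float(np.linalg.norm(pos[h] - cen))
            if dist > p.cutoff_pi:
                continue
            ang = _angle(pos[d], pos[h], cen)
            if ang >= p.angle_min:
                out.append(HBond(d, h, ("ring", k), dist, ang, "pi-acceptor"))
    return out


def _angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    v1, v2 = a - b, c - b
    cosv = float(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))
    return float(np.degrees(np.arccos(np.clip(cosv, -1.0, 1.0))))


def hbond_topology(bonds: Iterable[HBond]) -> dict[str, list[list]]:
    """Decompose the donor→acceptor digraph into maximal simple paths and
    cycles.  Nodes are donor heavy atoms / acceptor atoms (or ring tags)."""
    edges = [(b.donor, b.acceptor) for b in bonds]
    out_edges: dict = {}
    in_deg: dict = {}
    nodes = set()
    for u, v in edges:
        out_edges.setdefault(u, []).append(v)
        in_deg[v] = in_deg.get(v, 0) + 1
        nodes.update((u, v))
    used: set[tuple] = set()
    paths, cycles = [], []

    def walk(start):
        path = [start]
        cur = start
        while True:
            nxt = [v for v in out_edges.get(cur, []) if (cur, v) not in used]
            if not nxt:
                return path, False
            v = nxt[0]
            used.add((cur, v))
            if v in path:
                return path + [v], v == path[0]
            path.append(v)
            cur = v

    for n in sorted(nodes, key=str):
        if in_deg.get(n, 0) == 0:
            while any((n, v) not in used for v in out_edges.get(n, [])):
                path, _ = walk(n)
                if len(path) > 1:
                    paths.append(path)
    for u, v in edges:
        if (u, v) not in used:
            cyc, closed = walk(u)
            if closed:
                cycles.append(cyc[:-1])
            else:
                paths.append(cyc)
    return {"paths": paths, "cycles": cycles}
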