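"""Level-n systematic molecular fragmentation with exact rational weights.

A molecule whose unit graph is a *chain* of m units is represented, at level
n, by the classic window sum: every run of n+1 consecutive units enters with
weight +1 and every interior run of n units with weight −1, so that the
total energy is

    E(M) = Σ_i w_i E(G_i) + E_nb ,

with E_nb collecting interactions between units that are never co-resident
in a fragment.  An N-cycle uses all N windows of both sizes.  For branched
unit graphs the weights are obtained as the minimum-norm solution of the
exactness constraints over *all* connected unit subsets of sizes n and n+1:

* every unit has net weight exactly 1,
* for every directed bond (a→b), the signed count of fragments containing
  a but not b (i.e. capped at that bond) vanishes.

These constraints make the weighted fragment sum exact for any strictly
atom-pairwise energy model once E_nb is added, and reduce to the chain and
cycle window rules (unique solutions there).  The minimum-norm solution is
invariant under graph automorphisms, which is what the "symmetrized" scheme
requires: fragments that differ only by the choice among topologically
equivalent branch directions receive equal fractional weights.

Weights are stored as exact :class:`fractions.Fraction` objects and
converted to float only when energies are summed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Any, Iterable, Mapping, Protocol, Sequence

import numpy as np

from .chemgraph import (
    STANDARD_XH_LENGTHS,
    Atom,
    Bond,
    MoleculeGraph,
    UnitGraph,
)

__all__ = [
    "Fragment",
    "FragmentationPlan",
    "EnergyEngine",
    "FragmentationError",
    "fragment",
    "cap_fragment",
    "reconstruct_total",
    "assemble_interaction",
    "reconstruct_property",
    "fragment_difference_analysis",
]

MAX_CANDIDATES = 200_000


class FragmentationError(RuntimeError):
    pass


class EnergyEngine(Protocol):
    """Contract for the *method* that evaluates fragments.

    Energies are in millihartree; tensor properties in atomic units.
    Implementations must be deterministic for a fixed input.
    """

    def evaluate(self, mol: MoleculeGraph) -> float: ...

    def evaluate_interaction(self, mol_a: MoleculeGraph, mol_b: MoleculeGraph) -> float: ...

    def evaluate_property(self, mol: MoleculeGraph, kind: str) -> np.ndarray: ...


@dataclass
class Fragment:
    units: tuple[int, ...]
    weight: Fraction
    caps: list[tuple[int, int, str]] = field(default_factory=list)
    # caps: (host_atom, direction_atom, cap_element) in parent-molecule indices

    @property
    def canonical_key(self) -> str:
        return ",".join(map(str, sorted(self.units)))

    @property
    def size(self) -> int:
        return len(self.units)


@dataclass
class FragmentationPlan:
    level: int
    fragments: list[Fragment]
    nonoverlap_terms: dict[frozenset[int], Fraction]
    unit_graph: UnitGraph | None = None

    @property
    def nonoverlap_pairs(self) -> set[frozenset[int]]:
        """Unit pairs never co-resident in any fragment (coefficient 1)."""
        return {p for p, nu in self.nonoverlap_terms.items() if nu == 1}

    def net_unit_weights(self) -> dict[int, Fraction]:
        net: dict[int, Fraction] = {}
        for fr in self.fragments:
            for u in fr.units:
                net[u] = net.get(u, Fraction(0)) + fr.weight
        return net

    def pair_coverage(self, u: int, v: int) -> Fraction:
        c = Fraction(0)
        for fr in self.fragments:
            if u in fr.units and v in fr.units:
                c += fr.weight
        return c

    # -- serialization -----------------------------------------------------
    def to_json(self) -> str:
        payload = {
            "level": self.level,
            "fragments": [
                {
                    "units": list(fr.units),
                    "weight": f"{fr.weight.numerator}/{fr.weight.denominator}",
                    "caps": [list(c) for c in fr.caps],
                }
                for fr in self.fragments
            ],
            "nonoverlap": [
                [min(p), max(p), f"{nu.numerator}/{nu.denominator}"]
                for p, nu in sorted(self.nonoverlap_terms.items(), key=lambda kv: sorted(kv[0]))
            ],
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str, unit_graph: UnitGraph | None = None) -> "FragmentationPlan":
        payload = json.loads(text)

        def frac(s: str) -> Fraction:
            p, q = s.split("/")
            return Fraction(int(p), int(q))

        frags = [
            Fragment(tuple(f["units"]), frac(f["weight"]),
                     [tuple(c) for c in f.get("caps", [])])
            for f in payload["fragments"]
        ]
        nb = {frozenset((u, v)): frac(s) for u, v, s in payload.get("nonoverlap", [])}
        return cls(payload["level"], frags, nb, unit_graph)


# ---------------------------------------------------------------------------
# weight construction
# ---------------------------------------------------------------------------

def _connected_subsets(adj: Mapping[int, set[int]], size: int) -> list[frozenset[int]]:
    out: set[frozenset[int]] = set()

    def grow(cur: frozenset[int], frontier: set[int]) -> None:
        if len(cur) == size:
            out.add(cur)
            return
        if len(out) > MAX_CANDIDATES:
            raise FragmentationError("unit graph too large for branched fragmentation")
        for v in sorted(frontier - cur):
            grow(cur | {v}, frontier | adj[v])

    for s in sorted(adj):
        grow(frozenset((s,)), set(adj[s]))
    return sorted(out, key=sorted)


def _constraint_system(
    adj: Mapping[int, set[int]], subsets: Sequence[frozenset[int]]
) -> tuple[np.ndarray, np.ndarray, list[tuple[str, Any]]]:
    labels: list[tuple[str, Any]] = [("unit", u) for u in sorted(adj)]
    labels += [("bond", (a, b)) for a in sorted(adj) for b in sorted(adj[a])]
    rows = np.zeros((len(labels), len(subsets)))
    b = np.zeros(len(labels))
    for r, (kind, obj) in enumerate(labels):
        if kind == "unit":
            b[r] = 1.0
            for c, S in enumerate(subsets):
                rows[r, c] = 1.0 if obj in S else 0.0
        else:
            a_, b_ = obj
            for c, S in enumerate(subsets):
                rows[r, c] = 1.0 if (a_ in S and b_ not in S) else 0.0
    return rows, b, labels


def _rationalize(
    w: np.ndarray, A: np.ndarray, b: np.ndarray, max_den: int = 10**6
) -> list[Fraction] | None:
    wr = [Fraction(float(x)).limit_denominator(max_den) for x in w]
    Ai = A.astype(int)
    for row, bi in zip(Ai, b.astype(int)):
        if sum(f for f, r in zip(wr, row) if r) != bi:
            return None
    return wr


def _exact_min_norm(A: np.ndarray, b: np.ndarray) -> list[Fraction]:
    """Rational fallback: select independent rows, then w = Aᵀ(AAᵀ)⁻¹b."""
    Ai = [[Fraction(int(x)) for x in row] for row in A.astype(int)]
    bi = [Fraction(int(x)) for x in b.astype(int)]
    # incremental row-independence with recorded reduced rows
    basis: list[tuple[list[Fraction], Fraction]] = []
    keep: list[int] = []
    pivots: list[int] = []
    for ridx, (row, rhs) in enumerate(zip(Ai, bi)):
        red, rr = list(row), rhs
        for (brow, brhs), piv in zip(basis, pivots):
            if red[piv]:
                f = red[piv] / brow[piv]
                red = [x - f * y for x, y in zip(red, brow)]
                rr = rr - f * brhs
        piv = next((k for k, x in enumerate(red) if x), None)
        if piv is None:
            if rr != 0:
                raise FragmentationError("no exact fragmentation weights exist")
            continue
        basis.append((red, rr))
        pivots.append(piv)
        keep.append(ridx)
    Ar = [Ai[k] for k in keep]
    br = [bi[k] for k in keep]
    r = len(Ar)
    G = [[sum(x * y for x, y in zip(Ar[i], Ar[j])) for j in range(r)] for i in range(r)]
    # solve G y = br (G symmetric positive definite)
    M = [Grow + [rhs] for Grow, rhs in zip(G, br)]
    for col in range(r):
        p = next(i for i in range(col, r) if M[i][col])
        M[col], M[p] = M[p], M[col]
        pv = M[col][col]
        M[col] = [x / pv for x in M[col]]
        for i in range(r):
            if i != col and M[i][col]:
                f = M[i][col]
                M[i] = [x - f * y for x, y in zip(M[i], M[col])]
    y = [M[i][r] for i in range(r)]
    n = len(Ai[0])
    return [sum(Ar[i][c] * y[i] for i in range(r)) for c in range(n)]


def _solve_weights(adj: Mapping[int, set[int]], level: int) -> dict[frozenset[int], Fraction]:
    subsets = _connected_subsets(adj, level + 1) + _connected_subsets(adj, level)
    A, b, _ = _constraint_system(adj, subsets)
    w, *_ = np.linalg.lstsq(A, b, rcond=None)
    if np.abs(A @ w - b).max() > 1e-8:
        raise FragmentationError("no exact fragmentation weights exist for this topology")
    wr = _rationalize(w, A, b)
    if wr is None:
        wr = _exact_min_norm(A, b)
    return {S: x for S, x in zip(subsets, wr) if x != 0}


def _window(order: Sequence[int], start: int, size: int, cyclic: bool) -> tuple[int, ...]:
    m = len(order)
    if cyclic:
        return tuple(order[(start + k) % m] for k in range(size))
    return tuple(order[start + k] for k in range(size))


def _chain_order(ug: UnitGraph) -> list[int]:
    ends = [u.unit_id for u in ug.units if len(ug.neighbors(u.unit_id)) <= 1]
    start = min(ends) if ends else min(u.unit_id for u in ug.units)
    order, prev, cur = [start], None, start
    while len(order) < len(ug.units):
        nxt = [n for n in ug.neighbors(cur) if n != prev]
        prev, cur = cur, nxt[0]
        order.append(cur)
    return order


def fragment(ug: UnitGraph, level: int) -> FragmentationPlan:
    """Build the level-``level`` fragmentation plan for a unit graph."""
    if level < 1:
        raise FragmentationError(f"fragmentation level must be >= 1, got {level}")
    m = len(ug.units)
    ids = [u.unit_id for u in ug.units]
    if m == 0:
        raise FragmentationError("empty unit graph")
    # connectivity
    seenu = {ids[0]}
    stack = [ids[0]]
    while stack:
        for nb in ug.neighbors(stack.pop()):
            if nb not in seenu:
                seenu.add(nb)
                stack.append(nb)
    if len(seenu) != m:
        raise FragmentationError("unit graph is disconnected")

    topo = ug.topology
    frags: list[Fragment] = []
    if m <= level + 1 and topo != "branched":
        frags = [Fragment(tuple(sorted(ids)), Fraction(1))]
    elif topo in ("chain", "cycle"):
        order = _chain_order(ug) if topo == "chain" else _cycle_order(ug)
        cyclic = topo == "cycle"
        npos = m if cyclic else m - level
        for k in range(npos):
            frags.append(Fragment(_window(order, k, level + 1, cyclic), Fraction(1)))
            if cyclic or k < npos - 1:
                frags.append(Fragment(_window(order, k + 1, level, cyclic), Fraction(-1)))
    else:
        weights = _solve_weights(ug.adjacency(), level)
        for S in sorted(weights, key=lambda s: (len(s), sorted(s))):
            frags.append(Fragment(tuple(sorted(S)), weights[S]))

    # deduplicate by canonical key, summing weights
    merged: dict[str, Fragment] = {}
    for fr in frags:
        key = fr.canonical_key
        if key in merged:
            merged[key] = Fragment(merged[key].units, merged[key].weight + fr.weight)
        else:
            merged[key] = fr
    frags = [fr for fr in merged.values() if fr.weight != 0]

    plan = FragmentationPlan(level, frags, {}, ug)
    # caps and non-overlap coefficients
    for fr in frags:
        fr.caps.extend(_cap_sites(fr, ug))
    allu = sorted(ids)
    for i, u in enumerate(allu):
        for v in allu[i + 1:]:
            nu = 1 - plan.pair_coverage(u, v)
            if nu != 0:
                plan.nonoverlap_terms[frozenset((u, v))] = nu
    return plan


def _cycle_order(ug: UnitGraph) -> list[int]:
    start = min(u.unit_id for u in ug.units)
    order, prev, cur = [start], None, start
    while True:
        nxt = sorted(n for n in ug.neighbors(cur) if n != prev)
        prev, cur = cur, nxt[0]
        if cur == start:
            return order
        order.append(cur)


# ---------------------------------------------------------------------------
# capping
# ---------------------------------------------------------------------------

def _cap_sites(fr: Fragment, ug: UnitGraph) -> list[tuple[int, int, str]]:
    inside_units = set(fr.units)
    inside_atoms = {a for uid in inside_units for a in ug.unit(uid).atoms}
    sites = []
    for b in ug.mol.bonds:
        ui, uj = ug.unit_of_atom(b.i), ug.unit_of_atom(b.j)
        if ui == uj:
            continue
        for host, out in ((b.i, b.j), (b.j, b.i)):
            if host in inside_atoms and out not in inside_atoms:
                if not b.is_breakable:
                    raise FragmentationError(
                        f"fragment {fr.canonical_key} breaks non-single bond ({b.i},{b.j})"
                    )
                sites.append((host, out, "H"))
    return sorted(sites)


def cap_fragment(fr: Fragment, ug: UnitGraph) -> MoleculeGraph:
    """Extract the fragment and saturate every broken single bond with a
    hydrogen placed along the broken-bond direction at the standard X–H
    length for the host element."""
    mol = ug.mol
    atom_ids = sorted({a for uid in fr.units for a in ug.unit(uid).atoms})
    remap = {old: new for new, old in enumerate(atom_ids)}
    atoms = [Atom(remap[i], mol.atoms[i].element, mol.atoms[i].coords) for i in atom_ids]
    bonds = [
        Bond(remap[b.i], remap[b.j], b.order)
        for b in mol.bonds
        if b.i in remap and b.j in remap
    ]
    nxt = len(atoms)
    for host, out, cap_el in fr.caps:
        coords = None
        if mol.atoms[host].coords is not None and mol.atoms[out].coords is not None:
            direction = mol.atoms[out].coords - mol.atoms[host].coords
            direction = direction / np.linalg.norm(direction)
            length = STANDARD_XH_LENGTHS.get(mol.atoms[host].element, 1.09)
            coords = mol.atoms[host].coords + length * direction
        atoms.append(Atom(nxt, cap_el, coords, is_cap=True))
        bonds.append(Bond(remap[host], nxt, 1))
        nxt += 1
    return MoleculeGraph(
        f"{mol.id}:frag[{fr.canonical_key}]", atoms, bonds, allow_multi_component=True
    )


def _fragment_molecule(fr: Fragment, ug: UnitGraph) -> MoleculeGraph:
    if ug.mol.has_coordinates:
        return cap_fragment(fr, ug)
    atom_ids = {a for uid in fr.units for a in ug.unit(uid).atoms}
    return ug.mol.subgraph(atom_ids, f"{ug.mol.id}:frag[{fr.canonical_key}]")


# ---------------------------------------------------------------------------
# reconstruction (Eq. 2 / Eq. 3 style)
# ---------------------------------------------------------------------------

def reconstruct_total(
    plan: FragmentationPlan, engine: EnergyEngine, include_nb: bool = True
) -> float:
    """Σ w_i E(G_i), plus the weighted non-overlap pair interactions when
    ``include_nb``."""
    ug = plan.unit_graph
    if ug is None:
        raise FragmentationError("plan is not attached to a unit graph")
    total = 0.0
    for idx, fr in enumerate(plan.fragments):
        try:
            e = engine.evaluate(_fragment_molecule(fr, ug))
        except Exception as exc:  # annotate failures with the fragment id
            raise FragmentationError(
                f"engine failed on fragment #{idx + 1} [{fr.canonical_key}]: {exc}"
            ) from exc
        total += float(fr.weight) * e
    if include_nb:
        unit_mols = {u.unit_id: ug.unit_molecule(u.unit_id) for u in ug.units}
        for pair, nu in plan.nonoverlap_terms.items():
            u, v = sorted(pair)
            total += float(nu) * engine.evaluate_interaction(unit_mols[u], unit_mols[v])
    return total


def assemble_interaction(
    plan: FragmentationPlan, guest: MoleculeGraph, engine: EnergyEngine
) -> tuple[list[dict], float]:
    """Host–guest interaction energy assembled fragment-by-fragment:
    Σ w_i E_int(G_i, A), the guest A left unfragmented.  No non-overlap
    term enters (each host unit is covered with net weight one)."""
    ug = plan.unit_graph
    if ug is None:
        raise FragmentationError("plan is not attached to a unit graph")
    records = []
    total = 0.0
    for idx, fr in enumerate(plan.fragments):
        if hasattr(engine, "interaction_for_fragment"):
            e = engine.interaction_for_fragment(idx, fr)
        else:
            try:
                e = engine.evaluate_interaction(_fragment_molecule(fr, ug), guest)
            except Exception as exc:
                raise FragmentationError(
                    f"engine failed on fragment #{idx + 1} [{fr.canonical_key}]: {exc}"
                ) from exc
        records.append(
            {"fragment": idx + 1, "units": fr.units, "weight": fr.weight, "energy": e}
        )
        total += float(fr.weight) * e
    return records, total


def reconstruct_property(
    plan: FragmentationPlan, engine: EnergyEngine, kind: str
) -> np.ndarray:
    """Componentwise Σ w_i P(G_i); the non-bonded contribution is neglected."""
    if kind not in ("dipole", "polarizability"):
        raise ValueError(f"unsupported property kind {kind!r}")
    ug = plan.unit_graph
    if ug is None:
        raise FragmentationError("plan is not attached to a unit graph")
    acc: np.ndarray | None = None
    for fr in plan.fragments:
        p = np.asarray(engine.evaluate_property(_fragment_molecule(fr, ug), kind), float)
        term = float(fr.weight) * p
        acc = term if acc is None else acc + term
    assert acc is not None
    return acc


def fragment_difference_analysis(
    records: Sequence[Mapping[str, Any]], focus_unit: int
) -> list[dict]:
    """Attribute energy changes to single units: for every pair of fragments
    that share ``focus_unit`` and differ by exactly one unit, report the
    added unit and ΔE = E(with) − E(without)."""
    with_focus = [r for r in records if focus_unit in r["units"]]
    if not with_focus:
        raise ValueError(f"focus unit {focus_unit} is absent from all fragments")
    out = []
    for ra in with_focus:
        sa = set(ra["units"])
        for rb in with_focus:
            sb = set(rb["units"])
            if len(sa) == len(sb) + 1 and sb < sa:
                (added,) = sa - sb
                out.append(
                    {
                        "added_unit": added,
                        "delta_e": ra["energy"] - rb["energy"],
                        "fragment_with": ra["fragment"],
                        "fragment_without": rb["fragment"],
                    }
                )
    return out
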