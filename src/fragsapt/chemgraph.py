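"""Molecular graph model, file I/O and partition of a molecule into units.

A *unit* is the smallest fragmentation block: either a single heavy atom or
a group of heavy atoms connected by multiple/aromatic bonds, together with
all hydrogens bonded to them.  Units are the vertices of the :class:`UnitGraph`
on which systematic molecular fragmentation operates; its edges are the
breakable single bonds between units.

Only topology is needed for fragmentation.  Cartesian coordinates (in Å) are
optional and are required only for hydrogen capping, dihedral angles and
hydrogen-bond detection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "AROMATIC",
    "Atom",
    "Bond",
    "MoleculeGraph",
    "Unit",
    "UnitGraph",
    "ValidationError",
    "load_molecule",
    "perceive_units",
    "merge_terminal_pendants",
    "dihedral_angle",
    "COVALENT_RADII",
]

#: sentinel bond order for aromatic bonds (treated as "multiple" by unit
#: perception, never breakable)
AROMATIC = 1.5

# Covalent radii (Å), Cordero et al. values for the elements that occur in
# organic host-guest chemistry; used for distance-based bond perception.
COVALENT_RADII: dict[str, float] = {
    "H": 0.31, "B": 0.84, "C": 0.76, "N": 0.71, "O": 0.66, "F": 0.57,
    "Si": 1.11, "P": 1.07, "S": 1.05, "Cl": 1.02, "Br": 1.20, "I": 1.39,
}

STANDARD_XH_LENGTHS: dict[str, float] = {"C": 1.09, "O": 0.96, "N": 1.01, "S": 1.34}


class ValidationError(ValueError):
    """Raised when a molecule fails structural validation."""


@dataclass
class Atom:
    index: int
    element: str
    coords: np.ndarray | None = None
    is_cap: bool = False

    def __post_init__(self) -> None:
        if self.element not in COVALENT_RADII:
            raise ValidationError(f"unknown element symbol {self.element!r}")
        if self.coords is not None:
            self.coords = np.asarray(self.coords, dtype=float)
            if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
                raise ValidationError(
                    f"atom {self.index}: coordinates must be a finite 3-vector"
                )

    @property
    def is_hydrogen(self) -> bool:
        return self.element == "H"


@dataclass(frozen=True)
class Bond:
    i: int
    j: int
    order: float = 1  # 1, 2, 3 or AROMATIC

    def __post_init__(self) -> None:
        if self.i == self.j:
            raise ValidationError(f"self-bond on atom {self.i}")
        if self.order not in (1, 2, 3, AROMATIC):
            raise ValidationError(f"unsupported bond order {self.order!r}")

    @property
    def key(self) -> frozenset[int]:
        return frozenset((self.i, self.j))

    @property
    def is_breakable(self) -> bool:
        """Only ordinary single bonds may be broken by fragmentation."""
        return self.order == 1


class MoleculeGraph:
    """Atoms + bonds + optional coordinates."""

    def __init__(
        self,
        mol_id: str,
        atoms: Sequence[Atom],
        bonds: Iterable[Bond],
        allow_multi_component: bool = False,
    ) -> None:
        self.id = mol_id
        self.atoms = list(atoms)
        self.bonds = list(bonds)
        self.allow_multi_component = allow_multi_component
        self._adj: dict[int, set[int]] = {a.index: set() for a in self.atoms}
        seen: set[frozenset[int]] = set()
        for b in self.bonds:
            if b.i not in self._adj or b.j not in self._adj:
                raise ValidationError(f"bond ({b.i},{b.j}) references a missing atom")
            if b.key in seen:
                raise ValidationError(f"duplicate bond ({b.i},{b.j})")
            seen.add(b.key)
            self._adj[b.i].add(b.j)
            self._adj[b.j].add(b.i)
        self._bond_by_key = {b.key: b for b in self.bonds}
        self.validate()

    # -- structural checks -------------------------------------------------
    def validate(self) -> None:
        indices = [a.index for a in self.atoms]
        if indices != list(range(len(indices))):
            raise ValidationError("atom indices must be 0..n-1 in order")
        for a in self.atoms:
            if a.is_hydrogen and len(self._adj[a.index]) != 1:
                raise ValidationError(
                    f"hydrogen atom {a.index} has {len(self._adj[a.index])} bonds"
                )
        if not self.allow_multi_component and len(self.atoms) > 1:
            if len(self.connected_components()) != 1:
                raise ValidationError(
                    f"molecule {self.id!r} is disconnected "
                    "(pass allow_multi_component=True for complexes)"
                )

    def connected_components(self) -> list[set[int]]:
        todo = {a.index for a in self.atoms}
        comps = []
        while todo:
            stack = [todo.pop()]
            comp = set(stack)
            while stack:
                for nb in self._adj[stack.pop()]:
                    if nb not in comp:
                        comp.add(nb)
                        stack.append(nb)
            todo -= comp
            comps.append(comp)
        return comps

    # -- convenience -------------------------------------------------------
    def neighbors(self, idx: int) -> set[int]:
        return self._adj[idx]

    def bond_between(self, i: int, j: int) -> Bond | None:
        return self._bond_by_key.get(frozenset((i, j)))

    @property
    def has_coordinates(self) -> bool:
        return all(a.coords is not None for a in self.atoms)

    def coords_array(self) -> np.ndarray:
        if not self.has_coordinates:
            raise ValidationError(f"molecule {self.id!r} has no coordinates")
        return np.array([a.coords for a in self.atoms])

    def formula(self) -> str:
        """Hill-order empirical formula, cap hydrogens included."""
        counts: dict[str, int] = {}
        for a in self.atoms:
            counts[a.element] = counts.get(a.element, 0) + 1
        parts = []
        for el in ["C", "H"] + sorted(e for e in counts if e not in ("C", "H")):
            if counts.get(el):
                n = counts[el]
                parts.append(el + (str(n) if n > 1 else ""))
        return "".join(parts)

    def subgraph(self, atom_indices: Iterable[int], mol_id: str | None = None) -> "MoleculeGraph":
        """Induced subgraph with atoms renumbered 0..k-1."""
        keep = sorted(set(atom_indices))
        remap = {old: new for new, old in enumerate(keep)}
        atoms = [
            Atom(remap[i], self.atoms[i].element, self.atoms[i].coords,
                 self.atoms[i].is_cap)
            for i in keep
        ]
        bonds = [
            Bond(remap[b.i], remap[b.j], b.order)
            for b in self.bonds
            if b.i in remap and b.j in remap
        ]
        return MoleculeGraph(mol_id or f"{self.id}[sub]", atoms, bonds,
                             allow_multi_component=True)

    def translated(self, shift: Sequence[float]) -> "MoleculeGraph":
        shift = np.asarray(shift, float)
        atoms = [Atom(a.index, a.element, None if a.coords is None else a.coords + shift,
                      a.is_cap) for a in self.atoms]
        return MoleculeGraph(self.id, atoms, self.bonds,
                             allow_multi_component=self.allow_multi_component)

    # -- writers -----------------------------------------------------------
    def to_xyz(self) -> str:
        lines = [str(len(self.atoms)), self.id]
        for a in self.atoms:
            x, y, z = (0.0, 0.0, 0.0) if a.coords is None else a.coords
            lines.append(f"{a.element:<2s} {x:14.8f} {y:14.8f} {z:14.8f}")
        return "\n".join(lines) + "\n"

    def to_molblock(self) -> str:
        """MOL V2000 record (aromatic bonds written with type 4)."""
        lines = [self.id, "  fragsapt", "", ""]
        lines[3] = f"{len(self.atoms):3d}{len(self.bonds):3d}  0  0  0  0  0  0  0  0999 V2000"
        for a in self.atoms:
            x, y, z = (0.0, 0.0, 0.0) if a.coords is None else a.coords
            lines.append(f"{x:10.4f}{y:10.4f}{z:10.4f} {a.element:<3s} 0  0  0  0  0  0  0  0  0  0  0  0")
        for b in self.bonds:
            btype = 4 if b.order == AROMATIC else int(b.order)
            lines.append(f"{b.i + 1:3d}{b.j + 1:3d}{btype:3d}  0  0  0  0")
        lines.append("M  END")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _from_rdkit(rdmol, mol_id: str) -> MoleculeGraph:
    from rdkit import Chem

    conf = rdmol.GetConformer() if rdmol.GetNumConformers() else None
    atoms = []
    for at in rdmol.GetAtoms():
        coords = None
        if conf is not None:
            p = conf.GetAtomPosition(at.GetIdx())
            coords = np.array([p.x, p.y, p.z])
        atoms.append(Atom(at.GetIdx(), at.GetSymbol(), coords))
    bonds = []
    for b in rdmol.GetBonds():
        if b.GetIsAromatic() or b.GetBondType() == Chem.BondType.AROMATIC:
            order: float = AROMATIC
        else:
            order = int(b.GetBondTypeAsDouble())
        bonds.append(Bond(b.GetBeginAtomIdx(), b.GetEndAtomIdx(), order))
    return MoleculeGraph(mol_id, atoms, bonds, allow_multi_component=True)


def _load_sdf(path: Path, allow_multi_component: bool = False) -> MoleculeGraph:
    """SDF/MOL V2000 via RDKit.  Sanitization aromatizes Kekulé input, so a
    benzene ring written with alternating single/double bonds is still
    perceived as one unit."""
    from rdkit import Chem

    rdmol = Chem.MolFromMolFile(str(path), removeHs=False, sanitize=True)
    if rdmol is None:
        raise ValidationError(f"could not parse SDF/MOL file {path}")
    name = rdmol.GetProp("_Name").strip() if rdmol.HasProp("_Name") else ""
    mol = _from_rdkit(rdmol, name or path.stem)
    mol.allow_multi_component = allow_multi_component
    if not allow_multi_component:
        mol.validate()
    return mol


def perceive_bonds_from_distances(
    atoms: Sequence[Atom], factor: float = 1.15
) -> list[Bond]:
    """Single bonds wherever the interatomic distance is below ``factor``
    times the covalent-radius sum.  Distance criteria cannot recover bond
    orders, so multiple/aromatic bonds are not distinguished; use SDF input
    when the unit partition must honour multiply-bonded groups."""
    bonds = []
    for i, ai in enumerate(atoms):
        for j in range(i + 1, len(atoms)):
            aj = atoms[j]
            cut = factor * (COVALENT_RADII[ai.element] + COVALENT_RADII[aj.element])
            if float(np.linalg.norm(ai.coords - aj.coords)) < cut:
                bonds.append(Bond(i, j, 1))
    return bonds


def _load_xyz(path: Path, bond_factor: float = 1.15,
              allow_multi_component: bool = False) -> MoleculeGraph:
    lines = Path(path).read_text().splitlines()
    try:
        n = int(lines[0].split()[0])
    except (IndexError, ValueError) as exc:
        raise ValidationError(f"bad XYZ header in {path}") from exc
    comment = lines[1].strip() if len(lines) > 1 else ""
    atoms = []
    for k, line in enumerate(lines[2 : 2 + n]):
        parts = line.split()
        if len(parts) < 4:
            raise ValidationError(f"bad XYZ atom line {k + 3} in {path}")
        atoms.append(Atom(k, parts[0], [float(p) for p in parts[1:4]]))
    if len(atoms) != n:
        raise ValidationError(f"XYZ declares {n} atoms, found {len(atoms)}")
    bonds = perceive_bonds_from_distances(atoms, bond_factor)
    return MoleculeGraph(comment or path.stem, atoms, bonds,
                         allow_multi_component=allow_multi_component)


def load_molecule(
    source: str | Path,
    fmt: str | None = None,
    bond_factor: float = 1.15,
    allow_multi_component: bool = False,
) -> MoleculeGraph:
    """Read a molecule from an SDF/MOL (explicit bonds) or XYZ file
    (bonds perceived from distances).  Complexes (several molecules in one
    file) need ``allow_multi_component=True``."""
    path = Path(source)
    if fmt is None:
        fmt = {".sdf": "sdf", ".mol": "sdf", ".xyz": "xyz"}.get(path.suffix.lower())
    if fmt == "sdf":
        return _load_sdf(path, allow_multi_component)
    if fmt == "xyz":
        return _load_xyz(path, bond_factor, allow_multi_component)
    raise ValidationError(f"unknown molecule format for {source!r}")


# ---------------------------------------------------------------------------
# units
# ---------------------------------------------------------------------------

@dataclass
class Unit:
    unit_id: int
    heavy_atoms: set[int]
    hydrogens: set[int] = field(default_factory=set)
    pendant_of: int | None = None

    @property
    def atoms(self) -> set[int]:
        return self.heavy_atoms | self.hydrogens

    @property
    def n_heavy(self) -> int:
        return len(self.heavy_atoms)


class UnitGraph:
    """Vertices: units; edges: breakable single bonds between units."""

    def __init__(self, mol: MoleculeGraph, units: Sequence[Unit]) -> None:
        self.mol = mol
        self.units = list(units)
        self._unit_of_atom: dict[int, int] = {}
        for u in self.units:
            for a in u.atoms:
                self._unit_of_atom[a] = u.unit_id
        edges: set[frozenset[int]] = set()
        for b in mol.bonds:
            ui, uj = self._unit_of_atom[b.i], self._unit_of_atom[b.j]
            if ui != uj:
                if not b.is_breakable:
                    raise ValidationError(
                        f"non-single bond ({b.i},{b.j}) crosses units {ui},{uj}"
                    )
                edges.add(frozenset((ui, uj)))
        self.edges = edges
        self._adj: dict[int, set[int]] = {u.unit_id: set() for u in self.units}
        for e in edges:
            a, b_ = sorted(e)
            self._adj[a].add(b_)
            self._adj[b_].add(a)

    def unit_of_atom(self, idx: int) -> int:
        return self._unit_of_atom[idx]

    def unit(self, unit_id: int) -> Unit:
        for u in self.units:
            if u.unit_id == unit_id:
                return u
        raise KeyError(unit_id)

    def neighbors(self, unit_id: int) -> set[int]:
        return self._adj[unit_id]

    def adjacency(self) -> dict[int, set[int]]:
        return {k: set(v) for k, v in self._adj.items()}

    @property
    def topology(self) -> str:
        degs = [len(self._adj[u.unit_id]) for u in self.units]
        if len(self.units) <= 1:
            return "chain"
        if all(d == 2 for d in degs):
            return "cycle"
        if max(degs) <= 2:
            return "chain"
        return "branched"

    def unit_molecule(self, unit_id: int) -> MoleculeGraph:
        u = self.unit(unit_id)
        return self.mol.subgraph(u.atoms, f"{self.mol.id}:unit{unit_id}")


def perceive_units(mol: MoleculeGraph) -> UnitGraph:
    """Join heavy atoms connected by multiple/aromatic bonds into one unit
    (transitive closure); every other heavy atom is its own unit; hydrogens
    follow their heavy atom.  Idempotent by construction."""
    parent = {a.index: a.index for a in mol.atoms if not a.is_hydrogen}

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for b in mol.bonds:
        if b.order != 1:
            hi, hj = mol.atoms[b.i], mol.atoms[b.j]
            if not hi.is_hydrogen and not hj.is_hydrogen:
                parent[find(b.i)] = find(b.j)

    groups: dict[int, set[int]] = {}
    for idx in parent:
        groups.setdefault(find(idx), set()).add(idx)

    units = []
    for uid, (_, heavy) in enumerate(sorted(groups.items(), key=lambda kv: min(kv[1]))):
        hyd = {
            nb
            for h in heavy
            for nb in mol.neighbors(h)
            if mol.atoms[nb].is_hydrogen
        }
        units.append(Unit(uid, heavy, hyd))
    return UnitGraph(mol, units)


def merge_terminal_pendants(ug: UnitGraph) -> UnitGraph:
    """Absorb every single-heavy-atom unit whose only neighbour is a
    multi-atom (ring) unit into that neighbour, repeatedly, recording
    ``pendant_of``.  This reproduces the phenol-with-hydroxyl fragments of
    calixarene fragmentation while leaving e.g. tert-butyl trees intact
    (their single-atom units hang off a single-atom central carbon, not a
    ring).  Idempotent at its fixed point."""
    units = {
        u.unit_id: Unit(u.unit_id, set(u.heavy_atoms), set(u.hydrogens), u.pendant_of)
        for u in ug.units
    }
    adj = ug.adjacency()
    changed = True
    while changed:
        changed = False
        for uid in sorted(units):
            u = units[uid]
            if u.n_heavy != 1 or len(adj[uid]) != 1:
                continue
            host = next(iter(adj[uid]))
            if units[host].n_heavy < 2:
                continue
            units[host].heavy_atoms |= u.heavy_atoms
            units[host].hydrogens |= u.hydrogens
            u.pendant_of = host
            for nb in adj[uid]:
                adj[nb].discard(uid)
            del units[uid], adj[uid]
            changed = True
            break

    renumber = {old: new for new, old in enumerate(sorted(units))}
    merged = [
        Unit(renumber[uid], u.heavy_atoms, u.hydrogens, None)
        for uid, u in sorted(units.items())
    ]
    return UnitGraph(ug.mol, merged)


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def dihedral_angle(
    p1: Sequence[float], p2: Sequence[float], p3: Sequence[float], p4: Sequence[float]
) -> float:
    """Signed torsion p1-p2-p3-p4 in degrees, IUPAC right-hand convention,
    range (−180, 180]."""
    p1, p2, p3, p4 = (np.asarray(p, float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise ValueError("dihedral undefined: three consecutive points are collinear")
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    ang = math.degrees(math.atan2(float(np.dot(m1, n2)), float(np.dot(n1, n2))))
    if ang <= -180.0:
        ang += 360.0
    return ang
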