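import numpy as np
import pytest

from fragsapt.chemgraph import (
    Atom,
    Bond,
    MoleculeGraph,
    load_molecule,
    merge_terminal_pendants,
    perceive_units,
)
from fragsapt.fragmentation import fragment
from fragsapt.synthetic import PairwiseEngine, fixtures


@pytest.fixture(scope="session")
def fixture_paths():
    return fixtures()


@pytest.fixture(scope="session")
def cx_unit_graph(fixture_paths):
    mol = load_molecule(fixture_paths["calix6arene"])
    return merge_terminal_pendants(perceive_units(mol))


@pytest.fixture(scope="session")
def bcx_unit_graph(fixture_paths):
    mol = load_molecule(fixture_paths["tbc6arene"])
    return merge_terminal_pendants(perceive_units(mol))


@pytest.fixture(scope="session")
def cx_plan(cx_unit_graph):
    return fragment(cx_unit_graph, 3)


@pytest.fixture(scope="session")
def bcx_plan(bcx_unit_graph):
    return fragment(bcx_unit_graph, 3)


@pytest.fixture(scope="session")
def engine():
    return PairwiseEngine()


def linear_alkane(n_carbons: int) -> MoleculeGraph:
    """C_nH_(2n+2) zig-zag chain with explicit hydrogens."""
    atoms, bonds = [], []

    def add(el, xyz):
        atoms.append(Atom(len(atoms), el, np.asarray(xyz, float)))
        return len(atoms) - 1

    cids = []
    for k in range(n_carbons):
        c = add("C", [1.3 * k, 0.4 * (k % 2), 0.0])
        cids.append(c)
        if k:
            bonds.append(Bond(cids[k - 1], c, 1))
    for k, c in enumerate(cids):
        nh = 3 if k in (0, n_carbons - 1) else 2
        if n_carbons == 1:
            nh = 4
        for m in range(nh):
            h = add("H", [1.3 * k + 0.3 * m, 0.4 * (k % 2) - 0.9, 0.8 + 0.25 * m])
            bonds.append(Bond(c, h, 1))
    return MoleculeGraph(f"C{n_carbons}-alkane", atoms, bonds)


def zmatrix_chain(lengths, angles, dihedrals) -> list[np.ndarray]:
    """Place a chain of points from internal coordinates (independent
    geometric construction used as the oracle for torsion tests)."""
    pts = [np.zeros(3), np.array([lengths[0], 0.0, 0.0])]
    a0 = np.radians(angles[0])
    pts.append(pts[1] + lengths[1] * np.array([-np.cos(a0), np.sin(a0), 0.0]))
    for r, ang, dih in zip(lengths[2:], angles[1:], dihedrals):
        p1, p2, p3 = pts[-3], pts[-2], pts[-1]
        b1, b2 = p2 - p1, p3 - p2
        b2n = b2 / np.linalg.norm(b2)
        n = np.cross(b1, b2)
        n /= np.linalg.norm(n)
        m = np.cross(n, b2n)
        ang_r, dih_r = np.radians(ang), np.radians(dih)
        d = r * (
            -b2n * np.cos(ang_r)
            + m * np.sin(ang_r) * np.cos(dih_r)
            - n * np.sin(ang_r) * np.sin(dih_r)
        )
        pts.append(p3 + d)
    return pts
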