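import warnings

import numpy as np
import pytest

from fragsapt.chemgraph import Atom, Bond, MoleculeGraph
from fragsapt.geometry import (
    ConformerDescriptor,
    HBondParams,
    classify_conformer,
    conformer_descriptors,
    detect_hbonds,
    hbond_topology,
)
from fragsapt.synthetic import make_toy_macrocycle

from conftest import zmatrix_chain


def descriptor(conf, **kw):
    mol, ann = make_toy_macrocycle(6, conf)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return conformer_descriptors(mol, ann, **kw), mol, ann


def transformed(mol, rot=None, shift=(0, 0, 0), mirror=False):
    rot = np.eye(3) if rot is None else rot
    flip = np.diag([1.0, 1.0, -1.0]) if mirror else np.eye(3)
    atoms = [
        Atom(a.index, a.element, flip @ (rot @ a.coords) + np.asarray(shift, float))
        for a in mol.atoms
    ]
    return MoleculeGraph(mol.id, atoms, mol.bonds)


class TestDescriptors:
    @pytest.mark.parametrize("conf,label", [
        ("cone", "pc"), ("alternate", "al"), ("winged", "wc"),
    ])
    def test_generated_conformers_classified(self, conf, label):
        d, _, _ = descriptor(conf)
        assert d.n_linkers == 6
        assert d.label == label

    def test_cone_pairs_all_sign_alternating(self):
        d, _, _ = descriptor("cone")
        for phi, chi in d.pairs:
            assert phi * chi < 0

    def test_rigid_motion_invariance(self):
        d0, mol, ann = descriptor("cone")
        th = np.radians(37.0)
        rot = np.array(
            [[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0], [0, 0, 1]]
        )
        moved = transformed(mol, rot=rot, shift=(5.0, -3.0, 2.0))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            d1 = conformer_descriptors(moved, ann)
        for (a0, b0), (a1, b1) in zip(d0.pairs, d1.pairs):
            assert a1 == pytest.approx(a0, abs=1e-6)
            assert b1 == pytest.approx(b0, abs=1e-6)

    @pytest.mark.parametrize("conf", ["cone", "alternate", "winged"])
    def test_mirror_image_label_invariant(self, conf):
        d0, mol, ann = descriptor(conf)
        mirrored = transformed(mol, mirror=True)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            d1 = conformer_descriptors(mirrored, ann)
        assert d1.label == d0.label

    def test_diphenylmethane_reference_pair_signs(self):
        """A single linker geometry built with the reference torsions
        (-62°, 118°) reproduces the (−, +) sign pair."""
        # chain C1-C2-C3-C4-C5 with prescribed torsions about C2-C3 and C3-C4
        pts = zmatrix_chain([1.5, 1.51, 1.51, 1.5], [114, 113, 114], [-62.0, 118.0])
        from fragsapt.chemgraph import dihedral_angle

        phi = dihedral_angle(*pts[0:4])
        chi = dihedral_angle(*pts[1:5])
        assert phi == pytest.approx(-62.0, abs=1e-6)
        assert chi == pytest.approx(118.0, abs=1e-6)
        assert phi < 0 < chi

    def test_non_macrocyclic_input_rejected(self):
        mol, ann = make_toy_macrocycle(6, "cone")
        broken = {"rings": ann["rings"][:2], "linkers": ann["linkers"][:2]}
        with pytest.raises(ValueError):
            conformer_descriptors(mol, broken)

    def test_alternate_tie_warns_without_orientation(self):
        mol, ann = make_toy_macrocycle(6, "alternate")
        with pytest.warns(UserWarning):
            conformer_descriptors(mol, ann)


class TestClassifyConformer:
    def _desc(self, pattern):
        return ConformerDescriptor(pairs=[(0.0, 0.0)] * 6, sign_pattern=pattern)

    @pytest.mark.parametrize("pattern,label", [
        ("PMPPMP", "pc"),
        ("MPMMPM", "pc"),      # global flip
        ("MPPMPP", "pc"),      # rotation of the flip
        ("MMPPMM", "al"),
        ("PPMMPP", "al"),
        ("MNMPBP", "wc"),
        ("MBMPNP", "wc"),
        ("PPPPPP", "other"),
        ("NNNNNN", "other"),
    ])
    def test_template_matching(self, pattern, label):
        assert classify_conformer(self._desc(pattern)) == label

    def test_wrong_pair_count(self):
        d = ConformerDescriptor(pairs=[(0.0, 0.0)] * 5, sign_pattern="PMPPM")
        with pytest.raises(ValueError):
            classify_conformer(d)


def water_pair(d_ho=1.8, angle_deg=180.0):
    """Donor water O-H...O acceptor with prescribed H...O distance and
    D-H...A angle."""
    oh = 0.9572
    a = np.radians(180.0 - angle_deg)
    acc = np.array([oh + d_ho * np.cos(a), d_ho * np.sin(a), 0.0])
    atoms = [
        Atom(0, "O", [0.0, 0.0, 0.0]),
        Atom(1, "H", [oh, 0.0, 0.0]),
        Atom(2, "H", [-0.24, 0.93, 0.0]),
        Atom(3, "O", acc),
        Atom(4, "H", acc + np.array([0.3, 0.9, 0.0])),
        Atom(5, "H", acc + np.array([0.3, -0.9, 0.0])),
    ]
    bonds = [Bond(0, 1, 1), Bond(0, 2, 1), Bond(3, 4, 1), Bond(3, 5, 1)]
    return MoleculeGraph("water-dimer", atoms, bonds, allow_multi_component=True)


class TestHBondDetection:
    def test_collinear_water_dimer(self):
        found = detect_hbonds(water_pair(1.8))
        assert len(found) == 1
        hb = found[0]
        assert (hb.donor, hb.hydrogen, hb.acceptor) == (0, 1, 3)
        assert hb.distance == pytest.approx(1.8)
        assert hb.angle == pytest.approx(180.0)
        assert hb.kind == "classic"

    def test_too_long_contact_rejected(self):
        assert detect_hbonds(water_pair(3.5)) == []

    def test_bent_contact_rejected(self):
        assert detect_hbonds(water_pair(1.8, angle_deg=100.0)) == []

    def test_cone_hydroxyl_ring(self):
        mol, _ = make_toy_macrocycle(6, "cone")
        classic = [b for b in detect_hbonds(mol) if b.kind == "classic"]
        assert len(classic) == 6
        topo = hbond_topology(classic)
        assert topo["paths"] == []
        assert [len(c) for c in topo["cycles"]] == [6]

    @pytest.mark.parametrize("conf", ["alternate", "winged"])
    def test_two_chain_motif(self, conf):
        mol, _ = make_toy_macrocycle(6, conf)
        classic = [b for b in detect_hbonds(mol) if b.kind == "classic"]
        assert len(classic) == 4
        topo = hbond_topology(classic)
        assert sorted(len(p) - 1 for p in topo["paths"]) == [2, 2]
        assert topo["cycles"] == []

    def test_monotone_in_cutoff(self):
        mol, _ = make_toy_macrocycle(6, "cone")
        tight = {(b.donor, b.hydrogen, b.acceptor)
                 for b in detect_hbonds(mol, HBondParams(cutoff=2.0, angle_min=150))}
        loose = {(b.donor, b.hydrogen, b.acceptor)
                 for b in detect_hbonds(mol, HBondParams(cutoff=2.4, angle_min=120))}
        assert tight <= loose

    def test_jitter_stability(self):
        """Perturbing coordinates by 0.05 Å changes no assignment."""
        ref, _ = make_toy_macrocycle(6, "cone")
        keys0 = {(b.donor, b.hydrogen, b.acceptor)
                 for b in detect_hbonds(ref) if b.kind == "classic"}
        for seed in range(3):
            mol, _ = make_toy_macrocycle(6, "cone", seed=seed, jitter=0.05)
            keys = {(b.donor, b.hydrogen, b.acceptor)
                    for b in detect_hbonds(mol) if b.kind == "classic"}
            assert keys == keys0

    def test_missing_coordinates_rejected(self):
        mol = MoleculeGraph(
            "bare", [Atom(0, "O"), Atom(1, "H")], [Bond(0, 1, 1)]
        )
        with pytest.raises(ValueError):
            detect_hbonds(mol)

    def test_pi_acceptor_geometry(self):
        """An O-H pointing at a benzene ring centroid is reported as a
        pi-acceptor hydrogen bond."""
        atoms = [Atom(i, "C") for i in range(6)]
        coords = [
            1.39 * np.array([np.cos(k * np.pi / 3), np.sin(k * np.pi / 3), 0.0])
            for k in range(6)
        ]
        atoms = [Atom(i, "C", c) for i, c in enumerate(coords)]
        bonds = [Bond(i, (i + 1) % 6, 1.5) for i in range(6)]
        atoms += [
            Atom(6 + i, "H", c * (1.39 + 1.09) / 1.39) for i, c in enumerate(coords)
        ]
        bonds += [Bond(i, 6 + i, 1) for i in range(6)]
        atoms.append(Atom(12, "O", [0.0, 0.0, 3.3]))
        atoms.append(Atom(13, "H", [0.0, 0.0, 2.34]))
        bonds.append(Bond(12, 13, 1))
        mol = MoleculeGraph("oh-over-benzene", atoms, bonds,
                            allow_multi_component=True)
        found = detect_hbonds(mol)
        assert [b.kind for b in found] == ["pi-acceptor"]
        assert found[0].acceptor == ("ring", 0)
        assert found[0].distance == pytest.approx(2.34)


class TestHbondTopology:
    def test_empty(self):
        assert hbond_topology([]) == {"paths": [], "cycles": []}
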