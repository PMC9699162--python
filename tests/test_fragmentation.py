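from collections import Counter
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from fragsapt.chemgraph import merge_terminal_pendants, perceive_units
from fragsapt.fragmentation import (
    FragmentationError,
    FragmentationPlan,
    assemble_interaction,
    cap_fragment,
    fragment,
    fragment_difference_analysis,
    reconstruct_property,
    reconstruct_total,
)
from fragsapt.synthetic import (
    LookupEngine,
    PairwiseEngine,
    SurrogateParams,
    make_toy_guest,
    make_toy_macrocycle,
)

from conftest import linear_alkane


def unit_graph_of(mol):
    return merge_terminal_pendants(perceive_units(mol))


class TestWindowRules:
    def test_five_unit_chain_level3(self):
        plan = fragment(unit_graph_of(linear_alkane(5)), 3)
        got = {fr.units: fr.weight for fr in plan.fragments}
        assert got == {
            (0, 1, 2, 3): Fraction(1),
            (1, 2, 3, 4): Fraction(1),
            (1, 2, 3): Fraction(-1),
        }

    def test_short_chain_single_fragment(self):
        plan = fragment(unit_graph_of(linear_alkane(3)), 3)
        assert len(plan.fragments) == 1
        assert plan.fragments[0].weight == 1
        assert plan.fragments[0].units == (0, 1, 2)
        assert plan.fragments[0].caps == []

    @pytest.mark.parametrize("m", [5, 6, 9])
    def test_chain_counts_and_net_weights(self, m):
        plan = fragment(unit_graph_of(linear_alkane(m)), 3)
        sizes = Counter(fr.size for fr in plan.fragments)
        assert sizes == {4: m - 3, 3: m - 4}
        assert set(plan.net_unit_weights().values()) == {Fraction(1)}

    def test_level_below_one_rejected(self):
        with pytest.raises(FragmentationError):
            fragment(unit_graph_of(linear_alkane(5)), 0)


class TestCalixarenePlans:
    def test_cx_24_fragments_alternating_weights(self, cx_plan):
        assert len(cx_plan.fragments) == 24
        sizes = Counter((fr.size, fr.weight) for fr in cx_plan.fragments)
        assert sizes == {(4, Fraction(1)): 12, (3, Fraction(-1)): 12}
        # plan order interleaves +1/-1 like the window construction
        assert [fr.weight for fr in cx_plan.fragments] == [
            Fraction(1), Fraction(-1)
        ] * 12

    def test_cx_capped_species_inventory(self, cx_unit_graph, cx_plan):
        formulas = Counter(
            cap_fragment(fr, cx_unit_graph).formula() for fr in cx_plan.fragments
        )
        # methyl-capped diphenol, diphenol, dimethylphenol
        assert formulas == {"C14H14O2": 12, "C13H12O2": 6, "C8H10O": 6}

    def test_bcx_150_fragments_with_fractional_weights(self, bcx_plan):
        assert len(bcx_plan.fragments) == 150
        assert set(plan_net := bcx_plan.net_unit_weights().values()) == {Fraction(1)}
        assert any(fr.weight.denominator > 1 for fr in bcx_plan.fragments)
        sizes = Counter(fr.size for fr in bcx_plan.fragments)
        assert sizes == {4: 90, 3: 60}

    def test_cap_cancellation_per_bond(self, cx_plan, cx_unit_graph):
        """At every broken bond the weights of fragments capped there sum
        to zero."""
        by_site: dict[tuple[int, int], Fraction] = {}
        for fr in cx_plan.fragments:
            for host, out, _ in fr.caps:
                key = (host, out)
                by_site[key] = by_site.get(key, Fraction(0)) + fr.weight
        assert by_site and set(by_site.values()) == {Fraction(0)}

    def test_cycle_relabeling_invariance(self, fixture_paths):
        """The fragment multiset of an N-cycle does not depend on where the
        traversal starts."""
        from fragsapt.chemgraph import Atom, Bond, MoleculeGraph, load_molecule

        mol = load_molecule(fixture_paths["calix6arene"])
        n = len(mol.atoms)
        shift = 17
        perm = {i: (i + shift) % n for i in range(n)}
        inv = {v: k for k, v in perm.items()}
        atoms = [
            Atom(i, mol.atoms[inv[i]].element, mol.atoms[inv[i]].coords)
            for i in range(n)
        ]
        bonds = [Bond(perm[b.i], perm[b.j], b.order) for b in mol.bonds]
        permuted = MoleculeGraph("permuted", atoms, bonds)
        plan = fragment(unit_graph_of(permuted), 3)
        ref = fragment(unit_graph_of(mol), 3)
        assert Counter((fr.size, fr.weight) for fr in plan.fragments) == Counter(
            (fr.size, fr.weight) for fr in ref.fragments
        )


class TestCapping:
    def test_caps_sit_on_broken_single_bonds_only(self, cx_unit_graph, cx_plan):
        for fr in cx_plan.fragments:
            capped = cap_fragment(fr, cx_unit_graph)
            n_caps = sum(a.is_cap for a in capped.atoms)
            assert n_caps == len(fr.caps) == 2  # every window breaks two bonds
            for a in capped.atoms:
                if a.is_cap:
                    assert a.element == "H"

    def test_cap_bond_length_is_standard(self, cx_unit_graph, cx_plan):
        fr = cx_plan.fragments[0]
        capped = cap_fragment(fr, cx_unit_graph)
        for b in capped.bonds:
            ai, aj = capped.atoms[b.i], capped.atoms[b.j]
            if ai.is_cap or aj.is_cap:
                host = aj if ai.is_cap else ai
                d = float(np.linalg.norm(ai.coords - aj.coords))
                assert d == pytest.approx({"C": 1.09, "O": 0.96}[host.element], abs=1e-9)


class TestReconstruction:
    @pytest.mark.parametrize("n_rings", [3, 5, 8])
    def test_total_energy_oracle(self, n_rings, engine):
        """With a strictly pairwise engine, the weighted fragment sum plus
        the non-overlap term equals direct evaluation."""
        mol, _ = make_toy_macrocycle(n_rings, "cone")
        plan = fragment(unit_graph_of(mol), 3)
        direct = engine.evaluate(mol)
        rec = reconstruct_total(plan, engine, include_nb=True)
        assert rec == pytest.approx(direct, rel=1e-10)

    def test_omitting_nb_leaves_exactly_the_far_pairs(self, engine):
        mol, _ = make_toy_macrocycle(6, "cone")
        ug = unit_graph_of(mol)
        plan = fragment(ug, 3)
        gap = reconstruct_total(plan, engine, include_nb=True) - reconstruct_total(
            plan, engine, include_nb=False
        )
        expected = sum(
            float(nu)
            * engine.evaluate_interaction(
                ug.unit_molecule(min(p)), ug.unit_molecule(max(p))
            )
            for p, nu in plan.nonoverlap_terms.items()
        )
        # gap is a difference of two large totals: tolerance follows from
        # double-precision cancellation, not from the method
        assert gap == pytest.approx(expected, abs=1e-6)
        # on a 12-cycle at level 3 the uncovered pairs sit at ring distance >= 4
        assert all(nu == 1 for nu in plan.nonoverlap_terms.values())

    def test_single_fragment_plan_is_identity(self, engine):
        mol = linear_alkane(3)
        plan = fragment(unit_graph_of(mol), 3)
        assert reconstruct_total(plan, engine) == pytest.approx(
            engine.evaluate(mol), rel=1e-12
        )

    def test_branched_reconstruction_exact(self, fixture_paths, bcx_plan, engine):
        from fragsapt.chemgraph import load_molecule

        mol = load_molecule(fixture_paths["tbc6arene"])
        direct = engine.evaluate(mol)
        rec = reconstruct_total(bcx_plan, engine, include_nb=True)
        assert rec == pytest.approx(direct, rel=1e-10)

    def test_three_body_engine_breaks_additivity(self):
        eng = PairwiseEngine(SurrogateParams(three_body=5.0))
        mol, _ = make_toy_macrocycle(3, "cone")
        plan = fragment(unit_graph_of(mol), 3)
        direct = eng.evaluate(mol)
        rec = reconstruct_total(plan, eng, include_nb=True)
        assert abs(rec - direct) > 1e-6  # controlled fragmentation error


class TestInteractionAssembly:
    @pytest.mark.parametrize("n_rings", [3, 6, 8])
    def test_interaction_oracle(self, n_rings, engine):
        mol, _ = make_toy_macrocycle(n_rings, "cone")
        plan = fragment(unit_graph_of(mol), 3)
        guest = make_toy_guest("glycinelike", (0.6, -0.4, 4.0))
        direct = engine.evaluate_interaction(mol, guest)
        _, total = assemble_interaction(plan, guest, engine)
        assert total == pytest.approx(direct, rel=1e-10)

    def test_printed_table_lookup_assembly(self, cx_plan, fixture_paths):
        t4 = pd.read_csv(fixture_paths["cx_gly_fragment_energies"])
        records, total = assemble_interaction(
            cx_plan, make_toy_guest("water"), LookupEngine(t4["al_cx"].tolist())
        )
        assert [float(r["weight"]) for r in records] == t4["weight"].tolist()
        assert total == pytest.approx(-58.9, abs=0.15)

    def test_far_guest_with_cutoff_engine_is_zero(self, cx_plan):
        eng = PairwiseEngine(SurrogateParams(cutoff=50.0))
        guest = make_toy_guest("water", (0.0, 0.0, 1e6))
        _, total = assemble_interaction(cx_plan, guest, eng)
        assert total == 0.0


class TestPropertyReconstruction:
    @pytest.mark.parametrize("kind", ["dipole", "polarizability"])
    def test_additive_property_oracle(self, kind, engine):
        mol, _ = make_toy_macrocycle(5, "cone")
        plan = fragment(unit_graph_of(mol), 3)
        direct = engine.evaluate_property(mol, kind)
        rec = reconstruct_property(plan, engine, kind)
        np.testing.assert_allclose(rec, direct, rtol=1e-10, atol=1e-12)

    def test_symmetric_molecule_dipole_vanishes(self, engine):
        """Per-fragment dipoles are large but the weighted sum respects the
        n-fold symmetry of the macrocycle."""
        mol, _ = make_toy_macrocycle(6, "cone")
        plan = fragment(unit_graph_of(mol), 3)
        frag_norms = [
            np.linalg.norm(engine.evaluate_property(
                cap_fragment(fr, plan.unit_graph), "dipole"))
            for fr in plan.fragments[:4]
        ]
        rec = reconstruct_property(plan, engine, "dipole")
        assert np.linalg.norm(rec[:2]) < 1e-8 * max(frag_norms)

    def test_unsupported_property_kind(self, cx_plan, engine):
        with pytest.raises(ValueError):
            reconstruct_property(cx_plan, engine, "quadrupole")


class TestDifferenceAnalysis:
    def _records(self, plan):
        return [
            {"fragment": i + 1, "units": fr.units, "weight": fr.weight, "energy": 0.0}
            for i, fr in enumerate(plan.fragments)
        ]

    def test_identical_energies_give_zero_deltas(self, cx_plan):
        recs = self._records(cx_plan)
        out = fragment_difference_analysis(recs, focus_unit=recs[0]["units"][0])
        assert out and all(r["delta_e"] == 0.0 for r in out)

    def test_single_unit_carries_all_attraction(self, cx_plan):
        hot = cx_plan.fragments[0].units[0]
        recs = [
            {"fragment": i + 1, "units": fr.units, "weight": fr.weight,
             "energy": -20.0 if hot in fr.units else 0.0}
            for i, fr in enumerate(cx_plan.fragments)
        ]
        focus = next(
            u for u in cx_plan.fragments[0].units if u != hot
        )
        out = fragment_difference_analysis(recs, focus)
        for r in out:
            assert r["delta_e"] == (-20.0 if r["added_unit"] == hot else 0.0)

    def test_absent_focus_unit_raises(self, cx_plan):
        with pytest.raises(ValueError):
            fragment_difference_analysis(self._records(cx_plan), focus_unit=999)


class TestPlanSerialization:
    def test_json_round_trip(self, bcx_plan, bcx_unit_graph):
        text = bcx_plan.to_json()
        again = FragmentationPlan.from_json(text, bcx_unit_graph)
        assert again.level == bcx_plan.level
        assert [(fr.units, fr.weight) for fr in again.fragments] == [
            (fr.units, fr.weight) for fr in bcx_plan.fragments
        ]
        assert again.nonoverlap_terms == bcx_plan.nonoverlap_terms
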