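import numpy as np
import pytest

from pocketlit.extraction import ExtractedPocket, Provenance
from pocketlit.fixtures import FixtureSpec, PlantedPocket, make_alpha_spheres, make_structure, planted_truth
from pocketlit.geometry import (
    AlphaSphere,
    GeometricPocket,
    geometric_pocket_residues,
    jaccard,
    merge_pockets,
    read_fpocket_dir,
    residue_contact_fraction,
    select_pockets,
    SelectedPocket,
)
from pocketlit.mapping import MappedPocket, resolve_pockets
from pocketlit.structures import Atom, ResidueRef, vdw_radius


def atom(x, y, z, serial=1, element="C"):
    return Atom(serial=serial, name="C1", element=element, coords=np.array([x, y, z], float),
                vdw_radius=vdw_radius(element), is_heavy=True)


def sphere(x, y, z, r):
    return AlphaSphere(center=np.array([x, y, z], float), radius=r)


def mapped(refs, name="site", doc="paper_1", chains=("A",), interface=False):
    src = ExtractedPocket(name=name, description="", residues=tuple(refs),
                          provenance=Provenance(doc, "refined"))
    return MappedPocket(source=src, residues=tuple(refs), interface=interface,
                        chains=frozenset(chains))


class TestReadFpocketDir:
    def test_round_trip_of_fixture_layout(self, tmp_path, interface_spec):
        st = make_structure(interface_spec)
        written = make_alpha_spheres(st, interface_spec, tmp_path)
        loaded = read_fpocket_dir(tmp_path)
        assert [p.id for p in loaded] == [p.id for p in written]
        for a, b in zip(written, loaded):
            np.testing.assert_allclose(
                [s.center for s in a.spheres], [s.center for s in b.spheres], atol=1e-3
            )
            np.testing.assert_allclose(
                [s.radius for s in a.spheres], [s.radius for s in b.spheres], atol=1e-3
            )
            assert {r.key for r in a.residue_refs()} == {r.key for r in b.residue_refs()}

    def test_small_hand_fixture(self, tmp_path):
        pockets = tmp_path / "pockets"
        pockets.mkdir()
        (pockets / "pocket1_atm.pdb").write_text(
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C\nEND\n"
        )
        (pockets / "pocket1_vert.pqr").write_text(
            "ATOM      1 APOL STP     1       0.000   0.000   0.000   0.0000   3.2000\n"
            "ATOM      2 APOL STP     1       1.000   0.000   0.000   0.0000   2.1000\n"
        )
        (loaded,) = read_fpocket_dir(tmp_path)
        assert len(loaded.spheres) == 2
        assert loaded.spheres[0].radius == pytest.approx(3.2)

    def test_empty_dir(self, tmp_path):
        (tmp_path / "pockets").mkdir()
        assert read_fpocket_dir(tmp_path) == []

    def test_missing_vert_skips_pocket(self, tmp_path, caplog):
        pockets = tmp_path / "pockets"
        pockets.mkdir()
        (pockets / "pocket1_atm.pdb").write_text(
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C\nEND\n"
        )
        with caplog.at_level("WARNING", logger="pocketlit.geometry"):
            assert read_fpocket_dir(tmp_path) == []
        assert "missing" in caplog.text


class TestResidueContactFraction:
    def test_all_atoms_inside(self):
        atoms = [atom(0.1 * i, 0, 0, serial=i) for i in range(4)]
        assert residue_contact_fraction(atoms, [sphere(0, 0, 0, 2.0)]) == 1.0

    def test_half_within_radius_plus_tol(self):
        atoms = [atom(0, 0, 0), atom(2.5, 0, 0), atom(10, 0, 0), atom(11, 0, 0)]
        # cutoff = 2.0 + 1.0 = 3.0 -> first two in contact
        assert residue_contact_fraction(atoms, [sphere(0, 0, 0, 2.0)], contact_tol=1.0) == 0.5

    def test_empty_sphere_list(self):
        assert residue_contact_fraction([atom(0, 0, 0)], []) == 0.0


class TestGeometricPocketResidues:
    def _pocket(self):
        # residues with contact fractions 1.0, 0.5, 0.25 against one sphere
        s = sphere(0, 0, 0, 2.0)
        atoms, refs = [], []
        fractions = {1: [0.0, 1.0], 2: [0.0, 10.0], 3: [0.0, 10.0, 11.0, 12.0]}
        for res_id, xs in fractions.items():
            for x in xs:
                atoms.append(atom(x, 0, 0, serial=len(atoms) + 1))
                refs.append(ResidueRef("A", "ALA", res_id))
        return GeometricPocket(id=1, spheres=[s], atoms=atoms, atom_residues=refs)

    @pytest.mark.parametrize("threshold,expected_ids", [
        (0.0, {1, 2, 3}),   # any contacting atom qualifies
        (0.5, {1, 2}),
        (1.0, {1}),         # only fully enclosed residues
    ])
    def test_threshold_behaviour(self, threshold, expected_ids):
        refs = geometric_pocket_residues(self._pocket(), residue_match_threshold=threshold, contact_tol=1.0)
        assert {r.res_id for r in refs} == expected_ids


class TestJaccard:
    @pytest.mark.parametrize("a,b,expected", [
        ({("A", 1, "")}, {("A", 1, "")}, 1.0),
        ({("A", 1, "")}, {("A", 2, "")}, 0.0),
        ({("A", i, "") for i in range(3)}, {("A", i, "") for i in range(1, 5)}, 2 / 5),
        (set(), set(), 0.0),
    ])
    def test_values(self, a, b, expected):
        assert jaccard(a, b) == pytest.approx(expected)


class TestSelectPockets:
    def _setup(self, spec):
        st = make_structure(spec)
        geom = make_alpha_spheres(st, spec)
        truths = planted_truth(spec)
        pockets = [
            ExtractedPocket(name=t.name, description="", residues=tuple(t.literature_residues),
                            provenance=Provenance("paper_1", "refined"))
            for t in truths
        ]
        return st, geom, resolve_pockets(pockets, st)

    def test_planted_selected_decoys_discarded(self, interface_spec):
        st, geom, mp = self._setup(interface_spec)
        selected = select_pockets(geom, mp, st)
        assert [s.pocket.id for s in selected] == [1]  # two decoys dropped
        assert selected[0].support_jaccards == [pytest.approx(1.0)]

    def test_no_mapped_pockets_gives_empty_selection(self, interface_spec):
        st, geom, _ = self._setup(interface_spec)
        assert select_pockets(geom, [], st) == []

    def test_monotone_in_jaccard_threshold(self, interface_spec):
        st, geom, mp = self._setup(interface_spec)
        sizes = [len(select_pockets(geom, mp, st, pocket_match_jaccard=t))
                 for t in (0.0, 0.3, 0.7, 1.0)]
        assert sizes == sorted(sizes, reverse=True)

    def test_threshold_comparison_inclusive(self):
        refs = [ResidueRef("A", "ALA", i) for i in range(1, 5)]
        atoms = [atom(0, 0, 0, serial=i + 1) for i in range(4)]
        gp = GeometricPocket(id=1, spheres=[sphere(0, 0, 0, 2.0)], atoms=atoms, atom_residues=refs)
        # geometric residues {1..4}; mapped {3..6} -> jaccard 2/6 = 1/3
        mp = mapped([ResidueRef("A", "ALA", i) for i in range(3, 7)])
        assert select_pockets([gp], [mp], pocket_match_jaccard=1 / 3)
        assert not select_pockets([gp], [mp], pocket_match_jaccard=1 / 3 + 1e-9)


class TestMergePockets:
    def _selected(self, ids_residues, supports):
        out = []
        for pid, (ids, sup) in enumerate(zip(ids_residues, supports), start=1):
            refs = [ResidueRef("A", "ALA", i) for i in ids]
            atoms = [atom(float(i), 0, 0, serial=i) for i in ids]
            gp = GeometricPocket(
                id=pid,
                spheres=[sphere(float(pid) * 10, 0, 0, 2.0)],
                atoms=atoms,
                atom_residues=refs,
            )
            out.append(SelectedPocket(pocket=gp, residues=frozenset(refs),
                                      supports=sup, support_jaccards=[1.0] * len(sup)))
        return out

    def test_high_overlap_merges_with_sphere_union(self):
        m1, m2 = mapped([ResidueRef("A", "ALA", 1)], doc="p1"), mapped([ResidueRef("A", "ALA", 2)], doc="p2")
        sel = self._selected([range(1, 6), range(1, 5)], [[m1], [m2]])
        merged = merge_pockets(sel, merge_overlap_threshold=0.5)  # jaccard 4/5 = 0.8
        assert len(merged) == 1
        assert len(merged[0].spheres) == 2  # union without duplication
        assert merged[0].ids == (1, 2)

    def test_disjoint_pockets_untouched(self):
        m1, m2 = mapped([ResidueRef("A", "ALA", 1)], name="s1"), mapped([ResidueRef("A", "ALA", 20)], name="s2")
        sel = self._selected([range(1, 5), range(20, 24)], [[m1], [m2]])
        assert len(merge_pockets(sel)) == 2

    def test_merge_threshold_is_strict(self):
        m1, m2 = mapped([ResidueRef("A", "ALA", 1)], name="s1"), mapped([ResidueRef("A", "ALA", 2)], name="s2")
        sel = self._selected([{1, 2}, {2, 3}], [[m1], [m2]])  # jaccard 1/3
        assert len(merge_pockets(sel, merge_overlap_threshold=1 / 3)) == 2

    def test_transitive_closure(self):
        ms = [mapped([ResidueRef("A", "ALA", i)], name=f"s{i}") for i in range(3)]
        # A∩B and B∩C overlap; A and C disjoint
        sel = self._selected([{1, 2, 3}, {3, 4, 5}, {5, 6, 7}], [[m] for m in ms])
        merged = merge_pockets(sel, merge_overlap_threshold=0.1)
        assert len(merged) == 1 and merged[0].ids == (1, 2, 3)

    def test_shared_support_merges_disjoint_fragments(self):
        shared = mapped([ResidueRef("A", "ALA", i) for i in range(1, 10)], name="big site")
        sel = self._selected([{1, 2}, {8, 9}], [[shared], [shared]])
        merged = merge_pockets(sel, merge_overlap_threshold=0.9)
        assert len(merged) == 1  # Fpocket split of one site reunified via support

    def test_sphere_count_conserved(self):
        ms = [mapped([ResidueRef("A", "ALA", i)], name=f"s{i}") for i in range(3)]
        sel = self._selected([{1, 2, 3}, {3, 4}, {30, 31}], [[ms[0]], [ms[1]], [ms[2]]])
        merged = merge_pockets(sel, merge_overlap_threshold=0.1)
        assert sum(len(m.spheres) for m in merged) == sum(len(s.pocket.spheres) for s in sel)

    def test_multi_paper_descriptions_consolidated(self):
        m1 = mapped([ResidueRef("A", "ALA", 1)], name="ATP site", doc="p1")
        m2 = mapped([ResidueRef("A", "ALA", 2)], name="catalytic site", doc="p2")
        sel = self._selected([range(1, 6), range(1, 6)], [[m1], [m2]])
        (merged,) = merge_pockets(sel)
        assert merged.name == "ATP site / catalytic site"
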