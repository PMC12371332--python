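import numpy as np
import pytest

from pocketlit.extraction import ExtractedPocket, Provenance
from pocketlit.fixtures import FixtureSpec, PlantedPocket, make_structure, planted_truth
from pocketlit.mapping import (
    UnmappablePocketError,
    assign_chains,
    chain_similarity,
    cluster_residues,
    match_cluster_to_pocket,
    resolve_pockets,
)
from pocketlit.structures import ResidueRef


def lit_pocket(refs, name="site", doc="paper_1"):
    return ExtractedPocket(
        name=name, description="", residues=tuple(refs),
        provenance=Provenance(doc, "refined"),
    )


def seq_refs(structure, chain, ids, lit_chain=None):
    """Literature refs for structure residues (optionally with a quoted chain)."""
    out = []
    for i in ids:
        res = structure.get_residue(chain, i)
        out.append(ResidueRef(lit_chain or chain, res.ref.res_name, i))
    return out


class TestChainSimilarity:
    def test_all_present(self, interface_structure):
        refs = seq_refs(interface_structure, "A", [5, 6, 7, 8, 9])
        assert chain_similarity(refs, interface_structure, "A") == 1.0

    def test_counting_rule(self, interface_structure):
        st = interface_structure
        refs = seq_refs(st, "A", [5, 6, 7])
        wrong_name = ResidueRef("A", "TRP" if st.get_residue("A", 8).ref.res_name != "TRP" else "GLY", 8)
        absent = ResidueRef("A", "ALA", 999)
        score = chain_similarity(refs + [wrong_name, absent], st, "A")
        assert score == pytest.approx(0.6)  # 3 of 5

    def test_out_of_range_residues(self, interface_structure):
        refs = [ResidueRef("A", "ALA", 900 + i) for i in range(4)]
        assert chain_similarity(refs, interface_structure, "A") == 0.0

    def test_empty_pocket_raises(self, interface_structure):
        with pytest.raises(ValueError):
            chain_similarity([], interface_structure, "A")


class TestAssignChains:
    def test_homodimer_lists_both_identical_chains(self, interface_structure):
        pocket = lit_pocket(seq_refs(interface_structure, "A", [5, 6, 7, 8, 9]))
        a = assign_chains(pocket, interface_structure)
        assert set(a.chain_ids) == {"A", "B"}
        assert all(s == 1.0 for _, s, _ in a.candidates)

    def test_threshold_is_inclusive(self, interface_structure):
        st = interface_structure
        refs = seq_refs(st, "A", [5, 6, 7]) + [
            ResidueRef("A", "ALA", 901), ResidueRef("A", "ALA", 902),
        ]
        # exactly 3/5 = 0.6 on both identical chains
        a = assign_chains(lit_pocket(refs), st, chain_threshold=0.6)
        assert set(a.chain_ids) == {"A", "B"}

    def test_no_chain_passes_raises_with_best_score(self, interface_structure):
        refs = seq_refs(interface_structure, "A", [5, 6]) + [
            ResidueRef("A", "ALA", 900 + i) for i in range(3)
        ]
        with pytest.raises(UnmappablePocketError) as err:
            assign_chains(lit_pocket(refs), interface_structure)
        assert err.value.best_score == pytest.approx(0.4)

    def test_raising_threshold_never_adds_chains(self, interface_structure):
        st = interface_structure
        refs = seq_refs(st, "A", [5, 6, 7]) + [ResidueRef("A", "ALA", 901)]
        counts = []
        for thr in (0.2, 0.5, 0.75, 1.0):
            try:
                counts.append(len(assign_chains(lit_pocket(refs), st, thr).candidates))
            except UnmappablePocketError:
                counts.append(0)
        assert counts == sorted(counts, reverse=True)

    def test_offset_scan_recovers_renumbered_construct(self, interface_structure):
        st = interface_structure
        refs = [ResidueRef("A", st.get_residue("A", i).ref.res_name, i + 3) for i in [5, 6, 7, 8]]
        with pytest.raises(UnmappablePocketError):
            assign_chains(lit_pocket(refs), st, offset_scan=0)
        a = assign_chains(lit_pocket(refs), st, offset_scan=5)
        assert a.candidates[0][2] == -3  # recovered numbering shift


class TestClusterResidues:
    def test_two_distant_groups(self, monomer_spec):
        st = make_structure(monomer_spec)
        near = [st.get_residue("A", i).ref for i in (1, 2, 3)]
        far = [st.get_residue("A", i).ref for i in (20, 21, 22)]  # ~70 Å away
        clusters = cluster_residues(st, near + far, bandwidth=8.0)
        assert len(clusters) == 2
        assert {frozenset(r.res_id for r in c.members) for c in clusters} == {
            frozenset({1, 2, 3}), frozenset({20, 21, 22})
        }

    def test_single_residue(self, monomer_spec):
        st = make_structure(monomer_spec)
        ref = st.get_residue("A", 5).ref
        clusters = cluster_residues(st, [ref])
        assert len(clusters) == 1 and clusters[0].members == (ref,)

    def test_tight_group_is_one_cluster(self, monomer_spec):
        st = make_structure(monomer_spec)
        refs = [st.get_residue("A", i).ref for i in (1, 2)]
        assert len(cluster_residues(st, refs, bandwidth=8.0)) == 1

    def test_centroid_is_mean_of_representatives(self, monomer_spec):
        st = make_structure(monomer_spec)
        refs = [st.get_residue("A", i).ref for i in (1, 2)]
        (cluster,) = cluster_residues(st, refs, bandwidth=8.0)
        expected = np.mean([st.find(r).heavy_centroid() for r in refs], axis=0)
        np.testing.assert_allclose(cluster.centroid, expected)

    def test_deterministic_across_runs(self, interface_structure):
        refs = [interface_structure.get_residue("A", i).ref for i in range(1, 20)]
        a = cluster_residues(interface_structure, refs)
        b = cluster_residues(interface_structure, refs)
        assert [c.members for c in a] == [c.members for c in b]


class TestMatchClusterToPocket:
    def _cluster(self, st, ids, chain="A"):
        return cluster_residues(st, [st.get_residue(chain, i).ref for i in ids], bandwidth=1e6)[0]

    def test_full_overlap(self, interface_structure):
        st = interface_structure
        cluster = self._cluster(st, range(1, 6))
        mapped = {"A": [st.get_residue("A", i).ref for i in range(1, 6)]}
        overlap, matched = match_cluster_to_pocket(cluster, mapped)
        assert overlap == 1.0 and matched

    def test_seventy_percent_is_inclusive_boundary(self, interface_structure):
        st = interface_structure
        cluster = self._cluster(st, range(1, 8))  # 7 residues
        mapped = {"A": [st.get_residue("A", i).ref for i in range(1, 11)]}  # 10
        overlap, matched = match_cluster_to_pocket(cluster, mapped, cluster_threshold=0.7)
        assert overlap == pytest.approx(0.7) and matched

    def test_low_overlap_not_matched(self, interface_structure):
        st = interface_structure
        cluster = self._cluster(st, [1])
        mapped = {"A": [st.get_residue("A", i).ref for i in range(1, 11)]}
        overlap, matched = match_cluster_to_pocket(cluster, mapped)
        assert overlap == pytest.approx(0.1) and not matched

    def test_ambiguous_chains_compared_by_number(self, interface_structure):
        st = interface_structure
        cluster = self._cluster(st, range(1, 6), chain="B")
        mapped = {c: [st.get_residue(c, i).ref for i in range(1, 6)] for c in "AB"}
        overlap, matched = match_cluster_to_pocket(cluster, mapped)
        assert overlap == 1.0 and matched


class TestResolvePockets:
    def test_interface_fixture_gives_one_interface_pocket(self, interface_spec):
        st = make_structure(interface_spec)
        truth = planted_truth(interface_spec)[0]
        pocket = lit_pocket(truth.literature_residues, name=truth.name)
        mapped = resolve_pockets([pocket], st)
        assert len(mapped) == 1
        mp = mapped[0]
        assert mp.interface and mp.chains == frozenset({"A", "B"})
        assert frozenset(mp.residues) == truth.all_planted()

    def test_homotetramer_gives_four_replicas(self, tetramer_spec):
        st = make_structure(tetramer_spec)
        truth = planted_truth(tetramer_spec)[0]
        pocket = lit_pocket(truth.literature_residues, name=truth.name)
        mapped = resolve_pockets([pocket], st)
        assert len(mapped) == 4
        assert all(not mp.interface for mp in mapped)
        assert sorted(min(mp.chains) for mp in mapped) == ["A", "B", "C", "D"]
        for mp in mapped:
            chain = min(mp.chains)
            assert frozenset(mp.residues) == frozenset(truth.residues_by_chain[chain])

    def test_monomer_trivial_replica(self, monomer_spec):
        st = make_structure(monomer_spec)
        truth = planted_truth(monomer_spec)[0]
        mapped = resolve_pockets([lit_pocket(truth.literature_residues)], st)
        assert len(mapped) == 1
        assert frozenset(mapped[0].residues) == frozenset(truth.residues_by_chain["A"])

    def test_unmappable_pocket_skipped_not_fatal(self, monomer_spec, caplog):
        st = make_structure(monomer_spec)
        truth = planted_truth(monomer_spec)[0]
        bogus = lit_pocket([ResidueRef("A", "ALA", 900 + i) for i in range(4)], name="bogus")
        good = lit_pocket(truth.literature_residues, name="good")
        with caplog.at_level("WARNING", logger="pocketlit.mapping"):
            mapped = resolve_pockets([bogus, good], st)
        assert [mp.name for mp in mapped] == ["good"]
        assert "unmappable" in caplog.text

    def test_each_residue_in_at_most_one_output_set(self, tetramer_spec):
        st = make_structure(tetramer_spec)
        truth = planted_truth(tetramer_spec)[0]
        mapped = resolve_pockets([lit_pocket(truth.literature_residues)], st)
        seen = []
        for mp in mapped:
            seen.extend(r.key for r in mp.residues)
        assert len(seen) == len(set(seen))

    def test_determinism(self, interface_spec):
        st = make_structure(interface_spec)
        truth = planted_truth(interface_spec)[0]
        pocket = lit_pocket(truth.literature_residues)
        assert resolve_pockets([pocket], st) == resolve_pockets([pocket], st)
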