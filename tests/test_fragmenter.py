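"""Base-fragment cutting, connected-subset enumeration, assembly, pipeline."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from rdkit import Chem

from fragspace import (
    FragmentationError,
    FragmentationParams,
    MoleculeParseError,
    MoleculeRecord,
    assemble,
    builtin_ruleset,
    cut_to_base_fragments,
    enumerate_connected_subsets,
    find_cut_bonds,
    fragment_molecule,
)
from fragspace.fixtures import (
    brute_force_connected_subsets,
    chain_molecule,
    drug_like_library,
)


def strip_dummies(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    em = Chem.RWMol(mol)
    for idx in sorted(
        (a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() == 0), reverse=True
    ):
        em.RemoveAtom(idx)
    out = em.GetMol()
    Chem.SanitizeMol(out)
    return out


class TestMoleculeRecord:
    def test_multi_component_rejected(self):
        with pytest.raises(MoleculeParseError, match="multi-component"):
            MoleculeRecord.from_smiles("CC.[Na+]", "salt")

    def test_bad_smiles_rejected(self):
        with pytest.raises(MoleculeParseError):
            MoleculeRecord.from_smiles("notasmiles", "bad")

    def test_stereochemistry_stripped(self):
        rec = MoleculeRecord.from_smiles("C[C@H](N)C(=O)O", "ala")
        assert "@" not in Chem.MolToSmiles(rec.mol)


class TestCutToBaseFragments:
    def test_no_cuts_single_node(self, recap):
        rec = MoleculeRecord.from_smiles("c1ccccc1", "bz")
        g = cut_to_base_fragments(rec, [])
        assert len(g.nodes) == 1 and len(g.edges) == 0
        assert g.nodes[0] == frozenset(range(6))

    def test_n_phenylbenzamide_path_of_three(self, recap):
        rec = MoleculeRecord.from_smiles("O=C(c1ccccc1)Nc1ccccc1", "npb")
        cuts = find_cut_bonds(rec, recap)
        assert len(cuts) == 2
        g = cut_to_base_fragments(rec, cuts)
        assert len(g.nodes) == 3 and len(g.edges) == 2
        degrees = sorted(sum(1 for i, j, _ in g.edges if n in (i, j)) for n in range(3))
        assert degrees == [1, 1, 2]  # path topology

    @pytest.mark.parametrize("m", [1, 2, 4])
    def test_chain_molecule_gives_path(self, recap, m):
        rec = MoleculeRecord.from_smiles(chain_molecule(m), f"chain{m}")
        cuts = find_cut_bonds(rec, recap)
        assert len(cuts) == m
        g = cut_to_base_fragments(rec, cuts)
        assert len(g.nodes) == m + 1 and len(g.edges) == m

    def test_nodes_partition_parent_atoms(self, extended_recap, examples):
        for rec in examples.values():
            g = cut_to_base_fragments(rec, find_cut_bonds(rec, extended_recap))
            union = set().union(*g.nodes)
            assert union == set(range(rec.mol.GetNumAtoms()))
            assert sum(len(n) for n in g.nodes) == rec.mol.GetNumAtoms()


class TestEnumerateConnectedSubsets:
    def test_path_of_three_k2(self):
        adj = [{1}, {0, 2}, {1}]
        subs = enumerate_connected_subsets(adj, k=2)
        assert subs == [
            frozenset({0}), frozenset({1}), frozenset({2}),
            frozenset({0, 1}), frozenset({1, 2}),
        ]

    def test_single_node(self):
        assert enumerate_connected_subsets([set()], k=5) == [frozenset({0})]

    def test_triangle_unlimited_gives_all_seven(self):
        adj = [{1, 2}, {0, 2}, {0, 1}]
        assert len(enumerate_connected_subsets(adj, k=-1)) == 7

    def test_guard_cap_raises_named_error(self):
        # complete graph on 18 nodes: 2^18 - 1 connected subsets
        n = 18
        adj = [set(range(n)) - {i} for i in range(n)]
        with pytest.raises(FragmentationError, match="1000"):
            enumerate_connected_subsets(adj, k=-1, guard_cap=1000)

    @given(st.integers(min_value=2, max_value=7), st.data())
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_matches_brute_force_on_random_connected_graphs(self, n, data):
        # random connected graph: a spanning path plus random extra edges
        extra = data.draw(
            st.sets(
                st.tuples(
                    st.integers(0, n - 1), st.integers(0, n - 1)
                ).filter(lambda t: t[0] < t[1]),
                max_size=6,
            )
        )
        adj = [set() for _ in range(n)]
        for i in range(n - 1):
            adj[i].add(i + 1)
            adj[i + 1].add(i)
        for a, b in extra:
            adj[a].add(b)
            adj[b].add(a)
        k = data.draw(st.integers(min_value=-1, max_value=n))
        assert enumerate_connected_subsets(adj, k) == brute_force_connected_subsets(adj, k)


class TestAssemble:
    @pytest.fixture()
    def npb_graph(self, recap):
        rec = MoleculeRecord.from_smiles("O=C(c1ccccc1)Nc1ccccc1", "npb")
        return cut_to_base_fragments(rec, find_cut_bonds(rec, recap))

    def test_acyl_plus_nitrogen_pair(self, npb_graph):
        # the benzoyl node always contains atom 0 (the carbonyl O)
        benzoyl = next(i for i, n in enumerate(npb_graph.nodes) if 0 in n)
        nitrogen = next(i for i, n in enumerate(npb_graph.nodes) if len(n) == 1)
        frag = assemble(npb_graph, {benzoyl, nitrogen}, x=True)
        assert frag.capped_smiles == Chem.CanonSmiles("O=C(c1ccccc1)N*")
        assert frag.boundary_cuts == 1

    def test_full_graph_reproduces_parent(self, npb_graph):
        frag = assemble(npb_graph, {0, 1, 2}, x=True)
        assert "*" not in frag.capped_smiles
        assert frag.capped_smiles == Chem.MolToSmiles(npb_graph.parent.mol)
        assert frag.boundary_cuts == 0

    def test_dummy_and_hydrogen_caps_are_consistent(self, npb_graph):
        for members in [{0}, {1}, {2}, {0, 1}, {1, 2}]:
            with_x = assemble(npb_graph, members, x=True)
            without = assemble(npb_graph, members, x=False)
            stripped = Chem.MolToSmiles(strip_dummies(with_x.capped_smiles))
            assert stripped == without.capped_smiles
            assert with_x.heavy_atoms == without.heavy_atoms

    def test_disconnected_members_rejected(self, npb_graph):
        with pytest.raises(ValueError, match="connected"):
            assemble(npb_graph, {0, 2}, x=True)

    def test_star_count_equals_boundary_cuts(self, extended_recap, examples):
        for rec in examples.values():
            g = cut_to_base_fragments(rec, find_cut_bonds(rec, extended_recap))
            for members in enumerate_connected_subsets(g, k=-1):
                frag = assemble(g, members, x=True)
                assert frag.capped_smiles.count("*") == frag.boundary_cuts


class TestFragmentMolecule:
    PARAMS = dict(n_min=5, s_rel=0.99)

    def test_benzene_yields_nothing(self, recap):
        rec = MoleculeRecord.from_smiles("c1ccccc1", "bz")
        out = fragment_molecule(rec, recap, FragmentationParams(k=1, **self.PARAMS))
        assert out == []

    def test_phenylethylamine_ccq_single_fragment(self, ccq):
        rec = MoleculeRecord.from_smiles("NCCc1ccccc1", "pea")
        out = fragment_molecule(
            rec, ccq, FragmentationParams(k=1, x=True, **self.PARAMS)
        )
        assert [f.capped_smiles for f in out] == ["*Cc1ccccc1"]

    def test_two_base_fragments_k8_equals_k1(self, ccq):
        # with 2 base fragments the only size-2 union is the parent, removed by s
        rec = MoleculeRecord.from_smiles("NCCc1ccccc1", "pea")
        k1 = fragment_molecule(rec, ccq, FragmentationParams(k=1, x=True, **self.PARAMS))
        k8 = fragment_molecule(rec, ccq, FragmentationParams(k=8, x=True, **self.PARAMS))
        assert [f.capped_smiles for f in k1] == [f.capped_smiles for f in k8]

    @pytest.mark.parametrize("m,k", [(3, 1), (3, 2), (5, -1), (5, 3)])
    def test_path_closed_form_before_filtering(self, recap, m, k):
        rec = MoleculeRecord.from_smiles(chain_molecule(m), f"chain{m}")
        g = cut_to_base_fragments(rec, find_cut_bonds(rec, recap))
        subs = enumerate_connected_subsets(g, k)
        nodes = m + 1
        kk = nodes if k <= 0 or k > nodes else k
        expected = sum(nodes - j + 1 for j in range(1, kk + 1))
        assert len(subs) == expected
        assert subs == brute_force_connected_subsets(g.adjacency(), k)

    def test_monotone_in_k(self, extended_recap, examples):
        for rec in examples.values():
            prev: set = set()
            for k in (1, 2, 3):
                out = {
                    f.capped_smiles
                    for f in fragment_molecule(
                        rec, extended_recap, FragmentationParams(k=k, x=True, **self.PARAMS)
                    )
                }
                assert prev <= out
                prev = out

    def test_parent_never_emitted_with_s_below_one(self, extended_recap, examples):
        for rec in examples.values():
            parent = Chem.MolToSmiles(rec.mol)
            for x in (False, True):
                out = fragment_molecule(
                    rec, extended_recap, FragmentationParams(k=-1, x=x, n_min=1, s_rel=0.99)
                )
                assert parent not in {f.capped_smiles for f in out}

    def test_dummy_capping_refines_hydrogen_capping(self, extended_recap, examples):
        for rec in examples.values():
            n_x = len(
                fragment_molecule(rec, extended_recap, FragmentationParams(k=8, x=True, **self.PARAMS))
            )
            n_h = len(
                fragment_molecule(rec, extended_recap, FragmentationParams(k=8, x=False, **self.PARAMS))
            )
            assert n_x >= n_h

    def test_every_fragment_is_parent_substructure(self, extended_recap, examples):
        for rec in examples.values():
            for x in (False, True):
                out = fragment_molecule(
                    rec, extended_recap, FragmentationParams(k=-1, x=x, n_min=1)
                )
                for f in out:
                    query = strip_dummies(f.capped_smiles)
                    assert rec.mol.HasSubstructMatch(query), (
                        rec.compound_id, f.capped_smiles
                    )

    def test_heavy_atom_filters_ignore_caps(self, extended_recap):
        # fragments counted by heavy atoms only, so filters match across x
        rec = MoleculeRecord.from_smiles("O1CCN(Cc2ccccc2)CC1", "morph")
        for n_min in (2, 5, 7):
            a = fragment_molecule(
                rec, extended_recap, FragmentationParams(k=8, x=True, n_min=n_min, s_rel=0.99)
            )
            b = fragment_molecule(
                rec, extended_recap, FragmentationParams(k=8, x=False, n_min=n_min, s_rel=0.99)
            )
            assert {f.heavy_atoms for f in a} == {f.heavy_atoms for f in b}


@given(st.data())
@settings(max_examples=25, deadline=None, derandomize=True)
def test_invariants_on_random_library_molecules(data):
    """Substructure, cut-accounting and dedup invariants on randomly
    drawn drug-like fixture molecules and parameters."""
    fx = drug_like_library()
    cid, smi = data.draw(st.sampled_from(fx.molecules))
    k = data.draw(st.sampled_from([1, 2, 8, -1]))
    x = data.draw(st.booleans())
    rec = MoleculeRecord.from_smiles(smi, cid)
    rs = builtin_ruleset(data.draw(st.sampled_from(["RECAP", "extendedRECAP", "CCQ"])))
    out = fragment_molecule(rec, rs, FragmentationParams(k=k, x=x, n_min=1, s_rel=0.99))
    smiles = [f.capped_smiles for f in out]
    assert len(smiles) == len(set(smiles))  # per-compound dedup
    for f in out:
        if x:
            assert f.capped_smiles.count("*") == f.boundary_cuts
        assert f.heavy_atoms <= 0.99 * rec.heavy_atoms
        assert rec.mol.HasSubstructMatch(strip_dummies(f.capped_smiles))
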