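"""Exhaustive fragmentation of a molecule.

The pipeline: cut every rule-matched acyclic single bond to obtain the
smallest ("base") fragments, build the fragment-adjacency graph (nodes =
base fragments, edges = cut bonds), enumerate every connected union of
up to ``k`` base fragments, and reassemble each union into a capped
fragment — open valences become dummy atoms (``*``) when the cut-point
flag ``x`` is on, implicit hydrogens otherwise.  Size, relative-size and
weight filters then select fragment-like outputs.

With ``k=1`` this reduces to standard smallest-fragment ("extensive")
fragmentation; with ``k`` unlimited it emits the complete connected
fragment space of the molecule under the given rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
from rdkit import Chem
from rdkit.Chem import Descriptors

from .rules import CutBond, RuleSet, find_cut_bonds

__all__ = [
    "MoleculeRecord",
    "FragmentGraph",
    "AssembledFragment",
    "FragmentationParams",
    "FragmentationError",
    "MoleculeParseError",
    "cut_to_base_fragments",
    "enumerate_connected_subsets",
    "assemble",
    "fragment_molecule",
]

DEFAULT_SUBSET_GUARD = 100_000


class MoleculeParseError(ValueError):
    """Raised for unparsable or multi-component input SMILES."""


class FragmentationError(RuntimeError):
    """Raised when the combinatorial guard cap is exceeded."""


@dataclass(frozen=True)
class MoleculeRecord:
    """A parsed input compound.

    Stereochemistry is stripped on parse: fragment identity throughout
    this package is constitution-level.
    """

    compound_id: str
    smiles: str
    mol: Chem.Mol = field(repr=False, compare=False)
    heavy_atoms: int
    mol_weight: float

    @classmethod
    def from_smiles(cls, smiles: str, compound_id: str = "MOL") -> "MoleculeRecord":
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise MoleculeParseError(f"{compound_id}: SMILES does not parse: {smiles!r}")
        n_comp = len(Chem.GetMolFrags(mol))
        if n_comp != 1:
            raise MoleculeParseError(
                f"{compound_id}: multi-component SMILES ({n_comp} components); "
                "strip salts/mixtures upstream"
            )
        Chem.RemoveStereochemistry(mol)
        if mol.GetNumAtoms() < 1:
            raise MoleculeParseError(f"{compound_id}: no heavy atoms")
        return cls(
            compound_id=compound_id,
            smiles=smiles,
            mol=mol,
            heavy_atoms=mol.GetNumAtoms(),
            mol_weight=Descriptors.MolWt(mol),
        )


@dataclass(frozen=True)
class FragmentGraph:
    """Quotient graph of a molecule under its cut bonds.

    ``nodes[i]`` is the frozen atom-index set of base fragment *i*; the
    node sets partition the parent's heavy atoms.  ``edges`` holds one
    entry per cut bond, joining the two nodes its atoms fall in.
    """

    parent: MoleculeRecord
    nodes: tuple[frozenset[int], ...]
    edges: tuple[tuple[int, int, CutBond], ...]

    def adjacency(self) -> list[set[int]]:
        adj: list[set[int]] = [set() for _ in self.nodes]
        for i, j, _ in self.edges:
            adj[i].add(j)
            adj[j].add(i)
        return adj


@dataclass(frozen=True)
class AssembledFragment:
    """A connected union of base fragments with capped open valences."""

    member_nodes: frozenset[int]
    atom_set: frozenset[int]
    boundary_cuts: int
    capped_smiles: str
    heavy_atoms: int
    mol_weight: float


@dataclass(frozen=True)
class FragmentationParams:
    """Run parameters.

    k
        Maximum number of base fragments combined per output fragment;
        ``k <= 0`` (or k >= node count) means unlimited, i.e. exhaustive.
    n_min
        Minimal heavy-atom count of an output fragment.
    m_max
        Maximal heavy-atom count (None = no cap).
    s_rel
        Maximal size relative to the parent, as a fraction of the
        parent's heavy atoms; a value just below 1 excludes the parent
        itself while keeping every proper substructure.
    w_max
        Maximal molecular weight of the capped fragment (None = no cap).
    x
        Cut-point flag: cap open valences with dummy atoms instead of
        hydrogens.
    """

    k: int = 1
    n_min: int = 1
    m_max: int | None = None
    s_rel: float | None = None
    w_max: float | None = None
    x: bool = False
    guard_cap: int = DEFAULT_SUBSET_GUARD

    def __post_init__(self) -> None:
        if self.n_min < 1:
            raise ValueError("n_min must be >= 1")
        if self.s_rel is not None and not (0.0 < self.s_rel <= 1.0):
            raise ValueError("s_rel must lie in (0, 1]")


def cut_to_base_fragments(mol: MoleculeRecord, cuts: list[CutBond]) -> FragmentGraph:
    """Remove every cut bond and return the fragment-adjacency graph.

    With no cuts the graph is a single node holding all heavy atoms.
    """
    g = nx.Graph()
    g.add_nodes_from(range(mol.mol.GetNumAtoms()))
    cut_idx = {c.bond_index for c in cuts}
    for bond in mol.mol.GetBonds():
        if bond.GetIdx() not in cut_idx:
            g.add_edge(bond.GetBeginAtomIdx(), bond.GetEndAtomIdx())
    comps = [frozenset(c) for c in nx.connected_components(g)]
    comps.sort(key=min)
    atom_to_node = {a: i for i, comp in enumerate(comps) for a in comp}
    edges = []
    for cut in cuts:
        i, j = atom_to_node[cut.atom_a], atom_to_node[cut.atom_b]
        edges.append((min(i, j), max(i, j), cut))
    return FragmentGraph(parent=mol, nodes=tuple(comps), edges=tuple(edges))


def enumerate_connected_subsets(
    graph: FragmentGraph | list[set[int]],
    k: int,
    guard_cap: int = DEFAULT_SUBSET_GUARD,
) -> list[frozenset[int]]:
    """Enumerate every node set inducing a connected subgraph, |set| <= k.

    ``k <= 0`` means no size limit.  Expansion proceeds from each node by
    repeatedly adding one neighbour, with a visited set to keep every
    subset unique.  Output is sorted by size, then by node indices.

    Raises
    ------
    FragmentationError
        If more than ``guard_cap`` subsets would be produced.
    """
    adj = graph.adjacency() if isinstance(graph, FragmentGraph) else graph
    n = len(adj)
    kmax = n if k <= 0 or k > n else k
    seen: set[frozenset[int]] = set()
    frontier = [frozenset([v]) for v in range(n)]
    seen.update(frontier)
    while frontier:
        nxt = []
        for sub in frontier:
            if len(sub) >= kmax:
                continue
            boundary = set().union(*(adj[v] for v in sub)) - sub
            for w in boundary:
                cand = sub | {w}
                if cand not in seen:
                    seen.add(cand)
                    if len(seen) > guard_cap:
                        raise FragmentationError(
                            f"more than {guard_cap} connected subsets; raise the "
                            "guard cap or lower k"
                        )
                    nxt.append(cand)
        frontier = nxt
    return sorted(seen, key=lambda s: (len(s), sorted(s)))


def _dummies_to_hydrogens(mol: Chem.Mol) -> Chem.Mol:
    em = Chem.RWMol(mol)
    for atom in em.GetAtoms():
        if atom.GetAtomicNum() == 0:
            atom.SetAtomicNum(1)
            atom.SetIsotope(0)
    out = em.GetMol()
    Chem.SanitizeMol(out)
    return Chem.RemoveHs(out)


def assemble(graph: FragmentGraph, members: frozenset[int] | set[int], x: bool) -> AssembledFragment:
    """Reassemble a connected set of base fragments into a capped fragment.

    Bonds internal to the member set — including cut bonds between member
    fragments — are restored exactly as in the parent; every boundary cut
    becomes a cap: a dummy atom when ``x`` is on, an implicit hydrogen
    otherwise.  The SMILES is canonical.
    """
    members = frozenset(members)
    if not members:
        raise ValueError("member set must be non-empty")
    adj = graph.adjacency()
    if not _is_connected(adj, members):
        raise ValueError("member nodes do not induce a connected subgraph")
    atom_set = frozenset().union(*(graph.nodes[i] for i in members))
    boundary = [
        cut for i, j, cut in graph.edges if (i in members) != (j in members)
    ]
    parent = graph.parent.mol
    if boundary:
        pieces = Chem.FragmentOnBonds(
            parent,
            [c.bond_index for c in boundary],
            addDummies=True,
            dummyLabels=[(0, 0)] * len(boundary),
        )
        keep = None
        for frag_atoms in Chem.GetMolFrags(pieces):
            real = {a for a in frag_atoms if a < parent.GetNumAtoms()}
            if real <= atom_set and real:
                if keep is None:
                    keep = set(frag_atoms)
                else:
                    keep.update(frag_atoms)
        sub = _extract_atoms(pieces, keep)
    else:
        # no boundary cut: the member set covers the whole (connected) parent
        sub = Chem.Mol(parent)
    if not x:
        sub = _dummies_to_hydrogens(sub)
    smiles = Chem.MolToSmiles(sub)
    heavy = sum(1 for a in sub.GetAtoms() if a.GetAtomicNum() > 1)
    return AssembledFragment(
        member_nodes=members,
        atom_set=atom_set,
        boundary_cuts=len(boundary),
        capped_smiles=smiles,
        heavy_atoms=heavy,
        mol_weight=Descriptors.MolWt(sub),
    )


def _extract_atoms(mol: Chem.Mol, atoms: set[int]) -> Chem.Mol:
    em = Chem.RWMol(mol)
    for idx in sorted(set(range(mol.GetNumAtoms())) - atoms, reverse=True):
        em.RemoveAtom(idx)
    out = em.GetMol()
    Chem.SanitizeMol(out)
    return out


def _is_connected(adj: list[set[int]], members: frozenset[int]) -> bool:
    start = next(iter(members))
    seen = {start}
    stack = [start]
    while stack:
        for w in adj[stack.pop()] & members:
            if w not in seen:
                seen.add(w)
                stack.append(w)
    return seen == members


def fragment_molecule(
    mol: MoleculeRecord, ruleset: RuleSet, params: FragmentationParams
) -> list[AssembledFragment]:
    """Full per-molecule pipeline: cut, combine, cap, filter, deduplicate.

    Filters: ``n_min <= heavy_atoms``; ``heavy_atoms <= m_max`` if set;
    ``heavy_atoms <= s_rel * parent heavy atoms`` if set; ``mol_weight <=
    w_max`` if set.  Atom counts are heavy atoms only — dummy caps and
    hydrogens never count, so the filters are invariant under ``x``.
    Fragments identical by capped canonical SMILES are collapsed within
    the compound; output is sorted by (heavy_atoms, capped_smiles).
    """
    cuts = find_cut_bonds(mol, ruleset)
    graph = cut_to_base_fragments(mol, cuts)
    subsets = enumerate_connected_subsets(graph, params.k, params.guard_cap)
    out: dict[str, AssembledFragment] = {}
    for members in subsets:
        frag = assemble(graph, members, params.x)
        if frag.heavy_atoms < params.n_min:
            continue
        if params.m_max is not None and frag.heavy_atoms > params.m_max:
            continue
        if params.s_rel is not None and frag.heavy_atoms > params.s_rel * mol.heavy_atoms:
            continue
        if params.w_max is not None and frag.mol_weight > params.w_max:
            continue
        out.setdefault(frag.capped_smiles, frag)
    return sorted(out.values(), key=lambda f: (f.heavy_atoms, f.capped_smiles))
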