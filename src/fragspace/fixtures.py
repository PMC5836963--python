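"""Deterministic test structures and independent brute-force oracles.

Everything here is generated programmatically: worked-example molecules
exercising each rule family (amides, esters, amines, sulphonamides,
morpholines, heteroatom-flanked C-C bonds, an uncuttable macrocycle),
synthetic chain molecules whose fragment-adjacency graph is a path of a
chosen length, and a ~50-molecule drug-like library assembled from
core x linker x tail motifs for distribution-level tests.

The oracles are deliberately naive: power-set enumeration with a
connectivity check, and a symmetry-orbit count for capped-benzene
patterns.  They exist to cross-check the production algorithms and are
never used in the pipeline itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

from rdkit import Chem

__all__ = [
    "FixtureSet",
    "chain_molecule",
    "benzene_pattern_count",
    "hexagon_orbit_count",
    "brute_force_connected_subsets",
    "worked_examples",
    "drug_like_library",
]


@dataclass(frozen=True)
class FixtureSet:
    name: str
    molecules: tuple[tuple[str, str], ...]  # (compound_id, smiles)
    expected: dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cid, smi in self.molecules:
            mol = Chem.MolFromSmiles(smi)
            if mol is None or len(Chem.GetMolFrags(mol)) != 1:
                raise ValueError(f"fixture {cid!r}: bad SMILES {smi!r}")


def chain_molecule(m: int) -> str:
    """A linear molecule with exactly ``m`` RECAP-cleavable bonds.

    Para-phenylene units joined by ester links: each C(=O)-O bond is the
    only RECAP match per link (the ester oxygen is excluded from the
    ether rule), so the fragment-adjacency graph is a path of ``m + 1``
    nodes and every base fragment has at least 5 heavy atoms.
    """
    if m < 0:
        raise ValueError("m must be >= 0")
    return "c1ccc(cc1)" + "C(=O)Oc1ccc(cc1)" * m if m else "c1ccccc1"


def benzene_pattern_count(min_cuts: int, max_cuts: int) -> int:
    """Distinct capped-benzene SMILES with min..max dummy cut points.

    Every subset of ring positions of the given sizes gets a dummy atom
    per position; canonical SMILES deduplication counts the distinct
    substitution patterns, i.e. the orbit count under the hexagon's
    symmetry group.
    """
    if not (0 <= min_cuts <= max_cuts <= 6):
        raise ValueError("need 0 <= min_cuts <= max_cuts <= 6")
    seen: set[str] = set()
    for j in range(min_cuts, max_cuts + 1):
        for positions in combinations(range(6), j):
            em = Chem.RWMol(Chem.MolFromSmiles("c1ccccc1"))
            for pos in positions:
                d = em.AddAtom(Chem.Atom(0))
                em.AddBond(pos, d, Chem.BondType.SINGLE)
            mol = em.GetMol()
            Chem.SanitizeMol(mol)
            seen.add(Chem.MolToSmiles(mol))
    return len(seen)


def hexagon_orbit_count(min_marks: int, max_marks: int) -> int:
    """Graph-free oracle for benzene_pattern_count.

    Counts orbits of vertex subsets of a hexagon under the dihedral
    group D6 (rotations and reflections), restricted to subset sizes in
    [min_marks, max_marks].  Independent of any chemistry toolkit.
    """
    verts = range(6)
    perms = []
    for r in range(6):
        perms.append([(v + r) % 6 for v in verts])  # rotation
        perms.append([(r - v) % 6 for v in verts])  # reflection
    count = 0
    for j in range(min_marks, max_marks + 1):
        reps = {
            min(tuple(sorted(p[v] for v in subset)) for p in perms)
            for subset in combinations(verts, j)
        }
        count += len(reps)
    return count


def brute_force_connected_subsets(adj: list[set[int]], k: int) -> list[frozenset[int]]:
    """Power-set + connectivity-check oracle for connected-subset enumeration."""
    n = len(adj)
    kmax = n if k <= 0 or k > n else k
    out = []
    for size in range(1, kmax + 1):
        for combo in combinations(range(n), size):
            members = frozenset(combo)
            start = combo[0]
            seen = {start}
            stack = [start]
            while stack:
                for w in adj[stack.pop()] & members:
                    if w not in seen:
                        seen.add(w)
                        stack.append(w)
            if seen == members:
                out.append(members)
    return sorted(out, key=lambda s: (len(s), sorted(s)))


def worked_examples() -> FixtureSet:
    """Curated molecules exercising every rule family and edge case."""
    mols = (
        # benzene / toluene bearing, 1..5 cleavable substituents
        ("benzyl_1", "OCC(=O)OCc1ccccc1"),
        ("benzyl_2", "OCC(=O)OCc1ccc(COC(=O)CO)cc1"),
        ("benzyl_3", "OCC(=O)OCc1cc(COC(=O)CO)cc(COC(=O)CO)c1"),
        ("toluene_amide", "CC(=O)NCc1ccc(C)cc1"),
        # morpholine: N-linked vs C-linked attachment
        ("morpholine_n_linked", "O1CCN(Cc2ccccc2)CC1"),
        ("morpholine_c_linked", "O1CCNCC1Cc1ccccc1"),
        # sulphonamides
        ("sulfonamide_1", "CS(=O)(=O)Nc1ccccc1"),
        ("sulfonamide_2", "O=S(=O)(NCCc1ccccc1)c1ccc(N)cc1"),
        # amide / ester / amine RECAP substrates
        ("n_phenylbenzamide", "O=C(c1ccccc1)Nc1ccccc1"),
        ("phenyl_acetate", "CC(=O)Oc1ccccc1"),
        ("dimethylbenzylamine", "CN(C)Cc1ccccc1"),
        # heteroatom-flanked C-C bond for CCQ
        ("phenylethylamine", "NCCc1ccccc1"),
        # macrocyclic peptide-like ring: no rule can open the ring
        ("macrocycle", "O=C1CN(Cc2ccccc2)C(=O)CNC(=O)CNC(=O)CN1"),
        # no cleavable bonds at all
        ("benzene", "c1ccccc1"),
    )
    return FixtureSet(name="worked_examples", molecules=mols)


# Motif pools for the generated drug-like library.  Cores are templates
# with one substitution site; combined deterministically so every run
# yields the same molecules.
_CORES = (
    "c1ccc({R})cc1",
    "c1ccnc({R})c1",
    "c1ccc2cc({R})ccc2c1",
    "c1cc({R})sc1",
    "c1ccc(F)c({R})c1",
)
_LINKERS = ("C(=O)N", "C(=O)O", "S(=O)(=O)N", "CN", "OC", "C(=O)")
# tails use ring-closure digit 8 so they can sit inside an open core ring
_TAILS = ("CCN(C)C", "Cc8ccccc8", "C8CCNCC8", "CCO", "CC(C)C", "CCc8ccco8")


def drug_like_library(size: int = 50) -> FixtureSet:
    """A generated library of ~50 small drug-like molecules.

    Cartesian combinations of aryl cores, common linkers and aliphatic /
    heteroaryl tails, taken in a fixed order.  It emulates the motif
    variety of a small-molecule drug collection (amides, esters,
    sulphonamides, amines and ethers spread over aromatic cores) — not
    any specific database.
    """
    mols: list[tuple[str, str]] = []
    for core in _CORES:
        for linker in _LINKERS:
            for tail in _TAILS:
                if len(mols) >= size:
                    return FixtureSet(name="drug_like_library", molecules=tuple(mols))
                smi = core.format(R=linker + tail)
                mol = Chem.MolFromSmiles(smi)
                if mol is None or len(Chem.GetMolFrags(mol)) != 1:
                    continue
                mols.append((f"LIB{len(mols) + 1:03d}", smi))
    return FixtureSet(name="drug_like_library", molecules=tuple(mols))
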