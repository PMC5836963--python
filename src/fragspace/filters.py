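"""Fragment physicochemical properties and the rule-of-three filter panel.

Properties are computed on the capped representation exactly as emitted:
with hydrogen caps, a cap hydrogen on N or O counts as a hydrogen-bond
donor (the inflation that motivates dummy-atom cut points); with dummy
caps, dummy atoms contribute nothing to any property and bonds to them
are terminal, hence never rotatable.

Definitions used here (conventional Lipinski-style counting, fixed so
the counts are reproducible):

* donors (HBD): N or O bearing at least one explicit or implicit H;
* acceptors (HBA): N or O, excluding pyrrole-type aromatic NH and N
  bonded to a carbonyl/thiocarbonyl or sulfonyl group;
* rotatable non-terminal bonds: acyclic single bonds between two
  non-terminal heavy atoms, excluding amide C-N bonds and bonds to
  dummy atoms (a dummy neighbour does not make an atom non-terminal);
* logP: the Wildman-Crippen atom-contribution estimate (an xlogP-style
  surrogate; dummy atoms contribute 0).

Rule-of-three thresholds: MW < 300, logP <= 3, HBD <= 3, HBA <= 3,
rotatable non-terminal bonds <= 3.
"""

from __future__ import annotations

from dataclasses import dataclass

from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors

from .fragmenter import AssembledFragment

__all__ = ["Ro3Properties", "compute_ro3", "apply_ro3_filters", "RO3_FILTER_KEYS"]

RO3_FILTER_KEYS = ("weight", "xlogp", "hbd", "hba", "rotb")


@dataclass(frozen=True)
class Ro3Properties:
    mol_weight: float
    xlogp: float
    hbd: int
    hba: int
    rotb_nt: int

    def passes(self, key: str) -> bool:
        if key == "weight":
            return self.mol_weight < 300
        if key == "xlogp":
            return self.xlogp <= 3
        if key == "hbd":
            return self.hbd <= 3
        if key == "hba":
            return self.hba <= 3
        if key == "rotb":
            return self.rotb_nt <= 3
        raise ValueError(f"unknown filter key {key!r}; valid: {RO3_FILTER_KEYS}")


def _is_donor(atom: Chem.Atom) -> bool:
    return atom.GetAtomicNum() in (7, 8) and atom.GetTotalNumHs() > 0


def _is_acceptor(atom: Chem.Atom) -> bool:
    if atom.GetAtomicNum() not in (7, 8):
        return False
    if atom.GetAtomicNum() == 7:
        if atom.GetIsAromatic() and atom.GetTotalNumHs() > 0:
            return False  # pyrrole-type N
        for nbr in atom.GetNeighbors():
            b = atom.GetOwningMol().GetBondBetweenAtoms(atom.GetIdx(), nbr.GetIdx())
            if b.GetBondType() != Chem.BondType.SINGLE:
                continue
            if nbr.GetAtomicNum() in (6, 16) and any(
                bb.GetBondType() == Chem.BondType.DOUBLE
                and bb.GetOtherAtom(nbr).GetAtomicNum() in (8, 16)
                for bb in nbr.GetBonds()
            ):
                return False  # amide / sulfonamide N
    return True


_AMIDE_BOND = Chem.MolFromSmarts("[C;$(C=O)]-[N]")


def _rotatable_nonterminal(mol: Chem.Mol) -> int:
    amide = {frozenset(m) for m in mol.GetSubstructMatches(_AMIDE_BOND)}

    def heavy_degree(atom: Chem.Atom) -> int:
        # dummies count like hydrogens: they do not confer non-terminality
        return sum(1 for n in atom.GetNeighbors() if n.GetAtomicNum() > 1)

    count = 0
    for bond in mol.GetBonds():
        a, b = bond.GetBeginAtom(), bond.GetEndAtom()
        if bond.IsInRing() or bond.GetBondType() != Chem.BondType.SINGLE:
            continue
        if a.GetAtomicNum() <= 1 or b.GetAtomicNum() <= 1:
            continue
        if frozenset((a.GetIdx(), b.GetIdx())) in amide:
            continue
        if heavy_degree(a) < 2 or heavy_degree(b) < 2:
            continue
        count += 1
    return count


def compute_ro3(frag: AssembledFragment | str) -> Ro3Properties:
    """Compute the rule-of-three property panel for a capped fragment.

    Accepts an AssembledFragment or a bare (possibly dummy-bearing)
    SMILES string.
    """
    smiles = frag if isinstance(frag, str) else frag.capped_smiles
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"fragment SMILES does not parse: {smiles!r}")
    return Ro3Properties(
        mol_weight=Descriptors.MolWt(mol),
        xlogp=Crippen.MolLogP(mol),
        hbd=sum(1 for a in mol.GetAtoms() if _is_donor(a)),
        hba=sum(1 for a in mol.GetAtoms() if _is_acceptor(a)),
        rotb_nt=_rotatable_nonterminal(mol),
    )


def apply_ro3_filters(
    frags: list[AssembledFragment],
    which: tuple[str, ...] | list[str] = RO3_FILTER_KEYS,
) -> tuple[list[AssembledFragment], dict[str, int]]:
    """Filter fragments by the selected rule-of-three criteria.

    Returns the fragments passing the conjunction of the selected
    filters, plus survivor counts for every individual filter and for
    the conjunction (key ``"combined"``).  Filter order never matters:
    each filter is evaluated per fragment independently.
    """
    for key in which:
        if key not in RO3_FILTER_KEYS:
            raise ValueError(f"unknown filter key {key!r}; valid: {RO3_FILTER_KEYS}")
    props = [compute_ro3(f) for f in frags]
    counts = {key: sum(1 for p in props if p.passes(key)) for key in RO3_FILTER_KEYS}
    survivors = [
        f for f, p in zip(frags, props) if all(p.passes(key) for key in which)
    ]
    counts["combined"] = sum(
        1 for p in props if all(p.passes(key) for key in RO3_FILTER_KEYS)
    )
    return survivors, counts
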