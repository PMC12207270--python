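"""Substrate parsing and symmetry-equivalence analysis.

Symmetry-equivalent reaction sites (and directing-group heteroatoms) are
detected by a canonical-SMILES marking test: a copy of the molecule is
marked at one atom -- with a labelled explicit hydrogen for C-H sites, or
with a dummy atom bonded to the heteroatom for directing groups -- and two
atoms are equivalent iff the marked copies canonicalize to the same string.
The test works on the constitutional graph; stereo descriptors are ignored.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable

from rdkit import Chem

__all__ = [
    "Substrate",
    "SymmetryClass",
    "InvalidSmilesError",
    "parse_substrate",
    "sp2_ch_sites",
    "donor_heteroatoms",
    "site_symmetry_classes",
    "dg_symmetry_classes",
]

# isotope label for the marked hydrogen; must survive canonicalization
_MARK_ISOTOPE = 3


class InvalidSmilesError(ValueError):
    """Raised when a SMILES string cannot be parsed."""


@dataclass(frozen=True)
class Substrate:
    """An immutable parsed substrate with stable canonical atom indexing.

    ``mol`` is the sanitized RDKit molecule (implicit hydrogens); atom
    indices used throughout the package refer to this object and are
    stable for its lifetime.
    """

    smiles: str
    mol: Chem.Mol = field(repr=False, compare=False)
    net_charge: int = 0

    @property
    def atoms(self) -> list[tuple[str, bool, str, int, int]]:
        """(element, aromatic, hybridization, formal charge, H count) per atom."""
        return [
            (
                a.GetSymbol(),
                a.GetIsAromatic(),
                str(a.GetHybridization()),
                a.GetFormalCharge(),
                a.GetTotalNumHs(),
            )
            for a in self.mol.GetAtoms()
        ]

    @property
    def bonds(self) -> list[tuple[int, int, float]]:
        return [
            (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), b.GetBondTypeAsDouble())
            for b in self.mol.GetBonds()
        ]

    @property
    def num_atoms(self) -> int:
        return self.mol.GetNumAtoms()


@dataclass(frozen=True)
class SymmetryClass:
    """One equivalence class of atoms under the canonical-SMILES marking test."""

    class_id: int
    member_atom_indices: frozenset[int]

    @property
    def representative(self) -> int:
        return min(self.member_atom_indices)


def parse_substrate(smiles: str) -> Substrate:
    """Parse a SMILES string into an immutable :class:`Substrate`.

    Atom order follows the input SMILES (RDKit parse order), which is kept
    as the canonical indexing for the object's lifetime.

    Raises
    ------
    InvalidSmilesError
        if the string is not valid SMILES.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidSmilesError(f"unparsable SMILES: {smiles!r}")
    net_charge = sum(a.GetFormalCharge() for a in mol.GetAtoms())
    return Substrate(smiles=Chem.MolToSmiles(mol), mol=mol, net_charge=net_charge)


def sp2_ch_sites(sub: Substrate) -> list[int]:
    """Indices of sp2-hybridized carbons carrying at least one hydrogen.

    Aromatic CH carbons qualify, as do non-aromatic carbons with exactly
    three neighbours (counting hydrogens) and one double bond, e.g. vinyl
    and formyl carbons.
    """
    out = []
    for a in sub.mol.GetAtoms():
        if a.GetAtomicNum() != 6 or a.GetTotalNumHs() < 1:
            continue
        if a.GetIsAromatic():
            out.append(a.GetIdx())
            continue
        n_double = sum(
            1 for b in a.GetBonds() if b.GetBondType() == Chem.BondType.DOUBLE
        )
        if a.GetTotalDegree() == 3 and n_double == 1:
            out.append(a.GetIdx())
    return out


def _lone_pairs(atom: Chem.Atom) -> int:
    pt = Chem.GetPeriodicTable()
    outer = pt.GetNOuterElecs(atom.GetAtomicNum())
    electrons = outer - atom.GetTotalValence() - atom.GetFormalCharge()
    return max(electrons, 0) // 2


def donor_heteroatoms(sub: Substrate, allow_phosphorus: bool = False) -> list[int]:
    """Heteroatoms able to coordinate Pd through an available lone pair.

    N, O and S with at least one sigma lone pair qualify.  Pyrrole-type
    aromatic nitrogens are excluded: their single lone pair is part of the
    pi system.  For aromatic O/S one lone pair is likewise committed to the
    ring, but a second in-plane pair remains available.  Phosphorus donors
    are off by default.
    """
    allowed = {7, 8, 16} | ({15} if allow_phosphorus else set())
    out = []
    for a in sub.mol.GetAtoms():
        z = a.GetAtomicNum()
        if z not in allowed:
            continue
        lp = _lone_pairs(a)
        if a.GetIsAromatic():
            if z == 7 and (a.GetTotalNumHs() > 0 or a.GetDegree() == 3):
                lp -= 1  # pyrrole-type: lone pair lives in the pi system
            elif z in (8, 16):
                lp -= 1  # one pair donated to the aromatic sextet
        if lp >= 1:
            out.append(a.GetIdx())
    return out


def _marked_site_smiles(sub: Substrate, site: int) -> str:
    """Canonical SMILES with one labelled explicit H attached at ``site``."""
    rw = Chem.RWMol(sub.mol)
    atom = rw.GetAtomWithIdx(site)
    if atom.GetTotalNumHs() < 1:
        raise ValueError(f"atom {site} carries no hydrogen")
    h = Chem.Atom(1)
    h.SetIsotope(_MARK_ISOTOPE)
    h_idx = rw.AddAtom(h)
    rw.AddBond(site, h_idx, Chem.BondType.SINGLE)
    atom.SetNumExplicitHs(max(atom.GetNumExplicitHs() - 1, 0))
    rw.UpdatePropertyCache(strict=False)
    return Chem.MolToSmiles(rw.GetMol())


def _marked_dg_smiles(sub: Substrate, heteroatom: int) -> str:
    """Canonical SMILES with a dummy atom bonded to ``heteroatom``."""
    rw = Chem.RWMol(sub.mol)
    d_idx = rw.AddAtom(Chem.Atom(0))
    rw.AddBond(heteroatom, d_idx, Chem.BondType.SINGLE)
    rw.UpdatePropertyCache(strict=False)
    return Chem.MolToSmiles(rw.GetMol())


def _classes_from_keys(keys: dict[int, str]) -> list[SymmetryClass]:
    groups: dict[str, set[int]] = defaultdict(set)
    for idx, key in keys.items():
        groups[key].add(idx)
    classes = []
    for cid, members in enumerate(
        sorted(groups.values(), key=lambda m: min(m))
    ):
        classes.append(SymmetryClass(class_id=cid, member_atom_indices=frozenset(members)))
    return classes


def site_symmetry_classes(
    sub: Substrate, candidate_sites: Iterable[int]
) -> list[SymmetryClass]:
    """Partition C-H sites into symmetry-equivalence classes.

    Two sites are equivalent iff marking each with an explicit labelled
    hydrogen yields the same canonical SMILES.  Classes are numbered by
    the smallest member index.

    Raises
    ------
    ValueError
        if a candidate site carries no hydrogen.
    """
    keys = {s: _marked_site_smiles(sub, s) for s in sorted(set(candidate_sites))}
    return _classes_from_keys(keys)


def dg_symmetry_classes(
    sub: Substrate, heteroatoms: Iterable[int]
) -> list[SymmetryClass]:
    """Partition directing-group heteroatoms into symmetry classes.

    Marking uses a dummy atom (atomic number 0) bonded to the heteroatom.
    """
    keys = {h: _marked_dg_smiles(sub, h) for h in sorted(set(heteroatoms))}
    return _classes_from_keys(keys)


def class_of(classes: Iterable[SymmetryClass], atom: int) -> SymmetryClass:
    """The class containing ``atom``; raises ``KeyError`` if absent."""
    for c in classes:
        if atom in c.member_atom_indices:
            return c
    raise KeyError(f"atom {atom} is in no symmetry class")
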