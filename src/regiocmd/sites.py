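"""Enumeration of ortho (C-H site, directing heteroatom) candidate pairs.

Candidates are all combinations of an sp2 C-H carbon and a lone-pair
heteroatom 2-5 bonds apart; closing the shortest path through a Pd
placeholder yields palladacycle ring sizes of 4-7 atoms.  A 2D planar
embedding screens out candidates whose ring cannot adopt angles near those
of the regular polygon, and duplicates are removed by site symmetry, DG
symmetry and DG resonance equivalence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdCoordGen

from regiocmd.substrate import (
    Substrate,
    donor_heteroatoms,
    dg_symmetry_classes,
    site_symmetry_classes,
    sp2_ch_sites,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Provenance",
    "CandidatePair",
    "find_ortho_pairs",
    "ideal_ring_angle",
    "passes_angle_filter",
    "dedup_pairs",
]

MIN_PATH_BONDS = 2
MAX_PATH_BONDS = 5

# two equivalent terminal oxygens bound to the same central atom
_NITRO = Chem.MolFromSmarts("[N;$([N](~[O;D1])~[O;D1])](~[O;D1])~[O;D1]")
_CARBOXYLATE = Chem.MolFromSmarts("[C;$(C(~[O;D1])~[O;D1])](~[O;D1])~[O;D1]")


class Provenance(str, Enum):
    ORTHO_SMARTS = "ortho_smarts"
    REMOTE_CARTESIAN = "remote_cartesian"


@dataclass(frozen=True, order=True)
class CandidatePair:
    """One (sp2 C-H site, directing heteroatom) combination.

    ``ring_size`` counts the atoms of the palladacycle that would close the
    shortest path between the two atoms through Pd: path atoms plus the
    metal.
    """

    site_atom: int
    dg_atom: int
    path_bonds: int
    ring_size: int
    provenance: Provenance = Provenance.ORTHO_SMARTS

    def __post_init__(self) -> None:
        if self.site_atom == self.dg_atom:
            raise ValueError("site and directing atom coincide")
        if self.ring_size != self.path_bonds + 2:
            raise ValueError("ring_size must equal path_bonds + 2")


def find_ortho_pairs(sub: Substrate) -> list[CandidatePair]:
    """All (sp2 C-H, donor heteroatom) pairs whose shortest path is 2-5 bonds.

    This is the raw candidate list prior to the geometric angle filter and
    symmetry deduplication.  The shortest path is measured on the bond
    graph regardless of bond order.
    """
    pairs = []
    donors = donor_heteroatoms(sub)
    for site in sp2_ch_sites(sub):
        for dg in donors:
            path = Chem.GetShortestPath(sub.mol, site, dg)
            if not path:
                continue  # disconnected fragments
            n_bonds = len(path) - 1
            if MIN_PATH_BONDS <= n_bonds <= MAX_PATH_BONDS:
                pairs.append(
                    CandidatePair(
                        site_atom=site,
                        dg_atom=dg,
                        path_bonds=n_bonds,
                        ring_size=n_bonds + 2,
                    )
                )
    return pairs


def ideal_ring_angle(n_atoms: int) -> float:
    """Internal angle of the regular ``n_atoms``-gon, in degrees."""
    if n_atoms < 3:
        raise ValueError(f"a ring needs at least 3 atoms, got {n_atoms}")
    return (n_atoms - 2) * 180.0 / n_atoms


def _ring_angles_2d(coords: np.ndarray, ring: list[int]) -> list[float]:
    n = len(ring)
    angles = []
    for k in range(n):
        a, b, c = ring[(k - 1) % n], ring[k], ring[(k + 1) % n]
        v1 = coords[a] - coords[b]
        v2 = coords[c] - coords[b]
        cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
        angles.append(float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))))
    return angles


def ring_within_tolerance(
    angles: list[float], ideal: float, tolerance: float = 0.10
) -> bool:
    """True iff every angle deviates relatively from ``ideal`` by at most
    ``tolerance`` (inclusive at the boundary)."""
    return all(abs(a - ideal) / ideal <= tolerance for a in angles)


def passes_angle_filter(
    sub: Substrate,
    pair: CandidatePair,
    tolerance: float = 0.10,
    include_pd_angle: bool = True,
) -> bool:
    """Screen a candidate pair by 2D ring-angle strain.

    A single-plane 2D depiction of the substrate plus a Pd placeholder
    closing the ring through ``site_atom`` and ``dg_atom`` is generated;
    the pair fails if any internal angle of that ring deviates relatively
    from the regular-polygon angle by more than ``tolerance`` (the
    threshold is inclusive).  By default the angle at the Pd placeholder
    itself participates.  A failed 2D embedding counts as a filter failure.
    """
    try:
        path = list(Chem.GetShortestPath(sub.mol, pair.site_atom, pair.dg_atom))
        rw = Chem.RWMol(sub.mol)
        pd_idx = rw.AddAtom(Chem.Atom(46))
        rw.AddBond(pair.site_atom, pd_idx, Chem.BondType.SINGLE)
        rw.AddBond(pair.dg_atom, pd_idx, Chem.BondType.SINGLE)
        rw.UpdatePropertyCache(strict=False)
        mol = rw.GetMol()
        Chem.FastFindRings(mol)
        # CoordGen keeps standard ring geometries and lets the closure ring
        # absorb the strain; the default layout does the opposite and would
        # hide exactly the strain this filter looks for
        rdCoordGen.AddCoords(mol)
        conf = mol.GetConformer()
        coords = np.array(
            [list(conf.GetAtomPosition(i))[:2] for i in range(mol.GetNumAtoms())]
        )
    except Exception as exc:  # noqa: BLE001 - any depiction failure rejects
        logger.warning(
            "2D embedding failed for pair (%d, %d): %s",
            pair.site_atom,
            pair.dg_atom,
            exc,
        )
        return False
    ring = path + [pd_idx]
    if not include_pd_angle:
        ring_angles = _ring_angles_2d(coords, ring)[: len(path)]
    else:
        ring_angles = _ring_angles_2d(coords, ring)
    return ring_within_tolerance(
        ring_angles, ideal_ring_angle(pair.ring_size), tolerance
    )


def _resonance_group(sub: Substrate, dg_atom: int) -> tuple[str, int] | None:
    """Identify ``dg_atom`` as a terminal oxygen of a nitro/carboxylate group.

    Returns a key naming the central atom so that the two equivalent
    oxygens collapse, or None if the atom is not part of such a group.
    """
    for tag, query in (("nitro", _NITRO), ("carboxylate", _CARBOXYLATE)):
        if query is None:
            continue
        for match in sub.mol.GetSubstructMatches(query):
            central, o_a, o_b = match[0], match[1], match[2]
            if dg_atom in (o_a, o_b):
                return (tag, central)
    return None


def dedup_pairs(sub: Substrate, pairs: list[CandidatePair]) -> list[CandidatePair]:
    """One representative per symmetry/resonance equivalence class of pairs.

    Pairs are equivalent when their sites fall in the same site-symmetry
    class and their directing atoms fall in the same DG-symmetry class, or
    when the directing atoms are the two oxygens of one nitro or
    carboxylate group.  The representative is the pair with the smallest
    (site_atom, dg_atom) tuple.
    """
    if not pairs:
        return []
    site_classes = site_symmetry_classes(sub, {p.site_atom for p in pairs})
    dg_classes = dg_symmetry_classes(sub, {p.dg_atom for p in pairs})
    site_of = {
        a: c.class_id for c in site_classes for a in c.member_atom_indices
    }
    dg_of = {a: c.class_id for c in dg_classes for a in c.member_atom_indices}

    best: dict[tuple, CandidatePair] = {}
    for p in sorted(pairs, key=lambda q: (q.site_atom, q.dg_atom)):
        res = _resonance_group(sub, p.dg_atom)
        dg_key = ("res",) + res if res is not None else ("cls", dg_of[p.dg_atom])
        # path_bonds stays in the key: a site can reach two symmetry-related
        # donors through rings of different size, which are distinct complexes
        key = (site_of[p.site_atom], dg_key, p.path_bonds, p.provenance)
        if key not in best:
            best[key] = p
    return sorted(best.values(), key=lambda q: (q.site_atom, q.dg_atom))
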