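"""Candidate screening beyond ortho-directing groups.

For meta/para/remote directing groups the 2-5 bond window no longer
applies, so candidates are built as the Cartesian product of all unique
sp2 C-H site classes and all unique donor-heteroatom classes.  Each
candidate is screened by ring strain: a dummy ring is closed with a CCl2
fragment standing in for the Pd(OAc)2 catalyst (MMFF94s carries no
transition-metal parameters), embedded in 3D, optimized, and kept only if
the sum of the force field's out-of-plane bending and torsion terms stays
below a threshold (default 10 kcal/mol).  Candidates whose dummy ring
cannot even be embedded are discarded outright.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from rdkit import Chem
from rdkit.Chem import (  # noqa: F401 - ChemicalForceFields registers MMFF props
    ChemicalForceFields,
    rdDistGeom,
    rdForceFieldHelpers,
)

from regiocmd.sites import CandidatePair, Provenance
from regiocmd.substrate import (
    Substrate,
    dg_symmetry_classes,
    donor_heteroatoms,
    site_symmetry_classes,
    sp2_ch_sites,
)

logger = logging.getLogger(__name__)

__all__ = ["StrainResult", "enumerate_all_pairs", "strain_screen"]

DEFAULT_STRAIN_THRESHOLD_KCAL = 10.0
DEFAULT_EMBED_SEED = 0xC0FFEE  # 12648430, well below 2**31
MAX_EMBED_ATTEMPTS = 10


@dataclass(frozen=True)
class StrainResult:
    """Outcome of the force-field strain screen for one candidate pair."""

    pair: CandidatePair
    embed_ok: bool
    strain_kcal: float | None
    kept: bool
    reason: str = ""


def enumerate_all_pairs(sub: Substrate) -> list[CandidatePair]:
    """Cartesian product of unique C-H site classes and unique donor classes.

    No path-length restriction applies; each class is represented by its
    smallest atom index.  Pairs carry ``remote_cartesian`` provenance.
    """
    sites = sp2_ch_sites(sub)
    donors = donor_heteroatoms(sub)
    if not sites or not donors:
        return []
    site_reps = sorted(c.representative for c in site_symmetry_classes(sub, sites))
    dg_reps = sorted(c.representative for c in dg_symmetry_classes(sub, donors))
    pairs = []
    for s in site_reps:
        for d in dg_reps:
            path = Chem.GetShortestPath(sub.mol, s, d)
            if not path:
                continue
            n_bonds = len(path) - 1
            if n_bonds < 1:
                continue
            pairs.append(
                CandidatePair(
                    site_atom=s,
                    dg_atom=d,
                    path_bonds=n_bonds,
                    ring_size=n_bonds + 2,
                    provenance=Provenance.REMOTE_CARTESIAN,
                )
            )
    return pairs


def _build_dummy_ring(sub: Substrate, pair: CandidatePair) -> Chem.Mol:
    """Substrate with the site H replaced by a CCl2 bridge to the DG atom.

    The bridging carbon is tetravalent (two chlorines plus the two ring
    bonds); the extra bond on the directing heteroatom is legalized by
    incrementing its formal charge, which MMFF typing requires.
    """
    mol_h = Chem.AddHs(sub.mol)
    rw = Chem.RWMol(mol_h)
    site = rw.GetAtomWithIdx(pair.site_atom)
    hs = [n.GetIdx() for n in site.GetNeighbors() if n.GetAtomicNum() == 1]
    if not hs:
        raise ValueError(f"site atom {pair.site_atom} has no hydrogen")
    rw.RemoveAtom(hs[0])
    c = rw.AddAtom(Chem.Atom(6))
    for _ in range(2):
        cl = rw.AddAtom(Chem.Atom(17))
        rw.AddBond(c, cl, Chem.BondType.SINGLE)
    rw.AddBond(pair.site_atom, c, Chem.BondType.SINGLE)
    rw.AddBond(pair.dg_atom, c, Chem.BondType.SINGLE)
    dg = rw.GetAtomWithIdx(pair.dg_atom)
    dg.SetFormalCharge(dg.GetFormalCharge() + 1)
    dg.SetNumExplicitHs(dg.GetNumExplicitHs())
    mol = rw.GetMol()
    Chem.SanitizeMol(mol)
    return mol


def strain_screen(
    sub: Substrate,
    pair: CandidatePair,
    threshold_kcal: float = DEFAULT_STRAIN_THRESHOLD_KCAL,
    seed: int = DEFAULT_EMBED_SEED,
    max_attempts: int = MAX_EMBED_ATTEMPTS,
) -> StrainResult:
    """Screen one candidate by MMFF94s out-of-plane + torsion strain.

    The dummy-ring structure is embedded with ETKDG (up to ``max_attempts``
    seeds derived from ``seed``), optimized with MMFF94s, and the
    out-of-plane bending and torsion contributions of the optimized
    geometry are summed.  The pair is kept iff embedding succeeded and the
    sum is at or below ``threshold_kcal``.
    """
    try:
        mol = _build_dummy_ring(sub, pair)
    except Exception as exc:  # noqa: BLE001
        logger.warning("dummy-ring construction failed for %s: %s", pair, exc)
        return StrainResult(pair, False, None, False, f"construction failed: {exc}")

    cid = -1
    for attempt in range(max_attempts):
        params = rdDistGeom.ETKDGv3()
        params.randomSeed = (seed + attempt) % (2**31)
        cid = rdDistGeom.EmbedMolecule(mol, params)
        if cid >= 0:
            break
    if cid < 0:
        return StrainResult(pair, False, None, False, "3D embedding failed")

    props = rdForceFieldHelpers.MMFFGetMoleculeProperties(mol, mmffVariant="MMFF94s")
    if props is None:
        return StrainResult(pair, True, None, False, "MMFF94s cannot type molecule")
    ff = rdForceFieldHelpers.MMFFGetMoleculeForceField(mol, props, confId=cid)
    if ff is None:
        return StrainResult(pair, True, None, False, "MMFF94s setup failed")
    ff.Minimize(maxIts=10000, energyTol=1e-8)

    strain_props = rdForceFieldHelpers.MMFFGetMoleculeProperties(
        mol, mmffVariant="MMFF94s"
    )
    for off in (
        "SetMMFFBondTerm",
        "SetMMFFAngleTerm",
        "SetMMFFStretchBendTerm",
        "SetMMFFVdWTerm",
        "SetMMFFEleTerm",
    ):
        getattr(strain_props, off)(False)
    strain_ff = rdForceFieldHelpers.MMFFGetMoleculeForceField(
        mol, strain_props, confId=cid
    )
    strain = float(strain_ff.CalcEnergy())
    return StrainResult(
        pair,
        embed_ok=True,
        strain_kcal=strain,
        kept=strain <= threshold_kcal,
        reason="" if strain <= threshold_kcal else "strain above threshold",
    )
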