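"""Construction and conformer sampling of substrate-Pd(OAc) palladacycles.

The intermediate is the substrate, deprotonated at the reaction site, with
Pd bonded to the site carbon and the directing heteroatom, and a bidentate
(kappa-2) acetate completing the square-planar coordination sphere.
Conformers are generated with distance geometry; because the standard
knowledge-based torsion/planarity potentials have no notion of a metal
ring, the embedding runs plain distance geometry with explicit Pd-ligand
distance bounds derived from covalent radii (+/-15%).  Ensembles are
reduced by heavy-atom RMSD clustering, keeping the medoid of each cluster.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from rdkit import Chem, rdBase
from rdkit.Chem import rdDistGeom, rdMolDescriptors

from regiocmd.sites import CandidatePair
from regiocmd.substrate import Substrate

logger = logging.getLogger(__name__)

__all__ = [
    "PalladacycleComplex",
    "ConformerEnsemble",
    "build_complex",
    "generate_conformers",
    "cluster_conformers",
    "count_rotatable_bonds",
    "write_xyz",
    "write_sdf",
]

PD_BOUNDS_SLACK = 0.15
DEFAULT_RMSD_CUTOFF = 1.0  # Angstrom
ACETATE_ATOM_COUNT = 7  # CH3-C(=O)O


@dataclass(frozen=True)
class PalladacycleComplex:
    """Molecular graph of one palladacycle intermediate.

    ``mol`` holds explicit hydrogens and kekulized bonds (the metal centre
    defeats aromaticity perception, so aromatic flags are cleared before
    assembly).  Index attributes point into ``mol``: the metal, the
    deprotonated site carbon, the coordinating heteroatom, and the two
    acetate oxygens.  The complex is a neutral-singlet bookkeeping object:
    Pd(II), acetate(-1) and the aryl(-1) carbanion sum to the substrate's
    net charge.
    """

    pair: CandidatePair
    mol: Chem.Mol = field(repr=False, compare=False)
    pd: int
    site_c: int
    dg_x: int
    o1: int
    o2: int
    net_charge: int
    spin_multiplicity: int = 1
    n_substrate_heavy: int = 0

    @property
    def pd_partners(self) -> tuple[int, int, int, int]:
        return (self.site_c, self.dg_x, self.o1, self.o2)

    def heavy_atom_indices(self) -> list[int]:
        return [
            a.GetIdx() for a in self.mol.GetAtoms() if a.GetAtomicNum() > 1
        ]

    def bond_set(self, exclude_metal: bool = False) -> frozenset[frozenset[int]]:
        out = set()
        for b in self.mol.GetBonds():
            i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
            if exclude_metal and self.pd in (i, j):
                continue
            out.add(frozenset((i, j)))
        return frozenset(out)


@dataclass
class ConformerEnsemble:
    """3D conformers of one palladacycle complex.

    ``conformers`` maps conformer ids of ``complex.mol`` in generation
    order; ``cluster_representatives`` is filled by
    :func:`cluster_conformers`.
    """

    complex: PalladacycleComplex
    conformer_ids: list[int]
    n_requested: int
    cluster_representatives: list[int] = field(default_factory=list)

    @property
    def empty(self) -> bool:
        return not self.conformer_ids

    def coordinates(self, conf_id: int) -> np.ndarray:
        conf = self.complex.mol.GetConformer(conf_id)
        return np.array(conf.GetPositions())


def count_rotatable_bonds(sub: Substrate) -> int:
    """Rotatable single bonds of the substrate (standard strict definition,
    excluding ring and terminal bonds)."""
    return int(rdMolDescriptors.CalcNumRotatableBonds(sub.mol))


def build_complex(sub: Substrate, pair: CandidatePair) -> PalladacycleComplex:
    """Assemble the substrate-Pd(OAc) palladacycle graph for one pair.

    One hydrogen is removed from the site carbon; Pd is bonded to the site
    carbon, the directing heteroatom and both acetate oxygens.
    """
    mol_h = Chem.AddHs(sub.mol)
    Chem.Kekulize(mol_h, clearAromaticFlags=True)
    rw = Chem.RWMol(mol_h)
    site = rw.GetAtomWithIdx(pair.site_atom)
    hs = [n.GetIdx() for n in site.GetNeighbors() if n.GetAtomicNum() == 1]
    if not hs:
        raise RuntimeError(
            f"site atom {pair.site_atom} has no hydrogen; "
            "pair should have been excluded upstream"
        )
    rw.RemoveAtom(hs[0])
    pd = rw.AddAtom(Chem.Atom(46))
    c_methyl = rw.AddAtom(Chem.Atom(6))
    c_carboxyl = rw.AddAtom(Chem.Atom(6))
    o1 = rw.AddAtom(Chem.Atom(8))
    o2 = rw.AddAtom(Chem.Atom(8))
    for _ in range(3):
        h = rw.AddAtom(Chem.Atom(1))
        rw.AddBond(c_methyl, h, Chem.BondType.SINGLE)
    rw.AddBond(c_methyl, c_carboxyl, Chem.BondType.SINGLE)
    rw.AddBond(c_carboxyl, o1, Chem.BondType.SINGLE)
    rw.AddBond(c_carboxyl, o2, Chem.BondType.DOUBLE)
    rw.AddBond(pd, pair.site_atom, Chem.BondType.SINGLE)
    rw.AddBond(pd, pair.dg_atom, Chem.BondType.SINGLE)
    rw.AddBond(pd, o1, Chem.BondType.SINGLE)
    rw.AddBond(pd, o2, Chem.BondType.SINGLE)
    mol = rw.GetMol()
    mol.UpdatePropertyCache(strict=False)
    Chem.FastFindRings(mol)
    return PalladacycleComplex(
        pair=pair,
        mol=mol,
        pd=pd,
        site_c=pair.site_atom,
        dg_x=pair.dg_atom,
        o1=o1,
        o2=o2,
        net_charge=sub.net_charge,
        n_substrate_heavy=sub.num_atoms,
    )


def _metal_bounds_matrix(mol: Chem.Mol, pd: int) -> np.ndarray:
    pt = Chem.GetPeriodicTable()
    bm = rdDistGeom.GetMoleculeBoundsMatrix(mol)
    for b in mol.GetAtomWithIdx(pd).GetBonds():
        j = b.GetOtherAtomIdx(pd)
        d = pt.GetRcovalent(46) + pt.GetRcovalent(
            mol.GetAtomWithIdx(j).GetAtomicNum()
        )
        lo, hi = min(pd, j), max(pd, j)
        bm[lo][hi] = d * (1 + PD_BOUNDS_SLACK)  # upper bound
        bm[hi][lo] = d * (1 - PD_BOUNDS_SLACK)  # lower bound
    return bm


def generate_conformers(
    cx: PalladacycleComplex, seed: int, n_rotatable: int | None = None
) -> ConformerEnsemble:
    """Generate 3*N_rot + 3 distance-geometry conformers of the complex.

    ``N_rot`` counts rotatable bonds of the substrate only, not the
    Pd-ligand framework; pass it explicitly or it is recomputed from the
    substrate part of the complex.  Embedding failures are dropped without
    retry (the quota is attempted, not guaranteed); an ensemble with no
    conformers is flagged empty and excluded from ranking by the caller.
    """
    if n_rotatable is None:
        sub_only = Chem.Mol(cx.mol)
        n_rotatable = int(
            rdMolDescriptors.CalcNumRotatableBonds(
                _substrate_fragment(sub_only, cx)
            )
        )
    n_req = 3 * n_rotatable + 3
    mol = cx.mol
    mol.RemoveAllConformers()
    with rdBase.BlockLogs():  # UFF typer grumbles about Pd during bounds setup
        bm = _metal_bounds_matrix(mol, cx.pd)
    params = rdDistGeom.ETKDGv3()
    params.randomSeed = seed % (2**31)
    params.useRandomCoords = True
    # the knowledge-based torsion/planarity potentials reject the metal
    # ring wholesale, so the embedding runs on plain distance geometry
    params.useExpTorsionAnglePrefs = False
    params.useBasicKnowledge = False
    params.SetBoundsMat(bm)
    with rdBase.BlockLogs():
        cids = list(rdDistGeom.EmbedMultipleConfs(mol, n_req, params))
    if len(cids) < n_req:
        logger.warning(
            "complex (%d,%d): %d of %d embeddings failed",
            cx.site_c,
            cx.dg_x,
            n_req - len(cids),
            n_req,
        )
    return ConformerEnsemble(complex=cx, conformer_ids=cids, n_requested=n_req)


def _substrate_fragment(mol: Chem.Mol, cx: PalladacycleComplex) -> Chem.Mol:
    """The substrate part of the complex (metal and acetate removed)."""
    rw = Chem.RWMol(mol)
    drop = {cx.pd}
    # acetate atoms are everything bonded into the Pd/acetate block
    stack = [n.GetIdx() for n in mol.GetAtomWithIdx(cx.pd).GetNeighbors()
             if n.GetIdx() in (cx.o1, cx.o2)]
    while stack:
        i = stack.pop()
        if i in drop:
            continue
        drop.add(i)
        for n in mol.GetAtomWithIdx(i).GetNeighbors():
            if n.GetIdx() not in drop and n.GetIdx() != cx.pd:
                stack.append(n.GetIdx())
    for i in sorted(drop, reverse=True):
        rw.RemoveAtom(i)
    frag = rw.GetMol()
    frag.UpdatePropertyCache(strict=False)
    Chem.FastFindRings(frag)
    return frag


def _kabsch_rmsd(p: np.ndarray, q: np.ndarray) -> float:
    """Least-squares superposition RMSD between two identically-ordered
    coordinate sets (no symmetry correction)."""
    pc = p - p.mean(axis=0)
    qc = q - q.mean(axis=0)
    h = pc.T @ qc
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    rot = u @ np.diag([1.0, 1.0, d]) @ vt
    diff = pc @ rot - qc
    return float(np.sqrt((diff**2).sum() / len(p)))


def rmsd_matrix(ens: ConformerEnsemble) -> np.ndarray:
    """Pairwise heavy-atom RMSD matrix over the ensemble's conformers."""
    heavy = ens.complex.heavy_atom_indices()
    coords = [ens.coordinates(cid)[heavy] for cid in ens.conformer_ids]
    n = len(coords)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = _kabsch_rmsd(coords[i], coords[j])
    return mat


def cluster_by_distance(dist: np.ndarray, cutoff: float) -> list[list[int]]:
    """Leader-style (Butina) clustering on a distance matrix.

    Repeatedly picks the unassigned item with the most unassigned
    neighbours within ``cutoff`` (ties to the lowest index) as a cluster
    seed and assigns it together with those neighbours.
    """
    n = len(dist)
    unassigned = set(range(n))
    clusters = []
    while unassigned:
        best_seed, best_nbrs = None, None
        for i in sorted(unassigned):
            nbrs = [j for j in unassigned if j != i and dist[i, j] <= cutoff]
            if best_nbrs is None or len(nbrs) > len(best_nbrs):
                best_seed, best_nbrs = i, nbrs
        cluster = sorted([best_seed] + best_nbrs)
        clusters.append(cluster)
        unassigned -= set(cluster)
    return clusters


def medoid(dist: np.ndarray, members: list[int]) -> int:
    """The member minimizing total distance to the others (ties to the
    lowest index)."""
    sums = [(sum(dist[m, o] for o in members), m) for m in members]
    return min(sums)[1]


def cluster_conformers(
    ens: ConformerEnsemble, cutoff_angstrom: float = DEFAULT_RMSD_CUTOFF
) -> ConformerEnsemble:
    """Cluster conformers by heavy-atom RMSD and retain cluster medoids.

    Cluster members lie within ``cutoff_angstrom`` of their cluster seed;
    the retained "centroid" is realized as the medoid (the member
    minimizing total RMSD to its cluster), which by the triangle
    inequality is within twice the cutoff of every member.
    """
    if ens.empty:
        return ens
    dist = rmsd_matrix(ens)
    clusters = cluster_by_distance(dist, cutoff_angstrom)
    reps = sorted(
        ens.conformer_ids[medoid(dist, members)] for members in clusters
    )
    return replace(ens, cluster_representatives=reps)


def write_xyz(cx: PalladacycleComplex, conf_id: int, path: str) -> None:
    """Write one conformer as an XYZ file (element symbols, Cartesian A)."""
    block = Chem.MolToXYZBlock(cx.mol, confId=conf_id)
    with open(path, "w") as fh:
        fh.write(block)


def write_sdf(ens: ConformerEnsemble, path: str) -> None:
    """Write all conformers to an SDF with charge and pair metadata."""
    mol = Chem.Mol(ens.complex.mol)
    mol.SetIntProp("net_charge", ens.complex.net_charge)
    mol.SetIntProp("site_atom", ens.complex.pair.site_atom)
    mol.SetIntProp("dg_atom", ens.complex.pair.dg_atom)
    writer = Chem.SDWriter(path)
    writer.SetKekulize(False)
    for cid in ens.conformer_ids:
        writer.write(mol, confId=cid)
    writer.close()
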