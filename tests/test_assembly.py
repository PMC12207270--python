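"""Palladacycle assembly, conformer generation, and RMSD clustering."""

import numpy as np
import pytest
from rdkit import Chem

from regiocmd import (
    build_complex,
    cluster_conformers,
    find_ortho_pairs,
    generate_conformers,
    parse_substrate,
)
from regiocmd.assembly import (
    ACETATE_ATOM_COUNT,
    ConformerEnsemble,
    cluster_by_distance,
    count_rotatable_bonds,
    medoid,
    rmsd_matrix,
)


@pytest.fixture()
def phpy_complex(phenylpyridine):
    pair = next(
        p
        for p in find_ortho_pairs(phenylpyridine)
        if p.site_atom == 2 and p.dg_atom == 9
    )
    return build_complex(phenylpyridine, pair)


class TestBuildComplex:
    def test_atom_bookkeeping(self, phenylpyridine, phpy_complex):
        n_sub = Chem.AddHs(phenylpyridine.mol).GetNumAtoms()
        # substrate - 1 H + Pd + acetate (CH3COO = 7 atoms)
        assert phpy_complex.mol.GetNumAtoms() == n_sub - 1 + 1 + ACETATE_ATOM_COUNT

    def test_pd_coordination_sphere(self, phpy_complex):
        cx = phpy_complex
        nbrs = {
            n.GetIdx() for n in cx.mol.GetAtomWithIdx(cx.pd).GetNeighbors()
        }
        assert nbrs == set(cx.pd_partners)
        assert len(nbrs) == 4

    def test_metallacycle_ring_present(self, phpy_complex):
        cx = phpy_complex
        rings = [set(r) for r in Chem.GetSymmSSSR(cx.mol)]
        expected = {cx.pd, 2, 3, 4, 9}  # Pd + C,C,C,N of the 5-ring
        assert expected in rings

    def test_neutral_substrate_neutral_complex_singlet(self, phpy_complex):
        assert phpy_complex.net_charge == 0
        assert phpy_complex.spin_multiplicity == 1

    def test_site_lost_one_hydrogen(self, phenylpyridine, phpy_complex):
        before = phenylpyridine.mol.GetAtomWithIdx(2).GetTotalNumHs()
        site = phpy_complex.mol.GetAtomWithIdx(2)
        after = sum(1 for n in site.GetNeighbors() if n.GetAtomicNum() == 1)
        assert after == before - 1


class TestGenerateConformers:
    def test_request_formula(self, phenylpyridine, phpy_complex):
        assert count_rotatable_bonds(phenylpyridine) == 1  # the biaryl bond
        ens = generate_conformers(phpy_complex, seed=5, n_rotatable=0)
        assert ens.n_requested == 3
        ens2 = generate_conformers(phpy_complex, seed=5, n_rotatable=2)
        assert ens2.n_requested == 9

    def test_fixed_seed_bit_identical(self, phenylpyridine):
        pair = next(
            p
            for p in find_ortho_pairs(phenylpyridine)
            if p.site_atom == 2 and p.dg_atom == 9
        )
        c1 = build_complex(phenylpyridine, pair)
        c2 = build_complex(phenylpyridine, pair)
        e1 = generate_conformers(c1, seed=42, n_rotatable=1)
        e2 = generate_conformers(c2, seed=42, n_rotatable=1)
        assert e1.conformer_ids == e2.conformer_ids
        for cid in e1.conformer_ids:
            np.testing.assert_array_equal(
                e1.coordinates(cid), e2.coordinates(cid)
            )


def _point_ensemble(cx, coord_sets):
    """Wrap explicit coordinate sets as conformers of a complex."""
    mol = cx.mol
    mol.RemoveAllConformers()
    ids = []
    for coords in coord_sets:
        conf = Chem.Conformer(mol.GetNumAtoms())
        for i, xyz in enumerate(coords):
            conf.SetAtomPosition(i, [float(x) for x in xyz])
        ids.append(mol.AddConformer(conf, assignId=True))
    return ConformerEnsemble(complex=cx, conformer_ids=ids, n_requested=len(ids))


def _oracle_butina_medoids(dist, cutoff):
    """Independent O(n^2) reference: leader clustering by neighbour count,
    then the member minimizing total in-cluster distance."""
    n = len(dist)
    todo = set(range(n))
    reps = []
    while todo:
        counts = {
            i: sum(1 for j in todo if j != i and dist[i][j] <= cutoff)
            for i in todo
        }
        seed = min(
            todo, key=lambda i: (-counts[i], i)
        )
        members = [seed] + [
            j for j in sorted(todo) if j != seed and dist[seed][j] <= cutoff
        ]
        best, best_sum = None, None
        for m in members:
            s = sum(dist[m][o] for o in members)
            if best_sum is None or s < best_sum - 1e-12:
                best, best_sum = m, s
        reps.append(best)
        todo -= set(members)
    return sorted(reps)


class TestClustering:
    def test_identical_conformers_one_representative(self, phpy_complex):
        base = generate_conformers(phpy_complex, seed=1, n_rotatable=0)
        coords = base.coordinates(base.conformer_ids[0])
        ens = _point_ensemble(phpy_complex, [coords, coords, coords])
        clustered = cluster_conformers(ens)
        assert len(clustered.cluster_representatives) == 1

    def test_distant_conformers_stay_separate(self, phpy_complex):
        base = generate_conformers(phpy_complex, seed=1, n_rotatable=0)
        coords = base.coordinates(base.conformer_ids[0])
        rot = coords @ np.array(
            [[0.0, 1.0, 0.0], [-1.0, 0.0, 0.0], [0.0, 0.0, 1.0]]
        ) * 1.5  # scaled: RMSD to the original well above 1 A
        ens = _point_ensemble(phpy_complex, [coords, rot])
        clustered = cluster_conformers(ens, cutoff_angstrom=1.0)
        assert len(clustered.cluster_representatives) == 2

    def test_infinite_cutoff_single_representative(self, phpy_complex):
        ens = generate_conformers(phpy_complex, seed=3, n_rotatable=2)
        clustered = cluster_conformers(ens, cutoff_angstrom=1e9)
        assert len(clustered.cluster_representatives) == 1

    def test_every_conformer_near_a_representative(self, phpy_complex):
        """Each member sits within the cutoff of its cluster seed, hence
        within 2x cutoff of the retained medoid (triangle inequality)."""
        ens = generate_conformers(phpy_complex, seed=3, n_rotatable=3)
        cutoff = 1.0
        clustered = cluster_conformers(ens, cutoff_angstrom=cutoff)
        dist = rmsd_matrix(ens)
        pos = {cid: k for k, cid in enumerate(ens.conformer_ids)}
        reps = [pos[c] for c in clustered.cluster_representatives]
        for k in range(len(ens.conformer_ids)):
            assert min(dist[k, r] for r in reps) <= 2 * cutoff + 1e-9

    @pytest.mark.parametrize("n,cutoff", [(8, 0.4), (15, 0.8), (30, 1.2)])
    def test_matches_brute_force_medoid_oracle(self, rng, n, cutoff):
        pts = rng.normal(size=(n, 3))
        dist = np.abs(pts[:, None, :] - pts[None, :, :]).sum(axis=-1)
        dist = (dist + dist.T) / 2
        np.fill_diagonal(dist, 0.0)
        clusters = cluster_by_distance(dist, cutoff)
        reps = sorted(medoid(dist, c) for c in clusters)
        assert reps == _oracle_butina_medoids(dist.tolist(), cutoff)

    def test_never_increases_count(self, phpy_complex):
        ens = generate_conformers(phpy_complex, seed=9, n_rotatable=2)
        clustered = cluster_conformers(ens, cutoff_angstrom=0.5)
        assert len(clustered.cluster_representatives) <= len(ens.conformer_ids)
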