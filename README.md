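# regiocmd

Regioselectivity prediction for directing-group-assisted, Pd-mediated C–H
activation.

Site-selective functionalization of aromatic C–H bonds with Pd(OAc)₂-type
catalysts proceeds through concerted metalation–deprotonation (CMD): the
metal, anchored by a coordinating directing group (DG), forms a σ-bond to
one ring carbon while an acetate ligand abstracts the proton, giving a
cyclic palladacycle intermediate.  By the Bell–Evans–Polanyi principle the
relative stability of that intermediate tracks the activation barrier, so
ranking the palladacycles for all candidate (C–H site, DG) combinations
predicts which position reacts.  `regiocmd` is aimed at synthetic and
computational chemists who want that ranking from nothing but a SMILES
string.

Two predictors are provided:

* **Palladacycle energy ranking** — enumerate candidate (sp² C–H,
  lone-pair heteroatom) pairs, prune geometrically impossible rings,
  deduplicate by molecular symmetry, build the 3D substrate–Pd(OAc)
  intermediates, sample conformers, optimize with a pluggable energy
  engine, and report every site whose best complex lies within an energy
  threshold (default 1 kcal·mol⁻¹) of the global minimum.  External
  GFN1-xTB (optimization, ALPB solvation) and ORCA (r²SCAN-3c single-point
  refinement) binaries are discovered at runtime; a deterministic mock
  engine and a UFF force-field engine run everywhere.
* **SMARTS lookup table** — a sub-second predictor that matches a table of
  DG patterns (each annotated with a directing strength in kcal·mol⁻¹,
  more negative = stronger) onto the substrate and resolves overlapping
  matches per site by three sequential keys: most heavy atoms matched,
  largest atomic-number sum over the matched heavy atoms, lowest DG
  strength.

## Worked example: the lookup-table predictor

```bash
regiocmd patterns --smiles "CCCN(C)C(=O)c1ccc(C(=O)c2ccccc2)cc1"
```

The substrate carries a tertiary amide and an aryl ketone.  Six ring CH
sites match patterns from the bundled table; the output annotates each
(sites are numbered 1–6 in ascending atom-index order, atom indices are
0-based parse order):

```json
{
  "predicted_site_atoms": [8, 20],
  "sites": [
    {
      "atom_id": 1,
      "site_atom": 8,
      "assigned_strength_kcal": -2.7,
      "matches": [
        {"rank": 1, "smarts": "[cH1]cC(N(C)A)=O",         "n_heavy": 7, "z_sum": 45, "dg_strength_kcal": -2.7},
        {"rank": 2, "smarts": "[cH1]cC(N([C,c])[C,c])=O", "n_heavy": 7, "z_sum": 45, "dg_strength_kcal": -2.5},
        {"rank": 3, "smarts": "[cH1]cCN(C)C",             "n_heavy": 6, "z_sum": 37, "dg_strength_kcal": -14.3}
      ]
    }
  ]
}
```

Reading the ranking at site 1: two patterns tie on 7 heavy atoms and
Σ Z = 45, so the third key prefers the stronger (−2.7 vs −2.5) amide
pattern; the dimethylamino pattern, despite its far stronger −14.3,
ranks third because it matches fewer atoms and is therefore less
specific.  The amide-ortho sites (atoms 8 and 20, a symmetric pair) win
over the four ketone-ortho sites (assigned −1.7), so they are the
predicted reaction sites.

## The energy pipeline

```bash
regiocmd predict --smiles "c1ccc(-c2ccccn2)cc1" --engine mock --seed 11
```

```json
{
  "predicted_site_atoms": [6, 2],
  "relative_energies_kcal": {"6": 0.0, "2": 0.94}
}
```

For 2-phenylpyridine two symmetry-unique candidate palladacycles survive
enumeration (the phenyl ortho site, atom 2, and a pyridine-ring site,
atom 6); both fall within the 1 kcal·mol⁻¹ window here because the mock
engine scores geometry by a deterministic toy function — it exists to
exercise and test the pipeline, not to be chemically meaningful.  Swap in
`--engine xtb` (with `xtb` on PATH) for GFN1-xTB energies, add
`--refine dft` for r²SCAN-3c single points through ORCA, and
`--mode remote` to screen meta/para/remote DGs via the MMFF94s dummy-ring
strain filter.  Supplying `--observed <atom>` labels the prediction
`correct` / `semi_correct` / `incorrect`.

A random-guessing baseline for benchmark comparisons:

```bash
regiocmd nullmodel --counts 2,2,2,3,4 --method exact
# {"expected_correct": 2.083, "ci95": [0.0, 4.0], "method": "exact"}
```

## Layout

- `src/regiocmd/substrate.py` — parsing, symmetry classes via canonical-SMILES marking
- `src/regiocmd/sites.py` — ortho pair enumeration, 2D ring-angle filter, dedup
- `src/regiocmd/remote.py` — Cartesian-product enumeration + MMFF94s strain screen
- `src/regiocmd/assembly.py` — palladacycle construction, conformers, RMSD clustering
- `src/regiocmd/engines.py` — mock/UFF/xtb/ORCA engines, geometry validation
- `src/regiocmd/ranking.py` — threshold ranking, refinement, evaluation, null model
- `src/regiocmd/patterns.py` — lookup-table predictor
- `src/regiocmd/pipeline.py`, `cli.py` — orchestration, fixtures, CLI

See `docs/methods.md` for the model, parameter choices and limitations.
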