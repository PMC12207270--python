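# Methods

## Model

The package predicts the regioselectivity of directing-group-assisted,
Pd(OAc)₂-mediated C–H activation under the concerted
metalation–deprotonation (CMD) mechanism.  The rate-determining CMD step
leads to a palladacycle intermediate in which Pd is σ-bonded to the
activated ring carbon, coordinated by the directing group's heteroatom,
and chelated by a κ² acetate.  Instead of locating CMD transition states,
the workflow ranks these intermediates: by the Bell–Evans–Polanyi (BEP)
principle, the lower the intermediate energy the lower the preceding
barrier, so the site with the most stable palladacycle is predicted to
react.  This is an approximation — BEP correlations are imperfect
(literature R² values of ~0.7 are common for related reaction families) —
which is why every site within a configurable energy window of the
minimum is reported rather than a single winner.

## Candidate enumeration

**Ortho mode.** Candidates are all pairs of (a) an sp² carbon bearing at
least one hydrogen (aromatic CH, or a non-aromatic carbon with three
neighbours and one double bond) and (b) an N/O/S atom with an available
σ lone pair, whose shortest bond path is 2–5 bonds.  Closing that path
through Pd gives 4–7-membered metallacycles.  The lone-pair rule excludes
pyrrole-type nitrogens (lone pair in the π system) and quaternary/charged
donors; aromatic O/S keep one in-plane pair and qualify.  Phosphorus
donors are off by default (`allow_phosphorus=True` admits them): the DG
inventory this tool targets is N/O/S.  Candidates are detected
graph-algorithmically rather than by an enumerated SMARTS library — the
graph walk is a superset of any fixed pattern set, and the geometric
filter below prunes the impossible ones.

**Geometry filter.** Each candidate ring is screened in 2D: the substrate
plus a Pd placeholder closing the ring is laid out in a plane (CoordGen),
and every internal angle of the closure ring — including the angle at
Pd — is compared with the ideal regular-polygon angle
(N − 2)·180°/N.  A relative deviation above 10% (inclusive boundary:
exactly 10% passes) rejects the pair, as does a failed 2D layout.
CoordGen is used deliberately: it preserves standard substrate ring
geometry and pushes strain into the closure ring, whereas the default
depiction idealizes the closure ring and would hide the strain being
screened for.  The filter is a cheap pre-screen; layouts of some fused
ring closures still pass, and such candidates are simply carried to the
energy stage, which ranks them out.  Whether the angle at Pd itself
participates is configurable (`include_pd_angle`, default on): the
polygon criterion is only fully determined when the whole ring is
measured.

**Symmetry deduplication.** Two sites are equivalent iff attaching a
labelled explicit hydrogen (isotope tag, so canonicalization sees it) at
each yields the same canonical SMILES; DG atoms are compared with a
dummy-atom bond in the same way.  Stereo descriptors are ignored — the
comparison is on the constitutional graph.  The two oxygens of nitro and
carboxylate groups are additionally merged by SMARTS, since canonical
SMILES distinguishes their resonance forms.  One pair per
(site class, DG class, path length) survives; the path length stays in
the key because a site can reach two symmetry-equivalent donors through
rings of different size, which are distinct intermediates.

**Remote mode.** For meta/para/remote DGs the bond window no longer
applies: candidates are the Cartesian product of unique site classes and
unique donor classes, at any path length.  Each is screened by closing a
dummy ring with a CCl₂ fragment (a stand-in for the metal — the MMFF94s
force field used next has no transition-metal parameters), embedding in
3D with ETKDG (up to 10 seeds; failure to embed rejects the pair),
optimizing with MMFF94s, and summing the force field's out-of-plane
bending and torsion terms of the optimized structure.  Pairs at or below
10 kcal·mol⁻¹ survive.  In-plane angle bending is *not* part of the sum:
it carries a large baseline for any substituted arene (15–20 kcal·mol⁻¹
even for clearly feasible five-membered closures, which would make the
cutoff unsatisfiable), while the oop+torsion sum is near zero for
feasible rings and grows for distorted ones.  The extra bond the bridge
adds to the DG heteroatom is legalized by a formal charge inside the
throwaway probe structure only.

## Intermediate assembly and conformers

The palladacycle graph is the substrate minus one site hydrogen, plus Pd
bonded to the site carbon and DG heteroatom, plus a κ²-acetate (both
oxygens bound).  The complex is treated as a closed-shell singlet with
the substrate's net charge (Pd(II) + acetate⁻ + aryl⁻ cancel).  Aromatic
flags are cleared (kekulized bonds) because the metal defeats aromaticity
perception.

3·N_rot + 3 conformers are requested per complex, with N_rot the
substrate's rotatable-bond count (standard strict definition; the
Pd/acetate framework contributes none).  Embedding uses distance geometry
with random initial coordinates and explicit Pd–ligand distance bounds of
(r_cov(Pd) + r_cov(X)) ± 15%; the knowledge-based torsion/planarity
potentials of ETKDG are disabled for the complex because they reject the
metal ring outright (zero successful embeddings in every tested
configuration).  Failed embeddings are dropped without retry — the quota
is attempted, not guaranteed — and a complex with no conformers is
excluded from ranking and reported.

Conformers are clustered on heavy-atom RMSD (least-squares superposition,
no graph-automorphism symmetry correction — a deliberate cost/benefit
choice) with a 1.0 Å cutoff, leader/Butina style: the unassigned
conformer with the most unassigned neighbours seeds each cluster.  The
retained representative is the cluster medoid (conformers live in
coordinate space, where a coordinate mean is not a conformer).  Members
are within the cutoff of their seed by construction and hence within
twice the cutoff of the medoid; the medoid itself may sit slightly
farther from a member than the cutoff.

## Energy engines and validation

Engines expose `optimize` and `single_point`, both returning kcal·mol⁻¹
(engine-native units converted at the adapter boundary,
1 Hartree = 627.509474 kcal·mol⁻¹).

* **mock** — no relaxation; energy is the sum of inverse pairwise atomic
  distances, or a per-site rigged value when an energy map is supplied.
  Deterministic and bit-reproducible, it lets the entire pipeline run and
  be tested without external programs.  Because it does not move atoms,
  its results are marked geometrically valid by contract (the planarity
  angle is still computed and reported).
* **forcefield** — UFF, the only bundled force field with Pd parameters
  (generic fallback typing for the metal centre; gas phase).
* **tightbinding** — external `xtb` binary, GFN1-xTB with ALPB implicit
  solvation (default CH₂Cl₂); discovered on PATH, absence is a
  configuration error with the engine named.
* **dft_singlepoint** — external ORCA, r²SCAN-3c with CPCM; single points
  only, used by the refinement stage.

Optimizer convergence settings of external engines are left at their
defaults and captured in the per-call logs.

A relaxed geometry enters ranking only if (1) it converged, (2) bond
connectivity perceived from the coordinates (bond iff distance ≤ 1.25 ×
sum of covalent radii) is unchanged between the input and output
geometries, ignoring all bonds to Pd — distance criteria are unreliable
for the metal — and (3) the four Pd coordination partners are coplanar
with it: the angle between the normals of plane(Pd, C_site, X_DG) and
plane(Pd, O, O), folded into [0°, 90°] because plane normals have no
sign, is strictly below 5° (the boundary itself fails; pinned to within
1e-9° numerically).  Collinear atom triples make a plane undefined and
count as invalid.

## Ranking, refinement, evaluation

Per complex the best valid conformer energy is taken; relative energies
are measured from the global minimum.  Every site class whose best
complex lies within the threshold (default 1 kcal·mol⁻¹ — roughly
chemical accuracy; threshold 0 reduces to the argmin) is predicted, in
energy order with ties broken by site atom index.  Optional refinement
recomputes single-point energies for the within-threshold complexes and
re-applies the threshold on the refined values; refined energies fully
replace unrefined ones for those complexes (mixing levels across the
threshold boundary is a known approximation), and an engine failure
leaves the affected complex at its unrefined energy.  Complexes whose
conformers all failed validation are excluded and reported, never
silently treated as high energy.

Against an observed site (resolved to its symmetry class first):
`correct` = unique predicted site, `semi_correct` = among several
predicted, `incorrect` = not predicted.  The null model guesses uniformly
among each molecule's k candidate sites: expected correct = Σ 1/kᵢ, with
a 95% interval from Monte Carlo simulation or the exact Poisson-binomial
distribution (dynamic-programming convolution).

## Lookup-table predictor

Table rows are (SMARTS whose first atom is the reactive `[cH1]`, DG
strength in kcal·mol⁻¹).  All patterns are matched; per (site, pattern)
the best substructure match is kept, generic SMARTS atoms contributing
the atomic number of the atom actually matched.  Per site, matches are
ordered by heavy-atom count (desc), atomic-number sum (desc), strength
(asc), stable on ties; the site's assigned strength is its rank-1 match
and the minimum assigned strength over sites (ties included) is the
prediction.  Note that maximal-specificity ranking can select a more
specific pattern than a less specific one with a very different strength
— this is inherent to the three-key rule and is the documented behaviour.
The bundled table carries the four worked-example patterns; the TSV
format (`smarts`, `dg_strength_kcal`) accepts complete user tables.
Annotated-output site numbers are 1..N over matched sites in ascending
atom-index order; all other outputs use 0-based parse-order atom indices.

## Synthetic fixtures and what tests show

The fixture generator emits small substrates with known symmetry
structure (benzene, toluene, 2-phenylpyridine, N,N-dimethylbenzamide, a
nitroarene, anilide/ether/ketone examples, and the worked-example amide)
plus rigged mock-engine energy maps: one designated site at 0 and the
rest ≥ 2 kcal·mol⁻¹ higher with seed-derived jitter, so the pipeline must
recover the designated site.  This validates the plumbing — enumeration,
symmetry handling, assembly, clustering, thresholding, labelling — under
a controlled energy function.  It does not validate the chemistry: real
predictive accuracy depends on the external tight-binding/DFT energies
and conformer coverage, which the offline suite deliberately does not
exercise.  Problem sizes are kept small (≤ ~25 heavy atoms, ≤ 12
conformers per complex, 30-point clustering oracles) so the whole suite
runs in minutes on one CPU.

## Known limitations

* BEP ranking of intermediates, not transition states; sites closer than
  ~1 kcal·mol⁻¹ are genuinely unresolved (hence `semi_correct`).
* Constitutional symmetry only — E/Z and atropisomerism are ignored in
  site equivalence.
* κ¹ acetate binding, alternative catalysts/ligands, π-coordinating DGs
  and cyclization-controlled selectivity are out of scope.
* The 2D angle filter is a heuristic pre-screen whose discrimination
  depends on the layout engine; false passes cost compute only.
* UFF energies for Pd complexes rely on generic parameter fallbacks and
  should be treated as qualitative.
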