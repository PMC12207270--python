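"""End-to-end prediction pipeline, run configuration, and test fixtures.

``run_predict`` wires the stages together: candidate enumeration (ortho
window + angle filter, or remote Cartesian product + strain screen),
symmetry deduplication, palladacycle assembly, conformer generation and
clustering, engine optimization with geometry validation, ranking, and the
optional evaluation against an observed site.  Results are written as JSON
together with SDF geometries and a run manifest.

Atom indexing in all outputs is the 0-based order of the parsed substrate.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

import regiocmd
from regiocmd.assembly import (
    build_complex,
    cluster_conformers,
    count_rotatable_bonds,
    generate_conformers,
    write_sdf,
)
from regiocmd.engines import MockEngine
from regiocmd.ranking import (
    EvaluationLabel,
    Prediction,
    evaluate,
    rank_sites,
    refine,
)
from regiocmd.remote import enumerate_all_pairs, strain_screen
from regiocmd.sites import dedup_pairs, find_ortho_pairs, passes_angle_filter
from regiocmd.substrate import (
    Substrate,
    parse_substrate,
    site_symmetry_classes,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_predict", "generate_fixtures", "Fixture", "NoSitesError"]


class NoSitesError(RuntimeError):
    """The substrate has no surviving candidate (site, DG) pair."""


@dataclass
class RunConfig:
    """Configuration of one prediction run."""

    engine: object  # any object with optimize/single_point
    mode: str = "ortho"  # ortho | remote
    threshold_kcal: float = 1.0
    refine_engine: object | None = None
    seed: int = 7
    solvent: str = "ch2cl2"
    output_dir: Path | None = None

    def __post_init__(self) -> None:
        if self.threshold_kcal < 0:
            raise ValueError("threshold must be non-negative")
        if self.mode not in ("ortho", "remote"):
            raise ValueError(f"unknown mode {self.mode!r}")


def _candidate_pairs(sub: Substrate, config: RunConfig):
    if config.mode == "ortho":
        pairs = [
            p
            for p in find_ortho_pairs(sub)
            if passes_angle_filter(sub, p)
        ]
        return dedup_pairs(sub, pairs)
    pairs = enumerate_all_pairs(sub)
    kept = []
    for p in pairs:
        res = strain_screen(sub, p, seed=config.seed)
        if res.kept:
            kept.append(p)
        else:
            logger.info("strain screen dropped %s (%s)", p, res.reason)
    return kept


def run_predict(
    config: RunConfig, smiles: str, observed_site: int | None = None
) -> tuple[Prediction, EvaluationLabel | None]:
    """Run the full palladacycle-ranking prediction for one substrate.

    ``observed_site`` is an atom index of the substrate; it is resolved to
    its site symmetry class before comparison.  When an output directory
    is configured the function writes ``results.json``, per-complex SDF
    geometries, and ``manifest.json``.
    """
    sub = parse_substrate(smiles)
    pairs = _candidate_pairs(sub, config)
    if not pairs:
        raise NoSitesError(f"no candidate reaction sites for {smiles!r}")

    site_classes = site_symmetry_classes(sub, {p.site_atom for p in pairs})
    class_of_site = {
        a: c.class_id for c in site_classes for a in c.member_atom_indices
    }

    n_rot = count_rotatable_bonds(sub)
    results = []
    ensembles = []
    for i, pair in enumerate(pairs):
        cx = build_complex(sub, pair)
        ens = generate_conformers(
            cx, seed=(config.seed + 1000 * i) % (2**31), n_rotatable=n_rot
        )
        if ens.empty:
            logger.warning("all embeddings failed for %s; complex excluded", pair)
            continue
        ens = cluster_conformers(ens)
        ensembles.append(ens)
        opt = [
            config.engine.optimize(cx, ens.coordinates(cid))
            for cid in ens.cluster_representatives
        ]
        results.append((cx, class_of_site[pair.site_atom], opt))

    prediction = rank_sites(results, threshold_kcal=config.threshold_kcal)
    if config.refine_engine is not None and len(prediction.predicted_sites) > 1:
        prediction = refine(prediction, config.refine_engine)

    label = None
    if observed_site is not None:
        observed_class = class_of_site.get(observed_site)
        if observed_class is None:
            # the observed atom may be symmetry-equivalent to a retained site
            all_classes = site_symmetry_classes(
                sub, {p.site_atom for p in pairs} | {observed_site}
            )
            lookup = {
                a: c.class_id
                for c in all_classes
                for a in c.member_atom_indices
            }
            rep_class = {
                lookup[p.site_atom]: class_of_site[p.site_atom] for p in pairs
            }
            if lookup[observed_site] not in rep_class:
                raise ValueError(
                    f"observed site {observed_site} is not a candidate site"
                )
            observed_class = rep_class[lookup[observed_site]]
        label = evaluate(prediction, observed_class)

    if config.output_dir is not None:
        _write_outputs(config, sub, prediction, label, ensembles)
    return prediction, label


def _write_outputs(config, sub, prediction, label, ensembles) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    doc = {
        "comment": "atom indices are 0-based positions in the parsed substrate",
        "smiles": sub.smiles,
        "threshold_kcal": config.threshold_kcal,
        "refined": prediction.refined,
        "predicted_site_classes": list(prediction.predicted_sites),
        "predicted_site_atoms": [
            r.complex.pair.site_atom
            for r in prediction.per_complex
            if r.site_class in prediction.predicted_sites
            and r.relative_energy_kcal <= config.threshold_kcal + 1e-12
        ],
        "per_complex": [
            {
                "site_atom": r.complex.pair.site_atom,
                "dg_atom": r.complex.pair.dg_atom,
                "site_class": r.site_class,
                "energy_kcal": r.best_energy_kcal,
                "relative_energy_kcal": r.relative_energy_kcal,
            }
            for r in prediction.per_complex
        ],
        "dropped": [list(d) for d in prediction.dropped],
        "evaluation": None if label is None else label.value,
    }
    (out / "results.json").write_text(json.dumps(doc, indent=2))
    for ens in ensembles:
        p = ens.complex.pair
        write_sdf(ens, str(out / f"complex_site{p.site_atom}_dg{p.dg_atom}.sdf"))
    manifest = {
        "package_version": regiocmd.__version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "mode": config.mode,
        "engine": getattr(
            getattr(config.engine, "spec", None), "name", type(config.engine).__name__
        ),
        "solvent": config.solvent,
        "threshold_kcal": config.threshold_kcal,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


# ---------------------------------------------------------------------------
# fixtures


@dataclass(frozen=True)
class Fixture:
    """A small substrate with known symmetry structure and a rigged
    mock-engine energy map keyed by site atom index."""

    name: str
    smiles: str
    favoured_site: int | None
    rigged_energies: dict[int, float] = field(default_factory=dict)


#: worked-example substrate used in the pattern-matching documentation
WORKED_EXAMPLE_SMILES = "CCCN(C)C(=O)c1ccc(C(=O)c2ccccc2)cc1"


def generate_fixtures(seed: int = 0) -> list[Fixture]:
    """Small offline fixture set with rigged mock-engine energies.

    For every fixture with candidate pairs, one site class representative
    is designated as favoured (energy 0) and all other sites sit at least
    2 kcal/mol higher, with deterministic seed-derived jitter, so the
    rigged pipeline must label the favoured site correct.
    """
    rng = np.random.default_rng(seed)
    specs = [
        ("benzene", "c1ccccc1"),
        ("toluene", "Cc1ccccc1"),
        ("2-phenylpyridine", "c1ccc(-c2ccccn2)cc1"),
        ("nn-dimethylbenzamide", "CN(C)C(=O)c1ccccc1"),
        ("nitrobenzene", "O=[N+]([O-])c1ccccc1"),
        ("acetanilide", "CC(=O)Nc1ccccc1"),
        ("2-methoxypyridine", "COc1ccccn1"),
        ("benzophenone", "O=C(c1ccccc1)c2ccccc2"),
        ("worked-example", WORKED_EXAMPLE_SMILES),
    ]
    fixtures = []
    for name, smi in specs:
        sub = parse_substrate(smi)
        pairs = dedup_pairs(
            sub,
            [p for p in find_ortho_pairs(sub) if passes_angle_filter(sub, p)],
        )
        sites = sorted({p.site_atom for p in pairs})
        if not sites:
            fixtures.append(Fixture(name, smi, None, {}))
            continue
        favoured = sites[0]
        energies = {favoured: 0.0}
        for s in sites[1:]:
            energies[s] = 2.0 + float(rng.uniform(0.0, 3.0))
        fixtures.append(Fixture(name, smi, favoured, energies))
    return fixtures


def rigged_engine(fixture: Fixture) -> MockEngine:
    """Mock engine rigged with the fixture's site energy map."""
    return MockEngine(energy_map=fixture.rigged_energies)
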