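"""Site ranking, optional single-point refinement, and evaluation.

The complex with the overall lowest-energy valid conformer defines the
top-ranked site; every complex whose best conformer lies within an energy
threshold (default 1 kcal/mol) of that minimum contributes a predicted
site.  Predictions are labelled against an experimentally observed site:
``correct`` when the observed site is the unique prediction,
``semi_correct`` when it is among several within the threshold, and
``incorrect`` otherwise.  A null model that guesses uniformly among a
molecule's candidate sites provides the comparison baseline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np

from regiocmd.assembly import PalladacycleComplex
from regiocmd.engines import OptimizationResult

logger = logging.getLogger(__name__)

__all__ = [
    "ComplexRanking",
    "Prediction",
    "EvaluationLabel",
    "PredictionError",
    "rank_sites",
    "refine",
    "evaluate",
    "null_model",
    "NullModelResult",
]

DEFAULT_THRESHOLD_KCAL = 1.0


class PredictionError(RuntimeError):
    """No complex produced any valid conformer; carries per-complex reasons."""


class EvaluationLabel(str, Enum):
    CORRECT = "correct"
    SEMI_CORRECT = "semi_correct"
    INCORRECT = "incorrect"


@dataclass(frozen=True)
class ComplexRanking:
    """Best valid conformer of one complex and its rank information."""

    complex: PalladacycleComplex
    site_class: int
    best_energy_kcal: float
    relative_energy_kcal: float
    best_result: OptimizationResult = field(repr=False, compare=False)


@dataclass(frozen=True)
class Prediction:
    """Ranked reaction-site prediction for one substrate."""

    per_complex: tuple[ComplexRanking, ...]
    predicted_sites: tuple[int, ...]  # site-class ids within threshold
    threshold_kcal: float
    refined: bool = False
    dropped: tuple[tuple[str, str], ...] = ()  # (complex tag, reason)

    @property
    def top_site(self) -> int:
        return self.predicted_sites[0]


def _predicted(
    rankings: list[ComplexRanking], threshold: float
) -> tuple[int, ...]:
    within = [
        r for r in rankings if r.relative_energy_kcal <= threshold + 1e-12
    ]
    # order by energy, ties by site atom index for determinism
    within.sort(
        key=lambda r: (r.relative_energy_kcal, r.complex.pair.site_atom)
    )
    seen, out = set(), []
    for r in within:
        if r.site_class not in seen:
            seen.add(r.site_class)
            out.append(r.site_class)
    return tuple(out)


def rank_sites(
    results: list[tuple[PalladacycleComplex, int, list[OptimizationResult]]],
    threshold_kcal: float = DEFAULT_THRESHOLD_KCAL,
) -> Prediction:
    """Rank complexes by their best valid conformer energy.

    ``results`` pairs each complex with its site symmetry-class id and its
    per-conformer optimization results; invalid results (non-converged,
    changed connectivity, non-planar coordination) are discarded here.
    Complexes left with no valid conformer are excluded and reported in
    ``Prediction.dropped``; if every complex is dropped a
    :class:`PredictionError` lists the reasons.
    """
    if threshold_kcal < 0:
        raise ValueError("threshold must be non-negative")
    rankings: list[ComplexRanking] = []
    dropped: list[tuple[str, str]] = []
    for cx, site_class, opt_results in results:
        tag = f"site{cx.pair.site_atom}-dg{cx.pair.dg_atom}"
        valid = [r for r in opt_results if r.valid]
        if not valid:
            reasons = {
                (
                    "non-converged" if not r.converged
                    else "connectivity changed" if not r.valid_connectivity
                    else "coordination not planar"
                )
                for r in opt_results
            }
            dropped.append((tag, "; ".join(sorted(reasons)) or "no conformers"))
            continue
        best = min(valid, key=lambda r: r.energy_kcal)
        rankings.append(
            ComplexRanking(
                complex=cx,
                site_class=site_class,
                best_energy_kcal=best.energy_kcal,
                relative_energy_kcal=0.0,
                best_result=best,
            )
        )
    if not rankings:
        raise PredictionError(
            "no complex produced a valid conformer: "
            + "; ".join(f"{t}: {r}" for t, r in dropped)
        )
    e_min = min(r.best_energy_kcal for r in rankings)
    rankings = [
        replace(r, relative_energy_kcal=r.best_energy_kcal - e_min)
        for r in rankings
    ]
    rankings.sort(
        key=lambda r: (r.relative_energy_kcal, r.complex.pair.site_atom)
    )
    return Prediction(
        per_complex=tuple(rankings),
        predicted_sites=_predicted(rankings, threshold_kcal),
        threshold_kcal=threshold_kcal,
        dropped=tuple(dropped),
    )


def refine(prediction: Prediction, dft_engine) -> Prediction:
    """Re-rank the within-threshold complexes with single-point energies.

    Applies only when at least two distinct sites are predicted; the
    single-point engine recomputes the energy of each within-threshold
    complex's best conformer, and the threshold is re-applied on the
    refined energies.  An engine failure leaves that complex at its
    unrefined energy (logged).
    """
    if len(prediction.predicted_sites) < 2:
        return prediction
    within = [
        r
        for r in prediction.per_complex
        if r.relative_energy_kcal <= prediction.threshold_kcal + 1e-12
    ]
    refined = []
    for r in within:
        try:
            e = dft_engine.single_point(r.complex, r.best_result.coordinates)
        except Exception as exc:  # noqa: BLE001
            logger.warning(
                "refinement failed for site %d: %s; keeping unrefined energy",
                r.complex.pair.site_atom,
                exc,
            )
            e = r.best_energy_kcal
        refined.append(replace(r, best_energy_kcal=e))
    e_min = min(r.best_energy_kcal for r in refined)
    refined = [
        replace(r, relative_energy_kcal=r.best_energy_kcal - e_min)
        for r in refined
    ]
    refined.sort(
        key=lambda r: (r.relative_energy_kcal, r.complex.pair.site_atom)
    )
    return Prediction(
        per_complex=tuple(refined),
        predicted_sites=_predicted(refined, prediction.threshold_kcal),
        threshold_kcal=prediction.threshold_kcal,
        refined=True,
        dropped=prediction.dropped,
    )


def evaluate(prediction: Prediction, observed_site_class: int) -> EvaluationLabel:
    """Label a prediction against the experimentally observed site class."""
    candidates = {r.site_class for r in prediction.per_complex}
    if observed_site_class not in candidates:
        raise ValueError(
            f"observed site class {observed_site_class} is not among the "
            f"candidate site classes {sorted(candidates)}"
        )
    predicted = set(prediction.predicted_sites)
    if observed_site_class not in predicted:
        return EvaluationLabel.INCORRECT
    if len(predicted) == 1:
        return EvaluationLabel.CORRECT
    return EvaluationLabel.SEMI_CORRECT


@dataclass(frozen=True)
class NullModelResult:
    expected_correct: float
    ci95: tuple[float, float]
    method: str


def null_model(
    site_counts: list[int],
    n_sim: int = 100_000,
    seed: int = 0,
    method: str = "simulation",
) -> NullModelResult:
    """Baseline of guessing one candidate site uniformly at random.

    For molecules with k_i candidate sites the expected number of correct
    guesses is sum(1/k_i).  The 95% interval is obtained either by Monte
    Carlo (``method='simulation'``) or from the exact Poisson-binomial
    distribution of the sum of independent Bernoulli(1/k_i) variables
    (``method='exact'``).
    """
    counts = list(site_counts)
    if any(k < 2 for k in counts):
        raise ValueError("each molecule must have at least 2 candidate sites")
    p = np.array([1.0 / k for k in counts])
    expected = float(p.sum())
    if method == "simulation":
        rng = np.random.default_rng(seed)
        draws = (rng.random((n_sim, len(p))) < p).sum(axis=1)
        lo, hi = np.percentile(draws, [2.5, 97.5])
        return NullModelResult(expected, (float(lo), float(hi)), "simulation")
    if method == "exact":
        # Poisson-binomial pmf by dynamic-programming convolution
        pmf = np.array([1.0])
        for pi in p:
            pmf = np.convolve(pmf, [1.0 - pi, pi])
        cdf = np.cumsum(pmf)
        lo = int(np.searchsorted(cdf, 0.025))
        hi = int(np.searchsorted(cdf, 0.975))
        return NullModelResult(expected, (float(lo), float(hi)), "exact")
    raise ValueError(f"unknown method {method!r}")
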