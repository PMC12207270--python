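"""Site ranking, refinement, evaluation labels, and the null model."""

import numpy as np
import pytest

from regiocmd import (
    EvaluationLabel,
    PredictionError,
    evaluate,
    null_model,
    parse_substrate,
    rank_sites,
    refine,
)
from regiocmd.assembly import build_complex
from regiocmd.engines import OptimizationResult
from regiocmd.sites import CandidatePair


def _result(energy, valid=True):
    return OptimizationResult(
        coordinates=np.zeros((3, 3)),
        energy_kcal=energy,
        converged=valid,
        valid_connectivity=True,
        valid_planarity=True,
        planarity_angle_deg=0.0,
    )


@pytest.fixture()
def two_complexes(phenylpyridine):
    pairs = [CandidatePair(2, 9, 3, 5), CandidatePair(6, 9, 3, 5)]
    return [build_complex(phenylpyridine, p) for p in pairs]


class TestRankSites:
    def test_clear_winner(self, two_complexes):
        a, b = two_complexes
        pred = rank_sites(
            [(a, 0, [_result(0.0)]), (b, 1, [_result(2.0)])], threshold_kcal=1.0
        )
        assert pred.predicted_sites == (0,)
        assert pred.per_complex[0].relative_energy_kcal == 0.0
        assert pred.per_complex[1].relative_energy_kcal == pytest.approx(2.0)

    def test_close_pair_both_predicted(self, two_complexes):
        a, b = two_complexes
        pred = rank_sites(
            [(a, 0, [_result(0.0)]), (b, 1, [_result(0.5)])], threshold_kcal=1.0
        )
        assert pred.predicted_sites == (0, 1)

    def test_zero_threshold_singleton_argmin(self, two_complexes):
        a, b = two_complexes
        pred = rank_sites(
            [(a, 0, [_result(3.0)]), (b, 1, [_result(1.0)])], threshold_kcal=0.0
        )
        assert pred.predicted_sites == (1,)

    def test_best_conformer_per_complex(self, two_complexes):
        a, b = two_complexes
        pred = rank_sites(
            [
                (a, 0, [_result(5.0), _result(0.2)]),
                (b, 1, [_result(0.0), _result(9.0)]),
            ],
            threshold_kcal=1.0,
        )
        assert pred.predicted_sites == (1, 0)

    def test_invalid_results_excluded_and_reported(self, two_complexes):
        a, b = two_complexes
        pred = rank_sites(
            [(a, 0, [_result(0.0, valid=False)]), (b, 1, [_result(4.0)])]
        )
        assert pred.predicted_sites == (1,)
        assert len(pred.dropped) == 1

    def test_all_invalid_raises_with_reasons(self, two_complexes):
        a, b = two_complexes
        with pytest.raises(PredictionError, match="non-converged"):
            rank_sites(
                [
                    (a, 0, [_result(0.0, valid=False)]),
                    (b, 1, [_result(1.0, valid=False)]),
                ]
            )

    def test_threshold_monotonicity(self, two_complexes):
        a, b = two_complexes
        results = [(a, 0, [_result(0.0)]), (b, 1, [_result(0.9)])]
        prev: set = set()
        for thr in (0.0, 0.5, 1.0, 2.0):
            cur = set(rank_sites(results, threshold_kcal=thr).predicted_sites)
            assert prev <= cur
            prev = cur

    def test_global_minimum_always_predicted(self, two_complexes):
        a, b = two_complexes
        for thr in (0.0, 0.3, 1.0):
            pred = rank_sites(
                [(a, 0, [_result(1.7)]), (b, 1, [_result(0.4)])],
                threshold_kcal=thr,
            )
            assert 1 in pred.predicted_sites


class _ConstEngine:
    """Single-point engine returning rigged energies keyed by site atom."""

    def __init__(self, by_site):
        self.by_site = by_site

    def single_point(self, cx, coords):
        return self.by_site[cx.pair.site_atom]


class TestRefine:
    def test_single_site_is_noop(self, two_complexes):
        a, b = two_complexes
        pred = rank_sites(
            [(a, 0, [_result(0.0)]), (b, 1, [_result(5.0)])], threshold_kcal=1.0
        )
        assert refine(pred, _ConstEngine({})) is pred

    def test_refined_energies_can_invert_order(self, two_complexes):
        a, b = two_complexes
        pred = rank_sites(
            [(a, 0, [_result(0.0)]), (b, 1, [_result(0.5)])], threshold_kcal=1.0
        )
        out = refine(pred, _ConstEngine({2: 10.0, 6: 0.0}))
        assert out.refined
        assert out.predicted_sites == (1,)

    def test_membership_stable_when_refined_within_threshold(self, two_complexes):
        a, b = two_complexes
        pred = rank_sites(
            [(a, 0, [_result(0.0)]), (b, 1, [_result(0.5)])], threshold_kcal=1.0
        )
        out = refine(pred, _ConstEngine({2: 0.0, 6: 0.8}))
        assert set(out.predicted_sites) == {0, 1}

    def test_engine_failure_keeps_unrefined_energy(self, two_complexes):
        a, b = two_complexes
        pred = rank_sites(
            [(a, 0, [_result(0.0)]), (b, 1, [_result(0.5)])], threshold_kcal=1.0
        )

        class Boom:
            def single_point(self, cx, coords):
                raise RuntimeError("engine exploded")

        out = refine(pred, Boom())
        assert set(out.predicted_sites) == {0, 1}


class TestEvaluate:
    def _pred(self, two_complexes, energies, thr=1.0):
        a, b = two_complexes
        return rank_sites(
            [(a, 0, [_result(energies[0])]), (b, 1, [_result(energies[1])])],
            threshold_kcal=thr,
        )

    def test_unique_hit_is_correct(self, two_complexes):
        pred = self._pred(two_complexes, [0.0, 5.0])
        assert evaluate(pred, 0) is EvaluationLabel.CORRECT

    def test_observed_among_several_is_semi_correct(self, two_complexes):
        pred = self._pred(two_complexes, [0.0, 0.5])
        assert evaluate(pred, 1) is EvaluationLabel.SEMI_CORRECT

    def test_observed_outside_is_incorrect(self, two_complexes):
        pred = self._pred(two_complexes, [0.0, 5.0])
        assert evaluate(pred, 1) is EvaluationLabel.INCORRECT

    def test_unknown_site_rejected(self, two_complexes):
        pred = self._pred(two_complexes, [0.0, 5.0])
        with pytest.raises(ValueError, match="not among the candidate"):
            evaluate(pred, 99)

    def test_exactly_one_label(self, two_complexes):
        pred = self._pred(two_complexes, [0.0, 0.5])
        labels = {evaluate(pred, c) for c in (0, 1)}
        assert labels <= set(EvaluationLabel)


class TestNullModel:
    def test_sixty_two_site_molecules_expect_thirty(self):
        res = null_model([2] * 60, n_sim=10, seed=1)
        assert res.expected_correct == pytest.approx(30.0, abs=0)

    def test_single_four_site_molecule(self):
        res = null_model([4], n_sim=10, seed=1)
        assert res.expected_correct == pytest.approx(0.25, abs=0)

    def test_counts_below_two_rejected(self):
        with pytest.raises(ValueError):
            null_model([2, 1])

    def test_simulation_agrees_with_closed_form(self):
        counts = [2] * 30 + [3] * 20 + [4] * 10
        res = null_model(counts, n_sim=100_000, seed=7)
        rng = np.random.default_rng(7)
        p = np.array([1 / k for k in counts])
        draws = (rng.random((100_000, len(p))) < p).sum(axis=1)
        # MC standard error of the mean ~ sigma/sqrt(n) << 0.1
        assert abs(draws.mean() - res.expected_correct) < 0.1

    def test_exact_and_simulated_intervals_agree(self):
        counts = [2] * 60
        sim = null_model(counts, n_sim=200_000, seed=3, method="simulation")
        exact = null_model(counts, method="exact")
        assert abs(sim.ci95[0] - exact.ci95[0]) <= 1
        assert abs(sim.ci95[1] - exact.ci95[1]) <= 1
        # binomial(60, 1/2): 95% of the mass within ~ +/- 8 of 30
        assert 20 < exact.ci95[0] < 30 < exact.ci95[1] < 40
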