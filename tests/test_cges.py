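import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gsprog.cges import (
    CGESModel,
    CgesResult,
    CgesWeights,
    cges_permutation_test,
    cges_score,
    compute_weights,
    logrank_chi2,
    loocv_cges,
    rank_significant_sets,
)
from gsprog.io import GeneSet, SurvivalTable

from _oracles import logrank_chi2_naive
from conftest import make_matrix


class TestCgesScore:
    def test_hand_evaluated_fixture(self):
        w = CgesWeights(("A", "B"), np.array([1.0, -0.5]), 0.1)
        score = cges_score(np.array([[0.8], [0.4]]), w)
        assert score[0] == pytest.approx(0.6224593312018546, abs=1e-12)

    def test_median_linear_score_maps_to_half(self):
        w = CgesWeights(("A",), np.array([2.0]), 3.0)
        assert cges_score(np.array([[1.5]]), w)[0] == pytest.approx(0.5, abs=1e-15)

    def test_open_interval_and_monotone(self):
        w = CgesWeights(("A",), np.array([1.0]), 0.0)
        x = np.linspace(-30, 30, 41)[None, :]
        s = cges_score(x, w)
        assert np.all(s > 0) and np.all(s < 1)
        assert np.all(np.diff(s) > 0)

    def test_shift_invariance_through_m(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((3, 10))
        beta = np.array([0.5, -1.0, 2.0])
        a = cges_score(x, CgesWeights(("A", "B", "C"), beta, 0.7))
        shifted = x + 2.0  # adds 2*sum(beta) to every linear term
        b = cges_score(shifted, CgesWeights(("A", "B", "C"), beta, 0.7 + 2.0 * beta.sum()))
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_gene_mismatch_reported(self):
        w = CgesWeights(("A", "B"), np.array([1.0, 1.0]), 0.0)
        em = make_matrix([[-1.0, 1.0]], genes=["A"])
        with pytest.raises(ValueError, match="mismatch"):
            cges_score(em, w)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.floats(-5, 5), st.floats(-5, 5))
    def test_strict_monotonicity_pairwise(self, a, b):
        w = CgesWeights(("A",), np.array([1.0]), 0.3)
        sa = cges_score(np.array([[a]]), w)[0]
        sb = cges_score(np.array([[b]]), w)[0]
        if a < b:
            assert sa < sb
        elif a > b:
            assert sa > sb

    def test_weights_factory_asserts_median(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((2, 15))
        w = CgesWeights.from_training(("A", "B"), np.array([1.0, 2.0]), x)
        assert w.m == pytest.approx(np.median(np.array([1.0, 2.0]) @ x))


class TestLoocv:
    def test_returns_one_score_per_patient(self, small_cohort):
        expr, surv, collection, _ = small_cohort
        scores, flagged, samples = loocv_cges(expr, surv, collection["PLANTED_1"])
        assert scores.shape == (surv.n,)
        assert np.all((scores > 0) & (scores < 1))

    def test_score_independent_of_held_out_outcome(self, small_cohort):
        expr, surv, collection, _ = small_cohort
        base, _, _ = loocv_cges(expr, surv, collection["PLANTED_1"])
        flipped_event = surv.event.copy()
        flipped_event[0] = 1 - flipped_event[0]
        surv2 = SurvivalTable(surv.sample_ids, surv.time, flipped_event)
        other, _, _ = loocv_cges(expr, surv2, collection["PLANTED_1"])
        assert other[0] == pytest.approx(base[0], abs=1e-12)

    def test_requires_ten_patients(self):
        surv = SurvivalTable(tuple(map(str, range(5))), np.arange(1.0, 6.0), np.ones(5, int))
        rng = np.random.default_rng(0)
        z = rng.standard_normal((3, 5))
        z = (z - z.mean(1, keepdims=True)) / z.std(1, keepdims=True)
        expr = make_matrix(z, genes=["A", "B", "C"], samples=list(surv.sample_ids))
        with pytest.raises(ValueError, match="10"):
            loocv_cges(expr, surv, GeneSet("S", ("A", "B", "C")))

    def test_duplicated_patient_barely_moves_other_scores(self):
        # stability fixture: a 150-patient cohort, duplicate the first patient
        from gsprog.io import log_standardize
        from gsprog.simulate import CohortSpec, PlantedSet, simulate_cohort

        spec = CohortSpec(n_patients=150, n_genes=20, seed=606,
                          planted_sets=(PlantedSet(5, 0.7),), censor_rate=0.3)
        expr_raw, surv, collection, _ = simulate_cohort(spec)
        expr = log_standardize(expr_raw)
        base, _, _ = loocv_cges(expr, surv, collection["PLANTED_1"])
        dup_data = expr.data.copy()
        dup_data["DUP"] = dup_data[expr.sample_ids[0]]
        vals = dup_data.to_numpy()
        vals = (vals - vals.mean(1, keepdims=True)) / vals.std(1, keepdims=True)
        expr2 = make_matrix(vals, genes=list(dup_data.index), samples=list(dup_data.columns))
        surv2 = SurvivalTable(
            surv.sample_ids + ("DUP",),
            np.append(surv.time, surv.time[0]),
            np.append(surv.event, surv.event[0]),
        )
        dup, _, _ = loocv_cges(expr2, surv2, collection["PLANTED_1"])
        assert np.max(np.abs(dup[1 : surv.n] - base[1:])) < 0.1

    def test_null_set_scores_uncorrelated_with_outcome(self):
        from gsprog.io import log_standardize
        from gsprog.simulate import CohortSpec, simulate_cohort

        spec = CohortSpec(n_patients=100, n_genes=10, seed=77, censor_rate=0.0)
        expr_raw, surv, _, _ = simulate_cohort(spec)
        expr = log_standardize(expr_raw)
        scores, _, _ = loocv_cges(expr, surv, GeneSet("NULL", tuple(expr.gene_ids[:5])))
        r = np.corrcoef(scores, np.log(surv.time))[0, 1]
        assert abs(r) < 0.3


class TestLogrank:
    def test_identical_groups_give_zero(self):
        time = np.array([2.0, 5.0, 7.0, 2.0, 5.0, 7.0])
        event = np.array([1, 0, 1, 1, 0, 1])
        surv = SurvivalTable(tuple(map(str, range(6))), time, event)
        groups = np.array([True, True, True, False, False, False])
        assert logrank_chi2(groups, surv) == pytest.approx(0.0, abs=1e-12)

    def test_label_swap_symmetric(self):
        rng = np.random.default_rng(3)
        surv = SurvivalTable(
            tuple(map(str, range(20))),
            rng.exponential(10, 20) + 0.1,
            rng.integers(0, 2, 20) | np.array([1] + [0] * 19),
        )
        g = rng.uniform(size=20) < 0.5
        g[0], g[1] = True, False
        assert logrank_chi2(g, surv) == pytest.approx(logrank_chi2(~g, surv), abs=1e-12)

    def test_ten_patient_instance_matches_tabulation_oracle(self):
        time = np.array([3.0, 5.0, 7.0, 2.0, 18.0, 16.0, 2.0, 9.0, 16.0, 5.0])
        event = np.array([1, 1, 0, 1, 0, 1, 1, 1, 1, 0])
        groups = np.array([1, 1, 1, 1, 1, 0, 0, 0, 0, 0], dtype=bool)
        surv = SurvivalTable(tuple(map(str, range(10))), time, event)
        assert logrank_chi2(groups, surv) == pytest.approx(
            logrank_chi2_naive(groups, time, event), abs=1e-10
        )

    def test_matches_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(8)
        time = np.round(rng.exponential(30, 40)) + 1
        event = (rng.uniform(size=40) < 0.7).astype(int)
        groups = rng.uniform(size=40) < 0.4
        groups[:2] = [True, False]
        surv = SurvivalTable(tuple(map(str, range(40))), time, event)
        res = lifelines.statistics.logrank_test(
            time[groups], time[~groups], event[groups], event[~groups]
        )
        assert logrank_chi2(groups, surv) == pytest.approx(res.test_statistic, abs=1e-10)

    def test_empty_group_rejected(self, toy_surv):
        with pytest.raises(ValueError, match="non-empty"):
            logrank_chi2(np.ones(6, dtype=bool), toy_surv)


class TestPermutationTest:
    def test_planted_set_detected(self, small_cohort):
        expr, surv, collection, _ = small_cohort
        r = cges_permutation_test(expr, surv, collection["PLANTED_1"], n_perm=200, seed=5)
        assert r.p_perm < 0.05
        assert r.hazard_ratio > 1.0

    def test_seed_determinism(self, small_cohort):
        expr, surv, collection, _ = small_cohort
        a = cges_permutation_test(expr, surv, collection["PLANTED_1"], n_perm=100, seed=9)
        b = cges_permutation_test(expr, surv, collection["PLANTED_1"], n_perm=100, seed=9)
        assert (a.p_perm, a.chi2_obs, a.z_score) == (b.p_perm, b.chi2_obs, b.z_score)

    def test_strict_null_agrees_in_direction(self, small_cohort):
        expr, surv, collection, _ = small_cohort
        r = cges_permutation_test(
            expr, surv, collection["PLANTED_1"], n_perm=30, seed=2, strict_null=True
        )
        assert r.p_perm < 0.2

    def test_invalid_nperm_rejected(self, small_cohort):
        expr, surv, collection, _ = small_cohort
        with pytest.raises(ValueError, match="positive"):
            cges_permutation_test(expr, surv, collection["PLANTED_1"], n_perm=0)


class TestRankSignificant:
    def _res(self, name, p, z):
        return CgesResult(name, 5.0, p, z, 1.5, 1000, 0)

    def test_zero_p_ties_ranked_by_z(self):
        ranked = rank_significant_sets([self._res("A", 0.0, 2.3), self._res("B", 0.0, 5.1)])
        assert [r.set_name for r in ranked] == ["B", "A"]

    def test_all_above_alpha_empty(self):
        assert rank_significant_sets([self._res("A", 0.5, 1.0)]) == []

    def test_full_tie_breaks_by_name(self):
        ranked = rank_significant_sets([self._res("B", 0.01, 2.0), self._res("A", 0.01, 2.0)])
        assert [r.set_name for r in ranked] == ["A", "B"]


class TestModelSurface:
    def test_fit_collection_and_summary(self, small_cohort):
        expr, surv, collection, _ = small_cohort
        null_set = GeneSet("BACKGROUND", tuple(expr.gene_ids[20:25]))
        model = CGESModel(expr, surv, list(collection) + [null_set])
        res = model.fit(n_perm=100, seed=3)
        assert res.frame.shape[0] == 2
        assert "gene sets tested" in res.summary()
        assert set(res.permutation_summaries()) == {"PLANTED_1", "BACKGROUND"}
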