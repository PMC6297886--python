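import itertools
import math

import numpy as np
import pytest

from orddcm.design import ModelKind, QMatrix, derive_w_matrix, enumerate_profiles
from orddcm.exceptions import ConstraintError, DataError, DesignError
from orddcm.models import (
    NaturalItemParams,
    PseudoItemParams,
    class_conditional_table,
    marginal_log_likelihood,
    mordm_to_ordm,
    natural_to_pseudo,
    option_probabilities,
    ordm_to_nrdm,
    pseudo_to_natural,
    validate_constraints,
)
from orddcm import reference

from conftest import random_natural, random_pseudo


def _null_params(kind, q, m=4):
    terms = ((0,), (1,), (0, 1)) if q.n_attributes == 2 else tuple((k,) for k in range(q.n_attributes))
    n_items = q.n_items
    kind = ModelKind.coerce(kind)
    kwargs = dict(model_kind=kind, options=(m,) * n_items, effect_terms=terms)
    if kind is ModelKind.NRDM:
        kwargs["intercepts"] = [np.zeros(m - 1)] * n_items
        kwargs["effects"] = [np.zeros((m - 1, len(terms)))] * n_items
    elif kind is ModelKind.ORDM:
        kwargs["intercepts"] = [np.zeros(m - 1)] * n_items
        kwargs["effects"] = [np.zeros(len(terms))] * n_items
    else:
        w = derive_w_matrix(q)
        kwargs["effects"] = [np.zeros(len(terms))] * n_items
        kwargs["item_intercepts"] = np.zeros(n_items)
        kwargs["shared_intercepts"] = [np.zeros(m - 1) for _ in range(w.n_sets)]
    return NaturalItemParams(**kwargs)


class TestPseudoNaturalTransforms:
    def test_published_worked_example(self, mordm_truth):
        # item intercept 5.834 plus shared option-2 natural intercept
        # (-6.204 - 2.871) composes to -3.241
        value = mordm_truth.item_intercepts[0] + mordm_truth.shared_intercepts[0][1]
        assert value == pytest.approx(-3.241, abs=1e-9)

    def test_all_zero(self, survey_q):
        pseudo = random_pseudo("ordm", survey_q, 4, np.random.default_rng(0))
        zeroed = PseudoItemParams(
            model_kind="ordm",
            options=pseudo.options,
            effect_terms=pseudo.effect_terms,
            intercepts=[np.zeros_like(a) for a in pseudo.intercepts],
            effects=[np.zeros_like(a) for a in pseudo.effects],
        )
        nat = pseudo_to_natural(zeroed)
        assert all(not a.any() for a in nat.intercepts)
        assert all(not a.any() for a in nat.effects)

    def test_cumulative_sum_by_hand(self):
        # NRDM effect family: base 1.0 and increments (0.5, 0.25)
        q = QMatrix(entries=np.array([[1]]))
        pseudo = PseudoItemParams(
            model_kind="nrdm",
            options=(4,),
            effect_terms=((0,),),
            intercepts=[np.array([0.0, -0.1, -0.1])],
            effects=[np.array([[1.0], [0.5], [0.25]])],
        )
        nat = pseudo_to_natural(pseudo)
        np.testing.assert_allclose(nat.effects[0][:, 0], [1.0, 1.5, 1.75])

    def test_natural_to_pseudo_differences(self):
        q = QMatrix(entries=np.array([[1]]))
        nat = NaturalItemParams(
            model_kind="nrdm",
            options=(4,),
            effect_terms=((0,),),
            intercepts=[np.array([0.0, -0.1, -0.2])],
            effects=[np.array([[1.0], [1.5], [1.75]])],
        )
        pseudo = natural_to_pseudo(nat)
        np.testing.assert_allclose(pseudo.effects[0][:, 0], [1.0, 0.5, 0.25])

    def test_published_intercept_increments(self, ordm_truth):
        # cumulated option intercepts of the first item decompose back into
        # the printed base and increments
        np.testing.assert_allclose(ordm_truth.intercepts[0], [-0.390, -4.478, -9.799])
        pseudo = natural_to_pseudo(ordm_truth)
        np.testing.assert_allclose(pseudo.intercepts[0], [-0.390, -4.088, -5.321], atol=1e-12)

    def test_zeros_natural_to_pseudo(self, survey_q):
        nat = _null_params("ordm", survey_q)
        pseudo = natural_to_pseudo(nat)
        assert all(not a.any() for a in pseudo.intercepts)

    @pytest.mark.parametrize("kind", ["nrdm", "ordm", "mordm"])
    def test_round_trip(self, survey_q, kind):
        rng = np.random.default_rng(42)
        for _ in range(5):
            pseudo = random_pseudo(kind, survey_q, 4, rng)
            back = natural_to_pseudo(pseudo_to_natural(pseudo))
            for a, b in zip(pseudo.effects, back.effects):
                np.testing.assert_allclose(a, b, atol=1e-10)
            if pseudo.intercepts is not None:
                for a, b in zip(pseudo.intercepts, back.intercepts):
                    np.testing.assert_allclose(a, b, atol=1e-10)

    def test_sign_violation_raises(self, survey_q):
        pseudo = random_pseudo("ordm", survey_q, 4, np.random.default_rng(1))
        bad_intercepts = [a.copy() for a in pseudo.intercepts]
        bad_intercepts[0][1] = 0.5  # positive increment
        bad = PseudoItemParams(
            model_kind="ordm",
            options=pseudo.options,
            effect_terms=pseudo.effect_terms,
            intercepts=bad_intercepts,
            effects=pseudo.effects,
        )
        with pytest.raises(ConstraintError, match="item 0"):
            pseudo_to_natural(bad)


class TestValidateConstraints:
    def test_published_ordm_estimates_pass(self, ordm_truth, survey_q):
        assert validate_constraints(ordm_truth, q=survey_q, strict=True).ok

    def test_published_mordm_estimates_pass(self, mordm_truth, survey_q):
        assert validate_constraints(mordm_truth, q=survey_q, strict=True).ok

    def test_increasing_intercepts_fail(self):
        nat = NaturalItemParams(
            model_kind="ordm",
            options=(3,),
            effect_terms=((0,),),
            intercepts=[np.array([0.5, 1.0])],
            effects=[np.array([1.0])],
        )
        report = validate_constraints(nat)
        assert not report.ok
        failing = [c for c in report if not c.passed]
        assert "intercept" in failing[0].name

    def test_negative_effect_fails(self):
        nat = NaturalItemParams(
            model_kind="ordm",
            options=(3,),
            effect_terms=((0,),),
            intercepts=[np.array([0.5, 0.0])],
            effects=[np.array([-0.2])],
        )
        assert not validate_constraints(nat).ok


class TestOptionProbabilities:
    @pytest.mark.parametrize("kind", ["nrdm", "ordm", "mordm"])
    def test_null_parameters_uniform(self, survey_q, kind):
        params = _null_params(kind, survey_q)
        p = option_probabilities(kind, params, 0, (0, 0), survey_q)
        np.testing.assert_allclose(p, 0.25)

    def test_binary_logistic_reduction(self):
        q = QMatrix(entries=np.array([[1]]))
        params = NaturalItemParams(
            model_kind="ordm",
            options=(2,),
            effect_terms=((0,),),
            intercepts=[np.array([0.0])],
            effects=[np.array([1.0])],
        )
        p = option_probabilities("ordm", params, 0, (1,), q)
        assert p[1] == pytest.approx(math.e / (1 + math.e), abs=1e-12)

    def test_hand_evaluated_cumulative_form(self):
        q = QMatrix(entries=np.array([[1]]))
        params = NaturalItemParams(
            model_kind="ordm",
            options=(4,),
            effect_terms=((0,),),
            intercepts=[np.array([1.0, 0.0, -1.0])],
            effects=[np.array([1.0])],
        )
        p = option_probabilities("ordm", params, 0, (0,), q)
        e = math.e
        np.testing.assert_allclose(p, np.array([1, e, e, 1]) / (2 + 2 * e), atol=1e-12)

    def test_profile_length_mismatch(self, survey_q, ordm_truth):
        with pytest.raises(DesignError):
            option_probabilities("ordm", ordm_truth, 0, (1, 0, 1), survey_q)

    def test_overflow_safe(self):
        # predictors near +-18 must not overflow (values of this order occur
        # in published NRDM estimates)
        q = QMatrix(entries=np.array([[1]]))
        params = NaturalItemParams(
            model_kind="ordm",
            options=(4,),
            effect_terms=((0,),),
            intercepts=[np.array([18.0, -0.1, -0.1])],
            effects=[np.array([18.0])],
        )
        p = option_probabilities("ordm", params, 0, (1,), q)
        assert np.isfinite(p).all() and p.sum() == pytest.approx(1.0, abs=1e-12)


class TestClassConditionalTable:
    def test_null_uniform(self):
        q = QMatrix(entries=np.array([[1]]))
        params = _null_params("ordm", q, m=3)
        table = class_conditional_table("ordm", params, q)
        assert table.probs.shape == (1, 2, 3)
        np.testing.assert_allclose(table.probs, 1 / 3)

    def test_normalization(self, survey_q, ordm_truth):
        table = class_conditional_table("ordm", ordm_truth, survey_q)
        np.testing.assert_allclose(table.probs.sum(axis=2), 1.0, atol=1e-12)

    def test_masters_have_higher_expected_code(self, survey_q, ordm_truth):
        table = class_conditional_table("ordm", ordm_truth, survey_q)
        codes = np.arange(4)
        # profiles (1,0) and (1,1) possess attribute 1 measured by item 0
        e_master = table.probs[0, 1] @ codes
        e_nonmaster = table.probs[0, 0] @ codes
        assert e_master > e_nonmaster

    @pytest.mark.parametrize("kind", ["nrdm", "ordm", "mordm"])
    def test_agrees_with_option_probabilities(self, survey_q, kind):
        rng = np.random.default_rng(3)
        params = random_natural(kind, survey_q, 4, rng)
        w = derive_w_matrix(survey_q)
        table = class_conditional_table(kind, params, survey_q, w)
        space = table.profile_space
        for _ in range(100):
            i = rng.integers(survey_q.n_items)
            c = rng.integers(space.n_classes)
            expected = option_probabilities(kind, params, int(i), space.profiles[c], survey_q, w)
            np.testing.assert_allclose(table.probs[i, c, :4], expected, atol=1e-14)


class TestNesting:
    def test_ordm_nested_in_nrdm(self, survey_q):
        rng = np.random.default_rng(11)
        for _ in range(5):
            params = random_natural("ordm", survey_q, 4, rng)
            as_nrdm = ordm_to_nrdm(params)
            t1 = class_conditional_table("ordm", params, survey_q)
            t2 = class_conditional_table("nrdm", as_nrdm, survey_q)
            np.testing.assert_allclose(t1.probs, t2.probs, atol=1e-12)

    def test_mordm_nested_in_ordm(self, survey_q, survey_w):
        rng = np.random.default_rng(12)
        for _ in range(5):
            params = random_natural("mordm", survey_q, 4, rng)
            as_ordm = mordm_to_ordm(params, survey_w)
            t1 = class_conditional_table("mordm", params, survey_q, survey_w)
            t2 = class_conditional_table("ordm", as_ordm, survey_q)
            np.testing.assert_allclose(t1.probs, t2.probs, atol=1e-12)


class TestStochasticOrdering:
    @pytest.mark.parametrize("kind", ["ordm", "mordm"])
    def test_cdf_dominance(self, survey_q, kind):
        rng = np.random.default_rng(21)
        w = derive_w_matrix(survey_q)
        space = enumerate_profiles(2)
        for _ in range(10):
            params = random_natural(kind, survey_q, 4, rng)
            table = class_conditional_table(kind, params, survey_q, w)
            for i in range(survey_q.n_items):
                master = space.index_of(survey_q.entries[i])
                cdf_master = np.cumsum(table.probs[i, master])
                cdf_none = np.cumsum(table.probs[i, 0])
                assert (cdf_master <= cdf_none + 1e-12).all()


class TestMarginalLogLikelihood:
    def test_uniform_table(self):
        q = QMatrix(entries=np.array([[1]]))
        params = _null_params("ordm", q, m=4)
        table = class_conditional_table("ordm", params, q)
        total, pointwise = marginal_log_likelihood(np.array([[2], [0], [3]]), table, [0.3, 0.7])
        np.testing.assert_allclose(pointwise, np.log(0.25), atol=1e-12)
        assert total == pytest.approx(3 * np.log(0.25), abs=1e-12)

    def test_degenerate_prevalence(self, survey_q, ordm_truth):
        table = class_conditional_table("ordm", ordm_truth, survey_q)
        x = np.array([[0, 1, 2, 3, 0, 1, 2, 3]])
        _, pointwise = marginal_log_likelihood(x, table, [1.0, 0.0, 0.0, 0.0])
        expected = sum(np.log(table.probs[i, 0, x[0, i]]) for i in range(8))
        assert pointwise[0] == pytest.approx(expected, abs=1e-10)

    def test_brute_force_small_designs(self):
        # exhaustive oracle: explicit sum over classes, product over items
        rng = np.random.default_rng(33)
        for k, n_items, n in [(1, 2, 3), (2, 3, 6), (3, 4, 10)]:
            entries = np.zeros((n_items, k), dtype=int)
            while (entries.sum(axis=1) == 0).any() or (entries.sum(axis=0) == 0).any():
                entries = rng.integers(0, 2, (n_items, k))
            q = QMatrix(entries=entries)
            params = random_natural("ordm", q, 3, rng)
            table = class_conditional_table("ordm", params, q)
            space = table.profile_space
            pi = rng.dirichlet(np.ones(space.n_classes))
            x = rng.integers(0, 3, (n, n_items))
            total, pointwise = marginal_log_likelihood(x, table, pi)
            for e in range(n):
                acc = 0.0
                for c in range(space.n_classes):
                    prod = pi[c]
                    for i in range(n_items):
                        prod *= option_probabilities("ordm", params, i, space.profiles[c], q)[x[e, i]]
                    acc += prod
                assert pointwise[e] == pytest.approx(math.log(acc), abs=1e-10)
            assert total == pytest.approx(pointwise.sum(), abs=1e-10)

    def test_out_of_range_code(self, survey_q, ordm_truth):
        table = class_conditional_table("ordm", ordm_truth, survey_q)
        x = np.zeros((2, 8), dtype=int)
        x[1, 3] = 4
        with pytest.raises(DataError, match="respondent 1, item 3"):
            marginal_log_likelihood(x, table, [0.25] * 4)


class TestParamsJson:
    @pytest.mark.parametrize("kind", ["nrdm", "ordm", "mordm"])
    def test_round_trip(self, survey_q, kind):
        params = random_natural(kind, survey_q, 4, np.random.default_rng(7))
        back = NaturalItemParams.from_json_dict(params.to_json_dict())
        assert back.model_kind == params.model_kind
        for a, b in zip(params.effects, back.effects):
            np.testing.assert_array_equal(a, b)
        if params.intercepts is not None:
            for a, b in zip(params.intercepts, back.intercepts):
                np.testing.assert_array_equal(a, b)
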