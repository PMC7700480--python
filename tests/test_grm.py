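"""Graded response model: response functions, information, EM, scoring."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.optimize import minimize
from scipy.special import expit, logsumexp
from scipy.stats import kendalltau, norm

from periogrm.grm import (
    CategoryCollapseError,
    GradedResponseModel,
    GRMItemParams,
    boundary_prob,
    category_probs,
    eap_ability,
    information_criteria,
    item_information,
    item_information_integral,
    score_table,
)
from periogrm.reference import REFERENCE_MODEL4
from periogrm.simulate import generate_from_grm

CAL_ITEMS = [p for _, p in REFERENCE_MODEL4["CAL"]]

params_strategy = st.builds(
    lambda a, b1, gap: GRMItemParams(a, (b1, b1 + gap)),
    a=st.floats(0.3, 5.0),
    b1=st.floats(-2.5, 2.0),
    gap=st.floats(0.1, 2.5),
)


class TestResponseFunctions:
    def test_boundary_midpoint_and_saturation(self):
        assert boundary_prob(2.0, 0.7, 0.7) == pytest.approx(0.5)
        assert boundary_prob(2.0, 0.0, 50.0) == pytest.approx(1.0)
        assert boundary_prob(2.0, 0.0, -50.0) == pytest.approx(0.0, abs=1e-12)

    def test_boundary_spot_value(self):
        # 1 / (1 + e^{2.03 * 0.53}) evaluated directly
        assert boundary_prob(2.03, 0.53, 0.0) == pytest.approx(0.2543, abs=1e-4)

    def test_category_probs_spot_value(self):
        p = category_probs(GRMItemParams(3.07, (0.28, 1.28)), 0.28)
        assert p == pytest.approx([0.5, 0.4556, 0.0444], abs=1e-4)

    @given(params_strategy, st.floats(-8, 8))
    def test_category_probs_sum_to_one_and_positive(self, params, theta):
        p = category_probs(params, theta)
        assert abs(p.sum() - 1.0) < 1e-12
        assert (p >= 0).all()

    def test_distant_second_threshold_recovers_2pl(self):
        graded = category_probs(GRMItemParams(2.0, (0.5, 40.0)), 1.0)
        p_star = expit(2.0 * (1.0 - 0.5))
        assert graded[0] == pytest.approx(1 - p_star)
        assert graded[1] == pytest.approx(p_star)
        assert graded[2] == pytest.approx(0.0, abs=1e-12)


def information_by_finite_difference(params: GRMItemParams, theta: float, h: float = 1e-4):
    """Independent Fisher-information oracle: -E[d^2 log P_k / d theta^2]."""
    total = 0.0
    pk = category_probs(params, theta)
    for k in range(params.n_categories):
        lp = [
            np.log(category_probs(params, theta + d)[k])
            for d in (-h, 0.0, h)
        ]
        d2 = (lp[0] - 2 * lp[1] + lp[2]) / h**2
        total += pk[k] * (-d2)
    return total


class TestInformation:
    def test_dichotomous_closed_form(self):
        p = GRMItemParams(3.0, (0.8,))
        theta = np.linspace(-4, 4, 41)
        pstar = expit(3.0 * (theta - 0.8))
        assert item_information(p, theta) == pytest.approx(9.0 * pstar * (1 - pstar))
        assert item_information(p, 0.8) == pytest.approx(9.0 / 4)

    @given(params_strategy, st.floats(-6, 6))
    def test_nonnegative(self, params, theta):
        assert item_information(params, theta) >= 0

    @pytest.mark.parametrize("params", CAL_ITEMS)
    @pytest.mark.parametrize("theta", [-1.0, 0.3, 1.5])
    def test_matches_finite_difference_oracle(self, params, theta):
        assert item_information(params, theta) == pytest.approx(
            information_by_finite_difference(params, theta), rel=1e-4
        )

    def test_dichotomous_integral_equals_discrimination(self):
        # exact closed form a (P*(10) - P*(-10)); for moderate a the tail
        # mass outside [-10, 10] is negligible and the integral equals a
        for a in (0.5, 1.7, 3.7, 4.0):
            integral = item_information_integral(GRMItemParams(a, (1.3,)))
            closed = a * (expit(a * (10 - 1.3)) - expit(a * (-10 - 1.3)))
            assert integral == pytest.approx(closed, abs=1e-6)
        for a in (1.7, 3.7, 4.0):
            assert item_information_integral(GRMItemParams(a, (1.3,))) == pytest.approx(
                a, abs=0.005
            )

    def test_integral_vanishes_with_discrimination(self):
        assert item_information_integral(GRMItemParams(1e-6, (0.5, 1.5))) < 1e-5


class TestInformationCriteria:
    def test_zero_parameters(self):
        aic, bic = information_criteria(-50.0, 0, 100)
        assert aic == bic == 100.0

    def test_arithmetic(self):
        aic, bic = information_criteria(-100.0, 5, 100)
        assert aic == pytest.approx(210.0)
        assert bic == pytest.approx(223.03, abs=0.01)

    def test_bic_aic_gap_at_study_size(self):
        # 6 graded items, 3 parameters each, n = 254
        aic, bic = information_criteria(-880.0, 18, 254)
        assert bic - aic == pytest.approx(63.67, abs=0.005)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            information_criteria(-1.0, -1, 10)


def direct_marginal_loglik(resp, a1, b1, a2, b2, n_nodes=201):
    """Marginal log-likelihood computed independently of the EM machinery."""
    nodes = np.linspace(-8, 8, n_nodes)
    w = norm.pdf(nodes)
    w = w / w.sum()
    p1 = np.clip(expit(a1 * (nodes - b1)), 1e-12, 1 - 1e-12)
    p2 = np.clip(expit(a2 * (nodes - b2)), 1e-12, 1 - 1e-12)
    logp = [
        np.log(np.vstack([1 - p1, p1])),
        np.log(np.vstack([1 - p2, p2])),
    ]
    ll = logp[0][resp[:, 0]] + logp[1][resp[:, 1]] + np.log(w)
    return float(logsumexp(ll, axis=1).sum())


class TestEMFit:
    def test_empty_category_raises_collapse_error(self):
        resp = np.ones((30, 1), dtype=int)
        with pytest.raises(CategoryCollapseError, match="merge categories"):
            GradedResponseModel().fit(resp, n_categories=[2])

    def test_loglik_monotone_and_fit_statistics(self):
        data = generate_from_grm(CAL_ITEMS, n=400, seed=3)
        m = GradedResponseModel().fit(data)
        assert np.all(np.diff(m.loglik_path_) > -1e-8)
        assert m.n_parameters_ == 18
        assert m.aic_ == pytest.approx(-2 * m.loglik_ + 36)
        assert m.bic_ == pytest.approx(-2 * m.loglik_ + 18 * np.log(400))

    def test_two_item_fit_matches_direct_maximizer(self):
        items = [GRMItemParams(1.5, (-0.5,)), GRMItemParams(2.2, (0.8,))]
        data = generate_from_grm(items, n=200, seed=1)
        m = GradedResponseModel(tol=1e-8, max_iter=2000).fit(data)

        resp = data.responses

        def nll(x):
            la1, b1, la2, b2 = x
            return -direct_marginal_loglik(resp, np.exp(la1), b1, np.exp(la2), b2)

        # independent oracle: grid of starts, each polished by Nelder-Mead
        import itertools

        best = np.inf
        for start in itertools.product(
            np.log([1.0, 2.0]), (-0.5, 0.5), np.log([1.0, 2.0]), (-0.5, 0.5)
        ):
            res = minimize(
                nll, list(start), method="Nelder-Mead",
                options={"xatol": 1e-7, "fatol": 1e-10, "maxfev": 8000},
            )
            best = min(best, res.fun)
        assert m.loglik_ == pytest.approx(-best, abs=1e-3)

    def test_parameter_recovery_large_sample(self):
        data = generate_from_grm(CAL_ITEMS, n=2000, seed=42)
        m = GradedResponseModel().fit(data)
        a_true = np.array([p.a for p in CAL_ITEMS])
        b_true = np.vstack([p.b for p in CAL_ITEMS])
        assert np.abs(m.discrimination_ - a_true).mean() < 0.4
        assert np.abs(np.vstack(m.thresholds_) - b_true).mean() < 0.15

    def test_information_rank_recovery_at_study_size(self):
        # at n = 254 the fitted information ranks the items in strong
        # agreement with the generating ranking (exact order is not
        # identifiable: two generating values differ by only 0.04)
        true_info = np.array([item_information_integral(p) for p in CAL_ITEMS])
        taus = []
        for seed in range(20):
            data = generate_from_grm(CAL_ITEMS, n=254, seed=300 + seed)
            m = GradedResponseModel(tol=1e-4).fit(data)
            taus.append(kendalltau(m.information_integrals(), true_info).statistic)
        assert np.mean(taus) >= 0.5

    def test_information_order_recovery_large_sample(self):
        true_info = np.array([item_information_integral(p) for p in CAL_ITEMS])
        data = generate_from_grm(CAL_ITEMS, n=5000, seed=77)
        est = GradedResponseModel().fit(data).information_integrals()
        for i in range(len(CAL_ITEMS)):
            for j in range(len(CAL_ITEMS)):
                if true_info[i] - true_info[j] >= 0.5:
                    assert est[i] > est[j]

    def test_missing_responses_are_dropped_not_imputed(self):
        items = [GRMItemParams(2.0, (0.0,)), GRMItemParams(2.0, (0.5,))]
        data = generate_from_grm(items, n=300, seed=1)
        resp = data.responses.copy()
        resp[:150, 1] = -1
        m = GradedResponseModel().fit(resp, n_categories=[2, 2])
        # subjects with a missing item contribute a one-item likelihood
        single = m.score_samples(np.array([[1, -1]]))
        both = m.score_samples(np.array([[1, 1]]))
        assert single[0] > both[0]


class TestEAP:
    @pytest.fixture(scope="class")
    def model(self):
        return GradedResponseModel.from_parameters(REFERENCE_MODEL4["CAL"])

    def test_all_missing_pattern_returns_prior(self, model):
        est = eap_ability(model, [-1] * 6)
        assert est.theta == pytest.approx(0.0, abs=1e-9)
        assert est.se == pytest.approx(1.0, abs=1e-3)

    def test_dominance_monotonicity(self, model):
        low = eap_ability(model, [0] * 6)
        high = eap_ability(model, [2] * 6)
        assert high.theta > low.theta

    def test_matches_dense_grid_oracle(self, model):
        pattern = np.array([2, 1, 0, 1, 2, 0])
        grid = np.linspace(-10, 10, 10_001)
        like = norm.pdf(grid)
        for params, k in zip([p for _, p in REFERENCE_MODEL4["CAL"]], pattern):
            like = like * category_probs(params, grid)[k]
        oracle = np.trapezoid(grid * like, grid) / np.trapezoid(like, grid)
        est = eap_ability(model, pattern)
        assert est.theta == pytest.approx(oracle, abs=1e-3)

    def test_invariant_to_item_order(self, model):
        perm = [3, 1, 5, 0, 4, 2]
        permuted = GradedResponseModel.from_parameters(
            [REFERENCE_MODEL4["CAL"][i] for i in perm]
        )
        pattern = [2, 0, 1, 1, 0, 2]
        assert eap_ability(model, pattern).theta == pytest.approx(
            eap_ability(permuted, [pattern[i] for i in perm]).theta, abs=1e-12
        )

    def test_out_of_range_category_rejected(self, model):
        with pytest.raises(ValueError, match="out of range"):
            eap_ability(model, [3, 0, 0, 0, 0, 0])


class TestScoreTable:
    @pytest.fixture(scope="class")
    def table(self):
        model = GradedResponseModel.from_parameters(REFERENCE_MODEL4["CAL"])
        return score_table(model), model

    def test_enumerates_every_pattern(self, table):
        t, _ = table
        assert len(t.patterns) == 3**6
        assert t.patterns["sum_score"].max() == 12
        assert len(t.by_sum_score) == 13

    def test_rows_agree_with_eap(self, table):
        t, model = table
        row = t.patterns.iloc[400]
        pattern = row[model.item_labels_].to_numpy(dtype=int)
        assert row["ability"] == pytest.approx(eap_ability(model, pattern).theta)

    def test_ability_monotone_under_single_category_increase(self, table):
        t, model = table
        df = t.patterns
        ability = {
            tuple(r): ab
            for r, ab in zip(df[model.item_labels_].to_numpy(), df["ability"])
        }
        for pattern, ab in ability.items():
            for j in range(6):
                if pattern[j] < 2:
                    bumped = list(pattern)
                    bumped[j] += 1
                    assert ability[tuple(bumped)] > ab

    def test_cap_enforced(self):
        model = GradedResponseModel.from_parameters(REFERENCE_MODEL4["CAL"])
        with pytest.raises(ValueError, match="cap"):
            score_table(model, cap=100)


class TestSklearnInterface:
    def test_get_set_params_round_trip(self):
        m = GradedResponseModel(tol=1e-5, max_iter=77)
        params = m.get_params()
        assert params["tol"] == 1e-5
        m2 = GradedResponseModel().set_params(**params)
        assert m2.max_iter == 77

    def test_transform_returns_column_vector(self):
        data = generate_from_grm(CAL_ITEMS[:2], n=120, seed=8)
        m = GradedResponseModel().fit(data)
        out = m.transform(data)
        assert out.shape == (120, 1)

    def test_parameter_table_layout(self):
        m = GradedResponseModel.from_parameters(
            REFERENCE_MODEL4["CAL"], n_subjects=254, loglik=-880.0
        )
        t = m.parameter_table()
        assert list(t.columns) == [
            "item", "Extrmt1", "Extrmt2", "Dscrmn", "ItemInformation", "AIC", "BIC",
        ]
        assert len(t) == 6
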