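"""BP/BN combination rules, likelihood-ratio optimality, and risk scores."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bayesdta.combined_tests import (
    LikelihoodRatioTable,
    bp_bn_posteriors,
    fit_risk_score,
    lr_roc,
    mann_whitney_auc,
    marginal_ordinal_aucs,
    risk_score_auc,
    truncated_cell_probs,
)
from bayesdta.posterior_engine import beta_margin, dirichlet_posterior, draw
from bayesdta.synthetic import gen_logistic_subjects, gen_ordinal_joint
from bayesdta.tables_io import OrdinalCounts, PairedBinaryCounts


class TestBpBnPosteriors:
    @pytest.mark.parametrize(
        "measure, published",
        [
            ("tpfbn", 0.5965),
            ("tpfbp", 0.7901),
            ("fpfbn", 0.1627),
            ("fpfbp", 0.2959),
            ("tpf1", 0.7739),
            ("fpf1", 0.2918),
            ("tpf2", 0.6127),
            ("fpf2", 0.1668),
        ],
    )
    def test_stenosis_published_means(self, stenosis, measure, published):
        result = bp_bn_posteriors(stenosis, n_draws=25_000, seed=81)
        s = result[measure]
        assert s.mean == pytest.approx(published, abs=max(0.005, 4 * s.mc_error))

    def test_component_tpf_matches_beta_oracle(self, stenosis):
        post = dirichlet_posterior(np.array(stenosis.diseased))
        exact = beta_margin(post, {2, 3}, {0, 1, 2, 3}).mean
        assert exact == pytest.approx(48 / 62, abs=1e-12)
        s = bp_bn_posteriors(stenosis, n_draws=25_000, seed=82)["tpf1"]
        assert abs(s.mean - exact) < 4 * s.mc_error

    def test_statement_one_inequalities_hold_per_draw(self, stenosis):
        theta = draw(dirichlet_posterior(np.array(stenosis.diseased)), 5_000, 83)
        phi = draw(dirichlet_posterior(np.array(stenosis.nondiseased)), 5_000, 84)
        tpf1, tpf2 = theta[:, 2] + theta[:, 3], theta[:, 1] + theta[:, 3]
        fpf1, fpf2 = phi[:, 2] + phi[:, 3], phi[:, 1] + phi[:, 3]
        tpfbp, fpfbp = 1 - theta[:, 0], 1 - phi[:, 0]
        tpfbn, fpfbn = theta[:, 3], phi[:, 3]
        assert np.all(tpfbp >= np.maximum(tpf1, tpf2) - 1e-12)
        assert np.all(fpfbp <= fpf1 + fpf2 + 1e-12)
        assert np.all(tpfbn >= tpf1 + tpf2 - 1 - 1e-12)
        assert np.all(fpfbn <= np.minimum(fpf1, fpf2) + 1e-12)

    def test_always_positive_bn_limit(self):
        tables = PairedBinaryCounts(diseased=(0, 0, 0, 200), nondiseased=(1, 1, 1, 1))
        s = bp_bn_posteriors(tables, n_draws=25_000, seed=85)["tpfbn"]
        assert s.mean == pytest.approx(201 / 204, abs=4 * s.mc_error)

    def test_truncated_probs_are_column_normalized(self):
        cells = np.array([0.1, 0.2, 0.3, 0.4])
        trunc = truncated_cell_probs(cells)
        np.testing.assert_allclose(trunc.sum(axis=0), 1.0)


class TestLrRoc:
    def test_two_cell_hand_example(self):
        table = LikelihoodRatioTable(theta=[0.7, 0.3], phi=[0.2, 0.8])
        pts, area = lr_roc(table)
        np.testing.assert_allclose(pts, [[0, 0], [0.2, 0.7], [1, 1]])
        assert area == pytest.approx(0.75)

    def test_identical_distributions_give_diagonal(self):
        table = LikelihoodRatioTable(theta=[0.25] * 4, phi=[0.25] * 4)
        _, area = lr_roc(table)
        assert area == pytest.approx(0.5)

    def test_infinite_lr_cell_ranked_first(self):
        table = LikelihoodRatioTable(theta=[0.5, 0.5], phi=[0.0, 1.0])
        pts, area = lr_roc(table)
        assert pts[1].tolist() == [0.0, 0.5]

    def test_lr_rule_dominates_every_deterministic_rule(self):
        """Brute force over all subsets of a 3-cell grid: no decision rule
        achieves a higher TPF at the same or lower FPF than the LR frontier."""
        rng = np.random.default_rng(86)
        for _ in range(20):
            theta = rng.dirichlet(np.ones(3))
            phi = rng.dirichlet(np.ones(3))
            table = LikelihoodRatioTable(theta, phi)
            pts, _ = lr_roc(table)
            for cells in itertools.product([0, 1], repeat=3):
                mask = np.array(cells, dtype=bool)
                tpf, fpf = theta[mask].sum(), phi[mask].sum()
                frontier_tpf = np.interp(fpf, pts[:, 0], pts[:, 1])
                assert tpf <= frontier_tpf + 1e-9

    def test_misclassification_and_cost_utilities(self):
        table = LikelihoodRatioTable(theta=[0.7, 0.3], phi=[0.2, 0.8], prevalence=0.3)
        assert table.misclassification(0.7, 0.2) == pytest.approx(
            0.3 * 0.3 + 0.7 * 0.2
        )
        assert table.expected_cost(0.7, 0.2, cost_fn=10, cost_fp=1) == pytest.approx(
            10 * 0.3 * 0.3 + 0.7 * 0.2
        )


@pytest.fixture(scope="module")
def recovered():
    x, d = gen_logistic_subjects((-2.0, 0.4, 0.3), n=2000, seed=87)
    model = fit_risk_score(x, d, n_iter=15_000, burnin=3_000, seed=88)
    return x, d, model


class TestRiskScore:
    def test_posterior_tracks_the_mle_and_covers_truth(self, recovered):
        """With n=2000 and a vague prior the posterior mean should sit on the
        maximum-likelihood fit (independent statsmodels oracle) and the 95%
        intervals should cover the generating coefficients."""
        sm = pytest.importorskip("statsmodels.api")
        x, d, model = recovered
        mle = sm.Logit(d, sm.add_constant(x)).fit(disp=0).params
        truth = (-2.0, 0.4, 0.3)
        for i, name in enumerate(("b1", "b2", "b3")):
            s = model[name]
            assert s.mean == pytest.approx(mle[i], abs=0.05)
            assert s.q025 - 0.05 <= truth[i] <= s.q975 + 0.05
        assert 0.2 < model.acceptance_rate < 0.6

    def test_binormal_and_mann_whitney_routes_agree(self, recovered):
        _, _, model = recovered
        mw = risk_score_auc(model, method="mann-whitney")
        bn = risk_score_auc(model, method="binormal", n_iter=8_000, burnin=1_000, seed=89)
        assert bn.mean == pytest.approx(mw, abs=0.03)

    def test_collinear_predictors_identify_only_the_sum(self):
        x1, d = gen_logistic_subjects((-1.0, 0.7), n=1500, seed=90)
        x = np.column_stack([x1, x1])
        model = fit_risk_score(x, d, n_iter=15_000, burnin=3_000, seed=91)
        assert model["b2"].mean + model["b3"].mean == pytest.approx(0.7, abs=0.2)

    def test_degenerate_labels_rejected(self):
        with pytest.raises(ValueError):
            fit_risk_score(np.ones((10, 1)), np.ones(10), n_iter=100, burnin=10, seed=0)

    def test_perfectly_separated_risk_scores_have_unit_auc(self):
        assert mann_whitney_auc(
            np.array([0.9, 0.8, 0.1, 0.2]), np.array([1, 1, 0, 0])
        ) == pytest.approx(1.0)


@settings(max_examples=30, deadline=None)
@given(
    k=st.integers(2, 5),
    seed=st.integers(0, 10_000),
    prevalence=st.floats(0.05, 0.95),
)
def test_true_risk_scores_reproduce_the_lr_roc_area_exactly(k, seed, prevalence):
    """The risk score P(D=1|Y) is monotone increasing in the likelihood
    ratio, so scoring each cell by its true risk gives exactly the optimal
    LR ROC area, for any small discrete joint."""
    rng = np.random.default_rng(seed)
    theta = rng.dirichlet(np.ones(k))
    phi = rng.dirichlet(np.ones(k))
    table = LikelihoodRatioTable(theta, phi, prevalence=prevalence)
    _, lr_area = lr_roc(table)
    with np.errstate(divide="ignore", invalid="ignore"):
        rs = theta * prevalence / (theta * prevalence + phi * (1 - prevalence))
    rs = np.nan_to_num(rs, nan=0.0)
    # probability-weighted Mann-Whitney across cells
    gt = np.sum(np.where(rs[:, None] > rs[None, :], theta[:, None] * phi[None, :], 0))
    eq = np.sum(np.where(rs[:, None] == rs[None, :], theta[:, None] * phi[None, :], 0))
    assert gt + eq / 2 == pytest.approx(lr_area, abs=1e-10)


class TestMarginalOrdinalAucs:
    def test_margin_areas_match_the_bilinear_expectation_oracle(self, mammography):
        """The margin area is bilinear in the (independent) diseased and
        non-diseased cell probabilities, so its exact posterior mean is the
        bilinear form at the posterior-mean margins of the 25-cell
        Dirichlets."""
        from bayesdta.ordinal_roc import auc_from_category_probs

        d = np.diag(mammography.diseased)
        nd = np.diag(mammography.nondiseased)
        out = marginal_ordinal_aucs(d, nd, n_draws=30_000, seed=92)
        k = d.shape[0]
        theta_mean = ((d + 1) / (d + 1).sum()).sum(axis=1)
        phi_mean = ((nd + 1) / (nd + 1).sum()).sum(axis=1)
        a1, a2 = auc_from_category_probs(theta_mean, phi_mean)
        s = out["test1"]["area"]
        assert abs(s.mean - (a1 + a2 / 2)) < 4 * s.mc_error

    def test_concentrated_joints_drive_areas_to_extremes(self):
        k = 3
        d = np.zeros((k, k), dtype=int)
        nd = np.zeros((k, k), dtype=int)
        d[k - 1, k - 1] = 200
        nd[0, 0] = 200
        out = marginal_ordinal_aucs(d, nd, n_draws=10_000, seed=94)
        assert out["test1"]["area"].mean > 0.95
        assert out["test2"]["area"].mean > 0.95

    def test_independent_uniform_joints_sit_at_half(self):
        joint = np.full((3, 3), 1 / 9)
        d, nd = gen_ordinal_joint(joint, joint, 4000, 4000, seed=95)
        out = marginal_ordinal_aucs(d, nd, n_draws=10_000, seed=96)
        assert out["test1"]["area"].mean == pytest.approx(0.5, abs=0.03)
        assert out["test2"]["area"].mean == pytest.approx(0.5, abs=0.03)
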