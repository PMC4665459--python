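"""Accuracy of combined diagnostic tests.

Three ways of combining two tests are covered:

**BP / BN rules for paired binary tests.**  With believe-the-positive (BP)
the combination is positive when either test is; with believe-the-negative
(BN) only when both are.  Writing ``theta`` / ``phi`` for the (test1, test2)
cell probabilities among diseased / non-diseased subjects (independent
Dirichlet posteriors), per draw::

    tpf_bp = theta01 + theta10 + theta11     fpf_bp = phi01 + phi10 + phi11
    tpf_bn = theta11                         fpf_bn = phi11

BP can only raise sensitivity (at the price of a higher FPF, bounded by
fpf1 + fpf2); BN can only lower the FPF (with sensitivity staying above
tpf1 + tpf2 - 1).

**Likelihood-ratio rules.**  By the Neyman–Pearson lemma, thresholding the
likelihood ratio ``LR(Y) = P[Y | D=1] / P[Y | D=0]`` of the joint score
maximizes TPF at every FPF, so the ROC traced by ranking the discrete cells
of the joint distribution by decreasing LR dominates every other decision
rule built from the same scores.  ``lr_roc`` computes that optimal ROC and
its trapezoidal area, plus misclassification/cost evaluations of an LR
threshold rule.

**Risk scores.**  The risk score ``RS(Y) = P[D=1 | Y]`` is a monotone
increasing function of LR(Y), hence shares its optimal ROC.  In practice RS
is estimated by Bayesian logistic regression of disease on the test scores
(vague normal priors, mean 0, precision 1e-4), sampled here with an adaptive
random-walk Metropolis algorithm, and the ROC area of the fitted risk scores
is then estimated either by the binormal model or by the empirical
Mann–Whitney statistic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import optimize

from . import binormal_roc
from .ordinal_roc import auc_from_category_probs
from .posterior_engine import (
    DEFAULT_DRAWS,
    PosteriorSummary,
    dirichlet_posterior,
    draw,
    summarize,
    summarize_many,
)
from .tables_io import PairedBinaryCounts, ScoreSet

__all__ = [
    "CombinedBinaryResult",
    "LikelihoodRatioTable",
    "RiskScoreModel",
    "bp_bn_posteriors",
    "truncated_cell_probs",
    "lr_roc",
    "fit_risk_score",
    "risk_score_auc",
    "marginal_ordinal_aucs",
]

BP_BN_DRAWS = 25_000
LOGISTIC_ITER = 45_000
LOGISTIC_BURNIN = 5_000
COEF_PRIOR_PRECISION = 1e-4


@dataclass(frozen=True)
class CombinedBinaryResult:
    """Posterior summaries for component tests and the BP/BN combinations."""

    summaries: Mapping[str, PosteriorSummary]
    n_draws: int
    seed: int

    MEASURES = ("tpf1", "fpf1", "tpf2", "fpf2", "tpfbp", "fpfbp", "tpfbn", "fpfbn")

    def __getitem__(self, name: str) -> PosteriorSummary:
        return self.summaries[name]


def truncated_cell_probs(cells: np.ndarray) -> np.ndarray:
    """Column-normalized cell probabilities theta*_ij = theta_ij / theta_.j.

    Exposed for completeness; the BP/BN fractions use the plain cell
    probabilities, not these.
    """
    cells = np.asarray(cells, dtype=float).reshape(-1, 2, 2)
    colsum = cells.sum(axis=1, keepdims=True)
    out = cells / colsum
    return out[0] if out.shape[0] == 1 else out


def bp_bn_posteriors(
    tables: PairedBinaryCounts,
    n_draws: int = BP_BN_DRAWS,
    seed: int = 0,
) -> CombinedBinaryResult:
    """Posterior accuracy of two binary tests and their BP/BN combinations."""
    rng = np.random.default_rng(seed)
    theta = draw(dirichlet_posterior(np.array(tables.diseased)), n_draws, rng)
    phi = draw(dirichlet_posterior(np.array(tables.nondiseased)), n_draws, rng)
    # cell order (00, 01, 10, 11), first index test1
    draws = {
        "tpf1": theta[:, 2] + theta[:, 3],
        "tpf2": theta[:, 1] + theta[:, 3],
        "fpf1": phi[:, 2] + phi[:, 3],
        "fpf2": phi[:, 1] + phi[:, 3],
        "tpfbp": 1.0 - theta[:, 0],
        "fpfbp": 1.0 - phi[:, 0],
        "tpfbn": theta[:, 3],
        "fpfbn": phi[:, 3],
    }
    return CombinedBinaryResult(
        summaries=summarize_many(draws, seed=seed), n_draws=n_draws, seed=seed
    )


@dataclass(frozen=True)
class LikelihoodRatioTable:
    """Joint cell probabilities of a discrete score under each disease class.

    ``theta`` and ``phi`` are flat arrays over the same cell grid (each
    summing to one); ``prevalence`` is the disease rate used by the
    misclassification and cost utilities.
    """

    theta: np.ndarray
    phi: np.ndarray
    prevalence: float = 0.5

    def __post_init__(self) -> None:
        theta = np.asarray(self.theta, dtype=float).ravel()
        phi = np.asarray(self.phi, dtype=float).ravel()
        if theta.size != phi.size or theta.size < 2:
            raise ValueError("theta and phi must share a grid of >= 2 cells")
        for name, v in (("theta", theta), ("phi", phi)):
            if np.any(v < 0) or not np.isclose(v.sum(), 1.0):
                raise ValueError(f"{name} must be a probability vector")
        if not (0.0 < self.prevalence < 1.0):
            raise ValueError("prevalence must lie in (0, 1)")
        object.__setattr__(self, "theta", theta)
        object.__setattr__(self, "phi", phi)

    @property
    def lr(self) -> np.ndarray:
        """Per-cell likelihood ratio theta/phi, +inf where phi=0 < theta."""
        with np.errstate(divide="ignore", invalid="ignore"):
            lr = self.theta / self.phi
        lr = np.where((self.phi == 0) & (self.theta > 0), np.inf, lr)
        return np.where((self.phi == 0) & (self.theta == 0), 0.0, lr)

    def misclassification(self, tpf: float, fpf: float) -> float:
        """Overall error rate rho (1 - TPF) + (1 - rho) FPF of a rule."""
        return self.prevalence * (1.0 - tpf) + (1.0 - self.prevalence) * fpf

    def expected_cost(
        self, tpf: float, fpf: float, cost_fn: float = 1.0, cost_fp: float = 1.0
    ) -> float:
        """Expected cost with unit costs per false negative / false positive."""
        return cost_fn * self.prevalence * (1.0 - tpf) + cost_fp * (
            1.0 - self.prevalence
        ) * fpf


def lr_roc(table: LikelihoodRatioTable) -> tuple[np.ndarray, float]:
    """Optimal ROC of the likelihood-ratio rule and its trapezoidal area.

    Cells are ranked by decreasing LR, ties grouped into a single step, and
    (fpf, tpf) accumulated; by the Neyman–Pearson lemma no decision rule on
    the same cells does better at any FPF.
    """
    lr = table.lr
    order = np.argsort(-lr, kind="stable")
    points = [(0.0, 0.0)]
    fpf = tpf = 0.0
    i = 0
    while i < lr.size:
        j = i
        while j < lr.size and lr[order[j]] == lr[order[i]]:
            j += 1
        block = order[i:j]
        tpf += table.theta[block].sum()
        fpf += table.phi[block].sum()
        points.append((fpf, tpf))
        i = j
    pts = np.array(points)
    area = float(np.trapezoid(pts[:, 1], pts[:, 0]))
    return pts, area


@dataclass(frozen=True)
class RiskScoreModel:
    """Posterior of a Bayesian logistic regression and its risk scores."""

    coef_summaries: Mapping[str, PosteriorSummary]
    coef_draws: np.ndarray  # (kept, p+1), column 0 the intercept
    risk_scores: np.ndarray  # posterior-mean P[D=1 | Y] per subject
    labels: np.ndarray
    acceptance_rate: float
    n_iter: int
    burnin: int
    seed: int

    def __getitem__(self, name: str) -> PosteriorSummary:
        return self.coef_summaries[name]


def _logistic_map(eta: np.ndarray) -> np.ndarray:
    out = np.empty_like(eta)
    pos = eta >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-eta[pos]))
    e = np.exp(eta[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def _log_posterior(beta: np.ndarray, x: np.ndarray, d: np.ndarray) -> float:
    eta = x @ beta
    # log-lik = sum d*eta - log(1 + exp(eta)), stably
    ll = float(np.dot(d, eta) - np.logaddexp(0.0, eta).sum())
    ll -= 0.5 * COEF_PRIOR_PRECISION * float(beta @ beta)
    return ll


def _mle_and_cov(x: np.ndarray, d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Posterior mode and inverse Hessian, for the Metropolis proposal."""
    p = x.shape[1]

    def neg(beta):
        return -_log_posterior(beta, x, d)

    def grad(beta):
        mu = _logistic_map(x @ beta)
        return -(x.T @ (d - mu)) + COEF_PRIOR_PRECISION * beta

    res = optimize.minimize(neg, np.zeros(p), jac=grad, method="BFGS")
    mode = res.x
    mu = _logistic_map(x @ mode)
    w = mu * (1.0 - mu)
    hess = x.T @ (x * w[:, None]) + COEF_PRIOR_PRECISION * np.eye(p)
    return mode, np.linalg.inv(hess)


def fit_risk_score(
    predictors: np.ndarray,
    labels: np.ndarray,
    n_iter: int = LOGISTIC_ITER,
    burnin: int = LOGISTIC_BURNIN,
    seed: int = 0,
) -> RiskScoreModel:
    """Bayesian logistic regression of disease on test scores.

    ``predictors`` is (n, p) with one column per test (an intercept is added
    internally); priors are N(0, precision 1e-4) on every coefficient.  The
    posterior is sampled by random-walk Metropolis with a proposal shaped by
    the posterior-mode inverse Hessian and a scale adapted during burn-in to
    an acceptance rate in the 0.3–0.45 band.  Returns coefficient summaries
    and the per-subject posterior-mean risk scores.
    """
    x = np.column_stack([np.ones(len(labels)), np.asarray(predictors, dtype=float)])
    d = np.asarray(labels, dtype=float)
    if set(np.unique(d)) - {0.0, 1.0}:
        raise ValueError("labels must be 0/1")
    if d.min() == d.max():
        raise ValueError("both disease classes must be present")
    if n_iter <= burnin or burnin < 0:
        raise ValueError("need n_iter > burnin >= 0")
    p = x.shape[1]
    rng = np.random.default_rng(seed)

    mode, cov = _mle_and_cov(x, d)
    chol = np.linalg.cholesky(cov)
    scale = 2.38 / np.sqrt(p)

    beta = mode.copy()
    lp = _log_posterior(beta, x, d)
    kept = n_iter - burnin
    coef_draws = np.empty((kept, p))
    rs_sum = np.zeros(len(d))
    accepted = 0
    window_acc = 0
    for it in range(n_iter):
        prop = beta + scale * (chol @ rng.standard_normal(p))
        lp_prop = _log_posterior(prop, x, d)
        if np.log(rng.random()) < lp_prop - lp:
            beta, lp = prop, lp_prop
            accepted += 1
            window_acc += 1
        # adapt the scalar step during burn-in toward 0.3-0.45 acceptance
        if it < burnin and (it + 1) % 200 == 0:
            rate = window_acc / 200.0
            if rate < 0.30:
                scale *= 0.8
            elif rate > 0.45:
                scale *= 1.25
            window_acc = 0
        if it >= burnin:
            j = it - burnin
            coef_draws[j] = beta
            rs_sum += _logistic_map(x @ beta)

    names = ["b1"] + [f"b{i + 2}" for i in range(p - 1)]
    summaries = {
        name: summarize(coef_draws[:, i], seed=seed) for i, name in enumerate(names)
    }
    return RiskScoreModel(
        coef_summaries=summaries,
        coef_draws=coef_draws,
        risk_scores=rs_sum / kept,
        labels=d.astype(np.int64),
        acceptance_rate=accepted / n_iter,
        n_iter=n_iter,
        burnin=burnin,
        seed=seed,
    )


def mann_whitney_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Empirical AUC = P(S_D > S_H) + (1/2) P(S_D = S_H)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    sd = scores[labels == 1]
    sh = scores[labels == 0]
    if sd.size == 0 or sh.size == 0:
        raise ValueError("both classes must be present")
    gt = (sd[:, None] > sh[None, :]).sum()
    eq = (sd[:, None] == sh[None, :]).sum()
    return float((gt + 0.5 * eq) / (sd.size * sh.size))


def risk_score_auc(
    model: RiskScoreModel,
    method: str = "binormal",
    n_iter: int = binormal_roc.DEFAULT_ITER,
    burnin: int = binormal_roc.DEFAULT_BURNIN,
    seed: int = 0,
):
    """ROC area of the fitted risk scores.

    ``method="binormal"`` feeds the posterior-mean risk scores into the
    binormal Gibbs sampler by disease class and returns that fit's ``auc``
    summary (a ``PosteriorSummary``); ``method="mann-whitney"`` returns the
    empirical AUC of the risk scores as a float.  Risk scores are not
    normally distributed, so the Mann–Whitney route is the distribution-free
    check on the binormal one.
    """
    rs = model.risk_scores
    if np.allclose(rs, rs[0]):
        raise ValueError("risk scores are all identical; ROC undefined")
    if method == "mann-whitney":
        return mann_whitney_auc(rs, model.labels)
    if method == "binormal":
        fit = binormal_roc.fit_binormal(
            ScoreSet(values=rs, labels=model.labels),
            n_iter=n_iter,
            burnin=burnin,
            seed=seed,
        )
        return fit["auc"]
    raise ValueError("method must be 'binormal' or 'mann-whitney'")


def marginal_ordinal_aucs(
    diseased_joint: np.ndarray,
    nondiseased_joint: np.ndarray,
    n_draws: int = DEFAULT_DRAWS,
    seed: int = 0,
) -> dict[str, Mapping[str, PosteriorSummary]]:
    """Per-test ROC areas from a paired k-category joint table.

    ``diseased_joint`` and ``nondiseased_joint`` are k-by-k count tables
    (rows test 1, columns test 2).  The 2k^2 cell probabilities get
    independent Dirichlet posteriors; per draw each test's margins are formed
    and its ordinal AUC (strict part plus half the ties) evaluated.
    """
    nd = np.asarray(diseased_joint, dtype=np.int64)
    nh = np.asarray(nondiseased_joint, dtype=np.int64)
    if nd.shape != nh.shape or nd.ndim != 2 or nd.shape[0] != nd.shape[1]:
        raise ValueError("joint tables must be square and of equal shape")
    k = nd.shape[0]
    rng = np.random.default_rng(seed)
    theta = draw(dirichlet_posterior(nd.ravel()), n_draws, rng).reshape(-1, k, k)
    phi = draw(dirichlet_posterior(nh.ravel()), n_draws, rng).reshape(-1, k, k)
    out: dict[str, Mapping[str, PosteriorSummary]] = {}
    for test, axis in (("test1", 2), ("test2", 1)):
        td = theta.sum(axis=axis)
        ph = phi.sum(axis=axis)
        a1, a2 = auc_from_category_probs(td, ph)
        out[test] = summarize_many(
            {"area": a1 + a2 / 2.0, "a1": a1, "a2": a2}, seed=seed
        )
    return out
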