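"""Empirical ROC points and Bayesian AUC for ordinal-score tests.

A k-category ordinal test is "positive at threshold c" when the score is at
least c.  Sweeping c over the categories traces the empirical ROC; with the
degenerate endpoints (1,1) (everything positive) and (0,0) appended, the
trapezoidal area under those points equals

    AUC = P(Y > X) + (1/2) P(Y = X)

where Y is the score of a random diseased subject and X of a random
non-diseased one.  With category probabilities ``theta`` (diseased) and
``phi`` (non-diseased) given independent Dirichlet posteriors (uniform
priors), the AUC per draw is the bilinear form

    AUC(theta, phi) = sum_{i>j} theta_i phi_j + (1/2) sum_i theta_i phi_i.

Because the form is bilinear and the posteriors independent, the posterior
mean of AUC is exactly the form evaluated at the posterior means — used here
as a closed-form oracle for the Monte Carlo estimate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .posterior_engine import (
    DEFAULT_DRAWS,
    DirichletPosterior,
    PosteriorSummary,
    dirichlet_posterior,
    draw,
    summarize_many,
)
from .tables_io import OrdinalCounts

__all__ = [
    "RocPoints",
    "AucResult",
    "empirical_roc_points",
    "auc_ordinal_posterior",
    "auc_ordinal_expectation",
    "auc_from_category_probs",
    "trapezoid_area",
]


@dataclass(frozen=True)
class RocPoints:
    """Empirical ROC points (threshold, fpf, tpf), highest threshold first.

    Includes the degenerate endpoints: threshold 1 gives (1, 1) and the
    never-positive rule gives (0, 0).
    """

    thresholds: tuple
    fpf: tuple
    tpf: tuple

    def as_curve(self) -> np.ndarray:
        """(fpf, tpf) pairs ordered left-to-right for plotting/trapezoids."""
        pts = sorted(zip(self.fpf, self.tpf))
        return np.array(pts)


@dataclass(frozen=True)
class AucResult:
    """Posterior summaries for AUC and its components A1 = P(Y>X), A2 = P(Y=X)."""

    summaries: Mapping[str, PosteriorSummary]
    n_draws: int
    seed: int

    def __getitem__(self, name: str) -> PosteriorSummary:
        return self.summaries[name]


def empirical_roc_points(counts: OrdinalCounts) -> RocPoints:
    """Observed (fpf, tpf) per threshold, 'positive' meaning score >= c."""
    d = np.asarray(counts.diseased, dtype=float)
    nd = np.asarray(counts.nondiseased, dtype=float)
    # cumulative from the top: fraction with score >= c
    tpf = np.cumsum(d[::-1])[::-1] / d.sum()
    fpf = np.cumsum(nd[::-1])[::-1] / nd.sum()
    thresholds = list(range(1, counts.k + 1)) + [counts.k + 1]
    return RocPoints(
        thresholds=tuple(thresholds),
        fpf=tuple(fpf) + (0.0,),
        tpf=tuple(tpf) + (0.0,),
    )


def trapezoid_area(points: RocPoints) -> float:
    """Trapezoidal area under the empirical ROC points."""
    curve = points.as_curve()
    return float(np.trapezoid(curve[:, 1], curve[:, 0]))


def auc_from_category_probs(theta: np.ndarray, phi: np.ndarray) -> tuple:
    """(A1, A2) for category-probability rows theta (diseased), phi (healthy).

    Vectorized over leading dimensions: theta and phi may be (k,) vectors or
    (n, k) draw matrices.
    """
    theta = np.atleast_2d(theta)
    phi = np.atleast_2d(phi)
    k = theta.shape[1]
    # cumulative P(X < i) per draw
    phi_below = np.concatenate(
        [np.zeros((phi.shape[0], 1)), np.cumsum(phi, axis=1)[:, :-1]], axis=1
    )
    a1 = (theta * phi_below).sum(axis=1)
    a2 = (theta * phi).sum(axis=1)
    if a1.size == 1:
        return float(a1[0]), float(a2[0])
    return a1, a2


def auc_ordinal_posterior(
    counts: OrdinalCounts,
    n_draws: int = DEFAULT_DRAWS,
    seed: int = 0,
) -> AucResult:
    """Monte Carlo posterior of the ordinal AUC under uniform priors."""
    rng = np.random.default_rng(seed)
    theta = draw(dirichlet_posterior(np.array(counts.diseased)), n_draws, rng)
    phi = draw(dirichlet_posterior(np.array(counts.nondiseased)), n_draws, rng)
    a1, a2 = auc_from_category_probs(theta, phi)
    draws = {"auc": a1 + a2 / 2.0, "a1": a1, "a2": a2}
    return AucResult(
        summaries=summarize_many(draws, seed=seed), n_draws=n_draws, seed=seed
    )


def auc_ordinal_expectation(
    theta_posterior: DirichletPosterior, phi_posterior: DirichletPosterior
) -> float:
    """Exact posterior mean of the ordinal AUC.

    Valid because AUC is bilinear in (theta, phi) and the two Dirichlet
    posteriors are independent, so expectations factor.
    """
    if theta_posterior.alpha.size != phi_posterior.alpha.size:
        raise ValueError("theta and phi must have the same number of categories")
    a1, a2 = auc_from_category_probs(theta_posterior.mean, phi_posterior.mean)
    return a1 + a2 / 2.0
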