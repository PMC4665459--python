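"""Latent-class Gibbs sampler for two binary tests without a gold standard.

When no gold standard exists, the accuracy of a new test T is often reported
relative to an imperfect reference R, which is misleading: both the apparent
sensitivity and specificity of T are distorted by the reference's own errors.
The latent-class model instead treats the true disease status D of every
subject as missing data.  Assuming T and R are conditionally independent
given D, the complete-data likelihood for prevalence ``p``, the new test's
sensitivity/specificity ``s1``/``c1`` and the reference's ``s2``/``c2`` is a
product of Bernoulli terms in which the latent per-cell diseased counts
``y[r][t]`` (out of the observed cross-tab counts ``n[r][t]``, first index R,
second index T) appear as exponents.  All full conditionals are standard:

* each ``y[r][t] | rest ~ Binomial(n[r][t], m[r][t])`` where ``m[r][t]`` is
  the conditional probability that a subject in that cell is diseased;
* ``p | rest ~ Beta(y.. + a_p, n.. - y.. + b_p)`` and similarly conjugate
  Beta conditionals for s1, s2, c1, c2, whose counts are read off the cells
  in which each parameter appears (e.g. s1's successes are the diseased
  subjects with T=1: cells (1,1) and (0,1)).

Uniform priors correspond to all hyperparameters equal to one; informative
Beta priors simply replace them.  With only two tests and uniform priors the
model is not identified: the likelihood is invariant under the relabeling
``(p, s1, s2, c1, c2) -> (1-p, 1-c1, 1-c2, 1-s1, 1-s2)``, so the posterior is
bimodal and informative priors (or a constraint) are needed for a usable
answer.  ``log_likelihood`` exposes the observed-data likelihood so this
symmetry can be checked directly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.special import logsumexp

from .posterior_engine import PosteriorSummary, summarize_many
from .tables_io import NoGoldCrossTab

__all__ = [
    "LatentClassPriors",
    "LatentClassFit",
    "UNIFORM_PRIORS",
    "cell_assignment_probs",
    "gibbs_no_gold",
    "observed_vs_reference",
    "log_likelihood",
]

DEFAULT_ITER = 125_000
DEFAULT_BURNIN = 10_000

PARAMS = ("p", "s1", "s2", "c1", "c2")


@dataclass(frozen=True)
class LatentClassPriors:
    """Beta(alpha, beta) hyperparameters for each model parameter."""

    p: tuple = (1.0, 1.0)
    s1: tuple = (1.0, 1.0)
    s2: tuple = (1.0, 1.0)
    c1: tuple = (1.0, 1.0)
    c2: tuple = (1.0, 1.0)

    def __post_init__(self) -> None:
        for name in PARAMS:
            a, b = getattr(self, name)
            if a <= 0 or b <= 0:
                raise ValueError(f"prior for {name} must have positive hyperparameters")


UNIFORM_PRIORS = LatentClassPriors()


@dataclass(frozen=True)
class LatentClassFit:
    summaries: Mapping[str, PosteriorSummary]
    draws: Mapping[str, np.ndarray]
    n_iter: int
    burnin: int
    seed: int

    def __getitem__(self, name: str) -> PosteriorSummary:
        return self.summaries[name]


def cell_assignment_probs(
    p: float, s1: float, s2: float, c1: float, c2: float
) -> np.ndarray:
    """P(diseased | cell) for the four (R, T) cells, as a 2x2 array.

    ``m[r][t]`` is the probability that a subject with reference result r and
    new-test result t is diseased, given the parameters.  For example both
    tests positive gives ``m[1][1] = p s1 s2 / (p s1 s2 + (1-p)(1-c1)(1-c2))``.
    """
    for name, v in zip(("p", "s1", "s2", "c1", "c2"), (p, s1, s2, c1, c2)):
        if not (0.0 < v < 1.0):
            raise ValueError(f"{name} must lie strictly in (0, 1)")
    q = 1.0 - p
    # diseased / non-diseased likelihood of each (R, T) cell; T terms use
    # (s1, c1), R terms use (s2, c2)
    like_d = np.array(
        [
            [(1 - s2) * (1 - s1), (1 - s2) * s1],
            [s2 * (1 - s1), s2 * s1],
        ]
    )
    like_h = np.array(
        [
            [c2 * c1, c2 * (1 - c1)],
            [(1 - c2) * c1, (1 - c2) * (1 - c1)],
        ]
    )
    denom = p * like_d + q * like_h
    if np.any(denom <= 0):
        raise ValueError("degenerate cell with zero probability under both classes")
    return p * like_d / denom


def gibbs_no_gold(
    counts: NoGoldCrossTab,
    priors: LatentClassPriors = UNIFORM_PRIORS,
    n_iter: int = DEFAULT_ITER,
    burnin: int = DEFAULT_BURNIN,
    seed: int = 0,
) -> LatentClassFit:
    """Gibbs sampler for (p, s1, s2, c1, c2) from an R-by-T cross-tab."""
    if n_iter <= burnin or burnin < 0:
        raise ValueError("need n_iter > burnin >= 0")
    n = np.asarray(counts.n, dtype=np.int64)
    n_tot = int(n.sum())
    rng = np.random.default_rng(seed)

    ap, bp = priors.p
    as1, bs1 = priors.s1
    as2, bs2 = priors.s2
    ac1, bc1 = priors.c1
    ac2, bc2 = priors.c2

    kept = n_iter - burnin
    out = {k: np.empty(kept) for k in PARAMS}

    # initialize parameters at their prior means (clipped into (0,1))
    eps = 1e-6
    p = np.clip(ap / (ap + bp), eps, 1 - eps)
    s1 = np.clip(as1 / (as1 + bs1), eps, 1 - eps)
    s2 = np.clip(as2 / (as2 + bs2), eps, 1 - eps)
    c1 = np.clip(ac1 / (ac1 + bc1), eps, 1 - eps)
    c2 = np.clip(ac2 / (ac2 + bc2), eps, 1 - eps)

    for it in range(n_iter):
        # --- latent diseased counts per cell -------------------------------
        m = cell_assignment_probs(p, s1, s2, c1, c2)
        y = rng.binomial(n, m)
        y_tot = y.sum()
        # cell sums entering each conditional: T=1 column is (·,1), R=1 row (1,·)
        y_tpos = y[0, 1] + y[1, 1]
        y_tneg = y[0, 0] + y[1, 0]
        y_rpos = y[1, 0] + y[1, 1]
        y_rneg = y[0, 0] + y[0, 1]
        n_tpos = n[0, 1] + n[1, 1]
        n_tneg = n[0, 0] + n[1, 0]
        n_rpos = n[1, 0] + n[1, 1]
        n_rneg = n[0, 0] + n[0, 1]

        # --- conjugate Beta conditionals -----------------------------------
        p = rng.beta(y_tot + ap, n_tot - y_tot + bp)
        s1 = rng.beta(y_tpos + as1, y_tneg + bs1)
        s2 = rng.beta(y_rpos + as2, y_rneg + bs2)
        c1 = rng.beta(n_tneg - y_tneg + ac1, n_tpos - y_tpos + bc1)
        c2 = rng.beta(n_rneg - y_rneg + ac2, n_rpos - y_rpos + bc2)
        p = min(max(p, eps), 1 - eps)
        s1 = min(max(s1, eps), 1 - eps)
        s2 = min(max(s2, eps), 1 - eps)
        c1 = min(max(c1, eps), 1 - eps)
        c2 = min(max(c2, eps), 1 - eps)

        if it >= burnin:
            j = it - burnin
            out["p"][j] = p
            out["s1"][j] = s1
            out["s2"][j] = s2
            out["c1"][j] = c1
            out["c2"][j] = c2

    return LatentClassFit(
        summaries=summarize_many(out, seed=seed),
        draws=out,
        n_iter=n_iter,
        burnin=burnin,
        seed=seed,
    )


def observed_vs_reference(counts: NoGoldCrossTab) -> tuple[float, float]:
    """Apparent (sensitivity, specificity) of T taking R as if it were gold."""
    n = np.asarray(counts.n)
    if n[1].sum() == 0 or n[0].sum() == 0:
        raise ValueError("both reference strata must be non-empty")
    sens = n[1, 1] / n[1].sum()
    spec = n[0, 0] / n[0].sum()
    return float(sens), float(spec)


def log_likelihood(
    counts: NoGoldCrossTab, p: float, s1: float, s2: float, c1: float, c2: float
) -> float:
    """Observed-data log-likelihood (latent counts marginalized out)."""
    n = np.asarray(counts.n, dtype=float)
    like_d = np.array(
        [[(1 - s2) * (1 - s1), (1 - s2) * s1], [s2 * (1 - s1), s2 * s1]]
    )
    like_h = np.array([[c2 * c1, c2 * (1 - c1)], [(1 - c2) * c1, (1 - c2) * (1 - c1)]])
    cell = p * like_d + (1 - p) * like_h
    if np.any(cell[n > 0] <= 0):
        return -np.inf
    with np.errstate(divide="ignore"):
        return float(np.sum(n * np.where(n > 0, np.log(cell), 0.0)))


def brute_force_prevalence_posterior(
    counts: NoGoldCrossTab,
    s1: float,
    s2: float,
    c1: float,
    c2: float,
    prior: tuple = (1.0, 1.0),
) -> float:
    """Exact posterior mean of p with the accuracy parameters held fixed.

    Enumerates every latent configuration (feasible only for tiny tables) and
    mixes the conjugate Beta(y.. + a, n.. - y.. + b) means with the exact
    configuration weights.  Serves as a small-instance oracle for the Gibbs
    sampler.
    """
    from itertools import product
    from scipy.special import betaln, gammaln

    n = np.asarray(counts.n, dtype=np.int64)
    a, b = prior
    like_d = np.array(
        [[(1 - s2) * (1 - s1), (1 - s2) * s1], [s2 * (1 - s1), s2 * s1]]
    ).ravel()
    like_h = np.array(
        [[c2 * c1, c2 * (1 - c1)], [(1 - c2) * c1, (1 - c2) * (1 - c1)]]
    ).ravel()
    flat = n.ravel()
    n_tot = int(flat.sum())
    log_w = []
    means = []
    for ys in product(*(range(v + 1) for v in flat)):
        y = np.array(ys)
        lw = 0.0
        for yi, ni, ld, lh in zip(y, flat, like_d, like_h):
            lw += (
                gammaln(ni + 1)
                - gammaln(yi + 1)
                - gammaln(ni - yi + 1)
                + yi * np.log(ld)
                + (ni - yi) * np.log(lh)
            )
        y_tot = int(y.sum())
        # integrate p out of the complete-data likelihood
        lw += betaln(y_tot + a, n_tot - y_tot + b) - betaln(a, b)
        log_w.append(lw)
        means.append((y_tot + a) / (n_tot + a + b))
    log_w = np.asarray(log_w)
    w = np.exp(log_w - logsumexp(log_w))
    return float(np.dot(w, means))
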