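"""Bias-corrected accuracy when disease verification is incomplete.

In many accuracy studies only a subset of subjects — typically those testing
positive — are referred to the gold standard, so naive accuracy estimates
computed from the verified subjects alone are biased (both TPF and FPF are
inflated when positives are preferentially verified).  Under the
missing-at-random (MAR) assumption that verification depends only on the
observed test result,

    P[V=1 | D, Y] = P[V=1 | Y],

the likelihood factors into the disease-given-result probabilities
``phi_i = P[D=1 | Y=i]`` (estimated from the verified subjects in category i)
and the result margins ``theta_i = P[Y=i]`` (estimated from everybody,
verified or not).  With uniform priors,

    phi_i | data ~ Beta(s_i + 1, r_i + 1)
    theta | data ~ Dir(m_1 + 1, ..., m_k + 1)

and Bayes' theorem converts each joint draw into the result-given-disease
fractions

    alpha_i = P[Y=i | D=1] = phi_i theta_i / P[D=1]
    beta_i  = P[Y=i | D=0] = (1 - phi_i) theta_i / P[D=0]

with ``P[D=1] = sum_i phi_i theta_i``.  For a binary test ``alpha_1`` is the
corrected TPF and ``beta_1`` the corrected FPF; for an ordinal test the
corrected ROC area is ``A = A1 + A2/2`` with ``A1 = sum_{i>j} alpha_i beta_j``
and ``A2 = sum_i alpha_i beta_i``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .ordinal_roc import auc_from_category_probs
from .posterior_engine import (
    DEFAULT_DRAWS,
    PosteriorSummary,
    dirichlet_posterior,
    draw,
    summarize_many,
)
from .tables_io import VerificationCounts

__all__ = [
    "CorrectedBinaryResult",
    "CorrectedOrdinalResult",
    "naive_estimates",
    "corrected_binary",
    "corrected_ordinal_auc",
    "corrected_fraction_draws",
]


@dataclass(frozen=True)
class CorrectedBinaryResult:
    """Posterior summaries of MAR-corrected TPF and FPF for a binary test."""

    summaries: Mapping[str, PosteriorSummary]
    n_draws: int
    seed: int

    def __getitem__(self, name: str) -> PosteriorSummary:
        return self.summaries[name]


@dataclass(frozen=True)
class CorrectedOrdinalResult:
    """Posterior summaries of the MAR-corrected ordinal ROC area.

    ``a`` is the area, ``a1`` the strict-inequality part P(Y_D > Y_H), and
    ``half_a2`` half the tie probability (so ``a = a1 + half_a2``, matching
    the conventional result-table layout); the full tie probability is
    reported as ``a2_full``.
    """

    summaries: Mapping[str, PosteriorSummary]
    n_draws: int
    seed: int

    def __getitem__(self, name: str) -> PosteriorSummary:
        return self.summaries[name]


def naive_estimates(v: VerificationCounts) -> tuple[float, float]:
    """Observed (sensitivity, fpf) among verified subjects of a binary test.

    These are the biased point estimates the correction exists to fix; under
    preferential verification of positives both are too large.
    """
    if v.k != 2:
        raise ValueError("naive_estimates applies to binary tests (k=2)")
    s0, s1 = v.s  # index 0 = Y=0, index 1 = Y=1
    r0, r1 = v.r
    if s0 + s1 == 0 or r0 + r1 == 0:
        raise ValueError("need verified subjects in both disease classes")
    return s1 / (s1 + s0), r1 / (r1 + r0)


def corrected_fraction_draws(
    v: VerificationCounts,
    n_draws: int = DEFAULT_DRAWS,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Joint posterior draws of alpha_i, beta_i, and P[D=1] under MAR.

    Returns (n_draws, k) matrices ``alpha`` and ``beta`` plus the vector
    ``prevalence``; per draw the rows of alpha and beta each sum to one.
    """
    rng = np.random.default_rng(seed)
    s = np.asarray(v.s)
    r = np.asarray(v.r)
    m = np.asarray(v.m)
    # phi_i ~ Beta(s_i+1, r_i+1) independently; theta ~ Dir(m+1)
    phi = rng.beta(s + 1.0, r + 1.0, size=(n_draws, v.k))
    theta = draw(dirichlet_posterior(m), n_draws, rng)
    joint = phi * theta
    prev = joint.sum(axis=1)
    alpha = joint / prev[:, None]
    beta = (1.0 - phi) * theta / (1.0 - prev)[:, None]
    return {"alpha": alpha, "beta": beta, "prevalence": prev}


def corrected_binary(
    v: VerificationCounts,
    n_draws: int = DEFAULT_DRAWS,
    seed: int = 0,
) -> CorrectedBinaryResult:
    """MAR-corrected posterior of TPF and FPF for a binary test."""
    if v.k != 2:
        raise ValueError("corrected_binary applies to binary tests (k=2)")
    fr = corrected_fraction_draws(v, n_draws=n_draws, seed=seed)
    draws = {
        "tpf": fr["alpha"][:, 1],  # alpha_1: category index 1 is Y=1
        "fpf": fr["beta"][:, 1],
        "prevalence": fr["prevalence"],
    }
    return CorrectedBinaryResult(
        summaries=summarize_many(draws, seed=seed), n_draws=n_draws, seed=seed
    )


def corrected_ordinal_auc(
    v: VerificationCounts,
    n_draws: int = DEFAULT_DRAWS,
    seed: int = 0,
) -> CorrectedOrdinalResult:
    """MAR-corrected posterior of the ordinal ROC area."""
    fr = corrected_fraction_draws(v, n_draws=n_draws, seed=seed)
    a1, a2 = auc_from_category_probs(fr["alpha"], fr["beta"])
    draws = {
        "a": a1 + a2 / 2.0,
        "a1": a1,
        "half_a2": a2 / 2.0,
        "a2_full": a2,
        "prevalence": fr["prevalence"],
    }
    return CorrectedOrdinalResult(
        summaries=summarize_many(draws, seed=seed), n_draws=n_draws, seed=seed
    )
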