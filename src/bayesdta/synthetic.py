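"""Synthetic-data generators matching each model's assumed structure.

Each generator samples from exactly the probability model its downstream
analysis assumes (multinomial cells, MAR verification, conditional
independence given a latent class, binormal scores, a logistic risk model),
so parameter-recovery and coverage tests can be run without external data.
All generators are deterministic given a seed and return the same container
types the readers produce.
"""

from __future__ import annotations

import numpy as np

from .tables_io import (
    CountTable2x2,
    NoGoldCrossTab,
    OrdinalCounts,
    PairedBinaryCounts,
    ScoreSet,
    VerificationCounts,
)

__all__ = [
    "gen_binary",
    "gen_verified",
    "gen_no_gold",
    "gen_paired_binary",
    "gen_ordinal",
    "gen_ordinal_joint",
    "gen_scores",
    "gen_logistic_subjects",
]


def _check_prob(value, name: str) -> None:
    arr = np.atleast_1d(np.asarray(value, dtype=float))
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValueError(f"{name} must lie in [0, 1]")


def gen_binary(
    tpf: float, fpf: float, prevalence: float, n: int, seed: int = 0
) -> CountTable2x2:
    """Sample a (test, disease) 2x2 table: D ~ Bern(prevalence), X | D."""
    for v, name in ((tpf, "tpf"), (fpf, "fpf"), (prevalence, "prevalence")):
        _check_prob(v, name)
    if n < 1:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    # cell probabilities in the (n00, n01, n10, n11) order
    probs = np.array(
        [
            (1 - prevalence) * (1 - fpf),
            prevalence * (1 - tpf),
            (1 - prevalence) * fpf,
            prevalence * tpf,
        ]
    )
    counts = rng.multinomial(n, probs)
    return CountTable2x2(*counts)


def gen_verified(
    tpf: float,
    fpf: float,
    prevalence: float,
    verify_probs: tuple,
    n: int,
    seed: int = 0,
) -> VerificationCounts:
    """Sample a binary-test verification study under MAR.

    ``verify_probs = (v0, v1)`` are the verification probabilities given a
    negative / positive test result; verification never looks at D, which is
    exactly the MAR mechanism the corrected estimator assumes.
    """
    for v, name in (
        (tpf, "tpf"),
        (fpf, "fpf"),
        (prevalence, "prevalence"),
        (verify_probs, "verify_probs"),
    ):
        _check_prob(v, name)
    rng = np.random.default_rng(seed)
    d = rng.random(n) < prevalence
    y = np.where(d, rng.random(n) < tpf, rng.random(n) < fpf).astype(int)
    v = rng.random(n) < np.asarray(verify_probs, dtype=float)[y]
    s = [int(np.sum(v & d & (y == i))) for i in (0, 1)]
    r = [int(np.sum(v & ~d & (y == i))) for i in (0, 1)]
    u = [int(np.sum(~v & (y == i))) for i in (0, 1)]
    return VerificationCounts(s=tuple(s), r=tuple(r), u=tuple(u))


def gen_no_gold(
    p: float, s1: float, s2: float, c1: float, c2: float, n: int, seed: int = 0
) -> NoGoldCrossTab:
    """Sample an R-by-T cross-tab with latent D and conditional independence.

    T has sensitivity ``s1`` / specificity ``c1``; the reference R has
    ``s2`` / ``c2``; only the cross-tab (no disease labels) is returned.
    """
    for v, name in ((p, "p"), (s1, "s1"), (s2, "s2"), (c1, "c1"), (c2, "c2")):
        _check_prob(v, name)
    rng = np.random.default_rng(seed)
    d = rng.random(n) < p
    t = np.where(d, rng.random(n) < s1, rng.random(n) >= c1).astype(int)
    r = np.where(d, rng.random(n) < s2, rng.random(n) >= c2).astype(int)
    cells = [[int(np.sum((r == i) & (t == j))) for j in (0, 1)] for i in (0, 1)]
    return NoGoldCrossTab(n=tuple(tuple(row) for row in cells))


def gen_paired_binary(
    diseased_probs, nondiseased_probs, n_diseased: int, n_nondiseased: int, seed: int = 0
) -> PairedBinaryCounts:
    """Sample paired binary tests from per-class cell probabilities.

    Probabilities are given in the (00, 01, 10, 11) cell order with first
    index test 1; each vector must sum to one.
    """
    rng = np.random.default_rng(seed)
    out = []
    for probs, n in ((diseased_probs, n_diseased), (nondiseased_probs, n_nondiseased)):
        probs = np.asarray(probs, dtype=float)
        if probs.size != 4 or not np.isclose(probs.sum(), 1.0) or np.any(probs < 0):
            raise ValueError("cell probabilities must be a length-4 simplex vector")
        out.append(tuple(int(v) for v in rng.multinomial(n, probs)))
    return PairedBinaryCounts(diseased=out[0], nondiseased=out[1])


def gen_ordinal(
    diseased_probs, nondiseased_probs, n_diseased: int, n_nondiseased: int, seed: int = 0
) -> OrdinalCounts:
    """Sample per-category ordinal counts for each disease class."""
    rng = np.random.default_rng(seed)
    groups = []
    for probs, n in ((diseased_probs, n_diseased), (nondiseased_probs, n_nondiseased)):
        probs = np.asarray(probs, dtype=float)
        if not np.isclose(probs.sum(), 1.0) or np.any(probs < 0):
            raise ValueError("category probabilities must form a simplex vector")
        groups.append(tuple(int(v) for v in rng.multinomial(n, probs)))
    return OrdinalCounts(diseased=groups[0], nondiseased=groups[1])


def gen_ordinal_joint(
    diseased_joint, nondiseased_joint, n_diseased: int, n_nondiseased: int, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Sample paired k-by-k ordinal joint count tables per disease class."""
    rng = np.random.default_rng(seed)
    out = []
    for probs, n in ((diseased_joint, n_diseased), (nondiseased_joint, n_nondiseased)):
        probs = np.asarray(probs, dtype=float)
        if probs.ndim != 2 or probs.shape[0] != probs.shape[1]:
            raise ValueError("joint probabilities must be a square matrix")
        if not np.isclose(probs.sum(), 1.0) or np.any(probs < 0):
            raise ValueError("joint probabilities must sum to one")
        out.append(rng.multinomial(n, probs.ravel()).reshape(probs.shape))
    return out[0], out[1]


def gen_scores(
    mu_diseased: float,
    sd_diseased: float,
    mu_nondiseased: float,
    sd_nondiseased: float,
    n_diseased: int,
    n_nondiseased: int,
    seed: int = 0,
) -> ScoreSet:
    """Sample binormal scores: one normal per disease class."""
    if sd_diseased <= 0 or sd_nondiseased <= 0:
        raise ValueError("standard deviations must be positive")
    rng = np.random.default_rng(seed)
    yd = rng.normal(mu_diseased, sd_diseased, n_diseased)
    yh = rng.normal(mu_nondiseased, sd_nondiseased, n_nondiseased)
    return ScoreSet(
        values=np.concatenate([yd, yh]),
        labels=np.concatenate([np.ones(n_diseased, int), np.zeros(n_nondiseased, int)]),
    )


def gen_logistic_subjects(
    coefs, predictor_sampler=None, n: int = 1000, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Sample (predictors, labels) from a logistic disease model.

    ``coefs = (intercept, b2, b3, ...)``; by default each predictor is an
    independent standard normal, or pass ``predictor_sampler(rng, n)``
    returning an (n, p) matrix (e.g. ordinal scores).
    """
    coefs = np.asarray(coefs, dtype=float)
    p = coefs.size - 1
    if p < 1:
        raise ValueError("need an intercept and at least one predictor")
    rng = np.random.default_rng(seed)
    x = (
        predictor_sampler(rng, n)
        if predictor_sampler is not None
        else rng.standard_normal((n, p))
    )
    eta = coefs[0] + x @ coefs[1:]
    prob = 1.0 / (1.0 + np.exp(-eta))
    d = (rng.random(n) < prob).astype(int)
    return x, d
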