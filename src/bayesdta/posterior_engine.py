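"""Conjugate posteriors, Monte Carlo draws, and posterior summaries.

Every model in this package reduces, at least in part, to Dirichlet or Beta
posteriors obtained by conjugate updating of multinomial/binomial counts under
a (by default uniform) Dirichlet/Beta prior.  This module holds the shared
machinery: posterior construction, reproducible i.i.d. sampling, the
``PosteriorSummary`` record that mirrors the standard MCMC output table
(mean, sd, Monte Carlo error, 2.5% / median / 97.5% quantiles), and an exact
Beta aggregation identity used as a closed-form oracle in tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "DirichletPosterior",
    "BetaPosterior",
    "PosteriorSummary",
    "dirichlet_posterior",
    "beta_posterior",
    "draw",
    "summarize",
    "summarize_many",
    "beta_margin",
    "summary_frame",
    "DEFAULT_DRAWS",
    "MC_BATCHES",
]

#: Default number of i.i.d. posterior draws for the conjugate analyses.
DEFAULT_DRAWS = 55_000

#: Number of batches for the batch-means Monte Carlo error estimate.
MC_BATCHES = 50


@dataclass(frozen=True)
class DirichletPosterior:
    """Dirichlet distribution with concentration vector ``alpha``."""

    alpha: np.ndarray

    def __post_init__(self) -> None:
        alpha = np.asarray(self.alpha, dtype=float)
        if alpha.ndim != 1 or alpha.size < 2:
            raise ValueError("alpha must be a vector of length >= 2")
        if not np.all(alpha > 0):
            raise ValueError("all Dirichlet parameters must be positive")
        object.__setattr__(self, "alpha", alpha)

    @property
    def mean(self) -> np.ndarray:
        return self.alpha / self.alpha.sum()


@dataclass(frozen=True)
class BetaPosterior:
    """Beta distribution with shape parameters ``a`` and ``b``."""

    a: float
    b: float

    def __post_init__(self) -> None:
        # b == 0 is allowed as the degenerate point mass at 1 (it arises from
        # beta_margin when numerator == denominator).
        if self.a <= 0 or self.b < 0:
            raise ValueError("Beta parameters must be positive")

    @property
    def mean(self) -> float:
        return self.a / (self.a + self.b)


@dataclass(frozen=True)
class PosteriorSummary:
    """Posterior summary mirroring the usual MCMC output table columns."""

    mean: float
    sd: float
    mc_error: float
    q025: float
    median: float
    q975: float
    n_draws: int
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (self.q025 <= self.median <= self.q975):
            raise ValueError("quantiles out of order")
        if self.sd < 0 or self.mc_error < 0:
            raise ValueError("sd and mc_error must be non-negative")

    def as_dict(self) -> dict:
        return {
            "mean": self.mean,
            "sd": self.sd,
            "mc_error": self.mc_error,
            "q025": self.q025,
            "median": self.median,
            "q975": self.q975,
            "n_draws": self.n_draws,
        }


def dirichlet_posterior(
    counts: Sequence[int], prior: Sequence[float] | None = None
) -> DirichletPosterior:
    """Conjugate Dirichlet posterior for multinomial counts.

    With a uniform prior (the default, ``prior=None`` meaning all ones) the
    posterior concentration is simply ``counts + 1`` component-wise.
    """
    counts = np.asarray(counts)
    if counts.ndim != 1:
        raise ValueError("counts must be a vector")
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    if prior is None:
        prior = np.ones_like(counts, dtype=float)
    prior = np.asarray(prior, dtype=float)
    if prior.shape != counts.shape:
        raise ValueError("prior and counts must have the same length")
    if not np.all(prior > 0):
        raise ValueError("prior parameters must be positive")
    return DirichletPosterior(counts + prior)


def beta_posterior(
    successes: int, failures: int, prior: tuple[float, float] = (1.0, 1.0)
) -> BetaPosterior:
    """Conjugate Beta posterior for binomial data (uniform prior by default)."""
    if successes < 0 or failures < 0:
        raise ValueError("counts must be non-negative")
    a0, b0 = prior
    return BetaPosterior(successes + a0, failures + b0)


Posterior = Union[DirichletPosterior, BetaPosterior]


def draw(
    posterior: Posterior,
    n_draws: int = DEFAULT_DRAWS,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Generate i.i.d. samples from a conjugate posterior.

    Returns an ``(n_draws, m)`` matrix for a Dirichlet and an ``(n_draws,)``
    vector for a Beta.  Identical ``seed`` gives bit-identical output.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be at least 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if isinstance(posterior, DirichletPosterior):
        return rng.dirichlet(posterior.alpha, size=n_draws)
    if isinstance(posterior, BetaPosterior):
        if posterior.b == 0:
            return np.ones(n_draws)
        return rng.beta(posterior.a, posterior.b, size=n_draws)
    raise TypeError(f"unsupported posterior type: {type(posterior).__name__}")


def _batch_means_error(x: np.ndarray, n_batches: int = MC_BATCHES) -> float:
    n = x.size
    if n < n_batches:
        n_batches = max(1, n // 2)
    if n_batches < 2:
        return 0.0
    usable = n - (n % n_batches)
    means = x[:usable].reshape(n_batches, -1).mean(axis=1)
    return float(means.std(ddof=1) / np.sqrt(n_batches))


def summarize(draws: np.ndarray, seed: int | None = None) -> PosteriorSummary:
    """Summarize a vector of posterior draws.

    Mean and sd are sample moments, quantiles are empirical order statistics
    with linear interpolation, and the Monte Carlo error is estimated by batch
    means with ``MC_BATCHES`` batches.
    """
    x = np.asarray(draws, dtype=float).ravel()
    if x.size < 100:
        raise ValueError("need at least 100 draws to summarize")
    q025, median, q975 = np.quantile(x, [0.025, 0.5, 0.975])
    return PosteriorSummary(
        mean=float(x.mean()),
        sd=float(x.std(ddof=1)),
        mc_error=_batch_means_error(x),
        q025=float(q025),
        median=float(median),
        q975=float(q975),
        n_draws=int(x.size),
        seed=seed,
    )


def summarize_many(
    draws: Mapping[str, np.ndarray], seed: int | None = None
) -> dict[str, PosteriorSummary]:
    return {name: summarize(x, seed=seed) for name, x in draws.items()}


def beta_margin(
    posterior: DirichletPosterior,
    numerator: Iterable[int],
    denominator: Iterable[int],
) -> BetaPosterior:
    """Exact Beta law of a sub-sum ratio of Dirichlet components.

    If ``theta ~ Dir(alpha)`` and ``A`` is a subset of ``B`` then
    ``sum(theta[A]) / sum(theta[B]) ~ Beta(sum(alpha[A]), sum(alpha[B\\A]))``
    by the aggregation property of the Dirichlet.  Measures such as TPF, FPF,
    PPV and NPV are all of this form, so this gives their posteriors (and in
    particular exact means) in closed form — used as the test oracle for the
    Monte Carlo route.
    """
    num = frozenset(numerator)
    den = frozenset(denominator)
    if not num or not den:
        raise ValueError("index sets must be non-empty")
    if not num <= den:
        raise ValueError("numerator must be a subset of denominator")
    alpha = posterior.alpha
    if max(den) >= alpha.size or min(den) < 0:
        raise ValueError("index out of range")
    a = float(alpha[list(num)].sum())
    rest = den - num
    b = float(alpha[list(rest)].sum()) if rest else 0.0
    return BetaPosterior(a, b)


def summary_frame(summaries: Mapping[str, PosteriorSummary]) -> pd.DataFrame:
    """Tabulate summaries with the conventional result-table columns."""
    rows = {name: s.as_dict() for name, s in summaries.items()}
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "parameter"
    return frame
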