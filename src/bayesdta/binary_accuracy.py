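"""Posterior accuracy measures for one binary test, and paired comparisons.

For a single binary test cross-classified with a gold standard, the cell
probabilities ``theta = (theta00, theta01, theta10, theta11)`` of the
(test, disease) table get a conjugate Dirichlet posterior ``Dir(counts + 1)``
under a uniform prior.  Every accuracy measure is a function of ``theta``:

* ``TPF  = theta11 / (theta11 + theta01)`` — sensitivity, P(X=1 | D=1)
* ``FPF  = theta10 / (theta00 + theta10)`` — 1 - specificity, P(X=1 | D=0)
* ``PPV  = theta11 / (theta10 + theta11)`` — P(D=1 | X=1)
* ``NPV  = theta00 / (theta00 + theta01)`` — P(D=0 | X=0)
* ``PDLR = TPF / FPF`` and ``NDLR = FNF / TNF`` — diagnostic likelihood
  ratios, with ``FNF = 1 - TPF`` and ``TNF = 1 - FPF``.

Posterior summaries are Monte Carlo: each measure is evaluated on i.i.d.
Dirichlet draws and summarized.  For the sub-sum-ratio measures (TPF, FPF,
PPV, NPV) the exact posterior is also available in closed form via
``posterior_engine.beta_margin``, which the test-suite uses as an oracle.

For two binary tests applied to the same subjects, the diseased and
non-diseased (test1, test2) cell probabilities get independent Dirichlet
posteriors; each modality's TPF (FPF) is its positive-margin sum among the
diseased (non-diseased) cells, and modalities are compared through per-draw
ratios of those fractions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .posterior_engine import (
    DEFAULT_DRAWS,
    PosteriorSummary,
    dirichlet_posterior,
    draw,
    summarize_many,
)
from .tables_io import CountTable2x2, PairedBinaryCounts

__all__ = ["AccuracyResult", "PairedComparisonResult", "basic_measures", "compare_paired"]

# Cell order used throughout: (n00, n01, n10, n11) with indices (test, disease).
_I00, _I01, _I10, _I11 = range(4)

# Probability-zero events under a Dirichlet have measure zero, but guard
# ratios against numerical underflow anyway.
_FLOOR = 1e-300


@dataclass(frozen=True)
class AccuracyResult:
    """Posterior summaries for the eight accuracy measures of one test."""

    summaries: Mapping[str, PosteriorSummary]
    n_draws: int
    seed: int

    MEASURES = ("tpf", "fpf", "fnf", "tnf", "ppv", "npv", "pdlr", "ndlr")

    def __getitem__(self, measure: str) -> PosteriorSummary:
        return self.summaries[measure]


@dataclass(frozen=True)
class PairedComparisonResult:
    """Posterior summaries for two modalities and their TPF/FPF ratios."""

    summaries: Mapping[str, PosteriorSummary]
    n_draws: int
    seed: int

    MEASURES = ("tpf1", "tpf2", "fpf1", "fpf2", "rtpf", "rfpf")

    def __getitem__(self, measure: str) -> PosteriorSummary:
        return self.summaries[measure]


def measure_draws(theta: np.ndarray) -> dict[str, np.ndarray]:
    """Evaluate all accuracy measures on an (n, 4) matrix of cell draws."""
    t00, t01, t10, t11 = (theta[:, i] for i in range(4))
    tpf = t11 / np.maximum(t11 + t01, _FLOOR)
    fpf = t10 / np.maximum(t00 + t10, _FLOOR)
    fnf = 1.0 - tpf
    tnf = 1.0 - fpf
    # PPV is P(D=1 | X=1): positive-test cells in the denominator.
    ppv = t11 / np.maximum(t10 + t11, _FLOOR)
    npv = t00 / np.maximum(t00 + t01, _FLOOR)
    pdlr = tpf / np.maximum(fpf, _FLOOR)
    ndlr = fnf / np.maximum(tnf, _FLOOR)
    return {
        "tpf": tpf,
        "fpf": fpf,
        "fnf": fnf,
        "tnf": tnf,
        "ppv": ppv,
        "npv": npv,
        "pdlr": pdlr,
        "ndlr": ndlr,
    }


def basic_measures(
    table: CountTable2x2,
    n_draws: int = DEFAULT_DRAWS,
    seed: int = 0,
    prior: np.ndarray | None = None,
) -> AccuracyResult:
    """Posterior summaries of TPF, FPF, PPV, NPV, PDLR, NDLR (and FNF, TNF)."""
    post = dirichlet_posterior(table.counts, prior=prior)
    theta = draw(post, n_draws=n_draws, seed=seed)
    draws = measure_draws(theta)
    return AccuracyResult(
        summaries=summarize_many(draws, seed=seed), n_draws=n_draws, seed=seed
    )


def paired_fraction_draws(
    tables: PairedBinaryCounts,
    n_draws: int = DEFAULT_DRAWS,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Per-draw TPF/FPF of each modality from independent Dirichlet posteriors.

    Cells are ordered (00, 01, 10, 11) with first index test1, so test1's
    positive margin is cells {10, 11} and test2's is {01, 11}.
    """
    rng = np.random.default_rng(seed)
    theta = draw(dirichlet_posterior(np.array(tables.diseased)), n_draws, rng)
    phi = draw(dirichlet_posterior(np.array(tables.nondiseased)), n_draws, rng)
    return {
        "tpf1": theta[:, _I10] + theta[:, _I11],
        "tpf2": theta[:, _I01] + theta[:, _I11],
        "fpf1": phi[:, _I10] + phi[:, _I11],
        "fpf2": phi[:, _I01] + phi[:, _I11],
        "theta": theta,
        "phi": phi,
    }


def compare_paired(
    tables: PairedBinaryCounts,
    n_draws: int = DEFAULT_DRAWS,
    seed: int = 0,
) -> PairedComparisonResult:
    """Compare two binary modalities on the same subjects.

    The ratio summaries are means of per-draw ratios ``TPF1/TPF2`` and
    ``FPF1/FPF2`` (not ratios of means), which is how the joint posterior
    propagates into the comparison.
    """
    fr = paired_fraction_draws(tables, n_draws=n_draws, seed=seed)
    draws = {
        "tpf1": fr["tpf1"],
        "tpf2": fr["tpf2"],
        "fpf1": fr["fpf1"],
        "fpf2": fr["fpf2"],
        "rtpf": fr["tpf1"] / np.maximum(fr["tpf2"], _FLOOR),
        "rfpf": fr["fpf1"] / np.maximum(fr["fpf2"], _FLOOR),
    }
    return PairedComparisonResult(
        summaries=summarize_many(draws, seed=seed), n_draws=n_draws, seed=seed
    )
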