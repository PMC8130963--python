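"""Strain-correlation scoring of GCF-MF links and its hypergeometric null.

The raw score walks over every strain in the population and adds a weight per
strain depending on which of four categories it falls in: it carries both the
gene cluster family and the metabolite (+10 by default), the metabolite only
(-10), neither (+1), or the gene cluster family only (0).  In terms of the
counts (m, g, o, n) this is

    sigma_corr = w_both*o + w_met_only*(m-o) + w_gcf_only*(g-o)
                 + w_neither*(n-m-g+o).

The raw score depends strongly on m, g and n, so scores are not comparable
across links.  Under the null hypothesis that the two strain sets are
uncorrelated, the overlap o follows a hypergeometric distribution with
population n, m positives and sample size g; standardising the raw score by
its exact mean and standard deviation under that null yields a score with
mean 0 and variance 1 that is comparable across set sizes.  Significance is
the null probability of a score at least as large as the observed one (with
the default weights, the hypergeometric upper tail of the overlap).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

from metabolink.core_model import (
    OccurrenceData,
    enumerate_link_candidates,
    validate_counts,
)

__all__ = [
    "ScoreWeights",
    "CorrelationScoreResult",
    "raw_score",
    "overlap_pmf",
    "score_moments",
    "standardised_score",
    "link_significance",
    "score_all_links",
    "SCORE_TABLE_COLUMNS",
]


@dataclass(frozen=True)
class ScoreWeights:
    """Per-strain-category weights; defaults are the published +10/-10/+1/0."""

    w_both: float = 10.0
    w_met_only: float = -10.0
    w_neither: float = 1.0
    w_gcf_only: float = 0.0

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.w_both, self.w_met_only, self.w_neither, self.w_gcf_only)


DEFAULT_WEIGHTS = ScoreWeights()


@dataclass(frozen=True)
class CorrelationScoreResult:
    """Raw score plus its null moments, standardised value and significance."""

    raw: float
    expected: float
    variance: float
    standardised: float
    p_value: float


def raw_score(m: int, g: int, o: int, n: int, w: ScoreWeights = DEFAULT_WEIGHTS) -> float:
    """Raw strain-correlation score for overlap counts (m, g, o, n)."""
    validate_counts(m, g, o, n)
    return _raw(m, g, o, n, w.as_tuple())


def _raw(m: int, g: int, o: int, n: int, w: tuple[float, float, float, float]) -> float:
    w_both, w_met_only, w_neither, w_gcf_only = w
    return (
        w_both * o
        + w_met_only * (m - o)
        + w_gcf_only * (g - o)
        + w_neither * (n - m - g + o)
    )


def overlap_support(m: int, g: int, n: int) -> np.ndarray:
    """Feasible overlap sizes k = max(0, m+g-n) ... min(m, g)."""
    return np.arange(max(0, m + g - n), min(m, g) + 1)


def overlap_pmf(m: int, g: int, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Null distribution of the overlap: hypergeometric pmf over its support.

    Returns ``(k, p)`` where ``p[i]`` is the probability of overlap ``k[i]``
    when a size-g set is drawn uniformly from an n-strain population
    containing m positives.
    """
    validate_counts(m, g, min(m, g), n)
    k = overlap_support(m, g, n)
    p = stats.hypergeom.pmf(k, n, m, g)
    return k, p


@lru_cache(maxsize=65536)
def _moments_cached(
    m: int, g: int, n: int, w: tuple[float, float, float, float]
) -> tuple[float, float]:
    k, p = overlap_pmf(m, g, n)
    scores = np.array([_raw(m, g, int(kk), n, w) for kk in k])
    expected = float(p @ scores)
    second = float(p @ scores**2)
    variance = second - expected**2
    # clamp rounding residue (negative, or tiny relative to the score scale)
    if variance <= 1e-12 * max(1.0, abs(second)):
        variance = 0.0
    return expected, variance


def score_moments(
    m: int, g: int, n: int, w: ScoreWeights = DEFAULT_WEIGHTS
) -> tuple[float, float]:
    """Exact mean and variance of the raw score under the hypergeometric null.

    Computed by direct summation over the overlap support (at most
    ``min(m, g) + 1`` terms), which stays exact for arbitrary weights.
    """
    validate_counts(m, g, min(m, g), n)
    return _moments_cached(m, g, n, w.as_tuple())


def standardised_score(
    m: int, g: int, o: int, n: int, w: ScoreWeights = DEFAULT_WEIGHTS
) -> CorrelationScoreResult:
    """Standardise the raw score by its null moments.

    When the null variance is zero (the overlap is deterministic, e.g. the
    gene cluster family spans every strain) the standardised score is defined
    as 0: such a link carries no correlation evidence either way.
    """
    validate_counts(m, g, o, n)
    raw = raw_score(m, g, o, n, w)
    expected, variance = score_moments(m, g, n, w)
    if variance > 0:
        standardised = (raw - expected) / np.sqrt(variance)
    else:
        standardised = 0.0
    return CorrelationScoreResult(
        raw=raw,
        expected=expected,
        variance=variance,
        standardised=float(standardised),
        p_value=link_significance(m, g, o, n, w),
    )


def link_significance(
    m: int, g: int, o: int, n: int, w: ScoreWeights = DEFAULT_WEIGHTS
) -> float:
    """Null probability of a raw score at least as large as the observed one.

    Generic over weights: sums the hypergeometric pmf over every overlap k
    whose score reaches the observed score.  With the default weights the raw
    score is strictly increasing in o, so this reduces to the hypergeometric
    upper tail P(overlap >= o).
    """
    validate_counts(m, g, o, n)
    k, p = overlap_pmf(m, g, n)
    observed = _raw(m, g, o, n, w.as_tuple())
    scores = np.array([_raw(m, g, int(kk), n, w.as_tuple()) for kk in k])
    return float(min(1.0, p[scores >= observed - 1e-12].sum()))


SCORE_TABLE_COLUMNS = [
    "gcf_id",
    "mf_id",
    "m",
    "g",
    "o",
    "n",
    "raw",
    "expected",
    "variance",
    "standardised",
    "p_value",
]


def score_all_links(
    occ: OccurrenceData, w: ScoreWeights = DEFAULT_WEIGHTS
) -> pd.DataFrame:
    """Correlation-score every GCF-MF pair in an occurrence dataset.

    Returns one row per candidate link with the raw score, null moments,
    standardised score and significance; moments are cached per (m, g) pair.
    """
    rows = []
    for cand in enumerate_link_candidates(occ):
        res = standardised_score(cand.m, cand.g, cand.o, cand.n, w)
        rows.append(
            (
                cand.gcf_id,
                cand.mf_id,
                cand.m,
                cand.g,
                cand.o,
                cand.n,
                res.raw,
                res.expected,
                res.variance,
                res.standardised,
                res.p_value,
            )
        )
    return pd.DataFrame(rows, columns=SCORE_TABLE_COLUMNS)
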