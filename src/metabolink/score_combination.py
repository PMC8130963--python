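"""Combining correlation- and feature-based link scores, ranking, enrichment.

The two score families live on different scales, so the feature (IOKR) score
is first standardised empirically — z-scored over the set of all links where
it is defined.  The standardised pair (x, y) is then combined with the signed
l_{1/2} functional

    sigma_sum = sgn(x) sqrt(|x|) + sgn(y) sqrt(|y|),

which ranks like the l_{1/2} "radius" in the positive quadrant but penalises
links that score negatively on either axis.  The general l_p functional
(|x|^p + |y|^p)^(1/p) is available for other p; for 0 < p < 1 it is not a
norm (no triangle inequality) but remains a valid ranking functional.

Evaluation against validated links uses (a) the per-GCF rank of a link under
a chosen ordering, including the product (dominance) partial order, and
(b) enrichment of validated links above an upper percentile of the score
distribution, tested with a one-sided Fisher exact test on the 2x2
validated x above-threshold contingency table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CombinedScore",
    "EnrichmentResult",
    "standardise_iokr",
    "lp_value",
    "sigma_sum",
    "combine_score_table",
    "rank_links_for_gcf",
    "percentile_enrichment",
]

ORDERINGS = ("iokr", "std_corr", "lp", "product_order", "sigma_sum")


@dataclass(frozen=True)
class CombinedScore:
    """One link's standardised scores and their signed l_{1/2} combination."""

    std_corr: float
    std_iokr: float
    p_exponent: float
    sigma_sum: float


@dataclass(frozen=True)
class EnrichmentResult:
    """Enrichment of validated links above a score percentile.

    ``proportion_overall`` is validated/all over the whole table;
    ``proportion_above`` is validated/above-threshold within the
    above-threshold set.  ``contingency`` is the 2x2 table
    [[validated & above, validated & not-above],
     [other & above, other & not-above]] and ``p_value`` the one-sided
    Fisher exact tail for over-representation of validated links above the
    threshold.
    """

    percentile: float
    which: str
    proportion_overall: float
    proportion_above: float
    contingency: tuple[tuple[int, int], tuple[int, int]]
    p_value: float
    threshold: float | tuple[float, float]


def standardise_iokr(scores) -> np.ndarray:
    """Empirical z-scores of the IOKR link scores over all defined links.

    Mean and (population) variance are taken over the set of all links where
    the score is defined; missing entries (NaN) stay missing.  A constant
    score vector is an error: it carries no ranking information and cannot
    be standardised.
    """
    x = np.asarray(scores, dtype=float)
    defined = ~np.isnan(x)
    if defined.sum() < 2:
        raise ValueError("need >= 2 defined scores to standardise")
    mu = x[defined].mean()
    sd = x[defined].std()  # population (ddof=0)
    if sd == 0:
        raise ValueError("scores have zero variance; cannot standardise")
    out = np.full_like(x, np.nan)
    out[defined] = (x[defined] - mu) / sd
    return out


def lp_value(x: float, y: float, p: float) -> float:
    """l_p functional (|x|^p + |y|^p)^(1/p); requires p > 0."""
    if p <= 0:
        raise ValueError("p must be > 0")
    return float((abs(x) ** p + abs(y) ** p) ** (1.0 / p))


def sigma_sum(std_corr: float, std_iokr: float) -> float:
    """Signed l_{1/2} combination: sgn(a)sqrt(|a|) + sgn(b)sqrt(|b|).

    Missing inputs (NaN) propagate to a missing combined score.
    """
    if math.isnan(std_corr) or math.isnan(std_iokr):
        return float("nan")
    return float(
        math.copysign(math.sqrt(abs(std_corr)), std_corr)
        + math.copysign(math.sqrt(abs(std_iokr)), std_iokr)
    )


def combine_score_table(
    corr_table: pd.DataFrame,
    iokr_scores: pd.Series | Sequence[float],
    p_exponent: float = 0.5,
) -> pd.DataFrame:
    """Attach IOKR, standardised-IOKR, sigma_sum and l_p columns to a score table.

    ``corr_table`` is the output of
    :func:`metabolink.strain_correlation.score_all_links`; ``iokr_scores``
    aligns with its rows (NaN where the IOKR score is undefined for a link).
    """
    out = corr_table.copy()
    out["iokr"] = np.asarray(iokr_scores, dtype=float)
    out["std_iokr"] = standardise_iokr(out["iokr"].to_numpy())
    out["sigma_sum"] = [
        sigma_sum(a, b) for a, b in zip(out["standardised"], out["std_iokr"])
    ]
    out["lp"] = [
        np.nan if (np.isnan(a) or np.isnan(b)) else lp_value(a, b, p_exponent)
        for a, b in zip(out["standardised"], out["std_iokr"])
    ]
    return out


def _ordering_scores(table: pd.DataFrame, ordering: str, p: float) -> np.ndarray:
    if ordering == "iokr":
        return table["iokr"].to_numpy(dtype=float)
    if ordering == "std_corr":
        return table["standardised"].to_numpy(dtype=float)
    if ordering == "sigma_sum":
        return np.array(
            [sigma_sum(a, b) for a, b in zip(table["standardised"], table["std_iokr"])]
        )
    if ordering == "lp":
        return np.array(
            [
                np.nan if (np.isnan(a) or np.isnan(b)) else lp_value(a, b, p)
                for a, b in zip(table["standardised"], table["std_iokr"])
            ]
        )
    raise ValueError(f"unknown ordering {ordering!r}; expected one of {ORDERINGS}")


def rank_links_for_gcf(
    table: pd.DataFrame,
    gcf_id: str,
    ordering: str = "sigma_sum",
    p: float = 0.5,
) -> pd.DataFrame:
    """Rank the candidate links of one gene cluster family.

    The rank of a link is 1 + the number of links strictly better than it
    under the requested ordering, so tied links share a rank.  For
    ``product_order``, "better" means at least as good on both the
    standardised correlation and IOKR scores and strictly better on at least
    one; links incomparable to the query do not count, which makes the
    product-order rank a lower bound on both single-score ranks.

    Rows are returned sorted by rank (ties broken by MF id); undefined
    scores exclude a link from orderings that need them.
    """
    sub = table[table["gcf_id"] == gcf_id].copy()
    if sub.empty:
        raise KeyError(f"no links for GCF {gcf_id!r} in the score table")
    if ordering == "product_order":
        x = sub["standardised"].to_numpy(dtype=float)
        y = sub["iokr"].to_numpy(dtype=float)
        ok = ~(np.isnan(x) | np.isnan(y))
        sub = sub[ok]
        x, y = x[ok], y[ok]
        ge_x = x[:, None] >= x[None, :]
        ge_y = y[:, None] >= y[None, :]
        gt = ge_x & ge_y & ((x[:, None] > x[None, :]) | (y[:, None] > y[None, :]))
        sub["rank"] = 1 + gt.sum(axis=0)
    else:
        s = _ordering_scores(sub, ordering, p)
        ok = ~np.isnan(s)
        sub = sub[ok]
        s = s[ok]
        sub["rank"] = 1 + (s[:, None] > s[None, :]).sum(axis=0)
    return sub.sort_values(["rank", "mf_id"], kind="mergesort").reset_index(drop=True)


def _percentile_mask(scores: np.ndarray, q: float) -> tuple[np.ndarray, float]:
    """Boolean above-threshold mask over *defined* scores, plus the threshold.

    The threshold is the linear-interpolation q-th percentile of the defined
    scores; "above" means strictly greater.  Undefined (NaN) entries are
    never above.
    """
    defined = ~np.isnan(scores)
    if defined.sum() == 0:
        raise ValueError("no defined scores")
    thr = float(np.percentile(scores[defined], q))
    above = np.zeros(scores.shape, dtype=bool)
    above[defined] = scores[defined] > thr
    return above, thr


def percentile_enrichment(
    table: pd.DataFrame,
    validated_links: Sequence[tuple[str, str]],
    q: float = 90.0,
    which: str = "corr",
) -> EnrichmentResult:
    """Test whether validated links are enriched above the q-th percentile.

    ``which`` selects the score: ``"corr"`` (standardised correlation),
    ``"raw_corr"``, ``"iokr"``, or ``"both"`` (above the per-score
    thresholds of standardised correlation *and* IOKR simultaneously).
    Percentiles are computed over links where the score is defined; all
    links stay in the contingency denominators.  The p-value is the
    one-sided Fisher exact tail for validated links being over-represented
    above the threshold.
    """
    if not 0 < q < 100:
        raise ValueError("percentile q must lie in (0, 100)")
    pairs = set(zip(table["gcf_id"], table["mf_id"]))
    missing = [vl for vl in validated_links if tuple(vl) not in pairs]
    if missing:
        raise ValueError(f"validated links absent from the score table: {missing}")
    if not validated_links:
        raise ValueError("no validated links supplied")

    is_validated = np.array(
        [
            (g, m) in {tuple(v) for v in validated_links}
            for g, m in zip(table["gcf_id"], table["mf_id"])
        ]
    )
    if which == "corr":
        above, thr = _percentile_mask(table["standardised"].to_numpy(float), q)
        threshold: float | tuple[float, float] = thr
    elif which == "raw_corr":
        above, thr = _percentile_mask(table["raw"].to_numpy(float), q)
        threshold = thr
    elif which == "iokr":
        above, thr = _percentile_mask(table["iokr"].to_numpy(float), q)
        threshold = thr
    elif which == "both":
        a1, t1 = _percentile_mask(table["standardised"].to_numpy(float), q)
        a2, t2 = _percentile_mask(table["iokr"].to_numpy(float), q)
        above, threshold = a1 & a2, (t1, t2)
    else:
        raise ValueError(
            f"unknown score selector {which!r}; expected corr/raw_corr/iokr/both"
        )

    a = int((is_validated & above).sum())
    b = int((is_validated & ~above).sum())
    c = int((~is_validated & above).sum())
    d = int((~is_validated & ~above).sum())
    _, p_value = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
    n_above = a + c
    return EnrichmentResult(
        percentile=q,
        which=which,
        proportion_overall=(a + b) / len(table),
        proportion_above=a / n_above if n_above else 0.0,
        contingency=((a, b), (c, d)),
        p_value=float(p_value),
        threshold=threshold,
    )
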