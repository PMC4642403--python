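"""Covariate-adjusted drug ratings and pairwise online-trend deduction.

Within a condition that passed the ANCOVA screen, each drug's adjusted
rating is the fitted model's prediction at the condition's most common age
and gender, removing covariate imbalance between the drugs' reviewer
populations. Every unordered drug pair is then evaluated: a pair deduces
an online trend ("drug_hi is a better drug than drug_lo") when the
adjusted ratings differ by at least half a point AND the two drugs' raw
rating samples differ by a Mann-Whitney U test at P < .01 (two-sided).

The U test uses midranks for ties. For pooled sample sizes up to 12 the
two-sided p-value is computed by exhaustive enumeration of all group-label
assignments. For larger samples over a small ordinal support (at most ten
distinct pooled values — always the case for 1-5 ratings) the permutation
distribution of the rank sum is computed exactly by dynamic programming
over the tie groups (a multivariate hypergeometric convolution), since the
normal approximation can err by a few percent on heavily tied lattices.
Only for large samples with many distinct values does the test fall back
to the normal approximation with tie-corrected variance and continuity
correction.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from itertools import combinations
from math import comb, sqrt

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import make_pair_id
from .preprocess import ConditionDataset
from .screen import AgeParseError, ConditionModel, age_to_numeric

DEFAULT_DIFF_THRESHOLD = 0.5
DEFAULT_P_THRESHOLD = 0.01
EXACT_LIMIT = 12
MAX_DISTINCT_FOR_EXACT = 10
# rough shift-add budget for the tie-group convolution; beyond this the
# asymptotic approximation is used (its error shrinks with sample size)
MAX_EXACT_OPS = 2e8


@dataclass(slots=True)
class AdjustedRating:
    """A drug's model-predicted rating at the condition's modal covariates."""

    ingredient_key: str  # group key (ingredient, plus mode suffix if any)
    condition: str
    adjusted_score: float
    modal_age: float
    modal_gender: str
    n_reviews: int


@dataclass(slots=True)
class TrendPair:
    """An ordered drug pair; ``passes`` marks a deduced online trend."""

    condition: str
    drug_hi: str
    drug_lo: str
    adj_hi: float
    adj_lo: float
    diff: float
    mw_u: float
    mw_p: float
    passes: bool

    @property
    def pair_id(self) -> str:
        return make_pair_id(self.condition, self.drug_hi, self.drug_lo)


def modal_covariates(dataset: ConditionDataset) -> tuple[float, str]:
    """Most common age band (as years) and gender across the condition's
    modeled reviews (those with a parseable age band).

    Ties break deterministically: the younger age band, then the
    lexicographically smaller gender label.
    """
    band_counts: Counter[str] = Counter()
    gender_counts: Counter[str] = Counter()
    band_years: dict[str, float] = {}
    for group in dataset.drug_groups:
        for review in group.reviews:
            try:
                years = age_to_numeric(review.age_range)
            except AgeParseError:
                continue
            band = review.age_range.strip().lower()
            band_counts[band] += 1
            band_years[band] = years
            gender_counts[review.gender] += 1
    if not band_counts:
        raise ValueError(
            f"condition {dataset.condition!r}: no parseable ages, cannot adjust ratings"
        )
    modal_band = min(band_counts, key=lambda b: (-band_counts[b], band_years[b]))
    modal_gender = min(gender_counts, key=lambda g: (-gender_counts[g], g))
    return band_years[modal_band], modal_gender


def adjusted_rating(
    model: ConditionModel,
    group_key: str,
    modal_age: float,
    modal_gender: str,
    n_reviews: int,
) -> AdjustedRating:
    """Predicted rating for one drug at the condition's modal covariates."""
    return AdjustedRating(
        ingredient_key=group_key,
        condition=model.condition,
        adjusted_score=model.predict(group_key, modal_age, modal_gender),
        modal_age=modal_age,
        modal_gender=modal_gender,
        n_reviews=n_reviews,
    )


def adjusted_ratings(dataset: ConditionDataset, model: ConditionModel) -> list[AdjustedRating]:
    """Adjusted ratings for every drug group of a screened condition, all
    evaluated at the same (modal age, modal gender)."""
    age, gender = modal_covariates(dataset)
    return [
        adjusted_rating(model, g.group_key, age, gender, g.n_reviews)
        for g in dataset.drug_groups
    ]


def _u_statistic(ranks_x_sum: float, n1: int) -> float:
    return ranks_x_sum - n1 * (n1 + 1) / 2.0


def _exact_tied_p(
    pooled: np.ndarray, sample_ranks: np.ndarray, n1: int, mean_rank: float
) -> float:
    """Exact two-sided permutation p for the rank sum over a tied lattice.

    Convolves, tie group by tie group, the joint distribution of (number of
    sample-1 members drawn, doubled rank sum) under the multivariate
    hypergeometric null. Doubling the midranks keeps the lattice integral.
    Counts are held in float64; relative error stays near machine epsilon.
    """
    tie_counts = np.unique(pooled, return_counts=True)[1]
    r2, start = [], 1
    for t in tie_counts:
        r2.append(2 * start + (int(t) - 1))  # doubled midrank of the tie group
        start += int(t)
    smax = int(max(r2) * n1) + 1
    dist = np.zeros((n1 + 1, smax))
    dist[0, 0] = 1.0
    for t, rr in zip(tie_counts, r2):
        new = np.zeros_like(dist)
        for c in range(min(int(t), n1) + 1):
            shift = c * rr
            if shift >= smax:
                break
            new[c:, shift:] += comb(int(t), c) * dist[: n1 + 1 - c, : smax - shift]
        dist = new
    final = dist[n1]
    w2_obs = 2.0 * float(sample_ranks.sum())
    mu2 = 2.0 * n1 * mean_rank
    dev = abs(w2_obs - mu2)
    support = np.arange(smax)
    mass = final[np.abs(support - mu2) >= dev - 1e-9].sum()
    return float(mass / final.sum())


def mann_whitney(x, y, exact_limit: int = EXACT_LIMIT) -> tuple[float, float]:
    """Mann-Whitney U test with midranks for ties.

    Returns (U for the first sample, two-sided p); extremity is measured
    symmetrically by |U - n1*n2/2|. The p-value is exact — by exhaustive
    enumeration of all C(n1+n2, n1) label assignments when
    n1+n2 <= exact_limit, or by the tie-group convolution when the pooled
    sample has few distinct values — and falls back to a tie-corrected
    normal approximation with continuity correction otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("mann_whitney requires two non-empty samples")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    u_obs = _u_statistic(float(ranks[:n1].sum()), n1)
    mu = n1 * n2 / 2.0

    if n1 + n2 <= exact_limit:
        dev_obs = abs(u_obs - mu)
        hits = 0
        total = comb(n1 + n2, n1)
        for idx in combinations(range(n1 + n2), n1):
            u = _u_statistic(float(ranks[list(idx)].sum()), n1)
            if abs(u - mu) >= dev_obs - 1e-9:
                hits += 1
        return u_obs, hits / total

    tie_sizes = np.unique(pooled, return_counts=True)[1]
    if len(tie_sizes) <= MAX_DISTINCT_FOR_EXACT:
        # |U - n1*n2/2| is symmetric in the two samples; convolving over the
        # smaller one bounds the DP table size
        n_small = min(n1, n2)
        smax = 2.0 * float(ranks.max()) * n_small
        ops = (n_small + 1) * smax * float(np.minimum(tie_sizes, n_small).sum() + len(tie_sizes))
        if ops <= MAX_EXACT_OPS:
            sample_ranks = ranks[:n1] if n1 <= n2 else ranks[n1:]
            return u_obs, _exact_tied_p(pooled, sample_ranks, n_small, float(ranks.mean()))

    n = n1 + n2
    tie_counts = np.array(list(Counter(pooled.tolist()).values()), dtype=float)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (n * (n - 1)))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:  # all pooled values identical
        return u_obs, 1.0
    dev = abs(u_obs - mu)
    z = max(dev - 0.5, 0.0) / sqrt(var)
    return u_obs, min(1.0, 2.0 * float(stats.norm.sf(z)))


def deduce_trends(
    dataset: ConditionDataset,
    ratings: list[AdjustedRating],
    diff_threshold: float = DEFAULT_DIFF_THRESHOLD,
    p_threshold: float = DEFAULT_P_THRESHOLD,
) -> list[TrendPair]:
    """Evaluate all unordered drug pairs of a screened condition.

    Each pair is oriented so drug_hi has the larger adjusted score (exact
    ties orient lexicographically and cannot pass). A pair passes — i.e.
    deduces the online trend "drug_hi is better than drug_lo" — when the
    adjusted difference is >= diff_threshold and the Mann-Whitney p on the
    drugs' raw ratings is < p_threshold.
    """
    by_key = {r.ingredient_key: r for r in ratings}
    groups = {g.group_key: g for g in dataset.drug_groups}
    pairs: list[TrendPair] = []
    for key_a, key_b in combinations(sorted(groups), 2):
        ra, rb = by_key[key_a], by_key[key_b]
        if rb.adjusted_score > ra.adjusted_score:
            hi, lo = rb, ra
        else:
            hi, lo = ra, rb
        diff = hi.adjusted_score - lo.adjusted_score
        u, p = mann_whitney(groups[hi.ingredient_key].ratings(), groups[lo.ingredient_key].ratings())
        pairs.append(
            TrendPair(
                condition=dataset.condition,
                drug_hi=hi.ingredient_key,
                drug_lo=lo.ingredient_key,
                adj_hi=hi.adjusted_score,
                adj_lo=lo.adjusted_score,
                diff=diff,
                mw_u=u,
                mw_p=p,
                passes=bool(diff >= diff_threshold and p < p_threshold),
            )
        )
    return pairs


def write_trend_pairs(pairs: list[TrendPair], path) -> None:
    rows = [
        (
            p.condition,
            p.drug_hi,
            p.drug_lo,
            round(p.adj_hi, 2),
            round(p.adj_lo, 2),
            round(p.diff, 2),
            p.mw_u,
            p.mw_p,
            p.passes,
        )
        for p in sorted(pairs, key=lambda p: (p.condition, p.drug_hi, p.drug_lo))
    ]
    pd.DataFrame(
        rows,
        columns=["condition", "drug_hi", "drug_lo", "adj_hi", "adj_lo", "diff", "mw_u", "mw_p", "passes"],
    ).to_csv(path, index=False)
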