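"""Comment text mining: term-mention frequencies, 2x2 chi-square
comparisons, rating-conditional shares, and stopword-filtered term ranking.

A review "mentions" a term when its lowercased comment contains the term
as a substring, so inflected forms count ("addictive" and "addicting" both
match "addict"). Each review is counted at most once regardless of how
many terms, or occurrences, it contains.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .data_model import Review
from .stopwords import STOPWORDS

logger = logging.getLogger(__name__)

_TOKEN = re.compile(r"[a-z0-9]+")


@dataclass(slots=True)
class TermStats:
    """Fraction of a drug's reviews whose comment mentions any target term."""

    ingredient_key: str
    terms: frozenset[str]
    n_hit: int
    n_total: int

    @property
    def frequency(self) -> float:
        return self.n_hit / self.n_total


def term_hits(reviews: list[Review], terms) -> list[Review]:
    """Reviews whose comment contains any of the terms (case-insensitive
    substring match)."""
    lowered = [t.lower() for t in terms]
    return [r for r in reviews if any(t in r.comment.lower() for t in lowered)]


def term_frequency(reviews: list[Review], terms, ingredient_key: str = "") -> TermStats:
    """Share of reviews mentioning any target term."""
    if not reviews:
        raise ValueError("term_frequency requires at least one review")
    hits = term_hits(reviews, terms)
    return TermStats(
        ingredient_key=ingredient_key,
        terms=frozenset(t.lower() for t in terms),
        n_hit=len(hits),
        n_total=len(reviews),
    )


def chi_square_2x2(
    hit1: int, total1: int, hit2: int, total2: int, yates: bool = False
) -> tuple[float, float]:
    """Pearson chi-square on the 2x2 table [[hit, miss]] x two groups, 1 df.

    No continuity correction by default; pass ``yates=True`` to apply it.
    A zero marginal (no hits in either group, or no misses) makes the test
    undefined; the function returns (0, 1) with a warning.
    """
    if total1 < 1 or total2 < 1 or not (0 <= hit1 <= total1) or not (0 <= hit2 <= total2):
        raise ValueError("invalid 2x2 counts")
    a, b = hit1, total1 - hit1
    c, d = hit2, total2 - hit2
    n = a + b + c + d
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if any(m == 0 for m in margins):
        logger.warning("degenerate 2x2 table with a zero marginal; returning chi2=0, p=1")
        return 0.0, 1.0
    dev = abs(a * d - b * c)
    if yates:
        dev = max(dev - n / 2.0, 0.0)
    statistic = n * dev * dev / (margins[0] * margins[1] * margins[2] * margins[3])
    return float(statistic), float(stats.chi2.sf(statistic, 1))


def rating_conditional_share(hit_reviews: list[Review], rating_cutoff: int = 4) -> float:
    """Share of term-mentioning reviews whose rating is >= rating_cutoff."""
    if not hit_reviews:
        raise ValueError("rating_conditional_share requires at least one hit review")
    return sum(1 for r in hit_reviews if r.rating >= rating_cutoff) / len(hit_reviews)


def tokenize(text: str) -> list[str]:
    """Lowercase and split on non-alphanumeric runs."""
    return _TOKEN.findall(text.lower())


def top_terms(
    reviews: list[Review], stopwords=STOPWORDS, k: int = 20
) -> list[tuple[str, int]]:
    """Rank non-stopword tokens across all comments by occurrence count.

    Tokens shorter than two characters are dropped. Ties break
    alphabetically; the top k (term, count) pairs are returned — the data
    behind a word cloud.
    """
    counts: Counter[str] = Counter()
    for review in reviews:
        for token in tokenize(review.comment):
            if len(token) >= 2 and token not in stopwords:
                counts[token] += 1
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:k]


def write_term_stats(stats_list: list[TermStats], path) -> None:
    rows = [
        (s.ingredient_key, ";".join(sorted(s.terms)), s.n_hit, s.n_total, s.frequency)
        for s in sorted(stats_list, key=lambda s: s.ingredient_key)
    ]
    pd.DataFrame(
        rows, columns=["ingredient_key", "terms", "n_hit", "n_total", "frequency"]
    ).to_csv(path, index=False)


def write_top_terms(ranked: list[tuple[str, int]], path, label: str = "") -> None:
    rows = [(label, term, count) for term, count in ranked]
    pd.DataFrame(rows, columns=["group", "term", "count"]).to_csv(path, index=False)
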