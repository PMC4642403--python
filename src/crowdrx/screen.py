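"""Per-condition ANCOVA screen for drug effects on satisfaction ratings.

For each condition a linear model is fitted with the 1-5 satisfaction
rating as response and three main effects: drug group (categorical),
gender (categorical, with "unknown" as a third level) and age (numeric,
years, the midpoint of the reviewer's age band). The drug factor is tested
with a partial F-test — full model (drug + gender + age) against the
reduced model (gender + age) — which for a main-effects-only model equals
the Type-III test of the drug term. Raw p-values are Bonferroni-corrected
across the number of conditions actually modeled in the batch.

Reviews whose age band cannot be parsed are excluded from model fitting
(they remain available to rank tests and text mining downstream).
"""

from __future__ import annotations

import dataclasses
import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import ConditionDataset

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05

# Open-ended bands are treated as fixed-width bands: "75 or over" as 75-84,
# "under 18" as 13-17, keeping the midpoint mapping deterministic.
_CLOSED = re.compile(r"^(\d+)\s*-\s*(\d+)$")
_SINGLE = re.compile(r"^(\d+)$")
_OPEN_UPPER = re.compile(r"^(?:(\d+)\s*(?:\+|or\s+(?:over|older|above))|over\s+(\d+))$")
_OPEN_LOWER = re.compile(r"^(?:under\s+(\d+)|(\d+)\s+(?:or|and)\s+under)$")


class AgeParseError(ValueError):
    """Raised when an age-band string cannot be mapped to years."""


class ScreenSkip(RuntimeError):
    """Raised when a condition cannot be modeled (insufficient residual df)."""


def age_to_numeric(age_range: str) -> float:
    """Convert an age band to years as the band midpoint.

    "25-34" -> 29.5; a bare number maps to itself; "75 or over" is read as
    the ten-year band 75-84 (-> 79.5) and "under 18" as the five-year band
    13-17 (-> 15.0).
    """
    band = str(age_range).strip().lower()
    if m := _CLOSED.match(band):
        lo, hi = int(m.group(1)), int(m.group(2))
        if lo > hi:
            raise AgeParseError(f"inverted age band {age_range!r}")
        return (lo + hi) / 2.0
    if m := _SINGLE.match(band):
        return float(m.group(1))
    if m := _OPEN_UPPER.match(band):
        lo = int(m.group(1) or m.group(2))
        return (lo + (lo + 9)) / 2.0
    if m := _OPEN_LOWER.match(band):
        hi = int(m.group(1) or m.group(2)) - 1
        return ((hi - 4) + hi) / 2.0
    raise AgeParseError(f"unparseable age band {age_range!r}")


@dataclass(slots=True)
class ScreenResult:
    """Outcome of the drug-factor partial F-test for one condition."""

    condition: str
    f_statistic: float
    df_num: int
    df_den: int
    p_raw: float
    p_adjusted: float = float("nan")
    significant: bool = False


class ConditionModel:
    """Least-squares fit of rating ~ drug + gender + age for one condition.

    The design uses treatment coding with the lexicographically first drug
    and gender levels as references. Rank-deficient designs are handled by
    the minimum-norm least-squares solution; degrees of freedom follow the
    numerical matrix ranks, so a collinear column is effectively dropped.
    """

    def __init__(self, dataset: ConditionDataset):
        self.condition = dataset.condition
        rows: list[tuple[str, str, float, float]] = []
        n_excluded = 0
        for group in dataset.drug_groups:
            for review in group.reviews:
                try:
                    age = age_to_numeric(review.age_range)
                except AgeParseError:
                    n_excluded += 1
                    continue
                rows.append((group.group_key, review.gender, age, float(review.rating)))
        if n_excluded:
            logger.info(
                "condition %r: %d reviews without parseable age excluded from model",
                self.condition,
                n_excluded,
            )
        if not rows:
            raise ScreenSkip(f"condition {self.condition!r}: no reviews with parseable age")
        self.drug = np.array([r[0] for r in rows])
        self.gender = np.array([r[1] for r in rows])
        self.age = np.array([r[2] for r in rows])
        self.y = np.array([r[3] for r in rows])
        self.drug_levels = sorted(set(self.drug))
        self.gender_levels = sorted(set(self.gender))
        self.n_modeled = len(rows)
        self.n_excluded = n_excluded

        X_full = self._design(include_drug=True)
        X_red = self._design(include_drug=False)
        self.coef, self.sse_full, self.rank_full = _lstsq(X_full, self.y)
        _, self.sse_reduced, self.rank_reduced = _lstsq(X_red, self.y)
        if self.rank_full < X_full.shape[1]:
            logger.warning(
                "condition %r: rank-deficient design (rank %d < %d columns); "
                "collinear column(s) dropped from the test df",
                self.condition,
                self.rank_full,
                X_full.shape[1],
            )

    def _row(self, drug: str | None, gender: str, age: float) -> np.ndarray:
        cols = [1.0]
        if drug is not None:
            cols.extend(1.0 if drug == lv else 0.0 for lv in self.drug_levels[1:])
        cols.extend(1.0 if gender == lv else 0.0 for lv in self.gender_levels[1:])
        cols.append(age)
        return np.array(cols)

    def _design(self, include_drug: bool) -> np.ndarray:
        rows = [
            self._row(d if include_drug else None, g, a)
            for d, g, a in zip(self.drug, self.gender, self.age)
        ]
        return np.vstack(rows)

    def predict(self, drug: str, age: float, gender: str) -> float:
        """Linear predictor at the given drug, age (years) and gender."""
        if drug not in self.drug_levels:
            raise KeyError(f"drug {drug!r} not in model for condition {self.condition!r}")
        return float(self._row(drug, gender, age) @ self.coef)


def _lstsq(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float, int]:
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return coef, float(resid @ resid), int(rank)


def ancova_drug_test(
    dataset: ConditionDataset, model: ConditionModel | None = None
) -> ScreenResult:
    """Partial F-test of the drug factor for one condition.

    F = ((SSE_reduced - SSE_full)/df_num) / (SSE_full/df_den). A saturated
    or exhausted design (df_den <= 0) raises :class:`ScreenSkip`; a perfect
    fit with no drug contribution yields F=0, p=1.
    """
    if len(dataset.drug_groups) < 2:
        raise ValueError(f"condition {dataset.condition!r}: need >= 2 drug groups")
    if model is None:
        model = ConditionModel(dataset)
    df_num = model.rank_full - model.rank_reduced
    df_den = model.n_modeled - model.rank_full
    if df_num < 1:
        raise ScreenSkip(
            f"condition {dataset.condition!r}: drug factor adds no estimable contrast"
        )
    if df_den < 1:
        raise ScreenSkip(
            f"condition {dataset.condition!r}: no residual degrees of freedom "
            f"(n={model.n_modeled}, rank={model.rank_full})"
        )
    ss_drug = max(model.sse_reduced - model.sse_full, 0.0)
    if model.sse_full <= 1e-12 * max(1.0, float(model.y @ model.y)):
        # perfect fit: drug either explains nothing extra (F=0) or everything
        f_stat, p_raw = (0.0, 1.0) if ss_drug <= 1e-12 else (float("inf"), 0.0)
    else:
        f_stat = (ss_drug / df_num) / (model.sse_full / df_den)
        p_raw = float(stats.f.sf(f_stat, df_num, df_den))
    return ScreenResult(
        condition=dataset.condition,
        f_statistic=f_stat,
        df_num=df_num,
        df_den=df_den,
        p_raw=p_raw,
    )


def bonferroni_screen(
    results: list[ScreenResult], alpha: float = DEFAULT_ALPHA
) -> list[ScreenResult]:
    """Bonferroni-correct raw p-values over the batch of tested conditions.

    p_adjusted = min(1, p_raw * N_tested); a condition is significant when
    p_adjusted < alpha. N_tested is the number of conditions in `results`,
    i.e. conditions actually modeled, not a fixed constant.
    """
    n = len(results)
    out = []
    for r in results:
        p_adj = min(1.0, r.p_raw * n)
        out.append(
            dataclasses.replace(r, p_adjusted=p_adj, significant=bool(p_adj < alpha))
        )
    return out


def write_screen_results(results: list[ScreenResult], path) -> None:
    rows = [
        (r.condition, r.f_statistic, r.df_num, r.df_den, r.p_raw, r.p_adjusted, r.significant)
        for r in sorted(results, key=lambda r: r.condition)
    ]
    pd.DataFrame(
        rows,
        columns=["condition", "f", "df_num", "df_den", "p_raw", "p_adjusted", "significant"],
    ).to_csv(path, index=False)
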