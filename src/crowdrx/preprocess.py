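"""Brand-to-ingredient grouping and eligibility filtering.

Reviews of brands sharing the same active ingredient(s) and the same
delivery mode are pooled into a single analysis unit ("drug group") within
each condition; conditions are analyzed as fully independent strata. Brands
absent from the ingredient map keep their own name as a singleton group
key. Two eligibility filters then apply, in order: a drug group must have
a minimum number of reviews for its condition (default 30), and a condition
must retain at least two drug groups after that.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .data_model import IngredientMapEntry, Review, norm_name

logger = logging.getLogger(__name__)

DEFAULT_MIN_REVIEWS = 30
DEFAULT_MIN_DRUGS = 2


@dataclass(slots=True)
class DrugGroup:
    """Reviews pooled by active ingredient + delivery mode within one condition."""

    ingredient_key: str
    delivery_mode: str
    condition: str
    member_brands: set[str] = field(default_factory=set)
    reviews: list[Review] = field(default_factory=list)

    @property
    def group_key(self) -> str:
        """Analysis key: ingredient key, suffixed by mode when one is known."""
        if self.delivery_mode:
            return f"{self.ingredient_key}|{self.delivery_mode}"
        return self.ingredient_key

    @property
    def n_reviews(self) -> int:
        return len(self.reviews)

    def ratings(self) -> list[int]:
        return [r.rating for r in self.reviews]


@dataclass(slots=True)
class ConditionDataset:
    """All eligible drug groups for one condition."""

    condition: str
    drug_groups: list[DrugGroup]

    @property
    def n_reviews(self) -> int:
        return sum(g.n_reviews for g in self.drug_groups)


def group_reviews(reviews: list[Review], mapping: list[IngredientMapEntry]) -> list[DrugGroup]:
    """Assign every review to exactly one drug group.

    Brands found in the ingredient map merge with other brands sharing the
    same (ingredient_key, delivery_mode); unmapped brands form self-keyed
    groups (so identically named unmapped rows still merge). The total
    review count is conserved: no review is dropped or duplicated.
    """
    by_brand: dict[str, IngredientMapEntry] = {}
    for entry in mapping:
        if entry.brand_name in by_brand:
            # (brand, mode) uniqueness allows one brand under several modes;
            # reviews carry no mode so the lexicographically first mode wins.
            keep = min(by_brand[entry.brand_name], entry, key=lambda e: e.delivery_mode)
            logger.warning(
                "brand %r mapped under multiple delivery modes; using %r",
                entry.brand_name,
                keep.delivery_mode,
            )
            by_brand[entry.brand_name] = keep
        else:
            by_brand[entry.brand_name] = entry

    groups: dict[tuple[str, str, str], DrugGroup] = {}
    n_unmapped = 0
    for review in reviews:
        brand = norm_name(review.drug_name)
        entry = by_brand.get(brand)
        if entry is None:
            n_unmapped += 1
            key, mode = brand, ""
        else:
            key, mode = entry.ingredient_key, entry.delivery_mode
        gk = (norm_name(review.condition), key, mode)
        group = groups.get(gk)
        if group is None:
            group = groups[gk] = DrugGroup(
                ingredient_key=key, delivery_mode=mode, condition=gk[0]
            )
        group.member_brands.add(brand)
        group.reviews.append(review)
    if n_unmapped:
        logger.info("%d reviews of unmapped brands kept under their own names", n_unmapped)
    return [groups[k] for k in sorted(groups)]


def filter_eligible(
    groups: list[DrugGroup],
    min_reviews: int = DEFAULT_MIN_REVIEWS,
    min_drugs: int = DEFAULT_MIN_DRUGS,
) -> list[ConditionDataset]:
    """Apply the two eligibility filters and bundle survivors per condition.

    The per-drug review-count filter runs strictly before the per-condition
    drug-count filter, so `min_drugs` refers to surviving groups. Both
    thresholds are inclusive ("at least"). The operation is idempotent.
    """
    if min_reviews < 1:
        raise ValueError("min_reviews must be >= 1")
    if min_drugs < 2:
        raise ValueError("min_drugs must be >= 2")
    surviving = [g for g in groups if g.n_reviews >= min_reviews]
    by_condition: dict[str, list[DrugGroup]] = {}
    for g in surviving:
        by_condition.setdefault(g.condition, []).append(g)
    datasets = []
    for condition in sorted(by_condition):
        members = sorted(by_condition[condition], key=lambda g: g.group_key)
        if len(members) >= min_drugs:
            datasets.append(ConditionDataset(condition=condition, drug_groups=members))
        else:
            logger.info(
                "condition %r dropped: %d surviving drug group(s) < %d",
                condition,
                len(members),
                min_drugs,
            )
    return datasets


def write_grouped(groups: list[DrugGroup], path) -> None:
    """Audit table of group composition (one row per drug group)."""
    rows = [
        (g.ingredient_key, g.delivery_mode, g.condition, g.n_reviews, ";".join(sorted(g.member_brands)))
        for g in sorted(groups, key=lambda g: (g.condition, g.group_key))
    ]
    pd.DataFrame(
        rows, columns=["ingredient_key", "delivery_mode", "condition", "n_reviews", "member_brands"]
    ).to_csv(path, index=False)
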