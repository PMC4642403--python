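"""Core record types and delimited-table I/O for the review pipeline.

All tables are UTF-8 CSV with a header row. Five schemas are supported:

``reviews``        drug_name,condition,rating,age_range,gender,comment
``ingredient_map`` brand_name,ingredient_key,delivery_mode
``labels``         ingredient_key,black_box,indicated_conditions,abuse_dependence
``publications``   pair_id,source,pub_type,status
``condition_map``  site_condition,preferred_term

Drug and condition names are scraped consumer-site strings, so they are
trimmed and compared case-insensitively everywhere; readers normalize them
to lowercase on ingest. Review rows violating invariants (rating outside
1-5, empty drug or condition) are rejected individually with row-numbered
diagnostics on the module logger rather than aborting the whole load.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

VALID_RATINGS = frozenset({1, 2, 3, 4, 5})
GENDERS = ("male", "female", "unknown")
PUBLICATION_SOURCES = frozenset({"pubmed", "scholar", "regulatory"})
PUBLICATION_TYPES = frozenset({"head_to_head", "review", "meta_analysis", "other"})
PUBLICATION_STATUSES = frozenset({"agree", "disagree"})

REVIEW_COLUMNS = ["drug_name", "condition", "rating", "age_range", "gender", "comment"]

TABLE_COLUMNS = {
    "ingredient_map": ["brand_name", "ingredient_key", "delivery_mode"],
    "labels": ["ingredient_key", "black_box", "indicated_conditions", "abuse_dependence"],
    "publications": ["pair_id", "source", "pub_type", "status"],
    "condition_map": ["site_condition", "preferred_term"],
}


class SchemaError(ValueError):
    """Raised when a table's header or records violate its schema."""


def norm_name(s: str) -> str:
    """Trim and lowercase a scraped drug/condition name for comparison."""
    return str(s).strip().lower()


def norm_gender(s: str) -> str:
    """Map free-form gender strings onto {male, female, unknown}."""
    g = str(s).strip().lower()
    return g if g in ("male", "female") else "unknown"


def make_pair_id(condition: str, key_a: str, key_b: str) -> str:
    """Order-normalized identifier for a drug pair within a condition.

    The two ingredient keys are sorted lexicographically so that the id is
    stable regardless of which drug rated higher, giving a reliable join
    key between deduced trend pairs and publication records.
    """
    lo, hi = sorted((norm_name(key_a), norm_name(key_b)))
    return f"{norm_name(condition)}|{lo}|{hi}"


@dataclass(slots=True)
class Review:
    """One consumer rating event: a drug, a condition, a 1-5 score,
    reviewer demographics and a free-text comment."""

    drug_name: str
    condition: str
    rating: int
    age_range: str = ""
    gender: str = "unknown"
    comment: str = ""


@dataclass(slots=True)
class IngredientMapEntry:
    """Brand name to canonical active-ingredient group, per delivery mode."""

    brand_name: str
    ingredient_key: str
    delivery_mode: str = ""


@dataclass(slots=True)
class LabelInfo:
    """Attributes extracted from a drug's FDA label."""

    ingredient_key: str
    black_box: bool
    indicated_conditions: frozenset[str] = field(default_factory=frozenset)
    abuse_dependence: bool = False


@dataclass(slots=True)
class PublicationRecord:
    """One adjudicated publication for a drug pair: does its conclusion
    agree with the deduced online trend?  Unclear conclusions must be
    encoded as ``disagree`` by the adjudicator before ingest."""

    pair_id: str
    source: str
    pub_type: str
    status: str


@dataclass(slots=True)
class ConditionMapEntry:
    """Site condition name to standardized preferred term."""

    site_condition: str
    preferred_term: str


def _read_csv(path: str | Path, columns: list[str], dialect: dict | None = None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    opts = {"dtype": str, "keep_default_na": False}
    if dialect:
        opts.update(dialect)
    frame = pd.read_csv(path, **opts)
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    return frame


def load_reviews(path: str | Path, dialect: dict | None = None) -> list[Review]:
    """Read a reviews table, returning one :class:`Review` per accepted row.

    Rows failing the invariants (non-integer or out-of-range rating, empty
    drug or condition after trimming) are skipped, each with a row-numbered
    warning on the module logger. Gender values outside {male, female} are
    retained as ``unknown``.
    """
    frame = _read_csv(path, REVIEW_COLUMNS, dialect)
    reviews: list[Review] = []
    n_rejected = 0
    for idx, row in enumerate(frame.itertuples(index=False), start=2):  # 1-based + header
        drug = norm_name(row.drug_name)
        condition = norm_name(row.condition)
        raw_rating = str(row.rating).strip()
        try:
            rating = int(raw_rating)
        except ValueError:
            rating = -1
        if rating not in VALID_RATINGS:
            logger.warning("%s row %d: rating %r outside 1-5, row rejected", path, idx, raw_rating)
            n_rejected += 1
            continue
        if not drug or not condition:
            logger.warning("%s row %d: empty drug or condition, row rejected", path, idx)
            n_rejected += 1
            continue
        reviews.append(
            Review(
                drug_name=drug,
                condition=condition,
                rating=rating,
                age_range=str(row.age_range).strip(),
                gender=norm_gender(row.gender),
                comment=str(row.comment),
            )
        )
    if n_rejected:
        logger.info("%s: accepted %d rows, rejected %d", path, len(reviews), n_rejected)
    return reviews


def _parse_bool(value: str, where: str) -> bool:
    v = str(value).strip().lower()
    if v in ("true", "1", "yes"):
        return True
    if v in ("false", "0", "no", ""):
        return False
    raise SchemaError(f"{where}: cannot interpret {value!r} as a boolean")


def load_table(path: str | Path, schema: str, dialect: dict | None = None) -> list:
    """Read and validate one of the auxiliary tables.

    ``schema`` is one of ``ingredient_map``, ``labels``, ``publications``,
    ``condition_map``. Duplicate keys and out-of-vocabulary category values
    raise :class:`SchemaError` naming the offending row.
    """
    if schema not in TABLE_COLUMNS:
        raise ValueError(f"unknown schema {schema!r}; expected one of {sorted(TABLE_COLUMNS)}")
    frame = _read_csv(path, TABLE_COLUMNS[schema], dialect)
    records: list = []
    seen: set = set()
    for idx, row in enumerate(frame.itertuples(index=False), start=2):
        where = f"{path} row {idx}"
        if schema == "ingredient_map":
            entry = IngredientMapEntry(
                brand_name=norm_name(row.brand_name),
                ingredient_key=norm_name(row.ingredient_key),
                delivery_mode=norm_name(row.delivery_mode),
            )
            key = (entry.brand_name, entry.delivery_mode)
            if key in seen:
                raise SchemaError(f"{where}: duplicate (brand_name, delivery_mode) {key}")
            seen.add(key)
        elif schema == "labels":
            key = norm_name(row.ingredient_key)
            if key in seen:
                raise SchemaError(f"{where}: duplicate ingredient_key {key!r}")
            seen.add(key)
            conditions = frozenset(
                norm_name(c) for c in str(row.indicated_conditions).split(";") if c.strip()
            )
            entry = LabelInfo(
                ingredient_key=key,
                black_box=_parse_bool(row.black_box, where),
                indicated_conditions=conditions,
                abuse_dependence=_parse_bool(row.abuse_dependence, where),
            )
        elif schema == "publications":
            status = str(row.status).strip().lower()
            if status == "unclear":
                raise SchemaError(
                    f"{where}: status 'unclear' is not accepted; encode unclear "
                    "publication conclusions as 'disagree' before ingest"
                )
            if status not in PUBLICATION_STATUSES:
                raise SchemaError(f"{where}: status must be agree/disagree, got {status!r}")
            source = str(row.source).strip().lower()
            if source not in PUBLICATION_SOURCES:
                raise SchemaError(f"{where}: unknown source {source!r}")
            pub_type = str(row.pub_type).strip().lower()
            if pub_type not in PUBLICATION_TYPES:
                raise SchemaError(f"{where}: unknown pub_type {pub_type!r}")
            entry = PublicationRecord(
                pair_id=str(row.pair_id).strip().lower(),
                source=source,
                pub_type=pub_type,
                status=status,
            )
        else:  # condition_map
            key = norm_name(row.site_condition)
            if key in seen:
                raise SchemaError(f"{where}: duplicate site_condition {key!r}")
            seen.add(key)
            entry = ConditionMapEntry(site_condition=key, preferred_term=norm_name(row.preferred_term))
        records.append(entry)
    return records


def write_reviews(reviews: list[Review], path: str | Path) -> None:
    frame = pd.DataFrame(
        [
            (r.drug_name, r.condition, r.rating, r.age_range, r.gender, r.comment)
            for r in reviews
        ],
        columns=REVIEW_COLUMNS,
    )
    frame.to_csv(path, index=False)


def write_table(records: list, path: str | Path, schema: str) -> None:
    """Serialize typed records back to their CSV schema (inverse of load_table)."""
    if schema == "ingredient_map":
        rows = [(r.brand_name, r.ingredient_key, r.delivery_mode) for r in records]
    elif schema == "labels":
        rows = [
            (
                r.ingredient_key,
                str(r.black_box).lower(),
                ";".join(sorted(r.indicated_conditions)),
                str(r.abuse_dependence).lower(),
            )
            for r in records
        ]
    elif schema == "publications":
        rows = [(r.pair_id, r.source, r.pub_type, r.status) for r in records]
    elif schema == "condition_map":
        rows = [(r.site_condition, r.preferred_term) for r in records]
    else:
        raise ValueError(f"unknown schema {schema!r}")
    pd.DataFrame(rows, columns=TABLE_COLUMNS[schema]).to_csv(path, index=False)
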