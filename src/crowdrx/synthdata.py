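"""Seeded generator of synthetic review corpora.

Ratings follow a latent-Gaussian model: for each review a latent score is
drawn as

    latent = true_mean + age_slope * (age_years - 40)
             + gender_effect * 1[female] + Normal(0, noise_sd)

and the observed 1-5 rating is the latent value rounded to the nearest
integer and clipped into [1, 5]. The reference age of 40 centers the age
effect so ``true_mean`` is the expected latent score for a mid-aged male
reviewer. Comments are filler tokens plus optional injected target terms
(each with a per-drug probability), supporting text-mining tests.

A single global seed drives per-condition substreams (hashed from the
condition name), so adding or reordering conditions does not perturb the
reviews generated for the others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .data_model import (
    ConditionMapEntry,
    IngredientMapEntry,
    LabelInfo,
    PublicationRecord,
    Review,
    write_reviews,
    write_table,
)
from .screen import age_to_numeric

REFERENCE_AGE = 40.0

_FILLER = (
    "took this for months and the pain was manageable",
    "my doctor switched me after the first prescription",
    "works within the hour most days",
    "had some dizziness in the first week",
    "no real change in my symptoms yet",
    "sleep improved and energy is back",
    "the dose needed adjusting twice",
    "pharmacy kept it in stock which helped",
    "mild stomach upset but tolerable",
    "been on it two years with steady results",
)


@dataclass(slots=True)
class DrugSpec:
    """One synthetic drug: its latent mean rating, sample size, brand
    names and optional comment-term injection probabilities."""

    ingredient_key: str
    true_mean: float
    n_reviews: int
    brands: list[str] = field(default_factory=list)
    delivery_mode: str = "oral"
    term_injection: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.n_reviews < 1:
            raise ValueError("n_reviews must be >= 1")
        if not self.brands:
            self.brands = [self.ingredient_key]


@dataclass(slots=True)
class ConditionSpec:
    """One synthetic condition: its drugs and reviewer-population mix."""

    condition: str
    drugs: list[DrugSpec]
    age_band_weights: dict[str, float] = field(
        default_factory=lambda: {"25-34": 0.2, "35-44": 0.25, "45-54": 0.3, "55-64": 0.15, "65-74": 0.1}
    )
    gender_weights: dict[str, float] = field(
        default_factory=lambda: {"female": 0.6, "male": 0.35, "unknown": 0.05}
    )
    age_slope: float = 0.0
    gender_effect: float = 0.0
    noise_sd: float = 0.8


@dataclass(slots=True)
class SynthConfig:
    conditions: list[ConditionSpec]
    seed: int = 0


def _validate_weights(weights: dict[str, float], what: str) -> None:
    total = sum(weights.values())
    if not weights or abs(total - 1.0) > 1e-6:
        raise ValueError(f"{what} weights must sum to 1, got {total}")
    if any(w < 0 for w in weights.values()):
        raise ValueError(f"{what} weights must be non-negative")


def _condition_rng(seed: int, condition: str) -> np.random.Generator:
    # stable 32-bit hash keeps substreams independent of condition order
    return np.random.default_rng([seed, zlib.crc32(condition.encode("utf-8"))])


def expected_rating(true_mean: float, noise_sd: float) -> float:
    """Expectation of the rounded-and-clipped latent rating, by exact
    integration of the Gaussian over the rounding/clipping bins."""
    from scipy.stats import norm

    if noise_sd == 0:
        return float(np.clip(np.rint(true_mean), 1, 5))
    edges = [-np.inf, 1.5, 2.5, 3.5, 4.5, np.inf]
    probs = np.diff(norm.cdf(edges, loc=true_mean, scale=noise_sd))
    return float(np.dot(np.arange(1, 6), probs))


def generate(config: SynthConfig) -> list[Review]:
    """Generate the full synthetic review corpus (deterministic in seed)."""
    reviews: list[Review] = []
    for cond in config.conditions:
        _validate_weights(cond.age_band_weights, "age band")
        _validate_weights(cond.gender_weights, "gender")
        if cond.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        rng = _condition_rng(config.seed, cond.condition)
        bands = sorted(cond.age_band_weights)
        band_p = np.array([cond.age_band_weights[b] for b in bands])
        band_years = np.array([age_to_numeric(b) for b in bands])
        genders = sorted(cond.gender_weights)
        gender_p = np.array([cond.gender_weights[g] for g in genders])
        for drug in cond.drugs:
            n = drug.n_reviews
            band_idx = rng.choice(len(bands), size=n, p=band_p)
            gender_idx = rng.choice(len(genders), size=n, p=gender_p)
            is_female = np.array([genders[i] == "female" for i in gender_idx])
            latent = (
                drug.true_mean
                + cond.age_slope * (band_years[band_idx] - REFERENCE_AGE)
                + cond.gender_effect * is_female
                + rng.normal(0.0, cond.noise_sd, size=n)
            )
            rating = np.clip(np.rint(latent), 1, 5).astype(int)
            brand_idx = rng.integers(0, len(drug.brands), size=n)
            terms = sorted(drug.term_injection)
            term_draws = rng.random((n, len(terms))) if terms else None
            filler_idx = rng.integers(0, len(_FILLER), size=n)
            for i in range(n):
                comment = _FILLER[filler_idx[i]]
                if terms:
                    injected = [
                        t for j, t in enumerate(terms)
                        if term_draws[i, j] < drug.term_injection[t]
                    ]
                    if injected:
                        comment = comment + " " + " ".join(injected)
                reviews.append(
                    Review(
                        drug_name=drug.brands[brand_idx[i]].strip().lower(),
                        condition=cond.condition.strip().lower(),
                        rating=int(rating[i]),
                        age_range=bands[band_idx[i]],
                        gender=genders[gender_idx[i]],
                        comment=comment,
                    )
                )
    return reviews


def ingredient_map_for(config: SynthConfig) -> list[IngredientMapEntry]:
    """Ingredient-map rows implied by the config's brand lists."""
    entries: dict[tuple[str, str], IngredientMapEntry] = {}
    for cond in config.conditions:
        for drug in cond.drugs:
            for brand in drug.brands:
                key = (brand.strip().lower(), drug.delivery_mode.strip().lower())
                entries[key] = IngredientMapEntry(
                    brand_name=key[0],
                    ingredient_key=drug.ingredient_key.strip().lower(),
                    delivery_mode=key[1],
                )
    return [entries[k] for k in sorted(entries)]


def config_from_yaml(path: str | Path) -> SynthConfig:
    """Load a SynthConfig from a YAML document mirroring the dataclasses."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    conditions = []
    for c in raw.get("conditions", []):
        drugs = [DrugSpec(**d) for d in c.pop("drugs")]
        conditions.append(ConditionSpec(drugs=drugs, **c))
    return SynthConfig(conditions=conditions, seed=int(raw.get("seed", 0)))


# --- the worked-example fixture -------------------------------------------

FIXTURE_SEED = 20121023  # fixed; the fixture is a frozen regression surface


def fixture_config() -> SynthConfig:
    """Small corpus engineered to exercise every pipeline stage.

    A hypertension-like condition carries four drugs with well separated
    latent means (so the ANCOVA screen fires and several pairs clear the
    half-point + rank-test thresholds, one pair mirroring the published
    0.7-point felodipine/amlodipine example); a muscle-spasm-like
    condition carries a modest, sub-threshold difference with an
    abuse-labeled drug whose comments mention addictiveness; an insomnia
    condition has a single under-sized drug that the eligibility filters
    remove.
    """
    hypertension = ConditionSpec(
        condition="high blood pressure",
        drugs=[
            DrugSpec("felodipine", 3.4, 80, brands=["Plendil", "Felodipine ER"]),
            DrugSpec("telmisartan", 3.3, 80, brands=["Micardis"]),
            DrugSpec("amlodipine", 2.5, 80, brands=["Norvasc", "Amlodipine Besylate"]),
            DrugSpec("hydralazine", 1.6, 80, brands=["Apresoline"]),
        ],
        age_slope=0.01,
        gender_effect=0.15,
        noise_sd=1.0,
    )
    muscle_spasm = ConditionSpec(
        condition="muscle spasm",
        drugs=[
            DrugSpec(
                "carisoprodol",
                3.7,
                70,
                brands=["Soma"],
                term_injection={"addict": 0.10, "abuse": 0.04},
            ),
            DrugSpec("cyclobenzaprine", 3.55, 70, brands=["Flexeril"]),
        ],
        noise_sd=1.0,
    )
    insomnia = ConditionSpec(
        condition="insomnia",
        drugs=[DrugSpec("zolpidem", 3.5, 29, brands=["Ambien"])],
        noise_sd=1.0,
    )
    return SynthConfig(conditions=[hypertension, muscle_spasm, insomnia], seed=FIXTURE_SEED)


def fixture_labels() -> list[LabelInfo]:
    return [
        LabelInfo("felodipine", False, frozenset({"hypertension", "angina"}), False),
        LabelInfo("telmisartan", False, frozenset({"hypertension"}), False),
        LabelInfo("amlodipine", True, frozenset({"hypertension", "angina"}), False),
        LabelInfo("hydralazine", False, frozenset({"heart failure"}), False),
        LabelInfo("carisoprodol", False, frozenset({"muscle spasm"}), True),
        LabelInfo("cyclobenzaprine", False, frozenset({"muscle spasm"}), False),
    ]


def fixture_condition_map() -> list[ConditionMapEntry]:
    return [
        ConditionMapEntry("high blood pressure", "hypertension"),
        ConditionMapEntry("muscle spasm", "muscle spasm"),
        ConditionMapEntry("insomnia", "insomnia"),
    ]


def fixture_publications() -> list[PublicationRecord]:
    """Adjudicated publications for the fixture's passing pairs.

    Constructed to exercise every verdict rule: a 3-agree/1-disagree
    majority, a 2-2 inconclusive tie, a unanimous disagreement whose
    lower-rated drug carries a black box warning (reconciliation flips
    it), an off-label disagreement, and a unanimous agreement.
    """

    def rec(a: str, b: str, source: str, pub_type: str, status: str) -> PublicationRecord:
        lo, hi = sorted((a, b))
        return PublicationRecord(f"hypertension|{lo}|{hi}", source, pub_type, status)

    return [
        # felodipine vs amlodipine: 3 agree, 1 disagree -> agree
        rec("felodipine", "amlodipine", "pubmed", "head_to_head", "agree"),
        rec("felodipine", "amlodipine", "pubmed", "head_to_head", "agree"),
        rec("felodipine", "amlodipine", "scholar", "review", "agree"),
        rec("felodipine", "amlodipine", "scholar", "head_to_head", "disagree"),
        # telmisartan vs amlodipine: unanimous disagree; amlodipine (lower
        # rated) has a black box warning -> reconciliation flips to agree
        rec("telmisartan", "amlodipine", "pubmed", "head_to_head", "disagree"),
        rec("telmisartan", "amlodipine", "scholar", "head_to_head", "disagree"),
        # amlodipine vs hydralazine: 2-2 tie -> inconclusive, excluded
        rec("amlodipine", "hydralazine", "pubmed", "head_to_head", "agree"),
        rec("amlodipine", "hydralazine", "pubmed", "review", "agree"),
        rec("amlodipine", "hydralazine", "scholar", "head_to_head", "disagree"),
        rec("amlodipine", "hydralazine", "scholar", "other", "disagree"),
        # felodipine vs hydralazine: unanimous disagree; hydralazine is
        # off-label for hypertension -> tagged, not flipped
        rec("felodipine", "hydralazine", "pubmed", "head_to_head", "disagree"),
        rec("felodipine", "hydralazine", "scholar", "meta_analysis", "disagree"),
        # telmisartan vs hydralazine: unanimous agree
        rec("telmisartan", "hydralazine", "regulatory", "other", "agree"),
        # a pair outside the screened conditions: ignored by the pipeline
        PublicationRecord(
            "muscle spasm|carisoprodol|cyclobenzaprine", "pubmed", "head_to_head", "disagree"
        ),
    ]


def make_paper_fixture(out_dir: str | Path | None = None):
    """Build the complete fixture bundle; optionally write it as CSVs plus
    a ready-to-run pipeline config.

    Returns a dict with keys reviews, ingredient_map, labels,
    publications, condition_map (record lists) and, when ``out_dir`` is
    given, the written paths under "paths".
    """
    config = fixture_config()
    bundle = {
        "reviews": generate(config),
        "ingredient_map": ingredient_map_for(config),
        "labels": fixture_labels(),
        "publications": fixture_publications(),
        "condition_map": fixture_condition_map(),
        "synth_config": config,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "reviews": out / "reviews.csv",
            "ingredient_map": out / "ingredient_map.csv",
            "labels": out / "labels.csv",
            "publications": out / "publications.csv",
            "condition_map": out / "condition_map.csv",
        }
        write_reviews(bundle["reviews"], paths["reviews"])
        for schema in ("ingredient_map", "labels", "publications", "condition_map"):
            write_table(bundle[schema], paths[schema], schema)
        # paths are stored relative to the config file so the bundle is portable
        run_cfg = {name: paths[name].name for name in paths}
        run_cfg["out_dir"] = "results"
        cfg_path = out / "config.yaml"
        with open(cfg_path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(run_cfg, fh, sort_keys=True)
        paths["config"] = cfg_path
        bundle["paths"] = paths
    return bundle
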