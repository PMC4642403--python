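"""End-to-end orchestration: ingest -> group -> screen -> trends ->
concordance -> text mining, plus the concordance-versus-threshold curve.

The run writes one CSV per stage into the output directory together with a
structured, machine-parseable text report whose content depends only on
the inputs and configuration (reruns are byte-identical). Missing optional
inputs degrade gracefully: without a publications table the concordance
stage is skipped with a warning; without labels, reconciliation is an
identity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import yaml

from . import preprocess, screen, textmine, trends
from .concordance import (
    ConcordanceResult,
    Verdict,
    concordance,
    pair_join_id,
    reconcile_with_labels,
    summarize_verdicts,
    write_verdicts,
)
from .data_model import load_reviews, load_table

logger = logging.getLogger(__name__)

DEFAULT_CURVE_THRESHOLDS = (0.5, 0.6, 0.7, 0.8, 0.9, 1.0)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass(slots=True)
class RunConfig:
    """Input paths and analysis thresholds for one pipeline run."""

    reviews: str
    ingredient_map: str
    out_dir: str
    labels: str | None = None
    publications: str | None = None
    condition_map: str | None = None
    min_reviews: int = 30
    min_drugs: int = 2
    alpha: float = 0.05
    diff_threshold: float = 0.5
    p_threshold: float = 0.01
    curve_thresholds: tuple[float, ...] = DEFAULT_CURVE_THRESHOLDS
    terms: tuple[str, ...] = ("addict", "abuse")
    top_k: int = 10
    seed: int = 0

    def __post_init__(self):
        if min(self.min_reviews, self.min_drugs) < 1 or self.alpha <= 0:
            raise ValueError("thresholds must be positive")
        if self.diff_threshold < 0 or not (0 < self.p_threshold <= 1):
            raise ValueError("invalid pair thresholds")
        ts = tuple(float(t) for t in self.curve_thresholds)
        if list(ts) != sorted(ts):
            raise ValueError("curve_thresholds must be sorted ascending")
        self.curve_thresholds = ts

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        base = path.parent
        for key in ("reviews", "ingredient_map", "labels", "publications", "condition_map", "out_dir"):
            if raw.get(key) is not None:
                p = Path(raw[key])
                raw[key] = str(p if p.is_absolute() else base / p)
        for key in ("curve_thresholds", "terms"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass(slots=True)
class CurvePoint:
    """Concordance at one rating-difference cutoff, raw and reconciled."""

    threshold: float
    raw: ConcordanceResult
    reconciled: ConcordanceResult


def concordance_curve(
    pairs: list[trends.TrendPair],
    verdicts: dict[str, Verdict],
    labels,
    thresholds,
    condition_map: dict[str, str] | None = None,
) -> list[CurvePoint]:
    """Concordance at each rating-difference cutoff, before and after
    black-box label reconciliation.

    At cutoff t the passing pairs are restricted to those whose adjusted
    difference is >= t; verdicts are then matched by pair id (inconclusive
    ones drop out). Cutoffs with no matched verdicts are omitted with a
    warning. The pair sets shrink monotonically as t rises.
    """
    points: list[CurvePoint] = []
    passing = [p for p in pairs if p.passes]
    for t in thresholds:
        sel = [p for p in passing if p.diff >= t]
        matched = [
            verdicts[jid]
            for p in sel
            if (jid := pair_join_id(p, condition_map)) in verdicts
            and verdicts[jid].verdict != "inconclusive"
        ]
        if not matched:
            logger.warning("no verdicts at diff threshold %.2f; point omitted", t)
            continue
        raw = concordance(matched)
        revised = reconcile_with_labels(matched, sel, labels, condition_map)
        points.append(CurvePoint(threshold=t, raw=raw, reconciled=concordance(revised)))
    return points


def _fmt(value) -> str:
    if isinstance(value, bool):
        return str(value).lower()
    if isinstance(value, float):
        return f"{value:.10g}"
    return str(value)


def _write_report(report: dict, path: Path) -> None:
    lines = []
    for section in sorted(report):
        lines.append(f"[{section}]")
        for key in sorted(report[section]):
            lines.append(f"{key} = {_fmt(report[section][key])}")
        lines.append("")
    path.write_text("\n".join(lines), encoding="utf-8")


def run(config: RunConfig) -> dict:
    """Execute every stage in order; returns the structured report dict.

    Any stage failure raises :class:`StageError` naming the stage.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict[str, dict] = {"counts": {}, "screen": {}, "trends": {}, "concordance": {}, "textmine": {}}

    # --- ingest ---
    try:
        reviews = load_reviews(config.reviews)
        mapping = load_table(config.ingredient_map, "ingredient_map")
        labels = load_table(config.labels, "labels") if _readable(config.labels) else []
        publications = (
            load_table(config.publications, "publications")
            if _readable(config.publications)
            else None
        )
        cmap_records = (
            load_table(config.condition_map, "condition_map")
            if _readable(config.condition_map)
            else []
        )
    except (OSError, ValueError) as exc:
        raise StageError("ingest", str(exc)) from exc
    if config.publications is not None and publications is None:
        logger.warning("publications table %r not readable; concordance will be skipped", config.publications)
    condition_map = {c.site_condition: c.preferred_term for c in cmap_records}
    report["counts"]["reviews_loaded"] = len(reviews)

    # --- preprocess ---
    try:
        groups = preprocess.group_reviews(reviews, mapping)
        preprocess.write_grouped(groups, out_dir / "grouped_reviews.csv")
        datasets = preprocess.filter_eligible(groups, config.min_reviews, config.min_drugs)
    except ValueError as exc:
        raise StageError("preprocess", str(exc)) from exc
    report["counts"]["drug_groups_total"] = len(groups)
    report["counts"]["conditions_eligible"] = len(datasets)
    report["counts"]["drug_groups_eligible"] = sum(len(d.drug_groups) for d in datasets)
    report["counts"]["reviews_eligible"] = sum(d.n_reviews for d in datasets)

    # --- screen ---
    models: dict[str, screen.ConditionModel] = {}
    results = []
    skipped = 0
    for dataset in datasets:
        try:
            model = screen.ConditionModel(dataset)
            results.append(screen.ancova_drug_test(dataset, model))
            models[dataset.condition] = model
        except screen.ScreenSkip as exc:
            logger.warning("screen: %s", exc)
            skipped += 1
    results = screen.bonferroni_screen(results, config.alpha)
    screen.write_screen_results(results, out_dir / "screen_results.csv")
    significant = {r.condition for r in results if r.significant}
    report["counts"]["conditions_tested"] = len(results)
    report["counts"]["conditions_skipped"] = skipped
    report["counts"]["conditions_significant"] = len(significant)
    for r in results:
        report["screen"][f"{r.condition}.p_adjusted"] = r.p_adjusted
        report["screen"][f"{r.condition}.significant"] = r.significant

    # --- trends ---
    all_pairs: list[trends.TrendPair] = []
    try:
        for dataset in datasets:
            if dataset.condition not in significant:
                continue
            ratings = trends.adjusted_ratings(dataset, models[dataset.condition])
            all_pairs.extend(
                trends.deduce_trends(dataset, ratings, config.diff_threshold, config.p_threshold)
            )
    except (KeyError, ValueError) as exc:
        raise StageError("trends", str(exc)) from exc
    trends.write_trend_pairs(all_pairs, out_dir / "trend_pairs.csv")
    passing = [p for p in all_pairs if p.passes]
    report["counts"]["pairs_evaluated"] = len(all_pairs)
    report["counts"]["pairs_passing"] = len(passing)
    for p in sorted(passing, key=lambda p: (p.condition, p.drug_hi, p.drug_lo)):
        report["trends"][f"{p.condition}.{p.drug_hi}>{p.drug_lo}.diff"] = round(p.diff, 2)

    # --- concordance ---
    if publications is not None:
        try:
            verdicts = summarize_verdicts(publications)
            passing_ids = {pair_join_id(p, condition_map) for p in passing}
            matched = [v for pid, v in verdicts.items() if pid in passing_ids]
            decided = [v for v in matched if v.verdict != "inconclusive"]
            revised = reconcile_with_labels(decided, passing, labels, condition_map)
            write_verdicts(
                revised + [v for v in matched if v.verdict == "inconclusive"],
                out_dir / "verdicts.csv",
            )
            tally = {
                "agree": sum(1 for v in decided if v.verdict == "agree"),
                "disagree": sum(1 for v in decided if v.verdict == "disagree"),
                "inconclusive": sum(1 for v in matched if v.verdict == "inconclusive"),
                "absent": len(passing) - len(matched),
            }
            report["concordance"].update({f"verdicts_{k}": v for k, v in tally.items()})
            if decided:
                raw = concordance(decided)
                rec = concordance(revised)
                report["concordance"]["raw"] = f"{raw.n_agree}/{raw.n_total}"
                report["concordance"]["raw_p"] = raw.p_binomial
                report["concordance"]["reconciled"] = f"{rec.n_agree}/{rec.n_total}"
                report["concordance"]["reconciled_p"] = rec.p_binomial
            curve = concordance_curve(
                all_pairs, verdicts, labels, config.curve_thresholds, condition_map
            )
            _write_curve(curve, out_dir / "concordance.csv")
            for pt in curve:
                key = f"t{pt.threshold:.2f}"
                report["concordance"][f"{key}.raw"] = f"{pt.raw.n_agree}/{pt.raw.n_total}"
                report["concordance"][f"{key}.reconciled"] = (
                    f"{pt.reconciled.n_agree}/{pt.reconciled.n_total}"
                )
        except ValueError as exc:
            raise StageError("concordance", str(exc)) from exc
    else:
        logger.warning("no publications table; concordance stage skipped")
        report["concordance"]["skipped"] = True

    # --- textmine ---
    try:
        stats_list = []
        for dataset in datasets:
            for group in dataset.drug_groups:
                stats_list.append(
                    textmine.term_frequency(group.reviews, config.terms, group.group_key)
                )
        textmine.write_term_stats(stats_list, out_dir / "term_stats.csv")
        top_rows = []
        for dataset in datasets:
            for group in dataset.drug_groups:
                for term, count in textmine.top_terms(group.reviews, k=config.top_k):
                    top_rows.append((f"{dataset.condition}:{group.group_key}", term, count))
        import pandas as pd

        pd.DataFrame(top_rows, columns=["group", "term", "count"]).to_csv(
            out_dir / "top_terms.csv", index=False
        )
        for s in stats_list:
            if s.n_hit:
                report["textmine"][f"{s.ingredient_key}.term_frequency"] = round(s.frequency, 4)
    except ValueError as exc:
        raise StageError("textmine", str(exc)) from exc

    _write_report(report, out_dir / "report.txt")
    return report


def _readable(path: str | None) -> bool:
    return path is not None and Path(path).exists()


def _write_curve(points: list[CurvePoint], path: Path) -> None:
    import pandas as pd

    rows = []
    for pt in points:
        rows.append(
            (pt.threshold, pt.raw.n_agree, pt.raw.n_total, pt.raw.proportion, pt.raw.p_binomial, False)
        )
        rows.append(
            (
                pt.threshold,
                pt.reconciled.n_agree,
                pt.reconciled.n_total,
                pt.reconciled.proportion,
                pt.reconciled.p_binomial,
                True,
            )
        )
    pd.DataFrame(
        rows, columns=["threshold", "n_agree", "n_total", "proportion", "p_binomial", "reconciled"]
    ).to_csv(path, index=False)
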