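"""Literature verdicts, binomial concordance, and FDA-label reconciliation.

Each deduced online trend may have several adjudicated publications, each
recorded as agreeing or disagreeing with the trend. They are combined by
majority vote into a single verdict; ties are inconclusive and excluded
from downstream counting. Concordance is the fraction of verdicts that
agree, tested against chance with a one-sided cumulative binomial at
success probability 0.5 (the probability of observing at least the
attained number of agreements).

Disagreeing verdicts are then reconciled against FDA-label attributes:
when the lower-rated drug carries a black box warning and the higher-rated
one does not, the online trend is taken as supported by the label and the
verdict is flipped to agree. Off-label use of the lower-rated drug and
abuse/dependence potential of the higher-rated drug are recorded as
explanatory tags without altering the verdict.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from math import comb, lgamma, log, log1p

import numpy as np
import pandas as pd

from .data_model import LabelInfo, PublicationRecord, make_pair_id, norm_name

logger = logging.getLogger(__name__)

TAG_BLACK_BOX = "black_box"
TAG_OFF_LABEL = "off_label"
TAG_ADDICTIVE = "addictive"
TAG_UNEXPLAINED = "unexplained"


@dataclass(slots=True)
class Verdict:
    """Majority-vote summary of publication records for one drug pair."""

    pair_id: str
    n_agree: int
    n_disagree: int
    verdict: str  # agree | disagree | inconclusive
    unanimous: bool
    tag: str = ""


@dataclass(slots=True)
class ConcordanceResult:
    """Agreement count, proportion and one-sided binomial tail p-value."""

    n_agree: int
    n_total: int
    proportion: float
    p_binomial: float


def summarize_verdict(records: list[PublicationRecord]) -> Verdict:
    """Combine one pair's publication records into a single verdict.

    agree if agreements outnumber disagreements, disagree if the reverse,
    inconclusive on a tie. Unanimous means every publication voted the
    same way. An empty record list has no verdict at all (error), which is
    distinct from inconclusive.
    """
    if not records:
        raise ValueError("summarize_verdict requires at least one publication record")
    pair_ids = {r.pair_id for r in records}
    if len(pair_ids) != 1:
        raise ValueError(f"records span multiple pairs: {sorted(pair_ids)}")
    n_agree = sum(1 for r in records if r.status == "agree")
    n_disagree = len(records) - n_agree
    if n_agree > n_disagree:
        verdict = "agree"
    elif n_disagree > n_agree:
        verdict = "disagree"
    else:
        verdict = "inconclusive"
    return Verdict(
        pair_id=records[0].pair_id,
        n_agree=n_agree,
        n_disagree=n_disagree,
        verdict=verdict,
        unanimous=min(n_agree, n_disagree) == 0,
    )


def summarize_verdicts(records: list[PublicationRecord]) -> dict[str, Verdict]:
    """Group publication records by pair and summarize each pair."""
    by_pair: dict[str, list[PublicationRecord]] = {}
    for r in records:
        by_pair.setdefault(r.pair_id, []).append(r)
    return {pid: summarize_verdict(recs) for pid, recs in sorted(by_pair.items())}


def binomial_tail(n_agree: int, n_total: int, p_success: float = 0.5) -> float:
    """Exact one-sided upper-tail binomial probability P(X >= n_agree).

    For p = 0.5 the sum of binomial coefficients over 2**n is evaluated
    with exact integer arithmetic; otherwise terms are accumulated in
    log-space for numerical stability.
    """
    if not (0 <= n_agree <= n_total) or n_total < 1:
        raise ValueError(f"invalid counts ({n_agree}, {n_total})")
    if not (0.0 <= p_success <= 1.0):
        raise ValueError("p_success must be a probability")
    if n_agree == 0:
        return 1.0
    if p_success == 0.5:
        return float(sum(comb(n_total, k) for k in range(n_agree, n_total + 1)) / 2**n_total)
    if p_success in (0.0, 1.0):
        return float(p_success == 1.0 or n_agree == 0)
    log_terms = [
        lgamma(n_total + 1)
        - lgamma(k + 1)
        - lgamma(n_total - k + 1)
        + k * log(p_success)
        + (n_total - k) * log1p(-p_success)
        for k in range(n_agree, n_total + 1)
    ]
    m = max(log_terms)
    return float(min(1.0, np.exp(m) * np.sum(np.exp(np.array(log_terms) - m))))


def concordance(verdicts: list[Verdict]) -> ConcordanceResult:
    """Concordance of agree/disagree verdicts with their online trends.

    Inconclusive verdicts are excluded (they carry no direction); the
    remaining list must be non-empty.
    """
    decided = [v for v in verdicts if v.verdict in ("agree", "disagree")]
    if not decided:
        raise ValueError("concordance requires at least one decided verdict")
    n_agree = sum(1 for v in decided if v.verdict == "agree")
    n_total = len(decided)
    return ConcordanceResult(
        n_agree=n_agree,
        n_total=n_total,
        proportion=n_agree / n_total,
        p_binomial=binomial_tail(n_agree, n_total),
    )


def off_label_flag(label: LabelInfo, condition_preferred_term: str) -> bool:
    """True when the condition's preferred term is absent from the label's
    indicated conditions (case-insensitive exact match)."""
    return norm_name(condition_preferred_term) not in label.indicated_conditions


def _ingredient_of(group_key: str) -> str:
    # group keys may carry a "|mode" suffix; labels are keyed by ingredient
    return group_key.split("|", 1)[0]


def pair_join_id(pair, condition_map: dict[str, str] | None = None) -> str:
    """Join key linking a trend pair to publication records.

    Publications are indexed by the condition's preferred term (literature
    vocabulary) and the two ingredient keys without delivery-mode
    suffixes; the optional condition map translates the site condition.
    """
    cmap = condition_map or {}
    term = cmap.get(pair.condition, pair.condition)
    return make_pair_id(term, _ingredient_of(pair.drug_hi), _ingredient_of(pair.drug_lo))


def reconcile_with_labels(
    verdicts: list[Verdict],
    pairs,
    labels: list[LabelInfo],
    condition_map: dict[str, str] | None = None,
) -> list[Verdict]:
    """Tag disagreeing verdicts with FDA-label observations; flip black-box cases.

    For each disagree verdict whose pair is known, the first applicable
    observation is recorded (precedence black_box > off_label > addictive):

    * black_box — the lower-rated drug has a black box warning and the
      higher-rated one does not; the label supports the online trend, so
      the verdict is flipped to agree.
    * off_label — the condition is absent from the lower-rated drug's
      indications but present in the higher-rated drug's (annotation only).
    * addictive — the higher-rated drug notes abuse/dependence and the
      lower-rated does not (annotation only).

    Attributes shared by both drugs yield no observation. Disagreements
    with no applicable observation (or missing labels) are tagged
    "unexplained". Agree and inconclusive verdicts are never modified.
    """
    if not labels:
        return [dataclasses.replace(v) for v in verdicts]
    by_key = {l.ingredient_key: l for l in labels}
    by_pair = {pair_join_id(p, condition_map): p for p in pairs}
    cmap = condition_map or {}
    out: list[Verdict] = []
    for v in verdicts:
        if v.verdict != "disagree":
            out.append(dataclasses.replace(v))
            continue
        pair = by_pair.get(v.pair_id)
        if pair is None:
            logger.warning("verdict %r has no matching trend pair; left untagged", v.pair_id)
            out.append(dataclasses.replace(v, tag=TAG_UNEXPLAINED))
            continue
        hi = by_key.get(_ingredient_of(pair.drug_hi))
        lo = by_key.get(_ingredient_of(pair.drug_lo))
        term = cmap.get(pair.condition, pair.condition)
        tag = TAG_UNEXPLAINED
        flip = False
        if hi is not None and lo is not None:
            if lo.black_box and not hi.black_box:
                tag, flip = TAG_BLACK_BOX, True
            elif off_label_flag(lo, term) and not off_label_flag(hi, term):
                tag = TAG_OFF_LABEL
            elif hi.abuse_dependence and not lo.abuse_dependence:
                tag = TAG_ADDICTIVE
        revised = dataclasses.replace(v, tag=tag)
        if flip:
            revised.verdict = "agree"
        out.append(revised)
    return out


def write_verdicts(verdicts: list[Verdict], path) -> None:
    rows = [
        (v.pair_id, v.n_agree, v.n_disagree, v.verdict, v.unanimous, v.tag)
        for v in sorted(verdicts, key=lambda v: v.pair_id)
    ]
    pd.DataFrame(
        rows, columns=["pair_id", "n_agree", "n_disagree", "verdict", "unanimous", "tag"]
    ).to_csv(path, index=False)
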