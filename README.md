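# crowdrx

Can crowd-sourced consumer drug reviews tell you which of two drugs works
better? `crowdrx` implements a pharmacovigilance-style pipeline that turns
tables of consumer reviews — a drug name, a condition, a 1–5 satisfaction
rating, reviewer age band and gender, and a free-text comment — into
statistically screened pairwise **online trends** ("drug A outperforms
drug B for condition C"), and then measures how often those trends are
supported by adjudicated literature verdicts and FDA-label attributes.

It is aimed at researchers studying consumer-generated health data:
everything runs from plain CSV tables, and a seeded synthetic-review
generator stands in for scraped corpora so every stage is testable and
reproducible offline.

## Method

For each condition *c* with at least two drug groups (brands pooled by
active ingredient and delivery mode, each with ≥ 30 reviews):

1. **ANCOVA screen.** Fit the linear model

   `rating ~ drug + gender + age`

   (main effects only; age in years = the midpoint of the reviewer's age
   band, e.g. "25-34" → 29.5). Test the drug factor with the partial
   F-statistic `F = ((SSE_red − SSE_full)/Δdf) / (SSE_full/df_res)` —
   equal to the Type-III test for this model — and Bonferroni-correct
   across the N conditions tested: a condition passes when
   `min(1, N·p) < .05`.

2. **Trend pairs.** Within passing conditions, each drug's *adjusted
   rating* is the model prediction at the condition's most common age and
   gender. An ordered pair (hi, lo) deduces an online trend when
   `adj_hi − adj_lo ≥ 0.5` **and** the two drugs' raw ratings differ by a
   Mann-Whitney U test at two-sided `P < .01` (exact permutation tail on
   the tied 1–5 lattice; see `docs/methods.md`).

3. **Concordance.** Publications adjudicated as agreeing/disagreeing with
   each trend are majority-voted into verdicts (ties are inconclusive and
   excluded). With *k* agreeing of *n* verdicts, the chance-support
   p-value is the exact binomial upper tail
   `P(X ≥ k) = Σ_{j≥k} C(n,j)/2^n`.

4. **Label reconciliation.** A disagreeing verdict whose lower-rated drug
   carries an FDA black box warning (and the higher-rated does not) is
   flipped to agree; off-label use of the lower-rated drug and
   abuse/dependence of the higher-rated drug are recorded as explanatory
   tags. A concordance-versus-cutoff curve is reported raw and
   reconciled.

5. **Text mining.** Per-drug term-mention rates (substring matching, so
   "addicting" hits "addict"), 2×2 chi-square contrasts between drugs,
   rating shares among term-mentioning reviews, and stopword-filtered
   token rankings (word-cloud data).

## Worked example

The package ships a seeded worked-example corpus: a hypertension-like
condition with four drugs whose planted satisfaction levels differ, a
muscle-spasm condition with an abuse-labeled drug, matching publication
adjudications and FDA-label attributes.

```bash
crowdrx fixture --out demo
crowdrx run --config demo/config.yaml
```

prints

```
report written to demo/results/report.txt
conditions_eligible = 2
conditions_significant = 1
conditions_skipped = 0
conditions_tested = 2
drug_groups_eligible = 6
drug_groups_total = 7
pairs_evaluated = 6
pairs_passing = 5
reviews_eligible = 460
reviews_loaded = 489
```

Reading the report: of 489 generated reviews, the insomnia condition is
dropped by the eligibility filters (one drug, 29 reviews), the
hypertension-like condition passes the Bonferroni-corrected ANCOVA screen
while muscle spasm does not, and 5 of its 6 drug pairs clear the
half-point + rank-test thresholds. The concordance section shows the
constructed publication verdicts: 2 of 4 decided verdicts agree with the
online trends, rising to 3 of 4 after the black-box flip, with one 2–2
publication tie excluded as inconclusive. `demo/results/` also contains
per-stage CSVs (`screen_results.csv`, `trend_pairs.csv`, `verdicts.csv`,
`concordance.csv`, `term_stats.csv`, `top_terms.csv`).

Synthetic corpora with your own structure come from a YAML generator
config:

```bash
crowdrx simulate --config my_sim.yaml --out data/
```

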