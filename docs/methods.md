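# Methods

This note records the statistical model behind `crowdrx`, the choices made
where the design was genuinely open, and what the synthetic-data tests do
and do not establish about real review corpora.

## Data model and normalization

All inputs are UTF-8 CSVs with fixed headers (see `crowdrx.data_model`).
Drug and condition names from consumer sites are noisy, so they are
trimmed and lowercased on ingest and compared case-insensitively
throughout. Ratings must be integers 1–5; rows violating this (or with an
empty drug/condition) are rejected individually with row-numbered log
diagnostics, never silently. Gender strings outside {male, female} are
retained as a third level, "unknown" — the model treats gender as an
unordered factor, so no information is lost and no reviews are discarded.
Publication adjudications must be binary; an "unclear" conclusion is the
adjudicator's responsibility to encode as `disagree` before ingest (the
reader refuses it with guidance rather than guessing).

## Grouping and eligibility

Brands sharing active ingredient(s) *and* delivery mode are pooled within
each condition; conditions are fully independent strata. Brands missing
from the ingredient map keep their own (lowercased) name as a singleton
key, so identically named unmapped rows still merge. If one brand appears
in the map under several delivery modes, reviews (which carry no mode)
are assigned to the lexicographically first mode, with a warning — a
deterministic resolution of an ambiguity the input format allows.

Two inclusive filters apply in order: a drug group needs at least
`min_reviews` (default 30) reviews for its condition, and a condition
then needs at least `min_drugs` (default 2) surviving groups. Running the
drug filter first means the two-drug requirement refers to groups that
can actually be analyzed. The filter is idempotent.

## The ANCOVA screen

Per condition, `rating ~ drug + gender + age` is fitted by least squares
(treatment coding, lexicographically first levels as references; age in
years from the band midpoint). The drug factor is tested by the partial
F-test of the full model against `rating ~ gender + age`, which equals
the Type-III drug test for a main-effects-only model while avoiding
contrast-coding ambiguity. Raw p-values are Bonferroni-corrected by the
number of conditions actually modeled in the batch — not a fixed
constant — so the screen generalizes to any corpus; `alpha` defaults to
.05.

Numerical choices:

* Open-ended age bands map to fixed-width bands: "75 or over" is read as
  75–84 (→ 79.5), "under 18" as 13–17 (→ 15.0). Unparseable bands exclude
  the review from model fitting only; it still contributes to rank tests
  and text mining, maximizing usable data while keeping age numeric.
* Degrees of freedom follow numerical matrix ranks, so a collinear column
  (e.g. a drug whose reviewers all share one age band) is effectively
  dropped with a warning instead of aborting; the minimum-norm
  least-squares solution keeps fitted values well-defined.
* A saturated design (no residual df) or a drug factor with no estimable
  contrast skips the condition with a named diagnostic.
* A perfect fit where drugs add nothing yields F = 0, p = 1 (all-identical
  ratings fall here).

## Adjusted ratings and trend pairs

A drug's adjusted rating is the model prediction at the condition's modal
age band (converted to years) and modal gender, computed over all modeled
reviews of the condition; every drug in a condition is evaluated at the
same covariate point, removing demographic imbalance between reviewer
populations. Ties break deterministically: younger band, then
lexicographically smaller gender label. Adjusted scores are linear
predictions and may leave [1, 5]; outputs round to 2 decimals but
pass/fail decisions use unrounded values.

Every unordered drug pair in a screened condition is evaluated. A pair
deduces an online trend when the adjusted difference is ≥ 0.5 points
(inclusive, "at least half a point") and the Mann-Whitney p on the drugs'
raw ratings — not residuals — is strictly below .01.

### The Mann-Whitney p-value on tied ordinal data

Ratings take five values, so ties dominate and the usual normal
approximation is at its weakest. The implementation uses midranks and
measures two-sided extremity symmetrically by |U − n₁n₂/2|, with three
regimes:

* pooled n ≤ 12: exhaustive enumeration of all C(n₁+n₂, n₁) label
  assignments;
* few distinct pooled values (≤ 10, always true for 1–5 ratings) and a
  modest table size: the exact permutation distribution of the rank sum,
  computed by dynamic programming over tie groups — a multivariate
  hypergeometric convolution on the doubled-midrank lattice. This was
  chosen after measuring that the tie-corrected normal approximation
  (with or without an Edgeworth correction) can be off by up to ~0.02 in
  two-sided p against a 20,000-draw permutation oracle at n = 40 + 40;
  the DP is exact and costs milliseconds at that size;
* otherwise: normal approximation with tie-corrected variance and a 0.5
  continuity correction (matching standard asymptotic implementations).

The DP convolves per tie group the number of first-sample members drawn
against the accumulated doubled rank sum; float64 accumulation of
binomial-coefficient weights keeps relative error near machine epsilon,
verified against exhaustive enumeration.

## Verdicts, concordance, reconciliation

Publications per pair are majority-voted: agree if agreements outnumber
disagreements, disagree if the reverse, inconclusive on a tie (excluded
from all counting; a pair with *no* publications is absent, a distinct
state). The concordance p-value is the exact one-sided upper binomial
tail at success probability 0.5 — for p = 0.5 an exact integer sum over
2^n, otherwise a log-space accumulation.

Reconciliation examines only disagreeing verdicts, with one observation
tag per pair at precedence black_box > off_label > addictive:

* **black_box** (flips the verdict to agree): lower-rated drug has a
  black box warning, higher-rated does not — the label independently
  supports the crowd's preference;
* **off_label** (tag only): the condition's preferred term is absent from
  the lower-rated drug's indications but present in the higher-rated
  drug's;
* **addictive** (tag only): the higher-rated drug notes abuse/dependence,
  the lower-rated does not.

Attributes shared by both drugs are no observation; anything else is
"unexplained". Only the black-box rule changes counts, matching the
(48+7)/77 style of arithmetic the analysis is designed to reproduce. An
"alternative/second-line" explanation cannot be derived from label
attributes and must come from the analyst, not this code. Pair join keys
use the condition's preferred term (the vocabulary literature searches
use) and ingredient keys with delivery-mode suffixes stripped.

The concordance curve re-slices the already-deduced pairs by adjusted
difference cutoffs (default 0.5–1.0); the rank-test threshold stays fixed
at .01. Cutoffs with no matched verdicts are omitted with a warning.

## Text mining

A review mentions a term when its lowercased comment contains the term as
a substring — deliberate, so inflections ("addicting", "addictive") count
— and each review counts once however many terms match. The 2×2
chi-square uses the closed form N(ad−bc)²/((a+b)(c+d)(a+c)(b+d)) with 1
df and no Yates correction by default (a flag enables it); a zero
marginal degenerates to (0, 1) with a warning. Token ranking lowercases,
splits on non-alphanumeric runs, drops tokens shorter than 2 characters
and a fixed English stopword list shipped in `crowdrx.stopwords`
(reproducible bit-for-bit, overridable), and breaks count ties
alphabetically.

## Synthetic data generator

Ratings follow a latent-Gaussian mechanism:

    latent = true_mean + age_slope·(age − 40) + gender_effect·1[female] + N(0, noise_sd)
    rating = clip(round(latent), 1, 5)

the simplest model producing ordinal 1–5 data with controllable drug
means and covariate effects; the analysis itself treats ratings as
numeric, so nothing finer is needed. The reference age 40 centers the age
effect, making `true_mean` the expected latent score of a mid-aged male
reviewer. `expected_rating` integrates the Gaussian over the
rounding/clipping bins, giving an exact oracle for the observed mean.
One global seed drives per-condition substreams hashed from the condition
name, so adding or reordering conditions leaves the others' reviews
byte-identical. Comments are sampled filler phrases plus injected target
terms with per-drug probabilities.

What the generator does **not** emulate: reviewer self-selection,
correlation between rating and comment sentiment, dosage/duration
covariates, non-Gaussian rating polarization (real review corpora are
often bimodal at 1 and 5). Tests passing on this generator establish the
estimators' correctness and calibration under the assumed model — not
that real consumer reviews satisfy those assumptions.

The built-in worked-example fixture (`make_paper_fixture`, fixed internal
seed) plants a four-drug hypertension-like condition spanning adjusted
differences from ~0.1 (below threshold) to ~1.5, a sub-threshold
muscle-spasm condition whose higher-rated drug is abuse-labeled and has
addiction-mentioning comments injected, an under-sized insomnia condition
for the filters, and publication/label tables exercising every verdict
and reconciliation rule (a 3–1 majority, a 2–2 tie, a black-box flip, an
off-label tag). Its pipeline outcomes at the fixed seed (1 significant
condition, 5 passing pairs, 2/4 → 3/4 concordance) are frozen as
regression values.

## Problem sizes in the test suite

Statistical property tests use scaled simulation designs chosen to give
tight Monte-Carlo error at interactive runtimes: type-I control over 500
null replicates (3 drugs × 40 reviews), planted-pair detection over 200
replicates (2 drugs × 100 reviews, 1.0 latent-point gap), mean recovery
over 50 seeds (2 drugs × 500 reviews), screen power over 200 replicates
(0.5-point gap, 2 × 200). The full suite runs in a few seconds.

## Known limitations

* The ANCOVA treats ordinal ratings as numeric (as the analysis it
  implements does); an ordinal-logit screen is out of scope.
* No multiplicity correction across pairs within a condition — the design
  bounds multiplicity at the condition level only.
* Brand-name matching is exact after normalization; no fuzzy matching.
* The concordance machinery assumes publications were adjudicated
  upstream; it cannot detect adjudication bias.
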