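# Methods

## Exposure-era model

The unit of classification is the *exposure era*: a maximal period of
continuous medication supply for one patient and drug class. A fill on date
`d` with `days_supply s` covers days `d … d+s−1` inclusive; the gap to a
next fill on date `f` is `f − (d+s)` whole days, and the era continues iff
that gap is strictly less than `gap_days` (default 30). Duration is
`end − start + 1` days. Two conventions were genuinely open and are fixed as
follows:

- **Supply-end convention.** The fill date counts as the first supplied day,
  so "end of supply" is the last covered day. The boundary case is pinned by
  test: a 30-day gap splits eras; a 29-day gap merges them.
- **Overlapping fills.** Same-day and overlapping refills merge
  unconditionally; coverage is the union of covered days (a long early fill
  can bridge past a short later one). Stockpiling — carrying unused supply
  forward — is not modeled.

Era construction is verified against an independent brute-force oracle that
marks supplied days on a literal calendar, bridges uncovered runs shorter
than `gap_days`, and takes connected components; equivalence is
property-tested over random claim sets for `gap_days ∈ {1, 15, 30, 60}`.

## Code matching

ICD-9 codes normalize to `CATEGORY[.SUBCODE]` with a zero-padded category
(`070.22`; V- and E-codes keep their letter), so dotted, undotted and
unpadded spellings compare equal. The canonical form keeps the dot:
wildcards such as `130.*` and `114.X` then mean "the three-digit category
and all its subcodes" and can never match an unrelated longer string.
Undotted numeric codes are assumed zero-padded (the standard claims
convention); a four-digit undotted code like `7022` is therefore read as
category `702`, subcode `2` — a documented limitation, irrelevant to the
shipped code lists. GPI drug patterns are exact ten-digit codes or class
prefixes (`1210xxx`); exact patterns take precedence, so the three specific
TDF/FTC-component products are never absorbed into the generic
antiretroviral class. The prophylaxis V-codes printed undotted (`V078`,
`V079`) are read as `V07.8` / `V07.9`.

The code table omits a code for nonspecific serologic evidence of HIV
(795.71 would be conventional); the default codebook follows the table, and
the config file can add it to `HIV_DX` if desired.

## Classifier decisions

- **"Before the index date" means on-or-before.** A diagnosis dated the day
  an era starts already rules out PrEP; this is the conservative reading and
  is pinned by test.
- **Reasons are exhaustively recorded.** The criteria are evaluated in their
  fixed order without short-circuiting, because the exclusion categories are
  not mutually exclusive; the first firing reason determines the label.
- **PEP rule.** The published PEP sub-algorithm this rule replaces is not
  specified in detail anywhere reproducible, so PEP detection is the
  needle-stick / prophylaxis-code rule with a symmetric ±30-day window
  around the index date, plus an optional, off-by-default duration heuristic
  (isolated era ≤ 28 days carrying an exposure-contact code from a
  configurable extension list). Exposure-contact codes V01.6 / V01.79 /
  V01.9 are deliberately *not* in the default logic — they were identified
  descriptively in chart review, not used as algorithm inputs — but can be
  supplied via the codebook's `PEP_EXTENSION` list.
- **Encounter evidence defaults to dx AND px.** The categorical definition
  ("at least 1 procedure and 1 diagnosis") is the stricter and more explicit
  of the two phrasings of criterion 7; the OR reading is selectable
  (`encounter_rule = REQUIRE_DX_OR_PX`), as is restricting the lookup to
  records on or before the era end (`encounter_window`).
- **Criterion 2 uses all prior history**: an other-antiretroviral era ending
  at any time before the index date fires `ARV_PRIOR`, with no washout.

## Validation statistics

Cohen's unweighted κ for the 2×2 PrEP / not-PrEP table, with bands closed on
the printed cut points (0.41–0.60 moderate, 0.61–0.80 substantial, >0.80
almost perfect; everything below 0.41 is reported as "below moderate").
Sensitivity, specificity, PPV, NPV and accuracy each carry a two-sided Wald
(Gaussian-approximation) CI on their own denominator, truncated to [0, 1];
Wilson intervals are available behind a flag. Metrics with zero denominators
are reported as undefined rather than raising, so batch validation never
aborts. All metrics are cross-checked in tests against brute-force recounts
from raw label lists, and κ against scikit-learn's implementation.

Two reported quantities from the original evaluations are knowingly not
recoverable from their own printed inputs, and the package anchors to the
arithmetic, not the printed value: the clinic study's specificity (the
printed 2×2 counts give 1739/2001 = 86.9%, not the quoted 87.1%), and the
high-risk-behavior code's enrichment ratio (the printed presence counts,
123/531 vs 4/593, give ≈ 34.3, not the quoted 47.5 — the comparison set
behind the published figure is ambiguous). Published CIs likewise do not
match a Wald interval on the stated denominators, so only point estimates
are regression-anchored; the CI method itself is as documented above.

## Synthetic cohorts

The generator emulates the five archetypes the classifier distinguishes
(HIV, CHB, PEP, PrEP, medication-only); per-indication mean era durations
default to 126 / 239 / 96 / 26 days. Only means are externally given, so the
distributional shape is a declared invention: refill counts are geometric
with mean `target_mean / supply` at 30-day supplies (duration = refills ×
supply, giving the target mean exactly in expectation), except PEP, which is
a single fill of 24–28 days (mean 26). Medication-only patients reuse the
PrEP refill process (mean 96 days), since no separate figure exists for
them. Refills are contiguous by default — within-era gaps are configurable
but default to zero so configured means are exact — and each patient
receives one era whose truth is recorded per era, allowing longitudinal
PrEP-then-treatment patients to be composed from parts. In-care archetypes
also carry a nonspecific symptom diagnosis and a generic procedure, so
encounter evidence does not hinge on the indication marker itself. The
default mixture (35% HIV, 10% CHB, 10% PEP, 35% PrEP, 10% medication-only)
is a deliberately balanced test condition, not a calibration to any real
population.

Coding noise drops diagnosis / procedure rows and injects miscodes at
configured rates, never touching the truth table. Drop decisions use one
uniform draw per row in canonical order, so for a fixed seed the dropped
sets are nested as rates grow — which makes noise-response properties (PPV
falling as the missing-diagnosis rate rises) testable with coupled seeds.
Observed misclassification fractions in the original evaluations were
outcomes, not generating rates, so noise defaults are zero and experiment
scripts set them explicitly (0.3 missing-diagnosis probability in the
prevalence-contrast experiment).

What passing synthetic tests shows — and what it does not: the pipeline
recovers a truth that satisfies the classifier's own assumptions (complete,
correctly-dated coding at zero noise). Real claims carry correlated
missingness, transferred patients, event-driven dosing and ICD-10-era
coding, none of which the generator models; performance numbers on real
data come from the validation-study machinery, not from these simulations.

## Problem sizes and determinism

The bundled experiments use 500 patients (zero-noise recovery), 2000 eras
per class (duration recovery), 900 patients per arm (prevalence contrast)
and 1000 random claim sets × 4 gap values (era oracle) — sizes at which the
checked quantities are stable to well within their tolerances while the
whole acceptance run completes in seconds. All randomness flows from numpy
`SeedSequence` spawns of a single seed; identical configs produce
byte-identical serialized datasets.
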