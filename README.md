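# prepclaims

Claims-based classification of TDF/FTC prescription eras by likely clinical
indication — PrEP, HIV treatment, chronic hepatitis B (CHB), post-exposure
prophylaxis (PEP), or not classifiable — with the diagnostic-agreement
machinery to validate the classification against a gold standard, and a
synthetic-claims generator so the whole pipeline is testable without any
proprietary dataset.

## The problem

Tenofovir disoproxil fumarate / emtricitabine (TDF/FTC) is prescribed for
HIV pre-exposure prophylaxis (PrEP), but the same product is also used in
HIV treatment regimens, in ~28-day PEP courses, and off-label for chronic
hepatitis B. Pharmacy claims record the prescription but not the indication,
so surveillance of PrEP uptake from administrative data needs a validated
rule to separate PrEP use from the competing indications. `prepclaims` is
aimed at pharmacoepidemiologists and public-health analysts who run or audit
such estimates.

## The algorithm

1. **Exposure eras.** Per patient and drug class, prescriptions are merged
   into maximal *exposure eras*: a fill on day *d* with supply *s* covers
   days *d … d+s−1*, and a following fill extends the era iff the uncovered
   gap is **< 30 days** (configurable). The era's *index date* is its start.
2. **Sequential exclusion.** Each TDF/FTC-class era is tested, in order,
   for: (1) HIV or opportunistic-infection diagnosis on or before the index
   date; (2) prior use of other antiretrovirals; (3) concomitant use of
   other antiretrovirals; (4) prior CHB diagnosis; (5) concurrent or prior
   hepatitis-B agents; (6) PEP markers (needle-stick / prophylaxis codes
   within ±30 days of the index date); (7) absence of encounter evidence
   (at least one diagnosis *and* one procedure record). Criteria are not
   mutually exclusive: every firing reason is recorded, and the first one
   determines the label. An era that survives all seven is **PrEP**.
3. **Validation.** Against a gold standard (era-level chart review or a
   patient-level reference list), the package computes the 2×2 agreement
   table, Cohen's κ = (p_o − p_e)/(1 − p_e) with the conventional bands
   (0.41–0.60 moderate, 0.61–0.80 substantial, >0.80 almost perfect), and
   sensitivity / specificity / PPV / NPV / accuracy with two-sided Wald
   (Gaussian) confidence intervals.

The code dictionary (ICD-9 diagnosis, CPT procedure and GPI drug patterns,
including wildcards such as `130.*` and `1210xxx`) ships with defaults and
is overridable from a YAML file.

## Worked example

```sh
prepclaims simulate --n-patients 120 --seed 4 --out sim/
prepclaims classify --pharmacy sim/pharmacy.csv --dx sim/dx.csv \
    --px sim/px.csv --out results.csv
```

The classify step prints a summary like:

```json
{
  "n_eras": 120,
  "n_patients": 120,
  "label_counts": {"CHB": 18, "HIV": 41, "NOT_CLASSIFIABLE": 9, "PEP": 15, "PREP": 37},
  "label_pct": {"CHB": 15.0, "HIV": 34.2, "NOT_CLASSIFIABLE": 7.5, "PEP": 12.5, "PREP": 30.8},
  "mean_duration_days": {"CHB": 188.3, "HIV": 149.3, "NOT_CLASSIFIABLE": 100.0,
                         "PEP": 25.5, "PREP": 101.4}
}
```

— 120 synthetic patients, one TDF/FTC era each; every era received a label,
and mean exposure durations per label reflect the generator's targets
(HIV ≈ 126 d, CHB ≈ 239 d, PrEP ≈ 96 d, PEP ≈ 26 d; small-sample means
vary). Scoring against the generator's truth:

```sh
prepclaims validate --results results.csv --gold sim/gold.csv \
    --unit era --out report.json
```

yields `kappa = 1.0`, sensitivity and specificity 1.0 — with zero coding
noise the truth is recovered exactly. Adding noise (a `simulate` config with
`p_missing_dx > 0`) produces the false positives and prevalence-dependent
PPV that real claims data show.

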