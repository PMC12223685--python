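# Methods

## Problem and scope

Violent-death surveillance systems pair each death record with two
unstructured narratives — one abstracted from law-enforcement (LE) reports,
one from coroner/medical-examiner (CME) reports — alongside coded fields.
Supervised NLP can recover outcomes that coded fields capture (police
shooting, drive-by shooting, additional nonfatal shooting victims, injury
at home), but practitioners face three design questions before any
modeling: how many records must be hand-labeled, whether text
preprocessing (jargon expansion, dropping the CME narrative) matters, and
whether enriching training data with rare positive cases beats labeling
more data.  A fourth question is whether classifier accuracy differs
across demographic subgroups whose narratives are known to differ in
length and completeness.

`narrsim` implements this simulation study as a pipeline over synthetic
cohorts.  Record-level narrative data is access-restricted and cannot ship
with the package, so a seeded generator produces cohorts whose statistical
structure matches what the simulation design depends on; every downstream
stage also accepts a user-supplied record table in the same CSV/JSONL
schema, so the pipeline can be pointed at real data inside an approved
environment.

## Synthetic cohort model

Each record draws, from its own child RNG stream (single root seed,
streams spawned per record, so cohorts are reproducible and stable under
partial regeneration):

* **Demographics** — (race/ethnicity, sex) from a categorical mix; the
  packaged default is the normalized outer product of marginals (Black
  non-Hispanic 60.5%, White non-Hispanic 21.6%, Hispanic 14.5%, AIAN/API
  ~1.1% each; male 84.3%).
* **Outcomes** — four independent Bernoulli draws at prevalences 9.2%
  (drive-by), 5.9% (legal intervention), 15.2% (others nonfatally shot),
  24.8% (injured at home).  Independence is an assumption: each outcome is
  treated as its own classification task with its own denominator.
* **Narrative lengths** — log-normal per (race group, narrative source),
  parameterized by matching a target median m and IQR width w:
  mu = ln m and sigma = asinh(w / 2m) / z₀.₇₅.  Defaults follow published
  descriptive tables (LE medians 67–99 words by race; CME 85–103).
  Lengths are whitespace-token counts, truncated at 1.
* **Circumstances-known flag** — Bernoulli per race group (71% for Black
  non-Hispanic decedents vs ~83% for Hispanic/White).  When false, the LE
  narrative collapses to a short uninformative template (≤15 words); the
  configured LE medians therefore describe the informative subset, and
  calibration checks compare against circumstances-known records.  CME
  narratives are never truncated by this flag.
* **Planted signal** — each outcome has six fixed multi-word signal-phrase
  variants, each with an expanded and an abbreviated surface form
  (abbreviations drawn from the packaged map: "v"→victim, "s"→suspect,
  "gsw"→gunshot wound, "leo"→law enforcement officer, ...).  A positive
  record carries its outcome's phrase with probability `signal_strength`
  (default 0.9); a negative leaks it with probability `leak_rate` (0.05).
  When circumstances are known, the LE and CME narratives each draw an
  independent surface variant (two reports describe one event in their own
  words); otherwise only the CME narrative carries it.  The abbreviated
  form is used with probability `abbrev_rate` (default 0.3).
* **Context tokens** — positives additionally plant weaker
  outcome-correlated vocabulary: 12 Bernoulli slots at `context_rate`
  (default 0.7), each emitting one of the outcome's 16 context tokens.
  The same tokens occur in background filler at a low rate, so they are
  informative but individually unreliable.  This second, diffuse channel
  is what gives learning curves their shape: small training sets learn the
  compact phrase inventory quickly but need many positives to pin down the
  context profile, while large ones recover positives that carry no phrase
  at all.
* **Filler text** — narratives are padded to their target length with
  generic abstractor-report vocabulary drawn at Zipfian frequencies (a few
  ubiquitous tokens carrying no class information, a long tail of rare
  ones), as in natural text.  Phrases and context tokens replace filler
  rather than extending the text, so length distributions are independent
  of outcome status.
* **Planted bias** — `bias_knobs` maps a subgroup category value to a
  multiplier in (0, 1] that scales that subgroup's length distribution
  (median and IQR together) and thins its entire planted signal (phrase
  carriage and context planting alike).  Degrading carriage alone would be
  nearly undetectable because the context channel carries most of the
  recoverable signal.

What the generator deliberately does not emulate: natural language (text
is template-based), label noise, cross-outcome correlation, sex-specific
length differences (the bias knobs are the controllable dial instead), and
the several hundred coded fields of a real surveillance record.  Passing
tests therefore demonstrate that the *harness* — splits, weighting,
metrics, subgroup audit — behaves correctly on data with known structure,
not that any model reaches a particular accuracy on real narratives; the
synthetic tasks are easier than real ones, and absolute F1 values here are
not comparable to published values on restricted data.

## Preprocessing

Cleaning is lowercase → digit removal → punctuation/special-character
removal → whitespace collapse (idempotent; digit removal first so "V1"
reduces to the expandable token "v").  Abbreviation expansion is
exact-token, single-pass, never re-scanning expansion output.  Model input
is the cleaned LE narrative, optionally concatenated with the cleaned CME
narrative (combined mode, LE first), optionally abbreviation-expanded,
truncated to the first `max_tokens` (default 512) tokens.  The packaged
abbreviation map covers victim/suspect/police/gunshot-wound jargon and
ships as an editable two-column CSV; the full abbreviation inventory used
with real data is not public, so the default is a reconstruction.

## Split design

Per outcome: a simple-random 30% held-out test set (round-half-up);
nested training sets at budgets 100, 200, 500, 1000, 1500, 2000 where each
budget extends the previous one and the positive count is exactly
round(budget × pool positive fraction), clamped to availability — exact
stratification removes sampling noise from learning-curve comparisons.
The oversampling arm starts from the 1000-record base and adds the
*minimal* number of positive cases (outside base and test, additions
nested across fractions) so that positives reach each target fraction f:
n_add = max(0, ceil((f·(P+N) − P) / (1 − f))), with f interpreted exactly
as the decimal written (0.2 means 1/5, so boundary compositions need no
additions).  All sampling shuffles lexicographically sorted ids under a
seeded generator; plans serialize to JSON and are exactly replayable.

## Classifiers

Both backends share one contract: balanced inverse-frequency class weights
w_c = N / (2 N_c) (so Σ N_c w_c = N and balanced data yields unit
weights), a fixed 0.5 decision threshold, deterministic prediction, and a
hard error on single-class training sets (the runner skips such cells and
records them in the manifest rather than aborting the grid).

* **linear_baseline** — binary (presence/absence) bag-of-words with
  class-weighted logistic regression (L2, C = 1, lbfgs).  Presence
  features rather than raw counts keep long narratives from drowning rare
  signal tokens in length-correlated noise.  The token pattern keeps
  single-character tokens so bare abbreviations remain features.  Bit-exact
  reproducibility given the seed.
* **compact_transformer** — fine-tunes a compact pretrained transformer
  (distilBERT by default) with weighted cross-entropy; epochs 4, learning
  rate 5e-5, batch 16, max 512 tokens, all overridable.  It is an optional
  extra (`pip install narrsim[transformer]`); without it, selecting the
  backend raises an actionable ImportError.  Statistical claims in the
  test suite rest on the linear baseline, which exercises the identical
  harness.

## Evaluation

Positive-class precision, recall, F1 and false-negative rate from 2×2
confusion counts, with fixed zero-denominator conventions (0 for
precision/recall/F1, FNR 0 when no positives exist) so curves are
well-defined at tiny budgets; recall + FNR = 1 whenever positives exist
and is asserted on every row.  Subgroup rows are computed per demographic
key on the shared test set, suppressing groups below 25 members; max−min
F1 across subgroup rows is the disparity measure.  The all-positive naive
baseline F1 is 2p/(1+p) at prevalence p.  Results are written as a tidy
CSV (one row per outcome × variant × budget × subgroup) from which the
report step pivots wide F1 tables, flags the best variant per cell, and
tabulates disparities.

## Problem sizes and numerical choices

The packaged calibration cohort is 20,000 records (calibration and split
invariants are checked there: 99% exact-binomial intervals for rates,
±10% for medians).  Statistical harness properties use 4,000–8,000-record
cohorts over five seeds with majority rules (learning-curve recovery,
planted-bias detection, weighted-vs-unweighted recall, replacement gains);
these sizes give each test cell dozens-to-hundreds of positives while
keeping the full suite at desk scale.  The bias audit compares the three
race groups with materially sized test cells (White/Black/Hispanic);
AIAN/API cells at realistic mixes hold only a handful of positives, where
F1 is degenerate — the same reason published subgroup tables report only
the larger groups.  The replacement-gain check thins the context channel
(context_rate 0.2) to isolate the phrase channel whose surface forms
expansion consolidates; at the default context rate the context channel
saturates performance and masks the effect.

## Known limitations

* Synthetic difficulty is set by construction; learning-curve plateaus and
  disparity magnitudes are properties of the generator's knobs, not
  estimates of real-data behavior.
* The oversampling arithmetic is the minimal-addition rule above; other
  plausible conventions (e.g. adding a fixed count per step) give
  different added-case totals.
* The transformer backend is code-complete but exercised only for its
  contract in the default environment; its fine-tuning defaults are
  conventional settings, not a tuned configuration.
* `min_group_n` suppresses small subgroups by member count, not by
  positive count; rare outcomes can still yield unstable subgroup F1 just
  above the threshold.
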