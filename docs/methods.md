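# Methods

## The battery and its scoring model

The engine administers five short tasks in a fixed order (LL → CR → LNS →
DLL → VMT) and scores them deterministically. The score ranges — 30, 24,
21, 10, 30, total 115 — are structural: they fix the item counts the
battery must carry.

* **List learning (LL, 0–30).** A 10-word list is played at the start of
  each of 3 trials; the subject speaks as many words as they can recall.
  The score is the number of distinct list words in each trial's
  transcript, summed over trials. Repeating a word within a trial earns
  credit once (the standard verbal-learning convention); words not on the
  list are ignored, never penalized.
* **Consonant repetition (CR, 0–24).** Each trial plays a short consonant
  sequence, interposes a drag-and-drop filler (sort 5 numbers into
  descending order, new sets served until the filler period ends), then
  asks the subject to type the letters. Credit is per correctly recalled
  letter, order-insensitive and unique per target letter — the criterion
  counts letters, not sequences. The battery ships 8 trials × 3 consonants
  = 24. Filler performance is recorded (set shown, response, strict
  descending correctness) but unscored.
* **Letter–number sequencing (LNS, 0–21).** Mixed digit/letter strings are
  re-typed with digits ascending first, then letters alphabetical.
  Credit is all-or-nothing per sequence ("correctly sorted sequences").
  21 items (7 lengths × 3, lengths 2–8, the WAIS convention) plus a
  5-sequence practice set that is administered but never scored. Stimuli
  with duplicate tokens are rejected at construction so the expected
  answer is always unambiguous.
* **Delayed list learning (DLL, 0–10).** Free recall of the same 10 words
  with no replay; scored as the one-trial restriction of the LL rule.
* **Visuomotor tracking (VMT, 0–30).** A key of 6 letters ↔ 6 symbol codes
  (length-3 strings over a circle/asterisk alphabet, rendered "o"/"*";
  length 3 is the shortest giving 2³ = 8 ≥ 6 distinct codes) and a stream
  of 30 codes to answer within 30 s. Credit is positional; unanswered
  positions score 0. A short 3-code warm-up precedes the timed stream and
  is excluded from scoring.

All string comparison is casefolded, whitespace-trimmed and Unicode
NFC-normalized, so Danish æ/ø/å compare reliably across serialization
round-trips.

The bundled word lists contain the canonical recall words for each language
padded to 10 with neutral common nouns. They make the engine testable;
clinical use requires substituting licensed screening lists, which is why
batteries are fully configurable via a YAML document (`load_battery` /
`dump_battery` round-trip losslessly and re-validate every invariant).

## Session administration

A session is a deterministic state machine over three injected
collaborators: a **responder** (the subject), a **transcriber** (the ASR
contract: utterance → token sequence), and a **clock** (monotonic,
advanced explicitly — wall time is never consulted, so records are
reproducible). The recall word list reaches the responder only as the
stimulus of each immediate-recall trial and never before delayed recall;
an editing or review surface would reveal the list and inflate scores, so
the information flow is asserted in tests. Responder exhaustion aborts the
session with the partial record attached. Records serialize to a strict,
schema-versioned JSON document (unknown fields rejected, canonical task
order enforced, VMT entry timestamps bounded by the time limit).

Nominal durations (word playback 1 s/word, recall window 10 s, one filler
sort per 6 s) only give timestamps a plausible scale; no logic depends on
them.

## ASR transcript evaluation

`align_words` computes the minimal-cost word-level alignment by dynamic
programming with unit substitution/deletion/insertion costs. The S, D, I
counts at minimal cost can differ across co-optimal paths, so the
backtrace uses a fixed preference (match/substitute, then delete, then
insert) making the op trace — and therefore the reported decomposition —
reproducible; total errors S+D+I always equal the edit distance, which the
tests verify exhaustively against a brute-force oracle for every pair of
sequences up to length 6 over a 3-token alphabet. WER is undefined at
N = 0 (raised, never NaN). Aggregation across recall phases is **pooled**
(ΣS+ΣD+ΣI)/ΣN by default, with per-session **macro** averaging available;
both are reported with the mode labelled, because they diverge whenever
session lengths are unbalanced. WER is computed per recall phase (one
reference transcript per trial) and aggregated afterwards. Scoring
consumes hypothesis transcripts; WER compares hypothesis to manual
reference — the two uses are kept strictly separate.

## Usability and validity statistics

PSSUQ: 19 items rated 1–5; factors are arithmetic means over the
instrument's published blocks (system usefulness 1–8, information quality
9–15, interface quality 16–18, overall 1–19). Missing items are skipped
(mean over present items, the instrument's conventional rule); a factor
with no present items is an error, not a silent NaN. The item–factor
mapping is an argument, so alternative mappings load from config.

Pearson correlation delegates to `scipy.stats.pearsonr` (two-tailed p via
the exact t transform on n−2 df); the test suite checks it against an
independently coded covariance-formula oracle to 1e-12. Validity reports
correlate matched instrument columns with pairwise deletion and per-row n,
flagging significance at .05; no multiple-comparison correction is
applied. Boxplot summaries use Tukey hinges (halves include the median
when n is odd) — chosen over interpolated quantiles because hinges are the
classical boxplot convention; the helper is exposed directly so the choice
is inspectable.

## The simulator

The generative model is linear-Gaussian latent ability + Bernoulli item
responses — the simplest model with tunable inter-instrument correlation
and ceiling behavior.

* **Subjects.** Ability per domain (verbal memory, working memory,
  executive, psychomotor) in [0, 1]. List-word recall in trial t is
  Bernoulli(clamp(a + (t−1)·g)) with learning gain g ∈ [0, 0.5]
  (default 0.1, a moderate learning curve: 0.5 → 0.6 → 0.7 across
  trials); delayed recall uses the post-learning level clamp(a + 2g).
  CR letters and LNS items are Bernoulli in the working-memory and
  executive abilities; VMT entries take a fixed 1 s each (so ability
  affects accuracy, not speed; 30 entries exactly fill the 30 s limit)
  and are correct with the psychomotor ability.
* **ASR channel.** Each token is independently substituted with
  probability `sub_rate` or deleted with probability `del_rate`
  (`sub + del ≤ 1`); substitutions draw from a fixed distractor pool
  disjoint from the default word lists, so a corrupted token can never
  accidentally earn recall credit. Insertions default to rate 0 —
  recall-style speech essentially never produces them — but the rates are
  configurable for robustness studies. Pooled WER therefore converges to
  `sub_rate + del_rate`, which the recovery tests check within 3 binomial
  standard errors. Default cohort rates (5% substitution, 2% deletion)
  represent a well-behaved ASR system on short recall utterances.
* **Paired instruments.** For each domain, both instruments observe
  `w·Z + σ·ε` with shared Z and independent ε, giving the exact induced
  correlation `w²/√((w²+σ_a²)(w²+σ_b²))`. The default σ = 0.3 with
  w = 0.8 induces r ≈ 0.88 — a strong but imperfect inter-instrument
  agreement. The `binomial` observation mode maps latents through
  `clamp(mean + sd·latent)` onto Binomial(subtest max) scores;
  concentrating working-memory ability near 1 piles CR scores at 24 and
  attenuates the observed instrument correlation relative to the latent
  coupling, reproducing the ceiling effect qualitatively (asserted as
  attenuation, never as a specific r).

What the simulator does **not** emulate: acoustics and microphone effects,
response-time structure beyond the uniform VMT interval, correlated
within-subject error bursts (fast unpunctuated recall degrading
recognition), non-native-speaker effects, or item-difficulty variation
within a task. Passing recovery tests therefore demonstrates that the
scoring/analysis machinery is correct and unbiased under the stated
generative model — not that real participants would produce any particular
WER or validity coefficient; participant-derived study values are out of
reach by design.

## Problem sizes and numerical choices

The recovery studies use the sizes at which their tolerances are
meaningful: ≥10,000 channel tokens (3-SE binomial band), 200 replicate
cohorts of n = 500 for the coupling check (mean r within 0.05 of the
closed form), 2,000 subjects for the ceiling contrast, and 10,000 seeds
for the immediate-recall expectation check. Error-ratio sums are checked
to 1e-9; the Pearson oracle to 1e-12. Degenerate inputs raise typed
errors (`UndefinedRateError`, `UndefinedRatioError`,
`UndefinedCorrelationError`, `EmptyReportError`) rather than returning
NaN.

## Known limitations

* CR trial layout (8×3), the 21-item LNS construction, the 30 s filler and
  sorting-set sizes are conventions consistent with the printed score
  ranges, not published task tables; all are configurable.
* The per-trial filler sort cadence (one set per 6 s) is nominal; real
  sorting speed is neither modeled nor scored.
* PSSUQ scoring assumes the standard 19-item form; short forms need a
  custom factor mapping.
* The engine treats instrument labels in validity tables as opaque pair
  names; it does not model versioned variants of the reference
  instrument.
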