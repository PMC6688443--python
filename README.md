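# cogbattery

A headless, fully testable engine for a five-subtest, web-era digital
cognitive screening battery of the kind used to screen for cognitive
impairment in affective disorders. It is aimed at researchers building or
validating patient-administered cognitive tests: everything the interactive
front end of such a tool does — administer tasks, collect responses, pass
spoken recall through speech recognition, score, and analyze — is available
here as a deterministic library, so scoring rules, ASR evaluation, and
validity analyses can be developed and regression-tested without
participants, audio, or any external service.

## What it implements

**The battery.** Five tasks in fixed order, with their scoring rules and
score ranges:

| id  | task                         | measure                  | range |
|-----|------------------------------|--------------------------|-------|
| LL  | list learning, 3 trials      | immediate verbal memory  | 0–30  |
| CR  | consonant repetition         | working memory           | 0–24  |
| LNS | letter–number sequencing     | executive function       | 0–21  |
| DLL | delayed list learning        | delayed verbal memory    | 0–10  |
| VMT | visuomotor tracking (coding) | psychomotor speed        | 0–30  |

Recall tasks count correctly recalled list words (unique credit per trial);
CR counts recalled letters order-insensitively after a descending-number
drag-and-drop filler; LNS requires digits sorted ascending then letters
alphabetical, all-or-nothing per sequence; VMT counts positionally correct
letters typed against a stream of 30 circle/asterisk symbol codes within a
30 s limit. The total is the plain sum (0–115).

**ASR evaluation.** Spoken recall is assessed by comparing the ASR
hypothesis transcript to a manual reference transcript via a minimal
word-level edit alignment with unit costs. With N reference words and S, D,
I substitutions/deletions/insertions,

```
WER = (S + D + I) / N
```

plus the error decomposition (each error type as a percentage of S+D+I),
per-word recognition accuracy tables, and pooled/macro aggregation.

**Analysis.** PSSUQ usability scoring (19 items, 1–5; factors = means over
the published item blocks), Pearson two-tailed correlation
(t = r·√((n−2)/(1−r²)) on n−2 df) for concurrent-validity reports, and
Tukey-hinge five-number score summaries.

**Simulation.** Subjects with latent per-domain abilities in [0, 1] drive
Bernoulli item responses (with trial-wise verbal learning), spoken recall
passes through a substitution/deletion ASR corruption channel, and paired
instruments share latent abilities with coupling weight `w` plus Gaussian
noise, giving a closed-form induced correlation `w²/(w² + σ²)` for checking
validity analyses end to end.

## Worked example

```python
import cogbattery as cb

battery = cb.default_battery("en")           # or "da"
responder = cb.ScriptedResponder.perfect(battery)
record = cb.run_session(battery, responder, cb.NormalizingTranscriber())
print(cb.score_session(battery, record).as_dict())

ref = cb.normalize_transcript("milk coffee garden", "en")
hyp = cb.normalize_transcript("milk copy", "en")
a = cb.align_words(ref, hyp)
print(a.n_ref, a.substitutions, a.deletions, a.insertions,
      round(cb.word_error_rate(a), 3))
```

prints

```
{'LL': 30, 'CR': 24, 'LNS': 21, 'DLL': 10, 'VMT': 30, 'total': 115}
3 1 1 0 0.667
```

— a flawless scripted subject reaches every subtest ceiling (total 115),
and recognizing "milk copy" for "milk coffee garden" is one substitution
(coffee→copy) plus one deletion (garden) over three reference words, a WER
of 0.667.

The same pipeline runs from the shell:

```sh
cogbattery simulate --n 50 --seed 7 --language da --out sims/
cogbattery score --session sims/sim-0000.json --language da --out scores.csv
cogbattery analyze validity --pairs pairs.csv --out validity.csv
```

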