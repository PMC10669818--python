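# Methods

## Problem and approach

Echocardiogram reports are semi-structured narratives: section headings
("Aortic Valve:", "Aorta:") delimit heart regions, and inside them short
clauses mix free text with measurements ("AV Vmax 4.2 m/s MPD 46 mmHg VTI
103 cm") and qualitative gradings ("Trivial aortic regurgitation"). The
same outcome appears under many surface forms, units and layouts, which is
what makes bulk statistical use of these reports expensive.

`echoextract` converts such text into one structured row per
(report, outcome) using a deterministic, fully auditable cascade:

1. **Tokenisation.** Regex-based; numbers with internal decimal points and
   compound unit symbols (`m/s`, `mmHg`, `cm^2`) are single tokens. The
   adjacent-number pattern `38 9` is deliberately *not* merged into `38.9`
   (see "Known reporting error modes" below).
2. **Sentence splitting** at `.`, `;`, ellipsis and newlines; decimal
   points never split.
3. **Gazetteer lookup.** The outcome dictionary (43 outcomes: 35
   continuous, 8 discrete, across nine heart regions) maps surface aliases
   to canonical outcomes, longest match first, case-insensitively —
   except short all-caps abbreviations (`AS`, `AR`, `TR` …), which match
   case-sensitively so that the English word "as" never fires.
   Ambiguous bare aliases (`VTI`, `MPD`, `PPD`, `Vmax`, `regurgitation`,
   `stenosis`) are resolved by context: the heart-region of the nearest
   preceding outcome mention in the sentence, else the current section
   heading, else a configured default. Exclusion terms (`AVA (VTI)`,
   `AVAi VTI` — valve areas, not velocity-time integrals) consume their
   tokens so no inner alias can fire.
4. **Rule cascade.** Declarative rules (priority-ordered patterns over the
   token/lookup stream with bindable elements, plus an action list) bind
   values, ranges and units to continuous outcomes and severity labels to
   discrete ones. Overlapping candidates are resolved by
   (priority desc, span length desc, start asc); the operation is
   idempotent. Every emitted annotation carries the matched span, rule
   name and flags, so a textual trace can reproduce exactly why each
   database cell has its value.
5. **Normalisation.** Units are converted to each outcome's canonical unit
   by a multiplicative table (exact for the bundled power-of-ten factors;
   products are rounded to 9 decimals so 0.47 m → 47 cm exactly). A range
   `a–b` yields varValue1 = a, varValue2 = b and varValue = (a+b)/2
   (45–50% → 47.5%). Severity labels map to consecutive integer codes
   starting at 0; combined grades map to their upper member
   ("Trivial–Mild" → same code as "Mild"); negated mentions
   ("No aortic regurgitation", "No significant regurgitation") map to 0
   with the `negated` flag set and any qualifier kept in provenance.
6. **Output.** Long format (one row per report × outcome; the evaluation
   atom) and wide format (one row per report, one column per outcome).
   Absent extractions are empty cells, never zeros — the downstream
   false-negative / true-negative distinction depends on this.

## Ordinal scales

* Regurgitation (aortic, mitral, tricuspid): 0 none, 1 trivial, 2 mild
  (or trivial–mild), 3 moderate (or mild–moderate), 4 severe (or
  moderate–severe).
* LV systolic function (qualitative, no negation-zero): hyperdynamic,
  normal, borderline, mild, mild–moderate, moderate, moderate–severe,
  severe → codes 0–7 in listing order; results are reported by label.
* Stenosis (aortic, mitral, tricuspid, pulmonary): no published grading
  accompanied the validation counts, so this package uses 0 none, 1 mild,
  2 moderate, 3 severe with the same upper-member convention — a design
  choice of this implementation.

## Inferred alias conventions

Report excerpts pair "PPD" with peak-velocity values and "MPD" with the
smaller gradient of the two, so this package reads **MPD as the mean
pressure gradient (AV MPG) and PPD as the peak gradient (AV max PG)**.
This is an inference from co-occurrence patterns, not a documented
convention; both mappings live in the dictionary file and can be edited
without code changes. Likewise a bare `MPD`/`VTI` after an `LVOT` anchor
binds to the LVOT family; the LVOT mean gradient is not a dictionary
outcome, so `MPD 1.2 mmHg` in LVOT context yields no extraction.

Canonical units per outcome are not universally standardised either; the
bundled choices (velocities m/s, tissue-Doppler velocities cm/s, gradients
mmHg, linear dimensions and VTIs cm, areas cm², volumes mL, EF %, times
ms, ratios dimensionless) follow the most frequently reported unit for
each measure and are recorded per outcome in the dictionary.

## Multiplicity, prosthesis context and negation scope

* One primary value per (report, outcome): when several non-overlapping
  mentions survive, the first in document order wins and later mentions
  stay in the annotation list flagged `suppressed` +
  `conflicting-mention`. First-mention is the simplest auditable rule.
* Prosthetic-valve context (`AVR`, `TAVI`, `paravalvular`,
  `paraprosthetic`, "in situ"): a heading qualifier
  ("Aortic Valve (TAVI):") marks its whole section; a cue word marks the
  section from the cue onward, so a native-valve grading before the cue
  stays native. Native readings outrank prosthetic ones in multiplicity
  resolution; prosthetic extractions are kept and tagged.
* Negation and value binding are clause-scoped (clauses break at commas
  and sentence boundaries), and a bound value must follow its outcome
  mention within at most 3 intervening word/punctuation tokens. The small
  window limits false positives; colons, equals signs and qualifier words
  ("significant", "obvious", "eccentric") all fit inside it.

## Known reporting error modes

* **Malformed decimals** ("38 9" intended as 38.9): no merge rule is
  defined by observed practice, so the package extracts the first number
  and flags the annotation `suspected-malformed-decimal`. The synthetic
  generator marks such ground-truth records `uncertain` and round-trip
  equality excludes them. This is a documented divergence: merging is
  plausible but unverifiable.
* **Wrong terminology** (a measurement phrased outside the dictionary's
  alias set): inherently unextractable by a rule system; emulated by the
  generator's miss-rate noise.

## Validation metrics

Continuous outcomes are treated as a two-rater agreement problem on pairs
aligned by report id:

* **R²** — squared Pearson correlation of complete pairs.
* **ICC(2,1)** — two-way random effects, absolute agreement, single
  measure, computed from the ANOVA mean squares
  `ICC = (MSR − MSE) / (MSR + (k−1)MSE + k(MSC − MSE)/n)` with a
  one-sided F-test (`F = MSR/MSE`, df `n−1, (n−1)(k−1)`) and the
  conventional reliability bands poor < 0.5 ≤ moderate < 0.75 ≤ good
  < 0.9 ≤ excellent. The variant choice (absolute agreement,
  single-rater) is the standard one for two-rater method comparison; a
  degenerate table with all cells identical is ICC 1 by convention with
  an undefined p-value. The two statistics are complementary by design:
  a system extracting the right number on the wrong unit scale keeps
  R² = 1 while absolute agreement collapses ICC — the signature used to
  detect unit-scale mismatches.
* **Bubble calibration** — per outcome, total reference magnitude vs
  total system magnitude with extraction frequency as size; points below
  the diagonal indicate under-extraction.

Discrete outcomes are presence-plus-category classification per
(report, outcome) instance: TP if both sides assert the same category,
FP if the system asserts where the reference is silent *or* asserts the
wrong category (one cell per instance, never double-counted), FN if only
the reference asserts, TN if both are silent. Precision, recall and F1
are reported at 2 decimals; zero denominators raise an undefined-metric
signal rather than returning 0, and rare outcomes (the four valve
stenoses) are aggregated cell-wise before metrics are taken. Pooled
accuracy is Σ(TP+TN)/Σ(all cells) over all tallies. No multiple-testing
correction is applied to the ICC p-values.

## Synthetic corpus generator

The generator emulates the measurement-bearing grammar of TTE reports —
section-heading layout, the template inventory above, ranges, unit
variation, negation, prosthesis context, run-on aortic-valve lines with
bare aliases, malformed decimals and unextractable phrasings — with every
mention backed by exactly one ground-truth record on canonical
units/scales. Defaults: inclusion probabilities loosely follow clinical
prevalence (EF in 90% of reports, mitral/tricuspid regurgitation grades
common, valve stenoses rare at 4–6%), values are uniform over clinically
plausible ranges stored per outcome in the dictionary (e.g. EF 10–80%,
TR Vmax 1.5–5.5 m/s), all noise rates default to 0. A fixed seed makes
the corpus byte-identical.

What it does **not** model: narrative free text beyond the
measurement-bearing grammar, spelling errors, cross-report longitudinal
structure, vendor-specific layouts, and alias inventories beyond the
bundled dictionary. Passing round-trip tests therefore show the cascade
is correct *for the supported grammar*; they do not bound performance on
real hospital text, whose alias and phrasing variety is wider.

Noise semantics: unit jitter and ranges stay in-grammar (truth unchanged
on the canonical scale; the cascade must convert/average back); negation
changes the truth itself (code 0); a malformed decimal keeps the truth
value but flags it `uncertain`; miss-rate renders the mention in wording
the cascade cannot match while keeping the truth record, so measured
recall estimates 1 − miss-rate; confusion-rate prints a wrong grade, so
measured precision responds to it (slightly above 1 − rate, because
negated mentions are not confusable).

## Numerical choices

* Unit conversion and range averaging round to 9 decimals, making the
  bundled power-of-ten factors exact in binary floating point.
* Reported metrics round to 2 decimals; internal computation is at full
  precision.
* Metric ties and boundaries: ICC bands are half-open upwards (0.75 is
  "good", 0.9 is "excellent").
* Overlap ties break deterministically by (priority, span length, start).
* Degenerate inputs: empty documents are rejected at tokenisation;
  whitespace-only documents tokenise to nothing; an all-zero tally or a
  zero-variance series raises an undefined-metric signal.

## Problem sizes used in tests and the acceptance script

The bundled acceptance run uses 500 noise-free reports for the zero-noise
round trip (≈12 000 record pairs), 1 000 reports at miss-rate 0.2 for
recall recovery (≈2 000 discrete instances), 50 random small series for
the ICC/ANOVA cross-check and 60 pairs for the scale-mismatch signature
— sizes chosen so sampling error is small relative to the effects being
demonstrated while the whole run stays fast on one CPU.

## Known limitations

* The alias inventory covers the 43 bundled outcomes plus the variation
  grammar above; extending to further outcomes is a dictionary-file
  change, but genuinely novel phrasings need new aliases or rules.
* No spell correction or fuzzy matching; no machine-learned components.
* The multiplicity rule (first mention wins) can pick a preliminary
  mention over a considered later one; the suppressed annotations and
  conflict flags make such cases auditable.
* The stenosis scale and the MPD/PPD readings are inferences (see above).
* Evaluation requires a reference standard sharing report ids; the
  discrete track's true-negative count depends on the report universe
  supplied (default: union of ids seen in either table).
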