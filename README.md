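# echoextract

Rule-based extraction of structured outcome measures from trans-thoracic
echocardiogram (TTE) report text, with a dual-track validation pipeline
and a ground-truthed synthetic report generator.

## The problem

Echo reports are the fundamental record of a cardiovascular examination,
but they are written as semi-structured narrative: section headings per
heart region, then clauses mixing free text with measurements
(`AV Vmax 4.2 m/s MPD 46 mmHg VTI 103 cm`) and qualitative gradings
(`Trivial aortic regurgitation`). The same outcome appears under many
aliases, units and layouts, so hospital-scale statistical use of these
reports requires converting them into one structured row per
(report, outcome). `echoextract` does that conversion deterministically
and audibly, for clinicians, cardiac researchers and data engineers who
need echo measurements as a table rather than as prose.

## What it does

* **Gazetteer + rule cascade.** An editable outcome dictionary (43
  bundled outcomes: 35 continuous, 8 discrete) drives longest-match
  lookup with context resolution for ambiguous short aliases (`VTI`
  under an aortic-valve heading vs after an `LVOT` anchor). Declarative,
  priority-ordered rules bind values, ranges and units, map severity
  labels to ordinal scales, handle negation and prosthetic-valve
  context, and carry full provenance (matched span + rule name) per
  extraction.
* **Normalisation.** Units convert to each outcome's canonical unit
  (`0.47 m → 47 cm`); ranges average (`EF 45–50% → 47.5%`); severity
  grades map to integer codes (regurgitation: 0 none … 4 severe, with
  combined grades such as Trivial–Mild taking the upper member's code).
* **Validation.** Continuous outcomes: R² and ICC(2,1) (two-way random
  effects, absolute agreement) with Koo–Li reliability bands and
  bubble-plot calibration data. Discrete outcomes: per-outcome
  TP/FN/FP/TN tallies, precision/recall/F1, rare-outcome aggregation and
  pooled confusion-matrix accuracy.
* **Synthetic corpora.** A seeded generator emulates the report grammar
  (templates, ranges, unit jitter, negation, prosthesis context,
  malformed decimals, unextractable phrasings) with exact ground truth,
  so the whole pipeline is testable without any clinical data.

## Worked example

```python
import echoextract as ee

lexicon = ee.load_lexicon()
rules = ee.load_rules(lexicon=lexicon)

text = """Left Ventricle: Ejection Fraction (EF) 45-50%.
Aortic Valve: No aortic stenosis. Trivial aortic regurgitation. AV Vmax 4.2 m/s MPD 46 mmHg VTI 103 cm
Aorta: Ascending aorta 34 mm."""

doc = ee.annotate("r001", text, lexicon)
annotations = ee.apply_rules(doc, rules, lexicon)
print(ee.render_trace(doc, annotations))
```

prints the provenance trace

```
report r001: 7 annotation(s)
  [16:45] 'Ejection Fraction (EF) 45-50%' -> EF = 47.5 % range 45-50 rule=continuous-range section=left ventricle
  [61:79] 'No aortic stenosis' -> AV Stenosis = 0 (no) rule=severity-before section=aortic valve negated
  [81:109] 'Trivial aortic regurgitation' -> AR level = 1 (trivial) rule=severity-before section=aortic valve
  [111:126] 'AV Vmax 4.2 m/s' -> AV Vmax = 4.2 m/s rule=continuous-single section=aortic valve
  [127:138] 'MPD 46 mmHg' -> AV MPG = 46 mmHg rule=continuous-single section=aortic valve
  [139:149] 'VTI 103 cm' -> AV VTI = 103 cm rule=continuous-single section=aortic valve
  [157:178] 'Ascending aorta 34 mm' -> Ascending Aorta = 3.4 cm rule=continuous-single section=aorta
```

— the EF range was averaged to 47.5%, the negated stenosis became
ordinal code 0, `Trivial` became AR code 1, the bare aliases `MPD`/`VTI`
resolved to the aortic-valve gradient and VTI from context, and 34 mm was
standardised to 3.4 cm. `ee.to_long(ee.records_from_annotations("r001",
annotations))` turns the same result into the long table

```
report_id         outcome  value unit ordinal_label  negated
     r001              EF   47.5    %                  False
     r001     AV Stenosis    0.0                 no     True
     r001        AR level    1.0            trivial    False
     r001         AV Vmax    4.2  m/s                  False
     r001          AV MPG   46.0 mmHg                  False
     r001          AV VTI  103.0   cm                  False
     r001 Ascending Aorta    3.4   cm                  False
```

The same pipeline runs from the shell:

```sh
echoextract synth --n 100 --seed 7 --out corpus/
echoextract extract --input corpus/reports --out extracted/ --trace
echoextract evaluate --system extracted/extractions_long.csv \
                     --reference corpus/ground_truth.csv --out metrics/
```

## Layout

```
src/echoextract/
  lexicon.py    outcome dictionary, severity scales, unit table
  textproc.py   tokeniser, sentence splitter, section/gazetteer matching
  rules.py      declarative rule cascade, overlap resolution, tracing
  outputs.py    long/wide tables and CSV I/O
  evaluation.py ICC/R², tallies, precision/recall/F1, pooled accuracy
  synthgen.py   ground-truthed synthetic report corpora
  cli.py        extract / evaluate / synth subcommands
  data/         bundled lexicon, unit table, rules, templates (editable)
```

Design notes, inferred conventions and known limitations are documented
in `docs/methods.md`.
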