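# Report-text templates for the synthetic corpus generator.
#
# Placeholders: {alias} outcome surface form, {value} printed number (with
# range or malformed-decimal variants substituted in), {unit} printed unit
# incl. leading space ("" for dimensionless, "%" attached), {phrase}
# natural-language name of a discrete outcome, {label} severity grade.
# Weights steer the per-mention template draw. The `miss` templates render
# a mention in out-of-grammar wording the cascade cannot match (wrong
# terminology, as seen in real reports); the `cluster` template renders the
# run-on aortic-valve measurement line with bare context-resolved aliases.
continuous:
  - {id: plain,     weight: 3, pattern: "{alias} {value}{unit}."}
  - {id: colon,     weight: 3, pattern: "{alias}: {value}{unit}."}
  - {id: equals,    weight: 1, pattern: "{alias} = {value}{unit}."}
  - {id: semicolon, weight: 1, pattern: "{alias} {value}{unit};"}
discrete:
  - {id: grade-before, weight: 3, pattern: "{label} {phrase}."}
  - {id: grade-after,  weight: 2, pattern: "{phrase_cap}: {label_cap}."}
  - {id: assessment,   weight: 1,
     pattern: "Overall assessment is of {label} {phrase}."}
negation:
  - {id: negated,             weight: 2, pattern: "No {phrase}."}
  - {id: negated-significant, weight: 1, pattern: "No significant {phrase}."}
miss:
  - {id: miss-continuous,
     pattern: "Additional measurement {value}{unit} noted by sonographer."}
  - {id: miss-discrete, pattern: "Some {phrase} may be present."}
cluster:
  - {id: av-cluster, weight: 1,
     pattern: "AV Vmax {v1} m/s MPD {v2} mmHg VTI {v3} cm"}
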