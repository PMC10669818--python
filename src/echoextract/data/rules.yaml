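# Bundled extraction rule cascade.
#
# Rules pattern-match over the per-sentence item stream produced by the
# gazetteer stage (items are tokens, with multi-token dictionary matches
# collapsed into single lookup/severity items). Higher priority wins where
# candidate matches overlap.
#
# LHS element kinds:
#   lookup   : an outcome dictionary match; constrain with data_type or
#              outcome (canonical name)
#   severity : a severity-label match (graded label or negation form)
#   number   : numeric token
#   unit     : unit token
#   range_sep: a range connector (hyphen, en dash, "to")
#   gap      : up to `max` intervening word/punctuation items (never numbers,
#              units, lookups or severities, so values cannot be skipped)
# Elements may carry bind: <name> (referenced by the RHS) and optional: true.
#
# RHS actions:
#   bind_value   : varValue from a bound number
#   bind_range   : varValue1/varValue2 from two bound numbers; varValue is
#                  their mean
#   bind_unit    : unit from a bound unit item (absent bound item means the
#                  outcome's canonical unit); value converted to canonical
#   map_severity : varValue from the bound severity label via the outcome's
#                  ordinal scale; negation forms set the negated flag and
#                  map to 0 where the scale allows

rules:
  - name: continuous-range
    priority: 120
    lhs:
      - {kind: lookup, data_type: continuous, bind: out}
      - {kind: gap, max: 3}
      - {kind: number, bind: lo}
      - {kind: range_sep}
      - {kind: number, bind: hi}
      - {kind: unit, bind: u, optional: true}
    rhs:
      - {action: bind_range, lo: lo, hi: hi}
      - {action: bind_unit, from: u}

  - name: severity-before
    priority: 110
    lhs:
      - {kind: severity, bind: sev}
      - {kind: gap, max: 3}
      - {kind: lookup, data_type: discrete, bind: out}
    rhs:
      - {action: map_severity, from: sev}

  - name: continuous-single
    priority: 100
    lhs:
      - {kind: lookup, data_type: continuous, bind: out}
      - {kind: gap, max: 3}
      - {kind: number, bind: val}
      - {kind: unit, bind: u, optional: true}
    rhs:
      - {action: bind_value, from: val}
      - {action: bind_unit, from: u}

  - name: severity-after
    priority: 95
    lhs:
      - {kind: lookup, data_type: discrete, bind: out}
      - {kind: gap, max: 4}
      - {kind: severity, bind: sev}
    rhs:
      - {action: map_severity, from: sev}
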