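# Bundled unit table: multiplicative conversion factors between the unit
# spellings that occur in report text and the canonical units of the outcome
# dictionary. Schema: list of {from, to, factor}. Identity entries are
# implicit; the loader adds the inverse of every listed pair, so each pair
# need only be stated once. Alternative spellings are normalised by the
# tokeniser before lookup (cm2 -> cm^2, sec -> s, ml -> mL).
conversions:
  - {from: m,    to: cm,   factor: 100}
  - {from: mm,   to: cm,   factor: 0.1}
  - {from: m,    to: mm,   factor: 1000}
  - {from: ms,   to: s,    factor: 0.001}
  - {from: m/s,  to: cm/s, factor: 100}
  - {from: mm/s, to: cm/s, factor: 0.1}
  - {from: L,    to: mL,   factor: 1000}
  - {from: mm^2, to: cm^2, factor: 0.01}
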