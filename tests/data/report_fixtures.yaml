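# Hand-adjudicated extraction fixtures: realistic report-text variation
# patterns for the aortic-valve VTI family (continuous) and aortic
# regurgitation grading (discrete), including prosthetic-valve contexts and
# known reporting error modes.
#
# Adjudication conventions (documented in docs/methods.md):
#   * "MPD" is read as the mean pressure gradient (AV MPG) and "PPD" as the
#     peak gradient (AV max PG); both are inferences from the co-occurrence
#     pattern of the two abbreviations and are flagged as such in the docs.
#   * A bare "MPD"/"VTI" after an LVOT anchor binds to the LVOT family;
#     the LVOT mean gradient is not a dictionary outcome, so "MPD 1.2 mmHg"
#     in LVOT context yields no extraction.
#   * "AVA (VTI)" and friends are aortic-valve-area terms, not VTIs: excluded.
#   * "No significant regurgitation" is negation (code 0); the qualifier is
#     kept in provenance flags.
#   * Combined grades map to the upper member: "Trivial–mild" -> mild (2).
#   * A severity mention without a grade ("Aortic regurgitation present")
#     yields nothing; a later graded mention of the same outcome wins.
#   * "38 9" style malformed decimals are NOT merged: the first number is
#     extracted and flagged suspected-malformed-decimal.

continuous:
  - id: av-cluster-bare-aliases
    text: "AV Vmax 4.2 m/s MPD 46 mmHg VTI 103 cm"
    expected:
      - {outcome: AV Vmax, value: 4.2, unit: m/s}
      - {outcome: AV MPG, value: 46, unit: mmHg}
      - {outcome: AV VTI, value: 103, unit: cm}
  - id: av-cluster-integer-vmax
    text: "AV Vmax 4 m/s MPD 42 mmHg VTI 87.9 cm"
    expected:
      - {outcome: AV Vmax, value: 4, unit: m/s}
      - {outcome: AV MPG, value: 42, unit: mmHg}
      - {outcome: AV VTI, value: 87.9, unit: cm}
  - id: ao-vti-with-ava-exclusion
    text: "Ao VTI 36 cm; AVA (VTI) 1.8 cm^2"
    expected:
      - {outcome: AV VTI, value: 36, unit: cm}
  - id: ao-vti-semicolon
    text: "Ao VTI 36 cm;"
    expected:
      - {outcome: AV VTI, value: 36, unit: cm}
  - id: narrative-then-measurements
    text: "Aortic Valve: Appears Trileaflet. Thickening of LCC/NCC with reduced mobility of these cusps. V max 2.8 m/s, PPD: 32 mmHg, MPD: 19 mmHg, VTI: 62.3 cm."
    expected:
      - {outcome: AV Vmax, value: 2.8, unit: m/s}
      - {outcome: AV max PG, value: 32, unit: mmHg}
      - {outcome: AV MPG, value: 19, unit: mmHg}
      - {outcome: AV VTI, value: 62.3, unit: cm}
  - id: av-then-lvot-context-switch
    text: "AV Vmax 4 m/s MPD 42 mmHg VTI 87.9 cm LVOT 2.7 cm Peak V = 0.7 m/s, MPD 1.2 mmHg, VTI 16.2 cm"
    expected:
      - {outcome: AV Vmax, value: 4, unit: m/s}
      - {outcome: AV MPG, value: 42, unit: mmHg}
      - {outcome: AV VTI, value: 87.9, unit: cm}
      - {outcome: LVOT Diam, value: 2.7, unit: cm}
      - {outcome: LVOT Vmax, value: 0.7, unit: m/s}
      - {outcome: LVOT VTI, value: 16.2, unit: cm}
  - id: colon-separated-gradients
    text: "AV Vmax: 4.8 m/s, PPD: 91 mmHg, MPD: 57 mmHg, VTI: 107 cm"
    expected:
      - {outcome: AV Vmax, value: 4.8, unit: m/s}
      - {outcome: AV max PG, value: 91, unit: mmHg}
      - {outcome: AV MPG, value: 57, unit: mmHg}
      - {outcome: AV VTI, value: 107, unit: cm}
  - id: mean-pg-and-area-exclusions
    text: "AV mean PG: 54 mmHg. AV VTI: 78 cm. AVA VTI: 0.88 cm^2. AVAi VTI: 0.45 cm/m^2"
    expected:
      - {outcome: AV MPG, value: 54, unit: mmHg}
      - {outcome: AV VTI, value: 78, unit: cm}
  - id: plain-av-vti
    text: "AV VTI 61.3 cm"
    expected:
      - {outcome: AV VTI, value: 61.3, unit: cm}
  - id: ao-vti-large
    text: "Ao VTI 106 cm;"
    expected:
      - {outcome: AV VTI, value: 106, unit: cm}
  - id: av-vti-colon
    text: "AV VTI: 78 cm."
    expected:
      - {outcome: AV VTI, value: 78, unit: cm}

discrete:
  - id: avr-no-significant-regurg
    text: "Aortic Valve (biological AVR): AVR in situ, well seated. … No significant regurgitation. … Aorta:"
    expected:
      - {outcome: AR level, value: 0, label: "no", negated: true,
         prosthetic: true}
  - id: avr-mild-paraprosthetic
    text: "Aortic Valve (unclear imaging of AVR): … AVR seen in situ with a mild paraprosthetic regurgitation. … Aorta:"
    expected:
      - {outcome: AR level, value: 2, label: mild, prosthetic: true}
  - id: in-situ-no-ar
    text: "Aortic Valve: … with valve type/size in situ No aortic regurgitation Right Ventricle:"
    expected:
      - {outcome: AR level, value: 0, label: "no", negated: true,
         prosthetic: true}
  - id: no-as-trivial-ar-vmax
    text: "Aortic Valve: … No aortic stenosis. Trivial aortic regurgitation. AV Vmax: 1.6 m/s. Aorta:"
    expected:
      - {outcome: AV Stenosis, value: 0, label: "no", negated: true}
      - {outcome: AR level, value: 1, label: trivial}
      - {outcome: AV Vmax, value: 1.6, unit: m/s}
  - id: tavi-trivial-mild-paravalvular
    text: "Aortic Valve (TAVI): … No aortic stenosis/obstruction indicated. Trivial–mild paravalvular aortic regurgitation. … Aorta:"
    expected:
      - {outcome: AV Stenosis, value: 0, label: "no", negated: true,
         prosthetic: true}
      - {outcome: AR level, value: 2, label: mild, prosthetic: true}
  - id: avr-no-obstruction-no-ar
    text: "Aortic Valve: AVR in situ. …No significant obstruction/stenosis indicated. No obvious aortic regurgitation. … Aorta:"
    expected:
      - {outcome: AV Stenosis, value: 0, label: "no", negated: true,
         prosthetic: true}
      - {outcome: AR level, value: 0, label: "no", negated: true,
         prosthetic: true}
  - id: mild-eccentric-paravalvular
    text: "Aortic Valve: … Mild eccentric paravalvular aortic regurgitation seen. Aorta:"
    expected:
      - {outcome: AR level, value: 2, label: mild, prosthetic: true}
  - id: mild-transvalvular
    text: "Aortic Valve: …. Mild transvalvular aortic regurgitation. …"
    expected:
      - {outcome: AR level, value: 2, label: mild}
  - id: ungraded-then-overall-mild
    text: "Aorta: Aortic Valve: … Aortic regurgitation present …Overall assessment is of mild aortic regurgitation. AV Vmax: 1.5 m/s. Aorta:"
    expected:
      - {outcome: AR level, value: 2, label: mild}
      - {outcome: AV Vmax, value: 1.5, unit: m/s}
  - id: bav-moderate-as-trivial-ar
    text: "Aortic Valve: … ? BAV. Moderate AS. Trivial AR …. Aorta:"
    expected:
      - {outcome: AV Stenosis, value: 2, label: moderate}
      - {outcome: AR level, value: 1, label: trivial}
  - id: overall-severe-ar
    text: "Aortic Valve: …. Overall assessment is of severe aortic regurgitation. … Aorta:"
    expected:
      - {outcome: AR level, value: 4, label: severe}
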