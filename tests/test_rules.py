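"""Extraction rule cascade: matching, normalisation, overlap resolution."""

import pytest

import echoextract as ee
from echoextract.rules import OutcomeAnnotation
from echoextract.textproc import Span


def primary(annotations):
    return {a.outcome: a for a in annotations if not a.suppressed}


class TestApplyRules:
    def test_run_on_measurement_line(self, extract):
        got = primary(extract("AV Vmax 4.2 m/s MPD 46 mmHg VTI 103 cm"))
        assert got["AV Vmax"].var_value == 4.2
        assert got["AV Vmax"].unit == "m/s"
        assert got["AV MPG"].var_value == 46
        assert got["AV VTI"].var_value == 103

    def test_range_averaging(self, extract):
        got = primary(extract("Ejection Fraction (EF) 45–50%"))
        ann = got["EF"]
        assert (ann.var_value1, ann.var_value2) == (45, 50)
        assert ann.var_value == 47.5
        assert ann.unit == "%"

    def test_range_mean_invariant(self, extract):
        for text in ["EF 45–50%", "LVIDd 4.2-5.2 cm", "DcT 180 to 220 ms"]:
            for ann in extract(text):
                if ann.var_value1 is not None:
                    assert ann.var_value == pytest.approx(
                        (ann.var_value1 + ann.var_value2) / 2)

    def test_severity_mapping(self, extract):
        got = primary(extract("Trivial aortic regurgitation."))
        assert got["AR level"].var_value == 1
        assert got["AR level"].label == "trivial"

    def test_unit_conversion_to_canonical(self, extract):
        got = primary(extract("LVOT diam 27 mm"))
        assert got["LVOT Diam"].var_value == 2.7
        assert got["LVOT Diam"].unit == "cm"

    def test_no_lexicon_terms_yields_nothing(self, extract):
        assert extract("The patient was comfortable throughout.") == []

    def test_malformed_decimal_flagged_not_merged(self, extract):
        got = primary(extract("AV max PG 38 9 mmHg"))
        ann = got["AV max PG"]
        assert ann.var_value == 38
        assert "suspected-malformed-decimal" in ann.flags

    def test_negation_scoped_to_clause(self, extract):
        got = primary(extract(
            "Aortic Valve: No aortic stenosis, mild aortic regurgitation."))
        assert got["AV Stenosis"].var_value == 0
        assert got["AV Stenosis"].negated
        assert got["AR level"].var_value == 2
        assert not got["AR level"].negated

    def test_value_binding_does_not_cross_clause(self, extract):
        # the number belongs to the second clause, not the stranded alias
        got = primary(extract("AV VTI not measured, weight 80 kg"))
        assert "AV VTI" not in got

    def test_provenance_carried(self, extract):
        ann = primary(extract("Ao VTI 36 cm;"))["AV VTI"]
        assert ann.rule_name == "continuous-single"
        assert ann.matched_text == "Ao VTI 36 cm"
        assert ann.span.start == 0

    def test_unknown_outcome_in_rule_file_fails_at_load(self, tmp_path,
                                                        lexicon):
        path = tmp_path / "rules.yaml"
        path.write_text(
            "rules:\n"
            "  - name: bad\n"
            "    priority: 1\n"
            "    lhs:\n"
            "      - {kind: lookup, outcome: Nonexistent, bind: out}\n"
            "    rhs:\n"
            "      - {action: bind_value, from: out}\n")
        with pytest.raises(ee.RuleConfigError, match="Nonexistent"):
            ee.load_rules(path, lexicon)

    def test_duplicate_priorities_rejected(self, tmp_path):
        path = tmp_path / "rules.yaml"
        path.write_text(
            "rules:\n"
            "  - {name: a, priority: 1,\n"
            "     lhs: [{kind: lookup, bind: out}],\n"
            "     rhs: [{action: bind_value, from: out}]}\n"
            "  - {name: b, priority: 1,\n"
            "     lhs: [{kind: lookup, bind: out}],\n"
            "     rhs: [{action: bind_value, from: out}]}\n")
        with pytest.raises(ee.RuleConfigError, match="unique"):
            ee.load_rules(path)

    def test_unbound_rhs_reference_rejected(self):
        with pytest.raises(ee.RuleConfigError, match="unbound"):
            ee.Rule(name="x", priority=1,
                    lhs=({"kind": "lookup"},),
                    rhs=({"action": "bind_value", "from": "missing"},))


def _ann(outcome, priority, start, end, prosthetic=False, value=1.0):
    return OutcomeAnnotation(
        outcome=outcome, var_value=value, unit="", span=Span(start, end),
        rule_name="t", priority=priority, prosthetic=prosthetic)


class TestResolveOverlaps:
    def test_higher_priority_wins_on_overlap(self):
        keep = ee.resolve_overlaps([_ann("AR level", 10, 0, 5),
                                    _ann("AR level", 5, 2, 7)])
        assert [a.priority for a in keep] == [10]

    def test_single_candidate_unchanged(self):
        ann = _ann("AR level", 10, 0, 5)
        assert ee.resolve_overlaps([ann]) == [ann]

    def test_non_overlapping_same_outcome_both_kept(self):
        keep = ee.resolve_overlaps([_ann("AR level", 10, 0, 5),
                                    _ann("AR level", 10, 6, 9)])
        assert len(keep) == 2

    def test_different_outcomes_may_overlap(self):
        keep = ee.resolve_overlaps([_ann("AR level", 10, 0, 5),
                                    _ann("AV Stenosis", 5, 2, 7)])
        assert len(keep) == 2

    def test_idempotence(self):
        cands = [_ann("AR level", 10, 0, 5), _ann("AR level", 5, 2, 7),
                 _ann("EF", 3, 1, 4), _ann("EF", 3, 10, 12)]
        once = ee.resolve_overlaps(cands)
        assert ee.resolve_overlaps(once) == once


class TestMultiplicity:
    def test_first_mention_wins_and_conflict_flagged(self, extract):
        anns = extract("Trivial aortic regurgitation. "
                       "Mild aortic regurgitation.")
        kept = [a for a in anns if not a.suppressed]
        dropped = [a for a in anns if a.suppressed]
        assert len(kept) == 1 and kept[0].var_value == 1
        assert len(dropped) == 1
        assert "conflicting-mention" in dropped[0].flags

    def test_native_outranks_prosthetic(self, extract):
        anns = extract(
            "Aortic Valve: Trivial AR. AVR seen in situ with a mild "
            "paraprosthetic regurgitation.")
        kept = primary(anns)
        assert kept["AR level"].var_value == 1
        assert not kept["AR level"].prosthetic
        dropped = [a for a in anns if a.suppressed]
        assert len(dropped) == 1 and dropped[0].prosthetic


class TestGroupToParent:
    def test_grouping_and_conservation(self, lexicon, extract):
        anns = extract("Sinotubular junction 2.8 cm. EF 55%. "
                       "Trivial aortic regurgitation.")
        grouped = ee.group_to_parent(anns, lexicon)
        assert any(a.outcome == "Sinotubular Junction"
                   for a in grouped["VesselsMeasurements"])
        assert sum(len(v) for v in grouped.values()) == len(anns)

    def test_empty_input(self, lexicon):
        assert ee.group_to_parent([], lexicon) == {}

    def test_missing_parent_level_is_config_error(self, lexicon):
        with pytest.raises(ee.RuleConfigError):
            ee.group_to_parent([_ann("not-an-outcome", 1, 0, 1)], lexicon)


def test_render_trace_mentions_rule_and_span(extract, lexicon):
    doc = ee.annotate("r77", "Ao VTI 36 cm;", lexicon)
    anns = ee.apply_rules(doc, ee.load_rules(lexicon=lexicon), lexicon)
    trace = ee.render_trace(doc, anns)
    assert "r77" in trace
    assert "AV VTI" in trace
    assert "continuous-single" in trace
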