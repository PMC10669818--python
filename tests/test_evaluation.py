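"""Agreement and classification metrics against independent oracles."""

import numpy as np
import pandas as pd
import pytest

import echoextract as ee
from echoextract.evaluation import DiscreteTally

# Published per-outcome confusion counts with their printed metric values,
# used as fixed arithmetic oracles for precision/recall/F1.
TALLY_METRICS = [
    ("AR level", (24, 3, 4, 67), (0.86, 0.89, 0.87)),
    ("LV Systolic Function", (12, 17, 3, 66), (0.80, 0.41, 0.55)),
    ("MV Regurgitation Level", (59, 2, 1, 36), (0.98, 0.97, 0.98)),
    ("AV + MV + PV + TV Stenosis", (5, 4, 8, 375), (0.38, 0.56, 0.45)),
    ("TR Level", (57, 32, 2, 105), (0.97, 0.64, 0.77)),
]


def _tally(name, cells):
    tp, fn, fp, tn = cells
    return DiscreteTally(outcome=name, tp=tp, fn=fn, fp=fp, tn=tn)


def _long(mapping):
    """{report_id: {outcome: value}} -> long DataFrame."""
    rows = [{"report_id": rid, "outcome": o, "value": v}
            for rid, d in mapping.items() for o, v in d.items()]
    return pd.DataFrame(rows, columns=["report_id", "outcome", "value"])


class TestTallyDiscrete:
    def test_exact_agreement_is_tp(self):
        t = ee.tally_discrete(_long({"r1": {"AR level": 1}}),
                              _long({"r1": {"AR level": 1}}), "AR level",
                              ["r1"])
        assert (t.tp, t.fn, t.fp, t.tn) == (1, 0, 0, 0)

    def test_reference_only_is_fn(self):
        t = ee.tally_discrete(_long({}), _long({"r1": {"AR level": 2}}),
                              "AR level", ["r1"])
        assert (t.tp, t.fn, t.fp, t.tn) == (0, 1, 0, 0)

    def test_system_only_is_fp(self):
        t = ee.tally_discrete(_long({"r1": {"AR level": 2}}), _long({}),
                              "AR level", ["r1"])
        assert t.fp == 1

    def test_category_disagreement_is_single_fp(self):
        t = ee.tally_discrete(_long({"r1": {"AR level": 2}}),
                              _long({"r1": {"AR level": 3}}), "AR level",
                              ["r1"])
        assert (t.tp, t.fn, t.fp, t.tn) == (0, 0, 1, 0)
        assert t.total == 1  # no double counting

    def test_both_absent_is_tn_and_conservation(self):
        sys = _long({"r1": {"AR level": 1}})
        ref = _long({"r2": {"AR level": 1}})
        t = ee.tally_discrete(sys, ref, "AR level", ["r1", "r2", "r3"])
        assert (t.tp, t.fn, t.fp, t.tn) == (0, 1, 1, 1)
        assert t.total == 3

    def test_constructed_corpus_reproduces_target_tally(self):
        """A corpus built to contain 24 agreements, 3 reference-only, 4
        system-side errors and 67 joint absences tallies exactly so."""
        sys, ref = {}, {}
        rid = 0
        for _ in range(24):
            rid += 1
            sys[f"r{rid}"] = {"AR level": 2}
            ref[f"r{rid}"] = {"AR level": 2}
        for _ in range(3):
            rid += 1
            sys[f"r{rid}"] = {}
            ref[f"r{rid}"] = {"AR level": 1}
        for _ in range(4):
            rid += 1
            sys[f"r{rid}"] = {"AR level": 3}
            ref[f"r{rid}"] = {}
        for _ in range(67):
            rid += 1
            sys[f"r{rid}"] = {}
            ref[f"r{rid}"] = {}
        t = ee.tally_discrete(_long(sys), _long(ref), "AR level",
                              [f"r{i}" for i in range(1, rid + 1)])
        assert (t.tp, t.fn, t.fp, t.tn) == (24, 3, 4, 67)


class TestPrecisionRecallF1:
    @pytest.mark.parametrize("name,cells,expected", TALLY_METRICS)
    def test_published_metric_arithmetic(self, name, cells, expected):
        assert ee.precision_recall_f1(_tally(name, cells)) == expected

    def test_perfect_single_positive(self):
        assert ee.precision_recall_f1(_tally("x", (1, 0, 0, 0))) == \
            (1.0, 1.0, 1.0)

    def test_all_zero_is_undefined_not_zero(self):
        with pytest.raises(ee.UndefinedMetric):
            ee.precision_recall_f1(_tally("x", (0, 0, 0, 0)))


class TestAggregateAndPool:
    def test_rare_outcome_aggregation(self):
        parts = [_tally("AV Stenosis", (2, 1, 3, 94)),
                 _tally("MV Stenosis", (1, 1, 2, 94)),
                 _tally("PV Stenosis", (1, 1, 2, 94)),
                 _tally("TV Stenosis", (1, 1, 1, 93))]
        merged = ee.aggregate_rare(parts)
        assert (merged.tp, merged.fn, merged.fp, merged.tn) == (5, 4, 8, 375)
        assert "AV Stenosis" in merged.outcome

    def test_single_tally_identity(self):
        t = _tally("x", (1, 2, 3, 4))
        merged = ee.aggregate_rare([t])
        assert (merged.tp, merged.fn, merged.fp, merged.tn) == (1, 2, 3, 4)

    def test_zero_tallies_sum_to_zero(self):
        merged = ee.aggregate_rare([_tally("a", (0, 0, 0, 0)),
                                    _tally("b", (0, 0, 0, 0))])
        assert merged.total == 0

    def test_pooled_accuracy_on_published_counts(self):
        tallies = [_tally(n, c) for n, c, _ in TALLY_METRICS]
        accuracy, fn_pct, fp_pct, total = ee.pooled_accuracy(tallies)
        assert total == 882
        assert accuracy == 91.38
        assert fn_pct == pytest.approx(round(100 * 58 / 882, 2))
        assert fp_pct == pytest.approx(round(100 * 18 / 882, 2))

    @pytest.mark.parametrize("cells,expected", [
        ((1, 0, 0, 0), 100.0), ((0, 1, 0, 0), 0.0)])
    def test_pooled_accuracy_degenerate(self, cells, expected):
        assert ee.pooled_accuracy([_tally("x", cells)])[0] == expected


class TestRSquared:
    def test_identical_vectors(self):
        s = ee.PairedSeries("x", [1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert ee.r_squared(s) == pytest.approx(1.0)

    def test_scale_mismatch_keeps_r2_perfect(self):
        s = ee.PairedSeries("x", [1.0, 2.0, 3.0], [2.0, 4.0, 6.0])
        assert ee.r_squared(s) == pytest.approx(1.0)

    def test_independent_pairs_near_zero(self):
        rng = np.random.default_rng(0)
        s = ee.PairedSeries("x", rng.normal(size=1000),
                            rng.normal(size=1000))
        assert ee.r_squared(s) < 0.02

    def test_zero_variance_undefined(self):
        with pytest.raises(ee.UndefinedMetric):
            ee.r_squared(ee.PairedSeries("x", [1.0, 1.0, 1.0],
                                         [1.0, 2.0, 3.0]))


def icc_oracle(ref, sys_):
    """Plainly-coded two-way ANOVA mean squares, the textbook route."""
    import itertools
    n, k = len(ref), 2
    table = [[ref[i], sys_[i]] for i in range(n)]
    grand = sum(itertools.chain(*table)) / (n * k)
    row_means = [sum(row) / k for row in table]
    col_means = [sum(table[i][j] for i in range(n)) / n for j in range(k)]
    ssr = k * sum((m - grand) ** 2 for m in row_means)
    ssc = n * sum((m - grand) ** 2 for m in col_means)
    sst = sum((x - grand) ** 2 for x in itertools.chain(*table))
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestIcc:
    def test_identical_vectors_perfect(self):
        value, p, band = ee.icc(ee.PairedSeries("x", [1.0, 2.0, 3.0],
                                                [1.0, 2.0, 3.0]))
        assert value == pytest.approx(1.0)
        assert band == "excellent"
        assert p == pytest.approx(0.0)

    def test_absolute_agreement_penalises_scale(self):
        s = ee.PairedSeries("x", [1.0, 2.0, 3.0], [2.0, 4.0, 6.0])
        value, _, _ = ee.icc(s)
        assert value < ee.r_squared(s)
        assert value == pytest.approx(icc_oracle([1, 2, 3], [2, 4, 6]),
                                      abs=1e-12)

    def test_degenerate_constant_table(self):
        value, p, band = ee.icc(ee.PairedSeries("x", [2.0, 2.0],
                                                [2.0, 2.0]))
        assert value == 1.0
        assert np.isnan(p)

    def test_matches_anova_oracle_on_random_series(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            n = int(rng.integers(3, 12))
            ref = rng.normal(10, 3, size=n)
            sys_ = ref + rng.normal(0, 1, size=n)
            value, _, _ = ee.icc(ee.PairedSeries("x", ref, sys_))
            assert value == pytest.approx(icc_oracle(list(ref), list(sys_)),
                                          abs=1e-10)

    def test_matches_pingouin_icc2(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(21)
        ref = rng.normal(20, 5, size=30)
        sys_ = ref + rng.normal(0, 2, size=30)
        value, p, _ = ee.icc(ee.PairedSeries("x", ref, sys_))
        df = pd.DataFrame({
            "targets": np.repeat(np.arange(30), 2),
            "raters": ["ref", "sys"] * 30,
            "ratings": np.column_stack([ref, sys_]).ravel(),
        })
        res = pingouin.intraclass_corr(df, targets="targets",
                                       raters="raters", ratings="ratings")
        icc2 = res.set_index("Type").loc["ICC(A,1)"]  # absolute, single
        assert value == pytest.approx(float(icc2["ICC"]), abs=1e-9)
        assert p == pytest.approx(float(icc2["pval"]), abs=1e-9)

    @pytest.mark.parametrize("value,band", [
        (0.2, "poor"), (0.6, "moderate"), (0.85, "good"), (0.95, "excellent")])
    def test_reliability_bands(self, value, band):
        assert ee.icc_band(value) == band


class TestBubbleData:
    def test_absent_outcome_is_zero_triple(self):
        out = ee.bubble_data(_long({}), _long({}), ["EF"])
        assert out.iloc[0].tolist() == ["EF", 0.0, 0.0, 0]

    def test_calibrated_corpus_on_diagonal(self):
        sys = _long({"r1": {"EF": 55.0}, "r2": {"EF": 60.0}})
        out = ee.bubble_data(sys, sys.copy(), ["EF"])
        row = out.iloc[0]
        assert row["reference_magnitude"] == row["system_magnitude"] == 115.0
        assert row["frequency"] == 2

    def test_under_extraction_below_diagonal(self):
        ref = _long({"r1": {"EF": 55.0}, "r2": {"EF": 60.0}})
        sys = _long({"r1": {"EF": 55.0}})
        row = ee.bubble_data(sys, ref, ["EF"]).iloc[0]
        assert row["system_magnitude"] < row["reference_magnitude"]


class TestParameterRecovery:
    def test_recall_tracks_injected_miss_rate(self, lexicon, ruleset, units,
                                              gazetteer):
        """With a fraction m of mentions worded unextractably, recall over
        the discrete track falls inside the binomial band around 1-m."""
        m = 0.2
        profile = ee.GeneratorProfile(
            n_reports=300, seed=17, noise=ee.NoiseProfile(miss_rate=m))
        corpus = ee.generate_corpus(profile, lexicon)
        system = _extract_corpus(corpus, lexicon, ruleset, units, gazetteer)
        reference = corpus.truth
        ids = [r.report_id for r in corpus.reports]
        tp = fn = 0
        for outcome in lexicon.discrete:
            t = ee.tally_discrete(system, reference, outcome.canonical_name,
                                  ids)
            tp, fn = tp + t.tp, fn + t.fn
        n = tp + fn
        recall = tp / n
        half_width = 1.96 * np.sqrt(m * (1 - m) / n)
        assert abs(recall - (1 - m)) < half_width + 0.02

    def test_precision_tracks_injected_confusion(self, lexicon, ruleset,
                                                 units, gazetteer):
        c = 0.15
        profile = ee.GeneratorProfile(
            n_reports=300, seed=23, noise=ee.NoiseProfile(confusion_rate=c))
        corpus = ee.generate_corpus(profile, lexicon)
        system = _extract_corpus(corpus, lexicon, ruleset, units, gazetteer)
        ids = [r.report_id for r in corpus.reports]
        tp = fp = 0
        for outcome in lexicon.discrete:
            t = ee.tally_discrete(system, corpus.truth,
                                  outcome.canonical_name, ids)
            tp, fp = tp + t.tp, fp + t.fp
        precision = tp / (tp + fp)
        # confusion only hits graded (non-negated) mentions, so expected
        # precision is slightly above 1-c; bound it loosely both ways
        assert 1 - c - 0.05 < precision < 1.0


def _extract_corpus(corpus, lexicon, ruleset, units, gazetteer):
    records = []
    for rep in corpus.reports:
        doc = ee.annotate(rep.report_id, rep.text, lexicon, gazetteer)
        anns = ee.apply_rules(doc, ruleset, lexicon, units)
        records.extend(ee.records_from_annotations(rep.report_id, anns))
    return ee.to_long(records)
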