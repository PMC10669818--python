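from pathlib import Path

import pytest
import yaml

import echoextract as ee

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def lexicon():
    return ee.load_lexicon()


@pytest.fixture(scope="session")
def units():
    return ee.load_unit_table()


@pytest.fixture(scope="session")
def ruleset(lexicon):
    return ee.load_rules(lexicon=lexicon)


@pytest.fixture(scope="session")
def gazetteer(lexicon):
    return ee.Gazetteer(lexicon)


@pytest.fixture(scope="session")
def report_fixtures():
    with open(DATA_DIR / "report_fixtures.yaml", encoding="utf-8") as fh:
        return yaml.safe_load(fh)


@pytest.fixture(scope="session")
def extract(lexicon, ruleset, units, gazetteer):
    """Run the full cascade on one text, returning primary annotations."""

    def _extract(text, report_id="r"):
        doc = ee.annotate(report_id, text, lexicon, gazetteer)
        return ee.apply_rules(doc, ruleset, lexicon, units)

    return _extract
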