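"""Ground-truthed synthetic echocardiogram report corpora.

Real hospital report corpora cannot be shared, so every stage of the
pipeline is exercised against synthetic reports that emulate the textual
variation patterns of semi-structured echo reporting: section-heading
layout ("Aortic Valve: ... Aorta: ..."), measurement clauses in several
spellings ("AV Vmax 4.2 m/s", "Ao VTI: 36 cm;", run-on lines with bare
context-dependent aliases), value ranges ("EF 45–50%"), unit variation
("27 mm" for 2.7 cm), graded and negated qualitative findings ("Trivial
aortic regurgitation", "No significant regurgitation"), prosthetic-valve
context, and two observed error modes: malformed decimals ("38 9" for
38.9) and out-of-grammar terminology the extractor cannot match.

Every emitted mention carries exactly one ground-truth record on canonical
units and scales (ranges pre-averaged), so extraction accuracy is
measurable without any manual annotation. A fixed seed makes the corpus
byte-identical across runs.

The generator's defaults are the study conditions: mention-inclusion
probabilities approximate the clinical prevalence of each outcome in a
general TTE population (common chamber measures in most reports, valve
stenoses rare), and value distributions are uniform over clinically
plausible ranges recorded in the outcome dictionary. They are generator
conveniences for producing realistic-looking corpora, not clinical claims.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .lexicon import Lexicon, OutcomeDefinition, load_lexicon

logger = logging.getLogger(__name__)

SECTION_ORDER = [
    ("left ventricle", "Left Ventricle"),
    ("right ventricle", "Right Ventricle"),
    ("left atrium", "Left Atrium"),
    ("right atrium", "Right Atrium"),
    ("mitral valve", "Mitral Valve"),
    ("aortic valve", "Aortic Valve"),
    ("tricuspid valve", "Tricuspid Valve"),
    ("pulmonary valve", "Pulmonary Valve"),
    ("aorta", "Aorta"),
]

#: default inclusion probability per outcome (clinical prevalence flavour);
#: anything not listed uses the data-type default below.
DEFAULT_INCLUSION = {
    "EF": 0.9, "LVIDd": 0.8, "LVIDs": 0.7, "IVS": 0.7, "PWd": 0.7,
    "LA Area": 0.8, "LA Volume": 0.7, "RA Area": 0.7,
    "LV Systolic Function": 0.35,
    "AR level": 0.3, "MV Regurgitation Level": 0.6, "TR level": 0.6,
    "AV Stenosis": 0.06, "MV Stenosis": 0.05, "TV Stenosis": 0.04,
    "PV Stenosis": 0.04,
}
_DEFAULT_P_CONTINUOUS = 0.6
_DEFAULT_P_DISCRETE = 0.3

#: canonical unit -> (printed alternative, factor canonical->printed)
_JITTER_UNITS = {
    "cm": ("mm", 10.0), "m/s": ("cm/s", 100.0), "ms": ("s", 0.001),
    "mL": ("L", 0.001), "cm^2": ("mm^2", 100.0), "cm/s": ("mm/s", 10.0),
}

_RANGE_SEPS = ("–", "-", " to ")


class ProfileError(ValueError):
    """Raised for invalid generator configuration."""


@dataclass
class NoiseProfile:
    """Rates of the emulated reporting irregularities, all in [0, 1]."""

    miss_rate: float = 0.0            # mention worded so extraction must miss
    confusion_rate: float = 0.0       # discrete grade printed wrong
    unit_jitter_rate: float = 0.0     # non-canonical unit printed
    range_rate: float = 0.0           # "a–b" range instead of one value
    negation_rate: float = 0.0        # explicit absence instead of a grade
    malformed_decimal_rate: float = 0.0  # "38 9" for 38.9
    prosthesis_rate: float = 0.0      # prosthetic aortic-valve context

    def __post_init__(self) -> None:
        for name, value in vars(self).items():
            if not 0.0 <= value <= 1.0:
                raise ProfileError(f"noise rate {name}={value} outside [0, 1]")


@dataclass
class GeneratorProfile:
    """Everything that determines a corpus; the seed fixes it byte-exactly."""

    n_reports: int = 100
    seed: int = 0
    outcome_inclusion_probs: dict[str, float] = field(default_factory=dict)
    value_distributions: dict[str, tuple[float, float]] = field(default_factory=dict)
    template_weights: dict[str, float] = field(default_factory=dict)
    noise: NoiseProfile = field(default_factory=NoiseProfile)
    cluster_rate: float = 0.25  # run-on aortic measurement line
    force: Optional[dict] = None  # {"outcome", "template", "value"} override

    def __post_init__(self) -> None:
        if self.n_reports < 0:
            raise ProfileError("n_reports must be >= 0")
        for name, p in self.outcome_inclusion_probs.items():
            if not 0.0 <= p <= 1.0:
                raise ProfileError(f"inclusion prob for {name!r} outside [0, 1]")
        if not 0.0 <= self.cluster_rate <= 1.0:
            raise ProfileError("cluster_rate outside [0, 1]")


@dataclass
class Mention:
    """One intended finding: the ground truth plus its rendering decisions."""

    outcome: str
    category: str
    data_type: str
    value: float                     # canonical-scale truth (ordinal code if discrete)
    unit: str
    alias: str
    template: str
    label: Optional[str] = None      # severity label (discrete)
    shown_label: Optional[str] = None  # printed label (differs under confusion)
    lo: Optional[float] = None
    hi: Optional[float] = None
    printed_value: Optional[str] = None
    printed_unit: Optional[str] = None
    negated: bool = False
    uncertain: bool = False          # malformed decimal: excluded from equality
    extractable: bool = True         # False: worded so the cascade must miss
    prosthetic: bool = False


@dataclass
class SynthReport:
    report_id: str
    mentions: list[Mention]
    text: str = ""


@dataclass
class Corpus:
    reports: list[SynthReport]
    profile: GeneratorProfile

    @property
    def truth(self) -> pd.DataFrame:
        return truth_frame(self.reports)


def load_templates(path: Optional[str | Path] = None) -> dict:
    if path is None:
        text = resources.files("echoextract.data").joinpath(
            "templates.yaml").read_text("utf-8")
    else:
        text = Path(path).read_text("utf-8")
    return yaml.safe_load(text)


def _fmt(value: float) -> str:
    return f"{value:g}"


def _unit_str(unit: str) -> str:
    if unit == "":
        return ""
    if unit == "%":
        return "%"
    return f" {unit}"


def _natural_phrase(outcome: OutcomeDefinition) -> str:
    for alias in outcome.aliases:
        if " " in alias and "(" not in alias:
            return alias
    return outcome.canonical_name


def _pick(rng: np.random.Generator, entries: list[dict],
          weights_override: dict[str, float]) -> dict:
    weights = np.array([
        float(weights_override.get(e["id"], e.get("weight", 1.0)))
        for e in entries
    ])
    weights = weights / weights.sum()
    return entries[int(rng.choice(len(entries), p=weights))]


def _display_label(rng: np.random.Generator, label: str) -> str:
    """Print a scale label with natural connector/case variation."""
    if "-" in label:
        sep = _RANGE_SEPS[int(rng.integers(0, 3))]
        label = label.replace("-", sep if sep != " to " else " to ")
    return label[0].upper() + label[1:]


# ---------------------------------------------------------------------------
# mention construction and noise
# ---------------------------------------------------------------------------


def _sample_mentions(lexicon: Lexicon, profile: GeneratorProfile,
                     templates: dict, rng: np.random.Generator) -> list[Mention]:
    mentions: list[Mention] = []
    for outcome in lexicon:
        name = outcome.canonical_name
        p = profile.outcome_inclusion_probs.get(
            name, DEFAULT_INCLUSION.get(
                name,
                _DEFAULT_P_DISCRETE if outcome.is_discrete
                else _DEFAULT_P_CONTINUOUS))
        if rng.random() >= p:
            continue
        if outcome.is_discrete:
            scale = outcome.severity_scale
            low = 0 if not scale.allows_negation_zero else 1
            code = int(rng.integers(low, scale.max_code + 1))
            template = _pick(rng, templates["discrete"],
                             profile.template_weights)
            label = scale.code_to_label(code)
            phrase = (_natural_phrase(outcome) if rng.random() < 0.7
                      else name)
            mentions.append(Mention(
                outcome=name, category=outcome.category, data_type="discrete",
                value=float(code), unit="", alias=phrase,
                template=template["id"], label=label, shown_label=label,
            ))
        else:
            lo, hi = profile.value_distributions.get(
                name, outcome.plausible_range or (1.0, 10.0))
            value = round(float(rng.uniform(lo, hi)), outcome.decimals)
            aliases = [a for a in outcome.aliases if "(" not in a]
            alias = aliases[0] if rng.random() < 0.7 else \
                aliases[int(rng.integers(0, len(aliases)))]
            template = _pick(rng, templates["continuous"],
                             profile.template_weights)
            mentions.append(Mention(
                outcome=name, category=outcome.category,
                data_type="continuous", value=value,
                unit=outcome.canonical_unit or "", alias=alias,
                template=template["id"],
            ))
    return mentions


def _apply_noise(mentions: list[Mention], noise: NoiseProfile,
                 lexicon: Lexicon, rng: np.random.Generator) -> list[Mention]:
    """Apply at most one noise mode per mention, updating truth where the
    wording genuinely changes the finding (negation)."""
    out: list[Mention] = []
    prosthetic_av = rng.random() < noise.prosthesis_rate
    for m in mentions:
        m = replace(m)
        if prosthetic_av and m.category == "aortic valve":
            m.prosthetic = True
        scale = (lexicon[m.outcome].severity_scale
                 if m.data_type == "discrete" else None)
        if rng.random() < noise.miss_rate:
            m.extractable = False
            m.template = ("miss-discrete" if m.data_type == "discrete"
                          else "miss-continuous")
        elif m.data_type == "discrete":
            if scale.allows_negation_zero and rng.random() < noise.negation_rate:
                m.value, m.negated = 0.0, True
                m.label = scale.code_to_label(0)
                m.shown_label = None
                m.template = "negated" if rng.random() < 0.7 else \
                    "negated-significant"
            elif rng.random() < noise.confusion_rate:
                others = [c for c, _ in scale.levels
                          if c != int(m.value) and c > 0]
                if others:
                    wrong = int(others[int(rng.integers(0, len(others)))])
                    m.shown_label = scale.code_to_label(wrong)
        else:
            if m.unit in _JITTER_UNITS and rng.random() < noise.unit_jitter_rate:
                alt, factor = _JITTER_UNITS[m.unit]
                m.printed_unit = alt
                m.printed_value = _fmt(round(m.value * factor, 9))
            elif rng.random() < noise.range_rate:
                outcome = lexicon[m.outcome]
                # range half-width scaled so the lower bound stays positive
                if outcome.decimals == 0:
                    delta = 2.0
                elif m.value > 1.0:
                    delta = 0.5
                else:
                    delta = 0.1
                m.lo = round(m.value - delta, outcome.decimals)
                m.hi = round(m.value + delta, outcome.decimals)
                m.value = round((m.lo + m.hi) / 2.0, 9)
            elif ("." in _fmt(m.value)
                  and rng.random() < noise.malformed_decimal_rate):
                m.printed_value = _fmt(m.value).replace(".", " ")
                m.uncertain = True
        out.append(m)
    return out


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def _render_mention(m: Mention, templates: dict,
                    rng: np.random.Generator) -> str:
    by_id = {e["id"]: e for group in templates.values() for e in group}
    pattern = by_id[m.template]["pattern"]
    if m.data_type == "discrete":
        phrase = m.alias
        if not m.extractable:
            return pattern.format(phrase=phrase)
        if m.negated:
            return pattern.format(phrase=phrase)
        label = _display_label(rng, m.shown_label or m.label)
        return pattern.format(
            phrase=phrase, label=label[0].lower() + label[1:],
            phrase_cap=phrase[0].upper() + phrase[1:], label_cap=label,
        )
    value = m.printed_value
    if value is None:
        if m.lo is not None:
            sep = _RANGE_SEPS[int(rng.integers(0, 3))]
            value = f"{_fmt(m.lo)}{sep}{_fmt(m.hi)}"
        else:
            value = _fmt(m.value)
    unit = _unit_str(m.printed_unit if m.printed_unit else m.unit)
    return pattern.format(alias=m.alias, value=value, unit=unit)


def _render_report(report: SynthReport, lexicon: Lexicon, templates: dict,
                   profile: GeneratorProfile, rng: np.random.Generator) -> str:
    sections: list[str] = []
    for category, heading in SECTION_ORDER:
        ms = [m for m in report.mentions if m.category == category]
        if not ms:
            continue
        sentences: list[str] = []
        if category == "aortic valve":
            cluster_names = {"AV Vmax", "AV MPG", "AV VTI"}
            clusterable = {m.outcome: m for m in ms
                           if m.outcome in cluster_names
                           and m.data_type == "continuous"
                           and m.extractable and m.printed_value is None
                           and m.printed_unit is None and m.lo is None}
            if (set(clusterable) == cluster_names
                    and rng.random() < profile.cluster_rate):
                pattern = templates["cluster"][0]["pattern"]
                sentences.append(pattern.format(
                    v1=_fmt(clusterable["AV Vmax"].value),
                    v2=_fmt(clusterable["AV MPG"].value),
                    v3=_fmt(clusterable["AV VTI"].value),
                ))
                ms = [m for m in ms if m.outcome not in cluster_names]
        for m in ms:
            sentences.append(_render_mention(m, templates, rng))
        if category == "aortic valve" and any(m.prosthetic for m in ms):
            heading = f"{heading} (AVR)"
            sentences.insert(0, "AVR in situ, well seated.")
        sections.append(f"{heading}: " + " ".join(sentences))
    return "\n".join(sections) + "\n" if sections else ""


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------


def generate_corpus(profile: GeneratorProfile,
                    lexicon: Optional[Lexicon] = None) -> Corpus:
    """Generate ``profile.n_reports`` reports with their ground truth.

    The same profile (seed included) always yields a byte-identical corpus.
    A ``force`` override renders exactly one specified mention per report,
    which pins down single-template behaviour for testing.
    """
    lexicon = lexicon or load_lexicon()
    templates = load_templates()
    rng = np.random.default_rng(profile.seed)
    reports: list[SynthReport] = []
    for i in range(profile.n_reports):
        report_id = f"R{i + 1:04d}"
        if profile.force is not None:
            outcome = lexicon[profile.force["outcome"]]
            value = float(profile.force["value"])
            mention = Mention(
                outcome=outcome.canonical_name, category=outcome.category,
                data_type=outcome.data_type, value=value,
                unit=outcome.canonical_unit or "",
                alias=profile.force.get("alias", outcome.canonical_name),
                template=profile.force["template"],
            )
            mentions = [mention]
        else:
            mentions = _sample_mentions(lexicon, profile, templates, rng)
            mentions = _apply_noise(mentions, profile.noise, lexicon, rng)
        report = SynthReport(report_id=report_id, mentions=mentions)
        report.text = _render_report(report, lexicon, templates, profile, rng)
        reports.append(report)
    return Corpus(reports=reports, profile=profile)


def perturb(report: SynthReport, noise: NoiseProfile, seed: int,
            lexicon: Optional[Lexicon] = None) -> SynthReport:
    """Apply a noise profile to a generated report and re-render it.

    Ground truth follows the wording where the finding itself changes
    (negation sets the truth code to 0) and is flagged where the wording
    becomes unreliable (malformed decimals -> ``uncertain``; missed
    phrasings -> ``extractable=False``). Zero rates return an equal report.
    """
    lexicon = lexicon or load_lexicon()
    templates = load_templates()
    rng = np.random.default_rng(seed)
    mentions = _apply_noise([replace(m) for m in report.mentions], noise,
                            lexicon, rng)
    new = SynthReport(report_id=report.report_id, mentions=mentions)
    new.text = _render_report(new, lexicon, templates, GeneratorProfile(), rng)
    return new


def truth_frame(reports: Sequence[SynthReport]) -> pd.DataFrame:
    """Ground truth in long format (canonical units and scales)."""
    rows = []
    for report in reports:
        for m in report.mentions:
            rows.append({
                "report_id": report.report_id,
                "outcome": m.outcome,
                "value": m.value,
                "unit": m.unit,
                "ordinal_label": m.label or "",
                "negated": m.negated,
                "context": "prosthetic" if m.prosthetic else "",
                "uncertain": m.uncertain,
                "extractable": m.extractable,
            })
    return pd.DataFrame(rows, columns=[
        "report_id", "outcome", "value", "unit", "ordinal_label", "negated",
        "context", "uncertain", "extractable",
    ])


def write_corpus(corpus: Corpus, outdir: str | Path) -> None:
    """Write report text files and the ground-truth long CSV."""
    outdir = Path(outdir)
    reports_dir = outdir / "reports"
    reports_dir.mkdir(parents=True, exist_ok=True)
    for report in corpus.reports:
        (reports_dir / f"{report.report_id}.txt").write_text(
            report.text, encoding="utf-8")
    corpus.truth.to_csv(outdir / "ground_truth.csv", index=False,
                        encoding="utf-8")
    logger.info("wrote %d reports to %s", len(corpus.reports), reports_dir)
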