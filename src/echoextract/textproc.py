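"""Tokenisation, sentence splitting and gazetteer lookup.

Turns raw report text into an :class:`AnnotatedDocument` carrying Token,
Sentence and Lookup annotations — the linguistic pre-processing stages that
feed the extraction rule cascade. Offsets are 0-based, half-open,
everywhere.

Echo reports are semi-structured: section headings ("Aortic Valve:",
"Aorta:") delimit regions of the heart, and short measurement clauses mix
words, numbers and unit strings ("AV Vmax 4.2 m/s"). The tokeniser therefore
treats compound unit symbols (``m/s``, ``mmHg``, ``cm^2``) as single tokens
of class ``unit``, and the gazetteer resolves ambiguous short aliases
("VTI") against the nearest heart-region context.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from .lexicon import BareAlias, Lexicon, NEGATION_FORMS, normalise_label

# ---------------------------------------------------------------------------
# spans and annotations
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class Span:
    """Character offsets, 0-based, half-open."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid span [{self.start}, {self.end})")

    def overlaps(self, other: "Span") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass
class Annotation:
    span: Span
    kind: str  # Token | Sentence | Lookup | Severity | Outcome
    features: dict = field(default_factory=dict)

    def text_in(self, text: str) -> str:
        return text[self.span.start:self.span.end]


@dataclass
class AnnotatedDocument:
    report_id: str
    text: str
    tokens: list[Annotation] = field(default_factory=list)
    sentences: list[Annotation] = field(default_factory=list)
    lookups: list[Annotation] = field(default_factory=list)

    def check_bounds(self) -> None:
        n = len(self.text)
        for ann in [*self.tokens, *self.sentences, *self.lookups]:
            if ann.span.end > n:
                raise ValueError(
                    f"annotation span {ann.span} out of bounds (len {n})"
                )


# ---------------------------------------------------------------------------
# tokeniser
# ---------------------------------------------------------------------------

# Unit symbols recognised as single tokens. Case-sensitive so that "MS"
# (mitral stenosis) is not a millisecond. Alternative spellings normalise
# to the canonical symbol used by the unit table.
_UNIT_NORMALISE = {
    "mmHg": "mmHg", "m/s": "m/s", "cm/s": "cm/s", "mm/s": "mm/s",
    "cm/m^2": "cm/m^2", "cm/m2": "cm/m^2",
    "cm^2": "cm^2", "cm2": "cm^2", "cm²": "cm^2",
    "mm^2": "mm^2", "mm²": "mm^2",
    "cm": "cm", "mm": "mm", "m": "m",
    "mL": "mL", "ml": "mL", "L": "L",
    "msec": "ms", "ms": "ms", "sec": "s", "s": "s",
    "%": "%", "bpm": "bpm",
}

_UNIT_ALT = "|".join(
    re.escape(u) for u in sorted(_UNIT_NORMALISE, key=len, reverse=True)
)

_TOKEN_RE = re.compile(
    rf"""
    (?P<number>\d+\.\d+|\d+)
    | (?P<unit>(?:{_UNIT_ALT})(?![A-Za-z0-9^²]))
    | (?P<word>[A-Za-z][A-Za-z0-9'’]*)
    | (?P<punct>\S)
    """,
    re.VERBOSE,
)

_SENTENCE_FINAL = {".", ";", "…"}


def tokenize(text: str) -> list[Annotation]:
    """Split report text into Token annotations.

    Token classes: ``number`` (decimals kept whole: "4.2"), ``unit``
    ("m/s", "mmHg", "cm^2"), ``word`` (apostrophes kept: "E'"), and
    ``punctuation``. Concatenating token surfaces with the skipped
    whitespace reproduces the input. Malformed decimals such as "38 9"
    stay two separate number tokens.
    """
    if text == "":
        raise ValueError("cannot tokenise an empty document")
    tokens: list[Annotation] = []
    for m in _TOKEN_RE.finditer(text):
        kind = m.lastgroup
        surface = m.group()
        feats = {"text": surface, "class": kind}
        if kind == "unit":
            feats["unit"] = _UNIT_NORMALISE[surface]
        elif kind == "punct":
            feats["class"] = "punctuation"
        tokens.append(Annotation(Span(m.start(), m.end()), "Token", feats))
    return tokens


def split_sentences(doc: AnnotatedDocument) -> list[Annotation]:
    """Group tokens into Sentence annotations.

    Boundaries fall after sentence-final punctuation (``.``, ``;``, the
    ellipsis) and at newlines; decimal points never split (they live inside
    number tokens). Every token lies in exactly one sentence.
    """
    if not doc.tokens:
        return []
    sentences: list[Annotation] = []
    current: list[Annotation] = []

    def flush() -> None:
        if current:
            sentences.append(Annotation(
                Span(current[0].span.start, current[-1].span.end),
                "Sentence", {"n_tokens": len(current)},
            ))
            current.clear()

    prev_end: Optional[int] = None
    for tok in doc.tokens:
        if prev_end is not None and "\n" in doc.text[prev_end:tok.span.start]:
            flush()
        current.append(tok)
        if tok.features["text"] in _SENTENCE_FINAL:
            flush()
        prev_end = tok.span.end
    flush()
    doc.sentences = sentences
    return sentences


# ---------------------------------------------------------------------------
# section headings
# ---------------------------------------------------------------------------

#: heading surface (normalised) -> heart-region context key
SECTION_HEADINGS = {
    "left ventricle": "left ventricle",
    "right ventricle": "right ventricle",
    "left atrium": "left atrium",
    "right atrium": "right atrium",
    "aortic valve": "aortic valve",
    "mitral valve": "mitral valve",
    "tricuspid valve": "tricuspid valve",
    "pulmonary valve": "pulmonary valve",
    "aorta": "aorta",
    "valves": None,
    "conclusion": None,
    "summary": None,
}

_PROSTHESIS_WORDS = {
    "avr", "mvr", "tavi", "tavr", "prosthesis", "prosthetic", "bioprosthesis",
    "bioprosthetic", "replacement", "paraprosthetic", "paravalvular",
}


def _match_key(tok: Annotation) -> str:
    """Normalised match key of one token."""
    return normalise_label(tok.features["text"].replace("’", "'"))


def detect_sections(doc: AnnotatedDocument) -> list[tuple[int, Optional[str], bool]]:
    """Find section headings: a known heading phrase, an optional
    parenthetical qualifier, then a colon.

    Returns (token index after the colon, context key, prosthetic flag)
    per heading; the parenthetical ("(biological AVR)", "(TAVI)") sets the
    prosthetic flag for the section.
    """
    toks = doc.tokens
    keys = [_match_key(t) for t in toks]
    headings: list[tuple[int, Optional[str], bool]] = []
    max_len = max((len(h.split()) for h in SECTION_HEADINGS), default=1)
    i = 0
    while i < len(toks):
        matched = None
        for n in range(max_len, 0, -1):
            phrase = " ".join(keys[i:i + n])
            if phrase in SECTION_HEADINGS and i + n <= len(toks):
                matched = (n, SECTION_HEADINGS[phrase])
                break
        if matched:
            n, context = matched
            j = i + n
            prosthetic = False
            if j < len(toks) and toks[j].features["text"] == "(":
                k = j + 1
                while k < len(toks) and toks[k].features["text"] != ")":
                    if keys[k] in _PROSTHESIS_WORDS:
                        prosthetic = True
                    k += 1
                if k < len(toks):
                    j = k + 1
            if j < len(toks) and toks[j].features["text"] == ":":
                headings.append((j + 1, context, prosthetic))
                i = j + 1
                continue
        i += 1
    return headings


# ---------------------------------------------------------------------------
# gazetteer
# ---------------------------------------------------------------------------


def _alias_tokens(surface: str) -> tuple[str, ...]:
    """Tokenise an alias surface with the document tokeniser so matching is
    insensitive to spacing conventions in the dictionary file."""
    return tuple(_match_key(t) for t in tokenize(surface))


def _case_sensitive(surface: str) -> bool:
    """Short all-caps abbreviations (AS, AR, TR ...) match case-sensitively
    to avoid colliding with common English words."""
    return surface.isupper() and len(surface) <= 3 and surface.isalpha()


class Gazetteer:
    """Longest-match-wins dictionary matcher over token sequences."""

    def __init__(self, lexicon: Lexicon):
        self.lexicon = lexicon
        # entries: (token_keys, exact_surfaces or None, kind, payload)
        # kind: "exclusion" | "outcome" | "bare" | "severity"
        entries: list[tuple[tuple[str, ...], Optional[tuple[str, ...]], str, object]] = []
        for surface in lexicon.exclusions:
            entries.append((_alias_tokens(surface), None, "exclusion", surface))
        for outcome in lexicon:
            for alias in outcome.aliases:
                exact = None
                if _case_sensitive(alias):
                    exact = (alias,)
                entries.append(
                    (_alias_tokens(alias), exact, "outcome", outcome.canonical_name)
                )
        for bare in lexicon.bare_aliases:
            exact = (bare.surface,) if _case_sensitive(bare.surface) else None
            entries.append((_alias_tokens(bare.surface), exact, "bare", bare))
        seen_sev: set[tuple[str, ...]] = set()
        for scale in lexicon.scales.values():
            for _, labels in scale.levels:
                for lab in labels:
                    toks = _alias_tokens(lab)
                    if toks not in seen_sev:
                        seen_sev.add(toks)
                        entries.append((toks, None, "severity", lab))
        for neg in NEGATION_FORMS:
            toks = _alias_tokens(neg)
            if toks not in seen_sev:
                seen_sev.add(toks)
                entries.append((toks, None, "severity", neg))
        # index by first token key; longest entries first; exclusions and
        # qualified outcome aliases outrank bare and severity forms of the
        # same length
        rank = {"exclusion": 0, "outcome": 1, "bare": 2, "severity": 3}
        self.index: dict[str, list] = {}
        for toks, exact, kind, payload in entries:
            self.index.setdefault(toks[0], []).append((toks, exact, kind, payload))
        for bucket in self.index.values():
            bucket.sort(key=lambda e: (-len(e[0]), rank[e[2]]))

    def match(self, doc: AnnotatedDocument) -> list[Annotation]:
        """Produce Lookup (outcome) and Severity annotations.

        Matching is case-insensitive except for short all-caps aliases,
        longest match wins, and matched tokens are consumed left to right.
        Bare aliases resolve against the nearest preceding outcome lookup
        in the sentence, else the current section heading, else their
        default target; an unresolvable bare alias is consumed silently.
        """
        if not doc.sentences:
            split_sentences(doc)
        toks = doc.tokens
        keys = [_match_key(t) for t in toks]
        surfaces = [t.features["text"] for t in toks]

        headings = detect_sections(doc)
        # section regions: document start / each heading up to the next one.
        # A region is prosthetic if its heading qualifier says so or a
        # prosthesis cue ("AVR in situ", "TAVI", "paravalvular") occurs
        # anywhere inside it.
        starts = [0] + [h[0] for h in headings]
        contexts: list[Optional[str]] = [None] + [h[1] for h in headings]
        heading_prosthetic = [False] + [h[2] for h in headings]
        bounds = starts[1:] + [len(toks)]
        section_at: list[tuple[Optional[str], bool]] = [(None, False)] * len(toks)
        for r, (lo, hi_) in enumerate(zip(starts, bounds)):
            cue_idx = None
            for i in range(lo, hi_):
                if keys[i] in _PROSTHESIS_WORDS or (
                        keys[i] == "in" and i + 1 < hi_
                        and keys[i + 1] == "situ"):
                    cue_idx = i
                    break
            for i in range(lo, hi_):
                prosthetic = heading_prosthetic[r] or (
                    cue_idx is not None and i >= cue_idx)
                section_at[i] = (contexts[r], prosthetic)

        # sentence index per token
        sent_of = [0] * len(toks)
        ti = 0
        for si, sent in enumerate(doc.sentences):
            while ti < len(toks) and toks[ti].span.end <= sent.span.end:
                sent_of[ti] = si
                ti += 1

        lookups: list[Annotation] = []
        last_outcome_in_sentence: dict[int, str] = {}

        i = 0
        while i < len(toks):
            hit = None
            for toks_seq, exact, kind, payload in self.index.get(keys[i], []):
                n = len(toks_seq)
                if i + n > len(toks):
                    continue
                if tuple(keys[i:i + n]) != toks_seq:
                    continue
                if exact is not None and surfaces[i] not in exact:
                    continue
                if sent_of[i + n - 1] != sent_of[i]:
                    continue
                hit = (n, kind, payload)
                break
            if hit is None:
                i += 1
                continue
            n, kind, payload = hit
            span = Span(toks[i].span.start, toks[i + n - 1].span.end)
            section, prosthetic = section_at[i]
            if kind == "exclusion":
                pass  # consume; no annotation
            elif kind == "severity":
                lookups.append(Annotation(span, "Severity", {
                    "label": " ".join(keys[i:i + n]),
                    "sentence": sent_of[i],
                }))
            else:
                target: Optional[str]
                if kind == "bare":
                    bare: BareAlias = payload  # type: ignore[assignment]
                    context = last_outcome_in_sentence.get(sent_of[i], section)
                    if context in bare.by_context:
                        target = bare.by_context[context]
                    else:
                        target = bare.default
                else:
                    target = payload  # type: ignore[assignment]
                if target is not None:
                    outcome = self.lexicon[target]
                    lookups.append(Annotation(span, "Lookup", {
                        "target": target,
                        "data_type": outcome.data_type,
                        "section": section,
                        "prosthetic": prosthetic,
                        "sentence": sent_of[i],
                    }))
                    last_outcome_in_sentence[sent_of[i]] = outcome.category
            i += n
        doc.lookups = lookups
        return lookups


def gazetteer_match(doc: AnnotatedDocument, lexicon: Lexicon) -> list[Annotation]:
    """Convenience wrapper: build a gazetteer and annotate one document."""
    return Gazetteer(lexicon).match(doc)


def annotate(report_id: str, text: str, lexicon: Lexicon,
             gazetteer: Optional[Gazetteer] = None) -> AnnotatedDocument:
    """Run the full pre-processing stack on one report."""
    doc = AnnotatedDocument(report_id=report_id, text=text)
    doc.tokens = tokenize(text)
    split_sentences(doc)
    (gazetteer or Gazetteer(lexicon)).match(doc)
    doc.check_bounds()
    return doc


# ---------------------------------------------------------------------------
# batch input
# ---------------------------------------------------------------------------


def read_reports(source: str | Path) -> list[tuple[str, str]]:
    """Read a batch of reports.

    ``source`` is either a directory of ``.txt`` files (report id = file
    stem) or a delimited file with two columns, report_id and text (TSV or
    CSV by extension).
    """
    path = Path(source)
    if path.is_dir():
        return [
            (p.stem, p.read_text("utf-8"))
            for p in sorted(path.glob("*.txt"))
        ]
    delim = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    out: list[tuple[str, str]] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter=delim)
        rows = list(reader)
    if rows and [c.strip().lower() for c in rows[0][:2]] == ["report_id", "text"]:
        rows = rows[1:]
    for row in rows:
        if len(row) < 2:
            raise ValueError(f"{source}: expected two columns, got {row!r}")
        out.append((row[0], row[1]))
    return out


def iter_report_texts(pairs: Iterable[tuple[str, str]], lexicon: Lexicon):
    """Annotate a stream of (report_id, text) pairs with a shared gazetteer."""
    gaz = Gazetteer(lexicon)
    for report_id, text in pairs:
        yield annotate(report_id, text, lexicon, gaz)
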