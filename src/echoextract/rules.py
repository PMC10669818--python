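"""Priority-ordered extraction rule cascade.

Rules are declarative data (see ``data/rules.yaml``): a left-hand-side
pattern over the per-sentence stream of tokens and dictionary lookups, and a
right-hand-side list of actions that bind the measurement value(s), convert
units to the outcome's canonical unit, average ranges, and map severity
labels to ordinal codes. Overlapping candidate matches are resolved by
priority, mirroring a sequential cascade where higher-priority rules
suppress lower ones.

Each emitted :class:`OutcomeAnnotation` carries full provenance (matched
span, rule name, flags), so every database cell can be traced back to the
report text that produced it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import yaml

from .lexicon import (
    Lexicon, UnitTable, UnitConversionError, convert_unit, load_unit_table,
    severity_to_ordinal, NEGATION_FORMS, normalise_label,
)
from .textproc import AnnotatedDocument, Annotation, Span

logger = logging.getLogger(__name__)

_RANGE_SEPS = {"-", "to"}
_CLAUSE_BREAKS = {","}
_PROSTHESIS_CUES = {
    "avr", "mvr", "tavi", "tavr", "prosthesis", "prosthetic",
    "bioprosthesis", "bioprosthetic", "paraprosthetic", "paravalvular",
}

_LHS_KINDS = {"lookup", "severity", "number", "unit", "range_sep", "gap"}
_RHS_ACTIONS = {"bind_value", "bind_range", "bind_unit", "map_severity"}


class RuleConfigError(ValueError):
    """Raised for malformed rule files (including unknown outcome names)."""


@dataclass(frozen=True)
class Rule:
    name: str
    priority: int
    lhs: tuple[dict, ...]
    rhs: tuple[dict, ...]

    def __post_init__(self) -> None:
        bound = set()
        for el in self.lhs:
            kind = el.get("kind")
            if kind not in _LHS_KINDS:
                raise RuleConfigError(f"rule {self.name!r}: bad LHS kind {kind!r}")
            if "bind" in el:
                bound.add(el["bind"])
        for action in self.rhs:
            act = action.get("action")
            if act not in _RHS_ACTIONS:
                raise RuleConfigError(f"rule {self.name!r}: bad action {act!r}")
            for key in ("from", "lo", "hi"):
                if key in action and action[key] not in bound:
                    raise RuleConfigError(
                        f"rule {self.name!r}: RHS references unbound "
                        f"{action[key]!r}"
                    )


@dataclass
class OutcomeAnnotation:
    """One normalised extraction: outcome, value, unit, provenance."""

    outcome: str
    var_value: float  # measurement, or ordinal code for discrete outcomes
    unit: str
    span: Span
    rule_name: str
    priority: int
    var_value1: Optional[float] = None
    var_value2: Optional[float] = None
    label: Optional[str] = None  # scale label for discrete outcomes
    negated: bool = False
    context: Optional[str] = None  # section heading context
    prosthetic: bool = False
    matched_text: str = ""
    flags: tuple[str, ...] = ()
    suppressed: bool = False


def load_rules(path: Optional[str | Path] = None,
               lexicon: Optional[Lexicon] = None) -> list[Rule]:
    """Load a rule file (bundled default when ``path`` is None).

    Priorities must be unique; a rule constrained to an outcome name that
    the lexicon does not define fails here, at load time.
    """
    if path is None:
        text = resources.files("echoextract.data").joinpath(
            "rules.yaml").read_text("utf-8")
    else:
        text = Path(path).read_text("utf-8")
    raw = yaml.safe_load(text) or {}
    rules = [
        Rule(
            name=str(r["name"]),
            priority=int(r["priority"]),
            lhs=tuple(dict(el) for el in r["lhs"]),
            rhs=tuple(dict(a) for a in r["rhs"]),
        )
        for r in raw.get("rules") or []
    ]
    prios = [r.priority for r in rules]
    if len(set(prios)) != len(prios):
        raise RuleConfigError("rule priorities must be unique within a file")
    if lexicon is not None:
        for rule in rules:
            for el in rule.lhs:
                name = el.get("outcome")
                if name is not None and name not in lexicon:
                    raise RuleConfigError(
                        f"rule {rule.name!r} references unknown outcome "
                        f"{name!r}"
                    )
    return rules


# ---------------------------------------------------------------------------
# item stream
# ---------------------------------------------------------------------------


@dataclass
class _Item:
    kind: str  # lookup | severity | number | unit | word | punct
    span: Span
    surface: str
    features: dict = field(default_factory=dict)

    @property
    def is_range_sep(self) -> bool:
        return normalise_label(self.surface) in _RANGE_SEPS

    @property
    def is_clause_break(self) -> bool:
        return self.surface in _CLAUSE_BREAKS


def _sentence_items(doc: AnnotatedDocument) -> list[list[_Item]]:
    """Collapse tokens and dictionary matches into per-sentence item streams."""
    lookups = sorted(
        doc.lookups, key=lambda a: (a.span.start, -(a.span.end - a.span.start))
    )
    li = 0
    sentences: list[list[_Item]] = [[] for _ in doc.sentences]
    for si, sent in enumerate(doc.sentences):
        items = sentences[si]
        toks = [t for t in doc.tokens
                if sent.span.start <= t.span.start and t.span.end <= sent.span.end]
        ti = 0
        while ti < len(toks):
            tok = toks[ti]
            while li < len(lookups) and lookups[li].span.start < tok.span.start:
                li += 1
            if li < len(lookups) and lookups[li].span.start == tok.span.start:
                ann = lookups[li]
                kind = "lookup" if ann.kind == "Lookup" else "severity"
                items.append(_Item(kind, ann.span, ann.text_in(doc.text),
                                   dict(ann.features)))
                li += 1
                while ti < len(toks) and toks[ti].span.start < ann.span.end:
                    ti += 1
                continue
            cls = tok.features["class"]
            if cls == "number":
                items.append(_Item("number", tok.span, tok.features["text"]))
            elif cls == "unit":
                items.append(_Item("unit", tok.span, tok.features["text"],
                                   {"unit": tok.features["unit"]}))
            elif cls == "word":
                items.append(_Item("word", tok.span, tok.features["text"]))
            else:
                items.append(_Item("punct", tok.span, tok.features["text"]))
            ti += 1
    return sentences


def _sentence_prosthetic(items: Sequence[_Item]) -> bool:
    keys = [normalise_label(it.surface) for it in items]
    if any(k in _PROSTHESIS_CUES for k in keys):
        return True
    for a, b in zip(keys, keys[1:]):
        if a == "in" and b == "situ":
            return True
    return False


# ---------------------------------------------------------------------------
# matching
# ---------------------------------------------------------------------------


def _element_matches(el: dict, item: _Item) -> bool:
    kind = el["kind"]
    if kind == "range_sep":
        return item.kind in {"word", "punct"} and item.is_range_sep
    if kind != item.kind:
        return False
    if kind == "lookup":
        if "data_type" in el and item.features.get("data_type") != el["data_type"]:
            return False
        if "outcome" in el and item.features.get("target") != el["outcome"]:
            return False
    return True


def _match_rule(rule: Rule, items: Sequence[_Item], start: int
                ) -> Optional[tuple[dict, int, int]]:
    """Try to match ``rule.lhs`` at ``start``.

    Returns (bindings, first matched index, last matched index) or None.
    Gap elements absorb up to ``max`` word/punctuation items (shortest gap
    first) and never cross a clause break, a number, a unit or another
    dictionary match.
    """

    def rec(i: int, ei: int, bindings: dict) -> Optional[tuple[dict, int]]:
        if ei == len(rule.lhs):
            return bindings, i - 1
        el = rule.lhs[ei]
        if el["kind"] == "gap":
            for glen in range(el.get("max", 0) + 1):
                j = i + glen
                if glen > 0:
                    if j > len(items):
                        break
                    skipped = items[i:j]
                    if any(s.kind not in {"word", "punct"} or s.is_clause_break
                           for s in skipped):
                        break
                result = rec(j, ei + 1, bindings)
                if result is not None:
                    return result
            return None
        if i < len(items) and _element_matches(el, items[i]):
            nxt = dict(bindings)
            if "bind" in el:
                nxt[el["bind"]] = (i, items[i])
            result = rec(i + 1, ei + 1, nxt)
            if result is not None:
                return result
        if el.get("optional"):
            return rec(i, ei + 1, bindings)
        return None

    out = rec(start, 0, {})
    if out is None:
        return None
    bindings, last = out
    return bindings, start, last


def _build_annotation(rule: Rule, bindings: dict, items: Sequence[_Item],
                      last_idx: int, lexicon: Lexicon, units: UnitTable,
                      doc_text: str, sentence_prosthetic: bool
                      ) -> Optional[OutcomeAnnotation]:
    out_item: _Item = bindings["out"][1]
    outcome = lexicon[out_item.features["target"]]
    flags: list[str] = []
    value: Optional[float] = None
    v1 = v2 = None
    label = None
    negated = False
    unit = outcome.canonical_unit or ""

    for action in rule.rhs:
        act = action["action"]
        if act == "bind_value":
            idx, item = bindings[action["from"]]
            value = float(item.surface)
            if idx + 1 < len(items) and items[idx + 1].kind == "number":
                flags.append("suspected-malformed-decimal")
        elif act == "bind_range":
            _, lo_item = bindings[action["lo"]]
            _, hi_item = bindings[action["hi"]]
            v1, v2 = float(lo_item.surface), float(hi_item.surface)
            value = round((v1 + v2) / 2.0, 9)
        elif act == "bind_unit":
            if action["from"] not in bindings:
                continue  # optional unit absent: canonical unit assumed
            _, unit_item = bindings[action["from"]]
            src = unit_item.features["unit"]
            target = outcome.canonical_unit or ""
            if target == "" or src == target:
                continue
            try:
                if value is not None:
                    value = convert_unit(value, src, target, units)
                if v1 is not None:
                    v1 = convert_unit(v1, src, target, units)
                if v2 is not None:
                    v2 = convert_unit(v2, src, target, units)
            except UnitConversionError:
                flags.append("unit-unconverted")
                unit = src
        elif act == "map_severity":
            _, sev_item = bindings[action["from"]]
            scale = outcome.severity_scale
            if scale is None:
                return None
            code = severity_to_ordinal(sev_item.surface, scale)
            if code is None:
                return None
            value = float(code)
            label = scale.code_to_label(code)
            key = normalise_label(sev_item.surface)
            if key.split("-", 1)[0].split(" ", 1)[0] in NEGATION_FORMS:
                negated = True
                lead = key.split(" ")
                if len(lead) > 1:
                    flags.append("negation-qualifier:" + " ".join(lead[1:]))
    if value is None:
        return None
    first_idx = min(i for i, _ in bindings.values())
    span = Span(items[first_idx].span.start, items[last_idx].span.end)
    return OutcomeAnnotation(
        outcome=outcome.canonical_name,
        var_value=value,
        var_value1=v1,
        var_value2=v2,
        label=label,
        negated=negated,
        unit=unit,
        context=out_item.features.get("section"),
        prosthetic=bool(out_item.features.get("prosthetic")) or sentence_prosthetic,
        span=span,
        matched_text=doc_text[span.start:span.end],
        rule_name=rule.name,
        priority=rule.priority,
        flags=tuple(flags),
    )


def resolve_overlaps(candidates: Sequence[OutcomeAnnotation]
                     ) -> list[OutcomeAnnotation]:
    """Keep, per outcome, a non-overlapping set of candidates.

    Ties break by (priority desc, span length desc, start asc); the
    operation is idempotent.
    """
    order = sorted(
        candidates,
        key=lambda a: (-a.priority, -(a.span.end - a.span.start), a.span.start),
    )
    kept: list[OutcomeAnnotation] = []
    for cand in order:
        if any(k.outcome == cand.outcome and k.span.overlaps(cand.span)
               for k in kept):
            continue
        kept.append(cand)
    return sorted(kept, key=lambda a: (a.span.start, a.outcome))


def _resolve_multiplicity(annotations: list[OutcomeAnnotation]
                          ) -> list[OutcomeAnnotation]:
    """At most one primary mention per outcome.

    Native-valve readings outrank prosthesis-context ones; within a class
    the first mention in document order wins. Losers stay in the output,
    flagged ``suppressed`` with a ``conflicting-mention`` provenance flag.
    """
    chosen: dict[str, int] = {}
    for idx, ann in enumerate(annotations):
        cur = chosen.get(ann.outcome)
        if cur is None:
            chosen[ann.outcome] = idx
        else:
            best = annotations[cur]
            if best.prosthetic and not ann.prosthetic:
                chosen[ann.outcome] = idx
    out = []
    for idx, ann in enumerate(annotations):
        if chosen[ann.outcome] != idx:
            ann = replace(ann, suppressed=True,
                          flags=ann.flags + ("conflicting-mention",))
        out.append(ann)
    return out


def apply_rules(doc: AnnotatedDocument, rules: Sequence[Rule],
                lexicon: Lexicon,
                units: Optional[UnitTable] = None) -> list[OutcomeAnnotation]:
    """Run the cascade over one annotated document.

    Pattern matching happens within sentences; candidates from all rules
    compete under :func:`resolve_overlaps`, and a single primary mention per
    outcome survives multiplicity resolution (non-primary mentions are kept
    but flagged ``suppressed``).
    """
    if units is None:
        units = load_unit_table()
    candidates: list[OutcomeAnnotation] = []
    for items in _sentence_items(doc):
        prosthetic = _sentence_prosthetic(items)
        for rule in rules:
            for start in range(len(items)):
                hit = _match_rule(rule, items, start)
                if hit is None:
                    continue
                bindings, _, last = hit
                if "out" not in bindings:
                    continue
                ann = _build_annotation(rule, bindings, items, last, lexicon,
                                        units, doc.text, prosthetic)
                if ann is not None:
                    candidates.append(ann)
    resolved = resolve_overlaps(candidates)
    return _resolve_multiplicity(resolved)


def group_to_parent(annotations: Sequence[OutcomeAnnotation],
                    lexicon: Lexicon) -> dict[str, list[OutcomeAnnotation]]:
    """Group annotations by the lexicon's parent ontology level.

    The total annotation count is conserved; an outcome without a parent
    level is a configuration error.
    """
    grouped: dict[str, list[OutcomeAnnotation]] = {}
    for ann in annotations:
        outcome = lexicon.get(ann.outcome)
        if outcome is None or not outcome.parent_level:
            raise RuleConfigError(
                f"outcome {ann.outcome!r} has no parent_level in the lexicon"
            )
        grouped.setdefault(outcome.parent_level, []).append(ann)
    return grouped


def render_trace(doc: AnnotatedDocument,
                 annotations: Sequence[OutcomeAnnotation]) -> str:
    """Human-readable per-report extraction log (textual provenance view)."""
    lines = [f"report {doc.report_id}: {len(annotations)} annotation(s)"]
    for ann in annotations:
        parts = [
            f"  [{ann.span.start}:{ann.span.end}] {ann.matched_text!r}",
            f"-> {ann.outcome} = {ann.var_value:g}",
        ]
        if ann.label is not None:
            parts.append(f"({ann.label})")
        if ann.unit:
            parts.append(ann.unit)
        if ann.var_value1 is not None:
            parts.append(f"range {ann.var_value1:g}-{ann.var_value2:g}")
        parts.append(f"rule={ann.rule_name}")
        if ann.context:
            parts.append(f"section={ann.context}")
        if ann.prosthetic:
            parts.append("prosthetic")
        if ann.negated:
            parts.append("negated")
        if ann.suppressed:
            parts.append("suppressed")
        for flag in ann.flags:
            parts.append(f"flag={flag}")
        lines.append(" ".join(parts))
    return "\n".join(lines) + "\n"
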