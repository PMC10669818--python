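"""Outcome dictionary, severity scales and unit tables.

The lexicon is the data backbone of the extraction system: one record per
echocardiographic outcome measure (e.g. ``AV VTI``, aortic valve
velocity-time integral), carrying its surface-form aliases for gazetteer
matching, its data type (continuous measurement vs. ordinal severity grade),
its canonical reporting unit, and its parent ontology level used when
grouping extractions into output tables.

The bundled default dictionary seeds the 43 most clinically relevant
outcomes (35 continuous, 8 discrete) across nine heart regions. The file
format is documented in ``data/lexicon.yaml``; adding outcomes is a data
change, not a code change.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator, Mapping, Optional, Sequence

import yaml

logger = logging.getLogger(__name__)

CATEGORIES = frozenset({
    "left ventricle", "right ventricle", "left atrium", "right atrium",
    "aortic valve", "mitral valve", "tricuspid valve", "pulmonary valve",
    "aorta",
})

#: Surface forms that negate a finding ("No aortic regurgitation").
NEGATION_FORMS = frozenset({"no", "none", "not", "absent", "without"})

_DASHES = re.compile(r"[‐-―−]")  # hyphen/en/em dashes, minus


class LexiconError(ValueError):
    """Raised for malformed or inconsistent lexicon content."""


class UnitConversionError(KeyError):
    """Raised when no conversion factor links two unit symbols."""

    def __init__(self, from_unit: str, to_unit: str):
        super().__init__(f"no conversion factor from {from_unit!r} to {to_unit!r}")
        self.from_unit = from_unit
        self.to_unit = to_unit


def normalise_label(label: str) -> str:
    """Canonical key for a severity label: lower case, uniform hyphens.

    En dash, em dash and hyphen are equivalent range/grade connectors, and
    whitespace around them is ignored, so ``"Trivial–Mild"`` and
    ``"trivial - mild"`` share one key.
    """
    s = _DASHES.sub("-", label.strip().lower())
    s = re.sub(r"\s*-\s*", "-", s)
    return re.sub(r"\s+", " ", s)


@dataclass(frozen=True)
class SeverityScale:
    """An ordered severity grading (e.g. regurgitation none..severe).

    Ordinal codes are consecutive integers starting at 0. Combined grades
    such as "trivial-mild" carry the code of their upper member.
    """

    name: str
    levels: tuple[tuple[int, tuple[str, ...]], ...]
    allows_negation_zero: bool = True

    def __post_init__(self) -> None:
        codes = [code for code, _ in self.levels]
        if codes != list(range(len(codes))):
            raise LexiconError(
                f"scale {self.name!r}: codes must be consecutive from 0, got {codes}"
            )

    @property
    def label_to_code(self) -> Mapping[str, int]:
        return {
            normalise_label(lab): code
            for code, labels in self.levels
            for lab in labels
        }

    def code_to_label(self, code: int) -> str:
        for c, labels in self.levels:
            if c == code:
                return labels[0]
        raise LexiconError(f"scale {self.name!r} has no code {code}")

    @property
    def max_code(self) -> int:
        return self.levels[-1][0]


@dataclass(frozen=True)
class OutcomeDefinition:
    """One canonical outcome measure of the dictionary."""

    canonical_name: str
    clinician_name: str
    definition: str
    category: str
    data_type: str  # "continuous" | "discrete"
    canonical_unit: Optional[str] = None  # "" allowed: dimensionless ratio
    severity_scale: Optional[SeverityScale] = None
    aliases: tuple[str, ...] = ()
    parent_level: str = ""
    plausible_range: Optional[tuple[float, float]] = None
    decimals: int = 1

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise LexiconError(
                f"{self.canonical_name!r}: unknown category {self.category!r}"
            )
        if self.data_type == "continuous":
            if self.canonical_unit is None:
                raise LexiconError(
                    f"{self.canonical_name!r}: continuous outcome requires a "
                    "canonical_unit (empty string for dimensionless)"
                )
            if self.severity_scale is not None:
                raise LexiconError(
                    f"{self.canonical_name!r}: continuous outcome cannot carry "
                    "a severity scale"
                )
        elif self.data_type == "discrete":
            if self.severity_scale is None:
                raise LexiconError(
                    f"{self.canonical_name!r}: discrete outcome requires a "
                    "severity_scale"
                )
        else:
            raise LexiconError(
                f"{self.canonical_name!r}: data_type must be continuous or "
                f"discrete, got {self.data_type!r}"
            )

    @property
    def is_discrete(self) -> bool:
        return self.data_type == "discrete"


@dataclass(frozen=True)
class BareAlias:
    """An ambiguous short form ("VTI", "MPD") resolved by heart-region context.

    ``by_context`` maps a category to a canonical name (or None to drop the
    mention in that context); ``default`` applies when no context is known.
    """

    surface: str
    by_context: Mapping[str, Optional[str]]
    default: Optional[str] = None


class Lexicon(Sequence[OutcomeDefinition]):
    """Validated outcome dictionary plus scales, bare aliases and exclusions."""

    def __init__(
        self,
        outcomes: Sequence[OutcomeDefinition],
        scales: Mapping[str, SeverityScale],
        bare_aliases: Sequence[BareAlias] = (),
        exclusions: Sequence[str] = (),
    ):
        names = [o.canonical_name for o in outcomes]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise LexiconError(f"duplicate canonical names: {sorted(dupes)}")
        self._outcomes = list(outcomes)
        self._by_name = {o.canonical_name: o for o in outcomes}
        self.scales = dict(scales)
        self.bare_aliases = list(bare_aliases)
        self.exclusions = list(exclusions)
        for ba in self.bare_aliases:
            for target in list(ba.by_context.values()) + [ba.default]:
                if target is not None and target not in self._by_name:
                    raise LexiconError(
                        f"bare alias {ba.surface!r} references unknown "
                        f"outcome {target!r}"
                    )

    def __len__(self) -> int:
        return len(self._outcomes)

    def __iter__(self) -> Iterator[OutcomeDefinition]:
        return iter(self._outcomes)

    def __getitem__(self, i):
        if isinstance(i, str):
            return self._by_name[i]
        return self._outcomes[i]

    def __contains__(self, name: object) -> bool:
        return name in self._by_name or name in self._outcomes

    def get(self, name: str) -> Optional[OutcomeDefinition]:
        return self._by_name.get(name)

    @property
    def continuous(self) -> list[OutcomeDefinition]:
        return [o for o in self._outcomes if not o.is_discrete]

    @property
    def discrete(self) -> list[OutcomeDefinition]:
        return [o for o in self._outcomes if o.is_discrete]


def _bundled(name: str) -> str:
    return resources.files("echoextract.data").joinpath(name).read_text("utf-8")


def load_lexicon(path: Optional[str | Path] = None) -> Lexicon:
    """Load and validate an outcome dictionary.

    With no ``path`` the bundled default (43 outcomes) is loaded. Malformed
    records raise :class:`LexiconError` naming the offending outcome; an
    empty file yields an empty lexicon with a warning.
    """
    text = _bundled("lexicon.yaml") if path is None else Path(path).read_text("utf-8")
    raw = yaml.safe_load(text)
    if raw is None:
        logger.warning("lexicon file %s is empty", path)
        return Lexicon([], {})
    if not isinstance(raw, dict):
        raise LexiconError("lexicon file must be a mapping at top level")

    scales: dict[str, SeverityScale] = {}
    for name, spec in (raw.get("scales") or {}).items():
        levels = tuple(
            (int(lv["code"]), tuple(str(x) for x in lv["labels"]))
            for lv in spec["levels"]
        )
        scales[name] = SeverityScale(
            name=name,
            levels=levels,
            allows_negation_zero=bool(spec.get("allows_negation_zero", True)),
        )

    outcomes: list[OutcomeDefinition] = []
    for rec in raw.get("outcomes") or []:
        name = rec.get("canonical_name", "<unnamed>")
        try:
            scale = None
            if rec.get("severity_scale") is not None:
                scale_name = rec["severity_scale"]
                if scale_name not in scales:
                    raise LexiconError(f"unknown severity scale {scale_name!r}")
                scale = scales[scale_name]
            rng = rec.get("plausible_range")
            outcomes.append(OutcomeDefinition(
                canonical_name=str(name),
                clinician_name=str(rec.get("clinician_name", name)),
                definition=str(rec.get("definition", "")),
                category=str(rec["category"]),
                data_type=str(rec["data_type"]),
                canonical_unit=(
                    str(rec["canonical_unit"])
                    if "canonical_unit" in rec else None
                ),
                severity_scale=scale,
                aliases=tuple(str(a) for a in rec.get("aliases", ())),
                parent_level=str(rec.get("parent_level", "")),
                plausible_range=(float(rng[0]), float(rng[1])) if rng else None,
                decimals=int(rec.get("decimals", 1)),
            ))
        except (KeyError, LexiconError, TypeError, ValueError) as exc:
            raise LexiconError(f"malformed record {name!r}: {exc}") from exc

    bare = [
        BareAlias(
            surface=str(b["surface"]),
            by_context={str(k): (None if v is None else str(v))
                        for k, v in (b.get("by_context") or {}).items()},
            default=None if b.get("default") is None else str(b["default"]),
        )
        for b in raw.get("bare_aliases") or []
    ]
    exclusions = [str(x) for x in raw.get("exclusions") or []]
    return Lexicon(outcomes, scales, bare, exclusions)


def severity_to_ordinal(label: str, scale: SeverityScale) -> Optional[int]:
    """Map a severity surface form to its ordinal code.

    Matching is case-insensitive and dash-agnostic; a combined grade maps to
    its upper member's code. A phrase led by a negation word ("No aortic
    regurgitation") maps to 0 when the scale allows negation. Returns None
    for an unrecognised label (caller decides whether to skip or flag).
    """
    key = normalise_label(label)
    code = scale.label_to_code.get(key)
    if code is not None:
        return code
    first = key.split(" ", 1)[0].split("-", 1)[0]
    if scale.allows_negation_zero and first in NEGATION_FORMS:
        return 0
    return None


@dataclass
class UnitTable:
    """Multiplicative unit conversions; symmetric and identity-closed."""

    entries: dict[tuple[str, str], float] = field(default_factory=dict)

    def add(self, from_unit: str, to_unit: str, factor: float) -> None:
        if factor == 0:
            raise LexiconError(f"zero factor for {from_unit!r}->{to_unit!r}")
        self.entries[(from_unit, to_unit)] = float(factor)
        self.entries[(to_unit, from_unit)] = 1.0 / float(factor)

    def factor(self, from_unit: str, to_unit: str) -> float:
        if from_unit == to_unit:
            return 1.0
        try:
            return self.entries[(from_unit, to_unit)]
        except KeyError:
            raise UnitConversionError(from_unit, to_unit) from None


def load_unit_table(path: Optional[str | Path] = None) -> UnitTable:
    """Load the unit table (bundled default when ``path`` is None)."""
    text = _bundled("units.yaml") if path is None else Path(path).read_text("utf-8")
    raw = yaml.safe_load(text) or {}
    table = UnitTable()
    for rec in raw.get("conversions") or []:
        table.add(str(rec["from"]), str(rec["to"]), float(rec["factor"]))
    return table


def convert_unit(value: float, from_unit: str, to_unit: str,
                 table: UnitTable) -> float:
    """Convert ``value`` between units by the table's multiplicative factor.

    The product is rounded to 9 decimals so that the bundled power-of-ten
    factors are exact in binary floating point (0.47 m -> 47 cm exactly).
    """
    return round(value * table.factor(from_unit, to_unit), 9)
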