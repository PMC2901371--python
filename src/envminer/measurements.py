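"""Extraction of physicochemical measurements from sentences and tables.

A measurement is a numeric *measure* followed by a unit surface form from the
lexicon ("320 mts depth", "5 mg liter-1"). Extraction proceeds in three
steps per sentence:

1. every numeric token becomes a candidate measure; enumerations sharing one
   trailing unit ("-20 and -80 degrees C", "1, 3, 5 and 15 mM") are expanded
   so each number gets the unit (flag-controlled, on by default);
2. the longest lexicon surface starting right after the measure is matched,
   including multi-part combination units joined by "/", "per" or a
   reciprocal "-1" suffix (grams/liter, gr liter-1, nanogram per milliliter);
3. the unit is linked to a physicochemical variable: an in-window trigger
   word wins (explicit), else a combination rule or a unique unit→variable
   mapping applies (implicit), else the dimension's covering variable is
   reported with the full candidate list retained (ambiguous).

Trigger words of variables incompatible with the unit's dimension never
override it, so "269 kg of manure ha-1" resolves through the mass/area
combination rather than to a bare weight.
"""

from __future__ import annotations

import json
import re
from collections import Counter
from dataclasses import dataclass, field

from .document import Document, SectionKind, Sentence, Table, Token, tokenize
from .lexicon import CombinationRule, Lexicon, UnitEntry, strip_inverse

__all__ = [
    "Measure",
    "Measurement",
    "find_measures",
    "match_unit",
    "resolve_variable",
    "extract_sentence",
    "extract_from_table",
    "extract_document",
    "measurements_to_tsv",
    "measurements_to_json",
]

#: words marking a centrifugation context, where a bare "g" means relative
#: centrifugal force (a speed) rather than grams
CENTRIFUGE_CUES = ("centrifug", "spun", "rpm")

#: connector tokens allowed between the numbers of an enumerated measure
_ENUM_CONNECTORS = {",", "and", "or", "to", "-", "−", "–", ";"}


@dataclass(frozen=True)
class Measure:
    value: float
    raw_text: str
    span: tuple[int, int]


@dataclass
class Measurement:
    measure: Measure
    unit_surface: str | None
    canonical_unit: str | None
    variable: str | None
    status: str  # explicit | implicit | ambiguous | unlinked
    section_kind: SectionKind = SectionKind.OTHER
    sentence_index: int = -1
    candidates: list[str] = field(default_factory=list)
    note: str = ""

    @property
    def value(self) -> float:
        return self.measure.value


def _parse_number(raw: str) -> float:
    return float(raw.replace(",", "").replace("−", "-"))


def find_measures(sentence: Sentence) -> list[Measure]:
    """Every numeric token in the sentence, in order of appearance."""
    return [
        Measure(_parse_number(t.surface), t.surface, (t.char_start, t.char_end))
        for t in sentence.tokens
        if t.is_number
    ]


@dataclass(frozen=True)
class _UnitMatch:
    surface: str            # raw matched text, e.g. "mg liter-1"
    canonical: str          # e.g. "milligram/liter"
    parts: tuple[UnitEntry, ...]
    dims: tuple[str, ...]
    combination: CombinationRule | None
    start: int              # token index of first unit token
    end: int                # token index one past the last unit token


def _match_unit_at(tokens: list[Token], i: int, lexicon: Lexicon) -> _UnitMatch | None:
    """Greedy longest unit (or combination) match starting at tokens[i]."""
    surfaces = [t.surface for t in tokens]
    if i < len(tokens) and surfaces[i] in {"-", "−"}:  # hyphenated "1.5-ha"
        i += 1
    first = lexicon.match_surface_at(surfaces, i)
    if first is None:
        return None
    n1, unit1, surf1, inv1 = first
    parts = [unit1]
    dims = [unit1.dimension]
    raw = [surf1]
    pos = i + n1
    combo = None

    def try_extend(pos: int, allow_space: bool, lookahead: int) -> tuple[int, bool]:
        """Try to attach one more unit part; returns (new pos, attached)."""
        j = pos
        joiner = False
        if j < len(tokens) and surfaces[j] == "/":
            joiner = True
            j += 1
        elif j < len(tokens) and surfaces[j].casefold() == "per":
            joiner = True
            j += 1
        if joiner or allow_space:
            m = lexicon.match_surface_at(surfaces, j)
            if m is not None:
                n, unit, surf, inv = m
                parts.append(unit)
                dims.append(unit.dimension)
                if joiner:
                    raw.append("/" if surfaces[pos] == "/" else "per")
                raw.append(surf)
                return j + n, True
        # reciprocal-suffixed unit a few words on ("269 kg of manure ha-1")
        k = j
        seen = 0
        while k < len(tokens) and seen < lookahead:
            if not tokens[k].is_word:
                break
            base, inv = strip_inverse(surfaces[k])
            if inv:
                m = lexicon.match_surface_at(surfaces, k)
                if m is not None:
                    n, unit, surf, _ = m
                    parts.append(unit)
                    dims.append(unit.dimension)
                    raw.append(surf)
                    return k + n, True
                break
            k += 1
            seen += 1
        return pos, False

    pos2, ok = try_extend(pos, allow_space=False, lookahead=3)
    if ok:
        pos = pos2
        # optional third part; space join allowed ("mol/liter day", "mol/h gr")
        pos3, ok3 = try_extend(pos, allow_space=True, lookahead=0)
        if ok3 and lexicon.combination_for(tuple(dims)) is not None:
            pos = pos3
        elif ok3:
            parts.pop()
            dims.pop()
            raw.pop()
            if raw and raw[-1] in ("/", "per"):
                raw.pop()
        combo = lexicon.combination_for(tuple(dims))
        if combo is None:
            # unknown dimension pattern: fall back to the first unit alone
            parts[:] = parts[:1]
            dims[:] = dims[:1]
            raw[:] = raw[:1]
            pos = i + n1
    canonical = (
        "/".join(p.canonical for p in parts) if len(parts) > 1 else unit1.canonical
    )
    return _UnitMatch(
        surface=" ".join(raw).replace(" / ", "/"),
        canonical=canonical,
        parts=tuple(parts),
        dims=tuple(dims),
        combination=combo,
        start=i,
        end=pos,
    )


def match_unit(
    measure: Measure, sentence: Sentence, lexicon: Lexicon
) -> tuple[str, str] | None:
    """(surface, canonical unit) of the unit following ``measure``, if any."""
    idx = _token_index_of(sentence, measure)
    if idx is None:
        return None
    m = _match_unit_at(sentence.tokens, idx + 1, lexicon)
    if m is None:
        return None
    return m.surface, m.canonical


def _token_index_of(sentence: Sentence, measure: Measure) -> int | None:
    for i, t in enumerate(sentence.tokens):
        if (t.char_start, t.char_end) == measure.span:
            return i
    return None


def _window_phrases(words: list[str], lo: int, hi: int, exclude: range) -> list[str]:
    """Unigrams and bigrams in the word-position window, skipping ``exclude``."""
    out = []
    for k in range(max(0, lo), min(len(words), hi + 1)):
        if k in exclude:
            continue
        out.append(words[k])
        if k + 1 < len(words) and (k + 1) not in exclude:
            out.append(words[k] + " " + words[k + 1])
    return out


def resolve_variable(
    measurement: Measurement,
    sentence: Sentence,
    lexicon: Lexicon,
    unit_match: _UnitMatch | None = None,
    window: int = 5,
) -> Measurement:
    """Link a matched unit to its physicochemical variable.

    Cascade: in-window trigger word of a compatible variable (explicit) →
    combination rule (implicit) → unique unit→variable mapping (implicit) →
    covering variable of the unit's dimension, candidates retained
    (ambiguous). Without a unit match the status stays ``unlinked``.
    """
    if unit_match is None:
        measurement.status = "unlinked"
        measurement.variable = None
        return measurement

    words = [t for t in sentence.tokens if t.is_word or t.is_number]
    unit_word_positions = [
        k for k, t in enumerate(words)
        if unit_match.start <= sentence.tokens.index(t) < unit_match.end
    ] or [0]
    lo = min(unit_word_positions) - window
    hi = max(unit_word_positions) + window
    exclude = range(min(unit_word_positions), max(unit_word_positions) + 1)
    phrases = _window_phrases([w.surface.casefold() for w in words], lo, hi, exclude)

    if unit_match.combination is not None:
        compatible = [unit_match.combination.variable]
    else:
        compatible = list(unit_match.parts[0].variables)

    # centrifugation context turns a bare "g" into a rotational-speed measure
    if (
        unit_match.surface == "g"
        and unit_match.combination is None
        and any(
            any(w.surface.casefold().startswith(cue) for cue in CENTRIFUGE_CUES)
            for w in words
        )
    ):
        measurement.variable = "speed"
        measurement.status = "implicit"
        measurement.note = "g interpreted as relative centrifugal force"
        return measurement

    triggered = []
    for phrase in phrases:
        for vname in lexicon.triggered_variables(phrase):
            if vname in compatible and vname not in triggered:
                triggered.append(vname)
    if triggered:
        order = {v: i for i, v in enumerate(compatible)}
        measurement.variable = min(triggered, key=lambda v: order[v])
        measurement.status = "explicit"
        return measurement
    if unit_match.combination is not None:
        measurement.variable = unit_match.combination.variable
        measurement.status = "implicit"
        return measurement
    if len(compatible) == 1:
        measurement.variable = compatible[0]
        measurement.status = "implicit"
        return measurement
    measurement.variable = lexicon.covering_variable(unit_match.parts[0])
    measurement.status = "ambiguous"
    measurement.candidates = [v for v in compatible if v != measurement.variable]
    return measurement


def extract_sentence(
    sentence: Sentence,
    lexicon: Lexicon,
    enumerations: bool = True,
    window: int = 5,
    include_unlinked: bool = False,
) -> list[Measurement]:
    """All measurements of one sentence.

    With ``enumerations`` on, a number whose following tokens up to the next
    number are only enumeration connectors inherits that number's unit, so
    "-20 and -80 degrees C" yields two temperature measurements.
    """
    tokens = sentence.tokens
    numeric_idx = [i for i, t in enumerate(tokens) if t.is_number]
    matches: dict[int, _UnitMatch | None] = {}
    claimed: set[int] = set()  # token positions already consumed by a unit
    for i in numeric_idx:
        m = _match_unit_at(tokens, i + 1, lexicon)
        if m is not None and any(k in claimed for k in range(m.start, m.end)):
            m = None  # one unit occurrence serves one direct match only
        matches[i] = m
        if m is not None:
            claimed.update(range(m.start, m.end))

    if enumerations:
        for pos, i in enumerate(numeric_idx):
            if matches[i] is not None:
                continue
            # walk forward over connectors and further numbers
            j = i + 1
            ok = False
            while j < len(tokens):
                t = tokens[j]
                if t.surface.casefold() in _ENUM_CONNECTORS:
                    j += 1
                    continue
                if t.is_number:
                    ok = True
                    break
                break
            if ok:
                # inherit from the nearest following number that has a unit
                for k in numeric_idx[pos + 1:]:
                    if matches.get(k) is not None:
                        # every token between must be a connector or number
                        between = tokens[i + 1 : k]
                        if all(
                            b.is_number or b.surface.casefold() in _ENUM_CONNECTORS
                            for b in between
                        ):
                            matches[i] = matches[k]
                        break

    out: list[Measurement] = []
    for i in numeric_idx:
        t = tokens[i]
        measure = Measure(_parse_number(t.surface), t.surface, (t.char_start, t.char_end))
        m = matches[i]
        meas = Measurement(
            measure=measure,
            unit_surface=m.surface if m else None,
            canonical_unit=m.canonical if m else None,
            variable=None,
            status="unlinked",
            section_kind=sentence.section_kind,
        )
        meas = resolve_variable(meas, sentence, lexicon, unit_match=m, window=window)
        if m is not None or include_unlinked:
            out.append(meas)
    return out


_PAREN_RE = re.compile(r"\(([^)]*)\)")


def resolve_table_header(
    header: str, lexicon: Lexicon, window: int = 5
) -> tuple[str, str | None, str] | None:
    """Resolve a header cell like "Temperature (degrees C)" to
    (variable, canonical unit or None, status); None if unresolvable."""
    unit_match = None
    for paren in _PAREN_RE.findall(header):
        toks = tokenize(paren)
        if toks:
            unit_match = _match_unit_at(toks, 0, lexicon)
            if unit_match is not None:
                break
    words = [t.surface.casefold() for t in tokenize(_PAREN_RE.sub(" ", header)) if t.is_word]
    phrases = _window_phrases(words, 0, len(words), range(0))
    if unit_match is not None:
        compatible = (
            [unit_match.combination.variable]
            if unit_match.combination
            else list(unit_match.parts[0].variables)
        )
        for phrase in phrases:
            for vname in lexicon.triggered_variables(phrase):
                if vname in compatible:
                    return vname, unit_match.canonical, "explicit"
        if unit_match.combination is not None:
            return unit_match.combination.variable, unit_match.canonical, "implicit"
        if len(compatible) == 1:
            return compatible[0], unit_match.canonical, "implicit"
        return (
            lexicon.covering_variable(unit_match.parts[0]),
            unit_match.canonical,
            "ambiguous",
        )
    for phrase in phrases:
        hits = lexicon.triggered_variables(phrase)
        if hits:
            return sorted(hits)[0], None, "explicit"
    return None


def extract_from_table(
    table: Table, lexicon: Lexicon, section_kind: SectionKind = SectionKind.OTHER
) -> tuple[list[Measurement], list[str]]:
    """Measurements from a table: the header row names each column's variable
    (and unit, when parenthesized); numeric data cells inherit them.

    Returns (measurements, warnings); a column whose header resolves to no
    variable is skipped with a warning.
    """
    measurements: list[Measurement] = []
    warnings: list[str] = []
    for col, header in enumerate(table.header_cells):
        resolved = resolve_table_header(header, lexicon)
        if resolved is None:
            if header.strip():
                warnings.append(f"table column {col} ({header!r}): no variable resolved")
            continue
        variable, canonical, status = resolved
        for row in table.rows:
            cell = row[col].strip()
            toks = tokenize(cell)
            if len(toks) == 1 and toks[0].is_number:
                measurements.append(
                    Measurement(
                        measure=Measure(
                            _parse_number(cell), cell, (toks[0].char_start, toks[0].char_end)
                        ),
                        unit_surface=header,
                        canonical_unit=canonical,
                        variable=variable,
                        status=status,
                        section_kind=section_kind,
                        note="table",
                    )
                )
    return measurements, warnings


def extract_document(
    doc: Document,
    lexicon: Lexicon,
    enumerations: bool = True,
    window: int = 5,
    include_unlinked: bool = False,
) -> tuple[list[Measurement], dict]:
    """All measurements of a document plus a tally.

    The tally reports counts per section kind and, per variable, the count
    and the modal (most frequent) unit.
    """
    measurements: list[Measurement] = []
    warnings: list[str] = []
    sent_index = 0
    for section in doc.sections:
        for sentence in section.sentences:
            found = extract_sentence(
                sentence,
                lexicon,
                enumerations=enumerations,
                window=window,
                include_unlinked=include_unlinked,
            )
            for m in found:
                m.sentence_index = sent_index
            measurements.extend(found)
            sent_index += 1
        for table in section.tables:
            got, warn = extract_from_table(table, lexicon, section_kind=section.kind)
            measurements.extend(got)
            warnings.extend(warn)

    by_section: Counter[str] = Counter()
    per_variable: dict[str, Counter] = {}
    for m in measurements:
        if m.status == "unlinked":
            continue
        by_section[m.section_kind.value] += 1
        per_variable.setdefault(m.variable, Counter())[m.canonical_unit] += 1
    tally = {
        "by_section": dict(sorted(by_section.items())),
        "by_variable": {
            var: {
                "count": sum(units.values()),
                "modal_unit": min(
                    units.items(), key=lambda kv: (-kv[1], kv[0])
                )[0],
            }
            for var, units in sorted(per_variable.items())
        },
        "warnings": warnings,
    }
    return measurements, tally


def measurement_to_dict(m: Measurement) -> dict:
    return {
        "section_kind": m.section_kind.value,
        "sentence_index": m.sentence_index,
        "value": m.measure.value,
        "raw_text": m.measure.raw_text,
        "span": list(m.measure.span),
        "unit_surface": m.unit_surface,
        "canonical_unit": m.canonical_unit,
        "variable": m.variable,
        "status": m.status,
        "candidates": list(m.candidates),
        "note": m.note,
    }


def measurements_to_json(measurements: list[Measurement], tally: dict | None = None) -> str:
    payload: dict = {"measurements": [measurement_to_dict(m) for m in measurements]}
    if tally is not None:
        payload["tally"] = tally
    return json.dumps(payload, sort_keys=True, ensure_ascii=False, indent=2)


def measurements_to_tsv(measurements: list[Measurement]) -> str:
    header = "section_kind\tsentence_index\tvalue\tunit_surface\tcanonical_unit\tvariable\tstatus"
    rows = [
        "\t".join(
            [
                m.section_kind.value,
                str(m.sentence_index),
                format(m.measure.value, "g"),
                m.unit_surface or "",
                m.canonical_unit or "",
                m.variable or "",
                m.status,
            ]
        )
        for m in measurements
    ]
    return "\n".join([header] + rows) + "\n"
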