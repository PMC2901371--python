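"""Structured representation of an article: sections, sentences, tokens, tables.

Articles arrive as HTML, XML (JATS-like), or plain text. Parsing produces a
:class:`Document` whose sections carry a canonical kind (abstract,
introduction, methods, results, discussion, other) derived from the verbatim
header, sentences with token character offsets (0-based, half-open, into the
section text), and HTML tables as rectangular cell grids.

Everything here is deterministic and rule-based: the sentence splitter uses
terminal punctuation followed by a capitalized token, with an exception list
for abbreviations (including common unit abbreviations such as "min." or
"approx."), so no statistical model or download is ever needed.
"""

from __future__ import annotations

import enum
import json
import re
import unicodedata
from dataclasses import dataclass, field

from lxml import etree, html as lxml_html

__all__ = [
    "SectionKind",
    "Token",
    "Sentence",
    "Table",
    "Section",
    "Document",
    "tokenize",
    "split_sentences",
    "canonicalize_section",
    "parse_document",
]


class SectionKind(str, enum.Enum):
    ABSTRACT = "abstract"
    INTRODUCTION = "introduction"
    METHODS = "methods"
    RESULTS = "results"
    DISCUSSION = "discussion"
    OTHER = "other"


# Numeric token: optional sign, optional thousands separators, optional
# decimal part ("6.5", "-20", "200,000"). Word tokens may carry an attached
# reciprocal exponent ("liter-1", "ha-1") and unicode letters used by units
# (µ, °). "/" and "%" are single-character tokens so unit combinations like
# "cells/ml" split into parts.
NUMBER_RE = re.compile(r"[+\-−]?\d{1,3}(?:,\d{3})+(?:\.\d+)?|[+\-−]?\d+(?:\.\d+)?")
_TOKEN_RE = re.compile(
    # a sign binds to the number only when not preceded by a digit
    # ("-20 degrees" yes; the hyphen of the range "5-10" no)
    r"(?:(?<![\d.])[+\-−])?\d{1,3}(?:,\d{3})+(?:\.\d+)?"  # 200,000
    r"|(?:(?<![\d.])[+\-−])?\d+(?:\.\d+)?"                # 6.5, -20
    r"|[A-Za-z°µμ][A-Za-z0-9°µμ]*(?:[\-−]1(?!\d))?"       # word, liter-1
    r"|[%/]"
    r"|[^\sA-Za-z0-9]"                # punctuation, one char at a time
)


@dataclass(frozen=True)
class Token:
    surface: str
    char_start: int
    char_end: int

    @property
    def is_number(self) -> bool:
        return bool(NUMBER_RE.fullmatch(self.surface))

    @property
    def is_word(self) -> bool:
        return bool(self.surface) and self.surface[0].isalpha()


@dataclass
class Sentence:
    text: str
    tokens: list[Token]
    section_kind: SectionKind = SectionKind.OTHER
    char_start: int = 0  # offset of sentence start within the section text

    def word_tokens(self) -> list[Token]:
        """Tokens that are words or numbers (punctuation skipped)."""
        return [t for t in self.tokens if t.is_word or t.is_number]


@dataclass
class Table:
    header_cells: list[str]
    rows: list[list[str]]

    def __post_init__(self) -> None:
        width = len(self.header_cells)
        self.rows = [
            (row + [""] * (width - len(row)))[:width] if width else list(row)
            for row in self.rows
        ]


@dataclass
class Section:
    label: str
    kind: SectionKind
    text: str = ""
    sentences: list[Sentence] = field(default_factory=list)
    tables: list[Table] = field(default_factory=list)


@dataclass
class Document:
    id: str
    title: str
    sections: list[Section] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def sentences(self):
        for section in self.sections:
            yield from section.sentences

    def to_json(self) -> str:
        """Canonical JSON serialization (stable key order, stable floats)."""
        payload = {
            "id": self.id,
            "title": self.title,
            "warnings": list(self.warnings),
            "sections": [
                {
                    "label": s.label,
                    "kind": s.kind.value,
                    "sentences": [
                        {
                            "text": sent.text,
                            "char_start": sent.char_start,
                            "tokens": [
                                [t.surface, t.char_start, t.char_end]
                                for t in sent.tokens
                            ],
                        }
                        for sent in s.sentences
                    ],
                    "tables": [
                        {"header": t.header_cells, "rows": t.rows} for t in s.tables
                    ],
                }
                for s in self.sections
            ],
        }
        return json.dumps(payload, sort_keys=True, ensure_ascii=False)


def tokenize(text: str, offset: int = 0) -> list[Token]:
    """Tokenize ``text``; offsets are shifted by ``offset``.

    Tokens tile the text left to right (whitespace discarded).
    """
    return [
        Token(m.group(0), m.start() + offset, m.end() + offset)
        for m in _TOKEN_RE.finditer(text)
    ]


# Words before a "." that never end a sentence. Includes unit abbreviations
# so "5 min. At ..." style strings do not split inside a measurement.
DEFAULT_ABBREVIATIONS = frozenset(
    {
        "al", "approx", "ca", "cf", "dr", "e.g", "eq", "fig", "figs", "i.e",
        "mr", "mrs", "no", "prof", "st", "vs",
        # unit abbreviations
        "cm", "ft", "gal", "gr", "hr", "hrs", "kg", "km", "lb", "lbs", "mg",
        "min", "mins", "ml", "mm", "mol", "mt", "mts", "sec", "secs", "ug",
        "ul", "yr", "yrs",
    }
)

_SENT_BOUNDARY_RE = re.compile(r"([.!?]+)(\s+)(?=[\"'(\[]?[A-Z0-9])")


def split_sentences(
    section_text: str, abbreviations: frozenset[str] = DEFAULT_ABBREVIATIONS
) -> list[Sentence]:
    """Deterministic rule-based sentence segmentation.

    A boundary is terminal punctuation followed by whitespace and a
    capitalized (or numeric) token, unless the word before the period is a
    known abbreviation (single letters always count as abbreviations).
    Empty input yields an empty list.
    """
    if not section_text.strip():
        return []
    boundaries: list[int] = []
    for m in _SENT_BOUNDARY_RE.finditer(section_text):
        before = section_text[: m.start(1)]
        last = re.search(r"([A-Za-z][\w.]*)$", before)
        if last is not None and "." in m.group(1):
            word = last.group(1).lower().rstrip(".")
            if word in abbreviations or len(word) == 1:
                continue
        boundaries.append(m.end(2))
    sentences: list[Sentence] = []
    start = 0
    for b in boundaries + [len(section_text)]:
        chunk = section_text[start:b]
        stripped = chunk.strip()
        if stripped:
            lead = len(chunk) - len(chunk.lstrip())
            s0 = start + lead
            sentences.append(
                Sentence(
                    text=stripped,
                    tokens=tokenize(stripped, offset=s0),
                    char_start=s0,
                )
            )
        start = b
    return sentences


_KIND_PATTERNS: list[tuple[str, SectionKind]] = [
    ("abstract", SectionKind.ABSTRACT),
    ("summary", SectionKind.ABSTRACT),
    ("introduction", SectionKind.INTRODUCTION),
    ("background", SectionKind.INTRODUCTION),
    ("method", SectionKind.METHODS),
    ("experimental procedures", SectionKind.METHODS),
    ("result", SectionKind.RESULTS),
    ("discussion", SectionKind.DISCUSSION),
    ("conclusion", SectionKind.DISCUSSION),
]


def canonicalize_section(label: str, parent_kind: SectionKind | None = None) -> SectionKind:
    """Map a verbatim header to a canonical section kind (case-insensitive).

    Unmatched subsection labels (e.g. "Sample collection" under Materials and
    Methods) inherit ``parent_kind`` when given; unmatched top-level labels
    map to ``other``.
    """
    low = label.casefold()
    for needle, kind in _KIND_PATTERNS:
        if needle in low:
            return kind
    if parent_kind is not None:
        return parent_kind
    return SectionKind.OTHER


def _finish_section(section: Section) -> None:
    section.text = unicodedata.normalize("NFC", section.text).strip()
    section.sentences = split_sentences(section.text)
    for s in section.sentences:
        s.section_kind = section.kind


def _element_text(el) -> str:
    """Flatten an element to plain text; <sup>-1</sup> becomes a bare "-1"."""
    return "".join(el.itertext())


def _parse_table(el) -> Table:
    rows: list[list[str]] = []
    for tr in el.iter("tr"):
        cells = [
            re.sub(r"\s+", " ", _element_text(td)).strip()
            for td in tr
            if isinstance(td.tag, str) and td.tag in ("td", "th")
        ]
        if cells:
            rows.append(cells)
    if not rows:
        return Table(header_cells=[], rows=[])
    return Table(header_cells=rows[0], rows=rows[1:])


_HEADING_TAGS = {"h1": 1, "h2": 2, "h3": 3, "h4": 4, "h5": 5, "h6": 6}


def _parse_markup(source_text: str, fmt: str, doc: Document) -> None:
    if fmt == "html":
        try:
            root = lxml_html.fromstring(source_text)
        except Exception as exc:  # lxml is lenient; only hard failures land here
            doc.warnings.append(f"malformed markup: {exc}")
            _parse_plain(source_text, doc)
            return
    else:
        try:
            root = etree.fromstring(source_text.encode("utf-8"))
        except etree.XMLSyntaxError as exc:
            doc.warnings.append(f"malformed markup: {exc}")
            try:
                root = etree.fromstring(
                    source_text.encode("utf-8"),
                    parser=etree.XMLParser(recover=True),
                )
            except Exception:
                root = None
            if root is None:
                _parse_plain(source_text, doc)
                return

    title_el = root.find(".//title")
    if title_el is not None and title_el.text:
        doc.title = title_el.text.strip()

    current = Section(label="", kind=SectionKind.OTHER)
    # (heading_level, kind) stack so subsections inherit their parent's kind
    stack: list[tuple[int, SectionKind]] = []

    def open_section(label: str, level: int) -> None:
        nonlocal current
        if current.text.strip() or current.tables or current.label:
            _finish_section(current)
            if current.text or current.tables:
                doc.sections.append(current)
        while stack and stack[-1][0] >= level:
            stack.pop()
        parent = stack[-1][1] if stack else None
        kind = canonicalize_section(label, parent_kind=parent)
        stack.append((level, kind))
        current = Section(label=label, kind=kind)

    skip = {"script", "style", "head", "title"}
    for el in root.iter():
        tag = el.tag if isinstance(el.tag, str) else None
        if tag is None or tag in skip:
            continue
        if tag in _HEADING_TAGS:
            open_section(re.sub(r"\s+", " ", _element_text(el)).strip(), _HEADING_TAGS[tag])
        elif tag == "table":
            current.tables.append(_parse_table(el))
        elif tag in ("p", "li", "caption"):
            # paragraph-level text; skip text nested inside tables and
            # list items that merely wrap paragraphs (avoid double counting)
            if any(anc.tag == "table" for anc in el.iterancestors()):
                continue
            if tag == "li" and el.find("p") is not None:
                continue
            text = re.sub(r"\s+", " ", _element_text(el)).strip()
            if text:
                current.text += text + " "
        elif fmt == "xml" and tag == "sec":
            t = el.find("title")
            if t is not None and t.text:
                # depth of nesting gives the heading level
                level = sum(1 for _ in t.iterancestors("sec"))
                open_section(t.text.strip(), level)
    _finish_section(current)
    if current.text or current.tables:
        doc.sections.append(current)


def _parse_plain(source_text: str, doc: Document) -> None:
    section = Section(label="", kind=SectionKind.OTHER, text=source_text)
    _finish_section(section)
    doc.sections.append(section)


def parse_document(source_text: str, format: str = "plain", doc_id: str = "doc") -> Document:
    """Parse an article into a :class:`Document`.

    ``format`` is one of ``html``, ``xml``, ``plain``. For markup formats,
    heading tags open sections and ``<table>`` elements become cell grids;
    plain text becomes one section of kind ``other``. Malformed markup is
    parsed best-effort with a warning record. Empty input is an error.
    PDF is not accepted: callers must convert to text or markup first.
    """
    if not source_text or not source_text.strip():
        raise ValueError("empty document")
    if format not in ("html", "xml", "plain"):
        raise ValueError(f"unknown format: {format!r} (expected html, xml or plain)")
    source_text = unicodedata.normalize("NFC", source_text)
    doc = Document(id=doc_id, title="")
    if format == "plain":
        _parse_plain(source_text, doc)
    else:
        _parse_markup(source_text, format, doc)
    if not doc.sections:
        doc.sections.append(Section(label="", kind=SectionKind.OTHER))
    return doc
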