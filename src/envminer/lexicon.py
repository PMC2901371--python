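"""The unit-variable lexicon and its bootstrap from raw article text.

A physicochemical measurement in text is a numeric *measure* followed by a
*unit* ("320 mts depth"); one unit may serve several *variables* (a meter can
measure depth, length, distance...). The lexicon records unit surface forms
(a gram appears as "gram", "gr", "grs" or "g"), each unit's dimension, the
unit→variable mapping, and combination rules by which multi-part units imply
a variable (mass over volume → concentration).

Two corpus-driven operations rebuild such a lexicon from scratch:

* :func:`harvest_candidate_units` scans for numbers and keeps the longest run
  of following words absent from an English dictionary — ordinary words
  ("we repeated the experiment 10 times") are rejected, unit-like strings
  ("5 mg liter-1") survive for manual curation.
* :func:`learn_unit_variable_associations` links units to variables by
  same-sentence co-occurrence within a word window (default 5), iteratively
  proposing new variables from the frequent neighbours of unmatched units.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .document import Document, Sentence, Token

__all__ = [
    "DIMENSIONS",
    "COVERING_VARIABLE",
    "SEED_VARIABLES",
    "UnitEntry",
    "VariableEntry",
    "CombinationRule",
    "Lexicon",
    "LexiconError",
    "load_lexicon",
    "load_dictionary",
    "default_lexicon",
    "default_dictionary",
    "harvest_candidate_units",
    "learn_unit_variable_associations",
]

DIMENSIONS = frozenset(
    {
        "linear", "mass", "volume", "time", "temperature", "amount",
        "count", "angle", "pressure_base", "area", "other",
    }
)

# Broadest variable covering a dimension, used when a unit maps to several
# variables and no trigger word disambiguates (a bare "20 cm" is a size).
COVERING_VARIABLE = {
    "linear": "size",
    "mass": "weight",
    "volume": "volume",
    "time": "time",
    "temperature": "temperature",
    "amount": "concentration",
    "count": "cell number",
    "area": "area",
    "pressure_base": "pressure",
    "angle": "angle",
}

# The ten starting variables of the iterative unit-variable bootstrap.
SEED_VARIABLE_NAMES = (
    "temperature", "size", "volume", "ph", "concentration",
    "time", "weight", "area", "pressure", "salinity",
)


class LexiconError(ValueError):
    """Lexicon schema or validation failure; ``problems`` lists every issue."""

    def __init__(self, problems: list[str]):
        self.problems = list(problems)
        super().__init__("; ".join(problems))


@dataclass
class UnitEntry:
    canonical: str
    surfaces: list[str]
    dimension: str
    variables: list[str]  # first entry is the default


@dataclass
class VariableEntry:
    name: str
    trigger_words: set[str]
    curated: bool = True

    def __post_init__(self) -> None:
        self.trigger_words = {w.casefold() for w in self.trigger_words}
        self.trigger_words.add(self.name.casefold())


@dataclass
class CombinationRule:
    pattern: tuple[str, ...]
    joiners: set[str]
    variable: str


def SEED_VARIABLES() -> list[VariableEntry]:
    return [VariableEntry(name, {name}) for name in SEED_VARIABLE_NAMES]


_INVERSE_RE = re.compile(r"^(.*?)[\-−]1$")


def strip_inverse(token: str) -> tuple[str, bool]:
    """Split an attached reciprocal exponent: "liter-1" -> ("liter", True)."""
    m = _INVERSE_RE.match(token)
    if m and m.group(1):
        return m.group(1), True
    return token, False


@dataclass
class Lexicon:
    units: list[UnitEntry]
    variables: list[VariableEntry]
    combinations: list[CombinationRule]

    # derived indexes, built in __post_init__
    _exact: dict[str, UnitEntry] = field(default_factory=dict, repr=False)
    _folded: dict[str, UnitEntry] = field(default_factory=dict, repr=False)
    _max_surface_tokens: int = field(default=1, repr=False)
    _var_by_name: dict[str, VariableEntry] = field(default_factory=dict, repr=False)
    _trigger_index: dict[str, set[str]] = field(default_factory=dict, repr=False)
    _combo_by_pattern: dict[tuple[str, ...], CombinationRule] = field(
        default_factory=dict, repr=False
    )

    def __post_init__(self) -> None:
        self.validate()
        folded_counts: Counter[str] = Counter()
        for unit in self.units:
            for surf in unit.surfaces:
                self._exact[surf] = unit
                folded_counts[surf.casefold()] += 1
                self._max_surface_tokens = max(
                    self._max_surface_tokens, len(surf.split())
                )
        for unit in self.units:
            for surf in unit.surfaces:
                f = surf.casefold()
                if folded_counts[f] == 1:
                    self._folded[f] = unit
        self._var_by_name = {v.name: v for v in self.variables}
        for v in self.variables:
            for w in v.trigger_words:
                self._trigger_index.setdefault(w, set()).add(v.name)
        self._combo_by_pattern = {c.pattern: c for c in self.combinations}

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        problems: list[str] = []
        names = {v.name for v in self.variables}
        exact_seen: dict[str, str] = {}
        for unit in self.units:
            if not unit.surfaces:
                problems.append(f"unit {unit.canonical!r}: empty surface set")
            if unit.canonical.casefold() not in {s.casefold() for s in unit.surfaces}:
                problems.append(
                    f"unit {unit.canonical!r}: canonical form missing from surfaces"
                )
            if unit.dimension not in DIMENSIONS:
                problems.append(
                    f"unit {unit.canonical!r}: unknown dimension {unit.dimension!r}"
                )
            if not unit.variables:
                problems.append(f"unit {unit.canonical!r}: no variables")
            for var in unit.variables:
                if var not in names:
                    problems.append(
                        f"unit {unit.canonical!r}: undeclared variable {var!r}"
                    )
            for surf in unit.surfaces:
                if surf in exact_seen and exact_seen[surf] != unit.canonical:
                    problems.append(
                        f"surface {surf!r} maps to both "
                        f"{exact_seen[surf]!r} and {unit.canonical!r}"
                    )
                exact_seen[surf] = unit.canonical
        for combo in self.combinations:
            if len(combo.pattern) < 2:
                problems.append(f"combination {combo.pattern!r}: pattern too short")
            for dim in combo.pattern:
                if dim not in DIMENSIONS:
                    problems.append(
                        f"combination {combo.pattern!r}: unknown dimension {dim!r}"
                    )
            if combo.variable not in names:
                problems.append(
                    f"combination {combo.pattern!r}: undeclared variable "
                    f"{combo.variable!r}"
                )
        if problems:
            raise LexiconError(problems)

    # -- lookup -------------------------------------------------------------

    def lookup_surface(self, surface: str) -> UnitEntry | None:
        """Exact-case match first, then case-insensitive where unambiguous."""
        unit = self._exact.get(surface)
        if unit is None:
            unit = self._folded.get(surface.casefold())
        return unit

    def match_surface_at(
        self, tokens: list[str], i: int
    ) -> tuple[int, UnitEntry, str, bool] | None:
        """Longest unit surface match starting at ``tokens[i]``.

        Returns (token count consumed, entry, matched surface, inverse flag).
        A trailing "-1" on the last token marks a reciprocal ("liter-1").
        """
        for n in range(min(self._max_surface_tokens, len(tokens) - i), 0, -1):
            window = tokens[i : i + n]
            base_last, inverse = strip_inverse(window[-1])
            surface = " ".join(window[:-1] + [base_last])
            unit = self.lookup_surface(surface)
            if unit is not None:
                return n, unit, " ".join(window), inverse
        return None

    def variable(self, name: str) -> VariableEntry | None:
        return self._var_by_name.get(name)

    def triggered_variables(self, word: str) -> set[str]:
        return self._trigger_index.get(word.casefold(), set())

    def combination_for(self, dims: tuple[str, ...]) -> CombinationRule | None:
        return self._combo_by_pattern.get(dims)

    def covering_variable(self, unit: UnitEntry) -> str:
        cover = COVERING_VARIABLE.get(unit.dimension)
        if cover is not None and cover in self._var_by_name:
            return cover
        return unit.variables[0]

    def all_surfaces(self) -> set[str]:
        return set(self._exact)


# -- file I/O ----------------------------------------------------------------

def _split_multi(cell: str) -> list[str]:
    return [p.strip() for p in cell.split("|") if p.strip()]


def load_lexicon(path: str | Path) -> Lexicon:
    """Load the sectioned lexicon TSV (see the bundled ``data/lexicon.tsv``).

    Schema violations raise :class:`LexiconError` naming every offending row.
    """
    text = Path(path).read_text(encoding="utf-8")
    return parse_lexicon(text)


def parse_lexicon(text: str) -> Lexicon:
    units: list[UnitEntry] = []
    variables: list[VariableEntry] = []
    combinations: list[CombinationRule] = []
    problems: list[str] = []
    section = None
    expect_header = False
    headers = {
        "[units]": ["canonical", "surfaces", "dimension", "variables"],
        "[variables]": ["name", "trigger_words"],
        "[combinations]": ["pattern", "joiners", "variable"],
    }
    seen_sections: set[str] = set()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        if line.strip() in headers:
            section = line.strip()
            seen_sections.add(section)
            expect_header = True
            continue
        if section is None:
            problems.append(f"line {lineno}: data before any section header")
            continue
        cells = line.split("\t")
        if expect_header:
            expect_header = False
            if [c.strip() for c in cells] != headers[section]:
                problems.append(
                    f"line {lineno}: {section} header must be "
                    f"{chr(9).join(headers[section])!r}"
                )
            continue
        want = len(headers[section])
        if len(cells) != want:
            problems.append(
                f"line {lineno}: expected {want} columns, got {len(cells)}"
            )
            continue
        if section == "[units]":
            units.append(
                UnitEntry(
                    canonical=cells[0].strip(),
                    surfaces=_split_multi(cells[1]),
                    dimension=cells[2].strip(),
                    variables=_split_multi(cells[3]),
                )
            )
        elif section == "[variables]":
            variables.append(
                VariableEntry(name=cells[0].strip(), trigger_words=set(_split_multi(cells[1])))
            )
        else:
            combinations.append(
                CombinationRule(
                    pattern=tuple(_split_multi(cells[0])),
                    joiners=set(_split_multi(cells[1])),
                    variable=cells[2].strip(),
                )
            )
    if not seen_sections:
        problems.append("no section headers found (expected [units], [variables], [combinations])")
    if "[units]" in seen_sections and not units:
        problems.append("[units] section is empty")
    if problems:
        raise LexiconError(problems)
    return Lexicon(units=units, variables=variables, combinations=combinations)


def load_dictionary(path: str | Path, lexicon: Lexicon | None = None) -> frozenset[str]:
    """Load a one-word-per-line wordlist, casefolded.

    Unit surface forms are stripped defensively when a lexicon is given, per
    the harvesting precondition that common unit words are removed from the
    dictionary.
    """
    words = {
        line.strip().casefold()
        for line in Path(path).read_text(encoding="utf-8").splitlines()
        if line.strip() and not line.lstrip().startswith("#")
    }
    if lexicon is not None:
        words -= {s.casefold() for s in lexicon.all_surfaces()}
    return frozenset(words)


def _data_path(name: str) -> Path:
    return Path(str(resources.files("envminer").joinpath("data", name)))


def default_lexicon() -> Lexicon:
    """The curated lexicon bundled with the package."""
    return load_lexicon(_data_path("lexicon.tsv"))


def default_dictionary(lexicon: Lexicon | None = None) -> frozenset[str]:
    return load_dictionary(_data_path("dictionary.txt"), lexicon=lexicon)


# -- bootstrap: unit harvesting ----------------------------------------------

def _word_positions(sentence: Sentence) -> list[Token]:
    return sentence.word_tokens()


def harvest_candidate_units(
    corpus: list[Document], dictionary: frozenset[str]
) -> list[tuple[str, int]]:
    """Candidate unit strings found after numbers, with corpus frequencies.

    For each numeric token, the longest run of immediately following words
    each absent from ``dictionary`` becomes one (possibly multi-word)
    candidate; a following dictionary word ("times") stops the run at once.
    Sorted by descending frequency, then alphabetically, for curation.
    """
    counts: Counter[str] = Counter()
    for doc in corpus:
        for sentence in doc.sentences():
            tokens = sentence.tokens
            i = 0
            while i < len(tokens):
                if not tokens[i].is_number:
                    i += 1
                    continue
                run: list[str] = []
                j = i + 1
                while j < len(tokens):
                    tok = tokens[j]
                    if tok.surface == "/" and run and j + 1 < len(tokens):
                        nxt = tokens[j + 1]
                        base, _ = strip_inverse(nxt.surface)
                        if nxt.is_word and base.casefold() not in dictionary:
                            run.append("/")
                            j += 1
                            continue
                        break
                    if not tok.is_word:
                        break
                    base, _ = strip_inverse(tok.surface)
                    if base.casefold() in dictionary:
                        break
                    run.append(tok.surface)
                    j += 1
                if run:
                    counts[" ".join(run).replace(" / ", "/")] += 1
                i = j if j > i + 1 else i + 1
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))


# -- bootstrap: unit-variable association -------------------------------------

def _candidate_occurrences(
    words: list[Token], candidate_tokens: list[str]
) -> list[int]:
    """Positions (word index of first token) where the candidate occurs."""
    folded = [strip_inverse(w.surface)[0].casefold() for w in words]
    target = [strip_inverse(t)[0].casefold() for t in candidate_tokens]
    n = len(target)
    return [
        i
        for i in range(len(folded) - n + 1)
        if folded[i : i + n] == target
    ]


def learn_unit_variable_associations(
    corpus: list[Document],
    candidates: list[str],
    seed_variables: list[VariableEntry] | None = None,
    window: int = 5,
    proposal_support: int = 2,
) -> list[tuple[str, str, int]]:
    """Associate candidate units with variables by windowed co-occurrence.

    A (unit, variable) pair is emitted when a unit occurrence and a variable
    trigger word appear in one sentence within ``window`` word positions of
    each other (punctuation not counted). Units left unmatched propose new
    variables from their most frequent in-window co-words; proposals reaching
    ``proposal_support`` are appended as uncurated variables and the pass
    repeats until no new association appears.
    """
    if window < 1:
        raise ValueError(f"window must be >= 1, got {window}")
    variables = list(seed_variables) if seed_variables is not None else SEED_VARIABLES()
    cand_tokens = {c: c.replace("/", " ").split() for c in candidates}

    # (unit, sentence words, occurrence position) sites, computed once
    sites: list[tuple[str, list[Token], int]] = []
    for doc in corpus:
        for sentence in doc.sentences():
            words = _word_positions(sentence)
            for cand in candidates:
                for pos in _candidate_occurrences(words, cand_tokens[cand]):
                    sites.append((cand, words, pos))

    def in_window_words(words: list[Token], pos: int, span: int) -> list[tuple[int, str]]:
        lo = max(0, pos - window)
        hi = min(len(words), pos + span - 1 + window + 1)
        return [
            (k, words[k].surface.casefold())
            for k in range(lo, hi)
            if not (pos <= k < pos + span)
        ]

    associations: Counter[tuple[str, str]] = Counter()
    known_triggers = lambda: {w for v in variables for w in v.trigger_words}
    while True:
        associations.clear()
        trigger_map: dict[str, set[str]] = {}
        for v in variables:
            for w in v.trigger_words:
                trigger_map.setdefault(w, set()).add(v.name)
        matched_units: set[str] = set()
        proposals: Counter[tuple[str, str]] = Counter()
        for cand, words, pos in sites:
            span = len(cand_tokens[cand])
            hit = False
            for _, w in in_window_words(words, pos, span):
                for vname in trigger_map.get(w, ()):
                    associations[(cand, vname)] += 1
                    hit = True
            if hit:
                matched_units.add(cand)
        # unmatched units propose new variables from in-window co-words
        existing = known_triggers()
        for cand, words, pos in sites:
            if cand in matched_units:
                continue
            span = len(cand_tokens[cand])
            for k, w in in_window_words(words, pos, span):
                if words[k].is_number or w in existing or not words[k].is_word:
                    continue
                if w in {t.casefold() for t in cand_tokens[cand]}:
                    continue
                proposals[(cand, w)] += 1
        new_words = sorted(
            {w for (_, w), n in proposals.items() if n >= proposal_support}
            - {v.name for v in variables}
        )
        if not new_words:
            break
        before = len(variables)
        for w in new_words:
            variables.append(VariableEntry(name=w, trigger_words={w}, curated=False))
        if len(variables) == before:  # pragma: no cover - defensive
            break
    return sorted(
        ((u, v, n) for (u, v), n in associations.items()),
        key=lambda t: (-t[2], t[0], t[1]),
    )
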