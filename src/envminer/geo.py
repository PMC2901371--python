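"""Geographic location extraction and toponym disambiguation.

Candidate place names are capitalized noun phrases; candidates are checked
against a gazetteer (a GeoNames-style table of names, alternate names,
coordinates, country, admin parent, feature class and a relevance ordering).
A name with several gazetteer records ("Margate" exists in ZA, GB, AU, US
and CA) is resolved by a cascade:

1. a single candidate is taken as-is;
2. *country match* — another location in the same sentence shares a
   candidate's country (admin containment counts: Tasmania ⊂ Australia);
3. *minimum distance* — among same-country survivors, the candidate closest
   (great-circle) to the co-mentioned location wins;
4. *closest country* — when several countries appear in the sentence, the
   one nearest in token distance to the mention decides;
5. *relevance* — the gazetteer's rank-1 record.

Names absent from the gazetteer but containing a generic feature word
("Ganghwa Island") are kept as locations without coordinates. Candidates
with no country (mostly undersea features) skip rules 2-4.

The default chunker is rule-based (maximal runs of capitalized tokens, with
connector-joined compounds tried against the gazetteer first); a real POS
tagger can be injected but is never required.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .document import Document, Sentence

__all__ = [
    "GazetteerRecord",
    "Gazetteer",
    "NounPhrase",
    "GeoMention",
    "FeatureWordList",
    "load_feature_words",
    "default_feature_words",
    "default_gazetteer",
    "haversine_km",
    "extract_noun_phrases",
    "query_gazetteer",
    "detect_feature_word_location",
    "disambiguate",
    "extract_sentence_locations",
    "extract_document_locations",
    "mentions_to_geojson",
]

EARTH_RADIUS_KM = 6371.0

#: lowercase connectors that may join capitalized tokens inside one name
NP_CONNECTORS = frozenset({"of", "de", "del", "la", "le", "da", "dos", "van", "von"})

#: capitalized sentence-initial function/discourse words never form an NP alone
NP_STOPWORDS = frozenset(
    {
        "a", "an", "the", "this", "these", "those", "it", "its", "we", "our",
        "in", "on", "at", "to", "for", "from", "with", "by", "of", "as",
        "however", "therefore", "thus", "here", "there", "also", "although",
        "while", "when", "after", "before", "during", "since", "then",
        "finally", "moreover", "furthermore", "nevertheless", "additionally",
        "both", "all", "most", "many", "some", "several", "each", "other",
        "first", "second", "third", "one", "two", "three", "no", "not",
        "and", "or", "but", "if", "using", "within",
    }
)

#: tokens that flag the following capitalized phrase as a person's name
PERSON_CUES = frozenset({"dr", "dr.", "prof", "prof.", "mr", "mr.", "mrs", "mrs.", "et"})
CITATION_CLOSERS = frozenset({"]", ")"})


@dataclass(frozen=True)
class GazetteerRecord:
    name: str
    alternate_names: frozenset[str]
    latitude: float
    longitude: float
    country_code: str | None
    admin_parent: str | None
    feature_class: str
    relevance_rank: int

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"{self.name}: latitude {self.latitude} out of bounds")
        if not -180.0 <= self.longitude <= 180.0:
            raise ValueError(f"{self.name}: longitude {self.longitude} out of bounds")


@dataclass
class NounPhrase:
    tokens: list[str]
    span: tuple[int, int]
    token_start: int  # index of first token within the sentence token list
    token_end: int = -1  # one past the last token index
    compound: bool = False

    @property
    def has_capitalized(self) -> bool:
        return any(t[:1].isupper() for t in self.tokens)

    @property
    def surface(self) -> str:
        return " ".join(self.tokens)


@dataclass
class GeoMention:
    surface: str
    span: tuple[int, int]
    sentence_index: int = -1
    candidates: list[GazetteerRecord] = field(default_factory=list)
    resolved: GazetteerRecord | None = None
    method: str = "unresolved"  # unique | country_match | min_distance |
    #                             closest_country | relevance | feature_word | unresolved
    token_start: int = 0
    tie: bool = False

    @property
    def has_coordinates(self) -> bool:
        return self.resolved is not None


class RemoteGazetteerUnavailable(RuntimeError):
    """A remote gazetteer adapter failed; distinct from an empty result."""


class Gazetteer:
    """Offline gazetteer over a TSV with a GeoNames-style column subset:
    name, alternate_names (pipe-separated), latitude, longitude,
    country_code, admin_parent, feature_class, relevance_rank."""

    COLUMNS = [
        "name", "alternate_names", "latitude", "longitude",
        "country_code", "admin_parent", "feature_class", "relevance_rank",
    ]

    def __init__(self, records: list[GazetteerRecord]):
        self.records = list(records)
        self._by_name: dict[str, list[GazetteerRecord]] = {}
        for rec in self.records:
            for key in {rec.name.casefold(), *{a.casefold() for a in rec.alternate_names}}:
                self._by_name.setdefault(key, []).append(rec)
        for lst in self._by_name.values():
            lst.sort(key=lambda r: r.relevance_rank)
        # relevance ranks must be unique among same-name records
        for name, lst in self._by_name.items():
            ranks = [r.relevance_rank for r in lst]
            if len(set(ranks)) != len(ranks):
                raise ValueError(f"duplicate relevance_rank for name {name!r}")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Gazetteer":
        records = []
        lines = Path(path).read_text(encoding="utf-8").splitlines()
        header: list[str] | None = None
        for line in lines:
            if not line.strip() or line.startswith("#"):
                continue
            cells = line.split("\t")
            if header is None:
                header = [c.strip() for c in cells]
                if header != cls.COLUMNS:
                    raise ValueError(
                        f"gazetteer header must be {cls.COLUMNS}, got {header}"
                    )
                continue
            row = dict(zip(header, cells))
            records.append(
                GazetteerRecord(
                    name=row["name"].strip(),
                    alternate_names=frozenset(
                        a.strip() for a in row["alternate_names"].split("|") if a.strip()
                    ),
                    latitude=float(row["latitude"]),
                    longitude=float(row["longitude"]),
                    country_code=row["country_code"].strip() or None,
                    admin_parent=row["admin_parent"].strip() or None,
                    feature_class=row["feature_class"].strip(),
                    relevance_rank=int(row["relevance_rank"]),
                )
            )
        return cls(records)

    def query(self, name: str) -> list[GazetteerRecord]:
        """Case-insensitive lookup over names and alternate names,
        ordered by relevance rank."""
        return list(self._by_name.get(name.casefold(), []))

    def countries_of(self, record: GazetteerRecord) -> set[str]:
        """The record's country code plus codes reachable via admin parents."""
        out: set[str] = set()
        seen: set[str] = set()
        current: GazetteerRecord | None = record
        while current is not None and current.name not in seen:
            seen.add(current.name)
            if current.country_code:
                out.add(current.country_code)
            parent = current.admin_parent
            current = None
            if parent:
                hits = self.query(parent)
                if hits:
                    current = hits[0]
        return out

    def is_country(self, record: GazetteerRecord) -> bool:
        return record.feature_class == "PCLI"


@dataclass
class FeatureWordList:
    words: frozenset[str]

    def __post_init__(self) -> None:
        self.words = frozenset(w.casefold() for w in self.words)
        if not self.words:
            raise ValueError("feature word list must be non-empty")

    def __contains__(self, word: str) -> bool:
        return word.casefold() in self.words


def load_feature_words(path: str | Path) -> FeatureWordList:
    words = {
        line.strip()
        for line in Path(path).read_text(encoding="utf-8").splitlines()
        if line.strip() and not line.lstrip().startswith("#")
    }
    return FeatureWordList(frozenset(words))


def _data_path(name: str) -> Path:
    return Path(str(resources.files("envminer").joinpath("data", name)))


def default_feature_words() -> FeatureWordList:
    return load_feature_words(_data_path("feature_words.txt"))


def default_gazetteer() -> Gazetteer:
    """The bundled offline mini-gazetteer."""
    return Gazetteer.from_tsv(_data_path("mini_gazetteer.tsv"))


# -- distance ------------------------------------------------------------------

def haversine_km(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Great-circle distance in km on a sphere of radius 6371.0 km.

    Inputs are (latitude, longitude) in decimal degrees (WGS84 assumed).
    """
    for lat, lon in (a, b):
        if not -90.0 <= lat <= 90.0 or not -180.0 <= lon <= 180.0:
            raise ValueError(f"coordinates out of bounds: ({lat}, {lon})")
    lat1, lon1 = map(math.radians, a)
    lat2, lon2 = map(math.radians, b)
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = math.sin(dlat / 2) ** 2 + math.cos(lat1) * math.cos(lat2) * math.sin(dlon / 2) ** 2
    return 2.0 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(h)))


# -- noun phrase chunking -------------------------------------------------------

def extract_noun_phrases(sentence: Sentence, tagger=None) -> list[NounPhrase]:
    """Capitalized noun phrases of a sentence.

    The default chunker takes maximal runs of capitalized tokens as primary
    NPs and additionally emits compounds joined across single lowercase
    connectors ("Gulf" + "of" + "Mexico"), flagged ``compound`` so the
    pipeline can prefer them only when the gazetteer knows the full name.
    A ``tagger`` callable (tokens -> NounPhrase list) may be injected; on
    failure the rule-based chunker is used.
    """
    if tagger is not None:
        try:
            return [np for np in tagger(sentence) if np.has_capitalized]
        except Exception:
            pass  # fall back to the rule-based chunker

    tokens = sentence.tokens

    def _cap(k: int) -> bool:
        return tokens[k].is_word and tokens[k].surface[:1].isupper()

    runs: list[tuple[int, int]] = []  # [start, end) token index ranges
    i = 0
    while i < len(tokens):
        if _cap(i):
            j = i + 1
            while j < len(tokens):
                if _cap(j):
                    j += 1
                # hyphen bridging two capitalized words: "Mid-Atlantic Ridge"
                elif (
                    tokens[j].surface in ("-", "−")
                    and j + 1 < len(tokens)
                    and _cap(j + 1)
                ):
                    j += 2
                else:
                    break
            runs.append((i, j))
            i = j
        else:
            i += 1

    def _stitch(start: int, end: int) -> list[str]:
        """Token surfaces with hyphens merged into their neighbours."""
        out: list[str] = []
        for t in tokens[start:end]:
            if t.surface in ("-", "−") and out:
                out[-1] += "-"
            elif out and out[-1].endswith("-"):
                out[-1] += t.surface
            else:
                out.append(t.surface)
        return out

    nps: list[NounPhrase] = []
    for start, end in runs:
        toks = _stitch(start, end)
        # sentence-initial lone function words do not qualify
        if start == 0 and end - start == 1 and toks[0].casefold() in NP_STOPWORDS:
            continue
        # drop leading capitalized stopwords ("The Piora Valley")
        while len(toks) > 1 and toks[0].casefold() in NP_STOPWORDS:
            start += 1
            toks = toks[1:]
        nps.append(
            NounPhrase(
                tokens=toks,
                span=(tokens[start].char_start, tokens[end - 1].char_end),
                token_start=start,
                token_end=end,
            )
        )

    # compounds across single lowercase connectors
    compounds: list[NounPhrase] = []
    for a, b in zip(nps, nps[1:]):
        between = tokens[a.token_end : b.token_start]
        if (
            len(between) == 1
            and between[0].is_word
            and between[0].surface.casefold() in NP_CONNECTORS
        ):
            compounds.append(
                NounPhrase(
                    tokens=a.tokens + [between[0].surface] + b.tokens,
                    span=(a.span[0], b.span[1]),
                    token_start=a.token_start,
                    token_end=b.token_end,
                    compound=True,
                )
            )
    return nps + compounds



# -- gazetteer query & feature words -------------------------------------------

def query_gazetteer(name: str, gazetteer: Gazetteer) -> list[GazetteerRecord]:
    """Case-insensitive gazetteer lookup ordered by relevance rank."""
    return gazetteer.query(name)


def detect_feature_word_location(
    np: NounPhrase, gazetteer_hits: list[GazetteerRecord], feature_words: FeatureWordList
) -> GeoMention | None:
    """Fallback for names absent from the gazetteer: a capitalized NP
    containing a generic feature word ("Ganghwa Island") is a location
    without coordinates."""
    if gazetteer_hits:
        return None
    if any(tok in feature_words for tok in np.tokens):
        return GeoMention(
            surface=np.surface,
            span=np.span,
            token_start=np.token_start,
            method="feature_word",
        )
    return None


# -- disambiguation cascade -----------------------------------------------------

def _co_records(mention: GeoMention) -> list[GazetteerRecord]:
    if mention.resolved is not None:
        return [mention.resolved]
    return list(mention.candidates)


def disambiguate(
    mention: GeoMention,
    co_mentions: list[GeoMention],
    gazetteer: Gazetteer,
) -> GeoMention:
    """Resolve an ambiguous mention against same-sentence co-mentions.

    The first cascade rule that yields a unique record wins; ``method``
    records which one. Candidates without a country (undersea features)
    skip the country-based rules. An empty candidate list leaves the
    mention unresolved, never raises.
    """
    cands = mention.candidates
    if not cands:
        mention.method = "unresolved"
        return mention
    if len(cands) == 1:
        mention.resolved = cands[0]
        mention.method = "unique"
        return mention

    with_country = [c for c in cands if c.country_code]
    others = [m for m in co_mentions if m.surface != mention.surface]

    if with_country:
        # rule 2: country match via any co-mention (admin containment counts)
        survivors: list[GazetteerRecord] = []
        anchors: dict[str, list[GazetteerRecord]] = {}
        for c in with_country:
            c_countries = gazetteer.countries_of(c)
            for m in others:
                for d in _co_records(m):
                    if c_countries & gazetteer.countries_of(d):
                        if c not in survivors:
                            survivors.append(c)
                        anchors.setdefault(c.country_code, []).append(d)
        if len(survivors) == 1:
            mention.resolved = survivors[0]
            mention.method = "country_match"
            return mention
        if len(survivors) > 1:
            countries = {c.country_code for c in survivors}
            if len(countries) == 1:
                # rule 3: smallest great-circle distance to the disambiguator
                anchor_records = anchors[next(iter(countries))]
                # the anchor is not the mention itself; use the first
                anchor = anchor_records[0]
                best = sorted(
                    survivors,
                    key=lambda c: (
                        haversine_km(
                            (c.latitude, c.longitude),
                            (anchor.latitude, anchor.longitude),
                        ),
                        c.relevance_rank,
                    ),
                )
                d0 = haversine_km(
                    (best[0].latitude, best[0].longitude),
                    (anchor.latitude, anchor.longitude),
                )
                d1 = haversine_km(
                    (best[1].latitude, best[1].longitude),
                    (anchor.latitude, anchor.longitude),
                )
                mention.resolved = best[0]
                mention.method = "min_distance"
                mention.tie = abs(d0 - d1) < 1e-9
                return mention
            # rule 4: several countries in the sentence; the nearest one
            # in token distance decides
            country_mentions = [
                (m, d)
                for m in others
                for d in _co_records(m)
                if gazetteer.is_country(d)
            ]
            if country_mentions:
                nearest = min(
                    country_mentions,
                    key=lambda md: (
                        abs(md[0].token_start - mention.token_start),
                        md[1].relevance_rank,
                    ),
                )
                code = nearest[1].country_code
                filt = [c for c in survivors if c.country_code == code]
                if filt:
                    mention.resolved = min(filt, key=lambda c: c.relevance_rank)
                    mention.method = "closest_country"
                    return mention
    # rule 5: the most relevant record
    mention.resolved = min(cands, key=lambda c: c.relevance_rank)
    mention.method = "relevance"
    return mention


# -- document pipeline ----------------------------------------------------------

def _acronym_like(np: NounPhrase) -> bool:
    return (
        len(np.tokens) == 1
        and np.tokens[0].isupper()
        and len(np.tokens[0]) <= 4
    )


def _person_like(np: NounPhrase, sentence: Sentence) -> bool:
    i = np.token_start
    if i == 0:
        return False
    prev = sentence.tokens[i - 1].surface.casefold()
    if prev in PERSON_CUES:
        return True
    if prev == "." and i >= 2 and sentence.tokens[i - 2].surface.casefold() in PERSON_CUES:
        return True
    return prev in CITATION_CLOSERS


def extract_sentence_locations(
    sentence: Sentence,
    gazetteer: Gazetteer,
    feature_words: FeatureWordList,
    tagger=None,
) -> list[GeoMention]:
    """Locations of one sentence: chunk, filter, query, then disambiguate
    ambiguous mentions against the sentence's other mentions."""
    nps = extract_noun_phrases(sentence, tagger=tagger)
    primaries = [np for np in nps if not np.compound]
    compounds = [np for np in nps if np.compound]

    mentions: list[GeoMention] = []
    consumed: set[int] = set()
    # compounds first: "Gulf of Mexico" beats "Gulf" + "Mexico", but only
    # with a gazetteer hit
    for np in compounds:
        hits = query_gazetteer(np.surface, gazetteer)
        if hits:
            mentions.append(
                GeoMention(
                    surface=np.surface,
                    span=np.span,
                    token_start=np.token_start,
                    candidates=hits,
                )
            )
            consumed.update(range(np.token_start, np.token_end))
    for np in primaries:
        if np.token_start in consumed:
            continue
        if not np.has_capitalized or _person_like(np, sentence):
            continue
        hits = query_gazetteer(np.surface, gazetteer)
        if not hits and _acronym_like(np):
            continue
        if hits:
            mentions.append(
                GeoMention(
                    surface=np.surface,
                    span=np.span,
                    token_start=np.token_start,
                    candidates=hits,
                )
            )
        else:
            fw = detect_feature_word_location(np, hits, feature_words)
            if fw is not None:
                mentions.append(fw)

    for m in mentions:
        if m.method == "feature_word":
            continue
        disambiguate(m, [x for x in mentions if x is not m], gazetteer)
    return mentions


def extract_document_locations(
    doc: Document,
    gazetteer: Gazetteer,
    feature_words: FeatureWordList,
    tagger=None,
    document_scope: bool = False,
) -> tuple[list[GeoMention], dict]:
    """Full location pipeline over all sentences of a document.

    Returns (mentions, report); the report counts mentions resolved with and
    without coordinates. With ``document_scope``, mentions left to the
    relevance fallback are re-disambiguated against country mentions from the
    whole document (off by default).
    """
    mentions: list[GeoMention] = []
    sent_index = 0
    for section in doc.sections:
        for sentence in section.sentences:
            found = extract_sentence_locations(
                sentence, gazetteer, feature_words, tagger=tagger
            )
            for m in found:
                m.sentence_index = sent_index
            mentions.extend(found)
            sent_index += 1

    if document_scope:
        doc_countries = [
            m
            for m in mentions
            if m.resolved is not None and gazetteer.is_country(m.resolved)
        ]
        for m in mentions:
            if m.method == "relevance" and doc_countries:
                redo = GeoMention(
                    surface=m.surface,
                    span=m.span,
                    sentence_index=m.sentence_index,
                    candidates=list(m.candidates),
                    token_start=m.token_start,
                )
                disambiguate(redo, doc_countries, gazetteer)
                if redo.method in ("country_match", "min_distance"):
                    m.resolved = redo.resolved
                    m.method = redo.method + "_document_scope"

    report = {
        "mentions": len(mentions),
        "with_coordinates": sum(1 for m in mentions if m.has_coordinates),
        "without_coordinates": sum(1 for m in mentions if not m.has_coordinates),
        "by_method": dict(
            sorted(
                (method, sum(1 for m in mentions if m.method == method))
                for method in {m.method for m in mentions}
            )
        ),
    }
    return mentions, report


def mention_to_dict(m: GeoMention) -> dict:
    return {
        "surface": m.surface,
        "span": list(m.span),
        "sentence_index": m.sentence_index,
        "method": m.method,
        "tie": m.tie,
        "n_candidates": len(m.candidates),
        "resolved": (
            {
                "name": m.resolved.name,
                "latitude": round(m.resolved.latitude, 4),
                "longitude": round(m.resolved.longitude, 4),
                "country_code": m.resolved.country_code,
            }
            if m.resolved is not None
            else None
        ),
    }


def mentions_to_geojson(mentions: list[GeoMention]) -> str:
    """GeoJSON FeatureCollection with one Point per mention with coordinates."""
    features = [
        {
            "type": "Feature",
            "geometry": {
                "type": "Point",
                "coordinates": [
                    round(m.resolved.longitude, 4),
                    round(m.resolved.latitude, 4),
                ],
            },
            "properties": {
                "surface": m.surface,
                "method": m.method,
                "country": m.resolved.country_code,
            },
        }
        for m in mentions
        if m.resolved is not None
    ]
    return json.dumps(
        {"type": "FeatureCollection", "features": features},
        sort_keys=True,
        ensure_ascii=False,
    )
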