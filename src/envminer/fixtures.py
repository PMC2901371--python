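"""Seeded synthetic fixtures with machine-readable ground truth.

Every pipeline stage is testable offline: :func:`generate_corpus` produces
HTML articles with the five canonical sections, planted measurements that
follow the measure-then-unit adjacency grammar, planted locations drawn from
the bundled mini-gazetteer (ambiguous ones optionally paired with a
same-sentence country cue), and one HTML table per document with variable
headers. Each planted item is recorded in a gold annotation at generation
time, so extraction can be scored exactly.

:func:`build_mini_gazetteer` returns the bit-exact content of the committed
``data/mini_gazetteer.tsv``: it contains the classic worked cases (five
Margates in ZA/GB/AU/US/CA, Tasmania under Australia, San Jose with
candidates in three countries, Lake Cadagno and the Piora Valley in
Switzerland, undersea features without a country) plus filler records.

:func:`generate_labeled_sentences` builds two-class sentence corpora whose
class vocabularies share a controlled overlap fraction, together with the
closed-form expected accuracy of the Bayes-optimal decision rule.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field, asdict

__all__ = [
    "FixtureConfig",
    "GoldAnnotation",
    "build_mini_gazetteer",
    "generate_corpus",
    "generate_labeled_sentences",
]


@dataclass
class FixtureConfig:
    seed: int = 0
    n_documents: int = 5
    measurements_per_doc: tuple[int, int] = (8, 14)
    out_of_lexicon_rate: float = 0.0
    ambiguous_location_rate: float = 0.4
    country_cue_rate: float = 1.0
    class_vocab_overlap: float = 0.5
    n_sentences_per_class: int = 40
    feature_word_location_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in (
            "out_of_lexicon_rate",
            "ambiguous_location_rate",
            "country_cue_rate",
            "class_vocab_overlap",
            "feature_word_location_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        lo, hi = self.measurements_per_doc
        if lo < 0 or hi < lo:
            raise ValueError(f"bad measurements_per_doc range {self.measurements_per_doc}")


@dataclass
class GoldAnnotation:
    doc_id: str
    measurements: list[dict] = field(default_factory=list)
    locations: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)


# -- mini gazetteer ------------------------------------------------------------
# (name, alternate_names, lat, lon, country_code, admin_parent, feature_class, rank)

_COUNTRIES = [
    ("Australia", "", -25.2744, 133.7751, "AU"),
    ("Brazil", "", -10.3333, -53.2, "BR"),
    ("Canada", "", 56.1304, -106.3468, "CA"),
    ("Chile", "", -31.7613, -71.3188, "CL"),
    ("China", "", 35.0, 105.0, "CN"),
    ("Costa Rica", "", 9.7489, -83.7534, "CR"),
    ("Egypt", "", 26.8206, 30.8025, "EG"),
    ("France", "", 46.2276, 2.2137, "FR"),
    ("Germany", "", 51.1657, 10.4515, "DE"),
    ("Iceland", "", 64.9631, -19.0208, "IS"),
    ("India", "", 20.5937, 78.9629, "IN"),
    ("Italy", "", 41.8719, 12.5674, "IT"),
    ("Jamaica", "", 18.1096, -77.2975, "JM"),
    ("Japan", "", 36.2048, 138.2529, "JP"),
    ("Kenya", "", -0.0236, 37.9062, "KE"),
    ("Mexico", "", 23.6345, -102.5528, "MX"),
    ("Morocco", "", 31.7917, -7.0926, "MA"),
    ("Norway", "", 60.472, 8.4689, "NO"),
    ("Peru", "", -9.19, -75.0152, "PE"),
    ("Russia", "", 61.524, 105.3188, "RU"),
    ("South Africa", "", -30.5595, 22.9375, "ZA"),
    ("South Korea", "Korea", 35.9078, 127.7669, "KR"),
    ("Spain", "", 40.4637, -3.7492, "ES"),
    ("Switzerland", "", 46.8182, 8.2275, "CH"),
    ("United Kingdom", "England|Great Britain|UK", 55.3781, -3.436, "GB"),
    ("United States", "United States of America|USA", 37.0902, -95.7129, "US"),
    ("Venezuela", "", 6.4238, -66.5897, "VE"),
]

_PLACES = [
    # the five Margates, one per country, AU's inside Tasmania
    ("Margate", "", -30.8636, 30.3706, "ZA", "South Africa", "PPL", 1),
    ("Margate", "", 51.3813, 1.3862, "GB", "England", "PPL", 2),
    ("Margate", "", -43.0279, 147.2623, "AU", "Tasmania", "PPL", 3),
    ("Margate", "", 26.2445, -80.2064, "US", "United States", "PPL", 4),
    ("Margate", "", 46.405, -63.5, "CA", "Canada", "PPL", 5),
    ("Tasmania", "", -42.0, 147.0, "AU", "Australia", "ADM1", 1),
    ("San Jose", "San José", 9.9281, -84.0907, "CR", "Costa Rica", "PPL", 1),
    ("San Jose", "San José", 37.3382, -121.8863, "US", "United States", "PPL", 2),
    ("San Jose", "San José de Guanipa", 8.8925, -64.1611, "VE", "Venezuela", "PPL", 3),
    ("Richmond", "", 37.5407, -77.436, "US", "United States", "PPL", 1),
    ("Richmond", "", 51.4613, -0.3037, "GB", "England", "PPL", 2),
    ("Richmond", "", 49.1666, -123.1336, "CA", "Canada", "PPL", 3),
    ("Richmond", "", -33.5994, 150.7491, "AU", "Australia", "PPL", 4),
    ("Springfield", "", 39.8017, -89.6437, "US", "United States", "PPL", 1),
    ("Springfield", "", 42.1015, -72.5898, "US", "United States", "PPL", 2),
    ("Kingston", "", 17.9971, -76.7936, "JM", "Jamaica", "PPL", 1),
    ("Caracas", "", 10.4806, -66.9036, "VE", "Venezuela", "PPL", 1),
    ("Lake Cadagno", "", 46.55, 8.7117, "CH", "Switzerland", "LK", 1),
    ("Piora Valley", "Val Piora", 46.5486, 8.73, "CH", "Switzerland", "VAL", 1),
    ("Boston", "", 42.3601, -71.0589, "US", "United States", "PPL", 1),
    ("Hobart", "", -42.8826, 147.3257, "AU", "Tasmania", "PPL", 1),
    ("Launceston", "", -41.4388, 147.1347, "AU", "Tasmania", "PPL", 1),
    ("Gulf of Mexico", "", 25.0, -90.0, "MX", "Mexico", "GULF", 1),
    # undersea features: no country
    ("Mid-Atlantic Ridge", "", 0.0, -25.0, "", "", "RDGU", 1),
    ("Mariana Trench", "", 11.35, 142.2, "", "", "TRNU", 1),
    # unambiguous filler cities
    ("Nairobi", "", -1.2921, 36.8219, "KE", "Kenya", "PPL", 1),
    ("Mombasa", "", -4.0435, 39.6682, "KE", "Kenya", "PPL", 1),
    ("Barcelona", "", 41.3851, 2.1734, "ES", "Spain", "PPL", 1),
    ("Valencia", "", 39.4699, -0.3763, "ES", "Spain", "PPL", 1),
    ("Zurich", "Zürich", 47.3769, 8.5417, "CH", "Switzerland", "PPL", 1),
    ("Geneva", "", 46.2044, 6.1432, "CH", "Switzerland", "PPL", 1),
    ("Bern", "", 46.948, 7.4474, "CH", "Switzerland", "PPL", 1),
    ("Lyon", "", 45.764, 4.8357, "FR", "France", "PPL", 1),
    ("Marseille", "", 43.2965, 5.3698, "FR", "France", "PPL", 1),
    ("Toulouse", "", 43.6047, 1.4442, "FR", "France", "PPL", 1),
    ("Hamburg", "", 53.5511, 9.9937, "DE", "Germany", "PPL", 1),
    ("Munich", "München", 48.1351, 11.582, "DE", "Germany", "PPL", 1),
    ("Heidelberg", "", 49.3988, 8.6724, "DE", "Germany", "PPL", 1),
    ("Kyoto", "", 35.0116, 135.7681, "JP", "Japan", "PPL", 1),
    ("Osaka", "", 34.6937, 135.5023, "JP", "Japan", "PPL", 1),
    ("Sapporo", "", 43.0618, 141.3545, "JP", "Japan", "PPL", 1),
    ("Cusco", "Cuzco", -13.5319, -71.9675, "PE", "Peru", "PPL", 1),
    ("Arequipa", "", -16.409, -71.5375, "PE", "Peru", "PPL", 1),
    ("Valparaiso", "Valparaíso", -33.0472, -71.6127, "CL", "Chile", "PPL", 1),
    ("Antofagasta", "", -23.6509, -70.3975, "CL", "Chile", "PPL", 1),
    ("Alexandria", "", 31.2001, 29.9187, "EG", "Egypt", "PPL", 1),
    ("Casablanca", "", 33.5731, -7.5898, "MA", "Morocco", "PPL", 1),
    ("Busan", "", 35.1796, 129.0756, "KR", "South Korea", "PPL", 1),
    ("Daejeon", "", 36.3504, 127.3845, "KR", "South Korea", "PPL", 1),
    ("Salvador", "", -12.9777, -38.5016, "BR", "Brazil", "PPL", 1),
    ("Manaus", "", -3.119, -60.0217, "BR", "Brazil", "PPL", 1),
    ("Recife", "", -8.0476, -34.877, "BR", "Brazil", "PPL", 1),
    ("Oaxaca", "", 17.0732, -96.7266, "MX", "Mexico", "PPL", 1),
    ("Merida", "Mérida", 20.9674, -89.5926, "MX", "Mexico", "PPL", 1),
    ("Pune", "", 18.5204, 73.8567, "IN", "India", "PPL", 1),
    ("Jaipur", "", 26.9124, 75.7873, "IN", "India", "PPL", 1),
    ("Varanasi", "", 25.3176, 82.9739, "IN", "India", "PPL", 1),
    ("Guangzhou", "", 23.1291, 113.2644, "CN", "China", "PPL", 1),
    ("Chengdu", "", 30.5728, 104.0668, "CN", "China", "PPL", 1),
    ("Qingdao", "", 36.0671, 120.3826, "CN", "China", "PPL", 1),
    ("Perth", "", -31.9505, 115.8605, "AU", "Australia", "PPL", 1),
    ("Durban", "", -29.8587, 31.0218, "ZA", "South Africa", "PPL", 1),
    ("Pretoria", "", -25.7479, 28.2293, "ZA", "South Africa", "PPL", 1),
    ("Cardiff", "", 51.4816, -3.1791, "GB", "England", "PPL", 1),
    ("Leeds", "", 53.8008, -1.5491, "GB", "England", "PPL", 1),
    ("Calgary", "", 51.0447, -114.0719, "CA", "Canada", "PPL", 1),
    ("Halifax", "", 44.6488, -63.5752, "CA", "Canada", "PPL", 1),
    ("Monteverde", "", 10.3, -84.8167, "CR", "Costa Rica", "PPL", 1),
    ("Maracaibo", "", 10.6666, -71.6124, "VE", "Venezuela", "PPL", 1),
    ("Tromso", "Tromsø", 69.6492, 18.9553, "NO", "Norway", "PPL", 1),
    ("Bergen", "", 60.3913, 5.3221, "NO", "Norway", "PPL", 1),
    ("Reykjavik", "Reykjavík", 64.1466, -21.9426, "IS", "Iceland", "PPL", 1),
    ("Akureyri", "", 65.6826, -18.0907, "IS", "Iceland", "PPL", 1),
    ("Turin", "Torino", 45.0703, 7.6869, "IT", "Italy", "PPL", 1),
    ("Naples", "Napoli", 40.8518, 14.2681, "IT", "Italy", "PPL", 1),
    # natural features
    ("Lake Victoria", "", -1.0, 33.0, "KE", "Kenya", "LK", 1),
    ("Lake Baikal", "", 53.5, 108.0, "RU", "Russia", "LK", 1),
    ("Lake Geneva", "Lac Léman", 46.45, 6.55, "CH", "Switzerland", "LK", 1),
    ("Lake Titicaca", "", -15.8402, -69.3354, "PE", "Peru", "LK", 1),
    ("Amazon River", "Rio Amazonas", -2.0, -55.0, "BR", "Brazil", "STM", 1),
    ("Mount Fuji", "Fujisan", 35.3606, 138.7274, "JP", "Japan", "MT", 1),
    ("Atacama Desert", "", -24.5, -69.25, "CL", "Chile", "DSRT", 1),
    ("Great Barrier Reef", "", -18.2871, 147.6992, "AU", "Australia", "RF", 1),
]


def build_mini_gazetteer() -> str:
    """TSV content of the bundled mini-gazetteer (bit-exact, regenerable)."""
    lines = [
        "name\talternate_names\tlatitude\tlongitude\tcountry_code\tadmin_parent\tfeature_class\trelevance_rank"
    ]
    # countries are the top of the admin hierarchy (no parent)
    rows = [
        (name, alts, lat, lon, cc, "", "PCLI", 1)
        for (name, alts, lat, lon, cc) in _COUNTRIES
    ] + _PLACES
    for name, alts, lat, lon, cc, parent, fclass, rank in rows:
        lines.append(
            f"{name}\t{alts}\t{lat}\t{lon}\t{cc}\t{parent}\t{fclass}\t{rank}"
        )
    return "\n".join(lines) + "\n"


def cc_name(code: str) -> str | None:
    """Country name for an ISO alpha-2 code present in the mini-gazetteer."""
    for name, _, _, _, cc in _COUNTRIES:
        if cc == code:
            return name
    return None


# -- article corpus ------------------------------------------------------------

_SECTIONS = [
    ("Abstract", 0.014),
    ("Introduction", 0.035),
    ("Materials and Methods", 0.741),
    ("Results", 0.159),
    ("Discussion", 0.051),
]

# (variable, [(unit surface, canonical unit)], sentence template, status)
_MEASUREMENT_PLANTS = [
    ("depth", [("m", "meter"), ("mts", "meter"), ("meters", "meter")],
     "Samples were collected at {v} {u} depth.", "explicit"),
    ("temperature", [("degrees C", "degree c"), ("°C", "degree c")],
     "The waters were kept at {v} {u} during the survey.", "implicit"),
    ("weight", [("gr", "gram"), ("kg", "kilogram"), ("mg", "milligram")],
     "About {v} {u} of material were processed from the site.", "implicit"),
    ("time", [("min", "minute"), ("hours", "hour"), ("days", "day")],
     "The mixture was incubated for {v} {u} before analysis.", "implicit"),
    ("volume", [("ml", "milliliter"), ("liters", "liter"), ("ul", "microliter")],
     "A volume of {v} {u} was filtered through the membrane.", "explicit"),
    ("concentration", [("mM", "millimolar"), ("nM", "nanomolar"), ("ppm", "ppm")],
     "The solution contained {v} {u} of dissolved nitrate.", "implicit"),
    ("concentration", [("mg liter-1", "milligram/liter"), ("g/l", "gram/liter")],
     "Cultures were amended with {v} {u} of acetate.", "implicit"),
    ("salinity", [("psu", "psu")],
     "Salinity reached {v} {u} near the mouth of the estuary.", "explicit"),
    ("area", [("ha", "hectare"), ("m2", "square meter")],
     "The study plot covered {v} {u} of grassland.", "implicit"),
    ("pressure", [("atm", "atmosphere"), ("bar", "bar"), ("kPa", "kilopascal")],
     "The chamber was maintained at {v} {u} throughout.", "implicit"),
    ("size", [("cm", "centimeter"), ("mm", "millimeter")],
     "Particles of {v} {u} were retained on the sieve.", "ambiguous"),
    ("distance", [("km", "kilometer")],
     "The station lay at a distance of {v} {u} from the shore.", "explicit"),
    ("cell density", [("cells/ml", "cell/milliliter")],
     "Counts averaged {v} {u} in surface waters.", "implicit"),
    ("flux", [("ml/min", "milliliter/minute")],
     "The pump operated at {v} {u} during sampling.", "implicit"),
]

_OOL_TABLE_HEADERS = [
    "Signal (fluorescence units)",
    "Turbidity (arbitrary units)",
]

_OOL_TEMPLATES = [
    ("fluorescence units", "The signal reached {v} fluorescence units in the assay."),
    ("arbitrary units", "Turbidity rose to {v} arbitrary units after mixing."),
    ("relative units", "Expression levels climbed to {v} relative units overall."),
]

_FILLERS = [
    "The community structure was examined in detail.",
    "Nucleic acids were purified following standard protocols.",
    "Replicate observations agreed closely across the transect.",
    "Environmental conditions remained stable over the campaign.",
    "Further work will address seasonal variability.",
    "The assemblages were dominated by heterotrophic organisms.",
    "All reagents were of analytical grade.",
    "Differences among treatments were assessed statistically.",
]

_AMBIGUOUS_NAMES = ["Margate", "San Jose", "Richmond"]
_UNAMBIGUOUS_NAMES = [
    "Nairobi", "Zurich", "Bern", "Kyoto", "Cusco", "Valparaiso", "Hamburg",
    "Heidelberg", "Busan", "Manaus", "Pune", "Guangzhou", "Perth", "Durban",
    "Cardiff", "Calgary", "Bergen", "Akureyri", "Mombasa", "Toulouse",
    "Marseille", "Lyon", "Sapporo", "Arequipa", "Qingdao", "Jaipur",
]
_FEATURE_WORD_NAMES = ["Ganghwa Island", "Lake Siso", "Kodori Gorge", "Wadi Qelt"]

_LOCATION_TEMPLATES = [
    "Sampling took place near {loc} over two seasons.",
    "Sediment cores were retrieved off {loc} in early autumn.",
    "Additional material originated from {loc} as described previously.",
]
_LOCATION_CUE_TEMPLATE = "Sampling took place near {loc}, {country}, over two seasons."

# table column plants: (header, variable, canonical unit)
_TABLE_COLUMNS = [
    ("Depth (m)", "depth", "meter"),
    ("Temperature (degrees C)", "temperature", "degree c"),
    ("Salinity (psu)", "salinity", "psu"),
]


def _fmt(v: float) -> str:
    return format(v, "g")


def _draw_value(rng: random.Random, used: set) -> float:
    while True:
        v = round(rng.uniform(0.5, 500.0), 1)
        v = float(_fmt(v))
        if v not in used:
            used.add(v)
            return v


def _records_for(name: str):
    return [r for r in _PLACES if r[0] == name]


def generate_corpus(config: FixtureConfig) -> tuple[list[tuple[str, str]], list[GoldAnnotation]]:
    """Generate HTML articles plus gold annotations.

    Returns ([(doc_id, html)], [GoldAnnotation]); same seed, same bytes.
    """
    rng = random.Random(config.seed)
    docs: list[tuple[str, str]] = []
    golds: list[GoldAnnotation] = []
    section_names = [s for s, _ in _SECTIONS]
    section_weights = [w for _, w in _SECTIONS]
    for d in range(config.n_documents):
        doc_id = f"S{config.seed}D{d:03d}"
        gold = GoldAnnotation(doc_id=doc_id)
        sentences: dict[str, list[str]] = {s: [] for s in section_names}
        used_values: dict[str, set] = {s: set() for s in section_names}

        n_meas = rng.randint(*config.measurements_per_doc)
        for _ in range(n_meas):
            section = rng.choices(section_names, weights=section_weights, k=1)[0]
            kind = _SECTION_KIND[section]
            value = _draw_value(rng, used_values[section])
            if rng.random() < config.out_of_lexicon_rate:
                unit, template = rng.choice(_OOL_TEMPLATES)
                sentences[section].append(template.format(v=_fmt(value)))
                gold.measurements.append(
                    {
                        "section_kind": kind,
                        "value": value,
                        "unit_surface": unit,
                        "canonical_unit": None,
                        "variable": None,
                        "status": None,
                        "out_of_lexicon": True,
                    }
                )
            else:
                variable, units, template, status = rng.choice(_MEASUREMENT_PLANTS)
                surface, canonical = rng.choice(units)
                sentences[section].append(template.format(v=_fmt(value), u=surface))
                gold.measurements.append(
                    {
                        "section_kind": kind,
                        "value": value,
                        "unit_surface": surface,
                        "canonical_unit": canonical,
                        "variable": variable,
                        "status": status,
                        "out_of_lexicon": False,
                    }
                )

        # locations: planted in the abstract and methods sections
        for _ in range(rng.randint(2, 4)):
            section = rng.choice(["Abstract", "Materials and Methods"])
            if rng.random() < config.feature_word_location_rate:
                name = rng.choice(_FEATURE_WORD_NAMES)
                sentences[section].append(
                    rng.choice(_LOCATION_TEMPLATES).format(loc=name)
                )
                gold.locations.append(
                    {
                        "section_kind": _SECTION_KIND[section],
                        "surface": name,
                        "latitude": None,
                        "longitude": None,
                        "country_code": None,
                        "cue_present": False,
                        "feature_word_only": True,
                    }
                )
                continue
            if rng.random() < config.ambiguous_location_rate:
                name = rng.choice(_AMBIGUOUS_NAMES)
                record = rng.choice(_records_for(name))
                cue = rng.random() < config.country_cue_rate
                if cue:
                    country = next(c for c in _COUNTRIES if c[4] == record[4])
                    sentences[section].append(
                        _LOCATION_CUE_TEMPLATE.format(
                            loc=name, country=country[0]
                        )
                    )
                    # the cue country is itself a mention in the text
                    gold.locations.append(
                        {
                            "section_kind": _SECTION_KIND[section],
                            "surface": country[0],
                            "latitude": country[2],
                            "longitude": country[3],
                            "country_code": country[4],
                            "cue_present": False,
                            "feature_word_only": False,
                        }
                    )
                else:
                    sentences[section].append(
                        rng.choice(_LOCATION_TEMPLATES).format(loc=name)
                    )
            else:
                name = rng.choice(_UNAMBIGUOUS_NAMES)
                record = _records_for(name)[0]
                cue = False
                sentences[section].append(
                    rng.choice(_LOCATION_TEMPLATES).format(loc=name)
                )
            gold.locations.append(
                {
                    "section_kind": _SECTION_KIND[section],
                    "surface": name,
                    "latitude": record[2],
                    "longitude": record[3],
                    "country_code": record[4],
                    "cue_present": cue,
                    "feature_word_only": False,
                }
            )

        # one table in Materials and Methods; whole columns may carry an
        # unlisted unit (the out-of-lexicon rate applies per column)
        n_cols = rng.randint(2, 3)
        cols = []
        for header, variable, canonical in rng.sample(_TABLE_COLUMNS, n_cols):
            if rng.random() < config.out_of_lexicon_rate:
                header = rng.choice(_OOL_TABLE_HEADERS)
                cols.append((header, None, None))
            else:
                cols.append((header, variable, canonical))
        n_rows = rng.randint(2, 4)
        table_rows = []
        for _ in range(n_rows):
            row = []
            for header, variable, canonical in cols:
                value = _draw_value(rng, used_values["Materials and Methods"])
                row.append(_fmt(value))
                gold.measurements.append(
                    {
                        "section_kind": "methods",
                        "value": value,
                        "unit_surface": header,
                        "canonical_unit": canonical,
                        "variable": variable,
                        "status": None if variable is None else "explicit",
                        "out_of_lexicon": variable is None,
                        "table_column": header,
                    }
                )
            table_rows.append(row)

        # filler so every section has prose
        for section in section_names:
            sentences[section].insert(
                rng.randint(0, max(0, len(sentences[section]))),
                rng.choice(_FILLERS),
            )

        html_parts = [
            "<html><head><title>Synthetic environmental survey "
            f"{doc_id}</title></head><body>",
            f"<h1>Synthetic environmental survey {doc_id}</h1>",
        ]
        for section in section_names:
            html_parts.append(f"<h2>{section}</h2>")
            html_parts.append("<p>" + " ".join(sentences[section]) + "</p>")
            if section == "Materials and Methods":
                header_html = "".join(f"<th>{h}</th>" for h, _, _ in cols)
                rows_html = "".join(
                    "<tr>" + "".join(f"<td>{c}</td>" for c in row) + "</tr>"
                    for row in table_rows
                )
                html_parts.append(
                    f"<table><tr>{header_html}</tr>{rows_html}</table>"
                )
        html_parts.append("</body></html>")
        docs.append((doc_id, "\n".join(html_parts)))
        golds.append(gold)
    return docs, golds


_SECTION_KIND = {
    "Abstract": "abstract",
    "Introduction": "introduction",
    "Materials and Methods": "methods",
    "Results": "results",
    "Discussion": "discussion",
}


# -- labeled sentence corpus ----------------------------------------------------

SENTENCE_LENGTH = 6
VOCAB_SIZE_PER_CLASS = 30


def generate_labeled_sentences(config: FixtureConfig) -> tuple[str, dict]:
    """Two-class sentence corpus with controlled vocabulary overlap.

    Each class draws ``SENTENCE_LENGTH`` tokens uniformly from its
    ``VOCAB_SIZE_PER_CLASS``-word vocabulary; a fraction
    ``class_vocab_overlap`` of each vocabulary is shared between classes.
    Returns (corpus TSV text, gold) where gold carries the closed-form
    expected accuracy of the Bayes rule with ties broken toward the
    majority class: 1 - p_minority * overlap**length.
    """
    rng = random.Random(config.seed)
    V = VOCAB_SIZE_PER_CLASS
    n_shared = round(config.class_vocab_overlap * V)
    shared = [f"shw{i:02d}" for i in range(n_shared)]
    env_vocab = shared + [f"envw{i:02d}" for i in range(V - n_shared)]
    exp_vocab = shared + [f"expw{i:02d}" for i in range(V - n_shared)]
    n = config.n_sentences_per_class
    rows = []
    labels = []
    for label, vocab in (("env", env_vocab), ("exp", exp_vocab)):
        for _ in range(n):
            toks = [rng.choice(vocab) for _ in range(SENTENCE_LENGTH)]
            rows.append(f"{label}\t{' '.join(toks)}")
            labels.append(label)
    order = list(range(len(rows)))
    rng.shuffle(order)
    tsv = "\n".join(rows[i] for i in order) + "\n"
    f = n_shared / V
    p_minority = 0.5  # equal class sizes by construction
    expected_accuracy = 1.0 - p_minority * (f ** SENTENCE_LENGTH)
    if f == 1.0:
        expected_accuracy = 0.5  # everything collapses to the majority prior
    gold = {
        "expected_accuracy": expected_accuracy,
        "overlap": f,
        "sentence_length": SENTENCE_LENGTH,
        "n_per_class": n,
        "labels": [labels[i] for i in order],
    }
    return tsv, gold


def write_fixture_bundle(config: FixtureConfig, out_dir) -> None:
    """Write documents (HTML), gold (JSON), gazetteer (TSV) and the labeled
    corpus (TSV) to a directory — the `simulate` CLI entry point."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    docs, golds = generate_corpus(config)
    for doc_id, html in docs:
        (out / f"{doc_id}.html").write_text(html, encoding="utf-8")
    (out / "gold.json").write_text(
        json.dumps([g.to_dict() for g in golds], sort_keys=True, indent=2),
        encoding="utf-8",
    )
    (out / "mini_gazetteer.tsv").write_text(build_mini_gazetteer(), encoding="utf-8")
    tsv, gold = generate_labeled_sentences(config)
    (out / "labeled_sentences.tsv").write_text(tsv, encoding="utf-8")
    (out / "labeled_sentences.gold.json").write_text(
        json.dumps(gold, sort_keys=True, indent=2), encoding="utf-8"
    )
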