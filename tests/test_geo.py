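"""Geolocation: chunking, gazetteer, feature words, cascade, distances."""

import json
import math
import random

import pytest

from envminer.document import parse_document, split_sentences
from envminer.geo import (
    GeoMention,
    NounPhrase,
    detect_feature_word_location,
    disambiguate,
    extract_document_locations,
    extract_noun_phrases,
    extract_sentence_locations,
    haversine_km,
    mentions_to_geojson,
    query_gazetteer,
)


def _sentence(text: str):
    return split_sentences(text)[0]


def _surfaces(text: str):
    return [np.surface for np in extract_noun_phrases(_sentence(text))]


class TestHaversine:
    def test_identical_points(self):
        assert haversine_km((12.3, 45.6), (12.3, 45.6)) == 0.0

    def test_antipodal_closed_form(self):
        assert haversine_km((0, 0), (0, 180)) == pytest.approx(6371.0 * math.pi, rel=1e-9)
        assert haversine_km((90, 0), (-90, 0)) == pytest.approx(6371.0 * math.pi, rel=1e-9)

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError):
            haversine_km((91, 0), (0, 0))
        with pytest.raises(ValueError):
            haversine_km((0, 0), (0, 181))

    def test_symmetry_and_law_of_cosines_agreement(self):
        """Symmetric, and equal to the spherical law of cosines (independent
        formula) on random pairs."""
        rng = random.Random(0)
        for _ in range(300):
            a = (rng.uniform(-90, 90), rng.uniform(-180, 180))
            b = (rng.uniform(-90, 90), rng.uniform(-180, 180))
            d1, d2 = haversine_km(a, b), haversine_km(b, a)
            assert d1 == pytest.approx(d2, abs=1e-9)
            cos_d = (
                math.sin(math.radians(a[0])) * math.sin(math.radians(b[0]))
                + math.cos(math.radians(a[0]))
                * math.cos(math.radians(b[0]))
                * math.cos(math.radians(a[1] - b[1]))
            )
            d_loc = 6371.0 * math.acos(max(-1.0, min(1.0, cos_d)))
            assert d1 == pytest.approx(d_loc, abs=1e-6 * 6371.0 * math.pi)

    def test_triangle_inequality_on_random_triples(self):
        rng = random.Random(1)
        for _ in range(300):
            pts = [(rng.uniform(-90, 90), rng.uniform(-180, 180)) for _ in range(3)]
            ab = haversine_km(pts[0], pts[1])
            bc = haversine_km(pts[1], pts[2])
            ac = haversine_km(pts[0], pts[2])
            assert ac <= ab + bc + 1e-9


class TestNounPhrases:
    def test_worked_example_nps(self):
        got = _surfaces("Lake Cadagno is a meromictic lake in the Piora Valley of Switzerland.")
        for expected in ("Lake Cadagno", "Piora Valley", "Switzerland"):
            assert expected in got

    def test_no_capitalized_np(self):
        assert _surfaces("the samples were frozen overnight.") == []

    def test_acronym_filtered_in_pipeline(self, gazetteer, feature_words):
        ms = extract_sentence_locations(
            _sentence("The DNA was extracted at the laboratory."), gazetteer, feature_words
        )
        assert ms == []

    def test_person_name_cue_blocks_mention(self, gazetteer, feature_words):
        ms = extract_sentence_locations(
            _sentence("Cultures were provided by Dr. Boston for this work."),
            gazetteer,
            feature_words,
        )
        assert ms == []

    def test_hyphenated_name_is_one_phrase(self):
        assert "Mid-Atlantic Ridge" in _surfaces("Sediments of the Mid-Atlantic Ridge were sampled.")


class TestGazetteerQuery:
    def test_margate_has_five_records(self, gazetteer):
        recs = query_gazetteer("Margate", gazetteer)
        assert len(recs) == 5
        assert {r.country_code for r in recs} == {"ZA", "GB", "AU", "US", "CA"}

    def test_absent_name(self, gazetteer):
        assert query_gazetteer("Xqzvw", gazetteer) == []

    def test_case_insensitive(self, gazetteer):
        assert query_gazetteer("san jose", gazetteer) == query_gazetteer("San Jose", gazetteer)

    def test_alternate_names_resolve(self, gazetteer):
        assert query_gazetteer("England", gazetteer)[0].name == "United Kingdom"

    def test_ordered_by_relevance(self, gazetteer):
        ranks = [r.relevance_rank for r in query_gazetteer("Margate", gazetteer)]
        assert ranks == sorted(ranks)


class TestFeatureWords:
    def test_ganghwa_island(self, feature_words):
        np = NounPhrase(tokens=["Ganghwa", "Island"], span=(0, 14), token_start=0, token_end=2)
        m = detect_feature_word_location(np, [], feature_words)
        assert m is not None and m.method == "feature_word" and not m.has_coordinates

    def test_lake_siso(self, feature_words):
        np = NounPhrase(tokens=["Lake", "Siso"], span=(0, 9), token_start=0, token_end=2)
        assert detect_feature_word_location(np, [], feature_words) is not None

    def test_company_name_is_not_a_location(self, feature_words):
        np = NounPhrase(tokens=["Applied", "Biosystems"], span=(0, 18), token_start=0, token_end=2)
        assert detect_feature_word_location(np, [], feature_words) is None


def _run(text, gazetteer, feature_words):
    return extract_sentence_locations(_sentence(text), gazetteer, feature_words)


class TestDisambiguation:
    def test_margate_tasmania_country_match(self, gazetteer, feature_words):
        ms = _run("Margate is a city located in the island of Tasmania.", gazetteer, feature_words)
        margate = next(m for m in ms if m.surface == "Margate")
        assert margate.method == "country_match"
        assert margate.resolved.country_code == "AU"

    def test_same_country_homonyms_resolved_by_distance(self, gazetteer, feature_words):
        ms = _run(
            "The site near Springfield was compared with one at Boston.",
            gazetteer,
            feature_words,
        )
        springfield = next(m for m in ms if m.surface == "Springfield")
        assert springfield.method == "min_distance"
        assert springfield.resolved.latitude == pytest.approx(42.1015)  # the MA record

    def test_san_jose_closest_country_in_text(self, gazetteer, feature_words):
        ms = _run(
            "These cities are San Jose, Costa Rica, Kingston, Jamaica, and Caracas, Venezuela.",
            gazetteer,
            feature_words,
        )
        sj = next(m for m in ms if m.surface == "San Jose")
        assert sj.method == "closest_country"
        assert sj.resolved.country_code == "CR"

    def test_no_co_mention_falls_back_to_relevance(self, gazetteer, feature_words):
        ms = _run("Additional sampling occurred near Margate as before.", gazetteer, feature_words)
        margate = next(m for m in ms if m.surface == "Margate")
        assert margate.method == "relevance"
        assert margate.resolved.relevance_rank == 1

    def test_empty_candidates_stay_unresolved(self, gazetteer):
        m = GeoMention(surface="Nowhere", span=(0, 7))
        out = disambiguate(m, [], gazetteer)
        assert out.method == "unresolved" and out.resolved is None

    def test_undersea_feature_is_unique_without_country(self, gazetteer, feature_words):
        ms = _run("Cores came from the Mariana Trench this decade.", gazetteer, feature_words)
        assert ms[0].method == "unique"
        assert ms[0].resolved.country_code is None

    def test_cascade_matches_bruteforce_enumeration(self, gazetteer):
        """For every (ambiguous name, co-mention record) pair the cascade
        equals brute-force country filtering + exhaustive distance
        minimization (spherical law of cosines as independent metric)."""
        ambiguous = ["Margate", "San Jose", "Richmond", "Springfield"]
        for name in ambiguous:
            cands = gazetteer.query(name)
            for rec in gazetteer.records:
                if rec.name == name:
                    continue
                mention = GeoMention(surface=name, span=(0, 1), candidates=list(cands))
                co = GeoMention(
                    surface=rec.name, span=(2, 3), candidates=[rec], resolved=rec,
                    method="unique", token_start=5,
                )
                got = disambiguate(mention, [co], gazetteer)
                # oracle
                matched = [
                    c for c in cands
                    if c.country_code and rec.country_code
                    and c.country_code == rec.country_code
                ]
                if len(matched) == 1:
                    assert got.method == "country_match"
                    assert got.resolved is matched[0]
                elif len(matched) > 1:
                    def slc(c):
                        cd = (
                            math.sin(math.radians(c.latitude)) * math.sin(math.radians(rec.latitude))
                            + math.cos(math.radians(c.latitude)) * math.cos(math.radians(rec.latitude))
                            * math.cos(math.radians(c.longitude - rec.longitude))
                        )
                        return 6371.0 * math.acos(max(-1.0, min(1.0, cd)))
                    best = min(matched, key=lambda c: (slc(c), c.relevance_rank))
                    assert got.method == "min_distance"
                    assert got.resolved is best
                else:
                    assert got.method == "relevance"
                    assert got.resolved.relevance_rank == min(c.relevance_rank for c in cands)


class TestDocumentPipeline:
    def test_three_planted_resolvable_locations(self, gazetteer, feature_words):
        html = (
            "<html><body><h2>Abstract</h2>"
            "<p>Sampling occurred near Nairobi during winter. "
            "Further cores came from Bergen in spring. "
            "Final surveys covered Kyoto in autumn.</p></body></html>"
        )
        doc = parse_document(html, format="html")
        mentions, report = extract_document_locations(doc, gazetteer, feature_words)
        assert report["mentions"] == 3 and report["with_coordinates"] == 3

    def test_document_with_no_locations(self, gazetteer, feature_words):
        doc = parse_document("the samples were frozen overnight.", format="plain")
        mentions, report = extract_document_locations(doc, gazetteer, feature_words)
        assert mentions == [] and report["mentions"] == 0

    def test_feature_word_counts_as_resolved_without_coordinates(self, gazetteer, feature_words):
        doc = parse_document("Water was sampled at Lake Siso during summer.", format="plain")
        mentions, report = extract_document_locations(doc, gazetteer, feature_words)
        assert report["without_coordinates"] == 1
        assert mentions[0].method == "feature_word"

    def test_geojson_output_shape(self, gazetteer, feature_words):
        doc = parse_document("Cores were taken off Nairobi last year.", format="plain")
        mentions, _ = extract_document_locations(doc, gazetteer, feature_words)
        gj = json.loads(mentions_to_geojson(mentions))
        assert gj["type"] == "FeatureCollection"
        (feat,) = gj["features"]
        assert feat["geometry"]["type"] == "Point"
        assert feat["properties"]["surface"] == "Nairobi"

    def test_resolution_is_deterministic(self, gazetteer, feature_words):
        text = "Margate is a city located in the island of Tasmania."
        outs = [
            [(m.surface, m.method, m.resolved.latitude if m.resolved else None)
             for m in _run(text, gazetteer, feature_words)]
            for _ in range(2)
        ]
        assert outs[0] == outs[1]
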