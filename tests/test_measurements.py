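"""Measurement extraction: measures, unit matching, variable resolution."""

import pytest

from envminer.document import Table, parse_document, split_sentences
from envminer.measurements import (
    extract_document,
    extract_from_table,
    extract_sentence,
    find_measures,
    match_unit,
    measurements_to_json,
)


def _sentence(text: str):
    return split_sentences(text)[0]


def _extract(text: str, lexicon, **kw):
    return extract_sentence(_sentence(text), lexicon, **kw)


class TestFindMeasures:
    def test_single_measure(self):
        ms = find_measures(_sentence("the waters were at 5 degrees C"))
        assert [m.value for m in ms] == [5.0]

    def test_no_digits(self):
        assert find_measures(_sentence("no numbers here")) == []

    def test_signed_and_thousands(self):
        ms = find_measures(_sentence("from -20 up to 200,000 events"))
        assert [m.value for m in ms] == [-20.0, 200000.0]


class TestMatchUnit:
    @pytest.mark.parametrize(
        "text,surface,canonical",
        [
            ("320 mts depth", "mts", "meter"),
            ("5 mg liter-1 final", "mg liter-1", "milligram/liter"),
            ("2 grams/liter added", "grams/liter", "gram/liter"),
            ("4 nanogram per milliliter found", "nanogram per milliliter", "nanogram/milliliter"),
        ],
    )
    def test_matches(self, lexicon, text, surface, canonical):
        s = _sentence(text)
        out = match_unit(find_measures(s)[0], s, lexicon)
        assert out == (surface, canonical)

    def test_dictionary_word_is_not_a_unit(self, lexicon):
        s = _sentence("we repeated the experiment 10 times")
        assert match_unit(find_measures(s)[0], s, lexicon) is None


class TestResolveVariable:
    @pytest.mark.parametrize(
        "text,variable,status",
        [
            ("samples were collected at 320 mts depth", "depth", "explicit"),
            ("3 gr of soil were collected", "weight", "implicit"),
            ("the waters were at 5 degrees C", "temperature", "implicit"),
            ("diluted to 5 mg liter-1 final", "concentration", "implicit"),
            ("the filter measured 20 cm", "size", "ambiguous"),
        ],
    )
    def test_cascade(self, lexicon, text, variable, status):
        (m,) = _extract(text, lexicon)
        assert (m.variable, m.status) == (variable, status)

    def test_ambiguous_keeps_candidates(self, lexicon):
        (m,) = _extract("the filter measured 20 cm", lexicon)
        assert set(m.candidates) == {"depth", "length", "distance", "height", "width", "diameter"}

    def test_mass_per_area_combination_beats_bare_weight(self, lexicon):
        (m,) = _extract("269 kg of manure ha-1 were spread", lexicon)
        assert m.variable == "areal concentration"
        assert m.canonical_unit == "kilogram/hectare"

    def test_incompatible_trigger_never_overrides_dimension(self, lexicon):
        # "depth" nearby cannot turn a gram into a depth
        (m,) = _extract("at depth we weighed 3 gr samples", lexicon)
        assert m.variable == "weight"

    def test_g_with_centrifuge_cue_is_speed(self, lexicon):
        out = _extract("centrifuged at 5,000 g for 10 min", lexicon)
        assert (out[0].variable, out[0].measure.value) == ("speed", 5000.0)
        assert (out[1].variable, out[1].status) == ("time", "implicit")

    def test_g_without_cue_stays_weight(self, lexicon):
        (m,) = _extract("about 3 g of sediment was used", lexicon)
        assert m.variable == "weight"


class TestEnumerations:
    def test_two_temperatures_share_one_unit(self, lexicon):
        out = _extract("stored at -20 and -80 degrees C", lexicon)
        assert [m.measure.value for m in out] == [-20.0, -80.0]
        assert {m.variable for m in out} == {"temperature"}

    def test_long_comma_list(self, lexicon):
        out = _extract("with 1, 3, 5, 10, 12, and 15 mM added", lexicon)
        assert [m.measure.value for m in out] == [1, 3, 5, 10, 12, 15]
        assert {m.canonical_unit for m in out} == {"millimolar"}

    def test_range_yields_two_measurements(self, lexicon):
        out = _extract("sampled between 5-10 m below", lexicon)
        assert [m.measure.value for m in out] == [5.0, 10.0]
        assert {m.canonical_unit for m in out} == {"meter"}

    def test_flag_off_drops_enumerated_heads(self, lexicon):
        out = _extract("stored at -20 and -80 degrees C", lexicon, enumerations=False)
        assert [m.measure.value for m in out] == [-80.0]


class TestTableExtraction:
    def test_depth_column(self, lexicon):
        table = Table(header_cells=["Depth (m)"], rows=[["10"], ["50"]])
        got, warnings = extract_from_table(table, lexicon)
        assert [(m.variable, m.measure.value) for m in got] == [("depth", 10.0), ("depth", 50.0)]
        assert warnings == []

    def test_non_numeric_column_is_skipped(self, lexicon):
        table = Table(header_cells=["Station name"], rows=[["A"], ["B"]])
        got, warnings = extract_from_table(table, lexicon)
        assert got == []
        assert warnings  # header resolves to no variable

    def test_empty_table(self, lexicon):
        got, warnings = extract_from_table(Table(header_cells=[], rows=[]), lexicon)
        assert got == [] and warnings == []


class TestExtractDocument:
    def test_tally_counts_sections_and_variables(self, lexicon):
        html = (
            "<html><body><h2>Materials and Methods</h2>"
            "<p>Samples were incubated at 30 degrees C for 10 min.</p></body></html>"
        )
        doc = parse_document(html, format="html")
        ms, tally = extract_document(doc, lexicon)
        assert tally["by_section"] == {"methods": 2}
        assert tally["by_variable"]["temperature"]["count"] == 1
        assert tally["by_variable"]["time"]["count"] == 1
        assert tally["by_variable"]["time"]["modal_unit"] == "minute"

    def test_empty_document_empty_tally(self, lexicon):
        doc = parse_document("Nothing quantitative was recorded here.", format="plain")
        ms, tally = extract_document(doc, lexicon)
        assert ms == [] and tally["by_section"] == {} and tally["by_variable"] == {}

    def test_byte_identical_json_across_runs(self, lexicon):
        html = (
            "<html><body><h2>Methods</h2><p>Stored at -20 and -80 degrees C. "
            "Diluted to 5 mg liter-1 final volume of 2 ml.</p></body></html>"
        )
        outs = []
        for _ in range(2):
            doc = parse_document(html, format="html", doc_id="d")
            ms, tally = extract_document(doc, lexicon)
            outs.append(measurements_to_json(ms, tally))
        assert outs[0] == outs[1]

    def test_spans_lie_inside_their_sentence(self, lexicon):
        s = _sentence("stored at -20 and -80 degrees C for 10 min")
        for m in extract_sentence(s, lexicon):
            lo, hi = m.measure.span
            assert 0 <= lo < hi <= s.tokens[-1].char_end

    def test_direct_matches_never_share_a_unit_occurrence(self, lexicon):
        # "5 m" then "10 m": each unit occurrence serves one direct match
        out = _extract("poles of 5 m and towers of 10 m stood", lexicon)
        assert len(out) == 2
        assert len({m.measure.span for m in out}) == 2
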