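# envminer

Text mining of **contextual sample metadata** from scientific articles, for
microbial-ecology and environmental-genomics work where the conditions of a
sampling experiment (its physicochemical variables and its geographic
location) are buried in free text rather than structured records.

`envminer` extracts three kinds of information:

* **Physicochemical measurements.** A measurement in text is a numeric
  *measure* followed by a *unit* ("320 mts depth", "5 mg liter-1"), and the
  *variable* being measured (depth, concentration, ...) is often implicit in
  the unit. A curated lexicon maps unit surface forms ("gram", "gr", "grs",
  "g") to canonical units and variables; multi-part combination units imply
  a variable through their dimension pattern (mass over volume →
  concentration). A unit with several possible variables is resolved by a
  trigger word within a five-word window (explicit), by uniqueness
  (implicit), or reported under the covering variable of its dimension with
  candidates retained (ambiguous: a bare "20 cm" is a *size*). HTML tables
  are mined through their header row ("Depth (m)" types a whole column).
* **Geographic locations with coordinates.** Capitalized noun phrases are
  checked against a gazetteer (a GeoNames-style table with alternate names,
  coordinates, country, admin parent and a relevance ordering). Homonyms —
  "Margate" exists in five countries — are resolved by a cascade: unique
  candidate → same-sentence country match (admin containment counts:
  Tasmania ⊂ Australia) → smallest great-circle distance among same-country
  survivors → closest country name in the sentence → gazetteer relevance.
  Names absent from the gazetteer but containing a generic feature word
  ("Ganghwa Island") are kept as locations without coordinates.
* **Environmental vs experimental sentences.** A multinomial naive Bayes
  classifier with Laplace smoothing, over a vocabulary filtered to words
  that occur in more than one sentence and whose frequency in one class at
  least doubles that in the other, separates sentences describing the
  environment from those describing lab procedure. Evaluation is
  leave-one-out, with feature selection redone inside every fold.

A seeded synthetic-fixture generator produces HTML articles, gold
annotations, a mini-gazetteer and labeled sentence corpora, so the whole
pipeline is testable offline with exact ground truth.

## Worked example

```python
from envminer import default_lexicon, default_gazetteer, default_feature_words
from envminer.document import parse_document
from envminer.measurements import extract_document
from envminer.geo import extract_document_locations

html = """<html><body><h2>Materials and Methods</h2>
<p>Samples were collected at 320 mts depth near Margate, Tasmania.
The waters were at 5 degrees C. Cultures received 5 mg liter-1 of acetate.</p>
</body></html>"""

doc = parse_document(html, format="html", doc_id="example")
lex = default_lexicon()
measurements, tally = extract_document(doc, lex)
for m in measurements:
    print(m.measure.value, m.unit_surface, "->", m.variable, f"({m.status})")
mentions, _ = extract_document_locations(doc, default_gazetteer(), default_feature_words())
for m in mentions:
    r = m.resolved
    print(m.surface, "->", r.name if r else None, r.country_code if r else "", m.method)
```

prints

```
320.0 mts -> depth (explicit)
5.0 degrees C -> temperature (implicit)
5.0 mg liter-1 -> concentration (implicit)
Margate -> Margate AU country_match
Tasmania -> Tasmania AU unique
```

— the depth is explicit (its trigger word is in the window), the temperature
and the concentration are implied by their units (the second through the
mass/volume combination rule), and the ambiguous "Margate" lands on the
Australian record because Tasmania shares its country.

The same functionality is available from the shell:

```bash
envminer measurements article.html --json
envminer locations article.html --geojson points.json
envminer classify-train corpus.tsv --model model.json
envminer classify-eval corpus.tsv
envminer simulate --seed 7 --out fixtures/
```

## Layout

```
src/envminer/
  document.py     article parsing: sections, sentences, tokens, tables
  lexicon.py      unit-variable lexicon, harvesting, association bootstrap
  measurements.py measure detection, unit matching, variable resolution
  geo.py          NP chunking, gazetteer, disambiguation cascade, haversine
  classifier.py   multinomial naive Bayes + jackknife evaluation
  fixtures.py     seeded synthetic articles, gazetteer, labeled sentences
  scoring.py      recall/precision/F scoring against gold annotations
  pipeline.py     end-to-end runner producing one JSON report
  cli.py          `envminer` command-line interface
  data/           bundled lexicon, wordlist, feature words, mini-gazetteer
```

See `docs/methods.md` for the model details, parameter choices and known
limitations.
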