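# Methods

This note documents the models and procedures implemented in `envminer`,
the parameters that matter, what the synthetic fixtures do and do not
emulate, and the design choices made where the design was genuinely open.

## Document model

Articles are parsed from HTML, XML (JATS-like `<sec><title>` nesting is
understood) or plain text into sections, sentences and tables. Text is
NFC-normalized on ingest; token offsets are 0-based half-open into the
section text. Formatting tags are flattened before tokenization, so
`liter<sup>-1</sup>` reaches the matcher as `liter-1` — the lexicon stores
flattened surface forms. PDF is rejected: converting it loses the
typographic cues (headers, bold) that section detection needs, so callers
must supply text or markup.

Sentence segmentation is rule-based and deterministic: a boundary is
terminal punctuation followed by whitespace and a capitalized or numeric
token, with an exception list covering common abbreviations *including unit
abbreviations* ("min.", "approx."), so measurements never split a sentence.
No statistical model is used and nothing is downloaded. Section headers map
case-insensitively onto six canonical kinds (abstract, introduction,
methods, results, discussion, other); a subsection whose label matches
nothing ("Sample collection") inherits its parent's kind.

Numeric tokens allow an optional sign, thousands separators and a decimal
part ("6.5", "-20", "200,000"). A sign binds to the number only when not
preceded by a digit, so the hyphen in the range "5-10" is a separator, not
a minus.

## Unit–variable lexicon

The bundled lexicon (110 unit entries, 38 variables, 15 combination rules)
is a curated TSV with three sections: units (canonical form, surface forms,
dimension, ordered variable list), variables (name plus trigger words), and
combination rules (dimension pattern → variable). Surface matching is
exact-case first, then case-insensitive where the folded form is
unambiguous: `mM` (millimolar) and `mm` (millimeter) stay distinct, while
`ML` still finds the milliliter. Validation enumerates every violated
invariant at load time instead of stopping at the first.

Two operations rebuild such a lexicon from a corpus:

* **Unit harvesting** scans for numbers and keeps, for each, the longest
  run of immediately following words absent from a bundled English
  wordlist (from which unit words were removed). Ordinary words stop the
  run at once — "10 times" yields nothing, "5 mg liter-1 final" yields
  `mg liter-1`. Output is frequency-sorted for manual curation; harvesting
  proposes candidates, it does not edit the lexicon.
* **Association learning** links candidate units to variables when both
  co-occur in one sentence within a window of five word positions
  (punctuation not counted; the window is inclusive of distance 5).
  It starts from ten seed variables — temperature, size, volume, pH,
  concentration, time, weight, area, pressure, salinity — and iterates:
  units with no association propose new variables from their in-window
  co-words; a proposal needs support ≥ 2 before being appended (flagged
  uncurated), and the pass repeats until nothing new appears. The support
  threshold is this package's stopping rule for a bootstrap that is
  otherwise open-ended; it trades a little recall for noise control.

## Measurement extraction

Per sentence: every numeric token is a candidate measure; the longest
lexicon surface starting at the next token is matched, including
combinations joined by `/`, `per`, or a reciprocal `-1` suffix
(`grams/liter`, `gr liter-1`, `nanogram per milliliter`). A
reciprocal-marked unit may sit up to three words downstream, which is what
lets "269 kg of manure ha-1" parse as mass/area (an areal concentration)
instead of a bare weight. A third combination part may follow by space
alone (`mol/liter day`), but only when the three-dimension pattern names a
known rule.

Variable resolution cascade, in order: (1) a trigger word of a
unit-compatible variable within five word positions of the unit → that
variable, *explicit*; (2) a combination rule → its variable, *implicit*;
(3) a unit with exactly one variable → that variable, *implicit*; (4) the
covering variable of the unit's dimension (linear → size), *ambiguous*,
with the remaining candidates retained. Trigger words of variables
incompatible with the unit's dimension never override it. Two special
rules: a bare `g` in a sentence with a centrifugation cue (`centrifug*`,
`spun`, `rpm`) is a rotational-speed measure, not grams; and enumerations
("-20 and -80 degrees C", "1, 3, 5, 10, 12, and 15 mM") and ranges
("5-10 m") expand so every number inherits the shared trailing unit. The
enumeration expansion is on by default and can be disabled
(`--no-enumerations`) for the stricter adjacent-unit-only behavior.

Tables are mined through the header row: a header cell resolves to a
variable via its trigger words and/or a parenthesized unit
("Temperature (degrees C)"); numeric cells in that column inherit both.
Unresolvable columns are skipped with a warning, never an error.

Every textual instance is counted, including repeats of the same physical
quantity within a sentence.

## Geolocation

The default chunker takes maximal runs of capitalized tokens as noun
phrases (hyphens between capitalized words are bridged: "Mid-Atlantic
Ridge"), and additionally emits compounds joined across single lowercase
connectors ("Gulf of Mexico"); a compound is preferred only when the
gazetteer knows the full name, so "Piora Valley of Switzerland" still
yields its parts. A real POS tagger can be injected through the `tagger`
parameter but is never required: determinism without model downloads is
worth more here than chunking finesse. Filters target known error sources:
sentence-initial lone function words, all-caps tokens of length ≤ 4 with no
gazetteer hit (acronyms like DNA), and phrases preceded by personal-title
cues ("Dr.", "et") or citation closers — person names are the main
confusion class for this kind of extractor.

The gazetteer is a TSV whose columns are a documented subset of a
GeoNames-style dump (name, alternate names, WGS84 decimal-degree
coordinates, ISO country code, admin parent, feature class, relevance
rank), so a real dump can be loaded unchanged. The bundled mini-gazetteer
(110 records) exists for offline tests and fixtures: it carries the classic
ambiguity cases (five Margates, San Jose in three countries, Springfield
twice within the US), the admin containment chain Tasmania → Australia, a
set of one-record filler cities and features, and undersea features with no
country. Relevance ranks are taken as given in the file; how a production
gazetteer orders relevance is its own concern. Remote gazetteer services
are an adapter slot only, disabled by default and never used in tests; a
network failure there raises an error distinct from "no match".

Disambiguation follows the five-rule cascade listed in the README; the
first rule producing a unique record wins and is recorded as the mention's
`method`. Candidates without a country skip the country rules. Distance is
the haversine great-circle distance on a sphere of radius 6371.0 km;
distance ties under rule 3 break by relevance rank and set a `tie` flag on
the mention. A document-scope fallback (re-running rule 2/3 against country
mentions from the whole document for mentions that fell through to
relevance) exists but is off by default — sentence scope is the primary
semantics, document scope an alternative strategy.

Output is a JSON report plus a GeoJSON FeatureCollection (one Point per
mention with coordinates, properties: surface, method, country);
coordinates are printed to 4 decimal places.

## Sentence classifier

Multinomial naive Bayes over bag-of-words tokens (lower-cased, punctuation
stripped, numbers collapsed to `<num>` — measures are classifier-relevant
but individually sparse). The feature filter admits a word only if it
occurs in more than one sentence and its token frequency in one class at
least doubles the other's, evaluated inclusively on raw counts (4 vs 2
passes); a flag switches to class-size-normalized rates for imbalanced
corpora. Training uses Laplace smoothing with α = 1.0 by default
(configurable): likelihood(w|c) = (count(w,c)+α)/(tokens(c)+α·|V|), priors
from sentence counts, out-of-vocabulary tokens ignored at train and
classify time. Posteriors are normalized over the two classes; a sentence
with no in-vocabulary tokens is labeled by prior alone and flagged; exact
ties go to `exp`, the majority class in this domain.

Leave-one-out (jackknife) evaluation redoes feature selection *inside*
every fold — selecting features once globally would leak the held-out
sentence's counts into its own training set. The report gives per-class
original/classified/correct counts, recall, precision and F.

## Synthetic fixtures

`generate_corpus` emits HTML articles with the five canonical sections.
Measurements are planted from a fixed template table whose sentences follow
the measure-then-unit adjacency grammar (several are the classic example
sentences of this task, e.g. "samples were collected at {value} {unit}
depth"); each template declares the variable, unit and resolution status
the extractor should produce, and that declaration is the gold record —
gold and document are generated atomically. Section placement follows the
empirical distribution of measurements in full-text articles (abstract
1.4%, introduction 3.5%, methods 74.1%, results 15.9%, discussion 5.1%).
Values are drawn uniquely within a (document, section) pair so that value
identity is equivalent to span identity for scoring. A fraction
`out_of_lexicon_rate` of plants (and, with the same probability, whole
table columns) use invented unit strings ("fluorescence units") — these are
deliberate misses emulating units absent from any curated list. Locations
are sampled from the mini-gazetteer; ambiguous names get a same-sentence
country cue with probability `country_cue_rate` (the cue country is itself
recorded as a planted mention), and `feature_word_location_rate` plants
names that only the feature-word fallback can catch ("Lake Siso").

`generate_labeled_sentences` draws, for each class, fixed-length sentences
(6 tokens) uniformly from a 30-word class vocabulary sharing a fraction
`class_vocab_overlap` with the other class. Under the true model, a
sentence is misclassifiable only when every token is shared, so with equal
class sizes and ties to the majority class the expected accuracy is
1 − 0.5·overlap^6, which the generator reports in its gold record
(overlap 1 collapses to the majority prior). Default corpus size is 40
sentences per class — large enough for the jackknife estimate to sit within
a few points of that expectation, small enough that a 10-seed evaluation
runs in seconds.

What the fixtures do **not** emulate: publisher-specific HTML dialects,
OCR noise, genuinely novel unit notations beyond the planted inventory,
free-form prose (sentences are templated), person-name/location ambiguity
in running text, and gazetteers at real-world scale. Passing tests
demonstrate the mechanics are correct under the stated grammar and
gazetteer; they do not bound recall on arbitrary published text, where
coverage of the curated lexicon and gazetteer dominates.

## Scoring

Recall is retrieved/total, precision correct/retrieved, F their harmonic
mean; correct additionally requires unit and variable agreement (a
variable-linkage-only view exists). The conventional correct/total is also
reported as `strict_recall`. Instance matching on generated corpora is
one-to-one on (document, section kind, value); span-overlap matching is
used when both sides carry spans, and the rule is configurable. For
locations, `precision_without_coordinates` counts correctly named mentions
over all mentions, `precision_with_coordinates` additionally requires the
resolved coordinates to match the gold record — feature-word mentions
therefore count toward the former only. The two precisions use different
numerators over the same denominator and need not be ordered in general.

## Numerical and degenerate-input choices

Empty document → error; malformed markup → best-effort parse with a warning
record; empty candidate list in disambiguation → `unresolved`, never an
exception; empty table → no measurements; window < 1 or α ≤ 0 → parameter
errors. All randomness flows from explicit integer seeds through
`random.Random`; reports serialize with sorted keys so identical inputs
give byte-identical output. Haversine inputs are bounds-checked; its
argument to `asin` is clamped to 1 against rounding.

## Problem sizes

The test suite and the acceptance script run on corpora of 10–40 synthetic
documents (≈ 100–900 planted measurements), a 110-record gazetteer
(≈ 430 cascade pairs against brute force), and 80-sentence labeled corpora
jackknifed over 10 seeds — sizes chosen so the whole cycle completes in
seconds while every code path, including the degraded and ambiguous ones,
is exercised.

## Known limitations

* Units written *before* the measure ("pH 7.2", "OD600 of 0.5") are not
  captured; the grammar is strictly measure-then-unit.
* Unit conversion (°F → °C) and full dimensional algebra are out of scope;
  combination rules cover only the curated dimension patterns.
* The doubling feature filter on raw counts favors the larger class in
  imbalanced corpora; the normalized variant is available but not default.
* Chemical-compound recognition is deferred to dedicated tools; "5 mM" is
  extracted without identifying *what* is at 5 mM.
* The rule-based chunker under-segments unusual capitalization (all-caps
  headlines, German nouns); inject a POS tagger where that matters.
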