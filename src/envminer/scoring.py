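"""Scoring of extractions against gold annotations.

Metric semantics follow the retrieval convention used throughout this
package's evaluation tables: recall = retrieved / total instances,
precision = correct / retrieved, F = harmonic mean. ``strict_recall``
(correct / total) is reported alongside.

Measurement matching on generated corpora pairs predictions with gold
instances one-to-one on (document, section kind, value) — generated values
are unique within a section, which makes this equivalent to span overlap;
when both sides carry character spans (hand-built fixtures), span-overlap
matching is used instead via ``mode="span"``.
"""

from __future__ import annotations

from dataclasses import dataclass

from .geo import GeoMention
from .measurements import Measurement

__all__ = ["ExtractionScore", "LocationScore", "score_measurements", "score_locations"]


@dataclass
class ExtractionScore:
    total: int
    retrieved: int
    correct: int

    @property
    def recall(self) -> float:
        return self.retrieved / self.total if self.total else 0.0

    @property
    def strict_recall(self) -> float:
        return self.correct / self.total if self.total else 0.0

    @property
    def precision(self) -> float:
        return self.correct / self.retrieved if self.retrieved else 0.0

    @property
    def f_value(self) -> float:
        r, p = self.recall, self.precision
        return 2 * r * p / (r + p) if r + p else 0.0

    def to_dict(self) -> dict:
        return {
            "total": self.total,
            "retrieved": self.retrieved,
            "correct": self.correct,
            "recall": self.recall,
            "strict_recall": self.strict_recall,
            "precision": self.precision,
            "f_value": self.f_value,
        }


@dataclass
class LocationScore:
    total: int
    retrieved: int
    correct_name: int
    correct_coordinates: int

    @property
    def recall(self) -> float:
        return self.retrieved / self.total if self.total else 0.0

    @property
    def precision_without_coordinates(self) -> float:
        n = self.retrieved
        return self.correct_name / n if n else 0.0

    @property
    def precision_with_coordinates(self) -> float:
        n = self.retrieved
        return self.correct_coordinates / n if n else 0.0

    def to_dict(self) -> dict:
        return {
            "total": self.total,
            "retrieved": self.retrieved,
            "correct_name": self.correct_name,
            "correct_coordinates": self.correct_coordinates,
            "recall": self.recall,
            "precision_without_coordinates": self.precision_without_coordinates,
            "precision_with_coordinates": self.precision_with_coordinates,
        }


def score_measurements(
    predicted: dict[str, list[Measurement]],
    gold,
    variable_linkage_only: bool = False,
    mode: str = "value",
) -> ExtractionScore:
    """Score predicted measurements against gold annotations.

    ``predicted`` maps doc_id to measurement lists; ``gold`` is a list of
    GoldAnnotation (or equivalent dicts). A prediction *retrieves* a gold
    instance when doc, section kind and value coincide (``mode="value"``) or
    the spans overlap (``mode="span"``); it is *correct* when canonical unit
    and variable also match. With ``variable_linkage_only`` only variable
    agreement is required (the "linked to variables" view).
    """
    gold_ids = {g.doc_id if hasattr(g, "doc_id") else g["doc_id"] for g in gold}
    missing = set(predicted) - gold_ids
    if missing:
        raise ValueError(f"predictions reference unknown documents: {sorted(missing)}")

    total = 0
    retrieved = 0
    correct = 0
    for g in gold:
        doc_id = g.doc_id if hasattr(g, "doc_id") else g["doc_id"]
        gold_items = g.measurements if hasattr(g, "measurements") else g["measurements"]
        total += len(gold_items)
        preds = list(predicted.get(doc_id, []))
        retrieved += len(preds)
        unused = list(gold_items)
        for p in preds:
            match = None
            for item in unused:
                if mode == "span":
                    span = item.get("span")
                    if span and not (
                        p.measure.span[1] <= span[0] or span[1] <= p.measure.span[0]
                    ):
                        match = item
                        break
                else:
                    if (
                        item["section_kind"] == p.section_kind.value
                        and item["value"] == p.measure.value
                    ):
                        match = item
                        break
            if match is None:
                continue
            unused.remove(match)
            if variable_linkage_only:
                ok = match["variable"] == p.variable
            else:
                ok = (
                    match["variable"] == p.variable
                    and match["canonical_unit"] == p.canonical_unit
                )
            if ok:
                correct += 1
    return ExtractionScore(total=total, retrieved=retrieved, correct=correct)


def score_locations(
    predicted: dict[str, list[GeoMention]],
    gold,
    coord_tolerance: float = 1e-4,
) -> LocationScore:
    """Score predicted location mentions against gold annotations.

    ``correct_name`` counts predictions whose surface matches a gold planted
    location of the same document (feature-word hits qualify);
    ``correct_coordinates`` additionally requires the resolved coordinates to
    equal the gold record's, so feature-word-only locations lower the
    with-coordinates precision but not the without-coordinates one.
    """
    gold_ids = {g.doc_id if hasattr(g, "doc_id") else g["doc_id"] for g in gold}
    missing = set(predicted) - gold_ids
    if missing:
        raise ValueError(f"predictions reference unknown documents: {sorted(missing)}")

    total = 0
    retrieved = 0
    correct_name = 0
    correct_coords = 0
    for g in gold:
        doc_id = g.doc_id if hasattr(g, "doc_id") else g["doc_id"]
        gold_items = g.locations if hasattr(g, "locations") else g["locations"]
        total += len(gold_items)
        preds = list(predicted.get(doc_id, []))
        retrieved += len(preds)
        unused = list(gold_items)
        for p in preds:
            same_surface = [
                item
                for item in unused
                if item["surface"].casefold() == p.surface.casefold()
            ]
            # prefer the coordinate-consistent pairing when a name repeats
            match = next(
                (
                    item
                    for item in same_surface
                    if p.resolved is not None
                    and item["latitude"] is not None
                    and abs(p.resolved.latitude - item["latitude"]) <= coord_tolerance
                    and abs(p.resolved.longitude - item["longitude"]) <= coord_tolerance
                ),
                same_surface[0] if same_surface else None,
            )
            if match is None:
                continue
            unused.remove(match)
            correct_name += 1
            if (
                p.resolved is not None
                and match["latitude"] is not None
                and abs(p.resolved.latitude - match["latitude"]) <= coord_tolerance
                and abs(p.resolved.longitude - match["longitude"]) <= coord_tolerance
            ):
                correct_coords += 1
    return LocationScore(
        total=total,
        retrieved=retrieved,
        correct_name=correct_name,
        correct_coordinates=correct_coords,
    )
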