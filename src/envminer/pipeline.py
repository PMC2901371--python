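"""End-to-end pipeline: parse documents, extract measurements and locations,
optionally classify sentences, and emit one structured JSON report."""

from __future__ import annotations

import json
from pathlib import Path

from . import classifier as clf
from .document import parse_document
from .geo import (
    Gazetteer,
    default_feature_words,
    default_gazetteer,
    extract_document_locations,
    load_feature_words,
    mention_to_dict,
)
from .lexicon import default_lexicon, load_lexicon
from .measurements import extract_document, measurement_to_dict

__all__ = ["PipelineConfig", "load_resources", "run_pipeline"]

DEFAULT_CONFIG = {
    "lexicon": None,          # path; None = bundled
    "gazetteer": None,        # path; None = bundled mini-gazetteer
    "feature_words": None,    # path; None = bundled
    "model": None,            # path to a trained classifier model (optional)
    "enumerations": True,
    "document_scope": False,
    "format": "html",
}


class StartupError(RuntimeError):
    """Missing or unreadable resource files, listed one per line."""


def load_resources(config: dict):
    cfg = {**DEFAULT_CONFIG, **(config or {})}
    problems = []
    for key in ("lexicon", "gazetteer", "feature_words", "model"):
        p = cfg.get(key)
        if p is not None and not Path(p).exists():
            problems.append(f"missing {key} file: {p}")
    if problems:
        raise StartupError("\n".join(problems))
    lexicon = load_lexicon(cfg["lexicon"]) if cfg["lexicon"] else default_lexicon()
    gazetteer = (
        Gazetteer.from_tsv(cfg["gazetteer"]) if cfg["gazetteer"] else default_gazetteer()
    )
    feature_words = (
        load_feature_words(cfg["feature_words"])
        if cfg["feature_words"]
        else default_feature_words()
    )
    model = None
    if cfg.get("model"):
        model = clf.ClassifierModel.from_json(Path(cfg["model"]).read_text("utf-8"))
    return cfg, lexicon, gazetteer, feature_words, model


def run_pipeline(paths: list[str | Path], config: dict | None = None) -> dict:
    """Process documents and return the full JSON-serializable report.

    ``paths`` are article files; ``config`` keys are those of
    ``DEFAULT_CONFIG`` (flat, CLI flags override). Missing resources raise
    :class:`StartupError` listing every absent file.
    """
    cfg, lexicon, gazetteer, feature_words, model = load_resources(config or {})
    missing = [str(p) for p in paths if not Path(p).exists()]
    if missing:
        raise StartupError("\n".join(f"missing input file: {p}" for p in missing))

    report: dict = {"config": {k: v for k, v in cfg.items()}, "documents": []}
    for path in sorted(Path(p) for p in paths):
        text = path.read_text(encoding="utf-8")
        doc = parse_document(text, format=cfg["format"], doc_id=path.stem)
        measurements, tally = extract_document(
            doc, lexicon, enumerations=cfg["enumerations"]
        )
        mentions, geo_report = extract_document_locations(
            doc, gazetteer, feature_words, document_scope=cfg["document_scope"]
        )
        entry = {
            "doc_id": doc.id,
            "warnings": doc.warnings,
            "measurements": [measurement_to_dict(m) for m in measurements],
            "tally": tally,
            "locations": [mention_to_dict(m) for m in mentions],
            "location_report": geo_report,
        }
        if model is not None:
            entry["sentences"] = [
                {
                    "text": s.text,
                    "label": lab,
                    "posterior": round(post, 6),
                    "prior_only": prior_only,
                }
                for s in doc.sentences()
                for lab, post, prior_only in [clf.classify(model, s.text)]
            ]
        report["documents"].append(entry)
    return report


def report_to_json(report: dict) -> str:
    return json.dumps(report, sort_keys=True, ensure_ascii=False, indent=2)
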