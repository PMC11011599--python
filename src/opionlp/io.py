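"""Readers/writers for the pipeline's file formats, and the run config.

Formats are plain text throughout: note corpora as JSONL (one JSON object
per line) or CSV with identical columns; snippets, annotations, patient
tables, ICD tables and comparison tables as RFC-4180 CSV with a header
row, UTF-8, ISO-8601 dates.
"""

from __future__ import annotations

import datetime as dt
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from .cascade import ClassifiedSnippet, PatientRecord
from .lexicon import Snippet

log = logging.getLogger("opionlp")

CORPUS_COLUMNS = ("note_id", "patient_id", "note_date", "note_type", "text")
ANNOTATION_COLUMNS = ("snippet_id", "key_phrase", "text", "label")
PATIENT_REQUIRED = ("patient_id",)
ICD_COLUMNS = ("patient_id", "code", "date")


def _require_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{what}: missing required columns {missing}")


def read_corpus(path: str | Path) -> pd.DataFrame:
    """Read a note corpus from JSONL (or CSV, by extension)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"corpus file not found: {path}")
    if path.suffix.lower() in (".jsonl", ".json", ".ndjson"):
        records = []
        with path.open(encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    records.append(json.loads(line))
                except json.JSONDecodeError as exc:
                    raise ValueError(f"{path}: malformed JSON on line {lineno}: {exc}") from exc
        df = pd.DataFrame(records)
    else:
        df = pd.read_csv(path, dtype=str)
    _require_columns(df, CORPUS_COLUMNS, str(path))
    df = df.astype({c: str for c in CORPUS_COLUMNS})
    log.info("read %d notes from %s", len(df), path)
    return df


def write_corpus(notes: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for rec in notes.to_dict(orient="records"):
            fh.write(json.dumps(rec, sort_keys=True) + "\n")
    log.info("wrote %d notes to %s", len(notes), path)


def write_table(rows: pd.DataFrame, path: str | Path) -> None:
    """Write a table as UTF-8 comma-separated CSV with a header row."""
    rows.to_csv(path, index=False, encoding="utf-8", lineterminator="\n")
    log.info("wrote %d rows to %s", len(rows), path)


def read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"table not found: {path}")
    return pd.read_csv(path)


def snippets_to_frame(snippets: Sequence[Snippet]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "note_id": [s.note_id for s in snippets],
            "patient_id": [s.patient_id for s in snippets],
            "key_phrase": [s.key_phrase for s in snippets],
            "key_phrase_token_index": [s.key_phrase_token_index for s in snippets],
            "tokens_before": [" ".join(s.tokens_before) for s in snippets],
            "matched_tokens": [" ".join(s.matched_tokens) for s in snippets],
            "tokens_after": [" ".join(s.tokens_after) for s in snippets],
        }
    )


def frame_to_snippets(df: pd.DataFrame) -> list[Snippet]:
    _require_columns(
        df, ("note_id", "patient_id", "key_phrase", "tokens_before",
             "matched_tokens", "tokens_after"), "snippet table"
    )
    out = []
    for rec in df.to_dict(orient="records"):
        out.append(
            Snippet(
                key_phrase=str(rec["key_phrase"]),
                tokens_before=tuple(str(rec["tokens_before"]).split())
                if not pd.isna(rec["tokens_before"]) else (),
                matched_tokens=tuple(str(rec["matched_tokens"]).split()),
                tokens_after=tuple(str(rec["tokens_after"]).split())
                if not pd.isna(rec["tokens_after"]) else (),
                note_id=str(rec["note_id"]),
                patient_id=str(rec["patient_id"]),
            )
        )
    return out


def classified_to_frame(classified: Sequence[ClassifiedSnippet]) -> pd.DataFrame:
    base = snippets_to_frame([c.snippet for c in classified])
    base["label"] = [c.label for c in classified]
    base["method"] = [c.method for c in classified]
    base["tier"] = [c.tier for c in classified]
    return base


def frame_to_classified(df: pd.DataFrame) -> list[ClassifiedSnippet]:
    _require_columns(df, ("label", "method"), "classified snippet table")
    snippets = frame_to_snippets(df)
    return [
        ClassifiedSnippet(s, str(r["label"]), str(r["method"]),
                          "" if pd.isna(r.get("tier")) else str(r.get("tier", "")))
        for s, (_, r) in zip(snippets, df.iterrows())
    ]


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Annotated snippet file: snippet_id, key_phrase, text, label."""
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, ANNOTATION_COLUMNS, str(path))
    bad = set(df["label"]) - {"positive", "suspected", "negative"}
    if bad:
        raise ValueError(f"{path}: unknown labels {sorted(bad)}")
    return df


def load_patients(
    patients_path: str | Path, icd_path: Optional[str | Path] = None
) -> list[PatientRecord]:
    """Build patient records from a patient CSV and optional ICD table."""
    pats = pd.read_csv(patients_path, dtype={"patient_id": str})
    _require_columns(pats, PATIENT_REQUIRED, str(patients_path))
    codes: dict[str, list] = {}
    if icd_path is not None:
        icd = pd.read_csv(icd_path, dtype=str)
        _require_columns(icd, ICD_COLUMNS, str(icd_path))
        for rec in icd.to_dict(orient="records"):
            date = None
            if rec.get("date") and not pd.isna(rec["date"]):
                date = dt.date.fromisoformat(str(rec["date"]))
            codes.setdefault(str(rec["patient_id"]), []).append((str(rec["code"]), date))
    out = []
    for rec in pats.to_dict(orient="records"):
        pid = str(rec["patient_id"])
        attrs = {k: v for k, v in rec.items() if k != "patient_id"}
        out.append(PatientRecord(pid, codes.get(pid, []), attrs))
    return out


@dataclass
class RunConfig:
    """Paths and knobs for a pipeline run, loadable from YAML or JSON."""

    lexicon: Optional[str] = None
    patterns: Optional[str] = None
    corpus: Optional[str] = None
    annotations: Optional[str] = None
    patients: Optional[str] = None
    icd: Optional[str] = None
    model: Optional[str] = None
    output_dir: str = "."
    seed: int = 0
    min_document_frequency: int = 2
    split_fraction: float = 0.8
    threshold: float = 0.85

    def __post_init__(self) -> None:
        if not 0.0 < self.split_fraction < 1.0:
            raise ValueError("split_fraction must lie in (0, 1)")
        if not 0.0 < self.threshold <= 1.0:
            raise ValueError("threshold must lie in (0, 1]")


def load_run_config(path: str | Path) -> RunConfig:
    path = Path(path)
    data = yaml.safe_load(path.read_text("utf-8"))
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    return RunConfig(**data)
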