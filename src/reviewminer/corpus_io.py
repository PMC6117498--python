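"""Data model and I/O for physician-review corpora.

A :class:`Review` is one rated encounter: the free-text comment a patient left
for a doctor, optionally pre-segmented into tokens, optionally annotated with a
set of taxonomy labels, plus the metadata used for group comparisons (disease,
hospital level, doctor id).  A :class:`Corpus` is an ordered collection of
reviews; a :class:`Taxonomy` is the fixed set of topic labels (9 labels in 3
domains for the packaged default); a :class:`GroupingScheme` maps a metadata
field onto two-group contrasts (acute vs chronic disease, mild vs serious
disease, high vs low hospital level).

The canonical on-disk format is JSONL, one review per line; CSV is accepted
with tokens / tags / labels as space-joined strings.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
import yaml

_DATA_PACKAGE = "reviewminer.data"

HOSPITAL_LEVELS = ("A", "B", "C")


class CorpusFormatError(ValueError):
    """A corpus file record violates the Review contract."""


def _data_path(name: str):
    return resources.files(_DATA_PACKAGE).joinpath(name)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class Review:
    """One physician review with optional annotations and group metadata."""

    doc_id: str
    raw_text: Optional[str] = None
    tokens: Optional[list[str]] = None
    pos_tags: Optional[list[str]] = None
    labels: Optional[set[str]] = None
    disease: str = ""
    hospital_level: Optional[str] = None
    doctor_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.raw_text is None and self.tokens is None:
            raise CorpusFormatError(
                f"review {self.doc_id!r}: needs at least one of raw_text or tokens"
            )
        if self.pos_tags is not None:
            if self.tokens is None or len(self.pos_tags) != len(self.tokens):
                raise CorpusFormatError(
                    f"review {self.doc_id!r}: pos_tags must parallel tokens"
                )
        if self.hospital_level is not None and self.hospital_level not in HOSPITAL_LEVELS:
            raise CorpusFormatError(
                f"review {self.doc_id!r}: hospital_level must be one of "
                f"{HOSPITAL_LEVELS}, got {self.hospital_level!r}"
            )
        if self.labels is not None:
            self.labels = set(self.labels)

    @property
    def n_tokens(self) -> int:
        return 0 if self.tokens is None else len(self.tokens)


@dataclass
class Corpus:
    """An ordered collection of reviews."""

    reviews: list[Review] = field(default_factory=list)

    @property
    def M(self) -> int:
        return len(self.reviews)

    @property
    def N_d(self) -> list[int]:
        return [r.n_tokens for r in self.reviews]

    def __len__(self) -> int:
        return self.M

    def __iter__(self):
        return iter(self.reviews)

    def __getitem__(self, i):
        return self.reviews[i]

    def validate_labels(self, taxonomy: "Taxonomy") -> None:
        """Check every annotated label set against the taxonomy."""
        known = set(taxonomy.label_ids)
        for r in self.reviews:
            if r.labels is not None and not r.labels <= known:
                raise CorpusFormatError(
                    f"review {r.doc_id!r}: labels {sorted(r.labels - known)} "
                    "not in taxonomy"
                )


@dataclass(frozen=True)
class TaxonomyLabel:
    label_id: str
    name: str
    domain: str


@dataclass
class Taxonomy:
    """Ordered topic labels, each in exactly one domain."""

    labels: list[TaxonomyLabel]
    keywords: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [lab.label_id for lab in self.labels]
        if not ids:
            raise ValueError("taxonomy must define at least one label")
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate label ids in taxonomy")
        for lab in self.labels:
            if not lab.domain:
                raise ValueError(f"label {lab.label_id!r} has no domain")

    @property
    def L(self) -> int:
        return len(self.labels)

    @property
    def label_ids(self) -> list[str]:
        return [lab.label_id for lab in self.labels]

    def index(self, label_id: str) -> int:
        return self.label_ids.index(label_id)

    def domains(self) -> dict[str, list[str]]:
        """Domain -> label ids, preserving label order."""
        out: dict[str, list[str]] = {}
        for lab in self.labels:
            out.setdefault(lab.domain, []).append(lab.label_id)
        return out


@dataclass
class GroupingScheme:
    """Maps one metadata field (disease or hospital_level) to group tags.

    Keys are matched case-insensitively after trimming; an unmapped key leaves
    the review ungrouped (``None``), never misassigned.
    """

    name: str
    field: str
    mapping: dict[str, str]

    def __post_init__(self) -> None:
        self.mapping = {
            str(k).strip().lower(): str(v) for k, v in self.mapping.items()
        }

    @property
    def groups(self) -> list[str]:
        seen: list[str] = []
        for g in self.mapping.values():
            if g not in seen:
                seen.append(g)
        return seen


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

_REVIEW_FIELDS = (
    "doc_id", "raw_text", "tokens", "pos_tags", "labels",
    "disease", "hospital_level", "doctor_id",
)


def _review_from_record(rec: dict, lineno: int) -> Review:
    if "doc_id" not in rec or rec["doc_id"] in (None, ""):
        raise CorpusFormatError(f"line {lineno}: missing field 'doc_id'")
    if rec.get("raw_text") in (None, "") and not rec.get("tokens"):
        raise CorpusFormatError(
            f"line {lineno}: record needs raw_text or tokens"
        )
    labels = rec.get("labels")
    try:
        return Review(
            doc_id=str(rec["doc_id"]),
            raw_text=rec.get("raw_text") or None,
            tokens=list(rec["tokens"]) if rec.get("tokens") else None,
            pos_tags=list(rec["pos_tags"]) if rec.get("pos_tags") else None,
            labels=set(labels) if labels else None,
            disease=str(rec.get("disease", "") or ""),
            hospital_level=rec.get("hospital_level") or None,
            doctor_id=str(rec["doctor_id"]) if rec.get("doctor_id") else None,
        )
    except CorpusFormatError as exc:
        raise CorpusFormatError(f"line {lineno}: {exc}") from exc


def read_corpus(path: str | Path, dialect: str = "jsonl") -> Corpus:
    """Read a corpus from JSONL (canonical) or CSV.

    Input order is preserved.  Malformed records raise
    :class:`CorpusFormatError` naming the offending line.
    """
    path = Path(path)
    reviews: list[Review] = []
    if dialect == "jsonl":
        with path.open(encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    rec = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise CorpusFormatError(f"line {lineno}: invalid JSON ({exc})")
                reviews.append(_review_from_record(rec, lineno))
    elif dialect == "csv":
        with path.open(encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh)
            for lineno, row in enumerate(reader, start=2):
                rec = dict(row)
                for key in ("tokens", "pos_tags", "labels"):
                    if rec.get(key):
                        rec[key] = rec[key].split()
                    else:
                        rec[key] = None
                reviews.append(_review_from_record(rec, lineno))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return Corpus(reviews)


def write_corpus(corpus: Corpus, path: str | Path, dialect: str = "jsonl") -> None:
    """Write a corpus; lossless round-trip partner of :func:`read_corpus`."""
    path = Path(path)
    if dialect == "jsonl":
        with path.open("w", encoding="utf-8") as fh:
            for r in corpus:
                rec = {
                    "doc_id": r.doc_id,
                    "raw_text": r.raw_text,
                    "tokens": r.tokens,
                    "pos_tags": r.pos_tags,
                    "labels": sorted(r.labels) if r.labels is not None else None,
                    "disease": r.disease,
                    "hospital_level": r.hospital_level,
                    "doctor_id": r.doctor_id,
                }
                rec = {k: v for k, v in rec.items() if v is not None}
                fh.write(json.dumps(rec, ensure_ascii=False) + "\n")
    elif dialect == "csv":
        with path.open("w", encoding="utf-8", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=_REVIEW_FIELDS)
            writer.writeheader()
            for r in corpus:
                writer.writerow({
                    "doc_id": r.doc_id,
                    "raw_text": r.raw_text or "",
                    "tokens": " ".join(r.tokens) if r.tokens else "",
                    "pos_tags": " ".join(r.pos_tags) if r.pos_tags else "",
                    "labels": " ".join(sorted(r.labels)) if r.labels else "",
                    "disease": r.disease,
                    "hospital_level": r.hospital_level or "",
                    "doctor_id": r.doctor_id or "",
                })
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def load_taxonomy(path: str | Path | None = None) -> Taxonomy:
    """Load a taxonomy YAML; ``None`` loads the packaged 9-label default."""
    if path is None:
        text = _data_path("taxonomy.yaml").read_text(encoding="utf-8")
    else:
        text = Path(path).read_text(encoding="utf-8")
    spec = yaml.safe_load(text)
    entries = spec.get("labels") if isinstance(spec, dict) else None
    if not entries:
        raise ValueError("taxonomy file defines no labels")
    labels, keywords = [], {}
    for e in entries:
        if "domain" not in e or not e["domain"]:
            raise ValueError(f"label {e.get('id')!r} has no domain")
        labels.append(TaxonomyLabel(str(e["id"]), str(e.get("name", e["id"])),
                                    str(e["domain"])))
        if e.get("keywords"):
            keywords[str(e["id"])] = [str(k) for k in e["keywords"]]
    return Taxonomy(labels, keywords)


def load_grouping_scheme(name_or_path: str | Path) -> GroupingScheme:
    """Load one of the packaged schemes by name, or any scheme YAML by path.

    Packaged names: ``acute_vs_chronic``, ``mild_vs_serious``,
    ``high_vs_low_hospital``.
    """
    packaged = yaml.safe_load(
        _data_path("grouping_schemes.yaml").read_text(encoding="utf-8"))
    key = str(name_or_path)
    if key in packaged:
        entry = packaged[key]
        return GroupingScheme(key, entry["field"], entry["mapping"])
    path = Path(name_or_path)
    spec = yaml.safe_load(path.read_text(encoding="utf-8"))
    if len(spec) == 1:
        ((key, entry),) = spec.items()
        return GroupingScheme(key, entry["field"], entry["mapping"])
    raise ValueError(f"cannot resolve grouping scheme {name_or_path!r}")


def assign_group(review: Review, scheme: GroupingScheme) -> Optional[str]:
    """Deterministic group tag for a review, or ``None`` if its key is unmapped."""
    value = getattr(review, scheme.field, None)
    if value is None:
        return None
    return scheme.mapping.get(str(value).strip().lower())


# ---------------------------------------------------------------------------
# Descriptive summaries
# ---------------------------------------------------------------------------

def summarize_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Descriptive statistics from per-group counts.

    ``counts`` needs columns ``group``, ``n_reviews``, ``n_doctors`` and
    optionally ``mean_length``.  Adds ``share_pct`` (percentage of all reviews,
    2 dp), ``doctor_share_pct`` and ``reviews_per_doctor`` (1 dp; NaN when a
    group has zero doctors rather than a division failure).  Internal values
    stay full precision; rounding here follows the display convention.
    """
    df = counts.copy()
    total_reviews = df["n_reviews"].sum()
    total_doctors = df["n_doctors"].sum()
    df["share_pct"] = (100.0 * df["n_reviews"] / total_reviews).round(2)
    df["doctor_share_pct"] = (100.0 * df["n_doctors"] / total_doctors).round(2)
    rpd = df["n_reviews"] / df["n_doctors"].where(df["n_doctors"] > 0)
    df["reviews_per_doctor"] = rpd.round(1)
    if "mean_length" in df.columns:
        df["mean_length"] = df["mean_length"].round().astype("Int64")
    return df


def corpus_summary(corpus: Corpus, by: str = "disease") -> pd.DataFrame:
    """Per-group review counts, shares, doctors, reviews/doctor, mean length.

    Doctors are counted within each group (a doctor reviewed under two diseases
    contributes to both groups), matching how per-disease physician counts are
    conventionally tabulated for these data.
    """
    rows: dict[str, dict] = {}
    for r in corpus:
        key = getattr(r, by, None)
        if key is None or key == "":
            continue
        entry = rows.setdefault(str(key), {"doctors": set(), "n": 0, "len_sum": 0})
        entry["n"] += 1
        entry["len_sum"] += r.n_tokens
        if r.doctor_id is not None:
            entry["doctors"].add(r.doctor_id)
    if not rows:
        raise ValueError(f"no review has a value for field {by!r}")
    counts = pd.DataFrame({
        "group": list(rows),
        "n_reviews": [e["n"] for e in rows.values()],
        "n_doctors": [len(e["doctors"]) for e in rows.values()],
        "mean_length": [e["len_sum"] / e["n"] for e in rows.values()],
    })
    return summarize_counts(counts)


def load_review_statistics() -> pd.DataFrame:
    """Packaged per-disease counts of the reference review dataset."""
    with resources.as_file(_data_path("review_statistics.csv")) as p:
        df = pd.read_csv(p)
    return df.rename(columns={"disease": "group"})


def load_benchmark_scores() -> pd.DataFrame:
    """Packaged per-disease precision/recall/F benchmark of the reference
    labeled-LDA classifier on its blind test set."""
    with resources.as_file(_data_path("benchmark_scores.csv")) as p:
        return pd.read_csv(p)
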