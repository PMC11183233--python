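"""Data model and I/O for series/sample metadata and annotation tables.

The pipeline operates on GEO-style studies: a *series* (GSE) holding
*samples* (GSM) whose free-text ``characteristics`` lines describe the
experimental variables.  One experimental-design call — which samples are
controls, which are perturbed, and what the perturbation is — is an
:class:`AnnotationRecord`.

The on-disk formats are a small line-oriented SOFT dialect for series
metadata (``^SERIES``/``^SAMPLE`` blocks with ``!Series_``/``!Sample_``
attribute lines) and a tab-separated annotation table with pipe-separated
sample-identifier lists.
"""

from __future__ import annotations

import enum
import json
import re
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd
from pydantic import BaseModel, ConfigDict, field_serializer, field_validator, model_validator

__all__ = [
    "PertType",
    "SampleRecord",
    "SeriesRecord",
    "AnnotationRecord",
    "SoftParseError",
    "AnnotationValidationError",
    "KeyClasses",
    "DEFAULT_KEY_CLASSES",
    "normalize_key",
    "normalize_characteristics",
    "parse_soft",
    "serialize_soft",
    "read_annotations",
    "write_annotations",
    "validate_annotation_against_series",
]


class PertType(str, enum.Enum):
    """Kind of experimental perturbation distinguishing the two groups."""

    drug = "drug"
    disease = "disease"
    gene = "gene"


class SoftParseError(ValueError):
    """Malformed SOFT-dialect input; the message names the offending line."""


class AnnotationValidationError(ValueError):
    """Annotation table row violating the record contract."""


_WS = re.compile(r"\s+")


def normalize_key(key: str) -> str:
    """Case-fold, trim, and collapse internal whitespace of a characteristic key."""
    return _WS.sub(" ", key.strip()).casefold()


class KeyClasses:
    """Configurable synonym classes for characteristic keys ignored by QC.

    Sex and age are expressly ignored when comparing sample characteristics
    between control and perturbation groups; GEO submitters spell those keys
    many ways, so the class membership is a configurable synonym list.
    """

    def __init__(
        self,
        sex_keys: Iterable[str] = ("sex", "gender"),
        age_keys: Iterable[str] = ("age", "age (years)", "age_yrs", "age_years", "age (yrs)"),
    ) -> None:
        self.sex_keys = frozenset(normalize_key(k) for k in sex_keys)
        self.age_keys = frozenset(normalize_key(k) for k in age_keys)

    def classify(self, key: str) -> Optional[str]:
        """Return ``"sex"``, ``"age"`` or ``None`` for a (raw or normalized) key."""
        k = normalize_key(key)
        if k in self.sex_keys:
            return "sex"
        if k in self.age_keys:
            return "age"
        return None

    def is_ignored(self, key: str) -> bool:
        return self.classify(key) is not None


DEFAULT_KEY_CLASSES = KeyClasses()


class SampleRecord(BaseModel):
    """One sample (GSM) with its free-text characteristics."""

    model_config = ConfigDict(frozen=True)

    sample_id: str
    title: str = ""
    organism: str = ""
    source: str = ""
    characteristics: dict[str, str] = {}
    platform_id: str = ""
    raw: tuple[str, ...] = ()

    @field_validator("sample_id")
    @classmethod
    def _non_empty_id(cls, v: str) -> str:
        if not v.strip():
            raise ValueError("sample_id must be non-empty")
        return v

    def text_blob(self) -> str:
        """All searchable text of the sample (title, source, characteristic values)."""
        parts = [self.title, self.source]
        parts.extend(f"{k}: {v}" for k, v in self.characteristics.items())
        return " | ".join(p for p in parts if p)


class SeriesRecord(BaseModel):
    """One study (GSE) and its samples."""

    model_config = ConfigDict(frozen=True)

    series_id: str
    title: str = ""
    summary: str = ""
    overall_design: str = ""
    samples: tuple[SampleRecord, ...] = ()
    raw: tuple[str, ...] = ()

    @model_validator(mode="after")
    def _unique_sample_ids(self) -> "SeriesRecord":
        ids = [s.sample_id for s in self.samples]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sample id(s): {', '.join(dupes)}")
        return self

    def sample_map(self) -> dict[str, SampleRecord]:
        return {s.sample_id: s for s in self.samples}


class AnnotationRecord(BaseModel):
    """One experimental-design call: controls vs perturbed samples."""

    model_config = ConfigDict(frozen=True)

    series_id: str
    ctrl_ids: frozenset[str]
    pert_ids: frozenset[str]
    pert_type: PertType
    pert_name: str
    cell_type: str = ""
    annotator_tag: str = ""
    round_index: int = 1

    @model_validator(mode="after")
    def _groups_valid(self) -> "AnnotationRecord":
        if not self.ctrl_ids or not self.pert_ids:
            raise ValueError("ctrl_ids and pert_ids must each be non-empty")
        overlap = self.ctrl_ids & self.pert_ids
        if overlap:
            raise ValueError(f"overlapping groups: {', '.join(sorted(overlap))}")
        if self.round_index < 1:
            raise ValueError("round_index must be >= 1")
        return self

    @field_serializer("ctrl_ids", "pert_ids")
    def _ser_ids(self, v: frozenset[str]) -> list[str]:
        return sorted(v)

    def key(self) -> str:
        """Stable reference for this design call, independent of round/tag."""
        return "{}:{}|{}".format(
            self.series_id, ",".join(sorted(self.ctrl_ids)), ",".join(sorted(self.pert_ids))
        )


def normalize_characteristics(sample: SampleRecord, key_classes: KeyClasses = DEFAULT_KEY_CLASSES) -> SampleRecord:
    """Return a copy of ``sample`` with normalized characteristic keys.

    Keys are case-folded, trimmed, and internal whitespace collapsed; values
    are trimmed.  Keys colliding after normalization get a numeric suffix to
    keep the mapping unique.  The operation is idempotent.
    """
    out: dict[str, str] = {}
    for k, v in sample.characteristics.items():
        nk = normalize_key(k)
        if nk in out:
            i = 2
            while f"{nk}_{i}" in out:
                i += 1
            nk = f"{nk}_{i}"
        out[nk] = v.strip()
    return sample.model_copy(update={"characteristics": out})


# ---------------------------------------------------------------------------
# SOFT-dialect reader / writer
# ---------------------------------------------------------------------------

_KNOWN_SERIES_ATTRS = {
    "!series_title": "title",
    "!series_summary": "summary",
    "!series_overall_design": "overall_design",
}
_KNOWN_SAMPLE_ATTRS = {
    "!sample_title": "title",
    "!sample_organism_ch1": "organism",
    "!sample_source_name_ch1": "source",
    "!sample_platform_id": "platform_id",
}


def parse_soft(text: str) -> SeriesRecord:
    """Parse one series block with its sample blocks from SOFT-dialect text.

    Only ``^SERIES``/``^SAMPLE`` blocks and ``!Series_``/``!Sample_``
    attribute lines are interpreted; unknown lines are preserved verbatim in
    the ``raw`` field of the enclosing record.  Characteristic lines of the
    form ``key: value`` are split into the characteristics mapping; lines
    without a colon become key ``characteristic_<n>``.
    """
    series_kw: dict[str, object] = {}
    series_raw: list[str] = []
    samples: list[SampleRecord] = []
    cur: Optional[dict[str, object]] = None  # current sample under construction
    seen_series = False
    seen_ids: set[str] = set()

    def _flush() -> None:
        nonlocal cur
        if cur is not None:
            chars = cur.pop("characteristics")
            raw = cur.pop("raw")
            samples.append(SampleRecord(characteristics=dict(chars), raw=tuple(raw), **cur))
            cur = None

    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            continue
        low = stripped.casefold()
        if low.startswith("^series"):
            if seen_series:
                raise SoftParseError(f"line {lineno}: second ^SERIES block: {stripped!r}")
            seen_series = True
            series_kw["series_id"] = stripped.split("=", 1)[1].strip() if "=" in stripped else ""
        elif low.startswith("^sample"):
            if not seen_series:
                raise SoftParseError(f"line {lineno}: sample block before series block: {stripped!r}")
            _flush()
            sid = stripped.split("=", 1)[1].strip() if "=" in stripped else ""
            if sid in seen_ids:
                raise SoftParseError(f"line {lineno}: duplicate sample id {sid!r}")
            seen_ids.add(sid)
            cur = {"sample_id": sid, "characteristics": {}, "raw": [], "_n_anon": 0}
        elif stripped.startswith("!") and "=" in stripped:
            attr, value = (p.strip() for p in stripped.split("=", 1))
            attr_l = attr.casefold()
            if cur is None:
                if not seen_series:
                    raise SoftParseError(f"line {lineno}: attribute before ^SERIES: {stripped!r}")
                if attr_l in _KNOWN_SERIES_ATTRS:
                    field = _KNOWN_SERIES_ATTRS[attr_l]
                    # repeated summary lines are concatenated, as in real SOFT
                    prev = series_kw.get(field, "")
                    series_kw[field] = f"{prev} {value}".strip() if prev else value
                else:
                    series_raw.append(stripped)
            else:
                if attr_l in _KNOWN_SAMPLE_ATTRS:
                    cur[_KNOWN_SAMPLE_ATTRS[attr_l]] = value
                elif attr_l.startswith("!sample_characteristics"):
                    chars = cur["characteristics"]  # type: ignore[index]
                    if ":" in value:
                        key, val = value.split(":", 1)
                        key = normalize_key(key)
                        val = val.strip()
                    else:
                        cur["_n_anon"] = cur.get("_n_anon", 0) + 1  # type: ignore[operator]
                        key, val = f"characteristic_{cur['_n_anon']}", value
                    if key in chars:  # type: ignore[operator]
                        i = 2
                        while f"{key}_{i}" in chars:  # type: ignore[operator]
                            i += 1
                        key = f"{key}_{i}"
                    chars[key] = val  # type: ignore[index]
                else:
                    cur["raw"].append(stripped)  # type: ignore[union-attr]
        else:
            (series_raw if cur is None else cur["raw"]).append(stripped)  # type: ignore[union-attr]

    if not seen_series:
        raise SoftParseError("no ^SERIES block found")
    _flush()
    if not samples:
        raise SoftParseError("series block contains no ^SAMPLE blocks")
    for extra in ("_n_anon",):
        series_kw.pop(extra, None)
    return SeriesRecord(samples=tuple(samples), raw=tuple(series_raw), **series_kw)  # type: ignore[arg-type]


def serialize_soft(series: SeriesRecord) -> str:
    """Serialize a series back to the SOFT dialect; inverse of :func:`parse_soft`."""
    lines = [f"^SERIES = {series.series_id}"]
    if series.title:
        lines.append(f"!Series_title = {series.title}")
    if series.summary:
        lines.append(f"!Series_summary = {series.summary}")
    if series.overall_design:
        lines.append(f"!Series_overall_design = {series.overall_design}")
    lines.extend(series.raw)
    for s in series.samples:
        lines.append(f"^SAMPLE = {s.sample_id}")
        if s.title:
            lines.append(f"!Sample_title = {s.title}")
        if s.organism:
            lines.append(f"!Sample_organism_ch1 = {s.organism}")
        if s.source:
            lines.append(f"!Sample_source_name_ch1 = {s.source}")
        if s.platform_id:
            lines.append(f"!Sample_platform_id = {s.platform_id}")
        for k, v in s.characteristics.items():
            lines.append(f"!Sample_characteristics_ch1 = {k}: {v}")
        lines.extend(s.raw)
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Annotation tables (TSV, CREEDS-like schema)
# ---------------------------------------------------------------------------

_ANN_COLUMNS = ["series_id", "ctrl_ids", "pert_ids", "pert_type", "cell_type", "pert_name", "annotator_tag", "round_index"]


def write_annotations(records: Iterable[AnnotationRecord], path: str | Path) -> None:
    """Write annotation records to a TSV with pipe-separated id lists."""
    rows = [
        {
            "series_id": r.series_id,
            "ctrl_ids": "|".join(sorted(r.ctrl_ids)),
            "pert_ids": "|".join(sorted(r.pert_ids)),
            "pert_type": r.pert_type.value,
            "cell_type": r.cell_type,
            "pert_name": r.pert_name,
            "annotator_tag": r.annotator_tag,
            "round_index": r.round_index,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=_ANN_COLUMNS).to_csv(path, sep="\t", index=False)


def read_annotations(path: str | Path) -> list[AnnotationRecord]:
    """Read an annotation TSV; inverse of :func:`write_annotations`.

    Raises :class:`AnnotationValidationError` on unknown ``pert_type`` tokens
    or rows violating the record invariants.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"series_id", "ctrl_ids", "pert_ids", "pert_type", "cell_type", "pert_name"}
    missing = required - set(df.columns)
    if missing:
        raise AnnotationValidationError(f"missing column(s): {', '.join(sorted(missing))}")
    out: list[AnnotationRecord] = []
    allowed = {t.value for t in PertType}
    for i, row in df.iterrows():
        if row["pert_type"] not in allowed:
            raise AnnotationValidationError(
                f"row {i}: unknown pert_type {row['pert_type']!r}; allowed values: "
                + ", ".join(sorted(allowed))
            )
        try:
            out.append(
                AnnotationRecord(
                    series_id=row["series_id"],
                    ctrl_ids=frozenset(x for x in row["ctrl_ids"].split("|") if x),
                    pert_ids=frozenset(x for x in row["pert_ids"].split("|") if x),
                    pert_type=PertType(row["pert_type"]),
                    cell_type=row["cell_type"],
                    pert_name=row["pert_name"],
                    annotator_tag=row.get("annotator_tag", ""),
                    round_index=int(row.get("round_index", 1) or 1),
                )
            )
        except ValueError as exc:
            raise AnnotationValidationError(f"row {i}: {exc}") from exc
    return out


def validate_annotation_against_series(annotation: AnnotationRecord, series: SeriesRecord) -> list[str]:
    """Return the annotation sample ids that do not exist in the series."""
    known = {s.sample_id for s in series.samples}
    return sorted((annotation.ctrl_ids | annotation.pert_ids) - known)


def series_to_json(series: SeriesRecord) -> str:
    """Stable JSON serialization of a series (sorted keys)."""
    return json.dumps(series.model_dump(), sort_keys=True)


def series_from_json(text: str) -> SeriesRecord:
    return SeriesRecord.model_validate(json.loads(text))
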