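"""Deterministic rule engine for the three annotation-quality criteria.

An experimental-design annotation passes quality control only when all
three criteria hold:

1. **Alignment** — every sample characteristic other than sex and age
   (expressly ignored) and the designated perturbation key is balanced
   between the control and perturbation groups (group-wise set equality of
   values).
2. **Uniformity** — samples of the same type are consolidated: no sample
   left out of the annotation shares the full non-ignored characteristic
   profile of an assigned sample, and neither group mixes distinct
   perturbation-key values.
3. **Perturbation assignment** — the perturbation type is one of
   drug/disease/gene, the perturbation name is non-empty and is actually
   found in the perturbation-group metadata, and the direction is right
   (the control group does not carry the perturbation).

A second, optional QC channel delegates the same judgement to a
language-model role; :func:`consensus_qc` arbitrates between channels the
way multi-round QC protocols do (two agreeing verdicts decide; a
disagreement demands a third verdict and majority rule).
"""

from __future__ import annotations

import enum
import json
from typing import Literal, Optional, Sequence

from pydantic import BaseModel, ConfigDict, model_validator

from .metadata_model import (
    DEFAULT_KEY_CLASSES,
    AnnotationRecord,
    KeyClasses,
    PertType,
    SampleRecord,
    SeriesRecord,
    normalize_characteristics,
    validate_annotation_against_series,
)

__all__ = [
    "Channel",
    "Grade",
    "ErrorCause",
    "ManualGrade",
    "QCVerdict",
    "ConsensusPendingError",
    "designate_perturbation_key",
    "qc_criterion_alignment",
    "qc_criterion_uniformity",
    "qc_criterion_perturbation",
    "run_rule_qc",
    "run_llm_qc",
    "consensus_qc",
]

_ABSENT = "<absent>"


class Channel(str, enum.Enum):
    rule = "rule"
    llm = "llm"
    manual = "manual"


class Grade(str, enum.Enum):
    """Manual QC grade: better than, equivalent to, or worse than a curator."""

    Excellent = "Excellent"
    Moderate = "Moderate"
    Error = "Error"


class ErrorCause(str, enum.Enum):
    multiple_disturbances = "multiple_disturbances"
    age_difference = "age_difference"
    name_inconsistency = "name_inconsistency"
    other = "other"


class ManualGrade(BaseModel):
    model_config = ConfigDict(frozen=True)

    grade: Grade
    cause: Optional[ErrorCause] = None

    @model_validator(mode="after")
    def _cause_only_on_error(self) -> "ManualGrade":
        if self.cause is not None and self.grade != Grade.Error:
            raise ValueError("cause may only accompany grade == Error")
        return self


class QCVerdict(BaseModel):
    """Success/Fail verdict for one annotation on one QC channel."""

    model_config = ConfigDict(frozen=True)

    series_id: str
    annotation_ref: str
    channel: Channel
    status: Literal["Success", "Fail"]
    criterion_alignment: bool = False
    criterion_uniformity: bool = False
    criterion_perturbation: bool = False
    reasons: tuple[str, ...] = ()
    manual_grade: Optional[ManualGrade] = None
    qc_round: int = 1

    @model_validator(mode="after")
    def _status_consistent(self) -> "QCVerdict":
        if self.channel in (Channel.rule, Channel.llm):
            all_ok = self.criterion_alignment and self.criterion_uniformity and self.criterion_perturbation
            if (self.status == "Success") != all_ok:
                raise ValueError("status must be Success iff all three criteria hold")
        elif self.manual_grade is None:
            raise ValueError("manual channel requires a manual_grade")
        return self


class ConsensusPendingError(RuntimeError):
    """Two verdicts disagree; a third QC round is required before consensus."""


def _grouped_samples(
    annotation: AnnotationRecord, series: SeriesRecord, key_classes: KeyClasses
) -> tuple[list[SampleRecord], list[SampleRecord], list[SampleRecord]]:
    norm = {s.sample_id: normalize_characteristics(s, key_classes) for s in series.samples}
    ctrl = [norm[i] for i in sorted(annotation.ctrl_ids)]
    pert = [norm[i] for i in sorted(annotation.pert_ids)]
    rest = [norm[i] for i in sorted(set(norm) - annotation.ctrl_ids - annotation.pert_ids)]
    return ctrl, pert, rest


def designate_perturbation_key(
    annotation: AnnotationRecord,
    series: SeriesRecord,
    override: Optional[str] = None,
    key_classes: KeyClasses = DEFAULT_KEY_CLASSES,
) -> Optional[str]:
    """Pick the characteristic key that encodes the perturbation itself.

    Synthetic corpora label the key explicitly (``override``).  Otherwise:
    the first key whose name or perturbation-group values mention the
    perturbation name; failing that, the unique key whose control and
    perturbation value sets are disjoint; failing that, ``None`` (criterion
    1 then ranges over all non-ignored keys and criterion 3 falls back to
    free-text search).
    """
    if override is not None:
        return override
    ctrl, pert, _ = _grouped_samples(annotation, series, key_classes)
    keys: list[str] = []
    for s in ctrl + pert:
        for k in s.characteristics:
            if k not in keys and not key_classes.is_ignored(k):
                keys.append(k)
    needle = annotation.pert_name.casefold()
    if needle:
        for k in keys:
            if needle in k:
                return k
            if any(needle in s.characteristics.get(k, "").casefold() for s in pert):
                return k
    separating = []
    for k in keys:
        cv = {s.characteristics.get(k, _ABSENT) for s in ctrl}
        pv = {s.characteristics.get(k, _ABSENT) for s in pert}
        if not cv & pv:
            separating.append(k)
    if len(separating) == 1:
        return separating[0]
    return None


def qc_criterion_alignment(
    annotation: AnnotationRecord,
    series: SeriesRecord,
    pert_key: Optional[str] = None,
    key_classes: KeyClasses = DEFAULT_KEY_CLASSES,
) -> tuple[bool, list[str]]:
    """Criterion 1: non-ignored characteristics balanced between groups.

    For every normalized key that is neither sex/age class nor the
    designated perturbation key, the set of values observed in the control
    group must equal the set observed in the perturbation group (sets, not
    multisets: replicate counts may legitimately differ).
    """
    ctrl, pert, _ = _grouped_samples(annotation, series, key_classes)
    keys = {k for s in ctrl + pert for k in s.characteristics}
    reasons = []
    for k in sorted(keys):
        if key_classes.is_ignored(k) or k == pert_key:
            continue
        cv = {s.characteristics.get(k, _ABSENT) for s in ctrl}
        pv = {s.characteristics.get(k, _ABSENT) for s in pert}
        if cv != pv:
            reasons.append(f"characteristic {k!r} differs between groups ({sorted(cv)} vs {sorted(pv)})")
    return not reasons, reasons


def _profile(sample: SampleRecord, keys: Sequence[str], key_classes: KeyClasses) -> tuple:
    return tuple((k, sample.characteristics.get(k, _ABSENT)) for k in keys if not key_classes.is_ignored(k))


def qc_criterion_uniformity(
    annotation: AnnotationRecord,
    series: SeriesRecord,
    pert_key: Optional[str] = None,
    key_classes: KeyClasses = DEFAULT_KEY_CLASSES,
) -> tuple[bool, list[str]]:
    """Criterion 2: same-type samples consolidated into a single group.

    Fails when an unassigned sample shares the full non-ignored
    characteristic profile of an assigned sample (that sample was split
    out of its group), or when either group mixes two distinct
    perturbation-key values (a mixed group can always be split, so mixing
    is never accepted).
    """
    ctrl, pert, rest = _grouped_samples(annotation, series, key_classes)
    keys = sorted({k for s in ctrl + pert + rest for k in s.characteristics})
    reasons = []
    assigned_profiles = {_profile(s, keys, key_classes) for s in ctrl + pert}
    for s in rest:
        if _profile(s, keys, key_classes) in assigned_profiles:
            reasons.append(f"sample {s.sample_id} left unassigned but matches an assigned group's profile")
    if pert_key is not None:
        for name, group in (("ctrl_ids", ctrl), ("pert_ids", pert)):
            vals = {s.characteristics.get(pert_key, _ABSENT) for s in group}
            if len(vals) > 1:
                reasons.append(f"{name} mixes distinct {pert_key!r} values: {sorted(vals)}")
    return not reasons, reasons


def qc_criterion_perturbation(
    annotation: AnnotationRecord,
    series: SeriesRecord,
    pert_key: Optional[str] = None,
    key_classes: KeyClasses = DEFAULT_KEY_CLASSES,
    synonyms: Optional[dict[str, Sequence[str]]] = None,
) -> tuple[bool, list[str]]:
    """Criterion 3: perturbation details correct and correctly directed.

    The perturbation name (or a configured synonym) must occur in the
    perturbation-group sample metadata, and must not occur as the control
    group's perturbation-key value (otherwise the groups are swapped).
    Matching is case-insensitive substring; deliberately no fuzzy matching,
    so name inconsistencies surface instead of being silently absorbed.
    """
    reasons = []
    if not isinstance(annotation.pert_type, PertType):
        reasons.append(f"invalid pert_type {annotation.pert_type!r}")
    needles = [annotation.pert_name.casefold()]
    if synonyms:
        needles.extend(s.casefold() for s in synonyms.get(annotation.pert_name, ()))
    needles = [n for n in needles if n]
    if not needles:
        reasons.append("empty pert_name")
        return False, reasons
    ctrl, pert, _ = _grouped_samples(annotation, series, key_classes)
    found = any(n in s.text_blob().casefold() for s in pert for n in needles)
    if not found:
        reasons.append(f"pert_name {annotation.pert_name!r} not found in perturbation-group metadata")
    if pert_key is not None:
        ctrl_vals = [s.characteristics.get(pert_key, "").casefold() for s in ctrl]
        if any(n in v for v in ctrl_vals for n in needles):
            reasons.append("direction: control group carries the perturbation")
    else:
        # free-text fallback: perturbation must not be better evidenced in controls
        ctrl_hits = sum(any(n in s.text_blob().casefold() for n in needles) for s in ctrl)
        pert_hits = sum(any(n in s.text_blob().casefold() for n in needles) for s in pert)
        if ctrl and ctrl_hits == len(ctrl) and pert_hits < len(pert):
            reasons.append("direction: control group carries the perturbation")
    return not reasons, reasons


def run_rule_qc(
    annotation: AnnotationRecord,
    series: SeriesRecord,
    pert_key: Optional[str] = None,
    key_classes: KeyClasses = DEFAULT_KEY_CLASSES,
    synonyms: Optional[dict[str, Sequence[str]]] = None,
    qc_round: int = 1,
) -> QCVerdict:
    """Evaluate all three criteria deterministically; Success iff all hold."""
    unknown = validate_annotation_against_series(annotation, series)
    if unknown:
        return QCVerdict(
            series_id=series.series_id,
            annotation_ref=annotation.key(),
            channel=Channel.rule,
            status="Fail",
            criterion_alignment=False,
            criterion_uniformity=False,
            criterion_perturbation=False,
            reasons=(f"unknown sample: {', '.join(unknown)}",),
            qc_round=qc_round,
        )
    key = designate_perturbation_key(annotation, series, override=pert_key, key_classes=key_classes)
    a_ok, a_reasons = qc_criterion_alignment(annotation, series, key, key_classes)
    u_ok, u_reasons = qc_criterion_uniformity(annotation, series, key, key_classes)
    p_ok, p_reasons = qc_criterion_perturbation(annotation, series, key, key_classes, synonyms)
    ok = a_ok and u_ok and p_ok
    return QCVerdict(
        series_id=series.series_id,
        annotation_ref=annotation.key(),
        channel=Channel.rule,
        status="Success" if ok else "Fail",
        criterion_alignment=a_ok,
        criterion_uniformity=u_ok,
        criterion_perturbation=p_ok,
        reasons=tuple(a_reasons + u_reasons + p_reasons),
        qc_round=qc_round,
    )


def run_llm_qc(
    annotation: AnnotationRecord,
    series: SeriesRecord,
    template,
    backend,
    pert_key: Optional[str] = None,
    qc_round: int = 1,
) -> QCVerdict:
    """Delegate the verdict to the quality-controller role of a backend.

    The role receives the full series metadata plus the annotation and must
    answer in the verdict JSON schema; one re-prompt retry is allowed, then
    the verdict is a Fail with reason "unparseable".
    """
    payload = {
        "series": series.model_dump(),
        "annotation": annotation.model_dump(),
        "pert_key": pert_key,
        "qc_round": qc_round,
    }
    for attempt in range(2):
        text = backend.complete(template, payload)
        try:
            obj = json.loads(text)
            status = obj["status"]
            if status not in ("Success", "Fail"):
                raise ValueError(status)
            verdict = QCVerdict(
                series_id=series.series_id,
                annotation_ref=annotation.key(),
                channel=Channel.llm,
                status=status,
                criterion_alignment=bool(obj["criterion_alignment"]),
                criterion_uniformity=bool(obj["criterion_uniformity"]),
                criterion_perturbation=bool(obj["criterion_perturbation"]),
                reasons=tuple(obj.get("reasons", ())),
                qc_round=qc_round,
            )
            backend.log[-1].parse_status = "ok"
            return verdict
        except (ValueError, KeyError, TypeError):
            backend.log[-1].parse_status = "failed"
            backend.log[-1].retry_count = attempt
    return QCVerdict(
        series_id=series.series_id,
        annotation_ref=annotation.key(),
        channel=Channel.llm,
        status="Fail",
        criterion_alignment=False,
        criterion_uniformity=False,
        criterion_perturbation=False,
        reasons=("unparseable",),
        qc_round=qc_round,
    )


def consensus_qc(verdicts: Sequence[QCVerdict]) -> QCVerdict:
    """Arbitrate 2–3 verdicts for one annotation.

    Two agreeing verdicts decide the status outright.  Two disagreeing
    verdicts raise :class:`ConsensusPendingError` demanding a third round;
    with three verdicts the majority status wins.  Reasons are concatenated
    across the contributing verdicts.
    """
    if len(verdicts) < 2:
        raise ValueError("consensus requires at least 2 verdicts")
    refs = {v.annotation_ref for v in verdicts}
    if len(refs) > 1:
        raise ValueError(f"verdicts reference different annotations: {sorted(refs)}")
    statuses = [v.status for v in verdicts]
    if len(verdicts) == 2 and statuses[0] != statuses[1]:
        raise ConsensusPendingError("two QC rounds disagree; a third round is required")
    majority = "Success" if statuses.count("Success") > statuses.count("Fail") else "Fail"
    reasons = tuple(r for v in verdicts for r in v.reasons)
    exemplar = next(v for v in verdicts if v.status == majority)
    return exemplar.model_copy(update={"reasons": reasons})
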