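"""Role-conditioned completion backends and structured-response parsing.

Every annotator / quality-control role converses through a backend that
takes a :class:`PromptTemplate` plus a structured payload and returns raw
text.  Two backends exist:

* :class:`MockBackend` — a deterministic, rule-based stand-in that lets the
  entire pipeline run offline.  It is a pure function of
  ``(template, payload, seed)``; its only sources of wrong answers are the
  explicit error-injection plan and the configured QC disagreement rate, so
  tests always know the ground truth.
* :class:`LiveBackend` — a thin OpenAI-compatible chat client (stdlib HTTP)
  with a retry limit; optional, never required by the pipeline.

Roles must answer in a fixed JSON schema; :func:`parse_annotation_response`
turns raw text into a validated record or a structured failure and never
raises on arbitrary input.
"""

from __future__ import annotations

import enum
import hashlib
import json
import re
import time
import urllib.request
from collections import Counter
from dataclasses import dataclass, field
from typing import Any, Mapping, Optional, Sequence, Union

from pydantic import BaseModel, ConfigDict

from .metadata_model import (
    DEFAULT_KEY_CLASSES,
    AnnotationRecord,
    KeyClasses,
    PertType,
    SampleRecord,
    SeriesRecord,
    normalize_characteristics,
)

__all__ = [
    "Role",
    "PromptTemplate",
    "ExchangeLogEntry",
    "ParseFailure",
    "BackendError",
    "Backend",
    "MockBackend",
    "LiveBackend",
    "DIRECTIVES",
    "parse_annotation_response",
    "parse_annotations_response",
    "mock_annotate",
    "CONTROL_TOKENS",
]


class Role(str, enum.Enum):
    original_annotator = "original_annotator"
    result_checker = "result_checker"
    prompt_optimizer = "prompt_optimizer"
    optimal_annotator = "optimal_annotator"
    quality_controller = "quality_controller"


#: Instruction-text directives the mock backend interprets as rule classes.
#: The prompt optimizer activates one of these to address the dominant
#: discrepancy field; appending a directive is what "editing the prompt"
#: means for the deterministic backend.
DIRECTIVES: dict[str, str] = {
    "dose_grouping": "Group each distinct perturbation value (e.g. each dose arm) as its own perturbation group.",
    "name_fidelity": "Report the perturbation name exactly as written in the sample characteristics.",
    "cell_type_extraction": "Extract the cell type verbatim from the sample characteristics.",
    "type_inference": "Infer the perturbation type (drug, disease, or gene) from the characteristic key naming.",
}


class PromptTemplate(BaseModel):
    """Versioned prompt for one role.

    ``version`` strictly increases along an optimization lineage; the mock
    backend gates its dose-aware grouping rules on ``version >= 1`` or on
    the explicit directive sentence in ``instruction_text``.
    """

    model_config = ConfigDict(frozen=True)

    role_name: Role
    system_text: str = ""
    instruction_text: str = ""
    few_shot_examples: tuple[tuple[str, str], ...] = ()
    version: int = 0

    def evolved(self, extra_instruction: str) -> "PromptTemplate":
        """Next-version template with ``extra_instruction`` appended."""
        new_text = (self.instruction_text + "\n" + extra_instruction).strip()
        return self.model_copy(update={"instruction_text": new_text, "version": self.version + 1})

    def active_rule_classes(self) -> frozenset[str]:
        active = {name for name, text in DIRECTIVES.items() if text in self.instruction_text}
        if self.version >= 1:
            active.add("dose_grouping")
        return frozenset(active)


@dataclass
class ExchangeLogEntry:
    """One backend call; the log is append-only, one entry per call."""

    timestamp: float
    call_index: int
    role_name: str
    payload_digest: str
    raw_response: str
    parse_status: str = "unparsed"
    retry_count: int = 0

    def to_json(self) -> str:
        return json.dumps(
            {
                "call_index": self.call_index,
                "role_name": self.role_name,
                "payload_digest": self.payload_digest,
                "parse_status": self.parse_status,
                "retry_count": self.retry_count,
                "raw_response": self.raw_response,
            },
            sort_keys=True,
        )


@dataclass
class ParseFailure:
    """Structured parse failure carrying the offending fragment."""

    reason: str
    fragment: str = ""


class BackendError(RuntimeError):
    """Transport failure after exhausting the retry limit."""


def _digest(payload: Mapping[str, Any]) -> str:
    return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()


def _stable_uniform(*parts: object) -> float:
    """Deterministic uniform(0,1) draw from a tuple of hashable parts."""
    h = hashlib.sha256("\x1f".join(str(p) for p in parts).encode()).digest()
    return int.from_bytes(h[:8], "big") / 2**64


class Backend:
    """Completion contract: ``complete(template, payload) -> raw text``.

    Subclasses implement ``_transport``; the base class owns logging."""

    def __init__(self) -> None:
        self.log: list[ExchangeLogEntry] = []

    def complete(self, template: PromptTemplate, payload: Mapping[str, Any]) -> str:
        response, retries = self._transport(template, payload)
        self.log.append(
            ExchangeLogEntry(
                timestamp=time.time(),
                call_index=len(self.log),
                role_name=template.role_name.value,
                payload_digest=_digest(payload),
                raw_response=response,
                retry_count=retries,
            )
        )
        return response

    def _transport(self, template: PromptTemplate, payload: Mapping[str, Any]) -> tuple[str, int]:
        raise NotImplementedError


class MockBackend(Backend):
    """Deterministic rule-based backend; the offline test double for every role.

    Parameters
    ----------
    seed:
        Drives every stochastic knob (QC disagreement draws).  Identical
        ``(template, payload, seed)`` triples give byte-identical responses.
    qc_disagreement_rate:
        Probability that the mock quality-controller role flips the rule
        verdict for an annotation (Bernoulli per annotation, derived from
        the seed and the annotation reference, so it is order-invariant).
    error_plan:
        Mapping ``series_id -> error class`` (``"swap"`` or
        ``"name_inconsistency"``); the only source of wrong annotator answers.
    """

    def __init__(
        self,
        seed: int = 0,
        qc_disagreement_rate: float = 0.0,
        error_plan: Optional[Mapping[str, str]] = None,
        key_classes: KeyClasses = DEFAULT_KEY_CLASSES,
    ) -> None:
        super().__init__()
        if not 0.0 <= qc_disagreement_rate <= 1.0:
            raise ValueError("qc_disagreement_rate must be in [0, 1]")
        self.seed = seed
        self.qc_disagreement_rate = qc_disagreement_rate
        self.error_plan = dict(error_plan or {})
        self.key_classes = key_classes

    def _transport(self, template: PromptTemplate, payload: Mapping[str, Any]) -> tuple[str, int]:
        role = template.role_name
        if role in (Role.original_annotator, Role.optimal_annotator):
            series = SeriesRecord.model_validate(payload["series"])
            error_class = self.error_plan.get(series.series_id)
            return mock_annotate(series, template, self.seed, error_class=error_class, key_classes=self.key_classes), 0
        if role == Role.quality_controller:
            return self._qc_response(payload), 0
        # checker/optimizer roles are computed locally in the workflow; echo.
        return json.dumps({"ack": template.role_name.value}, sort_keys=True), 0

    def _qc_response(self, payload: Mapping[str, Any]) -> str:
        from . import quality_controller as qc  # local import avoids a cycle

        series = SeriesRecord.model_validate(payload["series"])
        annotation = AnnotationRecord.model_validate(payload["annotation"])
        rule = qc.run_rule_qc(annotation, series, pert_key=payload.get("pert_key"), key_classes=self.key_classes)
        draw = _stable_uniform(self.seed, "llm-qc", annotation.key(), payload.get("qc_round", 1))
        flip = draw < self.qc_disagreement_rate
        success = (rule.status == "Success") ^ flip
        if success:
            crits = {"criterion_alignment": True, "criterion_uniformity": True, "criterion_perturbation": True}
            reasons: list[str] = [] if not flip else ["mock disagreement: forced Success"]
        elif flip:
            crits = {"criterion_alignment": False, "criterion_uniformity": True, "criterion_perturbation": True}
            reasons = ["mock disagreement: forced Fail"]
        else:
            crits = {
                "criterion_alignment": rule.criterion_alignment,
                "criterion_uniformity": rule.criterion_uniformity,
                "criterion_perturbation": rule.criterion_perturbation,
            }
            reasons = list(rule.reasons)
        return json.dumps(
            {"status": "Success" if success else "Fail", "reasons": reasons, **crits},
            sort_keys=True,
        )


class LiveBackend(Backend):
    """Minimal OpenAI-compatible chat-completions client with bounded retries.

    Offline pipelines never need this class; it exists so a configured
    endpoint can replace the mock without touching any other module.
    """

    def __init__(self, endpoint: str, model: str, api_key: str = "", retry_limit: int = 2, timeout: float = 60.0) -> None:
        super().__init__()
        self.endpoint = endpoint
        self.model = model
        self.api_key = api_key
        self.retry_limit = retry_limit
        self.timeout = timeout

    def _transport(self, template: PromptTemplate, payload: Mapping[str, Any]) -> tuple[str, int]:
        body = json.dumps(
            {
                "model": self.model,
                "temperature": 0,
                "messages": [
                    {"role": "system", "content": template.system_text},
                    {
                        "role": "user",
                        "content": template.instruction_text + "\n\n" + json.dumps(payload, default=str),
                    },
                ],
            }
        ).encode()
        last_error: Optional[Exception] = None
        for attempt in range(self.retry_limit + 1):
            try:
                req = urllib.request.Request(
                    self.endpoint,
                    data=body,
                    headers={"Content-Type": "application/json", "Authorization": f"Bearer {self.api_key}"},
                )
                with urllib.request.urlopen(req, timeout=self.timeout) as resp:
                    data = json.loads(resp.read().decode())
                return data["choices"][0]["message"]["content"], attempt
            except Exception as exc:  # noqa: BLE001 - any transport error triggers retry
                last_error = exc
        raise BackendError(f"transport failed after {self.retry_limit + 1} attempt(s): {last_error}")


# ---------------------------------------------------------------------------
# Structured-response parsing
# ---------------------------------------------------------------------------

def _extract_json(text: str) -> Optional[Any]:
    """First balanced JSON value embedded in ``text``, or None."""
    decoder = json.JSONDecoder()
    for m in re.finditer(r"[{\[]", text):
        try:
            obj, _ = decoder.raw_decode(text, m.start())
            return obj
        except ValueError:
            continue
    return None


def _record_from_obj(obj: Any) -> Union[AnnotationRecord, ParseFailure]:
    if not isinstance(obj, dict):
        return ParseFailure("annotation is not a JSON object", json.dumps(obj)[:200])
    missing = [f for f in ("series_id", "ctrl_ids", "pert_ids", "pert_type", "pert_name") if f not in obj]
    if missing:
        return ParseFailure(f"missing required field(s): {', '.join(missing)}", json.dumps(obj)[:200])
    if obj["pert_type"] not in {t.value for t in PertType}:
        return ParseFailure(
            f"unknown pert_type {obj['pert_type']!r}; allowed: drug, disease, gene", json.dumps(obj)[:200]
        )
    ctrl, pert = frozenset(obj["ctrl_ids"]), frozenset(obj["pert_ids"])
    if ctrl & pert:
        return ParseFailure("overlapping groups", ",".join(sorted(ctrl & pert)))
    try:
        return AnnotationRecord(
            series_id=str(obj["series_id"]),
            ctrl_ids=ctrl,
            pert_ids=pert,
            pert_type=PertType(obj["pert_type"]),
            pert_name=str(obj["pert_name"]),
            cell_type=str(obj.get("cell_type", "")),
            annotator_tag=str(obj.get("annotator_tag", "")),
            round_index=int(obj.get("round_index", 1)),
        )
    except (ValueError, TypeError) as exc:
        return ParseFailure(str(exc), json.dumps(obj)[:200])


def parse_annotation_response(text: str) -> Union[AnnotationRecord, ParseFailure]:
    """Parse one annotation from raw response text; total (never raises)."""
    results = parse_annotations_response(text)
    for r in results:
        if isinstance(r, AnnotationRecord):
            return r
    return results[0] if results else ParseFailure("no JSON object found", text[:200])


def parse_annotations_response(text: str) -> list[Union[AnnotationRecord, ParseFailure]]:
    """Parse an annotation response that may carry several design calls.

    Accepts a bare object, a JSON array, or an ``{"annotations": [...]}``
    envelope.  Each element is validated independently; invalid elements
    become :class:`ParseFailure` entries rather than exceptions.
    """
    if not isinstance(text, str):
        return [ParseFailure("response is not text")]
    obj = _extract_json(text)
    if obj is None:
        return [ParseFailure("no JSON object found", text[:200])]
    if isinstance(obj, dict) and "annotations" in obj:
        obj = obj["annotations"]
    items = obj if isinstance(obj, list) else [obj]
    if not items:
        return [ParseFailure("empty annotation list", text[:200])]
    return [_record_from_obj(item) for item in items]


# ---------------------------------------------------------------------------
# Mock annotator rules
# ---------------------------------------------------------------------------

#: Characteristic values recognized as control-arm markers.
CONTROL_TOKENS = frozenset(
    {
        "vehicle", "control", "untreated", "none", "mock", "dmso", "pbs",
        "placebo", "healthy", "normal", "wild type", "wt", "scramble", "baseline",
    }
)

_KEY_TYPE_HINTS: tuple[tuple[tuple[str, ...], PertType], ...] = (
    (("genotype", "transfection", "knockdown", "variation", "gene"), PertType.gene),
    (("disease", "diagnosis", "condition"), PertType.disease),
    (("treatment", "agent", "compound", "drug", "dose"), PertType.drug),
)

_DOSE_SUFFIX = re.compile(r"\s+\d+(?:\.\d+)?\s*(?:mg|ug|µg|ng|nm|um|µm|mm)(?:/\S+)?\s*$", re.IGNORECASE)


def _strip_dose(value: str) -> str:
    return _DOSE_SUFFIX.sub("", value).strip()


def _infer_pert_type(key: str) -> PertType:
    for hints, ptype in _KEY_TYPE_HINTS:
        if any(h in key for h in hints):
            return ptype
    return PertType.drug


def _cell_type_of(samples: Sequence[SampleRecord]) -> str:
    for key in ("cell line", "cell type", "cell"):
        vals = {s.characteristics[key] for s in samples if key in s.characteristics}
        if len(vals) == 1:
            return next(iter(vals))
    return ""


def mock_annotate(
    series: SeriesRecord,
    template: PromptTemplate,
    seed: int = 0,
    error_class: Optional[str] = None,
    key_classes: KeyClasses = DEFAULT_KEY_CLASSES,
) -> str:
    """Deterministic rule-based annotation of a series, emitted as JSON text.

    The annotator scans normalized characteristics for the first
    non-ignored key that both varies across samples and contains a
    control-like value (``CONTROL_TOKENS``); control samples form
    ``ctrl_ids`` and the rest ``pert_ids``.  With the ``dose_grouping``
    rule class inactive (template version 0, no directive) all perturbed
    samples are merged into a single group — the planted "dose-blind"
    deficiency that prompt optimization repairs.  With it active, each
    distinct perturbation value becomes its own design call.

    ``error_class`` injects the documented failure modes: ``"swap"``
    exchanges the two groups, ``"name_inconsistency"`` rewrites the
    perturbation name to a token absent from the metadata.  A series with
    no partitioning key yields one deliberately ungrounded annotation
    (arbitrary split, perturbation name "unknown") that downstream QC
    rejects.
    """
    samples = [normalize_characteristics(s, key_classes) for s in series.samples]
    rules = template.active_rule_classes()

    # ordered key scan: first appearance across samples
    keys: list[str] = []
    for s in samples:
        for k in s.characteristics:
            if k not in keys:
                keys.append(k)

    pert_key = None
    for k in keys:
        if key_classes.is_ignored(k):
            continue
        values = [s.characteristics.get(k) for s in samples]
        present = [v for v in values if v is not None]
        if len(set(present)) < 2:
            continue
        if any(v.casefold() in CONTROL_TOKENS for v in present):
            pert_key = k
            break

    annotations: list[dict[str, Any]] = []
    if pert_key is None:
        ids = [s.sample_id for s in samples]
        annotations.append(
            {
                "series_id": series.series_id,
                "ctrl_ids": sorted(ids[:1]),
                "pert_ids": sorted(ids[1:]),
                "pert_type": "drug",
                "pert_name": "unknown",
                "cell_type": _cell_type_of(samples),
            }
        )
    else:
        ctrl = [s.sample_id for s in samples if s.characteristics.get(pert_key, "").casefold() in CONTROL_TOKENS]
        pert_samples = [
            s
            for s in samples
            if pert_key in s.characteristics and s.characteristics[pert_key].casefold() not in CONTROL_TOKENS
        ]
        ptype = _infer_pert_type(pert_key)
        cell = _cell_type_of(samples)
        if "dose_grouping" in rules:
            groups: dict[str, list[str]] = {}
            for s in pert_samples:
                groups.setdefault(s.characteristics[pert_key], []).append(s.sample_id)
            for value in sorted(groups):
                annotations.append(
                    {
                        "series_id": series.series_id,
                        "ctrl_ids": sorted(ctrl),
                        "pert_ids": sorted(groups[value]),
                        "pert_type": ptype.value,
                        "pert_name": _strip_dose(value).casefold(),
                        "cell_type": cell,
                    }
                )
        else:
            counts = Counter(s.characteristics[pert_key] for s in pert_samples)
            top = min(sorted(counts), key=lambda v: (-counts[v], v)) if counts else ""
            annotations.append(
                {
                    "series_id": series.series_id,
                    "ctrl_ids": sorted(ctrl),
                    "pert_ids": sorted(s.sample_id for s in pert_samples),
                    "pert_type": ptype.value,
                    "pert_name": _strip_dose(top).casefold(),
                    "cell_type": cell,
                }
            )

    if error_class == "swap":
        for ann in annotations:
            ann["ctrl_ids"], ann["pert_ids"] = ann["pert_ids"], ann["ctrl_ids"]
    elif error_class == "name_inconsistency":
        for ann in annotations:
            ann["pert_name"] = ann["pert_name"] + " hydrochloride"

    return json.dumps({"annotations": annotations}, sort_keys=True)
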