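"""Staged annotation workflow with a prompt-optimization feedback loop.

The stages mirror a waterfall data flow with one negative-feedback loop:

1. an annotator role pre-annotates training series;
2. a checker compares the annotations to a gold standard and emits
   field-level discrepancies;
3. a prompt optimizer turns the dominant discrepancy class into a template
   revision, and the loop repeats until the annotations are concordant (or
   an iteration budget is exhausted) — the surviving template is the
   *optimal annotator*;
4. the optimal annotator sweeps the production corpus; every annotation is
   quality-controlled on the configured channels, and annotations whose QC
   channels disagree get exactly one re-annotation round before a
   consensus verdict.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .evaluation_metrics import MetricsReport, build_metrics_report
from .llm_backend import (
    Backend,
    BackendError,
    DIRECTIVES,
    ParseFailure,
    PromptTemplate,
    Role,
    parse_annotations_response,
)
from .metadata_model import AnnotationRecord, SeriesRecord
from .quality_controller import (
    Channel,
    ConsensusPendingError,
    QCVerdict,
    consensus_qc,
    run_llm_qc,
    run_rule_qc,
)

__all__ = [
    "DiscrepancyField",
    "Discrepancy",
    "TrainingHistory",
    "AnnotationOutcome",
    "RunReport",
    "default_annotator_template",
    "default_qc_template",
    "annotate_series",
    "check_against_gold",
    "optimize_prompt",
    "train_optimal_annotator",
    "run_waterfall",
]


class DiscrepancyField(str, enum.Enum):
    ctrl_ids = "ctrl_ids"
    pert_ids = "pert_ids"
    pert_type = "pert_type"
    pert_name = "pert_name"
    cell_type = "cell_type"
    grouping = "grouping"


@dataclass(frozen=True)
class Discrepancy:
    """One field-level disagreement between an annotation and its gold match."""

    series_id: str
    field: DiscrepancyField
    expected: str
    observed: str


@dataclass
class IterationRecord:
    template_version: int
    n_discrepancies: int
    discrepancy_rate: float


@dataclass
class TrainingHistory:
    iterations: list[IterationRecord]
    converged: bool
    final_template: PromptTemplate


@dataclass
class AnnotationOutcome:
    """Final state of one design call after QC and (possibly) re-annotation."""

    annotation: AnnotationRecord
    verdicts: list[QCVerdict]
    final_status: str
    reannotated: bool = False


@dataclass
class RunReport:
    annotations: list[AnnotationRecord]
    outcomes: list[AnnotationOutcome]
    failures: list[tuple[str, str]]  # (series_id, reason)
    metrics: MetricsReport

    def to_json(self) -> str:
        """Deterministic JSON serialization (stable key and record order)."""
        payload = {
            "annotations": [json.loads(a.model_dump_json()) for a in self.annotations],
            "outcomes": [
                {
                    "annotation_ref": o.annotation.key(),
                    "round_index": o.annotation.round_index,
                    "final_status": o.final_status,
                    "reannotated": o.reannotated,
                    "verdicts": [json.loads(v.model_dump_json()) for v in o.verdicts],
                }
                for o in self.outcomes
            ],
            "failures": self.failures,
            "metrics": self.metrics.to_dict(),
        }
        return json.dumps(payload, sort_keys=True, indent=1)


def default_annotator_template(role: Role = Role.original_annotator, version: int = 0) -> PromptTemplate:
    """Baseline annotator prompt (functional stand-in; the mock interprets it)."""
    return PromptTemplate(
        role_name=role,
        system_text="You curate gene-expression series metadata into control/perturbation designs.",
        instruction_text=(
            "Read the series and per-sample characteristics. Identify control and perturbed "
            "samples and answer with a JSON object {\"annotations\": [...]} where each item has "
            "series_id, ctrl_ids, pert_ids, pert_type (drug|disease|gene), pert_name, cell_type."
        ),
        version=version,
    )


def default_qc_template() -> PromptTemplate:
    return PromptTemplate(
        role_name=Role.quality_controller,
        system_text="You check annotation quality against three criteria.",
        instruction_text=(
            "Verify characteristic alignment (ignore sex and age), grouping uniformity, and "
            "perturbation assignment. Answer with JSON: status, criterion_alignment, "
            "criterion_uniformity, criterion_perturbation, reasons."
        ),
    )


def annotate_series(
    series: SeriesRecord, template: PromptTemplate, backend: Backend, round_index: int = 1
) -> tuple[list[AnnotationRecord], list[ParseFailure]]:
    """Annotate one series; unparseable responses are recorded, not raised.

    A fully unparseable response is re-prompted once; on persistent failure
    the failures list carries the structured reason.  Backend errors
    propagate with the series identifier attached.
    """
    payload = {"series": series.model_dump(), "round_index": round_index}
    records: list[AnnotationRecord] = []
    failures: list[ParseFailure] = []
    for attempt in range(2):
        try:
            text = backend.complete(template, payload)
        except BackendError as exc:
            raise BackendError(f"series {series.series_id}: {exc}") from exc
        parsed = parse_annotations_response(text)
        records = [
            p.model_copy(update={"round_index": round_index, "annotator_tag": f"{template.role_name.value}/v{template.version}"})
            for p in parsed
            if isinstance(p, AnnotationRecord)
        ]
        failures = [p for p in parsed if isinstance(p, ParseFailure)]
        backend.log[-1].parse_status = "ok" if records else "failed"
        backend.log[-1].retry_count = attempt
        if records:
            break
    return records, failures


def _jaccard(a: frozenset[str], b: frozenset[str]) -> float:
    return len(a & b) / len(a | b) if a | b else 0.0


def _sig(ann: AnnotationRecord) -> str:
    return "ctrl={};pert={}".format(",".join(sorted(ann.ctrl_ids)), ",".join(sorted(ann.pert_ids)))


def check_against_gold(
    annotations: Sequence[AnnotationRecord], gold: Sequence[AnnotationRecord]
) -> list[Discrepancy]:
    """Compare annotations to gold records; empty list iff fully concordant.

    Each annotation is paired to the gold record maximizing Jaccard
    similarity of its combined sample-id set (ties: pert_name equality,
    then gold order).  A ctrl/pert swap is one conceptual error and emits a
    single ``grouping`` discrepancy rather than two id-set ones.  Gold
    records left unmatched, and annotations matching no gold, are
    ``grouping`` discrepancies too.
    """
    if not gold:
        raise ValueError("gold standard is empty for this series")
    out: list[Discrepancy] = []
    matched_gold: set[int] = set()
    for ann in annotations:
        scored = sorted(
            range(len(gold)),
            key=lambda i: (
                -_jaccard(ann.ctrl_ids | ann.pert_ids, gold[i].ctrl_ids | gold[i].pert_ids),
                gold[i].pert_name.casefold() != ann.pert_name.casefold(),
                i,
            ),
        )
        gi = scored[0]
        g = gold[gi]
        if _jaccard(ann.ctrl_ids | ann.pert_ids, g.ctrl_ids | g.pert_ids) == 0.0:
            out.append(Discrepancy(ann.series_id, DiscrepancyField.grouping, "any gold design", _sig(ann)))
            continue
        matched_gold.add(gi)
        if ann.ctrl_ids == g.pert_ids and ann.pert_ids == g.ctrl_ids:
            out.append(Discrepancy(ann.series_id, DiscrepancyField.grouping, _sig(g), _sig(ann) + " (swapped)"))
        else:
            if ann.ctrl_ids != g.ctrl_ids:
                out.append(
                    Discrepancy(
                        ann.series_id,
                        DiscrepancyField.ctrl_ids,
                        ",".join(sorted(g.ctrl_ids)),
                        ",".join(sorted(ann.ctrl_ids)),
                    )
                )
            if ann.pert_ids != g.pert_ids:
                out.append(
                    Discrepancy(
                        ann.series_id,
                        DiscrepancyField.pert_ids,
                        ",".join(sorted(g.pert_ids)),
                        ",".join(sorted(ann.pert_ids)),
                    )
                )
        if ann.pert_type != g.pert_type:
            out.append(Discrepancy(ann.series_id, DiscrepancyField.pert_type, g.pert_type.value, ann.pert_type.value))
        if ann.pert_name.casefold() != g.pert_name.casefold():
            out.append(Discrepancy(ann.series_id, DiscrepancyField.pert_name, g.pert_name, ann.pert_name))
        if ann.cell_type.casefold() != g.cell_type.casefold():
            out.append(Discrepancy(ann.series_id, DiscrepancyField.cell_type, g.cell_type, ann.cell_type))
    for gi, g in enumerate(gold):
        if gi not in matched_gold:
            out.append(Discrepancy(g.series_id, DiscrepancyField.grouping, _sig(g), "missing annotation"))
    return out


#: Which instruction directive repairs which discrepancy field.
_FIELD_TO_DIRECTIVE = {
    DiscrepancyField.grouping: DIRECTIVES["dose_grouping"],
    DiscrepancyField.ctrl_ids: DIRECTIVES["dose_grouping"],
    DiscrepancyField.pert_ids: DIRECTIVES["dose_grouping"],
    DiscrepancyField.pert_name: DIRECTIVES["name_fidelity"],
    DiscrepancyField.cell_type: DIRECTIVES["cell_type_extraction"],
    DiscrepancyField.pert_type: DIRECTIVES["type_inference"],
}

_FIELD_PRIORITY = list(DiscrepancyField)


def optimize_prompt(template: PromptTemplate, discrepancies: Sequence[Discrepancy]) -> PromptTemplate:
    """Revise the template to address the most frequent discrepancy field.

    Returns a template with version incremented by exactly one and the
    directive for the majority field appended to the instruction text (the
    deterministic analogue of an optimizer role proposing a prompt edit).
    """
    if not discrepancies:
        raise ValueError("optimize_prompt requires a non-empty discrepancy list")
    counts: dict[DiscrepancyField, int] = {}
    for d in discrepancies:
        counts[d.field] = counts.get(d.field, 0) + 1
    majority = max(counts, key=lambda f: (counts[f], -_FIELD_PRIORITY.index(f)))
    return template.evolved(_FIELD_TO_DIRECTIVE[majority])


def train_optimal_annotator(
    corpus: Sequence[tuple[SeriesRecord, Sequence[AnnotationRecord]]],
    template0: PromptTemplate,
    backend: Backend,
    max_iters: int = 5,
    target_rate: float = 0.0,
) -> TrainingHistory:
    """Iterate annotate → check → optimize until concordance with gold.

    The discrepancy rate is the total discrepancy count divided by the
    number of gold design calls.  ``max_iters`` bounds the number of
    prompt revisions; the history records every evaluated template.
    """
    if not corpus:
        raise ValueError("training corpus is empty")
    if max_iters < 0:
        raise ValueError("max_iters must be >= 0")
    n_gold = sum(len(gold) for _, gold in corpus)
    template = template0
    history: list[IterationRecord] = []
    converged = False
    for iteration in range(max_iters + 1):
        all_disc: list[Discrepancy] = []
        for series, gold in corpus:
            anns, _ = annotate_series(series, template, backend)
            all_disc.extend(check_against_gold(anns, gold))
        rate = len(all_disc) / n_gold
        history.append(IterationRecord(template.version, len(all_disc), rate))
        if rate <= target_rate:
            converged = True
            break
        if iteration == max_iters:
            break
        template = optimize_prompt(template, all_disc)
    return TrainingHistory(iterations=history, converged=converged, final_template=template)


def run_waterfall(
    corpus: Sequence[SeriesRecord],
    optimal: PromptTemplate,
    backend: Backend,
    qc_channels: Sequence[str] = ("rule", "llm"),
    qc_template: Optional[PromptTemplate] = None,
    pert_keys: Optional[Mapping[str, str]] = None,
    error_labels: Optional[Mapping[str, str]] = None,
) -> RunReport:
    """Annotate a corpus, QC every annotation, re-annotate on disagreement.

    With both QC channels configured, an annotation whose rule and LLM
    verdicts disagree in round 1 is re-annotated exactly once; the round-2
    verdicts decide, with a third QC draw arbitrating if they disagree
    again.  Per-series failures are logged and skipped, never fatal for the
    run.  With the mock backend and a fixed seed the report is
    byte-identical across invocations.
    """
    qc_template = qc_template or default_qc_template()
    pert_keys = pert_keys or {}
    annotations: list[AnnotationRecord] = []
    outcomes: list[AnnotationOutcome] = []
    failures: list[tuple[str, str]] = []
    use_llm = "llm" in qc_channels
    use_rule = "rule" in qc_channels

    for series in corpus:
        if len(series.samples) < 2:
            failures.append((series.series_id, "fewer than 2 samples"))
            continue
        try:
            anns, parse_failures = annotate_series(series, optimal, backend, round_index=1)
        except BackendError as exc:
            failures.append((series.series_id, str(exc)))
            continue
        for pf in parse_failures:
            failures.append((series.series_id, f"unparseable annotation: {pf.reason}"))
        for ann in anns:
            annotations.append(ann)
            pk = pert_keys.get(series.series_id)
            verdicts: list[QCVerdict] = []
            if use_rule:
                verdicts.append(run_rule_qc(ann, series, pert_key=pk))
            if use_llm:
                verdicts.append(run_llm_qc(ann, series, qc_template, backend, pert_key=pk, qc_round=1))
            if len(verdicts) == 2 and verdicts[0].status != verdicts[1].status:
                # disagreement: one re-annotation round, then consensus
                re_anns, _ = annotate_series(series, optimal, backend, round_index=2)
                re_ann = _best_match(ann, re_anns) or ann.model_copy(update={"round_index": 2})
                annotations.append(re_ann)
                r2 = [
                    run_rule_qc(re_ann, series, pert_key=pk, qc_round=2),
                    run_llm_qc(re_ann, series, qc_template, backend, pert_key=pk, qc_round=2),
                ]
                try:
                    final = consensus_qc(r2)
                except ConsensusPendingError:
                    r3 = run_llm_qc(re_ann, series, qc_template, backend, pert_key=pk, qc_round=3)
                    final = consensus_qc(r2 + [r3])
                    r2 = r2 + [r3]
                outcomes.append(
                    AnnotationOutcome(
                        annotation=re_ann,
                        verdicts=verdicts + r2,
                        final_status=final.status,
                        reannotated=True,
                    )
                )
            else:
                outcomes.append(
                    AnnotationOutcome(annotation=ann, verdicts=verdicts, final_status=verdicts[0].status)
                )

    metrics = build_metrics_report(outcomes, error_labels=error_labels)
    return RunReport(annotations=annotations, outcomes=outcomes, failures=failures, metrics=metrics)


def _best_match(ann: AnnotationRecord, candidates: Sequence[AnnotationRecord]) -> Optional[AnnotationRecord]:
    if not candidates:
        return None
    return max(
        candidates,
        key=lambda c: (_jaccard(ann.ctrl_ids | ann.pert_ids, c.ctrl_ids | c.pert_ids), c.pert_name == ann.pert_name),
    )
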