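"""Consistency and pass-rate metrics for the annotation pipeline.

Three headline proportions summarize a run:

* **QCC** (quality-control consistency) — fraction of annotations whose two
  QC channels agree on the final status;
* **APR** (annotation pass rate) — fraction of annotations whose final
  status is Success;
* **DPR** (dataset pass rate) — fraction of datasets with at least one
  passing annotation (a dataset passes with one conforming design call).

The manual-grade cross-tabulation compares a curator's three-level grade
(Excellent / Moderate / Error) against the automatic Success/Fail verdict;
{Excellent, Moderate} agreeing with Success and Error agreeing with Fail
count as consistent — an Error/Fail cell means the controller correctly
caught a bad grouping.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Any, Mapping, Optional, Sequence

from .quality_controller import Grade, ManualGrade, QCVerdict

__all__ = [
    "UndefinedMetricError",
    "MetricsReport",
    "compute_qcc",
    "compute_apr",
    "compute_dpr",
    "crosstab_grades",
    "error_cause_report",
    "build_metrics_report",
]


class UndefinedMetricError(ValueError):
    """A proportion over an empty denominator; raised rather than reported 0."""


def compute_qcc(pairs: Sequence[tuple[QCVerdict, QCVerdict]]) -> float:
    """Proportion of verdict pairs agreeing on status.

    Each pair must reference the same annotation; consistency compares the
    final status only, not the per-criterion flags.
    """
    if not pairs:
        raise UndefinedMetricError("QCC undefined: no verdict pairs")
    agree = 0
    for a, b in pairs:
        if a.annotation_ref != b.annotation_ref:
            raise ValueError(f"pair references different annotations: {a.annotation_ref} vs {b.annotation_ref}")
        agree += a.status == b.status
    return agree / len(pairs)


def compute_apr(verdicts: Sequence[QCVerdict]) -> float:
    """Proportion of annotations whose verdict is Success."""
    if not verdicts:
        raise UndefinedMetricError("APR undefined: no verdicts")
    return sum(v.status == "Success" for v in verdicts) / len(verdicts)


def compute_dpr(by_dataset: Mapping[str, Sequence[QCVerdict]]) -> float:
    """Proportion of datasets with at least one Success verdict."""
    if not by_dataset:
        raise UndefinedMetricError("DPR undefined: no datasets")
    passing = sum(any(v.status == "Success" for v in vs) for vs in by_dataset.values())
    return passing / len(by_dataset)


def crosstab_grades(
    manual: Sequence[ManualGrade], auto: Sequence[QCVerdict]
) -> tuple[dict[tuple[Grade, str], int], float]:
    """3×2 manual-grade vs automatic-status table plus the consistency fraction.

    Agreement convention: (Excellent|Moderate, Success) and (Error, Fail)
    are the two consistent cells.
    """
    if len(manual) != len(auto):
        raise ValueError(f"length mismatch: {len(manual)} manual grades vs {len(auto)} verdicts")
    if not manual:
        raise UndefinedMetricError("crosstab undefined: no annotations")
    table: dict[tuple[Grade, str], int] = {(g, s): 0 for g in Grade for s in ("Success", "Fail")}
    consistent = 0
    for m, v in zip(manual, auto):
        table[(m.grade, v.status)] += 1
        if (m.grade in (Grade.Excellent, Grade.Moderate)) == (v.status == "Success"):
            consistent += 1
    return table, consistent / len(manual)


def error_cause_report(
    failed: Sequence[Any], labels: Optional[Mapping[str, str]] = None
) -> dict[str, int]:
    """Count injected error causes among failed annotations.

    ``failed`` holds objects exposing ``series_id`` (annotations or
    verdicts); ``labels`` maps series id to the generator's cause class.
    Without labels (real data) the report carries only an ``unlabeled``
    marker, never fabricated counts.
    """
    if labels is None:
        return {"unlabeled": len(failed)} if failed else {}
    counts: Counter[str] = Counter()
    for item in failed:
        cause = labels.get(item.series_id)
        if cause is not None:
            counts[cause] += 1
    return dict(sorted(counts.items()))


@dataclass
class MetricsReport:
    """Aggregated run metrics; proportions are None when undefined."""

    qcc: Optional[float]
    apr: float
    dpr: float
    n_annotations: int
    n_datasets: int
    per_round: dict[int, tuple[int, float]] = field(default_factory=dict)
    crosstab: dict[tuple[Grade, str], int] = field(default_factory=dict)
    consistency: Optional[float] = None
    error_causes: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        return {
            "qcc": self.qcc,
            "apr": self.apr,
            "dpr": self.dpr,
            "n_annotations": self.n_annotations,
            "n_datasets": self.n_datasets,
            "per_round": {str(r): {"n": n, "apr": apr} for r, (n, apr) in sorted(self.per_round.items())},
            "crosstab": {f"{g.value}|{s}": c for (g, s), c in sorted(self.crosstab.items(), key=lambda kv: (kv[0][0].value, kv[0][1]))},
            "consistency": self.consistency,
            "error_causes": dict(sorted(self.error_causes.items())),
        }

    def to_text(self) -> str:
        lines = [
            f"annotations: {self.n_annotations}   datasets: {self.n_datasets}",
            f"QCC: {self.qcc:.4f}" if self.qcc is not None else "QCC: n/a (single channel)",
            f"APR: {self.apr:.4f}",
            f"DPR: {self.dpr:.4f}",
        ]
        for r, (n, apr) in sorted(self.per_round.items()):
            lines.append(f"round {r}: n={n} APR={apr:.4f}")
        if self.error_causes:
            lines.append("error causes: " + ", ".join(f"{k}={v}" for k, v in sorted(self.error_causes.items())))
        return "\n".join(lines)


def build_metrics_report(
    outcomes: Sequence[Any], error_labels: Optional[Mapping[str, str]] = None
) -> MetricsReport:
    """Assemble a :class:`MetricsReport` from per-annotation outcomes.

    ``outcomes`` expose ``annotation`` (with ``series_id``/``round_index``),
    ``verdicts`` (round-1 channel verdicts first) and ``final_status``.
    QCC is computed over annotations carrying two round-1 channel verdicts;
    APR/DPR over final statuses.  An empty run yields an empty report with
    zero rates rather than an error, so corpus-scale tooling can emit a
    report unconditionally.
    """
    if not outcomes:
        return MetricsReport(qcc=None, apr=0.0, dpr=0.0, n_annotations=0, n_datasets=0)
    pairs: list[tuple[QCVerdict, QCVerdict]] = []
    by_dataset: dict[str, list[str]] = defaultdict(list)
    by_round: dict[int, list[str]] = defaultdict(list)
    for o in outcomes:
        r1 = [v for v in o.verdicts if v.qc_round == 1]
        if len(r1) == 2:
            pairs.append((r1[0], r1[1]))
        by_dataset[o.annotation.series_id].append(o.final_status)
        by_round[o.annotation.round_index].append(o.final_status)
    qcc = compute_qcc(pairs) if pairs else None
    statuses = [o.final_status for o in outcomes]
    apr = sum(s == "Success" for s in statuses) / len(statuses)
    dpr = sum(any(s == "Success" for s in ss) for ss in by_dataset.values()) / len(by_dataset)
    per_round = {
        r: (len(ss), sum(s == "Success" for s in ss) / len(ss)) for r, ss in sorted(by_round.items())
    }
    failed = [o.annotation for o in outcomes if o.final_status == "Fail"]
    causes = error_cause_report(failed, error_labels) if error_labels is not None else {}
    return MetricsReport(
        qcc=qcc,
        apr=apr,
        dpr=dpr,
        n_annotations=len(outcomes),
        n_datasets=len(by_dataset),
        per_round=per_round,
        error_causes=causes,
    )
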