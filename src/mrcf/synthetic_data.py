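"""Synthetic series generator with gold annotations and planted errors.

Every other module is testable offline because this generator emits the
whole study material: GEO-like series metadata with coherent control /
perturbation designs, the gold-standard annotation for each design, a
bookkeeping label for every injected error, and expression matrices with
planted per-gene effects.

Injected error classes (drawn per series at the configured rates):

``confounder``
    a non-ignored characteristic (tissue) differs between the groups, so
    the alignment criterion must fail;
``multiple_disturbances``
    a second intervention varies alongside the primary one — alignment
    must fail;
``swap``
    the *emitted* annotation exchanges control and perturbation groups
    (the series and gold stay correct) — the direction check must fail;
``name_inconsistency``
    the emitted annotation carries a perturbation-name variant absent from
    the metadata — the name check must fail;
``age_difference``
    sample ages differ between groups.  This class is benign by design:
    sex and age are expressly ignored, so QC must still pass it.

Determinism: all randomness flows through one ``numpy`` generator seeded
from the spec; two calls with the same spec give identical corpora.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .metadata_model import AnnotationRecord, PertType, SampleRecord, SeriesRecord
from .signature_pipeline import ExpressionMatrix, Scale

__all__ = [
    "CorpusSpec",
    "GoldBundle",
    "generate_corpus",
    "generate_expression",
    "error_plan",
    "cause_labels",
    "BENIGN_CLASSES",
]

ERROR_CLASSES = ("confounder", "swap", "name_inconsistency", "age_difference", "multiple_disturbances")
#: classes that must NOT cause a QC failure
BENIGN_CLASSES = frozenset({"age_difference"})
#: classes realized by editing the emitted annotation rather than the series
ANNOTATOR_CLASSES = frozenset({"swap", "name_inconsistency"})

_DRUGS = (
    "imatinib", "aspirin", "dexamethasone", "metformin", "sorafenib",
    "erlotinib", "thalidomide", "hydrocortisone", "gefitinib", "rapamycin",
)
_GENES = ("kras overexpression", "tp53 knockdown", "myc overexpression", "brca1 knockdown")
_DISEASES = ("rheumatoid arthritis", "acute myeloid leukemia", "type 2 diabetes", "psoriasis")
_TISSUES = ("liver", "kidney", "lung", "blood", "skin")
_CELL_LINES = ("HepG2", "K562", "A549", "MCF7", "THP-1")
_SECOND_AGENTS = ("lipopolysaccharide", "tunicamycin", "rotenone")


@dataclass(frozen=True)
class CorpusSpec:
    """Study conditions for one synthetic corpus."""

    n_series: int = 50
    samples_per_group: tuple[int, int] = (2, 4)
    error_rates: Mapping[str, float] = field(default_factory=dict)
    multi_design_rate: float = 0.0
    pert_type_weights: tuple[float, float, float] = (0.7, 0.15, 0.15)  # drug, gene, disease
    seed: int = 0

    def validate(self) -> None:
        for cls, rate in self.error_rates.items():
            if cls not in ERROR_CLASSES:
                raise ValueError(f"unknown error class {cls!r}; allowed: {', '.join(ERROR_CLASSES)}")
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"error rate for {cls!r} must be in [0, 1]")
        total = sum(self.error_rates.values())
        if total > 1.0 + 1e-9:
            raise ValueError(f"error rates sum to {total:.3f} > 1")
        if self.multi_design_rate > 0 and total >= 1.0:
            raise ValueError("multi-design series require a non-zero clean fraction")
        if self.samples_per_group[0] < 2:
            raise ValueError("groups need at least 2 samples")


@dataclass
class GoldBundle:
    """One generated series with its gold annotations and bookkeeping."""

    series: SeriesRecord
    gold: list[AnnotationRecord]
    label: Optional[str]  # injected error class, or None when clean
    pert_key: str
    planted_effects: Optional[np.ndarray] = None


def error_plan(bundles: Sequence[GoldBundle]) -> dict[str, str]:
    """Annotator-level injections, keyed by series id (feeds the mock backend)."""
    return {b.series.series_id: b.label for b in bundles if b.label in ANNOTATOR_CLASSES}


def cause_labels(bundles: Sequence[GoldBundle], include_benign: bool = True) -> dict[str, str]:
    """series id -> injected cause class for every non-clean bundle."""
    return {
        b.series.series_id: b.label
        for b in bundles
        if b.label is not None and (include_benign or b.label not in BENIGN_CLASSES)
    }


def generate_corpus(spec: CorpusSpec) -> list[GoldBundle]:
    """Generate ``spec.n_series`` bundles, deterministic in ``spec.seed``."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    classes = list(ERROR_CLASSES)
    probs = np.array([spec.error_rates.get(c, 0.0) for c in classes] + [0.0])
    probs[-1] = 1.0 - probs.sum()  # clean mass
    bundles = []
    for i in range(spec.n_series):
        label_idx = rng.choice(len(classes) + 1, p=probs)
        label = classes[label_idx] if label_idx < len(classes) else None
        multi = label is None and rng.random() < spec.multi_design_rate
        bundles.append(_make_bundle(i, label, multi, spec, rng))
    return bundles


def _make_bundle(index: int, label: Optional[str], multi_design: bool, spec: CorpusSpec, rng: np.random.Generator) -> GoldBundle:
    series_id = f"GSE{10000 + index}"
    kind_idx = rng.choice(3, p=np.asarray(spec.pert_type_weights) / sum(spec.pert_type_weights))
    lo, hi = spec.samples_per_group
    n_ctrl = int(rng.integers(lo, hi + 1))
    n_pert = int(rng.integers(lo, hi + 1))

    if kind_idx == 0:
        pert_type = PertType.drug
        pert_key = "treatment"
        ctrl_value = "vehicle"
        base_name = str(rng.choice(_DRUGS))
    elif kind_idx == 1:
        pert_type = PertType.gene
        pert_key = "genotype"
        ctrl_value = "wild type"
        base_name = str(rng.choice(_GENES))
    else:
        pert_type = PertType.disease
        pert_key = "disease state"
        ctrl_value = "healthy"
        base_name = str(rng.choice(_DISEASES))

    tissue = str(rng.choice(_TISSUES))
    cell_line = str(rng.choice(_CELL_LINES))
    base_age = int(rng.integers(25, 70))

    if multi_design and pert_type == PertType.drug:
        arm_values = [f"{base_name} 10 mg", f"{base_name} 50 mg"]
    else:
        arm_values = [base_name]
        multi_design = False

    pert_tissue = tissue
    if label == "confounder":
        pert_tissue = str(rng.choice([t for t in _TISSUES if t != tissue]))

    samples: list[SampleRecord] = []
    sid = 0

    def _mk(value: str, group: str, group_tissue: str) -> SampleRecord:
        nonlocal sid
        sid += 1
        age = str(int(rng.integers(25, 70))) if label == "age_difference" else str(base_age)
        chars: dict[str, str] = {pert_key: value}
        if label == "multiple_disturbances" and group != "ctrl":
            chars["secondary treatment"] = str(rng.choice(_SECOND_AGENTS))
        elif label == "multiple_disturbances":
            chars["secondary treatment"] = "none"
        chars.update({"tissue": group_tissue, "cell line": cell_line, "age": age, "sex": "female"})
        return SampleRecord(
            sample_id=f"GSM{1000 * (index + 1) + sid}",
            title=f"{group_tissue}, {value}, rep{sid}",
            organism="Homo sapiens",
            source=f"{cell_line} cells, {group_tissue}",
            characteristics=chars,
            platform_id="GPL570",
        )

    ctrl_samples = [_mk(ctrl_value, "ctrl", tissue) for _ in range(n_ctrl)]
    arm_samples: list[list[SampleRecord]] = [
        [_mk(v, "pert", pert_tissue) for _ in range(n_pert)] for v in arm_values
    ]
    samples = ctrl_samples + [s for arm in arm_samples for s in arm]

    series = SeriesRecord(
        series_id=series_id,
        title=f"Expression profiling of {cell_line} cells after {base_name} perturbation",
        summary=(
            f"We profiled {tissue} {cell_line} cells to characterize the transcriptional "
            f"response to {base_name}."
        ),
        overall_design=(
            f"{n_ctrl} {ctrl_value} samples versus "
            + "; ".join(f"{len(arm)} samples with {v}" for v, arm in zip(arm_values, arm_samples))
        ),
        samples=tuple(samples),
    )

    ctrl_ids = frozenset(s.sample_id for s in ctrl_samples)
    gold = [
        AnnotationRecord(
            series_id=series_id,
            ctrl_ids=ctrl_ids,
            pert_ids=frozenset(s.sample_id for s in arm),
            pert_type=pert_type,
            pert_name=_strip_dose(value),
            cell_type=cell_line,
            annotator_tag="gold",
        )
        for value, arm in zip(arm_values, arm_samples)
    ]
    return GoldBundle(series=series, gold=gold, label=label, pert_key=pert_key)


def _strip_dose(value: str) -> str:
    import re

    return re.sub(r"\s+\d+(?:\.\d+)?\s*mg\s*$", "", value, flags=re.IGNORECASE).strip()


def generate_expression(
    bundle: GoldBundle,
    n_genes: int = 200,
    effect: Optional[np.ndarray] = None,
    effect_size: float = 1.0,
    noise_sd: float = 1.0,
    baseline: float = 7.0,
    scale: Scale = Scale.log_intensity,
    seed: int = 0,
    negate: bool = False,
) -> ExpressionMatrix:
    """Expression matrix for a bundle's first gold design with planted effects.

    Log-intensity matrices are Gaussian around ``baseline`` with the effect
    vector added to perturbation samples; count matrices draw
    negative-binomial counts around the corresponding linear-scale means.
    Passing a shared (or ``negate``-d) ``effect`` vector to two bundles
    plants a similar (or opposing) signature relationship between them.
    The realized effect vector is stored on ``bundle.planted_effects``.
    """
    if not bundle.gold:
        raise ValueError("bundle has no gold annotation")
    rng = np.random.default_rng(seed)
    ann = bundle.gold[0]
    ctrl = sorted(ann.ctrl_ids)
    pert = sorted(ann.pert_ids)
    genes = [f"gene_{g:04d}" for g in range(n_genes)]
    if effect is None:
        effect = rng.normal(0.0, effect_size, size=n_genes)
    effect = np.asarray(effect, dtype=float)
    if effect.shape != (n_genes,):
        raise ValueError(f"effect vector must have shape ({n_genes},)")
    if negate:
        effect = -effect
    bundle.planted_effects = effect

    log_means = np.tile(baseline, (n_genes, len(ctrl) + len(pert))).astype(float)
    log_means[:, len(ctrl):] += effect[:, None]
    noise = rng.normal(0.0, noise_sd, size=log_means.shape)
    if scale == Scale.log_intensity:
        values = log_means + noise
    else:
        mu = np.exp2(log_means + noise)
        dispersion = 10.0
        values = rng.negative_binomial(dispersion, dispersion / (dispersion + mu)).astype(float)
    df = pd.DataFrame(values, index=genes, columns=ctrl + pert)
    return ExpressionMatrix(values=df, scale=scale)
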