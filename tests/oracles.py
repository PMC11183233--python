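"""Independent oracles used to cross-check the implementation.

The QC oracle re-derives every verdict with naive loops, literally
restating each criterion definition, and shares no code with
``mrcf.quality_controller``.  The metric oracles are the one-line counting
definitions of QCC/APR/DPR.
"""

from __future__ import annotations

import numpy as np

from mrcf.metadata_model import AnnotationRecord, PertType, SampleRecord, SeriesRecord

_SEX = {"sex", "gender"}
_AGE = {"age", "age (years)", "age_yrs", "age_years", "age (yrs)"}
ABSENT = "<absent>"


def _norm_key(key: str) -> str:
    return " ".join(key.split()).lower()


def _norm_chars(sample: SampleRecord) -> dict[str, str]:
    out: dict[str, str] = {}
    for k, v in sample.characteristics.items():
        nk = _norm_key(k)
        if nk in out:
            i = 2
            while f"{nk}_{i}" in out:
                i += 1
            nk = f"{nk}_{i}"
        out[nk] = v.strip()
    return out


def _ignored(key: str) -> bool:
    return key in _SEX or key in _AGE


def naive_qc(annotation: AnnotationRecord, series: SeriesRecord, pert_key=None):
    """Brute-force verdict: (status, alignment, uniformity, perturbation)."""
    chars = {s.sample_id: _norm_chars(s) for s in series.samples}
    texts = {s.sample_id: (s.title, s.source, chars[s.sample_id]) for s in series.samples}
    known = set(chars)
    if any(i not in known for i in annotation.ctrl_ids | annotation.pert_ids):
        return ("Fail", False, False, False)
    ctrl = sorted(annotation.ctrl_ids)
    pert = sorted(annotation.pert_ids)
    rest = sorted(known - annotation.ctrl_ids - annotation.pert_ids)

    # -- perturbation-key designation, restated naively --
    if pert_key is None:
        keys_in_order: list[str] = []
        for sid in ctrl + pert:
            for k in chars[sid]:
                if k not in keys_in_order and not _ignored(k):
                    keys_in_order.append(k)
        needle = annotation.pert_name.lower()
        if needle:
            for k in keys_in_order:
                if needle in k:
                    pert_key = k
                    break
                hit = False
                for sid in pert:
                    if needle in chars[sid].get(k, "").lower():
                        hit = True
                if hit:
                    pert_key = k
                    break
        if pert_key is None:
            separating = []
            for k in keys_in_order:
                cv = set(chars[sid].get(k, ABSENT) for sid in ctrl)
                pv = set(chars[sid].get(k, ABSENT) for sid in pert)
                disjoint = True
                for v in cv:
                    if v in pv:
                        disjoint = False
                if disjoint:
                    separating.append(k)
            if len(separating) == 1:
                pert_key = separating[0]

    # -- criterion 1: every non-ignored, non-perturbation key balanced --
    align = True
    all_keys = set()
    for sid in ctrl + pert:
        all_keys |= set(chars[sid])
    for k in all_keys:
        if _ignored(k) or k == pert_key:
            continue
        cv = set(chars[sid].get(k, ABSENT) for sid in ctrl)
        pv = set(chars[sid].get(k, ABSENT) for sid in pert)
        if cv != pv:
            align = False

    # -- criterion 2: same-type samples consolidated --
    uniform = True
    profile_keys = set()
    for sid in ctrl + pert + rest:
        profile_keys |= set(chars[sid])
    profile_keys = sorted(k for k in profile_keys if not _ignored(k))

    def profile(sid):
        return tuple(chars[sid].get(k, ABSENT) for k in profile_keys)

    for u in rest:
        for a in ctrl + pert:
            if profile(u) == profile(a):
                uniform = False
    if pert_key is not None:
        for group in (ctrl, pert):
            vals = set(chars[sid].get(pert_key, ABSENT) for sid in group)
            if len(vals) > 1:
                uniform = False

    # -- criterion 3: perturbation correctly assigned and directed --
    perturb = isinstance(annotation.pert_type, PertType)
    needle = annotation.pert_name.lower()
    if not needle:
        perturb = False
    else:
        found = False
        for sid in pert:
            title, source, cs = texts[sid]
            parts = [title, source] + [f"{k}: {v}" for k, v in cs.items()]
            if any(needle in p.lower() for p in parts):
                found = True
        if not found:
            perturb = False
        if pert_key is not None:
            for sid in ctrl:
                if needle in chars[sid].get(pert_key, "").lower():
                    perturb = False
        else:
            ctrl_hits = 0
            for sid in ctrl:
                title, source, cs = texts[sid]
                parts = [title, source] + [f"{k}: {v}" for k, v in cs.items()]
                if any(needle in p.lower() for p in parts):
                    ctrl_hits += 1
            pert_hits = 0
            for sid in pert:
                title, source, cs = texts[sid]
                parts = [title, source] + [f"{k}: {v}" for k, v in cs.items()]
                if any(needle in p.lower() for p in parts):
                    pert_hits += 1
            if ctrl and ctrl_hits == len(ctrl) and pert_hits < len(pert):
                perturb = False

    status = "Success" if (align and uniform and perturb) else "Fail"
    return (status, align, uniform, perturb)


# ---------------------------------------------------------------------------
# one-line metric oracles
# ---------------------------------------------------------------------------

def naive_qcc(status_pairs):
    return sum(a == b for a, b in status_pairs) / len(status_pairs)


def naive_apr(statuses):
    return sum(s == "Success" for s in statuses) / len(statuses)


def naive_dpr(dataset_statuses):
    return sum("Success" in ss for ss in dataset_statuses.values()) / len(dataset_statuses)


# ---------------------------------------------------------------------------
# random QC cases for oracle-equivalence checks
# ---------------------------------------------------------------------------

_KEY_POOL = ["treatment", " Tissue ", "cell line", "Sex", "age", "strain", "dose"]
_VALUE_POOL = ["vehicle", "imatinib", "liver", "kidney", "HepG2", "male", "34", "b6", "10 mg", "aspirin"]
_NAME_POOL = ["imatinib", "aspirin", "vehicle", "liver", "zzz-novel", ""]


def random_qc_case(rng: np.random.Generator):
    """One random small series + annotation (+ optional pert-key override)."""
    n = int(rng.integers(2, 7))
    keys = list(rng.choice(_KEY_POOL, size=int(rng.integers(1, 5)), replace=False))
    samples = []
    for j in range(n):
        chars = {}
        for k in keys:
            if rng.random() < 0.9:  # occasionally missing keys
                chars[k] = str(rng.choice(_VALUE_POOL))
        samples.append(
            SampleRecord(
                sample_id=f"S{j}",
                title=f"sample {j} " + str(rng.choice(_VALUE_POOL)),
                source=str(rng.choice(_VALUE_POOL)),
                characteristics=chars,
            )
        )
    series = SeriesRecord(series_id="GSEX", samples=tuple(samples))
    ids = [s.sample_id for s in samples]
    perm = list(rng.permutation(ids))
    n_ctrl = int(rng.integers(1, n))
    n_pert = int(rng.integers(1, n - n_ctrl + 1))
    annotation = AnnotationRecord(
        series_id="GSEX",
        ctrl_ids=frozenset(perm[:n_ctrl]),
        pert_ids=frozenset(perm[n_ctrl : n_ctrl + n_pert]),
        pert_type=PertType(str(rng.choice(["drug", "disease", "gene"]))),
        pert_name=str(rng.choice([x for x in _NAME_POOL if x] + [""])),
        cell_type="HepG2",
    )
    override = None
    if rng.random() < 0.3:
        override = _norm_key(str(rng.choice(keys)))
    return series, annotation, override
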