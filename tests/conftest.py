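from __future__ import annotations

import pytest
from hypothesis import settings

from mrcf.llm_backend import MockBackend, Role
from mrcf.metadata_model import AnnotationRecord, PertType, SampleRecord, SeriesRecord
from mrcf.roles_workflow import default_annotator_template
from mrcf.synthetic_data import CorpusSpec, generate_corpus

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


def make_series(series_id="GSE1", groups=(("vehicle", 2), ("imatinib", 2)), extra=None, pert_key="treatment"):
    """Small handmade series: one sample group per (value, count) pair."""
    samples = []
    i = 0
    for value, count in groups:
        for _ in range(count):
            i += 1
            chars = {pert_key: value, "tissue": "liver", "cell line": "HepG2"}
            if extra:
                chars.update(extra(value, i))
            samples.append(
                SampleRecord(
                    sample_id=f"GSM{i}",
                    title=f"liver, {value}, rep{i}",
                    source="HepG2 cells",
                    characteristics=chars,
                )
            )
    return SeriesRecord(series_id=series_id, title="toy", samples=tuple(samples))


def make_annotation(series, ctrl_value="vehicle", pert_key="treatment", **kw):
    ctrl, pert = set(), set()
    for s in series.samples:
        (ctrl if s.characteristics.get(pert_key) == ctrl_value else pert).add(s.sample_id)
    defaults = dict(
        series_id=series.series_id,
        ctrl_ids=frozenset(ctrl),
        pert_ids=frozenset(pert),
        pert_type=PertType.drug,
        pert_name="imatinib",
        cell_type="HepG2",
    )
    defaults.update(kw)
    return AnnotationRecord(**defaults)


@pytest.fixture
def toy_series():
    return make_series()


@pytest.fixture
def toy_annotation(toy_series):
    return make_annotation(toy_series)


@pytest.fixture
def clean_bundles():
    return generate_corpus(CorpusSpec(n_series=20, seed=11))


@pytest.fixture
def optimal_template():
    return default_annotator_template(Role.optimal_annotator, version=1)


@pytest.fixture
def mock_backend():
    return MockBackend(seed=0)
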