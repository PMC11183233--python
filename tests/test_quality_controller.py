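import numpy as np
import pytest

from mrcf.llm_backend import MockBackend
from mrcf.metadata_model import SampleRecord, SeriesRecord
from mrcf.quality_controller import (
    Channel,
    ConsensusPendingError,
    Grade,
    ManualGrade,
    QCVerdict,
    consensus_qc,
    qc_criterion_alignment,
    qc_criterion_perturbation,
    qc_criterion_uniformity,
    run_llm_qc,
    run_rule_qc,
)
from mrcf.roles_workflow import default_qc_template
from tests.conftest import make_annotation, make_series
from tests.oracles import naive_qc, random_qc_case


class TestAlignment:
    def test_groups_identical_except_treatment(self, toy_series, toy_annotation):
        ok, reasons = qc_criterion_alignment(toy_annotation, toy_series, pert_key="treatment")
        assert ok and not reasons

    def test_age_only_difference_ignored(self):
        series = make_series(extra=lambda v, i: {"age": "34" if v == "vehicle" else "60"})
        ok, _ = qc_criterion_alignment(make_annotation(series), series, pert_key="treatment")
        assert ok

    def test_tissue_confounder_named_in_reason(self):
        series = make_series(extra=lambda v, i: {"tissue": "liver" if v == "vehicle" else "kidney"})
        ok, reasons = qc_criterion_alignment(make_annotation(series), series, pert_key="treatment")
        assert not ok
        assert any("tissue" in r for r in reasons)


class TestUniformity:
    def test_split_out_identical_sample_fails(self):
        # 3 identical vehicle samples; only 2 assigned as controls
        series = make_series(groups=(("vehicle", 3), ("imatinib", 2)))
        ann = make_annotation(series)
        short = ann.model_copy(update={"ctrl_ids": frozenset(sorted(ann.ctrl_ids)[:2])})
        ok, reasons = qc_criterion_uniformity(short, series, pert_key="treatment")
        assert not ok and any("unassigned" in r for r in reasons)

    def test_all_same_profile_samples_grouped(self, toy_series, toy_annotation):
        ok, _ = qc_criterion_uniformity(toy_annotation, toy_series, pert_key="treatment")
        assert ok

    def test_mixed_dose_group_fails(self):
        series = make_series(groups=(("vehicle", 2), ("imatinib 10 mg", 2), ("imatinib 50 mg", 2)))
        ann = make_annotation(series)  # merges both dose arms into pert_ids
        ok, reasons = qc_criterion_uniformity(ann, series, pert_key="treatment")
        assert not ok and any("mixes" in r for r in reasons)


class TestPerturbation:
    def test_clean_drug_assignment(self, toy_series, toy_annotation):
        ok, _ = qc_criterion_perturbation(toy_annotation, toy_series, pert_key="treatment")
        assert ok

    def test_swapped_groups_fail_direction(self, toy_series, toy_annotation):
        swapped = toy_annotation.model_copy(
            update={"ctrl_ids": toy_annotation.pert_ids, "pert_ids": toy_annotation.ctrl_ids}
        )
        ok, reasons = qc_criterion_perturbation(swapped, toy_series, pert_key="treatment")
        assert not ok and any("direction" in r for r in reasons)

    def test_empty_pert_name_fails(self, toy_series, toy_annotation):
        # bypass record validation to probe the criterion directly
        ann = toy_annotation.model_copy(update={"pert_name": ""})
        ok, reasons = qc_criterion_perturbation(ann, toy_series, pert_key="treatment")
        assert not ok and "empty pert_name" in reasons

    def test_name_absent_from_metadata_fails(self, toy_series, toy_annotation):
        ann = toy_annotation.model_copy(update={"pert_name": "imatinib hydrochloride"})
        ok, reasons = qc_criterion_perturbation(ann, toy_series, pert_key="treatment")
        assert not ok and any("not found" in r for r in reasons)

    def test_synonym_table_rescues_name(self, toy_series, toy_annotation):
        ann = toy_annotation.model_copy(update={"pert_name": "STI-571"})
        ok, _ = qc_criterion_perturbation(
            ann, toy_series, pert_key="treatment", synonyms={"STI-571": ["imatinib"]}
        )
        assert ok


class TestRuleQC:
    def test_clean_annotation_success(self, toy_series, toy_annotation):
        v = run_rule_qc(toy_annotation, toy_series)
        assert v.status == "Success"
        assert (v.criterion_alignment, v.criterion_uniformity, v.criterion_perturbation) == (True, True, True)

    def test_unknown_sample_hard_fail(self, toy_series, toy_annotation):
        bad = toy_annotation.model_copy(update={"pert_ids": toy_annotation.pert_ids | {"GSM999"}})
        v = run_rule_qc(bad, toy_series)
        assert v.status == "Fail"
        assert any("unknown sample" in r for r in v.reasons)

    def test_idempotent_and_deterministic(self, toy_series, toy_annotation):
        assert run_rule_qc(toy_annotation, toy_series) == run_rule_qc(toy_annotation, toy_series)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(4)
        for _ in range(25):
            series, ann, override = random_qc_case(rng)
            v1 = run_rule_qc(ann, series, pert_key=override)
            order = rng.permutation(len(series.samples))
            shuffled_samples = []
            for i in order:
                s = series.samples[i]
                items = list(s.characteristics.items())
                perm = rng.permutation(len(items))
                shuffled_samples.append(
                    SampleRecord(
                        sample_id=s.sample_id,
                        title=s.title,
                        source=s.source,
                        characteristics=dict(items[j] for j in perm),
                    )
                )
            shuffled = SeriesRecord(series_id=series.series_id, samples=tuple(shuffled_samples))
            v2 = run_rule_qc(ann, shuffled, pert_key=override)
            assert (v1.status, v1.criterion_alignment, v1.criterion_uniformity, v1.criterion_perturbation) == (
                v2.status, v2.criterion_alignment, v2.criterion_uniformity, v2.criterion_perturbation,
            )

    def test_agrees_with_bruteforce_oracle_smoke(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            series, ann, override = random_qc_case(rng)
            v = run_rule_qc(ann, series, pert_key=override)
            assert naive_qc(ann, series, pert_key=override) == (
                v.status, v.criterion_alignment, v.criterion_uniformity, v.criterion_perturbation,
            )


class TestLlmChannel:
    def test_rate_zero_identical_to_rule(self, clean_bundles, optimal_template):
        from mrcf.roles_workflow import annotate_series

        backend = MockBackend(seed=1, qc_disagreement_rate=0.0)
        tpl = default_qc_template()
        for b in clean_bundles:
            anns, _ = annotate_series(b.series, optimal_template, backend)
            for a in anns:
                rule = run_rule_qc(a, b.series, pert_key=b.pert_key)
                llm = run_llm_qc(a, b.series, tpl, backend, pert_key=b.pert_key)
                assert llm.status == rule.status

    def test_rate_one_flips_every_status(self, clean_bundles, optimal_template):
        from mrcf.roles_workflow import annotate_series

        backend = MockBackend(seed=1, qc_disagreement_rate=1.0)
        tpl = default_qc_template()
        for b in clean_bundles:
            anns, _ = annotate_series(b.series, optimal_template, backend)
            for a in anns:
                rule = run_rule_qc(a, b.series, pert_key=b.pert_key)
                llm = run_llm_qc(a, b.series, tpl, backend, pert_key=b.pert_key)
                assert llm.status != rule.status

    def test_unparseable_after_retry_is_fail(self, toy_series, toy_annotation):
        class GarbageBackend(MockBackend):
            def _transport(self, template, payload):
                return "not json at all", 0

        v = run_llm_qc(toy_annotation, toy_series, default_qc_template(), GarbageBackend())
        assert v.status == "Fail" and "unparseable" in v.reasons


def _verdict(status, ref="GSE1:a|b", round_=1):
    ok = status == "Success"
    return QCVerdict(
        series_id="GSE1",
        annotation_ref=ref,
        channel=Channel.rule,
        status=status,
        criterion_alignment=ok,
        criterion_uniformity=ok,
        criterion_perturbation=ok,
        qc_round=round_,
    )


class TestConsensus:
    def test_two_agreeing(self):
        assert consensus_qc([_verdict("Success"), _verdict("Success")]).status == "Success"

    def test_majority_of_three(self):
        got = consensus_qc([_verdict("Success"), _verdict("Fail"), _verdict("Fail")])
        assert got.status == "Fail"

    def test_two_disagreeing_demand_third_round(self):
        with pytest.raises(ConsensusPendingError):
            consensus_qc([_verdict("Success"), _verdict("Fail")])

    def test_fewer_than_two_is_error(self):
        with pytest.raises(ValueError):
            consensus_qc([_verdict("Success")])


class TestVerdictModel:
    def test_status_must_match_criteria(self):
        with pytest.raises(ValueError):
            QCVerdict(
                series_id="g", annotation_ref="r", channel=Channel.rule, status="Success",
                criterion_alignment=True, criterion_uniformity=False, criterion_perturbation=True,
            )

    def test_manual_channel_needs_grade(self):
        with pytest.raises(ValueError):
            QCVerdict(series_id="g", annotation_ref="r", channel=Channel.manual, status="Fail")
        v = QCVerdict(
            series_id="g", annotation_ref="r", channel=Channel.manual, status="Fail",
            manual_grade=ManualGrade(grade=Grade.Error, cause="multiple_disturbances"),
        )
        assert v.manual_grade.grade == Grade.Error

    def test_cause_only_on_error_grade(self):
        with pytest.raises(ValueError):
            ManualGrade(grade=Grade.Moderate, cause="other")
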