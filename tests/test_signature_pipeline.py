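import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from mrcf.metadata_model import AnnotationRecord, PertType
from mrcf.signature_pipeline import (
    ConnectivityResult,
    Direction,
    ExpressionMatrix,
    Scale,
    Signature,
    compute_signature,
    connectivity,
    rank_repurposing,
)
from mrcf.synthetic_data import CorpusSpec, GoldBundle, generate_corpus, generate_expression


def annotation(ctrl, pert):
    return AnnotationRecord(
        series_id="GSE1", ctrl_ids=frozenset(ctrl), pert_ids=frozenset(pert),
        pert_type=PertType.drug, pert_name="imatinib",
    )


def toy_matrix(values, genes=None, samples=None, scale=Scale.log_intensity):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{i}" for i in range(values.shape[1])]
    return ExpressionMatrix(values=pd.DataFrame(values, index=genes, columns=samples), scale=scale)


def random_signature(rng, n=1000, label="sig"):
    return Signature(label=label, stats=pd.Series(rng.normal(size=n), index=[f"g{i}" for i in range(n)]), n_ctrl=3, n_pert=3)


class TestExpressionMatrix:
    def test_duplicate_gene_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate gene"):
            toy_matrix(np.ones((2, 2)), genes=["g", "g"])

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="counts"):
            toy_matrix([[-1, 2], [3, 4]], scale=Scale.counts)

    def test_tsv_and_mtx_round_trip(self, tmp_path):
        m = toy_matrix(np.arange(12.0).reshape(3, 4))
        m.to_tsv(tmp_path / "m.tsv")
        again = ExpressionMatrix.from_tsv(tmp_path / "m.tsv")
        pd.testing.assert_frame_equal(m.values, again.values)
        m.to_mtx(tmp_path / "m")
        again2 = ExpressionMatrix.from_mtx(tmp_path / "m")
        np.testing.assert_allclose(m.values.to_numpy(), again2.values.to_numpy())


class TestComputeSignature:
    def test_zero_variance_gene_dropped(self):
        vals = np.array([[1.0, 1.0, 1.0, 1.0], [1, 2, 3, 4]])
        sig = compute_signature(toy_matrix(vals), annotation(["s0", "s1"], ["s2", "s3"]))
        assert list(sig.stats.index) == ["g1"]

    def test_welch_t_matches_manual_formula(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(7, 1, size=(6, 5))
        ann = annotation(["s0", "s1"], ["s2", "s3", "s4"])
        sig = compute_signature(toy_matrix(vals), ann)
        c, p = vals[:, :2], vals[:, 2:]
        t_manual = (p.mean(1) - c.mean(1)) / np.sqrt(p.var(1, ddof=1) / 3 + c.var(1, ddof=1) / 2)
        np.testing.assert_allclose(sig.stats.to_numpy(), t_manual, rtol=1e-12)

    def test_counts_are_cpm_log_transformed(self):
        rng = np.random.default_rng(6)
        counts = rng.integers(0, 500, size=(8, 6)).astype(float)
        ann = annotation(["s0", "s1", "s2"], ["s3", "s4", "s5"])
        sig = compute_signature(toy_matrix(counts, scale=Scale.counts), ann)
        log = np.log2(counts / counts.sum(0) * 1e6 + 1)
        expected = sps.ttest_ind(log[:, 3:], log[:, :3], axis=1, equal_var=False).statistic
        np.testing.assert_allclose(sig.stats.to_numpy(), expected, rtol=1e-10)

    def test_planted_upregulated_gene_positive(self):
        rng = np.random.default_rng(7)
        vals = rng.normal(7, 0.1, size=(10, 6))
        vals[0, 3:] += 1.0  # 2-fold on log2 scale
        sig = compute_signature(toy_matrix(vals), annotation(["s0", "s1", "s2"], ["s3", "s4", "s5"]))
        assert sig.stats["g0"] > 0

    def test_swapping_labels_negates_statistics(self):
        rng = np.random.default_rng(8)
        vals = rng.normal(size=(5, 6))
        a = compute_signature(toy_matrix(vals), annotation(["s0", "s1", "s2"], ["s3", "s4", "s5"]))
        b = compute_signature(toy_matrix(vals), annotation(["s3", "s4", "s5"], ["s0", "s1", "s2"]))
        np.testing.assert_allclose(a.stats.to_numpy(), -b.stats.to_numpy(), rtol=1e-12)

    def test_insufficient_replicates_error(self):
        vals = np.ones((3, 3))
        with pytest.raises(ValueError, match="insufficient replicates"):
            compute_signature(toy_matrix(vals), annotation(["s0"], ["s1", "s2"]))


class TestConnectivity:
    def test_identity_is_exactly_one(self):
        s = random_signature(np.random.default_rng(0))
        r = connectivity(s, s, n_perm=100)
        assert r.correlation == 1.0 and r.direction == Direction.similar

    def test_negation_is_exactly_minus_one(self):
        s = random_signature(np.random.default_rng(1))
        neg = Signature(label="neg", stats=-s.stats, n_ctrl=3, n_pert=3)
        r = connectivity(s, neg, n_perm=100)
        assert r.correlation == -1.0 and r.direction == Direction.opposing

    def test_matches_scipy_spearman(self):
        rng = np.random.default_rng(2)
        a, b = random_signature(rng, 300, "a"), random_signature(rng, 300, "b")
        r = connectivity(a, b, n_top=300, n_perm=50)
        expected = sps.spearmanr(a.stats.to_numpy(), b.stats.to_numpy()).statistic
        assert r.correlation == pytest.approx(expected, abs=1e-12)

    def test_too_few_shared_genes(self):
        rng = np.random.default_rng(3)
        a = random_signature(rng, 20, "a")
        b = Signature(label="b", stats=pd.Series(rng.normal(size=5), index=[f"g{i}" for i in range(5)]), n_ctrl=2, n_pert=2)
        with pytest.raises(ValueError, match="shared genes"):
            connectivity(a, b)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(4)
        a, b = random_signature(rng, 400, "a"), random_signature(rng, 400, "b")
        scaled = Signature(label="b2", stats=b.stats * 2.5, n_ctrl=3, n_pert=3)
        r1 = connectivity(a, b, n_perm=50, seed=9)
        r2 = connectivity(a, scaled, n_perm=50, seed=9)
        assert r1.correlation == pytest.approx(r2.correlation, abs=1e-12)
        assert r1.p_value == r2.p_value

    def test_independent_signatures_weak_correlation(self):
        rng = np.random.default_rng(5)
        a, b = random_signature(rng, 1000, "a"), random_signature(rng, 1000, "b")
        r = connectivity(a, b, n_perm=500, seed=0)
        assert abs(r.correlation) < 0.2


class TestRankRepurposing:
    def test_query_in_library_ranks_first(self):
        rng = np.random.default_rng(6)
        q = random_signature(rng, 500, "query")
        library = [random_signature(rng, 500, f"lib{i}") for i in range(3)] + [q]
        results = rank_repurposing(q, library, n_perm=200)
        assert results[0].target == "query" and results[0].correlation == 1.0

    def test_planted_anticorrelated_signature_found(self):
        rng = np.random.default_rng(7)
        q = random_signature(rng, 500, "query")
        anti = Signature(label="anti", stats=-q.stats + rng.normal(0, 0.2, 500), n_ctrl=3, n_pert=3)
        library = [random_signature(rng, 500, f"lib{i}") for i in range(4)] + [anti]
        results = rank_repurposing(q, library, n_perm=500)
        negatives = [r for r in results if r.correlation < 0]
        most_negative = min(results, key=lambda r: r.correlation)
        assert most_negative.target == "anti"
        assert most_negative.q_value == min(r.q_value for r in negatives)

    def test_empty_overlap_member_skipped_with_warning(self):
        rng = np.random.default_rng(8)
        q = random_signature(rng, 200, "query")
        stranger = Signature(
            label="stranger", stats=pd.Series(rng.normal(size=50), index=[f"x{i}" for i in range(50)]),
            n_ctrl=2, n_pert=2,
        )
        with pytest.warns(UserWarning, match="stranger"):
            results = rank_repurposing(q, [q, stranger], n_perm=50)
        assert [r.target for r in results] == ["query"]

    def test_bh_q_values_monotone_in_p_rank(self):
        rng = np.random.default_rng(9)
        q = random_signature(rng, 400, "query")
        library = [random_signature(rng, 400, f"lib{i}") for i in range(8)]
        results = rank_repurposing(q, library, n_perm=200)
        by_p = sorted(results, key=lambda r: r.p_value)
        qs = [r.q_value for r in by_p]
        assert all(a <= b + 1e-12 for a, b in zip(qs, qs[1:]))


class TestGeneratedExpression:
    def test_zero_effect_statistics_centered_at_zero(self):
        (bundle,) = generate_corpus(CorpusSpec(n_series=1, samples_per_group=(4, 4), seed=3))
        m = generate_expression(bundle, n_genes=400, effect=np.zeros(400), seed=0)
        sig = compute_signature(m, bundle.gold[0])
        assert abs(sig.stats.mean()) < 0.15

    def test_shared_and_negated_effects_plant_connectivity_sign(self):
        bundles = generate_corpus(CorpusSpec(n_series=3, samples_per_group=(3, 4), seed=4))
        rng = np.random.default_rng(0)
        effect = rng.normal(0, 1, 200)
        sigs = []
        for b, neg in zip(bundles, (False, False, True)):
            m = generate_expression(b, n_genes=200, effect=effect, negate=neg, noise_sd=1.0, seed=11)
            sigs.append(compute_signature(m, b.gold[0]))
        similar = connectivity(sigs[0], sigs[1], n_top=200, n_perm=100)
        opposing = connectivity(sigs[0], sigs[2], n_top=200, n_perm=100)
        assert similar.correlation > 0 and similar.direction == Direction.similar
        assert opposing.correlation < 0 and opposing.direction == Direction.opposing
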